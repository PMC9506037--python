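"""Pure-fluid and binary parameter registry, plus molecular-weight correlations.

The registry ships the CPA parameter sets for CO2, low-molecular-weight
alcohols, glycerol, the four oligoethylene glycols, lauric acid, five fatty
acid methyl esters, five triglycerides and the polyethylene-glycol (PEG)
family.  Each pure fluid carries the five CPA parameters (a0, b, c1, and for
self-associating fluids the association energy eps and volume beta), the
critical temperature used by the Soave alpha function, and an association
scheme label:

``none``
    inert fluid (the CPA reduces to SRK); such a fluid may still acquire a
    single positive *solvation* site when a binary declares cross-association
    parameters for it (mCR1 or explicit rule), which is how CO2 is treated
    in mixtures with glycerol and alcohols.
``1A``
    one bipolar site (carboxylic acids; the site pairs with itself).
``2B``
    one proton donor + one acceptor (alcohols).
``4C``
    two donors + two acceptors (glycols, PEGs).
``3x2B``
    three donors + three acceptors (glycerol, one 2B pair per hydroxyl).

The PEG family is generated from ordinary-least-squares correlations of the
glycol parameters against molecular weight: the co-volume ``b`` is linear in
mw, and the attractive-energy parameter ``a0`` is available from both a
linear and a quadratic law.  The association parameters are held constant
across the family (eps = 143.37 bar.L/mol, beta = 0.0188, 4C).  The
correlations are refitted from the four glycol entries at import time, so the
tabulated PEG rows in the registry double as a regression check rather than
being the source of the correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PureComponent",
    "BinaryInteraction",
    "CorrelationModel",
    "UnknownComponentError",
    "UnknownBinaryError",
    "get_component",
    "get_binary",
    "get_binary_variants",
    "list_components",
    "register_component",
    "fit_mw_correlation",
    "predict_peg_component",
    "peg_correlations",
    "GLYCOL_NAMES",
    "PEG_MW_DOMAIN",
]

_SCHEMES = ("none", "1A", "2B", "4C", "3x2B")
_CROSS_RULES = ("none", "CR1", "mCR1", "explicit")

#: The four oligoethylene glycols whose parameters anchor the PEG correlations.
GLYCOL_NAMES = (
    "ethylene_glycol",
    "diethylene_glycol",
    "triethylene_glycol",
    "tetraethylene_glycol",
)

#: Molecular-weight interval (g/mol) on which the PEG correlations are valid.
PEG_MW_DOMAIN = (62.0, 650.0)

_PEG_EPS = 143.37
_PEG_BETA = 0.0188


class UnknownComponentError(KeyError):
    """Raised when a component name is absent from the parameter registry."""


class UnknownBinaryError(KeyError):
    """Raised when a pair has no entry in the binary-parameter registry."""


@dataclass(frozen=True)
class PureComponent:
    """CPA parameter set for one pure fluid.

    Parameters
    ----------
    name : str
        Registry identifier.
    mw : float
        Molar mass, g/mol.
    tc : float
        Critical temperature, K (argument of the Soave alpha function).
    a0 : float
        Attractive-energy parameter, L^2.bar/mol^2.
    b : float
        Co-volume, L/mol.
    c1 : float
        Soave slope, dimensionless.
    eps_assoc, beta_assoc : float
        Self-association energy (bar.L/mol) and volume (dimensionless);
        both zero for non-self-associating fluids.
    scheme : str
        Association scheme, one of ``none, 1A, 2B, 4C, 3x2B``.
    """

    name: str
    mw: float
    tc: float
    a0: float
    b: float
    c1: float
    eps_assoc: float = 0.0
    beta_assoc: float = 0.0
    scheme: str = "none"
    a0_poly: float | None = None

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"{self.name}: co-volume b must be positive")
        if self.a0 < 0 or self.tc <= 0:
            raise ValueError(f"{self.name}: a0 must be >= 0 and tc > 0")
        if self.eps_assoc < 0 or self.beta_assoc < 0:
            raise ValueError(f"{self.name}: association parameters must be >= 0")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"{self.name}: unknown association scheme {self.scheme!r}")
        if self.scheme == "none" and (self.eps_assoc != 0 or self.beta_assoc != 0):
            raise ValueError(f"{self.name}: inert fluid must have zero association parameters")
        if self.scheme != "none" and self.beta_assoc <= 0:
            raise ValueError(f"{self.name}: scheme {self.scheme} requires beta_assoc > 0")

    @property
    def self_associating(self) -> bool:
        return self.scheme != "none" and self.eps_assoc > 0


@dataclass(frozen=True)
class BinaryInteraction:
    """Binary parameters for one pair: kij and the cross-association rule.

    ``cross_rule`` selects how cross-association parameters are obtained:
    ``none`` (no cross association), ``CR1`` (arithmetic-mean energy,
    geometric-mean volume, both partners self-associating), ``mCR1``
    (arithmetic-mean energy with a non-self-associating partner contributing
    zero; volume adjustable, stored in ``beta_cross``), or ``explicit``
    (both ``eps_cross`` and ``beta_cross`` stored).
    """

    pair: tuple[str, str]
    kij: float
    cross_rule: str = "none"
    eps_cross: float | None = None
    beta_cross: float | None = None
    variant: str | None = None
    temp_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cross_rule not in _CROSS_RULES:
            raise ValueError(f"unknown cross rule {self.cross_rule!r}")
        if self.cross_rule == "explicit" and (self.eps_cross is None or self.beta_cross is None):
            raise ValueError("explicit rule requires eps_cross and beta_cross")
        if self.cross_rule == "mCR1" and self.beta_cross is None:
            raise ValueError("mCR1 rule requires beta_cross")


@dataclass(frozen=True)
class CorrelationModel:
    """A fitted parameter-versus-molecular-weight law (linear or quadratic).

    ``coefficients`` are in the monomial basis, intercept first, so
    ``value(mw) = c0 + c1*mw (+ c2*mw**2)``.
    """

    parameter_name: str
    form: str
    coefficients: tuple[float, ...]
    domain: tuple[float, float] = PEG_MW_DOMAIN

    def __post_init__(self) -> None:
        n = {"linear": 2, "quadratic": 3}.get(self.form)
        if n is None:
            raise ValueError(f"unknown form {self.form!r}")
        if len(self.coefficients) != n:
            raise ValueError(f"{self.form} form requires exactly {n} coefficients")

    def __call__(self, mw: float) -> float:
        return float(np.polyval(self.coefficients[::-1], mw))


def _canonical(name: str) -> str:
    return name.strip().lower().replace(" ", "_").replace("-", "_")


def _pair_key(name_i: str, name_j: str) -> tuple[str, str]:
    a, b = sorted((_canonical(name_i), _canonical(name_j)))
    return a, b


class _Registry:
    """In-memory view of the bundled parameter file plus user additions."""

    def __init__(self) -> None:
        self._components: dict[str, PureComponent] = {}
        self._aliases: dict[str, str] = {}
        self._binaries: dict[tuple[str, str], dict[str, BinaryInteraction]] = {}
        self._default_variant: dict[tuple[str, str], str] = {}
        self._load_bundled()

    def _load_bundled(self) -> None:
        text = resources.files("cpaeos.data").joinpath("parameters.json").read_text()
        raw = json.loads(text)
        for rec in raw["components"]:
            synonyms = rec.pop("synonyms", [])
            comp = PureComponent(**rec)
            self.add_component(comp, synonyms)
        for rec in raw["binaries"]:
            rec = dict(rec)
            pair = tuple(rec.pop("pair"))
            default = rec.pop("default_variant", False)
            tr = rec.pop("temp_range", None)
            inter = BinaryInteraction(
                pair=_pair_key(*pair),
                temp_range=tuple(tr) if tr else None,
                **rec,
            )
            self.add_binary(inter, default=default)

    def add_component(self, comp: PureComponent, synonyms: Iterable[str] = ()) -> None:
        key = _canonical(comp.name)
        self._components[key] = comp
        self._aliases[key] = key
        for syn in synonyms:
            self._aliases[_canonical(syn)] = key

    def add_binary(self, inter: BinaryInteraction, default: bool = False) -> None:
        key = inter.pair
        variants = self._binaries.setdefault(key, {})
        label = inter.variant or "default"
        variants[label] = inter
        if default or len(variants) == 1:
            self._default_variant[key] = label

    def component(self, name: str) -> PureComponent:
        key = self._aliases.get(_canonical(name))
        if key is None:
            known = ", ".join(sorted(self._components))
            raise UnknownComponentError(
                f"component {name!r} is not in the cpaeos parameter registry "
                f"(known: {known})"
            )
        return self._components[key]

    def binary(self, name_i: str, name_j: str, variant: str | None = None) -> BinaryInteraction:
        # resolve aliases through the component table when possible
        def resolve(n: str) -> str:
            return self._aliases.get(_canonical(n), _canonical(n))

        key = tuple(sorted((resolve(name_i), resolve(name_j))))
        variants = self._binaries.get(key)
        if not variants:
            raise UnknownBinaryError(
                f"pair {name_i!r}-{name_j!r} has no entry in the cpaeos binary registry"
            )
        label = variant or self._default_variant[key]
        if label not in variants:
            raise UnknownBinaryError(
                f"pair {name_i!r}-{name_j!r} has no variant {label!r} "
                f"(available: {sorted(variants)})"
            )
        return variants[label]

    def binary_variants(self, name_i: str, name_j: str) -> dict[str, BinaryInteraction]:
        def resolve(n: str) -> str:
            return self._aliases.get(_canonical(n), _canonical(n))

        key = tuple(sorted((resolve(name_i), resolve(name_j))))
        variants = self._binaries.get(key)
        if not variants:
            raise UnknownBinaryError(
                f"pair {name_i!r}-{name_j!r} has no entry in the cpaeos binary registry"
            )
        return dict(variants)

    def names(self) -> list[str]:
        return sorted(self._components)


_REGISTRY = _Registry()


def get_component(name: str) -> PureComponent:
    """Return the registered parameter set for ``name`` (case-insensitive)."""
    return _REGISTRY.component(name)


def get_binary(name_i: str, name_j: str, variant: str | None = None) -> BinaryInteraction:
    """Return the binary parameters for a pair (order-insensitive).

    Pairs shipping several parameterizations (CO2-glycerol: ``inert`` with
    kij only, ``one_site`` with kij + beta_cross under mCR1) honour
    ``variant``; the default is the variant used for multicomponent
    predictions (``one_site`` for CO2-glycerol).
    """
    return _REGISTRY.binary(name_i, name_j, variant)


def get_binary_variants(name_i: str, name_j: str) -> dict[str, BinaryInteraction]:
    """All registered parameterizations for a pair, keyed by variant label."""
    return _REGISTRY.binary_variants(name_i, name_j)


def list_components() -> list[str]:
    """Sorted canonical names of all registered components."""
    return _REGISTRY.names()


def register_component(comp: PureComponent, synonyms: Iterable[str] = ()) -> None:
    """Add a user-supplied component to the in-memory registry."""
    _REGISTRY.add_component(comp, synonyms)


def fit_mw_correlation(
    points: Sequence[tuple[float, float]],
    form: str = "linear",
    parameter_name: str = "value",
) -> CorrelationModel:
    """Ordinary least squares of a parameter against molecular weight.

    Parameters
    ----------
    points : sequence of (mw, value)
        Molecular weights (g/mol) and parameter values.
    form : {"linear", "quadratic"}
        Monomial basis order.

    Returns
    -------
    CorrelationModel
        Fitted law; its domain spans the input molecular weights.
    """
    order = {"linear": 1, "quadratic": 2}.get(form)
    if order is None:
        raise ValueError(f"unknown form {form!r}")
    mw = np.asarray([p[0] for p in points], dtype=float)
    val = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(mw)) < order + 1:
        raise ValueError(
            f"{form} fit needs at least {order + 1} distinct molecular weights, "
            f"got {len(np.unique(mw))}"
        )
    # Vandermonde least squares; rcond=None silences legacy behaviour
    A = np.vander(mw, order + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(A, val, rcond=None)
    if rank < order + 1:
        raise ValueError("collinear molecular weights: underdetermined fit")
    return CorrelationModel(
        parameter_name=parameter_name,
        form=form,
        coefficients=tuple(float(c) for c in coef),
        domain=(float(mw.min()), float(mw.max())),
    )


@lru_cache(maxsize=1)
def peg_correlations() -> dict[str, CorrelationModel]:
    """Correlations of b and a0 vs molecular weight, refitted from the glycols.

    Returns a dict with keys ``b`` (linear), ``a0_linear`` and
    ``a0_quadratic``, each valid on ``PEG_MW_DOMAIN``.
    """
    glycols = [get_component(n) for n in GLYCOL_NAMES]
    pts_b = [(g.mw, g.b) for g in glycols]
    pts_a = [(g.mw, g.a0) for g in glycols]
    models = {
        "b": fit_mw_correlation(pts_b, "linear", "b"),
        "a0_linear": fit_mw_correlation(pts_a, "linear", "a0"),
        "a0_quadratic": fit_mw_correlation(pts_a, "quadratic", "a0"),
    }
    return {
        k: replace(m, domain=PEG_MW_DOMAIN) for k, m in models.items()
    }


# c1 and tc have no recoverable functional form; the tabulated PEG values are
# authoritative and intermediate molecular weights are piecewise-linearly
# interpolated (clamped at the table edges).
_PEG_TABLE_MW = (150.0, 200.0, 300.0, 400.0, 600.0)


def _peg_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tcs = np.array([get_component(f"PEG{int(m)}").tc for m in _PEG_TABLE_MW])
    c1s = np.array([get_component(f"PEG{int(m)}").c1 for m in _PEG_TABLE_MW])
    return np.array(_PEG_TABLE_MW), tcs, c1s


def predict_peg_component(mw: float, a0_form: str = "linear") -> PureComponent:
    """Predict the CPA parameter set of a polyethylene glycol of mass ``mw``.

    ``b`` and ``a0`` come from the glycol correlations (``a0_form`` selects
    the linear or quadratic a0 law); the association parameters are the
    family constants.  At the five tabulated molecular weights (150, 200,
    300, 400, 600 g/mol), c1 and tc are the tabulated values; elsewhere they
    are interpolated piecewise-linearly.
    """
    lo, hi = PEG_MW_DOMAIN
    if not lo <= mw <= hi:
        raise ValueError(
            f"mw = {mw} g/mol outside the PEG correlation domain [{lo}, {hi}]"
        )
    if a0_form not in ("linear", "quadratic"):
        raise ValueError(f"a0_form must be 'linear' or 'quadratic', got {a0_form!r}")
    corr = peg_correlations()
    b = corr["b"](mw)
    a0 = corr[f"a0_{a0_form}"](mw)
    mws, tcs, c1s = _peg_table()
    tc = float(np.interp(mw, mws, tcs))
    c1 = float(np.interp(mw, mws, c1s))
    return PureComponent(
        name=f"PEG{mw:g}",
        mw=mw,
        tc=tc,
        a0=a0,
        b=b,
        c1=c1,
        eps_assoc=_PEG_EPS,
        beta_assoc=_PEG_BETA,
        scheme="4C",
    )
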