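"""CPA equation of state: physical SRK part plus Wertheim association term.

The pressure-explicit form is

    P = RT/(Vm - b) - a(T)/(Vm(Vm + b))
        - (1/2)(RT/Vm)(1 + rho dln g/drho) sum_i x_i sum_Ai (1 - X_Ai)

with the simplified radial distribution function g = 1/(1 - 1.9 eta),
eta = b rho / 4, a Soave temperature dependence a(T) = a0 [1 + c1 (1 -
sqrt(T/Tc))]^2, van der Waals one-fluid mixing rules (single binary
correction kij on the geometric-mean cross energy), and site fractions X_Ai
solved from the mass-action equations

    X_Ai = 1 / (1 + rho sum_j x_j sum_Bj X_Bj Delta^{AiBj}),
    Delta^{AiBj} = g [exp(eps/(R T)) - 1] b_ij beta.

Association sites are grouped into classes with a multiplicity (2B = one
donor + one acceptor; 4C = 2 + 2; 3x2B = 3 + 3; 1A = one bipolar site that
pairs with itself).  A non-self-associating fluid whose binary declares
cross-association parameters (mCR1 or explicit rule) carries one positive
solvation site active only toward such partners; this is how CO2 is treated
in mixtures with glycerol and alcohols, while it stays fully inert toward
PEGs and glycerides.

The residual Helmholtz energy (reduced, per mole)

    a_res = -ln(1 - b rho) - a/(b R T) ln(1 + b rho)
            + sum_i x_i sum_Ai (ln X_Ai - X_Ai/2 + 1/2)

is the generating function for fugacity coefficients; its analytic volume
and composition derivatives reproduce the pressure equation and are
cross-checked numerically in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import R
from .parameters import BinaryInteraction, PureComponent, get_binary, get_component

__all__ = [
    "Mixture",
    "EosEvaluation",
    "VolumeRootError",
    "SiteConvergenceError",
    "soave_a",
    "mix_ab",
    "radial_distribution",
    "cross_association_parameters",
    "association_strength",
    "solve_site_fractions",
    "closed_form_site_fraction",
    "pressure",
    "reduced_residual_helmholtz",
    "fugacity_coefficients",
    "solve_volume",
]

_SITE_TOL = 1e-12
_SITE_MAX_ITER = 2000
_SITE_DAMPING = 0.5


class VolumeRootError(RuntimeError):
    """No molar volume satisfies P(T, Vm) = P (mechanically unstable request)."""


class SiteConvergenceError(RuntimeError):
    """The site-fraction solver failed to reach its residual tolerance."""


def soave_a(comp: PureComponent, T: float) -> float:
    """Soave attractive-energy parameter a(T) = a0 [1 + c1 (1 - sqrt(T/Tc))]^2.

    The same expression is used below and above the critical temperature
    (supercritical extrapolation, e.g. CO2 above 304.2 K).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return comp.a0 * (1.0 + comp.c1 * (1.0 - math.sqrt(T / comp.tc))) ** 2


def radial_distribution(eta: float) -> tuple[float, float]:
    """Return (g, rho dln g/drho) for the simplified hard-sphere g(eta).

    g = 1/(1 - 1.9 eta); the density-derivative term entering the
    association pressure is rho dln g/drho = 1.9 eta / (1 - 1.9 eta).
    """
    eta = float(eta)
    if not 0.0 <= eta < 1.0 / 1.9:
        raise ValueError(f"reduced density eta = {eta} outside [0, 1/1.9)")
    denom = 1.0 - 1.9 * eta
    return 1.0 / denom, 1.9 * eta / denom


def cross_association_parameters(
    inter: BinaryInteraction, comp_i: PureComponent, comp_j: PureComponent
) -> tuple[float, float]:
    """Resolve (eps_cross, beta_cross) for a pair according to its rule.

    CR-1: arithmetic-mean energy and geometric-mean volume, both partners
    self-associating.  mCR-1: arithmetic-mean energy (a non-self-associating
    partner contributes zero) with the stored, adjustable volume.  explicit:
    both values stored.
    """
    rule = inter.cross_rule
    if rule == "none":
        raise ValueError("pair declares no cross association")
    if rule == "CR1":
        if not (comp_i.self_associating and comp_j.self_associating):
            raise ValueError(
                "CR1 requires two self-associating components "
                f"({comp_i.name}, {comp_j.name})"
            )
        eps = 0.5 * (comp_i.eps_assoc + comp_j.eps_assoc)
        beta = math.sqrt(comp_i.beta_assoc * comp_j.beta_assoc)
        return eps, beta
    if rule == "mCR1":
        eps = 0.5 * (comp_i.eps_assoc + comp_j.eps_assoc)
        return eps, float(inter.beta_cross)
    # explicit
    return float(inter.eps_cross), float(inter.beta_cross)


def association_strength(
    eps: float, beta: float, T: float, g: float, b_ij: float
) -> float:
    """Delta = g [exp(eps/(R T)) - 1] b_ij beta, in L/mol."""
    if beta == 0.0:
        return 0.0
    return g * math.expm1(eps / (R * T)) * b_ij * beta


def closed_form_site_fraction(scheme: str, rho_delta: float) -> float:
    """Analytic site fraction for a pure fluid with a symmetric scheme.

    For n equivalent donor/acceptor pairs (n = 1 for 1A and 2B, 2 for 4C,
    3 for 3x2B) the mass action law collapses to a quadratic with root
    X = (-1 + sqrt(1 + 4 n rho Delta)) / (2 n rho Delta), continuously
    extended to X = 1 at rho Delta = 0.  Serves as the independent oracle
    for the iterative solver.
    """
    n = {"1A": 1, "2B": 1, "4C": 2, "3x2B": 3}.get(scheme)
    if n is None:
        raise ValueError(f"no closed form for scheme {scheme!r}")
    c = n * rho_delta
    # 2/(1 + sqrt(1 + 4c)) is algebraically identical to
    # (-1 + sqrt(1 + 4c))/(2c) but stays fully accurate as c -> 0
    return 2.0 / (1.0 + math.sqrt(1.0 + 4.0 * c))


# ---------------------------------------------------------------------------
# Mixture assembly


_SCHEME_SITES: dict[str, tuple[tuple[int, float], ...]] = {
    # (polarity, multiplicity); polarity 0 = bipolar (acid site)
    "none": (),
    "1A": ((0, 1.0),),
    "2B": ((+1, 1.0), (-1, 1.0)),
    "4C": ((+1, 2.0), (-1, 2.0)),
    "3x2B": ((+1, 3.0), (-1, 3.0)),
}


@dataclass
class EosEvaluation:
    """Diagnostic bundle for one state point."""

    T: float
    Vm: float
    x: np.ndarray
    a_mix: float
    b_mix: float
    g: float
    rho_dlng_drho: float
    delta: np.ndarray
    X: np.ndarray
    P: float
    ares: float
    Z: float
    lnphi: np.ndarray

    def as_dict(self) -> dict:
        d = {
            "T_K": self.T,
            "Vm_L_per_mol": self.Vm,
            "x": list(map(float, self.x)),
            "a_mix": self.a_mix,
            "b_mix": self.b_mix,
            "g": self.g,
            "rho_dlng_drho": self.rho_dlng_drho,
            "site_fractions": list(map(float, self.X)),
            "P_bar": self.P,
            "ares": self.ares,
            "Z": self.Z,
            "lnphi": list(map(float, self.lnphi)),
        }
        return d


class Mixture:
    """A mixture assembled from pure components and binary interactions.

    Parameters
    ----------
    components : sequence of PureComponent or str
        Strings are looked up in the bundled registry.
    interactions : iterable of BinaryInteraction, optional
        Pairs not listed default to kij = 0 with no cross association
        (use :func:`cpaeos.parameters.get_binary` or explicit objects to
        supply fitted values; the prediction CLI refuses silent defaults).
    """

    def __init__(
        self,
        components: Sequence[PureComponent | str],
        interactions: Iterable[BinaryInteraction] = (),
    ) -> None:
        self.components: list[PureComponent] = [
            get_component(c) if isinstance(c, str) else c for c in components
        ]
        nc = len(self.components)
        if nc == 0:
            raise ValueError("mixture needs at least one component")
        self.nc = nc
        self._name_index = {c.name.lower(): i for i, c in enumerate(self.components)}

        self.kij = np.zeros((nc, nc))
        self._inter: dict[tuple[int, int], BinaryInteraction] = {}
        for inter in interactions:
            i = self._index_of(inter.pair[0])
            j = self._index_of(inter.pair[1])
            if i == j:
                raise ValueError(f"self-pair in interactions: {inter.pair}")
            self.kij[i, j] = self.kij[j, i] = inter.kij
            self._inter[(min(i, j), max(i, j))] = inter

        self.b = np.array([c.b for c in self.components])
        self.bij = 0.5 * (self.b[:, None] + self.b[None, :])
        self._build_sites()

    def _index_of(self, name: str) -> int:
        key = name.lower()
        if key in self._name_index:
            return self._name_index[key]
        # fall back through registry canonicalization (synonyms)
        canonical = get_component(name).name.lower()
        if canonical in self._name_index:
            return self._name_index[canonical]
        raise KeyError(f"component {name!r} not in this mixture")

    def interaction(self, i: int, j: int) -> BinaryInteraction | None:
        return self._inter.get((min(i, j), max(i, j)))

    # -- site catalog -------------------------------------------------------

    def _build_sites(self) -> None:
        comps = self.components
        site_comp: list[int] = []
        site_pol: list[int] = []
        site_mult: list[float] = []
        for i, c in enumerate(comps):
            for pol, mult in _SCHEME_SITES[c.scheme]:
                site_comp.append(i)
                site_pol.append(pol)
                site_mult.append(mult)
        # solvation site: inert fluid in a pair declaring cross parameters
        for i, c in enumerate(comps):
            if c.self_associating:
                continue
            declares = any(
                inter.cross_rule in ("mCR1", "explicit")
                for (a, b), inter in self._inter.items()
                if i in (a, b)
            )
            if declares:
                site_comp.append(i)
                site_pol.append(+1)
                site_mult.append(1.0)
        self.site_comp = np.array(site_comp, dtype=int)
        self.site_pol = np.array(site_pol, dtype=int)
        self.site_mult = np.array(site_mult)
        ns = len(site_comp)
        self.ns = ns

        eps = np.zeros((ns, ns))
        beta = np.zeros((ns, ns))
        active = np.zeros((ns, ns), dtype=bool)
        for s in range(ns):
            for t in range(s, ns):
                i, j = self.site_comp[s], self.site_comp[t]
                ps, pt = self.site_pol[s], self.site_pol[t]
                if not (ps == 0 or pt == 0 or ps * pt == -1):
                    continue
                if i == j:
                    ci = comps[i]
                    if not ci.self_associating:
                        continue  # a lone solvation site never self-associates
                    e, bta = ci.eps_assoc, ci.beta_assoc
                else:
                    inter = self.interaction(int(i), int(j))
                    if inter is None or inter.cross_rule == "none":
                        continue
                    e, bta = cross_association_parameters(inter, comps[i], comps[j])
                if bta <= 0:
                    continue
                eps[s, t] = eps[t, s] = e
                beta[s, t] = beta[t, s] = bta
                active[s, t] = active[t, s] = True
        self.site_eps = eps
        self.site_beta = beta
        self.site_active = active
        # kappa = b_ij * beta per site pair (temperature independent)
        bij_sites = self.bij[np.ix_(self.site_comp, self.site_comp)] if ns else np.zeros((0, 0))
        self.site_kappa = bij_sites * beta
        self.has_association = bool(ns and active.any())

    # -- per-(T, x) context -------------------------------------------------

    def context(self, T: float, x: Sequence[float]) -> "StateContext":
        return StateContext(self, T, np.asarray(x, dtype=float))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        names = ", ".join(c.name for c in self.components)
        return f"Mixture({names})"


class StateContext:
    """Precomputed temperature- and composition-dependent quantities."""

    __slots__ = (
        "mix", "T", "x", "ai", "aij", "a", "bm", "w", "D", "has_assoc",
    )

    def __init__(self, mix: Mixture, T: float, x: np.ndarray) -> None:
        if x.shape != (mix.nc,):
            raise ValueError(f"composition must have length {mix.nc}")
        if np.any(x < -1e-12) or abs(float(x.sum()) - 1.0) > 1e-8:
            raise ValueError("mole fractions must be nonnegative and sum to 1")
        self.mix = mix
        self.T = float(T)
        self.x = np.clip(x, 0.0, None)
        ai = np.array([soave_a(c, T) for c in mix.components])
        self.ai = ai
        self.aij = np.sqrt(np.outer(ai, ai)) * (1.0 - mix.kij)
        self.a = float(self.x @ self.aij @ self.x)
        self.bm = float(self.x @ mix.b)
        if mix.ns:
            self.w = self.x[mix.site_comp] * mix.site_mult
            # temperature part of Delta, without g:  (exp(eps/RT)-1) * b_ij * beta
            self.D = np.expm1(mix.site_eps / (R * T)) * mix.site_kappa
            self.has_assoc = bool(np.any(self.w > 0) and mix.has_association)
        else:
            self.w = np.zeros(0)
            self.D = np.zeros((0, 0))
            self.has_assoc = False


# ---------------------------------------------------------------------------
# Site fractions


def _solve_sites_scalar(
    ctx: StateContext, rho: float, g: float, X0: np.ndarray | None = None
) -> np.ndarray:
    """Site fractions at one state: bounded Newton, damped-SS fallback.

    The site systems arising here are tiny (a handful of site classes), so
    a clamped Newton iteration on the mass-action defect is both the
    fastest and the most robust route; the damped successive-substitution
    loop backs it up from a few fresh starting points.
    """
    ns = len(ctx.w)
    X = np.full(ns, 0.5) if X0 is None else np.clip(X0, 1e-12, 1.0)
    Xn = _newton_sites(ctx, rho, g, X)
    if Xn is not None:
        return Xn
    # fallback: damped successive substitution
    D = ctx.D * g
    w = ctx.w
    X = np.full(ns, 0.5)
    omega = _SITE_DAMPING
    for it in range(_SITE_MAX_ITER):
        s = rho * (D @ (w * X))
        X_new = 1.0 / (1.0 + s)
        if np.max(np.abs(X_new - X)) < _SITE_TOL:
            return X_new
        X = omega * X_new + (1.0 - omega) * X
    Xn = _newton_sites(ctx, rho, g, X)
    if Xn is not None:
        return Xn
    raise SiteConvergenceError(
        f"site fractions did not converge (residual {np.max(np.abs(X_new - X)):.2e})"
    )


def _newton_sites(
    ctx: StateContext, rho: float, g: float, X0: np.ndarray
) -> np.ndarray | None:
    D = ctx.D * g
    w = ctx.w
    ns = len(w)
    X = X0.copy()
    I = np.eye(ns)
    for _ in range(100):
        s = rho * (D @ (w * X))
        F = X * (1.0 + s) - 1.0
        if np.max(np.abs(F / (1.0 + s))) < _SITE_TOL:
            return 1.0 / (1.0 + s)
        J = np.diag(1.0 + s) + rho * X[:, None] * D * w[None, :]
        try:
            dX = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        X = np.clip(X + dX, 1e-14, 1.0)
    return None


def _solve_sites_grid(
    ctx: StateContext, rho: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """Vectorized damped successive substitution over a density grid."""
    m = len(rho)
    ns = len(ctx.w)
    X = np.full((m, ns), 0.5)
    wD = ctx.D * ctx.w[None, :]  # (ns, ns), sum over t of wD[s,t] X[t]
    omega = _SITE_DAMPING
    coef = rho[:, None] * g[:, None]
    for _ in range(_SITE_MAX_ITER):
        s = coef * (X @ wD.T)
        X_new = 1.0 / (1.0 + s)
        if np.max(np.abs(X_new - X)) < _SITE_TOL:
            return X_new
        X = omega * X_new + (1.0 - omega) * X
    # fall back per point
    for k in range(m):
        X[k] = _solve_sites_scalar(ctx, float(rho[k]), float(g[k]), X[k])
    return X


def solve_site_fractions(
    mix: Mixture,
    T: float,
    rho: float,
    x: Sequence[float],
    X0: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the mass-action equations for the free-site fractions.

    Returns one value per site class, ordered as ``mix.site_comp``;
    multiplicities are folded into the sums.  X = 1 for sites with no
    active partners.
    """
    if rho <= 0:
        raise ValueError("density must be positive")
    ctx = mix.context(T, x)
    if not ctx.has_assoc:
        return np.ones(mix.ns)
    eta = ctx.bm * rho / 4.0
    g, _ = radial_distribution(eta)
    return _solve_sites_scalar(ctx, rho, g, X0)


# ---------------------------------------------------------------------------
# Pressure, Helmholtz energy, fugacity coefficients


def _pressure_ctx(
    ctx: StateContext, Vm: float, X0: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    if Vm <= ctx.bm:
        raise ValueError(f"Vm = {Vm} must exceed b_mix = {ctx.bm}")
    T = ctx.T
    rho = 1.0 / Vm
    P = R * T / (Vm - ctx.bm) - ctx.a / (Vm * (Vm + ctx.bm))
    if not ctx.has_assoc:
        return P, np.ones(len(ctx.w))
    eta = ctx.bm * rho / 4.0
    g, dlng = radial_distribution(eta)
    X = _solve_sites_scalar(ctx, rho, g, X0)
    h = float(ctx.w @ (1.0 - X))
    P -= 0.5 * (R * T / Vm) * (1.0 + dlng) * h
    return P, X


def pressure(mix: Mixture, T: float, Vm: float, x: Sequence[float]) -> float:
    """CPA pressure (bar) at molar volume Vm (L/mol)."""
    P, _ = _pressure_ctx(mix.context(T, x), Vm)
    return P


def _ares_ctx(
    ctx: StateContext, Vm: float, X0: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    T = ctx.T
    rho = 1.0 / Vm
    brho = ctx.bm * rho
    ares = -math.log1p(-brho) - ctx.a / (ctx.bm * R * T) * math.log1p(brho)
    if not ctx.has_assoc:
        return ares, np.ones(len(ctx.w))
    eta = brho / 4.0
    g, _ = radial_distribution(eta)
    X = _solve_sites_scalar(ctx, rho, g, X0)
    ares += float(ctx.w @ (np.log(X) - X / 2.0 + 0.5))
    return ares, X


def reduced_residual_helmholtz(
    mix: Mixture, T: float, Vm: float, x: Sequence[float]
) -> float:
    """Reduced residual Helmholtz energy a_res = A_res/(nRT) at (T, Vm, x)."""
    ctx = mix.context(T, x)
    if Vm <= ctx.bm:
        raise ValueError(f"Vm = {Vm} must exceed b_mix = {ctx.bm}")
    ares, _ = _ares_ctx(ctx, Vm)
    return ares


def _lnphi_ctx(
    ctx: StateContext,
    Vm: float,
    X0: np.ndarray | None = None,
    P_at: float | None = None,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Analytic ln(phi) at a given volume root.

    Returns (lnphi, P, Z, X).  The association contribution uses the
    stationarity of the site-fraction equations: the explicit composition
    derivative is taken at fixed X, plus the radial-distribution term
    -(h/2)(dln g/dn_i) that survives because g depends on composition
    through the packing fraction.  ``P_at`` substitutes the target pressure
    for the recomputed one in Z (identical to root-finder precision; avoids
    sign noise at extremely low saturation pressures).
    """
    mix = ctx.mix
    T = ctx.T
    rho = 1.0 / Vm
    bm, a = ctx.bm, ctx.a
    brho = bm * rho
    bi = mix.b
    Di = 2.0 * (ctx.aij @ ctx.x)  # d(n^2 a_mix)/dn_i at n = 1

    ln1p = math.log1p(brho)
    dF = (
        -math.log1p(-brho)
        + bi / (Vm - bm)
        - (1.0 / (R * T))
        * ((Di / bm - a * bi / bm**2) * ln1p + a * bi / (bm * (Vm + bm)))
    )

    P = R * T / (Vm - bm) - a / (Vm * (Vm + bm))
    X = np.ones(len(ctx.w))
    if ctx.has_assoc:
        eta = brho / 4.0
        g, dlng = radial_distribution(eta)
        X = _solve_sites_scalar(ctx, rho, g, X0)
        h = float(ctx.w @ (1.0 - X))
        P -= 0.5 * (R * T / Vm) * (1.0 + dlng) * h
        lnX = np.log(X)
        site_term = np.zeros(mix.nc)
        np.add.at(site_term, mix.site_comp, mix.site_mult * lnX)
        dF = dF + site_term - 0.5 * h * (1.9 / (1.0 - 1.9 * eta)) * bi / (4.0 * Vm)
    if P_at is not None:
        P = P_at
    Z = P * Vm / (R * T)
    lnphi = dF - math.log(Z)
    return lnphi, P, Z, X


# ---------------------------------------------------------------------------
# Volume roots


def _volume_roots_ctx(
    ctx: StateContext, P: float, n_grid: int = 40
) -> list[tuple[float, np.ndarray]]:
    """All mechanically stable volume roots (dP/dV < 0) via a log-spaced scan."""
    T, bm = ctx.T, ctx.bm
    v_lo = bm * (1.0 + 1e-5)
    v_hi = max(20.0 * R * T / P, 10.0 * bm)
    # dense in the liquid region (catches the narrow dip near the liquid
    # spinodal), coarse out to the vapor branch
    dense = np.geomspace(v_lo, 8.0 * bm, max(n_grid // 2, 22))
    coarse = np.geomspace(8.0 * bm, v_hi, max(n_grid // 2, 18))[1:]
    grid = np.concatenate([dense, coarse]) if v_hi > 8.0 * bm else dense
    rho = 1.0 / grid
    Pg = R * T / (grid - bm) - ctx.a / (grid * (grid + bm))
    if ctx.has_assoc:
        eta = bm * rho / 4.0
        g = 1.0 / (1.0 - 1.9 * eta)
        dlng = 1.9 * eta / (1.0 - 1.9 * eta)
        Xg = _solve_sites_grid(ctx, rho, g)
        h = (1.0 - Xg) @ ctx.w
        Pg = Pg - 0.5 * (R * T * rho) * (1.0 + dlng) * h
    f = Pg - P
    while f[-1] > 0:  # extend toward ideal gas until pressure falls below target
        v_hi *= 10.0
        extra = np.geomspace(grid[-1] * 1.5, v_hi, 10)
        grid = np.concatenate([grid, extra])
        Pe = np.array([_pressure_ctx(ctx, v)[0] for v in extra])
        f = np.concatenate([f, Pe - P])

    roots: list[tuple[float, np.ndarray]] = []
    warm: np.ndarray | None = None
    for k in range(len(f) - 1):
        if f[k] > 0 >= f[k + 1]:  # stable branch crossing (P decreasing)
            root, X = _refine_root(ctx, P, grid[k], grid[k + 1], warm)
            roots.append((root, X))
            warm = X
    if not roots:
        raise VolumeRootError(f"no volume root at T = {T} K, P = {P} bar")
    return roots


def _refine_root(
    ctx: StateContext,
    P: float,
    v_a: float,
    v_b: float,
    X0: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    """Brent-style bracketed refinement of P(V) = P on [v_a, v_b]."""
    from scipy.optimize import brentq

    state = {"X": X0}

    def fun(V: float) -> float:
        Pv, X = _pressure_ctx(ctx, V, state["X"])
        state["X"] = X
        return Pv - P

    root = brentq(fun, v_a, v_b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    # Newton polish: push |P(V) - P| to the relative floor (brentq's absolute
    # xtol on V leaves ~1e-9 relative pressure error on steep liquid branches)
    for _ in range(3):
        f0, X0 = _pressure_ctx(ctx, root, state["X"])
        state["X"] = X0
        err = f0 - P
        if abs(err) <= 1e-13 * max(abs(P), 1e-300):
            break
        dv = root * 1e-7
        f1, _ = _pressure_ctx(ctx, root + dv, X0)
        slope = (f1 - f0) / dv
        if slope == 0:
            break
        step = err / slope
        if abs(step) > 0.1 * root:
            break
        new_root = root - step
        if new_root <= ctx.bm:
            break
        root = new_root
    _, X = _pressure_ctx(ctx, root, state["X"])
    return float(root), X


def _gibbs_reduced(ctx: StateContext, Vm: float, P: float) -> float:
    """G/(nRT) up to a composition-only constant, for root selection."""
    ares, _ = _ares_ctx(ctx, Vm)
    Z = P * Vm / (R * ctx.T)
    return ares + Z - 1.0 - math.log(Z)


def _solve_volume_ctx(
    ctx: StateContext,
    P: float,
    phase_hint: str | None = None,
    V0: float | None = None,
    X0: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Volume root for the hinted phase, with an optional warm start.

    A warm start tries a narrow bracket around the previous root before
    falling back to the full scan; the hinted root is the smallest
    (liquid) or largest (vapor) stable root.
    """
    if V0 is not None and V0 > ctx.bm:
        lo, hi = V0 / 1.35, V0 * 1.35
        lo = max(lo, ctx.bm * (1.0 + 1e-7))
        try:
            f_lo, X_lo = _pressure_ctx(ctx, lo, X0)
            f_hi, _ = _pressure_ctx(ctx, hi, X_lo)
            if (f_lo - P) > 0 >= (f_hi - P):
                return _refine_root(ctx, P, lo, hi, X_lo)
        except (ValueError, SiteConvergenceError):
            pass
    roots = _volume_roots_ctx(ctx, P)
    if phase_hint == "liquid":
        return roots[0]
    if phase_hint == "vapor":
        return roots[-1]
    if len(roots) == 1:
        return roots[0]
    # lowest Gibbs energy; ties resolve to the vapor-like root
    gvals = [_gibbs_reduced(ctx, r, P) for r, _ in roots]
    k = int(np.argmin(gvals))
    if abs(gvals[k] - gvals[-1]) < 1e-12:
        k = len(roots) - 1
    return roots[k]


def solve_volume(
    mix: Mixture,
    T: float,
    P: float,
    x: Sequence[float],
    phase_hint: str | None = None,
) -> float:
    """Molar volume root of P(T, Vm) = P.

    With ``phase_hint`` 'liquid'/'vapor' the smallest/largest mechanically
    stable root is returned; without a hint, the root of lowest Gibbs
    energy (ties resolving to the vapor-like root).
    """
    if T <= 0 or P <= 0:
        raise ValueError("T and P must be positive")
    ctx = mix.context(T, x)
    V, _ = _solve_volume_ctx(ctx, P, phase_hint)
    return V


def volume_roots(mix: Mixture, T: float, P: float, x: Sequence[float]) -> list[float]:
    """All mechanically stable volume roots at (T, P, x)."""
    ctx = mix.context(T, x)
    return [r for r, _ in _volume_roots_ctx(ctx, P)]


def fugacity_coefficients(
    mix: Mixture,
    T: float,
    P: float,
    x: Sequence[float],
    phase_hint: str | None = None,
) -> np.ndarray:
    """Log fugacity coefficients ln(phi_i) at (T, P, x) for the hinted phase."""
    ctx = mix.context(T, x)
    V, X = _solve_volume_ctx(ctx, P, phase_hint)
    lnphi, _, _, _ = _lnphi_ctx(ctx, V, X)
    return lnphi


def evaluate(
    mix: Mixture,
    T: float,
    P: float,
    x: Sequence[float],
    phase_hint: str | None = None,
) -> EosEvaluation:
    """Full diagnostic evaluation (volume root, site fractions, lnphi, ...)."""
    ctx = mix.context(T, x)
    V, Xw = _solve_volume_ctx(ctx, P, phase_hint)
    lnphi, Pc, Z, X = _lnphi_ctx(ctx, V, Xw)
    ares, _ = _ares_ctx(ctx, V, X)
    rho = 1.0 / V
    eta = ctx.bm * rho / 4.0
    g, dlng = radial_distribution(eta)
    delta = ctx.D * g if ctx.has_assoc else np.zeros((0, 0))
    return EosEvaluation(
        T=T, Vm=V, x=ctx.x, a_mix=ctx.a, b_mix=ctx.bm, g=g,
        rho_dlng_drho=dlng, delta=delta, X=X, P=Pc, ares=ares, Z=Z, lnphi=lnphi,
    )


def mix_ab(
    mix: Mixture, x: Sequence[float], T: float
) -> tuple[float, float, np.ndarray]:
    """Van der Waals one-fluid mixing rules.

    Returns (a_mix, b_mix, b_ij) with a_mix = sum_ij x_i x_j sqrt(a_i a_j)
    (1 - kij), b_mix = sum_i x_i b_i and b_ij = (b_i + b_j)/2.
    """
    ctx = mix.context(T, x)
    return ctx.a, ctx.bm, mix.bij.copy()
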