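"""Synthetic pseudo-experimental VLE data generation.

The experimental datasets these tools emulate are isothermal binary
T-P-x-y tables for CO2 + glycol / glycerol / triglyceride systems
(303-393 K, up to ~350 bar), fixed-composition ternary bubble-point
curves, and a CO2 + five-ester "biodiesel" system.  Data are generated
from the CPA model itself and perturbed with multiplicative noise, so
zero-noise datasets are exactly model-consistent — the identifiability
property every recovery test in the package rests on.

Noise is multiplicative (relative), matching the relative-deviation
metrics used throughout: value * exp(sigma * z), z ~ N(0, 1).  The
``heavy_tailed`` scatter mode uses a wide log-normal on the heavy
component's vapor fraction (sigma on the log scale up to ln 10),
emulating literature vapor-phase solubilities of heavy glycerides that
disagree between sources by up to two orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import VleDataset
from .eos import Mixture
from .equilibrium import (
    ConvergenceError,
    bubble_pressure,
    pure_saturation,
    trace_isotherm,
)
from .parameters import BinaryInteraction, get_binary, get_component

__all__ = [
    "NoiseSpec",
    "gen_pure_saturation",
    "gen_binary_vle",
    "gen_multicomponent_bubble",
    "make_biodiesel_mixture",
    "biodiesel_feed",
    "BIODIESEL_ESTERS",
    "DEFAULT_BIODIESEL_FRACTIONS",
    "CO2_GLYCEROL_METHANOL_FEEDS",
    "CO2_GLYCEROL_ETHANOL_FEEDS",
    "CO2_METHANOL_LAURIC_ACID_FEEDS",
    "ternary_fixture",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Relative noise magnitudes for pseudo-experimental data.

    Parameters
    ----------
    sigma_P : float
        Relative standard deviation on pressure (default 1%).
    sigma_y : float
        Relative standard deviation on the heavy component's vapor mole
        fraction (default 10%); in ``heavy_tailed`` mode this is the
        standard deviation of ln(y) instead (default ln(10)/2).
    sigma_v : float
        Relative standard deviation on liquid molar volumes (saturation
        data only).
    scatter_mode : {"normal", "heavy_tailed"}
        Heavy-tailed mode applies the wide log-normal to vapor fractions.
    seed : int
        Seed of the generator; identical seeds give identical bytes.
    """

    sigma_P: float = 0.01
    sigma_y: float = 0.10
    sigma_v: float = 0.005
    scatter_mode: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_P, self.sigma_y, self.sigma_v) < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if self.scatter_mode not in ("normal", "heavy_tailed"):
            raise ValueError(f"unknown scatter mode {self.scatter_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(rng: np.random.Generator, sigma: float, size=None):
    if sigma == 0:
        return np.ones(size) if size else 1.0
    return np.exp(sigma * rng.standard_normal(size))


def gen_pure_saturation(
    comp,
    t_range: tuple[float, float],
    n: int = 20,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Saturation-curve dataset (T, psat, vliq) with multiplicative noise.

    Temperatures are evenly spaced on ``t_range``, which must be
    subcritical for the component.
    """
    comp = get_component(comp) if isinstance(comp, str) else comp
    T_lo, T_hi = t_range
    rng = noise.rng()
    rows = []
    for T in np.linspace(T_lo, T_hi, n):
        psat, vl, _ = pure_saturation(comp, float(T))  # raises if supercritical
        rows.append((float(T), psat, vl))
    frame = pd.DataFrame(rows, columns=["T", "psat", "vliq"])
    frame["psat"] *= _lognormal_factor(rng, noise.sigma_P, len(frame))
    frame["vliq"] *= _lognormal_factor(rng, noise.sigma_v, len(frame))
    return frame


def gen_binary_vle(
    mix: Mixture,
    temps: Sequence[float],
    x1_grid: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    mode: str = "both",
) -> VleDataset:
    """Isothermal binary T-P-x-y records from bubble-point sweeps.

    ``mode`` mimics the measurement patterns of the literature datasets:
    ``both`` (full T-P-x-y), ``liquid_only`` (x measured, y absent, the
    tributyrin-like pattern) and ``vapor_only`` (y measured, x absent, the
    trimyristin-like pattern).  Component 1 is the volatile solute (CO2).
    Unconverged sweep points are dropped and noted in the metadata.
    """
    if mix.nc != 2:
        raise ValueError("gen_binary_vle expects a binary mixture")
    if mode not in ("both", "liquid_only", "vapor_only"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = noise.rng()
    rows = []
    dropped = 0
    for T in temps:
        for res in trace_isotherm(mix, float(T), x1_grid):
            if not res.converged:
                dropped += 1
                continue
            P = res.P * float(_lognormal_factor(rng, noise.sigma_P))
            y2 = float(res.y[1])
            sig = noise.sigma_y
            if noise.scatter_mode == "heavy_tailed":
                y2 *= float(_lognormal_factor(rng, max(sig, 1e-12)))
            else:
                y2 *= float(_lognormal_factor(rng, sig))
            y2 = min(y2, 0.999999)
            rows.append(
                {
                    "T": float(T), "P": P,
                    "x_1": float(res.x[0]), "x_2": float(res.x[1]),
                    "y_1": 1.0 - y2, "y_2": y2,
                    "weight": 1.0,
                }
            )
    frame = pd.DataFrame(rows)
    if mode == "liquid_only":
        frame[["y_1", "y_2"]] = np.nan
    elif mode == "vapor_only":
        frame[["x_1", "x_2"]] = np.nan
    meta = {
        "source": "cpaeos synthetic generator",
        "noise": f"sigma_P={noise.sigma_P}, sigma_y={noise.sigma_y}, "
                 f"mode={noise.scatter_mode}, seed={noise.seed}",
        "mode": mode,
        "dropped_points": str(dropped),
    }
    names = tuple(c.name for c in mix.components)
    return VleDataset(components=names, frame=frame, meta=meta)


def gen_multicomponent_bubble(
    mix: Mixture,
    feeds: Sequence[Sequence[float]],
    t_grid: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Fixed-composition bubble-point curves P(T) with pressure noise.

    Returns a frame with columns ``feed`` (index into ``feeds``), ``T``,
    ``P`` and ``converged``; unconverged points carry NaN pressure.
    """
    rng = noise.rng()
    rows = []
    for kf, z in enumerate(feeds):
        z = np.asarray(z, dtype=float)
        P0 = K0 = None
        for T in t_grid:
            try:
                res = bubble_pressure(mix, float(T), z, P0=P0, K0=K0)
                ok = res.converged
            except ConvergenceError:
                ok = False
            if ok:
                P0, K0 = res.P, res.K
                P = res.P * float(_lognormal_factor(rng, noise.sigma_P))
            else:
                P = math.nan
            rows.append({"feed": kf, "T": float(T), "P": P, "converged": ok})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Biodiesel surrogate


#: The five fatty-acid methyl esters making up the biodiesel surrogate.
BIODIESEL_ESTERS = (
    "methyl_palmitate",    # C16:0
    "methyl_stearate",     # C18:0
    "methyl_oleate",       # C18:1
    "methyl_linoleate",    # C18:2
    "methyl_linolenate",   # C18:3
)

#: Synthetic default ester profile (typical soybean-type FAME distribution);
#: a stand-in for a real fuel analysis, which is a required user input when
#: comparing against a specific sample.
DEFAULT_BIODIESEL_FRACTIONS = {
    "methyl_palmitate": 0.11,
    "methyl_stearate": 0.04,
    "methyl_oleate": 0.23,
    "methyl_linoleate": 0.53,
    "methyl_linolenate": 0.09,
}


def make_biodiesel_mixture(
    fractions: dict[str, float] | None = None,
) -> tuple[Mixture, np.ndarray]:
    """CO2 + five-methyl-ester mixture with registry binary parameters.

    All CO2-ester kij come from the bundled registry; ester-ester pairs
    carry an explicitly declared kij = 0 (similar molecular structures);
    every ester is inert (no association sites).  Returns the mixture
    (CO2 first) and the normalized ester fractions in mixture order.
    """
    fractions = dict(DEFAULT_BIODIESEL_FRACTIONS if fractions is None else fractions)
    unknown = set(map(str.lower, fractions)) - set(BIODIESEL_ESTERS)
    if unknown:
        raise ValueError(f"unknown esters {sorted(unknown)}; expected {BIODIESEL_ESTERS}")
    vec = np.array([float(fractions.get(e, 0.0)) for e in BIODIESEL_ESTERS])
    if np.any(vec < 0) or vec.sum() <= 0:
        raise ValueError("ester fractions must be nonnegative and sum to a positive value")
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError(f"ester fractions must sum to 1 (got {vec.sum():.6f})")
    vec = vec / vec.sum()
    inters: list[BinaryInteraction] = []
    for e in BIODIESEL_ESTERS:
        inters.append(get_binary("CO2", e))
    for i, a in enumerate(BIODIESEL_ESTERS):
        for b in BIODIESEL_ESTERS[i + 1:]:
            inters.append(get_binary(a, b))
    mix = Mixture(["CO2", *BIODIESEL_ESTERS], inters)
    return mix, vec


def biodiesel_feed(x_co2: float, fractions: dict[str, float] | None = None) -> np.ndarray:
    """Overall composition [CO2, esters...] at a given CO2 mole fraction."""
    if not 0 <= x_co2 < 1:
        raise ValueError("x_co2 must be in [0, 1)")
    _, vec = make_biodiesel_mixture(fractions)
    return np.concatenate([[x_co2], (1.0 - x_co2) * vec])


# ---------------------------------------------------------------------------
# Ternary fixed-composition fixtures (printed feed compositions)


#: CO2-glycerol-methanol feeds (component order: CO2, glycerol, methanol).
CO2_GLYCEROL_METHANOL_FEEDS = {
    "mixture_1": (0.3373, 0.0212, 0.6415),
    "mixture_2": (0.4352, 0.0180, 0.5468),
    "mixture_3": (0.5359, 0.0148, 0.4493),
    "mixture_4": (0.6430, 0.0114, 0.3456),
}

#: CO2-glycerol-ethanol feeds (component order: CO2, glycerol, ethanol).
CO2_GLYCEROL_ETHANOL_FEEDS = {
    "mixture_1": (0.1333, 0.0413, 0.8254),
    "mixture_2": (0.2808, 0.0342, 0.6850),
    "mixture_3": (0.4276, 0.0273, 0.5451),
    "mixture_4": (0.4985, 0.0239, 0.4776),
}

#: CO2-methanol-lauric acid feeds (component order: CO2, methanol, lauric acid).
CO2_METHANOL_LAURIC_ACID_FEEDS = {
    "mixture_1": (0.6675, 0.2217, 0.1108),
    "mixture_2": (0.7492, 0.1672, 0.0836),
    "mixture_3": (0.8248, 0.1168, 0.0584),
}

_TERNARY_SYSTEMS = {
    ("CO2", "glycerol", "methanol"): CO2_GLYCEROL_METHANOL_FEEDS,
    ("CO2", "glycerol", "ethanol"): CO2_GLYCEROL_ETHANOL_FEEDS,
    ("CO2", "methanol", "lauric_acid"): CO2_METHANOL_LAURIC_ACID_FEEDS,
}


def ternary_fixture(components: Sequence[str]) -> tuple[Mixture, dict[str, tuple]]:
    """Build a ternary mixture with registry parameters plus its fixed feeds.

    ``components`` must name one of the three bundled ternary systems
    (order-insensitive).  All binary parameters come from the registry —
    no ternary adjustment exists anywhere in the pipeline.
    """
    key = None
    want = sorted(get_component(c).name for c in components)
    for names in _TERNARY_SYSTEMS:
        if sorted(names) == want:
            key = names
            break
    if key is None:
        known = [list(k) for k in _TERNARY_SYSTEMS]
        raise KeyError(f"no bundled feeds for {list(components)}; known systems: {known}")
    inters = [
        get_binary(key[0], key[1]),
        get_binary(key[0], key[2]),
        get_binary(key[1], key[2]),
    ]
    return Mixture(list(key), inters), dict(_TERNARY_SYSTEMS[key])
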