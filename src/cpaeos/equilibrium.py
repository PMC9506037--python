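"""Phase-equilibrium solvers: pure saturation, bubble/dew points, flash.

All solvers work in the phi-phi formulation: equality of component
fugacities between a liquid and a vapor phase, both described by the CPA
equation of state.  Bubble- and dew-point pressures use damped successive
substitution on the K-values with a pressure update from the summation
condition; the isothermal flash combines Rachford-Rice material balance
with K-value substitution.  Ternary and multicomponent calls use only
binary-fitted parameters by construction — the solvers take a mixture and
a composition, never any multicomponent adjustment input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .constants import R
from .eos import (
    Mixture,
    StateContext,
    VolumeRootError,
    _lnphi_ctx,
    _pressure_ctx,
    _solve_sites_grid,
    _solve_volume_ctx,
)
from .parameters import PureComponent

__all__ = [
    "EquilibriumResult",
    "ConvergenceError",
    "SupercriticalError",
    "pure_saturation",
    "bubble_pressure",
    "dew_pressure",
    "pt_flash",
    "trace_isotherm",
    "binary_xy_at_tp",
    "vapor_composition_minimum",
]

_FUG_TOL = 1e-10
_MAX_OUTER = 500


class ConvergenceError(RuntimeError):
    """An equilibrium iteration failed to converge."""


class SupercriticalError(ValueError):
    """Pure saturation requested above the fluid's critical temperature."""


@dataclass
class EquilibriumResult:
    """Converged two-phase state (or flagged single-phase outcome)."""

    T: float
    P: float
    x: np.ndarray
    y: np.ndarray
    vapor_fraction: float | None = None
    K: np.ndarray | None = None
    iterations: int = 0
    residual: float = math.nan
    converged: bool = True
    message: str = ""

    def fugacity_residual(self, mix: Mixture) -> float:
        """Max |ln(f_i^V / f_i^L)| over components present in both phases."""
        ctxL = mix.context(self.T, self.x)
        ctxV = mix.context(self.T, self.y)
        VL, XL = _solve_volume_ctx(ctxL, self.P, "liquid")
        VV, XV = _solve_volume_ctx(ctxV, self.P, "vapor")
        lnphiL, _, _, _ = _lnphi_ctx(ctxL, VL, XL, self.P)
        lnphiV, _, _, _ = _lnphi_ctx(ctxV, VV, XV, self.P)
        mask = (self.x > 1e-14) & (self.y > 1e-14)
        res = np.zeros(mix.nc)
        res[mask] = (
            lnphiL[mask] + np.log(self.x[mask]) - lnphiV[mask] - np.log(self.y[mask])
        )
        return float(np.max(np.abs(res))) if mask.any() else 0.0


# ---------------------------------------------------------------------------
# Pure-fluid saturation


def _spinodal_window(ctx: StateContext) -> tuple[float, float]:
    """Pressure window (P_lo, P_hi) inside which two volume roots exist."""
    bm = ctx.bm
    T = ctx.T
    grid = np.geomspace(bm * (1.0 + 1e-5), bm * 1e7, 600)
    rho = 1.0 / grid
    P = R * T / (grid - bm) - ctx.a / (grid * (grid + bm))
    if ctx.has_assoc:
        eta = bm * rho / 4.0
        g = 1.0 / (1.0 - 1.9 * eta)
        dlng = 1.9 * eta / (1.0 - 1.9 * eta)
        X = _solve_sites_grid(ctx, rho, g)
        h = (1.0 - X) @ ctx.w
        P = P - 0.5 * (R * T * rho) * (1.0 + dlng) * h
    dP = np.diff(P)
    rising = dP > 0
    if not rising.any():
        raise SupercriticalError(
            f"no two-phase region at T = {T} K (supercritical or single root)"
        )
    k_lo = int(np.argmax(rising))  # first index where P starts rising: liquid spinodal
    k_hi = k_lo + int(np.argmax(~rising[k_lo:]))  # where it stops: vapor spinodal
    # polish the vapor-spinodal maximum (the grid only brackets it)
    lo_b = grid[max(k_hi - 1, 0)]
    hi_b = grid[min(k_hi + 1, len(grid) - 1)]
    opt = minimize_scalar(
        lambda V: -_pressure_ctx(ctx, V)[0],
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": lo_b * 1e-12},
    )
    P_min = float(P[k_lo])
    P_max = float(-opt.fun)
    if P_max <= 0:
        raise SupercriticalError(f"vapor spinodal pressure non-positive at T = {T} K")
    return max(P_min, 0.0), P_max


def pure_saturation(
    comp: PureComponent | Mixture, T: float
) -> tuple[float, float, float]:
    """Saturation pressure and phase volumes of a pure fluid at T.

    Returns (Psat [bar], V_liquid, V_vapor [L/mol]).  Solves the equal
    fugacity condition ln(phi_L) = ln(phi_V) by bracketed root finding on
    ln P inside the spinodal window.  Raises :class:`SupercriticalError`
    when no two-root region exists at T.
    """
    mix = comp if isinstance(comp, Mixture) else Mixture([comp])
    if mix.nc != 1:
        raise ValueError("pure_saturation requires a single-component system")
    ctx = mix.context(T, np.array([1.0]))
    P_lo, P_hi = _spinodal_window(ctx)
    lo = math.log(max(P_lo * 1.000001, P_hi * 1e-12, 1e-280))
    hi = math.log(P_hi * 0.999999)

    def dg(lnP: float) -> float:
        P = math.exp(lnP)
        VL, XL = _solve_volume_ctx(ctx, P, "liquid")
        VV, XV = _solve_volume_ctx(ctx, P, "vapor")
        lnphiL, _, _, _ = _lnphi_ctx(ctx, VL, XL, P)
        lnphiV, _, _, _ = _lnphi_ctx(ctx, VV, XV, P)
        return float(lnphiL[0] - lnphiV[0])

    f_lo = dg(lo)
    for _ in range(60):  # coincident roots give dg = 0: step inside the window
        if f_lo != 0.0:
            break
        lo = lo + math.log(1.005)
        f_lo = dg(lo)
    # walk the upper bound down until two distinct roots give a valid sign
    f_hi = dg(hi)
    for _ in range(60):
        if f_lo * f_hi <= 0 and f_hi != 0.0:
            break
        hi = hi + math.log(0.995)
        f_hi = dg(hi)
    if f_lo * f_hi > 0:
        raise ConvergenceError(
            f"saturation bracket failed at T = {T} K (dg = {f_lo:.3g}, {f_hi:.3g})"
        )
    lnPs = brentq(dg, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    Psat = math.exp(lnPs)
    VL, _ = _solve_volume_ctx(ctx, Psat, "liquid")
    VV, _ = _solve_volume_ctx(ctx, Psat, "vapor")
    return Psat, VL, VV


_psat_cache: dict[tuple[str, float, float], float] = {}


def _psat_estimate(comp: PureComponent, T: float) -> float:
    """Pure saturation pressure, extrapolated above the critical region.

    Supercritical fluids (CO2 above ~304 K) get a Clausius-Clapeyron
    extrapolation of ln Psat vs 1/T anchored at 0.80 and 0.90 Tc, which is
    only ever used to initialize K-values.
    """
    key = (comp.name, comp.mw, round(T, 8))
    if key in _psat_cache:
        return _psat_cache[key]
    try:
        if T < 0.95 * comp.tc:
            psat = pure_saturation(comp, T)[0]
        else:
            raise SupercriticalError("extrapolate")
    except (SupercriticalError, ConvergenceError, VolumeRootError):
        T1, T2 = 0.80 * comp.tc, 0.90 * comp.tc
        p1 = pure_saturation(comp, T1)[0]
        p2 = pure_saturation(comp, T2)[0]
        B = math.log(p2 / p1) / (1.0 / T1 - 1.0 / T2)
        A = math.log(p1) + B / T1
        psat = math.exp(A - B / T)
    _psat_cache[key] = psat
    return psat


# ---------------------------------------------------------------------------
# Bubble and dew points


def _raoult_init(mix: Mixture, T: float) -> np.ndarray:
    return np.array([_psat_estimate(c, T) for c in mix.components])


def bubble_pressure(
    mix: Mixture,
    T: float,
    x: Sequence[float],
    P0: float | None = None,
    K0: np.ndarray | None = None,
    tol: float = _FUG_TOL,
    P_cap: float = 5e4,
) -> EquilibriumResult:
    """Bubble-point pressure of a liquid of composition x at temperature T.

    Successive substitution on K_i = phi_i^L / phi_i^V with the pressure
    updated from the summation condition sum(x K) = 1; initialization is
    Raoult-type from EoS pure saturation pressures (extrapolated above Tc).
    """
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    if K0 is None or P0 is None:
        psat = _raoult_init(mix, T)
        P = float(x @ psat) if P0 is None else P0
        K = psat / P if K0 is None else np.asarray(K0, float)
    else:
        P, K = float(P0), np.asarray(K0, float).copy()

    ctxL = mix.context(T, x)
    VL = VV = None
    XL = XV = None
    prev: tuple[float, float] | None = None
    dlnK_prev: np.ndarray | None = None
    lnx = np.where(x > 0, np.log(np.clip(x, 1e-300, None)), 0.0)
    it = 0
    for it in range(1, _MAX_OUTER + 1):
        y = K * x
        S = float(y.sum())
        y = y / S
        try:
            VL, XL = _solve_volume_ctx(ctxL, P, "liquid", VL, XL)
            lnphiL, _, _, XL = _lnphi_ctx(ctxL, VL, XL, P)
            ctxV = mix.context(T, y)
            VV, XV = _solve_volume_ctx(ctxV, P, "vapor", VV, XV)
            lnphiV, _, _, XV = _lnphi_ctx(ctxV, VV, XV, P)
        except (VolumeRootError, ValueError) as exc:
            raise ConvergenceError(f"bubble point failed at P = {P:.4g} bar: {exc}")
        K_new = np.exp(lnphiL - lnphiV)
        dlnK = np.log(K_new / K)
        dK = float(np.max(np.abs(dlnK)[x > 0]))
        # dominant-eigenvalue extrapolation collapses slow linear tails of
        # the successive-substitution K loop (CO2-rich, near-critical feeds)
        if dlnK_prev is not None and 1e-12 < dK < 1e-2 and it % 3 == 0:
            denom = float(dlnK_prev @ dlnK_prev)
            lam = float(dlnK_prev @ dlnK) / denom if denom > 0 else 0.0
            if 0.2 < lam < 0.995:
                K_new = K_new * np.exp(dlnK * min(lam / (1.0 - lam), 200.0))
                dlnK = None  # extrapolated step: not a plain SS difference
        dlnK_prev = dlnK
        K = K_new
        S = float((K * x).sum())
        if abs(S - 1.0) < tol and dK < 10.0 * tol:
            break
        # pressure update from the summation condition: secant on ln S(ln P)
        # once near the solution, damped direct substitution otherwise
        lnS = math.log(S)
        if prev is not None and abs(lnS) < 0.3 and prev[1] != lnS:
            lnP_new = math.log(P) - lnS * (math.log(P) - prev[0]) / (lnS - prev[1])
            lnP_new = min(max(lnP_new, math.log(P) - 1.1), math.log(P) + 1.1)
            prev = (math.log(P), lnS)
            P = math.exp(lnP_new)
        else:
            prev = (math.log(P), lnS)
            P *= min(max(S, 0.3), 3.0)
        if not 1e-10 < P < P_cap:
            raise ConvergenceError(
                f"bubble pressure diverged (P = {P:.3g} bar): composition likely "
                "outside the two-phase region"
            )
    y = K * x
    y = y / y.sum()
    converged = abs(S - 1.0) < 1e-8 and dK < 1e-7
    message = ""
    if np.max(np.abs(x - y)) < 1e-5:
        converged = False
        message = "trivial solution (x = y): near-critical point"
    res = np.abs(np.log(K) + lnx - np.log(np.clip(y, 1e-300, None)))
    residual = float(np.max(res[x > 0]))
    if not converged and not message:
        message = f"not converged after {it} iterations (|S-1| = {abs(S-1.0):.2e})"
    return EquilibriumResult(
        T=T, P=P, x=x, y=y, vapor_fraction=0.0, K=K,
        iterations=it, residual=residual, converged=converged, message=message,
    )


def dew_pressure(
    mix: Mixture,
    T: float,
    y: Sequence[float],
    P0: float | None = None,
    K0: np.ndarray | None = None,
    tol: float = _FUG_TOL,
) -> EquilibriumResult:
    """Dew-point pressure of a vapor of composition y (mirror of bubble)."""
    y = np.asarray(y, dtype=float)
    y = y / y.sum()
    if K0 is None or P0 is None:
        psat = _raoult_init(mix, T)
        with np.errstate(divide="ignore"):
            P = 1.0 / float(np.sum(y / psat)) if P0 is None else P0
        K = psat / P if K0 is None else np.asarray(K0, float)
    else:
        P, K = float(P0), np.asarray(K0, float).copy()

    ctxV = mix.context(T, y)
    VL = VV = None
    XL = XV = None
    prev: tuple[float, float] | None = None
    dlnK_prev: np.ndarray | None = None
    it = 0
    for it in range(1, _MAX_OUTER + 1):
        x = y / K
        S = float(x.sum())
        x = x / S
        try:
            ctxL = mix.context(T, x)
            VL, XL = _solve_volume_ctx(ctxL, P, "liquid", VL, XL)
            lnphiL, _, _, XL = _lnphi_ctx(ctxL, VL, XL, P)
            VV, XV = _solve_volume_ctx(ctxV, P, "vapor", VV, XV)
            lnphiV, _, _, XV = _lnphi_ctx(ctxV, VV, XV, P)
        except (VolumeRootError, ValueError) as exc:
            raise ConvergenceError(f"dew point failed at P = {P:.4g} bar: {exc}")
        K_new = np.exp(lnphiL - lnphiV)
        dlnK = np.log(K_new / K)
        dK = float(np.max(np.abs(dlnK)[y > 0]))
        if dlnK_prev is not None and 1e-12 < dK < 1e-2 and it % 3 == 0:
            denom = float(dlnK_prev @ dlnK_prev)
            lam = float(dlnK_prev @ dlnK) / denom if denom > 0 else 0.0
            if 0.2 < lam < 0.995:
                K_new = K_new * np.exp(dlnK * min(lam / (1.0 - lam), 200.0))
                dlnK = None
        dlnK_prev = dlnK
        K = K_new
        S = float((y / K).sum())
        if abs(S - 1.0) < tol and dK < 10.0 * tol:
            break
        lnS = math.log(S)
        if prev is not None and abs(lnS) < 0.3 and prev[1] != lnS:
            lnP_new = math.log(P) - lnS * (math.log(P) - prev[0]) / (lnS - prev[1])
            lnP_new = min(max(lnP_new, math.log(P) - 1.1), math.log(P) + 1.1)
            prev = (math.log(P), lnS)
            P = math.exp(lnP_new)
        else:
            prev = (math.log(P), lnS)
            P /= min(max(S, 0.3), 3.0)
        if not 1e-10 < P < 5e4:
            raise ConvergenceError(
                f"dew pressure diverged (P = {P:.3g} bar): composition likely "
                "outside the two-phase region"
            )
    x = y / K
    x = x / x.sum()
    x[y == 0] = 0.0
    x = x / x.sum()
    converged = abs(S - 1.0) < 1e-8 and dK < 1e-7
    message = ""
    if np.max(np.abs(x - y)) < 1e-5:
        converged = False
        message = "trivial solution (x = y): near-critical point"
    if not converged and not message:
        message = f"not converged after {it} iterations (|S-1| = {abs(S-1.0):.2e})"
    mask = y > 0
    residual = float(
        np.max(np.abs(np.log(K[mask] * x[mask] / y[mask])))
    )
    return EquilibriumResult(
        T=T, P=P, x=x, y=y, vapor_fraction=1.0, K=K,
        iterations=it, residual=residual, converged=converged, message=message,
    )


# ---------------------------------------------------------------------------
# Isothermal flash


def _rachford_rice(z: np.ndarray, K: np.ndarray) -> float:
    """Vapor fraction solving the Rachford-Rice equation (negative flash)."""
    Km = K - 1.0
    if np.all(np.abs(Km) < 1e-14):
        return 0.5
    b_lo = -1.0 / Km.max() + 1e-12 if Km.max() > 0 else -1e6
    b_hi = -1.0 / Km.min() - 1e-12 if Km.min() < 0 else 1e6

    def g(beta: float) -> float:
        return float(np.sum(z * Km / (1.0 + beta * Km)))

    lo, hi = b_lo, b_hi
    if g(lo) < 0:
        return lo
    if g(hi) > 0:
        return hi
    return brentq(g, lo, hi, xtol=1e-14, maxiter=200)


def pt_flash(
    mix: Mixture,
    T: float,
    P: float,
    z: Sequence[float],
    K0: np.ndarray | None = None,
    tol: float = 1e-10,
) -> EquilibriumResult:
    """Isothermal two-phase flash at (T, P, z).

    Rachford-Rice inner solve with phi-phi successive substitution on the
    K-values (negative-flash window internally); single-phase outcomes are
    reported with vapor_fraction 0 or 1 and x = y = z.
    """
    z = np.asarray(z, dtype=float)
    z = z / z.sum()
    if K0 is None:
        psat = _raoult_init(mix, T)
        K = psat / P
    else:
        K = np.asarray(K0, float).copy()
    VL = VV = None
    XL = XV = None
    beta = 0.5
    it = 0
    for it in range(1, _MAX_OUTER + 1):
        beta = _rachford_rice(z, K)
        x = z / (1.0 + beta * (K - 1.0))
        y = K * x
        x = x / x.sum()
        y = y / y.sum()
        try:
            ctxL = mix.context(T, x)
            VL, XL = _solve_volume_ctx(ctxL, P, "liquid", VL, XL)
            lnphiL, _, _, XL = _lnphi_ctx(ctxL, VL, XL, P)
            ctxV = mix.context(T, y)
            VV, XV = _solve_volume_ctx(ctxV, P, "vapor", VV, XV)
            lnphiV, _, _, XV = _lnphi_ctx(ctxV, VV, XV, P)
        except (VolumeRootError, ValueError) as exc:
            raise ConvergenceError(f"flash failed at (T={T}, P={P}): {exc}")
        K_new = np.exp(lnphiL - lnphiV)
        dK = float(np.max(np.abs(np.log(K_new / K))))
        K = K_new
        if dK < tol:
            break
    beta = _rachford_rice(z, K)
    if beta <= 0.0:
        return EquilibriumResult(
            T=T, P=P, x=z, y=z, vapor_fraction=0.0, K=K, iterations=it,
            residual=0.0, converged=True, message="single liquid phase",
        )
    if beta >= 1.0:
        return EquilibriumResult(
            T=T, P=P, x=z, y=z, vapor_fraction=1.0, K=K, iterations=it,
            residual=0.0, converged=True, message="single vapor phase",
        )
    x = z / (1.0 + beta * (K - 1.0))
    y = K * x
    x = x / x.sum()
    y = y / y.sum()
    converged = dK < 1e-8
    message = "" if converged else f"not converged after {it} iterations"
    if np.max(np.abs(x - y)) < 1e-5:
        converged = False
        message = "trivial solution (x = y): near phase boundary or critical"
    residual = float(np.max(np.abs(np.log(K * x / y))))
    return EquilibriumResult(
        T=T, P=P, x=x, y=y, vapor_fraction=float(beta), K=K,
        iterations=it, residual=residual, converged=converged, message=message,
    )


# ---------------------------------------------------------------------------
# Isotherm tracing and the vapor-composition minimum


def trace_isotherm(
    mix: Mixture,
    T: float,
    x1_grid: Sequence[float],
    component: int = 0,
) -> list[EquilibriumResult]:
    """Bubble-point sweep over liquid mole fractions of one component.

    Each point warm-starts from its converged neighbour; failures are
    recorded as non-converged results without aborting the sweep.
    """
    if mix.nc != 2:
        raise ValueError("trace_isotherm expects a binary mixture")
    results: list[EquilibriumResult] = []
    P0: float | None = None
    K0: np.ndarray | None = None
    for x1 in x1_grid:
        x = np.zeros(2)
        x[component] = x1
        x[1 - component] = 1.0 - x1
        try:
            res = bubble_pressure(mix, T, x, P0=P0, K0=K0)
        except ConvergenceError as exc:
            res = EquilibriumResult(
                T=T, P=math.nan, x=x, y=np.full(2, math.nan),
                converged=False, message=str(exc),
            )
        results.append(res)
        if res.converged:
            P0, K0 = res.P, res.K
    return results


def binary_xy_at_tp(
    mix: Mixture,
    T: float,
    P: float,
    x1_guess: float = 0.2,
    component: int = 0,
    tol: float = 1e-10,
) -> EquilibriumResult:
    """Coexisting binary compositions at fixed (T, P).

    Solves bubble_P(x1) = P for the liquid fraction of ``component`` by
    safeguarded secant iteration (bracket expansion on failure).  For a
    binary two-phase state the (x, y) pair is independent of overall
    composition, so this pins the full equilibrium at (T, P).
    """
    if mix.nc != 2:
        raise ValueError("binary_xy_at_tp expects a binary mixture")

    warm: dict = {"P": None, "K": None}
    cap = 30.0 * P

    def bubble_at(x1: float) -> EquilibriumResult:
        x = np.zeros(2)
        x[component] = x1
        x[1 - component] = 1.0 - x1
        res = bubble_pressure(mix, T, x, P0=warm["P"], K0=warm["K"], P_cap=cap)
        if res.converged:
            warm["P"], warm["K"] = res.P, res.K
        return res

    def f(x1: float) -> float:
        return bubble_at(x1).P - P

    # fast path: secant iteration from a good warm guess (sweeps, refits)
    try:
        x0 = min(max(x1_guess, 1e-5), 0.95)
        f0 = f(x0)
        if abs(f0) < 0.5 * P:
            x1s, f1s = x0 * 1.02, None
            f1s = f(x1s)
            for _ in range(20):
                if f1s == f0:
                    break
                x_next = x1s - f1s * (x1s - x0) / (f1s - f0)
                if not 1e-7 < x_next < 0.9999:
                    break
                x0, f0 = x1s, f1s
                x1s = x_next
                f1s = f(x1s)
                if abs(f1s) < 1e-9 * P:
                    res = bubble_at(x1s)
                    if res.converged:
                        return res
                    break
    except ConvergenceError:
        pass

    # The bubble pressure increases with the volatile fraction; a divergent
    # bubble solve means x1 exceeds the maximum solubility, which counts as
    # "above the target" for bracketing purposes.
    lo = min(max(x1_guess, 1e-5), 0.95)
    f_lo = None
    for _ in range(60):
        try:
            f_lo = f(lo)
        except ConvergenceError:
            lo *= 0.5
            continue
        if f_lo < 0:
            break
        lo *= 0.5
        if lo < 1e-9:
            raise ConvergenceError(
                f"P = {P} bar below the dilute bubble branch at T = {T} K"
            )
    if f_lo is None or f_lo >= 0:
        raise ConvergenceError(f"no lower bracket for P = {P} bar at T = {T} K")
    hi = lo
    f_hi = f_lo
    hi_bad = None  # smallest known x1 with no bubble point
    for _ in range(80):
        if hi_bad is None:
            hi_try = min(hi * 1.5, 0.9999)
        else:
            hi_try = math.sqrt(hi * hi_bad)  # bisect toward the solubility limit
        try:
            f_try = f(hi_try)
        except ConvergenceError:
            hi_bad = hi_try
            if hi_bad / hi < 1.0 + 1e-5:
                raise ConvergenceError(
                    f"two-phase region ends below P = {P} bar at T = {T} K"
                )
            continue
        if f_try >= 0:
            hi, f_hi = hi_try, f_try
            break
        hi, f_hi = hi_try, f_try
        lo, f_lo = hi_try, f_try
    else:
        raise ConvergenceError(
            f"could not bracket P = {P} bar on the bubble curve at T = {T} K"
        )
    try:
        x1 = brentq(f, lo, hi, xtol=1e-12, maxiter=200)
    except ValueError:
        # warm-started f can show tiny hysteresis at a near-degenerate
        # bracket; fall back to the endpoint closer to the target
        x1 = lo if abs(f_lo) <= abs(f_hi) else hi
    res = bubble_at(x1)
    if abs(res.P - P) > 1e-5 * P:
        raise ConvergenceError(
            f"bubble curve does not reach P = {P} bar at T = {T} K "
            f"(closest {res.P:.6g} bar)"
        )
    return res


def vapor_composition_minimum(
    mix: Mixture,
    T: float,
    P_range: tuple[float, float],
    heavy: int = 1,
    n_scan: int = 24,
) -> tuple[float, float, bool]:
    """Locate the minimum of the heavy component's vapor fraction vs pressure.

    Scans y_heavy(P) along the isotherm, then refines any interior minimum
    by bounded golden-section/Brent search.  Returns (P_min, y_heavy_min,
    interior) where ``interior`` is False when the minimum sits on the
    boundary of ``P_range`` (monotone isotherm).
    """
    P_lo, P_hi = P_range
    if not 0 < P_lo < P_hi:
        raise ValueError("invalid pressure range")
    state = {"x1": 0.05}

    def y_heavy(P: float) -> float:
        res = binary_xy_at_tp(mix, T, P, x1_guess=state["x1"], component=1 - heavy)
        state["x1"] = float(res.x[1 - heavy])
        return float(res.y[heavy])

    Ps = np.linspace(P_lo, P_hi, n_scan)
    ys = np.array([y_heavy(P) for P in Ps])
    k = int(np.argmin(ys))
    if k in (0, n_scan - 1):
        return float(Ps[k]), float(ys[k]), False
    res = minimize_scalar(
        y_heavy,
        bounds=(Ps[k - 1], Ps[k + 1]),
        method="bounded",
        options={"xatol": (P_hi - P_lo) * 1e-5},
    )
    P_min, y_min = float(res.x), float(res.fun)
    interior = P_lo + 1e-9 < P_min < P_hi - 1e-9
    return P_min, y_min, interior
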