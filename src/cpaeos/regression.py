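"""Parameter regression: %AAD metric, binary-parameter and pure-fluid fits.

The binary fit adjusts a single temperature-independent kij (optionally
together with a cross-association volume beta_cross under the mCR-1 rule)
to isothermal VLE data, minimizing mean squared relative deviations of the
quantity selected by ``objective``:

``pressure``
    bubble pressure at each record's (T, x) against the measured P —
    the natural choice when liquid compositions were measured;
``liquid_x``
    the computed liquid fraction of the first component at (T, P);
``vapor_y``
    the computed vapor fraction of the second (heavy) component at (T, P)
    — used for systems where only vapor/fluid-phase solubilities exist;
``combined``
    liquid_x + vapor_y jointly.

The pure-fluid fit adjusts (a0, b, c1) to saturation pressures and liquid
molar volumes with the association parameters held fixed, mirroring how
families of hydrogen-bonding fluids are parameterized with shared
association constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .datasets import VleDataset
from .eos import Mixture
from .equilibrium import (
    ConvergenceError,
    SupercriticalError,
    binary_xy_at_tp,
    bubble_pressure,
    pure_saturation,
)
from .parameters import BinaryInteraction, PureComponent, get_component

__all__ = ["FitResult", "percent_aad", "fit_binary", "fit_pure"]

_KIJ_BOUNDS = (-0.3, 0.5)
_BETA_BOUNDS = (1e-4, 0.5)
_PENALTY = 1e4


def percent_aad(calc: Sequence[float], exp: Sequence[float]) -> float:
    """Average absolute relative deviation, 100 * mean(|exp - calc| / exp)."""
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape:
        raise ValueError("calc and exp must have equal length")
    if np.any(exp == 0):
        raise ValueError("experimental values must be strictly nonzero")
    return float(100.0 * np.mean(np.abs(exp - calc) / np.abs(exp)))


@dataclass
class FitResult:
    """Outcome of a parameter fit."""

    params: dict
    objective: float
    aad: dict
    n_eval: int
    converged: bool
    message: str = ""


class _BinaryObjective:
    """Relative-squared-error objective with per-record warm starts."""

    def __init__(
        self,
        dataset: VleDataset,
        base: BinaryInteraction,
        objective: str,
        free: tuple[str, ...],
    ) -> None:
        self.ds = dataset
        self.base = base
        self.kind = objective
        self.free = free
        self.comps = [get_component(n) for n in dataset.components]
        f = dataset.frame
        self.has_x = ~f[dataset.x_cols].isna().any(axis=1)
        self.has_y = ~f[dataset.y_cols].isna().any(axis=1)
        self.n_eval = 0
        # warm-start caches, keyed by record index
        self._warm_bub: dict[int, tuple[float, np.ndarray]] = {}
        self._warm_x1: dict[int, float] = {}

    def mixture(self, params: dict) -> Mixture:
        inter = replace(
            self.base,
            kij=params.get("kij", self.base.kij),
            beta_cross=params.get("beta_cross", self.base.beta_cross),
        )
        return Mixture(self.comps, [inter])

    def record_values(self, mix: Mixture) -> pd.DataFrame:
        """Model P (at T, x), x1 and y2 (at T, P) per record, as available."""
        f = self.ds.frame
        out = pd.DataFrame(index=f.index, columns=["P", "x1", "y2"], dtype=float)
        for i in f.index:
            T = float(f.at[i, "T"])
            P_exp = float(f.at[i, "P"])
            if self.has_x[i] and self.kind in ("pressure",):
                x = f.loc[i, self.ds.x_cols].to_numpy(dtype=float)
                warm = self._warm_bub.get(i, (None, None))
                res = None
                try:
                    res = bubble_pressure(mix, T, x, P0=warm[0], K0=warm[1])
                except ConvergenceError:
                    pass
                if (res is None or not res.converged) and warm[0] is not None:
                    try:  # a stale warm start can mislead: retry cold
                        res = bubble_pressure(mix, T, x)
                    except ConvergenceError:
                        res = None
                if res is None or not res.converged:
                    out.at[i, "P"] = np.nan
                    continue
                self._warm_bub[i] = (res.P, res.K)
                out.at[i, "P"] = res.P
            if self.kind in ("liquid_x", "vapor_y", "combined"):
                res = None
                for guess in (self._warm_x1.get(i, 0.1), 0.05):
                    try:
                        res = binary_xy_at_tp(mix, T, P_exp, x1_guess=guess, component=0)
                    except ConvergenceError:
                        res = None
                    if res is not None and res.converged:
                        break
                if res is None or not res.converged:
                    continue
                self._warm_x1[i] = float(res.x[0])
                out.at[i, "x1"] = res.x[0]
                out.at[i, "y2"] = res.y[1]
        return out

    def __call__(self, params: dict) -> float:
        self.n_eval += 1
        mix = self.mixture(params)
        vals = self.record_values(mix)
        f = self.ds.frame
        sq: list[float] = []
        if self.kind == "pressure":
            for i in f.index[self.has_x]:
                Pc = vals.at[i, "P"]
                if np.isnan(Pc):
                    sq.append(_PENALTY)
                else:
                    sq.append(((Pc - f.at[i, "P"]) / f.at[i, "P"]) ** 2)
        if self.kind in ("liquid_x", "combined"):
            for i in f.index[self.has_x]:
                xc = vals.at[i, "x1"]
                xe = float(f.at[i, "x_1"])
                sq.append(_PENALTY if np.isnan(xc) else ((xc - xe) / xe) ** 2)
        if self.kind in ("vapor_y", "combined"):
            for i in f.index[self.has_y]:
                yc = vals.at[i, "y2"]
                ye = float(f.at[i, "y_2"])
                sq.append(_PENALTY if np.isnan(yc) else ((yc - ye) / ye) ** 2)
        return float(np.mean(sq))

    def residual_vector(self, params: dict) -> np.ndarray:
        """Signed relative deviations per record (for least-squares fits)."""
        self.n_eval += 1
        mix = self.mixture(params)
        vals = self.record_values(mix)
        f = self.ds.frame
        res: list[float] = []
        pen = math.sqrt(_PENALTY)
        if self.kind == "pressure":
            for i in f.index[self.has_x]:
                Pc = vals.at[i, "P"]
                res.append(pen if np.isnan(Pc) else (Pc - f.at[i, "P"]) / f.at[i, "P"])
        if self.kind in ("liquid_x", "combined"):
            for i in f.index[self.has_x]:
                xc = vals.at[i, "x1"]
                xe = float(f.at[i, "x_1"])
                res.append(pen if np.isnan(xc) else (xc - xe) / xe)
        if self.kind in ("vapor_y", "combined"):
            for i in f.index[self.has_y]:
                yc = vals.at[i, "y2"]
                ye = float(f.at[i, "y_2"])
                res.append(pen if np.isnan(yc) else (yc - ye) / ye)
        return np.asarray(res)

    def aad_report(self, params: dict) -> dict:
        """Post-fit %AAD of every quantity the dataset supports."""
        mix = self.mixture(params)
        f = self.ds.frame
        report: dict = {}
        # bubble pressure AAD over liquid records
        if self.has_x.any():
            calc, exp = [], []
            warm: tuple = (None, None)
            for i in f.index[self.has_x]:
                x = f.loc[i, self.ds.x_cols].to_numpy(dtype=float)
                try:
                    res = bubble_pressure(mix, float(f.at[i, "T"]), x, P0=warm[0], K0=warm[1])
                except ConvergenceError:
                    continue
                if res.converged:
                    warm = (res.P, res.K)
                    calc.append(res.P)
                    exp.append(float(f.at[i, "P"]))
            if calc:
                report["pressure"] = percent_aad(calc, exp)
        # x1 / y2 AAD at measured (T, P)
        calc_x, exp_x, calc_y, exp_y = [], [], [], []
        guess = 0.1
        for i in f.index:
            if not (self.has_x[i] or self.has_y[i]):
                continue
            try:
                res = binary_xy_at_tp(
                    mix, float(f.at[i, "T"]), float(f.at[i, "P"]),
                    x1_guess=guess, component=0,
                )
            except ConvergenceError:
                continue
            if not res.converged:
                continue
            guess = float(res.x[0])
            if self.has_x[i]:
                calc_x.append(float(res.x[0]))
                exp_x.append(float(f.at[i, "x_1"]))
            if self.has_y[i]:
                calc_y.append(float(res.y[1]))
                exp_y.append(float(f.at[i, "y_2"]))
        if calc_x:
            report["x1"] = percent_aad(calc_x, exp_x)
        if calc_y:
            report["y2"] = percent_aad(calc_y, exp_y)
        return report


def fit_binary(
    dataset: VleDataset,
    free: Sequence[str] = ("kij",),
    objective: str = "pressure",
    base: BinaryInteraction | None = None,
    n_starts: int = 5,
    compute_aad: bool = True,
) -> FitResult:
    """Fit kij (and optionally beta_cross) to a binary VLE dataset.

    Parameters
    ----------
    dataset : VleDataset
        Binary T-P-x-y records.
    free : sequence of str
        ``("kij",)`` or ``("kij", "beta_cross")``; fitting beta_cross
        requires ``base.cross_rule`` mCR1 or explicit.
    objective : str
        pressure | liquid_x | vapor_y | combined (see module docstring).
    base : BinaryInteraction, optional
        Template carrying the cross-association rule; defaults to an inert
        pair (kij only, no cross association).
    n_starts : int
        Multi-start count for the two-parameter fit.
    """
    if len(dataset.components) != 2:
        raise ValueError("fit_binary expects a binary dataset")
    free = tuple(free)
    if not set(free) <= {"kij", "beta_cross"}:
        raise ValueError(f"unknown free parameters {free}")
    if objective not in ("pressure", "liquid_x", "vapor_y", "combined"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective in ("pressure", "liquid_x") and not dataset.has_liquid:
        raise ValueError(f"objective {objective!r} needs liquid-phase records")
    if objective in ("vapor_y",) and not dataset.has_vapor:
        raise ValueError("objective 'vapor_y' needs vapor-phase records")
    if objective == "combined" and not (dataset.has_liquid or dataset.has_vapor):
        raise ValueError("objective 'combined' needs measured compositions")
    if base is None:
        a, b = dataset.components
        base = BinaryInteraction(pair=(a, b), kij=0.0, cross_rule="none")
    if "beta_cross" in free and base.cross_rule not in ("mCR1", "explicit"):
        raise ValueError("fitting beta_cross requires an mCR1 or explicit cross rule")

    obj = _BinaryObjective(dataset, base, objective, free)

    if free == ("kij",):
        res = minimize_scalar(
            lambda k: obj({"kij": k}),
            bounds=_KIJ_BOUNDS,
            method="bounded",
            options={"xatol": 1e-7},
        )
        params = {"kij": float(res.x)}
        fval = float(res.fun)
        converged = bool(res.success) and fval < _PENALTY / 2
        message = "" if converged else "objective dominated by failed records"
    else:
        # multi-start bounded least squares on the per-record residual vector
        k_starts = np.linspace(-0.05, 0.35, n_starts)
        b_starts = np.geomspace(0.03, 0.2, n_starts)
        best: tuple[float, np.ndarray] | None = None
        for k0, b0 in zip(k_starts, b_starts):
            try:
                ls = least_squares(
                    lambda p: obj.residual_vector(
                        {"kij": float(p[0]), "beta_cross": float(p[1])}
                    ),
                    x0=[k0, b0],
                    bounds=([_KIJ_BOUNDS[0], _BETA_BOUNDS[0]],
                            [_KIJ_BOUNDS[1], _BETA_BOUNDS[1]]),
                    diff_step=1e-5,
                    xtol=1e-10,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            fval_k = float(np.mean(ls.fun**2))
            if best is None or fval_k < best[0]:
                best = (fval_k, ls.x)
            if fval_k < 1e-12:  # an essentially exact fit: stop early
                break
        if best is None:
            raise RuntimeError("all optimization starts failed")
        params = {"kij": float(best[1][0]), "beta_cross": float(best[1][1])}
        fval = best[0]
        converged = fval < _PENALTY / 2
        message = "" if converged else "objective dominated by failed records"

    aad = obj.aad_report(params) if compute_aad else {}
    return FitResult(
        params=params,
        objective=fval,
        aad=aad,
        n_eval=obj.n_eval,
        converged=converged,
        message=message,
    )


def fit_pure(
    template: PureComponent,
    sat_data: pd.DataFrame,
    free: Sequence[str] = ("a0", "b", "c1"),
) -> FitResult:
    """Fit (a0, b, c1) to saturation data with fixed association parameters.

    Parameters
    ----------
    template : PureComponent
        Supplies tc, the association parameters (held fixed) and the scheme.
    sat_data : DataFrame
        Columns ``T`` (K), ``psat`` (bar), ``vliq`` (L/mol); at least 6 rows.
    free : sequence of str
        Subset of ("a0", "b", "c1") to adjust; the rest stay at the
        template values.

    Minimizes equally weighted squared relative deviations of Psat and
    Vliq; reports %AAD of both.
    """
    req = {"T", "psat", "vliq"}
    if not req <= set(sat_data.columns):
        raise ValueError(f"sat_data needs columns {sorted(req)}")
    if len(sat_data) < 6:
        raise ValueError("need at least 6 saturation records")
    free = tuple(free)
    if not set(free) <= {"a0", "b", "c1"}:
        raise ValueError(f"unknown free parameters {free}")

    T = sat_data["T"].to_numpy(dtype=float)
    Pe = sat_data["psat"].to_numpy(dtype=float)
    Ve = sat_data["vliq"].to_numpy(dtype=float)

    # heuristics: the co-volume sits somewhat below the densest liquid volume
    x0_full = {
        "a0": template.a0 if template.a0 > 0 else 5.0,
        "b": template.b,
        "c1": template.c1,
    }
    if "b" in free:
        x0_full["b"] = 0.8 * float(Ve.min())
    if "a0" in free:
        x0_full["a0"] = 40.0 * x0_full["b"] * float(T.mean()) * 0.083145 / 4.0
    if "c1" in free:
        x0_full["c1"] = 1.0

    n_eval = {"n": 0}

    def residuals(p: np.ndarray) -> np.ndarray:
        n_eval["n"] += 1
        vals = dict(x0_full)
        vals.update(dict(zip(free, p)))
        comp = replace(
            template, a0=max(vals["a0"], 1e-6), b=max(vals["b"], 1e-6), c1=vals["c1"]
        )
        out = np.empty(2 * len(T))
        for k, Tk in enumerate(T):
            try:
                psat, vl, _ = pure_saturation(comp, float(Tk))
                out[k] = (psat - Pe[k]) / Pe[k]
                out[len(T) + k] = (vl - Ve[k]) / Ve[k]
            except (SupercriticalError, ConvergenceError, Exception):
                out[k] = 10.0
                out[len(T) + k] = 10.0
        return out

    x0 = np.array([x0_full[name] for name in free])
    scale = np.maximum(np.abs(x0), 1e-3)
    ls = least_squares(
        residuals, x0, x_scale=scale, diff_step=1e-6, xtol=1e-12, ftol=1e-14, gtol=1e-12
    )
    params = dict(zip(free, map(float, ls.x)))
    vals = dict(x0_full)
    vals.update(params)
    fitted = replace(template, a0=vals["a0"], b=vals["b"], c1=vals["c1"])

    calc_p, calc_v = [], []
    for Tk in T:
        psat, vl, _ = pure_saturation(fitted, float(Tk))
        calc_p.append(psat)
        calc_v.append(vl)
    aad = {
        "psat": percent_aad(calc_p, Pe),
        "vliq": percent_aad(calc_v, Ve),
    }
    resid = residuals(ls.x)
    flat = bool(np.all(np.abs(ls.jac) < 1e-12)) if ls.jac is not None else False
    return FitResult(
        params=params,
        objective=float(np.sum(resid**2)),
        aad=aad,
        n_eval=n_eval["n"],
        converged=bool(ls.success) and not flat,
        message="flat objective: parameters unidentifiable" if flat else ls.message,
    )
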