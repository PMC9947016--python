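"""Parameter estimation: degradation, cellular TD, and DEX PK fits.

All fits use naive-pooled weighted least squares with a proportional
residual-error model, residual = (obs - pred) / pred, minimized over
log-transformed parameters (which enforces positivity and makes the
reported standard errors directly interpretable as relative errors).
Precision is reported as %RSE = 100 * SE / estimate with SE taken from the
inverse Gauss-Newton approximation of the Hessian at the optimum; a seeded
bootstrap over replicates is available as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .model import IntegrationError, LinearPKSolution, _simulate_conditions_raw
from .dosing import build_regimen
from .params import DegradationParams, PKParamsDEX, TDParams

__all__ = [
    "IdentifiabilityError",
    "FitResult",
    "ViabilityDataset",
    "fit_exponential_decay",
    "fit_td_simultaneous",
    "fit_pk_dex",
    "default_td_init",
]

#: Canonical ordering of the nine TD parameters used throughout estimation.
TD_PARAM_NAMES = (
    "kg", "r0", "s_dox", "s_dex", "kmax_dox", "kc50_dox", "ktr_dox",
    "imax_dexi", "ic50_dexi",
)

# Broad positivity-box on the natural scale; optimization runs on log scale.
_TD_BOUNDS = {
    "kg": (1e-5, 1.0),
    "r0": (50.0, 150.0),
    "s_dox": (1e-6, 10.0),
    "s_dex": (1e-6, 10.0),
    "kmax_dox": (1e-5, 5.0),
    "kc50_dox": (1e-4, 1e3),
    "ktr_dox": (1e-3, 10.0),
    "imax_dexi": (1e-5, 5.0),
    "ic50_dexi": (1e-2, 1e4),
}

_PRED_FLOOR = 1e-9  # guards the proportional weight against underflow


class IdentifiabilityError(RuntimeError):
    """Raised when the dataset cannot structurally inform the requested fit."""


@dataclass
class FitResult:
    """Outcome of a weighted least-squares fit.

    ``estimates`` and ``rse_percent`` are keyed by parameter name;
    parameters that the dataset cannot inform are kept at their initial
    values and listed in ``fixed`` with an explanatory entry in ``flags``.
    """

    estimates: dict
    rse_percent: dict
    objective: float
    convergence: dict
    residuals: np.ndarray
    fixed: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "estimates": self.estimates,
            "rse_percent": {
                k: (None if v is None or not np.isfinite(v) else v)
                for k, v in self.rse_percent.items()
            },
            "objective": self.objective,
            "convergence": self.convergence,
            "fixed": self.fixed,
            "flags": self.flags,
            "seed": self.seed,
            "n_residuals": int(np.size(self.residuals)),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class ViabilityDataset:
    """Tidy in vitro viability records.

    One row per (condition, timepoint, replicate) with columns
    ``c_dox0_uM``, ``c_dex0_uM``, ``time_h``, ``replicate``,
    ``viability_pct``. Every condition must include a t = 0 record.
    """

    df: pd.DataFrame

    REQUIRED = ("c_dox0_uM", "c_dex0_uM", "time_h", "replicate", "viability_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"viability table is missing columns: {missing}")
        df = self.df
        if (df["viability_pct"] < 0).any():
            raise ValueError("viability must be >= 0")
        if (df["time_h"] < 0).any() or (df["c_dox0_uM"] < 0).any() or (df["c_dex0_uM"] < 0).any():
            raise ValueError("times and concentrations must be >= 0")
        for (cd, cx), grp in df.groupby(["c_dox0_uM", "c_dex0_uM"]):
            if not (grp["time_h"] == 0).any():
                raise ValueError(f"condition (DOX {cd}, DEX {cx}) lacks a t=0 record")

    def conditions(self) -> pd.DataFrame:
        """Unique (c_dox0, c_dex0) pairs in the dataset."""
        return (
            self.df[["c_dox0_uM", "c_dex0_uM"]]
            .drop_duplicates()
            .sort_values(["c_dox0_uM", "c_dex0_uM"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def fit_exponential_decay(times, concs) -> FitResult:
    """Estimate a first-order degradation rate from a concentration series.

    Least squares on log-concentration: ln C = ln C0 - kdeg * t. The
    standard error of ``kdeg`` comes from the linear-regression covariance.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0 for the log transform")
    reg = stats.linregress(t, np.log(c))
    kdeg = -reg.slope
    c0 = float(np.exp(reg.intercept))
    pred = c0 * np.exp(-kdeg * t)
    resid = (c - pred) / pred
    rse = 100.0 * reg.stderr / kdeg if kdeg > 0 else float("nan")
    return FitResult(
        estimates={"kdeg": float(kdeg), "c0": c0},
        rse_percent={"kdeg": float(rse), "c0": float(100.0 * reg.intercept_stderr)},
        objective=float(np.sum(resid**2)),
        convergence={"method": "log-linear least squares", "success": True},
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# Cellular TD model, simultaneous pooled fit
# ---------------------------------------------------------------------------

def default_td_init(data: ViabilityDataset) -> TDParams:
    """Data-driven starting values for the nine TD parameters.

    The growth rate comes from a log-linear prefit on the control arm,
    baseline is 100%, the Hill half-max constants start at the midpoint of
    the tested concentration ranges, and both growth-inhibition slopes start
    at 0.01/µM. The remaining rate constants start at generic values of the
    right order of magnitude for hour-scale cell-kill kinetics.
    """
    df = data.df
    ctrl = df[(df["c_dox0_uM"] == 0) & (df["c_dex0_uM"] == 0)]
    kg = 0.01
    if len(ctrl) >= 3 and ctrl["time_h"].nunique() >= 2:
        reg = stats.linregress(ctrl["time_h"], np.log(ctrl["viability_pct"].clip(lower=1e-6)))
        if 1e-5 < reg.slope < 1.0:
            kg = float(reg.slope)
    dox_levels = np.sort(df.loc[df["c_dox0_uM"] > 0, "c_dox0_uM"].unique())
    dex_levels = np.sort(df.loc[df["c_dex0_uM"] > 0, "c_dex0_uM"].unique())
    kc50 = float((dox_levels.min() + dox_levels.max()) / 2) if dox_levels.size else 1.0
    ic50 = float((dex_levels.min() + dex_levels.max()) / 2) if dex_levels.size else 50.0
    return TDParams(
        kg=kg, r0=100.0, s_dox=0.01, s_dex=0.01,
        kmax_dox=0.05, kc50_dox=kc50, ktr_dox=0.1, imax_dexi=0.03, ic50_dexi=ic50,
    )


def _estimable_mask(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Which TD parameters the present condition classes can inform."""
    has_any = len(df) > 0
    has_dox = bool((df["c_dox0_uM"] > 0).any())
    has_dex = bool((df["c_dex0_uM"] > 0).any())
    has_combo = bool(((df["c_dox0_uM"] > 0) & (df["c_dex0_uM"] > 0)).any())
    estimable = {
        "kg": has_any, "r0": has_any,
        "s_dox": has_dox, "kmax_dox": has_dox, "kc50_dox": has_dox, "ktr_dox": has_dox,
        "s_dex": has_dex,
        "imax_dexi": has_combo, "ic50_dexi": has_combo,
    }
    flags = []
    if not has_dox:
        flags.append("no DOX-exposed conditions: s_dox, kmax_dox, kc50_dox, ktr_dox inestimable")
    if not has_dex:
        flags.append("no DEX-exposed conditions: s_dex inestimable")
    if not has_combo:
        flags.append("no combination conditions: imax_dexi, ic50_dexi inestimable")
    return np.array([estimable[n] for n in TD_PARAM_NAMES]), flags


def _gauss_newton_rse(jac: np.ndarray, cost: float, n_obs: int) -> tuple[np.ndarray, bool]:
    """%RSE of log-scale parameters from the Gauss-Newton Hessian J'J.

    Returns (rse_percent, ok); ``ok`` is False when J'J is singular, in
    which case the fit is flagged non-identifiable rather than reporting
    meaningless standard errors.
    """
    n_par = jac.shape[1]
    dof = max(n_obs - n_par, 1)
    sigma2 = 2.0 * cost / dof
    jtj = jac.T @ jac
    if not np.all(np.isfinite(jtj)) or np.linalg.cond(jtj) > 1e12:
        return np.full(n_par, np.nan), False
    cov = sigma2 * np.linalg.inv(jtj)
    se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return 100.0 * se_log, True


def fit_td_simultaneous(
    data: ViabilityDataset,
    d: DegradationParams,
    init: TDParams | None = None,
    *,
    clamp_net_kill: bool = False,
    n_starts: int = 10,
    seed: int = 0,
    bootstrap: int = 0,
    xtol: float = 1e-10,
    ftol: float = 1e-10,
) -> FitResult:
    """Simultaneously fit the nine TD parameters to pooled viability data.

    All condition classes (control, DOX alone, DEX alone, combination) enter
    one proportional-error objective; degradation rates ``d`` are taken as
    fixed, mirroring their separate prior estimation. Multi-start (seeded,
    ±3-fold log-uniform jitter around the initial values) guards against
    local minima. Parameters a missing condition class cannot inform are
    held at their initial values and flagged.
    """
    df = data.df.reset_index(drop=True)
    if len(df) == 0:
        raise IdentifiabilityError("empty dataset")
    init = init if init is not None else default_td_init(data)
    theta0 = np.array([getattr(init, n) for n in TD_PARAM_NAMES])

    free_mask, flags = _estimable_mask(df)
    free_idx = np.where(free_mask)[0]
    if free_idx.size == 0:
        raise IdentifiabilityError("no estimable parameters: " + "; ".join(flags))

    conds = df[["c_dox0_uM", "c_dex0_uM"]].drop_duplicates().to_numpy()
    times = np.unique(df["time_h"].to_numpy(dtype=float))
    cond_lookup = {tuple(row): i for i, row in enumerate(conds)}
    time_lookup = {t: i for i, t in enumerate(times)}
    cond_of = np.array(
        [cond_lookup[(cd, cx)] for cd, cx in df[["c_dox0_uM", "c_dex0_uM"]].to_numpy()]
    )
    t_of = np.array([time_lookup[t] for t in df["time_h"].to_numpy(dtype=float)])
    obs = df["viability_pct"].to_numpy(dtype=float)
    cdox0, cdex0 = conds[:, 0], conds[:, 1]

    theta_full = theta0.copy()

    def residuals(log_free: np.ndarray) -> np.ndarray:
        theta = theta_full.copy()
        theta[free_idx] = np.exp(log_free)
        try:
            grid = _simulate_conditions_raw(
                cdox0, cdex0, theta, d.kdeg_dox, d.kdeg_dex, times,
                clamp_net_kill=clamp_net_kill,
            )
        except IntegrationError:
            return np.full(obs.size, 1e6)
        pred = np.maximum(grid[cond_of, t_of], _PRED_FLOOR)
        return (obs - pred) / pred

    lb = np.log([_TD_BOUNDS[TD_PARAM_NAMES[i]][0] for i in free_idx])
    ub = np.log([_TD_BOUNDS[TD_PARAM_NAMES[i]][1] for i in free_idx])
    x0 = np.clip(np.log(theta0[free_idx]), lb, ub)

    rng = np.random.default_rng(seed)
    best = None
    nfev_total = 0
    for start in range(max(n_starts, 1)):
        x_start = x0 if start == 0 else np.clip(
            x0 + rng.uniform(-np.log(3.0), np.log(3.0), size=x0.size), lb, ub
        )
        sol = least_squares(
            residuals, x_start, bounds=(lb, ub), method="trf",
            xtol=xtol, ftol=ftol, gtol=1e-12,
        )
        nfev_total += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    theta_hat = theta_full.copy()
    theta_hat[free_idx] = np.exp(best.x)
    rse_free, rse_ok = _gauss_newton_rse(best.jac, best.cost, obs.size)
    if not rse_ok:
        flags = flags + [
            "singular Gauss-Newton Hessian: standard errors withheld (non-identifiable fit)"
        ]

    estimates = {n: float(theta_hat[i]) for i, n in enumerate(TD_PARAM_NAMES)}
    rse = {n: float("nan") for n in TD_PARAM_NAMES}
    for j, i in enumerate(free_idx):
        rse[TD_PARAM_NAMES[i]] = float(rse_free[j])
    fixed = {TD_PARAM_NAMES[i]: float(theta0[i]) for i in np.where(~free_mask)[0]}

    convergence = {
        "success": bool(best.success),
        "status": int(best.status),
        "nfev": int(nfev_total),
        "n_starts": int(max(n_starts, 1)),
        "cost": float(best.cost),
        "optimality": float(best.optimality),
        "free_parameters": [TD_PARAM_NAMES[i] for i in free_idx],
    }
    result = FitResult(
        estimates=estimates,
        rse_percent=rse,
        objective=float(best.cost),
        convergence=convergence,
        residuals=residuals(best.x),
        fixed=fixed,
        flags=flags,
        seed=seed,
    )
    if bootstrap > 0:
        result.convergence["bootstrap_rse"] = _bootstrap_td_rse(
            df, d, result, free_idx, clamp_net_kill, bootstrap, seed,
        )
    return result


def _bootstrap_td_rse(df, d, result, free_idx, clamp, n_boot, seed) -> dict:
    """Seeded replicate-level bootstrap %RSE, for cross-checking the
    asymptotic standard errors."""
    rng = np.random.default_rng(seed + 1)
    start = TDParams(**result.estimates)
    draws = {TD_PARAM_NAMES[i]: [] for i in free_idx}
    for _ in range(n_boot):
        parts = []
        for _, grp in df.groupby(["c_dox0_uM", "c_dex0_uM", "time_h"]):
            take = rng.integers(0, len(grp), size=len(grp))
            parts.append(grp.iloc[take])
        boot = ViabilityDataset(pd.concat(parts, ignore_index=True))
        try:
            fit = fit_td_simultaneous(
                boot, d, init=start, clamp_net_kill=clamp, n_starts=1,
                seed=int(rng.integers(0, 2**31 - 1)), xtol=1e-8, ftol=1e-8,
            )
        except (IdentifiabilityError, IntegrationError):
            continue
        for i in free_idx:
            draws[TD_PARAM_NAMES[i]].append(fit.estimates[TD_PARAM_NAMES[i]])
    return {
        name: float(100.0 * np.std(v, ddof=1) / np.mean(v)) if len(v) > 2 else None
        for name, v in draws.items()
    }


# ---------------------------------------------------------------------------
# DEX PK
# ---------------------------------------------------------------------------

_PK_PARAM_NAMES = ("kel", "k12", "k21", "v")
_PK_BOUNDS = {
    "kel": (1e-8, 1e3), "k12": (1e-8, 1e3), "k21": (1e-8, 1e3), "v": (1e-2, 1e4),
}
# Distribution rates this small relative to elimination mean the peripheral
# compartment carries no information (one-compartment collapse).
_PK_COLLAPSE_FRACTION = 1e-3


def fit_pk_dex(
    data: pd.DataFrame,
    init: PKParamsDEX | None = None,
    *,
    infusion_duration_h: float = 0.25,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit the 2-compartment DEX PK model to pooled concentration data.

    ``data`` needs columns ``dose_mg_per_m2``, ``time_h``, ``conc_mg_L``
    and optionally ``bsa_m2`` (default 1.8). Each dose level is modeled as a
    single 15-min intravenous infusion starting at t = 0; all dose levels
    are fit jointly under a proportional-error model.
    """
    required = {"dose_mg_per_m2", "time_h", "conc_mg_L"}
    if not required.issubset(data.columns):
        raise ValueError(f"PK table must contain columns {sorted(required)}")
    df = data.reset_index(drop=True)
    if df["time_h"].nunique() < 4:
        raise IdentifiabilityError(
            "fewer distinct sampling times than PK parameters; "
            "a 2-compartment model cannot be identified"
        )
    bsa = df["bsa_m2"] if "bsa_m2" in df.columns else pd.Series(1.8, index=df.index)
    init = init if init is not None else PKParamsDEX(kel=0.5, k12=0.5, k21=0.5, v=20.0)
    theta0 = np.array([getattr(init, n) for n in _PK_PARAM_NAMES])
    obs = df["conc_mg_L"].to_numpy(dtype=float)

    groups = []
    for (dose, b), grp in df.groupby([df["dose_mg_per_m2"], bsa]):
        horizon = float(grp["time_h"].max()) + 1.0
        reg = build_regimen(
            "DEX", float(dose), bsa=float(b), interval_h=horizon, n_doses=1,
            duration_h=infusion_duration_h, horizon=horizon,
        )
        groups.append((reg, grp.index.to_numpy(), grp["time_h"].to_numpy(dtype=float)))

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        kel, k12, k21, v = np.exp(log_theta)
        M = np.array([[-(kel + k12), k21], [k12, -k21]])
        pred = np.empty_like(obs)
        for reg, idx, t in groups:
            try:
                sol = LinearPKSolution(M, reg, v, "DEX")
                pred[idx] = sol.conc(t)
            except np.linalg.LinAlgError:
                return np.full(obs.size, 1e6)
        pred = np.maximum(pred, _PRED_FLOOR)
        return (obs - pred) / pred

    lb = np.log([_PK_BOUNDS[n][0] for n in _PK_PARAM_NAMES])
    ub = np.log([_PK_BOUNDS[n][1] for n in _PK_PARAM_NAMES])
    x0 = np.clip(np.log(theta0), lb, ub)
    rng = np.random.default_rng(seed)
    best = None
    nfev = 0
    for start in range(max(n_starts, 1)):
        x_start = x0 if start == 0 else np.clip(
            x0 + rng.uniform(-np.log(3.0), np.log(3.0), size=4), lb, ub
        )
        sol = least_squares(residuals, x_start, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    theta_hat = np.exp(best.x)
    estimates = dict(zip(_PK_PARAM_NAMES, map(float, theta_hat)))
    rse_arr, rse_ok = _gauss_newton_rse(best.jac, best.cost, obs.size)
    flags = []
    if not rse_ok:
        flags.append("singular Gauss-Newton Hessian: standard errors withheld")
    if estimates["k12"] <= _PK_COLLAPSE_FRACTION * estimates["kel"]:
        flags.append(
            "k12 collapsed toward its lower bound: data are consistent with a "
            "reduced (one-compartment) model"
        )
    return FitResult(
        estimates=estimates,
        rse_percent=dict(zip(_PK_PARAM_NAMES, map(float, rse_arr))),
        objective=float(best.cost),
        convergence={
            "success": bool(best.success), "status": int(best.status),
            "nfev": int(nfev), "n_starts": int(max(n_starts, 1)),
            "cost": float(best.cost),
        },
        residuals=residuals(best.x),
        flags=flags,
        seed=seed,
    )
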