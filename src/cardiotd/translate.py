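"""In vitro-to-clinical translation of the cellular TD model.

Clinical infusion regimens are simulated through the compartmental PK
models, plasma concentrations (mg/L) are converted to µM by molar mass, and
the resulting time-varying concentrations drive the cellular TD model from
an initial viability of 100%. Toxicity of a regimen is summarized as the
area under the viability-time curve (AUEC, %·h); cardioprotection of a
DEX co-administration is the ratio AUEC(DOX+DEX)/AUEC(DOX), scanned over
DEX:DOX dose ratios to locate the optimum.

Clinical simulations default to the clamped net-kill mode (the transit-chain
input is floored at zero): plasma DEX concentrations far exceed the in
vitro interaction regime, and the literal combination equation would let a
DEX excess stimulate growth through the kill chain. The literal mode
remains available and scans report both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import Regimen, build_regimen
from .model import (
    ATOL,
    RTOL,
    IntegrationError,
    LinearPKSolution,
    _pk_matrix_dex,
    _pk_matrix_dox,
    _pk_solution,
)
from .params import (
    DEX_PK_DEFAULT,
    DOX_PK_DEFAULT,
    DEFAULT_TD,
    PKParamsDEX,
    PKParamsDOX,
    TDParams,
)

__all__ = [
    "MOLAR_MASS_DOX",
    "MOLAR_MASS_DEX",
    "PopulationSpec",
    "AUECSummary",
    "SubjectResult",
    "PopulationResult",
    "ScanResult",
    "to_micromolar",
    "simulate_subject",
    "population_simulate",
    "sample_population_params",
    "auec",
    "scan_dose_ratios",
    "compare_fractionation",
]

#: Molar masses used for the plasma mg/L -> µM bridge (free base / parent).
MOLAR_MASS_DOX = 543.52  # g/mol, doxorubicin
MOLAR_MASS_DEX = 268.27  # g/mol, dexrazoxane

#: Default dense output grid for clinical TD simulations, hours.
OUTPUT_DT = 0.25
#: Tie rule for the ratio scan: smallest ratio within this fraction of the max.
TIE_FRACTION = 0.01

Q3W_H = 504.0
Q1W_H = 168.0


def to_micromolar(conc_mg_L, molar_mass: float):
    """Convert a mass concentration (mg/L) to µM: conc * 1000 / molar_mass."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    out = np.asarray(conc_mg_L, dtype=float) * 1000.0 / molar_mass
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual-population settings: size, lognormal IIV on TD parameters.

    Per-subject parameters are drawn lognormally with median equal to the
    typical value and coefficient of variation ``iiv_cv``; PK parameters
    stay at typical values (variability is applied to the TD parameters
    only).
    """

    n_subjects: int = 500
    iiv_cv: float = 0.10
    seed: int = 0
    targets: tuple[str, ...] = (
        "kg", "r0", "s_dox", "s_dex", "kmax_dox", "kc50_dox", "ktr_dox",
        "imax_dexi", "ic50_dexi",
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.iiv_cv < 0:
            raise ValueError("iiv_cv must be >= 0")


@dataclass(frozen=True)
class AUECSummary:
    """Integrated viability exposure for one regimen over one window."""

    regimen_id: str
    auec: float  # %·h
    window: tuple[float, float]
    ratio_to_reference: float | None = None


@dataclass
class SubjectResult:
    """Dense viability profile (and driving concentrations) for one subject."""

    times: np.ndarray
    viability: np.ndarray
    c_dox_uM: np.ndarray
    c_dex_uM: np.ndarray
    clamp_net_kill: bool


@dataclass
class PopulationResult:
    times: np.ndarray
    profiles: np.ndarray  # (n_subjects, n_times)
    quantiles: dict  # {5: ..., 50: ..., 95: ...}
    parameters: pd.DataFrame


@dataclass
class ScanResult:
    table: pd.DataFrame
    optimum_ratio: float
    window: tuple[float, float]
    clamp_net_kill: bool
    summaries: list = field(default_factory=list)


def _shared_horizon(reg_dox: Regimen, reg_dex: Regimen) -> float:
    h = max(reg_dox.horizon, reg_dex.horizon)
    return h


def _with_horizon(reg: Regimen, horizon: float) -> Regimen:
    if reg.horizon == horizon:
        return reg
    return Regimen(events=reg.events, bsa=reg.bsa, horizon=horizon)


def simulate_subject(
    reg_dox: Regimen,
    reg_dex: Regimen,
    pk_dox: PKParamsDOX = DOX_PK_DEFAULT,
    pk_dex: PKParamsDEX = DEX_PK_DEFAULT,
    td: TDParams = DEFAULT_TD,
    *,
    r0: float = 100.0,
    clamp_net_kill: bool = True,
    dt: float = OUTPUT_DT,
) -> SubjectResult:
    """Drive the cellular TD model with simulated plasma concentrations.

    Both PK models are solved piecewise-analytically; plasma mg/L is
    converted to µM by molar mass, and the TD system is integrated from
    (R, K1..K3) = (``r0``, 0, 0, 0) over the shared regimen horizon on a
    dense ``dt`` grid. The clinical baseline is 100% viability by default
    (the in vitro fitted baseline is an assay property, not physiology).

    As in vitro, the DEX anti-kill arm is active only when the subject
    actually receives DOX; a DEX-only regimen reduces to growth inhibition.
    """
    horizon = _shared_horizon(reg_dox, reg_dex)
    sol_dox = _pk_solution(_with_horizon(reg_dox, horizon), _pk_matrix_dox(pk_dox),
                           pk_dox.v, "DOX")
    sol_dex = _pk_solution(_with_horizon(reg_dex, horizon), _pk_matrix_dex(pk_dex),
                           pk_dex.v, "DEX")
    dox_present = reg_dox.total_dose() > 0

    grid = np.arange(0.0, horizon + dt / 2, dt)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    cuts = np.unique(np.concatenate([sol_dox.breaks, sol_dex.breaks, [0.0, horizon]]))
    cuts = cuts[(cuts >= 0.0) & (cuts <= horizon)]

    kg, sdox, sdex = td.kg, td.s_dox, td.s_dex
    kmax, kc50, ktr = td.kmax_dox, td.kc50_dox, td.ktr_dox
    imax, ic50 = td.imax_dexi, td.ic50_dexi
    f_dox = 1000.0 / MOLAR_MASS_DOX / pk_dox.v
    f_dex = 1000.0 / MOLAR_MASS_DEX / pk_dex.v

    def rhs(t, y):
        r, k1, k2, k3 = y
        cd = max(sol_dox.amounts(t)[0, 0], 0.0) * f_dox
        cx = max(sol_dex.amounts(t)[0, 0], 0.0) * f_dex
        u = kmax * cd / (kc50 + cd)
        if dox_present:
            u -= imax * cx / (ic50 + cx)
        if clamp_net_kill and u < 0.0:
            u = 0.0
        growth = (1.0 - (sdox * cd + sdex * cx)) * kg * r
        return (growth - k3 * r, ktr * (u - k1), ktr * (k1 - k2), ktr * (k2 - k3))

    y = np.array([r0, 0.0, 0.0, 0.0])
    via = np.empty_like(grid)
    via[0] = r0
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        sel = (grid > t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[sel], [t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        rtol=RTOL, atol=ATOL)
        if not sol.success:
            raise IntegrationError(
                f"clinical TD integration failed on [{t0}, {t1}] h: {sol.message}"
            )
        via[sel] = sol.y[0][np.isin(t_eval, grid[sel])]
        y = sol.y[:, -1]

    return SubjectResult(
        times=grid,
        viability=via,
        c_dox_uM=to_micromolar(sol_dox.conc(grid), MOLAR_MASS_DOX),
        c_dex_uM=to_micromolar(sol_dex.conc(grid), MOLAR_MASS_DEX),
        clamp_net_kill=clamp_net_kill,
    )


def sample_population_params(spec: PopulationSpec, td: TDParams = DEFAULT_TD) -> pd.DataFrame:
    """Draw per-subject TD parameter sets (lognormal, median = typical)."""
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.iiv_cv**2))
    rows = {}
    for name in spec.targets:
        typical = getattr(td, name)
        rows[name] = typical * np.exp(sigma * rng.standard_normal(spec.n_subjects))
    for name in set(
        ("kg", "r0", "s_dox", "s_dex", "kmax_dox", "kc50_dox", "ktr_dox",
         "imax_dexi", "ic50_dexi")
    ) - set(spec.targets):
        rows[name] = np.full(spec.n_subjects, getattr(td, name))
    return pd.DataFrame(rows)


def population_simulate(
    spec: PopulationSpec,
    reg_dox: Regimen,
    reg_dex: Regimen,
    pk_dox: PKParamsDOX = DOX_PK_DEFAULT,
    pk_dex: PKParamsDEX = DEX_PK_DEFAULT,
    td: TDParams = DEFAULT_TD,
    *,
    r0: float = 100.0,
    clamp_net_kill: bool = True,
    dt: float = OUTPUT_DT,
) -> PopulationResult:
    """Virtual-population TD simulation with lognormal IIV on TD parameters.

    Returns every subject profile plus 5/50/95 percentile bands. With
    ``iiv_cv = 0`` all subjects coincide with the typical subject.
    """
    draws = sample_population_params(spec, td)
    profiles = []
    times = None
    for _, row in draws.iterrows():
        # r0 variability scales the physiological baseline, not the assay one
        td_i = TDParams(**{k: float(row[k]) for k in draws.columns})
        r0_i = r0 * float(row["r0"]) / td.r0 if "r0" in spec.targets else r0
        res = simulate_subject(
            reg_dox, reg_dex, pk_dox, pk_dex, td_i,
            r0=r0_i, clamp_net_kill=clamp_net_kill, dt=dt,
        )
        times = res.times
        profiles.append(res.viability)
    profiles = np.asarray(profiles)
    quantiles = {
        q: np.percentile(profiles, q, axis=0) for q in (5, 50, 95)
    }
    return PopulationResult(times=times, profiles=profiles, quantiles=quantiles,
                            parameters=draws)


def auec(times, viability, t_start: float, t_end: float) -> float:
    """Area under the viability-time curve over [t_start, t_end], %·h.

    Trapezoidal rule on the dense solver grid, with the window endpoints
    interpolated onto the grid. The window must lie inside the profile.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(viability, dtype=float)
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9 or t_end <= t_start:
        raise ValueError("AUEC window must be non-empty and inside the profile")
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inner], [t_end]])
    vv = np.concatenate([[np.interp(t_start, t, v)], v[inner], [np.interp(t_end, t, v)]])
    return float(np.trapezoid(vv, tt))


def _optimum_ratio(ratios: np.ndarray, values: np.ndarray) -> float:
    """Smallest ratio whose AUEC ratio is within TIE_FRACTION of the max."""
    vmax = np.max(values)
    ok = values >= vmax * (1.0 - TIE_FRACTION)
    return float(np.min(ratios[ok]))


def scan_dose_ratios(
    dox_dose_per_m2: float = 50.0,
    ratios=(0.0, 1.0, 5.0, 10.0, 20.0, 50.0),
    n_cycles: int = 3,
    interval_h: float = Q3W_H,
    *,
    bsa: float = 1.8,
    infusion_duration_h: float = 0.25,
    pk_dox: PKParamsDOX = DOX_PK_DEFAULT,
    pk_dex: PKParamsDEX = DEX_PK_DEFAULT,
    td: TDParams = DEFAULT_TD,
    r0: float = 100.0,
    clamp_net_kill: bool = True,
    include_literal: bool = True,
    mode: str = "typical",
    pop_spec: PopulationSpec | None = None,
    dt: float = OUTPUT_DT,
) -> ScanResult:
    """Scan DEX:DOX dose ratios for the maximally cardioprotective one.

    For each ratio r, DEX is co-administered at ``r * dox_dose_per_m2`` on
    the same schedule and AUEC(DOX+DEX)/AUEC(DOX) over the full horizon
    quantifies protection (1 = no protection; larger = more viability
    preserved). The optimum is the smallest ratio within 1% of the maximal
    AUEC ratio, so that jointly-maximal plateaus resolve to the lowest DEX
    burden. ``mode="population"`` repeats the scan per virtual subject and
    reports the median (with 5/95 percentiles) of paired per-subject AUEC
    ratios.
    """
    if mode not in ("typical", "population"):
        raise ValueError("mode must be 'typical' or 'population'")
    horizon = n_cycles * interval_h
    window = (0.0, horizon)
    reg_dox = build_regimen("DOX", dox_dose_per_m2, bsa, interval_h, n_cycles,
                            infusion_duration_h, horizon=horizon)

    def regimen_dex(ratio: float) -> Regimen:
        return build_regimen("DEX", ratio * dox_dose_per_m2, bsa, interval_h,
                             n_cycles, infusion_duration_h, horizon=horizon)

    rows = []
    summaries = []
    if mode == "typical":
        ref = simulate_subject(reg_dox, regimen_dex(0.0), pk_dox, pk_dex, td,
                               r0=r0, clamp_net_kill=clamp_net_kill, dt=dt)
        auec_dox = auec(ref.times, ref.viability, *window)
        ref_lit = None
        if include_literal:
            ref_lit = simulate_subject(reg_dox, regimen_dex(0.0), pk_dox, pk_dex, td,
                                       r0=r0, clamp_net_kill=False, dt=dt)
            auec_dox_lit = auec(ref_lit.times, ref_lit.viability, *window)
        for ratio in ratios:
            combo = simulate_subject(reg_dox, regimen_dex(ratio), pk_dox, pk_dex, td,
                                     r0=r0, clamp_net_kill=clamp_net_kill, dt=dt)
            a = auec(combo.times, combo.viability, *window)
            row = {
                "ratio": float(ratio),
                "dex_dose_per_m2": float(ratio * dox_dose_per_m2),
                "auec_dox": auec_dox,
                "auec_combo": a,
                "auec_ratio": a / auec_dox,
            }
            if include_literal:
                combo_lit = simulate_subject(
                    reg_dox, regimen_dex(ratio), pk_dox, pk_dex, td,
                    r0=r0, clamp_net_kill=False, dt=dt,
                )
                row["auec_ratio_literal"] = (
                    auec(combo_lit.times, combo_lit.viability, *window) / auec_dox_lit
                )
            rows.append(row)
            summaries.append(AUECSummary(
                regimen_id=f"DOX {dox_dose_per_m2:g} + DEX ratio {ratio:g}",
                auec=a, window=window, ratio_to_reference=a / auec_dox,
            ))
    else:
        spec = pop_spec if pop_spec is not None else PopulationSpec()
        draws = sample_population_params(spec, td)
        ratio_mat = np.empty((spec.n_subjects, len(ratios)))
        for i, (_, prow) in enumerate(draws.iterrows()):
            td_i = TDParams(**{k: float(prow[k]) for k in draws.columns})
            r0_i = r0 * float(prow["r0"]) / td.r0 if "r0" in spec.targets else r0
            ref = simulate_subject(reg_dox, regimen_dex(0.0), pk_dox, pk_dex, td_i,
                                   r0=r0_i, clamp_net_kill=clamp_net_kill, dt=dt)
            a0 = auec(ref.times, ref.viability, *window)
            for j, ratio in enumerate(ratios):
                combo = simulate_subject(reg_dox, regimen_dex(ratio), pk_dox, pk_dex,
                                         td_i, r0=r0_i,
                                         clamp_net_kill=clamp_net_kill, dt=dt)
                ratio_mat[i, j] = auec(combo.times, combo.viability, *window) / a0
        for j, ratio in enumerate(ratios):
            rows.append({
                "ratio": float(ratio),
                "dex_dose_per_m2": float(ratio * dox_dose_per_m2),
                "auec_ratio": float(np.median(ratio_mat[:, j])),
                "auec_ratio_p5": float(np.percentile(ratio_mat[:, j], 5)),
                "auec_ratio_p95": float(np.percentile(ratio_mat[:, j], 95)),
            })

    table = pd.DataFrame(rows)
    optimum = _optimum_ratio(table["ratio"].to_numpy(), table["auec_ratio"].to_numpy())
    return ScanResult(table=table, optimum_ratio=optimum, window=window,
                      clamp_net_kill=clamp_net_kill, summaries=summaries)


def compare_fractionation(
    dox_q3w_per_m2: float = 50.0,
    dox_q1w_per_m2: float = 16.67,
    dex_ratio: float = 10.0,
    *,
    n_weeks: int = 9,
    bsa: float = 1.8,
    pk_dox: PKParamsDOX = DOX_PK_DEFAULT,
    pk_dex: PKParamsDEX = DEX_PK_DEFAULT,
    td: TDParams = DEFAULT_TD,
    r0: float = 100.0,
    clamp_net_kill: bool = True,
    dt: float = OUTPUT_DT,
) -> pd.DataFrame:
    """Compare Q3W against weekly dose-fractionated DOX, with and without DEX.

    Four arms (Q3W, Q3W+DEX, Q1W, Q1W+DEX) at matched cumulative DOX dose
    are simulated over ``n_weeks`` weeks; AUEC is reported over the first
    cycle (3 weeks) and the full horizon, with the best (highest-viability)
    arm flagged per window and near-ties (within 1%) marked.
    """
    horizon = n_weeks * Q1W_H
    n_q3w = n_weeks // 3
    n_q1w = n_weeks
    arms = {
        "Q3W": (build_regimen("DOX", dox_q3w_per_m2, bsa, Q3W_H, n_q3w, horizon=horizon),
                build_regimen("DEX", 0.0, bsa, Q3W_H, n_q3w, horizon=horizon)),
        "Q3W+DEX": (build_regimen("DOX", dox_q3w_per_m2, bsa, Q3W_H, n_q3w, horizon=horizon),
                    build_regimen("DEX", dex_ratio * dox_q3w_per_m2, bsa, Q3W_H, n_q3w,
                                  horizon=horizon)),
        "Q1W": (build_regimen("DOX", dox_q1w_per_m2, bsa, Q1W_H, n_q1w, horizon=horizon),
                build_regimen("DEX", 0.0, bsa, Q1W_H, n_q1w, horizon=horizon)),
        "Q1W+DEX": (build_regimen("DOX", dox_q1w_per_m2, bsa, Q1W_H, n_q1w, horizon=horizon),
                    build_regimen("DEX", dex_ratio * dox_q1w_per_m2, bsa, Q1W_H, n_q1w,
                                  horizon=horizon)),
    }
    windows = {"cycle1_3wk": (0.0, 3 * Q1W_H), f"full_{n_weeks}wk": (0.0, horizon)}
    results = {
        name: simulate_subject(rd, rx, pk_dox, pk_dex, td, r0=r0,
                               clamp_net_kill=clamp_net_kill, dt=dt)
        for name, (rd, rx) in arms.items()
    }
    rows = []
    for wname, (t0, t1) in windows.items():
        vals = {name: auec(res.times, res.viability, t0, t1)
                for name, res in results.items()}
        best = max(vals, key=vals.get)
        for name, a in vals.items():
            rows.append({
                "arm": name,
                "window": wname,
                "t_start_h": t0,
                "t_end_h": t1,
                "auec": a,
                "best": name == best,
                "within_1pct_of_best": a >= vals[best] * (1.0 - TIE_FRACTION),
            })
    return pd.DataFrame(rows)
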