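"""Core toxicodynamic and pharmacokinetic model: closed forms, ODE
right-hand sides and forward simulators.

The cellular TD model couples exponential AC16 growth with a linear
growth-inhibition term for each drug and a delayed, Hill-type stimulation of
cell death by DOX, routed through three transit compartments; DEX
antagonizes the DOX death signal through a second Hill function acting on
the input of the transit chain:

    dR/dt  = (1 - (s_dox*C_DOX + s_dex*C_DEX)) * kg * R - K3 * R
    dK1/dt = ktr * ((K_DOX - K_DEXi) - K1)
    dK2/dt = ktr * (K1 - K2)
    dK3/dt = ktr * (K2 - K3)

with K_DOX = kmax*C/(kc50 + C) and K_DEXi = imax*C/(ic50 + C). Setting
C_DEX = 0 recovers the single-agent DOX model; C_DOX = 0 with the kill chain
at zero recovers the single-agent DEX model.

In vitro, drug concentrations decay mono-exponentially in the culture medium
and are fed to the TD system in closed form (not co-integrated). Clinically,
plasma concentrations come from linear mammillary compartment models solved
by eigendecomposition (exact piecewise-analytic infusion handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dosing import Regimen
from .params import DegradationParams, PKParamsDEX, PKParamsDOX, TDParams

__all__ = [
    "IntegrationError",
    "TDState",
    "InVitroCondition",
    "ConcentrationProfile",
    "conc_at",
    "dox_kill_rate",
    "dex_inhibition_rate",
    "control_viability",
    "td_rhs",
    "simulate_invitro",
    "simulate_conditions",
    "simulate_pk_dox",
    "simulate_pk_dex",
    "LinearPKSolution",
]

#: Solver contract for all stiff-capable integrations in this package.
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when an ODE solve fails; carries solver diagnostics."""


@dataclass
class TDState:
    """State of the cellular TD system.

    ``r`` is percent viability; ``k1``..``k3`` are the transit-compartment
    kill signals (1/h), all starting at zero.
    """

    r: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("viability must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.k1, self.k2, self.k3], dtype=float)


@dataclass(frozen=True)
class InVitroCondition:
    """One in vitro treatment arm: initial drug levels and sampling design."""

    c_dox0: float
    c_dex0: float
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 48.0, 72.0)
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.c_dox0 < 0 or self.c_dex0 < 0:
            raise ValueError("initial concentrations must be >= 0")
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        if list(tp) != sorted(tp) or (tp and tp[0] != 0.0):
            raise ValueError("timepoints must be sorted and start at 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def label(self) -> str:
        if self.c_dox0 == 0 and self.c_dex0 == 0:
            return "control"
        if self.c_dex0 == 0:
            return f"DOX {self.c_dox0:g} uM"
        if self.c_dox0 == 0:
            return f"DEX {self.c_dex0:g} uM"
        return f"DOX {self.c_dox0:g} uM + DEX {self.c_dex0:g} uM"


@dataclass(frozen=True)
class ConcentrationProfile:
    """A drug concentration time-course on a strictly increasing grid."""

    drug: str
    times: np.ndarray
    conc: np.ndarray
    unit: str = "mg/L"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if c.shape != t.shape:
            raise ValueError("conc must match times in shape")
        if np.any(c < -ATOL):
            raise ValueError("concentrations must be >= 0")


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def conc_at(c0: float, kdeg: float, t) -> np.ndarray | float:
    """Medium concentration under first-order degradation: c0*exp(-kdeg*t).

    Vectorized over ``t`` (hours). This closed form is what drives the in
    vitro TD model; co-integrating the degradation ODE gives the same
    trajectory to solver precision.
    """
    if c0 < 0 or kdeg < 0:
        raise ValueError("c0 and kdeg must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = c0 * np.exp(-kdeg * t)
    return float(out) if out.ndim == 0 else out


def dox_kill_rate(c_dox, p: TDParams):
    """Hill (Emax) stimulation of death by DOX: kmax*C/(kc50 + C), 1/h."""
    c = np.asarray(c_dox, dtype=float)
    out = p.kmax_dox * c / (p.kc50_dox + c)
    return float(out) if out.ndim == 0 else out


def dex_inhibition_rate(c_dex, p: TDParams):
    """Hill inhibition of the DOX death signal by DEX: imax*C/(ic50 + C), 1/h."""
    c = np.asarray(c_dex, dtype=float)
    out = p.imax_dexi * c / (p.ic50_dexi + c)
    return float(out) if out.ndim == 0 else out


def control_viability(t, p: TDParams):
    """Untreated AC16 viability: R0*exp(kg*t), percent."""
    t = np.asarray(t, dtype=float)
    out = p.r0 * np.exp(p.kg * t)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# TD right-hand side and in vitro simulator
# ---------------------------------------------------------------------------

def td_rhs(
    state,
    c_dox: float,
    c_dex: float,
    p: TDParams,
    clamp_net_kill: bool = False,
) -> np.ndarray:
    """Time derivative of (R, K1, K2, K3) at given drug concentrations.

    The transit-chain input is ``K_DOX - K_DEXi``; with ``clamp_net_kill``
    the input is floored at zero so that a DEX excess can never stimulate
    growth through the kill chain (relevant clinically, where DEX plasma
    levels far exceed the in vitro interaction regime).
    """
    if isinstance(state, TDState):
        state = state.as_array()
    r, k1, k2, k3 = state
    if c_dox < 0 or c_dex < 0:
        raise ValueError("concentrations must be >= 0")
    u = dox_kill_rate(c_dox, p) - dex_inhibition_rate(c_dex, p)
    if clamp_net_kill:
        u = max(u, 0.0)
    growth = (1.0 - (p.s_dox * c_dox + p.s_dex * c_dex)) * p.kg * r
    return np.array(
        [
            growth - k3 * r,
            p.ktr_dox * (u - k1),
            p.ktr_dox * (k1 - k2),
            p.ktr_dox * (k2 - k3),
        ]
    )


def _simulate_conditions_raw(
    c_dox0: np.ndarray,
    c_dex0: np.ndarray,
    theta: np.ndarray,
    kdeg_dox: float,
    kdeg_dex: float,
    times: np.ndarray,
    clamp_net_kill: bool = False,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> np.ndarray:
    """Vectorized in vitro simulation over many conditions at once.

    ``theta`` is the TD parameter vector in the canonical order
    (kg, r0, s_dox, s_dex, kmax, kc50, ktr, imax, ic50). All conditions are
    stacked into a single ODE system (4 states per condition), which keeps
    the pooled-fit objective cheap. Returns viability, shape
    (n_conditions, n_times).
    """
    kg, r0, s_dox, s_dex, kmax, kc50, ktr, imax, ic50 = theta
    cdox0 = np.asarray(c_dox0, dtype=float)
    cdex0 = np.asarray(c_dex0, dtype=float)
    n = cdox0.size
    times = np.asarray(times, dtype=float)
    tmax = times[-1]
    # The DEX anti-kill arm exists only where a DOX death signal exists:
    # single-agent DEX conditions follow the growth-inhibition-only model
    # (kill chain identically zero), as in the single-agent equations.
    dox_present = (cdox0 > 0).astype(float)

    def rhs(t, y):
        r = y[:n]
        k1 = y[n : 2 * n]
        k2 = y[2 * n : 3 * n]
        k3 = y[3 * n :]
        cd = cdox0 * np.exp(-kdeg_dox * t)
        cx = cdex0 * np.exp(-kdeg_dex * t)
        u = kmax * cd / (kc50 + cd) - dox_present * imax * cx / (ic50 + cx)
        if clamp_net_kill:
            u = np.maximum(u, 0.0)
        growth = (1.0 - (s_dox * cd + s_dex * cx)) * kg * r
        return np.concatenate(
            [growth - k3 * r, ktr * (u - k1), ktr * (k1 - k2), ktr * (k2 - k3)]
        )

    y0 = np.concatenate([np.full(n, r0), np.zeros(3 * n)])
    if tmax == 0.0:
        return np.tile(y0[:n, None], (1, times.size))
    sol = solve_ivp(
        rhs,
        (0.0, tmax),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"in vitro TD integration failed: {sol.message}")
    return sol.y[:n, :]


def simulate_conditions(
    conditions,
    p: TDParams,
    d: DegradationParams,
    times,
    clamp_net_kill: bool = False,
) -> np.ndarray:
    """Simulate viability for a list of :class:`InVitroCondition` on a shared
    time grid. Returns an array of shape (n_conditions, n_times)."""
    theta = np.array(
        [p.kg, p.r0, p.s_dox, p.s_dex, p.kmax_dox, p.kc50_dox, p.ktr_dox,
         p.imax_dexi, p.ic50_dexi]
    )
    cdox0 = np.array([c.c_dox0 for c in conditions], dtype=float)
    cdex0 = np.array([c.c_dex0 for c in conditions], dtype=float)
    return _simulate_conditions_raw(
        cdox0, cdex0, theta, d.kdeg_dox, d.kdeg_dex, np.asarray(times, float),
        clamp_net_kill=clamp_net_kill,
    )


def simulate_invitro(
    cond: InVitroCondition,
    p: TDParams,
    d: DegradationParams,
    out_times=None,
    clamp_net_kill: bool = False,
) -> np.ndarray:
    """Simulate one in vitro condition; returns viability (%) at ``out_times``.

    Medium concentrations follow the closed-form degradation curves and act
    as a time-varying forcing on the TD ODE system.
    """
    times = np.asarray(cond.timepoints if out_times is None else out_times, dtype=float)
    return simulate_conditions([cond], p, d, times, clamp_net_kill=clamp_net_kill)[0]


# ---------------------------------------------------------------------------
# Linear mammillary PK by eigendecomposition
# ---------------------------------------------------------------------------

def _pk_matrix_dox(p: PKParamsDOX) -> np.ndarray:
    k10 = p.cl / p.v
    k12, k21 = p.q2 / p.v, p.q2 / p.v2
    k13, k31 = p.q3 / p.v, p.q3 / p.v3
    return np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )


def _pk_matrix_dex(p: PKParamsDEX) -> np.ndarray:
    return np.array(
        [
            [-(p.kel + p.k12), p.k21],
            [p.k12, -p.k21],
        ]
    )


class LinearPKSolution:
    """Piecewise-analytic solution of a linear compartment model under
    piecewise-constant infusion input.

    The system ``da/dt = M a + b(t)`` (b = infusion rate into the central
    compartment) is solved exactly on each constant-rate segment through the
    eigendecomposition of M, so concentrations can be evaluated at arbitrary
    times without step-size error. Falls back to a stiff ODE solve if M is
    numerically defective.
    """

    def __init__(self, M: np.ndarray, regimen: Regimen, v_central: float, drug: str):
        self.M = M
        self.v = v_central
        self.drug = drug
        self.horizon = regimen.horizon
        for e in regimen.events:
            if e.drug != drug:
                raise ValueError(f"regimen contains non-{drug} events")
        n = M.shape[0]
        # segment boundaries: every infusion start/end plus 0 and horizon
        cuts = {0.0, regimen.horizon}
        for e in regimen.events:
            cuts.add(e.start)
            cuts.add(min(e.end, regimen.horizon))
        self.breaks = np.array(sorted(cuts))
        if self.breaks.size == 1:  # empty regimen with zero horizon
            self.breaks = np.array([0.0, 1.0])
        w, V = np.linalg.eig(M)
        if np.linalg.cond(V) > 1e10:  # defective / near-defective matrix
            raise np.linalg.LinAlgError("PK matrix is numerically defective")
        Vinv = np.linalg.inv(V)
        self._w, self._V, self._Vinv = w, V, Vinv
        # per-segment: start, particular solution a*, eigen coefficients
        self._seg_astar = np.zeros((len(self.breaks) - 1, n), dtype=complex)
        self._seg_coef = np.zeros((len(self.breaks) - 1, n), dtype=complex)
        a = np.zeros(n)
        for i, (t0, t1) in enumerate(zip(self.breaks[:-1], self.breaks[1:])):
            rate = sum(
                e.rate for e in regimen.events if e.start <= t0 and e.end >= t1
            )
            b = np.zeros(n)
            b[0] = rate
            astar = -np.linalg.solve(M, b) if rate != 0.0 else np.zeros(n)
            coef = Vinv @ (a - astar)
            self._seg_astar[i] = astar
            self._seg_coef[i] = coef
            a = self._eval_segment(i, np.array([t1]))[:, 0].real
        self._final = a

    def _eval_segment(self, i: int, t: np.ndarray) -> np.ndarray:
        tau = t - self.breaks[i]
        ew = np.exp(np.outer(self._w, tau))  # (n, nt)
        return self._V @ (ew * self._seg_coef[i][:, None]) + self._seg_astar[i][:, None]

    def amounts(self, times) -> np.ndarray:
        """Compartment amounts (mg) at the requested times, shape (n, nt)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < 0) or np.any(t > self.horizon + 1e-9):
            raise ValueError("times must lie within [0, horizon]")
        idx = np.clip(np.searchsorted(self.breaks, t, side="right") - 1, 0,
                      len(self.breaks) - 2)
        out = np.empty((self.M.shape[0], t.size))
        for i in np.unique(idx):
            sel = idx == i
            out[:, sel] = self._eval_segment(i, t[sel]).real
        return out

    def conc(self, times):
        """Central-compartment concentration, mg/L."""
        c = np.maximum(self.amounts(times)[0] / self.v, 0.0)
        return float(c[0]) if np.isscalar(times) or np.ndim(times) == 0 else c

    def profile(self, grid) -> ConcentrationProfile:
        return ConcentrationProfile(self.drug, np.asarray(grid, float), self.conc(grid))


def _pk_solution(regimen: Regimen, M: np.ndarray, v: float, drug: str) -> LinearPKSolution:
    try:
        return LinearPKSolution(M, regimen, v, drug)
    except np.linalg.LinAlgError:
        return _OdePKSolution(M, regimen, v, drug)


class _OdePKSolution(LinearPKSolution):
    """Stiff-ODE fallback used when the rate matrix is defective (repeated
    eigenvalues with deficient eigenspace, e.g. symmetric degenerate rate
    choices); interface-compatible with :class:`LinearPKSolution`."""

    def __init__(self, M, regimen, v_central, drug):  # noqa: D107
        self.M, self.v, self.drug, self.horizon = M, v_central, drug, regimen.horizon
        self._events = regimen.events

    def amounts(self, times):
        t = np.atleast_1d(np.asarray(times, dtype=float))
        n = self.M.shape[0]

        def rhs(tt, a):
            rate = sum(e.rate for e in self._events if e.start <= tt < e.end)
            b = np.zeros(n)
            b[0] = rate
            return self.M @ a + b

        grid = np.unique(np.concatenate([t, [0.0]]))
        sol = solve_ivp(rhs, (0.0, max(grid[-1], 1e-12)), np.zeros(n), method="LSODA",
                        t_eval=grid, rtol=RTOL, atol=ATOL, max_step=0.25)
        if not sol.success:
            raise IntegrationError(f"PK integration failed: {sol.message}")
        idx = np.searchsorted(grid, t)
        return sol.y[:, idx]


def simulate_pk_dox(regimen: Regimen, p: PKParamsDOX, grid) -> ConcentrationProfile:
    """Plasma DOX concentration (mg/L) for a DOX infusion regimen.

    Linear three-compartment mammillary model with elimination (CL) from the
    central compartment; C = A1/V. Linearity implies dose-proportionality
    and superposition across cycles.
    """
    sol = _pk_solution(regimen, _pk_matrix_dox(p), p.v, "DOX")
    return sol.profile(grid)


def simulate_pk_dex(regimen: Regimen, p: PKParamsDEX, grid) -> ConcentrationProfile:
    """Plasma DEX concentration (mg/L) for a DEX infusion regimen
    (two-compartment model, rate-constant parameterization)."""
    sol = _pk_solution(regimen, _pk_matrix_dex(p), p.v, "DEX")
    return sol.profile(grid)
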