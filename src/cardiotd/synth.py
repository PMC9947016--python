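"""Seeded synthetic-data generators emulating the study designs.

These generators stand in for the original raw data, which were never
deposited. They reproduce the statistical structure the estimation code
assumes: the in vitro viability design (concentration grid, 0-72 h
sampling, triplicates), mono-exponential drug loss in culture medium, and
single-infusion clinical DEX PK profiles across a wide dose range. Noise is
multiplicative lognormal (keeps every observation positive); the default
coefficient of variation of 7.5% is a stand-in chosen to resemble typical
CCK-8 replicate scatter, not a published value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dosing import build_regimen
from .fit import ViabilityDataset
from .model import InVitroCondition, conc_at, simulate_conditions, simulate_pk_dex
from .params import DegradationParams, PKParamsDEX, TDParams

__all__ = [
    "NoiseSpec",
    "DesignSpec",
    "default_design",
    "generate_viability",
    "generate_degradation",
    "generate_dex_pk",
    "write_manifest",
]

#: Default DEX PK sampling times, hours after infusion start.
DEX_PK_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal noise: obs = pred * exp(sigma * z), z~N(0,1).

    ``sigma = ln(1 + cv)``, a small-cv approximation under which the
    empirical CV of obs/pred is ~cv. Identical seeds reproduce identical
    datasets bit-for-bit.
    """

    cv: float = 0.075
    seed: int = 0
    model: str = "proportional"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.model != "proportional":
            raise ValueError("only the proportional noise model is implemented")

    @property
    def sigma(self) -> float:
        return float(np.log1p(self.cv))

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv == 0:
            return values.copy()
        return values * np.exp(self.sigma * rng.standard_normal(values.shape))


@dataclass(frozen=True)
class DesignSpec:
    """The in vitro experimental design: concentration grids and sampling.

    Defaults follow the published design: DOX 0.5-10 µM, DEX 5-100 µM,
    combinations of 0.5 µM DOX with each DEX level, sampling at
    0/12/24/48/72 h in triplicate. The range endpoints are the study's; the
    interior levels are this package's fixed choice.
    """

    dox_levels: tuple[float, ...] = (0.5, 1.0, 2.5, 5.0, 10.0)
    dex_levels: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 100.0)
    combo_dox: float = 0.5
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 48.0, 72.0)
    replicates: int = 3

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.dox_levels + self.dex_levels) or self.combo_dox <= 0:
            raise ValueError("treatment concentrations must be > 0")
        tp = tuple(float(t) for t in self.timepoints)
        if list(tp) != sorted(tp) or tp[0] != 0.0:
            raise ValueError("timepoints must be sorted and start at 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def conditions(self) -> list[InVitroCondition]:
        """Control + DOX alone + DEX alone + combinations, in that order."""
        conds = [InVitroCondition(0.0, 0.0, self.timepoints, self.replicates)]
        conds += [
            InVitroCondition(c, 0.0, self.timepoints, self.replicates)
            for c in self.dox_levels
        ]
        conds += [
            InVitroCondition(0.0, c, self.timepoints, self.replicates)
            for c in self.dex_levels
        ]
        conds += [
            InVitroCondition(self.combo_dox, c, self.timepoints, self.replicates)
            for c in self.dex_levels
        ]
        return conds

    def n_records(self) -> int:
        return len(self.conditions()) * len(self.timepoints) * self.replicates


def default_design() -> DesignSpec:
    """The default 16-condition design (240 records in triplicate)."""
    return DesignSpec()


def generate_viability(
    design: DesignSpec,
    p: TDParams,
    d: DegradationParams,
    noise: NoiseSpec,
) -> ViabilityDataset:
    """Simulate the full in vitro design and overlay replicate noise.

    With ``noise.cv == 0`` the records equal the model predictions exactly.
    """
    conds = design.conditions()
    times = np.asarray(design.timepoints, dtype=float)
    grid = simulate_conditions(conds, p, d, times)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for i, cond in enumerate(conds):
        for j, t in enumerate(times):
            pred = np.full(design.replicates, grid[i, j])
            obs = noise.apply(pred, rng)
            for rep in range(design.replicates):
                rows.append(
                    (cond.c_dox0, cond.c_dex0, t, rep + 1, obs[rep])
                )
    df = pd.DataFrame(
        rows, columns=["c_dox0_uM", "c_dex0_uM", "time_h", "replicate", "viability_pct"]
    )
    return ViabilityDataset(df)


def generate_degradation(
    c0: float,
    kdeg: float,
    times,
    noise: NoiseSpec,
    drug: str = "DOX",
) -> pd.DataFrame:
    """Noisy mono-exponential degradation series, CSV-ready.

    Columns: ``drug``, ``time_h``, ``conc_uM``.
    """
    t = np.asarray(times, dtype=float)
    pred = conc_at(c0, kdeg, t)
    rng = np.random.default_rng(noise.seed)
    obs = noise.apply(np.atleast_1d(pred), rng)
    return pd.DataFrame({"drug": drug, "time_h": t, "conc_uM": obs})


def generate_dex_pk(
    doses_mg_per_m2,
    p: PKParamsDEX,
    bsa: float = 1.8,
    times=DEX_PK_TIMES,
    noise: NoiseSpec = NoiseSpec(cv=0.0, seed=0),
    infusion_duration_h: float = 0.25,
) -> pd.DataFrame:
    """Synthetic serum DEX concentrations after single 15-min infusions.

    Emulates a dose-ranging (50-2500 mg/m²) phase-I style dataset: one
    profile per dose level, proportional noise. Columns:
    ``dose_mg_per_m2``, ``bsa_m2``, ``time_h``, ``conc_mg_L``.
    """
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(noise.seed)
    frames = []
    for dose in doses_mg_per_m2:
        if dose < 0:
            raise ValueError("doses must be >= 0")
        horizon = float(t.max()) + 1.0
        reg = build_regimen(
            "DEX", float(dose), bsa=bsa, interval_h=horizon, n_doses=1,
            duration_h=infusion_duration_h, horizon=horizon,
        )
        conc = simulate_pk_dex(reg, p, t).conc
        frames.append(
            pd.DataFrame(
                {
                    "dose_mg_per_m2": float(dose),
                    "bsa_m2": bsa,
                    "time_h": t,
                    "conc_mg_L": noise.apply(conc, rng),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_manifest(path: str | Path, *, seed: int, generator: str, parameters: dict) -> None:
    """Record generator provenance (version, parameters, seed) next to data."""
    from . import __version__

    payload = {
        "generator": generator,
        "version": __version__,
        "seed": seed,
        "parameters": parameters,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
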