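"""Parameter sets for the cellular toxicodynamic (TD) and clinical PK models.

Units are canonical throughout the package: time in hours, in vitro
concentrations in µM, clinical amounts in mg and volumes in L, viability in
percent. Conversions happen only at module boundaries
(:func:`cardiotd.translate.to_micromolar`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = [
    "DegradationParams",
    "TDParams",
    "PKParamsDOX",
    "PKParamsDEX",
    "DEFAULT_DEGRADATION",
    "DEFAULT_TD",
    "DOX_PK_DEFAULT",
    "DEX_PK_DEFAULT",
    "params_to_json",
    "params_from_json",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class DegradationParams:
    """First-order degradation rate constants of the two drugs in culture medium.

    Both drugs are lost from cell-culture medium at 37 °C by first-order
    kinetics; the rates are assumed concentration-independent and unaffected
    by co-incubation of the other drug.

    Attributes
    ----------
    kdeg_dox : float
        Degradation rate constant of doxorubicin, 1/h.
    kdeg_dex : float
        Degradation rate constant of dexrazoxane, 1/h.
    """

    kdeg_dox: float = 0.022
    kdeg_dex: float = 0.054

    _units = {"kdeg_dox": "1/h", "kdeg_dex": "1/h"}

    def __post_init__(self) -> None:
        _require(self.kdeg_dox >= 0, "kdeg_dox must be >= 0")
        _require(self.kdeg_dex >= 0, "kdeg_dex must be >= 0")


@dataclass(frozen=True)
class TDParams:
    """The nine cellular toxicodynamic parameters for AC16 cardiomyocytes.

    The model combines exponential growth (``kg``, ``r0``), linear
    growth-inhibition slopes for each drug (``s_dox``, ``s_dex``), a
    Hill-type (Emax) stimulation of cell death by DOX delayed through three
    transit compartments (``kmax_dox``, ``kc50_dox``, ``ktr_dox``), and a
    Hill-type inhibition by DEX of DOX's death signal (``imax_dexi``,
    ``ic50_dexi``).

    ``ktr_dox`` is the transit rate constant; the mean transit time per
    compartment is its inverse, :attr:`tau_dox`.
    """

    kg: float = 0.0115  # 1/h, first-order growth rate constant
    r0: float = 101.0  # %, baseline viability
    s_dox: float = 0.167  # 1/µM, DOX growth-inhibition slope
    s_dex: float = 0.00968  # 1/µM, DEX growth-inhibition slope
    kmax_dox: float = 0.0697  # 1/h, maximal killing rate constant
    kc50_dox: float = 0.107  # µM, DOX conc. at half-maximal kill
    ktr_dox: float = 0.126  # 1/h, transit rate (1/mean transit time)
    imax_dexi: float = 0.0625  # 1/h, maximal inhibition of DOX kill by DEX
    ic50_dexi: float = 39.0  # µM, DEX conc. at half-maximal inhibition

    _units = {
        "kg": "1/h",
        "r0": "%",
        "s_dox": "1/uM",
        "s_dex": "1/uM",
        "kmax_dox": "1/h",
        "kc50_dox": "uM",
        "ktr_dox": "1/h",
        "imax_dexi": "1/h",
        "ic50_dexi": "uM",
    }

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")
        _require(0 < self.r0 <= 150, "r0 must lie in (0, 150] percent")

    @property
    def tau_dox(self) -> float:
        """Mean transit time per kill-signal compartment, h."""
        return 1.0 / self.ktr_dox

    @classmethod
    def with_tau(cls, tau_dox: float, **kwargs) -> "TDParams":
        """Construct from the mean transit time instead of the transit rate."""
        _require(tau_dox > 0, "tau_dox must be > 0")
        return cls(ktr_dox=1.0 / tau_dox, **kwargs)

    def replace(self, **kwargs) -> "TDParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PKParamsDOX:
    """Three-compartment mammillary PK parameters for doxorubicin.

    Clearance parameterization; typical values refer to a 1.8 m² subject.
    Drug enters and is eliminated from the central compartment; two
    peripheral compartments exchange with it.
    """

    cl: float = 53.3  # L/h, clearance from central
    v: float = 17.7  # L, central volume
    q2: float = 58.7  # L/h, inter-compartmental clearance, peripheral 1
    v2: float = 1830.0  # L, peripheral volume 1
    q3: float = 21.8  # L/h, inter-compartmental clearance, peripheral 2
    v3: float = 71.6  # L, peripheral volume 2

    _units = {"cl": "L/h", "v": "L", "q2": "L/h", "v2": "L", "q3": "L/h", "v3": "L"}

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")


@dataclass(frozen=True)
class PKParamsDEX:
    """Two-compartment PK parameters for dexrazoxane (rate-constant form)."""

    kel: float = 1.0  # 1/h, elimination rate constant from central
    k12: float = 1.0  # 1/h, central -> peripheral
    k21: float = 1.0  # 1/h, peripheral -> central
    v: float = 14.6  # L, central volume

    _units = {"kel": "1/h", "k12": "1/h", "k21": "1/h", "v": "L"}

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")


#: Reference degradation rates in culture medium (literature estimates).
DEFAULT_DEGRADATION = DegradationParams()
#: Reference cellular TD parameter set estimated on AC16 cardiomyocytes.
DEFAULT_TD = TDParams()
#: Published clinical 3-compartment DOX PK typical values (1.8 m² subject).
DOX_PK_DEFAULT = PKParamsDOX()
#: Clinical 2-compartment DEX PK typical values.
DEX_PK_DEFAULT = PKParamsDEX()

_PARAM_CLASSES = {
    "DegradationParams": DegradationParams,
    "TDParams": TDParams,
    "PKParamsDOX": PKParamsDOX,
    "PKParamsDEX": PKParamsDEX,
}


def params_to_json(params, path: str | Path | None = None) -> str:
    """Serialize a parameter set to JSON with explicit unit annotations.

    Each field is written as ``{"value": x, "unit": u}`` together with the
    class name, so files are self-describing and round-trip through
    :func:`params_from_json`.
    """
    cls = type(params)
    payload = {
        "class": cls.__name__,
        "parameters": {
            f.name: {"value": getattr(params, f.name), "unit": cls._units[f.name]}
            for f in fields(params)
        },
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_json(source: str | Path):
    """Load a parameter set written by :func:`params_to_json`.

    Accepts a path or a JSON string; plain ``{"name": value}`` parameter
    maps are accepted as well.
    """
    text = str(source)
    p = Path(text) if len(text) < 4096 and "\n" not in text and "{" not in text else None
    if p is not None and p.exists():
        text = p.read_text()
    payload = json.loads(text)
    cls = _PARAM_CLASSES[payload["class"]]
    kwargs = {}
    for name, entry in payload["parameters"].items():
        value = entry["value"] if isinstance(entry, dict) else entry
        if isinstance(entry, dict) and "unit" in entry and entry["unit"] != cls._units[name]:
            raise ValueError(
                f"unit mismatch for {name}: file says {entry['unit']!r}, "
                f"expected {cls._units[name]!r}"
            )
        kwargs[name] = value
    return cls(**kwargs)
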