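"""Model parameters for the tumor-induced bone disease (TIBD) population model.

The model carries 36 named constants: 23 for the bone-resident-cell
(osteoblast/osteoclast) regulatory core, 6 for bone formation/resorption,
6 for tumor dynamics, and 1 for drug (zoledronic acid) action.  Six of them
are structural constants that are never adjusted during calibration; the
remaining 30 are adjustable.  Five of the adjustable parameters are
tumor-type specific and may be overridden per tumor line.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "TumorTypeOverrides",
    "PARAM_NAMES",
    "PARAM_UNITS",
    "FIXED_PARAMS",
    "TUMOR_PARAMS",
    "ADJUSTABLE_PARAMS",
]


@dataclass
class ModelParameters:
    """The 36 constants of the TIBD model, with literature defaults.

    Bone-resident-cell block (osteoblast/osteoclast regulatory core):

    Cs    pM        active-OC level at which pi_C = (1 + fO)/2
    DA    1/day     TGF-beta-enhanced OC death rate
    dB    1/day     differentiation rate of responding OBs
    DC    pM/day    differentiation rate of OC precursors
    DR    pM/day    differentiation rate of OB progenitors
    fO    --        minimum TGF-beta receptor occupancy (fixed)
    IL    pM/day    constant injected-RANKL rate (fixed)
    IO    pM/day    constant injected-OPG rate (fixed)
    IP    pM/day    constant injected-PTH/PTHrP rate (fixed)
    K     pM        fixed RANK receptor concentration
    k1    1/pM/day  OPG-RANKL binding
    k2    1/day     OPG-RANKL unbinding
    k3    1/pM/day  RANK-RANKL binding
    k4    1/day     RANK-RANKL unbinding
    k5    1/pM/day  PTH/PTHrP receptor binding
    k6    1/day     PTH/PTHrP receptor unbinding
    kB    1/day     active-OB death rate
    KLP   --        maximum RANKL per cell surface
    kO    1/day     OPG elimination rate
    KOP   1/day     minimal per-cell OPG production
    kP    1/day     PTH/PTHrP degradation rate
    rL    pM/day    net RANKL production/degradation rate
    SP    pM/day    systemic PTH synthesis rate

    Bone block:

    k1B   1/day     minimum per-cell OB bone production rate
    k2B   pM        [B] at which the per-cell production rate doubles
    nB    --        Hill coefficient for bone production (fixed)
    k1C   1/day     minimum per-cell OC bone resorption rate
    K2C   pM        [C] at which the per-cell resorption rate doubles
    nC    --        Hill coefficient for bone resorption (fixed)

    Tumor block:

    kTdiv   1/day     basal tumor division rate
    kTtgfb  1/day     TGF-beta-enhanced tumor division rate
    kTdth   1/day     tumor death rate
    M       pM        tumor carrying capacity
    kTpthrp 1/day     PTHrP production rate by tumor cells
    kTB     1/pM/day  tumor-induced active-OB loss rate

    Drug block:

    kZC   1/day     ZA-induced active-OC death rate (per unit reference dose)
    """

    Cs: float = 0.005
    DA: float = 0.7
    dB: float = 0.7
    DC: float = 0.0021
    DR: float = 0.0007
    fO: float = 0.05
    IL: float = 0.0
    IO: float = 0.0
    IP: float = 0.0
    K: float = 10.0
    k1: float = 0.01
    k2: float = 10.0
    k3: float = 0.00058
    k4: float = 0.017
    k5: float = 0.02
    k6: float = 3.0
    kB: float = 0.013
    KLP: float = 3.0e6
    kO: float = 0.35
    KOP: float = 2.0e5
    kP: float = 86.0
    rL: float = 1000.0
    SP: float = 250.0
    k1B: float = 3.36e6
    k2B: float = 0.1
    nB: float = 1.0
    k1C: float = 1.0e6
    K2C: float = 0.001
    nC: float = 1.0
    kTdiv: float = 1.0
    kTtgfb: float = 0.1
    kTdth: float = 0.6
    M: float = 0.9
    kTpthrp: float = 500.0
    kTB: float = 2.0
    kZC: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"parameter {name} must be non-negative, got {v!r}")
        if self.nB < 1.0 or self.nC < 1.0:
            raise ValueError("Hill coefficients nB and nC must be >= 1")

    # -- conversions -----------------------------------------------------
    def as_dict(self) -> Dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    def replace(self, **changes: float) -> "ModelParameters":
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def with_overrides(self, overrides: "TumorTypeOverrides") -> "ModelParameters":
        return self.replace(**overrides.values)

    def is_fixed(self, name: str) -> bool:
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return name in FIXED_PARAMS

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        p = str(path)
        if p.endswith((".yml", ".yaml")):
            return cls.from_yaml(path)
        return cls.from_json(path)


#: canonical ordering used for packed parameter vectors
PARAM_NAMES = tuple(f.name for f in dataclasses.fields(ModelParameters))

PARAM_UNITS: Dict[str, str] = {
    "Cs": "pM", "DA": "1/day", "dB": "1/day", "DC": "pM/day", "DR": "pM/day",
    "fO": "", "IL": "pM/day", "IO": "pM/day", "IP": "pM/day", "K": "pM",
    "k1": "1/pM/day", "k2": "1/day", "k3": "1/pM/day", "k4": "1/day",
    "k5": "1/pM/day", "k6": "1/day", "kB": "1/day", "KLP": "", "kO": "1/day",
    "KOP": "1/day", "kP": "1/day", "rL": "pM/day", "SP": "pM/day",
    "k1B": "1/day", "k2B": "pM", "nB": "", "k1C": "1/day", "K2C": "pM",
    "nC": "", "kTdiv": "1/day", "kTtgfb": "1/day", "kTdth": "1/day",
    "M": "pM", "kTpthrp": "1/day", "kTB": "1/pM/day", "kZC": "1/day",
}

#: structural constants held fixed during calibration
FIXED_PARAMS = frozenset({"fO", "IL", "IO", "IP", "nB", "nC"})

#: the five parameters allowed to differ between tumor types
TUMOR_PARAMS = ("kTdiv", "kTtgfb", "kTdth", "kTpthrp", "kTB")

#: the 30 adjustable parameters, in canonical order
ADJUSTABLE_PARAMS = tuple(n for n in PARAM_NAMES if n not in FIXED_PARAMS)


@dataclass(frozen=True)
class TumorTypeOverrides:
    """Per-tumor-type values for the five tumor-specific rate constants."""

    label: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(TUMOR_PARAMS):
            raise ValueError(
                f"overrides must specify exactly {sorted(TUMOR_PARAMS)}, got {sorted(keys)}"
            )
        object.__setattr__(self, "values", dict(self.values))


def override_table(overrides: Iterable[TumorTypeOverrides]) -> Dict[str, Dict[str, float]]:
    """Flatten a collection of per-type overrides into a nested dict."""
    return {ov.label: dict(ov.values) for ov in overrides}
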