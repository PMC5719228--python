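"""Risk-category binning for vitals (C1-C4) and labs (Low/Normal/High).

Numeric vitals are mapped to one of four ordered risk categories through
age-stratified boundaries; lab values are mapped to Low/Normal/High through
normal-range bounds.  The boundaries themselves are configuration (a YAML
table shipped with editable defaults), not scientific claims: the feature
operators are correct for any strictly increasing boundary set.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .synth import age_bin

VITAL_CATEGORIES = ("C1", "C2", "C3", "C4")
LAB_CATEGORIES = ("Low", "Normal", "High")


class BinningTable:
    """Maps numeric vitals to C1-C4 and lab values to Low/Normal/High."""

    def __init__(self, vitals: dict, labs: dict):
        self.vitals = {}
        self.descending = {}
        for vital, table in vitals.items():
            table = dict(table)
            self.descending[vital] = bool(table.pop("descending", False))
            per_bin = {}
            for bin_label, bounds in table.items():
                bounds = [float(b) for b in bounds]
                if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
                    raise ValueError(
                        f"boundaries for {vital}/{bin_label} must be strictly "
                        f"increasing: {bounds}")
                per_bin[bin_label] = np.asarray(bounds, dtype=float)
            self.vitals[vital] = per_bin
        self.labs = {}
        for lab, (low, high) in labs.items():
            low, high = float(low), float(high)
            if not low < high:
                raise ValueError(f"lab range for {lab} must satisfy low < high")
            self.labs[lab] = (low, high)

    @classmethod
    def from_yaml(cls, path) -> "BinningTable":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        return cls(vitals=raw.get("vitals", {}), labs=raw.get("labs", {}))

    @classmethod
    def default(cls) -> "BinningTable":
        ref = resources.files("icuward.data") / "default_binning.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls(vitals=raw.get("vitals", {}), labs=raw.get("labs", {}))

    def vital_category(self, vital: str, age_years: float, value: float) -> str:
        return self.vital_categories(vital, age_years, np.array([value]))[0]

    def vital_categories(self, vital: str, age_years: float,
                         values: np.ndarray) -> np.ndarray:
        """Vectorized C1-C4 assignment for one vital type at one age."""
        per_bin = self.vitals.get(vital)
        if per_bin is None:
            raise KeyError(f"no binning boundaries for vital {vital!r}")
        bounds = per_bin[age_bin(age_years)]
        idx = np.searchsorted(bounds, np.asarray(values, dtype=float),
                              side="right")
        if self.descending.get(vital, False):
            idx = len(bounds) - idx
        return np.array([VITAL_CATEGORIES[i] for i in idx], dtype=object)

    def lab_category(self, lab: str, value: float) -> str:
        rng = self.labs.get(lab)
        if rng is None:
            raise KeyError(f"no normal range for lab {lab!r}")
        low, high = rng
        if value < low:
            return "Low"
        if value > high:
            return "High"
        return "Normal"
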