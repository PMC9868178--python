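"""Standardized uptake value (SUV) computation for FDG-PET activity maps.

SUV = A(t) [kBq/mL] * W [kg] / (ID [MBq] * d), with the decay factor
d = 2**(-dt / T_half) correcting the injected dose to the scan start.
Under the standard 1 g/mL tissue-density convention the kBq/MBq and kg/mL
factors cancel, leaving SUV dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PETInput", "decay_factor", "suv_map", "F18_HALF_LIFE_MIN"]

F18_HALF_LIFE_MIN = 109.77  # physical half-life of 18F


@dataclass(frozen=True)
class PETInput:
    """Activity-concentration map plus the dose/weight/timing metadata."""

    activity_kbq_per_ml: np.ndarray
    weight_kg: float
    injected_dose_mbq: float
    delay_min: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.delay_min < 0:
            raise ValueError("injection-to-scan delay must be non-negative")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        a = np.asarray(self.activity_kbq_per_ml)
        if np.any(a[np.isfinite(a)] < 0):
            raise ValueError("activity concentrations must be non-negative")


def decay_factor(delay_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Radioactive decay factor d = 2**(-delay/half_life), in (0, 1]."""
    if delay_min < 0:
        raise ValueError("delay must be non-negative")
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    return float(2.0 ** (-delay_min / half_life_min))


def suv_map(pet: PETInput) -> np.ndarray:
    """Voxelwise SUV = A * W / (ID * d)."""
    d = decay_factor(pet.delay_min, pet.half_life_min)
    a = np.asarray(pet.activity_kbq_per_ml, dtype=float)
    return a * pet.weight_kg / (pet.injected_dose_mbq * d)
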