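"""Parametric respiratory motion with gated vs free-breathing sampling.

Displacement follows a raised cosine, ``d(t) = A (1 - cos 2*pi*t) / 2``,
zero at the reference phase (maximum expiration, where the planning scan is
acquired).  Internal targets move with the full amplitude vector; skin
fiducials move with ``coupling * A``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["BreathingMode", "RespiratoryModel", "displacement", "sample_phase"]


class BreathingMode(str, Enum):
    GATED = "GATED"
    FREE = "FREE"


@dataclass(frozen=True)
class RespiratoryModel:
    """Breathing parameters.

    ``internal_amplitude_mm`` is the peak displacement vector of internal
    targets (dominant cranio-caudal component, i.e. along the body's long
    axis, x in scene coordinates).  ``skin_coupling`` in [0, 1] scales it
    for skin fiducials.
    """

    period_s: float = 4.0
    internal_amplitude_mm: tuple[float, float, float] = (12.0, 0.0, 0.0)
    skin_coupling: float = 0.3
    reference_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if not 0.0 <= self.skin_coupling <= 1.0:
            raise ValueError("skin coupling must be in [0, 1]")

    def amplitude_for(self, structure: str) -> np.ndarray:
        amp = np.asarray(self.internal_amplitude_mm, dtype=float)
        if structure == "target":
            return amp
        if structure == "skin":
            return self.skin_coupling * amp
        raise ValueError(f"unknown structure kind {structure!r}")


def displacement(model: RespiratoryModel, structure: str, phase: float) -> np.ndarray:
    """Displacement vector (mm) of a structure at a respiratory phase in [0, 1)."""
    if not 0.0 <= phase < 1.0:
        raise ValueError("phase must lie in [0, 1)")
    amp = model.amplitude_for(structure)
    return amp * (1.0 - np.cos(2.0 * np.pi * (phase - model.reference_phase))) / 2.0


def sample_phase(
    mode: BreathingMode | str,
    rng: np.random.Generator,
    reference_phase: float = 0.0,
) -> float:
    """GATED: the reference phase exactly.  FREE: uniform random in [0, 1)."""
    mode = BreathingMode(mode)
    if mode is BreathingMode.GATED:
        return reference_phase
    return float(rng.random())
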