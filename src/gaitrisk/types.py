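"""Core domain containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: Trunk axes: vertical, mediolateral, anterior-posterior.
AXES = ("vt", "ml", "ap")

#: Standard gravity, m/s^2. The device range is +/- 6 g.
G = 9.80665
MAX_ABS_ACC = 6.0 * G


@dataclass
class AccelEpoch:
    """One 10-s tri-axial trunk acceleration segment (dynamic acceleration, m/s^2).

    The unit of gait-characteristic estimation. Axes follow the VT/ML/AP
    convention; gravity is assumed removed (each axis holds dynamic
    acceleration only).
    """

    vt: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    sample_rate: float = 100.0
    participant_id: str | None = None
    epoch_id: str | None = None

    def __post_init__(self) -> None:
        self.vt = np.asarray(self.vt, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.vt)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise KeyError(f"unknown axis {name!r}")
        return getattr(self, name)

    def validate(self, expected_samples: int | None = None) -> None:
        """Raise InvalidParameterError on range/shape violations."""
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        n = self.n_samples
        if not (len(self.ml) == n and len(self.ap) == n):
            raise InvalidParameterError("axes differ in length")
        if n == 0:
            raise InvalidParameterError("empty epoch")
        if expected_samples is not None and n != expected_samples:
            raise InvalidParameterError(
                f"epoch has {n} samples, expected {expected_samples}"
            )
        for ax in AXES:
            x = self.axis(ax)
            if not np.all(np.isfinite(x)):
                raise InvalidParameterError(f"non-finite samples on axis {ax}")
            if np.max(np.abs(x)) > MAX_ABS_ACC:
                raise InvalidParameterError(
                    f"|acceleration| exceeds 6 g on axis {ax}"
                )
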