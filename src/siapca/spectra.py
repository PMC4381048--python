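"""Domain containers for 2D ¹H{¹⁵N} correlation spectra and peak lists.

Conventions used throughout the package:

* A :class:`Spectrum2D` holds a real intensity matrix of shape
  ``(n_h, n_n)`` — axis 0 is the direct ¹H dimension, axis 1 the indirect
  ¹⁵N dimension.
* ppm decreases with increasing grid index (standard NMR display order);
  the ppm of point ``i`` on an axis is ``ppm_first - i * sw / n``.
* All grid indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping

import numpy as np

from .errors import EnsembleError, ValidationError

BASES = ("A", "C", "G", "U")

#: Tolerance on axis-calibration agreement between planes of one ensemble (ppm).
CALIBRATION_TOL = 1e-6


@dataclass(frozen=True)
class AxisCalibration:
    """Calibration of one spectral axis.

    Parameters
    ----------
    n_points
        Number of grid points along the axis.
    spectral_width
        Total spectral width in ppm; the point spacing is
        ``spectral_width / n_points``.
    ppm_first
        ppm coordinate of grid index 0 (the downfield edge).
    obs_mhz
        Observe (carrier) frequency in MHz, used only to convert ppm to Hz
        when writing NMRPipe headers.
    """

    n_points: int
    spectral_width: float
    ppm_first: float
    obs_mhz: float = 700.13

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError(f"axis needs >= 2 points, got {self.n_points}")
        if self.spectral_width <= 0 or self.obs_mhz <= 0:
            raise ValidationError("spectral_width and obs_mhz must be positive")

    @property
    def step(self) -> float:
        """Point spacing in ppm (positive; ppm decreases along the axis)."""
        return self.spectral_width / self.n_points

    @property
    def ppm_last(self) -> float:
        return self.ppm_first - (self.n_points - 1) * self.step

    def ppm_scale(self) -> np.ndarray:
        """ppm coordinate of every grid point, index 0 first."""
        return self.ppm_first - np.arange(self.n_points) * self.step

    def ppm_to_index(self, ppm: float) -> float:
        """Fractional grid index of a ppm coordinate."""
        return (self.ppm_first - ppm) / self.step

    def contains(self, ppm: float) -> bool:
        return self.ppm_last <= ppm <= self.ppm_first

    def close_to(self, other: "AxisCalibration", tol: float = CALIBRATION_TOL) -> bool:
        return (
            self.n_points == other.n_points
            and abs(self.spectral_width - other.spectral_width) <= tol
            and abs(self.ppm_first - other.ppm_first) <= tol
        )


@dataclass
class Spectrum2D:
    """A calibrated, real-valued frequency-domain 2D spectrum."""

    intensities: np.ndarray
    axis_h: AxisCalibration
    axis_n: AxisCalibration
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError(
                f"intensities must be 2D, got ndim={self.intensities.ndim}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("spectrum contains non-finite intensities")
        n1, n2 = self.intensities.shape
        if n1 < 2 or n2 < 2:
            raise ValidationError(f"grid too small: {n1} x {n2}")
        if self.axis_h.n_points != n1 or self.axis_n.n_points != n2:
            raise ValidationError(
                "axis point counts "
                f"({self.axis_h.n_points}, {self.axis_n.n_points}) do not match "
                f"matrix shape {self.intensities.shape}"
            )

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def same_grid(self, other: "Spectrum2D") -> bool:
        return self.axis_h.close_to(other.axis_h) and self.axis_n.close_to(other.axis_n)

    def with_label(self, label: str) -> "Spectrum2D":
        return replace(self, label=label)


@dataclass(frozen=True)
class PeakEntry:
    assignment_id: str
    delta_h: float
    delta_n: float
    intensity: float


@dataclass
class PeakList:
    """An assigned peak list: one entry per backbone amide resonance."""

    entries: List[PeakEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.assignment_id for e in self.entries]
        seen: set = set()
        for pid in ids:
            if pid in seen:
                raise ValidationError(f"duplicate assignment id {pid!r} in peak list")
            seen.add(pid)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PeakEntry]:
        return iter(self.entries)

    def ids(self) -> List[str]:
        return [e.assignment_id for e in self.entries]

    def by_id(self) -> Dict[str, PeakEntry]:
        return {e.assignment_id: e for e in self.entries}

    def get(self, assignment_id: str) -> PeakEntry:
        for e in self.entries:
            if e.assignment_id == assignment_id:
                return e
        raise KeyError(assignment_id)


@dataclass(frozen=True)
class PoolLabel:
    """Identity of one quasi-degenerate RNA pool: NNNAN-style.

    ``position`` is 1-based along the scanned RNA; the pool fixes ``base``
    there and randomizes every other position.
    """

    position: int
    base: str
    length: int = 5

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValidationError(f"base must be one of {BASES}, got {self.base!r}")
        if not 1 <= self.position <= self.length:
            raise ValidationError(
                f"position {self.position} outside 1..{self.length}"
            )

    @property
    def name(self) -> str:
        chars = ["N"] * self.length
        chars[self.position - 1] = self.base
        return "".join(chars)


PLANE_ORDER = ("free", "A", "C", "G", "U")


@dataclass
class EnsembleStack:
    """One position's PCA input: the free spectrum plus four pool complexes.

    Plane order is fixed as ``[free, A, C, G, U]``; all five planes share
    one grid and calibration.
    """

    reference: Spectrum2D
    bound: Dict[str, Spectrum2D]
    position: int

    def __post_init__(self) -> None:
        missing = [b for b in BASES if b not in self.bound]
        if missing:
            raise EnsembleError(f"missing bound spectra for base(s) {missing}")
        for base in BASES:
            spec = self.bound[base]
            if spec.shape != self.reference.shape:
                raise EnsembleError(
                    f"grid mismatch for base {base!r}: {spec.shape} vs "
                    f"reference {self.reference.shape}"
                )
            if not spec.same_grid(self.reference):
                raise EnsembleError(
                    f"axis calibration mismatch for base {base!r}"
                )
        # canonical plane order, independent of the insertion order of `bound`
        self.bound = {b: self.bound[b] for b in BASES}

    def planes(self) -> List[Spectrum2D]:
        return [self.reference] + [self.bound[b] for b in BASES]

    @property
    def plane_labels(self) -> tuple:
        return PLANE_ORDER

    @property
    def shape(self) -> tuple:
        return self.reference.shape


def stack_ensemble(
    reference: Spectrum2D,
    bound_by_base: Mapping[str, Spectrum2D],
    position: int,
) -> EnsembleStack:
    """Assemble and validate a five-plane ensemble for one RNA position.

    Raises
    ------
    EnsembleError
        If a base is missing, or a bound plane disagrees with the reference
        in grid dimensions or axis calibration (the offending base is named).
    """
    return EnsembleStack(reference=reference, bound=dict(bound_by_base), position=position)
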