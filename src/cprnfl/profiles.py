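"""Circumpapillary thickness profiles on a uniform circular grid.

A circle scan around the optic disc yields the RNFL thickness as a function
of angle over [0°, 360°). Profiles live on a fixed uniform angular grid
(default 768 samples, a typical A-scan count for a 3.5-mm circle scan).
Angle 0° is the temporal meridian, increasing through superior; profiles are
kept in right-eye canonical orientation.

Angular *regions* are half-open arcs ``(start_deg, end_deg)`` that may wrap
across 360°; ``(a, a)`` is empty and any span ≥ 360° is the full circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedValueError

DEFAULT_GRID_SIZE = 768
MIN_GRID_SIZE = 90


def canonical_angles(n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Uniform angular grid of ``n`` samples over [0°, 360°)."""
    if n < MIN_GRID_SIZE:
        raise ParameterError(f"grid size must be >= {MIN_GRID_SIZE}, got {n}")
    return np.arange(n) * (360.0 / n)


def angle_diff(angles, center):
    """Signed minimal circular difference ``angles - center`` in [-180, 180)."""
    return (np.asarray(angles, dtype=float) - center + 180.0) % 360.0 - 180.0


def region_width(region) -> float:
    """Circular width in degrees of a half-open arc ``(start, end)``."""
    start, end = region
    span = end - start
    if span == 0.0:
        return 0.0
    if span >= 360.0 or span <= -360.0:
        return 360.0
    return span % 360.0


def region_mask(angles: np.ndarray, region) -> np.ndarray:
    """Boolean mask of grid samples inside a (possibly wrapping) arc.

    Region boundaries are realized to the nearest grid step (the grid is
    uniform), so complementary arcs partition the circle exactly and an
    arc's realized width is within half a step of the requested one.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    start, end = float(region[0]), float(region[1])
    if end < start:
        end += 360.0
    width = end - start
    if width == 0.0:
        return np.zeros(n, dtype=bool)
    if width >= 360.0:
        return np.ones(n, dtype=bool)
    step = 360.0 / n
    # start and end snapped independently from the raw floats, so an arc
    # and its complement (sharing the same boundary value) tile exactly
    i0 = int(round(start / step))
    i1 = int(round(end / step))
    count = min(max(i1 - i0, 0), n)
    mask = np.zeros(n, dtype=bool)
    mask[np.arange(i0, i0 + count) % n] = True
    return mask


@dataclass
class ThicknessProfile:
    """One visit's cpRNFL thickness profile.

    Parameters
    ----------
    angles : array of float
        Uniform, strictly increasing grid in degrees over [0, 360).
    thickness : array of float
        Thickness in µm per grid sample, ≥ 0 and finite where ``valid``.
    valid : array of bool
        Per-sample validity mask. Samples lost to clipping are marked
        invalid but keep their (collapsed) measured value, mirroring how
        the device still folds them into its global average.
    vessel_markers : list of (center_deg, shadow_width_deg)
        Landmarks for the shadows retinal vessels cast on the b-scan,
        used to check scan alignment between visits.
    """

    angles: np.ndarray
    thickness: np.ndarray
    valid: np.ndarray = None
    vessel_markers: list = field(default_factory=list)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.angles.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.angles.ndim != 1 or self.angles.size < 2:
            raise ParameterError("angles must be a 1-D grid with >= 2 samples")
        if self.thickness.shape != self.angles.shape or self.valid.shape != self.angles.shape:
            raise ParameterError("thickness/valid must match the angular grid length")
        steps = np.diff(self.angles)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ParameterError("angles must be strictly increasing with uniform spacing")
        if np.any(~np.isfinite(self.thickness[self.valid])):
            raise ParameterError("thickness must be finite where valid")
        if np.any(self.thickness[np.isfinite(self.thickness)] < 0):
            raise ParameterError("thickness must be >= 0")
        self.vessel_markers = [(float(c) % 360.0, float(w)) for c, w in self.vessel_markers]

    @property
    def n(self) -> int:
        return self.angles.size

    @property
    def step(self) -> float:
        return 360.0 / self.n

    def copy(self) -> "ThicknessProfile":
        return ThicknessProfile(
            self.angles.copy(),
            self.thickness.copy(),
            self.valid.copy(),
            list(self.vessel_markers),
        )

    def same_grid(self, other: "ThicknessProfile") -> bool:
        return self.n == other.n and np.array_equal(self.angles, other.angles)


def exact_mean(values) -> float:
    """Correctly rounded mean (math.fsum): invariant under permutation,
    so rotating a profile changes its mean by exactly zero."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UndefinedValueError("mean of zero samples is undefined")
    return math.fsum(values) / values.size


def _mean_include_measured(profile: ThicknessProfile) -> float:
    return exact_mean(profile.thickness)


@dataclass
class VisitPair:
    """Baseline and follow-up profiles for one eye, with G and ΔG.

    The global metric G is the 360° mean thickness of one visit; ΔG is
    follow-up minus baseline, so negative values mean thinning. The
    derived values use the device-like ``include_measured`` policy (see
    :func:`cprnfl.metrics.global_mean`).
    """

    eye_id: str
    baseline: ThicknessProfile
    followup: ThicknessProfile

    def __post_init__(self):
        if not self.baseline.same_grid(self.followup):
            raise ParameterError("baseline and follow-up must share the angular grid")

    @property
    def g_baseline(self) -> float:
        return _mean_include_measured(self.baseline)

    @property
    def g_followup(self) -> float:
        return _mean_include_measured(self.followup)

    @property
    def delta_g(self) -> float:
        return self.g_followup - self.g_baseline
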