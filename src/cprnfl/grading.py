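"""Rule-based post hoc grading of defects and scan artifacts.

Operationalises the visual grading rules used to explain false positives
and false negatives of the ΔG metric:

* a *local* defect is a depression of the follow-up curve spanning less
  than 45° of the circle; *widespread* thinning keeps the curve in the
  below-normative range for at least 90°;
* a segmentation error counts when the poorly segmented arc exceeds 5°;
* a scan pair is *misaligned* when the vessel shadows shift by more than
  a vessel width between visits;
* a global multiplicative change of apparent retinal thickness (aΔRT) is
  at most ~5% and is estimated by least squares on clean samples;
* clipping is recognised from invalidated / collapsed runs.

Normative bands are estimated from the synthetic generator's own healthy
distribution (per-sample empirical 5th/1st percentiles), standing in for
a device normative database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UnsupportedInputError
from .metrics import contributions_by_cause, decompose_delta_g
from .profiles import ThicknessProfile, VisitPair, region_mask
from .synthetic import (
    LOCAL_MAX_WIDTH_DEG,
    SEGMENTATION_MIN_WIDTH_DEG,
    WIDESPREAD_MIN_WIDTH_DEG,
    EyeRecord,
    NormativeModel,
    make_normative_profile,
    mean_profile,
)



# --------------------------------------------------------------------------
# circular run helpers


def circular_runs(mask: np.ndarray):
    """Maximal circular runs of True as (start_index, length) pairs."""
    n = mask.size
    if not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    edges = np.flatnonzero(mask & ~np.roll(mask, 1))  # run starts
    runs = []
    for start in edges:
        length = 1
        while mask[(start + length) % n]:
            length += 1
        runs.append((int(start), int(length)))
    return runs


def _merge_runs(runs, n, gap_samples):
    """Merge circular runs separated by gaps smaller than gap_samples."""
    if len(runs) <= 1:
        return list(runs)
    runs = sorted(runs)
    merged = list(runs)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        merged = sorted(merged)
        out = []
        i = 0
        while i < len(merged):
            start, length = merged[i]
            if i + 1 < len(merged):
                nstart, nlength = merged[i + 1]
                gap = nstart - (start + length)
                if gap < gap_samples:
                    merged[i + 1] = (start, nstart + nlength - start)
                    changed = True
                    i += 1
                    continue
            out.append((start, length))
            i += 1
        merged = out
        # wrap-around merge between last and first run
        if len(merged) > 1:
            start0, len0 = merged[0]
            start1, len1 = merged[-1]
            gap = (start0 + n) - (start1 + len1)
            if gap < gap_samples:
                merged = merged[1:-1] + [(start1, start0 + len0 + n - start1)]
                changed = True
    return [(s % n, min(l, n)) for s, l in merged]


def _run_region(start, length, step):
    return (start * step, (start + length) * step)


# --------------------------------------------------------------------------
# domain types


@dataclass
class NormativeBands:
    """Per-sample normative percentile curves from healthy simulations."""

    angles: np.ndarray
    p5: np.ndarray
    p1: np.ndarray
    mean: np.ndarray

    def __post_init__(self):
        if not (np.all(self.p1 <= self.p5 + 1e-9) and np.all(self.p5 <= self.mean + 1e-9)):
            raise ParameterError("bands must satisfy p1 <= p5 <= mean per sample")

    @classmethod
    def from_model(cls, model: NormativeModel, n_eyes: int = 2000, seed=0) -> "NormativeBands":
        """Empirical bands over ``n_eyes`` simulated healthy visits."""
        samples = np.empty((n_eyes, model.grid_size))
        for i in range(n_eyes):
            samples[i] = make_normative_profile(model, [seed, i]).thickness
        angles = make_normative_profile(model, [seed, 0]).angles
        return cls(angles=angles,
                   p5=np.percentile(samples, 5, axis=0),
                   p1=np.percentile(samples, 1, axis=0),
                   mean=mean_profile(model))


@dataclass
class DefectRegion:
    """A detected depression of the follow-up thickness curve."""

    region: tuple
    width_deg: float
    mean_depth_um: float
    classification: str  # local | widespread | intermediate


@dataclass
class SegmentationFinding:
    """A graded segmentation-error arc on one visit."""

    region: tuple
    visit: str
    width_deg: float
    mean_error_um: float  # signed: measured − true


@dataclass
class FactorRank:
    """One ranked cause in a grading report (rank 1 = primary)."""

    cause: str
    rank: int
    contribution_um: float


@dataclass
class GradingReport:
    """Full rule-based grading of one synthetic eye."""

    eye_id: str
    defects: list = field(default_factory=list)
    segmentation_regions: list = field(default_factory=list)
    misaligned: bool = False
    shift_deg: float = 0.0
    scaling_s: float = 0.0
    scaling_flagged: bool = False
    clipped_regions: list = field(default_factory=list)
    factor_ranking: list = field(default_factory=list)


# --------------------------------------------------------------------------
# detectors


def detect_defects(pair: VisitPair, bands: NormativeBands, depth_min: float = 5.0,
                   merge_gap: float = 5.0, min_width: float = 6.0) -> list:
    """Detect depressions of the follow-up curve against baseline and norms.

    A defect run requires follow-up < baseline − depth_min *and*
    follow-up below the normative 5th-percentile band; runs separated by
    gaps under ``merge_gap`` degrees are merged, and merged runs
    narrower than ``min_width`` degrees (the noise-correlation scale;
    graded defects span a meaningful arc) are discarded. Classification:
    local if the run spans < 45°; widespread if the *below-band* run
    containing it spans ≥ 90° (regardless of depth); intermediate
    otherwise.
    """
    if not pair.baseline.same_grid(pair.followup):
        raise ParameterError("visits must share the angular grid")
    if bands.p5.size != pair.baseline.n:
        raise ParameterError("bands must be on the pair's angular grid")
    b, f = pair.baseline, pair.followup
    usable = b.valid & f.valid
    below_band = (f.thickness < bands.p5) & usable
    deepening = (f.thickness < b.thickness - depth_min) & below_band
    step = b.step
    gap_samples = max(1, int(round(merge_gap / step)))
    runs = _merge_runs(circular_runs(deepening), b.n, gap_samples)
    band_runs = circular_runs(below_band)

    defects = []
    for start, length in runs:
        width = length * step
        if width < min_width:
            continue
        idx = (start + np.arange(length)) % b.n
        depth = float(np.mean(b.thickness[idx] - f.thickness[idx]))
        band_width = width
        for bstart, blength in band_runs:
            covered = (start - bstart) % b.n < blength
            if covered:
                band_width = blength * step
                break
        if band_width >= WIDESPREAD_MIN_WIDTH_DEG:
            label = "widespread"
        elif width < LOCAL_MAX_WIDTH_DEG:
            label = "local"
        else:
            label = "intermediate"
        defects.append(DefectRegion(_run_region(start, length, step), width, depth, label))
    return defects


def grade_segmentation(record: EyeRecord, tol: float = 5.0) -> list:
    """Arcs where measured thickness departs from latent truth by > tol.

    Segmentation errors are *regional*: the global median of the
    measured−true difference (an ordinary G-level test-retest offset) is
    subtracted before thresholding, so only angular departures beyond
    ``tol`` are graded. Graded per visit; only runs wider than 5° are
    kept, and samples lost to clipping (invalid) are not charged to
    segmentation.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    if record.latent_truth is None:
        raise UnsupportedInputError("segmentation grading requires latent ground truth")
    latent = {"baseline": record.latent_truth[0], "followup": record.latent_truth[1]}
    findings = []
    for visit in ("baseline", "followup"):
        measured = getattr(record.pair, visit)
        err = measured.thickness - latent[visit].thickness
        if measured.valid.any():
            err = err - np.median(err[measured.valid])
        mask = (np.abs(err) > tol) & measured.valid
        step = measured.step
        for start, length in circular_runs(mask):
            width = length * step
            if width <= SEGMENTATION_MIN_WIDTH_DEG:
                continue
            idx = (start + np.arange(length)) % measured.n
            findings.append(SegmentationFinding(
                _run_region(start, length, step), visit, width, float(np.mean(err[idx]))))
    return findings


def check_alignment(pair: VisitPair):
    """Estimate inter-visit rotation from vessel-shadow landmarks.

    Markers are matched in order between visits; the shift is the median
    signed circular displacement. The pair is misaligned when the median
    absolute per-vessel shift exceeds the median vessel shadow width.
    """
    mb, mf = pair.baseline.vessel_markers, pair.followup.vessel_markers
    if not mb or not mf:
        raise UnsupportedInputError("alignment check requires vessel markers on both visits")
    k = min(len(mb), len(mf))
    diffs = np.array([((mf[i][0] - mb[i][0] + 180.0) % 360.0) - 180.0 for i in range(k)])
    widths = np.array([mb[i][1] for i in range(k)])
    shift = float(np.median(diffs))
    misaligned = bool(np.median(np.abs(diffs)) > np.median(widths))
    return misaligned, shift


def estimate_scaling(pair: VisitPair, exclude_mask=None, s_flag: float = 0.02):
    """Least-squares estimate of the global multiplicative factor s.

    Fits ``T_f ≈ a + (1+s)·T_b`` over samples valid on both visits and
    outside ``exclude_mask`` (defect/segmentation arcs should be
    excluded by the caller). The additive intercept absorbs G-level
    test-retest offsets, which would otherwise masquerade as scaling;
    the slope isolates the genuine multiplicative (aΔRT-like) change
    using the profile's angular dynamic range. For profiles with no
    angular variation the intercept is not identifiable and the plain
    ratio estimator Σ T_b·T_f / Σ T_b² − 1 is used. On noiseless
    proportional pairs both reduce to the exact ratio. Flags when
    |s| ≥ ``s_flag``.
    """
    usable = pair.baseline.valid & pair.followup.valid
    if exclude_mask is not None:
        usable = usable & ~np.asarray(exclude_mask, dtype=bool)
    if usable.sum() < pair.baseline.n / 2:
        raise UnsupportedInputError("scaling estimate needs >= 50% usable overlap")
    tb = pair.baseline.thickness[usable]
    tf = pair.followup.thickness[usable]
    if float(np.dot(tb, tb)) == 0:
        raise UnsupportedInputError("baseline profile is identically zero")
    if np.std(tb) < 1e-9:  # flat profile: intercept not identifiable
        s = float(np.dot(tb, tf) / np.dot(tb, tb) - 1.0)
    else:
        slope = float(np.cov(tb, tf, bias=True)[0, 1] / np.var(tb))
        s = slope - 1.0
    return s, bool(abs(s) >= s_flag)


def detect_clipping(profile: ThicknessProfile, clip_floor: float = 10.0,
                    clip_min_deg: float = 10.0) -> list:
    """Runs of invalidated or collapsed samples at least ``clip_min_deg`` wide."""
    mask = (~profile.valid) | (profile.thickness <= clip_floor)
    step = profile.step
    regions = []
    for start, length in circular_runs(mask):
        if length * step >= clip_min_deg:
            regions.append(_run_region(start, length, step))
    return regions


_RANK_CAUSE_NAMES = {"lesion": "local"}


def attribute_factors(record: EyeRecord, bands: NormativeBands = None,
                      depth_min: float = 5.0, merge_gap: float = 5.0,
                      min_width: float = 6.0, tol: float = 5.0,
                      s_flag: float = 0.02, clip_floor: float = 10.0,
                      clip_min_deg: float = 10.0,
                      min_contribution: float = 0.1) -> GradingReport:
    """Grade one synthetic eye and rank the causes of its ΔG.

    Causes are ranked by the absolute ground-truth contribution each
    makes to ΔG (rank 1 = primary); causes below ``min_contribution`` µm
    and residual noise are not ranked. Detector outputs (defects, graded
    segmentation arcs, alignment, scaling, clipping) are attached when
    computable; defect detection needs normative ``bands``.
    """
    contributions = decompose_delta_g(record)
    totals = contributions_by_cause(contributions)
    ranked = sorted(
        ((cause, total) for cause, total in totals.items()
         if cause not in ("noise", "unattributed") and abs(total) >= min_contribution),
        key=lambda item: -abs(item[1]),
    )
    ranking = [FactorRank(_RANK_CAUSE_NAMES.get(cause, cause), i + 1, total)
               for i, (cause, total) in enumerate(ranked)]

    report = GradingReport(eye_id=record.eye_id, factor_ranking=ranking)
    pair = record.pair
    if bands is not None:
        report.defects = detect_defects(pair, bands, depth_min, merge_gap, min_width)
    if record.latent_truth is not None:
        report.segmentation_regions = grade_segmentation(record, tol)
    if pair.baseline.vessel_markers and pair.followup.vessel_markers:
        report.misaligned, report.shift_deg = check_alignment(pair)
    exclude = np.zeros(pair.baseline.n, dtype=bool)
    for lesion in record.lesions:
        exclude |= region_mask(pair.baseline.angles, lesion.region)
    for finding in report.segmentation_regions:
        exclude |= region_mask(pair.baseline.angles, finding.region)
    try:
        report.scaling_s, report.scaling_flagged = estimate_scaling(pair, exclude, s_flag)
    except UnsupportedInputError:
        report.scaling_s, report.scaling_flagged = float("nan"), False
    clipped = []
    for visit in (pair.baseline, pair.followup):
        clipped.extend(detect_clipping(visit, clip_floor, clip_min_deg))
    report.clipped_regions = clipped
    return report
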