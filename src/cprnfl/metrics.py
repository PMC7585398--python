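"""The global cpRNFL thickness metric G, sector means, ΔG and its
region-wise decomposition.

G is the plain arithmetic mean of the grid samples (the grid is uniform,
so this is the 360° average the device prints at the center of its pie
chart). Region contributions use the same sample-mean quadrature —
``sum over region of (T_f − T_b) / n`` — so that contributions over any
partition of the circle sum to ΔG exactly, mirroring the
area-between-the-curves reading used to attribute ΔG to individual
defects and artifacts.

The ``include_measured`` validity policy (default) folds clipped samples'
collapsed measured values into G, reproducing how acquisition clipping
corrupts the device-reported ΔG; ``exclude`` averages valid samples only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedValueError, UnsupportedInputError
from .profiles import ThicknessProfile, VisitPair, exact_mean, region_mask, region_width
from .synthetic import (
    ARTIFACT_ORDER,
    EyeRecord,
    apply_artifact,
    apply_lesion,
    _sorted_artifacts,
)

VALID_POLICIES = ("include_measured", "exclude")

#: cause tags for region contributions
CAUSES = ("lesion", "segmentation", "clipping", "scaling", "noise", "unattributed")

_ARTIFACT_CAUSE = {
    "segmentation": "segmentation",
    "schisis": "segmentation",  # schisis-like offsets share segmentation semantics
    "scaling": "scaling",
    "clipping": "clipping",
    "rotation": "unattributed",  # exact zero for whole-step rotations
}


def global_mean(profile: ThicknessProfile, invalid_policy: str = "include_measured") -> float:
    """Global average thickness G in µm.

    ``include_measured`` (device-like) averages the measured values of
    all samples, valid or not; ``exclude`` drops invalid samples.
    """
    if invalid_policy not in VALID_POLICIES:
        raise ParameterError(f"invalid_policy must be one of {VALID_POLICIES}")
    if invalid_policy == "exclude":
        if not np.any(profile.valid):
            raise UndefinedValueError("all samples excluded; G undefined")
        return exact_mean(profile.thickness[profile.valid])
    return exact_mean(profile.thickness)


@dataclass
class SectorScheme:
    """Ordered sectors ``(label, start_deg, end_deg)`` partitioning the circle."""

    sectors: tuple

    def validate(self, angles: np.ndarray) -> None:
        cover = np.zeros(angles.shape, dtype=int)
        for _label, start, end in self.sectors:
            cover += region_mask(angles, (start, end)).astype(int)
        if np.any(cover != 1):
            raise ParameterError("sectors must partition [0,360) with no gaps or overlap")


#: Device-style six-sector scheme: temporal, temporal-superior,
#: nasal-superior, nasal, nasal-inferior, temporal-inferior.
DEFAULT_SECTORS = SectorScheme((
    ("T", 315.0, 405.0),
    ("TS", 45.0, 90.0),
    ("NS", 90.0, 135.0),
    ("N", 135.0, 225.0),
    ("NI", 225.0, 270.0),
    ("TI", 270.0, 315.0),
))


def sector_means(profile: ThicknessProfile, scheme: SectorScheme = DEFAULT_SECTORS,
                 invalid_policy: str = "include_measured") -> dict:
    """Per-sector mean thickness; recombines to G exactly by construction."""
    scheme.validate(profile.angles)
    if invalid_policy not in VALID_POLICIES:
        raise ParameterError(f"invalid_policy must be one of {VALID_POLICIES}")
    means = {}
    for label, start, end in scheme.sectors:
        mask = region_mask(profile.angles, (start, end))
        if invalid_policy == "exclude":
            mask = mask & profile.valid
        if not np.any(mask):
            raise UndefinedValueError(f"sector {label!r} has no usable samples")
        means[label] = exact_mean(profile.thickness[mask])
    return means


def delta_g(pair: VisitPair, invalid_policy: str = "include_measured") -> float:
    """ΔG = follow-up G − baseline G (negative = thinning)."""
    return (global_mean(pair.followup, invalid_policy)
            - global_mean(pair.baseline, invalid_policy))


def region_contribution(pair: VisitPair, region) -> float:
    """Signed share of ΔG carried by an angular region.

    The grid analogue of (1/360)·∫_region (T_f − T_b) dθ: the sum of the
    per-sample difference over the region divided by the total sample
    count. A zero-width region contributes 0. Contributions over any
    partition of the circle sum to ΔG exactly.
    """
    import math
    mask = region_mask(pair.baseline.angles, region)
    diff = pair.followup.thickness - pair.baseline.thickness
    return math.fsum(diff[mask]) / pair.baseline.n


@dataclass
class RegionContribution:
    """A tagged, signed share of ΔG attributed to one cause/region."""

    region: tuple
    contribution_um: float
    cause_tag: str = "unattributed"


def decompose_delta_g(record: EyeRecord, include_noise: bool = True) -> list:
    """Decompose an eye's measured ΔG into cause-tagged contributions.

    Requires ground truth (synthetic eyes): the artifact chain is replayed
    on the latent noise-free profiles, and each lesion/artifact is
    assigned the increment in G it produces at its step, with the sign
    convention of ΔG (a baseline-visit artifact enters with opposite
    sign). The residual — measured ΔG minus all tagged terms — is tagged
    ``noise``; by construction the contributions sum to ΔG exactly.

    The lesion terms alone equal the ΔG that would be observed with
    perfect segmentation and no artifacts.
    """
    if record.latent_truth is None:
        raise UnsupportedInputError("decomposition requires latent ground truth")
    latent_b, latent_f = record.latent_truth
    contributions = []

    # progression lesions: sequential increments on the latent baseline
    current = latent_b
    for lesion in record.lesions:
        before = global_mean(current)
        current = apply_lesion(current, lesion)
        contributions.append(RegionContribution(
            region=lesion.region,
            contribution_um=global_mean(current) - before,
            cause_tag="lesion",
        ))

    # measurement artifacts: replay per visit in canonical order
    for visit, start_profile, sign in (("baseline", latent_b, -1.0),
                                       ("followup", latent_f, +1.0)):
        current = start_profile
        for artifact in _sorted_artifacts(record.artifacts, visit):
            before = global_mean(current)
            current = apply_artifact(current, artifact)
            increment = global_mean(current) - before
            region = artifact.region if artifact.region is not None else (0.0, 360.0)
            contributions.append(RegionContribution(
                region=region,
                contribution_um=sign * increment,
                cause_tag=_ARTIFACT_CAUSE[artifact.kind],
            ))

    if include_noise:
        residual = record.pair.delta_g - sum(c.contribution_um for c in contributions)
        contributions.append(RegionContribution((0.0, 360.0), residual, "noise"))
    return contributions


def contributions_by_cause(contributions) -> dict:
    """Sum tagged contributions per cause."""
    totals = {}
    for c in contributions:
        totals[c.cause_tag] = totals.get(c.cause_tag, 0.0) + c.contribution_um
    return totals
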