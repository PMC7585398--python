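"""File formats, packaged fixtures and run configuration.

One canonical CSV dialect throughout: comma separated, dot decimal, LF
line endings, UTF-8 with a header row. Profile files have one row per
grid sample with columns ``eye_id,visit,angle_deg,thickness_um,valid,
vessel_marker``; ``vessel_marker`` holds the vessel shadow width (deg)
at the marker's grid sample and 0 elsewhere. Floats are written with
shortest-roundtrip precision so write∘read is the identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError
from .profiles import ThicknessProfile, VisitPair
from .synthetic import ArtifactSpec, CohortConfig, EyeRecord, LesionSpec, NormativeModel

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["eye_id", "visit", "angle_deg", "thickness_um", "valid", "vessel_marker"]
VISIT_NAMES = ("baseline", "followup")


@dataclass
class ProfileRecord:
    """One (eye, visit) profile as stored in a profile CSV."""

    eye_id: str
    visit: str
    profile: ThicknessProfile


def _profile_to_frame(rec: ProfileRecord) -> pd.DataFrame:
    prof = rec.profile
    marker = np.zeros(prof.n)
    for center, width in prof.vessel_markers:
        idx = int(round(center / prof.step)) % prof.n
        marker[idx] = width
    return pd.DataFrame({
        "eye_id": rec.eye_id,
        "visit": rec.visit,
        "angle_deg": prof.angles,
        "thickness_um": prof.thickness,
        "valid": prof.valid.astype(int),
        "vessel_marker": marker,
    })


def write_profiles(records, path) -> None:
    """Write ProfileRecords (or EyeRecords' measured pairs) to a profile CSV."""
    frames = []
    for rec in records:
        if isinstance(rec, EyeRecord):
            frames.append(_profile_to_frame(ProfileRecord(rec.eye_id, "baseline", rec.pair.baseline)))
            frames.append(_profile_to_frame(ProfileRecord(rec.eye_id, "followup", rec.pair.followup)))
        else:
            frames.append(_profile_to_frame(rec))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=PROFILE_COLUMNS))
    # shortest-roundtrip float repr so write -> read is lossless
    table.to_csv(path, index=False, lineterminator="\n",
                 float_format=lambda v: repr(float(v)))


def read_profiles(path) -> list:
    """Read a profile CSV back into ProfileRecords (round-trip lossless).

    Raises :class:`FormatError` (naming the first offending data row)
    for missing columns, non-uniform angle grids or duplicate
    (eye, visit, angle) entries.
    """
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse profile CSV {path}: {exc}") from exc
    missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"profile CSV {path} missing columns {missing}")
    if table.empty:
        logger.warning("profile CSV %s contains a header but no rows", path)
        return []
    bad_visit = table.loc[~table["visit"].isin(VISIT_NAMES)]
    if len(bad_visit):
        raise FormatError(f"unknown visit name at row {bad_visit.index[0] + 2}")
    records = []
    for (eye_id, visit), group in table.groupby(["eye_id", "visit"], sort=False):
        angles = group["angle_deg"].to_numpy(dtype=float)
        dup = group.duplicated(subset=["angle_deg"])
        if dup.any():
            raise FormatError(
                f"duplicate (eye, visit, angle) at row {group.index[dup][0] + 2}")
        if angles.size < 2:
            raise FormatError(f"profile {eye_id}/{visit} has fewer than 2 samples "
                              f"(row {int(group.index[0]) + 2})")
        steps = np.diff(angles)
        bad_idx = np.flatnonzero((steps <= 0) | ~np.isclose(steps, steps[0], atol=1e-9))
        if bad_idx.size:
            bad_row = int(group.index[bad_idx[0] + 1]) + 2  # +2: header and 1-based
            raise FormatError(f"non-uniform or gapped angle grid at row {bad_row}")
        marker_col = group["vessel_marker"].to_numpy(dtype=float)
        markers = [(float(a), float(w)) for a, w in zip(angles[marker_col > 0], marker_col[marker_col > 0])]
        profile = ThicknessProfile(
            angles,
            group["thickness_um"].to_numpy(dtype=float),
            group["valid"].to_numpy(dtype=float).astype(bool),
            markers,
        )
        records.append(ProfileRecord(str(eye_id), str(visit), profile))
    return records


def pairs_from_records(records) -> list:
    """Assemble VisitPairs from ProfileRecords that have both visits."""
    by_eye = {}
    for rec in records:
        by_eye.setdefault(rec.eye_id, {})[rec.visit] = rec.profile
    pairs = []
    for eye_id, visits in by_eye.items():
        if set(visits) == set(VISIT_NAMES):
            pairs.append(VisitPair(eye_id, visits["baseline"], visits["followup"]))
    return pairs


# --------------------------------------------------------------------------
# cohort manifest (ground-truth specs, JSON)


def _spec_dict(obj) -> dict:
    d = asdict(obj)
    if isinstance(obj, ArtifactSpec) and d["region"] is not None:
        d["region"] = list(d["region"])
    return d


def write_manifest(records, seed, path) -> None:
    payload = {"seed": seed, "eyes": []}
    for rec in records:
        payload["eyes"].append({
            "eye_id": rec.eye_id,
            "truth_label": rec.truth_label,
            "lesions": [_spec_dict(l) for l in rec.lesions],
            "artifacts": [_spec_dict(a) for a in rec.artifacts],
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    for eye in payload["eyes"]:
        eye["lesions"] = [LesionSpec(**l) for l in eye["lesions"]]
        eye["artifacts"] = [
            ArtifactSpec(a["kind"], a["visit"],
                         tuple(a["region"]) if a["region"] is not None else None,
                         a["magnitude"])
            for a in eye["artifacts"]
        ]
    return payload


# --------------------------------------------------------------------------
# packaged fixtures


FIXTURE_FILES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "table3": "table3.csv",
    "table4": "table4.csv",
}
_EXPECTED_ROWS = {"table1": 7, "table2": 5, "table3": 16, "table4": 6}


@dataclass
class FixtureTable:
    """One packaged result table, checksum-verified."""

    table_id: str
    rows: pd.DataFrame
    sha256: str


def load_fixture(table_id: str) -> FixtureTable:
    """Load and verify a packaged result table."""
    if table_id not in FIXTURE_FILES:
        raise ParameterError(f"unknown fixture {table_id!r}")
    data_dir = resources.files("cprnfl.data")
    raw = (data_dir / FIXTURE_FILES[table_id]).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    checksums = json.loads((data_dir / "checksums.json").read_text())
    if checksums[FIXTURE_FILES[table_id]] != digest:
        raise FormatError(f"fixture {table_id} checksum mismatch")
    frame = pd.read_csv(data_dir / FIXTURE_FILES[table_id], dtype={"criterion": str})
    if len(frame) != _EXPECTED_ROWS[table_id]:
        raise FormatError(
            f"fixture {table_id}: expected {_EXPECTED_ROWS[table_id]} rows, got {len(frame)}")
    return FixtureTable(table_id, frame, digest)


# --------------------------------------------------------------------------
# run configuration


@dataclass
class Thresholds:
    """Detector thresholds (all in the units of their rule)."""

    depth_min: float = 5.0     # µm below baseline to count as deepening
    merge_gap: float = 5.0     # ° — defect runs closer than this merge
    min_defect_width: float = 6.0  # ° — narrower merged runs are not graded
    tol: float = 5.0           # µm departure from truth graded as segmentation
    s_flag: float = 0.02       # |s| at which scaling is flagged (< the 5% ceiling)
    clip_floor: float = 10.0   # µm collapse value of clipped samples
    clip_min_deg: float = 10.0  # minimal clipped-run width reported

    def validate(self):
        for name, value in asdict(self).items():
            if value <= 0:
                raise ParameterError(f"threshold {name} must be > 0")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trip is lossless."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    criteria: tuple = ("qr:0.05", "fixed:3", "fixed:4", "fixed:5", "fixed:6",
                       "fixed:7", "fixed:8")
    thresholds: Thresholds = field(default_factory=Thresholds)
    qr_calibration_pairs: int = 500

    def validate(self):
        self.cohort.validate()
        self.thresholds.validate()
        if self.cohort.model.grid_size < 90:
            raise ParameterError("grid_size must be >= 90")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["criteria"] = list(self.criteria)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = dict(d.get("cohort", {}))
        model = NormativeModel(**_tuplify_model(cohort.pop("model", {})))
        cohort = {k: tuple(v) if isinstance(v, list) else v for k, v in cohort.items()}
        d["cohort"] = CohortConfig(model=model, **cohort)
        d["thresholds"] = Thresholds(**d.get("thresholds", {}))
        d["criteria"] = tuple(d.get("criteria", cls().criteria))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_listify(self.to_dict()), sort_keys=True).encode()).hexdigest()


def _tuplify_model(d: dict) -> dict:
    d = dict(d)
    for key in ("peak_params", "vessel_params"):
        if key in d:
            d[key] = tuple(tuple(item) for item in d[key])
    return d


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
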