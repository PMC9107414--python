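"""Domain types and file I/O for parcellated cortical thickness data.

The canonical interchange format is plain TSV: a subject x parcel matrix of
mean cortical thickness (CT) in millimetres, a demographics table
(subject_id, age, sex, group) and an optional parcel -> ROI lookup.  A thin
optional layer reads CIFTI-2 ``.pscalar.nii`` / ``.dlabel.nii`` files
(via nibabel) for data coming out of a FreeSurfer + Ciftify surface stream;
everything downstream operates on parcel means only.

Parcel order is defined once, by the parcellation, and enforced everywhere:
no function in this package reorders parcels implicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, IngestError

logger = logging.getLogger("mosaicct")

#: Plausible cortical thickness range in mm; values at or outside these
#: bounds are rejected at ingest (catches unit errors such as µm or cm).
CT_MIN_MM = 0.5
CT_MAX_MM = 5.0

#: Default significance threshold (inclusive) for labelling a parcel atrophic.
DEFAULT_ALPHA = 0.05

SEX_LEVELS = ("female", "male")

ROI_LABELS = ("motor", "parietal", "temporal", "frontal")
ROI_NONE = "none"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """Identity plus the demographics used for normative matching."""

    subject_id: str
    age: float
    sex: str
    group: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise IngestError(f"subject {self.subject_id!r}: age {self.age} is not a finite non-negative number")
        if self.sex not in SEX_LEVELS:
            raise IngestError(f"subject {self.subject_id!r}: sex {self.sex!r} not in {SEX_LEVELS}")


@dataclass
class MosaicParcellation:
    """An ordered set of cortical parcels ('mosaics').

    ``vertex_to_parcel`` maps a surface vertex index to a parcel index
    (position in ``parcel_ids``) or -1 for background; ``parcel_to_roi``
    assigns each parcel a composite ROI label or "none".
    """

    parcel_ids: list[str]
    vertex_to_parcel: np.ndarray | None = None
    parcel_to_roi: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise IngestError("duplicate parcel ids in parcellation")
        if self.parcel_to_roi is not None:
            bad = {r for r in self.parcel_to_roi.values() if r not in (*ROI_LABELS, ROI_NONE)}
            if bad:
                raise IngestError(f"unknown ROI labels in parcel_to_roi: {sorted(bad)}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def roi_vector(self) -> np.ndarray:
        """ROI label per parcel, in parcel order ('none' where unassigned)."""
        if self.parcel_to_roi is None:
            raise ConfigError("parcellation carries no parcel->ROI assignment")
        return np.array([self.parcel_to_roi.get(p, ROI_NONE) for p in self.parcel_ids])


@dataclass
class MosaicCTVector:
    """One subject's mean CT (mm) per parcel, aligned to a parcellation."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        bad = ~np.isfinite(self.values) | (self.values <= CT_MIN_MM) | (self.values >= CT_MAX_MM)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise IngestError(
                f"subject {self.subject_id!r}, parcel index {k}: CT value "
                f"{self.values[k]!r} outside plausible range ({CT_MIN_MM}, {CT_MAX_MM}) mm"
            )


@dataclass
class ControlBank:
    """Normative bank: healthy-control records and their CT matrix (controls x parcels)."""

    records: list[SubjectRecord]
    matrix: np.ndarray
    parcel_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.records):
            raise IngestError(
                f"control matrix shape {self.matrix.shape} does not match {len(self.records)} records"
            )
        if self.matrix.shape[1] != len(self.parcel_ids):
            raise IngestError("control matrix column count does not match parcel_ids")
        if not np.isfinite(self.matrix).all():
            raise IngestError("non-finite values in control matrix")

    @property
    def n_controls(self) -> int:
        return len(self.records)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        return np.array([r.sex for r in self.records])

    def subset(self, mask: np.ndarray) -> "ControlBank":
        idx = np.flatnonzero(mask)
        return ControlBank(
            records=[self.records[i] for i in idx],
            matrix=self.matrix[idx],
            parcel_ids=self.parcel_ids,
        )


@dataclass
class AtrophyMap:
    """Per-parcel z, rank p and binary atrophic label for one subject."""

    subject_id: str
    parcel_ids: list[str]
    z: np.ndarray
    p: np.ndarray
    atrophic: np.ndarray
    n_matched: int
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.atrophic = np.asarray(self.atrophic, dtype=int)
        n = len(self.parcel_ids)
        if not (self.z.shape == self.p.shape == self.atrophic.shape == (n,)):
            raise IngestError("atrophy map vectors must all have one entry per parcel")
        if ((self.p < 0) | (self.p > 1)).any():
            raise IngestError("rank p-values must lie in [0, 1]")


@dataclass
class HitMatrix:
    """Patients x parcels binary atrophy indicators for one clinical group."""

    patient_ids: list[str]
    parcel_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.patient_ids), len(self.parcel_ids)):
            raise IngestError(f"hit matrix shape {self.matrix.shape} inconsistent with ids")
        if not np.isin(self.matrix, (0, 1)).all():
            raise IngestError("hit matrix entries must be 0 or 1")


@dataclass
class FWERMap:
    """Per-parcel permutation p-values for a group hit matrix."""

    parcel_ids: list[str]
    observed_counts: np.ndarray
    p_fwer: np.ndarray
    n_iterations: int
    mode: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.p_fwer = np.asarray(self.p_fwer, dtype=float)
        self.observed_counts = np.asarray(self.observed_counts, dtype=int)


@dataclass
class RadarSummary:
    """Atrophic-parcel fraction per composite ROI plus whole brain."""

    fractions: dict[str, float]  # keys: motor/parietal/temporal/frontal
    whole_brain: float

    def as_dict(self) -> dict[str, float]:
        out = dict(self.fractions)
        out["whole_brain"] = self.whole_brain
        return out


# ---------------------------------------------------------------------------
# Readers / writers: TSV
# ---------------------------------------------------------------------------

def read_ct_matrix(path: str | Path, format: str = "tsv") -> tuple[list[MosaicCTVector], MosaicParcellation]:
    """Read a subject x parcel CT matrix.

    TSV dialect: first column ``subject_id``, remaining columns parcel ids,
    tab separated.  ``format='cifti_pscalar'`` reads a CIFTI-2 pscalar file
    (one subject per named map, parcel names from the parcel axis).
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    if format == "cifti_pscalar":
        return _read_pscalar(path)
    if format != "tsv":
        raise ConfigError(f"unknown CT matrix format {format!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2 or df.columns[0] != "subject_id":
        raise IngestError(f"{path}: malformed header; expected 'subject_id' then parcel columns")
    parcel_ids = list(df.columns[1:])
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise IngestError(f"{path}: duplicate subject_id {dup!r}")

    vectors = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        vals = np.empty(len(parcel_ids))
        for j, pid in enumerate(parcel_ids):
            try:
                vals[j] = float(row[pid])
            except (TypeError, ValueError):
                raise IngestError(
                    f"{path}: non-numeric CT value {row[pid]!r} at subject {sid!r}, parcel {pid!r}"
                ) from None
        try:
            vectors.append(MosaicCTVector(subject_id=sid, values=vals))
        except IngestError as e:
            raise IngestError(f"{path}: {e}") from None
    return vectors, MosaicParcellation(parcel_ids=parcel_ids)


def write_ct_matrix(vectors: Sequence[MosaicCTVector], parcellation: MosaicParcellation, path: str | Path) -> None:
    """Write vectors as the canonical subject x parcel TSV (full float precision)."""
    df = pd.DataFrame(
        [v.values for v in vectors],
        index=pd.Index([v.subject_id for v in vectors], name="subject_id"),
        columns=parcellation.parcel_ids,
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_demographics(path: str | Path) -> list[SubjectRecord]:
    """Read a TSV with columns subject_id, age, sex, group."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "sex": str, "group": str})
    required = {"subject_id", "age", "sex", "group"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"{path}: demographics table missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise IngestError(f"{path}: duplicate subject_id in demographics")
    return [
        SubjectRecord(subject_id=r.subject_id, age=float(r.age), sex=r.sex, group=r.group)
        for r in df.itertuples()
    ]


def write_demographics(records: Sequence[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_parcel_roi(path: str | Path) -> dict[str, str]:
    """Read a TSV parcel_id -> roi lookup (roi in motor/parietal/temporal/frontal/none)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"parcel_id", "roi"} <= set(df.columns):
        raise IngestError(f"{path}: expected columns parcel_id, roi")
    bad = ~df["roi"].isin((*ROI_LABELS, ROI_NONE))
    if bad.any():
        raise IngestError(f"{path}: unknown ROI label {df['roi'][bad].iloc[0]!r}")
    return dict(zip(df["parcel_id"], df["roi"]))


def write_parcel_roi(parcel_to_roi: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"parcel_id": list(parcel_to_roi.keys()), "roi": list(parcel_to_roi.values())}
    ).to_csv(path, sep="\t", index=False)


def control_bank_from_tables(
    vectors: Sequence[MosaicCTVector],
    records: Sequence[SubjectRecord],
    parcellation: MosaicParcellation,
    control_groups: Sequence[str] = ("HC",),
) -> ControlBank:
    """Assemble a ControlBank from CT vectors + demographics, keeping control groups only."""
    by_id = {r.subject_id: r for r in records}
    keep_records, rows = [], []
    for v in vectors:
        rec = by_id.get(v.subject_id)
        if rec is None:
            raise IngestError(f"subject {v.subject_id!r} has CT data but no demographics entry")
        if rec.group in control_groups:
            keep_records.append(rec)
            rows.append(v.values)
    if not keep_records:
        raise IngestError(f"no subjects with a control group label in {list(control_groups)}")
    return ControlBank(records=keep_records, matrix=np.vstack(rows), parcel_ids=list(parcellation.parcel_ids))


# ---------------------------------------------------------------------------
# Vertex-level parcellation
# ---------------------------------------------------------------------------

def parcellate_vertex_ct(vertex_ct: np.ndarray, parcellation: MosaicParcellation, subject_id: str = "subject") -> MosaicCTVector:
    """Average per-vertex CT into parcel means.

    ``parcellation.vertex_to_parcel`` must be present; background vertices
    (mapped to -1) are excluded.  A parcel with zero assigned vertices is an
    error — it would otherwise silently produce NaN.
    """
    if parcellation.vertex_to_parcel is None:
        raise ConfigError("parcellation has no vertex_to_parcel map")
    v2p = np.asarray(parcellation.vertex_to_parcel)
    vertex_ct = np.asarray(vertex_ct, dtype=float)
    if vertex_ct.shape != v2p.shape:
        raise IngestError(f"vertex CT length {vertex_ct.shape} does not match vertex map {v2p.shape}")
    n = parcellation.n_parcels
    counts = np.bincount(v2p[v2p >= 0], minlength=n)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        names = [parcellation.parcel_ids[i] for i in empty[:10]]
        raise IngestError(f"parcels with zero assigned vertices: {names}")
    sums = np.bincount(v2p[v2p >= 0], weights=vertex_ct[v2p >= 0], minlength=n)
    return MosaicCTVector(subject_id=subject_id, values=sums / counts)


# ---------------------------------------------------------------------------
# Result maps
# ---------------------------------------------------------------------------

def atrophy_map_frame(amap: AtrophyMap) -> pd.DataFrame:
    return pd.DataFrame(
        {"parcel_id": amap.parcel_ids, "z": amap.z, "p": amap.p, "atrophic": amap.atrophic}
    )


def write_atrophy_map(amap: AtrophyMap, path: str | Path, format: str = "tsv") -> None:
    """Serialise an AtrophyMap; TSV columns parcel_id, z, p, atrophic (parcel order);
    JSON additionally records n_matched and alpha."""
    path = Path(path)
    if format == "tsv":
        atrophy_map_frame(amap).to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif format == "json":
        payload = {
            "subject_id": amap.subject_id,
            "n_matched": amap.n_matched,
            "alpha": amap.alpha,
            "parcel_id": list(amap.parcel_ids),
            "z": [round(float(v), 6) for v in amap.z],
            "p": [float(v) for v in amap.p],
            "atrophic": [int(v) for v in amap.atrophic],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ConfigError(f"unknown atrophy map format {format!r}")


def read_atrophy_map(path: str | Path, subject_id: str | None = None, n_matched: int = 0, alpha: float = DEFAULT_ALPHA) -> AtrophyMap:
    """Read back a TSV or JSON atrophy map."""
    path = Path(path)
    if path.suffix == ".json":
        d = json.loads(path.read_text())
        return AtrophyMap(
            subject_id=d["subject_id"], parcel_ids=list(d["parcel_id"]),
            z=np.array(d["z"]), p=np.array(d["p"]), atrophic=np.array(d["atrophic"]),
            n_matched=int(d["n_matched"]), alpha=float(d["alpha"]),
        )
    df = pd.read_csv(path, sep="\t", dtype={"parcel_id": str})
    return AtrophyMap(
        subject_id=subject_id or path.stem, parcel_ids=list(df["parcel_id"]),
        z=df["z"].to_numpy(), p=df["p"].to_numpy(), atrophic=df["atrophic"].to_numpy(),
        n_matched=n_matched, alpha=alpha,
    )


def write_fwer_map(fmap: FWERMap, path: str | Path, alpha: float = DEFAULT_ALPHA) -> None:
    """TSV: parcel_id, observed_count, p_fwer, significant; metadata to a .json sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "parcel_id": fmap.parcel_ids,
            "observed_count": fmap.observed_counts,
            "p_fwer": fmap.p_fwer,
            "significant": (fmap.p_fwer <= alpha).astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
    meta = {"n_iterations": fmap.n_iterations, "mode": fmap.mode, "seed": fmap.seed, "alpha": alpha}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Optional CIFTI layer (nibabel)
# ---------------------------------------------------------------------------

def _read_pscalar(path: Path) -> tuple[list[MosaicCTVector], MosaicParcellation]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    ax0 = img.header.get_axis(0)  # scalar axis: one map per subject
    ax1 = img.header.get_axis(1)  # parcels axis
    parcel_ids = list(ax1.name)
    subjects = list(ax0.name)
    vectors = [MosaicCTVector(subject_id=s, values=data[i]) for i, s in enumerate(subjects)]
    return vectors, MosaicParcellation(parcel_ids=parcel_ids)


def read_dlabel_parcellation(path: str | Path) -> MosaicParcellation:
    """Read a CIFTI-2 dlabel parcellation into a vertex->parcel map.

    Label key 0 (usually '???') is treated as background.
    """
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()[0]).astype(int)
    ax = img.header.get_axis(0)
    table = ax.label[0]  # key -> (name, rgba)
    keys = sorted(k for k in table if k != 0)
    parcel_ids = [table[k][0] for k in keys]
    remap = {k: i for i, k in enumerate(keys)}
    v2p = np.array([remap.get(k, -1) for k in labels], dtype=int)
    return MosaicParcellation(parcel_ids=parcel_ids, vertex_to_parcel=v2p)
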