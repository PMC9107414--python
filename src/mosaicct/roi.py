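"""Composite-ROI overlay and regional thin-patch summaries (radar data).

Four composite ROIs are analysed: motor (pre- + paracentral gyri),
frontal, parietal and temporal cortices, defined as unions of
Desikan-Killiany regions.  The region -> composite membership ships as an
editable data file (``data/dk_composite_rois.tsv``); insula, cingulate and
occipital regions map to "none" and contribute to whole-brain fractions
only.

A mosaic parcel is assigned to the composite ROI containing the plurality
of its vertices; ties are broken by a fixed precedence order
(motor, frontal, parietal, temporal) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, IngestError
from .io import AtrophyMap, MosaicParcellation, RadarSummary, ROI_LABELS, ROI_NONE

logger = logging.getLogger("mosaicct")

#: Deterministic tie-break order for plurality votes.
ROI_PRECEDENCE = ("motor", "frontal", "parietal", "temporal")


@dataclass(frozen=True)
class ROIDefinition:
    roi_label: str
    anatomical_members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.anatomical_members:
            raise IngestError(f"ROI {self.roi_label!r} has no anatomical members")


def default_roi_definitions() -> list[ROIDefinition]:
    """Composite ROIs from the packaged Desikan-Killiany membership table."""
    with resources.files("mosaicct.data").joinpath("dk_composite_rois.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = []
    for roi in ROI_LABELS:
        members = tuple(df.loc[df["roi"] == roi, "region"])
        out.append(ROIDefinition(roi_label=roi, anatomical_members=members))
    return out


def overlay_parcellation(
    parcellation: MosaicParcellation,
    anatomical_labels: Sequence[str] | np.ndarray,
    rois: Sequence[ROIDefinition] | None = None,
) -> dict[str, str]:
    """Assign each parcel to the composite ROI holding the plurality of its vertices.

    ``anatomical_labels`` gives one anatomical-atlas region name per vertex,
    in the same vertex space as ``parcellation.vertex_to_parcel``.  Regions
    outside every composite ROI count toward "none".
    """
    if parcellation.vertex_to_parcel is None:
        raise IngestError("parcellation has no vertex_to_parcel map; cannot overlay")
    v2p = np.asarray(parcellation.vertex_to_parcel)
    labels = np.asarray(anatomical_labels)
    if labels.shape != v2p.shape:
        raise IngestError(
            f"vertex counts differ: {labels.shape[0]} anatomical labels vs {v2p.shape[0]} vertex map entries"
        )
    if rois is None:
        rois = default_roi_definitions()
    region_to_roi = {m: r.roi_label for r in rois for m in r.anatomical_members}

    roi_order = [*ROI_PRECEDENCE, ROI_NONE]
    roi_index = {r: i for i, r in enumerate(roi_order)}
    vert_roi = np.array([roi_index.get(region_to_roi.get(l, ROI_NONE), roi_index[ROI_NONE])
                         for l in labels])

    n = parcellation.n_parcels
    votes = np.zeros((n, len(roi_order)), dtype=np.int64)
    inside = v2p >= 0
    np.add.at(votes, (v2p[inside], vert_roi[inside]), 1)

    parcel_to_roi: dict[str, str] = {}
    best = votes.max(axis=1)
    for k, pid in enumerate(parcellation.parcel_ids):
        winners = np.flatnonzero(votes[k] == best[k])
        if best[k] == 0:
            parcel_to_roi[pid] = ROI_NONE
            continue
        if winners.size > 1:
            # precedence order of roi_order already resolves the tie (first wins)
            logger.warning(
                "parcel %r: plurality tie between %s; assigning %s",
                pid, [roi_order[w] for w in winners], roi_order[winners[0]],
            )
        parcel_to_roi[pid] = roi_order[winners[0]]
    return parcel_to_roi


def roi_fractions(amap: AtrophyMap, parcel_to_roi: Mapping[str, str]) -> RadarSummary:
    """Per-ROI and whole-brain fraction of atrophic parcels for one subject."""
    roi_vec = np.array([parcel_to_roi.get(p, ROI_NONE) for p in amap.parcel_ids])
    fractions = {}
    for roi in ROI_LABELS:
        mask = roi_vec == roi
        if not mask.any():
            raise DegenerateDataError(f"ROI {roi!r} contains no parcels")
        fractions[roi] = float(amap.atrophic[mask].mean())
    return RadarSummary(fractions=fractions, whole_brain=float(amap.atrophic.mean()))


def group_radar(maps: Sequence[AtrophyMap], parcel_to_roi: Mapping[str, str]) -> RadarSummary:
    """Group-level radar: arithmetic mean of per-subject ROI fractions."""
    if not maps:
        raise IngestError("no atrophy maps given")
    summaries = [roi_fractions(m, parcel_to_roi) for m in maps]
    fractions = {roi: float(np.mean([s.fractions[roi] for s in summaries])) for roi in ROI_LABELS}
    return RadarSummary(
        fractions=fractions,
        whole_brain=float(np.mean([s.whole_brain for s in summaries])),
    )
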