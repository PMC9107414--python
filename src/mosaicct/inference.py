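"""Group-level permutation inference on binary atrophy ('hit') matrices.

For each clinical group, individual atrophy maps are stacked into a
patients x parcels binary matrix.  The null hypothesis is that each
patient's atrophic parcels are placed at random over the cortex: every
iteration independently permutes each patient's row across parcel
positions (preserving that patient's total burden) and records the
per-parcel count of patients with a hit.

Two p-value modes are provided:

``paper_pointwise``
    p[k] = (# iterations whose permuted count at parcel k strictly exceeds
    the observed count) / n_iterations.  This is a per-parcel (pointwise)
    null; p may equal 0.

``max_statistic`` (default)
    per iteration the maximum count over parcels is recorded and
    p[k] = (1 + #{max ≥ observed count at k}) / (n_iterations + 1).
    The add-one correction makes this a valid family-wise
    error-controlling p-value in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, IngestError
from .io import AtrophyMap, FWERMap, HitMatrix, DEFAULT_ALPHA

logger = logging.getLogger("mosaicct")

MODES = ("paper_pointwise", "max_statistic")

#: Iterations are processed in fixed-size chunks so memory stays bounded;
#: the chunk size does not affect results (one RNG stream, fixed order).
_CHUNK = 500


@dataclass(frozen=True)
class PermutationConfig:
    n_iterations: int = 100_000
    mode: str = "max_statistic"
    seed: int = 0
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ConfigError(f"n_iterations must be >= 100, got {self.n_iterations}")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")


def build_hit_matrix(maps: Sequence[AtrophyMap], group: str | None = None) -> HitMatrix:
    """Stack atrophy maps of one group into a patients x parcels binary matrix."""
    if not maps:
        raise IngestError("no atrophy maps given")
    parcel_ids = maps[0].parcel_ids
    for m in maps[1:]:
        if m.parcel_ids != parcel_ids:
            raise IngestError(
                f"mixed parcellations: map {m.subject_id!r} does not share parcel order"
            )
    return HitMatrix(
        patient_ids=[m.subject_id for m in maps],
        parcel_ids=list(parcel_ids),
        matrix=np.vstack([m.atrophic for m in maps]),
    )


def permute_hits(hits: HitMatrix, config: PermutationConfig) -> FWERMap:
    """Monte-Carlo permutation p-map for a group hit matrix.

    Each iteration permutes every patient's row independently across parcels
    (row sums — per-patient burden — are conserved by construction) and
    tallies per-parcel counts of patients with a hit.
    """
    obs = np.asarray(hits.matrix, dtype=np.int8)
    n_pat, n_parc = obs.shape
    if n_pat < 1:
        raise IngestError("hit matrix has no patients")
    observed_counts = obs.sum(axis=0).astype(int)

    rng = np.random.default_rng(config.seed)
    if config.mode == "paper_pointwise":
        exceed = np.zeros(n_parc, dtype=np.int64)
    else:
        max_ge = np.zeros(n_parc, dtype=np.int64)

    done = 0
    while done < config.n_iterations:
        b = min(_CHUNK, config.n_iterations - done)
        block = np.broadcast_to(obs, (b, n_pat, n_parc)).copy()
        rng.permuted(block, axis=2, out=block)       # independent row shuffles
        counts = block.sum(axis=1)                   # (b, n_parc) permuted hit counts
        if config.mode == "paper_pointwise":
            exceed += (counts > observed_counts[None, :]).sum(axis=0)
        else:
            maxes = counts.max(axis=1)               # (b,) max statistic
            max_ge += (maxes[:, None] >= observed_counts[None, :]).sum(axis=0)
        done += b

    if config.mode == "paper_pointwise":
        p = exceed / config.n_iterations
    else:
        p = (1 + max_ge) / (config.n_iterations + 1)
    return FWERMap(
        parcel_ids=list(hits.parcel_ids),
        observed_counts=observed_counts,
        p_fwer=p,
        n_iterations=config.n_iterations,
        mode=config.mode,
        seed=config.seed,
    )


def threshold_fwer(fmap: FWERMap, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Binary significance map: 1 where p_fwer ≤ alpha (inclusive)."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    return (fmap.p_fwer <= alpha).astype(int)
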