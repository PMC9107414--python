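"""Single-subject normative scoring of parcellated cortical thickness.

The core procedure rates one patient's parcel-wise CT against a
demographically matched normative bank:

1. restrict the control bank to controls within ±2 years of the patient's
   age (inclusive) and of the same sex;
2. per parcel, build a non-parametric null by leave-one-out z-scoring each
   matched control against the remaining controls;
3. z-score the patient against the matched controls;
4. rank p-value = (# null z-scores strictly below the patient's z) / n;
5. label a parcel atrophic when p ≤ alpha (0.05 by default, inclusive).

The rank p-value takes only values k/n, so its resolution is set by the
matched-bank size: below 20 controls p ≤ 0.05 is unattainable, hence the
``min_controls`` floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateDataError, MatchingError
from .io import AtrophyMap, ControlBank, MosaicCTVector, SubjectRecord, DEFAULT_ALPHA

logger = logging.getLogger("mosaicct")

#: Two null z-scores closer than this are treated as tied in rank counting.
TIE_TOL = 1e-12


@dataclass(frozen=True)
class MatchSpec:
    """Demographic matching rule: age window (years, inclusive) and sex equality."""

    age_window: float = 2.0
    sex_match: bool = True
    min_controls: int = 20

    def __post_init__(self) -> None:
        if self.age_window < 0:
            raise ConfigError(f"age_window must be >= 0, got {self.age_window}")
        if self.min_controls < 3:
            raise ConfigError(f"min_controls must be >= 3, got {self.min_controls}")


@dataclass
class NullDistribution:
    """Leave-one-out z-scores of the matched controls at one parcel."""

    parcel_id: str
    z_controls: np.ndarray


def match_controls(patient: SubjectRecord, bank: ControlBank, spec: MatchSpec = MatchSpec()) -> ControlBank:
    """Subset the bank to age- and sex-matched controls for one patient.

    Ages are compared as real years, window endpoints inclusive.
    """
    if bank.n_controls == 0:
        raise MatchingError("control bank is empty")
    mask = np.abs(bank.ages - patient.age) <= spec.age_window
    if spec.sex_match:
        mask &= bank.sexes == patient.sex
    n = int(mask.sum())
    if n < spec.min_controls:
        raise MatchingError(
            f"patient {patient.subject_id!r} (age {patient.age}, {patient.sex}): "
            f"only {n} matched controls, need >= {spec.min_controls}"
        )
    if n < 30:
        logger.warning(
            "patient %r: only %d matched controls; rank p resolution is 1/%d",
            patient.subject_id, n, n,
        )
    return bank.subset(mask)


def _loo_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out mean and sample SD of the remaining values, per row element.

    For a (n,) or (n, P) array, returns arrays of the same shape where entry i
    holds mean/SD over the other n-1 entries of its column (sample SD, n-2
    denominator over the n-1 remaining values).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise DegenerateDataError(f"need >= 3 controls for leave-one-out nulls, got {n}")
    s = x.sum(axis=0, keepdims=True)
    ss = (x * x).sum(axis=0, keepdims=True)
    mean_o = (s - x) / (n - 1)
    var_o = (ss - x * x - (n - 1) * mean_o**2) / (n - 2)
    var_o = np.maximum(var_o, 0.0)  # guard tiny negative round-off
    return mean_o, np.sqrt(var_o)


def loo_z_null(matched: ControlBank, parcel: str) -> NullDistribution:
    """Null distribution for one parcel: each control z-scored against the rest."""
    try:
        j = matched.parcel_ids.index(parcel)
    except ValueError:
        raise ConfigError(f"unknown parcel {parcel!r}") from None
    x = matched.matrix[:, j]
    mean_o, sd_o = _loo_moments(x)
    if (sd_o == 0).any():
        raise DegenerateDataError(f"parcel {parcel!r}: zero spread among matched controls")
    return NullDistribution(parcel_id=parcel, z_controls=(x - mean_o) / sd_o)


def loo_z_null_matrix(matched: ControlBank) -> np.ndarray:
    """All parcels at once: (n_controls, n_parcels) leave-one-out z-scores."""
    mean_o, sd_o = _loo_moments(matched.matrix)
    zero = np.flatnonzero((sd_o == 0).any(axis=0))
    if zero.size:
        names = [matched.parcel_ids[k] for k in zero[:10]]
        raise DegenerateDataError(f"zero control spread at parcels {names}")
    return (matched.matrix - mean_o) / sd_o


def patient_z(patient_ct: MosaicCTVector, matched: ControlBank) -> np.ndarray:
    """Patient z per parcel against the matched controls (sample SD, n-1)."""
    if matched.n_controls < 3:
        raise DegenerateDataError(f"need >= 3 matched controls, got {matched.n_controls}")
    if len(patient_ct.values) != len(matched.parcel_ids):
        raise ConfigError("patient CT vector and control bank have different parcel counts")
    m = matched.matrix.mean(axis=0)
    s = matched.matrix.std(axis=0, ddof=1)
    zero = np.flatnonzero(s == 0)
    if zero.size:
        names = [matched.parcel_ids[k] for k in zero[:10]]
        raise DegenerateDataError(f"zero control spread at parcels {names}")
    return (patient_ct.values - m) / s


def rank_p(z_patient: float | np.ndarray, null: NullDistribution | np.ndarray, tie_mode: str = "strict") -> float | np.ndarray:
    """Rank p-value: fraction of null z-scores below the patient's z.

    ``strict`` counts only strictly smaller null values (ties, within
    ``TIE_TOL``, contribute 0); ``midrank`` lets ties contribute 0.5 for
    smoother calibration.  p may equal 0; values are multiples of 1/n.
    """
    zc = null.z_controls if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if zc.size == 0:
        raise DegenerateDataError("empty null distribution")
    if tie_mode not in ("strict", "midrank"):
        raise ConfigError(f"tie_mode must be 'strict' or 'midrank', got {tie_mode!r}")
    z = np.asarray(z_patient, dtype=float)
    smaller = (zc < z[..., None] - TIE_TOL).sum(axis=-1).astype(float)
    if tie_mode == "midrank":
        ties = (np.abs(zc - z[..., None]) <= TIE_TOL).sum(axis=-1)
        smaller = smaller + 0.5 * ties
    p = smaller / zc.shape[-1]
    return float(p) if np.isscalar(z_patient) or np.ndim(z_patient) == 0 else p


def label_atrophy(p: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Binary atrophy labels: 1 where p ≤ alpha (inclusive threshold)."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    return (np.asarray(p, dtype=float) <= alpha).astype(int)


def score_subject(
    patient: SubjectRecord,
    patient_ct: MosaicCTVector,
    bank: ControlBank,
    spec: MatchSpec = MatchSpec(),
    alpha: float = DEFAULT_ALPHA,
    tie_mode: str = "strict",
) -> AtrophyMap:
    """Full single-subject scoring: match, build nulls, z-score, rank, label.

    Deterministic given its inputs; all parcels are scored in the bank's
    parcel order.
    """
    matched = match_controls(patient, bank, spec)
    null_z = loo_z_null_matrix(matched)              # (n_matched, P)
    zp = patient_z(patient_ct, matched)              # (P,)
    # per-parcel rank of the patient within that parcel's null
    if tie_mode == "strict":
        smaller = (null_z < zp[None, :] - TIE_TOL).sum(axis=0).astype(float)
    elif tie_mode == "midrank":
        smaller = (null_z < zp[None, :] - TIE_TOL).sum(axis=0).astype(float)
        smaller += 0.5 * (np.abs(null_z - zp[None, :]) <= TIE_TOL).sum(axis=0)
    else:
        raise ConfigError(f"tie_mode must be 'strict' or 'midrank', got {tie_mode!r}")
    p = smaller / matched.n_controls
    return AtrophyMap(
        subject_id=patient.subject_id,
        parcel_ids=list(bank.parcel_ids),
        z=zp,
        p=p,
        atrophic=label_atrophy(p, alpha),
        n_matched=matched.n_controls,
        alpha=alpha,
    )


def thin_patch_stats(amap: AtrophyMap) -> tuple[int, float]:
    """Number and fraction of parcels labelled atrophic ('thin-patch count')."""
    count = int(amap.atrophic.sum())
    return count, count / len(amap.parcel_ids)
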