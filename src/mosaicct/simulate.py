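"""Synthetic data: normative control banks and patients with regional atrophy.

The generator emulates the statistical structure the scoring method
assumes: per-parcel mean CT is Gaussian across subjects with a cortical
baseline of 2.2 mm and between-subject SD of 0.10 mm (typical of
group-level parcel means in adult cohorts), ages uniform over the adult
range sampled, sexes Bernoulli.  Patients are drawn from the same
distribution and then a chosen fraction of each target ROI's parcels is
shifted downward by a multiple of the between-subject SD; the affected
parcels are returned as ground truth for recovery testing.

Parcels are independent by default (the scoring is rank-based per parcel);
an optional exchangeable between-parcel correlation stresses the
family-wise permutation inference, and an optional linear age slope lets
tests verify that demographic matching absorbs age confounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import (
    ControlBank,
    MosaicCTVector,
    MosaicParcellation,
    SubjectRecord,
    CT_MIN_MM,
    CT_MAX_MM,
    ROI_LABELS,
    ROI_NONE,
)

#: ROI sizes of the canonical 1000-parcel scheme overlaid on the
#: Desikan-Killiany atlas: motor, parietal, temporal, frontal.
CANONICAL_ROI_SIZES = {"motor": 122, "parietal": 185, "temporal": 150, "frontal": 200}
CANONICAL_N_PARCELS = 1000


@dataclass(frozen=True)
class BankSpec:
    """Parameters of a synthetic normative control bank."""

    n_controls: int = 200
    age_range: tuple[float, float] = (50.0, 73.0)
    mean_ct: float = 2.2       # mm, per-parcel baseline
    sd_ct: float = 0.10        # mm, between-subject SD
    sex_ratio: float = 0.5     # proportion female
    age_slope: float = 0.0     # mm per year, optional confound (e.g. -0.005)
    parcel_correlation: float = 0.0  # exchangeable between-parcel correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 3:
            raise ConfigError(f"n_controls must be >= 3, got {self.n_controls}")
        if self.sd_ct <= 0:
            raise ConfigError(f"sd_ct must be positive, got {self.sd_ct}")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigError(f"sex_ratio must lie in [0, 1], got {self.sex_ratio}")
        if not 0 <= self.parcel_correlation < 1:
            raise ConfigError(f"parcel_correlation must lie in [0, 1), got {self.parcel_correlation}")
        if self.age_range[1] <= self.age_range[0]:
            raise ConfigError(f"empty age_range {self.age_range}")


@dataclass(frozen=True)
class AtrophyScenario:
    """A phenotype-like atrophy pattern: per-ROI z-shifts in control-SD units."""

    group_label: str
    effects: dict = field(default_factory=dict)   # roi -> shift (negative = thinning)
    fraction_affected: float = 1.0                # proportion of each target ROI's parcels
    n_patients: int = 20
    age_mean: float = 61.5
    age_sd: float = 3.0
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_affected <= 1:
            raise ConfigError(f"fraction_affected must lie in [0, 1], got {self.fraction_affected}")
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        bad = set(self.effects) - {*ROI_LABELS, ROI_NONE}
        if bad:
            raise ConfigError(f"unknown ROI keys in effects: {sorted(bad)}")


#: Phenotype-like presets: focal anterior-temporal thinning (semantic-variant
#: PPA like), predominantly frontal thinning (behavioural-variant FTD like),
#: motor-predominant thinning (ALS like), and a pure null.
SCENARIO_PRESETS = {
    "null": AtrophyScenario(group_label="null", effects={}),
    "svppa_like": AtrophyScenario(group_label="svPPA", effects={"temporal": -3.0}, fraction_affected=1.0),
    "bvftd_like": AtrophyScenario(group_label="bvFTD", effects={"frontal": -2.5, "temporal": -1.0}, fraction_affected=0.6),
    "motor_like": AtrophyScenario(group_label="ALS", effects={"motor": -2.5}, fraction_affected=0.8),
}


def generate_toy_parcellation(
    n_parcels: int = CANONICAL_N_PARCELS,
    roi_sizes: dict | None = None,
) -> MosaicParcellation:
    """A parcellation with block ROI assignment; remainder labelled "none".

    With no ``roi_sizes`` the canonical 122/185/150/200 composition is used
    at n=1000 and scaled proportionally for miniatures.
    """
    if roi_sizes is None:
        scale = n_parcels / CANONICAL_N_PARCELS
        roi_sizes = {r: int(round(s * scale)) for r, s in CANONICAL_ROI_SIZES.items()}
    total = sum(roi_sizes.values())
    if total > n_parcels:
        raise ConfigError(f"ROI sizes sum to {total} > n_parcels {n_parcels}")
    parcel_ids = [f"parcel_{k:04d}" for k in range(n_parcels)]
    parcel_to_roi = {}
    k = 0
    for roi in ROI_LABELS:  # fixed block order: motor, parietal, temporal, frontal
        for _ in range(roi_sizes.get(roi, 0)):
            parcel_to_roi[parcel_ids[k]] = roi
            k += 1
    for pid in parcel_ids[k:]:
        parcel_to_roi[pid] = ROI_NONE
    return MosaicParcellation(parcel_ids=parcel_ids, parcel_to_roi=parcel_to_roi)


def _draw_ct(rng: np.random.Generator, n: int, ages: np.ndarray, spec: BankSpec, n_parcels: int) -> np.ndarray:
    rho = spec.parcel_correlation
    noise = rng.standard_normal((n, n_parcels))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    ct = spec.mean_ct + spec.sd_ct * noise + spec.age_slope * (ages[:, None] - mid_age)
    # truncate to the plausible range (essentially never triggers at defaults)
    return np.clip(ct, CT_MIN_MM + 1e-6, CT_MAX_MM - 1e-6)


def generate_control_bank(spec: BankSpec, parcellation: MosaicParcellation) -> ControlBank:
    """Draw a synthetic healthy-control bank; deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_controls)
    sexes = np.where(rng.random(spec.n_controls) < spec.sex_ratio, "female", "male")
    matrix = _draw_ct(rng, spec.n_controls, ages, spec, parcellation.n_parcels)
    records = [
        SubjectRecord(subject_id=f"hc_{i:04d}", age=float(ages[i]), sex=str(sexes[i]), group="HC")
        for i in range(spec.n_controls)
    ]
    return ControlBank(records=records, matrix=matrix, parcel_ids=list(parcellation.parcel_ids))


def generate_patients(
    scenario: AtrophyScenario,
    spec: BankSpec,
    parcellation: MosaicParcellation,
    seed: int = 1,
) -> tuple[list[SubjectRecord], list[MosaicCTVector], np.ndarray]:
    """Draw patients as controls plus region-targeted thinning.

    Within each ROI named in ``scenario.effects`` a random
    ``fraction_affected`` subset of parcels is shifted by
    effect x between-subject SD (independently per patient).  Returns
    (records, CT vectors, ground-truth affected mask of shape
    patients x parcels).

    Patient ages are clipped inside the bank's age range (inset by 2 years)
    so that every patient can draw a full matched reference group.
    """
    if parcellation.parcel_to_roi is None:
        raise ConfigError("parcellation carries no parcel->ROI assignment")
    rng = np.random.default_rng(seed)
    n, P = scenario.n_patients, parcellation.n_parcels
    lo, hi = spec.age_range[0] + 2.0, spec.age_range[1] - 2.0
    ages = np.clip(rng.normal(scenario.age_mean, scenario.age_sd, size=n), lo, hi)
    sexes = np.where(rng.random(n) < scenario.sex_ratio, "female", "male")
    matrix = _draw_ct(rng, n, ages, spec, P)

    roi_vec = parcellation.roi_vector()
    affected = np.zeros((n, P), dtype=bool)
    for roi, effect in scenario.effects.items():
        if effect == 0:
            continue
        roi_idx = np.flatnonzero(roi_vec == roi)
        n_hit = int(round(scenario.fraction_affected * roi_idx.size))
        for i in range(n):
            hit = rng.choice(roi_idx, size=n_hit, replace=False)
            matrix[i, hit] += effect * spec.sd_ct
            affected[i, hit] = True
    matrix = np.clip(matrix, CT_MIN_MM + 1e-6, CT_MAX_MM - 1e-6)

    records = [
        SubjectRecord(
            subject_id=f"{scenario.group_label}_{i:03d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            group=scenario.group_label,
        )
        for i in range(n)
    ]
    vectors = [MosaicCTVector(subject_id=records[i].subject_id, values=matrix[i]) for i in range(n)]
    return records, vectors, affected
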