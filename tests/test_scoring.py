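import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosaicct import (
    DegenerateDataError,
    MatchingError,
    MatchSpec,
    MosaicCTVector,
    SubjectRecord,
    label_atrophy,
    loo_z_null,
    loo_z_null_matrix,
    match_controls,
    patient_z,
    rank_p,
    score_subject,
    thin_patch_stats,
)
from conftest import make_bank


class TestMatchControls:
    def test_age_window_inclusive(self, patient_record):
        bank = make_bank(np.full((5, 2), 2.2), ages=[57, 58, 60, 62, 63])
        sub = match_controls(patient_record, bank, MatchSpec(min_controls=3))
        assert sorted(r.age for r in sub.records) == [58, 60, 62]

    def test_sex_mismatch_yields_no_matches(self, patient_record):
        bank = make_bank(np.full((5, 2), 2.2), sexes=["male"] * 5)
        with pytest.raises(MatchingError, match="0 matched"):
            match_controls(patient_record, bank, MatchSpec(min_controls=3))

    def test_zero_window_keeps_exact_ages_only(self, patient_record):
        bank = make_bank(np.full((6, 2), 2.2), ages=[59.0, 60.0, 60.0, 60.0, 61.0, 60.5])
        sub = match_controls(
            patient_record, bank, MatchSpec(age_window=0.0, min_controls=3)
        )
        assert all(r.age == 60.0 for r in sub.records) and sub.n_controls == 3


class TestLooZNull:
    def test_hand_computed_three_controls(self):
        bank = make_bank(np.array([[1.0], [2.0], [3.0]]) + 1.5)  # shift into CT range
        null = loo_z_null(bank, "p0")
        np.testing.assert_allclose(
            sorted(null.z_controls), [-2.1213, 0.0, 2.1213], atol=1e-4
        )

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        x = 2.2 + 0.1 * rng.standard_normal(25)
        bank = make_bank(x[:, None])
        fast = loo_z_null(bank, "p0").z_controls
        naive = np.array(
            [
                (x[i] - np.delete(x, i).mean()) / np.delete(x, i).std(ddof=1)
                for i in range(len(x))
            ]
        )
        np.testing.assert_allclose(fast, naive, rtol=1e-10)

    def test_constant_controls_are_degenerate(self):
        bank = make_bank(np.full((10, 1), 2.2))
        with pytest.raises(DegenerateDataError, match="p0"):
            loo_z_null(bank, "p0")

    def test_exchangeable_null_has_near_zero_mean(self):
        rng = np.random.default_rng(2)
        n = 400
        bank = make_bank(2.2 + 0.1 * rng.standard_normal((n, 1)))
        z = loo_z_null(bank, "p0").z_controls
        assert abs(z.mean()) < 3 * z.std() / np.sqrt(n)


class TestPatientZ:
    def test_hand_computed(self):
        bank = make_bank(np.array([[1.0], [2.0], [3.0]]) + 0.5)
        z = patient_z(MosaicCTVector("pt", [2.0]), bank)
        np.testing.assert_allclose(z, [-0.5])

    def test_zero_at_control_mean(self):
        rng = np.random.default_rng(4)
        m = 2.2 + 0.1 * rng.standard_normal((12, 3))
        bank = make_bank(m)
        z = patient_z(MosaicCTVector("pt", m.mean(axis=0)), bank)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        m = 2.2 + 0.1 * rng.standard_normal((15, 4))
        pt = 2.2 + 0.1 * rng.standard_normal(4)
        z0 = patient_z(MosaicCTVector("pt", pt), make_bank(m))
        z1 = patient_z(MosaicCTVector("pt", 0.5 * pt + 0.8), make_bank(0.5 * m + 0.8))
        np.testing.assert_allclose(z0, z1, rtol=1e-9)


class TestRankP:
    def test_continues_hand_example(self):
        p = rank_p(-0.5, np.array([-2.1213, 0.0, 2.1213]))
        assert p == pytest.approx(1 / 3)

    def test_extreme_rank_gives_zero(self):
        assert rank_p(-10.0, np.array([-2.0, 0.0, 2.0])) == 0.0

    def test_matches_naive_counting_loop(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            null = rng.standard_normal(rng.integers(3, 40))
            z = rng.standard_normal()
            assert rank_p(z, null) == sum(v < z for v in null) / len(null)

    def test_tie_handling(self):
        null = np.array([-1.0, 0.0, 1.0, 1.0])
        assert rank_p(1.0, null) == pytest.approx(0.5)          # ties excluded
        assert rank_p(1.0, null, tie_mode="midrank") == pytest.approx(0.75)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_patient_z(self, a, b):
        null = np.linspace(-2, 2, 17)
        lo, hi = min(a, b), max(a, b)
        assert rank_p(lo, null) <= rank_p(hi, null)


def test_label_atrophy_inclusive_threshold():
    p = np.array([0.0, 0.05, 0.0500000001, 0.06, 1.0])
    np.testing.assert_array_equal(label_atrophy(p, 0.05), [1, 1, 0, 0, 0])
    # relaxed display threshold labels a superset
    assert (label_atrophy(p, 0.06) >= label_atrophy(p, 0.05)).all()


class TestScoreSubject:
    def test_deterministic_and_order_invariant(self, small_bank, patient_record):
        rng = np.random.default_rng(8)
        ct = MosaicCTVector("pt0", 2.2 + 0.1 * rng.standard_normal(50))
        spec = MatchSpec(min_controls=10)
        a = score_subject(patient_record, ct, small_bank, spec)
        b = score_subject(patient_record, ct, small_bank, spec)
        np.testing.assert_array_equal(a.p, b.p)
        perm = rng.permutation(small_bank.n_controls)
        shuffled = small_bank.subset(np.argsort(np.argsort(perm)) >= 0)  # full mask
        shuffled.records = [small_bank.records[i] for i in perm]
        shuffled.matrix = small_bank.matrix[perm]
        c = score_subject(patient_record, ct, shuffled, spec)
        np.testing.assert_allclose(a.z, c.z, rtol=1e-12)
        np.testing.assert_array_equal(a.atrophic, c.atrophic)

    def test_p_values_are_multiples_of_reciprocal_n(self, small_bank, patient_record):
        rng = np.random.default_rng(9)
        ct = MosaicCTVector("pt0", 2.2 + 0.1 * rng.standard_normal(50))
        amap = score_subject(patient_record, ct, small_bank, MatchSpec(min_controls=10))
        k = amap.p * amap.n_matched
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)
        assert amap.n_matched == small_bank.n_controls

    def test_affine_shift_leaves_labels_unchanged(self, small_bank, patient_record):
        rng = np.random.default_rng(10)
        ct = 2.2 + 0.1 * rng.standard_normal(50)
        spec = MatchSpec(min_controls=10)
        a = score_subject(patient_record, MosaicCTVector("pt0", ct), small_bank, spec)
        shifted = make_bank(
            small_bank.matrix + 0.3,
            ages=[r.age for r in small_bank.records],
            sexes=[r.sex for r in small_bank.records],
            parcel_ids=small_bank.parcel_ids,
        )
        b = score_subject(patient_record, MosaicCTVector("pt0", ct + 0.3), shifted, spec)
        np.testing.assert_allclose(a.z, b.z, atol=1e-9)
        np.testing.assert_array_equal(a.atrophic, b.atrophic)

    def test_strong_focal_thinning_is_detected(self, small_bank, patient_record):
        rng = np.random.default_rng(12)
        ct = 2.2 + 0.1 * rng.standard_normal(50)
        ct[:20] -= 0.4  # -4 SD on 20 designated parcels
        amap = score_subject(
            patient_record, MosaicCTVector("pt0", ct), small_bank, MatchSpec(min_controls=10)
        )
        assert amap.atrophic[:20].mean() >= 0.95


def test_held_out_control_calibration():
    """A held-out control scored against the remaining 99 has P(p <= 0.05)
    within the binomial 99% CI of 0.05 (2000 replicates)."""
    rng = np.random.default_rng(123)
    reps, n = 2000, 100
    hits = 0
    for _ in range(reps):
        x = 2.2 + 0.1 * rng.standard_normal(n)
        bank = make_bank(x[1:][:, None])
        null = loo_z_null(bank, "p0").z_controls
        zp = patient_z(MosaicCTVector("pt", [x[0]]), bank)[0]
        hits += rank_p(zp, null) <= 0.05
    rate = hits / reps
    tol = 2.576 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < tol


def test_thin_patch_stats_identity():
    amap_args = dict(subject_id="s", parcel_ids=[f"p{i}" for i in range(10)],
                     z=np.zeros(10), n_matched=30)
    from mosaicct import AtrophyMap

    atro = np.array([1, 0, 1, 0, 0, 0, 0, 0, 1, 0])
    amap = AtrophyMap(p=atro * 0.05, atrophic=atro, **amap_args)
    count, frac = thin_patch_stats(amap)
    assert count == 3 and frac == pytest.approx(atro.mean())
    zero = AtrophyMap(p=np.ones(10), atrophic=np.zeros(10), **amap_args)
    assert thin_patch_stats(zero) == (0, 0.0)
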