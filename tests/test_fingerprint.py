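import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connfp.fc import DFCConfig, DynamicStates, cluster_states
from connfp.fingerprint import (
    CohortFC,
    SubjectFC,
    classify_sex,
    cosine_similarity,
    cross_condition_experiment,
    dfc_similarity,
    group_average_fc,
    identify,
    run_identification_experiment,
)
from connfp.io_core import FCVector, ValidationError, devectorize


def _vec(vals):
    vals = np.asarray(vals, dtype=float)
    # length must be triangular; tests use lengths 1, 3, 6, 10, ...
    from connfp.io_core import _n_from_triangular
    return FCVector(values=vals, n_nodes=_n_from_triangular(len(vals)))


def _states(vectors, counts):
    """DynamicStates with given (already occupancy-ordered) state vectors."""
    states = [devectorize(v, method_tag="dfc_state") for v in vectors]
    counts = np.asarray(counts)
    return DynamicStates(
        states=states, counts=counts,
        window_assignments=np.repeat(np.arange(len(states)), counts))


class TestCosineSimilarity:
    @pytest.mark.parametrize("x,y,expected", [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
        ([1.0, 0.0, 0.0], [0.0, 1.0, 0.0], 0.0),
        ([1.0, 1.0, 0.0], [1.0, 0.0, 0.0], 1.0 / np.sqrt(2)),
        ([1.0, 2.0, -1.0], [-1.0, -2.0, 1.0], -1.0),
    ])
    def test_closed_form_values(self, x, y, expected):
        assert cosine_similarity(_vec(x), _vec(y)) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValidationError, match="zero-norm"):
            cosine_similarity(_vec([0.0, 0.0, 0.0]), _vec([1.0, 0.0, 0.0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 2**20),
           a=st.floats(0.1, 10), b=st.floats(0.1, 10),
           sa=st.sampled_from([-1.0, 1.0]), sb=st.sampled_from([-1.0, 1.0]))
    def test_bounded_symmetric_scale_invariant(self, seed, a, b, sa, sb):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        cs = cosine_similarity(_vec(x), _vec(y))
        assert -1.0 - 1e-12 <= cs <= 1.0 + 1e-12
        assert cosine_similarity(_vec(y), _vec(x)) == pytest.approx(cs, abs=1e-12)
        scaled = cosine_similarity(_vec(sa * a * x), _vec(sb * b * y))
        assert scaled == pytest.approx(sa * sb * cs, abs=1e-9)


class TestDfcSimilarity:
    def test_identical_state_sets_give_one(self):
        s = _states([np.array([1.0, 0, 0]), np.array([0, 1.0, 0])], [6, 4])
        assert dfc_similarity(s, s, "rank") == pytest.approx(1.0)
        assert dfc_similarity(s, s, "best_match") == pytest.approx(1.0)

    def test_rank_swap_of_orthogonal_states(self):
        a = _states([np.array([1.0, 0, 0]), np.array([0, 1.0, 0])], [6, 4])
        b = _states([np.array([0, 1.0, 0]), np.array([1.0, 0, 0])], [6, 4])
        assert dfc_similarity(a, b, "rank") == pytest.approx(0.0)
        assert dfc_similarity(a, b, "best_match") == pytest.approx(1.0)

    def test_k1_reduces_to_cosine(self):
        x, y = np.array([1.0, 1, 0]), np.array([1.0, 0, 0])
        a, b = _states([x], [3]), _states([y], [3])
        assert dfc_similarity(a, b, "rank") == pytest.approx(
            cosine_similarity(_vec(x), _vec(y)))

    def test_state_count_mismatch_rejected(self):
        a = _states([np.array([1.0, 0, 0])], [3])
        b = _states([np.array([1.0, 0, 0]), np.array([0, 1.0, 0])], [2, 1])
        with pytest.raises(ValidationError):
            dfc_similarity(a, b)


class TestIdentify:
    def test_identity_assignment_for_duplicates(self, rng):
        base = [_vec(rng.standard_normal(10)) for _ in range(6)]
        np.testing.assert_array_equal(identify(base, base), np.arange(6))

    def test_single_baseline_takes_all(self, rng):
        base = [_vec(rng.standard_normal(10))]
        targets = [_vec(rng.standard_normal(10)) for _ in range(4)]
        np.testing.assert_array_equal(identify(base, targets), np.zeros(4, int))

    def test_small_perturbation_of_orthogonal_baselines(self, rng):
        eye = np.eye(10)
        base = [_vec(eye[k]) for k in range(5)]
        targets = []
        for k in range(5):
            noise = rng.standard_normal(10)
            noise *= 0.1 / np.linalg.norm(noise)
            targets.append(_vec(eye[k] + noise))
        np.testing.assert_array_equal(identify(base, targets), np.arange(5))

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValidationError):
            identify([], [_vec(np.ones(3))])


def _cohort_from_arrays(arrays, sexes=None):
    """arrays: (N, 2, E) -> CohortFC of FCVector sessions."""
    subjects = []
    for i, pair in enumerate(arrays):
        e = pair.shape[-1]
        from connfp.io_core import _n_from_triangular
        n = _n_from_triangular(e)
        subjects.append(SubjectFC(
            subject_id=f"sub{i:03d}",
            sex=(sexes[i] if sexes else ("M" if i % 2 == 0 else "F")),
            sessions={"S1": FCVector(values=pair[0], n_nodes=n),
                      "S2": FCVector(values=pair[1], n_nodes=n)},
        ))
    return CohortFC(subjects=subjects)


class TestIdentificationExperiment:
    def test_duplicate_sessions_are_perfectly_identified(self, rng):
        x = rng.standard_normal((8, 10))
        cohort = _cohort_from_arrays(np.stack([x, x], axis=1))
        res = run_identification_experiment(cohort, runs=20, seed=1)
        assert res.mean_accuracy == 100.0
        assert res.max_misidentifications == 0

    def test_reproducible_and_order_invariant(self, rng):
        arrays = rng.standard_normal((10, 2, 10))
        arrays[:, 1] = arrays[:, 0] + 0.5 * rng.standard_normal((10, 10))
        cohort = _cohort_from_arrays(arrays)
        res1 = run_identification_experiment(cohort, runs=15, seed=3)
        res2 = run_identification_experiment(cohort, runs=15, seed=3)
        np.testing.assert_array_equal(res1.per_run_accuracy, res2.per_run_accuracy)
        shuffled = CohortFC(subjects=list(reversed(cohort.subjects)))
        res3 = run_identification_experiment(shuffled, runs=15, seed=3)
        np.testing.assert_array_equal(res1.per_run_accuracy, res3.per_run_accuracy)

    def test_chance_level_without_subject_structure(self, rng):
        n = 50
        arrays = rng.standard_normal((n, 2, 45))  # sessions unrelated
        cohort = _cohort_from_arrays(arrays)
        res = run_identification_experiment(cohort, runs=100, seed=5)
        assert abs(res.mean_accuracy - 100.0 / n) < 3.0

    def test_misidentified_ids_recorded(self, rng):
        arrays = rng.standard_normal((5, 2, 10))
        cohort = _cohort_from_arrays(arrays)
        res = run_identification_experiment(cohort, runs=10, seed=2)
        assert len(res.misidentified) == 10
        assert res.max_misidentifications == max(len(m) for m in res.misidentified)
        for missed in res.misidentified:
            assert all(m.startswith("sub") for m in missed)

    def test_wrong_session_count_rejected(self, rng):
        cohort = _cohort_from_arrays(rng.standard_normal((4, 2, 10)))
        del cohort.subjects[0].sessions["S2"]
        with pytest.raises(ValidationError, match="exactly 2"):
            run_identification_experiment(cohort, runs=2, seed=0)


class TestCrossConditionExperiment:
    def test_same_cohort_reduces_to_within_cohort_experiment(self, rng):
        arrays = rng.standard_normal((6, 2, 10))
        arrays[:, 1] = arrays[:, 0]
        cohort = _cohort_from_arrays(arrays)
        res = cross_condition_experiment(cohort, cohort, runs=5, seed=1)
        assert res.mean_accuracy == 100.0

    def test_shared_shift_preserves_identification(self, rng):
        eye = np.eye(21)
        arrays = np.stack([eye[:6] * 3.0, eye[:6] * 3.0], axis=1)
        base = _cohort_from_arrays(arrays)
        shift = 0.2 * rng.standard_normal(21)
        shifted = arrays + shift  # identical shift for every subject
        target = _cohort_from_arrays(shifted)
        res = cross_condition_experiment(base, target, runs=10, seed=4)
        assert res.mean_accuracy == 100.0

    def test_random_targets_at_chance(self, rng):
        n = 40
        base = _cohort_from_arrays(rng.standard_normal((n, 2, 45)))
        target = _cohort_from_arrays(rng.standard_normal((n, 2, 45)))
        res = cross_condition_experiment(base, target, runs=50, seed=6)
        assert abs(res.mean_accuracy - 100.0 / n) < 3.0

    def test_subject_mismatch_rejected(self, rng):
        a = _cohort_from_arrays(rng.standard_normal((4, 2, 10)))
        b = _cohort_from_arrays(rng.standard_normal((5, 2, 10)))
        with pytest.raises(ValidationError, match="different subjects"):
            cross_condition_experiment(a, b, runs=1, seed=0)


class TestGroupAverage:
    def test_single_member_is_itself(self, random_fc):
        out = group_average_fc([random_fc])
        np.testing.assert_array_equal(out.values, random_fc.values)

    def test_opposite_members_cancel_then_zero_norm_surfaces(self, random_fc):
        from connfp.io_core import FCMatrix
        neg = FCMatrix(values=-random_fc.values, method_tag=random_fc.method_tag)
        avg = group_average_fc([random_fc, neg])
        assert np.all(avg.values == 0)
        with pytest.raises(ValidationError, match="zero-norm"):
            cosine_similarity(avg, random_fc)

    def test_elementwise_mean(self, rng):
        fcs = [devectorize(rng.standard_normal(45)) for _ in range(4)]
        avg = group_average_fc(fcs)
        np.testing.assert_allclose(
            avg.values, np.mean([f.values for f in fcs], axis=0))


class TestClassifySex:
    def test_disjoint_orthogonal_group_patterns(self):
        e = 10
        male = np.zeros(e); male[:3] = 1.0
        female = np.zeros(e); female[5:8] = 1.0
        arrays = np.stack([np.tile(male, (4, 1)), np.tile(male, (4, 1))], axis=1)
        arrays = np.concatenate([
            arrays,
            np.stack([np.tile(female, (4, 1)), np.tile(female, (4, 1))], axis=1),
        ])
        sexes = ["M"] * 4 + ["F"] * 4
        cohort = _cohort_from_arrays(arrays, sexes=sexes)
        res = classify_sex(cohort, runs=5, seed=1)
        assert res.mean_accuracy == 100.0

    def test_permuted_labels_at_chance(self, rng):
        n = 60
        arrays = rng.standard_normal((n, 2, 45))
        sexes = ["M" if k < n // 2 else "F" for k in rng.permutation(n)]
        cohort = _cohort_from_arrays(arrays, sexes=sexes)
        res = classify_sex(cohort, runs=50, seed=8)
        assert abs(res.mean_accuracy - 50.0) < 5.0

    def test_too_small_group_rejected(self, rng):
        arrays = rng.standard_normal((4, 2, 10))
        cohort = _cohort_from_arrays(arrays, sexes=["M", "M", "M", "F"])
        with pytest.raises(ValidationError, match="each sex"):
            classify_sex(cohort, runs=1, seed=0)
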