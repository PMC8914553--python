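import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matscale.confusion import PairCountMatrix, pair_counts
from matscale.data_io import DistanceUnit, default_vocabulary
from matscale.inference import DegenerateDataError
from matscale.msa import (
    MSAResult,
    analyze_exp1_msa,
    analyze_exp2_msa,
    chance_msa_groups,
    chance_msa_units,
    msa_from_counts,
    msa_from_vectors,
    rank_images,
    summarize_experiment,
)

VOCAB = default_vocabulary()
N_PAIRS_26 = 26 * 25 // 2  # 325


def brute_force_msa(counts: np.ndarray) -> float:
    """Independent oracle: explicit loop over unordered category pairs."""
    k = counts.shape[0]
    sq, n = 0.0, 0
    for a in range(k):
        for b in range(a + 1, k):
            sq += (counts[a, b] - counts[b, a]) ** 2
            n += 1
    return math.sqrt(sq / n)


def _matrix(counts, near_total=1, far_total=1, cats=None):
    counts = np.asarray(counts, dtype=float)
    cats = cats or tuple(f"c{i}" for i in range(counts.shape[0]))
    return PairCountMatrix("img", counts, tuple(cats), near_total, far_total)


class TestMSAFromCounts:
    def test_symmetric_matrix_is_zero(self):
        c = np.array([[0, 3, 1], [3, 0, 2], [1, 2, 5]], dtype=float)
        assert msa_from_counts(_matrix(c)) == 0.0

    def test_single_offdiagonal_cell_26_categories(self):
        m = pair_counts(["bark"] * 12, ["stone"] * 12)
        expected = math.sqrt(144**2 / N_PAIRS_26)  # = 7.9877
        assert msa_from_counts(m) == pytest.approx(expected)
        assert msa_from_counts(m) == pytest.approx(brute_force_msa(m.counts))

    def test_three_category_hand_enumeration(self):
        # pairs: (a,b): (3-1)^2=4; (a,c): (2-2)^2=0; (b,c): 0 -> sqrt(4/3)
        c = np.array([[0, 3, 2], [1, 0, 0], [2, 0, 0]], dtype=float)
        assert msa_from_counts(_matrix(c)) == pytest.approx(math.sqrt(4 / 3))
        assert msa_from_counts(_matrix(c)) == pytest.approx(1.1547, abs=1e-4)

    def test_degenerate_matrix_rejected(self):
        m = pair_counts([], ["stone"])
        with pytest.raises(DegenerateDataError):
            msa_from_counts(m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        c = rng.integers(0, 20, size=(k, k)).astype(float)
        m = _matrix(c)
        assert msa_from_counts(m) == pytest.approx(brute_force_msa(c))
        # transpose invariance: squared differences are sign-symmetric
        assert msa_from_counts(m.transpose()) == pytest.approx(msa_from_counts(m))

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_degree_one(self, seed, scale):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 10, size=(5, 5)).astype(float)
        base = msa_from_counts(_matrix(c))
        scaled = msa_from_counts(_matrix(c * scale))
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 10, size=(6, 6)).astype(float)
        perm = rng.permutation(6)
        relabeled = c[np.ix_(perm, perm)]
        assert msa_from_counts(_matrix(relabeled)) == pytest.approx(
            msa_from_counts(_matrix(c)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_vector_fast_path_equals_matrix_path(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.integers(0, 6, size=26)
        v = rng.integers(0, 6, size=26)
        if u.sum() == 0 or v.sum() == 0:
            return
        m = PairCountMatrix("img", np.outer(u, v), VOCAB.choice_categories,
                            int(u.sum()), int(v.sum()))
        assert msa_from_vectors(u, v) == pytest.approx(msa_from_counts(m))

    def test_observed_only_pair_set_shrinks_denominator(self):
        m = pair_counts(["bark"] * 12, ["stone"] * 12)
        full = msa_from_counts(m, pair_set="full_vocab")
        observed = msa_from_counts(m, pair_set="observed_only")
        assert observed == pytest.approx(144.0)  # single pair, denominator 1
        assert observed > full

    def test_normalized_count_scale(self):
        m = pair_counts(["bark"] * 12, ["stone"] * 12)
        norm = msa_from_counts(m, count_scale="normalized")
        assert norm == pytest.approx(math.sqrt(1.0 / N_PAIRS_26))


def exhaustive_chance_units(categories, units):
    """Oracle: mean MSA over all distinct near/far assignments."""
    from matscale.confusion import assign_distance_group
    index = {c: i for i, c in enumerate(VOCAB.choice_categories)}
    idx = np.array([index[c] for c in categories])
    n = len(categories)
    n_near = sum(assign_distance_group(u) == "near" for u in units)
    vals = []
    for near_pos in itertools.combinations(range(n), n_near):
        mask = np.zeros(n, dtype=bool)
        mask[list(near_pos)] = True
        u = np.bincount(idx[mask], minlength=26)
        v = np.bincount(idx[~mask], minlength=26)
        vals.append(msa_from_vectors(u, v))
    return float(np.mean(vals))


class TestChanceMSA:
    def test_all_same_category_is_zero(self):
        cats = ["bark"] * 24
        units = [DistanceUnit.CENTIMETER] * 12 + [DistanceUnit.METER] * 12
        assert chance_msa_units(cats, units, n_perm=50, seed=0) == 0.0

    def test_two_plus_two_exhaustive(self):
        cats = ["bark", "bark", "stone", "stone"]
        units = [DistanceUnit.CENTIMETER] * 2 + [DistanceUnit.METER] * 2
        oracle = exhaustive_chance_units(cats, units)
        approx = chance_msa_units(cats, units, n_perm=50_000, seed=1)
        assert approx == pytest.approx(oracle, rel=0.01)

    @pytest.mark.parametrize("cats, n_near", [
        (["bark", "stone", "sand", "wood", "ice"], 2),
        (["bark", "bark", "stone", "sand", "sand", "wood"], 3),
    ])
    def test_exhaustive_oracle_small_n(self, cats, n_near):
        units = ([DistanceUnit.MILLIMETER] * n_near
                 + [DistanceUnit.KILOMETER] * (len(cats) - n_near))
        oracle = exhaustive_chance_units(cats, units)
        approx = chance_msa_units(cats, units, n_perm=30_000, seed=7)
        assert approx == pytest.approx(oracle, rel=0.01)

    def test_degenerate_single_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            chance_msa_units(["bark", "stone"],
                             [DistanceUnit.METER, DistanceUnit.KILOMETER],
                             n_perm=10, seed=0)

    def test_group_permutation_identical_groups(self):
        # both groups respond identically on the single image
        resp = np.array([[0], [0], [1], [1]])
        near = np.array([True, True, False, False])
        chance = chance_msa_groups(resp, near, n_perm=3000, seed=0)
        # observed: near={0,0} far={1,1}; every permutation keeps 2v2 counts
        # with the same multiset; exhaustive check below
        oracle = []
        for near_pos in itertools.combinations(range(4), 2):
            mask = np.zeros(4, dtype=bool)
            mask[list(near_pos)] = True
            u = np.bincount(resp[mask, 0], minlength=2)
            v = np.bincount(resp[~mask, 0], minlength=2)
            oracle.append(msa_from_vectors(u, v))
        assert chance[0] == pytest.approx(np.mean(oracle), rel=0.05)

    def test_group_permutation_requires_two_groups(self):
        with pytest.raises(ValueError):
            chance_msa_groups(np.zeros((3, 1), dtype=int),
                              np.array([True, True, True]), n_perm=5, seed=0)


class TestPipelines:
    def test_exp1_msa_hand_computed(self):
        """12 near 'bark' + 12 far 'stone' responses give MSA = 144/sqrt(325)."""
        from matscale.data_io import (Block, Experiment, Group, ResponseRecord)
        records = []
        for i in range(24):
            near = i < 12
            pid = f"p{i:02d}"
            records.append(ResponseRecord(
                pid, Experiment.EXP1, Group.UNBIASED, "img000", Block.CHOICE,
                category="bark" if near else "stone", confidence=5))
            records.append(ResponseRecord(
                pid, Experiment.EXP1, Group.UNBIASED, "img000", Block.DISTANCE,
                distance_unit=(DistanceUnit.CENTIMETER if near
                               else DistanceUnit.METER),
                distance_value=1.0))
        [res] = analyze_exp1_msa(records, n_perm=100, seed=0)
        assert res.msa_observed == pytest.approx(144 / math.sqrt(325))
        assert not res.degenerate
        assert res.msa_chance < res.msa_observed

    def test_exp2_pipeline_runs(self, exp2a_records):
        records, _ = exp2a_records
        results = analyze_exp2_msa(records, n_perm=100, seed=3)
        assert len(results) == 8
        assert all(r.msa_observed >= 0 and r.msa_chance >= 0 for r in results)

    def test_summarize_experiment(self, exp1_records):
        records, _ = exp1_records
        results = analyze_exp1_msa(records, n_perm=150, seed=5)
        summary = summarize_experiment(results, "1", n_boot=2000, seed=5)
        assert summary.n_images == 8
        assert 0 <= summary.n_images_above_chance <= summary.n_images
        assert summary.ci_observed[0] <= summary.mean_msa_observed <= summary.ci_observed[1]
        assert summary.ci_chance[0] <= summary.mean_msa_chance <= summary.ci_chance[1]
        # lam = 0.6 design: real directional asymmetry should be detected
        assert summary.mean_msa_observed > summary.mean_msa_chance
        assert summary.p_value < 0.05


def _res(image_id, observed, chance=0.0):
    return MSAResult(image_id, observed, chance, 10, 0)


class TestRanking:
    def test_strict_descending(self):
        results = [_res("a", 1.0), _res("b", 3.0), _res("c", 2.0)]
        assert rank_images({"1": results}) == ["b", "c", "a"]

    def test_ties_broken_by_image_id(self):
        results = [_res("b", 1.0), _res("a", 1.0), _res("c", 1.0)]
        assert rank_images({"1": results}) == ["a", "b", "c"]

    def test_combined_mean_across_experiments(self):
        e1 = [_res("a", 4.0), _res("b", 0.0)]
        e2 = [_res("a", 0.0), _res("b", 3.0)]
        # means: a = 2.0, b = 1.5
        assert rank_images({"1": e1, "2A": e2}, combine=True) == ["a", "b"]
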