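"""Splitting strategies, Tanimoto/Butina machinery and the KS audit,
checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbtscreen import simgen, splitkit
from pbtscreen.chemprep import MoleculeRecord
from pbtscreen.splitkit import (
    SplitResult,
    butina_cluster,
    carve_validation,
    fingerprint,
    fingerprint_matrix,
    ks_two_sample,
    max_similarity_profile,
    split_cluster_centroids,
    split_cluster_singletons,
    split_random,
    tanimoto,
    validate_iid,
    validate_iid_matrices,
)


def _dummy_records(n):
    return [MoleculeRecord(id=f"d{i}", smiles_raw="C") for i in range(n)]


# ---------------------------------------------------------------------------
# fingerprints & tanimoto

class TestFingerprint:
    def test_deterministic(self):
        a = fingerprint("c1ccccc1Cl")
        b = fingerprint("c1ccccc1Cl")
        assert np.array_equal(a, b)
        assert a.shape == (2048,)

    def test_methane_sets_at_least_one_bit(self):
        assert fingerprint("C").sum() >= 1

    def test_chlorobenzene_differs_from_benzene(self):
        assert not np.array_equal(fingerprint("c1ccccc1"), fingerprint("Clc1ccccc1"))

    def test_path_based_kind_differs(self):
        m = "CCOc1ccccc1"
        assert not np.array_equal(fingerprint(m, "morgan"), fingerprint(m, "rdkit"))

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            fingerprint("((((")


class TestTanimoto:
    def _vec(self, bits, n=8):
        v = np.zeros(n, dtype=np.uint8)
        v[list(bits)] = 1
        return v

    def test_identical_nonempty_is_one(self):
        v = self._vec({1, 3})
        assert tanimoto(v, v) == 1.0

    def test_disjoint_supports_is_zero(self):
        assert tanimoto(self._vec({0, 1}), self._vec({2, 3})) == 0.0

    def test_partial_overlap(self):
        # |{2,3}| / |{1,2,3,4}| = 2/4
        assert tanimoto(self._vec({1, 2, 3}), self._vec({2, 3, 4})) == 0.5

    def test_both_empty_defined_as_one(self):
        assert tanimoto(self._vec(set()), self._vec(set())) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4), np.zeros(5))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.booleans(), min_size=4, max_size=4),
           st.lists(st.booleans(), min_size=4, max_size=4))
    def test_symmetric_and_bounded(self, a, b):
        va, vb = np.array(a, dtype=np.uint8), np.array(b, dtype=np.uint8)
        s = tanimoto(va, vb)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(vb, va)


# ---------------------------------------------------------------------------
# Butina clustering

def _bruteforce_sphere_exclusion(fps, cutoff):
    """Independent reference: recompute neighbor lists each round with
    explicit loops; most-neighbors compound (lowest index on ties) seeds."""
    n = len(fps)
    def dist(i, j):
        a, b = set(np.flatnonzero(fps[i])), set(np.flatnonzero(fps[j]))
        if not a and not b:
            return 0.0
        return 1.0 - len(a & b) / len(a | b)

    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_nbrs = None, None
        for i in sorted(unassigned):
            nbrs = [j for j in sorted(unassigned) if j != i and dist(i, j) <= cutoff]
            if best is None or len(nbrs) > len(best_nbrs):
                best, best_nbrs = i, nbrs
        clusters.append([best] + best_nbrs)
        unassigned -= set(clusters[-1])
    return clusters


class TestButina:
    def test_all_dissimilar_gives_singletons(self):
        fps = np.eye(8, dtype=np.uint8)  # pairwise similarity 0
        clusters = butina_cluster(fps, 0.4)
        assert len(clusters) == 8
        assert all(len(c) == 1 for c in clusters)

    def test_identical_fingerprints_one_cluster(self):
        fps = np.tile(fingerprint("c1ccccc1"), (5, 1))
        clusters = butina_cluster(fps, 0.4)
        assert len(clusters) == 1 and len(clusters[0]) == 5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_sphere_exclusion(self, seed):
        rng = np.random.default_rng(seed)
        fps = (rng.random((8, 16)) < 0.4).astype(np.uint8)
        for cutoff in (0.2, 0.4, 0.6):
            ours = butina_cluster(fps, cutoff)
            ref = _bruteforce_sphere_exclusion(fps, cutoff)
            assert [sorted(c) for c in ours] == [sorted(c) for c in ref]
            assert [c[0] for c in ours] == [c[0] for c in ref]  # centroids

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(11)
        fps = (rng.random((30, 64)) < 0.3).astype(np.uint8)
        counts = [len(butina_cluster(fps, c)) for c in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cutoff_range_enforced(self):
        with pytest.raises(ValueError):
            butina_cluster(np.eye(3, dtype=np.uint8), 1.5)


# ---------------------------------------------------------------------------
# split strategies

class TestSplitRandom:
    def test_80_20_on_5130_records(self):
        split = split_random(_dummy_records(5130), 0.8, seed=0)
        assert len(split.train_ids) == 4104
        assert len(split.test_ids) == 1026

    def test_even_split(self):
        split = split_random(_dummy_records(10), 0.5, seed=1)
        assert len(split.train_ids) == 5 and len(split.test_ids) == 5

    def test_seed_reproducibility(self):
        a = split_random(_dummy_records(100), seed=7)
        b = split_random(_dummy_records(100), seed=7)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_partition_is_disjoint_and_complete(self):
        split = split_random(_dummy_records(50), 0.8, seed=2)
        assert set(split.train_ids) | set(split.test_ids) == {f"d{i}" for i in range(50)}
        assert not set(split.train_ids) & set(split.test_ids)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_random(_dummy_records(1))


class TestClusterSplits:
    def test_singleton_split_on_planted_fixture(self, cluster_fixture):
        records, rows = cluster_fixture
        split = split_cluster_singletons(records, 0.4)
        expected = set(rows[rows.singleton].id)
        assert set(split.test_ids) == expected
        assert set(split.train_ids) == set(rows[~rows.singleton].id)
        # every test id sits in a size-1 cluster
        for cid, members in split.clusters.items():
            for m in members:
                if m in expected:
                    assert len(members) == 1

    def test_centroid_split_trains_on_butina_centroids(self, cluster_fixture):
        records, rows = cluster_fixture
        split = split_cluster_centroids(records, 0.4)
        fps = fingerprint_matrix(records)
        clusters = splitkit.butina_cluster(fps, 0.4)
        ids = [r.id for r in records]
        expected_train = {ids[c[0]] for c in clusters if len(c) >= 2}
        assert set(split.train_ids) == expected_train
        assert set(split.test_ids) == set(rows[rows.singleton].id)
        # non-centroid family members excluded from both sides
        n_family = int((~rows.singleton).sum())
        assert len(split.train_ids) < n_family

    def test_all_identical_warns_empty_test(self):
        records = [MoleculeRecord(id=f"m{i}", smiles_raw="c1ccccc1",
                                  smiles_canonical="c1ccccc1") for i in range(5)]
        with pytest.warns(UserWarning, match="test set is empty"):
            split = split_cluster_singletons(records, 0.4)
        assert split.test_ids == [] and len(split.train_ids) == 5

    def test_all_dissimilar_warns_empty_train(self, cluster_fixture):
        records, rows = cluster_fixture
        singles = [r for r in records if r.id.startswith("single")]
        with pytest.warns(UserWarning, match="train set is empty"):
            split = split_cluster_singletons(singles, 0.4)
        assert len(split.test_ids) == len(singles)

    def test_split_result_rejects_overlap(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitResult(strategy="random", train_ids=["a"], test_ids=["a"])

    def test_carve_validation(self):
        split = split_random(_dummy_records(100), 0.8, seed=0)
        with_val = carve_validation(split, 0.1, seed=0)
        assert len(with_val.val_ids) == 8
        assert set(with_val.val_ids) | set(with_val.train_ids) == set(split.train_ids)


# ---------------------------------------------------------------------------
# similarity profile

class TestMaxSimilarityProfile:
    def _records(self, smiles):
        return [MoleculeRecord(id=f"m{i}", smiles_raw=s, smiles_canonical=s)
                for i, s in enumerate(smiles)]

    def test_identical_populations_give_all_ones(self):
        smiles = ["CCO", "CCC", "c1ccccc1"]
        records = self._records(smiles * 2)
        split = SplitResult(strategy="random",
                            train_ids=[f"m{i}" for i in range(3)],
                            test_ids=[f"m{i}" for i in range(3, 6)])
        prof = max_similarity_profile(split, records)
        assert prof["median"] == 1.0
        assert prof["frac_above_cutoff"] == 1.0

    def test_matches_bruteforce_double_loop(self):
        smiles = ["CCO", "CCCC", "c1ccccc1", "CCN", "c1ccncc1"]
        records = self._records(smiles)
        split = SplitResult(strategy="random",
                            train_ids=["m0", "m1", "m2"], test_ids=["m3", "m4"])
        prof = max_similarity_profile(split, records)
        fps = {r.id: fingerprint(r) for r in records}
        expected = [
            max(tanimoto(fps[t], fps[tr]) for tr in split.train_ids)
            for t in split.test_ids
        ]
        assert np.allclose(sorted(prof["maxima"]), sorted(expected))
        assert prof["median"] == pytest.approx(float(np.median(expected)))

    def test_empty_side_rejected(self):
        records = self._records(["CCO", "CCC"])
        split = SplitResult(strategy="random", train_ids=["m0", "m1"], test_ids=[])
        with pytest.raises(ValueError):
            max_similarity_profile(split, records)


# ---------------------------------------------------------------------------
# KS audit

def _bruteforce_ks(x, y):
    """D = sup |F_x - F_y| by exhaustive evaluation at every sample point."""
    pts = sorted(set(list(x) + list(y)))
    d = 0.0
    for p in pts:
        fx = sum(1 for v in x if v <= p) / len(x)
        fy = sum(1 for v in y if v <= p) / len(y)
        d = max(d, abs(fx - fy))
    return d


class TestKS:
    def test_identical_samples_d_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_two_sample(x, x.copy())
        assert d == 0.0

    def test_separated_supports_d_one(self):
        d, _ = ks_two_sample(np.array([0.0, 1.0, 2.0]), np.array([10.0, 11.0]))
        assert d == 1.0

    def test_statistic_matches_exhaustive_ecdf_scan(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(0.5, 1.3, size=20)
        d, p = ks_two_sample(x, y)
        assert abs(d - _bruteforce_ks(x, y)) < 1e-9
        assert 0.0 <= p <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([]), np.array([1.0]))


class TestValidateIID:
    def _records(self, smiles):
        return [MoleculeRecord(id=f"m{i}", smiles_raw=s, smiles_canonical=s)
                for i, s in enumerate(smiles)]

    def test_copy_of_train_not_significant(self):
        records = self._records(["CCO", "CCC", "c1ccccc1", "CCCl"])
        report = validate_iid(records, records)
        assert report.n_significant == 0
        assert report.mean_ks_statistic == 0.0
        assert report.n_bits_tested == 2048

    def test_divergent_populations_flagged(self):
        halogenated = self._records(
            [f"Clc1ccc(cc1){'C' * i}" for i in range(1, 9)]
        )
        plain = [MoleculeRecord(id=f"p{i}", smiles_raw=s, smiles_canonical=s)
                 for i, s in enumerate(["CCO", "CCCO", "CCCCO", "CCN", "CCCN",
                                        "CCCCN", "CCOC", "CCCOC"])]
        report = validate_iid(halogenated, plain, alpha=0.05)
        assert report.n_significant > 0

    def test_type_one_error_rate_on_random_splits(self, planted):
        """Random 80:20 splits of a homogeneous population should flag at
        most ~alpha of the bits; averaged over 20 replicates the rate must
        stay below 2*alpha."""
        records, _ = planted
        X = fingerprint_matrix(records[:1000])
        rates = []
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = rng.permutation(X.shape[0])
            A, B = X[perm[:800]], X[perm[800:]]
            rep = validate_iid_matrices(A, B, alpha=0.05)
            rates.append(rep.n_significant / rep.n_bits_tested)
        assert np.mean(rates) <= 2 * 0.05

    def test_degenerate_constant_fingerprints(self):
        A = np.zeros((5, 16), dtype=np.uint8)
        rep = validate_iid_matrices(A, A.copy())
        assert rep.n_bits_tested == 16 and rep.mean_ks_statistic == 0.0


def test_difficulty_ordering_of_strategies(planted):
    """Nearest-training-neighbor medians decrease from random over
    cluster-singleton to cluster-centroid splitting."""
    records, _ = planted
    prof_r = max_similarity_profile(split_random(records, 0.8, seed=0), records)
    prof_s = max_similarity_profile(split_cluster_singletons(records, 0.4), records)
    prof_c = max_similarity_profile(split_cluster_centroids(records, 0.4), records)
    assert prof_r["median"] >= prof_s["median"] >= prof_c["median"]
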