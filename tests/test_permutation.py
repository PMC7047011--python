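import math

import numpy as np
import pytest

from anatcorr.permutation import (
    NullDistribution,
    TFCEParams,
    cluster_extent_correct,
    generate_permutations,
    kmax_fwer_correct,
    permutation_p,
    tfce_fwer_correct,
    tfce_transform,
    voxel_fwer_correct,
)
from anatcorr.statmap import p_to_statistic_threshold

from oracles import naive_tfce, oracle_cluster_extent, oracle_kmax_p, oracle_tfce_p, oracle_voxel_p


# --- scheme -----------------------------------------------------------------

def test_exhaustive_scheme_enumerates_all():
    sch = generate_permutations(3, exhaustive=True)
    assert sch.n_perm == 6
    assert len({tuple(p) for p in sch.permutations}) == 6
    assert np.array_equal(sch.permutations[0], [0, 1, 2])


def test_random_scheme_identity_first_and_deterministic():
    a = generate_permutations(8, n_perm=20, seed=5)
    b = generate_permutations(8, n_perm=20, seed=5)
    assert np.array_equal(a.permutations, b.permutations)
    assert np.array_equal(a.permutations[0], np.arange(8))
    c = generate_permutations(8, n_perm=20, seed=6)
    assert not np.array_equal(a.permutations, c.permutations)


def test_exhaustive_cap_refused():
    with pytest.raises(ValueError, match="cap"):
        generate_permutations(12, exhaustive=True)


def test_permutation_p_conventions():
    null = NullDistribution(np.array([5.0, 1.0, 2.0, 3.0]), "max_abs_voxel")
    assert permutation_p(5.0, null) == pytest.approx(1 / 4)   # top value
    assert permutation_p(0.5, null) == pytest.approx(1.0)     # below all
    assert permutation_p(2.5, null) == pytest.approx(2 / 4)
    with pytest.raises(ValueError):
        permutation_p(1.0, np.empty(0))


# --- enumeration-oracle agreement on the tiny instance ----------------------

def test_voxel_fwer_matches_enumeration(tiny_instance):
    stack, cov, mask = tiny_instance
    sch = generate_permutations(3, exhaustive=True)
    res = voxel_fwer_correct(stack, cov, mask, sch, alpha=0.05)
    assert np.array_equal(res.adjusted_p, oracle_voxel_p(stack, cov, mask))


@pytest.mark.parametrize("k", [1, 3, 12])
def test_kmax_matches_enumeration(tiny_instance, k):
    stack, cov, mask = tiny_instance
    sch = generate_permutations(3, exhaustive=True)
    res = kmax_fwer_correct(stack, cov, mask, sch, k=k, alpha=0.05)
    assert np.array_equal(res.adjusted_p, oracle_kmax_p(stack, cov, mask, k))
    if k == 1:
        assert np.array_equal(res.adjusted_p,
                              voxel_fwer_correct(stack, cov, mask, sch).adjusted_p)


def test_kmax_monotone_in_k(tiny_instance):
    stack, cov, mask = tiny_instance
    sch = generate_permutations(3, exhaustive=True)
    p1 = kmax_fwer_correct(stack, cov, mask, sch, k=1).adjusted_p
    pV = kmax_fwer_correct(stack, cov, mask, sch, k=12).adjusted_p
    assert np.all(pV <= p1)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_cluster_extent_matches_enumeration(tiny_instance, connectivity):
    stack, cov, mask = tiny_instance
    sch = generate_permutations(3, exhaustive=True)
    primary_p = 0.4  # with n=3 (df=1) a lenient threshold is needed for clusters
    res = cluster_extent_correct(stack, cov, mask, sch, primary_p=primary_p,
                                 connectivity=connectivity, alpha=0.05)
    r_thr = p_to_statistic_threshold(primary_p, 3)
    oracle = oracle_cluster_extent(stack, cov, mask, r_thr, connectivity)
    lab = res.unit_info["unit_labels"]
    assert res.params["n_clusters"] == len(oracle)
    for ci in range(1, res.params["n_clusters"] + 1):
        members = frozenset(map(tuple, np.argwhere(lab == ci)))
        ext, p = oracle[members]
        assert res.params["extents"][ci - 1] == ext
        assert res.adjusted_p[ci - 1] == p


def test_tfce_matches_enumeration(tiny_instance):
    stack, cov, mask = tiny_instance
    sch = generate_permutations(3, exhaustive=True)
    params = TFCEParams(H=2.0, E=0.5, dt=0.1)
    res = tfce_fwer_correct(stack, cov, mask, sch, params, connectivity=26)
    assert np.array_equal(res.adjusted_p, oracle_tfce_p(stack, cov, mask, 2.0, 0.5, 0.1, 26))


# --- TFCE transform ---------------------------------------------------------

def test_tfce_zero_map():
    assert not tfce_transform(np.zeros((4, 4, 4))).any()


def test_tfce_single_voxel_hand_value():
    vol = np.zeros((5, 5, 5))
    vol[2, 2, 2] = 1.0
    score = tfce_transform(vol, TFCEParams(H=2.0, E=0.5, dt=0.1))[2, 2, 2]
    # 0.1 * (0.01 + 0.04 + ... + 1.00) = 0.385
    assert score == pytest.approx(0.385, abs=1e-12)


def test_tfce_negative_signal_second_pass():
    vol = np.zeros((5, 5, 5))
    vol[1, 1, 1] = 1.0
    vol[3, 3, 3] = -1.0
    sc = tfce_transform(vol, TFCEParams())
    assert sc[1, 1, 1] == pytest.approx(sc[3, 3, 3], abs=1e-15)


def test_tfce_monotone_under_scaling():
    rng = np.random.default_rng(8)
    vol = rng.normal(size=(6, 6, 6))
    s1 = tfce_transform(vol)
    s2 = tfce_transform(2 * vol)
    assert np.all(s2 >= s1 - 1e-12)


def test_tfce_matches_naive_on_random_map():
    rng = np.random.default_rng(9)
    vol = rng.normal(size=(4, 4, 4))
    mask = np.ones((4, 4, 4), bool)
    mine = tfce_transform(vol, TFCEParams(), 26, mask)
    ref = naive_tfce(vol, mask, 2.0, 0.5, 0.1, 26)
    assert np.allclose(mine, ref, atol=1e-10)
    with pytest.raises(ValueError):
        TFCEParams(dt=0.0)


# --- behavioural properties -------------------------------------------------

def test_cluster_counting_and_connectivity_semantics():
    vol = np.zeros((9, 9, 9))
    vol[1:4, 1:4, 1:4] = 1.0  # 3x3x3 block
    stack = np.stack([vol * c for c in (0.5, 1.9, -0.2, 1.1)], axis=-1)
    cov = np.array([0.5, 1.9, -0.2, 1.1])
    sch = generate_permutations(4, exhaustive=True)
    res = cluster_extent_correct(stack, cov, None, sch, primary_p=0.05, connectivity=26)
    # constant-zero voxels leave the mask; the block is one 27-voxel cluster
    assert res.params["extents"] == [27]

    # two blocks touching only at a vertex: 2 clusters at conn 6, 1 at 26
    vol2 = np.zeros((9, 9, 9))
    vol2[2:4, 2:4, 2:4] = 1.0
    vol2[4:6, 4:6, 4:6] = 1.0
    stack2 = np.stack([vol2 * c for c in (0.5, 1.9, -0.2, 1.1)], axis=-1)
    r6 = cluster_extent_correct(stack2, cov, None, sch, primary_p=0.05, connectivity=6)
    r26 = cluster_extent_correct(stack2, cov, None, sch, primary_p=0.05, connectivity=26)
    assert r6.params["n_clusters"] == 2
    assert r26.params["n_clusters"] == 1


def test_noiseless_organ_all_significant(tiny_segmentation):
    # a fully active structure with zero noise is the global max everywhere
    rng = np.random.default_rng(3)
    cov = rng.normal(size=12)
    shape = tiny_segmentation.labels.shape
    stack = np.zeros((*shape, 12))
    organ = tiny_segmentation.labels == 2
    stack[organ] = cov
    sch = generate_permutations(12, n_perm=200, seed=0)
    res = voxel_fwer_correct(stack, cov, None, sch, alpha=0.05)
    assert res.sig_mask[organ].all()
    assert np.all(res.adjusted_p == 1 / 200)


def test_corrected_p_dominates_uncorrected(tiny_instance):
    from anatcorr.statmap import statistic_to_p, voxelwise_correlation

    stack, cov, mask = tiny_instance
    sch = generate_permutations(3, exhaustive=True)
    corrected = voxel_fwer_correct(stack, cov, mask, sch).adjusted_p
    raw = statistic_to_p(voxelwise_correlation(stack, cov, mask)).masked
    assert np.all(corrected >= raw - 1e-12)
    # and corrected p nonincreasing in the observed statistic
    obs = np.abs(voxelwise_correlation(stack, cov, mask).masked)
    order = np.argsort(obs)
    assert np.all(np.diff(corrected[order]) <= 1e-12)
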