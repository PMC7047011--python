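import numpy as np
import pytest

from anatcorr.anatomy import (
    accuracy_from_annotations,
    accuracy_from_border,
    anatomical_cluster_extent_correct,
    anatomical_tfce,
    anatomical_tfce_fwer_correct,
    cba_clusters,
    cba_correct,
    kmax_bound_from_segmentation,
    organ_level_test,
    organ_weighted_signal,
    scaled_extent,
)
from anatcorr.datatypes import Segmentation, StatMap
from anatcorr.parametric import holm_adjust
from anatcorr.permutation import TFCEParams, generate_permutations, tfce_transform
from anatcorr.statmap import p_to_statistic_threshold, statistic_to_p, voxelwise_correlation

from oracles import oracle_anat_cluster, oracle_cba_perm, oracle_organ


# --- accuracy maps -----------------------------------------------------------

def _seg_with_cube(shape=(7, 7, 7), lo=2, hi=5, label=1, name="organ"):
    labels = np.zeros(shape, np.int32)
    labels[lo:hi, lo:hi, lo:hi] = label
    return Segmentation(labels, {label: name})


def test_accuracy_from_annotations_majority_fractions():
    # 3 of 4 annotators call the voxel liver, 1 calls it kidney
    base = np.zeros((5, 5, 5), np.int32)
    anns = []
    for i in range(4):
        lab = base.copy()
        lab[2, 2, 2] = 1 if i < 3 else 2
        lab[1, 1, 1] = 1  # unanimous liver voxel
        anns.append(Segmentation(lab, {1: "liver", 2: "kidney"}))
    liver = accuracy_from_annotations(anns, 1)
    kidney = accuracy_from_annotations(anns, 2)
    flat = np.ravel_multi_index((2, 2, 2), (5, 5, 5))
    assert liver.weight_volume(1).ravel()[flat] == pytest.approx(0.75)
    assert kidney.weight_volume(2).ravel()[flat] == pytest.approx(0.25)
    assert liver.weight_volume(1)[1, 1, 1] == pytest.approx(1.0)
    # voxel labelled by no annotator is outside the support
    assert flat in liver.supports[1]
    assert np.ravel_multi_index((0, 0, 0), (5, 5, 5)) not in liver.supports[1]


def test_accuracy_from_border_cube_counts():
    seg = _seg_with_cube()  # 3x3x3 cube: 26 border voxels, 1 interior
    acc = accuracy_from_border(seg, inner_w=1.0, border_w=0.1)
    w = acc.weights[1]
    assert w.size == 27
    assert (w == 1.0).sum() == 1
    assert (w == 0.1).sum() == 26
    assert w.min() >= 0.1 and w.max() <= 1.0


def test_accuracy_border_single_voxel_organ():
    labels = np.zeros((5, 5, 5), np.int32)
    labels[2, 2, 2] = 1
    acc = accuracy_from_border(Segmentation(labels, {1: "dot"}), 1.0, 0.1)
    assert acc.weights[1].tolist() == [0.1]
    with pytest.raises(ValueError):
        accuracy_from_border(_seg_with_cube(), inner_w=0.5, border_w=0.9)


# --- weighted signal ---------------------------------------------------------

def test_organ_weighted_signal_formula():
    labels = np.zeros((3, 1, 1), np.int32)
    labels[:, 0, 0] = 1
    seg = Segmentation(labels, {1: "o"})
    from anatcorr.anatomy import AccuracyMap

    acc = AccuracyMap((3, 1, 1), {1: np.arange(3)}, {1: np.array([1.0, 1.0, 0.1])}, "manual")
    vol = np.array([2.0, 4.0, 6.0]).reshape(3, 1, 1)
    # (2 + 4 + 0.6) / 3, dividing by |U_k| not the weight sum
    assert organ_weighted_signal(vol, acc, 1) == pytest.approx(2.2)
    acc_unit = AccuracyMap((3, 1, 1), {1: np.arange(3)}, {1: np.ones(3)}, "uniform")
    assert organ_weighted_signal(vol, acc_unit, 1) == pytest.approx(4.0)
    assert organ_weighted_signal(np.zeros((3, 1, 1)), acc, 1) == 0.0


# --- organ-level permutation test --------------------------------------------

def test_organ_level_matches_enumeration(tiny_instance, tiny_segmentation):
    stack, cov, _ = tiny_instance
    seg = tiny_segmentation
    sch = generate_permutations(3, exhaustive=True)
    acc = accuracy_from_border(seg, 1.0, 0.1)
    res = organ_level_test(stack, cov, seg, sch, accuracy=acc, alpha=0.05)

    supports = {
        lab: [tuple(v) for v in np.argwhere(seg.labels == lab)] for lab in seg.organ_labels
    }
    weights = {
        lab: [acc.weight_volume(lab)[v] for v in supports[lab]] for lab in supports
    }
    labs, p_raw, p_holm = oracle_organ(stack, cov, seg.body_mask, seg.labels,
                                       supports, weights)
    assert res.table["label"].tolist() == labs
    assert np.array_equal(res.table["p"].to_numpy(), p_raw)
    assert np.allclose(res.table["p_holm"].to_numpy(), p_holm, atol=1e-12)
    assert np.all(res.table["p_holm"] >= res.table["p"] - 1e-15)


def test_organ_level_single_structure_holm_identity(tiny_instance):
    stack, cov, _ = tiny_instance
    labels = np.ones((3, 2, 2), np.int32)
    seg = Segmentation(labels, {1: "all"})
    sch = generate_permutations(3, exhaustive=True)
    res = organ_level_test(stack, cov, seg, sch)
    assert len(res.table) == 1
    assert res.table["p_holm"][0] == res.table["p"][0]


def test_organ_level_noiseless_effect_hits_floor(tiny_segmentation):
    rng = np.random.default_rng(12)
    cov = rng.normal(size=10)
    shape = tiny_segmentation.labels.shape
    stack = rng.normal(size=(*shape, 10)) * 0.01
    stack[tiny_segmentation.labels == 2] += cov * 10
    sch = generate_permutations(10, n_perm=250, seed=1)
    res = organ_level_test(stack, cov, tiny_segmentation, sch)
    row = res.table.set_index("label").loc[2]
    assert row["p"] == pytest.approx(1 / 250)
    assert bool(row["significant"])


# --- anatomical TFCE ---------------------------------------------------------

def test_anatomical_tfce_equals_plain_for_whole_mask_organ():
    rng = np.random.default_rng(21)
    vol = rng.normal(size=(6, 6, 6))
    seg = Segmentation(np.ones((6, 6, 6), np.int32), {1: "all"})
    plain = tfce_transform(vol, TFCEParams())
    anat = anatomical_tfce(vol, seg, TFCEParams())
    assert np.max(np.abs(plain - anat)) <= 1e-12


def test_anatomical_tfce_scaled_extent_equivalence():
    # a fully active small organ scores like a fully active large organ at
    # the same height: scaled extents are both e_max
    labels = np.zeros((12, 4, 4), np.int32)
    labels[0:2, 0:2, 0:2] = 1    # 8 voxels
    labels[4:8, 0:4, 0:4] = 2    # 64 voxels
    seg = Segmentation(labels, {1: "small", 2: "large"})
    vol = np.where(labels > 0, 1.0, 0.0)
    sc = anatomical_tfce(vol, seg, TFCEParams())
    vals = sc[labels > 0]
    assert np.allclose(vals, vals[0], atol=1e-12)
    assert sc[labels == 0].max() == 0.0


def test_anatomical_tfce_strict_mode():
    labels = np.zeros((4, 4, 4), np.int32)
    labels[:2] = 1
    seg = Segmentation(labels, {1: "half"})
    vol = np.ones((4, 4, 4))
    with pytest.raises(ValueError, match="no structure label"):
        anatomical_tfce(vol, seg, strict=True)
    # non-strict: unlabelled voxels are excluded, not scored
    sc = anatomical_tfce(vol, seg)
    assert sc[labels == 0].max() == 0.0


def test_scaled_extent_values():
    assert scaled_extent(3, 9, 45) == pytest.approx(15.0)
    assert scaled_extent(45, 45, 45) == pytest.approx(45.0)
    with pytest.raises(ValueError):
        scaled_extent(3, 0, 45)


# --- anatomical cluster extent -----------------------------------------------

def test_anat_cluster_matches_enumeration(tiny_instance, tiny_segmentation):
    stack, cov, _ = tiny_instance
    seg = tiny_segmentation
    sch = generate_permutations(3, exhaustive=True)
    primary_p = 0.4
    res = anatomical_cluster_extent_correct(stack, cov, seg, sch, primary_p=primary_p,
                                            connectivity=26, alpha=0.05)
    r_thr = p_to_statistic_threshold(primary_p, 3)
    oracle = oracle_anat_cluster(stack, cov, seg.body_mask, seg.labels, r_thr, 26,
                                 seg.organ_extents)
    lab = res.unit_info["unit_labels"]
    assert res.params["n_clusters"] == len(oracle)
    for ci in range(1, res.params["n_clusters"] + 1):
        members = frozenset(map(tuple, np.argwhere(lab == ci)))
        s, p = oracle[members]
        assert res.params["scaled_extents"][ci - 1] == s
        assert res.adjusted_p[ci - 1] == p


def test_anat_cluster_never_spans_labels_and_full_organ_scaling(tiny_segmentation):
    seg = tiny_segmentation
    rng = np.random.default_rng(31)
    cov = rng.normal(size=10)
    stack = rng.normal(size=(*seg.labels.shape, 10)) * 0.05
    stack[seg.body_mask] += cov * 5  # everything active
    sch = generate_permutations(10, n_perm=100, seed=2)
    res = anatomical_cluster_extent_correct(stack, cov, seg, sch, primary_p=0.01)
    lab = res.unit_info["unit_labels"]
    for ci in range(1, res.params["n_clusters"] + 1):
        organ_labels = np.unique(seg.labels[lab == ci])
        assert organ_labels.size == 1
    # fully active organs all get scaled extent e_max
    assert np.allclose(res.params["scaled_extents"], seg.e_max)
    assert not res.sig_mask[~seg.body_mask].any()


# --- CBA ---------------------------------------------------------------------

def test_cba_two_voxel_mask_single_cluster():
    rng = np.random.default_rng(4)
    pilot = rng.normal(size=(2, 1, 1, 6))
    cl = cba_clusters(pilot)
    assert cl.n_clusters == 1
    assert cl.is_partition_of(np.ones((2, 1, 1), bool))


def test_cba_independent_blocks_never_merge():
    # pilot built from two independent signals; zero cross-block correlation
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = np.array([2.0, -1.0, 4.0, 1.0, 6.0, 3.0])
    b = b - np.polyval(np.polyfit(a, b, 1), a)  # orthogonalize to a exactly
    pilot = np.zeros((4, 2, 2, 6))
    pilot[:2] = a
    pilot[2:] = b
    # tiny distinct jitter so within-block correlation stays 1 but series
    # are not constant
    cl = cba_clusters(pilot, connectivity=6)
    first = cl.cluster_labels[:2]
    second = cl.cluster_labels[2:]
    assert set(np.unique(first)).isdisjoint(set(np.unique(second)))


def test_cba_partition_and_anatomy_restriction(small_phantom):
    seg, cov, stack = small_phantom
    rng = np.random.default_rng(9)
    pilot = rng.normal(size=(*seg.labels.shape, 8))
    cl = cba_clusters(pilot, mask=seg.body_mask, voxel_size=seg.voxel_size,
                      segmentation=seg)
    assert cl.is_partition_of(seg.body_mask)
    lab = cl.cluster_labels
    for ci in range(1, cl.n_clusters + 1):
        assert np.unique(seg.labels[lab == ci]).size == 1


def test_cba_singleton_inner_holm_reduces_to_voxelwise_holm(tiny_instance):
    stack, cov, mask = tiny_instance
    rmap = voxelwise_correlation(stack, cov, mask)
    # all-singleton partition
    labels = np.arange(1, mask.size + 1, dtype=np.int32).reshape(mask.shape)
    from anatcorr.anatomy import ClusterSet

    cl = ClusterSet(labels, connectivity=26)
    res = cba_correct(rmap, cl, inner_method="holm")
    ref = holm_adjust(statistic_to_p(rmap).masked)
    # cluster order is C-order of the construction, matching masked order
    assert np.allclose(res.adjusted_p, ref, atol=1e-12)


def test_cba_perm_inner_matches_enumeration(tiny_instance):
    stack, cov, mask = tiny_instance
    rng = np.random.default_rng(5)
    pilot = rng.normal(size=(*mask.shape, 6))
    cl = cba_clusters(pilot, mask=mask)
    assert 1 < cl.n_clusters  # prepartition reduces the multiplicity burden
    rmap = voxelwise_correlation(stack, cov, mask)
    sch = generate_permutations(3, exhaustive=True)
    res = cba_correct(rmap, cl, inner_method="perm-voxel", stack=stack,
                      covariate=cov, scheme=sch)
    oracle = oracle_cba_perm(stack, cov, mask, cl.cluster_labels)
    assert np.array_equal(res.adjusted_p, oracle)


def test_cba_halves_multiplicity_when_clusters_nontrivial(small_phantom):
    seg, cov, stack = small_phantom
    rng = np.random.default_rng(13)
    # strongly smooth pilot so neighbours correlate and clusters grow
    from scipy import ndimage

    pilot = ndimage.gaussian_filter(rng.normal(size=(*seg.labels.shape, 10)),
                                    sigma=(2, 2, 2, 0))
    cl = cba_clusters(pilot, mask=seg.body_mask)
    if (cl.extents >= 2).all():
        assert cl.n_clusters <= seg.body_mask.sum() / 2


def test_kmax_bound():
    labels = np.zeros((8, 8, 8), np.int32)
    labels[:2] = 1
    labels[4:6, :4, :4] = 2
    seg = Segmentation(labels, {1: "big", 2: "small"})
    assert kmax_bound_from_segmentation(seg) == min(seg.organ_extents.values())
    assert kmax_bound_from_segmentation(seg, 0.5) == min(seg.organ_extents.values()) // 2
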