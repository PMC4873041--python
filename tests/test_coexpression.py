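"""Normalization, co-expression matrices, Gamma(d) and regulon analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from syntenon import coexpression as cx
from syntenon.formats import Operon, OperonMap, RegulonTable
from syntenon.segments import SegmentSet, SyntenySegment

from conftest import make_genome


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalize_hand_example():
    raw = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
    out = cx.quantile_normalize(raw)
    assert np.allclose(out["s1"], [1.5, 3.5])
    assert np.allclose(out["s2"], [1.5, 3.5])


def test_quantile_normalize_identical_and_single_column():
    raw = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    assert np.allclose(cx.quantile_normalize(raw), raw)
    single = pd.DataFrame({"a": [5.0, 2.0, 9.0]})
    assert np.allclose(cx.quantile_normalize(single), single)


def test_quantile_normalize_sorted_columns_identical(rng):
    raw = pd.DataFrame(rng.normal(size=(40, 6)))
    out = cx.quantile_normalize(raw).to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(out.shape[1]):
        assert np.allclose(np.sort(out[:, j]), ref)


def test_quantile_normalize_ties_get_mean_target():
    raw = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
    out = cx.quantile_normalize(raw)
    assert out["a"][0] == out["a"][1]


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_quantile_normalize_idempotent(seed):
    rng = np.random.default_rng(seed)
    raw = pd.DataFrame(rng.normal(size=(15, 4)))
    once = cx.quantile_normalize(raw)
    twice = cx.quantile_normalize(once)
    assert np.allclose(once, twice, atol=1e-12)


def test_gene_activity_probe_averaging():
    probes = pd.DataFrame({"c1": [2.0, 4.0, 7.0]}, index=["p1", "p2", "p3"])
    acts = cx.gene_activity(probes, {"gA": ["p1", "p2"], "gB": ["p2", "p3"],
                                     "gC": []})
    assert acts.loc["gA", "c1"] == 3.0
    assert acts.loc["gB", "c1"] == 5.5   # probe p2 contributes to both genes
    assert "gC" not in acts.index        # gene without probes dropped


# ---------------------------------------------------------------------------
# co-expression matrix
# ---------------------------------------------------------------------------

def test_coexpression_examples():
    A = pd.DataFrame([[1.0, -1.0, 0.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0],
                      [-1.0, 1.0, 0.0]], index=list("abcd"))
    C = cx.coexpression_matrix(A)
    assert C.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)  # orthogonal
    assert C.loc["a", "c"] == pytest.approx(1.0)
    assert C.loc["a", "d"] == pytest.approx(-1.0)


def test_coexpression_matches_brute_force(rng):
    A = pd.DataFrame(rng.normal(size=(50, 20)))
    C = cx.coexpression_matrix(A).to_numpy()
    M = A.to_numpy()
    for i in range(0, 50, 7):
        for j in range(0, 50, 11):
            r = np.corrcoef(M[i], M[j])[0, 1]
            assert C[i, j] == pytest.approx(r, abs=1e-10)


def test_coexpression_zero_variance_flagged():
    A = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
    C = cx.coexpression_matrix(A)
    assert np.isnan(C.loc["flat", "ok"])


def test_smoothing_preserves_mean_and_impulse(rng):
    M = pd.DataFrame(rng.normal(size=(40, 40)))
    S = cx.smooth_matrix(M, sigma=5)
    assert S.to_numpy().mean() == pytest.approx(M.to_numpy().mean(), abs=1e-10)
    const = pd.DataFrame(np.full((20, 20), 3.3))
    assert np.allclose(cx.smooth_matrix(const, sigma=4), 3.3)
    imp = np.zeros((31, 31)); imp[15, 15] = 1.0
    out = cx.smooth_matrix(pd.DataFrame(imp), sigma=3).to_numpy()
    assert out[15, 15] == out.max()


# ---------------------------------------------------------------------------
# Gamma(d)
# ---------------------------------------------------------------------------

def _toy_gamma_setup(n=30, spacing=1000):
    genes = [f"g{i}" for i in range(n)]
    positions = pd.Series(np.arange(n) * spacing, index=genes, dtype=float)
    return genes, positions, n * spacing


def test_gamma_constant_matrix():
    genes, pos, clen = _toy_gamma_setup()
    C = pd.DataFrame(0.42, index=genes, columns=genes)
    prof = cx.gamma_profile(C, pos, clen)
    assert np.allclose(prof.gamma, 0.42)


def test_gamma_equals_direct_enumeration(rng):
    genes, pos, clen = _toy_gamma_setup()
    M = rng.normal(size=(30, 30)); M = (M + M.T) / 2
    C = pd.DataFrame(M, index=genes, columns=genes)
    prof = cx.gamma_profile(C, pos, clen, half_width=500.0)
    # direct enumeration
    sums, counts = {}, {}
    for i in range(30):
        for j in range(i + 1, 30):
            d = abs(i - j) * 1000
            d = min(d, clen - d)
            b = int(d // 1000)
            sums[b] = sums.get(b, 0.0) + M[i, j]
            counts[b] = counts.get(b, 0) + 1
    for row in prof.itertuples():
        b = int((row.distance - 500) // 1000)
        assert row.gamma == pytest.approx(sums[b] / counts[b], abs=1e-12)
        assert row.n_pairs == counts[b]


def test_gamma_empty_filter():
    genes, pos, clen = _toy_gamma_setup()
    C = pd.DataFrame(0.5, index=genes, columns=genes)
    prof = cx.gamma_profile(C, pos, clen, pair_mask=np.zeros((30, 30), bool))
    assert prof.empty


def test_gamma_recovers_planted_block_structure(rng):
    """Block-correlated data: Gamma ~ rho inside blocks, ~ 0 beyond."""
    n_blocks, block, S, rho = 12, 5, 800, 0.6
    n = n_blocks * block
    z_block = rng.normal(size=(n_blocks, S))
    A = np.sqrt(rho) * np.repeat(z_block, block, axis=0) + \
        np.sqrt(1 - rho) * rng.normal(size=(n, S))
    genes = [f"g{i}" for i in range(n)]
    C = cx.coexpression_matrix(pd.DataFrame(A, index=genes))
    pos = pd.Series(np.arange(n) * 1000.0, index=genes)
    prof = cx.gamma_profile(C, pos, n * 1000)
    near = prof[prof.distance < block * 1000]
    far = prof[(prof.distance > 2 * block * 1000) & (prof.distance < 10 * block * 1000)]
    # pairs at d < block size are within-block with probability (block-d)/block
    expected_near = (near.distance.to_numpy() // 1000).astype(int)
    exp = rho * (block - expected_near / 1) / block
    exp = rho * (block - (near.distance.to_numpy() - 500) / 1000) / block
    assert np.allclose(near.gamma, exp, atol=0.05)
    assert abs(far.gamma.mean()) < 0.02


# ---------------------------------------------------------------------------
# regulon-aware statistics
# ---------------------------------------------------------------------------

def _regulon_setup():
    ops = OperonMap([Operon("op1", ("a", "b"), "+"), Operon("op2", ("c",), "+"),
                     Operon("op3", ("d",), "-")])
    reg = RegulonTable()
    reg.add("tfX", "TF", ["op1", "op2"])
    reg.add("sfY", "SF", ["op2", "op3"])
    return ops, reg


def test_factor_sharing_fraction_brute_force():
    ops, reg = _regulon_setup()
    genes = list("abcd")
    C = pd.DataFrame(0.5, index=genes, columns=genes)
    df = cx.factor_sharing_fraction(C, genes, ops, reg, bins=np.array([0.0, 1.0]))
    # different-operon pairs: ac, ad, bc, bd, cd -> share TF: ac, bc; SF: cd
    assert df.n_pairs.iloc[0] == 5
    assert df.share_tf.iloc[0] == pytest.approx(2 / 5)
    assert df.share_sf.iloc[0] == pytest.approx(1 / 5)
    assert df.share_either.iloc[0] == pytest.approx(3 / 5)


def test_factor_sharing_no_regulons():
    ops, _ = _regulon_setup()
    genes = list("abcd")
    C = pd.DataFrame(0.5, index=genes, columns=genes)
    df = cx.factor_sharing_fraction(C, genes, ops, RegulonTable(),
                                    bins=np.array([0.0, 1.0]))
    assert (df.share_either == 0).all()


def test_seg_regulation_classes():
    # segments s1, s2 share tfX; s3 has none
    segs = SegmentSet([
        SyntenySegment("g", "chr", ("a", "b"), (0, 2000)),
        SyntenySegment("g", "chr", ("c",), (5000, 6000)),
        SyntenySegment("g", "chr", ("d",), (9000, 10000)),
    ])
    ops, reg = _regulon_setup()
    genes = list("abcd")
    C = pd.DataFrame(0.3, index=genes, columns=genes)
    out = cx.seg_regulation_distributions(C, segs, ops, reg, kind="TF")
    # a,b in s1 (tfX); c in s2 (tfX); d in s3 (none)
    assert len(out["same"]) == 2      # a-c, b-c
    assert len(out["different"]) == 3  # a-d, b-d, c-d
    assert len(out["none"]) == 0


def test_regulated_operons_per_segment():
    segs = SegmentSet([SyntenySegment("g", "chr", ("a", "b", "c"), (0, 6000)),
                       SyntenySegment("g", "chr", ("d",), (9000, 10000))])
    ops, reg = _regulon_setup()
    df = cx.regulated_operons_per_segment(segs, ops, reg, kind="TF")
    two = df[df.n_operons == 2].iloc[0]
    assert two.mean_regulated == 2  # op1 and op2 both tfX-regulated
    one = df[df.n_operons == 1].iloc[0]
    assert one.mean_regulated == 0  # op3 has no TF


# ---------------------------------------------------------------------------
# cross-genome conservation
# ---------------------------------------------------------------------------

def test_proximity_conservation_reference_vs_self_and_random(small_sim):
    _, collection, truth = small_sim
    ref = next(iter(collection.genomes))
    genes = [g.id for g in collection[ref].genes][:150]
    C = pd.DataFrame(0.5, index=genes, columns=genes)
    curve = cx.proximity_conservation_curve(ref, collection, truth.distances, C,
                                            d0=10_000)
    self_bin = curve[(curve.div_bin == 0)]
    assert (self_bin.fraction == 1.0).any()  # the reference itself


def test_distant_synteny_nearest_neighbor_control():
    g = make_genome("g", [f"C{i}" for i in range(20)])
    genes = [x.id for x in g.genes]
    rngl = np.random.default_rng(1)
    M = rngl.normal(0, 0.1, size=(20, 20)); M = (M + M.T) / 2
    # pairs (0, 10) and (1, 11) in synteny with boosted C
    M[0, 10] = M[10, 0] = 0.8
    M[1, 11] = M[11, 1] = 0.8
    C = pd.DataFrame(M, index=genes, columns=genes)
    syn = {frozenset(("C0", "C10")), frozenset(("C1", "C11"))}
    out = cx.distant_synteny_coexpression(C, syn, g, min_distance=3000)
    curves = dict(out.groupby("curve")["mean_c"].mean())
    assert curves["synteny"] > curves["no_synteny"]
    assert curves["synteny"] > curves["neighbor_control"]


def test_conserved_decomposition_identical_species():
    g = make_genome("gA", [f"C{i}" for i in range(12)])
    genes = [x.id for x in g.genes]
    rngl = np.random.default_rng(2)
    M = rngl.uniform(-0.2, 0.9, size=(12, 12)); M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    C = pd.DataFrame(M, index=genes, columns=genes)
    ops = OperonMap([Operon(f"op{i}", (genes[i],), "+") for i in range(12)])
    segs = SegmentSet([SyntenySegment("gA", "chr", tuple(genes[:4]), (0, 4400))])
    reg = RegulonTable()
    reg.add("sigA", "SF", ["op0", "op1"])
    orth = {f"C{i}": (genes[i], genes[i]) for i in range(12)}
    out = cx.conserved_coexpression_decomposition(
        C, C, orth, g, g, segs, segs, ops, ops, reg, reg,
        housekeeping_sf=("sigA", "sigA"))
    assert not out.empty
    assert (out.proximity_or_hk >= out.proximity - 1e-12).all()
    with pytest.raises(ValueError):
        cx.conserved_coexpression_decomposition(
            C, C, {}, g, g, segs, segs, ops, ops, reg, reg)
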