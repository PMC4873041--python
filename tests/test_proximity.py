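"""The conserved-proximity statistic: distances, tail p-values, the
threshold scan, the positional null and the FDR calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from syntenon import phylo, proximity
from syntenon.formats import GenomeCollection
from syntenon.proximity import (
    CalibrationError, binomial_tail_pvalue, calibrate_threshold,
    fit_tail_exponent, multicopy_transform, normalized_distance,
    null_pihat_sample, pair_significance, pair_table, scan_min_pvalue,
    simulate_null,
)

from conftest import make_genome


def brute_force_binomial_tail(M, Mp, x):
    """P(Binomial(Mp, x) >= M) by direct summation (integer counts)."""
    return sum(comb(Mp, k, exact=True) * x**k * (1 - x) ** (Mp - k)
               for k in range(M, Mp + 1))


# ---------------------------------------------------------------------------
# normalized distance
# ---------------------------------------------------------------------------

def test_normalized_distance_examples():
    g = make_genome("g", ["A", "B"], spacing=125_000, gene_len=1000,
                    length=600_000)
    # midpoints 500 and 125500 -> d = 125 kb -> x = 0.5
    a, b = g.genes
    assert normalized_distance(a, b, g) == pytest.approx(0.5, abs=1e-4)


def test_normalized_distance_circular_minimum():
    g = make_genome("g", ["A", "B"], spacing=1, gene_len=1, length=600_000)
    # place midpoints at ~0 and ~500 kb on a 600 kb circle: d = 100 kb
    from syntenon.formats import Chromosome, Gene, Genome

    g = Genome("g", [Chromosome("chr", 600_000, True)], [
        Gene("a", "chr", 0, 2, "+", "A"),          # midpoint 1
        Gene("b", "chr", 499_999, 500_001, "+", "B"),  # midpoint 500000
    ])
    x = normalized_distance(g.genes[0], g.genes[1], g)
    assert x == pytest.approx(0.4, abs=1e-4)


def test_normalized_distance_coincident_and_cross_chromosome():
    from syntenon.formats import Chromosome, Gene, Genome

    g = Genome("g", [Chromosome("c1", 10_000, True), Chromosome("c2", 10_000, True)], [
        Gene("a", "c1", 100, 200, "+", "A"),
        Gene("b", "c1", 100, 200, "-", "B"),
        Gene("c", "c2", 100, 200, "+", "C"),
    ])
    assert normalized_distance(g.genes[0], g.genes[1], g) == 0.0
    assert normalized_distance(g.genes[0], g.genes[2], g) == 1.0


def test_normalized_distance_foreign_genome_rejected():
    g1 = make_genome("g1", ["A"])
    g2 = make_genome("g2", ["B"])
    with pytest.raises(ValueError):
        normalized_distance(g1.genes[0], g2.genes[0], make_genome("g3", ["C"]))


# ---------------------------------------------------------------------------
# beta tail p-value vs brute force
# ---------------------------------------------------------------------------

def test_binomial_tail_examples():
    assert binomial_tail_pvalue(0, 10, 0.3) == 1.0
    assert binomial_tail_pvalue(1, 1, 0.2) == pytest.approx(0.2, abs=1e-12)
    assert binomial_tail_pvalue(3, 10, 0.1) == pytest.approx(0.07019, abs=5e-6)
    with pytest.raises(ValueError):
        binomial_tail_pvalue(5, 3, 0.5)


def test_binomial_tail_matches_brute_force_grid():
    """|I_x(M, M'-M+1) - survival sum| < 1e-12 over integer grid up to 50."""
    xs = np.arange(0.01, 1.0, 0.07)
    for Mp in (1, 2, 5, 17, 50):
        for M in range(1, Mp + 1):
            for x in xs:
                assert binomial_tail_pvalue(M, Mp, x) == pytest.approx(
                    brute_force_binomial_tail(M, Mp, float(x)), abs=1e-12)


@settings(max_examples=60, derandomize=True)
@given(Mp=st.integers(1, 40), frac=st.floats(0.01, 1.0), x=st.floats(0.001, 0.999))
def test_binomial_tail_property(Mp, frac, x):
    M = max(1, int(round(frac * Mp)))
    assert binomial_tail_pvalue(M, Mp, x) == pytest.approx(
        brute_force_binomial_tail(M, Mp, x), abs=1e-10)


# ---------------------------------------------------------------------------
# multi-copy transform
# ---------------------------------------------------------------------------

def test_multicopy_examples():
    assert multicopy_transform(0.3, 1) == pytest.approx(0.3)
    assert multicopy_transform(0.0, 5) == 0.0
    assert multicopy_transform(0.1, 3) == pytest.approx(0.271)
    assert multicopy_transform(0.4, 0) == 1.0  # absence convention


@pytest.mark.parametrize("n", [1, 2, 5])
def test_multicopy_transform_uniform_under_null(n, rng):
    """p = 1-(1-x_min)^n is Uniform(0,1) for the min of n uniforms."""
    x_min = rng.random((10_000, n)).min(axis=1)
    p = 1 - (1 - x_min) ** n
    assert stats.kstest(p, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

def test_scan_single_observation():
    pi, x, mp = scan_min_pvalue(np.array([[0.2]]), np.ones(1), np.ones((1, 1), bool))
    assert pi[0] == pytest.approx(0.2)
    assert x[0] == pytest.approx(0.2)
    assert mp[0] == 1.0


def test_scan_exhaustive_enumeration_example():
    """Three unit-weight genomes with p = {0.1, 0.5, 1.0}.

    Candidates: t=0.1 (M=1, pi = 1 - 0.9^3 = 0.271) and t=0.5 (M=2,
    pi = P(Bin(3, 0.5) >= 2) = 0.5); the minimum is 0.271 at 0.1.
    """
    P = np.array([[0.1, 0.5, 1.0]])
    pi, x, mp = scan_min_pvalue(P, np.ones(3), np.ones((1, 3), bool))
    assert pi[0] == pytest.approx(0.271, abs=1e-12)
    assert x[0] == pytest.approx(0.1)
    assert mp[0] == 3.0


def test_scan_all_far_gives_one():
    P = np.ones((1, 4))
    pi, x, _ = scan_min_pvalue(P, np.ones(4), np.ones((1, 4), bool))
    assert pi[0] == 1.0
    assert np.isnan(x[0])


def test_scan_brute_force_random_instances(rng):
    """The scan minimum equals explicit evaluation at every candidate."""
    for _ in range(50):
        m = rng.integers(2, 12)
        w = rng.uniform(0.2, 1.0, size=m)
        present = rng.random(m) < 0.8
        if present.sum() == 0:
            present[0] = True
        p = np.where(rng.random(m) < 0.2, 1.0, rng.random(m))
        pi, _, mp = scan_min_pvalue(p[None], w, present[None])
        Mp = w[present].sum()
        best = 1.0
        for t in np.unique(p[present & (p < 1.0)]):
            M = w[present & (p <= t)].sum()
            best = min(best, binomial_tail_pvalue(M, Mp, t))
        assert pi[0] == pytest.approx(best, rel=1e-10)
        assert mp[0] == pytest.approx(Mp)


# ---------------------------------------------------------------------------
# pair statistics on collections
# ---------------------------------------------------------------------------

def _weights_for(collection, close=False):
    ids = list(collection.genomes)
    n = len(ids)
    D = pd.DataFrame(1.0 - np.eye(n), index=ids, columns=ids)
    return phylo.compute_weights(D)


def test_pair_single_copy_symmetry():
    genomes = [make_genome(f"g{i}", ["A", "B", "C"]) for i in range(3)]
    coll = GenomeCollection(genomes)
    w = _weights_for(coll)
    s = pair_significance("A", "B", coll, w)
    assert s.pi_i_given_j == pytest.approx(s.pi_j_given_i)
    assert s.pi_hat == pytest.approx(max(s.pi_i_given_j, s.pi_j_given_i))


def test_pair_multicopy_directions_differ():
    """j in 3 copies: pi_hat is the max (least significant) direction,
    and each direction matches an independent recomputation."""
    genomes = []
    for i in range(5):
        cogs = ["A", "J", ".", "J", ".", "J", ".", "."]
        genomes.append(make_genome(f"g{i}", cogs))
    coll = GenomeCollection(genomes)
    w = _weights_for(coll)
    s = pair_significance("A", "J", coll, w)
    assert s.pi_hat == pytest.approx(max(s.pi_i_given_j, s.pi_j_given_i))
    # independent recomputation of direction A|J per genome
    g = genomes[0]
    L = proximity.L_DEFAULT
    a = next(x for x in g.genes if x.cog == "A")
    xs = []
    clen = g.chromosomes["chr"].length
    for gene in g.genes:
        if gene.cog == "J":
            d = abs(a.midpoint - gene.midpoint)
            xs.append(min(1.0, 2 * min(d, clen - d) / L))
    p_expected = 1 - (1 - min(xs)) ** 3
    P = np.full((1, 5), p_expected)
    pi, _, _ = scan_min_pvalue(P, w.omega.to_numpy(), np.ones((1, 5), bool))
    assert s.pi_i_given_j == pytest.approx(pi[0])


def test_pair_same_cog_rejected():
    coll = GenomeCollection([make_genome("g0", ["A", "B"])])
    w = _weights_for(coll)
    with pytest.raises(ValueError):
        pair_significance("A", "A", coll, w)


def test_pair_table_fast_path_matches_per_pair(small_sim):
    _, collection, truth = small_sim
    w = phylo.compute_weights(truth.distances)
    cogs = collection.cogs[:12]
    pairs = [(a, b) for i, a in enumerate(cogs) for b in cogs[i + 1:]]
    table = pair_table(collection, w, pairs=pairs)
    for row in table.sample(8, random_state=0).itertuples():
        s = pair_significance(row.cog_i, row.cog_j, collection, w)
        assert row.pi_hat == pytest.approx(s.pi_hat, rel=1e-10)


def test_pihat_invariant_under_relabeling_and_clade_duplication(small_sim):
    from syntenon.formats import Gene, Genome

    _, collection, truth = small_sim
    w = phylo.compute_weights(truth.distances)
    s0 = pair_significance("COG0000", "COG0001", collection, w)

    # duplicate one genome at distance ~0 from itself
    gid = next(iter(collection.genomes))
    src = collection[gid]
    dup = Genome("dup", list(src.chromosomes.values()),
                 [Gene(g.id + "_d", g.chromosome, g.start, g.end, g.strand, g.cog)
                  for g in src.genes])
    coll2 = GenomeCollection(list(collection) + [dup])
    old = truth.distances.to_numpy()
    n = old.shape[0]
    new = np.zeros((n + 1, n + 1))
    new[:n, :n] = old
    k = list(truth.distances.index).index(gid)
    new[n, :n] = old[k, :]
    new[:n, n] = old[:, k]
    labels = list(truth.distances.index) + ["dup"]
    D = pd.DataFrame(new, index=labels, columns=labels)
    w2 = phylo.compute_weights(D)
    assert w2.effective_genomes == pytest.approx(
        phylo.compute_weights(truth.distances).effective_genomes)
    s2 = pair_significance("COG0000", "COG0001", coll2, w2)
    assert s2.pi_hat == pytest.approx(s0.pi_hat, rel=1e-9)


# ---------------------------------------------------------------------------
# positional null and calibration
# ---------------------------------------------------------------------------

def test_null_deterministic_under_seed(small_sim):
    _, collection, truth = small_sim
    w = phylo.compute_weights(truth.distances)
    a = simulate_null(collection, w, seed=7, n_pairs=300)
    b = simulate_null(collection, w, seed=7, n_pairs=300)
    c = simulate_null(collection, w, seed=8, n_pairs=300)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_null_single_genome_uniform():
    """With one genome the scan has a single candidate and pi = x exactly."""
    cogs = [f"C{i:03d}" for i in range(454)]  # chromosome ~ 499 kb < L
    coll = GenomeCollection([make_genome("g0", cogs)])
    D = pd.DataFrame([[0.0]], index=["g0"], columns=["g0"])
    w = phylo.compute_weights(D)
    pis = simulate_null(coll, w, seed=3, n_pairs=10_000, min_joint=1)
    assert stats.kstest(pis, "uniform").pvalue > 0.01


def test_null_tail_log_linear():
    """The tail of -ln(pi_hat) decays exponentially (R^2 > 0.95)."""
    pis = null_pihat_sample(np.ones(100), np.full(100, 4_000_000),
                            n_pairs=30_000, seed=2)
    a, r2, _ = fit_tail_exponent(pis)
    assert a > 0
    assert r2 > 0.95


def test_calibration_closed_forms(rng):
    """Exponential nulls with known exponent give pi* = (FDR * sigma_s)^(1/a)."""
    for a_true, expected in ((1.0, 5e-5), (2.0, np.sqrt(5e-5))):
        y = rng.exponential(1.0 / a_true, size=200_000)
        null = np.exp(-y)
        # empirical sample with sigma_s ~ 0.01 held constant near the
        # solution: 950 values far below it plus a dense candidate grid
        emp = np.concatenate([np.full(950, 1e-7),
                              np.geomspace(1e-5, 1e-1, 50),
                              np.full(99_000, 0.9)])
        cal = calibrate_threshold(emp, null, fdr=0.005)
        assert cal.a == pytest.approx(a_true, rel=0.1)
        # pi* solves pi^a = FDR * sigma_s with sigma_s ~ 0.01
        assert abs(np.log(cal.pi_star) - np.log(expected)) < 0.8


def test_calibration_requires_enough_null():
    with pytest.raises(ValueError):
        calibrate_threshold(np.array([0.5]), np.full(100, 0.5))


def test_calibration_failure_on_non_decaying_tail(rng):
    flat = rng.uniform(0.8, 1.0, size=20_000)  # y compressed near 0
    with pytest.raises(CalibrationError):
        calibrate_threshold(rng.random(1000), flat)
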