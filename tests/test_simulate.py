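"""The synthetic-data generator: determinism, planted structure, and the
closed-form correlation structure of simulated expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from syntenon.coexpression import coexpression_matrix
from syntenon.formats import GenomeCollection
from syntenon.simulate import (
    ExpressionConfig, SimulationConfig, simulate_expression, simulate_genomes,
    simulate_tracks,
)


def order_of(genome):
    return [g.cog for g in genome.genes]


def test_deterministic_under_seed():
    cfg = SimulationConfig(seed=9, n_genomes=6, n_cogs=120, planted_clusters=[(4, 1.0)] * 3)
    c1, t1 = simulate_genomes(cfg)
    c2, t2 = simulate_genomes(cfg)
    for g1, g2 in zip(c1, c2):
        assert [(g.id, g.start, g.strand, g.cog) for g in g1.genes] == \
               [(g.id, g.start, g.strand, g.cog) for g in g2.genes]
    assert t1.distances.equals(t2.distances)
    e1, *_ = simulate_expression(c1, t1, cfg)
    e2, *_ = simulate_expression(c2, t2, cfg)
    assert e1.equals(e2)
    b1, cov1, tss1, tus1 = simulate_tracks(c1, t1, cfg)
    b2, cov2, tss2, tus2 = simulate_tracks(c2, t2, cfg)
    assert b1.df.equals(b2.df)
    assert np.array_equal(cov1[0].get("chr", "+"), cov2[0].get("chr", "+"))
    assert list(tss1) == list(tss2)


def test_different_seed_differs():
    cfg1 = SimulationConfig(seed=9, n_genomes=6, n_cogs=120)
    cfg2 = SimulationConfig(seed=10, n_genomes=6, n_cogs=120)
    c1, _ = simulate_genomes(cfg1)
    c2, _ = simulate_genomes(cfg2)
    orders1 = [order_of(g) for g in c1]
    orders2 = [order_of(g) for g in c2]
    assert orders1 != orders2


def test_zero_relocation_rate_identical_orders():
    cfg = SimulationConfig(seed=2, n_genomes=8, n_cogs=100, relocation_rate=0.0,
                           planted_clusters=[])
    coll, _ = simulate_genomes(cfg)
    orders = [order_of(g) for g in coll]
    assert all(o == orders[0] for o in orders)


def test_retention_one_clusters_stay_contiguous():
    cfg = SimulationConfig(seed=3, n_genomes=10, n_cogs=150,
                           planted_clusters=[(5, 1.0)] * 4, relocation_rate=20.0)
    coll, truth = simulate_genomes(cfg)
    for genome in coll:
        for cl, members in truth.cluster_genes[genome.id].items():
            assert len(members) == 5
            idx = sorted(i for i, g in enumerate(genome.genes) if g.id in members)
            assert idx == list(range(idx[0], idx[0] + 5))  # consecutive
            # all 10 within-cluster pairs within the cluster extent
            genes = [genome.genes[i] for i in idx]
            extent = max(g.end for g in genes) - min(g.start for g in genes)
            assert extent <= 5 * cfg.spacing


def test_retention_zero_high_rate_distances_approach_uniform_null():
    """x values of a fixed COG pair across genomes ~ Uniform after heavy
    shuffling (chromosome spans the full normalization length)."""
    cfg = SimulationConfig(seed=4, n_genomes=60, n_cogs=455,
                           planted_clusters=[(5, 0.0)] * 2, relocation_rate=60.0)
    coll, truth = simulate_genomes(cfg)
    L = 500_000
    xs = []
    a, b = "COG0010", "COG0200"
    for genome in coll:
        ga = genome.cog_index[a][0]
        gb = genome.cog_index[b][0]
        clen = genome.chromosomes["chr"].length
        d = abs(ga.midpoint - gb.midpoint)
        d = min(d, clen - d)
        xs.append(min(1.0, 2 * d / L))
    assert stats.kstest(xs, "uniform").pvalue > 0.01


def test_cluster_exceeding_genome_rejected():
    with pytest.raises(ValueError, match="exceed"):
        SimulationConfig(n_cogs=10, planted_clusters=[(6, 1.0), (6, 1.0)]).validate()


def test_copy_number_law():
    cfg = SimulationConfig(seed=5, n_genomes=4, n_cogs=200, planted_clusters=[],
                           copy_number_law={0: 0.2, 1: 0.6, 2: 0.2})
    coll, _ = simulate_genomes(cfg)
    counts = []
    for genome in coll:
        per_cog = [genome.copy_number(f"COG{i:04d}") for i in range(200)]
        counts.extend(per_cog)
    counts = np.array(counts)
    assert abs((counts == 0).mean() - 0.2) < 0.06
    assert abs((counts == 2).mean() - 0.2) < 0.06


def test_rho_sum_validation():
    cfg = SimulationConfig(expression=ExpressionConfig(rho_op=0.5, rho_seg=0.4, rho_f=0.3))
    with pytest.raises(ValueError):
        cfg.validate()


def test_expression_closed_form_correlations():
    """Planted correlation shares are recovered by the Pearson matrix."""
    cfg = SimulationConfig(seed=5, n_genomes=3, n_cogs=200,
                           planted_clusters=[(6, 1.0)] * 8,
                           expression=ExpressionConfig(
                               n_conditions=2000, rho_op=0.2, rho_seg=0.3,
                               rho_f=0.2))
    coll, truth = simulate_genomes(cfg)
    expr, ops, _ = simulate_expression(coll, truth, cfg)
    C = coexpression_matrix(expr)
    gid = next(iter(coll.genomes))
    cm = truth.cluster_genes[gid]
    L = truth.loadings

    diff_op_with_f, cross_shared, cross_unshared = [], [], []
    for cl, members in cm.items():
        has_f = (L[cl] > 0).any()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if ops.operon_of(members[i]) != ops.operon_of(members[j]) and has_f:
                    diff_op_with_f.append(C.loc[members[i], members[j]])
    import itertools
    for a, b in itertools.combinations(cm, 2):
        share = ((L[a] > 0) & (L[b] > 0)).any()
        vals = [C.loc[gi, gj] for gi in cm[a][:3] for gj in cm[b][:3]]
        (cross_shared if share else cross_unshared).extend(vals)
    # same segment, different operon, factor-bearing: rho_seg + rho_f = 0.5
    assert np.mean(diff_op_with_f) == pytest.approx(0.5, abs=0.05)
    # different segments sharing a factor: rho_f = 0.2
    assert np.mean(cross_shared) == pytest.approx(0.2, abs=0.05)
    # unrelated segments: ~0
    assert np.mean(cross_unshared) == pytest.approx(0.0, abs=0.04)


def test_zero_rho_gives_uncorrelated_activities():
    cfg = SimulationConfig(seed=6, n_genomes=2, n_cogs=80, planted_clusters=[(5, 1.0)] * 2,
                           expression=ExpressionConfig(n_conditions=500, rho_op=0.0,
                                                       rho_seg=0.0, rho_f=0.0))
    coll, truth = simulate_genomes(cfg)
    expr, *_ = simulate_expression(coll, truth, cfg)
    C = coexpression_matrix(expr).to_numpy()
    off = C[np.triu_indices_from(C, k=1)]
    assert abs(off.mean()) < 0.01
    assert off.std() == pytest.approx(1 / np.sqrt(500), rel=0.25)


def test_tracks_uniform_binding_when_no_enrichment():
    cfg = SimulationConfig(seed=7, n_genomes=2, n_cogs=300, border_enrichment=1.0,
                           n_binding_regions=600, planted_clusters=[(5, 1.0)] * 4)
    coll, truth = simulate_genomes(cfg)
    binding, *_ = simulate_tracks(coll, truth, cfg)
    gid = next(iter(coll.genomes))
    clen = coll[gid].chromosomes["chr"].length
    mids = binding.midpoints("chr")
    assert stats.kstest(mids / clen, "uniform").pvalue > 0.01


def test_tracks_no_readthrough_tu_equals_operon():
    cfg = SimulationConfig(seed=8, n_genomes=2, n_cogs=100, gene_gap=300,
                           planted_clusters=[], readthrough_prob_in=0.0,
                           readthrough_prob_out=0.0)
    coll, truth = simulate_genomes(cfg)
    _, _, _, tus = simulate_tracks(coll, truth, cfg)
    long_sets = sorted(frozenset(t.genes) for t in tus.of_kind("long"))
    op_sets = sorted(frozenset(o.genes) for o in truth.operons)
    assert long_sets == op_sets


def test_emitted_genomes_are_valid_collections(small_sim):
    _, collection, truth = small_sim
    assert isinstance(collection, GenomeCollection)
    for genome in collection:
        starts = [g.start for g in genome.genes]
        assert starts == sorted(starts)
        for g in genome.genes:
            assert 0 <= g.start < g.end <= genome.chromosomes[g.chromosome].length
    # distance matrix is a valid phylo input
    from syntenon.phylo import validate_distance_matrix

    validate_distance_matrix(truth.distances)
    assert truth.distances.to_numpy().max() == pytest.approx(0.5)
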