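"""The phylogenetically weighted conserved-proximity statistic.

For a pair of orthology classes (COGs) i, j, each genome g contributes a
normalized inter-gene distance x = min(1, 2d/L) with L = 500 kb, computed
from gene midpoints with chromosomes formally circularized; genes on
distinct chromosomes (or an absent partner) give x = 1. Under a uniform
positional null the weighted count M_ij(x) of genomes with x_ij <= x is
binomial-like with success probability x, so the tail probability

    pi_ij(x) = I_x(M_ij(x), M'_ij - M_ij(x) + 1)

(regularized incomplete beta, generalizing the binomial survival function
to real-valued weighted counts) is a p-value at each threshold x. The
statistic minimizes pi over the observed thresholds; multi-copy COGs enter
through the probability-integral transform p = 1 - (1 - x_min)^n of the
nearest-copy distance. Directions are symmetrized by the maximum, and a
genome-wide significance threshold pi* is calibrated against a positional
null at a fixed false discovery rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc

from .formats import Gene, Genome, GenomeCollection
from .phylo import WeightVector

L_DEFAULT = 500_000  # normalization length in bp; distances cap at L/2
FDR_DEFAULT = 0.005


class CalibrationError(RuntimeError):
    """The null tail does not decay exponentially; no threshold can be set."""


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def normalized_distance(gene_a: Gene, gene_b: Gene, genome: Genome, L: int = L_DEFAULT) -> float:
    """Normalized midpoint distance x = min(1, 2d/L) within one genome.

    Chromosomes are formally circularized (circular-minimum distance on the
    chromosome length, linear or not); genes on distinct chromosomes give
    x = 1.
    """
    for g in (gene_a, gene_b):
        if g.chromosome not in genome.chromosomes or g not in genome:
            raise ValueError(f"gene {g.id} does not belong to genome {genome.id}")
    if gene_a.chromosome != gene_b.chromosome:
        return 1.0
    clen = genome.chromosomes[gene_a.chromosome].length
    d = abs(gene_a.midpoint - gene_b.midpoint)
    d = min(d, clen - d)
    return min(1.0, 2.0 * d / L)


def binomial_tail_pvalue(M: float, M_prime: float, x: float) -> float:
    """I_x(M, M'-M+1): for integer arguments, P(Binomial(M', x) >= M).

    Accepts real-valued (weighted) counts; M = 0 returns 1.
    """
    if M > M_prime:
        raise ValueError("weighted count M cannot exceed the effective count M'")
    if not (0.0 < x <= 1.0):
        raise ValueError("threshold x must be in (0, 1]")
    if M <= 0:
        return 1.0
    return float(betainc(M, M_prime - M + 1.0, x))


def multicopy_transform(x_min: float, n: int) -> float:
    """p = 1 - (1 - x_min)^n: uniform under the null for the nearest of n copies.

    n = 0 (partner COG absent) gives p = 1 by convention.
    """
    if n < 0:
        raise ValueError("copy count must be >= 0")
    if n == 0:
        return 1.0
    return 1.0 - (1.0 - x_min) ** n


# ---------------------------------------------------------------------------
# the minimization kernel
# ---------------------------------------------------------------------------

def scan_min_pvalue(P: np.ndarray, weights: np.ndarray, present: np.ndarray):
    """Minimize the beta-tail p-value over observed effective variates.

    Parameters
    ----------
    P : (n_pairs, n_genomes) effective per-genome variates in [0, 1]
        (1 = too far / partner absent).
    weights : (n_genomes,) phylogenetic weights.
    present : (n_pairs, n_genomes) boolean — both COGs present in the genome
        (defines M'_ij; genomes with present=False never count).

    Returns
    -------
    pi_hat : (n_pairs,) minimized p-values (1 where no candidate).
    x_hat : (n_pairs,) argmin thresholds (nan where no candidate).
    M_prime : (n_pairs,) per-pair effective genome counts.
    """
    P = np.asarray(P, dtype=float)
    present = np.asarray(present, dtype=bool)
    w = np.where(present, weights[None, :], 0.0)
    M_prime = w.sum(axis=1)

    # sort variates; absent genomes pushed to the end with zero weight
    Pm = np.where(present, P, np.inf)
    order = np.argsort(Pm, axis=1, kind="stable")
    Ps = np.take_along_axis(Pm, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    M = np.cumsum(ws, axis=1)

    candidate = (Ps < 1.0) & (np.take_along_axis(present, order, axis=1))
    a = np.where(candidate & (M > 0), M, 1.0)
    b = np.clip(M_prime[:, None] - a + 1.0, 1e-12, None)
    x_eval = np.clip(np.where(candidate, Ps, 0.5), 1e-300, 1.0)
    pi = betainc(a, b, x_eval)
    pi = np.where(candidate & (M > 0), pi, np.inf)

    idx = np.argmin(pi, axis=1)
    rows = np.arange(P.shape[0])
    pi_hat = pi[rows, idx]
    x_hat = Ps[rows, idx]
    no_candidate = ~np.isfinite(pi_hat)
    pi_hat = np.where(no_candidate, 1.0, np.minimum(pi_hat, 1.0))
    x_hat = np.where(no_candidate, np.nan, x_hat)
    return pi_hat, x_hat, M_prime


# ---------------------------------------------------------------------------
# per-pair statistics on a genome collection
# ---------------------------------------------------------------------------

@dataclass
class PairStatistic:
    cog_i: str
    cog_j: str
    x_hat: float
    pi_hat: float
    pi_i_given_j: float
    pi_j_given_i: float
    M_prime: float


class _CollectionIndex:
    """Per-genome COG positions flattened to arrays for fast pair loops."""

    def __init__(self, collection: GenomeCollection, weights: WeightVector):
        self.genome_ids = list(collection.genomes)
        self.weights = np.array([weights[g] for g in self.genome_ids])
        self.n_genomes = len(self.genome_ids)
        self.chrom_len: list[dict[str, int]] = []
        self.positions: list[dict[str, list[tuple[str, int]]]] = []
        for gid in self.genome_ids:
            genome = collection[gid]
            self.chrom_len.append({c.id: c.length for c in genome.chromosomes.values()})
            self.positions.append(
                {
                    cog: [(g.chromosome, g.midpoint) for g in genes]
                    for cog, genes in genome.cog_index.items()
                }
            )
        cogs: dict[str, int] = {}
        for pos in self.positions:
            for c in pos:
                cogs[c] = cogs.get(c, 0) + 1
        self.cogs = list(cogs)
        self.joint_universe = cogs  # cog -> number of genomes carrying it

    def x_min_and_counts(self, cog_i: str, cog_j: str):
        """Per genome: minimal normalized distance and both copy counts."""
        n = self.n_genomes
        x_min = np.ones(n)
        n_i = np.zeros(n, dtype=int)
        n_j = np.zeros(n, dtype=int)
        for k in range(n):
            pos = self.positions[k]
            pi_, pj_ = pos.get(cog_i), pos.get(cog_j)
            if pi_:
                n_i[k] = len(pi_)
            if pj_:
                n_j[k] = len(pj_)
            if not pi_ or not pj_:
                continue
            best = 1.0
            for (ca, ma) in pi_:
                for (cb, mb) in pj_:
                    if ca != cb:
                        continue
                    clen = self.chrom_len[k][ca]
                    d = abs(ma - mb)
                    d = min(d, clen - d)
                    x = min(1.0, 2.0 * d / L_DEFAULT)
                    if x < best:
                        best = x
            x_min[k] = best
        return x_min, n_i, n_j


def pair_significance(
    cog_i: str,
    cog_j: str,
    collection: GenomeCollection,
    weights: WeightVector,
    index: _CollectionIndex | None = None,
) -> PairStatistic:
    """Symmetrized conserved-proximity p-value for one COG pair."""
    if cog_i == cog_j:
        raise ValueError("self-synteny of a COG with itself is undefined")
    if index is None:
        index = _CollectionIndex(collection, weights)
    x_min, n_i, n_j = index.x_min_and_counts(cog_i, cog_j)
    both = (n_i > 0) & (n_j > 0)
    if not both.any():
        return PairStatistic(cog_i, cog_j, np.nan, 1.0, 1.0, 1.0, 0.0)
    # direction i|j: per genome containing i, nearest j-copy, n = copies of j
    p_ij = np.where(both, 1.0 - (1.0 - x_min) ** n_j, 1.0)
    p_ji = np.where(both, 1.0 - (1.0 - x_min) ** n_i, 1.0)
    pi_ij, x_ij, Mp = scan_min_pvalue(p_ij[None, :], index.weights, both[None, :])
    pi_ji, x_ji, _ = scan_min_pvalue(p_ji[None, :], index.weights, both[None, :])
    if pi_ij[0] >= pi_ji[0]:
        pi_hat, x_hat = pi_ij[0], x_ij[0]
    else:
        pi_hat, x_hat = pi_ji[0], x_ji[0]
    return PairStatistic(cog_i, cog_j, float(x_hat), float(pi_hat),
                         float(pi_ij[0]), float(pi_ji[0]), float(Mp[0]))


def directional_pair_pvalue(
    cog_i: str,
    cog_j: str,
    collection: GenomeCollection,
    weights: WeightVector,
) -> tuple[float, float]:
    """pi_hat_{i|j} and its argmin threshold (the i-conditional direction)."""
    index = _CollectionIndex(collection, weights)
    x_min, n_i, n_j = index.x_min_and_counts(cog_i, cog_j)
    both = (n_i > 0) & (n_j > 0)
    p_ij = np.where(both, 1.0 - (1.0 - x_min) ** n_j, 1.0)
    pi, x, _ = scan_min_pvalue(p_ij[None, :], index.weights, both[None, :])
    return float(pi[0]), float(x[0])


def pair_table(
    collection: GenomeCollection,
    weights: WeightVector,
    pairs=None,
    min_joint: int = 2,
    chunk: int = 4096,
) -> pd.DataFrame:
    """Conserved-proximity statistics for all unordered COG pairs.

    Pairs jointly present in fewer than ``min_joint`` genomes are assigned
    pi_hat = 1 without computation. COGs single-copy everywhere go through
    a vectorized path; pairs involving multi-copy COGs are computed one by
    one.
    """
    index = _CollectionIndex(collection, weights)
    cogs = index.cogs
    if pairs is None:
        pairs = list(itertools.combinations(cogs, 2))

    # classify cogs: "simple" = at most one copy in every genome, then
    # represent them as (chrom_code, midpoint) matrices
    simple = {}
    for c in cogs:
        copies = [len(index.positions[k].get(c, ())) for k in range(index.n_genomes)]
        if max(copies) <= 1:
            simple[c] = True
    chrom_codes: dict[tuple[int, str], int] = {}
    for k in range(index.n_genomes):
        for cid in index.chrom_len[k]:
            chrom_codes[(k, cid)] = len(chrom_codes)
    n_g = index.n_genomes
    sidx = {c: i for i, c in enumerate([c for c in cogs if c in simple])}
    pos = np.full((len(sidx), n_g), np.nan)
    chrm = np.full((len(sidx), n_g), -1, dtype=int)
    for c, i in sidx.items():
        for k in range(n_g):
            lst = index.positions[k].get(c)
            if lst:
                cid, mid = lst[0]
                pos[i, k] = mid
                chrm[i, k] = chrom_codes[(k, cid)]
    clen_of_code = np.zeros(len(chrom_codes))
    for (k, cid), code in chrom_codes.items():
        clen_of_code[code] = index.chrom_len[k][cid]

    joint = np.zeros(len(pairs), dtype=int)
    rows = []
    simple_pairs, slow_pairs = [], []
    for pi_, (a, b) in enumerate(pairs):
        if a in simple and b in simple:
            simple_pairs.append((pi_, a, b))
        else:
            slow_pairs.append((pi_, a, b))

    results: dict[int, PairStatistic] = {}
    for start in range(0, len(simple_pairs), chunk):
        block = simple_pairs[start: start + chunk]
        ia = np.array([sidx[a] for _, a, _ in block])
        ib = np.array([sidx[b] for _, _, b in block])
        pa, pb = pos[ia], pos[ib]
        ca, cb = chrm[ia], chrm[ib]
        present = ~np.isnan(pa) & ~np.isnan(pb)
        same_chrom = present & (ca == cb)
        d = np.abs(pa - pb)
        cl = clen_of_code[np.clip(ca, 0, None)]
        d = np.minimum(d, cl - d)
        x = np.where(same_chrom, np.minimum(1.0, 2.0 * d / L_DEFAULT), 1.0)
        x = np.where(present, x, 1.0)
        pih, xh, Mp = scan_min_pvalue(x, index.weights, present)
        nj = present.sum(axis=1)
        for r, (orig, a, b) in enumerate(block):
            joint[orig] = nj[r]
            if nj[r] < min_joint:
                results[orig] = PairStatistic(a, b, np.nan, 1.0, 1.0, 1.0, float(Mp[r]))
            else:
                # single-copy: both directions identical
                results[orig] = PairStatistic(a, b, float(xh[r]), float(pih[r]),
                                              float(pih[r]), float(pih[r]), float(Mp[r]))
    for orig, a, b in slow_pairs:
        x_min, n_i, n_j = index.x_min_and_counts(a, b)
        both = (n_i > 0) & (n_j > 0)
        joint[orig] = int(both.sum())
        if joint[orig] < min_joint:
            results[orig] = PairStatistic(a, b, np.nan, 1.0, 1.0, 1.0,
                                          float(index.weights[both].sum()))
            continue
        results[orig] = pair_significance(a, b, collection, weights, index=index)

    for i in range(len(pairs)):
        s = results[i]
        rows.append((s.cog_i, s.cog_j, s.x_hat, s.pi_hat,
                     s.pi_i_given_j, s.pi_j_given_i, s.M_prime, joint[i]))
    return pd.DataFrame(
        rows,
        columns=["cog_i", "cog_j", "x_hat", "pi_hat",
                 "pi_i_given_j", "pi_j_given_i", "M_prime", "n_joint"],
    )


# ---------------------------------------------------------------------------
# positional null and threshold calibration
# ---------------------------------------------------------------------------

def simulate_null(
    collection: GenomeCollection,
    weights: WeightVector,
    seed: int,
    n_pairs: int | None = None,
    min_joint: int = 2,
) -> np.ndarray:
    """Null pi_hat sample: gene positions redrawn uniformly per chromosome.

    Copy numbers, chromosome assignments and weights are preserved;
    conserved-proximity p-values are recomputed for ``n_pairs`` sampled COG
    pairs (all pairs of one randomization when None). When ``n_pairs``
    exceeds the number of available pairs, additional independent
    randomization replicates are drawn. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    collected = 0
    target = n_pairs
    while True:
        randomized = GenomeCollection()
        for genome in collection:
            genes = []
            for g in genome.genes:
                clen = genome.chromosomes[g.chromosome].length
                length = g.end - g.start
                start = int(rng.integers(0, clen))
                end = min(start + length, clen)  # truncated at origin; midpoint only matters
                genes.append(Gene(g.id, g.chromosome, start, max(end, start + 1), g.strand, g.cog))
            randomized.add(Genome(genome.id, list(genome.chromosomes.values()), genes))
        cogs = _CollectionIndex(randomized, weights).cogs
        all_pairs = list(itertools.combinations(cogs, 2))
        if target is not None and target - collected < len(all_pairs):
            idx = rng.choice(len(all_pairs), size=target - collected, replace=False)
            pairs = [all_pairs[i] for i in idx]
        else:
            pairs = all_pairs
        table = pair_table(randomized, weights, pairs=pairs, min_joint=min_joint)
        out.append(table.pi_hat.to_numpy())
        collected += len(pairs)
        if target is None or collected >= target:
            break
    return np.concatenate(out)


def null_pihat_sample(
    weights: np.ndarray,
    chromosome_lengths: np.ndarray,
    n_pairs: int,
    seed: int,
    L: int = L_DEFAULT,
    chunk: int = 2048,
) -> np.ndarray:
    """Fast positional null for single-copy COG pairs present everywhere.

    Each pair draws, in every genome, a uniform circular midpoint distance
    on that genome's chromosome; x = min(1, 2d/L). Used for large-scale
    tail studies where constructing explicit gene objects would be wasteful.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    scale = np.asarray(chromosome_lengths, dtype=float) / L  # x = U * len/L capped
    out = []
    for start in range(0, n_pairs, chunk):
        n = min(chunk, n_pairs - start)
        x = np.minimum(rng.random((n, weights.size)) * scale[None, :], 1.0)
        present = np.ones_like(x, dtype=bool)
        pih, _, _ = scan_min_pvalue(x, weights, present)
        out.append(pih)
    return np.concatenate(out)


@dataclass
class NullCalibration:
    """Exponential-tail fit of the null and the FDR-calibrated threshold.

    ``a`` is the decay exponent of the density of y = -ln(pi_hat) in
    natural-log units; ``a_per_decade = a * ln(10)`` is the same exponent
    per decade of pi_hat (the scale on which tail plots are usually drawn).
    """

    a: float
    a_per_decade: float
    pi_star: float
    fdr: float
    r_squared: float
    tail_window: tuple[float, float]
    n_null: int
    sigma_s: float  # empirical significant fraction at pi_star


def fit_tail_exponent(
    null_pihat: np.ndarray,
    tail_pct: tuple[float, float] = (75.0, 99.0),
    bin_width: float = 0.25,
) -> tuple[float, float, tuple[float, float]]:
    """Least-squares exponent of the exponential tail of y = -ln(pi_hat).

    The fit window spans the given percentiles of y (default 75th-99th,
    the early exponential region of the tail); the histogram uses fixed-width
    bins and empty bins are dropped.
    """
    y = -np.log(np.clip(np.asarray(null_pihat, dtype=float), 1e-300, 1.0))
    lo, hi = np.percentile(y, list(tail_pct))
    if hi - lo < 3 * bin_width:
        raise CalibrationError("null tail window too narrow to fit")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(y, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise CalibrationError("too few occupied bins in the null tail")
    slope, intercept = np.polyfit(centers[keep], np.log(counts[keep]), 1)
    resid = np.log(counts[keep]) - (slope * centers[keep] + intercept)
    ss_tot = np.var(np.log(counts[keep])) * keep.sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    a = -float(slope)
    if a <= 0:
        raise CalibrationError("null tail does not decay; calibration failure")
    return a, float(r2), (float(lo), float(hi))


def calibrate_threshold(
    empirical_pihat: np.ndarray,
    null_pihat: np.ndarray,
    fdr: float = FDR_DEFAULT,
    tail_pct: tuple[float, float] = (75.0, 99.0),
    bin_width: float = 0.25,
) -> NullCalibration:
    """FDR-calibrated significance threshold pi*.

    The false-positive fraction among pairs with pi_hat <= pi is estimated
    from the exponential null tail as sigma_fp(pi) = pi^a; the significant
    fraction sigma_s(pi) is the empirical fraction of pairs at or below pi.
    pi* is the largest observed value satisfying sigma_fp/sigma_s <= FDR.
    """
    null_pihat = np.asarray(null_pihat, dtype=float)
    if null_pihat.size < 10_000:
        raise ValueError("need >= 1e4 null values to calibrate the tail")
    a, r2, window = fit_tail_exponent(null_pihat, tail_pct, bin_width)
    emp = np.sort(np.asarray(empirical_pihat, dtype=float))
    n = emp.size
    sigma_s = np.arange(1, n + 1) / n
    ok = emp ** a <= fdr * sigma_s
    if not ok.any():
        pi_star, sig = 0.0, 0.0
    else:
        k = np.nonzero(ok)[0].max()
        pi_star, sig = float(emp[k]), float(sigma_s[k])
    return NullCalibration(
        a=a,
        a_per_decade=a * float(np.log(10.0)),
        pi_star=pi_star,
        fdr=fdr,
        r_squared=r2,
        tail_window=window,
        n_null=int(null_pihat.size),
        sigma_s=sig,
    )
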