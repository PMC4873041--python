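"""Co-expression analyses: normalization, correlation matrices and the
distance-resolved mean co-expression Gamma(d).

Activities are quantile-normalized across conditions; co-expression of two
genes is the Pearson correlation of their activities over conditions.
Gamma(d) averages C_ij over gene pairs at genomic (circular midpoint)
distance d within half-width bins, under composable pair filters
(different-operon, segment co-membership, orientation class, regulation
status). Further analyses relate co-expression to shared regulators
("seg-regulation": factors regulating at least one operon of a segment) and
to the conservation of proximity across genomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .formats import Genome, GenomeCollection, OperonMap, RegulonTable
from .segments import SegmentSet


# ---------------------------------------------------------------------------
# normalization and correlation
# ---------------------------------------------------------------------------

def quantile_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization of a genes x conditions matrix.

    Every condition column receives the across-column mean of sorted values
    at its ranks; ties get the mean of the target values over their rank
    span, so the procedure is deterministic and idempotent.
    """
    A = raw.to_numpy(float)
    if np.isnan(A).any():
        raise ValueError("missing values: impute or drop genes before normalizing")
    order = np.argsort(A, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(A, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(A)
    n = A.shape[0]
    for j in range(A.shape[1]):
        col = A[:, j]
        ranks = np.empty(n, dtype=int)
        ranks[order[:, j]] = np.arange(n)
        vals = target[ranks]
        # average target values over tied spans
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=vals)
            vals = (sums / counts)[inv]
        out[:, j] = vals
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def gene_activity(probe_values: pd.DataFrame, probe_gene_overlaps: dict[str, list[str]]) -> pd.DataFrame:
    """Per-gene activity = mean over the probes overlapping the gene.

    ``probe_gene_overlaps`` maps gene id -> overlapping probe ids (a probe
    overlapping two genes contributes to both). Genes with no probes are
    dropped.
    """
    rows, index = [], []
    for gene, probes in probe_gene_overlaps.items():
        probes = [p for p in probes if p in probe_values.index]
        if not probes:
            continue
        rows.append(probe_values.loc[probes].mean(axis=0))
        index.append(gene)
    return pd.DataFrame(rows, index=index)


def coexpression_matrix(activity: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of centered activity profiles across conditions."""
    if activity.shape[1] < 3:
        raise ValueError("need at least 3 conditions")
    A = activity.to_numpy(float)
    A = A - A.mean(axis=1, keepdims=True)
    norms = np.sqrt((A * A).sum(axis=1))
    zero = norms == 0
    norms[zero] = 1.0
    C = (A @ A.T) / np.outer(norms, norms)
    np.fill_diagonal(C, 1.0)
    C[zero, :] = np.nan
    C[:, zero] = np.nan
    return pd.DataFrame(C, index=activity.index, columns=activity.index)


def smooth_matrix(C: pd.DataFrame, sigma: float = 10.0) -> pd.DataFrame:
    """2-D Gaussian filtering in gene-index space with circular wrap."""
    M = C.to_numpy(float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    return pd.DataFrame(ndimage.gaussian_filter(M, sigma=sigma, mode="wrap"),
                        index=C.index, columns=C.columns)


# ---------------------------------------------------------------------------
# pair predicates (composable boolean n x n masks)
# ---------------------------------------------------------------------------

def circular_pair_distances(positions: np.ndarray, chromosome_length: int) -> np.ndarray:
    d = np.abs(positions[:, None] - positions[None, :])
    return np.minimum(d, chromosome_length - d)


def different_operon_mask(gene_ids, operons: OperonMap) -> np.ndarray:
    ops = np.array([operons.operon_of(g) or f"_none_{g}" for g in gene_ids], dtype=object)
    return ops[:, None] != ops[None, :]


def segment_comembership_mask(gene_ids, segments: SegmentSet) -> np.ndarray:
    member = segments.membership()
    sets = [member.get(g, set()) for g in gene_ids]
    n = len(sets)
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if not sets[i]:
            continue
        for j in range(i + 1, n):
            if sets[i] & sets[j]:
                out[i, j] = out[j, i] = True
    return out


def regulated_mask(gene_ids, operons: OperonMap, regulons: RegulonTable, kind: str) -> np.ndarray:
    """Per-gene flag: the gene's operon is regulated by >= 1 factor of ``kind``."""
    flags = []
    for g in gene_ids:
        op = operons.operon_of(g)
        flags.append(bool(op and regulons.factors_of_operon(op, kind)))
    return np.array(flags, dtype=bool)


def shared_factor_mask(gene_ids, operons: OperonMap, regulons: RegulonTable, kind: str) -> np.ndarray:
    """Pairs whose operons share at least one factor of ``kind``."""
    sets = []
    for g in gene_ids:
        op = operons.operon_of(g)
        sets.append(regulons.factors_of_operon(op, kind) if op else frozenset())
    n = len(sets)
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if not sets[i]:
            continue
        for j in range(i + 1, n):
            if sets[i] & sets[j]:
                out[i, j] = out[j, i] = True
    return out


def unregulated_pair_mask(gene_ids, operons: OperonMap, regulons: RegulonTable) -> np.ndarray:
    """Both genes not TF-regulated and not sharing a common SF."""
    tf = regulated_mask(gene_ids, operons, regulons, "TF")
    no_tf = ~tf[:, None] & ~tf[None, :]
    return no_tf & ~shared_factor_mask(gene_ids, operons, regulons, "SF")


# ---------------------------------------------------------------------------
# Gamma(d) profiles
# ---------------------------------------------------------------------------

def gamma_profile(
    C: pd.DataFrame,
    positions: pd.Series,
    chromosome_length: int,
    pair_mask: np.ndarray | None = None,
    half_width: float = 500.0,
    max_distance: float | None = None,
) -> pd.DataFrame:
    """Mean co-expression Gamma(d) over pairs at distance d +/- half_width.

    Distances are circular midpoint distances; bins are centered on
    multiples of 2*half_width. Empty bins are absent from the output.
    """
    genes = [g for g in C.index if g in positions.index]
    Cm = C.loc[genes, genes].to_numpy(float)
    pos = positions.loc[genes].to_numpy(float)
    D = circular_pair_distances(pos, chromosome_length)
    iu = np.triu_indices(len(genes), k=1)
    d, c = D[iu], Cm[iu]
    if pair_mask is not None:
        mask = pd.DataFrame(pair_mask, index=C.index, columns=C.index) \
            .loc[genes, genes].to_numpy(bool)[iu]
        d, c = d[mask], c[mask]
    keep = ~np.isnan(c)
    d, c = d[keep], c[keep]
    if max_distance is not None:
        keep = d <= max_distance
        d, c = d[keep], c[keep]
    if d.size == 0:
        return pd.DataFrame(columns=["distance", "gamma", "n_pairs"])
    width = 2.0 * half_width
    bin_idx = np.floor(d / width).astype(int)
    df = pd.DataFrame({"bin": bin_idx, "c": c})
    agg = df.groupby("bin")["c"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "distance": agg["bin"] * width + half_width,
        "gamma": agg["mean"],
        "n_pairs": agg["size"].astype(int),
    })


# ---------------------------------------------------------------------------
# regulon-aware analyses
# ---------------------------------------------------------------------------

def factor_sharing_fraction(
    C: pd.DataFrame,
    gene_ids,
    operons: OperonMap,
    regulons: RegulonTable,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of different-operon pairs sharing a TF, an SF, or either,
    per co-expression bin."""
    if bins is None:
        bins = np.linspace(-1.0, 1.0, 21)
    genes = list(gene_ids)
    Cm = C.loc[genes, genes].to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    diff_op = different_operon_mask(genes, operons)[iu]
    tf = shared_factor_mask(genes, operons, regulons, "TF")[iu]
    sf = shared_factor_mask(genes, operons, regulons, "SF")[iu]
    c = Cm[iu]
    keep = diff_op & ~np.isnan(c)
    c, tf, sf = c[keep], tf[keep], sf[keep]
    idx = np.digitize(c, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append({
            "c_low": bins[b], "c_high": bins[b + 1], "n_pairs": n,
            "share_tf": tf[sel].mean(),
            "share_sf": sf[sel].mean(),
            "share_either": (tf[sel] | sf[sel]).mean(),
        })
    return pd.DataFrame(rows)


def seg_factor_sets(
    segments: SegmentSet,
    operons: OperonMap,
    regulons: RegulonTable,
    kind: str,
) -> list[frozenset]:
    """Per segment, the factors of ``kind`` regulating >= 1 member operon."""
    out = []
    for seg in segments:
        ops = {operons.operon_of(g) for g in seg.genes}
        fs = frozenset().union(*(regulons.factors_of_operon(o, kind)
                                 for o in ops if o)) if ops else frozenset()
        out.append(fs)
    return out


def seg_regulation_distributions(
    C: pd.DataFrame,
    segments: SegmentSet,
    operons: OperonMap,
    regulons: RegulonTable,
    kind: str = "TF",
    gene_filter=None,
    exclude_factors: frozenset = frozenset(),
) -> dict[str, np.ndarray]:
    """C_ij distributions for cross-segment pairs grouped by seg-factor sets.

    Classes: "same" (identical non-empty factor sets), "different"
    (non-equal sets), "none" (both segments without factors of this kind).
    Pairs within a common segment are excluded. ``gene_filter`` optionally
    restricts the genes considered (e.g. to housekeeping-SF-only genes).
    """
    fsets = [fs - exclude_factors for fs in seg_factor_sets(segments, operons, regulons, kind)]
    member = segments.membership()
    genes = [g for g in C.index if member.get(g)]
    if gene_filter is not None:
        genes = [g for g in genes if gene_filter(g)]
    out = {"same": [], "different": [], "none": []}
    for i in range(len(genes)):
        segs_i = member[genes[i]]
        for j in range(i + 1, len(genes)):
            segs_j = member[genes[j]]
            if segs_i & segs_j:
                continue
            c = C.loc[genes[i], genes[j]]
            if np.isnan(c):
                continue
            # compare the union of seg-factor sets over each gene's segments
            fi = frozenset().union(*(fsets[s] for s in segs_i))
            fj = frozenset().union(*(fsets[s] for s in segs_j))
            if not fi and not fj:
                out["none"].append(c)
            elif fi == fj:
                out["same"].append(c)
            else:
                out["different"].append(c)
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def regulated_operons_per_segment(
    segments: SegmentSet,
    operons: OperonMap,
    regulons: RegulonTable,
    kind: str = "TF",
) -> pd.DataFrame:
    """Mean count of ``kind``-regulated operons per segment-size class."""
    rows = []
    for seg in segments:
        ops = sorted({o for g in seg.genes if (o := operons.operon_of(g))})
        n_reg = sum(1 for o in ops if regulons.factors_of_operon(o, kind))
        rows.append((len(ops), n_reg))
    if not rows:
        return pd.DataFrame(columns=["n_operons", "mean_regulated", "n_segments"])
    df = pd.DataFrame(rows, columns=["n_operons", "n_regulated"])
    agg = df.groupby("n_operons")["n_regulated"].agg(["mean", "size"]).reset_index()
    return agg.rename(columns={"mean": "mean_regulated", "size": "n_segments"})


# ---------------------------------------------------------------------------
# cross-genome conservation analyses
# ---------------------------------------------------------------------------

def proximity_conservation_curve(
    reference_id: str,
    collection: GenomeCollection,
    distances: pd.DataFrame,
    C: pd.DataFrame,
    d0: float = 10_000.0,
    c_bins: np.ndarray | None = None,
    divergence_bins: np.ndarray | None = None,
    operons: OperonMap | None = None,
) -> pd.DataFrame:
    """Fraction of reference pairs within d0 that stay within d0 elsewhere.

    Pairs are stratified by co-expression level in the reference (and by
    operon co-membership when an operon map is given); query genomes are
    binned by evolutionary divergence. Orthology is by COG label, restricted
    to single-copy COGs in both genomes; pairs with either ortholog missing
    count as not conserved.
    """
    if c_bins is None:
        c_bins = np.array([-1.0, 0.25, 0.5, 0.75, 1.01])
    if divergence_bins is None:
        divergence_bins = np.linspace(0.0, 1.0, 11)
    ref = collection[reference_id]
    chrom = next(iter(ref.chromosomes.values()))
    genes = [g for g in ref.genes if g.cog is not None and g.id in C.index
             and len(ref.cog_index[g.cog]) == 1]
    pos = np.array([g.midpoint for g in genes], dtype=float)
    D = circular_pair_distances(pos, chrom.length)
    iu = np.triu_indices(len(genes), k=1)
    close = D[iu] <= d0
    ii, jj = iu[0][close], iu[1][close]
    cvals = C.loc[[g.id for g in genes], [g.id for g in genes]].to_numpy(float)[
        (iu[0][close], iu[1][close])]
    same_op = None
    if operons is not None:
        ops = np.array([operons.operon_of(g.id) or f"_n{g.id}" for g in genes], dtype=object)
        same_op = ops[ii] == ops[jj]

    rows = []
    for qid in collection.genomes:
        query = collection[qid]
        div = float(distances.loc[reference_id, qid])
        qchrom = next(iter(query.chromosomes.values()))
        qpos = {}
        for cog, gl in query.cog_index.items():
            if len(gl) == 1:
                qpos[cog] = gl[0].midpoint
        for k in range(len(ii)):
            a, b = genes[ii[k]], genes[jj[k]]
            pa, pb = qpos.get(a.cog), qpos.get(b.cog)
            if pa is None or pb is None:
                conserved = False
            else:
                dq = abs(pa - pb)
                dq = min(dq, qchrom.length - dq)
                conserved = dq <= d0
            rows.append((div, cvals[k], bool(same_op[k]) if same_op is not None else False,
                         conserved))
    df = pd.DataFrame(rows, columns=["divergence", "c", "same_operon", "conserved"])
    df["div_bin"] = np.digitize(df.divergence, divergence_bins) - 1
    df["c_bin"] = np.digitize(df.c, c_bins) - 1
    agg = df.groupby(["div_bin", "c_bin", "same_operon"]).agg(
        fraction=("conserved", "mean"), n_pairs=("conserved", "size")).reset_index()
    agg["divergence"] = divergence_bins[agg.div_bin.clip(0, len(divergence_bins) - 2)]
    agg["c_low"] = c_bins[agg.c_bin.clip(0, len(c_bins) - 2)]
    return agg


def distant_synteny_coexpression(
    C: pd.DataFrame,
    synteny_pairs: set[frozenset],
    genome: Genome,
    operons: OperonMap | None = None,
    half_width: float = 5_000.0,
    min_distance: float = 0.0,
    pair_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean C vs distance for pairs in synteny, not in synteny, and the
    nearest-neighbor control of the in-synteny pairs.

    The control replaces the first gene of each in-synteny pair by its
    nearest chromosomal neighbor not in synteny with the second gene.
    """
    chrom = next(iter(genome.chromosomes.values()))
    genes = [g for g in genome.genes if g.cog is not None and g.id in C.index]
    ids = [g.id for g in genes]
    pos = np.array([g.midpoint for g in genes], dtype=float)
    Cm = C.loc[ids, ids].to_numpy(float)
    D = circular_pair_distances(pos, chrom.length)
    n = len(genes)
    mask_extra = None
    if pair_mask is not None:
        mask_extra = pd.DataFrame(pair_mask, index=C.index, columns=C.index) \
            .loc[ids, ids].to_numpy(bool)
    if operons is not None:
        diff_op = different_operon_mask(ids, operons)
        mask_extra = diff_op if mask_extra is None else (mask_extra & diff_op)

    order = np.argsort(pos)  # chromosomal order for neighbor search
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    def in_synteny(i, j):
        return frozenset((genes[i].cog, genes[j].cog)) in synteny_pairs

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] < min_distance:
                continue
            if mask_extra is not None and not mask_extra[i, j]:
                continue
            c = Cm[i, j]
            if np.isnan(c):
                continue
            if in_synteny(i, j):
                rows.append((D[i, j], c, "synteny"))
                # nearest neighbor of i (in chromosomal order) not in synteny with j
                for off in range(1, n):
                    for cand_rank in ((rank[i] + off) % n, (rank[i] - off) % n):
                        k = order[cand_rank]
                        if k in (i, j) or in_synteny(k, j):
                            continue
                        ck = Cm[k, j]
                        if not np.isnan(ck):
                            rows.append((D[k, j], ck, "neighbor_control"))
                        break
                    else:
                        continue
                    break
            else:
                rows.append((D[i, j], c, "no_synteny"))
    df = pd.DataFrame(rows, columns=["distance", "c", "curve"])
    if df.empty:
        return pd.DataFrame(columns=["curve", "distance", "mean_c", "n_pairs"])
    width = 2.0 * half_width
    df["bin"] = np.floor(df.distance / width).astype(int)
    agg = df.groupby(["curve", "bin"]).agg(
        mean_c=("c", "mean"), n_pairs=("c", "size")).reset_index()
    agg["distance"] = agg["bin"] * width + half_width
    return agg[["curve", "distance", "mean_c", "n_pairs"]]


def conserved_coexpression_decomposition(
    C_a: pd.DataFrame,
    C_b: pd.DataFrame,
    orthologs: dict[str, tuple[str, str]],
    genome_a: Genome,
    genome_b: Genome,
    segments_a: SegmentSet,
    segments_b: SegmentSet,
    operons_a: OperonMap,
    operons_b: OperonMap,
    regulons_a: RegulonTable,
    regulons_b: RegulonTable,
    housekeeping_sf: tuple[str, str] | None = None,
    proximity_threshold: float = 20_000.0,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fractions of ortholog pairs explained by proximity, shared direct
    factors or shared seg-factors, vs min(C_a, C_b).

    ``orthologs`` maps a COG to its unique (gene in A, gene in B); COGs
    multi-copy in either species must already be dropped.
    """
    if not orthologs:
        raise ValueError("empty orthologous pair set")
    if bins is None:
        bins = np.linspace(-0.2, 1.0, 13)
    cogs = sorted(orthologs)
    ga = [orthologs[c][0] for c in cogs]
    gb = [orthologs[c][1] for c in cogs]
    pos_a = {g.id: g.midpoint for g in genome_a.genes}
    pos_b = {g.id: g.midpoint for g in genome_b.genes}
    len_a = next(iter(genome_a.chromosomes.values())).length
    len_b = next(iter(genome_b.chromosomes.values())).length
    mem_a, mem_b = segments_a.membership(), segments_b.membership()
    sf_sets_a = seg_factor_sets(segments_a, operons_a, regulons_a, "SF")
    sf_sets_b = seg_factor_sets(segments_b, operons_b, regulons_b, "SF")

    def seg_sf(gene, mem, sets):
        segs = mem.get(gene, set())
        return frozenset().union(*(sets[s] for s in segs)) if segs else frozenset()

    rows = []
    n = len(cogs)
    Ca = C_a.loc[ga, ga].to_numpy(float)
    Cb = C_b.loc[gb, gb].to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            cmin = min(Ca[i, j], Cb[i, j])
            if np.isnan(cmin):
                continue
            da = abs(pos_a[ga[i]] - pos_a[ga[j]]); da = min(da, len_a - da)
            db = abs(pos_b[gb[i]] - pos_b[gb[j]]); db = min(db, len_b - db)
            prox = da <= proximity_threshold and db <= proximity_threshold
            shared_tf = bool(
                _direct(ga[i], operons_a, regulons_a, "TF") & _direct(ga[j], operons_a, regulons_a, "TF")) and bool(
                _direct(gb[i], operons_b, regulons_b, "TF") & _direct(gb[j], operons_b, regulons_b, "TF"))
            shared_sf = bool(
                _direct(ga[i], operons_a, regulons_a, "SF") & _direct(ga[j], operons_a, regulons_a, "SF")) and bool(
                _direct(gb[i], operons_b, regulons_b, "SF") & _direct(gb[j], operons_b, regulons_b, "SF"))
            sseg_a = seg_sf(ga[i], mem_a, sf_sets_a) & seg_sf(ga[j], mem_a, sf_sets_a)
            sseg_b = seg_sf(gb[i], mem_b, sf_sets_b) & seg_sf(gb[j], mem_b, sf_sets_b)
            shared_seg_factor = bool(sseg_a) and bool(sseg_b)
            hk = False
            if housekeeping_sf is not None:
                hk = housekeeping_sf[0] in sseg_a and housekeeping_sf[1] in sseg_b
            rows.append((cmin, prox, shared_tf, shared_sf, shared_seg_factor,
                         prox or hk))
    df = pd.DataFrame(rows, columns=[
        "c_min", "proximity", "shared_tf", "shared_sf", "shared_seg_factor",
        "proximity_or_hk_segregulation"])
    df["bin"] = np.digitize(df.c_min, bins) - 1
    agg = df.groupby("bin").agg(
        n_pairs=("c_min", "size"),
        proximity=("proximity", "mean"),
        shared_tf=("shared_tf", "mean"),
        shared_sf=("shared_sf", "mean"),
        shared_seg_factor=("shared_seg_factor", "mean"),
        proximity_or_hk=("proximity_or_hk_segregulation", "mean"),
    ).reset_index()
    agg["c_min_low"] = bins[agg.bin.clip(0, len(bins) - 2)]
    return agg


def _direct(gene: str, operons: OperonMap, regulons: RegulonTable, kind: str) -> frozenset:
    op = operons.operon_of(gene)
    return regulons.factors_of_operon(op, kind) if op else frozenset()
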