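"""Binding profiles at segment borders and enrichment/overlap tests.

For each segment k with borders x1(k) < x2(k), the per-segment profile
rho_k(x) averages the binding indicator at x1+x and (mirrored) at x2-x and
is normalized to sum to 1 over the window; the segment-average profile is
rho_seg(x) = sum_k rho_k(x) / N_seg. Positive offsets point into the
segment. Enrichment of regions near borders and overlap of domains with
segments are tested against a rotation null (the region set is rotated by a
uniform circular offset); the inclusion of whole operons in segments is
tested against a gene-translation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import Genome, IntervalTrack, OperonMap, TSSList
from .segments import SegmentSet


def occupancy_array(track: IntervalTrack, chromosome: str, length: int) -> np.ndarray:
    """Boolean per-base occupancy of a chromosome by track intervals."""
    occ = np.zeros(length, dtype=bool)
    for row in track.on(chromosome).itertuples(index=False):
        s, e = int(row.start), int(row.end)
        if s < 0 or e > length:
            raise ValueError(f"interval [{s},{e}) outside chromosome of length {length}")
        occ[s:e] = True
    return occ


def segment_borders(
    seg,
    genome: Genome,
    tss: TSSList | None = None,
    operons: OperonMap | None = None,
) -> tuple[int, int]:
    """Border positions x1 < x2 of a segment.

    Prefers the TSS upstream of the first member (promoter side) and the
    stop-codon end of the last member when annotation is available; falls
    back to the genomic span ends.
    """
    by_id = {g.id: g for g in genome.genes}
    first, last = by_id[seg.genes[0]], by_id[seg.genes[-1]]
    clen = genome.chromosomes[seg.chromosome].length
    x1 = first.start
    x2 = last.end
    if tss is not None:
        # nearest TSS upstream of the left border on either strand, within 500 bp
        cands = [t.position for t in tss
                 if t.chromosome == seg.chromosome
                 and 0 < (x1 - t.position) % clen <= 500]
        if cands:
            x1 = max(cands, key=lambda p: -((x1 - p) % clen))
        cands2 = [t.position for t in tss
                  if t.chromosome == seg.chromosome
                  and 0 < (t.position - x2) % clen <= 500]
        if cands2:
            x2 = min(cands2, key=lambda p: (p - x2) % clen)
    return x1, x2


@dataclass
class BorderProfile:
    offsets: np.ndarray       # bin centers; positive = into the segment
    rho: np.ndarray           # averaged normalized profile
    n_segments: int           # number of averaged units
    n_contributing: int       # units with nonzero occupancy in the window


def border_profile(
    track: IntervalTrack,
    segments: SegmentSet,
    genome: Genome,
    window: int = 5_000,
    bin_width: int = 50,
    tss: TSSList | None = None,
) -> BorderProfile:
    """Average binding profile around segment borders.

    rho_k(x) = (delta(x1(k)+x) + delta(x2(k)-x)) / (2 N) with N normalizing
    sum_x rho_k = 1; segments shorter than two bins are skipped with a
    warning entry in the profile count.
    """
    n_bins = 2 * window // bin_width
    offsets = (np.arange(n_bins) - n_bins // 2) * bin_width + bin_width / 2
    acc = np.zeros(n_bins)
    n_contrib = 0
    n_used = 0
    occ_cache: dict[str, np.ndarray] = {}
    for seg in segments:
        clen = genome.chromosomes[seg.chromosome].length
        if seg.extent < 2 * bin_width:
            continue
        if seg.chromosome not in occ_cache:
            occ_cache[seg.chromosome] = occupancy_array(track, seg.chromosome, clen)
        occ = occ_cache[seg.chromosome]
        x1, x2 = segment_borders(seg, genome, tss=tss)
        n_used += 1
        prof = np.zeros(n_bins)
        for b in range(n_bins):
            lo = (b - n_bins // 2) * bin_width
            # mean occupancy over the bin at x1+offset (into the segment for
            # positive offsets) and mirrored at x2-offset
            idx1 = (np.arange(x1 + lo, x1 + lo + bin_width)) % clen
            idx2 = (np.arange(x2 - lo - bin_width, x2 - lo)) % clen
            prof[b] = 0.5 * (occ[idx1].mean() + occ[idx2].mean())
        total = prof.sum()
        if total > 0:
            acc += prof / total
            n_contrib += 1
    n_seg = max(n_used, 1)
    return BorderProfile(offsets=offsets, rho=acc / n_seg,
                         n_segments=n_used, n_contributing=n_contrib)


def operon_border_profile(
    track: IntervalTrack,
    operons: OperonMap,
    genome: Genome,
    segments: SegmentSet | None = None,
    window: int = 5_000,
    bin_width: int = 50,
) -> BorderProfile:
    """Binding profile with respect to operons, oriented so transcription
    points inward; restricted to operons not at a segment border."""
    by_id = {g.id: g for g in genome.genes}
    border_genes: set[str] = set()
    if segments is not None:
        for seg in segments:
            border_genes.add(seg.genes[0])
            border_genes.add(seg.genes[-1])
    pseudo = SegmentSet()
    from .segments import SyntenySegment

    for op in operons:
        if set(op.genes) & border_genes:
            continue
        genes = [by_id[g] for g in op.genes]
        start = min(g.start for g in genes)
        end = max(g.end for g in genes)
        # the two-border averaged profile is symmetric under reversal, so the
        # inward orientation is automatic; members stay in positional order
        members = tuple(sorted(op.genes, key=lambda g: by_id[g].start))
        pseudo.append(SyntenySegment(genome.id, genes[0].chromosome, members, (start, end)))
    return border_profile(track, pseudo, genome, window=window, bin_width=bin_width)


# ---------------------------------------------------------------------------
# rotation-null tests
# ---------------------------------------------------------------------------

def _border_positions(segments: SegmentSet, genome: Genome) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for seg in segments:
        x1, x2 = segment_borders(seg, genome)
        out.setdefault(seg.chromosome, []).extend(
            (x1, x2 if not seg.wraps else (seg.span[0] + seg.extent) %
             genome.chromosomes[seg.chromosome].length))
    return {c: np.array(sorted(v)) for c, v in out.items()}


def _near_border_count(mids: np.ndarray, borders: np.ndarray, clen: int, margin: int) -> int:
    if borders.size == 0 or mids.size == 0:
        return 0
    d = np.abs(mids[:, None] - borders[None, :])
    d = np.minimum(d, clen - d)
    return int((d.min(axis=1) <= margin).sum())


def border_enrichment_test(
    regions: IntervalTrack,
    segments: SegmentSet,
    genome: Genome,
    margin: int = 3_000,
    n_null: int = 1_000,
    seed: int = 0,
) -> tuple[int, float]:
    """Count regions with midpoint within ``margin`` of a segment border,
    with a rotation-null p-value p = (1 + #{null >= obs}) / (1 + n_null)."""
    if not segments:
        raise ValueError("no segments to test against")
    rng = np.random.default_rng(seed)
    borders = _border_positions(segments, genome)
    obs = 0
    per_chrom = []
    for chrom in genome.chromosomes.values():
        mids = regions.midpoints(chrom.id)
        b = borders.get(chrom.id, np.array([]))
        obs += _near_border_count(mids, b, chrom.length, margin)
        per_chrom.append((mids, b, chrom.length))
    null_ge = 0
    for _ in range(n_null):
        tot = 0
        for mids, b, clen in per_chrom:
            shift = rng.integers(0, clen)
            tot += _near_border_count((mids + shift) % clen, b, clen, margin)
        if tot >= obs:
            null_ge += 1
    p = (1 + null_ge) / (1 + n_null)
    return obs, float(p)


def _segment_base_mask(segments: SegmentSet, genome: Genome) -> dict[str, np.ndarray]:
    masks = {c.id: np.zeros(c.length, dtype=bool) for c in genome.chromosomes.values()}
    for seg in segments:
        clen = genome.chromosomes[seg.chromosome].length
        m = masks[seg.chromosome]
        if seg.wraps:
            s = seg.span[0]
            e = (s + seg.extent) % clen
            m[s:] = True
            m[:e] = True
        else:
            m[seg.span[0]:seg.span[1]] = True
    return masks


def overlap_test(
    domains: IntervalTrack,
    segments: SegmentSet,
    genome: Genome,
    n_null: int = 1_000,
    seed: int = 0,
) -> tuple[int, float]:
    """Count domains sharing >= 1 base with a segment; rotation-null p-value."""
    if not segments:
        raise ValueError("no segments to test against")
    rng = np.random.default_rng(seed)
    masks = _segment_base_mask(segments, genome)

    def count(shifts: dict[str, int]) -> int:
        tot = 0
        for chrom in genome.chromosomes.values():
            mask = masks[chrom.id]
            sub = domains.on(chrom.id)
            shift = shifts.get(chrom.id, 0)
            for row in sub.itertuples(index=False):
                idx = (np.arange(int(row.start), int(row.end)) + shift) % chrom.length
                if mask[idx].any():
                    tot += 1
        return tot

    obs = count({})
    null_ge = 0
    for _ in range(n_null):
        shifts = {c.id: int(rng.integers(0, c.length)) for c in genome.chromosomes.values()}
        if count(shifts) >= obs:
            null_ge += 1
    return obs, float((1 + null_ge) / (1 + n_null))


# ---------------------------------------------------------------------------
# operon inclusion under the gene-translation null
# ---------------------------------------------------------------------------

def _partial_count(op_gene_sets: list[set[int]], seg_gene_sets: list[set[int]]) -> int:
    """Operons with >= 1 gene inside and >= 1 outside some segment."""
    count = 0
    for ops in op_gene_sets:
        for segs in seg_gene_sets:
            inter = len(ops & segs)
            if 0 < inter < len(ops):
                count += 1
                break
    return count


def operon_inclusion_test(
    segments: SegmentSet,
    operons: OperonMap,
    genome: Genome,
    n_translations: int | None = None,
    seed: int = 0,
) -> tuple[int, np.ndarray, float]:
    """Count operons partially overlapping a segment, against a null in
    which the segment map is translated by whole gene offsets.

    Returns (observed count, null histogram over translations, p-value for
    observing as few or fewer partial overlaps). The p-value uses the
    mid-rank of the observed count in the translation distribution: counts
    are heavily tied across translations, and the plain permutation form
    would be systematically conservative.
    """
    genes = genome.genes
    gene_idx = {g.id: i for i, g in enumerate(genes)}
    n = len(genes)
    op_sets = [set(gene_idx[g] for g in op.genes if g in gene_idx) for op in operons]
    op_sets = [s for s in op_sets if s]
    seg_sets = [set(gene_idx[g] for g in seg.genes if g in gene_idx) for seg in segments]
    seg_sets = [s for s in seg_sets if s]
    obs = _partial_count(op_sets, seg_sets)

    if n_translations is None or n_translations >= n:
        shifts = range(n)
    else:
        rng = np.random.default_rng(seed)
        shifts = rng.integers(0, n, size=n_translations)
    null = []
    for t in shifts:
        shifted = [set((i + t) % n for i in s) for s in seg_sets]
        null.append(_partial_count(op_sets, shifted))
    null = np.array(null)
    p = float(((null < obs).sum() + 0.5 * (null == obs).sum()) / null.size)
    return obs, null, p
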