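"""Synteny segments: maximal runs of consecutive genes pairwise in synteny.

A segment is a maximal set of consecutive genes in one genome such that
every pair of COG-annotated member genes is significantly conserved in
proximity (pi_hat < pi*). Genes without a COG label are skipped by the
pairwise condition (they stay inside the genomic span but are not members);
pairs of genes carrying the same COG are likewise skipped, since
self-synteny is undefined. Maximality means neither flanking COG-annotated
gene can extend the run, which allows overlapping segments, and a gene may
belong to zero, one or several segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import Gene, Genome


@dataclass(frozen=True)
class SyntenySegment:
    genome: str
    chromosome: str
    genes: tuple[str, ...]  # COG-annotated members, in chromosomal order
    span: tuple[int, int]   # genomic extent, first member start to last member end
    wraps: bool = False     # span crosses the origin of a circular chromosome

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def extent(self) -> int:
        return self.span[1] - self.span[0] if not self.wraps else self.span[1]

    def midpoint(self, chromosome_length: int) -> int:
        if not self.wraps:
            return (self.span[0] + self.span[1]) // 2
        # span = (start, total_extent) with wrap: midpoint modulo length
        return (self.span[0] + self.extent // 2) % chromosome_length


class SegmentSet(list):
    """Segments of one or several genomes; plain list plus helpers."""

    def for_genome(self, genome_id: str) -> "SegmentSet":
        return SegmentSet(s for s in self if s.genome == genome_id)

    def membership(self) -> dict[str, set[int]]:
        """gene id -> indices of segments it belongs to."""
        out: dict[str, set[int]] = {}
        for i, s in enumerate(self):
            for g in s.genes:
                out.setdefault(g, set()).add(i)
        return out

    def common_segment(self, gene_a: str, gene_b: str, _cache={}) -> bool:
        member = self.membership() if not hasattr(self, "_member") else self._member
        self._member = member
        return bool(member.get(gene_a, set()) & member.get(gene_b, set()))


def _compatible(gene_a: Gene, gene_b: Gene, significant: set[frozenset]) -> bool:
    if gene_a.cog == gene_b.cog:
        return True  # paralogous pair: skipped by the clique condition
    return frozenset((gene_a.cog, gene_b.cog)) in significant


def significant_pairs(table: pd.DataFrame, pi_star: float) -> set[frozenset]:
    """The set of COG pairs significant at the threshold (pi_hat <= pi*).

    The threshold itself is included: the FDR calibration defines the
    significant fraction with pi_hat <= pi*, and on gridded synthetic data
    exact ties at pi* are common.
    """
    if pi_star is None:
        raise ValueError("pi* is required to build segments")
    sub = table[table.pi_hat <= pi_star]
    return {frozenset((a, b)) for a, b in zip(sub.cog_i, sub.cog_j)}


def build_segments(
    genome: Genome,
    significant: set[frozenset] | pd.DataFrame,
    pi_star: float | None = None,
) -> SegmentSet:
    """All maximal pairwise-in-synteny runs of consecutive annotated genes.

    ``significant`` is either the set of significant COG pairs or the pair
    table together with ``pi_star``. Circular chromosomes are scanned with
    wrap-around; emitted segments are maximal (none contained in another).
    """
    if isinstance(significant, pd.DataFrame):
        significant = significant_pairs(significant, pi_star)

    out = SegmentSet()
    for chrom in genome.chromosomes.values():
        genes = [g for g in genome.genes_on(chrom.id) if g.cog is not None]
        n = len(genes)
        if n < 2:
            continue
        wrap = chrom.circular
        seq = genes + genes if wrap else genes
        limit = n

        # two-pointer scan: reach[s] = one past the last index extendable from s
        candidates = []
        e = 0
        for s in range(n):
            if e < s + 1:
                e = s + 1
            while e < s + limit and e < len(seq):
                new = seq[e]
                if all(_compatible(seq[k], new, significant) for k in range(s, e)):
                    e += 1
                else:
                    break
            if e - s >= 2:
                candidates.append((s, e))
        # keep only maximal intervals (not contained in another, modulo n)
        def covered(c, d):
            (s1, e1), (s2, e2) = c, d
            for shift in (0, n, -n):
                if s2 + shift <= s1 and e1 <= e2 + shift:
                    return True
            return False

        keep = []
        for i, c in enumerate(candidates):
            if any(i != j and covered(c, d) and (c != d or j < i) for j, d in enumerate(candidates)):
                continue
            keep.append(c)
        seen = set()
        for s, e in keep:
            members = tuple(seq[k].id for k in range(s, e))
            key = frozenset(members)
            if key in seen:
                continue
            seen.add(key)
            first, last = seq[s], seq[e - 1]
            wraps = wrap and e > n
            if not wraps and first.start <= last.end:
                span = (first.start, last.end)
            else:
                extent = (last.end - first.start) % chrom.length
                if extent == 0:
                    extent = chrom.length
                span = (first.start, extent)
                wraps = True
            out.append(SyntenySegment(genome.id, chrom.id, members, span, wraps))
    return out


def verify_segments(
    segments: SegmentSet,
    genome: Genome,
    significant: set[frozenset],
) -> None:
    """Re-check the clique and maximality invariants against the pair set."""
    for chrom in genome.chromosomes.values():
        genes = [g for g in genome.genes_on(chrom.id) if g.cog is not None]
        by_id = {g.id: g for g in genes}
        idx = {g.id: i for i, g in enumerate(genes)}
        n = len(genes)
        for seg in segments.for_genome(genome.id):
            if seg.chromosome != chrom.id:
                continue
            members = [by_id[g] for g in seg.genes]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if not _compatible(members[i], members[j], significant):
                        raise AssertionError(f"segment {seg.genes}: clique violated")
            if n > len(members):
                lo, hi = idx[seg.genes[0]], idx[seg.genes[-1]]
                for nb in ((lo - 1) % n, (hi + 1) % n):
                    if not chrom.circular and (nb == n - 1 and lo == 0 or nb == 0 and hi == n - 1):
                        continue
                    cand = genes[nb]
                    if cand.id in seg.genes:
                        continue
                    if all(_compatible(cand, m, significant) for m in members):
                        raise AssertionError(f"segment {seg.genes}: extendable by {cand.id}")


def segment_summary(
    segments: SegmentSet,
    genome: Genome | None = None,
    position_bin: int = 65_000,
) -> dict[str, pd.DataFrame]:
    """Positional histogram of segment midpoints and size distributions."""
    if not segments:
        return {
            "positions": pd.DataFrame(columns=["bin_start", "count"]),
            "sizes_kb": pd.DataFrame(columns=["size_kb", "fraction"]),
            "sizes_genes": pd.DataFrame(columns=["n_genes", "fraction"]),
        }
    mids, sizes_kb, sizes_genes = [], [], []
    for s in segments:
        clen = genome.chromosomes[s.chromosome].length if genome else None
        mids.append(s.midpoint(clen) if clen else (s.span[0] + s.span[1]) // 2)
        sizes_kb.append(s.extent / 1000.0)
        sizes_genes.append(s.n_genes)
    mids = np.array(mids)
    edges = np.arange(0, mids.max() + position_bin, position_bin)
    counts, edges = np.histogram(mids, bins=edges)
    positions = pd.DataFrame({"bin_start": edges[:-1].astype(int), "count": counts})
    kb = pd.Series(sizes_kb).value_counts(normalize=True).sort_index()
    ng = pd.Series(sizes_genes).value_counts(normalize=True).sort_index()
    return {
        "positions": positions,
        "sizes_kb": pd.DataFrame({"size_kb": kb.index, "fraction": kb.values}),
        "sizes_genes": pd.DataFrame({"n_genes": ng.index, "fraction": ng.values}),
    }
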