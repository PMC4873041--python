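"""Transcriptional read-through across operon junctions.

A junction joins two co-directional consecutive operons; its inter-operonic
region I runs from the upstream operon's stop to the downstream operon's
assigned TSS (fallback: the first downstream gene's start). Expression of a
region is the log of its mean per-base coverage. Read-through shows up as a
correlation, across junctions and conditions, between the sense expression
of I and the expression of the first downstream gene g — compared between
junctions inside and outside synteny segments, with the antisense strand as
a control. TU co-membership fractions quantify the same phenomenon from
annotated transcriptional units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CoverageTrack, Genome, OperonMap, TSSList, TUMap
from .segments import SegmentSet

MIN_GAP = 100  # bp; junctions with smaller inter-operonic regions are excluded


def assign_tss(tss: TSSList, operons: OperonMap, genome: Genome) -> dict[str, int]:
    """Choose, per operon, the closest upstream TSS on the operon's strand
    within its upstream inter-operonic region.

    Operons without such a TSS are absent from the result (excluded from
    junction analysis).
    """
    by_id = {g.id: g for g in genome.genes}
    out: dict[str, int] = {}
    for chrom in genome.chromosomes.values():
        genes = genome.genes_on(chrom.id)
        order = {g.id: i for i, g in enumerate(genes)}
        n = len(genes)
        clen = chrom.length
        for op in operons:
            first = by_id.get(op.genes[0] if op.strand == "+" else op.genes[-1])
            if first is None or first.chromosome != chrom.id:
                continue
            i = order[first.id]
            if op.strand == "+":
                prev = genes[(i - 1) % n]
                gap_len = (first.start - prev.end) % clen
                anchor = first.start
                cands = [t.position for t in tss
                         if t.chromosome == chrom.id and t.strand == "+"
                         and 0 <= (anchor - t.position) % clen <= gap_len]
                if cands:
                    out[op.id] = max(cands, key=lambda p: -((anchor - p) % clen))
            else:
                nxt = genes[(i + 1) % n]
                gap_len = (nxt.start - first.end) % clen
                anchor = first.end
                cands = [t.position for t in tss
                         if t.chromosome == chrom.id and t.strand == "-"
                         and 0 <= (t.position - anchor) % clen <= gap_len]
                if cands:
                    out[op.id] = min(cands, key=lambda p: (p - anchor) % clen)
    return out


def region_expression(
    coverage: CoverageTrack,
    chromosome: str,
    start: int,
    end: int,
    strand: str,
    pseudocount: float = 1.0,
) -> float:
    """log2(mean per-base coverage + pseudocount) over [start, end)."""
    if end <= start:
        raise ValueError("zero-length region")
    arr = coverage.get(chromosome, strand)
    return float(np.log2(arr[start:end].mean() + pseudocount))


@dataclass
class JunctionRecord:
    upstream: str
    downstream: str
    chromosome: str
    region: tuple[int, int]      # inter-operonic region I
    gene: str                    # first downstream gene g
    gene_span: tuple[int, int]
    strand: str
    gap: int
    in_segment: bool
    tss_assigned: bool


def build_junctions(
    operons: OperonMap,
    genome: Genome,
    segments: SegmentSet,
    tss_of_operon: dict[str, int] | None = None,
    min_gap: int = MIN_GAP,
) -> list[JunctionRecord]:
    """Co-directional consecutive operon pairs with inter-operonic region
    larger than ``min_gap``; in-segment means both operons lie entirely
    within the member set of a common segment."""
    by_id = {g.id: g for g in genome.genes}
    records = []
    seg_members = [set(s.genes) for s in segments]
    for chrom in genome.chromosomes.values():
        ops = [o for o in operons
               if by_id[o.genes[0]].chromosome == chrom.id]
        ops.sort(key=lambda o: min(by_id[g].start for g in o.genes))
        for a, b in zip(ops, ops[1:]):
            if a.strand != b.strand:
                continue
            strand = a.strand
            if strand == "+":
                up, down = a, b
                stop = max(by_id[g].end for g in up.genes)
                first_gene = by_id[down.genes[0]]
                tss_pos = (tss_of_operon or {}).get(down.id)
                region_end = tss_pos if tss_pos is not None and stop < tss_pos \
                    else first_gene.start
                region = (stop, region_end)
            else:
                up, down = b, a
                stop = min(by_id[g].start for g in up.genes)
                first_gene = by_id[max(down.genes, key=lambda g: by_id[g].end)]
                tss_pos = (tss_of_operon or {}).get(down.id)
                region_start = tss_pos if tss_pos is not None and tss_pos < stop \
                    else first_gene.end
                region = (region_start, stop)
            gap = region[1] - region[0]
            if gap <= min_gap:
                continue
            both = set(up.genes) | set(down.genes)
            in_seg = any(both <= m for m in seg_members)
            records.append(JunctionRecord(
                upstream=up.id, downstream=down.id, chromosome=chrom.id,
                region=region, gene=first_gene.id,
                gene_span=(first_gene.start, first_gene.end),
                strand=strand, gap=gap, in_segment=in_seg,
                tss_assigned=tss_pos is not None))
    return records


def readthrough_analysis(
    junctions: list[JunctionRecord],
    coverage_by_condition: list[CoverageTrack],
    min_pairs: int = 10,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pearson correlation of expr(I) with expr(g) per expr(g) bin.

    (junction x condition) points are pooled; strata are in/out of segment
    x sense/antisense; bins are unit-width in log2 expression of g.
    Under-populated bins are omitted.
    """
    other = {"+": "-", "-": "+"}
    rows = []
    for cond, cov in enumerate(coverage_by_condition):
        for j in junctions:
            eg = region_expression(cov, j.chromosome, *j.gene_span, j.strand,
                                   pseudocount)
            ei_sense = region_expression(cov, j.chromosome, *j.region, j.strand,
                                         pseudocount)
            ei_anti = region_expression(cov, j.chromosome, *j.region,
                                        other[j.strand], pseudocount)
            rows.append((cond, j.in_segment, eg, ei_sense, ei_anti))
    pts = pd.DataFrame(rows, columns=["condition", "in_segment", "expr_g",
                                      "expr_I_sense", "expr_I_antisense"])
    if pts.empty:
        return pd.DataFrame(columns=["in_segment", "strand_of_I", "bin",
                                     "correlation", "n_points"])
    pts["bin"] = np.floor(pts.expr_g).astype(int)
    out = []
    for in_seg in (True, False):
        sub = pts[pts.in_segment == in_seg]
        for strand_col, label in (("expr_I_sense", "sense"),
                                  ("expr_I_antisense", "antisense")):
            for b, grp in sub.groupby("bin"):
                if len(grp) < min_pairs:
                    continue
                x, y = grp[strand_col].to_numpy(), grp.expr_g.to_numpy()
                if x.std() == 0 or y.std() == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                out.append((in_seg, label, int(b), r, len(grp)))
            # pooled correlation across all bins
            if len(sub) >= min_pairs and sub[strand_col].std() > 0 \
                    and sub.expr_g.std() > 0:
                r = float(np.corrcoef(sub[strand_col], sub.expr_g)[0, 1])
                out.append((in_seg, label, None, r, len(sub)))
    return pd.DataFrame(out, columns=["in_segment", "strand_of_I", "bin",
                                      "correlation", "n_points"])


def tu_overlap_fraction(
    genome: Genome,
    operons: OperonMap,
    tus: TUMap,
    segments: SegmentSet,
    tu_kind: str = "long",
    restrict_codirectional: bool = False,
    min_gap: int = MIN_GAP,
) -> dict[str, float]:
    """Fraction of adjacent different-operon gene pairs co-resident in a TU
    of the requested kind, inside vs outside segments."""
    member = segments.membership()
    frac: dict[str, list[int]] = {"in": [], "out": []}
    for chrom in genome.chromosomes.values():
        genes = genome.genes_on(chrom.id)
        n = len(genes)
        adjacency = list(range(n - 1)) + ([n - 1] if chrom.circular else [])
        for i in adjacency:
            a, b = genes[i], genes[(i + 1) % n]
            op_a, op_b = operons.operon_of(a.id), operons.operon_of(b.id)
            if op_a is None or op_b is None or op_a == op_b:
                continue
            gap = (b.start - a.end) % chrom.length
            if gap <= min_gap:
                continue
            if restrict_codirectional and a.strand != b.strand:
                continue
            shared_tu = bool(tus.tus_of(a.id, tu_kind) & tus.tus_of(b.id, tu_kind))
            key = "in" if member.get(a.id, set()) & member.get(b.id, set()) else "out"
            frac[key].append(int(shared_tu))
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in frac.items()}
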