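"""Relative-orientation statistics of genes and operons in synteny segments.

Adjacent gene pairs are classified as codirectional (equal strands),
divergent (<- ->) or convergent (-> <-). The divergence index DI and
co-directionality index CoDI compare these counts between pairs inside
segments and outside; on an entire circular chromosome the number of
divergent and convergent adjacencies is equal, which is asserted as a
self-check. Configuration counts of 2- and 3-operon segments are tested
against a translation null in which the operon orientation sequence is
cyclically shifted while the segment map stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import Genome, OperonMap
from .segments import SegmentSet

CODIRECTIONAL, DIVERGENT, CONVERGENT = "codirectional", "divergent", "convergent"


def classify_orientation(strand_a: str, strand_b: str) -> str:
    """Orientation class of an ordered adjacent pair (a before b)."""
    if strand_a == strand_b:
        return CODIRECTIONAL
    return DIVERGENT if strand_a == "-" else CONVERGENT


@dataclass
class OrientationIndices:
    counts_in: dict[str, int]
    counts_out: dict[str, int]
    di: float | None   # Dir(in)/Conv(in) - Dir(out)/Conv(out)
    codi: float | None  # Codir/(Conv+Dir) difference
    chromosome_dir: int
    chromosome_conv: int


def _count_classes(pairs) -> dict[str, int]:
    out = {CODIRECTIONAL: 0, DIVERGENT: 0, CONVERGENT: 0}
    for a, b in pairs:
        out[classify_orientation(a, b)] += 1
    return out


def orientation_indices(genome: Genome, segments: SegmentSet) -> OrientationIndices:
    """DI and CoDI over adjacent gene pairs inside vs outside segments.

    A pair is "in" when both genes are members of at least one common
    segment. Indices are None (reported missing) when a convergent or
    mixed-orientation denominator vanishes.
    """
    member = segments.membership()
    pairs_in, pairs_out = [], []
    total_dir = total_conv = 0
    for chrom in genome.chromosomes.values():
        genes = genome.genes_on(chrom.id)
        n = len(genes)
        if n < 2:
            continue
        adjacency = list(range(n - 1)) + ([n - 1] if chrom.circular else [])
        for i in adjacency:
            a, b = genes[i], genes[(i + 1) % n]
            cls = classify_orientation(a.strand, b.strand)
            if cls == DIVERGENT:
                total_dir += 1
            elif cls == CONVERGENT:
                total_conv += 1
            if member.get(a.id, set()) & member.get(b.id, set()):
                pairs_in.append((a.strand, b.strand))
            else:
                pairs_out.append((a.strand, b.strand))
    cin, cout = _count_classes(pairs_in), _count_classes(pairs_out)
    di = codi = None
    if cin[CONVERGENT] > 0 and cout[CONVERGENT] > 0:
        di = cin[DIVERGENT] / cin[CONVERGENT] - cout[DIVERGENT] / cout[CONVERGENT]
    den_in = cin[CONVERGENT] + cin[DIVERGENT]
    den_out = cout[CONVERGENT] + cout[DIVERGENT]
    if den_in > 0 and den_out > 0:
        codi = cin[CODIRECTIONAL] / den_in - cout[CODIRECTIONAL] / den_out
    return OrientationIndices(cin, cout, di, codi, total_dir, total_conv)


# ---------------------------------------------------------------------------
# k-operon segment configurations under the translation null
# ---------------------------------------------------------------------------

def _canonical_config(strands: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical strand pattern up to reading the segment in either direction.

    Reversal flips both the order and every strand, so e.g. (+,+,-) and
    (+,-,-) are the same configuration.
    """
    flip = {"+": "-", "-": "+"}
    rev = tuple(flip[s] for s in reversed(strands))
    return min(strands, rev)


def config_label(strands: tuple[str, ...]) -> str:
    canon = _canonical_config(strands)
    if len(canon) == 2:
        return classify_orientation(*canon)
    return "".join(canon)


def segments_with_k_operons(segments: SegmentSet, operons: OperonMap, k: int):
    """Segments whose member genes comprise exactly k whole operons."""
    out = []
    for seg in segments:
        members = set(seg.genes)
        ops = sorted({o for g in seg.genes if (o := operons.operon_of(g))})
        whole = [o for o in ops if set(operons[o].genes) <= members]
        if len(whole) == k and len(whole) == len(ops):
            out.append((seg, whole))
    return out


def segment_config_stats(
    segments: SegmentSet,
    operons: OperonMap,
    genome: Genome,
    k: int = 2,
    n_translations: int | None = None,
    seed: int = 0,
    max_exhaustive: int = 10_000,
) -> pd.DataFrame:
    """Observed k-operon configuration counts vs the translation null.

    The operon orientation sequence is translated cyclically (all shifts
    when the operon count allows, otherwise sampled); counts per
    configuration over translations give the null mean and sd; z-scores
    assume the null is Gaussian and |z| > 1.65 flags over/under-
    representation. Degenerate configurations (null sd = 0) are reported
    with z = nan.
    """
    by_id = {g.id: g for g in genome.genes}
    op_list = sorted(operons, key=lambda o: by_id[o.genes[0]].start)
    op_index = {o.id: i for i, o in enumerate(op_list)}
    strands = [o.strand for o in op_list]
    n_ops = len(op_list)
    ksegs = segments_with_k_operons(segments, operons, k)
    seg_ops = [sorted(op_index[o] for o in ops) for _, ops in ksegs]

    def counts_for(shifted):
        out: dict[str, int] = {}
        for ops in seg_ops:
            label = config_label(tuple(shifted[i] for i in ops))
            out[label] = out.get(label, 0) + 1
        return out

    observed = counts_for(strands)
    if n_ops < 2:
        raise ValueError("need at least 2 distinct translations")
    if n_translations is None:
        n_translations = n_ops if n_ops <= max_exhaustive else max_exhaustive
    if n_ops <= max_exhaustive and n_translations >= n_ops:
        shifts = range(n_ops)
    else:
        rng = np.random.default_rng(seed)
        shifts = rng.integers(0, n_ops, size=n_translations)
    labels = sorted({config_label(tuple(c)) for c in _all_patterns(k)})
    null_counts = {lab: [] for lab in labels}
    for t in shifts:
        shifted = strands[t:] + strands[:t]
        cnt = counts_for(shifted)
        for lab in labels:
            null_counts[lab].append(cnt.get(lab, 0))
    rows = []
    total = max(len(seg_ops), 1)
    for lab in labels:
        arr = np.array(null_counts[lab], dtype=float)
        mean, sd = arr.mean(), arr.std(ddof=0)
        obs = observed.get(lab, 0)
        z = (obs - mean) / sd if sd > 0 else np.nan
        p = None
        if sd > 0:
            from scipy.stats import norm
            p = 2.0 * norm.sf(abs(z))
        rows.append({
            "configuration": lab, "observed": obs,
            "percent": 100.0 * obs / total,
            "null_mean": mean, "null_sd": sd, "z": z, "p": p,
            "over": bool(z > 1.65) if np.isfinite(z) else False,
            "under": bool(z < -1.65) if np.isfinite(z) else False,
            "degenerate": sd == 0,
        })
    return pd.DataFrame(rows)


def _all_patterns(k: int):
    import itertools

    return itertools.product("+-", repeat=k)
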