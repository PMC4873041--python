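"""Evolutionary distances between genomes and phylogenetic down-weighting.

Distances are derived from the sequence similarity of a small set of
single-copy marker genes: the similarity of two aligned marker sequences is
their fraction of identical residues over columns un-gapped in both, the
genome similarity S_gh averages this over usable markers, and the distance
is D_gh = 1 - S_gh.

Genomes with many close relatives in the collection are down-weighted:
omega_g = 1 / |{h : D_gh < delta}| (the genome counts itself), so a clade of
k near-identical strains carries total weight ~1. The effective number of
genomes is M' = sum_g omega_g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DELTA_DEFAULT = 0.25  # neighborhood radius on the 1 - identity scale

GAP_CHARS = frozenset("-.")


def marker_identity(seq_a: str, seq_b: str) -> float | None:
    """Fraction of identical residues over columns un-gapped in both rows.

    Returns None when no shared un-gapped column exists (undefined
    similarity, flagged to the caller). Multi-copy genes must be excluded
    by the caller before alignment.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned rows must have the same number of columns")
    shared = ident = 0
    for a, b in zip(seq_a, seq_b):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        shared += 1
        if a == b:
            ident += 1
    if shared == 0:
        return None
    return ident / shared


def genome_distance(similarities) -> float:
    """D = 1 - mean marker similarity; requires at least one usable marker."""
    sims = [s for s in similarities if s is not None]
    if not sims:
        raise ValueError("no usable marker for this genome pair")
    return 1.0 - float(np.mean(sims))


def distance_matrix_from_markers(
    alignments: dict[str, dict[str, str]],
) -> pd.DataFrame:
    """Build the pairwise distance matrix from per-marker alignment rows.

    ``alignments[marker][genome]`` is that genome's aligned (single-copy)
    marker sequence; genomes where the marker is absent or multi-copy are
    simply missing from the inner mapping.
    """
    genomes = sorted({g for rows in alignments.values() for g in rows})
    D = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    for i, g in enumerate(genomes):
        D.loc[g, g] = 0.0
        for h in genomes[i + 1:]:
            sims = []
            for rows in alignments.values():
                if g in rows and h in rows:
                    sims.append(marker_identity(rows[g], rows[h]))
            usable = [s for s in sims if s is not None]
            if usable:
                d = 1.0 - float(np.mean(usable))
                D.loc[g, h] = D.loc[h, g] = d
    return D


def read_marker_alignments(paths: dict[str, str]) -> dict[str, dict[str, str]]:
    """Read per-marker multi-FASTA alignments (marker name -> file path).

    Record ids are genome ids. Genomes appearing more than once in a
    marker's alignment carry that marker in multiple copies and are
    excluded from it, as the averaging requires single-copy markers.
    """
    from Bio import AlignIO

    out: dict[str, dict[str, str]] = {}
    for marker, path in paths.items():
        alignment = AlignIO.read(path, "fasta")
        counts: dict[str, int] = {}
        for rec in alignment:
            counts[rec.id] = counts.get(rec.id, 0) + 1
        out[marker] = {rec.id: str(rec.seq) for rec in alignment
                       if counts[rec.id] == 1}
    return out


def read_distance_matrix(path: str) -> pd.DataFrame:
    D = pd.read_csv(path, sep="\t", index_col=0)
    D.columns = D.columns.astype(str)
    D.index = D.index.astype(str)
    return D


def write_distance_matrix(D: pd.DataFrame, path: str) -> None:
    D.to_csv(path, sep="\t")


def validate_distance_matrix(D: pd.DataFrame) -> None:
    if list(D.index) != list(D.columns):
        raise ValueError("distance matrix must have identical row/column labels")
    A = D.to_numpy(float)
    if np.isnan(A).any():
        raise ValueError("distance matrix has missing entries")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(A), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if (A < 0).any() or (A > 1).any():
        raise ValueError("distances must lie in [0, 1]")


@dataclass
class WeightVector:
    """Per-genome weights omega in (0, 1] and the effective count M'."""

    omega: pd.Series
    delta: float

    @property
    def effective_genomes(self) -> float:
        return float(self.omega.sum())

    def __getitem__(self, genome: str) -> float:
        return float(self.omega[genome])


def compute_weights(D: pd.DataFrame, delta: float = DELTA_DEFAULT) -> WeightVector:
    """omega_g = 1 / #{h : D_gh < delta}, the genome itself included."""
    validate_distance_matrix(D)
    A = D.to_numpy(float)
    counts = (A < delta).sum(axis=1)  # diagonal (0 < delta) counts self
    omega = pd.Series(1.0 / counts, index=D.index, name="omega")
    return WeightVector(omega=omega, delta=delta)
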