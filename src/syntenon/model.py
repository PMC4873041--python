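"""Model-style front end: fit the conserved-proximity analysis to a corpus.

`SyntenyModel` bundles a genome collection with inter-genome evolutionary
distances; `fit()` computes phylogenetic weights, the per-pair statistics,
the positional-null calibration of the significance threshold and, lazily,
the synteny segments of each genome. The returned `SyntenyResults` carries
the estimates and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo, proximity, segments as seg_mod
from .formats import GenomeCollection
from .phylo import WeightVector


class SyntenyModel:
    """Conserved-proximity model over a collection of annotated genomes.

    Parameters
    ----------
    collection : GenomeCollection
    distances : DataFrame, symmetric inter-genome distances in [0, 1]
    delta : neighborhood radius for phylogenetic down-weighting
    L : distance normalization length in bp
    """

    def __init__(self, collection: GenomeCollection, distances: pd.DataFrame,
                 delta: float = phylo.DELTA_DEFAULT, L: int = proximity.L_DEFAULT):
        missing = [g for g in collection.genomes if g not in distances.index]
        if missing:
            raise ValueError(f"distance matrix lacks genomes: {missing[:5]}")
        order = list(collection.genomes)
        self.collection = collection
        self.distances = distances.loc[order, order]
        self.delta = delta
        self.L = L

    @classmethod
    def from_files(cls, annotation_paths: list[str], distances_path: str,
                   dialect: str = "table", **kwargs) -> "SyntenyModel":
        from .formats import read_collection

        collection = read_collection(annotation_paths, dialect=dialect)
        D = phylo.read_distance_matrix(distances_path)
        return cls(collection, D, **kwargs)

    def fit(self, fdr: float = proximity.FDR_DEFAULT, n_null: int = 100_000,
            seed: int = 0, pairs=None) -> "SyntenyResults":
        weights = phylo.compute_weights(self.distances, self.delta)
        table = proximity.pair_table(self.collection, weights, pairs=pairs)
        tested = table[table.n_joint >= 2]
        null = proximity.simulate_null(self.collection, weights, seed=seed,
                                       n_pairs=max(n_null, 10_000))
        calibration = proximity.calibrate_threshold(
            tested.pi_hat.to_numpy(), null, fdr=fdr)
        return SyntenyResults(self, weights, table, calibration, null)


@dataclass
class SyntenyResults:
    model: SyntenyModel
    weights: WeightVector
    pair_table: pd.DataFrame
    calibration: proximity.NullCalibration
    null_sample: np.ndarray

    @property
    def pi_star(self) -> float:
        return self.calibration.pi_star

    @property
    def significant_pairs(self) -> set[frozenset]:
        return seg_mod.significant_pairs(self.pair_table, self.pi_star)

    @property
    def n_significant(self) -> int:
        return int((self.pair_table.pi_hat <= self.pi_star).sum())

    def segments(self, genome_id: str | None = None) -> seg_mod.SegmentSet:
        sig = self.significant_pairs
        out = seg_mod.SegmentSet()
        targets = [genome_id] if genome_id else list(self.model.collection.genomes)
        for gid in targets:
            out.extend(seg_mod.build_segments(self.model.collection[gid], sig))
        return out

    def summary(self) -> str:
        c = self.calibration
        segs = self.segments()
        lines = [
            "Conserved-proximity synteny fit",
            "=" * 46,
            f"genomes                    {len(self.model.collection):>10d}",
            f"effective genomes M'       {self.weights.effective_genomes:>10.2f}",
            f"delta / L                  {self.model.delta:>6.2f} / {self.model.L}",
            f"COG pairs tested           {len(self.pair_table):>10d}",
            f"null sample size           {c.n_null:>10d}",
            f"tail exponent a (nat/dec)  {c.a:>6.3f} / {c.a_per_decade:.3f}",
            f"tail fit R^2               {c.r_squared:>10.3f}",
            f"FDR target                 {c.fdr:>10.4g}",
            f"threshold pi*              {c.pi_star:>10.3g}",
            f"significant pairs          {self.n_significant:>10d}",
            f"synteny segments           {len(segs):>10d}",
        ]
        return "\n".join(lines)
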