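"""Synthetic genome collections, expression, regulons, binding and coverage.

The generator emulates the statistical structure the analysis assumes:

* genomes evolve on a random ultrametric tree by single-gene relocations,
  except planted gene clusters whose members relocate as a block with a
  per-event retention probability (otherwise the hit gene leaves the
  cluster) — the planted clusters are the ground-truth synteny segments;
* expression has block-correlated structure: each gene's activity mixes an
  operon latent, a segment latent and shared regulatory-factor latents on
  top of independent noise, so pairwise correlations recover the planted
  rho values in closed form;
* binding regions concentrate near planted-segment borders, and stranded
  coverage carries transcriptional read-through across operon junctions
  with separate probabilities inside and outside planted segments.

Everything is deterministic under the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (
    Chromosome, CoverageTrack, Gene, Genome, GenomeCollection, IntervalTrack,
    Operon, OperonMap, RegulonTable, TSS, TSSList, TU, TUMap,
)


@dataclass
class ExpressionConfig:
    n_conditions: int = 400
    rho_op: float = 0.4     # shared-operon correlation
    rho_seg: float = 0.25   # shared-segment correlation
    rho_f: float = 0.15     # shared-regulatory-factor correlation
    noise_sd: float | None = None  # None: balance to unit total variance
    n_tf: int = 8
    n_sf: int = 4
    segments_per_factor: int = 2
    housekeeping_sf: str | None = None  # e.g. "SigA": broad SF over operons
    housekeeping_fraction: float = 0.5

    def validate(self) -> None:
        if self.rho_op + self.rho_seg + self.rho_f > 1.0:
            raise ValueError("rho_op + rho_seg + rho_f must not exceed 1")
        for r in (self.rho_op, self.rho_seg, self.rho_f):
            if not 0.0 <= r <= 1.0:
                raise ValueError("correlation shares must be in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genomes: int = 50
    # chromosome length n_cogs * spacing must comfortably exceed the 500 kb
    # distance-normalization length, as in real bacterial genomes; otherwise
    # the capped normalized distance never reaches 1 and the pair statistic
    # acquires a degenerate point mass at x_max^M'
    n_cogs: int = 1000
    gene_length: int = 1000
    gene_gap: int = 100
    circular: bool = True
    planted_clusters: list[tuple[int, float]] = field(
        default_factory=lambda: [(5, 1.0)] * 20)
    relocation_rate: float = 10.0  # events per unit branch length per gene
    copy_number_law: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    cluster_codir_prob: float = 0.9
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    operon_mean_size: int = 3
    # tracks
    n_binding_regions: int = 200
    binding_width: int = 200
    border_enrichment: float = 5.0
    border_margin: int = 3000
    readthrough_prob_in: float = 0.8
    readthrough_prob_out: float = 0.1
    readthrough_fraction: float = 0.3  # gap level as fraction of run level
    n_coverage_conditions: int = 7

    def validate(self) -> None:
        if self.n_genomes < 1 or self.n_cogs < 1:
            raise ValueError("sizes must be >= 1")
        if sum(s for s, _ in self.planted_clusters) > self.n_cogs:
            raise ValueError("planted clusters exceed genome size")
        for _, r in self.planted_clusters:
            if not 0.0 <= r <= 1.0:
                raise ValueError("retention must be in [0, 1]")
        total = sum(self.copy_number_law.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("copy_number_law must sum to 1")
        self.expression.validate()

    @property
    def spacing(self) -> int:
        return self.gene_length + self.gene_gap


@dataclass
class GroundTruth:
    """Planted structure, recorded as the generator emits it."""

    distances: pd.DataFrame | None = None
    clusters: dict[int, list[str]] = field(default_factory=dict)  # id -> COGs
    cluster_genes: dict[str, dict[int, list[str]]] = field(default_factory=dict)
    gene_segment: dict[str, int | None] = field(default_factory=dict)
    operons: OperonMap | None = None
    loadings: pd.DataFrame | None = None  # factor x cluster 0/1
    junction_readthrough: dict[tuple[str, str], bool] = field(default_factory=dict)

    def within_cluster_pairs(self) -> set[frozenset]:
        out = set()
        for cogs in self.clusters.values():
            for i in range(len(cogs)):
                for j in range(i + 1, len(cogs)):
                    out.add(frozenset((cogs[i], cogs[j])))
        return out


# ---------------------------------------------------------------------------
# random ultrametric tree
# ---------------------------------------------------------------------------

def _coalescent_tree(n: int, rng: np.random.Generator):
    """Random ultrametric tree; distances rescaled to span [0, 0.5].

    Topology is built by successive random pair merges; merge depths are
    sorted uniforms, so the number of surviving lineages decays linearly
    with depth and the collection is not dominated by one deep split (a
    Kingman depth law would collapse the effective genome count to ~2-4).
    Returns (root, children: node -> [(child, branch_length)], D: leaf
    distance matrix).
    """
    if n == 1:
        return 0, {}, np.zeros((1, 1))
    active = list(range(n))
    depth = {i: 0.0 for i in range(n)}
    children: dict[int, list[tuple[int, float]]] = {}
    leaves_below = {i: [i] for i in range(n)}
    merge_depths = np.sort(rng.random(n - 1))
    next_id = n
    for t in merge_depths:
        k = len(active)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        depth[next_id] = t
        children[next_id] = [(a, t - depth[a]), (b, t - depth[b])]
        leaves_below[next_id] = leaves_below[a] + leaves_below[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]
    D = np.zeros((n, n))
    for node, kids in children.items():
        for (a, _), (b, _) in [(kids[0], kids[1])]:
            for la in leaves_below[a]:
                for lb in leaves_below[b]:
                    D[la, lb] = D[lb, la] = 2.0 * depth[node]
    scale = 0.5 / D.max()
    D *= scale
    children = {p: [(c, bl * scale) for c, bl in kids] for p, kids in children.items()}
    return root, children, D


# ---------------------------------------------------------------------------
# genome evolution
# ---------------------------------------------------------------------------

def _evolve_branch(units, retention, rate, t, rng):
    """Single-gene relocations along one branch.

    ``units`` is a list of lists of COG indices: singleton units are free
    genes, longer units are intact planted clusters. A relocation event
    picks a gene uniformly; a cluster gene moves the whole block with
    probability equal to the cluster's retention, and otherwise leaves the
    cluster as a new singleton.
    """
    units = [list(u) for u in units]
    n_genes = sum(len(u) for u in units)
    k = rng.poisson(rate * t * n_genes)
    for _ in range(k):
        lengths = np.fromiter((len(u) for u in units), dtype=int)
        gene_idx = rng.integers(0, lengths.sum())
        u_idx = int(np.searchsorted(np.cumsum(lengths), gene_idx, side="right"))
        unit = units[u_idx]
        if len(unit) > 1:
            cog0 = unit[0]
            r = retention.get(_cluster_of(cog0, retention), 0.0)
            if rng.random() < r:
                block = units.pop(u_idx)
                units.insert(int(rng.integers(0, len(units) + 1)), block)
            else:
                offset = gene_idx - (np.cumsum(lengths)[u_idx] - lengths[u_idx])
                gene = unit.pop(int(offset))
                if not unit:
                    units.pop(u_idx)
                units.insert(int(rng.integers(0, len(units) + 1)), [gene])
        else:
            block = units.pop(u_idx)
            units.insert(int(rng.integers(0, len(units) + 1)), block)
    return units


def _cluster_of(cog_idx, retention):
    # retention maps cluster id -> prob; cluster id encoded during setup via
    # a module-level map set on the dict (see simulate_genomes)
    return retention["_cog2cluster"].get(cog_idx) if "_cog2cluster" in retention else None


def cog_label(i: int) -> str:
    return f"COG{i:04d}"


def simulate_genomes(config: SimulationConfig):
    """Evolve a genome collection on a random tree with planted clusters."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genomes
    root, children, D = _coalescent_tree(n, rng)

    # ancestral order: clusters as blocks interleaved with free genes
    clusters: dict[int, list[int]] = {}
    cog2cluster: dict[int, int] = {}
    retention: dict = {"_cog2cluster": cog2cluster}
    cursor = 0
    free = config.n_cogs - sum(s for s, _ in config.planted_clusters)
    n_cl = len(config.planted_clusters)
    gap_per = free // (n_cl + 1) if n_cl else free
    units: list[list[int]] = []
    next_cog = 0

    def add_free(count):
        nonlocal next_cog
        for _ in range(count):
            units.append([next_cog])
            next_cog += 1

    for ci, (size, r) in enumerate(config.planted_clusters):
        add_free(gap_per)
        block = list(range(next_cog, next_cog + size))
        for c in block:
            cog2cluster[c] = ci
        clusters[ci] = block
        retention[ci] = r
        units.append(block)
        next_cog += size
    add_free(config.n_cogs - next_cog)

    # evolve orders down the tree
    orders: dict[int, list[list[int]]] = {root: units}
    stack = [root]
    while stack:
        node = stack.pop()
        for child, bl in children.get(node, []):
            orders[child] = _evolve_branch(
                orders[node], retention, config.relocation_rate, bl, rng)
            stack.append(child)

    counts = np.array(sorted(config.copy_number_law))
    probs = np.array([config.copy_number_law[c] for c in counts])

    collection = GenomeCollection()
    truth = GroundTruth()
    genome_ids = [f"g{k:03d}" for k in range(n)]
    for k, gid in enumerate(genome_ids):
        flat: list[tuple[int, int | None]] = []  # (cog index, cluster id)
        for u in orders[k]:
            cl = cog2cluster.get(u[0]) if len(u) > 1 else None
            for c in u:
                flat.append((c, cl if len(u) > 1 else None))
        # copy-number variation on free genes
        emitted: list[tuple[int, int | None]] = []
        extra: list[int] = []
        for c, cl in flat:
            if cl is not None:
                emitted.append((c, cl))
                continue
            cn = int(rng.choice(counts, p=probs))
            if cn >= 1:
                emitted.append((c, None))
                extra.extend([c] * (cn - 1))
        for c in extra:
            emitted.insert(int(rng.integers(0, len(emitted) + 1)), (c, None))

        m = len(emitted)
        clen = m * config.spacing
        chrom = Chromosome("chr", clen, config.circular)
        genes, strands = [], {}
        cluster_members: dict[int, list[str]] = {}
        prev_cluster, prev_strand = None, None
        for i, (c, cl) in enumerate(emitted):
            start = i * config.spacing
            if cl is not None and cl == prev_cluster:
                if rng.random() < config.cluster_codir_prob:
                    strand = prev_strand
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            prev_cluster, prev_strand = cl, strand
            gene_id = f"{gid}_{i:04d}"
            genes.append(Gene(gene_id, "chr", start, start + config.gene_length,
                              strand, cog_label(c)))
            if cl is not None:
                cluster_members.setdefault(cl, []).append(gene_id)
            truth.gene_segment[gene_id] = cl
        collection.add(Genome(gid, [chrom], genes))
        truth.cluster_genes[gid] = cluster_members

    truth.clusters = {ci: [cog_label(c) for c in block] for ci, block in clusters.items()}
    truth.distances = pd.DataFrame(D, index=genome_ids, columns=genome_ids)
    return collection, truth


# ---------------------------------------------------------------------------
# operons
# ---------------------------------------------------------------------------

def derive_operons(genome: Genome, rng: np.random.Generator, mean_size: int = 3) -> OperonMap:
    """Partition same-strand gene runs into operons of geometric sizes."""
    operons = []
    serial = 0
    for chrom in genome.chromosomes.values():
        genes = genome.genes_on(chrom.id)
        i = 0
        while i < len(genes):
            j = i
            while j + 1 < len(genes) and genes[j + 1].strand == genes[i].strand:
                j += 1
            run = genes[i:j + 1]
            k = 0
            while k < len(run):
                size = min(int(rng.geometric(1.0 / mean_size)), len(run) - k)
                block = run[k:k + size]
                operons.append(Operon(f"{genome.id}_op{serial:04d}",
                                      tuple(g.id for g in block), block[0].strand))
                serial += 1
                k += size
            i = j + 1
    return OperonMap(operons)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(collection: GenomeCollection, truth: GroundTruth,
                        config: SimulationConfig, genome_id: str | None = None):
    """Block-correlated activities for a focal genome.

    a_si = sqrt(rho_op) z_op + sqrt(rho_seg) z_seg + sqrt(rho_f) sum_f L z_f
    + noise, with independent standard-normal latents per condition. Factors
    are labelled TF or SF, attached to planted segments (seg-regulation) and
    directly regulating one operon per attached segment.
    """
    cfg = config.expression
    cfg.validate()
    rng = np.random.default_rng([config.seed, 1])
    genome_id = genome_id or next(iter(collection.genomes))
    genome = collection[genome_id]
    if truth.operons is None:
        truth.operons = derive_operons(genome, np.random.default_rng([config.seed, 5]),
                                       config.operon_mean_size)
    operons = truth.operons
    genes = genome.genes
    S = cfg.n_conditions

    op_ids = [o.id for o in operons]
    op_idx = {o: i for i, o in enumerate(op_ids)}
    seg_of = {g.id: truth.gene_segment.get(g.id) for g in genes}
    cluster_ids = sorted(truth.clusters)
    seg_idx = {c: i for i, c in enumerate(cluster_ids)}

    # factor attachment: each factor takes segments_per_factor clusters,
    # disjointly, so each cluster carries at most one factor
    factors = [(f"TF{i:02d}", "TF") for i in range(cfg.n_tf)] + \
              [(f"SF{i:02d}", "SF") for i in range(cfg.n_sf)]
    pool = list(cluster_ids)
    rng.shuffle(pool)
    loadings = pd.DataFrame(0.0, index=[f for f, _ in factors], columns=cluster_ids)
    regulon = RegulonTable()
    for fname, kind in factors:
        take = [pool.pop() for _ in range(min(cfg.segments_per_factor, len(pool)))]
        direct = []
        for cl in take:
            loadings.loc[fname, cl] = 1.0
            members = truth.cluster_genes.get(genome_id, {}).get(cl, [])
            ops = sorted({operons.operon_of(g) for g in members if operons.operon_of(g)})
            if ops:
                direct.append(ops[int(rng.integers(0, len(ops)))])
        regulon.add(fname, kind, direct)
    if cfg.housekeeping_sf:
        n_hk = int(round(cfg.housekeeping_fraction * len(op_ids)))
        chosen = rng.choice(op_ids, size=n_hk, replace=False)
        regulon.add(cfg.housekeeping_sf, "SF", list(chosen))

    z_op = rng.standard_normal((len(op_ids), S))
    z_seg = rng.standard_normal((len(cluster_ids), S))
    z_gene = rng.standard_normal((len(genes), S))  # private segment latents
    z_f = rng.standard_normal((len(factors), S))
    fac_idx = {f: i for i, (f, _) in enumerate(factors)}

    A = np.zeros((len(genes), S))
    for gi, g in enumerate(genes):
        oi = op_idx.get(operons.operon_of(g.id))
        seg = seg_of[g.id]
        row = np.zeros(S)
        var = 0.0
        if oi is not None:
            row += np.sqrt(cfg.rho_op) * z_op[oi]
            var += cfg.rho_op
        if seg is not None:
            row += np.sqrt(cfg.rho_seg) * z_seg[seg_idx[seg]]
            fvec = loadings[seg].to_numpy()
            for f, li in fac_idx.items():
                if fvec[li] > 0:
                    row += np.sqrt(cfg.rho_f) * z_f[li]
                    var += cfg.rho_f
        else:
            row += np.sqrt(cfg.rho_seg) * z_gene[gi]
        var += cfg.rho_seg
        noise_sd = cfg.noise_sd if cfg.noise_sd is not None else np.sqrt(max(1.0 - var, 0.0))
        A[gi] = row + noise_sd * rng.standard_normal(S)

    truth.loadings = loadings
    expr = pd.DataFrame(A, index=[g.id for g in genes],
                        columns=[f"c{s:03d}" for s in range(S)])
    return expr, operons, regulon


# ---------------------------------------------------------------------------
# binding, coverage, TSS, TUs
# ---------------------------------------------------------------------------

def _cluster_spans(genome: Genome, truth: GroundTruth):
    spans = []
    by_id = {g.id: g for g in genome.genes}
    for cl, members in truth.cluster_genes.get(genome.id, {}).items():
        gs = [by_id[m] for m in members if m in by_id]
        if len(gs) >= 2:
            spans.append((min(g.start for g in gs), max(g.end for g in gs)))
    return spans


def simulate_tracks(collection: GenomeCollection, truth: GroundTruth,
                    config: SimulationConfig, genome_id: str | None = None):
    """Binding intervals, stranded coverage, TSS list and TU map."""
    rng = np.random.default_rng([config.seed, 2])
    genome_id = genome_id or next(iter(collection.genomes))
    genome = collection[genome_id]
    if truth.operons is None:
        truth.operons = derive_operons(genome, np.random.default_rng([config.seed, 5]),
                                       config.operon_mean_size)
    operons = truth.operons
    chrom = next(iter(genome.chromosomes.values()))
    clen = chrom.length
    by_id = {g.id: g for g in genome.genes}
    spans = _cluster_spans(genome, truth)

    # --- binding regions, denser within border_margin of segment borders
    borders = [b for s in spans for b in s]
    near = np.zeros(clen, dtype=bool)
    for b in borders:
        lo, hi = b - config.border_margin, b + config.border_margin
        if lo < 0:
            near[lo % clen:] = True
            near[:hi] = True
        elif hi > clen:
            near[lo:] = True
            near[:hi % clen] = True
        else:
            near[lo:hi] = True
    near_idx = np.nonzero(near)[0]
    far_idx = np.nonzero(~near)[0]
    E = config.border_enrichment
    p_near = (E * near_idx.size) / (E * near_idx.size + far_idx.size) \
        if near_idx.size else 0.0
    rows = []
    for r in range(config.n_binding_regions):
        if far_idx.size == 0 or (near_idx.size and rng.random() < p_near):
            mid = int(near_idx[rng.integers(0, near_idx.size)])
        else:
            mid = int(far_idx[rng.integers(0, far_idx.size)])
        half = config.binding_width // 2
        rows.append(("chr", max(0, mid - half), min(clen, mid + half),
                     f"region{r:03d}", None, None))
    binding = IntervalTrack(pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "name", "score", "strand"]))

    # --- operon order, junctions and read-through runs
    op_list = sorted(operons, key=lambda o: by_id[o.genes[0]].start)
    seg_member = {cl: set(m) for cl, m in truth.cluster_genes.get(genome_id, {}).items()}

    def op_in_segment(op: Operon):
        for cl, members in seg_member.items():
            if all(g in members for g in op.genes):
                return cl
        return None

    junctions = []  # (up_idx, down_idx, readthrough)
    linked = {}
    for i in range(len(op_list) - 1):
        up, down = op_list[i], op_list[i + 1]
        if up.strand != down.strand:
            continue
        same_seg = (op_in_segment(up) is not None
                    and op_in_segment(up) == op_in_segment(down))
        p = config.readthrough_prob_in if same_seg else config.readthrough_prob_out
        rt = bool(rng.random() < p)
        truth.junction_readthrough[(up.id, down.id)] = rt
        junctions.append((i, i + 1, rt))
        if rt:
            linked[i] = i + 1

    runs: list[list[int]] = []
    i = 0
    while i < len(op_list):
        run = [i]
        while run[-1] in linked:
            run.append(linked[run[-1]])
        runs.append(run)
        i = run[-1] + 1

    # --- TSS for every operon
    tss = TSSList()
    for op in op_list:
        first = by_id[op.genes[0]]
        last = by_id[op.genes[-1]]
        offset = int(rng.integers(20, 81))
        if op.strand == "+":
            tss.append(TSS("chr", (first.start - offset) % clen, "+"))
        else:
            tss.append(TSS("chr", (last.end + offset) % clen, "-"))

    # --- stranded coverage per condition
    coverage = []
    for _ in range(config.n_coverage_conditions):
        track = CoverageTrack()
        arr = {"+": np.zeros(clen), "-": np.zeros(clen)}
        # antisense / background noise
        for strand in "+-":
            arr[strand] += rng.exponential(0.05, size=clen)
        for run in runs:
            level = float(np.exp(rng.normal(2.0, 1.0)))
            strand = op_list[run[0]].strand
            for pos, oi in enumerate(run):
                op = op_list[oi]
                s = by_id[op.genes[0]].start
                e = by_id[op.genes[-1]].end
                arr[strand][s:e] += level
                if pos + 1 < len(run):
                    nxt = op_list[run[pos + 1]]
                    gap_s, gap_e = e, by_id[nxt.genes[0]].start
                    if gap_e > gap_s:
                        arr[strand][gap_s:gap_e] += config.readthrough_fraction * level
        track.set("chr", "+", arr["+"])
        track.set("chr", "-", arr["-"])
        coverage.append(track)

    # --- TUs: short = single operons, long = maximal read-through runs
    tus = []
    for i, op in enumerate(op_list):
        tus.append(TU(f"{genome_id}_tuS{i:04d}", op.genes, "short"))
    for r, run in enumerate(runs):
        genes = tuple(g for oi in run for g in op_list[oi].genes)
        tus.append(TU(f"{genome_id}_tuL{r:04d}", genes, "long"))
    return binding, coverage, tss, TUMap(tus)
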