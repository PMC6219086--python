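"""Deterministic fixture generators: planted-motif genomes and network pairs.

Every generator is a pure function of its parameters and an explicit seed,
so tests and benchmarks are replayable without stored binary fixtures.

The documented strong-planting profile used for acceptance-style checks is
20 regulon genes, 200-nt intergenic regions and mutation rate 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netmotif.genome_io import (
    BASES,
    GeneAnnotation,
    Genome,
    MarkovBackground,
    revcomp,
)
from netmotif.network_session import Network
from netmotif.sync_select import IdentityMap

STRONG_PLANTING = {
    "n_genes": 20,
    "gene_len": 300,
    "intergenic_len": 200,
    "mutation_rate": 0.05,
    "consensus": "GGGACTTAAGTCCC",
}


@dataclass(frozen=True)
class PlantedMotifSpec:
    """What to plant: an A/C/G/T/N consensus, the regulon genes, the allowed
    offset window upstream of each gene start, and a per-base mutation rate
    applied to non-N positions."""

    consensus: str
    regulon: frozenset
    offset_range: tuple[int, int] = (10, 100)
    mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5)")
        if self.offset_range[0] > self.offset_range[1] or self.offset_range[0] < 0:
            raise ValueError("invalid offset_range")


@dataclass(frozen=True)
class PlantedSite:
    locus_tag: str
    start: int  # 0-based forward-strand offset of the planted window
    strand: int


class PlacementError(ValueError):
    """Raised when a motif instance cannot be placed for some gene."""


def generate_genome(
    n_genes: int,
    gene_len: int = 300,
    intergenic_len: int = 200,
    bg: MarkovBackground | None = None,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> Genome:
    """Alternating intergenic/gene layout with random strands.

    Total length is ``n_genes*gene_len + (n_genes+1)*intergenic_len``; locus
    tags run g0001, g0002, ...  The sequence is sampled from ``bg`` (uniform
    order-0 when omitted); deterministic given the seed.
    """
    if n_genes <= 0 or gene_len <= 0 or intergenic_len <= 0:
        raise ValueError("all sizes must be positive")
    rng = np.random.default_rng(seed)
    bg = bg or MarkovBackground.uniform(0)
    total = n_genes * gene_len + (n_genes + 1) * intergenic_len
    if bg.order == 0:
        codes = rng.choice(4, size=total, p=bg.marginal)
        sequence = "".join(BASES[c] for c in codes)
    else:
        sequence = bg.sample(total, rng)
    genes = []
    pos = intergenic_len
    for i in range(n_genes):
        strand = 1 if rng.random() < 0.5 else -1
        genes.append(
            GeneAnnotation(
                locus_tag=f"g{i + 1:04d}", start=pos, end=pos + gene_len, strand=strand
            )
        )
        pos += gene_len + intergenic_len
    return Genome(id=genome_id, sequence=sequence, genes=genes)


def _instantiate(consensus: str, mutation_rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in consensus.upper():
        if ch == "N":
            out.append(BASES[rng.integers(4)])
        elif ch in BASES:
            if mutation_rate > 0 and rng.random() < mutation_rate:
                others = [b for b in BASES if b != ch]
                out.append(others[rng.integers(3)])
            else:
                out.append(ch)
        else:
            raise ValueError(f"unsupported consensus character {ch!r}")
    return "".join(out)


def plant_motif(
    genome: Genome, spec: PlantedMotifSpec, seed: int = 0
) -> tuple[Genome, list[PlantedSite]]:
    """Write one motif instance upstream of each regulon gene, on the gene's
    sense strand, at a random offset from ``spec.offset_range``.

    The offset is the gap in nt between the motif's gene-proximal edge and
    the gene's biological start.  Placements never touch a coding interval;
    an infeasible gene raises PlacementError naming it.  Returns the edited
    genome and the ground-truth site list.
    """
    rng = np.random.default_rng(seed)
    width = len(spec.consensus)
    unknown = set(spec.regulon) - {g.locus_tag for g in genome.genes}
    if unknown:
        raise KeyError(f"unknown regulon locus_tags: {sorted(unknown)}")
    seq = list(genome.sequence)
    sites: list[PlantedSite] = []
    occupied = [(g.start, g.end) for g in genome.genes]  # genes + planted sites

    def is_free(lo: int, hi: int) -> bool:
        return 0 <= lo and hi <= len(seq) and not any(s < hi and e > lo for s, e in occupied)

    for gene in genome.genes:
        if gene.locus_tag not in spec.regulon:
            continue
        offsets = list(range(spec.offset_range[0], spec.offset_range[1] + 1))
        rng.shuffle(offsets)
        placed = False
        for offset in offsets:
            if gene.strand == 1:
                lo = gene.start - offset - width
            else:
                lo = gene.end + offset
            hi = lo + width
            if not is_free(lo, hi):
                continue
            instance = _instantiate(spec.consensus, spec.mutation_rate, rng)
            forward = instance if gene.strand == 1 else revcomp(instance)
            seq[lo:hi] = list(forward)
            sites.append(PlantedSite(gene.locus_tag, lo, gene.strand))
            occupied.append((lo, hi))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"no feasible offset for {gene.locus_tag} in {spec.offset_range}"
            )
    edited = Genome(id=genome.id, sequence="".join(seq), genes=list(genome.genes))
    return edited, sites


def strong_planted_fixture(seed: int = 0) -> tuple[Genome, list[PlantedSite], str]:
    """The documented strong-planting profile; returns (genome, sites,
    planted consensus)."""
    p = STRONG_PLANTING
    genome = generate_genome(
        p["n_genes"], p["gene_len"], p["intergenic_len"], seed=seed
    )
    spec = PlantedMotifSpec(
        consensus=p["consensus"],
        regulon=frozenset(g.locus_tag for g in genome.genes),
        offset_range=(10, 100),
        mutation_rate=p["mutation_rate"],
    )
    genome, sites = plant_motif(genome, spec, seed=seed + 1)
    return genome, sites, p["consensus"]


def generate_network_pair(
    n_shared: int,
    n_only_a: int,
    n_only_b: int,
    edge_prob: float = 0.1,
    homolog_rename: bool = False,
    seed: int = 0,
) -> tuple[Network, Network, IdentityMap]:
    """Two networks over partially shared node sets, plus an identity map.

    Shared nodes are named SHD0001... in network a; with ``homolog_rename``
    they appear in b in capitalized-lowercase form (Shd0001) and the identity
    map records the pairs -- mimicking human/mouse symbol conventions.
    Edges are independent Bernoulli(edge_prob) per unordered node pair and
    network; deterministic given the seed.
    """
    if min(n_shared, n_only_a, n_only_b) < 0:
        raise ValueError("node counts must be >= 0")
    rng = np.random.default_rng(seed)
    shared_a = [f"SHD{i + 1:04d}" for i in range(n_shared)]
    shared_b = [name.capitalize() if homolog_rename else name for name in shared_a]
    only_a = [f"UNA{i + 1:04d}" for i in range(n_only_a)]
    only_b = [f"Unb{i + 1:04d}" for i in range(n_only_b)]

    def build(name: str, nodes: list[str]) -> Network:
        net = Network(name=name)
        for n in nodes:
            net.add_node(n)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < edge_prob:
                    net.add_edge(nodes[i], nodes[j], "pp")
        return net

    net_a = build("net_a", shared_a + only_a)
    net_b = build("net_b", shared_b + only_b)
    pairs = (
        {(a, b) for a, b in zip(shared_a, shared_b)} if homolog_rename else set()
    )
    identity_map = IdentityMap(pairs=pairs, spaces=("a", "b"))
    return net_a, net_b, identity_map
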