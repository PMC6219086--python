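"""Regulon exploration: aggregate intergenic motif occurrences per downstream
gene and iteratively expand a gene selection until the candidate regulon
converges.

The pipeline per round: extract upstream regions of the selected genes,
discover motifs (ZOOPS), scan the whole genome with each motif against the
genome background, reject occurrences overlapping any gene, assign flanking
genes, and merge occurrences per downstream gene with hit counts.  Each
table row records the 0-based index of its downstream/upstream gene within
the discovery stage's ordered score list, with -1 marking genes that were
not part of the discovery input -- those are the expansion candidates.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netmotif.genome_io import Genome, MarkovBackground, build_background, extract_upstream
from netmotif.motif_core import (
    DiscoveredMotif,
    MotifInputError,
    Occurrence,
    discover_zoops,
    scan,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Knobs for one discovery-scan-aggregate round."""

    upstream_length: int = 300
    truncate_at_neighbor: bool = True
    nmotifs: int = 5
    evalue_threshold: float = 1000.0
    background_order: int = 3
    p_threshold: float = 1e-4
    widths: tuple[int, ...] = (8, 10, 12, 14, 16, 18, 20)
    n_shuffles: int = 20
    seed: int = 0


@dataclass
class AggregatedOccurrence:
    """One output-table row: best occurrence per downstream gene."""

    downstream_gene: str
    sequence: str
    index_downstream: int
    index_upstream: int
    pvalue: float
    qvalue: float
    hit_count: int
    relative_position: int


@dataclass
class RunResult:
    """Result of one pipeline round."""

    status: str  # "ok" or a failure description
    motifs: list[DiscoveredMotif] = field(default_factory=list)
    tables: list[list[AggregatedOccurrence]] = field(default_factory=list)


@dataclass
class ExplorationState:
    """State of the iterative expansion."""

    selection: set[str]
    iteration: int
    tables: list[list[AggregatedOccurrence]]
    converged: bool
    history: list[int] = field(default_factory=list)
    motifs: list[DiscoveredMotif] = field(default_factory=list)
    status: str = "ok"


# ---------------------------------------------------------------------------
# Genic rejection and flank assignment

class _GeneIndex:
    """Sorted gene intervals with O(log n) overlap and flank queries."""

    def __init__(self, genome: Genome):
        self.genes = genome.genes  # sorted by start
        self.starts = [g.start for g in self.genes]
        ends = [g.end for g in self.genes]
        # prefix max of ends supports overlap queries on possibly nested genes
        self.prefix_max_end = []
        running = 0
        for e in ends:
            running = max(running, e)
            self.prefix_max_end.append(running)

    def overlaps(self, start: int, end: int) -> bool:
        """Does [start, end) overlap any gene by >= 1 nt?"""
        i = bisect_right(self.starts, end - 1)  # genes with g.start < end
        return i > 0 and self.prefix_max_end[i - 1] > start

    def flanks(self, start: int, end: int):
        """(left gene, right gene) around an intergenic interval; None at
        contig edges.  Left = greatest end <= start, right = least start >= end."""
        left = None
        for j in range(bisect_right(self.starts, start) - 1, -1, -1):
            g = self.genes[j]
            if g.end <= start:
                if left is None or g.end > left.end:
                    left = g
                if self.prefix_max_end[j] <= (left.end if left else 0):
                    break
        i = bisect_right(self.starts, end - 1)
        right = self.genes[i] if i < len(self.genes) else None
        return left, right


def reject_genic(occurrences: list[Occurrence], genome: Genome) -> list[Occurrence]:
    """Drop occurrences whose window overlaps any gene interval by >= 1 nt
    (either strand); input order is preserved."""
    index = _GeneIndex(genome)
    return [occ for occ in occurrences if not index.overlaps(occ.start, occ.end)]


def flanking_genes(occurrence: Occurrence, genome: Genome):
    """Assign the downstream and upstream flanking genes of an intergenic
    occurrence.

    The downstream gene is the flank the occurrence faces (the occurrence
    lies 5' of that gene's start on the gene's strand): the right flank when
    it runs forward (+), the left flank when it runs reverse (-).  For a
    divergent pair (both face it) the gene with the nearer start wins; for a
    convergent pair (neither faces it) the nearer gene wins.  Returns
    (downstream locus_tag or None, upstream locus_tag or None,
    relative_position), where relative_position is occ_start - gene_start for
    a + strand downstream gene and gene_end - (occ_start + width) for a
    - strand one (negative = upstream of the gene start).
    """
    return _assign_flanks(occurrence, _GeneIndex(genome))


def _assign_flanks(occurrence: Occurrence, index: _GeneIndex):
    if index.overlaps(occurrence.start, occurrence.end):
        raise ValueError("flanking_genes requires an intergenic occurrence")
    left, right = index.flanks(occurrence.start, occurrence.end)

    def distance(gene) -> int:
        if gene is None:
            return np.iinfo(np.int64).max
        if gene.start >= occurrence.end:  # right flank; biological start at .start if +
            return gene.start - occurrence.end if gene.strand == 1 else gene.start - occurrence.end
        return occurrence.start - gene.end

    left_faces = left is not None and left.strand == -1
    right_faces = right is not None and right.strand == 1

    if right_faces and not left_faces:
        downstream, upstream = right, left
    elif left_faces and not right_faces:
        downstream, upstream = left, right
    elif right_faces and left_faces:  # divergent pair: nearer biological start
        downstream, upstream = (right, left) if distance(right) <= distance(left) else (left, right)
    else:  # convergent pair or missing flanks: nearer gene
        if right is None and left is None:
            return None, None, 0
        downstream, upstream = (right, left) if distance(right) <= distance(left) else (left, right)
        if downstream is None:
            downstream, upstream = upstream, downstream

    if downstream is None:
        return None, None, 0
    if downstream.strand == 1:
        relative_position = occurrence.start - downstream.start
    else:
        relative_position = downstream.end - (occurrence.start + occurrence.width)
    return (
        downstream.locus_tag,
        upstream.locus_tag if upstream is not None else None,
        int(relative_position),
    )


def aggregate(
    occurrences: list[Occurrence], genome: Genome, motif: DiscoveredMotif
) -> list[AggregatedOccurrence]:
    """Merge intergenic occurrences per downstream gene, in p-value order.

    The first (best-p) occurrence of a downstream gene creates the row and
    fixes its sequence, p, q and relative position; every later occurrence
    with the same downstream gene only increments the row's hit count.
    Indices are the 0-based positions of the downstream/upstream genes in the
    motif's ordered score list, or -1 when absent.  Rows keep creation order.
    """
    if any(
        occurrences[i].pvalue > occurrences[i + 1].pvalue for i in range(len(occurrences) - 1)
    ):
        raise ValueError("occurrences must be sorted ascending by p-value")
    index = _GeneIndex(genome)
    rows: dict[str, AggregatedOccurrence] = {}
    order: list[str] = []
    for occ in occurrences:
        downstream, upstream, relative_position = _assign_flanks(occ, index)
        if downstream is None:
            continue
        if downstream in rows:
            rows[downstream].hit_count += 1
            continue
        rows[downstream] = AggregatedOccurrence(
            downstream_gene=downstream,
            sequence=occ.sequence,
            index_downstream=motif.index_of(downstream),
            index_upstream=motif.index_of(upstream) if upstream is not None else -1,
            pvalue=occ.pvalue,
            qvalue=occ.qvalue,
            hit_count=1,
            relative_position=relative_position,
        )
        order.append(downstream)
    return [rows[tag] for tag in order]


# ---------------------------------------------------------------------------
# Pipeline rounds and iterative expansion

def run_once(
    genome: Genome,
    selection: set[str],
    params: PipelineParams | None = None,
    background: MarkovBackground | None = None,
) -> RunResult:
    """One full round: upstream extraction, discovery, genome scan, genic
    rejection and per-gene aggregation for every discovered motif."""
    params = params or PipelineParams()
    upstream = extract_upstream(
        genome, selection, length=params.upstream_length,
        truncate_at_neighbor=params.truncate_at_neighbor,
    )
    try:
        motifs = discover_zoops(
            upstream,
            nmotifs=params.nmotifs,
            evalue_threshold=params.evalue_threshold,
            widths=params.widths,
            seed=params.seed,
            n_shuffles=params.n_shuffles,
        )
    except MotifInputError as exc:
        return RunResult(status=f"discovery failed: {exc}")
    if not motifs:
        return RunResult(status="no motif passed the E-value threshold")
    if background is None:
        background = build_background(genome, order=params.background_order)
    tables = []
    for motif in motifs:
        occurrences = scan(genome, motif.pwm, background, p_threshold=params.p_threshold)
        intergenic = reject_genic(occurrences, genome)
        tables.append(aggregate(intergenic, genome, motif))
    return RunResult(status="ok", motifs=motifs, tables=tables)


def expand_until_convergence(
    genome: Genome,
    initial_selection: set[str],
    top_k: int = 20,
    max_iter: int = 10,
    params: PipelineParams | None = None,
) -> ExplorationState:
    """Iterate the pipeline, each round adding the top-``top_k`` table genes
    that carry a -1 downstream index, until the top-k window has no -1
    (converged), the selection stops changing, or ``max_iter`` expansions.

    Expansion follows the best (lowest E-value) motif of each round.
    """
    if not initial_selection:
        raise ValueError("initial selection must be non-empty")
    params = params or PipelineParams()
    background = build_background(genome, order=params.background_order)
    selection = set(initial_selection)
    history = [len(selection)]
    iteration = 0
    while True:
        result = run_once(genome, selection, params, background=background)
        if result.status != "ok":
            return ExplorationState(
                selection=selection, iteration=iteration, tables=[],
                converged=False, history=history, status=result.status,
            )
        best_table = result.tables[0]
        window = best_table[:top_k]
        newcomers = {
            row.downstream_gene for row in window if row.index_downstream == -1
        }
        if not newcomers:
            return ExplorationState(
                selection=selection, iteration=iteration, tables=result.tables,
                converged=True, history=history, motifs=result.motifs,
            )
        if iteration >= max_iter or newcomers <= selection:
            return ExplorationState(
                selection=selection, iteration=iteration, tables=result.tables,
                converged=False, history=history, motifs=result.motifs,
            )
        selection |= newcomers
        iteration += 1
        history.append(len(selection))
        log.info("expansion round %d: selection size %d", iteration, len(selection))


# ---------------------------------------------------------------------------
# Table output

TABLE_COLUMNS = [
    "downstream_gene",
    "sequence",
    "index_downstream",
    "index_upstream",
    "p-value",
    "q-value",
    "hit_count",
    "relative_position",
]


def table_frame(table: list[AggregatedOccurrence]) -> pd.DataFrame:
    rows = [
        (
            r.downstream_gene, r.sequence, r.index_downstream, r.index_upstream,
            r.pvalue, r.qvalue, r.hit_count, r.relative_position,
        )
        for r in table
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_tables(tables: list[list[AggregatedOccurrence]], out_dir) -> list[str]:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, table in enumerate(tables, start=1):
        path = out_dir / f"motif_{i}.tsv"
        table_frame(table).to_csv(path, sep="\t", index=False)
        written.append(str(path))
    return written
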