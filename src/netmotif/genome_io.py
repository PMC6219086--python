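"""Genome and annotation handling.

GenBank parsing and writing, strand-aware upstream-region extraction, and
order-k Markov background estimation (default order 3, counted on both
strands with pseudocount smoothing).

Coordinates are 0-based half-open on the forward strand everywhere inside
the package; the 1-based inclusive convention appears only at the GenBank
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_IUPAC_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)
_IUPAC_SET = set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")


class GenomeFormatError(ValueError):
    """Raised on malformed GenBank input or inconsistent annotations."""


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC DNA alphabet (N maps to N)."""
    bad = set(seq) - _IUPAC_SET
    if bad:
        raise ValueError(f"non-IUPAC DNA characters: {sorted(bad)!r}")
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 (int8); any other character becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval: 0-based half-open on the forward strand."""

    locus_tag: str
    start: int
    end: int
    strand: int  # +1 / -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.locus_tag}: invalid interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"{self.locus_tag}: strand must be +1 or -1")


@dataclass
class Genome:
    """A single-contig DNA sequence with sorted gene annotations."""

    id: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.locus_tag))
        seen: set[str] = set()
        for gene in self.genes:
            if gene.end > len(self.sequence):
                raise GenomeFormatError(
                    f"{gene.locus_tag}: interval end {gene.end} exceeds genome "
                    f"length {len(self.sequence)}"
                )
            if gene.locus_tag in seen:
                raise GenomeFormatError(f"duplicate locus_tag {gene.locus_tag!r}")
            seen.add(gene.locus_tag)

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, locus_tag: str) -> GeneAnnotation:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)


# ---------------------------------------------------------------------------
# GenBank I/O

def read_genbank(path) -> Genome:
    """Read a single-record GenBank flat file into a Genome.

    One GeneAnnotation is produced per ``gene`` feature carrying a locus_tag;
    ``CDS`` features are used for locus_tags that have no gene feature.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        sequence = str(record.seq).upper()
    except Exception as exc:  # undefined sequence (no ORIGIN block)
        raise GenomeFormatError(f"{path}: GenBank record has no sequence") from exc
    if not sequence:
        raise GenomeFormatError(f"{path}: GenBank record has no sequence")

    genes: dict[str, GeneAnnotation] = {}

    def collect(feature_type: str) -> None:
        for feat in record.features:
            if feat.type != feature_type:
                continue
            tags = feat.qualifiers.get("locus_tag") or feat.qualifiers.get("gene")
            if not tags:
                continue
            locus_tag = tags[0]
            if locus_tag in genes:
                if feature_type == "gene":
                    raise GenomeFormatError(f"duplicate locus_tag {locus_tag!r}")
                continue  # CDS shadowed by its gene feature
            strand = -1 if feat.location.strand == -1 else 1
            genes[locus_tag] = GeneAnnotation(
                locus_tag=locus_tag,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
            )

    collect("gene")
    collect("CDS")
    return Genome(id=record.id or record.name or "genome", sequence=sequence,
                  genes=list(genes.values()))


def write_genbank(genome: Genome, path) -> None:
    """Write a Genome as a GenBank flat file with one gene feature per
    annotation (plus a mirroring CDS feature, as annotation pipelines emit)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace("|", "_"),
        description="synthetic genome",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for gene in genome.genes:
        loc = FeatureLocation(gene.start, gene.end, strand=gene.strand)
        qualifiers = {"locus_tag": [gene.locus_tag]}
        record.features.append(SeqFeature(loc, type="gene", qualifiers=dict(qualifiers)))
        record.features.append(SeqFeature(loc, type="CDS", qualifiers=dict(qualifiers)))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs (uppercased)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: list[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Upstream extraction

def extract_upstream(
    genome: Genome,
    locus_tags,
    length: int = 300,
    truncate_at_neighbor: bool = True,
) -> list[tuple[str, str]]:
    """Extract up-to-``length``-nt upstream regions for the given genes.

    For a + strand gene the region is ``[max(0, start-length), start)`` read
    forward; for a - strand gene it is ``[end, min(L, end+length))``
    reverse-complemented, so the returned sequence always runs 5'->3' toward
    the gene start.  With ``truncate_at_neighbor`` the region is clipped so it
    does not overlap any other gene's interval.  Zero-length regions are
    omitted with a warning.  Output is sorted by locus_tag.
    """
    unknown = set(locus_tags) - {g.locus_tag for g in genome.genes}
    if unknown:
        raise KeyError(f"unknown locus_tags: {sorted(unknown)}")
    out: list[tuple[str, str]] = []
    for locus_tag in sorted(set(locus_tags)):
        gene = genome.gene(locus_tag)
        if gene.strand == 1:
            lo, hi = max(0, gene.start - length), gene.start
            if truncate_at_neighbor:
                for other in genome.genes:
                    if other.locus_tag == locus_tag:
                        continue
                    if other.start < hi and other.end > lo:
                        lo = max(lo, min(other.end, hi))
            region = genome.sequence[lo:hi]
        else:
            lo, hi = gene.end, min(len(genome), gene.end + length)
            if truncate_at_neighbor:
                for other in genome.genes:
                    if other.locus_tag == locus_tag:
                        continue
                    if other.start < hi and other.end > lo:
                        hi = min(hi, max(other.start, lo))
            region = revcomp(genome.sequence[lo:hi])
        if not region:
            log.warning("upstream region of %s is empty; omitted", locus_tag)
            continue
        out.append((locus_tag, region))
    return out


# ---------------------------------------------------------------------------
# Markov background

class MarkovBackground:
    """Order-k Markov model over {A,C,G,T} with pseudocount smoothing.

    ``conditionals`` maps every length-``order`` context string to a length-4
    probability vector over the next base; ``marginal`` is the order-0 base
    distribution.  Both are estimated from counts on both strands.
    """

    PSEUDOCOUNT = 0.1

    def __init__(self, order: int, conditional_matrix: np.ndarray, marginal: np.ndarray):
        if order < 0:
            raise ValueError("order must be >= 0")
        self.order = order
        self.conditional_matrix = np.asarray(conditional_matrix, dtype=float)
        expected_shape = (4**order, 4)
        if self.conditional_matrix.shape != expected_shape:
            raise ValueError(
                f"conditional matrix shape {self.conditional_matrix.shape} != {expected_shape}"
            )
        self.marginal = np.asarray(marginal, dtype=float)
        if not np.allclose(self.conditional_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")
        if not np.isclose(self.marginal.sum(), 1.0, atol=1e-9):
            raise ValueError("marginal must sum to 1")

    # -- context helpers ---------------------------------------------------

    @staticmethod
    def context_string(code: int, order: int) -> str:
        chars = []
        for _ in range(order):
            chars.append(BASES[code % 4])
            code //= 4
        return "".join(reversed(chars))

    @property
    def conditionals(self) -> dict[str, np.ndarray]:
        return {
            self.context_string(code, self.order): self.conditional_matrix[code]
            for code in range(4**self.order)
        }

    def probability(self, context: str, base: str) -> float:
        code = 0
        for ch in context:
            code = code * 4 + _BASE_INDEX[ch]
        return float(self.conditional_matrix[code, _BASE_INDEX[base]])

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovBackground":
        return cls(order, np.full((4**order, 4), 0.25), np.full(4, 0.25))

    # -- sampling (used by the synthetic generators) -----------------------

    def sample(self, n: int, rng: np.random.Generator) -> str:
        """Draw an n-nt sequence from the chain (marginal warm-up)."""
        out = np.empty(n, dtype=np.int8)
        code = 0
        for i in range(n):
            if i < self.order:
                probs = self.marginal
            else:
                probs = self.conditional_matrix[code]
            base = int(rng.choice(4, p=probs))
            out[i] = base
            if self.order > 0:
                code = (code * 4 + base) % (4**self.order)
                if i + 1 < self.order:
                    pass  # context still warming up; harmless
        return "".join(BASES[b] for b in out)

    # -- text I/O (context + 4 probabilities per line) ---------------------

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# order {self.order} background; columns: context A C G T\n")
            fh.write("- " + " ".join(f"{p:.6e}" for p in self.marginal) + "\n")
            for code in range(4**self.order):
                context = self.context_string(code, self.order) or "-"
                probs = " ".join(f"{p:.6e}" for p in self.conditional_matrix[code])
                fh.write(f"{context} {probs}\n")

    @classmethod
    def read(cls, path) -> "MarkovBackground":
        marginal = None
        rows: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cells = line.split()
                context, probs = cells[0], np.array([float(c) for c in cells[1:5]])
                if marginal is None and context == "-":
                    marginal = probs
                else:
                    rows["" if context == "-" else context] = probs
        if marginal is None:
            raise GenomeFormatError(f"{path}: missing marginal line")
        order = len(next(iter(rows))) if rows else 0
        matrix = np.empty((4**order, 4))
        for context, probs in rows.items():
            code = 0
            for ch in context:
                code = code * 4 + _BASE_INDEX[ch]
            matrix[code] = probs
        return cls(order, matrix, marginal)


def _kmer_counts(codes: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """(context, next-base) counts and mononucleotide counts; positions
    touching an ambiguous base are excluded."""
    mono = np.zeros(4)
    for b in range(4):
        mono[b] = int(np.sum(codes == b))
    counts = np.zeros((4**order, 4))
    n = len(codes)
    if n < order + 1:
        return counts, mono
    valid = codes >= 0
    ctx = np.zeros(n - order, dtype=np.int64)
    ok = np.ones(n - order, dtype=bool)
    for j in range(order):
        ctx = ctx * 4 + np.where(valid[j : n - order + j], codes[j : n - order + j], 0)
        ok &= valid[j : n - order + j]
    nxt = codes[order:]
    ok &= valid[order:]
    np.add.at(counts, (ctx[ok], nxt[ok]), 1)
    return counts, mono


def build_background(genome, order: int = 3) -> MarkovBackground:
    """Estimate an order-``order`` background from a genome (or raw string).

    Counts (k+1)-mers over both strands, excludes windows containing
    ambiguous bases, and smooths with pseudocount 0.1 per cell.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    sequence = genome.sequence if isinstance(genome, Genome) else str(genome)
    if len(sequence) <= order:
        raise ValueError("genome shorter than background order")
    pc = MarkovBackground.PSEUDOCOUNT
    counts = np.zeros((4**order, 4))
    mono = np.zeros(4)
    for strand_seq in (sequence, revcomp(sequence)):
        c, m = _kmer_counts(encode_dna(strand_seq), order)
        counts += c
        mono += m
    conditional = (counts + pc) / (counts.sum(axis=1, keepdims=True) + 4 * pc)
    marginal = (mono + pc) / (mono.sum() + 4 * pc)
    return MarkovBackground(order, conditional, marginal)
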