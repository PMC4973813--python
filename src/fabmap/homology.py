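"""Reciprocal-best-hit ortholog anchoring from tabular homology hits.

Hits are consumed in the standard 12-column tabular format (query,
subject, %identity, alignment length, mismatches, gap opens, qstart,
qend, sstart, send, e-value, bit score).  Coordinates in files are
1-based inclusive; ``sstart > send`` encodes a minus-strand hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "HomologyHit",
    "OrthologAnchor",
    "parse_hits",
    "reciprocal_best_hits",
    "anchor_to_ortholog",
]

_GENE_ID_RE = re.compile(r"^Mt(\d)g(\d+)$")


@dataclass(frozen=True)
class HomologyHit:
    """One HSP from a pairwise homology search (tabular row)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def minus_strand(self) -> bool:
        return self.subject_start > self.subject_end

    @property
    def subject_range(self) -> tuple[int, int]:
        """Subject interval as 0-based half-open (strand-normalised)."""
        lo, hi = sorted((self.subject_start, self.subject_end))
        return lo - 1, hi


@dataclass(frozen=True)
class OrthologAnchor:
    """A contig pair tied to a single reference gene, or a rejection."""

    contig_a: str
    contig_b: str
    reference_gene_id: str | None
    reference_chromosome: int | None
    status: str  # "accepted" | "rejected"
    reason: str | None = None  # machine-readable when rejected

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def gene_chromosome(gene_id: str) -> int:
    """Chromosome number encoded in a MtXgYYYYYY-style identifier."""
    m = _GENE_ID_RE.match(gene_id)
    if m is None:
        raise ValueError(f"gene id {gene_id!r} does not match MtXgYYYYYY pattern")
    return int(m.group(1))


def parse_hits(stream: Iterable[str]) -> list[HomologyHit]:
    """Parse 12+ column tabular hit lines; '#' comment lines are skipped."""
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"line {lineno}: expected >=12 fields, got {len(fields)}")
        try:
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    query_start=int(fields[6]),
                    query_end=int(fields[7]),
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def _qualifying(hits: Iterable[HomologyHit], min_len: int, max_e: float) -> list[HomologyHit]:
    return [h for h in hits if h.alignment_length >= min_len and h.e_value <= max_e]


def _best_subject(hits: Sequence[HomologyHit]) -> str | None:
    """Unique best subject by lowest e-value, then highest bit score.

    Only the best HSP per subject represents that subject.  A residual
    tie between two different subjects means no unique best: None.
    """
    per_subject: dict[str, tuple[float, float]] = {}
    for h in hits:
        key = (h.e_value, -h.bit_score)
        if h.subject_id not in per_subject or key < per_subject[h.subject_id]:
            per_subject[h.subject_id] = key
    if not per_subject:
        return None
    ranked = sorted(per_subject.items(), key=lambda kv: kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def reciprocal_best_hits(
    hits_ab: Iterable[HomologyHit],
    hits_ba: Iterable[HomologyHit],
    min_len: int = 100,
    max_e: float = 1e-30,
) -> list[tuple[str, str]]:
    """Unique reciprocal best hits between two sequence sets.

    A pair (a, b) qualifies iff, after discarding hits shorter than
    ``min_len`` or weaker than ``max_e``, b is the unique best hit of a
    in the A-vs-B search and a is the unique best hit of b in B-vs-A.
    """
    ab = _qualifying(hits_ab, min_len, max_e)
    ba = _qualifying(hits_ba, min_len, max_e)
    by_query_ab: dict[str, list[HomologyHit]] = {}
    for h in ab:
        by_query_ab.setdefault(h.query_id, []).append(h)
    by_query_ba: dict[str, list[HomologyHit]] = {}
    for h in ba:
        by_query_ba.setdefault(h.query_id, []).append(h)

    pairs = []
    for a, hits_a in sorted(by_query_ab.items()):
        b = _best_subject(hits_a)
        if b is None:
            continue
        back = _best_subject(by_query_ba.get(b, []))
        if back == a:
            pairs.append((a, b))
    return pairs


def anchor_to_ortholog(
    pair: tuple[str, str],
    hits_to_genes: Iterable[HomologyHit],
    min_len: int = 100,
    max_e: float = 1e-30,
) -> OrthologAnchor:
    """Anchor a contig pair to a single reference gene.

    Accepted iff both contigs have qualifying hits to exactly one gene
    and it is the same gene.  Qualifying hits to more than one gene for
    either contig reject the pair (multi_gene); a contig without any
    qualifying hit rejects it (no_hit).
    """
    contig_a, contig_b = pair
    genes: dict[str, set[str]] = {contig_a: set(), contig_b: set()}
    for h in _qualifying(hits_to_genes, min_len, max_e):
        if h.query_id in genes:
            genes[h.query_id].add(h.subject_id)
    for contig in (contig_a, contig_b):
        if not genes[contig]:
            return OrthologAnchor(contig_a, contig_b, None, None, "rejected", "no_hit")
        if len(genes[contig]) > 1:
            return OrthologAnchor(contig_a, contig_b, None, None, "rejected", "multi_gene")
    (gene_a,) = genes[contig_a]
    (gene_b,) = genes[contig_b]
    if gene_a != gene_b:
        return OrthologAnchor(contig_a, contig_b, None, None, "rejected", "multi_gene")
    return OrthologAnchor(contig_a, contig_b, gene_a, gene_chromosome(gene_a), "accepted")
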