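"""Pairwise global alignment and a minimal k-mer seeded similarity search.

The global aligner wraps :class:`Bio.Align.PairwiseAligner` (affine gap
scoring, global mode) and exposes the gapped strings plus a per-column
coordinate map.  The k-mer search exists only so that synthetic
fixtures are self-contained: it produces pseudo-hits in the same shape
as parsed tabular hits, good enough to drive the RBH and paralog
filters on simulated transcriptomes.  It is not a substitute for a real
search engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

from .homology import HomologyHit

__all__ = ["PairwiseAlignment", "global_align", "kmer_hits"]

_IUPAC = set("ACGTRYSWKMBDHVN")

GAP = -1  # sentinel in column maps


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences.

    ``column_map`` holds, per alignment column, the 0-based offset into
    each input sequence or ``GAP`` (-1) where that sequence is gapped.
    Degapping ``aligned_a``/``aligned_b`` reproduces the inputs exactly.
    """

    aligned_a: str
    aligned_b: str
    score: float
    column_map: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences differ in length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


def _column_map(aligned_a: str, aligned_b: str) -> tuple[tuple[int, int], ...]:
    out = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        pa = GAP if ca == "-" else ia
        pb = GAP if cb == "-" else ib
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        out.append((pa, pb))
    return tuple(out)


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    A gap of length L costs ``gap_open + L * gap_extend``.  End gaps are
    penalised (true global alignment).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # PairwiseAligner charges open_gap_score for the first gapped base
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend

    aln = aligner.align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ga, gb, float(aln.score), _column_map(ga, gb))


def _kmer_positions(seq: str, k: int) -> Mapping[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def kmer_hits(
    query_id: str,
    query: str,
    subjects: Mapping[str, str],
    k: int = 15,
    min_kmers: int = 5,
    max_gap: int = 300,
) -> list[HomologyHit]:
    """Shared-k-mer pseudo-hits of one query against a set of subjects.

    Matched subject positions are clustered into loci separated by more
    than ``max_gap`` bases; each locus with at least ``min_kmers``
    seed matches yields one pseudo-hit whose coordinates span the locus,
    with ``e_value`` 0 and ``bit_score`` = seed count (so downstream
    e-value/length thresholds behave sensibly).
    """
    query = query.upper()
    qindex = _kmer_positions(query, k)
    hits: list[HomologyHit] = []
    for sid, sseq in subjects.items():
        sseq = sseq.upper()
        matches: list[tuple[int, int]] = []  # (subject pos, query pos)
        for i in range(len(sseq) - k + 1):
            kmer = sseq[i : i + k]
            if kmer in qindex:
                matches.append((i, qindex[kmer][0]))
        if len(matches) < min_kmers:
            continue
        matches.sort()
        # cluster by subject position into separate loci
        clusters: list[list[tuple[int, int]]] = [[matches[0]]]
        for m in matches[1:]:
            if m[0] - clusters[-1][-1][0] > max_gap:
                clusters.append([m])
            else:
                clusters[-1].append(m)
        for cluster in clusters:
            if len(cluster) < min_kmers:
                continue
            s_lo = cluster[0][0]
            s_hi = cluster[-1][0] + k
            q_lo = min(q for _, q in cluster)
            q_hi = max(q for _, q in cluster) + k
            ident = 100.0 * len(cluster) / max(1, s_hi - s_lo - k + 1)
            hits.append(
                HomologyHit(
                    query_id=query_id,
                    subject_id=sid,
                    percent_identity=min(100.0, ident),
                    alignment_length=s_hi - s_lo,
                    e_value=0.0,
                    bit_score=float(len(cluster)),
                    query_start=q_lo + 1,
                    query_end=q_hi,
                    subject_start=s_lo + 1,
                    subject_end=s_hi,
                )
            )
    return hits
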