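"""Candidate SNP mining from aligned contig pairs.

Anchored contig pairs are globally aligned; every substitution column
becomes a candidate, which must then survive three filters:

* flank   — the variant sits at least ``min_flank`` bases from both
            ends of both contigs;
* intron  — no reference intron junction within ``min_intron_dist``
            bases of the variant; flanks are truncated at the nearest
            junctions beyond that distance;
* paralog / multi-locus — the flanking consensus matches one contig
            per transcriptome and one locus on one reference
            chromosome.

Passing candidates are named ``Vf_<gene>_<serial>`` with a three-digit
serial unique per anchor gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import GAP, PairwiseAlignment, global_align, kmer_hits
from .annotation import GeneModel
from .homology import HomologyHit, OrthologAnchor

__all__ = [
    "CandidateSNP",
    "GeneStructureProjection",
    "call_candidate_snps",
    "project_gene_structure",
    "apply_intron_rule",
    "exclude_multilocus",
    "name_assay",
    "mine",
]

_AMBIGUITY = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}
_BASES = set("ACGT")


@dataclass
class CandidateSNP:
    """A mined biallelic variant with its consensus context."""

    snp_id: str
    anchor: OrthologAnchor | None
    pos_a: int  # 0-based offset on contig A
    pos_b: int
    allele_a: str
    allele_b: str
    consensus: str  # one char per alignment column; variant = allele_a
    consensus_pos: int
    flank_left: int
    flank_right: int
    secondary_snps: int = 0
    status: str = "pass"
    reason: str | None = None
    assay_name: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("alleles must differ")
        if self.allele_a not in _BASES or self.allele_b not in _BASES:
            raise ValueError("alleles must be unambiguous bases")

    @property
    def passed(self) -> bool:
        return self.status == "pass"

    def fail(self, reason: str) -> None:
        self.status, self.reason = "fail", reason

    @property
    def consensus_flank(self) -> str:
        left = self.consensus[self.consensus_pos - self.flank_left : self.consensus_pos]
        right = self.consensus[self.consensus_pos + 1 : self.consensus_pos + 1 + self.flank_right]
        return f"{left}[{self.allele_a}/{self.allele_b}]{right}"

    @property
    def flank_query_sequence(self) -> str:
        """Flank with the A allele at the variant, for similarity searches."""
        left = self.consensus[self.consensus_pos - self.flank_left : self.consensus_pos]
        right = self.consensus[self.consensus_pos + 1 : self.consensus_pos + 1 + self.flank_right]
        return left + self.allele_a + right


@dataclass(frozen=True)
class GeneStructureProjection:
    """Reference intron junctions projected onto a contig.

    Each insertion point is the 0-based contig offset of the last base
    before an intron; the intron sits between that base and the next.
    """

    source_gene: str
    intron_insertion_points: tuple[int, ...]

    def __post_init__(self) -> None:
        pts = self.intron_insertion_points
        if any(nxt <= cur for cur, nxt in zip(pts, pts[1:])):
            raise ValueError("insertion points must be strictly increasing")


def _consensus_char(ca: str, cb: str) -> str:
    if ca == cb:
        return ca
    if ca == "-":
        return cb
    if cb == "-":
        return ca
    return _AMBIGUITY.get(frozenset((ca, cb)), "N")


def call_candidate_snps(
    aln: PairwiseAlignment,
    min_flank: int = 50,
    contig_a: str = "a",
    contig_b: str = "b",
    anchor: OrthologAnchor | None = None,
) -> list[CandidateSNP]:
    """One candidate per substitution column of a contig-pair alignment.

    Gap columns are never variants.  A candidate fails the flank rule
    when its offset on either contig lies closer than ``min_flank``
    bases to either sequence end.
    """
    ga, gb = aln.aligned_a, aln.aligned_b
    len_a, len_b = len(aln.seq_a), len(aln.seq_b)
    consensus = "".join(_consensus_char(ca, cb) for ca, cb in zip(ga, gb))
    subs = [
        i
        for i, (ca, cb) in enumerate(zip(ga, gb))
        if ca != cb and ca in _BASES and cb in _BASES
    ]
    out = []
    for col in subs:
        pos_a, pos_b = aln.column_map[col]
        assert pos_a != GAP and pos_b != GAP
        snp = CandidateSNP(
            snp_id=f"{contig_a}:{pos_a}",
            anchor=anchor,
            pos_a=pos_a,
            pos_b=pos_b,
            allele_a=ga[col],
            allele_b=gb[col],
            consensus=consensus,
            consensus_pos=col,
            flank_left=min(col, min_flank * 4),
            flank_right=min(len(consensus) - col - 1, min_flank * 4),
            secondary_snps=len(subs) - 1,
        )
        margin = min(pos_a, len_a - 1 - pos_a, pos_b, len_b - 1 - pos_b)
        if margin < min_flank:
            snp.fail("flank")
        # flanks never extend past neighbouring indel-free context limits
        snp.flank_left = min(snp.flank_left, pos_a, pos_b)
        snp.flank_right = min(
            snp.flank_right, len_a - 1 - pos_a, len_b - 1 - pos_b
        )
        out.append(snp)
    return out


def project_gene_structure(
    anchor_alignment: HomologyHit,
    gene_model: GeneModel | Sequence[tuple[int, int]],
) -> GeneStructureProjection:
    """Map reference intron junctions through a contig-vs-transcript hit.

    ``anchor_alignment`` is the (assumed colinear) hit of the contig
    (query) against the gene's spliced transcript (subject), 1-based
    inclusive on both sides.
    """
    if not isinstance(gene_model, GeneModel):
        exons = list(gene_model)
        gene_model = GeneModel(
            gene_id="anonymous",
            chrom="?",
            start=min(s for s, _ in exons),
            end=max(e for _, e in exons),
            exons=exons,
        )
    h = anchor_alignment
    points = []
    for b in gene_model.internal_boundaries():  # b = 1-based pos of last exon base
        if h.subject_start <= b < h.subject_end:
            points.append(b - h.subject_start + h.query_start - 1)
    return GeneStructureProjection(gene_model.gene_id, tuple(points))


def apply_intron_rule(
    snp: CandidateSNP,
    proj: GeneStructureProjection,
    min_dist: int = 50,
) -> CandidateSNP:
    """Fail variants near an intron junction; truncate flanks at the rest.

    Distance is counted in bases between the variant and the junction:
    a junction immediately following base p is ``p - pos`` bases to the
    right of a variant at pos (p >= pos) or ``pos - p - 1`` bases to
    its left.  After truncation the flank rule is re-checked.
    """
    if not snp.passed:
        return snp
    pos = snp.pos_a
    left = [p for p in proj.intron_insertion_points if p < pos]
    right = [p for p in proj.intron_insertion_points if p >= pos]
    if left:
        d = pos - max(left) - 1
        if d < min_dist:
            snp.fail("intron_near")
            return snp
        snp.flank_left = min(snp.flank_left, d)
    if right:
        d = min(right) - pos
        if d < min_dist:
            snp.fail("intron_near")
            return snp
        snp.flank_right = min(snp.flank_right, d)
    if snp.flank_left < min_dist or snp.flank_right < min_dist:
        snp.fail("flank")
    return snp


def _overlap(r1: tuple[int, int], r2: tuple[int, int]) -> bool:
    return r1[0] < r2[1] and r2[0] < r1[1]


def exclude_multilocus(
    snp: CandidateSNP,
    hits_vs_a: Iterable[HomologyHit],
    hits_vs_b: Iterable[HomologyHit],
    hits_vs_chromosomes: Iterable[HomologyHit],
    max_e: float = 1e-30,
) -> CandidateSNP:
    """Reject flanks matching extra contigs or extra reference loci."""
    if not snp.passed:
        return snp
    for hits in (hits_vs_a, hits_vs_b):
        subjects = {h.subject_id for h in hits if h.e_value <= max_e}
        if len(subjects) > 1:
            snp.fail("paralog")
            return snp
    chrom_hits = [h for h in hits_vs_chromosomes if h.e_value <= max_e]
    chroms = {h.subject_id for h in chrom_hits}
    if len(chroms) > 1:
        snp.fail("multi_locus")
        return snp
    # >1 non-overlapping range on the single chromosome = extra locus
    ranges = sorted(h.subject_range for h in chrom_hits)
    loci: list[tuple[int, int]] = []
    for r in ranges:
        if loci and _overlap(loci[-1], r):
            loci[-1] = (loci[-1][0], max(loci[-1][1], r[1]))
        else:
            loci.append(r)
    if len(loci) > 1:
        snp.fail("multi_locus")
    return snp


def name_assay(anchor: OrthologAnchor, serial: int) -> str:
    """Assay name Vf_<gene>_<zero-padded serial>, serial in 1..999."""
    if not anchor.accepted:
        raise ValueError("cannot name an assay on a rejected anchor")
    if not 1 <= serial <= 999:
        raise ValueError(f"serial {serial} out of range 1..999")
    return f"Vf_{anchor.reference_gene_id}_{serial:03d}"


@dataclass
class MiningResult:
    candidates: list[CandidateSNP] = field(default_factory=list)

    @property
    def passing(self) -> list[CandidateSNP]:
        return [s for s in self.candidates if s.passed]


def mine(
    transcriptome_a: Mapping[str, str],
    transcriptome_b: Mapping[str, str],
    anchors: Iterable[OrthologAnchor],
    genes: Mapping[str, GeneModel],
    chromosome_seqs: Mapping[str, str] | None = None,
    reference_seqs: Mapping[str, str] | None = None,
    min_flank: int = 50,
    min_intron_dist: int = 50,
    max_e: float = 1e-30,
) -> MiningResult:
    """Run the full mining pipeline over accepted anchors.

    The intron filter projects junctions through a k-mer seeded hit of
    contig A on the spliced reference transcript; the paralog and
    multi-locus filters search the flanking consensus against both full
    transcriptomes and (when ``reference_seqs`` is given) the reference
    chromosomes.
    """
    result = MiningResult()
    serials: dict[str, int] = {}
    for anchor in anchors:
        if not anchor.accepted:
            continue
        seq_a = transcriptome_a[anchor.contig_a]
        seq_b = transcriptome_b[anchor.contig_b]
        aln = global_align(seq_a, seq_b)
        snps = call_candidate_snps(
            aln, min_flank, anchor.contig_a, anchor.contig_b, anchor
        )
        gene = genes.get(anchor.reference_gene_id)
        proj = None
        if gene is not None and chromosome_seqs is not None:
            transcript = gene.spliced(chromosome_seqs[gene.chrom])
            thits = kmer_hits(anchor.contig_a, seq_a, {gene.gene_id: transcript})
            if thits:
                best = max(thits, key=lambda h: h.bit_score)
                # hit is transcript-vs-contig inverted: query=contig
                proj = project_gene_structure(best, gene)
        for snp in snps:
            if proj is not None:
                apply_intron_rule(snp, proj, min_intron_dist)
            if snp.passed:
                flank = snp.flank_query_sequence
                hits_a = kmer_hits("flank", flank, transcriptome_a)
                hits_b = kmer_hits("flank", flank, transcriptome_b)
                hits_chrom: list[HomologyHit] = []
                if reference_seqs is not None:
                    hits_chrom = kmer_hits("flank", flank, reference_seqs)
                exclude_multilocus(snp, hits_a, hits_b, hits_chrom, max_e)
            if snp.passed and anchor.accepted:
                serial = serials.get(anchor.reference_gene_id, 0) + 1
                serials[anchor.reference_gene_id] = serial
                snp.assay_name = name_assay(anchor, serial)
            result.candidates.append(snp)
    return result
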