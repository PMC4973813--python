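"""Marker-to-reference synteny links, colinear blocks and interval queries."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import GeneModel
from .consensus import ConsensusMap
from .homology import HomologyHit, gene_chromosome

__all__ = [
    "SyntenyLink",
    "SyntenyBlock",
    "build_links",
    "detect_blocks",
    "interval_gene_content",
]

_NAME_GENE_RE = re.compile(r"^Vf_(Mt\dg\d+)_\d+$")


@dataclass(frozen=True)
class SyntenyLink:
    marker: str
    vf_group: str
    vf_pos: float  # cM
    ref_gene: str
    ref_chromosome: int
    ref_pos: float  # bp, gene midpoint
    e_value: float
    name_derived: bool = False


@dataclass
class SyntenyBlock:
    vf_group: str
    ref_chromosome: int
    links: list[SyntenyLink]
    orientation: str  # "+" | "-"

    @property
    def cm_span(self) -> tuple[float, float]:
        ps = [l.vf_pos for l in self.links]
        return min(ps), max(ps)

    @property
    def bp_span(self) -> tuple[float, float]:
        ps = [l.ref_pos for l in self.links]
        return min(ps), max(ps)


def build_links(
    cm: ConsensusMap,
    marker_hits: Iterable[HomologyHit],
    gene_coords: Mapping[str, GeneModel],
    max_e: float = 1e-37,
    warnings: list[str] | None = None,
) -> list[SyntenyLink]:
    """One link per mapped marker with a qualifying best hit to a gene.

    Markers named ``Vf_MtXgNNNNNN_*`` without any qualifying hit fall
    back to the gene id embedded in their name (flagged name-derived).
    Links whose gene is absent from the annotation are dropped with a
    warning.
    """
    best: dict[str, HomologyHit] = {}
    for h in marker_hits:
        if h.e_value > max_e:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bit_score) < (cur.e_value, -cur.bit_score):
            best[h.query_id] = h
    links = []
    for group in cm.groups:
        for locus in group.loci:
            for marker in locus.markers:
                gene_id: str | None = None
                e_value = 0.0
                name_derived = False
                if marker in best:
                    gene_id = best[marker].subject_id
                    e_value = best[marker].e_value
                else:
                    m = _NAME_GENE_RE.match(marker)
                    if m:
                        gene_id = m.group(1)
                        name_derived = True
                if gene_id is None:
                    continue
                gene = gene_coords.get(gene_id)
                if gene is None:
                    if warnings is not None:
                        warnings.append(
                            f"{marker}: gene {gene_id} absent from annotation; link dropped"
                        )
                    continue
                links.append(
                    SyntenyLink(
                        marker=marker,
                        vf_group=group.name,
                        vf_pos=locus.position,
                        ref_gene=gene_id,
                        ref_chromosome=gene_chromosome(gene_id),
                        ref_pos=gene.midpoint,
                        e_value=e_value,
                        name_derived=name_derived,
                    )
                )
    return links


def _sequential_chains(
    links: Sequence[SyntenyLink], max_skip: int
) -> list[tuple[list[int], int]]:
    """Greedy map-order chaining; returns (index chain, trend sign) pairs.

    A chain starts at the first unchained link; the trend is set by its
    first extension and each further link must continue it.  Up to
    ``max_skip`` consecutive off-trend links are tolerated — skipped,
    not consumed, so they can seed later chains.
    """
    remaining = list(range(len(links)))
    chains: list[tuple[list[int], int]] = []
    while remaining:
        chain = [remaining[0]]
        sign = 0
        skips = 0
        for j in remaining[1:]:
            delta = links[j].ref_pos - links[chain[-1]].ref_pos
            if sign == 0:
                if delta != 0:
                    sign = 1 if delta > 0 else -1
                chain.append(j)
                skips = 0
            elif sign * delta > 0 or delta == 0:
                chain.append(j)
                skips = 0
            else:
                skips += 1
                if skips > max_skip:
                    break
        chains.append((chain, sign if sign else 1))
        in_chain = set(chain)
        remaining = [i for i in remaining if i not in in_chain]
    return chains


def _refine_boundaries(
    chains: list[tuple[list[int], int]], links: Sequence[SyntenyLink]
) -> None:
    """Move a chain's terminal link to the next chain when it fits better.

    An inversion breakpoint leaves the first link of the reversed
    segment attached to the preceding chain (it still continues that
    trend); reassign it when it is closer in reference space to the
    next chain and continues that chain's trend.
    """
    for k in range(len(chains) - 1):
        chain, sign = chains[k]
        nxt, nsign = chains[k + 1]
        if len(chain) < 3 or len(nxt) < 2:
            continue
        last = links[chain[-1]]
        gap_own = abs(last.ref_pos - links[chain[-2]].ref_pos)
        gap_next = abs(links[nxt[0]].ref_pos - last.ref_pos)
        fits_next = nsign * (links[nxt[0]].ref_pos - last.ref_pos) > 0
        if fits_next and gap_next < gap_own:
            nxt.insert(0, chain.pop())


def detect_blocks(
    links: Iterable[SyntenyLink],
    min_block: int = 3,
    max_skip: int = 2,
) -> list[SyntenyBlock]:
    """Colinear blocks per (map group, reference chromosome).

    Links sorted along the genetic map are chained greedily while the
    reference position continues the chain's monotone trend; up to
    ``max_skip`` consecutive off-trend links are tolerated (skipped,
    left available for later chains).  Chains of at least ``min_block``
    links become blocks, oriented by the trend sign.
    """
    by_pair: dict[tuple[str, int], list[SyntenyLink]] = {}
    for l in links:
        by_pair.setdefault((l.vf_group, l.ref_chromosome), []).append(l)
    blocks = []
    for (group, chrom), pair_links in sorted(by_pair.items()):
        pair_links.sort(key=lambda l: (l.vf_pos, l.marker))
        chains = _sequential_chains(pair_links, max_skip)
        _refine_boundaries(chains, pair_links)
        for chain, sign in chains:
            if len(chain) < min_block:
                continue
            blocks.append(
                SyntenyBlock(
                    vf_group=group,
                    ref_chromosome=chrom,
                    links=[pair_links[i] for i in chain],
                    orientation="+" if sign > 0 else "-",
                )
            )
    return blocks


def interval_gene_content(
    flank_a: str,
    flank_b: str,
    links: Iterable[SyntenyLink],
    genes: Iterable[GeneModel],
    keyword: str | None = None,
) -> tuple[list[GeneModel], tuple[float, float]]:
    """Reference genes spanned by the interval between two linked markers.

    Both flanking markers must link to the same reference chromosome.
    Genes whose spans fall within the inclusive interval between the two
    linked gene positions are returned ordered by position; ``keyword``
    filters on the annotation text (case-insensitive).
    """
    by_marker = {l.marker: l for l in links}
    try:
        la, lb = by_marker[flank_a], by_marker[flank_b]
    except KeyError as exc:
        raise ValueError(f"flanking marker without a synteny link: {exc}") from exc
    if la.ref_chromosome != lb.ref_chromosome:
        raise ValueError(
            "interval not syntenic: flanks link to reference chromosomes "
            f"{la.ref_chromosome} and {lb.ref_chromosome}"
        )
    lo, hi = sorted((la.ref_pos, lb.ref_pos))
    # the flanking genes themselves define the interval ends (inclusive)
    out = []
    for g in genes:
        if gene_chromosome_safe(g.gene_id) != la.ref_chromosome:
            continue
        if g.gene_id in (la.ref_gene, lb.ref_gene) or (lo <= g.midpoint <= hi):
            out.append(g)
    out.sort(key=lambda g: g.midpoint)
    if keyword is not None:
        kw = keyword.lower()
        out = [g for g in out if kw in g.note.lower()]
    return out, (lo, hi)


def gene_chromosome_safe(gene_id: str) -> int | None:
    try:
        return gene_chromosome(gene_id)
    except ValueError:
        return None
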