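"""Gene-model annotation: a small GFF3 reader/writer and coordinate helpers.

GFF3 coordinates are 1-based inclusive on disk and converted to
0-based half-open only inside the helper methods.  Only ``gene`` and
``exon`` features are modelled — that is all the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

__all__ = ["GeneModel", "read_gff3", "write_gff3"]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    note: str = ""

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping or unsorted exons")
        self.exons = ex

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    def internal_boundaries(self) -> list[int]:
        """Transcript offsets (0-based) where an intron interrupts.

        A boundary value t means the intron sits between transcript
        positions t-1 and t.
        """
        bounds, cum = [], 0
        for length in self.exon_lengths[:-1]:
            cum += length
            bounds.append(cum)
        return bounds

    def spliced(self, chrom_seq: str) -> str:
        """Spliced transcript sequence (plus strand gene models)."""
        return "".join(chrom_seq[s - 1 : e] for s, e in self.exons)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(source: str | Path | TextIO) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_gff3(fh)
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for line in source:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
        attributes = _parse_attributes(attrs)
        if ftype == "gene":
            gid = attributes.get("ID")
            if gid is None:
                raise ValueError("gene feature without ID attribute")
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                note=attributes.get("Note", ""),
            )
        elif ftype == "exon":
            parent = attributes.get("Parent")
            if parent is None:
                raise ValueError("exon feature without Parent attribute")
            exons.setdefault(parent, []).append((int(start), int(end)))
    out = []
    for gid, gene in genes.items():
        ex = sorted(exons.get(gid, [(gene.start, gene.end)]))
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.chrom,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=ex,
                note=gene.note,
            )
        )
    return out


def write_gff3(genes: Iterable[GeneModel], dest: str | Path | TextIO) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_gff3(genes, fh)
        return
    dest.write("##gff-version 3\n")
    for g in genes:
        attrs = f"ID={g.gene_id}"
        if g.note:
            attrs += f";Note={g.note}"
        dest.write(
            f"{g.chrom}\tfabmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            dest.write(
                f"{g.chrom}\tfabmap\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
            )
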