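"""File readers/writers for maps, anchors and targets (all plain text)."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd

from .consensus import ConsensusGroup, ConsensusMap
from .homology import OrthologAnchor
from .linkage import GeneticMap, LinkageGroup, Locus
from .mining import CandidateSNP

__all__ = [
    "read_fasta",
    "read_map_csv",
    "write_map_csv",
    "read_consensus_csv",
    "write_consensus_csv",
    "write_anchors_csv",
    "write_targets_csv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_map_csv(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker", "group", "position_cM", "bin_id"])
        for lg in gmap.groups:
            for bin_id, locus in enumerate(lg.loci, start=1):
                for m in locus.markers:
                    w.writerow([m, lg.name, f"{locus.position:.4f}", bin_id])
        for m in gmap.unplaced:
            w.writerow([m, "unplaced", "", ""])


def read_map_csv(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, dtype={"marker": str, "group": str})
    groups: dict[str, dict[int, Locus]] = {}
    unplaced: list[str] = []
    for _, row in df.iterrows():
        if row["group"] == "unplaced" or pd.isna(row["position_cM"]):
            unplaced.append(row["marker"])
            continue
        loci = groups.setdefault(row["group"], {})
        bin_id = int(row["bin_id"])
        if bin_id not in loci:
            loci[bin_id] = Locus(position=float(row["position_cM"]), markers=[])
        loci[bin_id].markers.append(row["marker"])
    lgs = []
    for name in sorted(groups):
        ordered = [groups[name][b] for b in sorted(groups[name])]
        for locus in ordered:
            locus.markers.sort()
        lgs.append(LinkageGroup(name=name, loci=ordered))
    return GeneticMap(groups=lgs, unplaced=sorted(unplaced))


def write_consensus_csv(cm: ConsensusMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker", "group", "position_cM", "bin_id", "supporting_pops"])
        for g in cm.groups:
            for bin_id, locus in enumerate(g.loci, start=1):
                for m in locus.markers:
                    pops = ";".join(g.support.get(m, []))
                    w.writerow([m, g.name, f"{locus.position:.4f}", bin_id, pops])


def read_consensus_csv(path: str | Path) -> ConsensusMap:
    df = pd.read_csv(path, dtype={"marker": str, "group": str})
    groups: dict[str, dict[int, Locus]] = {}
    support: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        loci = groups.setdefault(row["group"], {})
        bin_id = int(row["bin_id"])
        if bin_id not in loci:
            loci[bin_id] = Locus(position=float(row["position_cM"]), markers=[])
        loci[bin_id].markers.append(row["marker"])
        pops = row.get("supporting_pops", "")
        support.setdefault(row["group"], {})[row["marker"]] = (
            str(pops).split(";") if isinstance(pops, str) and pops else []
        )
    out = []
    for name in sorted(groups):
        ordered = [groups[name][b] for b in sorted(groups[name])]
        for locus in ordered:
            locus.markers.sort()
        out.append(
            ConsensusGroup(name=name, loci=ordered, support=support.get(name, {}))
        )
    return ConsensusMap(groups=out)


def write_anchors_csv(anchors: Iterable[OrthologAnchor], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["contig_a", "contig_b", "gene", "chromosome", "status", "reason"])
        for a in anchors:
            w.writerow(
                [
                    a.contig_a,
                    a.contig_b,
                    a.reference_gene_id or "",
                    a.reference_chromosome or "",
                    a.status,
                    a.reason or "",
                ]
            )


def read_anchors_csv(path: str | Path) -> list[OrthologAnchor]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                OrthologAnchor(
                    contig_a=row["contig_a"],
                    contig_b=row["contig_b"],
                    reference_gene_id=row["gene"] or None,
                    reference_chromosome=int(row["chromosome"]) if row["chromosome"] else None,
                    status=row["status"],
                    reason=row["reason"] or None,
                )
            )
    return out


def write_targets_csv(snps: Iterable[CandidateSNP], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "assay_name",
                "contig_a",
                "pos_a",
                "allele_a",
                "allele_b",
                "gene",
                "chromosome",
                "status",
                "reason",
                "flank",
            ]
        )
        for s in snps:
            anchor = s.anchor
            w.writerow(
                [
                    s.assay_name or "",
                    s.snp_id.split(":")[0],
                    s.pos_a,
                    s.allele_a,
                    s.allele_b,
                    anchor.reference_gene_id if anchor else "",
                    anchor.reference_chromosome if anchor else "",
                    s.status,
                    s.reason or "",
                    s.consensus_flank,
                ]
            )
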