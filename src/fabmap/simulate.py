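"""Synthetic reference, transcriptomes, populations and fluorescence data.

Every generator is a pure function of (parameters, seed) and returns
both the synthetic dataset and the truth needed to verify downstream
stages.  Crossovers are simulated without interference (count per
chromosome ~ Poisson(length / 100), positions uniform), so Haldane
distances are the natural inverse; segregation distortion is produced
by post-hoc viability selection at designated loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .qc import GenotypeMatrix

__all__ = [
    "Reference",
    "VariantTruth",
    "TruthBundle",
    "make_reference",
    "make_parental_transcriptomes",
    "default_true_map",
    "simulate_population",
    "simulate_fluorescence",
    "write_fasta",
    "FLUOR_ARCHETYPES",
]

_BASES = np.array(list("ACGT"))


@dataclass
class Reference:
    chromosomes: dict[str, str]
    genes: list[GeneModel]

    def transcript(self, gene_id: str) -> str:
        gene = next(g for g in self.genes if g.gene_id == gene_id)
        return gene.spliced(self.chromosomes[gene.chrom])


@dataclass(frozen=True)
class VariantTruth:
    gene_id: str
    contig_a: str
    contig_b: str
    offset: int  # 0-based on both contigs (contigs are colinear)
    allele_a: str
    allele_b: str


@dataclass
class TruthBundle:
    reference: Reference
    variants: list[VariantTruth]
    true_map: dict[str, list[tuple[str, float]]]
    design: dict = field(default_factory=dict)
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_reference(
    n_chrom: int = 2,
    genes_per_chrom: int = 20,
    introns_per_gene: int = 2,
    seed: int = 0,
    exon_len: tuple[int, int] = (150, 350),
    intron_len: tuple[int, int] = (80, 250),
    spacer_len: tuple[int, int] = (200, 500),
) -> Reference:
    """Random chromosomes with non-overlapping intron-containing genes.

    Gene ids follow the MtXgNNNNNN pattern so chromosome numbers can be
    recovered from identifiers downstream.  Deterministic per seed.
    """
    if not 1 <= n_chrom <= 8:
        raise ValueError("n_chrom must be between 1 and 8")
    if not 0 <= introns_per_gene <= 4:
        raise ValueError("introns_per_gene must be between 0 and 4")
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    for c in range(1, n_chrom + 1):
        chrom_name = f"Mt{c}"
        parts: list[str] = []
        cursor = 0
        for gi in range(genes_per_chrom):
            spacer = int(rng.integers(*spacer_len))
            parts.append(_random_seq(rng, spacer))
            cursor += spacer
            exons = []
            gene_start = cursor + 1  # 1-based
            for e in range(introns_per_gene + 1):
                elen = int(rng.integers(*exon_len))
                exons.append((cursor + 1, cursor + elen))
                parts.append(_random_seq(rng, elen))
                cursor += elen
                if e < introns_per_gene:
                    ilen = int(rng.integers(*intron_len))
                    parts.append(_random_seq(rng, ilen))
                    cursor += ilen
            gene_id = f"Mt{c}g{(gi + 1) * 100:06d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom_name,
                    start=gene_start,
                    end=cursor,
                    exons=exons,
                    note="hypothetical protein",
                )
            )
        parts.append(_random_seq(rng, int(rng.integers(*spacer_len))))
        chromosomes[chrom_name] = "".join(parts)
    return Reference(chromosomes=chromosomes, genes=genes)


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(3))]
    return "".join(out)


def make_parental_transcriptomes(
    reference: Reference,
    snp_rate: float = 0.005,
    paralog_fraction: float = 0.0,
    paralog_divergence: tuple[float, float] = (0.02, 0.05),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], list[VariantTruth]]:
    """Two inbred transcript sets differing by planted biallelic SNPs.

    Line A contigs are the spliced reference transcripts; line B
    carries Bernoulli(snp_rate) substitutions per base.  A fraction of
    genes additionally contributes a diverged duplicate contig to both
    transcriptomes (decoys for the paralog filter, never listed in the
    variant truth).
    """
    rng = np.random.default_rng(seed)
    trans_a: dict[str, str] = {}
    trans_b: dict[str, str] = {}
    variants: list[VariantTruth] = []
    for gene in reference.genes:
        t = gene.spliced(reference.chromosomes[gene.chrom])
        name_a, name_b = f"cA_{gene.gene_id}", f"cB_{gene.gene_id}"
        trans_a[name_a] = t
        snp_positions = np.flatnonzero(rng.random(len(t)) < snp_rate)
        seq_b = list(t)
        for p in snp_positions:
            alternatives = [b for b in "ACGT" if b != t[p]]
            seq_b[p] = alternatives[int(rng.integers(3))]
            variants.append(
                VariantTruth(gene.gene_id, name_a, name_b, int(p), t[p], seq_b[p])
            )
        trans_b[name_b] = "".join(seq_b)
        if rng.random() < paralog_fraction:
            div = rng.uniform(*paralog_divergence)
            pos = np.flatnonzero(rng.random(len(t)) < div)
            para = _mutate(rng, t, pos)
            trans_a[f"{name_a}_p"] = para
            trans_b[f"{name_b}_p"] = para
    return trans_a, trans_b, variants


def default_true_map(
    reference: Reference, spacing_cm: float = 5.0
) -> dict[str, list[tuple[str, float]]]:
    """One marker per gene, evenly spaced per chromosome."""
    true_map: dict[str, list[tuple[str, float]]] = {}
    per_chrom: dict[str, list[str]] = {}
    for g in reference.genes:
        per_chrom.setdefault(g.chrom, []).append(g.gene_id)
    for chrom, gene_ids in per_chrom.items():
        true_map[chrom] = [
            (f"Vf_{gid}_001", i * spacing_cm) for i, gid in enumerate(gene_ids)
        ]
    return true_map


def _meiosis(
    rng: np.random.Generator,
    hap0: np.ndarray,
    hap1: np.ndarray,
    positions: np.ndarray,
    length: float,
) -> np.ndarray:
    n_xo = rng.poisson(max(length, 1e-9) / 100.0)
    xo = np.sort(rng.uniform(0.0, max(length, 1e-9), size=n_xo))
    phase = int(rng.integers(2))
    crossings = np.searchsorted(xo, positions)  # crossovers before each marker
    current = (phase + crossings) % 2
    return np.where(current == 0, hap0, hap1)


def _self(
    rng: np.random.Generator,
    individual: tuple[np.ndarray, np.ndarray],
    positions: np.ndarray,
    length: float,
) -> tuple[np.ndarray, np.ndarray]:
    g1 = _meiosis(rng, individual[0], individual[1], positions, length)
    g2 = _meiosis(rng, individual[0], individual[1], positions, length)
    return g1, g2


def simulate_population(
    true_map: Mapping[str, Sequence[tuple[str, float]]],
    design: str = "f2",
    n: int = 100,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    distortion: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    max_selfing: int = 40,
) -> GenotypeMatrix:
    """Simulate a segregating population from a true genetic map.

    Designs: ``f2`` (one meiosis per gamete from the F1), ``f5_ssd``
    (four generations of single-seed-descent selfing) and ``ril``
    (selfing to fixation).  ``distortion`` maps marker -> relative
    viabilities (w_AA, w_AB, w_BB); individuals are rejection-sampled.
    """
    if not true_map or all(len(v) == 0 for v in true_map.values()):
        raise ValueError("empty map")
    if design not in ("f2", "f5_ssd", "ril"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    groups = {
        g: (np.array([m for m, _ in loci]), np.array([p for _, p in loci], dtype=float))
        for g, loci in true_map.items()
    }
    marker_order = [m for g in groups.values() for m in g[0]]
    rows = []
    for _ in range(n):
        while True:
            doses: dict[str, int] = {}
            for markers, positions in groups.values():
                length = float(positions.max()) if len(positions) else 0.0
                k = len(markers)
                hap0, hap1 = np.zeros(k, dtype=int), np.ones(k, dtype=int)
                ind = (
                    _meiosis(rng, hap0, hap1, positions, length),
                    _meiosis(rng, hap0, hap1, positions, length),
                )
                n_gen = {"f2": 0, "f5_ssd": 3, "ril": max_selfing}[design]
                for _gen in range(n_gen):
                    if design == "ril" and not np.any(ind[0] != ind[1]):
                        break
                    ind = _self(rng, ind, positions, length)
                for m, dose in zip(markers, ind[0] + ind[1]):
                    doses[m] = int(dose)
            if distortion:
                fitness = 1.0
                for m, ws in distortion.items():
                    if m in doses:
                        fitness *= ws[doses[m]]
                if rng.random() > fitness:
                    continue
            break
        rows.append([("AA", "AB", "BB")[doses[m]] for m in marker_order])
    arr = np.array(rows, dtype=object)
    if error_rate > 0:
        err = rng.random(arr.shape) < error_rate
        for i, j in zip(*np.nonzero(err)):
            others = [c for c in ("AA", "AB", "BB") if c != arr[i, j]]
            arr[i, j] = others[int(rng.integers(2))]
    if missing_rate > 0:
        arr[rng.random(arr.shape) < missing_rate] = "NC"
    calls = pd.DataFrame(
        arr,
        index=[f"ind{i + 1:04d}" for i in range(n)],
        columns=marker_order,
    )
    return GenotypeMatrix(calls)


# archetype -> (cluster sd, extra no-call fraction)
FLUOR_ARCHETYPES: dict[str, tuple[float, float]] = {
    "I": (0.03, 0.00),
    "II": (0.12, 0.04),
    "III": (0.20, 0.10),
    "IV": (0.50, 0.30),
}

_CENTROIDS = {
    "AA": (0.90, 0.10),
    "BB": (0.10, 0.90),
    "AB": (0.55, 0.55),
    "NC": (0.08, 0.08),
}


def simulate_fluorescence(
    calls: Sequence[str],
    archetype: str = "I",
    seed: int = 0,
) -> pd.DataFrame:
    """Three-cluster 2-D fluorescence of tunable tightness.

    Returns a table (sample, x, y, call); a fraction of calls becomes
    NC according to the archetype, and NC points sit in a dim cloud
    near the origin.
    """
    if archetype not in FLUOR_ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    sd, nc_fraction = FLUOR_ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    out = []
    for i, call in enumerate(calls):
        c = call
        if c != "NC" and rng.random() < nc_fraction:
            c = "NC"
        cx, cy = _CENTROIDS[c]
        spread = 0.03 if c == "NC" else sd
        out.append(
            {
                "sample": f"s{i + 1:04d}",
                "x": float(rng.normal(cx, spread)),
                "y": float(rng.normal(cy, spread)),
                "call": c,
            }
        )
    return pd.DataFrame(out)


def write_fasta(seqs: Mapping[str, str], dest: str | Path | TextIO, width: int = 70) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_fasta(seqs, fh, width)
        return
    for name, seq in seqs.items():
        dest.write(f">{name}\n")
        for i in range(0, len(seq), width):
            dest.write(seq[i : i + width] + "\n")
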