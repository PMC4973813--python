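"""Genotype-matrix quality control and marker information statistics.

Genotype matrices are lines x markers with calls in {AA, AB, BB, NC}.
On disk: CSV with a header row of marker ids and the line id in the
first column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CALLS",
    "GenotypeMatrix",
    "AssayQuality",
    "AlleleStats",
    "DistortionVerdict",
    "classify_quality",
    "iterative_no_call_filter",
    "allele_stats",
    "line_heterozygosity",
    "concordance_audit",
    "distortion_filter",
    "distance_and_upgma",
]

CALLS = ("AA", "AB", "BB", "NC")


class GenotypeMatrix:
    """Rectangular matrix of genotype calls with enforced call domain."""

    def __init__(self, calls: pd.DataFrame):
        bad = set(np.unique(calls.values.astype(str))) - set(CALLS)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")
        if calls.index.duplicated().any() or calls.columns.duplicated().any():
            raise ValueError("duplicate line or marker identifiers")
        self.calls = calls.astype(str)

    @property
    def lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def marker_calls(self, marker: str) -> pd.Series:
        return self.calls[marker]

    def line_calls(self, line: str) -> pd.Series:
        return self.calls.loc[line]

    def nc_rate_by_line(self) -> pd.Series:
        return (self.calls == "NC").mean(axis=1)

    def nc_rate_by_marker(self) -> pd.Series:
        return (self.calls == "NC").mean(axis=0)

    def subset(self, lines: Sequence[str] | None = None, markers: Sequence[str] | None = None) -> "GenotypeMatrix":
        df = self.calls
        if lines is not None:
            df = df.loc[list(lines)]
        if markers is not None:
            df = df[list(markers)]
        return GenotypeMatrix(df.copy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeMatrix":
        return cls(pd.read_csv(path, index_col=0, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.calls.to_csv(path)


@dataclass(frozen=True)
class AssayQuality:
    marker: str
    call_rate: float
    separation_score: float
    quality_class: str  # I | II | III | IV


@dataclass(frozen=True)
class AlleleStats:
    marker: str
    p: float
    q: float
    gene_diversity: float  # 2pq
    pic: float  # 1 - p^2 - q^2 - 2 p^2 q^2
    private_to: str | None


@dataclass(frozen=True)
class DistortionVerdict:
    marker: str
    ratio: float
    rule: str  # "f2" | "inbred"
    verdict: str  # "keep" | "remove"
    reason: str | None = None  # "skew" | "missing_parental_allele"


_CLASS_THRESHOLDS = ((0.8, "I"), (0.6, "II"), (0.4, "III"))


def classify_quality(
    points: pd.DataFrame,
    marker: str = "",
    no_call_weight: float = 0.5,
    thresholds: Sequence[tuple[float, str]] = _CLASS_THRESHOLDS,
) -> AssayQuality:
    """Score cluster tightness of a 2-D fluorescence readout.

    ``points`` needs columns x, y, call.  Separation is silhouette-like:
    per called point, (distance to nearest other-class centroid minus
    distance to own centroid) / max of the two, clipped to [0, 1], then
    averaged.  The composite separation * call_rate**no_call_weight is
    cut at the class thresholds (defaults: I >= 0.8, II >= 0.6,
    III >= 0.4, else IV).
    """
    if len(points) < 6:
        raise ValueError("need at least 6 samples to classify an assay")
    called = points[points["call"] != "NC"]
    call_rate = len(called) / len(points)
    classes = sorted(called["call"].unique())
    if len(classes) < 2:
        return AssayQuality(marker, call_rate, 0.0, "IV")
    centroids = {
        c: called.loc[called["call"] == c, ["x", "y"]].mean().to_numpy()
        for c in classes
    }
    scores = []
    for _, row in called.iterrows():
        xy = row[["x", "y"]].to_numpy(dtype=float)
        own = float(np.linalg.norm(xy - centroids[row["call"]]))
        other = min(
            float(np.linalg.norm(xy - centroids[c])) for c in classes if c != row["call"]
        )
        denom = max(own, other)
        scores.append(0.0 if denom == 0 else min(1.0, max(0.0, (other - own) / denom)))
    separation = float(np.mean(scores))
    composite = separation * call_rate**no_call_weight
    quality = "IV"
    for cut, label in thresholds:
        if composite >= cut:
            quality = label
            break
    return AssayQuality(marker, call_rate, separation, quality)


def iterative_no_call_filter(
    gm: GenotypeMatrix, max_nc: float = 0.06
) -> tuple[GenotypeMatrix, list[tuple[str, str, float]]]:
    """Iteratively drop the single worst no-call offender until clean.

    Each round recomputes per-line and per-marker NC rates over the
    surviving matrix and removes the highest rate above ``max_nc``
    (ties: markers before lines, then lexicographic).  The removal log
    records (kind, identifier, rate at removal).
    """
    calls = gm.calls.copy()
    log: list[tuple[str, str, float]] = []
    while True:
        if calls.size == 0:
            raise ValueError("matrix exhausted: all lines or markers removed")
        nc = calls == "NC"
        marker_rates = nc.mean(axis=0)
        line_rates = nc.mean(axis=1)
        candidates = [
            ("marker", m, r) for m, r in marker_rates.items() if r > max_nc
        ] + [("line", l, r) for l, r in line_rates.items() if r > max_nc]
        if not candidates:
            return GenotypeMatrix(calls), log
        kind, ident, rate = sorted(
            candidates, key=lambda c: (-c[2], c[0] != "marker", c[1])
        )[0]
        if kind == "marker":
            calls = calls.drop(columns=[ident])
        else:
            calls = calls.drop(index=[ident])
        log.append((kind, ident, float(rate)))


def _allele_counts(calls: Iterable[str]) -> tuple[int, int]:
    a = b = 0
    for c in calls:
        if c == "AA":
            a += 2
        elif c == "BB":
            b += 2
        elif c == "AB":
            a += 1
            b += 1
    return a, b


def allele_stats(
    gm: GenotypeMatrix,
    marker: str,
    discovery_lines: tuple[str, str] | None = None,
) -> AlleleStats:
    """Allele frequency, gene diversity (2pq) and PIC for one marker.

    ``p`` is the major-allele frequency (ties resolved to the A
    allele); heterozygotes contribute one of each allele and NC calls
    are excluded.  The marker is private to a discovery line when every
    carrier of the minor allele in the panel is that line.
    """
    calls = gm.marker_calls(marker)
    n_a, n_b = _allele_counts(calls)
    total = n_a + n_b
    if total == 0:
        raise ValueError(f"marker {marker}: no called genotypes")
    freq_a = n_a / total
    p = max(freq_a, 1 - freq_a)
    q = 1 - p
    minor_calls = ("BB", "AB") if freq_a >= 0.5 else ("AA", "AB")
    carriers = [line for line, c in calls.items() if c in minor_calls]
    private_to = None
    if discovery_lines is not None and carriers:
        for d in discovery_lines:
            if set(carriers) == {d}:
                private_to = d
    return AlleleStats(
        marker=marker,
        p=p,
        q=q,
        gene_diversity=2 * p * q,
        pic=1 - p**2 - q**2 - 2 * p**2 * q**2,
        private_to=private_to,
    )


def line_heterozygosity(gm: GenotypeMatrix, line: str) -> tuple[float, float]:
    """(percent heterozygous, percent homozygous) of called genotypes."""
    calls = gm.line_calls(line)
    called = calls[calls != "NC"]
    if len(called) == 0:
        raise ValueError(f"line {line}: no called genotypes")
    het = 100.0 * (called == "AB").sum() / len(called)
    return het, 100.0 - het


def concordance_audit(
    gm: GenotypeMatrix,
    predicted: Mapping[str, Mapping[str, str]],
) -> tuple[dict[str, bool], float, list[str]]:
    """Check observed discovery-line calls against sequence predictions.

    ``predicted`` maps marker -> {discovery line -> expected homozygous
    call}.  A marker matches iff every discovery line's observed call
    equals its prediction; markers where a discovery line is NC are
    excluded from the denominator and returned in the third element.
    """
    flags: dict[str, bool] = {}
    excluded: list[str] = []
    for marker, expectations in predicted.items():
        observed = {line: gm.calls.at[line, marker] for line in expectations}
        if any(c == "NC" for c in observed.values()):
            excluded.append(marker)
            continue
        flags[marker] = all(observed[l] == exp for l, exp in expectations.items())
    summary = (
        concordance_fraction(sum(flags.values()), len(flags)) if flags else float("nan")
    )
    return flags, summary, excluded


def concordance_fraction(n_matching: int, n_total: int) -> float:
    """Summary fraction used by :func:`concordance_audit`."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_matching <= n_total:
        raise ValueError("n_matching out of range")
    return n_matching / n_total


def distortion_filter(
    calls: Iterable[str],
    design: str,
    marker: str = "",
    f2_bounds: tuple[float, float] = (0.4, 2.1),
    inbred_bounds: tuple[float, float] = (0.045, 0.25),
) -> DistortionVerdict:
    """Flag badly skewed markers in a segregating population.

    F2 rule: homozygote:heterozygote ratio (#AA+#BB)/#AB outside
    ``f2_bounds``.  Inbred (F5/RIL) rule: heterozygote:homozygote ratio
    #AB/(#AA+#BB) outside ``inbred_bounds`` — the published bounds can
    only bracket the selfing-series expectation (~1/15 for F5) in this
    orientation.  A missing homozygous parental class always removes.
    """
    if design not in ("f2", "inbred"):
        raise ValueError(f"unknown design {design!r}")
    counts = {c: 0 for c in CALLS}
    for c in calls:
        counts[c] += 1
    n_aa, n_ab, n_bb = counts["AA"], counts["AB"], counts["BB"]
    if design == "f2":
        ratio = (n_aa + n_bb) / n_ab if n_ab else math.inf
        lo, hi = f2_bounds
    else:
        ratio = n_ab / (n_aa + n_bb) if (n_aa + n_bb) else math.inf
        lo, hi = inbred_bounds
    if n_aa == 0 or n_bb == 0:
        return DistortionVerdict(marker, ratio, design, "remove", "missing_parental_allele")
    if ratio > hi or ratio < lo:
        return DistortionVerdict(marker, ratio, design, "remove", "skew")
    return DistortionVerdict(marker, ratio, design, "keep")


_SHARE = {
    ("AA", "AA"): 1.0, ("BB", "BB"): 1.0, ("AB", "AB"): 1.0,
    ("AA", "AB"): 0.5, ("AB", "AA"): 0.5,
    ("BB", "AB"): 0.5, ("AB", "BB"): 0.5,
    ("AA", "BB"): 0.0, ("BB", "AA"): 0.0,
}


def distance_and_upgma(gm: GenotypeMatrix) -> tuple[pd.DataFrame, str]:
    """Shared-allele distance matrix and UPGMA tree (Newick).

    Distance between two lines = 1 - mean shared-allele score over
    markers called in both (identical calls 1, one shared allele 0.5,
    opposite homozygotes 0).  The tree is ultrametric: each internal
    node sits at half its merge distance.
    """
    lines = gm.lines
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")
    arr = gm.calls.to_numpy()
    n = len(lines)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scores = [
                _SHARE[(a, b)]
                for a, b in zip(arr[i], arr[j])
                if a != "NC" and b != "NC"
            ]
            if not scores:
                raise ValueError(
                    f"lines {lines[i]} and {lines[j]} share no co-called markers"
                )
            dist[i, j] = dist[j, i] = 1.0 - float(np.mean(scores))
    z = linkage(squareform(dist, checks=False), method="average")
    return pd.DataFrame(dist, index=lines, columns=lines), _newick(z, lines)


def _newick(z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (i, j, d, _) in enumerate(z):
        i, j = int(i), int(j)
        h = d / 2.0
        left = f"{nodes[i]}:{h - heights[i]:.10g}"
        right = f"{nodes[j]}:{h - heights[j]:.10g}"
        nodes[n + k] = f"({left},{right})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"
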