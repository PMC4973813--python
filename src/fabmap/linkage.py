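"""Two-point linkage estimation and per-population map construction.

Recombination fractions are maximum-likelihood estimates obtained by EM
over the latent gamete-pair classes of the population design:

* ``f2_codominant``      — 9-class joint genotype table; the
  double-heterozygote class is a phase mixture handled in the E-step;
* ``f2_dominant_pair``   — a dominant trait score against a codominant
  marker (collapsed classes);
* ``inbred``             — F5/RIL two-class table; the observed
  recombinant-haplotype frequency R is mapped back through the
  selfing correction R = 2r / (1 + 2r).

Phase (and, for a trait, the identity of the dominant allele) is not
assumed: the likelihood is maximised over the possible orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PairwiseLinkage",
    "Locus",
    "LinkageGroup",
    "GeneticMap",
    "estimate_rf",
    "pairwise_linkages",
    "group_markers",
    "order_markers",
    "space_markers",
    "kosambi",
    "haldane",
    "build_map",
    "map_trait_locus",
]


@dataclass(frozen=True)
class PairwiseLinkage:
    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int


@dataclass
class Locus:
    position: float  # cM
    markers: list[str]  # co-segregating bin, sorted


@dataclass
class LinkageGroup:
    name: str
    loci: list[Locus]

    @property
    def markers(self) -> list[str]:
        return [m for locus in self.loci for m in locus.markers]

    @property
    def length(self) -> float:
        return self.loci[-1].position if self.loci else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    unplaced: list[str] = field(default_factory=list)

    @property
    def markers(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]


# ---------------------------------------------------------------------------
# two-point estimation

_CODE = {"AA": 0, "AB": 1, "BB": 2}

# 16 ordered gamete pairs; gamete = (allele at locus 1, allele at locus 2),
# recombinant (in coupling) iff the two alleles differ.
_GAMETES = [(0, 0), (0, 1), (1, 0), (1, 1)]
_PAIRS = [(g1, g2) for g1 in _GAMETES for g2 in _GAMETES]
_REC = np.array(
    [int(g1[0] != g1[1]) + int(g2[0] != g2[1]) for g1, g2 in _PAIRS], dtype=float
)


def _latent_probs(r: float) -> np.ndarray:
    g = np.array([(1 - r) / 2, r / 2])  # non-recombinant, recombinant gamete
    rec1 = np.array([int(g1[0] != g1[1]) for g1, _ in _PAIRS])
    rec2 = np.array([int(g2[0] != g2[1]) for _, g2 in _PAIRS])
    return g[rec1] * g[rec2]


def _class_matrix(design: str, dominant_allele: int = 0) -> tuple[np.ndarray, int]:
    """Indicator matrix (n_classes x 16) mapping latent pairs to classes."""
    if design == "f2_codominant":
        n_classes = 9
    elif design == "f2_dominant_pair":
        n_classes = 6
    else:
        raise ValueError(f"no latent-class table for design {design!r}")
    m = np.zeros((n_classes, 16))
    for k, (g1, g2) in enumerate(_PAIRS):
        dose1 = g1[0] + g2[0]
        dose2 = g1[1] + g2[1]
        if design == "f2_codominant":
            m[dose1 * 3 + dose2, k] = 1
        else:
            carries = (
                dose1 < 2 if dominant_allele == 0 else dose1 > 0
            )  # >=1 copy of the dominant allele
            m[(0 if carries else 1) * 3 + dose2, k] = 1
    return m, n_classes


def _em(counts: np.ndarray, m: np.ndarray, tol: float, max_iter: int) -> tuple[float, float]:
    """EM for r plus the log10-likelihood at the optimum."""
    n_gametes = 2 * counts.sum()
    r = 0.25
    for _ in range(max_iter):
        p = _latent_probs(r)
        class_p = m @ p
        exp_rec_num = m @ (p * _REC)
        with np.errstate(divide="ignore", invalid="ignore"):
            exp_rec = np.where(class_p > 0, exp_rec_num / np.where(class_p > 0, class_p, 1), 0.0)
        r_new = float((counts * exp_rec).sum() / n_gametes)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return r, _loglik(counts, m, r)


def _loglik(counts: np.ndarray, m: np.ndarray, r: float) -> float:
    class_p = m @ _latent_probs(r)
    mask = counts > 0
    if np.any(class_p[mask] <= 0):
        return -math.inf
    return float((counts[mask] * np.log10(class_p[mask])).sum())


def _joint_counts(
    calls_a: Sequence[str], calls_b: Sequence[str], design: str
) -> tuple[np.ndarray, int]:
    if design == "f2_codominant":
        counts = np.zeros(9)
        n = 0
        for a, b in zip(calls_a, calls_b):
            if a in _CODE and b in _CODE:
                counts[_CODE[a] * 3 + _CODE[b]] += 1
                n += 1
        return counts, n
    if design == "f2_dominant_pair":
        counts = np.zeros(6)
        n = 0
        for a, b in zip(calls_a, calls_b):
            if a in ("D", "R") and b in _CODE:
                counts[(0 if a == "D" else 1) * 3 + _CODE[b]] += 1
                n += 1
        return counts, n
    raise ValueError(f"unknown design {design!r}")


def _flip_marker2(counts: np.ndarray) -> np.ndarray:
    """Relabel AA<->BB at the second locus (phase flip)."""
    out = counts.reshape(-1, 3)[:, ::-1].reshape(-1)
    return np.ascontiguousarray(out)


def estimate_rf(
    calls_a: Sequence[str],
    calls_b: Sequence[str],
    design: str = "f2_codominant",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PairwiseLinkage:
    """Two-point ML recombination fraction and LOD for one marker pair.

    ``calls_a``/``calls_b`` are per-individual calls (AA/AB/BB/NC, or
    D/R for a dominant trait as the first argument of the
    ``f2_dominant_pair`` design).  Requires >= 10 jointly informative
    individuals.
    """
    if design == "inbred":
        return _estimate_rf_inbred(calls_a, calls_b)
    counts, n = _joint_counts(calls_a, calls_b, design)
    if n < 10:
        raise ValueError(f"only {n} jointly called individuals (need >= 10)")
    orientations = []
    dom_options = (0,) if design == "f2_codominant" else (0, 1)
    for dom in dom_options:
        m, _ = _class_matrix(design, dominant_allele=dom)
        for flip in (False, True):
            c = _flip_marker2(counts) if flip else counts
            r, ll = _em(c, m, tol, max_iter)
            ll_null = _loglik(c, m, 0.5)
            orientations.append((ll, r, ll - ll_null))
    ll, r, lod = max(orientations, key=lambda t: t[0])
    return PairwiseLinkage("a", "b", r, max(lod, 0.0), n)


def _estimate_rf_inbred(calls_a: Sequence[str], calls_b: Sequence[str]) -> PairwiseLinkage:
    n_same = n_diff = 0
    for a, b in zip(calls_a, calls_b):
        if a in ("AA", "BB") and b in ("AA", "BB"):
            if a == b:
                n_same += 1
            else:
                n_diff += 1
    n = n_same + n_diff
    if n < 10:
        raise ValueError(f"only {n} jointly called homozygous individuals (need >= 10)")
    rec = min(n_same, n_diff)  # phase chosen by ML
    big_r = rec / n
    r = big_r / (2 * (1 - big_r)) if big_r < 1 else 0.5
    r = min(r, 0.5)
    lod = 0.0
    if rec:
        lod += rec * math.log10(big_r / 0.5)
    if n - rec:
        lod += (n - rec) * math.log10((1 - big_r) / 0.5)
    return PairwiseLinkage("a", "b", r, max(lod, 0.0), n)


def pairwise_linkages(
    calls: Mapping[str, Sequence[str]],
    design: str = "f2_codominant",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> dict[tuple[str, str], PairwiseLinkage]:
    """Estimate all pairwise linkages among a set of markers.

    Pairs with fewer than 10 jointly informative individuals are
    silently treated as unlinked (omitted from the table).
    """
    table: dict[tuple[str, str], PairwiseLinkage] = {}
    for a, b in combinations(sorted(calls), 2):
        try:
            pl = estimate_rf(calls[a], calls[b], design, tol, max_iter)
        except ValueError:
            continue
        table[(a, b)] = PairwiseLinkage(a, b, pl.r_hat, pl.lod, pl.n_informative)
    return table


# ---------------------------------------------------------------------------
# grouping, ordering, spacing

def group_markers(
    linkages: Iterable[PairwiseLinkage],
    markers: Sequence[str] | None = None,
    min_lod: float = 5.0,
    max_r: float = 0.3,
) -> list[list[str]]:
    """Single-linkage partition over edges with lod >= min_lod, r <= max_r."""
    linkages = list(linkages)
    universe = set(markers) if markers is not None else set()
    for pl in linkages:
        universe.update((pl.marker_a, pl.marker_b))
    parent = {m: m for m in universe}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pl in linkages:
        if pl.lod >= min_lod and pl.r_hat <= max_r:
            ra, rb = find(pl.marker_a), find(pl.marker_b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for m in universe:
        groups.setdefault(find(m), []).append(m)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


class _RfLookup:
    def __init__(self, linkages: Iterable[PairwiseLinkage]):
        self._r: dict[tuple[str, str], float] = {}
        for pl in linkages:
            key = tuple(sorted((pl.marker_a, pl.marker_b)))
            self._r[key] = pl.r_hat

    def r(self, a: str, b: str) -> float:
        return self._r.get(tuple(sorted((a, b))), 0.5)


def _bin_cosegregating(group: Sequence[str], rf: _RfLookup, zero: float = 1e-6) -> list[list[str]]:
    parent = {m: m for m in group}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(sorted(group), 2):
        if rf.r(a, b) <= zero:
            parent[find(a)] = find(b)
    bins: dict[str, list[str]] = {}
    for m in group:
        bins.setdefault(find(m), []).append(m)
    return [sorted(b) for b in bins.values()]


def _bin_r(bin_a: Sequence[str], bin_b: Sequence[str], rf: _RfLookup) -> float:
    return float(np.mean([rf.r(a, b) for a in bin_a for b in bin_b]))


def sarf(order: Sequence[int], dist: np.ndarray) -> float:
    return float(sum(dist[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _two_opt(order: list[int], dist: np.ndarray) -> list[int]:
    improved = True
    best = sarf(order, dist)
    while improved:
        improved = False
        for i in range(len(order) - 1):
            for j in range(i + 1, len(order)):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                s = sarf(cand, dist)
                if s < best - 1e-12:
                    order, best, improved = cand, s, True
    return order


def _relocate(order: list[int], dist: np.ndarray) -> list[int]:
    """Single-node reinsertion passes until no SARF improvement."""
    improved = True
    best = sarf(order, dist)
    while improved:
        improved = False
        for i in range(len(order)):
            for j in range(len(order)):
                if i == j:
                    continue
                cand = order[:i] + order[i + 1 :]
                cand = cand[:j] + [order[i]] + cand[j:]
                s = sarf(cand, dist)
                if s < best - 1e-12:
                    order, best, improved = cand, s, True
    return order


def order_markers(
    group: Sequence[str],
    linkages: Iterable[PairwiseLinkage],
) -> list[list[str]]:
    """Order co-segregating bins by SARF (greedy chain + 2-opt).

    Returns the ordered list of bins; orientation is normalised so the
    lexicographically smallest terminal marker comes first.
    """
    rf = _RfLookup(linkages)
    bins = _bin_cosegregating(group, rf)
    bins.sort(key=lambda b: b[0])
    if len(bins) <= 1:
        return bins
    k = len(bins)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = _bin_r(bins[i], bins[j], rf)
    if k <= 8:
        # exhaustive SARF minimum (fix bin 0's side to halve the search)
        from itertools import permutations

        chain = min(
            (list(p) for p in permutations(range(k)) if p[0] < p[-1]),
            key=lambda p: (sarf(p, dist), p),
        )
    else:
        # greedy: start from the closest pair, extend the nearer end
        start = min(
            ((i, j) for i in range(k) for j in range(i + 1, k)),
            key=lambda ij: (dist[ij], ij),
        )
        chain = [start[0], start[1]]
        unused = set(range(k)) - set(chain)
        while unused:
            head, tail = chain[0], chain[-1]
            cand_head = min(unused, key=lambda u: (dist[head, u], u))
            cand_tail = min(unused, key=lambda u: (dist[tail, u], u))
            if dist[head, cand_head] < dist[tail, cand_tail]:
                chain.insert(0, cand_head)
                unused.remove(cand_head)
            else:
                chain.append(cand_tail)
                unused.remove(cand_tail)
        chain = _two_opt(chain, dist)
        chain = _relocate(chain, dist)
    ordered = [bins[i] for i in chain]
    if ordered[-1][0] < ordered[0][0]:
        ordered.reverse()
    return ordered


def kosambi(r: float) -> float:
    """Kosambi map distance in cM."""
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def haldane(r: float) -> float:
    """Haldane map distance in cM."""
    return -50.0 * math.log(1 - 2 * r)


_MAP_FUNCTIONS = {"kosambi": kosambi, "haldane": haldane}


def space_markers(
    ordered_bins: Sequence[Sequence[str]],
    linkages: Iterable[PairwiseLinkage],
    map_function: str = "kosambi",
    name: str = "G1",
    ceiling_cm: float = 50.0,
) -> LinkageGroup:
    """Cumulative cM positions from adjacent recombination fractions."""
    fn = _MAP_FUNCTIONS[map_function]
    rf = _RfLookup(linkages)
    loci = []
    pos = 0.0
    for i, b in enumerate(ordered_bins):
        if i > 0:
            r = _bin_r(ordered_bins[i - 1], b, rf)
            pos += ceiling_cm if r >= 0.5 - 1e-9 else fn(r)
        loci.append(Locus(position=pos, markers=sorted(b)))
    return LinkageGroup(name=name, loci=loci)


def build_map(
    calls: Mapping[str, Sequence[str]],
    design: str = "f2_codominant",
    min_lod: float = 5.0,
    max_r: float = 0.3,
    map_function: str = "kosambi",
) -> tuple[GeneticMap, dict[tuple[str, str], PairwiseLinkage]]:
    """Full per-population pipeline: estimate, group, order, space."""
    table = pairwise_linkages(calls, design)
    groups = group_markers(table.values(), markers=list(calls))
    lg_list, unplaced = [], []
    idx = 0
    for g in groups:
        if len(g) < 2:
            unplaced.extend(g)
            continue
        idx += 1
        ordered = order_markers(g, table.values())
        lg_list.append(
            space_markers(ordered, table.values(), map_function, name=f"G{idx}")
        )
    return GeneticMap(groups=lg_list, unplaced=sorted(unplaced)), table


def segregation_check(trait_calls: Sequence[str], ratio: tuple[int, int] = (3, 1)) -> float:
    """Chi-square p-value of a dominant phenotype against a 3:1 ratio.

    Yates continuity correction is applied (single degree of freedom).
    """
    from scipy.stats import chi2

    n_d = sum(1 for c in trait_calls if c == "D")
    n_r = sum(1 for c in trait_calls if c == "R")
    n = n_d + n_r
    if n == 0 or n_d == 0 or n_r == 0:
        raise ValueError("trait is monomorphic")
    expected = (n * ratio[0] / sum(ratio), n * ratio[1] / sum(ratio))
    stat = sum(
        (abs(obs - exp) - 0.5) ** 2 / exp
        for obs, exp in zip((n_d, n_r), expected)
    )
    return float(chi2.sf(stat, df=1))


def map_trait_locus(
    trait_calls: Sequence[str],
    calls: Mapping[str, Sequence[str]],
    genetic_map: GeneticMap,
    min_ratio_p: float = 0.0,
) -> tuple[str, int, tuple[str, str]]:
    """Place a dominant trait on an existing map.

    The trait is treated as a dominant marker; its recombination
    fraction to every mapped locus is estimated with the
    ``f2_dominant_pair`` design, and the trait is inserted where it
    least increases the sum of adjacent recombination fractions.
    Returns (group name, insertion index, flanking marker pair).
    """
    p = segregation_check(trait_calls)
    if p < min_ratio_p:
        raise ValueError(f"trait fails the segregation-ratio check (p={p:.3g})")
    best = None  # (sarf increase, group, insertion index)
    for lg in genetic_map.groups:
        reps = [locus.markers[0] for locus in lg.loci]
        r_to = {}
        for rep in reps:
            try:
                r_to[rep] = estimate_rf(trait_calls, calls[rep], "f2_dominant_pair").r_hat
            except ValueError:
                r_to[rep] = 0.5
        for i in range(len(reps) + 1):
            if i == 0:
                inc = r_to[reps[0]]
            elif i == len(reps):
                inc = r_to[reps[-1]]
            else:
                try:
                    r_adj = estimate_rf(calls[reps[i - 1]], calls[reps[i]]).r_hat
                except ValueError:
                    r_adj = 0.0
                inc = r_to[reps[i - 1]] + r_to[reps[i]] - r_adj
            cand = (inc, lg.name, i)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise ValueError("empty map")
    _, group_name, idx = best
    lg = next(g for g in genetic_map.groups if g.name == group_name)
    left = lg.loci[idx - 1].markers[0] if idx > 0 else lg.loci[0].markers[0]
    right = lg.loci[idx].markers[0] if idx < len(lg.loci) else lg.loci[-1].markers[0]
    return group_name, idx, (left, right)
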