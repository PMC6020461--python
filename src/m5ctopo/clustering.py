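"""Clustering statistics of methylated sites.

Three complementary views of the clustering effect: the proportion of
called sites with another called site within d nt, tested against a
conditional permutation null that reshuffles the per-gene number of called
states over that gene's covered cytosines; the fraction of called sites in
immediately adjacent (1 nt) dimers; and the distance-binned correlation of
methylation ratios between site pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .site_calling import CallResult

__all__ = [
    "prop_within",
    "permutation_test",
    "dimer_fraction",
    "distance_correlation",
    "PermutationResult",
    "group_positions",
    "DEFAULT_DISTANCE_BINS",
]

#: (low, high) inclusive nt distance bins used for comethylation correlation.
DEFAULT_DISTANCE_BINS = ((1, 3), (4, 10), (11, 30), (31, 100), (101, 300))


def group_positions(
    results: Sequence[CallResult], called_only: bool = True, contexts: set[str] | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """Deduplicated sorted positions per (chrom, strand)."""
    by: dict[tuple[str, str], set[int]] = defaultdict(set)
    for r in results:
        if called_only and not r.called:
            continue
        if contexts is not None and r.site.context not in contexts:
            continue
        by[(r.site.chrom, r.site.strand)].add(r.site.pos)
    return {k: np.array(sorted(v)) for k, v in by.items()}


def prop_within(positions: Mapping[tuple[str, str], np.ndarray], d: int = 10) -> float:
    """Fraction of called sites with >= 1 other called site within d nt.

    Distances are genomic, within a (chromosome, strand) track.  Fewer than
    two sites overall gives 0.
    """
    n_total = 0
    n_close = 0
    for pos in positions.values():
        n_total += len(pos)
        if len(pos) < 2:
            continue
        gaps_left = np.diff(pos)
        close = np.zeros(len(pos), dtype=bool)
        close[1:] |= gaps_left <= d
        close[:-1] |= gaps_left <= d
        n_close += int(close.sum())
    if n_total == 0:
        return 0.0
    return n_close / n_total


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_mean: float
    null_ci99: tuple[float, float]
    pvalue: float
    n_perm: int


def permutation_test(
    called: Mapping[str, Sequence[int]],
    candidates: Mapping[str, Sequence[int]],
    d: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "prop_within",
) -> PermutationResult:
    """Permutation null for the clustering statistic.

    ``called`` / ``candidates`` map a gene key (conventionally
    ``gene|chrom|strand``) to called positions and to *all* covered cytosine
    positions of genes carrying >= 1 called site.  Each permutation redraws,
    per gene, the same number of called states uniformly among that gene's
    candidates, preserving per-gene counts (the conditional null).  The
    p-value uses the add-one estimator (1 + #{null >= obs}) / (1 + n_perm).
    ``statistic`` is ``prop_within`` or ``dimer_fraction``.
    """
    genes = sorted(candidates)
    cand: dict[str, np.ndarray] = {}
    k_called: dict[str, int] = {}
    for g in genes:
        cpos = np.array(sorted(set(candidates[g])))
        kpos = set(called.get(g, ()))
        if not kpos <= set(cpos.tolist()):
            raise ValueError(f"called positions of {g!r} not a subset of its candidates")
        if len(kpos) > len(cpos):
            raise ValueError(f"gene {g!r} has more called sites than candidates")
        cand[g] = cpos
        k_called[g] = len(kpos)

    def stat(pos_by_gene: Mapping[str, np.ndarray]) -> float:
        merged = {("g:" + g, "+"): p for g, p in pos_by_gene.items() if len(p)}
        if statistic == "prop_within":
            return prop_within(merged, d)
        if statistic == "dimer_fraction":
            return _dimer_fraction_positions(merged, {("g:" + g, "+"): cand[g] for g in genes})
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat({g: np.array(sorted(called.get(g, ()))) for g in genes})
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        drawn = {
            g: np.sort(rng.choice(cand[g], size=k_called[g], replace=False))
            for g in genes
            if k_called[g]
        }
        null[i] = stat(drawn)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    lo, hi = np.quantile(null, [0.005, 0.995])
    return PermutationResult(
        observed=float(observed),
        null_mean=float(null.mean()),
        null_ci99=(float(lo), float(hi)),
        pvalue=float(p),
        n_perm=n_perm,
    )


def _dimer_fraction_positions(
    called: Mapping[tuple[str, str], np.ndarray],
    candidates: Mapping[tuple[str, str], np.ndarray],
) -> float:
    n_total = 0
    n_dimer = 0
    for key, pos in called.items():
        n_total += len(pos)
        if len(pos) == 0:
            continue
        called_set = set(pos.tolist())
        cand_set = set(candidates.get(key, np.array([], dtype=int)).tolist())
        for p in pos:
            for q in (p - 1, p + 1):
                if q in cand_set and q in called_set:
                    n_dimer += 1
                    break
    return n_dimer / n_total if n_total else 0.0


def dimer_fraction(
    called: Mapping[str, Sequence[int]], candidates: Mapping[str, Sequence[int]]
) -> float:
    """Fraction of called sites whose adjacent (1 nt) candidate C is called."""
    c = {("g:" + g, "+"): np.array(sorted(set(v))) for g, v in called.items()}
    cand = {("g:" + g, "+"): np.array(sorted(set(v))) for g, v in candidates.items()}
    return _dimer_fraction_positions(c, cand)


def distance_correlation(
    results: Sequence[CallResult],
    bins: Sequence[tuple[int, int]] = DEFAULT_DISTANCE_BINS,
    min_pairs: int = 3,
) -> dict[tuple[int, int], float | None]:
    """Pearson correlation of methylation ratios by pair distance.

    For each inclusive distance bin, all same-chromosome/strand site pairs
    with |pos_i - pos_j| in the bin are collected; each unordered pair
    contributes both orientations (the symmetric estimator), which makes the
    result invariant to input order.  Bins with fewer than ``min_pairs``
    pairs report ``None``.
    """
    by: dict[tuple[str, str], list[tuple[int, float]]] = defaultdict(list)
    for r in results:
        by[(r.site.chrom, r.site.strand)].append((r.site.pos, r.mratio))
    max_d = max(hi for _, hi in bins)
    pairs: dict[tuple[int, int], list[tuple[float, float]]] = {b: [] for b in bins}
    for items in by.values():
        items.sort()
        pos = np.array([p for p, _ in items])
        mr = np.array([m for _, m in items])
        for i in range(len(pos)):
            j = i + 1
            while j < len(pos) and pos[j] - pos[i] <= max_d:
                dist = int(pos[j] - pos[i])
                for b in bins:
                    if b[0] <= dist <= b[1]:
                        pairs[b].append((mr[i], mr[j]))
                        break
                j += 1
    out: dict[tuple[int, int], float | None] = {}
    for b, pr in pairs.items():
        if len(pr) < min_pairs:
            out[b] = None
            continue
        x = np.array([a for a, _ in pr] + [c for _, c in pr])
        y = np.array([c for _, c in pr] + [a for a, _ in pr])
        if np.std(x) == 0 or np.std(y) == 0:
            out[b] = None
            continue
        out[b] = float(stats.pearsonr(x, y)[0])
    return out
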