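"""Statistical calling of methylated cytosines against background nonconversion.

Bisulfite chemistry leaves a noise floor: an unmethylated C fails to convert
with small probability p0 (the background nonconversion rate, 0.8-3% in
typical RNA BS-Seq libraries).  A site is therefore called methylated only
when its unconverted/converted odds significantly exceed the pooled
background odds, by a one-sided Fisher's exact test, with Benjamini-Hochberg
control of the FDR across sites.  For multi-replicate designs a site is
called only when it passes FDR < alpha in *every* replicate, and uncalled
sites are retained only when covered above the minimum in every replicate;
counts are summed across replicates for the combined record.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import CytosineSiteRecord, ValidationError

__all__ = [
    "Background",
    "CallResult",
    "mratio",
    "estimate_background",
    "call_site",
    "bh_adjust",
    "call_sites",
    "combine_replicates",
]

DEFAULT_MIN_COVERAGE = 10
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Background:
    """Pooled unconverted/converted counts over all retained sites."""

    b_meth: int
    b_unmeth: int

    def __post_init__(self) -> None:
        if self.b_meth < 0 or self.b_unmeth < 0:
            raise ValidationError("background totals must be non-negative")

    @property
    def total(self) -> int:
        return self.b_meth + self.b_unmeth

    @property
    def rate(self) -> float:
        if self.total == 0:
            raise ValidationError("background has zero total reads")
        return self.b_meth / self.total


@dataclass(frozen=True)
class CallResult:
    """A site with its methylation ratio, test result and binary call."""

    site: CytosineSiteRecord
    mratio: float
    pvalue: float
    fdr: float
    called: bool

    @property
    def key(self) -> tuple[str, int, str]:
        return self.site.key


def mratio(n_meth: int, n_unmeth: int) -> float:
    """Methylation ratio: unconverted / (unconverted + converted) reads.

    Equals 1 minus the bisulfite conversion rate at the site.
    """
    cov = n_meth + n_unmeth
    if cov <= 0:
        raise ValidationError("mratio undefined at zero coverage")
    return n_meth / cov


def estimate_background(sites: Sequence[CytosineSiteRecord]) -> Background:
    """Pool counts over all (already filtered) sites into the background.

    The pooled rate estimates the nonconversion floor because the vast
    majority of covered cytosines are unmethylated.
    """
    if not sites:
        raise ValidationError("cannot estimate background from an empty site list")
    return Background(
        b_meth=int(sum(s.n_meth for s in sites)),
        b_unmeth=int(sum(s.n_unmeth for s in sites)),
    )


def call_site(
    site: CytosineSiteRecord,
    bg: Background,
    mode: Literal["fisher", "binomial"] = "fisher",
    exclude_self: bool = True,
) -> float:
    """One-sided p-value for excess nonconversion at one site.

    ``fisher``: one-sided Fisher's exact test on
    ``[[n_meth, n_unmeth], [B_meth, B_unmeth]]`` with alternative "the site's
    unconverted odds exceed the background odds".  The site's own counts are
    subtracted from the background row first (when they are part of the pool)
    so the site is not tested against itself.  ``binomial``: the limiting
    one-sided binomial tail P(X >= n_meth), X ~ Binomial(coverage, p0).
    """
    p = _call_many(
        np.array([site.n_meth]), np.array([site.n_unmeth]), bg, mode, exclude_self
    )
    return float(p[0])


def _call_many(
    n_meth: np.ndarray,
    n_unmeth: np.ndarray,
    bg: Background,
    mode: str,
    exclude_self: bool,
) -> np.ndarray:
    if bg.total == 0:
        raise ValidationError("background has zero total reads")
    if exclude_self:
        b_meth = bg.b_meth - n_meth
        b_unmeth = bg.b_unmeth - n_unmeth
        if np.any(b_meth < 0) or np.any(b_unmeth < 0):
            # the pool did not contain this site; fall back to the full pool
            b_meth = np.maximum(b_meth, 0)
            b_unmeth = np.maximum(b_unmeth, 0)
    else:
        b_meth = np.full_like(n_meth, bg.b_meth)
        b_unmeth = np.full_like(n_unmeth, bg.b_unmeth)
    cov = n_meth + n_unmeth
    if mode == "binomial":
        rate = b_meth / (b_meth + b_unmeth)
        return stats.binom.sf(n_meth - 1, cov, rate)
    if mode != "fisher":
        raise ValueError(f"unknown calling mode {mode!r}")
    # One-sided Fisher = hypergeometric upper tail at the observed table,
    # conditioning on both margins.
    total = cov + b_meth + b_unmeth
    col1 = n_meth + b_meth
    return stats.hypergeom.sf(n_meth - 1, total, col1, cov)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sites(
    sites: Sequence[CytosineSiteRecord],
    background: Background | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    alpha: float = DEFAULT_ALPHA,
    mode: Literal["fisher", "binomial"] = "fisher",
) -> list[CallResult]:
    """Call one replicate: coverage filter, test every site, BH-adjust.

    When ``background`` is None it is pooled from ``sites`` themselves (all
    sites, before the coverage filter, since low-coverage sites still inform
    the nonconversion floor); each tested site is excluded from the pool.
    """
    if background is None:
        background = estimate_background(sites)
        exclude_self = True
    else:
        exclude_self = False
    kept = [s for s in sites if s.coverage >= min_coverage]
    if not kept:
        return []
    n_meth = np.array([s.n_meth for s in kept])
    n_unmeth = np.array([s.n_unmeth for s in kept])
    pvals = _call_many(n_meth, n_unmeth, background, mode, exclude_self)
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
    fdrs = bh_adjust(pvals)
    return [
        CallResult(
            site=s,
            mratio=mratio(s.n_meth, s.n_unmeth),
            pvalue=float(p),
            fdr=float(f),
            called=bool(f < alpha),
        )
        for s, p, f in zip(kept, pvals, fdrs)
    ]


def combine_replicates(
    per_replicate: Sequence[Sequence[CallResult]],
    alpha: float = DEFAULT_ALPHA,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[CallResult]:
    """Combine replicate-level calls into consensus site records.

    A site is called methylated iff FDR < alpha in every replicate.  A
    non-called site is retained iff it is present with coverage > the
    minimum in every replicate.  Counts are summed across replicates; the
    reported p-value/FDR of a combined site is the maximum across replicates
    (the binding constraint of the every-replicate rule).

    With a single replicate this is the identity.
    """
    if not per_replicate:
        return []
    if len(per_replicate) == 1:
        return list(per_replicate[0])
    maps = [{r.key: r for r in rep} for rep in per_replicate]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    out: list[CallResult] = []
    for key in sorted(common):
        results = [m[key] for m in maps]
        called = all(r.called for r in results)
        if not called and not all(r.site.coverage > min_coverage for r in results):
            continue
        first = results[0].site
        n_meth = sum(r.site.n_meth for r in results)
        n_unmeth = sum(r.site.n_unmeth for r in results)
        combined_site = replace(
            first, n_meth=n_meth, n_unmeth=n_unmeth, replicate_id="combined"
        )
        out.append(
            CallResult(
                site=combined_site,
                mratio=mratio(n_meth, n_unmeth),
                pvalue=max(r.pvalue for r in results),
                fdr=max(r.fdr for r in results),
                called=called,
            )
        )
    return out
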