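"""Methylation vs expression change and mRNA half-life.

Expression and methylation are both quantified from the same bisulfite
libraries, so their errors are coupled; the replicate-splitting device
decouples them by estimating expression fold change from one replicate and
methylation fold change from the other two, over all three leave-one-in
splits.  Half-life association fits a binomial-family GLM (logistic
regression of methylation status on log half-life with log2 expression as
the calling-depth confounder); a tricube local-linear regression draws the
half-life trend within a fixed expression window.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import diff_or
from .formats_io import ValidationError

__all__ = [
    "split_replicates",
    "expression_fc",
    "methylation_fc",
    "fc_correlation",
    "run_fc_splits",
    "halflife_glm",
    "GlmFit",
    "local_regression",
]


def split_replicates(replicates: Sequence[str]) -> list[tuple[str, tuple[str, str]]]:
    """The three leave-one-in splits of a 3-replicate design.

    Expression comes from the singleton, methylation from the pair; splits
    are ordered lexicographically by the expression replicate.
    """
    if len(replicates) != 3 or len(set(replicates)) != 3:
        raise ValueError(
            "replicate splitting needs exactly 3 distinct replicates; "
            "supply explicit splits otherwise"
        )
    reps = sorted(replicates)
    return [(r, tuple(sorted(set(reps) - {r}))) for r in reps]


def expression_fc(
    counts_1: Mapping[str, int], counts_2: Mapping[str, int], pseudocount: float = 0.5
) -> dict[str, float]:
    """Per-gene log2 expression fold change with median-of-ratios scaling.

    Size factors are the median over genes of count / geometric mean (genes
    with a zero in either sample are excluded from the factor, as usual for
    the geometric-mean reference); the fold change is
    ``log2((c1/s1 + pseudocount) / (c2/s2 + pseudocount))``.  Genes zero in
    both samples are dropped.
    """
    genes = sorted(set(counts_1) & set(counts_2))
    c1 = np.array([counts_1[g] for g in genes], dtype=float)
    c2 = np.array([counts_2[g] for g in genes], dtype=float)
    keep = (c1 > 0) | (c2 > 0)
    genes = [g for g, k in zip(genes, keep) if k]
    c1, c2 = c1[keep], c2[keep]
    both = (c1 > 0) & (c2 > 0)
    if both.sum() == 0:
        raise ValidationError("no gene with nonzero counts in both samples")
    geo = np.sqrt(c1[both] * c2[both])
    s1 = float(np.median(c1[both] / geo))
    s2 = float(np.median(c2[both] / geo))
    fc = np.log2((c1 / s1 + pseudocount) / (c2 / s2 + pseudocount))
    return dict(zip(genes, fc.tolist()))


def methylation_fc(
    pooled_1: Mapping[str, tuple[int, int]], pooled_2: Mapping[str, tuple[int, int]]
) -> dict[str, float]:
    """Per-gene log2 methylation odds ratio from pooled counts."""
    out = {}
    for g in sorted(set(pooled_1) & set(pooled_2)):
        m1, u1 = pooled_1[g]
        m2, u2 = pooled_2[g]
        if m1 + u1 == 0 or m2 + u2 == 0:
            continue
        orr, _ = diff_or((m1, u1), (m2, u2))
        out[g] = float(np.log2(orr))
    return out


def fc_correlation(
    expr_fc: Mapping[str, float], meth_fc: Mapping[str, float], min_genes: int = 10
) -> tuple[float, int]:
    """Pearson correlation of the two fold-change vectors over common genes."""
    genes = sorted(set(expr_fc) & set(meth_fc))
    if len(genes) < min_genes:
        raise ValidationError(f"only {len(genes)} genes common to both vectors")
    x = np.array([expr_fc[g] for g in genes])
    y = np.array([meth_fc[g] for g in genes])
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("degenerate fold-change variance")
        return float("nan"), len(genes)
    return float(np.corrcoef(x, y)[0, 1]), len(genes)


def run_fc_splits(
    expr: pd.DataFrame, meth: pd.DataFrame, min_genes: int = 10
) -> pd.DataFrame:
    """Replicate-splitting correlation analysis on long-format count frames.

    ``expr`` columns: gene_id, condition, replicate, count.  ``meth``
    columns: gene_id, condition, replicate, n_meth, n_unmeth.  Both must
    hold two conditions with the same three replicate labels.  For each
    split, expression FC uses the singleton replicate of each condition and
    methylation FC the pooled pair, so no replicate informs both sides.
    """
    conds = sorted(expr["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    reps = sorted(expr["replicate"].unique())
    rows = []
    for expr_rep, meth_reps in split_replicates(reps):
        counts = {
            c: expr[(expr.condition == c) & (expr.replicate == expr_rep)]
            .set_index("gene_id")["count"]
            .to_dict()
            for c in conds
        }
        pooled = {}
        for c in conds:
            sub = meth[(meth.condition == c) & (meth.replicate.isin(meth_reps))]
            agg = sub.groupby("gene_id")[["n_meth", "n_unmeth"]].sum()
            pooled[c] = {g: (int(r.n_meth), int(r.n_unmeth)) for g, r in agg.iterrows()}
        efc = expression_fc(counts[conds[0]], counts[conds[1]])
        mfc = methylation_fc(pooled[conds[0]], pooled[conds[1]])
        r, n = fc_correlation(efc, mfc, min_genes=min_genes)
        rows.append({"split": expr_rep, "pearson_r": r, "n_genes": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlmFit:
    """Logistic-regression fit: methylated ~ log(half-life) + log2 expression."""

    coef: dict[str, float]
    se: dict[str, float]
    wald_p: dict[str, float]
    converged: bool
    separated: bool
    n_iter: int
    n_obs: int


def halflife_glm(
    methylated: Sequence[int],
    log_halflife: Sequence[float],
    log2_expr: Sequence[float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Binomial-family GLM linking methylation status to mRNA half-life.

    Fitted by iteratively reweighted least squares until the score norm
    drops below ``tol``; Wald p-values from the observed information.
    Complete separation is flagged (coefficients reported at the iteration
    cap with a warning).
    """
    y = np.asarray(methylated, dtype=float)
    names = ["intercept", "log_halflife"]
    cols = [np.ones_like(y), np.asarray(log_halflife, dtype=float)]
    if log2_expr is not None:
        names.append("log2_expr")
        cols.append(np.asarray(log2_expr, dtype=float))
    X = np.column_stack(cols)
    if y.size < X.shape[1] + 1 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("need a binary response with more rows than parameters")
    for cls in (0.0, 1.0):
        if np.sum(y == cls) < 3:
            raise ValueError(f"fewer than 3 observations in class {int(cls)}")
    beta = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    separated = bool(np.all(np.abs(mu - y) < 1e-6)) or bool(
        np.max(np.abs(beta)) > 25
    )
    if separated:
        warnings.warn("possible complete separation; coefficients unreliable")
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    from scipy import stats as _st

    pvals = 2 * _st.norm.sf(np.abs(z))
    return GlmFit(
        coef=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        wald_p=dict(zip(names, pvals.tolist())),
        converged=converged,
        separated=separated,
        n_iter=n_iter,
        n_obs=int(y.size),
    )


def local_regression(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    grid: Sequence[float] | None = None,
    n_grid: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local linear fit evaluated on a grid.

    At each grid point the ``span`` fraction of nearest data points gets
    tricube weights by scaled distance and a weighted straight line is
    fitted; the fit therefore reproduces globally linear data exactly.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must lie in (0, 1], got {span}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    k = max(2, int(np.ceil(span * x.size)))
    fit = np.empty_like(grid)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            fit[i] = float(np.mean(y[idx]))
            continue
        w = (1 - np.clip(d[idx] / h, 0, 1) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        X = np.column_stack([np.ones(idx.size), x[idx] - g])
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ y[idx])
        fit[i] = beta[0]
    return grid, fit
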