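"""Per-gene difference-in-proportions testing with multiple-testing control.

For each gene (or allele) *k*, the null hypothesis is that the proportion
of clonotypes using *k* is the same in both repertoire sets.  With x1 of
n1 clonotypes in set 1 and x2 of n2 in set 2, the large-sample score
statistic is

    z = (p1k - p2k) / sqrt( p(1-p) (1/n1 + 1/n2) ),   p = (x1+x2)/(n1+n2)

with the Wald (unpooled) standard error used for the confidence interval
on the difference.  When any of the four expected counts n1*p1k,
n1*(1-p1k), n2*p2k, n2*(1-p2k) is below 5 the normal approximation is
unreliable and Fisher's exact test on the 2x2 table replaces it.

Because one run tests every gene of the V, D and J groups jointly, raw
p-values are adjusted by seven procedures over that whole family:
familywise controls (Bonferroni, Holm, Hochberg, Sidak single-step and
step-down) and false-discovery-rate controls (Benjamini-Hochberg,
Benjamini-Yekutieli).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .repertoire import GeneCountTable

__all__ = [
    "PROCEDURES",
    "PropTestRow",
    "RejectionCurve",
    "small_count_guard",
    "ztest_two_proportions",
    "fisher_exact_two_sided",
    "adjust_pvalues",
    "run_comparison",
    "rejection_curves",
    "scatter_table",
]

#: the seven supported p-value adjustment procedures, in reporting order
PROCEDURES = ("bonferroni", "holm", "hochberg", "sidakSS", "sidakSD", "BH", "BY")

SMALL_COUNT_THRESHOLD = 5.0

#: -log10 cap applied where an adjusted or raw p underflows to exactly 0
NEGLOG10_CAP = -math.log10(np.finfo(float).tiny)

DEFAULT_ALPHA_GRID = np.round(np.arange(0.001, 0.2501, 0.001), 6)


def small_count_guard(x1: int, n1: int, x2: int, n2: int) -> bool:
    """True when the z approximation is invalid and Fisher must be used.

    Triggers when ANY of the four expected counts n*p, n*(1-p) per set
    falls below 5 (the classical validity rule for the normal
    approximation to a binomial proportion).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("set totals must be positive")
    p1, p2 = x1 / n1, x2 / n2
    return min(n1 * p1, n1 * (1.0 - p1), n2 * p2, n2 * (1.0 - p2)) < SMALL_COUNT_THRESHOLD


def ztest_two_proportions(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float, float, float, float]:
    """Pooled two-proportion z-test with an unpooled Wald CI.

    Returns ``(z, rawp, diff, ci_low, ci_high)``.  Caller must have
    checked :func:`small_count_guard`; calling with guarded counts is a
    contract violation.
    """
    if small_count_guard(x1, n1, x2, n2):
        raise ValueError(
            "small-count guard triggered: use fisher_exact_two_sided instead"
        )
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    pooled = (x1 + x2) / (n1 + n2)
    se_pooled = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = diff / se_pooled
    rawp = 2.0 * stats.norm.sf(abs(z))
    se_wald = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return z, min(rawp, 1.0), diff, diff - crit * se_wald, diff + crit * se_wald


def fisher_exact_two_sided(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided Fisher exact p for the table [[x1, n1-x1], [x2, n2-x2]].

    Probability-mass rule: the p-value sums hypergeometric probabilities
    of all tables with the observed margins whose probability does not
    exceed that of the observed table.
    """
    if x1 == 0 and x2 == 0:
        return 1.0
    _, p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]], alternative="two-sided")
    return float(min(p, 1.0))


def adjust_pvalues(rawp: Sequence[float], procedure: str) -> np.ndarray:
    """Adjust a family of raw p-values by one procedure.

    Supported procedures: bonferroni, holm, hochberg, sidakSS, sidakSD,
    BH, BY.  Results are returned in the input order and clipped to
    [rawp, 1].
    """
    p = np.asarray(rawp, dtype=float)
    if p.ndim != 1:
        raise ValueError("rawp must be one-dimensional")
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("raw p-values must lie in [0, 1]")

    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1)

    if procedure == "bonferroni":
        adj = np.minimum(1.0, p * m)
        return adj
    if procedure == "sidakSS":
        return 1.0 - (1.0 - p) ** m
    if procedure == "holm":
        adj_s = np.maximum.accumulate(np.minimum(1.0, (m - i + 1) * ps))
    elif procedure == "sidakSD":
        adj_s = np.maximum.accumulate(1.0 - (1.0 - ps) ** (m - i + 1))
    elif procedure == "hochberg":
        adj_s = np.minimum.accumulate(np.minimum(1.0, (m - i + 1) * ps)[::-1])[::-1]
    elif procedure == "BH":
        adj_s = np.minimum.accumulate(np.minimum(1.0, (m / i) * ps)[::-1])[::-1]
    elif procedure == "BY":
        c_m = np.sum(1.0 / np.arange(1, m + 1))
        adj_s = np.minimum.accumulate(np.minimum(1.0, (m * c_m / i) * ps)[::-1])[::-1]
    else:
        raise ValueError(f"unknown procedure {procedure!r}; choose from {PROCEDURES}")

    adj = np.empty(m)
    adj[order] = adj_s
    return adj


@dataclass
class PropTestRow:
    """Full statistical result for one gene or allele."""

    item: str
    gene_type: str
    level: str
    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    diff: float
    ci_low: float
    ci_high: float
    z: float | None
    method: str  # "z" | "fisher"
    rawp: float
    adj: dict[str, float] = field(default_factory=dict)
    interpretation: str = ""


def _interpret(rawp: float, adj: dict[str, float], alpha: float) -> str:
    hits = []
    if rawp < alpha:
        hits.append("rawp")
    hits.extend(proc for proc in PROCEDURES if adj.get(proc, 1.0) < alpha)
    return ",".join(hits) if hits else "NS"


def run_comparison(
    tables: GeneCountTable | Iterable[GeneCountTable],
    alpha: float = 0.05,
) -> list[PropTestRow]:
    """Test every single gene (or allele) of one or more count tables.

    The adjustment family is all items across the given tables jointly
    (e.g. all V, D and J genes of one locus in one run), mirroring how a
    whole-locus comparison multiplies hypotheses.  Items routed to Fisher
    by the small-count guard form the small-occurrence report accessible
    through each row's ``method`` field.
    """
    if isinstance(tables, GeneCountTable):
        tables = [tables]
    tables = list(tables)
    levels = {t.level for t in tables}
    if len(levels) > 1:
        raise ValueError("cannot mix gene-level and allele-level tables in one family")

    rows: list[PropTestRow] = []
    for table in tables:
        n1, n2 = table.totals
        if n1 <= 0 or n2 <= 0:
            raise ValueError("set totals must be positive")
        for item, (x1, x2) in table.rows.items():
            p1, p2 = x1 / n1, x2 / n2
            diff = p1 - p2
            if small_count_guard(x1, n1, x2, n2):
                rawp = fisher_exact_two_sided(x1, n1, x2, n2)
                # Wald CI is still reported for display, its normal
                # approximation caveat applies at these counts
                se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
                crit = stats.norm.ppf(1 - alpha / 2)
                row = PropTestRow(
                    item=item, gene_type=table.gene_type, level=table.level,
                    x1=x1, n1=n1, x2=x2, n2=n2, p1=p1, p2=p2, diff=diff,
                    ci_low=diff - crit * se, ci_high=diff + crit * se,
                    z=None, method="fisher", rawp=rawp,
                )
            else:
                z, rawp, diff, lo, hi = ztest_two_proportions(x1, n1, x2, n2, alpha)
                row = PropTestRow(
                    item=item, gene_type=table.gene_type, level=table.level,
                    x1=x1, n1=n1, x2=x2, n2=n2, p1=p1, p2=p2, diff=diff,
                    ci_low=lo, ci_high=hi, z=z, method="z", rawp=rawp,
                )
            rows.append(row)

    rawps = [r.rawp for r in rows]
    for proc in PROCEDURES:
        adj = adjust_pvalues(rawps, proc)
        for r, a in zip(rows, adj):
            r.adj[proc] = float(a)
    for r in rows:
        r.interpretation = _interpret(r.rawp, r.adj, alpha)
    return rows


@dataclass
class RejectionCurve:
    """Rejected-hypothesis counts over an alpha grid for one procedure."""

    procedure: str  # one of PROCEDURES or "rawp"
    alphas: np.ndarray
    n_rejected: np.ndarray


def rejection_curves(
    rows: Sequence[PropTestRow],
    procedures: Sequence[str] = PROCEDURES,
    alpha_grid: np.ndarray | None = None,
) -> list[RejectionCurve]:
    """Count rejections per alpha for the raw and each adjusted p family."""
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    curves = []
    for proc in ["rawp", *procedures]:
        pvals = np.array(
            [r.rawp if proc == "rawp" else r.adj[proc] for r in rows], dtype=float
        )
        counts = (pvals[None, :] < grid[:, None]).sum(axis=1)
        curves.append(RejectionCurve(proc, grid.copy(), counts))
    return curves


def scatter_table(rows: Sequence[PropTestRow], alpha: float = 0.05):
    """Scatter-plot data: z against -log10 of raw and adjusted p-values.

    Fisher-method rows carry no z.  p-values of exactly 0 are capped at
    :data:`NEGLOG10_CAP` instead of infinity.  ``significant`` flags raw
    p below alpha (the highlighted points), ``sign`` the direction of the
    difference in proportions.
    """
    import pandas as pd

    def neglog10(p: float) -> float:
        return NEGLOG10_CAP if p <= 0.0 else min(-math.log10(p), NEGLOG10_CAP)

    data = {
        "item": [r.item for r in rows],
        "gene_type": [r.gene_type for r in rows],
        "z": [r.z if r.method == "z" else np.nan for r in rows],
        "method": [r.method for r in rows],
        "neglog10_rawp": [neglog10(r.rawp) for r in rows],
    }
    for proc in PROCEDURES:
        data[f"neglog10_{proc}"] = [neglog10(r.adj[proc]) for r in rows]
    data["sign"] = [int(np.sign(r.diff)) for r in rows]
    data["significant"] = [r.rawp < alpha for r in rows]
    return pd.DataFrame(data)
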