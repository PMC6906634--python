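"""Hierarchical group inference on firing statistics.

The design: for each predictor (genotype, plus continuous covariates
binarized at their median), an omnibus one-way MANOVA asks whether the
joint mean of the response vector (firing rate, CV, CV2) differs between
the two predictor levels.  Only when the omnibus test rejects at
``alpha = 0.05`` are per-response pairwise Wilcoxon rank-sum tests run,
and their p-values corrected with the Benjamini-Hochberg step-up procedure
at a false discovery rate of 0.2.  Anatomical comparisons available only
as published summary statistics enter through :func:`t_from_summary`.

Wilk's lambda is ``det(E)/det(E+H)`` with E and H the within- and
between-group SSCP matrices.  For two groups and p responses the exact-F
identity is ``F = ((1-lambda)/lambda) * (N-p-1)/p`` on ``(p, N-p-1)``
degrees of freedom; reports additionally display the conventional
``(g-1, N-g)`` group degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .types import InvalidSpecification

__all__ = [
    "ManovaResult",
    "PairwiseResult",
    "TTestResult",
    "StatReport",
    "wilks_lambda_to_f",
    "wilks_manova",
    "wilcoxon_ranksum",
    "benjamini_hochberg",
    "median_split",
    "t_from_summary",
    "build_response_matrix",
    "analysis_workflow",
]

RESPONSES = ("rate_hz", "cv", "cv2")


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df_hypothesis: int
    df_error: int
    df_groups: tuple[int, int]  # display convention (g-1, N-g)
    p: float
    n_per_group: tuple[int, ...]


@dataclass(frozen=True)
class PairwiseResult:
    response: str
    z: float
    p: float
    bh_critical: float
    rejected: bool
    direction: str  # which level tends larger


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class StatReport:
    """Structured record of the full decision tree, JSON-serializable."""

    unit_type: str
    alpha: float
    fdr: float
    predictors: dict[str, dict] = field(default_factory=dict)
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        def enc(o):
            if isinstance(o, (ManovaResult, PairwiseResult, TTestResult)):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.bool_):
                return bool(o)
            raise TypeError(type(o))

        return json.dumps(
            {
                "unit_type": self.unit_type,
                "alpha": self.alpha,
                "fdr": self.fdr,
                "n_dropped": self.n_dropped,
                "warnings": self.warnings,
                "predictors": self.predictors,
            },
            default=enc, indent=2, **kwargs,
        )


def wilks_lambda_to_f(lam: float, n_total: int, p: int) -> tuple[float, int, int, float]:
    """Exact two-group conversion of Wilk's lambda to an F statistic.

    ``F = ((1-lambda)/lambda) * (N-p-1)/p`` on ``(p, N-p-1)`` degrees of
    freedom; returns (F, df_hypothesis, df_error, p-value).
    """
    if not (0 < lam <= 1):
        raise InvalidSpecification("lambda must lie in (0, 1]")
    df_h, df_e = p, n_total - p - 1
    if df_e <= 0:
        raise InvalidSpecification("need more observations than responses")
    f = ((1.0 - lam) / lam) * (df_e / df_h)
    return float(f), df_h, df_e, float(stats.f.sf(f, df_h, df_e))


def wilks_manova(X: np.ndarray, labels: np.ndarray) -> ManovaResult:
    """One-way two-group MANOVA via Wilk's lambda with the exact-F conversion.

    ``X`` is (n cells, p responses); ``labels`` assigns each row to one of
    exactly two groups, each with more rows than responses.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2:
        raise InvalidSpecification("X must be 2-D (cells x responses)")
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise InvalidSpecification("exactly two groups are required")
    n, p = X.shape
    groups = [X[labels == g] for g in levels]
    for g in groups:
        if len(g) <= p:
            raise InvalidSpecification("each group needs more cells than responses")
    grand = X.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in groups:
        d = g - g.mean(axis=0)
        E += d.T @ d
        m = g.mean(axis=0) - grand
        H += len(g) * np.outer(m, m)
    det_e = np.linalg.det(E)
    if det_e <= 0 or not np.isfinite(det_e):
        raise InvalidSpecification("singular within-group covariance")
    lam = float(min(det_e / np.linalg.det(E + H), 1.0))
    f, df_h, df_e, pval = wilks_lambda_to_f(lam, n, p)
    return ManovaResult(
        wilks_lambda=lam, f_stat=float(f), df_hypothesis=df_h, df_error=df_e,
        df_groups=(1, n - 2), p=pval,
        n_per_group=tuple(len(g) for g in groups),
    )


def wilcoxon_ranksum(x, y, continuity: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test via the normal approximation.

    Midranks handle ties, with the tie-corrected variance.  The z sign is
    positive when the first sample tends larger.  ``continuity`` applies the
    0.5 continuity correction (off by default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidSpecification("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    d = w - mu
    if continuity and d != 0:
        d -= 0.5 * np.sign(d)
    z = d / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def benjamini_hochberg(pvals, fdr: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Sort the m p-values ascending; the i-th critical value is
    ``(i/m) * fdr``; reject every hypothesis whose rank is at most the
    largest i with ``p_(i) <= (i/m) * fdr``.  Returns (reject flags,
    critical values), both in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise InvalidSpecification("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    crit_sorted = (np.arange(1, m + 1) / m) * fdr
    passed = p[order] <= crit_sorted
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0]))
        reject[order[: k + 1]] = True
    crit = np.empty(m)
    crit[order] = crit_sorted
    return reject, crit


def median_split(values) -> tuple[np.ndarray, bool]:
    """Binarize a covariate at its median: <= median -> "low", else "high".

    The median is the midpoint of the central order statistics.  Returns
    (labels, degenerate) where degenerate flags a single-class split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidSpecification("need at least two values to split")
    med = float(np.median(v))
    labels = np.where(v <= med, "low", "high")
    degenerate = len(np.unique(labels)) < 2
    return labels, degenerate


def t_from_summary(mean1: float, sem1: float, n1: int,
                   mean2: float, sem2: float, n2: int) -> TTestResult:
    """Two-sample two-tailed Student's t-test from group summary statistics.

    For equal n this reduces to ``t = (m1 - m2)/sqrt(sem1^2 + sem2^2)``;
    unequal n uses the pooled-variance form.  df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidSpecification("each group needs n >= 2")
    if n1 == n2:
        denom = np.sqrt(sem1**2 + sem2**2)
    else:
        s1sq = sem1**2 * n1
        s2sq = sem2**2 * n2
        sp2 = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    if denom == 0:
        return TTestResult(t=float("inf") if mean1 != mean2 else 0.0, df=df,
                           p=0.0 if mean1 != mean2 else 1.0)
    t = (mean1 - mean2) / denom
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def build_response_matrix(metrics: pd.DataFrame, unit_type: str,
                          responses: tuple[str, ...] = RESPONSES
                          ) -> tuple[pd.DataFrame, int]:
    """Select one unit type and drop cells with any undefined response.

    Returns (complete rows incl. metadata, number of dropped cells).
    """
    sub = metrics[metrics["unit_type"] == unit_type].copy()
    complete = sub.dropna(subset=list(responses))
    return complete.reset_index(drop=True), len(sub) - len(complete)


def _pairwise_stage(df: pd.DataFrame, labels: np.ndarray, level_order: list,
                    responses: tuple[str, ...], fdr: float) -> list[PairwiseResult]:
    zs, ps, dirs = [], [], []
    a, b = level_order
    for r in responses:
        x = df.loc[labels == a, r].to_numpy()
        y = df.loc[labels == b, r].to_numpy()
        z, p = wilcoxon_ranksum(x, y)
        zs.append(z)
        ps.append(p)
        dirs.append(f"{a} > {b}" if z > 0 else (f"{b} > {a}" if z < 0 else "tied"))
    reject, crit = benjamini_hochberg(ps, fdr)
    return [
        PairwiseResult(response=r, z=z, p=p, bh_critical=float(c),
                       rejected=bool(rej), direction=d)
        for r, z, p, c, rej, d in zip(responses, zs, ps, crit, reject, dirs)
    ]


def analysis_workflow(metrics: pd.DataFrame, unit_type: str,
                      predictors: tuple[str, ...] = ("genotype",
                                                     "days_post_surgery",
                                                     "depth_mm"),
                      alpha: float = 0.05, fdr: float = 0.2,
                      responses: tuple[str, ...] = RESPONSES) -> StatReport:
    """Run the full omnibus-gated inference for one unit type.

    Categorical predictors are used as-is; numeric ones are median-split
    into low/high.  The pairwise Wilcoxon stage runs only when the omnibus
    MANOVA p-value is below ``alpha``; Benjamini-Hochberg correction is
    applied within each predictor's family of per-response p-values.
    """
    report = StatReport(unit_type=unit_type, alpha=alpha, fdr=fdr)
    df, dropped = build_response_matrix(metrics, unit_type, responses)
    report.n_dropped = dropped
    if df.empty:
        report.warnings.append(f"no complete cells for unit type {unit_type!r}")
        return report
    X = df[list(responses)].to_numpy()
    for pred in predictors:
        entry: dict = {}
        col = df[pred]
        if pd.api.types.is_numeric_dtype(col):
            labels, degenerate = median_split(col.to_numpy())
            entry["binarized"] = True
            if degenerate:
                report.warnings.append(
                    f"predictor {pred!r} is constant; skipped")
                entry["skipped"] = "degenerate median split"
                report.predictors[pred] = entry
                continue
        else:
            labels = col.to_numpy()
            entry["binarized"] = False
            if len(pd.unique(labels)) < 2:
                report.warnings.append(
                    f"predictor {pred!r} has a single level; skipped")
                entry["skipped"] = "single level"
                report.predictors[pred] = entry
                continue
        level_order = list(pd.unique(labels))
        try:
            manova = wilks_manova(X, labels)
        except InvalidSpecification as err:
            report.warnings.append(f"predictor {pred!r}: {err}")
            entry["skipped"] = str(err)
            report.predictors[pred] = entry
            continue
        entry["manova"] = manova
        entry["gate_passed"] = manova.p < alpha
        if entry["gate_passed"]:
            entry["pairwise"] = _pairwise_stage(df, labels, level_order,
                                                responses, fdr)
        report.predictors[pred] = entry
    return report
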