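"""Survival stratification: signature clustering, Kaplan-Meier estimation
and the two-group log-rank test.

A survival table is a data frame with columns ``sample_id, time, event``
(event = 1 for an observed death, 0 for censoring) plus an optional binary
``group`` column.  At tied times events are handled before censorings
(standard product-limit convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ValidationError
from .expression import ExpressionMatrix


def _validate_survival(table: pd.DataFrame, need_group: bool = False) -> pd.DataFrame:
    required = ["time", "event"] + (["group"] if need_group else [])
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"survival table missing column(s) {missing}")
    t = table["time"].astype(float)
    e = table["event"].astype(int)
    if (t < 0).any():
        raise ValidationError("negative follow-up times")
    if not set(e.unique()).issubset({0, 1}):
        raise ValidationError("event indicator must be 0/1")
    return table


@dataclass
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    all_censored: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    With zero events the curve is flat at 1 and flagged ``all_censored``.
    """
    table = _validate_survival(table)
    t = table["time"].astype(float).to_numpy()
    e = table["event"].astype(int).to_numpy()
    if e.sum() == 0:
        return KMCurve(
            event_times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([], dtype=int),
            all_censored=True,
        )
    times = np.unique(t[e == 1])
    surv = []
    risk = []
    s = 1.0
    for ti in times:
        n_at_risk = int((t >= ti).sum())  # censored at ti still at risk for ti
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risk.append(n_at_risk)
    return KMCurve(
        event_times=times, survival=np.array(surv), at_risk=np.array(risk, dtype=int)
    )


@dataclass
class LogrankResult:
    chi_square: float
    p: float
    group_sizes: tuple[int, int]
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_test(table: pd.DataFrame) -> LogrankResult:
    """Standard two-group log-rank test with 1 degree of freedom.

    At each distinct event time the observed group-1 events are compared
    with their hypergeometric expectation; chi-square = (O - E)^2 / V.
    """
    table = _validate_survival(table, need_group=True)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    t = table["time"].astype(float).to_numpy()
    e = table["event"].astype(int).to_numpy()
    g = (table["group"] == groups[1]).to_numpy()  # True = group 1
    if e.sum() == 0:
        raise ValidationError("no events observed")

    observed = 0.0
    expected = 0.0
    variance = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & g).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        raise ValidationError("log-rank variance is zero")
    chi = (observed - expected) ** 2 / variance
    p = float(np.clip(stats.chi2.sf(chi, df=1), np.finfo(float).tiny, 1.0))
    n0 = int((~g).sum())
    d_total = float(e.sum())
    return LogrankResult(
        chi_square=float(chi),
        p=p,
        group_sizes=(n0, int(g.sum())),
        observed=(d_total - observed, observed),
        expected=(d_total - expected, expected),
    )


def two_group_clustering(
    expr_subset: ExpressionMatrix | pd.DataFrame,
    metric: str = "euclidean",
    linkage_method: str = "average",
) -> pd.Series:
    """Cut an agglomerative tree over z-scored signature profiles into 2 groups.

    Genes are z-scored before the sample-sample distance is computed.  Label
    0 is assigned to the cluster with the lower mean (z-scored) signature
    expression so the output is reproducible.
    """
    values = expr_subset.values if isinstance(expr_subset, ExpressionMatrix) else expr_subset
    values = values.astype(float)
    if values.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if values.shape[0] < 1:
        raise ValidationError("need >= 1 signature gene")
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValidationError("zero-variance signature gene(s)")
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    X = z.T.to_numpy()  # samples x genes
    Z = linkage(X, method=linkage_method, metric=metric)
    raw = fcluster(Z, t=2, criterion="maxclust")
    labels = pd.Series(raw, index=values.columns)
    means = z.mean(axis=0)  # per-sample mean signature level
    cluster_means = {c: means[labels == c].mean() for c in labels.unique()}
    if len(cluster_means) == 1:
        raise ValidationError("clustering produced a single group")
    low = min(cluster_means, key=lambda c: (cluster_means[c], str(c)))
    return (labels != low).astype(int)
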