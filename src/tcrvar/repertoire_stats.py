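"""Per-sample descriptive statistics of a clonotype repertoire.

TOP-N subsets, cumulative clone-frequency curves, Shannon-Wiener diversity
and clone-frequency bin summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .repertoire_io import Repertoire

#: default half-open frequency bin thresholds, largest first
DEFAULT_BIN_EDGES = (1e-1, 1e-2, 1e-3, 1e-4)


@dataclass
class CumulativeCurve:
    """Cumulative frequency covered by the k most expanded clones, k = 1..N."""

    n_values: np.ndarray
    cum_freq: np.ndarray

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.cum_freq = np.asarray(self.cum_freq, dtype=float)
        if np.any(np.diff(self.cum_freq) < -1e-12):
            raise ValidationError("cumulative curve must be non-decreasing")
        if self.cum_freq.size and self.cum_freq[-1] > 1.0 + 1e-6:
            raise ValidationError("cumulative curve exceeds 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_values, "cum_freq": self.cum_freq})


@dataclass
class DiversityResult:
    shannon: float
    normalized_shannon: float
    richness: int


def top_n(rep: Repertoire, n: int = 100) -> Repertoire:
    """The min(n, richness) most frequent clones as a non-renormalized subset.

    Ties at the cut rank are broken by clone key ascending, so TOP-N
    membership is deterministic.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    picked = rep.sorted_clones()[: min(n, rep.richness)]
    return Repertoire(
        sample_id=rep.sample_id,
        stage=rep.stage,
        clones=tuple(c for _, c in picked),
        key_mode=rep.key_mode,
        strip_alleles=rep.strip_alleles,
        is_subset=True,
    )


def cumulative_frequency_curve(rep: Repertoire, n_max: int) -> CumulativeCurve:
    """cum_freq[k] = sum of the k largest clone frequencies, k = 1..n_max.

    Beyond the sample's richness the curve stays at the total frequency.
    """
    if n_max < 1:
        raise ValidationError(f"n_max must be >= 1, got {n_max}")
    freqs = np.sort([c.frequency for c in rep.clones])[::-1]
    cum = np.cumsum(freqs)
    if n_max <= cum.size:
        out = cum[:n_max]
    else:
        out = np.concatenate([cum, np.full(n_max - cum.size, cum[-1])])
    return CumulativeCurve(n_values=np.arange(1, n_max + 1), cum_freq=out)


def shannon_diversity(rep: Repertoire, base: float = math.e) -> DiversityResult:
    """Shannon-Wiener index over clone frequencies (natural log by default)."""
    p = np.array([c.frequency for c in rep.clones], dtype=float)
    if np.any(p <= 0):
        raise ValidationError("all clone frequencies must be positive")
    richness = p.size
    shannon = float(-(p * (np.log(p) / math.log(base))).sum()) if richness > 1 else 0.0
    shannon = max(shannon, 0.0)
    if richness > 1:
        normalized = shannon / (math.log(richness) / math.log(base))
    else:
        normalized = 0.0
    return DiversityResult(shannon=shannon, normalized_shannon=normalized, richness=richness)


def frequency_bin_summary(
    rep: Repertoire, bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Count clones per half-open frequency bin defined by decreasing edges.

    Edges (e1, ..., em) in (0, 1] define bins [e1, 1], [e2, e1), ...,
    (0, em).  Returns columns ``bin, n_clones, percent`` with percents
    summing to 100.
    """
    edges = tuple(float(e) for e in bin_edges)
    if not edges or any(not (0.0 < e <= 1.0) for e in edges):
        raise ValidationError("bin edges must lie in (0, 1]")
    if any(a <= b for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly decreasing")

    labels = [f">={edges[0]:g}"]
    labels += [f"[{lo:g},{hi:g})" for hi, lo in zip(edges, edges[1:])]
    labels += [f"<{edges[-1]:g}"]
    counts = [0] * (len(edges) + 1)
    for c in rep.clones:
        idx = len(edges)  # below the smallest edge
        for i, e in enumerate(edges):
            if c.frequency >= e:
                idx = i
                break
        counts[idx] += 1
    total = sum(counts)
    return pd.DataFrame(
        {
            "bin": labels,
            "n_clones": counts,
            "percent": [100.0 * k / total for k in counts],
        }
    )


def sample_summary(rep: Repertoire, n: int = 100) -> dict:
    """One-row summary used by the pipeline's per-sample stats table."""
    div = shannon_diversity(rep)
    curve = cumulative_frequency_curve(rep, n)
    return {
        "sample_id": rep.sample_id,
        "stage": rep.stage.value,
        "richness": rep.richness,
        "total_reads": sum(c.count for c in rep.clones),
        "shannon": div.shannon,
        "normalized_shannon": div.normalized_shannon,
        f"top{n}_cum_freq": float(curve.cum_freq[-1]),
    }
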