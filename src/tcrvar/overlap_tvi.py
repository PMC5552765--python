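"""Paired lesion/adjacent overlap statistics and the repertoire variation index.

The variation index for a matched pair is ``2 - F * (1 + C)`` where

* ``F`` is the cumulative lesion-side frequency of the lesion TOP-N clones
  that are also present anywhere in the adjacent repertoire, renormalized
  within the TOP-N subset, and
* ``C`` is the Spearman rank correlation of lesion vs adjacent frequencies
  over the shared clones that rank in the TOP-N of either sample.

The index ranges from 0 (identical repertoires) to 2 (fully divergent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError
from .repertoire_io import LesionAdjacentPair, Repertoire
from .repertoire_stats import top_n


@dataclass
class OverlapResult:
    n_shared: int
    overlap_ratio: float
    common_cum_freq: float
    direction: str  # which repertoire supplied the denominator and frequencies


@dataclass
class TVIResult:
    F: float
    C: float | None
    tvi: float | None
    n_common_top: int
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.tvi is not None


def common_clones(a: Repertoire, b: Repertoire) -> frozenset[str]:
    """Symmetric key-set intersection of two repertoires."""
    return a.key_set() & b.key_set()


def overlap_ratio(lesion: Repertoire, adjacent: Repertoire) -> OverlapResult:
    """Whole-repertoire overlap with lesion-side denominator and frequencies.

    overlap_ratio = |shared keys| / lesion richness; common_cum_freq is the
    summed lesion frequency of the shared clones.
    """
    shared = common_clones(lesion, adjacent)
    cum = sum(c.frequency for k, c in zip(lesion.keys(), lesion.clones) if k in shared)
    return OverlapResult(
        n_shared=len(shared),
        overlap_ratio=len(shared) / lesion.richness,
        common_cum_freq=float(cum),
        direction="lesion",
    )


def topn_overlap(
    lesion: Repertoire,
    adjacent: Repertoire,
    n: int = 100,
    renormalize: bool = True,
) -> OverlapResult:
    """Overlap of the lesion TOP-N with the full adjacent repertoire.

    ratio = (# lesion TOP-N clones found anywhere in adjacent) / min(n, richness).
    common_cum_freq is the shared TOP-N lesion frequency divided by the total
    TOP-N lesion frequency when ``renormalize`` is True (the F of the
    variation index), else on the whole-repertoire scale.
    """
    sub = top_n(lesion, n)
    adj_keys = adjacent.key_set()
    shared_freq = sum(
        c.frequency for k, c in zip(sub.keys(), sub.clones) if k in adj_keys
    )
    n_shared = sum(1 for k in sub.keys() if k in adj_keys)
    total_freq = sum(c.frequency for c in sub.clones)
    cum = shared_freq / total_freq if renormalize else shared_freq
    return OverlapResult(
        n_shared=n_shared,
        overlap_ratio=n_shared / sub.richness,
        common_cum_freq=float(cum),
        direction="lesion_topn",
    )


def top_common_clones(
    lesion: Repertoire, adjacent: Repertoire, n: int = 100
) -> list[tuple[str, float, float]]:
    """Shared clones ranking in the TOP-N of either sample.

    Membership-based: the list may hold fewer or more than ``n`` entries.
    Ordered by lesion frequency descending, then key ascending.
    """
    shared = common_clones(lesion, adjacent)
    top_keys = set(top_n(lesion, n).keys()) | set(top_n(adjacent, n).keys())
    eligible = shared & top_keys
    les_freq = {k: c.frequency for k, c in zip(lesion.keys(), lesion.clones)}
    adj_freq = {k: c.frequency for k, c in zip(adjacent.keys(), adjacent.clones)}
    out = [(k, les_freq[k], adj_freq[k]) for k in eligible]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def spearman_correlation(x, y) -> float:
    """Spearman rho with average ranks on ties.

    Raises :class:`UndefinedCorrelationError` for fewer than 3 points or
    zero rank variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {x.size}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedCorrelationError("zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_test(x, y) -> tuple[float, float]:
    """(rho, two-sided p) via the t approximation with df = n - 2."""
    rho = spearman_correlation(x, y)
    n = len(x)
    denom = max(1.0 - rho * rho, np.finfo(float).tiny)
    t = rho * np.sqrt((n - 2) / denom)
    p = float(np.clip(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny, 1.0))
    return rho, p


def tvi_from_f_c(F: float, C: float) -> float:
    """The variation index 2 - F*(1+C) on its analytic domain."""
    if not (0.0 <= F <= 1.0):
        raise ValidationError(f"F must be in [0, 1], got {F}")
    if not (-1.0 <= C <= 1.0):
        raise ValidationError(f"C must be in [-1, 1], got {C}")
    value = 2.0 - F * (1.0 + C)
    if value < -1e-9 or value > 2.0 + 1e-9:
        raise ValidationError(f"index {value} outside [0, 2]")
    return float(min(max(value, 0.0), 2.0))


def compute_tvi(pair: LesionAdjacentPair, n: int = 100) -> TVIResult:
    """Variation index of a matched pair.

    When fewer than 3 shared top clones exist, C is undefined: F = 0 forces
    the index to its upper limit 2; otherwise the result is flagged missing.
    """
    F = topn_overlap(pair.lesion, pair.adjacent, n=n).common_cum_freq
    tc = top_common_clones(pair.lesion, pair.adjacent, n=n)
    C: float | None = None
    note = ""
    if len(tc) >= 3:
        lf = [t[1] for t in tc]
        af = [t[2] for t in tc]
        try:
            C = spearman_correlation(lf, af)
        except UndefinedCorrelationError as exc:
            note = f"correlation undefined: {exc}"
    else:
        note = f"only {len(tc)} shared top clones"

    if C is not None:
        return TVIResult(F=F, C=C, tvi=tvi_from_f_c(F, C), n_common_top=len(tc))
    if F == 0.0:
        return TVIResult(F=0.0, C=None, tvi=2.0, n_common_top=len(tc),
                         note=note + "; F=0 short-circuit")
    return TVIResult(F=F, C=None, tvi=None, n_common_top=len(tc), note=note)
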