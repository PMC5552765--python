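"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the statistical structure the analysis assumes: skewed
power-law clone-frequency distributions (the 100 most expanded clones cover
roughly half the reads), stage-dependent lesion/adjacent clone sharing and
rank decay, expression with planted monotone variation-index correlations,
an interaction table with a planted chain-of-cliques module, and two-group
exponential survival.  All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import ExpressionMatrix
from .repertoire_io import CloneRecord, LesionAdjacentPair, Repertoire, Stage

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_V_GENES = [f"TRBV{i}" for i in range(1, 31)]
_J_GENES = [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7)]
_D_GENES = ["TRBD1", "TRBD2", ""]


@dataclass
class RepertoirePairParams:
    """Knobs of the paired-repertoire generator.

    Defaults are calibrated so the TOP100 of a generated sample covers about
    half of the reads.  ``shared_fraction`` sets which part of the lesion's
    clones is copied from the adjacent sample; ``rank_noise`` is the
    log-normal sd of the multiplicative perturbation applied to the copied
    clone weights, which degrades the shared-clone rank correlation.
    """

    n_clones_lesion: int = 20000
    n_clones_adjacent: int = 20000
    zipf_exponent: float = 1.01
    shared_fraction: float = 0.8
    rank_noise: float = 0.3
    total_reads: int = 300000
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones_lesion < 1 or self.n_clones_adjacent < 1:
            raise ValidationError("clone counts must be positive")
        if self.zipf_exponent <= 1.0:
            raise ValidationError("zipf_exponent must be > 1")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValidationError("shared_fraction must be in [0, 1]")
        if self.rank_noise < 0:
            raise ValidationError("rank_noise must be >= 0")
        if self.total_reads < self.n_clones_lesion:
            raise ValidationError("total_reads must be >= number of clones")


#: stage presets with monotonically increasing divergence (lower sharing,
#: stronger rank shuffling); sizes reduced for cheap Monte-Carlo use
STAGE_PRESETS: dict[str, dict] = {
    "LGIN": dict(shared_fraction=0.85, rank_noise=0.25),
    "HGIN": dict(shared_fraction=0.55, rank_noise=0.70),
    "EGC": dict(shared_fraction=0.30, rank_noise=1.40),
}
_PRESET_SIZES = dict(
    n_clones_lesion=4000, n_clones_adjacent=4000, total_reads=80000
)


def stage_params(stage: str, seed: int = 0, **overrides) -> RepertoirePairParams:
    """Preset parameters for an ``LGIN``/``HGIN``/``EGC``-like pair."""
    if stage not in STAGE_PRESETS:
        raise ValidationError(f"unknown stage preset {stage!r}")
    kwargs = {**_PRESET_SIZES, **STAGE_PRESETS[stage], "seed": seed, **overrides}
    return RepertoirePairParams(**kwargs)


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators for recovery tests."""

    positive_genes: set[str] = field(default_factory=set)
    negative_genes: set[str] = field(default_factory=set)
    planted_module: frozenset = frozenset()
    planted_k: int = 0
    true_groups: pd.Series | None = None
    true_hazard_ratio: float = 1.0


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**-exponent
    return w / w.sum()


def _random_sequences(rng: np.random.Generator, n: int, length: int, alphabet) -> list[str]:
    """n distinct random strings over the alphabet."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        block = rng.integers(0, len(alphabet), size=(n - len(out), length))
        for row in block:
            s = "".join(alphabet[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def _build_repertoire(
    sample_id: str,
    stage: Stage,
    counts: np.ndarray,
    nt: list[str],
    aa: list[str],
    v: np.ndarray,
    d: np.ndarray,
    j: np.ndarray,
) -> Repertoire:
    keep = counts > 0
    counts = counts[keep]
    total = counts.sum()
    idx = np.nonzero(keep)[0]
    clones = tuple(
        CloneRecord(
            count=int(counts[i]),
            frequency=float(counts[i] / total),
            cdr3_nt=nt[idx[i]],
            cdr3_aa=aa[idx[i]],
            v_gene=str(v[idx[i]]),
            d_gene=str(d[idx[i]]),
            j_gene=str(j[idx[i]]),
        )
        for i in range(len(idx))
    )
    return Repertoire(sample_id=sample_id, stage=stage, clones=clones)


def simulate_paired_repertoires(
    params: RepertoirePairParams,
    patient_id: str = "P1",
    lesion_stage: Stage | str = Stage.EGC,
) -> LesionAdjacentPair:
    """One matched lesion/adjacent pair with power-law clone frequencies.

    Adjacent clone weights follow a Zipf law; a ``shared_fraction`` subset
    of the lesion's clones is copied from the adjacent sample with
    log-normal weight perturbation, the rest are fresh clones with fresh
    Zipf weights.  Read counts are multinomial draws.  In the exact
    zero-divergence limit (``shared_fraction == 1`` and ``rank_noise == 0``
    with equal clone numbers) the lesion reuses the adjacent counts so the
    pair is literally identical.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lesion_stage = Stage(lesion_stage)

    n_adj = params.n_clones_adjacent
    n_les = params.n_clones_lesion
    n_shared = int(round(params.shared_fraction * n_les))
    n_shared = min(n_shared, n_adj)
    n_fresh = n_les - n_shared

    n_ids = n_adj + n_fresh
    nt = _random_sequences(rng, n_ids, 36, _NT)
    aa = _random_sequences(rng, n_ids, 12, _AA)
    v = rng.choice(_V_GENES, n_ids)
    d = rng.choice(_D_GENES, n_ids)
    j = rng.choice(_J_GENES, n_ids)

    adj_w = _zipf_weights(n_adj, params.zipf_exponent)
    adj_counts = rng.multinomial(params.total_reads, adj_w)

    identity_limit = (
        params.shared_fraction == 1.0 and params.rank_noise == 0.0 and n_les == n_adj
    )
    if identity_limit:
        les_counts = adj_counts.copy()
        les_ids = np.arange(n_adj)
    else:
        shared_idx = rng.choice(n_adj, size=n_shared, replace=False)
        shared_w = adj_w[shared_idx]
        if params.rank_noise > 0:
            shared_w = shared_w * rng.lognormal(0.0, params.rank_noise, n_shared)
        fresh_w = _zipf_weights(n_fresh, params.zipf_exponent) if n_fresh else np.array([])
        # lesion read mass splits shared_fraction : (1 - shared_fraction)
        # between copied and lesion-specific clones
        if n_shared and n_fresh:
            shared_w = shared_w / shared_w.sum() * params.shared_fraction
            fresh_w = fresh_w / fresh_w.sum() * (1.0 - params.shared_fraction)
        les_w = np.concatenate([shared_w, fresh_w])
        les_w = les_w / les_w.sum()
        les_counts = rng.multinomial(params.total_reads, les_w)
        les_ids = np.concatenate(
            [shared_idx, np.arange(n_adj, n_adj + n_fresh)]
        ).astype(int)

    adjacent = _build_repertoire(
        f"{patient_id}_adjacent", Stage.ADJACENT, adj_counts, nt, aa, v, d, j
    )
    take = lambda arr: [arr[i] for i in les_ids]  # noqa: E731
    lesion = _build_repertoire(
        f"{patient_id}_{lesion_stage.value}",
        lesion_stage,
        les_counts,
        take(nt),
        take(aa),
        np.asarray(take(v)),
        np.asarray(take(d)),
        np.asarray(take(j)),
    )
    return LesionAdjacentPair(patient_id=patient_id, lesion=lesion, adjacent=adjacent)


def simulate_expression(
    tvi_values,
    n_genes: int = 1000,
    n_pos: int = 50,
    n_neg: int = 50,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Expression matrix with genes planted to track the variation index.

    Planted genes follow ``+-effect * z(rank(tvi))`` plus Gaussian noise;
    the remaining genes are pure standard-normal noise.  With
    ``noise_sd = 0`` every planted gene is an exact monotone function of
    the index (|rho| = 1).
    """
    tvi = pd.Series(dict(tvi_values)) if not isinstance(tvi_values, pd.Series) else tvi_values
    tvi = tvi.astype(float)
    if tvi.nunique() < 2:
        raise ValidationError("variation index must not be constant")
    if len(tvi) < 5:
        raise ValidationError("need >= 5 samples")
    if n_pos + n_neg > n_genes:
        raise ValidationError("n_pos + n_neg must not exceed n_genes")
    if noise_sd < 0 or effect < 0:
        raise ValidationError("effect and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(tvi)
    ranks = tvi.rank().to_numpy()
    z = (ranks - ranks.mean()) / ranks.std(ddof=0)

    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    X = np.empty((n_genes, n))
    X[:n_pos] = effect * z + rng.normal(0.0, noise_sd, size=(n_pos, n))
    X[n_pos : n_pos + n_neg] = -effect * z + rng.normal(0.0, noise_sd, size=(n_neg, n))
    X[n_pos + n_neg :] = rng.normal(0.0, 1.0, size=(n_genes - n_pos - n_neg, n))
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=list(tvi.index)))
    truth = PlantedTruth(
        positive_genes=set(genes[:n_pos]),
        negative_genes=set(genes[n_pos : n_pos + n_neg]),
    )
    return expr, truth


def simulate_ppi(
    gene_universe,
    planted_module_size: int = 11,
    planted_k: int = 5,
    background_edge_prob: float = 0.03,
    decoy_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Scored edge table with a planted chain-of-cliques module.

    The module is a chain of overlapping ``planted_k``-cliques (consecutive
    cliques share ``planted_k - 1`` nodes) spanning ``planted_module_size``
    nodes, so it percolates exactly at k = planted_k.  Background edges are
    Erdos-Renyi at ``background_edge_prob`` with passing scores, drawn only
    over pairs with at least one endpoint outside the module (the module's
    internal wiring is exactly the planted chain); a
    ``decoy_fraction`` of the remaining non-edges is emitted with scores
    below the filter thresholds.
    """
    genes = sorted(map(str, set(gene_universe)))
    if planted_module_size < planted_k:
        raise ValidationError("planted_module_size must be >= planted_k")
    if planted_k < 3:
        raise ValidationError("planted_k must be >= 3")
    if len(genes) < planted_module_size:
        raise ValidationError("gene universe smaller than the planted module")
    if not (0.0 <= background_edge_prob <= 1.0) or not (0.0 <= decoy_fraction <= 1.0):
        raise ValidationError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    module = sorted(rng.choice(genes, size=planted_module_size, replace=False))
    module_edges: set[tuple[str, str]] = set()
    for start in range(planted_module_size - planted_k + 1):
        window = module[start : start + planted_k]
        for i in range(len(window)):
            for jdx in range(i + 1, len(window)):
                module_edges.add(tuple(sorted((window[i], window[jdx]))))

    all_pairs = [
        (a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]
    ]
    module_set = set(module)
    rows = []
    for a, b in all_pairs:
        pair = (a, b)
        if a in module_set and b in module_set:
            if pair not in module_edges:
                continue
            keep = True
        elif rng.random() < background_edge_prob:
            keep = True
        elif rng.random() < decoy_fraction:
            rows.append(
                {
                    "geneA": a,
                    "geneB": b,
                    "textmining": int(rng.integers(0, 201)),
                    "combined": int(rng.integers(0, 401)),
                }
            )
            continue
        else:
            continue
        if keep:
            rows.append(
                {
                    "geneA": a,
                    "geneB": b,
                    "textmining": int(rng.integers(300, 1001)),
                    "combined": int(rng.integers(500, 1001)),
                }
            )
    table = pd.DataFrame(rows, columns=["geneA", "geneB", "textmining", "combined"])
    truth = PlantedTruth(planted_module=frozenset(module), planted_k=planted_k)
    return table, truth


def simulate_survival(
    n_per_group: int = 50,
    hazard_ratio: float = 2.0,
    censoring_rate: float = 0.2,
    baseline_hazard: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Two-group exponential survival with independent exponential censoring."""
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ValidationError("hazards must be positive")
    if censoring_rate < 0:
        raise ValidationError("censoring_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.repeat([0, 1], n_per_group)
    hazard = np.where(group == 1, baseline_hazard * hazard_ratio, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        cens_time = rng.exponential(1.0 / censoring_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    width = len(str(n))
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i:0{width}d}" for i in range(1, n + 1)],
            "time": time,
            "event": event,
            "group": group,
        }
    )
    truth = PlantedTruth(
        true_groups=pd.Series(group, index=table["sample_id"].to_numpy()),
        true_hazard_ratio=hazard_ratio,
    )
    return table, truth


def simulate_two_group_expression(
    genes,
    n_per_group: int = 30,
    separation: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Signature-gene expression for a cohort split into two planted groups.

    Each gene gets a random up/down direction; group-1 samples are shifted
    by ``separation`` along it.  Returns the matrix and the true labels.
    """
    genes = list(map(str, genes))
    if not genes:
        raise ValidationError("need >= 1 gene")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if separation < 0 or noise_sd <= 0:
        raise ValidationError("separation must be >= 0 and noise_sd > 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    labels = np.repeat([0, 1], n_per_group)
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    X = rng.normal(0.0, noise_sd, size=(len(genes), n))
    X += np.outer(signs, labels * separation)
    width = len(str(n))
    samples = [f"S{i:0{width}d}" for i in range(1, n + 1)]
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
    return expr, pd.Series(labels, index=samples)
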