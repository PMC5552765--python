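import numpy as np
import pytest

from tcrvar.repertoire_io import CloneRecord, LesionAdjacentPair, Repertoire, Stage


def make_repertoire(
    freqs=None,
    counts=None,
    sample_id="S1",
    stage=Stage.ADJACENT,
    keys=None,
    **kwargs,
):
    """Small repertoire with auto-generated distinct CDR3s.

    ``keys`` gives the CDR3 nucleotide sequences explicitly (same V/J), so
    overlap between two repertoires can be scripted by sharing sequences.
    """
    if counts is not None:
        counts = list(counts)
        total = sum(counts)
        freqs = [c / total for c in counts]
    else:
        freqs = list(freqs)
        counts = [max(1, round(f * 1_000_000)) for f in freqs]
    if keys is None:
        keys = [_nt_seq(i) for i in range(len(freqs))]
    clones = tuple(
        CloneRecord(
            count=c,
            frequency=f,
            cdr3_nt=k,
            cdr3_aa="CASS",
            v_gene="TRBV7",
            d_gene="TRBD1",
            j_gene="TRBJ2-1",
        )
        for c, f, k in zip(counts, freqs, keys)
    )
    return Repertoire(sample_id=sample_id, stage=stage, clones=clones, **kwargs)


def _nt_seq(i: int, length: int = 12) -> str:
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(digits)


def random_repertoire(rng: np.random.Generator, n_clones: int, stage=Stage.ADJACENT,
                      sample_id="R", key_pool=None):
    """Random repertoire; drawing keys from ``key_pool`` creates overlap."""
    if key_pool is None:
        key_pool = [_nt_seq(i) for i in range(3 * n_clones)]
    keys = list(rng.choice(key_pool, size=n_clones, replace=False))
    counts = rng.integers(1, 1000, size=n_clones)
    return make_repertoire(counts=counts, keys=keys, sample_id=sample_id, stage=stage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pair():
    lesion = make_repertoire(
        counts=(50, 30, 20), keys=["AAAA", "CCCC", "GGGG"],
        sample_id="L", stage=Stage.EGC,
    )
    adjacent = make_repertoire(
        counts=(60, 25, 15), keys=["AAAA", "GGGG", "TTTT"],
        sample_id="A", stage=Stage.ADJACENT,
    )
    return LesionAdjacentPair(patient_id="P1", lesion=lesion, adjacent=adjacent)
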