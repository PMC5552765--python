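"""Clonotype table I/O, clone identity and the core repertoire types.

A clonotype table is a tab-delimited text file with a header row and the
canonical columns ``count, freq, cdr3nt, cdr3aa, v, d, j``.  Alternative
headers are accepted through a *dialect* mapping from canonical to actual
column names.  A :class:`Repertoire` is the validated in-memory form of one
sample's table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

CANONICAL_COLUMNS = ("count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j")

#: columns that must be resolvable in an input table (freq is recomputable,
#: cdr3aa and d may legitimately be empty)
REQUIRED_COLUMNS = ("count", "cdr3nt", "v", "j")

KEY_SEPARATOR = "|"
KEY_MODES = ("nt_vj", "nt_only", "aa_vj")

_ALLELE_RE = re.compile(r"\*\d+$")
_NT_ALPHABET = frozenset("ACGT")

#: tolerance for the sum-to-one invariant of stored frequencies
FREQ_SUM_TOL = 1e-6
#: looser tolerance under which a supplied frequency column is still trusted
#: (rescaled to sum exactly to one) rather than recomputed from counts
FREQ_TRUST_TOL = 1e-3


class Stage(str, Enum):
    """Pathological stage label of a sample."""

    ADJACENT = "adjacent"
    LGIN = "LGIN"
    HGIN = "HGIN"
    EGC = "EGC"


LESION_STAGES = (Stage.LGIN, Stage.HGIN, Stage.EGC)


def strip_allele(gene: str) -> str:
    """Drop a trailing allele suffix such as ``*01`` from a gene name."""
    return _ALLELE_RE.sub("", gene)


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype: read count, sample frequency, CDR3 and gene segments."""

    count: int
    frequency: float
    cdr3_nt: str
    cdr3_aa: str = ""
    v_gene: str = ""
    d_gene: str = ""
    j_gene: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"clone count must be >= 1, got {self.count}")
        if not (0.0 < self.frequency <= 1.0):
            raise ValidationError(
                f"clone frequency must be in (0, 1], got {self.frequency}"
            )
        if not self.cdr3_nt:
            raise ValidationError("cdr3_nt must be non-empty")
        if not _NT_ALPHABET.issuperset(self.cdr3_nt):
            raise ValidationError(f"cdr3_nt contains non-ACGT symbols: {self.cdr3_nt!r}")


def clone_key(
    record: CloneRecord,
    key_mode: str = "nt_vj",
    strip_alleles: bool = True,
) -> str:
    """Deterministic identity string for a clonotype.

    ``nt_vj`` (default) joins CDR3 nucleotide sequence, V gene and J gene;
    ``nt_only`` uses the nucleotide sequence alone; ``aa_vj`` uses the amino
    acid sequence with V and J.  Allele suffixes (``*01``) are stripped from
    gene names unless ``strip_alleles`` is False.
    """
    if key_mode not in KEY_MODES:
        raise ValidationError(f"unknown key_mode {key_mode!r}; expected one of {KEY_MODES}")
    v, j = record.v_gene, record.j_gene
    if strip_alleles:
        v, j = strip_allele(v), strip_allele(j)
    if key_mode == "nt_only":
        return record.cdr3_nt
    if key_mode == "aa_vj":
        return KEY_SEPARATOR.join((record.cdr3_aa, v, j))
    return KEY_SEPARATOR.join((record.cdr3_nt, v, j))


@dataclass
class Repertoire:
    """One sample's clone list with stage label and a deterministic order.

    ``is_subset`` marks derived objects (e.g. a TOP-N slice) whose
    frequencies intentionally do not sum to one; all other invariants still
    hold.
    """

    sample_id: str
    stage: Stage
    clones: tuple[CloneRecord, ...]
    key_mode: str = "nt_vj"
    strip_alleles: bool = True
    is_subset: bool = False
    _keys: tuple[str, ...] = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        self.clones = tuple(self.clones)
        if not self.clones:
            raise ValidationError(f"repertoire {self.sample_id!r} has no clones")
        self._keys = tuple(
            clone_key(c, self.key_mode, self.strip_alleles) for c in self.clones
        )
        if len(set(self._keys)) != len(self._keys):
            seen: set[str] = set()
            dup = next(k for k in self._keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate clone key in {self.sample_id!r}: {dup!r}")
        if not self.is_subset:
            total = math.fsum(c.frequency for c in self.clones)
            if abs(total - 1.0) > FREQ_SUM_TOL:
                raise ValidationError(
                    f"frequencies of {self.sample_id!r} sum to {total}, not 1"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def richness(self) -> int:
        """Number of distinct clones."""
        return len(self.clones)

    def keys(self) -> tuple[str, ...]:
        return self._keys

    def key_set(self) -> frozenset[str]:
        return frozenset(self._keys)

    def frequency_of(self, key: str) -> float:
        return dict(zip(self._keys, (c.frequency for c in self.clones)))[key]

    def sorted_clones(self) -> tuple[tuple[str, CloneRecord], ...]:
        """(key, clone) pairs by frequency descending, key ascending on ties."""
        pairs = list(zip(self._keys, self.clones))
        pairs.sort(key=lambda kc: (-kc[1].frequency, kc[0]))
        return tuple(pairs)

    def subset(self, keys: Iterable[str]) -> "Repertoire":
        wanted = set(keys)
        picked = tuple(c for k, c in zip(self._keys, self.clones) if k in wanted)
        return Repertoire(
            sample_id=self.sample_id,
            stage=self.stage,
            clones=picked,
            key_mode=self.key_mode,
            strip_alleles=self.strip_alleles,
            is_subset=True,
        )


@dataclass
class LesionAdjacentPair:
    """A matched lesion/adjacent repertoire pair from one patient."""

    patient_id: str
    lesion: Repertoire
    adjacent: Repertoire

    def __post_init__(self) -> None:
        if self.lesion.stage not in LESION_STAGES:
            raise ValidationError(
                f"lesion stage must be one of {[s.value for s in LESION_STAGES]}, "
                f"got {self.lesion.stage.value}"
            )
        if self.adjacent.stage != Stage.ADJACENT:
            raise ValidationError(
                f"adjacent repertoire has stage {self.adjacent.stage.value}"
            )

    @property
    def stage(self) -> Stage:
        return self.lesion.stage


# -- table I/O -------------------------------------------------------------


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    dialect = dict(dialect or {})
    resolved: dict[str, str] = {}
    for canonical in CANONICAL_COLUMNS:
        actual = dialect.get(canonical, canonical)
        if actual in columns:
            resolved[canonical] = actual
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing}; present columns: {list(columns)}"
        )
    return resolved


def read_clonotype_table(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    stage: Stage | str = Stage.ADJACENT,
    key_mode: str = "nt_vj",
    strip_alleles: bool = True,
    recompute_frequencies: str = "auto",
) -> Repertoire:
    """Read one tab-delimited clonotype table into a validated Repertoire.

    ``recompute_frequencies`` controls handling of a supplied ``freq``
    column: ``"auto"`` trusts it when it sums to 1 within ``FREQ_TRUST_TOL``
    (rescaling exactly to 1) and otherwise recomputes from counts;
    ``"always"`` recomputes unconditionally; ``"never"`` raises a
    :class:`ValidationError` instead of recomputing.  An absent column is
    always computed from counts.
    """
    if recompute_frequencies not in ("auto", "always", "never"):
        raise ValidationError(
            f"recompute_frequencies must be auto/always/never, got {recompute_frequencies!r}"
        )
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, dialect)

    try:
        counts = pd.to_numeric(df[cols["count"]], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric values in count column: {exc}") from exc
    if (counts < 0).any():
        raise ValidationError("negative clone counts")
    keep = counts > 0
    df = df.loc[keep].reset_index(drop=True)
    counts = counts.loc[keep].astype(int).reset_index(drop=True)
    if df.empty:
        raise ValidationError("clonotype table holds no clones with positive count")

    total = int(counts.sum())
    from_counts = (counts / total).to_numpy()
    if "freq" in cols and recompute_frequencies != "always":
        freqs = pd.to_numeric(df[cols["freq"]], errors="raise").to_numpy()
        s = math.fsum(freqs)
        if abs(s - 1.0) <= FREQ_SUM_TOL:
            pass
        elif abs(s - 1.0) <= FREQ_TRUST_TOL:
            freqs = freqs / s
        elif recompute_frequencies == "never":
            raise ValidationError(
                f"frequency column sums to {s}, outside tolerance {FREQ_TRUST_TOL}"
            )
        else:
            freqs = from_counts
    else:
        freqs = from_counts

    def col(name: str) -> list[str]:
        return df[cols[name]].astype(str).tolist() if name in cols else [""] * len(df)

    records = tuple(
        CloneRecord(
            count=int(c),
            frequency=float(f),
            cdr3_nt=nt,
            cdr3_aa=aa,
            v_gene=v,
            d_gene=d,
            j_gene=j,
        )
        for c, f, nt, aa, v, d, j in zip(
            counts, freqs, col("cdr3nt"), col("cdr3aa"), col("v"), col("d"), col("j")
        )
    )
    if sample_id is None:
        sample_id = Path(source).stem if isinstance(source, (str, Path)) else "sample"
    return Repertoire(
        sample_id=sample_id,
        stage=Stage(stage),
        clones=records,
        key_mode=key_mode,
        strip_alleles=strip_alleles,
    )


def write_clonotype_table(rep: Repertoire, sink: str | Path | IO[str]) -> None:
    """Write the canonical 7-column table, frequency-descending, key-ascending."""
    rows = [
        {
            "count": c.count,
            "freq": repr(c.frequency),
            "cdr3nt": c.cdr3_nt,
            "cdr3aa": c.cdr3_aa,
            "v": c.v_gene,
            "d": c.d_gene,
            "j": c.j_gene,
        }
        for _, c in rep.sorted_clones()
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(sink, sep="\t", index=False)
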