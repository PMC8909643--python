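"""Instrument selection: significance filtering, greedy LD clumping, F-statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SummaryTable

__all__ = [
    "LdMatrix",
    "InstrumentReport",
    "select_genomewide",
    "ld_clump",
    "f_statistics",
    "read_ld_matrix",
    "write_ld_matrix",
    "WEAK_INSTRUMENT_F",
]

#: conventional weak-instrument threshold
WEAK_INSTRUMENT_F = 10.0


@dataclass
class LdMatrix:
    """Square r² matrix over a set of SNPs (symmetric, unit diagonal)."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 must be square and match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if (self.r2 < 0).any() or (self.r2 > 1).any():
            raise ValueError("r2 entries must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LdMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))


@dataclass
class InstrumentReport:
    kept: list[str]
    removed: list[tuple[str, str]] = field(default_factory=list)
    f_stats: dict[str, float] = field(default_factory=dict)
    min_f: float | None = None

    def __post_init__(self) -> None:
        if set(self.kept) & {s for s, _ in self.removed}:
            raise ValueError("kept and removed sets overlap")


def select_genomewide(
    table: SummaryTable, p_threshold: float = 5e-8
) -> SummaryTable:
    """Keep records with p strictly below the genome-wide threshold."""
    if not (0 < p_threshold < 1 or p_threshold == 1.0):
        raise ValueError("p_threshold must lie in (0,1]")
    return SummaryTable(
        table.trait_name,
        table.trait_type,
        [r for r in table.records if r.pval < p_threshold],
    )


def ld_clump(
    table: SummaryTable,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    assume_independent: bool = False,
) -> InstrumentReport:
    """Greedy clumping: repeatedly keep the smallest-p SNP, remove its LD partners.

    SNPs with r² >= ``r2_threshold`` to a kept index SNP are removed, so the
    retained set is pairwise below the threshold. Equal p-values are broken by
    lexicographic snp_id for determinism. SNPs absent from the LD matrix raise
    unless ``assume_independent`` (then treated as r²=0 with everything and
    logged).
    """
    missing = [r.snp_id for r in table.records if r.snp_id not in ld._index]
    if missing and not assume_independent:
        raise KeyError(f"SNPs absent from LD matrix: {', '.join(missing)}")
    notes = [(s, "assumed independent: absent from LD matrix") for s in missing]
    missing_set = set(missing)
    removed: list[tuple[str, str]] = []

    remaining = sorted(table.records, key=lambda r: (r.pval, r.snp_id))
    kept: list[str] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index.snp_id)
        still = []
        for r in remaining:
            if (
                index.snp_id not in missing_set
                and r.snp_id not in missing_set
                and ld.lookup(index.snp_id, r.snp_id) >= r2_threshold
            ):
                removed.append((r.snp_id, f"r2 >= {r2_threshold} with {index.snp_id}"))
            else:
                still.append(r)
        remaining = still
    report = InstrumentReport(kept=kept, removed=removed)
    report.notes = notes  # type: ignore[attr-defined]
    return report


def f_statistics(table: SummaryTable, enforce: bool = False) -> InstrumentReport:
    """Per-SNP instrument strength F = (beta/se)².

    With ``enforce`` SNPs at F <= 10 are moved to ``removed``; otherwise they
    are only flagged via ``f_stats``/``min_f``.
    """
    f = {r.snp_id: (r.beta / r.se) ** 2 for r in table.records}
    weak = [s for s, v in f.items() if v <= WEAK_INSTRUMENT_F]
    kept = [r.snp_id for r in table.records if not (enforce and r.snp_id in set(weak))]
    removed = [(s, "weak instrument") for s in weak] if enforce else []
    kept_f = [f[s] for s in kept] or list(f.values())
    return InstrumentReport(
        kept=kept, removed=removed, f_stats=f, min_f=min(kept_f) if kept_f else None
    )


def read_ld_matrix(path: str | Path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
    return path
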