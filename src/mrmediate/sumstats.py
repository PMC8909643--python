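"""GWAS summary-statistics containers, I/O and two-sample allele harmonization.

Effect sizes for binary traits are carried on the natural-log-odds scale
throughout; odds ratios are presentation-layer ``exp(beta)``. Continuous
traits are in SD units per effect-allele copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryTable",
    "HarmonizedSet",
    "SumstatsFormatError",
    "EmptyInputError",
    "EmptyOverlapError",
    "DEFAULT_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
]

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default tab-separated column dialect (GWAS-SSF-like export)
DEFAULT_COLUMNS: Mapping[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

MISSING_TOKEN = "."

TraitType = Literal["binary", "continuous"]
PalindromePolicy = Literal["drop", "infer", "keep"]

#: EAF window in which a palindromic SNP cannot be oriented by frequency
AMBIGUOUS_EAF = (0.42, 0.58)


class SumstatsFormatError(ValueError):
    """Input file does not conform to the expected column dialect."""


class EmptyInputError(ValueError):
    """No valid rows survived parsing/validation."""


class EmptyOverlapError(ValueError):
    """No SNP is shared by all tables being harmonized."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        for reason in _row_problems(self):
            raise ValueError(f"{self.snp_id}: {reason}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


def _row_problems(v: VariantAssociation) -> list[str]:
    problems = []
    if v.effect_allele not in NUCLEOTIDES or v.other_allele not in NUCLEOTIDES:
        problems.append("invalid allele")
    elif v.effect_allele == v.other_allele:
        problems.append("identical alleles")
    if not (v.se > 0) or not math.isfinite(v.se):
        problems.append("nonpositive se")
    if not (0 < v.pval <= 1):
        problems.append("pval outside (0,1]")
    if not math.isfinite(v.beta):
        problems.append("non-finite beta")
    if v.eaf is not None and not (0 <= v.eaf <= 1):
        problems.append("eaf outside [0,1]")
    if v.n is not None and v.n < 1:
        problems.append("sample size < 1")
    return problems


@dataclass
class SummaryTable:
    """Ordered collection of per-SNP associations for one trait."""

    trait_name: str
    trait_type: TraitType
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trait_name:
            raise ValueError("trait_name must be non-empty")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.trait_name}: duplicate snp_id in records")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.snp_id: r for r in self.records}

    def subset(self, snp_ids: Iterable[str]) -> "SummaryTable":
        keep = set(snp_ids)
        return SummaryTable(
            self.trait_name,
            self.trait_type,
            [r for r in self.records if r.snp_id in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [r.snp_id for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


@dataclass
class HarmonizedSet:
    """Instrument-aligned effect arrays for K exposures and one outcome.

    ``bx``/``sx`` have shape (K, J); ``by``/``sy`` have shape (J,).  Every
    retained SNP is expressed on the first exposure's effect allele.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        j = len(self.snp_ids)
        k = len(self.exposure_names)
        if self.bx.shape != (k, j) or self.sx.shape != (k, j):
            raise ValueError("bx/sx shape mismatch with snp_ids/exposure_names")
        if self.by.shape != (j,) or self.sy.shape != (j,):
            raise ValueError("by/sy length mismatch with snp_ids")
        if j == 0:
            raise ValueError("empty HarmonizedSet")
        if not (self.sy > 0).all() or not (self.sx > 0).all():
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def univariable(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bx, sx, by, sy) 1-D views for a single-exposure set."""
        if self.n_exposures != 1:
            raise ValueError("univariable() requires exactly one exposure")
        return self.bx[0], self.sx[0], self.by, self.sy

    def drop_snps(self, snp_ids: Iterable[str], reason: str = "removed") -> "HarmonizedSet":
        drop = set(snp_ids)
        keep = [i for i, s in enumerate(self.snp_ids) if s not in drop]
        if not keep:
            raise ValueError("dropping all SNPs would leave an empty set")
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            exposure_names=list(self.exposure_names),
            bx=self.bx[:, keep],
            sx=self.sx[:, keep],
            by=self.by[keep],
            sy=self.sy[keep],
            dropped=self.dropped + [(s, reason) for s in self.snp_ids if s in drop],
            outcome_name=self.outcome_name,
        )


# ---------------------------------------------------------------------------
# I/O


def _parse_optional(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", MISSING_TOKEN):
        return None
    return float(value)


def read_sumstats(
    path: str | Path,
    trait_name: str,
    trait_type: TraitType,
    columns: Mapping[str, str] = DEFAULT_COLUMNS,
) -> tuple[SummaryTable, list[tuple[str, str]]]:
    """Read a tab-separated summary-statistics table.

    Rows violating field invariants are rejected with a per-row reason;
    duplicate ``snp_id`` rows keep the smallest p-value. Returns the table
    and the rejection log as ``(snp_id, reason)`` pairs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING_TOKEN, ""])
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )

    log: list[tuple[str, str]] = []
    records: dict[str, VariantAssociation] = {}
    for _, row in df.iterrows():
        snp = str(row[columns["snp_id"]])
        try:
            rec = VariantAssociation(
                snp_id=snp,
                effect_allele=str(row[columns["effect_allele"]]).upper(),
                other_allele=str(row[columns["other_allele"]]).upper(),
                eaf=_parse_optional(row[columns["eaf"]]),
                beta=float(row[columns["beta"]]),
                se=float(row[columns["se"]]),
                pval=float(row[columns["pval"]]),
                n=_parse_optional(row[columns["n"]]),
            )
        except (ValueError, TypeError) as exc:
            log.append((snp, str(exc).split(": ", 1)[-1]))
            continue
        prev = records.get(snp)
        if prev is None:
            records[snp] = rec
        elif rec.pval < prev.pval:  # duplicate: keep smallest p
            log.append((snp, "duplicate snp_id, kept smaller p-value"))
            records[snp] = rec
        else:
            log.append((snp, "duplicate snp_id, kept smaller p-value"))
    if not records:
        raise EmptyInputError(f"{path}: no valid rows")
    return SummaryTable(trait_name, trait_type, list(records.values())), log


def write_sumstats(table: SummaryTable, path: str | Path) -> Path:
    """Write a summary table in the default dialect; round-trips losslessly."""
    if not table.records:
        raise EmptyInputError("refusing to write an empty table")
    path = Path(path)
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)
    return path


# ---------------------------------------------------------------------------
# Harmonization


def _orient(
    rec: VariantAssociation, ref_ea: str, ref_oa: str
) -> VariantAssociation | None:
    """Express ``rec`` on the reference effect allele, or None if impossible."""
    ea, oa = rec.effect_allele, rec.other_allele
    if (ea, oa) == (ref_ea, ref_oa):
        return rec
    if (ea, oa) == (ref_oa, ref_ea):
        return _flip(rec, ref_ea, ref_oa)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return replace(rec, effect_allele=ref_ea, other_allele=ref_oa)
    if (cea, coa) == (ref_oa, ref_ea):
        return _flip(rec, ref_ea, ref_oa)
    return None


def _flip(rec: VariantAssociation, ref_ea: str, ref_oa: str) -> VariantAssociation:
    return replace(
        rec,
        effect_allele=ref_ea,
        other_allele=ref_oa,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _ambiguous_eaf(eaf: float | None) -> bool:
    return eaf is None or AMBIGUOUS_EAF[0] < eaf < AMBIGUOUS_EAF[1]


def _orient_palindromic(
    rec: VariantAssociation, ref: VariantAssociation, policy: PalindromePolicy
) -> tuple[VariantAssociation | None, str | None]:
    if policy == "drop":
        return None, "palindromic"
    if policy == "keep":
        aligned = _orient(rec, ref.effect_allele, ref.other_allele)
        return aligned, None if aligned is not None else "incompatible alleles"
    # infer: allele labels carry no strand signal for A/T and C/G SNPs, so
    # orientation is decided purely by which side of 0.5 the frequencies fall
    if {rec.effect_allele, rec.other_allele} != {ref.effect_allele, ref.other_allele}:
        return None, "incompatible alleles"
    if _ambiguous_eaf(ref.eaf) or _ambiguous_eaf(rec.eaf):
        return None, "palindromic, ambiguous frequency"
    if (rec.eaf < 0.5) == (ref.eaf < 0.5):
        aligned = replace(
            rec, effect_allele=ref.effect_allele, other_allele=ref.other_allele
        )
    else:
        aligned = _flip(rec, ref.effect_allele, ref.other_allele)
    return aligned, None


def harmonize(
    exposures: Sequence[SummaryTable] | SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: PalindromePolicy = "infer",
) -> HarmonizedSet:
    """Align exposure and outcome tables onto a shared effect allele.

    The first exposure defines the reference allele for every SNP.  Swapped
    alleles flip the sign of beta (and complement the EAF); strand flips are
    resolved through the A<->T / C<->G map; palindromic SNPs follow
    ``palindrome_policy`` ("infer" orients by allele frequency and drops
    SNPs whose frequency is missing or too close to 0.5).
    """
    if isinstance(exposures, SummaryTable):
        exposures = [exposures]
    if not exposures:
        raise ValueError("at least one exposure table required")
    maps = [t.by_id() for t in exposures]
    out_map = outcome.by_id()

    shared = [
        r.snp_id
        for r in exposures[0].records
        if all(r.snp_id in m for m in maps[1:]) and r.snp_id in out_map
    ]
    if not shared:
        raise EmptyOverlapError("no SNP shared by all exposure and outcome tables")

    dropped: list[tuple[str, str]] = []
    kept_ids: list[str] = []
    bx_cols: list[list[float]] = []
    sx_cols: list[list[float]] = []
    by: list[float] = []
    sy: list[float] = []

    for snp in shared:
        ref = maps[0][snp]
        others = [m[snp] for m in maps[1:]] + [out_map[snp]]
        if ref.is_palindromic:
            aligned, reason = [], None
            for rec in others:
                a, reason = _orient_palindromic(rec, ref, palindrome_policy)
                if a is None:
                    break
                aligned.append(a)
            if reason is not None:
                dropped.append((snp, reason))
                continue
        else:
            aligned = []
            ok = True
            for rec in others:
                a = _orient(rec, ref.effect_allele, ref.other_allele)
                if a is None:
                    dropped.append((snp, "incompatible alleles"))
                    ok = False
                    break
                aligned.append(a)
            if not ok:
                continue
        row = [ref] + aligned[:-1]
        out_rec = aligned[-1]
        kept_ids.append(snp)
        bx_cols.append([r.beta for r in row])
        sx_cols.append([r.se for r in row])
        by.append(out_rec.beta)
        sy.append(out_rec.se)

    if not kept_ids:
        raise EmptyOverlapError("no SNP survived harmonization")
    return HarmonizedSet(
        snp_ids=kept_ids,
        exposure_names=[t.trait_name for t in exposures],
        bx=np.array(bx_cols, dtype=float).T,
        sx=np.array(sx_cols, dtype=float).T,
        by=np.array(by, dtype=float),
        sy=np.array(sy, dtype=float),
        dropped=dropped,
        outcome_name=outcome.trait_name,
    )
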