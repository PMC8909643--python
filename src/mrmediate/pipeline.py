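"""Two-step mediation workflow over one exposure, M mediators, R outcomes.

Stage order mirrors the two-step scheme:

1. exposure instrument selection (genome-wide significance, LD clumping,
   F-statistics);
2. total effects: univariable IVW of exposure on each outcome with the full
   sensitivity battery (MR-Egger, medians, MR-PRESSO, single-SNP,
   leave-one-out);
3. step 1: IVW of exposure on each candidate mediator; mediators whose
   IVW p-value is not suggestive (p >= 0.05 by default) are excluded;
   Bonferroni significance is annotated within mediator families;
4. step 2: multivariable MR of (exposure, mediator) on each outcome over
   the union of their instruments; mediators failing the suggestive
   threshold are excluded; MVMR failures from inadequate SNPs are recorded;
5. mediation: per-mediator product-method proportions and the all-mediator
   combined (difference-method) proportion per outcome.

The pipeline adds no arithmetic of its own beyond rounding at
serialization; every reported number is reproducible by calling the
underlying module operations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instruments import (
    LdMatrix,
    f_statistics,
    ld_clump,
    read_ld_matrix,
    select_genomewide,
)
from .mediation import CombinedMediation, MediationResult, combined_mediation, mediate
from .mr_core import (
    InsufficientInstrumentsError,
    MrResult,
    ivw,
    leave_one_out,
    mr_egger,
    simple_median,
    single_snp_analysis,
    weighted_median,
)
from .mvmr import CollinearityError, MvmrResult, mvmr_ivw
from .presso import run_presso
from .sumstats import SummaryTable, harmonize, read_sumstats
from .worked_example import worked_example_report  # noqa: F401  (re-export)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "bonferroni_threshold",
    "run_study",
    "run_two_step",
    "worked_example_report",
]

log = logging.getLogger("mrmediate")


def bonferroni_threshold(family_size: int) -> float:
    """Significance threshold 0.05 / family_size for a mediator family."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return 0.05 / family_size


@dataclass
class StudyConfig:
    exposure: str
    mediators: list[tuple[str, str, str]]  # (name, path, family_id)
    outcomes: list[tuple[str, str]]  # (name, path)
    ld: str | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    suggestive_p: float = 0.05
    nsim: int = 1000
    seed: int = 0
    n_boot: int = 1000
    output_dir: str = "results"

    def __post_init__(self) -> None:
        # accept dict-form entries (as parsed from YAML) alongside tuples
        self.mediators = [
            (m["name"], m["path"], str(m.get("family", m["name"])))
            if isinstance(m, dict) else tuple(m)
            for m in self.mediators
        ]
        self.outcomes = [
            (o["name"], o["path"]) if isinstance(o, dict) else tuple(o)
            for o in self.outcomes
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            exposure=raw["exposure"],
            mediators=[
                (m["name"], m["path"], str(m.get("family", m["name"])))
                for m in raw["mediators"]
            ],
            outcomes=[(o["name"], o["path"]) for o in raw["outcomes"]],
            ld=raw.get("ld"),
            p_instrument=float(raw.get("p_instrument", 5e-8)),
            clump_r2=float(raw.get("clump_r2", 0.001)),
            suggestive_p=float(raw.get("suggestive_p", 0.05)),
            nsim=int(raw.get("nsim", 1000)),
            seed=int(raw.get("seed", 0)),
            n_boot=int(raw.get("n_boot", 1000)),
            output_dir=str(raw.get("output_dir", "results")),
        )


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    total_results: dict[str, MrResult] = field(default_factory=dict)
    step1_results: dict[str, MrResult] = field(default_factory=dict)
    step2_results: dict[tuple[str, str], MvmrResult] = field(default_factory=dict)
    mediation_results: dict[tuple[str, str], MediationResult] = field(
        default_factory=dict
    )
    combined_results: dict[str, CombinedMediation] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)


def _sensitivity_rows(h, nsim: int, seed: int, n_boot: int) -> list[dict]:
    """Table-style rows for the full sensitivity battery on one pair."""
    rows = []
    for res in (
        simple_median(h, n_boot=n_boot, seed=seed),
        weighted_median(h, n_boot=n_boot, seed=seed),
    ):
        rows.append(res.to_row())
    egger = mr_egger(h)
    rows.append(egger.to_row())
    rows.append(
        {
            "exposure": egger.exposure,
            "outcome": egger.outcome,
            "Analysis": "egger_intercept",
            "Nsnp": egger.nsnp,
            "Effect": egger.egger_intercept,
            "Se": egger.egger_intercept_se,
            "P-value": egger.egger_intercept_p,
            "OR": np.nan,
        }
    )
    rows.append(ivw(h).to_row())
    return rows


def _instrument_union(
    tables: list[SummaryTable],
    instrument_ids: list[set[str]],
) -> list[SummaryTable]:
    """Subset each full table to the union of instrument sets; SNPs missing
    from any table are dropped (logged)."""
    union = set().union(*instrument_ids)
    present = [set(r.snp_id for r in t.records) for t in tables]
    usable = set.intersection(*present) & union
    missing = union - usable
    if missing:
        log.info("dropping %d union instruments missing from some table", len(missing))
    return [t.subset(usable) for t in tables]


def run_study(
    exposure: SummaryTable,
    mediators: list[tuple[SummaryTable, str]],
    outcomes: list[SummaryTable],
    ld: LdMatrix | None = None,
    p_instrument: float = 5e-8,
    clump_r2: float = 0.001,
    suggestive_p: float = 0.05,
    nsim: int = 1000,
    seed: int = 0,
    n_boot: int = 1000,
) -> StudyReport:
    """Run the full two-step mediation workflow on in-memory tables.

    ``mediators`` pairs each candidate mediator table with a family id used
    for Bonferroni annotation. Stage failures (too few instruments,
    collinearity) are recorded in the report and do not abort other pairs.
    """
    report = StudyReport(tables={})
    families: dict[str, int] = {}
    for _, fam in mediators:
        families[fam] = families.get(fam, 0) + 1

    # --- exposure instruments -------------------------------------------
    gw = select_genomewide(exposure, p_instrument)
    if len(gw) == 0:
        raise InsufficientInstrumentsError(
            f"no genome-wide-significant instruments for {exposure.trait_name}"
        )
    if ld is not None:
        clump = ld_clump(gw, ld, clump_r2)
        gw = gw.subset(clump.kept)
    fstats = f_statistics(gw)
    exp_instruments = gw
    log.info(
        "%s: %d instruments selected (min F = %.1f)",
        exposure.trait_name, len(gw), fstats.min_f,
    )
    report.tables["instruments"] = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in gw.records],
            "pval": [r.pval for r in gw.records],
            "F": [fstats.f_stats[r.snp_id] for r in gw.records],
        }
    )

    # --- mediator instruments (for the MVMR union) ----------------------
    med_instruments: dict[str, SummaryTable] = {}
    for med, _ in mediators:
        mg = select_genomewide(med, p_instrument)
        if ld is not None and len(mg):
            mg = mg.subset(ld_clump(mg, ld, clump_r2).kept)
        med_instruments[med.trait_name] = mg

    # --- total effects + sensitivity battery ----------------------------
    total_rows: list[dict] = []
    presso_rows: list[dict] = []
    for outcome in outcomes:
        try:
            h = harmonize(exp_instruments, outcome)
            res = ivw(h)
            report.total_results[outcome.trait_name] = res
            total_rows.extend(_sensitivity_rows(h, nsim, seed, n_boot))
            pres = run_presso(h, nsim=nsim, seed=seed)
            presso_rows.append(
                {
                    "exposure": exposure.trait_name,
                    "outcome": outcome.trait_name,
                    "global_rss": pres.global_rss,
                    "global_p": pres.global_p,
                    "n_outliers": len(pres.outliers),
                    "outliers": ";".join(s for s, _ in pres.outliers),
                    "corrected_effect": (
                        pres.corrected.beta if pres.corrected else np.nan
                    ),
                    "distortion_p": (
                        pres.distortion_p if pres.distortion_p is not None else np.nan
                    ),
                }
            )
            report.tables.setdefault("single_snp", pd.DataFrame())
            ss = single_snp_analysis(h).assign(outcome=outcome.trait_name)
            loo = leave_one_out(h).assign(outcome=outcome.trait_name)
            report.tables["single_snp"] = pd.concat(
                [report.tables["single_snp"], ss], ignore_index=True
            )
            report.tables.setdefault("leave_one_out", pd.DataFrame())
            report.tables["leave_one_out"] = pd.concat(
                [report.tables["leave_one_out"], loo], ignore_index=True
            )
        except (InsufficientInstrumentsError, ValueError) as exc:
            report.errors.append(
                {"stage": "total", "pair": f"{exposure.trait_name}-{outcome.trait_name}",
                 "error": str(exc)}
            )
    report.tables["total_effects"] = pd.DataFrame(total_rows)
    report.tables["presso"] = pd.DataFrame(presso_rows)

    # --- step 1: exposure -> mediator -----------------------------------
    step1_rows = []
    eligible: list[str] = []
    for med, fam in mediators:
        name = med.trait_name
        try:
            h = harmonize(exp_instruments, med)
            res = ivw(h)
        except (InsufficientInstrumentsError, ValueError) as exc:
            report.errors.append(
                {"stage": "step1", "pair": f"{exposure.trait_name}-{name}",
                 "error": str(exc)}
            )
            continue
        report.step1_results[name] = res
        thr = bonferroni_threshold(families[fam])
        passed = res.pval < suggestive_p
        step1_rows.append(
            {
                "mediator": name, "family": fam, "Nsnp": res.nsnp,
                "Effect": res.beta, "Se": res.se, "P-value": res.pval,
                "suggestive": passed,
                "bonferroni_threshold": thr,
                "bonferroni_significant": res.pval < thr,
                "excluded": not passed,
            }
        )
        if passed:
            eligible.append(name)
    report.tables["step1"] = pd.DataFrame(step1_rows)

    # --- step 2: MVMR (exposure + mediator) -> outcome -------------------
    step2_rows = []
    med_tables = {m.trait_name: m for m, _ in mediators}
    for name in eligible:
        med_full = med_tables[name]
        ids = [
            {r.snp_id for r in exp_instruments.records},
            {r.snp_id for r in med_instruments[name].records},
        ]
        for outcome in outcomes:
            pair = f"{name}-{outcome.trait_name}"
            try:
                exp_sub, med_sub, out_sub = _instrument_union(
                    [exposure, med_full, outcome], ids
                )
                h = harmonize([exp_sub, med_sub], out_sub)
                res = mvmr_ivw(h)
            except (InsufficientInstrumentsError, CollinearityError, ValueError) as exc:
                report.errors.append(
                    {"stage": "step2", "pair": pair, "error": str(exc)}
                )
                step2_rows.append(
                    {"mediator": name, "outcome": outcome.trait_name,
                     "Nsnp": np.nan, "Effect": np.nan, "Se": np.nan,
                     "P-value": np.nan, "OR": np.nan,
                     "status": f"failed: {exc}"}
                )
                continue
            report.step2_results[(name, outcome.trait_name)] = res
            row = res.row(name)
            step2_rows.append(
                {"mediator": name, "outcome": outcome.trait_name,
                 "Nsnp": res.nsnp, "Effect": row["beta"], "Se": row["se"],
                 "P-value": row["pval"], "OR": row["or"],
                 "status": "ok" if row["pval"] < suggestive_p else "excluded_step2"}
            )
    report.tables["step2"] = pd.DataFrame(step2_rows)

    # --- mediation --------------------------------------------------------
    mediation_rows = []
    combined_rows = []
    for outcome in outcomes:
        oname = outcome.trait_name
        total = report.total_results.get(oname)
        if total is None:
            continue
        ok_mediators = []
        for name in eligible:
            res2 = report.step2_results.get((name, oname))
            if res2 is None:
                continue
            row = res2.row(name)
            flag = "ok" if row["pval"] < suggestive_p else "excluded_step2"
            med_res = mediate(
                report.step1_results[name], res2, total, mediator_name=name,
                flag=flag,
            )
            report.mediation_results[(name, oname)] = med_res
            mediation_rows.append({**med_res.to_row(), "outcome": oname})
            if flag == "ok":
                ok_mediators.append(name)
        for med, _ in mediators:
            name = med.trait_name
            if name in eligible or name not in report.step1_results:
                continue
            s1 = report.step1_results[name]
            mediation_rows.append(
                {
                    "mediator": name, "a": s1.beta, "se_a": s1.se,
                    "b": np.nan, "se_b": np.nan,
                    "indirect": np.nan, "se_indirect": np.nan,
                    "total": total.beta, "proportion": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "flag": "excluded_step1", "outcome": oname,
                }
            )
        # combined difference-method mediation over all retained mediators
        if ok_mediators:
            ids = [{r.snp_id for r in exp_instruments.records}] + [
                {r.snp_id for r in med_instruments[n].records} for n in ok_mediators
            ]
            try:
                subs = _instrument_union(
                    [exposure] + [med_tables[n] for n in ok_mediators] + [outcome],
                    ids,
                )
                h = harmonize(subs[:-1], subs[-1])
                res = mvmr_ivw(h)
                direct = res.row(exposure.trait_name)
                comb = combined_mediation(
                    total.beta, total.se, direct["beta"], direct["se"]
                )
                report.combined_results[oname] = comb
                combined_rows.append(
                    {
                        "outcome": oname,
                        "mediators": "+".join(ok_mediators),
                        "total": comb.total,
                        "direct_adjusted": comb.direct_adjusted,
                        "combined_indirect": comb.combined_indirect,
                        "se_indirect": comb.se_indirect,
                        "proportion": comb.combined_proportion,
                        "ci_low": comb.ci_low,
                        "ci_high": comb.ci_high,
                    }
                )
            except (InsufficientInstrumentsError, CollinearityError, ValueError) as exc:
                report.errors.append(
                    {"stage": "combined", "pair": oname, "error": str(exc)}
                )
    report.tables["mediation"] = pd.DataFrame(mediation_rows)
    report.tables["combined"] = pd.DataFrame(combined_rows)
    report.tables["errors"] = pd.DataFrame(report.errors)
    return report


def _round_report(df: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: effects/SE/OR to 2 decimals, proportions to
    whole percent."""
    def half_up(x, ndigits):
        scale = 10.0**ndigits
        return np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale

    out = df.copy()
    for col in out.columns:
        if col in ("Effect", "Se", "OR", "a", "se_a", "b", "se_b"):
            out[col] = half_up(out[col].astype(float), 2)
        elif col in ("proportion",):
            out[col] = half_up(100 * out[col].astype(float), 0)
    return out


def run_two_step(config: StudyConfig) -> Path:
    """File-based front end: read tables, run the study, write TSV reports.

    Returns the output directory. A manifest with the config hash, seed and
    package version accompanies the tables so a re-run is verifiable.
    """
    exposure, _ = read_sumstats(config.exposure, Path(config.exposure).stem, "binary")
    mediators = []
    for name, path, fam in config.mediators:
        table, _ = read_sumstats(path, name, "continuous")
        mediators.append((table, fam))
    outcomes = []
    for name, path in config.outcomes:
        table, _ = read_sumstats(path, name, "binary")
        outcomes.append(table)
    ld = read_ld_matrix(config.ld) if config.ld else None

    report = run_study(
        exposure, mediators, outcomes, ld=ld,
        p_instrument=config.p_instrument, clump_r2=config.clump_r2,
        suggestive_p=config.suggestive_p, nsim=config.nsim,
        seed=config.seed, n_boot=config.n_boot,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        if name in ("total_effects", "mediation"):
            _round_report(df).to_csv(
                out / f"{name}_report.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
    cfg_dict = {k: v for k, v in config.__dict__.items() if k != "output_dir"}
    cfg_repr = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
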