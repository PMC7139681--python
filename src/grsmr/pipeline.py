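"""End-to-end orchestration: per-SNP, score dose-response and stratified stages.

A study table is assembled from phenotypes and harmonized dosages (read
from files or simulated), the weighted score and its control-anchored
categories are computed once, and three analysis stages mirror the
standard reporting layout of an instrument-score case-control study:

* ``per_snp_stage`` - allele frequencies by arm plus an
  additive-dosage logistic odds ratio per instrument SNP;
* ``grs_stage`` - per-category odds ratios against the shortest
  category for each scheme (median / tertile / quartile) with a
  dose-response trend p;
* ``stratified_stage`` - the dichotomized comparison within sex strata
  (age-adjusted) and per histologic subtype against the full control
  set (age- and sex-adjusted), reusing the full-control cutpoints.

Internal estimates keep full precision; rounding happens only in the
rendered report tables.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc
from .grs import score_and_categorize
from .io import (
    format_or,
    format_p,
    impute_missing,
    load_packaged_instruments,
    read_dosage_tsv,
    read_instruments,
    read_phenotypes,
    read_vcf,
    write_report,
)
from .synth import DiseaseModel, SimConfig, SyntheticCohort, simulate_cohort, simulate_replicates
from .types import DosageMatrix, GRSResult, InstrumentTable, PhenotypeTable

__all__ = [
    "AnalysisConfig",
    "StudyTable",
    "build_study",
    "study_from_cohort",
    "dichotomized_recovery",
    "per_snp_stage",
    "grs_stage",
    "stratified_stage",
    "render_tables",
    "run",
]

logger = logging.getLogger("grsmr")

CATEGORY_LABELS = {
    "median": ["Short", "Long"],
    "tertile": ["Shortest", "Medium", "Longest"],
    "quartile": ["1 (shortest)", "2", "3", "4 (longest)"],
}

SUBTYPE_ORDER = ["Leiomyosarcoma", "GIST", "Liposarcoma", "Angiosarcoma", "Other"]


@dataclass(frozen=True)
class AnalysisConfig:
    """What to analyze and how to report it."""

    instruments_path: str | None = None  # None -> packaged instrument table
    vcf_path: str | None = None
    dosage_path: str | None = None  # TSV alternative to VCF
    phenotypes_path: str | None = None
    sim: SimConfig | None = None  # synthetic cohort instead of files
    covariates: tuple[str, ...] = ("age", "sex")
    schemes: tuple[str, ...] = ("median", "tertile", "quartile")
    strata: tuple[str, ...] = ("sex", "subtype")
    weighted: bool = True
    dosage_field: bool = False  # VCF DS instead of hard GT
    ties: str = "lower"
    rounding: int = 2
    seed: int = 0
    outdir: str = "grsmr-out"

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one categorization scheme required")
        if self.rounding < 0:
            raise ValueError("rounding decimals must be >= 0")
        unknown = set(self.schemes) - set(CATEGORY_LABELS)
        if unknown:
            raise ValueError(f"unknown scheme(s): {sorted(unknown)}")


@dataclass(frozen=True)
class StudyTable:
    """Joined cohort: one row per subject with score and categories."""

    phenotypes: PhenotypeTable
    dosages: DosageMatrix
    grs_result: GRSResult
    instruments: InstrumentTable
    n_dropped: int = 0

    @property
    def df(self) -> pd.DataFrame:
        out = self.phenotypes.df.copy()
        out["grs"] = self.grs_result.grs
        for scheme, cats in self.grs_result.categories.items():
            out[f"cat_{scheme}"] = cats
        return out

    def covariate_matrix(self, covariates: tuple[str, ...]) -> np.ndarray | None:
        """Numeric covariate columns: age in years, sex as female=1."""
        if not covariates:
            return None
        cols = []
        for name in covariates:
            if name == "age":
                cols.append(self.phenotypes.df["age"].to_numpy(dtype=float))
            elif name == "sex":
                cols.append(
                    (self.phenotypes.df["sex"] == "female").to_numpy(dtype=float)
                )
            else:
                raise ValueError(f"unsupported covariate {name!r}")
        return np.column_stack(cols)


def build_study(config: AnalysisConfig) -> StudyTable:
    """Load or simulate inputs and assemble the scored study table."""
    instruments = (
        read_instruments(config.instruments_path)
        if config.instruments_path
        else load_packaged_instruments()
    )
    if config.sim is not None:
        cohort = simulate_cohort(config.sim)
        phenotypes, dosages = cohort.phenotypes, cohort.dosages
        instruments = config.sim.resolved_instruments()
    else:
        if config.phenotypes_path is None:
            raise ValueError("phenotypes_path required when not simulating")
        phenotypes = read_phenotypes(config.phenotypes_path)
        if config.vcf_path is not None:
            dosages, report = read_vcf(
                config.vcf_path, instruments, dosage_field=config.dosage_field
            )
            if report.missing_instruments:
                logger.warning(
                    "missing instruments: %s", report.missing_instruments
                )
        elif config.dosage_path is not None:
            dosages = read_dosage_tsv(config.dosage_path)
        else:
            raise ValueError("either vcf_path or dosage_path is required")

    common = [s for s in phenotypes.subject_ids if s in set(dosages.subject_ids)]
    n_dropped = (len(phenotypes) - len(common)) + (len(dosages) - len(common))
    if n_dropped:
        logger.warning(
            "dropping %d subject(s) absent from phenotype/dosage intersection",
            n_dropped,
        )
    phenotypes = PhenotypeTable.from_frame(
        phenotypes.df.loc[common].reset_index(drop=True)
    )
    dosages = DosageMatrix.from_frame(dosages.df.loc[common])
    is_control = (phenotypes.df["status"] == "control").to_numpy()
    dosages = impute_missing(dosages, is_control)
    grs_result = score_and_categorize(
        dosages,
        instruments,
        is_control,
        schemes=tuple(config.schemes),
        weighted=config.weighted,
        ties=config.ties,
    )
    return StudyTable(
        phenotypes=phenotypes,
        dosages=dosages,
        grs_result=grs_result,
        instruments=instruments,
        n_dropped=n_dropped,
    )


def study_from_cohort(
    cohort: SyntheticCohort, config: AnalysisConfig | None = None
) -> StudyTable:
    """Assemble a scored study table directly from a simulated cohort."""
    config = config or AnalysisConfig()
    instruments = cohort.config.resolved_instruments()
    is_control = (cohort.phenotypes.df["status"] == "control").to_numpy()
    grs_result = score_and_categorize(
        cohort.dosages,
        instruments,
        is_control,
        schemes=tuple(config.schemes),
        weighted=config.weighted,
        ties=config.ties,
    )
    return StudyTable(
        phenotypes=cohort.phenotypes,
        dosages=cohort.dosages,
        grs_result=grs_result,
        instruments=instruments,
    )


def dichotomized_recovery(
    true_or: float,
    n_cases: int = 821,
    n_controls: int = 851,
    n_replicates: int = 200,
    seed: int = 1,
    subtype: str | None = None,
) -> pd.DataFrame:
    """Calibration study: re-estimate a known dichotomized effect.

    Simulates replicate cohorts whose disease model carries a true
    dichotomized-score log odds ratio of ``log(true_or)``, re-analyzes
    each with the reporting pipeline's adjusted logistic model (the
    overall dose-response stage, or the subtype-stratified stage when
    ``subtype`` is given), and returns one row per replicate with the
    estimated log-OR and its SE. Replicate ``r`` uses ``seed + r``.
    """
    base = SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        disease=DiseaseModel(log_or=math.log(true_or)),
        case_subtype=subtype,
        seed=seed,
    )
    config = AnalysisConfig(
        schemes=("median",),
        strata=("subtype",) if subtype is not None else (),
    )
    rows = []
    for r, cohort in enumerate(simulate_replicates(base, n_replicates)):
        study = study_from_cohort(cohort, config)
        if subtype is None:
            table = grs_stage(study, config)["median"]
            hit = table[~table["reference"]].iloc[0]
        else:
            table = stratified_stage(study, config)["by_subtype"]
            hit = table[(table["stratum"] == subtype) & (~table["reference"])].iloc[0]
        rows.append(
            {"replicate": r, "estimate": float(hit["estimate"]), "se": float(hit["se"])}
        )
    return pd.DataFrame(rows)


def per_snp_stage(study: StudyTable, config: AnalysisConfig) -> pd.DataFrame:
    """Allele frequencies and adjusted per-long-allele OR for each SNP.

    A fit failure (separation, rank deficiency) flags the row and the
    stage continues with the remaining SNPs.
    """
    y = study.phenotypes.is_case.to_numpy()
    covariates = study.covariate_matrix(config.covariates)
    is_case = y.astype(bool)
    rows = []
    for _, inst in study.instruments.df.iterrows():
        dos = study.dosages.df[inst.snp_id].to_numpy(dtype=float)
        row = {
            "snp_id": inst.snp_id,
            "chrom": inst.chrom,
            "pos": inst.pos,
            "gene": inst.gene,
            "alleles": f"{inst.short_allele}/{inst.long_allele}",
            "beta": inst.beta,
            "eaf_case": assoc.eaf(dos, is_case),
            "eaf_control": assoc.eaf(dos, ~is_case),
        }
        try:
            res = assoc.exposure_result(
                y,
                dos,
                covariates,
                covariate_names=list(config.covariates),
                exposure_name="dosage",
            )
            row.update(
                estimate=res.estimate,
                se=res.se,
                or_=res.or_,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p=res.p,
                n=res.n,
                error="",
            )
        except (assoc.SeparationError, assoc.RankDeficiencyError, ValueError) as exc:
            logger.warning("per-SNP fit failed for %s: %s", inst.snp_id, exc)
            row.update(
                estimate=np.nan,
                se=np.nan,
                or_=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                p=np.nan,
                n=len(y),
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _category_rows(
    y: np.ndarray,
    cats: np.ndarray,
    labels: list[str],
    covariates: np.ndarray | None,
    covariate_names: tuple[str, ...],
) -> pd.DataFrame:
    """Per-category counts and dummy-coded adjusted ORs, category 1 = reference."""
    k = len(labels)
    for c in range(1, k + 1):
        if not np.any(cats == c):
            raise ValueError(f"empty category: {labels[c - 1]!r}")
    n = y.shape[0]
    dummies = np.column_stack([(cats == c).astype(float) for c in range(2, k + 1)])
    cols = [np.ones(n), dummies]
    names = ["intercept"] + [f"cat{c}" for c in range(2, k + 1)]
    if covariates is not None:
        cols.append(covariates)
        names.extend(covariate_names)
    fit = assoc.fit_logistic(y, np.column_stack(cols), names)
    rows = []
    for c in range(1, k + 1):
        in_cat = cats == c
        n_control = int((in_cat & (y == 0)).sum())
        n_case = int((in_cat & (y == 1)).sum())
        total = n_control + n_case
        row = {
            "category": labels[c - 1],
            "n_control": n_control,
            "pct_control": 100.0 * n_control / total,
            "n_case": n_case,
            "pct_case": 100.0 * n_case / total,
        }
        if c == 1:
            row.update(
                estimate=0.0, se=np.nan, or_=1.0, ci_low=np.nan, ci_high=np.nan,
                p=np.nan, reference=True,
            )
        else:
            res = fit.result(f"cat{c}")
            row.update(
                estimate=res.estimate,
                se=res.se,
                or_=res.or_,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p=res.p,
                reference=False,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["n"] = n
    return out


def grs_stage(study: StudyTable, config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Dose-response tables per categorization scheme with trend p."""
    y = study.phenotypes.is_case.to_numpy()
    covariates = study.covariate_matrix(config.covariates)
    tables: dict[str, pd.DataFrame] = {}
    for scheme in config.schemes:
        cats = study.grs_result.categories[scheme].to_numpy()
        labels = CATEGORY_LABELS[scheme]
        table = _category_rows(y, cats, labels, covariates, config.covariates)
        table.insert(0, "scheme", scheme)
        table["trend_p"] = np.nan
        if len(labels) >= 3:
            trend = assoc.trend_test(
                y, cats, covariates, covariate_names=list(config.covariates)
            )
            table.loc[table.index[-1], "trend_p"] = trend.p
        tables[scheme] = table
    return tables


def stratified_stage(
    study: StudyTable, config: AnalysisConfig
) -> dict[str, pd.DataFrame]:
    """Dichotomized-score comparisons within sex and subtype strata.

    Sex strata adjust for age only; subtype strata compare one
    subtype's cases against the *full* control set, adjusting for age
    and sex. Cutpoints always come from the full control group, so
    every stratum shares the same Short/Long split.
    """
    if "median" not in study.grs_result.categories:
        raise ValueError("stratified stage requires the median scheme")
    cats = study.grs_result.categories["median"].to_numpy()
    pheno = study.phenotypes.df
    y_all = study.phenotypes.is_case.to_numpy()
    tables: dict[str, pd.DataFrame] = {}

    if "sex" in config.strata:
        blocks = []
        for sex in ("male", "female"):
            mask = (pheno["sex"] == sex).to_numpy()
            if not (y_all[mask] == 1).any():
                warnings.warn(f"no cases in sex stratum {sex!r}; skipped", stacklevel=2)
                continue
            age = pheno.loc[mask, "age"].to_numpy(dtype=float)[:, None]
            block = _category_rows(
                y_all[mask], cats[mask], CATEGORY_LABELS["median"], age, ("age",)
            )
            block.insert(0, "stratum", sex)
            blocks.append(block)
        if blocks:
            tables["by_sex"] = pd.concat(blocks, ignore_index=True)

    if "subtype" in config.strata:
        subtype = pheno["subtype"].replace("", "Other")
        case_subtypes = set(subtype[pheno["status"] == "case"])
        observed = [s for s in SUBTYPE_ORDER if s in case_subtypes] + sorted(
            case_subtypes - set(SUBTYPE_ORDER)
        )
        is_control = (pheno["status"] == "control").to_numpy()
        blocks = []
        for name in observed:
            mask = is_control | ((subtype == name) & ~is_control).to_numpy()
            y = y_all[mask]
            if not (y == 1).any():
                warnings.warn(
                    f"no cases in subtype stratum {name!r}; skipped", stacklevel=2
                )
                continue
            covars = np.column_stack(
                [
                    pheno.loc[mask, "age"].to_numpy(dtype=float),
                    (pheno.loc[mask, "sex"] == "female").to_numpy(dtype=float),
                ]
            )
            block = _category_rows(
                y, cats[mask], CATEGORY_LABELS["median"], covars, ("age", "sex")
            )
            block.insert(0, "stratum", name)
            blocks.append(block)
        if blocks:
            tables["by_subtype"] = pd.concat(blocks, ignore_index=True)
    return tables


def render_tables(
    tables: dict[str, pd.DataFrame], decimals: int = 2
) -> dict[str, pd.DataFrame]:
    """Report-layer formatting: OR (CI) to fixed decimals, p scientific < 1e-3."""
    rendered = {}
    for name, frame in tables.items():
        out = frame.copy()
        if {"or_", "ci_low", "ci_high"} <= set(out.columns):
            ref = out.get("reference")
            or_ci = []
            for i, row in out.iterrows():
                if ref is not None and bool(ref.loc[i]):
                    or_ci.append("1 (reference)")
                elif np.isnan(row["or_"]):
                    or_ci.append("NA")
                else:
                    or_ci.append(
                        f"{format_or(row['or_'], decimals)} "
                        f"({format_or(row['ci_low'], decimals)}-"
                        f"{format_or(row['ci_high'], decimals)})"
                    )
            out["or_95ci"] = or_ci
        for col in ("p", "trend_p"):
            if col in out.columns:
                out[col] = [
                    "" if (isinstance(v, float) and np.isnan(v)) else format_p(v)
                    for v in out[col]
                ]
        for col in ("pct_control", "pct_case", "eaf_case", "eaf_control"):
            if col in out.columns:
                out[col] = out[col].map(lambda v: f"{v:.2f}")
        drop = [
            c
            for c in ("estimate", "se", "or_", "ci_low", "ci_high", "reference")
            if c in out.columns
        ]
        rendered[name] = out.drop(columns=drop)
    return rendered


def run(config: AnalysisConfig) -> dict[str, Path]:
    """Execute every configured stage and write report TSVs plus a run log."""
    study = build_study(config)
    tables: dict[str, pd.DataFrame] = {}
    tables["per_snp"] = per_snp_stage(study, config)
    for scheme, frame in grs_stage(study, config).items():
        tables[f"grs_{scheme}"] = frame
    for name, frame in stratified_stage(study, config).items():
        tables[name] = frame

    rendered = render_tables(tables, config.rounding)
    outdir = Path(config.outdir)
    paths = write_report(rendered, outdir)
    n_case, n_control = study.phenotypes.counts()
    log = {
        "n_cases": n_case,
        "n_controls": n_control,
        "n_dropped": study.n_dropped,
        "seed": config.seed,
        "weighted": config.weighted,
        "cutpoints": {
            scheme: [float(c) for c in cuts]
            for scheme, cuts in study.grs_result.cutpoints.items()
        },
        "tables": sorted(tables),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %d report tables to %s", len(paths), outdir)
    return {p.stem: p for p in paths} | {"run_log": log_path}
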