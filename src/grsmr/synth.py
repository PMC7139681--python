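"""Synthetic case-control cohort generator.

Emulates the generative structure the analysis assumes: Hardy-Weinberg
genotypes at the instruments' reference allele frequencies, a latent
exposure (telomere length) equal to the weighted allele score plus
Gaussian noise, and a rare-disease logistic model in which risk rises
with the score. Case-control arms are then sampled from the simulated
population, with ages and sexes frequency-matched between arms, so
every downstream stage can be exercised and calibrated without any
external data.

Defaults reproduce the study conditions of the motivating case-control
design: 821 cases / 851 controls, control ages ~ N(57.0, 8.62) and case
ages ~ N(56.39, 11.58) years, 52.7% female in both arms, subtype shares
led by leiomyosarcoma and GIST, baseline disease prevalence 5%, and
residual noise calibrated so the score explains ~2% of latent-exposure
variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from . import grs as grs_mod
from .io import load_packaged_instruments
from .types import DosageMatrix, InstrumentTable, PhenotypeTable

__all__ = [
    "DiseaseModel",
    "SimConfig",
    "SyntheticCohort",
    "default_noise_sd",
    "sample_genotypes",
    "simulate_latent_ltl",
    "simulate_cohort",
    "simulate_replicates",
]

# Arm-level demographics used as frequency-matching targets.
DEFAULT_CASE_AGE = (56.39, 11.58)
DEFAULT_CONTROL_AGE = (57.00, 8.62)
DEFAULT_FEMALE_FRACTION = 0.527
DEFAULT_SUBTYPE_FRACTIONS = {
    "Leiomyosarcoma": 0.331,
    "GIST": 0.268,
    "Liposarcoma": 0.220,
    "Angiosarcoma": 0.073,
    "Other": 0.107,
}

_POPULATION_CAP = 2_000_000


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model: logit P(case) = alpha + log_or * exposure.

    ``effect_scale="dichotomized"`` uses an indicator of
    above-population-median score (so the simulated truth maps directly
    onto the reported dichotomized odds ratios);
    ``"per_unit_grs"`` uses the mean-centered continuous score. The
    intercept is solved so the null-exposure group sits exactly at
    ``baseline_prevalence``.
    """

    effect_scale: Literal["dichotomized", "per_unit_grs"] = "dichotomized"
    log_or: float = math.log(1.44)
    baseline_prevalence: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.effect_scale not in ("dichotomized", "per_unit_grs"):
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_cases: int = 821
    n_controls: int = 851
    instruments: InstrumentTable | None = None  # None -> packaged 11-SNP table
    ltl_noise_sd: float | None = None  # None -> calibrated, see default_noise_sd
    disease: DiseaseModel = field(default_factory=DiseaseModel)
    case_age: tuple[float, float] = DEFAULT_CASE_AGE
    control_age: tuple[float, float] = DEFAULT_CONTROL_AGE
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    subtype_fractions: dict[str, float] | None = None
    case_subtype: str | None = None  # force a single subtype (stratum studies)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("arm sizes must be positive")
        if self.ltl_noise_sd is not None and self.ltl_noise_sd < 0:
            raise ValueError("ltl_noise_sd must be nonnegative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")

    def resolved_instruments(self) -> InstrumentTable:
        return self.instruments or load_packaged_instruments()

    def resolved_noise_sd(self, instruments: InstrumentTable) -> float:
        if self.ltl_noise_sd is not None:
            return self.ltl_noise_sd
        return default_noise_sd(instruments)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated phenotypes and genotypes plus the hidden truth.

    ``latent_ltl`` and ``exposed`` (the true exposure indicator or
    centered score entering the disease model) are retained for
    calibration tests only; a real study never observes them.
    """

    phenotypes: PhenotypeTable
    dosages: DosageMatrix
    latent_ltl: pd.Series
    grs: pd.Series
    exposed: pd.Series
    config: SimConfig


def default_noise_sd(
    instruments: InstrumentTable, explained_fraction: float = 0.02
) -> float:
    """Residual SD making the score explain the given variance share.

    Under Hardy-Weinberg, the score variance is
    ``sum_j beta_j^2 * 2 p_j (1 - p_j)``; the residual SD is chosen so
    score variance / total latent variance equals ``explained_fraction``
    (default 2%).
    """
    if not 0.0 < explained_fraction < 1.0:
        raise ValueError("explained_fraction must lie in (0, 1)")
    b = instruments.betas.to_numpy()
    p = instruments.eafs.to_numpy()
    var_grs = float((b**2 * 2.0 * p * (1.0 - p)).sum())
    return math.sqrt(var_grs * (1.0 - explained_fraction) / explained_fraction)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_genotypes(eaf: float, n: int, seed) -> np.ndarray:
    """Hardy-Weinberg dosages: each of two alleles drawn Bernoulli(eaf)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= eaf <= 1.0:
        raise ValueError("eaf must lie in [0, 1]")
    return _rng(seed).binomial(2, eaf, size=n)


def simulate_latent_ltl(
    dosages: DosageMatrix | pd.DataFrame,
    instruments: InstrumentTable,
    noise_sd: float,
    seed,
) -> pd.Series:
    """Latent exposure: weighted score plus N(0, noise_sd^2) residual."""
    score = grs_mod.compute_grs(dosages, instruments, weighted=True)
    noise = _rng(seed).normal(0.0, noise_sd, size=len(score)) if noise_sd > 0 else 0.0
    return pd.Series(score.to_numpy() + noise, index=score.index, name="latent_ltl")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one case-control cohort under the configured model.

    A source population is simulated (genotypes -> latent exposure ->
    score -> disease), then the requested numbers of cases and controls
    are sampled without replacement. The population auto-scales until
    both arms are attainable, up to a hard cap.
    """
    rng = np.random.default_rng(config.seed)
    instruments = config.resolved_instruments()
    noise_sd = config.resolved_noise_sd(instruments)
    dm = config.disease

    # Expected case fraction guides the initial population size.
    p0 = dm.baseline_prevalence
    p1 = 1.0 / (1.0 + math.exp(-(_logit(p0) + dm.log_or)))
    case_frac = 0.5 * (p0 + p1) if dm.effect_scale == "dichotomized" else p0
    n_pop = int(
        1.4 * max(config.n_cases / case_frac, config.n_controls / (1.0 - case_frac))
    )
    n_pop = max(n_pop, 2_000)

    while True:
        if n_pop > _POPULATION_CAP:
            raise RuntimeError(
                f"cannot reach arm sizes ({config.n_cases}, {config.n_controls}) "
                f"within the population cap {_POPULATION_CAP}"
            )
        geno = {
            row.snp_id: rng.binomial(2, row.ref_eaf, size=n_pop)
            for _, row in instruments.df.iterrows()
        }
        dosage_df = pd.DataFrame(geno, index=[f"S{i:07d}" for i in range(n_pop)])
        dosage_df.index.name = "subject_id"
        latent = simulate_latent_ltl(dosage_df, instruments, noise_sd, rng)
        score = grs_mod.compute_grs(dosage_df, instruments, weighted=True)

        if dm.effect_scale == "dichotomized":
            exposure = (score.to_numpy() > np.median(score.to_numpy())).astype(float)
        else:
            exposure = score.to_numpy() - score.to_numpy().mean()
        eta = _logit(dm.baseline_prevalence) + dm.log_or * exposure
        p_case = 1.0 / (1.0 + np.exp(-eta))
        is_case = rng.random(n_pop) < p_case

        case_idx = np.flatnonzero(is_case)
        control_idx = np.flatnonzero(~is_case)
        if case_idx.size >= config.n_cases and control_idx.size >= config.n_controls:
            break
        n_pop *= 2

    chosen_cases = rng.choice(case_idx, size=config.n_cases, replace=False)
    chosen_controls = rng.choice(control_idx, size=config.n_controls, replace=False)
    order = np.concatenate([chosen_cases, chosen_controls])

    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    mean_case, sd_case = config.case_age
    mean_ctrl, sd_ctrl = config.control_age
    age = np.concatenate(
        [
            np.clip(rng.normal(mean_case, sd_case, config.n_cases), 18.0, None),
            np.clip(rng.normal(mean_ctrl, sd_ctrl, config.n_controls), 18.0, None),
        ]
    )
    sex = np.where(
        rng.random(order.size) < config.female_fraction, "female", "male"
    )
    subtype = np.array([""] * order.size, dtype=object)
    if config.case_subtype is not None:
        subtype[: config.n_cases] = config.case_subtype
    else:
        fractions = config.subtype_fractions or DEFAULT_SUBTYPE_FRACTIONS
        labels = list(fractions)
        probs = np.array([fractions[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        subtype[: config.n_cases] = rng.choice(
            labels, size=config.n_cases, p=probs
        )

    ids = dosage_df.index.to_numpy()[order]
    pheno = PhenotypeTable.from_frame(
        pd.DataFrame(
            {
                "subject_id": ids,
                "status": status,
                "age": age,
                "sex": sex,
                "subtype": subtype,
            }
        )
    )
    picked = dosage_df.index[order]
    return SyntheticCohort(
        phenotypes=pheno,
        dosages=DosageMatrix.from_frame(dosage_df.loc[picked]),
        latent_ltl=latent.loc[picked],
        grs=score.loc[picked],
        exposed=pd.Series(exposure[order], index=picked, name="exposed"),
        config=config,
    )


def simulate_replicates(config: SimConfig, n_replicates: int) -> Iterator[SyntheticCohort]:
    """Independent replicate cohorts; replicate r uses seed + r."""
    for r in range(n_replicates):
        yield simulate_cohort(replace(config, seed=config.seed + r))
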