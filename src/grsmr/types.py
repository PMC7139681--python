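"""Domain containers shared across the pipeline.

All tabular containers wrap a validated :class:`pandas.DataFrame` so that
downstream code can rely on column names, dtypes and invariants without
re-checking them at every call site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "InstrumentTable",
    "PhenotypeTable",
    "DosageMatrix",
    "ContingencyTable",
    "AssocResult",
    "GRSResult",
    "VALID_BASES",
]

VALID_BASES = frozenset("ACGT")

INSTRUMENT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "gene",
    "short_allele",
    "long_allele",
    "beta",
    "ref_eaf",
]

PHENOTYPE_COLUMNS = ["subject_id", "status", "age", "sex", "subtype"]


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass(frozen=True)
class InstrumentTable:
    """Instrument SNPs with per-long-allele weights.

    Each row holds one exposure-associated variant: its identifier,
    genomic location, nearest gene, the short (reference) and long
    (effect) allele, the per-long-allele effect ``beta`` on the exposure
    in GWAS units, and the long-allele reference frequency ``ref_eaf``.
    Betas are harmonized so the long allele always increases the
    exposure, hence ``beta > 0`` for every row.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InstrumentTable":
        missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"instrument table missing columns: {missing}")
        df = df.loc[:, INSTRUMENT_COLUMNS].reset_index(drop=True)
        if len(df) == 0:
            raise ValidationError("instrument table has no rows")
        df = df.astype(
            {
                "snp_id": str,
                "chrom": str,
                "pos": int,
                "gene": str,
                "short_allele": str,
                "long_allele": str,
                "beta": float,
                "ref_eaf": float,
            }
        )
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate snp_id: {sorted(dup.unique())}")
        for i, row in df.iterrows():
            label = f"row {i} ({row.snp_id})"
            for col in ("short_allele", "long_allele"):
                if row[col] not in VALID_BASES:
                    raise ValidationError(f"{label}: malformed allele {row[col]!r}")
            if row.short_allele == row.long_allele:
                raise ValidationError(f"{label}: short and long allele identical")
            if not row.beta > 0:
                raise ValidationError(
                    f"{label}: beta must be > 0 after long-allele harmonization"
                )
            if not 0.0 < row.ref_eaf < 1.0:
                raise ValidationError(f"{label}: ref_eaf must lie in (0, 1)")
        return cls(df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    @property
    def betas(self) -> pd.Series:
        return self.df.set_index("snp_id")["beta"]

    @property
    def eafs(self) -> pd.Series:
        return self.df.set_index("snp_id")["ref_eaf"]

    def row(self, snp_id: str) -> pd.Series:
        hit = self.df[self.df["snp_id"] == snp_id]
        if hit.empty:
            raise KeyError(snp_id)
        return hit.iloc[0]

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class PhenotypeTable:
    """Case-control phenotype records.

    ``status`` is ``"case"`` or ``"control"``; ``subtype`` is a histologic
    label for cases (empty string means unclassified and is grouped as
    ``"Other"`` by the stratified stage) and must be absent for controls.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = df.loc[:, PHENOTYPE_COLUMNS].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["subtype"] = df["subtype"].fillna("").astype(str)
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate subject_id: {sorted(dup.unique())[:5]}")
        bad_status = set(df["status"]) - {"case", "control"}
        if bad_status:
            raise ValidationError(f"unknown status token(s): {sorted(bad_status)}")
        bad_sex = set(df["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValidationError(f"unknown sex token(s): {sorted(bad_sex)}")
        if (df["age"].astype(float) < 0).any():
            raise ValidationError("negative age")
        offenders = df[(df["status"] == "control") & (df["subtype"] != "")]
        if not offenders.empty:
            raise ValidationError(
                "subtype present on control rows: "
                f"{list(offenders['subject_id'].head())}"
            )
        df["age"] = df["age"].astype(float)
        return cls(df.set_index("subject_id", drop=False))

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"])

    @property
    def is_case(self) -> pd.Series:
        return (self.df["status"] == "case").astype(int)

    def counts(self) -> tuple[int, int]:
        """(n_cases, n_controls)."""
        n_case = int((self.df["status"] == "case").sum())
        return n_case, len(self.df) - n_case

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class DosageMatrix:
    """Subjects x SNPs long-allele dosage matrix.

    Values are the count (or imputed expected count) of long alleles,
    in [0, 2]; NaN marks a missing genotype. Row index holds subject
    ids, columns hold SNP ids.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DosageMatrix":
        values = df.to_numpy(dtype=float)
        finite = np.isfinite(values)
        if ((values < 0) & finite).any() or ((values > 2) & finite).any():
            raise ValidationError("dosage outside [0, 2]")
        out = df.astype(float).copy()
        out.index = out.index.astype(str)
        out.index.name = "subject_id"
        out.columns = out.columns.astype(str)
        return cls(out)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df.columns)

    def missing_fraction(self) -> pd.Series:
        return self.df.isna().mean()

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows index exposure, columns index status.

    ``a`` unexposed controls, ``b`` exposed controls, ``c`` unexposed
    cases, ``d`` exposed cases, so the odds ratio for exposure is
    ``ad / bc``. In the score categorization, "unexposed" is the
    short (category 1) group and "exposed" the long group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError("cells must be nonnegative integers")
        if sum(cells) == 0:
            raise ValidationError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        """Rows = (unexposed, exposed), columns = (control, case)."""
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=float)

    def margins(self) -> tuple[int, int, int, int]:
        """(row unexposed, row exposed, col control, col case)."""
        return (self.a + self.c, self.b + self.d, self.a + self.b, self.c + self.d)


@dataclass(frozen=True)
class AssocResult:
    """One association comparison: log-OR, its SE, Wald CI and p."""

    estimate: float
    se: float
    p: float
    n: int
    model: str = ""
    level: float = 0.95
    corrected: bool = False  # Haldane-Anscombe 0.5 applied

    @property
    def or_(self) -> float:
        return math.exp(self.estimate)

    @property
    def ci_low(self) -> float:
        from .assoc import wald_ci  # local import to avoid a cycle

        return wald_ci(self.estimate, self.se, self.level)[0]

    @property
    def ci_high(self) -> float:
        from .assoc import wald_ci

        return wald_ci(self.estimate, self.se, self.level)[1]


@dataclass(frozen=True)
class GRSResult:
    """Per-subject score plus control-anchored category assignments.

    ``categories[scheme]`` maps each subject to a 1-based index where 1
    is the shortest (lowest-score) group; ``cutpoints[scheme]`` holds
    the control-derived thresholds that produced the assignment.
    """

    grs: pd.Series
    categories: Mapping[str, pd.Series] = field(default_factory=dict)
    cutpoints: Mapping[str, np.ndarray] = field(default_factory=dict)
    weighted: bool = True
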