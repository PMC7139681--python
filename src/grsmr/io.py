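"""Readers and writers for the formats the pipeline touches.

Instrument weights ship as a packaged TSV (11 telomere-length
instrument SNPs with long-allele weights and reference allele
frequencies). Genotypes enter either as VCF 4.2 (GT hard calls or a DS
dosage FORMAT field, read through :mod:`pysam`) or as a plain TSV
dosage matrix; phenotypes as CSV. Reports leave as TSV with a fixed,
documented column order so reruns are byte-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import (
    DosageMatrix,
    InstrumentTable,
    PhenotypeTable,
    ValidationError,
)

__all__ = [
    "HarmonizationError",
    "VcfReadReport",
    "load_packaged_instruments",
    "read_instruments",
    "read_phenotypes",
    "write_phenotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "impute_missing",
    "write_report",
    "format_or",
    "format_p",
]

logger = logging.getLogger("grsmr")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class HarmonizationError(ValueError):
    """Observed alleles cannot be reconciled with an instrument's alleles."""


@dataclass
class VcfReadReport:
    """Bookkeeping from a VCF read: what matched, flipped, or is absent."""

    matched: list[str] = field(default_factory=list)
    flipped: list[str] = field(default_factory=list)
    missing_instruments: list[str] = field(default_factory=list)
    ignored_variants: int = 0


def load_packaged_instruments() -> InstrumentTable:
    """The packaged 11-SNP telomere-length instrument table."""
    with resources.files("grsmr.data").joinpath("ltl_instruments.tsv").open() as fh:
        return read_instruments(fh)


def read_instruments(path) -> InstrumentTable:
    """Read an instrument weights TSV into a validated table."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty instrument file: {path}") from exc
    return InstrumentTable.from_frame(df)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a subject_id,status,age,sex,subtype CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "subtype": str})
    return PhenotypeTable.from_frame(df)


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    phenotypes.df.to_csv(path, index=False)


def read_dosage_tsv(path) -> DosageMatrix:
    """Read a subjects x SNPs dosage TSV (first column = subject_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DosageMatrix.from_frame(df)


def write_dosage_tsv(dosages: DosageMatrix, path) -> None:
    """Write dosages with full precision so read-back is exact."""
    df = dosages.df.copy()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def _revcomp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(short: str, long: str) -> bool:
    return short == _revcomp(long)


def read_vcf(
    path,
    instruments: InstrumentTable,
    dosage_field: bool = False,
    strict: bool = False,
) -> tuple[DosageMatrix, VcfReadReport]:
    """Extract long-allele dosages at the instrument sites from a VCF.

    Sites are matched on (chrom, pos) with allele verification, falling
    back to the ID column; variants not in the instrument table are
    counted and ignored. When the observed REF/ALT pair does not equal
    the instrument's allele pair directly, the default mode retries on
    the reverse-complemented strand — except for palindromic (A/T, C/G)
    instruments, which are never auto-flipped; ``strict=True`` turns
    every flip into a :class:`HarmonizationError`. Hard GT calls are
    used unless ``dosage_field=True`` selects the fractional DS field.
    Missing genotypes become NaN; instruments absent from the file are
    listed in the report rather than raising.
    """
    by_pos = {
        (str(r.chrom).removeprefix("chr"), int(r.pos)): r
        for _, r in instruments.df.iterrows()
    }
    by_id = {r.snp_id: r for _, r in instruments.df.iterrows()}

    report = VcfReadReport()
    columns: dict[str, np.ndarray] = {}
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    for rec in vcf:
        inst = by_pos.get((str(rec.chrom).removeprefix("chr"), rec.pos))
        if inst is None and rec.id in by_id:
            inst = by_id[rec.id]
        if inst is None:
            report.ignored_variants += 1
            continue
        if rec.alts is None or len(rec.alts) != 1:
            raise HarmonizationError(
                f"{inst.snp_id}: multi-allelic or ALT-less record not supported"
            )
        ref, alt = rec.ref.upper(), rec.alts[0].upper()
        pair = {ref, alt}
        short, long = inst.short_allele, inst.long_allele
        if pair == {short, long}:
            long_is_alt = alt == long
        elif pair == {_revcomp(short), _revcomp(long)}:
            if strict:
                raise HarmonizationError(
                    f"{inst.snp_id}: alleles {ref}/{alt} are strand-flipped "
                    f"relative to {short}/{long} (strict mode)"
                )
            if _is_palindromic(short, long):
                raise HarmonizationError(
                    f"{inst.snp_id}: palindromic alleles {short}/{long} cannot "
                    "be strand-resolved"
                )
            long_is_alt = alt == _revcomp(long)
            report.flipped.append(inst.snp_id)
        else:
            raise HarmonizationError(
                f"{inst.snp_id}: observed alleles {ref}/{alt} do not match "
                f"instrument alleles {short}/{long} on either strand"
            )
        dosages = np.full(len(samples), np.nan)
        for k, sample in enumerate(samples):
            call = rec.samples[sample]
            if dosage_field:
                ds = call.get("DS")
                if ds is None:
                    continue
                alt_dose = float(ds if np.isscalar(ds) else ds[0])
            else:
                gt = call.get("GT")
                if gt is None or any(g is None for g in gt):
                    continue
                alt_dose = float(sum(gt))
            dosages[k] = alt_dose if long_is_alt else 2.0 - alt_dose
        columns[inst.snp_id] = dosages
        report.matched.append(inst.snp_id)
    vcf.close()

    report.missing_instruments = [
        s for s in instruments.snp_ids if s not in columns
    ]
    if report.missing_instruments:
        logger.warning("instruments absent from VCF: %s", report.missing_instruments)
    if report.ignored_variants:
        logger.info("ignored %d non-instrument variants", report.ignored_variants)
    frame = pd.DataFrame(
        {s: columns[s] for s in instruments.snp_ids if s in columns},
        index=pd.Index(samples, name="subject_id"),
    )
    return DosageMatrix.from_frame(frame), report


def write_vcf(
    dosages: DosageMatrix,
    instruments: InstrumentTable,
    path,
) -> None:
    """Write dosages as a VCF 4.2 with REF = short, ALT = long allele.

    Integer dosages become hard GT calls; any fractional dosage is
    emitted through the DS field with GT set to the rounded call.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Long-allele dosage">'
    )
    for chrom in dict.fromkeys(instruments.df["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    for subject in dosages.subject_ids:
        header.add_sample(subject)

    fractional = bool(
        np.nanmax(np.abs(dosages.df.to_numpy() - np.round(dosages.df.to_numpy())))
        > 0
    ) if dosages.df.size else False

    rows = instruments.df.sort_values(["chrom", "pos"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, inst in rows.iterrows():
            if inst.snp_id not in dosages.df.columns:
                continue
            rec = out.new_record(
                contig=inst.chrom,
                start=inst.pos - 1,  # pysam start is 0-based
                alleles=(inst.short_allele, inst.long_allele),
                id=inst.snp_id,
            )
            col = dosages.df[inst.snp_id]
            for subject in dosages.subject_ids:
                x = col.loc[subject]
                call = rec.samples[subject]
                if np.isnan(x):
                    call["GT"] = (None, None)
                else:
                    hard = int(round(x))
                    call["GT"] = ((0, 0), (0, 1), (1, 1))[hard]
                    if fractional:
                        call["DS"] = float(x)
            out.write(rec)


def impute_missing(
    dosages: DosageMatrix,
    is_control: pd.Series | np.ndarray,
    max_missing: float = 0.10,
) -> DosageMatrix:
    """Mean-impute missing dosages from the control-group mean per SNP.

    SNPs missing in more than ``max_missing`` of subjects are dropped
    with a warning instead of imputed, keeping n constant for the rest.
    """
    df = dosages.df.copy()
    mask = np.asarray(is_control, dtype=bool)
    drop = []
    for snp in df.columns:
        frac = df[snp].isna().mean()
        if frac == 0:
            continue
        if frac > max_missing:
            drop.append(snp)
            continue
        control_mean = df.loc[mask, snp].mean()
        if np.isnan(control_mean):  # no control observed: fall back to overall
            control_mean = df[snp].mean()
        df[snp] = df[snp].fillna(control_mean)
    if drop:
        warnings.warn(
            f"dropping SNP(s) with > {max_missing:.0%} missing genotypes: {drop}",
            stacklevel=2,
        )
        df = df.drop(columns=drop)
    return DosageMatrix.from_frame(df)


def format_or(value: float, decimals: int = 2) -> str:
    return f"{value:.{decimals}f}"


def format_p(p: float) -> str:
    """Fixed 3 decimals down to 1e-3, scientific notation below."""
    if p >= 1e-3:
        return f"{p:.3f}"
    return f"{p:.2e}"


def write_report(tables: dict[str, pd.DataFrame], outdir) -> list[Path]:
    """Write one TSV per analysis stage; returns the written paths.

    Column order is the DataFrame's order, fixed by the pipeline; an
    empty mapping writes nothing and warns.
    """
    if not tables:
        warnings.warn("no result tables to write", stacklevel=2)
        return []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        target = outdir / f"{name}.tsv"
        frame.to_csv(target, sep="\t", index=False)
        written.append(target)
    return written
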