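"""Genetic risk score computation and control-anchored categorization.

The score for subject *i* is ``GRS_i = sum_j w_j x_ij`` over the
instrument SNPs, with ``x_ij`` the long-allele dosage and ``w_j`` the
per-allele exposure weight (``w_j = 1`` for the unweighted score).
Higher scores mean longer genetically inferred telomere length.
Category cutpoints (median / tertile / quartile) are always empirical
quantiles of the *control* score distribution, and the same cutpoints
are reused unchanged in every stratified analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import DosageMatrix, GRSResult, InstrumentTable

__all__ = [
    "SCHEMES",
    "compute_grs",
    "control_cutpoints",
    "assign_categories",
    "score_and_categorize",
]

# quantile probabilities per categorization scheme
SCHEMES: dict[str, tuple[float, ...]] = {
    "median": (0.5,),
    "tertile": (1 / 3, 2 / 3),
    "quartile": (0.25, 0.5, 0.75),
}


def _dosage_frame(dosages: DosageMatrix | pd.DataFrame) -> pd.DataFrame:
    return dosages.df if isinstance(dosages, DosageMatrix) else dosages


def compute_grs(
    dosages: DosageMatrix | pd.DataFrame,
    instruments: InstrumentTable,
    weighted: bool = True,
) -> pd.Series:
    """Per-subject genetic risk score.

    Raises ``KeyError`` naming any instrument SNP absent from the
    dosage matrix, and ``ValueError`` if unimputed missing dosages
    remain (apply the io missingness policy first).
    """
    df = _dosage_frame(dosages)
    missing = [s for s in instruments.snp_ids if s not in df.columns]
    if missing:
        raise KeyError(f"instrument SNP(s) absent from dosage matrix: {missing}")
    x = df.loc[:, instruments.snp_ids]
    if x.isna().any().any():
        raise ValueError("missing dosages present; impute or drop before scoring")
    w = (
        instruments.betas.loc[instruments.snp_ids].to_numpy()
        if weighted
        else np.ones(len(instruments))
    )
    score = x.to_numpy(dtype=float) @ w
    return pd.Series(score, index=df.index, name="grs")


def control_cutpoints(
    grs: pd.Series | np.ndarray,
    is_control: pd.Series | np.ndarray,
    scheme: str,
) -> np.ndarray:
    """Control-only empirical quantile thresholds for a scheme.

    Quantiles use linear interpolation between order statistics (the
    "type 7" definition shared by numpy and mainstream statistical
    environments), so cutpoints are bit-reproducible.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    values = np.asarray(grs, dtype=float)
    mask = np.asarray(is_control, dtype=bool)
    controls = values[mask]
    if controls.size == 0:
        raise ValueError("no controls: cutpoints undefined")
    cuts = np.quantile(controls, SCHEMES[scheme], method="linear")
    if np.unique(controls).size == 1:
        warnings.warn(
            "all control scores identical; degenerate cutpoints place every "
            "subject in category 1",
            stacklevel=2,
        )
    return cuts


def assign_categories(
    grs: pd.Series | np.ndarray,
    cutpoints: np.ndarray,
    ties: str = "lower",
) -> np.ndarray:
    """1-based category index per subject (1 = shortest).

    With the default ``ties="lower"``, intervals are
    ``(cut_{k-1}, cut_k]``: a score exactly at a cutpoint falls in the
    lower ("shorter") category. ``ties="upper"`` uses ``[cut_k, ...)``
    instead, exposing sensitivity to the opposite convention.
    """
    if ties not in ("lower", "upper"):
        raise ValueError("ties must be 'lower' or 'upper'")
    cuts = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(cuts) < 0):
        raise ValueError("cutpoints must be nondecreasing")
    side = "left" if ties == "lower" else "right"
    return np.searchsorted(cuts, np.asarray(grs, dtype=float), side=side) + 1


def score_and_categorize(
    dosages: DosageMatrix | pd.DataFrame,
    instruments: InstrumentTable,
    is_control: pd.Series | np.ndarray,
    schemes: tuple[str, ...] = ("median", "tertile", "quartile"),
    weighted: bool = True,
    ties: str = "lower",
) -> GRSResult:
    """Compute scores and all requested control-anchored categorizations."""
    grs = compute_grs(dosages, instruments, weighted=weighted)
    cutpoints: dict[str, np.ndarray] = {}
    categories: dict[str, pd.Series] = {}
    for scheme in schemes:
        cuts = control_cutpoints(grs, is_control, scheme)
        cutpoints[scheme] = cuts
        categories[scheme] = pd.Series(
            assign_categories(grs, cuts, ties=ties), index=grs.index, name=scheme
        )
    return GRSResult(grs=grs, categories=categories, cutpoints=cutpoints, weighted=weighted)
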