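"""Quality control and normalisation of metabolite concentration tables.

The QC chain applied to a raw samples x metabolites concentration matrix is,
in fixed order:

1. :func:`filter_lod` -- drop metabolites with more than a configurable
   fraction of values below the limit of detection (LOD);
2. :func:`impute_mean` -- replace every remaining missing / below-LOD value
   with the mean of the metabolite's observed values (raw scale);
3. :func:`log_zscore` -- natural-log transform, then Z-score each metabolite
   (sample standard deviation, n-1 denominator);
4. :func:`mask_outliers` -- re-mask cells whose |z| strictly exceeds k
   standard deviations (default 3); masked cells are excluded downstream via
   pairwise-complete correlation handling, not re-imputed.

Outlier exclusion removes individual cells, not whole samples; the choice and
its consequences are documented in the package methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# provenance codes for each cell of a ConcentrationMatrix
OBSERVED = 0
MISSING = 1
BELOW_LOD = 2
OUTLIER = 3

_STAGES = ("raw", "imputed", "normalized")


@dataclass
class ConcentrationMatrix:
    """Samples x metabolites concentration grid with per-cell provenance.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric grid, samples as rows, metabolites as columns.  Cells that
        are unavailable (missing, below LOD, outlier-masked) hold NaN.
    provenance : pandas.DataFrame, optional
        Integer grid of the same shape with codes ``OBSERVED``, ``MISSING``,
        ``BELOW_LOD``, ``OUTLIER``.  Defaults to ``MISSING`` wherever
        ``values`` is NaN and ``OBSERVED`` elsewhere.
    stage : str
        One of ``raw``, ``imputed``, ``normalized``.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        self.values = self.values.astype(float)
        if self.provenance is None:
            prov = np.where(self.values.isna(), MISSING, OBSERVED)
            self.provenance = pd.DataFrame(
                prov, index=self.values.index, columns=self.values.columns, dtype=np.int8
            )
        else:
            self.provenance = self.provenance.astype(np.int8)
        if self.provenance.shape != self.values.shape:
            raise ValueError("values and provenance must have identical shape")
        if not (
            self.provenance.index.equals(self.values.index)
            and self.provenance.columns.equals(self.values.columns)
        ):
            raise ValueError("values and provenance must share index and columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean grid: True where the value is currently unavailable."""
        return self.values.isna()

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.copy(), self.provenance.copy(), self.stage
        )


@dataclass
class QcReport:
    """Bookkeeping record of one or more QC steps."""

    excluded_metabolites: dict[str, float] = field(default_factory=dict)
    imputed_count: int = 0
    outlier_count: int = 0
    retained_metabolites: int = 0

    def merge(self, other: "QcReport") -> "QcReport":
        merged = dict(self.excluded_metabolites)
        merged.update(other.excluded_metabolites)
        return QcReport(
            excluded_metabolites=merged,
            imputed_count=self.imputed_count + other.imputed_count,
            outlier_count=self.outlier_count + other.outlier_count,
            retained_metabolites=other.retained_metabolites or self.retained_metabolites,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def filter_lod(
    matrix: ConcentrationMatrix, max_below_lod_fraction: float = 0.10
) -> tuple[ConcentrationMatrix, QcReport]:
    """Drop metabolites whose below-LOD fraction strictly exceeds the threshold.

    "More than 10%" is read as a strict inequality: a metabolite with exactly
    the threshold fraction below LOD is retained.
    """
    if not 0.0 <= max_below_lod_fraction <= 1.0:
        raise ValueError("max_below_lod_fraction must be in [0, 1]")
    if matrix.stage != "raw":
        raise ValueError("filter_lod expects a raw-stage matrix")
    lod_frac = (matrix.provenance == BELOW_LOD).mean(axis=0)
    excluded = lod_frac[lod_frac > max_below_lod_fraction]
    keep = matrix.metabolite_ids.difference(excluded.index, sort=False)
    if len(keep) == 0:
        raise ValueError("all metabolites exceed the below-LOD threshold")
    out = ConcentrationMatrix(
        matrix.values[keep].copy(), matrix.provenance[keep].copy(), "raw"
    )
    report = QcReport(
        excluded_metabolites={m: float(lod_frac[m]) for m in excluded.index},
        retained_metabolites=len(keep),
    )
    return out, report


def impute_mean(matrix: ConcentrationMatrix) -> tuple[ConcentrationMatrix, QcReport]:
    """Replace missing / below-LOD values with the metabolite's observed mean.

    Imputation happens on the raw concentration scale, before log transform,
    and never alters observed values.
    """
    if matrix.stage != "raw":
        raise ValueError("impute_mean expects a raw-stage matrix")
    values = matrix.values.copy()
    n_observed = values.notna().sum(axis=0)
    empty = n_observed[n_observed == 0]
    if len(empty):
        raise ValueError(
            f"cannot impute metabolites with zero observed values: {list(empty.index)}"
        )
    imputed_count = int(values.isna().to_numpy().sum())
    values = values.fillna(values.mean(axis=0))
    out = ConcentrationMatrix(values, matrix.provenance.copy(), "imputed")
    return out, QcReport(
        imputed_count=imputed_count, retained_metabolites=values.shape[1]
    )


def log_zscore(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Natural-log transform, then Z-score each metabolite column.

    Uses the sample standard deviation (n-1 denominator).  Requires strictly
    positive inputs; a non-positive cell or a zero-variance column raises.
    """
    if matrix.stage != "imputed":
        raise ValueError("log_zscore expects an imputed-stage matrix")
    vals = matrix.values
    bad = vals <= 0
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            "non-positive concentration at sample "
            f"{vals.index[row]!r}, metabolite {vals.columns[col]!r}"
        )
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    zero_sd = sd[(sd == 0) | sd.isna()]
    if len(zero_sd):
        raise ValueError(
            f"zero-variance metabolites cannot be Z-scored: {list(zero_sd.index)}"
        )
    z = (logged - logged.mean(axis=0)) / sd
    return ConcentrationMatrix(z, matrix.provenance.copy(), "normalized")


def mask_outliers(
    matrix: ConcentrationMatrix, k: float = 3.0
) -> tuple[ConcentrationMatrix, QcReport]:
    """Mask cells whose normalized value lies strictly beyond +-k SD.

    A value exactly at |z| = k is retained.  Masking applies per cell and is
    idempotent: re-running on its own output masks nothing new.
    """
    if matrix.stage != "normalized":
        raise ValueError("mask_outliers expects a normalized-stage matrix")
    if k <= 0:
        raise ValueError("k must be positive")
    values = matrix.values.copy()
    prov = matrix.provenance.copy()
    out_mask = values.abs() > k
    outlier_count = int(out_mask.to_numpy().sum())
    values[out_mask] = np.nan
    prov_arr = prov.to_numpy()
    prov_arr[out_mask.to_numpy()] = OUTLIER
    prov = pd.DataFrame(prov_arr, index=prov.index, columns=prov.columns)
    out = ConcentrationMatrix(values, prov, "normalized")
    return out, QcReport(
        outlier_count=outlier_count, retained_metabolites=values.shape[1]
    )


def preprocess(
    matrix: ConcentrationMatrix,
    lod_threshold: float = 0.10,
    outlier_k: float = 3.0,
) -> tuple[ConcentrationMatrix, QcReport]:
    """Run the full QC chain: LOD filter, mean imputation, log/Z-score, outlier mask."""
    filtered, rep1 = filter_lod(matrix, lod_threshold)
    imputed, rep2 = impute_mean(filtered)
    normalized = log_zscore(imputed)
    masked, rep3 = mask_outliers(normalized, outlier_k)
    return masked, rep1.merge(rep2).merge(rep3)
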