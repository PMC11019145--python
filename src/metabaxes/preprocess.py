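"""Metabolite QC, imputation, transforms, and phenotype harmonization.

The metabolite pipeline is: filter on presence and analytic CV, impute
left-censored missing values at half the per-column observed minimum,
then log-transform and standardize within cohort.  Phenotypes are
optionally log-transformed, optionally indexed to height^1.7, sign
oriented so higher always means healthier, and standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEIGHT_EXPONENT = 1.7
PRESENCE_MIN_DEFAULT = 0.90
CV_MAX_DEFAULT = 0.10


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


@dataclass
class MetaboliteMatrix:
    """Participants x metabolites intensity matrix.

    Parameters
    ----------
    values
        Raw non-negative intensities, participants in rows (indexed by
        participant id), metabolites in columns.  Missing values are NaN.
    qc
        Optional pooled-QC replicate rows (same columns as ``values``),
        used to compute the per-metabolite coefficient of variation.
    cv
        Optional externally supplied per-metabolite CV; used for
        metabolites when QC replicates are absent.
    """

    values: pd.DataFrame
    qc: pd.DataFrame | None = None
    cv: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise PreprocessError(f"duplicate metabolite ids: {dups}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise PreprocessError(f"duplicate participant ids: {dups}")
        if (self.values < 0).any().any():
            raise PreprocessError("metabolite intensities must be non-negative")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def presence_fraction(self) -> pd.Series:
        """Fraction of participants with an observed (non-missing) value."""
        return self.values.notna().mean(axis=0)

    def compute_cv(self) -> pd.Series:
        """Per-metabolite CV: SD/mean of raw QC replicate intensities.

        Falls back to the supplied ``cv`` column for metabolites without
        QC data; metabolites with neither get NaN.
        """
        out = pd.Series(np.nan, index=self.values.columns, dtype=float)
        if self.qc is not None and len(self.qc) >= 2:
            mean = self.qc.mean(axis=0)
            sd = self.qc.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = sd / mean
        if self.cv is not None:
            out = out.fillna(self.cv.reindex(self.values.columns))
        return out


@dataclass
class PhenotypeTable:
    """Participants x phenotypes table plus per-phenotype metadata.

    ``meta`` has one row per phenotype with columns ``domain``,
    ``adverse`` (True when a higher raw value is less healthy),
    ``transform`` (``none`` or ``log``), and ``index_to_height``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise PreprocessError(f"phenotypes without metadata: {sorted(missing)}")
        for col in ("domain", "adverse", "transform", "index_to_height"):
            if col not in self.meta.columns:
                raise PreprocessError(f"phenotype metadata missing column {col!r}")
        if self.meta["domain"].isna().any():
            bad = self.meta.index[self.meta["domain"].isna()].tolist()
            raise PreprocessError(f"phenotypes without a domain: {bad}")

    @property
    def domain_map(self) -> dict[str, str]:
        return self.meta["domain"].to_dict()


@dataclass
class StandardizationStats:
    """Frozen column means/SDs so a standardization can be replayed."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, log_values: pd.DataFrame) -> pd.DataFrame:
        aligned = log_values[self.mean.index]
        return (aligned - self.mean) / self.sd


@dataclass
class QCReport:
    """Exclusion report from :func:`qc_filter`."""

    kept: list[str]
    excluded: pd.DataFrame = field(repr=False)

    @property
    def n_in(self) -> int:
        return len(self.kept) + len(self.excluded)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def qc_filter(
    matrix: MetaboliteMatrix,
    presence_min: float = PRESENCE_MIN_DEFAULT,
    cv_max: float = CV_MAX_DEFAULT,
) -> tuple[MetaboliteMatrix, QCReport]:
    """Keep metabolites observed in >= ``presence_min`` of participants with CV <= ``cv_max``.

    Metabolites with no computable CV are excluded with reason
    ``cv_unavailable`` (logged, not fatal).  Returns the restricted
    matrix and an exclusion report listing each failing criterion.
    """
    presence = matrix.presence_fraction
    cv = matrix.compute_cv()
    records = []
    kept = []
    for met in matrix.values.columns:
        reasons = []
        if presence[met] < presence_min:
            reasons.append("presence")
        if np.isnan(cv[met]):
            reasons.append("cv_unavailable")
        elif cv[met] > cv_max:
            reasons.append("cv")
        if reasons:
            records.append(
                {
                    "metabolite_id": met,
                    "reason": "+".join(reasons),
                    "presence_fraction": presence[met],
                    "cv": cv[met],
                }
            )
        else:
            kept.append(met)
    excluded = pd.DataFrame(
        records, columns=["metabolite_id", "reason", "presence_fraction", "cv"]
    )
    out = MetaboliteMatrix(
        values=matrix.values[kept].copy(),
        qc=matrix.qc[kept].copy() if matrix.qc is not None else None,
        cv=cv[kept],
    )
    return out, QCReport(kept=kept, excluded=excluded)


def impute_half_min(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace each missing cell with half the column's observed minimum.

    Imputation is strictly within the given matrix (one cohort); never
    pool cohorts before calling this.
    """
    values = matrix.values
    all_missing = values.isna().all(axis=0)
    if all_missing.any():
        bad = values.columns[all_missing].tolist()
        raise PreprocessError(f"all-missing metabolite columns: {bad}")
    col_min = values.min(axis=0, skipna=True)
    filled = values.fillna(0.5 * col_min)
    return MetaboliteMatrix(values=filled, qc=matrix.qc, cv=matrix.cv)


def log_standardize(
    matrix: MetaboliteMatrix,
) -> tuple[pd.DataFrame, StandardizationStats]:
    """Log-transform, mean-center, and standardize each metabolite column.

    All values must be strictly positive (run imputation first).  SD uses
    the n-1 convention.  Returns the standardized matrix plus the column
    means/SDs of the log values so the transform can be replayed.
    """
    values = matrix.values
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise PreprocessError(f"missing values remain in: {bad}")
    if (values <= 0).any().any():
        bad = values.columns[(values <= 0).any()].tolist()
        raise PreprocessError(f"non-positive values in: {bad}")
    logged = np.log(values)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    zero_var = sd <= 0
    if zero_var.any():
        bad = values.columns[zero_var].tolist()
        raise PreprocessError(f"zero-variance metabolite columns after log: {bad}")
    stats = StandardizationStats(mean=mean, sd=sd)
    return stats.apply(logged), stats


def harmonize_phenotypes(
    table: PhenotypeTable,
    heights: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize raw phenotypes to mean-0, SD-1, healthier-is-higher columns.

    Pipeline order per phenotype: optional log transform, optional
    division by height^1.7, negation of adverse-high phenotypes, then
    center/standardize (SD with n-1).  ``heights`` (meters, indexed by
    participant) is required when any phenotype is flagged
    ``index_to_height``.

    Returns the harmonized values and the phenotype metadata with the
    applied sign recorded in a ``sign`` column.
    """
    values = table.values.copy().astype(float)
    meta = table.meta.copy()
    needs_height = meta.loc[values.columns, "index_to_height"].astype(bool)
    if needs_height.any():
        if heights is None:
            raise PreprocessError("heights required for height-indexed phenotypes")
        heights = heights.reindex(values.index)
        if heights.isna().any():
            bad = values.index[heights.isna()].tolist()
            raise PreprocessError(f"missing height for participants: {bad[:5]}")
        denom = heights.astype(float) ** HEIGHT_EXPONENT

    signs = {}
    for phen in values.columns:
        col = values[phen]
        if meta.loc[phen, "transform"] == "log":
            if (col.dropna() <= 0).any():
                raise PreprocessError(f"non-positive values in log phenotype {phen!r}")
            col = np.log(col)
        if meta.loc[phen, "index_to_height"]:
            col = col / denom
        sign = -1.0 if meta.loc[phen, "adverse"] else 1.0
        col = sign * col
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise PreprocessError(f"zero-variance phenotype {phen!r}")
        values[phen] = (col - col.mean()) / sd
        signs[phen] = sign

    meta["sign"] = pd.Series(signs)
    return values, meta


def standardize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean-0 / SD-1 (n-1) each column; errors on zero variance."""
    sd = frame.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = frame.columns[sd <= 0].tolist()
        raise PreprocessError(f"zero-variance columns: {bad}")
    return (frame - frame.mean(axis=0)) / sd


def audit_summary(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Per-metabolite presence fraction and CV, for audit logs."""
    return pd.DataFrame(
        {
            "presence_fraction": matrix.presence_fraction,
            "cv": matrix.compute_cv(),
        }
    )
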