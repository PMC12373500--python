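"""Metabolomics preprocessing: detection filter, total-signal normalization,
log10 transform and minimum-based imputation.

Order of operations: metabolites missing in more than ``max_missing_fraction``
of samples are dropped; a per-sample normalization factor is built from
fully observed metabolites with median log10 intensity inside a reference
window (median of per-metabolite intensity ratios, sample-wise); intensities
are divided by the factor and log10-transformed; remaining missing cells are
imputed with the metabolite's minimum observed normalized value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ValidationError
from .io import IntensityTable

DEFAULT_MAX_MISSING_FRACTION = 0.9
DEFAULT_REF_LOG10_LOW = 5.0
DEFAULT_REF_LOG10_HIGH = 10.0


@dataclass
class FilterResult:
    table: IntensityTable
    dropped: list[str]


def filter_by_detection(
    table: IntensityTable,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> FilterResult:
    """Drop metabolites whose missing fraction exceeds the threshold.

    The default (0.9) reads the exclusion rule as "missing in more than 90%
    of samples"; the alternative reading ("detected in less than 90%", i.e.
    missing in more than 10%) is reachable by passing 0.1.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValidationError("max_missing_fraction must be in [0, 1]")
    missing = table.missing_fraction()
    keep = missing <= max_missing_fraction
    dropped = sorted(missing.index[~keep])
    if not keep.any():
        raise EmptyResultError(
            "all metabolites dropped by the detection filter; raise "
            "max_missing_fraction"
        )
    return FilterResult(IntensityTable(table.values.loc[keep]), dropped)


@dataclass
class NormalizationFactors:
    """Per-sample factors plus the reference metabolites that built them."""

    factors: pd.Series
    reference_metabolites: list[str]


def compute_normalization_factors(
    table: IntensityTable,
    log10_low: float = DEFAULT_REF_LOG10_LOW,
    log10_high: float = DEFAULT_REF_LOG10_HIGH,
) -> NormalizationFactors:
    """Median-of-ratios total-signal factor per sample.

    Reference metabolites are those detected in every sample whose median
    log10 raw intensity lies in ``[log10_low, log10_high]``. For each
    reference metabolite the per-sample ratio to its own median intensity is
    taken; the factor of a sample is the median of these ratios.
    """
    values = table.values
    fully_observed = values.notna().all(axis=1)
    with np.errstate(divide="ignore"):
        med_log10 = np.log10(values.median(axis=1))
    in_window = (med_log10 >= log10_low) & (med_log10 <= log10_high)
    reference = values.index[fully_observed & in_window]
    if len(reference) == 0:
        raise EmptyResultError(
            "no fully observed metabolite has median log10 intensity in "
            f"[{log10_low}, {log10_high}]; widen the bounds"
        )
    ref_values = values.loc[reference]
    ratios = ref_values.div(ref_values.median(axis=1), axis=0)
    factors = ratios.median(axis=0)
    if (factors <= 0).any():
        bad = sorted(factors.index[factors <= 0])
        raise ValidationError(f"non-positive normalization factors for {bad}")
    return NormalizationFactors(factors=factors, reference_metabolites=list(reference))


@dataclass
class NormalizedTable:
    """Log10 normalized intensities with the imputation bookkeeping."""

    values: pd.DataFrame  # metabolites x samples, no missing entries
    normalization_factors: pd.Series
    imputation_mask: pd.DataFrame
    reference_metabolites: list[str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("normalized table must have no missing values")
        if (self.normalization_factors <= 0).any():
            raise ValidationError("normalization factors must be positive")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_log_impute(
    table: IntensityTable, factors: NormalizationFactors | pd.Series
) -> NormalizedTable:
    """Scale by per-sample factors, log10-transform, impute missing to row min."""
    if isinstance(factors, NormalizationFactors):
        reference = factors.reference_metabolites
        factors = factors.factors
    else:
        reference = []
    factors = factors.reindex(table.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValidationError("need one positive factor per sample")
    values = table.values
    zero = values == 0
    if zero.any().any():
        m = values.index[zero.any(axis=1)][0]
        s = values.columns[zero.loc[m]][0]
        raise ValidationError(
            f"zero intensity at metabolite {m!r}, sample {s!r}: log10 undefined"
        )
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        bad = sorted(values.index[all_missing])
        raise ValidationError(
            f"metabolites with no observed values (filter first): {bad}"
        )
    logged = np.log10(values.div(factors, axis=1))
    mask = logged.isna()
    imputed = logged.apply(lambda row: row.fillna(row.min()), axis=1)
    return NormalizedTable(
        values=imputed,
        normalization_factors=factors,
        imputation_mask=mask,
        reference_metabolites=list(reference),
    )


def preprocess(
    table: IntensityTable,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    log10_low: float = DEFAULT_REF_LOG10_LOW,
    log10_high: float = DEFAULT_REF_LOG10_HIGH,
) -> tuple[NormalizedTable, list[str]]:
    """Full pipeline: filter -> factors -> normalize/log/impute.

    Returns the normalized table and the dropped metabolite ids.
    """
    filtered = filter_by_detection(table, max_missing_fraction)
    factors = compute_normalization_factors(filtered.table, log10_low, log10_high)
    return normalize_log_impute(filtered.table, factors), filtered.dropped
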