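"""Per-metabolite fidelity and stability across serial passaging.

Fidelity: how much of a metabolite's variance across PDXs is explained by
the tumour of origin, and how well patient (P0) levels predict late-passage
(P6) levels. Stability: per-line drift of the metabolite with passage
number. Metabolites with origin-explained variance above 30% and a P0-P6
Pearson correlation above 0.3 are classified as characteristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import (
    VarianceFractions,
    _annotation_frame,
    _values,
    fit_multivariate,
    partition_variance,
)
from .errors import ValidationError

DEFAULT_VAR_THRESHOLD = 0.30
DEFAULT_R_THRESHOLD = 0.3


@dataclass
class PassageTrends:
    """Per-line OLS slopes (log10 per passage) and the pooled passage effect."""

    slopes: pd.DataFrame  # metabolites x lines
    pooled: pd.Series  # pooled passage coefficient per metabolite
    excluded_lines: list[str]


def passage_trends(norm, ann) -> PassageTrends:
    """Regress each metabolite on passage number within each PDX line.

    Lines (origins) with fewer than two distinct passages are excluded with
    a warning. The pooled effect is the passage coefficient from the joint
    passage + origin model.
    """
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    pdx = ann_df[ann_df["host"] == "mouse"]
    if pdx.empty:
        raise ValidationError("no PDX samples")
    slopes = {}
    excluded = []
    for origin, sub in pdx.groupby("origin"):
        passages = sub["passage"].to_numpy(dtype=float)
        if np.unique(passages).size < 2:
            excluded.append(str(origin))
            continue
        y = values[sub.index].to_numpy()
        x = passages - passages.mean()
        denom = float(x @ x)
        slopes[str(origin)] = (y - y.mean(axis=1, keepdims=True)) @ x / denom
    if excluded:
        warnings.warn(
            f"lines with a single distinct passage excluded: {sorted(excluded)}"
        )
    if not slopes:
        raise ValidationError("no line has >= 2 distinct passages")
    pdx_values = values[pdx.index]
    pooled_factors = ["passage"]
    if pdx["origin"].astype(str).nunique() > 1:
        pooled_factors.append("origin")
    pooled_fit = fit_multivariate(pdx_values, ann_df.loc[pdx.index], pooled_factors)
    pooled = (
        pooled_fit.table[pooled_fit.table["factor"] == "passage"]
        .set_index("metabolite")["effect_log10"]
        .reindex(values.index)
    )
    return PassageTrends(
        slopes=pd.DataFrame(slopes, index=values.index),
        pooled=pooled,
        excluded_lines=sorted(excluded),
    )


def p0_p6_correlation(
    norm, ann, p6_mode: str = "mean", last_passage: int = 6
) -> pd.DataFrame:
    """Pearson correlation between patient (P0) and late-passage levels.

    Per metabolite, correlates the P0 value of each origin with its
    late-passage value across origins. ``p6_mode="mean"`` averages late-
    passage replicates within origin first; ``"pooled"`` pairs every
    late-passage sample with its origin's P0 value. Returns a DataFrame
    with columns ``r`` and ``p`` (two-sided, via the t transform).
    """
    if p6_mode not in ("mean", "pooled"):
        raise ValidationError(f"unknown p6_mode {p6_mode!r}")
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    p0 = ann_df[ann_df["passage"] == 0]
    p6 = ann_df[ann_df["passage"] == last_passage]
    pairs_x, pairs_y = [], []
    n_origins = 0
    for origin, sub0 in p0.groupby("origin"):
        sub6 = p6[p6["origin"] == origin]
        if sub6.empty:
            continue
        n_origins += 1
        x = values[sub0.index].mean(axis=1)
        if p6_mode == "mean":
            pairs_x.append(x)
            pairs_y.append(values[sub6.index].mean(axis=1))
        else:
            for sample in sub6.index:
                pairs_x.append(x)
                pairs_y.append(values[sample])
    if n_origins < 3:
        raise ValidationError(
            f"need >= 3 origins with both P0 and P{last_passage} samples, "
            f"got {n_origins}"
        )
    X = pd.concat(pairs_x, axis=1).to_numpy()
    Y = pd.concat(pairs_y, axis=1).to_numpy()
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc * Yc).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return pd.DataFrame({"r": r, "p": p}, index=values.index)


@dataclass
class FidelityRecords:
    """Per-metabolite fidelity/stability table with the characteristic flag."""

    table: pd.DataFrame
    var_threshold: float
    r_threshold: float

    @property
    def characteristic_ids(self) -> list[str]:
        return sorted(self.table.index[self.table["characteristic"]])

    @property
    def n_characteristic(self) -> int:
        return int(self.table["characteristic"].sum())


def classify_characteristic(
    fractions: VarianceFractions,
    correlations: pd.DataFrame,
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    origin_factor: str = "origin",
) -> FidelityRecords:
    """Characteristic = origin variance fraction AND P0-P6 r strictly above
    their thresholds."""
    frac = fractions.table
    mismatch = set(frac.index) ^ set(correlations.index)
    if mismatch:
        raise ValidationError(
            f"metabolite universes differ between inputs: {sorted(mismatch)}"
        )
    correlations = correlations.reindex(frac.index)
    table = pd.DataFrame(
        {
            "origin_variance_fraction": frac[origin_factor],
            "passage_variance_fraction": frac.get(
                "passage", pd.Series(np.nan, index=frac.index)
            ),
            "p0_p6_pearson_r": correlations["r"],
            "p0_p6_p_value": correlations["p"],
        },
        index=frac.index,
    )
    table["characteristic"] = (
        (table["origin_variance_fraction"] > var_threshold)
        & (table["p0_p6_pearson_r"] > r_threshold)
    ).fillna(False)
    return FidelityRecords(
        table=table, var_threshold=var_threshold, r_threshold=r_threshold
    )


def fidelity_records(
    norm,
    ann,
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p6_mode: str = "mean",
    last_passage: int = 6,
) -> FidelityRecords:
    """Convenience pipeline: variance partition (PDX samples, passage +
    origin) plus P0-P6 correlation, then characteristic classification."""
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    pdx = ann_df[ann_df["host"] == "mouse"]
    fractions = partition_variance(
        values[pdx.index], ann_df.loc[pdx.index], ["passage", "origin"]
    )
    correlations = p0_p6_correlation(
        values, ann_df, p6_mode=p6_mode, last_passage=last_passage
    )
    return classify_characteristic(
        fractions, correlations, var_threshold, r_threshold
    )
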