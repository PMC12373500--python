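"""Metabolic fingerprint matching.

PDX samples are assigned to patient tumours by minimal Euclidean distance of
z-transformed metabolite profiles. The total distance between PDX profile x
and patient profile y over the selected metabolites is

    D_total = sqrt(sum_k (x_k - y_k)^2)

and decomposes into per-metabolite squared contributions d_k = (x_k - y_k)^2.
For each matched pair, Delta d_k = d_k(match) - mean d_k(non-match) measures
whether metabolite k pulls the matched pair together (negative) or apart
(positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .differential import _annotation_frame, _values
from .errors import ValidationError


def zscore_metabolites(
    norm,
    sample_subset: Sequence[str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Standardize each metabolite to mean 0, SD 1 across the given samples.

    Uses the sample SD (``ddof=1``) by default; the population convention is
    available via ``ddof=0``. Mean and SD are computed on — and applied to —
    the ``sample_subset`` (all samples when omitted), pooling patients and
    PDXs.
    """
    values = _values(norm)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in values.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        values = values[list(sample_subset)]
    sd = values.std(axis=1, ddof=ddof)
    if (sd == 0).any() or sd.isna().any():
        bad = sorted(values.index[(sd == 0) | sd.isna()])
        raise ValidationError(f"zero-SD metabolites cannot be z-scored: {bad}")
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class DistanceMatrix:
    """PDX (rows) x patient (columns) Euclidean distances."""

    values: pd.DataFrame
    metabolite_subset: list[str]

    @property
    def pdx_sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_sample_ids(self) -> list[str]:
        return list(self.values.columns)


def pairwise_distances(
    zscored: pd.DataFrame,
    pdx_ids: Sequence[str],
    patient_ids: Sequence[str],
    metabolite_subset: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Euclidean distance between every PDX and patient profile."""
    overlap = set(pdx_ids) & set(patient_ids)
    if overlap:
        raise ValidationError(f"ids in both PDX and patient sets: {sorted(overlap)}")
    if metabolite_subset is None:
        metabolite_subset = list(zscored.index)
    else:
        metabolite_subset = list(metabolite_subset)
        missing = [m for m in metabolite_subset if m not in zscored.index]
        if missing:
            raise ValidationError(f"metabolites not in table: {missing}")
    if not metabolite_subset:
        raise ValidationError("metabolite subset is empty")
    sub = zscored.loc[metabolite_subset]
    pdx = sub[list(pdx_ids)].to_numpy().T
    patients = sub[list(patient_ids)].to_numpy().T
    dist = cdist(pdx, patients, metric="euclidean")
    return DistanceMatrix(
        values=pd.DataFrame(dist, index=list(pdx_ids), columns=list(patient_ids)),
        metabolite_subset=metabolite_subset,
    )


@dataclass
class MatchResult:
    """Per-PDX origin assignment by minimal distance."""

    assignments: pd.DataFrame  # assigned_patient, assigned_origin, true_origin,
    # distance, correct, tie
    confusion: pd.DataFrame  # true origin x assigned origin counts

    @property
    def n_correct(self) -> int:
        return int(self.assignments["correct"].sum())

    @property
    def n_total(self) -> int:
        return len(self.assignments)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def match_pdx_to_patient(dist: DistanceMatrix, ann) -> MatchResult:
    """Assign each PDX to the origin of its nearest patient tumour.

    A PDX is correctly matched when the assigned origin equals its true
    origin. Ties on the minimal distance are broken by lexicographic patient
    id and flagged.
    """
    if dist.values.empty:
        raise ValidationError("empty distance matrix")
    ann_df = _annotation_frame(ann)
    for sample in [*dist.pdx_sample_ids, *dist.patient_sample_ids]:
        if sample not in ann_df.index:
            raise ValidationError(f"sample {sample!r} missing from annotation")
    patient_origin = ann_df.loc[dist.patient_sample_ids, "origin"]
    pdx_origin = ann_df.loc[dist.pdx_sample_ids, "origin"]
    missing = sorted(set(pdx_origin) - set(patient_origin))
    if missing:
        raise ValidationError(
            f"PDX origins without any patient tumour column: {missing}"
        )
    ordered = dist.values[sorted(dist.values.columns)]
    rows = []
    for pdx_id, row in ordered.iterrows():
        best = row.idxmin()  # first (lexicographically smallest) minimizer
        tie = bool((row == row[best]).sum() > 1)
        assigned_origin = patient_origin[best]
        rows.append(
            {
                "pdx_id": pdx_id,
                "assigned_patient": best,
                "assigned_origin": assigned_origin,
                "true_origin": pdx_origin[pdx_id],
                "distance": float(row[best]),
                "correct": bool(assigned_origin == pdx_origin[pdx_id]),
                "tie": tie,
            }
        )
    assignments = pd.DataFrame(rows).set_index("pdx_id")
    confusion = (
        assignments.groupby(["true_origin", "assigned_origin"])
        .size()
        .unstack(fill_value=0)
    )
    return MatchResult(assignments=assignments, confusion=confusion)


@dataclass
class DistanceDecomposition:
    """Per-metabolite squared-distance contributions for matched pairs.

    ``per_metabolite`` is long-form: pdx_id, metabolite, d_match,
    d_nonmatch_mean, delta_d. ``per_pair`` summarizes, per PDX, the count and
    fraction of metabolites with delta_d < 0 (delta_d = 0 counts as
    non-negative).
    """

    per_metabolite: pd.DataFrame
    per_pair: pd.DataFrame

    @property
    def mean_negative_fraction(self) -> float:
        return float(self.per_pair["frac_negative"].mean())


def decompose_distance(
    zscored: pd.DataFrame,
    ann,
    pdx_ids: Sequence[str],
    patient_ids: Sequence[str],
    metabolite_subset: Sequence[str] | None = None,
) -> DistanceDecomposition:
    """Split each matched pair's squared distance into per-metabolite terms.

    The matched pair of a PDX is the patient tumour of its true origin (the
    nearest one when an origin contributed several); non-matched pairs are
    all patient tumours of other origins.
    """
    ann_df = _annotation_frame(ann)
    if metabolite_subset is None:
        metabolite_subset = list(zscored.index)
    metabolite_subset = list(metabolite_subset)
    sub = zscored.loc[metabolite_subset]
    patient_ids = list(patient_ids)
    patient_origin = ann_df.loc[patient_ids, "origin"]
    if patient_origin.nunique() < 2:
        raise ValidationError(
            "need patient tumours from >= 2 origins for non-matched pairs"
        )
    patients = sub[patient_ids].to_numpy()  # k x n_patients
    met_rows, pair_rows = [], []
    for pdx_id in pdx_ids:
        x = sub[pdx_id].to_numpy()
        true_origin = ann_df.loc[pdx_id, "origin"]
        same = np.asarray(patient_origin == true_origin)
        if not same.any():
            raise ValidationError(
                f"PDX {pdx_id!r}: no patient tumour of origin {true_origin!r}"
            )
        sq = (patients - x[:, None]) ** 2  # k x n_patients
        same_idx = np.flatnonzero(same)
        if same_idx.size > 1:  # nearest same-origin patient is the match
            match_col = same_idx[np.argmin(sq[:, same_idx].sum(axis=0))]
        else:
            match_col = same_idx[0]
        d_match = sq[:, match_col]
        d_non = sq[:, ~same].mean(axis=1)
        delta = d_match - d_non
        n_negative = int((delta < 0).sum())
        met_rows.append(
            pd.DataFrame(
                {
                    "pdx_id": pdx_id,
                    "metabolite": metabolite_subset,
                    "d_match": d_match,
                    "d_nonmatch_mean": d_non,
                    "delta_d": delta,
                }
            )
        )
        pair_rows.append(
            {
                "pdx_id": pdx_id,
                "matched_patient": patient_ids[match_col],
                "true_origin": true_origin,
                "n_negative": n_negative,
                "n_metabolites": len(metabolite_subset),
                "frac_negative": n_negative / len(metabolite_subset),
                "d_total_squared": float(d_match.sum()),
            }
        )
    return DistanceDecomposition(
        per_metabolite=pd.concat(met_rows, ignore_index=True),
        per_pair=pd.DataFrame(pair_rows).set_index("pdx_id"),
    )


@dataclass
class WithinBetweenDistances:
    """Human-PDX distances split by shared vs different origin."""

    same_origin: pd.DataFrame  # human_id, pdx_id, distance
    different_origin: pd.DataFrame

    @property
    def n_same(self) -> int:
        return len(self.same_origin)

    @property
    def n_different(self) -> int:
        return len(self.different_origin)


def within_vs_between_distances(zscored: pd.DataFrame, ann) -> WithinBetweenDistances:
    """All human-to-PDX distances grouped by whether origins coincide."""
    ann_df = _annotation_frame(ann)
    samples = [s for s in zscored.columns if s in ann_df.index]
    human = [s for s in samples if ann_df.loc[s, "host"] == "human"]
    pdx = [s for s in samples if ann_df.loc[s, "host"] == "mouse"]
    if ann_df.loc[samples, "origin"].nunique() < 2:
        raise ValidationError("need >= 2 origins")
    if not human or not pdx:
        raise ValidationError("need both human and PDX samples")
    dist = cdist(zscored[human].to_numpy().T, zscored[pdx].to_numpy().T)
    rows_same, rows_diff = [], []
    for i, h in enumerate(human):
        for j, p in enumerate(pdx):
            record = {"human_id": h, "pdx_id": p, "distance": float(dist[i, j])}
            if ann_df.loc[h, "origin"] == ann_df.loc[p, "origin"]:
                rows_same.append(record)
            else:
                rows_diff.append(record)
    if not rows_same:
        raise ValidationError("no same-origin human-PDX pair")
    return WithinBetweenDistances(
        same_origin=pd.DataFrame(rows_same),
        different_origin=pd.DataFrame(rows_diff),
    )
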