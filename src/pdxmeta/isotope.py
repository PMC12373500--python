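"""13C isotope-tracing computations.

Natural-abundance correction of mass isotopomer distributions (MIDs),
total labelling, enrichment normalization to glucose M+6 and the
citrate M+2 / pyruvate M+3 (PDH surrogate) ratio.

A MID is a vector of fractional abundances ``M+0 .. M+n`` where ``n`` is the
number of tracer carbons of the measured fragment. Measured MIDs are
contaminated by naturally occurring heavy isotopes of every atom in the
ionized fragment (including silicon from silylation reagents); correction
deconvolves that contribution, leaving tracer-derived labelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .errors import ConfigError, ValidationError

#: Default natural isotope abundances by mass shift relative to the lightest
#: isotope. Editable: pass a custom mapping to FragmentComposition.
NATURAL_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (1.0 - 0.0107, 0.0107),
    "H": (1.0 - 0.000115, 0.000115),
    "N": (1.0 - 0.00364, 0.00364),
    "O": (1.0 - 0.00038 - 0.00205, 0.00038, 0.00205),
    "Si": (1.0 - 0.04685 - 0.03092, 0.04685, 0.03092),
    "S": (1.0 - 0.0075 - 0.0425, 0.0075, 0.0425),
}

_MID_SUM_TOL = 1e-6
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def validate_mid(mid: np.ndarray, tol: float = _MID_SUM_TOL) -> np.ndarray:
    """Check MID invariants (entries >= 0, sum 1) and return as float array."""
    arr = np.asarray(mid, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValidationError("MID must be a nonempty 1-D vector")
    if np.any(arr < -tol):
        raise ValidationError("MID entries must be nonnegative")
    if abs(arr.sum() - 1.0) > tol:
        raise ValidationError(f"MID must sum to 1, got {arr.sum():.6g}")
    return np.clip(arr, 0.0, None)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C9H20NO3Si2`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element = match.group(1)
        count = int(match.group(2) or 1)
        counts[element] = counts.get(element, 0) + count
    if pos != len(formula) or not counts:
        raise ValidationError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class FragmentComposition:
    """Elemental composition of a measured ion and its tracer carbon count."""

    element_counts: dict[str, int]
    n_tracer_carbons: int
    abundances: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(NATURAL_ABUNDANCES)
    )

    def __post_init__(self) -> None:
        for element, count in self.element_counts.items():
            if count < 0:
                raise ValidationError(f"negative atom count for {element}")
            if count > 0 and element not in self.abundances:
                raise ValidationError(
                    f"no natural-abundance entry for element {element!r}"
                )
        for element, vec in self.abundances.items():
            arr = np.asarray(vec, dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > _MID_SUM_TOL:
                raise ValidationError(
                    f"abundance vector for {element!r} must be nonnegative "
                    f"and sum to 1 (sum={arr.sum():.6g})"
                )
        n_carbon = self.element_counts.get("C", 0)
        if self.n_tracer_carbons > n_carbon:
            raise ValidationError(
                f"n_tracer_carbons ({self.n_tracer_carbons}) exceeds carbon "
                f"count ({n_carbon})"
            )
        if self.n_tracer_carbons < 0:
            raise ValidationError("n_tracer_carbons must be >= 0")

    @classmethod
    def from_formula(
        cls,
        formula: str,
        n_tracer_carbons: int,
        abundances: Mapping[str, tuple[float, ...]] | None = None,
    ) -> "FragmentComposition":
        return cls(
            parse_formula(formula),
            n_tracer_carbons,
            dict(abundances) if abundances is not None else dict(NATURAL_ABUNDANCES),
        )


def _poly_power(dist: np.ndarray, count: int) -> np.ndarray:
    """Distribution of the summed mass shift of ``count`` iid atoms."""
    out = np.array([1.0])
    for _ in range(count):
        out = np.convolve(out, dist)
    return out


def build_correction_matrix(
    comp: FragmentComposition,
    tracer_purity: float = 1.0,
    truncate: bool = True,
) -> np.ndarray:
    """Mass-shift convolution matrix for natural-abundance correction.

    Column ``j`` is the probability distribution of the observed mass shift
    (relative to the fully monoisotopic fragment) for a molecule carrying
    exactly ``j`` tracer-labelled carbons: the convolution of the natural
    isotope patterns of every atom outside the ``j`` labelled positions, with
    an optional binomial tracer-purity pattern over the labelled positions.
    With ``truncate`` the matrix is cut to ``(n+1) x (n+1)``; at purity 1 it
    is lower triangular with positive diagonal.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise ValidationError("tracer_purity must be in (0, 1]")
    n = comp.n_tracer_carbons
    size = n + 1
    columns = []
    for j in range(size):
        dist = np.array([1.0])
        for element, count in comp.element_counts.items():
            natural_count = count - j if element == "C" else count
            abund = np.asarray(comp.abundances[element], dtype=float)
            dist = np.convolve(dist, _poly_power(abund, natural_count))
        if tracer_purity < 1.0:
            purity = np.array([1.0 - tracer_purity, tracer_purity])
            dist = np.convolve(dist, _poly_power(purity, j))
        else:
            dist = np.concatenate([np.zeros(j), dist])
        if truncate:
            full = np.zeros(size)
            take = min(size, dist.size)
            full[:take] = dist[:take]
            dist = full
        columns.append(dist)
    width = max(col.size for col in columns)
    matrix = np.zeros((width, size))
    for j, col in enumerate(columns):
        matrix[: col.size, j] = col
    return matrix


@dataclass
class CorrectionResult:
    """Natural-abundance-corrected MID with the fit residual norm."""

    mid: np.ndarray
    residual: float


def correct_mid(
    measured: np.ndarray,
    comp: FragmentComposition,
    method: str = "nnls",
    tracer_purity: float = 1.0,
) -> CorrectionResult:
    """Solve ``CorrectionMatrix @ x = measured`` for the tracer-only MID.

    ``method="nnls"`` (default) fits nonnegative least squares and tolerates
    measurement noise; ``method="exact"`` uses the triangular solve (purity
    must be 1) and then clips negatives. The result is renormalized to sum 1.
    """
    measured = np.asarray(measured, dtype=float)
    n = comp.n_tracer_carbons
    if measured.shape != (n + 1,):
        raise ValidationError(
            f"measured MID must have length {n + 1}, got {measured.size}"
        )
    matrix = build_correction_matrix(comp, tracer_purity=tracer_purity)
    cond = np.linalg.cond(matrix)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            f"correction matrix is ill-conditioned (cond={cond:.3g})"
        )
    if method == "exact":
        if tracer_purity < 1.0:
            raise ConfigError("exact triangular solve requires tracer_purity=1")
        x = solve_triangular(matrix, measured, lower=True)
    elif method == "nnls":
        x, _ = nnls(matrix, measured)
    else:
        raise ConfigError(f"unknown correction method {method!r}")
    residual = float(np.linalg.norm(matrix @ np.clip(x, 0.0, None) - measured))
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValidationError("corrected MID sums to zero")
    return CorrectionResult(mid=x / total, residual=residual)


def total_labelling(mid: np.ndarray) -> float:
    """Fraction of molecules carrying at least one tracer carbon: 1 - M+0."""
    mid = validate_mid(mid)
    return float(1.0 - mid[0])


#: Isotopologue (metabolite -> mass shift) used for tumour-enrichment
#: normalization of glycolytic and TCA-cycle intermediates.
TUMOUR_ISOTOPOLOGUES: dict[str, int] = {
    "3-phosphoglycerate": 3,
    "pyruvate": 3,
    "lactate": 3,
    "alanine": 3,
    "citrate": 2,
    "glutamate": 2,
    "succinate": 2,
    "fumarate": 2,
    "malate": 2,
    "aspartate": 2,
}


@dataclass
class LabellingSummary:
    """Per-sample labelling metrics derived from corrected MIDs."""

    total_labelling: dict[str, float]
    plasma_normalized_total: dict[str, float] | None
    tumour_normalized_fractions: dict[str, float] | None
    cit_m2_pyr_m3_ratio: float | None


def normalize_enrichment(
    mids: Mapping[str, np.ndarray],
    plasma_glucose_m6: float | None = None,
    tumour_glucose_m6: float | None = None,
    isotopologues: Mapping[str, int] = TUMOUR_ISOTOPOLOGUES,
) -> LabellingSummary:
    """Summarize labelling for one sample's corrected MIDs.

    Plasma mode (``plasma_glucose_m6``) divides each metabolite's total
    labelling by the plasma glucose M+6 enrichment; tumour mode
    (``tumour_glucose_m6``) divides the designated isotopologue fraction of
    each listed intermediate by the same-sample tumour glucose M+6.
    """
    for name, value in (
        ("plasma_glucose_m6", plasma_glucose_m6),
        ("tumour_glucose_m6", tumour_glucose_m6),
    ):
        if value is not None and value <= 0:
            raise ValidationError(f"{name} must be > 0, got {value}")
    mids = {name: validate_mid(mid) for name, mid in mids.items()}
    totals = {name: total_labelling(mid) for name, mid in mids.items()}
    plasma_norm = None
    if plasma_glucose_m6 is not None:
        plasma_norm = {n: t / plasma_glucose_m6 for n, t in totals.items()}
    tumour_norm = None
    if tumour_glucose_m6 is not None:
        tumour_norm = {}
        for name, shift in isotopologues.items():
            if name in mids and mids[name].size > shift:
                tumour_norm[name] = float(mids[name][shift]) / tumour_glucose_m6
    ratio = None
    if "citrate" in mids and "pyruvate" in mids and mids["pyruvate"].size > 3:
        if mids["pyruvate"][3] > 0:
            ratio = pdh_ratio(mids["citrate"], mids["pyruvate"])
    return LabellingSummary(
        total_labelling=totals,
        plasma_normalized_total=plasma_norm,
        tumour_normalized_fractions=tumour_norm,
        cit_m2_pyr_m3_ratio=ratio,
    )


def paired_difference(
    pdx: LabellingSummary, patient: LabellingSummary
) -> dict[str, float]:
    """PDX-minus-patient differences of tumour-normalized fractions."""
    if pdx.tumour_normalized_fractions is None or (
        patient.tumour_normalized_fractions is None
    ):
        raise ValidationError("both summaries need tumour-normalized fractions")
    shared = set(pdx.tumour_normalized_fractions) & set(
        patient.tumour_normalized_fractions
    )
    return {
        name: pdx.tumour_normalized_fractions[name]
        - patient.tumour_normalized_fractions[name]
        for name in sorted(shared)
    }


def pdh_ratio(citrate: np.ndarray, pyruvate: np.ndarray) -> float:
    """Citrate M+2 over pyruvate M+3, a PDH-contribution surrogate."""
    citrate = validate_mid(citrate)
    pyruvate = validate_mid(pyruvate)
    if citrate.size < 3:
        raise ValidationError("citrate MID must extend to M+2")
    if pyruvate.size < 4:
        raise ValidationError("pyruvate MID must extend to M+3")
    if pyruvate[3] <= 0:
        raise ValidationError("pyruvate M+3 is zero; ratio undefined")
    return float(citrate[2] / pyruvate[3])
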