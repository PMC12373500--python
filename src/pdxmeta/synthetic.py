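"""Synthetic patient/PDX cohorts and synthetic isotopologue measurements.

The generator plants every effect the downstream analysis is designed to
recover — origin-specific fingerprints, host shifts, passage drift,
pigmentation shifts, per-sample scale factors and threshold-censored
missingness — and returns them explicitly as a :class:`GroundTruth` record.

Effects are additive on the log10 scale; the emitted intensities are
``10**x`` so that normalization is exercised non-trivially. Missingness is
left-censoring at a detection threshold, consistent with minimum-based
imputation downstream (the real data's missingness mechanism is unknown;
this is an explicit modelling assumption).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import IntensityTable, SampleAnnotation
from .isotope import FragmentComposition, build_correction_matrix, validate_mid


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator (all SDs in log10 units)."""

    n_origins: int = 11
    n_metabolites: int = 305
    n_pdx_per_origin_per_passage: int = 3
    passages: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    baseline_mean_log10: float = 6.0
    baseline_sd: float = 1.0
    origin_sd: float = 0.4
    host_shift_fraction: float = 0.2
    host_shift_sd: float = 0.5
    passage_slope_sd: float = 0.02
    pigmentation_shift_count: int = 15
    pigmentation_shift_sd: float = 0.3
    residual_sd: float = 0.25
    sample_scale_sd: float = 0.15
    detection_threshold_log10: float = -np.inf
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites <= 0 or self.n_origins <= 0:
            raise ConfigError("n_metabolites and n_origins must be positive")
        if self.n_origins < 2:
            raise ConfigError("n_origins must be >= 2 for matching analyses")
        if self.n_pdx_per_origin_per_passage <= 0:
            raise ConfigError("n_pdx_per_origin_per_passage must be positive")
        if not self.passages or any(p < 1 or p > 6 for p in self.passages):
            raise ConfigError("passages must be a nonempty subset of 1..6")
        for name in (
            "baseline_sd",
            "origin_sd",
            "host_shift_sd",
            "passage_slope_sd",
            "pigmentation_shift_sd",
            "sample_scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        if not 0.0 <= self.host_shift_fraction <= 1.0:
            raise ConfigError("host_shift_fraction must be in [0, 1]")
        if not 0 <= self.pigmentation_shift_count <= self.n_metabolites:
            raise ConfigError(
                "pigmentation_shift_count must be in [0, n_metabolites]"
            )


@dataclass
class GroundTruth:
    """Every planted effect, keyed exactly like the emitted tables."""

    baselines: pd.Series
    origin_offsets: pd.DataFrame  # metabolites x origins
    host_shifts: pd.Series  # 0 for unshifted metabolites
    host_shifted_ids: list[str]
    passage_slopes: pd.Series
    pigment_shifts: pd.Series
    pigment_shifted_ids: list[str]
    pigmented_origins: list[str]
    sample_scales: pd.Series  # log10 per-sample scale factors
    expected_log10: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baselines": self.baselines.to_dict(),
            "origin_offsets": self.origin_offsets.to_dict(),
            "host_shifts": self.host_shifts.to_dict(),
            "host_shifted_ids": self.host_shifted_ids,
            "passage_slopes": self.passage_slopes.to_dict(),
            "pigment_shifts": self.pigment_shifts.to_dict(),
            "pigment_shifted_ids": self.pigment_shifted_ids,
            "pigmented_origins": self.pigmented_origins,
            "sample_scales": self.sample_scales.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _sample_layout(config: SimulationConfig):
    origins = [f"OR{i + 1:02d}" for i in range(config.n_origins)]
    pigmented = origins[::2]
    rows = []
    for origin in origins:
        rows.append((f"{origin}-P0", origin, "human", 0))
        for passage in config.passages:
            for rep in range(config.n_pdx_per_origin_per_passage):
                rows.append(
                    (f"{origin}-P{passage}-{rep + 1}", origin, "mouse", passage)
                )
    ann = pd.DataFrame(
        rows, columns=["sample_id", "origin", "host", "passage"]
    ).set_index("sample_id")
    ann["pigmentation"] = np.where(
        ann["origin"].isin(pigmented), "pigmented", "non-pigmented"
    )
    ann["batch"] = "sim"
    return origins, pigmented, ann


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[IntensityTable, SampleAnnotation, GroundTruth]:
    """Generate one cohort: raw intensities, annotation and ground truth.

    Each origin contributes one patient tumour (P0, human) and
    ``n_pdx_per_origin_per_passage`` xenografts per passage. The log10
    intensity of metabolite ``m`` in sample ``s`` is::

        baseline[m] + origin_offset[m, origin(s)] + host_shift[m]*is_mouse
        + passage_slope[m]*passage(s) + pigment_shift[m]*is_pigmented
        + sample_scale[s] + noise

    Cells below ``detection_threshold_log10`` are censored to missing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    metabolites = [f"M{i + 1:04d}" for i in range(config.n_metabolites)]
    origins, pigmented, ann_df = _sample_layout(config)
    samples = list(ann_df.index)
    n_m, n_s = len(metabolites), len(samples)

    baselines = pd.Series(
        rng.normal(config.baseline_mean_log10, config.baseline_sd, n_m),
        index=metabolites,
    )
    origin_offsets = pd.DataFrame(
        rng.normal(0.0, config.origin_sd, (n_m, len(origins))),
        index=metabolites,
        columns=origins,
    )
    n_shifted = int(round(config.host_shift_fraction * n_m))
    shifted_idx = rng.choice(n_m, size=n_shifted, replace=False)
    host_shifts = pd.Series(0.0, index=metabolites)
    host_shifts.iloc[np.sort(shifted_idx)] = rng.normal(
        0.0, config.host_shift_sd, n_shifted
    )
    passage_slopes = pd.Series(
        rng.normal(0.0, config.passage_slope_sd, n_m), index=metabolites
    )
    pigment_idx = rng.choice(
        n_m, size=config.pigmentation_shift_count, replace=False
    )
    pigment_shifts = pd.Series(0.0, index=metabolites)
    pigment_shifts.iloc[np.sort(pigment_idx)] = rng.normal(
        0.0, config.pigmentation_shift_sd, config.pigmentation_shift_count
    )
    sample_scales = pd.Series(
        rng.normal(0.0, config.sample_scale_sd, n_s), index=samples
    )

    is_mouse = (ann_df["host"] == "mouse").to_numpy(float)
    is_pigmented = (ann_df["pigmentation"] == "pigmented").to_numpy(float)
    passage = ann_df["passage"].to_numpy(float)
    origin_col = origin_offsets.loc[:, ann_df["origin"]].to_numpy()

    expected = (
        baselines.to_numpy()[:, None]
        + origin_col
        + np.outer(host_shifts.to_numpy(), is_mouse)
        + np.outer(passage_slopes.to_numpy(), passage)
        + np.outer(pigment_shifts.to_numpy(), is_pigmented)
        + sample_scales.to_numpy()[None, :]
    )
    x = expected + rng.normal(0.0, config.residual_sd, (n_m, n_s))
    raw = np.power(10.0, x)
    raw[x < config.detection_threshold_log10] = np.nan

    table = IntensityTable(pd.DataFrame(raw, index=metabolites, columns=samples))
    annotation = SampleAnnotation(ann_df)
    truth = GroundTruth(
        baselines=baselines,
        origin_offsets=origin_offsets,
        host_shifts=host_shifts,
        host_shifted_ids=[metabolites[i] for i in np.sort(shifted_idx)],
        passage_slopes=passage_slopes,
        pigment_shifts=pigment_shifts,
        pigment_shifted_ids=[metabolites[i] for i in np.sort(pigment_idx)],
        pigmented_origins=pigmented,
        sample_scales=sample_scales,
        expected_log10=pd.DataFrame(expected, index=metabolites, columns=samples),
    )
    return table, annotation, truth


@dataclass(frozen=True)
class TracerSimConfig:
    """Parameters for simulating one measured mass isotopomer distribution."""

    n_tracer_carbons: int
    true_mid: tuple[float, ...]
    element_counts: Mapping[str, int]
    natural_abundances: Mapping[str, tuple[float, ...]] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        mid = np.asarray(self.true_mid, dtype=float)
        if mid.size != self.n_tracer_carbons + 1:
            raise ConfigError(
                f"true_mid must have length {self.n_tracer_carbons + 1}"
            )
        if np.any(mid < 0) or abs(mid.sum() - 1.0) > 1e-9:
            raise ConfigError("true_mid entries must be >= 0 and sum to 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def simulate_mid(config: TracerSimConfig) -> np.ndarray:
    """Forward-simulate a measured MID: natural-abundance convolution + noise.

    The noiseless measurement is the correction matrix applied to the true
    MID (renormalized after truncation); optional truncated Gaussian noise is
    added and the result renormalized to sum 1.
    """
    config.validate()
    kwargs = {}
    if config.natural_abundances is not None:
        kwargs["abundances"] = dict(config.natural_abundances)
    try:
        comp = FragmentComposition(
            dict(config.element_counts), config.n_tracer_carbons, **kwargs
        )
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    matrix = build_correction_matrix(comp)
    measured = matrix @ np.asarray(config.true_mid, dtype=float)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        measured = np.clip(
            measured + rng.normal(0.0, config.noise_sd, measured.size), 0.0, None
        )
    total = measured.sum()
    if total <= 0:
        raise ConfigError("simulated MID sums to zero; reduce noise_sd")
    return validate_mid(measured / total)
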