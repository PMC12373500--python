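"""Per-metabolite association models.

Four analyses share this module:

* univariate and multivariate ordinary-least-squares models with
  empirical-Bayes variance moderation and Benjamini-Hochberg adjustment;
* variance partitioning with categorical factors as random intercepts and
  numeric factors as fixed slopes (REML);
* selection of species-agnostic metabolites from a mixed model with host as
  a fixed effect and a random intercept per origin.

Moderation follows the canonical moderated-t construction: per-metabolite
residual variances are shrunk toward a prior variance ``s0^2`` with prior
degrees of freedom ``d0``, both estimated by method of moments on the log
residual variances; the moderated statistic is referred to a t distribution
with ``d0 + d`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from scipy.special import digamma, polygamma

from .errors import ValidationError
from .preprocessing import NormalizedTable

LOG10_TO_LOG2 = 1.0 / np.log10(2.0)


def _values(norm) -> pd.DataFrame:
    """Accept a NormalizedTable or a bare metabolites x samples DataFrame."""
    if isinstance(norm, NormalizedTable):
        return norm.values
    if isinstance(norm, pd.DataFrame):
        return norm
    raise TypeError(f"expected NormalizedTable or DataFrame, got {type(norm)}")


def _annotation_frame(ann) -> pd.DataFrame:
    table = getattr(ann, "table", ann)
    if not isinstance(table, pd.DataFrame):
        raise TypeError("expected SampleAnnotation or DataFrame")
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


@dataclass
class ModerationFit:
    df_prior: float
    s2_prior: float
    s2_posterior: np.ndarray


def squeeze_variances(s2: np.ndarray, df: float) -> ModerationFit:
    """Estimate (d0, s0^2) by method of moments on log residual variances.

    When the observed log-variance dispersion does not exceed what sampling
    noise alone predicts, the prior df is infinite and every variance is
    shrunk fully to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():  # fully degenerate: every fit is exact
        return ModerationFit(
            df_prior=np.inf, s2_prior=0.0, s2_posterior=np.zeros_like(s2)
        )
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0) if e.size > 1 else 0.0
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        posterior = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        # no excess dispersion: shrink fully to the common (geometric mean)
        # sample variance, so equal variances leave the t statistic unchanged
        d0 = np.inf
        s0_2 = float(np.exp(np.log(s2[ok]).mean())) if ok.any() else 0.0
        posterior = np.full_like(s2, s0_2)
    return ModerationFit(df_prior=d0, s2_prior=s0_2, s2_posterior=posterior)


def design_matrix(
    ann: pd.DataFrame, factor_names: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Intercept + treatment-coded categorical / numeric covariate columns.

    Returns the matrix, coefficient names and, per factor, the indices of
    its coefficient columns.
    """
    n = len(ann)
    columns = [np.ones(n)]
    names = ["intercept"]
    factor_cols: dict[str, list[int]] = {}
    for factor in factor_names:
        if factor not in ann.columns:
            raise ValidationError(f"annotation has no column {factor!r}")
        col = ann[factor]
        factor_cols[factor] = []
        if pd.api.types.is_numeric_dtype(col):
            values = col.to_numpy(dtype=float)
            if np.ptp(values) == 0:
                raise ValidationError(f"factor {factor!r} is constant")
            columns.append(values)
            names.append(factor)
            factor_cols[factor].append(len(names) - 1)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValidationError(f"factor {factor!r} is constant")
            for level in levels[1:]:
                columns.append((col.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{factor}[{level}]")
                factor_cols[factor].append(len(names) - 1)
    X = np.column_stack(columns)
    return X, names, factor_cols


@dataclass
class DifferentialResult:
    """Long table of per-metabolite, per-coefficient moderated statistics."""

    table: pd.DataFrame
    df_prior: float
    s2_prior: float

    def significant(self, factor: str, alpha: float = 0.05) -> list[str]:
        sub = self.table[self.table["factor"] == factor]
        return sorted(sub.loc[sub["p_adjusted"] < alpha, "metabolite"])


def _check_level_counts(col: pd.Series) -> None:
    if pd.api.types.is_numeric_dtype(col):
        return
    counts = col.astype(str).value_counts()
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise ValidationError(
            f"factor levels with fewer than 2 samples: {small}"
        )


def _fit_linear(
    values: pd.DataFrame, ann: pd.DataFrame, factor_names: list[str]
) -> DifferentialResult:
    X, coef_names, factor_cols = design_matrix(ann, factor_names)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {p} columns); aliased "
            f"factors among {factor_names}"
        )
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    Y = values.to_numpy()
    pinv = np.linalg.pinv(X)
    coef = Y @ pinv.T  # m x p
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df_resid
    zero = s2 <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} metabolite(s) with zero residual variance"
        )
    mod = squeeze_variances(s2[~zero] if zero.any() else s2, df_resid)
    if zero.any():
        posterior = np.where(
            zero,
            (mod.df_prior * mod.s2_prior) / (mod.df_prior + df_resid)
            if np.isfinite(mod.df_prior)
            else mod.s2_prior,
            0.0,
        )
        posterior[~zero] = mod.s2_posterior
    else:
        posterior = mod.s2_posterior
    unscaled = np.diag(np.linalg.inv(X.T @ X))
    df_total = mod.df_prior + df_resid
    rows = []
    for factor in factor_names:
        for j in factor_cols[factor]:
            beta = coef[:, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                t_ord = beta / np.sqrt(s2 * unscaled[j])
                t_mod = beta / np.sqrt(posterior * unscaled[j])
            t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
            if np.isfinite(df_total):
                pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
            else:
                pvals = 2.0 * stats.norm.sf(np.abs(t_mod))
            rows.append(
                pd.DataFrame(
                    {
                        "metabolite": values.index,
                        "factor": factor,
                        "coefficient": coef_names[j],
                        "effect_log10": beta,
                        "effect_log2": beta * LOG10_TO_LOG2,
                        "t_ordinary": t_ord,
                        "t_moderated": t_mod,
                        "df_residual": float(df_resid),
                        "df_prior": mod.df_prior,
                        "s2_prior": mod.s2_prior,
                        "p_value": pvals,
                        "p_adjusted": bh_adjust(pvals),
                    }
                )
            )
    return DifferentialResult(
        table=pd.concat(rows, ignore_index=True),
        df_prior=mod.df_prior,
        s2_prior=mod.s2_prior,
    )


def fit_univariate(norm, ann, factor_name: str) -> DifferentialResult:
    """Moderated single-factor model per metabolite, BH across metabolites."""
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    _check_level_counts(ann_df[factor_name])
    return _fit_linear(values, ann_df, [factor_name])


def fit_multivariate(norm, ann, factor_names: list[str]) -> DifferentialResult:
    """Joint moderated model; per-factor tests share one residual variance."""
    if len(factor_names) < 1:
        raise ValidationError("need at least one factor")
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    return _fit_linear(values, ann_df, list(factor_names))


# ---------------------------------------------------------------------------
# REML machinery


@dataclass
class REMLFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_resid: float
    sigma2_components: np.ndarray  # one per random component


class RandomInterceptREML:
    """REML for y = X b + Z u + e with a single random intercept component.

    The design is fixed across metabolites, so the eigendecomposition of
    Z Z' is done once; each fit is then a 1-D profiled-likelihood search
    over the variance ratio.
    """

    _LOG_LAMBDA_BOUNDS = (-15.0, 15.0)

    def __init__(self, X: np.ndarray, Z: np.ndarray) -> None:
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise ValidationError("fixed-effect design is rank deficient")
        eigvals, U = np.linalg.eigh(Z @ Z.T)
        self.eigvals = np.clip(eigvals, 0.0, None)
        self.U = U
        self.Xt = U.T @ X

    def _profile(self, log_lambda: float, yt: np.ndarray):
        lam = np.exp(log_lambda)
        w = 1.0 + lam * self.eigvals
        Xw = self.Xt / w[:, None]
        A = self.Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yt)
        r = yt - self.Xt @ beta
        q = float(np.sum(r * r / w))
        s2 = max(q / (self.n - self.p), 1e-300)
        crit = (
            float(np.sum(np.log(w)))
            + float(np.linalg.slogdet(A)[1])
            + (self.n - self.p) * np.log(s2)
        )
        return crit, beta, A, s2, lam

    def fit(self, y: np.ndarray) -> REMLFit:
        yt = self.U.T @ np.asarray(y, dtype=float)
        res = optimize.minimize_scalar(
            lambda ll: self._profile(ll, yt)[0],
            bounds=self._LOG_LAMBDA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-6},
        )
        candidates = [res.x, self._LOG_LAMBDA_BOUNDS[0]]
        best = min(candidates, key=lambda ll: self._profile(ll, yt)[0])
        _, beta, A, s2, lam = self._profile(best, yt)
        if best <= self._LOG_LAMBDA_BOUNDS[0] + 1e-9:
            lam = 0.0  # boundary: no between-group variance
        cov_beta = s2 * np.linalg.inv(A)
        return REMLFit(
            beta=beta,
            cov_beta=cov_beta,
            sigma2_resid=s2,
            sigma2_components=np.array([lam * s2]),
        )


class MultiComponentREML:
    """REML with several independent random-intercept components.

    V(lambda) = I + sum_i lambda_i Z_i Z_i'; the residual variance is
    profiled out and the lambda_i are optimized on the log scale.
    """

    _BOUND = 12.0

    def __init__(self, X: np.ndarray, Zs: list[np.ndarray]) -> None:
        self.X = X
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise ValidationError("fixed-effect design is rank deficient")
        self.Ks = [Z @ Z.T for Z in Zs]

    def _profile(self, log_lams: np.ndarray, y: np.ndarray):
        lams = np.exp(np.clip(log_lams, -self._BOUND, self._BOUND))
        V = np.eye(self.n)
        for lam, K in zip(lams, self.Ks):
            V = V + lam * K
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None, np.inf, lams
        Xw = solve_triangular(L, self.X, lower=True)
        yw = solve_triangular(L, y, lower=True)
        A = Xw.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yw)
        r = yw - Xw @ beta
        s2 = max(float(r @ r) / (self.n - self.p), 1e-300)
        crit = (
            2.0 * float(np.sum(np.log(np.diag(L))))
            + float(np.linalg.slogdet(A)[1])
            + (self.n - self.p) * np.log(s2)
        )
        return crit, beta, A, s2, lams

    def fit(self, y: np.ndarray) -> REMLFit:
        y = np.asarray(y, dtype=float)
        x0 = np.zeros(len(self.Ks))
        res = optimize.minimize(
            lambda ll: self._profile(ll, y)[0],
            x0,
            method="L-BFGS-B",
            bounds=[(-self._BOUND, self._BOUND)] * len(self.Ks),
        )
        _, beta, A, s2, lams = self._profile(res.x, y)
        lams = np.where(res.x <= -self._BOUND + 1e-6, 0.0, lams)
        cov_beta = s2 * np.linalg.inv(A)
        return REMLFit(
            beta=beta,
            cov_beta=cov_beta,
            sigma2_resid=s2,
            sigma2_components=lams * s2,
        )


def _indicator(col: pd.Series) -> np.ndarray:
    levels = sorted(col.astype(str).unique())
    return np.column_stack(
        [(col.astype(str) == level).to_numpy(dtype=float) for level in levels]
    )


@dataclass
class VarianceFractions:
    """Per-metabolite variance fraction per factor plus residual.

    ``table`` columns: one per factor, ``residual`` and a ``degenerate``
    flag for constant metabolites (all fractions reported as 0).
    """

    table: pd.DataFrame
    factor_names: list[str] = field(default_factory=list)


def partition_variance(norm, ann, factor_names: list[str]) -> VarianceFractions:
    """Share of each metabolite's variance attributable to each factor.

    Categorical factors enter as random intercepts whose REML variance
    component is reported directly; numeric factors enter as fixed slopes
    whose explained variance is ``beta^2 * var(x)``. Fractions are each
    component over the sum of all components plus the residual variance.
    """
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    categorical, numeric = [], []
    for factor in factor_names:
        if factor not in ann_df.columns:
            raise ValidationError(f"annotation has no column {factor!r}")
        if pd.api.types.is_numeric_dtype(ann_df[factor]):
            numeric.append(factor)
        else:
            if ann_df[factor].astype(str).nunique() < 2:
                raise ValidationError(f"factor {factor!r} is constant")
            categorical.append(factor)
    n = len(ann_df)
    fixed_cols = [np.ones(n)] + [
        ann_df[f].to_numpy(dtype=float) for f in numeric
    ]
    X = np.column_stack(fixed_cols)
    Zs = [_indicator(ann_df[f]) for f in categorical]
    if n < X.shape[1] + len(Zs) + 1:
        raise ValidationError("fewer samples than model components")
    if len(Zs) == 1:
        fitter = RandomInterceptREML(X, Zs[0])
    elif len(Zs) > 1:
        fitter = MultiComponentREML(X, Zs)
    else:
        fitter = None
    numeric_vars = {
        f: float(np.var(ann_df[f].to_numpy(dtype=float), ddof=1))
        for f in numeric
    }
    records = []
    for metabolite, y in values.iterrows():
        y = y.to_numpy(dtype=float)
        row: dict[str, float | bool] = {f: 0.0 for f in factor_names}
        row["residual"] = 0.0
        if float(np.var(y, ddof=1)) < 1e-12:
            row["degenerate"] = True
            records.append(row)
            continue
        row["degenerate"] = False
        if fitter is not None:
            fit = fitter.fit(y)
            for f, sigma2 in zip(categorical, fit.sigma2_components):
                row[f] = float(sigma2)
            beta = fit.beta
            resid_var = fit.sigma2_resid
        else:  # numeric factors only: plain OLS
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            resid_var = float(r @ r) / max(n - X.shape[1], 1)
        for j, f in enumerate(numeric, start=1):
            row[f] = float(beta[j] ** 2) * numeric_vars[f]
        row["residual"] = float(resid_var)
        total = sum(row[f] for f in factor_names) + row["residual"]
        if total > 0:
            for f in [*factor_names, "residual"]:
                row[f] = row[f] / total
        records.append(row)
    table = pd.DataFrame(records, index=values.index)
    return VarianceFractions(table=table, factor_names=list(factor_names))


@dataclass
class SpeciesAgnosticFlags:
    """Host-term mixed-model P per metabolite and the agnostic flag."""

    table: pd.DataFrame  # columns: p_host, effect_host, species_agnostic
    p_threshold: float

    @property
    def agnostic_ids(self) -> list[str]:
        return sorted(self.table.index[self.table["species_agnostic"]])


def select_species_agnostic(
    norm, ann, p_threshold: float = 0.1
) -> SpeciesAgnosticFlags:
    """Flag metabolites whose host effect is not detectable across origins.

    Per metabolite, a mixed model with host (human tumour vs PDX) as a fixed
    effect and a random intercept per origin is fitted by REML; the Wald t
    statistic of the host term is referred to a t distribution with
    ``n - n_origins - 1`` degrees of freedom (the within-origin containment
    df). A metabolite is species-agnostic when P > ``p_threshold``.
    """
    values = _values(norm)
    ann_df = _annotation_frame(ann).loc[values.columns]
    origins = ann_df["origin"].astype(str)
    if origins.nunique() < 2:
        raise ValidationError(
            "need >= 2 origins; random origin effect unidentifiable"
        )
    both = 0
    for _, sub in ann_df.groupby(origins):
        hosts = set(sub["host"])
        if {"human", "mouse"} <= hosts:
            both += 1
    if both < 2:
        raise ValidationError(
            "need >= 2 origins containing both a patient tumour and a PDX"
        )
    is_mouse = (ann_df["host"] == "mouse").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(ann_df)), is_mouse])
    Z = _indicator(origins)
    df = len(ann_df) - origins.nunique() - 1
    if df < 1:
        raise ValidationError("no residual degrees of freedom for the host test")
    fitter = RandomInterceptREML(X, Z)
    pvals, effects = [], []
    for _, y in values.iterrows():
        fit = fitter.fit(y.to_numpy(dtype=float))
        beta = fit.beta[1]
        se = np.sqrt(fit.cov_beta[1, 1])
        if se == 0.0:
            t = 0.0 if beta == 0.0 else np.inf
        else:
            t = beta / se
        pvals.append(2.0 * stats.t.sf(abs(t), df))
        effects.append(beta)
    table = pd.DataFrame(
        {
            "effect_host": effects,
            "p_host": pvals,
            "species_agnostic": np.asarray(pvals) > p_threshold,
        },
        index=values.index,
    )
    return SpeciesAgnosticFlags(table=table, p_threshold=p_threshold)
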