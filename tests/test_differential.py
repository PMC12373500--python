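import numpy as np
import pandas as pd
import pytest

from pdxmeta.differential import (
    MultiComponentREML,
    RandomInterceptREML,
    bh_adjust,
    design_matrix,
    fit_multivariate,
    fit_univariate,
    partition_variance,
    select_species_agnostic,
    squeeze_variances,
    trigamma_inverse,
)
from pdxmeta.errors import ValidationError

from conftest import make_annotation


def _noise_frame(rng, n_metabolites, samples):
    return pd.DataFrame(
        rng.normal(0, 1, (n_metabolites, len(samples))),
        index=[f"m{i}" for i in range(n_metabolites)],
        columns=samples,
    )


def _paired_annotation(n_pairs):
    rows = []
    for i in range(n_pairs):
        rows.append((f"o{i}-P0", f"o{i}", "human", 0))
        rows.append((f"o{i}-P1", f"o{i}", "mouse", 1))
    return make_annotation(rows)


class TestBHAdjust:
    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 500)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestModeration:
    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in [1e-7, 0.01, 0.5, 2.0, 1e8]:
            y = trigamma_inverse(x)
            assert polygamma(1, y) == pytest.approx(x, rel=1e-6)

    def test_equal_variances_collapse_to_ordinary_t(self):
        """Duplicated metabolite: shrinkage to the common variance is a no-op."""
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 20)
        values = pd.DataFrame(
            np.tile(base, (30, 1)),
            index=[f"m{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(20)],
        )
        ann = _paired_annotation(10)
        values.columns = ann.table.index
        result = fit_univariate(values, ann, "host")
        assert np.allclose(
            result.table["t_moderated"], result.table["t_ordinary"], atol=1e-10
        )
        assert result.df_prior == np.inf

    def test_moderated_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(5, 200) / 5.0
        fit = squeeze_variances(s2, 5.0)
        lower = np.minimum(s2, fit.s2_prior) - 1e-12
        upper = np.maximum(s2, fit.s2_prior) + 1e-12
        assert np.all(fit.s2_posterior >= lower)
        assert np.all(fit.s2_posterior <= upper)

    def test_null_calibration(self):
        """Raw P < 0.05 fraction within 3 binomial SE of 0.05 on null data."""
        rng = np.random.default_rng(4)
        ann = _paired_annotation(18)
        values = _noise_frame(rng, 2000, list(ann.table.index))
        result = fit_univariate(values, ann, "host")
        frac = (result.table["p_value"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * se


class TestLinearModels:
    def test_fold_change_base_conversion(self):
        ann = _paired_annotation(4)
        host = (ann.table["host"] == "mouse").to_numpy(float)
        # perturbation balanced within each host group: OLS effect stays exact
        values = pd.DataFrame(
            [5.0 + 0.30103 * host + np.array([0.01, 0.01, -0.01, -0.01, 0.02, 0.02, -0.02, -0.02])],
            index=["m0"],
            columns=ann.table.index,
        )
        # single metabolite: moderation is degenerate but the effect is exact OLS
        result = fit_univariate(values, ann, "host")
        assert result.table["effect_log10"].iloc[0] == pytest.approx(0.30103, abs=1e-9)
        assert result.table["effect_log2"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_orthogonal_design_matches_univariate(self):
        """Balanced two-factor design: joint estimates equal univariate ones."""
        rng = np.random.default_rng(5)
        rows, pig = [], []
        k = 0
        for host, passage in [("human", 0), ("mouse", 1)]:
            for pigmentation in ["pigmented", "non-pigmented"]:
                for _ in range(5):
                    rows.append((f"s{k}", f"o{k % 4}", host, passage))
                    pig.append(pigmentation)
                    k += 1
        ann = make_annotation(rows)
        ann.table["pigmentation"] = pig
        values = _noise_frame(rng, 50, list(ann.table.index))
        uni = fit_univariate(values, ann, "host")
        multi = fit_multivariate(values, ann, ["host", "pigmentation"])
        uni_host = uni.table.set_index("metabolite")["effect_log10"]
        multi_host = multi.table[multi.table["factor"] == "host"].set_index(
            "metabolite"
        )["effect_log10"]
        assert np.allclose(uni_host, multi_host.loc[uni_host.index], atol=1e-10)

    def test_planted_host_effect_leaves_pigmentation_centred(self):
        coefs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows, pig = [], []
            k = 0
            for host, passage in [("human", 0), ("mouse", 1)]:
                for pigmentation in ["pigmented", "non-pigmented"]:
                    for _ in range(4):
                        rows.append((f"s{k}", f"o{k % 4}", host, passage))
                        pig.append(pigmentation)
                        k += 1
            ann = make_annotation(rows)
            ann.table["pigmentation"] = pig
            host_vec = (ann.table["host"] == "mouse").to_numpy(float)
            values = _noise_frame(rng, 60, list(ann.table.index)) + 0.8 * host_vec
            multi = fit_multivariate(values, ann, ["host", "pigmentation"])
            coefs.append(
                multi.table[multi.table["factor"] == "pigmentation"][
                    "effect_log10"
                ].mean()
            )
        # mean of ~1200 independent coefficient estimates; 3 SE bound
        assert abs(np.mean(coefs)) < 0.05

    def test_constant_factor_rejected(self):
        ann = _paired_annotation(4)
        values = _noise_frame(np.random.default_rng(0), 5, list(ann.table.index))
        ann.table["braf"] = "mutant"
        with pytest.raises(ValidationError, match="constant"):
            fit_univariate(values, ann, "braf")

    def test_rank_deficient_design_rejected(self):
        ann = _paired_annotation(4)
        # passage is perfectly aliased with host here
        values = _noise_frame(np.random.default_rng(0), 5, list(ann.table.index))
        with pytest.raises(ValidationError, match="rank"):
            fit_multivariate(values, ann, ["host", "passage"])

    def test_small_level_rejected(self):
        rows = [("a", "o1", "human", 0), ("b", "o1", "mouse", 1),
                ("c", "o2", "mouse", 2), ("d", "o2", "mouse", 3)]
        ann = make_annotation(rows)
        values = _noise_frame(np.random.default_rng(0), 5, list(ann.table.index))
        with pytest.raises(ValidationError, match="fewer than 2"):
            fit_univariate(values, ann, "host")


class TestREMLAgainstStatsmodels:
    """Independent oracle: statsmodels MixedLM REML on the same data."""

    def _data(self, seed, n_groups=8, per_group=6):
        rng = np.random.default_rng(seed)
        groups = np.repeat(np.arange(n_groups), per_group)
        x = rng.normal(0, 1, groups.size)
        u = rng.normal(0, 0.7, n_groups)
        y = 1.0 + 0.5 * x + u[groups] + rng.normal(0, 0.4, groups.size)
        return y, x, groups

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_component_matches_mixedlm(self, seed):
        import statsmodels.api as sm

        y, x, groups = self._data(seed)
        X = np.column_stack([np.ones_like(x), x])
        Z = np.zeros((groups.size, groups.max() + 1))
        Z[np.arange(groups.size), groups] = 1.0
        fit = RandomInterceptREML(X, Z).fit(y)
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert fit.beta == pytest.approx(ref.fe_params, abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-3)
        assert fit.sigma2_components[0] == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-2, abs=1e-4
        )
        assert np.allclose(
            np.sqrt(np.diag(fit.cov_beta)), ref.bse_fe, rtol=5e-3
        )

    def test_multi_component_matches_single_on_one_factor(self):
        y, x, groups = self._data(3)
        X = np.column_stack([np.ones_like(x), x])
        Z = np.zeros((groups.size, groups.max() + 1))
        Z[np.arange(groups.size), groups] = 1.0
        one = RandomInterceptREML(X, Z).fit(y)
        multi = MultiComponentREML(X, [Z]).fit(y)
        assert multi.beta == pytest.approx(one.beta, abs=1e-5)
        assert multi.sigma2_components[0] == pytest.approx(
            one.sigma2_components[0], rel=1e-3, abs=1e-6
        )


class TestPartitionVariance:
    def test_origin_only_variation_gives_fraction_one(self):
        rows = []
        for o in range(4):
            for r in range(5):
                rows.append((f"o{o}-r{r}", f"o{o}", "mouse", r + 1))
        ann = make_annotation(rows)
        offsets = {f"o{o}": float(o) for o in range(4)}
        y = np.array([offsets[ann.table.loc[s, "origin"]] for s in ann.table.index])
        values = pd.DataFrame([y], index=["m0"], columns=ann.table.index)
        result = partition_variance(values, ann, ["origin"])
        assert result.table.loc["m0", "origin"] > 0.99

    def test_constant_metabolite_degenerate(self):
        rows = [(f"s{i}", f"o{i % 3}", "mouse", 1 + i % 2) for i in range(12)]
        ann = make_annotation(rows)
        values = pd.DataFrame(
            np.ones((1, 12)), index=["m0"], columns=ann.table.index
        )
        result = partition_variance(values, ann, ["origin", "passage"])
        assert bool(result.table.loc["m0", "degenerate"])
        assert result.table.loc["m0", ["origin", "passage", "residual"]].sum() == 0

    def test_fraction_bounds_and_sum(self, small_normalized):
        norm, ann = small_normalized
        pdx = ann.table[ann.table["host"] == "mouse"]
        result = partition_variance(
            norm.values[pdx.index], pdx, ["passage", "origin"]
        )
        frac = result.table[["passage", "origin", "residual"]]
        assert (frac.to_numpy() >= -1e-9).all()
        assert (frac.to_numpy() <= 1 + 1e-6).all()
        sums = frac.sum(axis=1)
        assert np.allclose(sums[~result.table["degenerate"]], 1.0, atol=1e-6)

    def test_too_few_samples_rejected(self):
        rows = [("a", "o1", "mouse", 1), ("b", "o2", "mouse", 2)]
        ann = make_annotation(rows)
        values = pd.DataFrame([[0.0, 1.0]], index=["m0"], columns=ann.table.index)
        with pytest.raises(ValidationError, match="fewer samples"):
            partition_variance(values, ann, ["origin", "passage"])


class TestSpeciesAgnostic:
    def _cohort(self, seed, n_origins=8, n_pdx=3, shift=0.0, residual=0.2,
                origin_sd=0.5, n_metabolites=30):
        rng = np.random.default_rng(seed)
        rows = []
        for o in range(n_origins):
            rows.append((f"o{o}-P0", f"o{o}", "human", 0))
            for r in range(n_pdx):
                rows.append((f"o{o}-P1-{r}", f"o{o}", "mouse", 1))
        ann = make_annotation(rows)
        is_mouse = (ann.table["host"] == "mouse").to_numpy(float)
        origin_codes = pd.factorize(ann.table["origin"])[0]
        values = []
        for _ in range(n_metabolites):
            u = rng.normal(0, origin_sd, n_origins)
            values.append(
                u[origin_codes] + shift * is_mouse
                + rng.normal(0, residual, len(rows))
            )
        frame = pd.DataFrame(
            values, index=[f"m{i}" for i in range(n_metabolites)],
            columns=ann.table.index,
        )
        return frame, ann

    def test_planted_shift_flagged_non_agnostic(self):
        values, ann = self._cohort(0, shift=2.0, residual=0.2)
        flags = select_species_agnostic(values, ann)
        assert (flags.table["p_host"] < 1e-6).all()
        assert not flags.table["species_agnostic"].any()

    def test_noiseless_zero_effect_flagged_agnostic(self):
        values, ann = self._cohort(1, shift=0.0, residual=0.0)
        flags = select_species_agnostic(values, ann)
        assert flags.table["species_agnostic"].all()

    def test_invariant_to_origin_relabeling(self):
        values, ann = self._cohort(2, shift=0.3)
        flags1 = select_species_agnostic(values, ann)
        relabeled = ann.table.copy()
        mapping = {f"o{i}": f"z{7 - i}" for i in range(8)}
        relabeled["origin"] = relabeled["origin"].map(mapping)
        flags2 = select_species_agnostic(values, relabeled)
        assert np.allclose(flags1.table["p_host"], flags2.table["p_host"], atol=1e-8)

    def test_single_origin_rejected(self):
        rows = [("a", "o1", "human", 0), ("b", "o1", "mouse", 1),
                ("c", "o1", "mouse", 1)]
        ann = make_annotation(rows)
        values = pd.DataFrame(
            [[0.0, 1.0, 2.0]], index=["m0"], columns=ann.table.index
        )
        with pytest.raises(ValidationError, match="origin"):
            select_species_agnostic(values, ann)

    def test_flag_matches_threshold_exactly(self):
        values, ann = self._cohort(3, shift=0.1)
        flags = select_species_agnostic(values, ann, p_threshold=0.5)
        assert (
            flags.table["species_agnostic"] == (flags.table["p_host"] > 0.5)
        ).all()
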