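"""Method-comparison statistics: balanced ANOVA, Tukey letters, MANOVA,
blank-compromise filter, correlation-matrix PCA, RSD summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vinomics.compare import (
    _balanced_anova,
    anova_per_isotope,
    blank_compromise_filter,
    manova_method_effect,
    pca_profiles,
    profile_matrix,
    summarize_rsd,
    tukey_letters,
)
from vinomics.core import DegenerateDesignError, UnbalancedDesignError


def _long_table(y, wines=2, methods=2, reps=2, element="Mn", mass=55):
    rows = []
    i = 0
    for w in [f"W{k}" for k in range(wines)]:
        for m in [f"M{k}" for k in range(methods)]:
            for r in range(1, reps + 1):
                rows.append(
                    {"wine": w, "method": m, "replicate": r, "role": "sample",
                     "element": element, "mass": mass, "concentration": y[i],
                     "censored": False}
                )
                i += 1
    return pd.DataFrame(rows)


class TestBalancedAnova:
    def test_matches_statsmodels_on_random_balanced_data(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, size=4 * 4 * 3)
        data = _long_table(y, wines=4, methods=4, reps=3)
        ours = _balanced_anova(data)
        model = ols(
            "concentration ~ C(wine) + C(replicate) + C(method)", data=data
        ).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for ours_key, sm_key in [
            ("wine", "C(wine)"), ("replicate", "C(replicate)"),
            ("method", "C(method)"),
        ]:
            assert ours["f"][ours_key] == pytest.approx(
                table.loc[sm_key, "F"], rel=1e-9
            )
            assert ours["p"][ours_key] == pytest.approx(
                table.loc[sm_key, "PR(>F)"], rel=1e-9
            )

    def test_sum_of_squares_decomposition_is_exact(self):
        rng = np.random.default_rng(1)
        y = rng.lognormal(2, 0.5, size=2 * 3 * 4)
        data = _long_table(y, wines=2, methods=3, reps=4)
        a = _balanced_anova(data)
        total = sum(a["ss"].values()) + a["ss_resid"]
        assert total == pytest.approx(a["ss_total"], rel=1e-12)

    def test_tiny_two_level_design_by_hand(self):
        # 2 wines × 2 methods × 2 replicates; y chosen so the marginal means
        # are easy: wine effect ±1, method effect ±2, no replicate effect.
        y = np.array([10 + 1 + 2, 10 + 1 + 2, 10 + 1 - 2, 10 + 1 - 2,
                      10 - 1 + 2, 10 - 1 + 2, 10 - 1 - 2, 10 - 1 - 2],
                     dtype=float)
        data = _long_table(y, wines=2, methods=2, reps=2)
        a = _balanced_anova(data)
        assert a["ss"]["wine"] == pytest.approx(8.0)  # 8 obs × (±1)²
        assert a["ss"]["method"] == pytest.approx(32.0)  # 8 obs × (±2)²
        assert a["ss"]["replicate"] == pytest.approx(0.0)
        assert a["ss_resid"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_response_flagged_degenerate(self):
        data = _long_table(np.full(8, 3.0), wines=2, methods=2, reps=2)
        a = _balanced_anova(data)
        assert a["degenerate"]

    def test_unbalanced_design_rejected(self):
        y = np.arange(8.0)
        data = _long_table(y, wines=2, methods=2, reps=2).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            anova_per_isotope(data)

    def test_injected_method_shift_detected(self, truth):
        from vinomics.quant import fit_all_calibrations, quantify_records
        from vinomics.simulate import (
            BatchDesign, InstrumentParams, MethodEffectParams, simulate_batch,
        )
        from vinomics.core import default_channels

        effects = MethodEffectParams.null(cv=0.15)
        effects.contamination = {"MW": {("Mn", 55): 200.0}}
        batch = simulate_batch(
            BatchDesign(include_spikes=False, include_method_blanks=False,
                        include_ccb=False, include_qc=False),
            truth, effects, InstrumentParams(), seed=13,
            channels=[ch for ch in default_channels() if ch.key == ("Mn", 55)],
        )
        conc = quantify_records(batch, fit_all_calibrations(batch), roles=("sample",))
        res = anova_per_isotope(conc)[0]
        assert res.p["method"] < 0.05
        assert res.letters["MW"] != res.letters["DD"]


class TestTukeyLetters:
    def test_equal_means_share_a_letter(self):
        letters = tukey_letters({"A": 5.0, "B": 5.0, "C": 5.0}, 1.0, 12, 3)
        assert set(letters.values()) == {"a"}

    def test_well_separated_groups_get_disjoint_letters(self):
        letters = tukey_letters({"A": 0.0, "B": 100.0}, 1.0, 12, 3)
        assert set(letters["A"]) & set(letters["B"]) == set()

    def test_nonpositive_mse_rejected(self):
        with pytest.raises(ValueError):
            tukey_letters({"A": 1.0, "B": 2.0}, 0.0, 10, 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_letters_agree_with_brute_force_pairwise(self, seed):
        """Shared letter ⇔ |Δmean| ≤ HSD for every pair (4–6 groups)."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 7))
        means = {f"G{i}": float(rng.normal(0, 2)) for i in range(k)}
        mse, df, n = 1.5, 20, 3
        letters = tukey_letters(means, mse, df, n)
        hsd = stats.studentized_range.ppf(0.95, k, df) * np.sqrt(mse / n)
        for a, b in itertools.combinations(means, 2):
            significant = abs(means[a] - means[b]) > hsd
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares == (not significant), (means, letters)


class TestManova:
    def test_channel_overload_raises_instructive_error(self, noisy_quant):
        with pytest.raises(DegenerateDesignError, match="subset"):
            manova_method_effect(noisy_quant.quant)

    def test_injected_mw_contamination_is_detected(self, noisy_quant):
        mv = manova_method_effect(
            noisy_quant.quant,
            channels=[("Al", 27), ("Ti", 47), ("Cr", 52), ("Mn", 55),
                      ("Co", 59), ("Ni", 60), ("Zn", 66), ("Mo", 98),
                      ("Ta", 181), ("W", 182)],
        )
        assert mv.p_value < 0.05

    def test_permuting_method_labels_destroys_significance(self, noisy_quant):
        q = noisy_quant.quant
        channels = [("Al", 27), ("Mn", 55), ("Co", 59), ("Ni", 60)]
        rng = np.random.default_rng(3)
        idx = q["role"] == "sample"
        units = (
            q.loc[idx, ["sample_id", "wine", "replicate", "method"]]
            .drop_duplicates("sample_id")
        )
        pvals = []
        for _ in range(5):
            mapping = {}
            # permute method labels within each (wine, replicate) block so the
            # permuted design stays fully crossed
            for _, grp in units.groupby(["wine", "replicate"]):
                shuffled = rng.permutation(grp["method"].to_numpy())
                mapping.update(dict(zip(grp["sample_id"], shuffled)))
            perm = q.copy()
            perm.loc[idx, "method"] = perm.loc[idx, "sample_id"].map(mapping)
            pvals.append(manova_method_effect(perm, channels=channels).p_value)
        original = manova_method_effect(q, channels=channels).p_value
        assert original < min(pvals)


class TestBlankFilter:
    def _quant(self, wine_level, blank_level, truth_varies=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for method in ("DD", "FA", "AF", "MW"):
            for wine in ("C", "PN", "S", "T", "BLANK"):
                base = blank_level if wine == "BLANK" else wine_level
                if truth_varies and wine != "BLANK":
                    base = base * (1 + 0.5 * ["C", "PN", "S", "T"].index(wine))
                for rep in range(1, 4):
                    rows.append(
                        {"wine": wine, "method": method, "replicate": rep,
                         "role": "method_blank" if wine == "BLANK" else "sample",
                         "element": "W", "mass": 182,
                         "concentration": base * (1 + 0.02 * rng.normal()),
                         "censored": False}
                    )
        return pd.DataFrame(rows)

    def test_blank_exceeding_sample_is_excluded(self):
        q = self._quant(wine_level=1.0, blank_level=5.0)
        res = blank_compromise_filter(q)
        assert ("W", 182) in res.excluded
        assert "blank-exceeds-sample" in res.reasons[("W", 182)]

    def test_flat_channel_excluded_for_no_sample_effect(self):
        q = self._quant(wine_level=1.0, blank_level=1.0, truth_varies=False)
        res = blank_compromise_filter(q)
        assert ("W", 182) in res.excluded
        assert "no-sample-effect" in res.reasons[("W", 182)]

    def test_clean_high_signal_channel_retained(self):
        q = self._quant(wine_level=100.0, blank_level=0.5)
        res = blank_compromise_filter(q)
        assert ("W", 182) not in res.excluded

    def test_missing_blanks_rejected(self):
        q = self._quant(1.0, 1.0)
        with pytest.raises(Exception):
            blank_compromise_filter(q[q["role"] == "sample"])


class TestPCA:
    def test_two_perfectly_correlated_columns(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame({"a": x, "b": 10 * x + 3})
        res = pca_profiles(m)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_retained_columns(self, noisy_quant):
        matrix = profile_matrix(noisy_quant.quant)
        res = pca_profiles(matrix)
        p = matrix.shape[1] - len(res.dropped)
        assert res.explained_fraction.sum() == pytest.approx(1.0)
        # correlation-matrix trace: eigenvalues sum to the column count
        Z = (matrix - matrix.mean()) / matrix.std(ddof=1)
        corr = np.asarray(Z.T @ Z) / (len(Z) - 1)
        assert np.trace(corr) == pytest.approx(p, rel=1e-9)

    def test_two_column_closed_form(self):
        # correlation matrix [[1, r], [r, 1]] has eigenvalues 1 ± r
        m = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.1, 0.9, 2.2]})
        r = np.corrcoef(m["a"], m["b"])[0, 1]
        res = pca_profiles(m)
        frac = res.explained_fraction
        assert frac[0] == pytest.approx((1 + abs(r)) / 2, rel=1e-9)
        assert frac[1] == pytest.approx((1 - abs(r)) / 2, rel=1e-9)

    def test_scores_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        res1 = pca_profiles(m)
        m2 = m * np.array([10.0, 0.1, 3.0, 7.0]) + np.array([1.0, -5.0, 0.0, 2.0])
        res2 = pca_profiles(m2)
        np.testing.assert_allclose(
            res1.scores.to_numpy(), res2.scores.to_numpy(), atol=1e-9
        )

    def test_zero_variance_column_dropped_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0],
                          "c": [2.0, 1.0, 4.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_profiles(m)
        assert res.dropped == ["b"]

    def test_wines_cluster_after_blank_filter(self, noisy_quant):
        """Within-wine profiles (all four prep methods) sit closer together
        in PC space than profiles of different wines."""
        res = blank_compromise_filter(noisy_quant.quant)
        matrix = profile_matrix(noisy_quant.quant, exclude=res.excluded)
        pca = pca_profiles(matrix)
        sc = pca.scores[["PC1", "PC2", "PC3"]].to_numpy()
        wines = pca.scores.index.get_level_values("wine").to_numpy()
        d = np.linalg.norm(sc[:, None, :] - sc[None, :, :], axis=2)
        iu = np.triu_indices(len(sc), 1)
        same = (wines[:, None] == wines[None, :])[iu]
        assert d[iu][same].mean() < d[iu][~same].mean()


class TestSummarizeRSD:
    def test_zero_noise_gives_zero_rsd(self, noise_free_quant):
        rsds = summarize_rsd(noise_free_quant.quant)
        assert (rsds.abs() < 1e-6).all()

    def test_censored_cells_excluded(self):
        rows = []
        for rep in range(1, 4):
            rows.append({"wine": "C", "method": "DD", "replicate": rep,
                         "role": "sample", "element": "Mn", "mass": 55,
                         "concentration": 10.0 + rep, "censored": False})
            rows.append({"wine": "C", "method": "DD", "replicate": rep,
                         "role": "sample", "element": "U", "mass": 238,
                         "concentration": 0.05, "censored": rep == 2})
        q = pd.DataFrame(rows)
        rsds = summarize_rsd(q)
        # only the uncensored Mn cell contributes
        from vinomics.quant import rsd as rsd_fn

        assert rsds["DD"] == pytest.approx(rsd_fn([11.0, 12.0, 13.0]))

    def test_mw_noisier_than_direct_methods_at_study_cvs(self, truth):
        """Averaged over batches the per-method mean replicate RSD tracks the
        generating CV (down-biased by the n=3 sample-SD factor c4 ≈ 0.886):
        microwave digestion ≈ 26%, direct methods ≈ 10–16%."""
        import warnings

        from vinomics.core import default_channels
        from vinomics.quant import quantify_batch
        from vinomics.simulate import (
            BatchDesign, InstrumentParams, MethodEffectParams, simulate_batch,
        )

        channels = [
            ch for ch in default_channels()
            if ch.element in ("Mn", "Rb", "Cu", "Sr", "Zn")
        ]
        per_method = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(20):
                batch = simulate_batch(
                    BatchDesign(include_spikes=False, include_qc=False),
                    truth, MethodEffectParams.default(), InstrumentParams(),
                    seed=100 + seed, channels=channels,
                )
                out = quantify_batch(batch)
                per_method.append(summarize_rsd(out.quant))
        mean = pd.concat(per_method, axis=1).mean(axis=1)
        assert 20.0 < mean["MW"] < 32.0
        for m in ("DD", "FA", "AF"):
            assert 8.0 < mean[m] < 20.0
            assert mean[m] < mean["MW"]
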