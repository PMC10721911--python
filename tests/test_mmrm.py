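"""MMRM engine: oracles (weighted ANCOVA, quadrature Tukey), invariances, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate, stats
from scipy.special import gammaln

from pswtrial.mmrm import (
    MmrmError,
    comparisons_to_frame,
    effect_size,
    fit_mmrm,
    ls_means,
    prepare_long_dataset,
    treatment_effects,
    tukey_adjusted_p,
    _neg2_reml,
)
from pswtrial.simulate import (
    MADRS,
    Arm,
    ClassLabel,
    ResponderClass,
    TrialDesign,
    generate_trial,
)

from conftest import subject_from_totals


def single_visit_frame(n: int = 40, seed: int = 3, weights: bool = True) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        arm = "placebo" if i < n // 2 else "active"
        base = rng.normal(25, 4)
        y = -5 - (3 if arm == "active" else 0) + 0.3 * base + rng.normal(0, 4)
        rows.append(
            dict(
                subject_id=f"S{i:03d}",
                arm=arm,
                visit_week=8.0,
                change_from_baseline=y,
                baseline_total=base,
                weight=rng.uniform(0.5, 3) if weights else 1.0,
            )
        )
    return pd.DataFrame(rows)


def multi_visit_frame(n: int = 30, seed: int = 5) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        arm = ("placebo", "a1", "a2")[i % 3]
        base = rng.normal(26, 4)
        u = rng.normal(0, 2)
        subj_weight = rng.uniform(0.5, 2)
        for w, frac in ((2.0, 0.4), (4.0, 0.8), (6.0, 1.0)):
            y = frac * (-6 - (4 if arm != "placebo" else 0) + 0.2 * base + u)
            y += rng.normal(0, 2)
            rows.append(
                dict(subject_id=f"S{i:03d}", arm=arm, visit_week=w,
                     change_from_baseline=y, baseline_total=base,
                     weight=subj_weight)
            )
    return pd.DataFrame(rows)


class TestPrepare:
    def test_change_from_baseline_arithmetic_and_unit_weights(self):
        subj = subject_from_totals("S1", "placebo", {-1.0: 31, 0.0: 30, 8.0: 18}, MADRS)
        other = subject_from_totals("S2", "active", {-1.0: 29, 0.0: 28, 8.0: 20}, MADRS)
        ds = prepare_long_dataset([subj, other], None, 8.0)
        row = ds.data.set_index("subject_id").loc["S1"]
        assert row["change_from_baseline"] == -12.0
        assert (ds.data["weight"] == 1.0).all()

    def test_subject_without_post_baseline_is_dropped_and_counted(self):
        subs = [
            subject_from_totals("S1", "placebo", {-1.0: 30, 0.0: 30, 8.0: 10}, MADRS),
            subject_from_totals("S2", "active", {-1.0: 30, 0.0: 30, 8.0: 12}, MADRS),
            subject_from_totals("S3", "active", {-1.0: 30, 0.0: 30}, MADRS),
        ]
        ds = prepare_long_dataset(subs, None, 8.0)
        assert ds.n_dropped_no_post_baseline == 1
        assert set(ds.data["subject_id"]) == {"S1", "S2"}

    def test_missing_score_for_retained_subject_errors(self):
        from pswtrial.propensity import PropensityScores

        subs = [
            subject_from_totals("S1", "placebo", {-1.0: 30, 0.0: 30, 8.0: 10}, MADRS),
            subject_from_totals("S2", "active", {-1.0: 30, 0.0: 30, 8.0: 12}, MADRS),
        ]
        scores = PropensityScores(
            table=pd.DataFrame(
                {"subject_id": ["S1"], "arm": ["placebo"], "p": [0.5],
                 "w_raw": [2.0], "w": [2.0]}
            ),
            p_floor=0.05,
            renormalized=False,
        )
        with pytest.raises(MmrmError):
            prepare_long_dataset(subs, scores, 8.0)


class TestFitOracle:
    def test_weighted_single_visit_equals_weighted_ancova(self):
        """With one visit and complete data, the REML fit collapses to WLS."""
        df = single_visit_frame()
        fit = fit_mmrm(df, normalize_weights=False)
        te = treatment_effects(fit, 8.0, "placebo")[0]
        X = np.column_stack(
            [np.ones(len(df)), df.baseline_total, (df.arm == "active").astype(float)]
        )
        wls = sm.WLS(df.change_from_baseline, X, weights=df.weight).fit()
        assert te.te == pytest.approx(-wls.params.iloc[2], abs=1e-8)
        assert te.std_err == pytest.approx(wls.bse.iloc[2], abs=1e-8)
        assert te.df == pytest.approx(wls.df_resid, rel=1e-3)
        assert te.p_adjusted == pytest.approx(wls.pvalues.iloc[2], rel=1e-4)

    def test_identical_arms_give_zero_te(self):
        changes = [-2.0, -7.5, -1.0, -9.0, -4.0, -6.5, 0.5, -3.0]
        bases = [25.0, 27.0, 22.0, 30.0, 26.0, 24.0, 28.0, 23.0]
        rows = []
        for i in range(8):
            for arm in ("placebo", "active"):
                rows.append(
                    dict(subject_id=f"{arm}{i}", arm=arm, visit_week=4.0,
                         change_from_baseline=changes[i], baseline_total=bases[i],
                         weight=1.0)
                )
        fit = fit_mmrm(pd.DataFrame(rows))
        te = treatment_effects(fit, 4.0, "placebo")[0]
        assert te.te == pytest.approx(0.0, abs=1e-8)

    def test_reml_objective_is_a_local_minimum(self, rng):
        """Profiling check: no random perturbation improves the REML objective."""
        df = multi_visit_frame()
        fit = fit_mmrm(df)
        T, p = len(fit.visit_weeks), len(fit.beta)
        for _ in range(50):
            theta = fit.theta + rng.normal(0, 0.05, size=len(fit.theta))
            assert _neg2_reml(theta, fit._patterns, T, p) >= fit.neg2_reml - 1e-6


class TestInvariances:
    def test_weight_rescaling_leaves_all_outputs_unchanged(self):
        df = multi_visit_frame()
        base = treatment_effects(fit_mmrm(df), 6.0, "placebo")
        scaled = treatment_effects(fit_mmrm(df.assign(weight=df.weight * 37.5)), 6.0, "placebo")
        for a, b in zip(base, scaled):
            assert a.te == pytest.approx(b.te, abs=1e-6)
            assert a.std_err == pytest.approx(b.std_err, abs=1e-6)
            assert a.effect_size == pytest.approx(b.effect_size, abs=1e-6)
            assert a.p_adjusted == pytest.approx(b.p_adjusted, abs=1e-6)

    def test_raw_weight_convention_scales_covariance_proportionally(self):
        df = multi_visit_frame()
        f1 = fit_mmrm(df, normalize_weights=False)
        f2 = fit_mmrm(df.assign(weight=df.weight * 10), normalize_weights=False)
        np.testing.assert_allclose(
            f2.Sigma.to_numpy(), 10.0 * f1.Sigma.to_numpy(), rtol=1e-4
        )
        np.testing.assert_allclose(
            f1.beta.to_numpy(), f2.beta.to_numpy(), atol=1e-6
        )

    def test_unit_weights_reproduce_reference_analysis_exactly(self):
        df = multi_visit_frame().assign(weight=1.0)
        f1 = fit_mmrm(df)
        f2 = fit_mmrm(df.copy())
        np.testing.assert_array_equal(f1.beta.to_numpy(), f2.beta.to_numpy())
        np.testing.assert_array_equal(f1.Sigma.to_numpy(), f2.Sigma.to_numpy())

    def test_translation_equivariance_of_ls_means(self):
        df = multi_visit_frame()
        c = 7.25
        f1, f2 = fit_mmrm(df), fit_mmrm(df.assign(change_from_baseline=df.change_from_baseline + c))
        m1, m2 = ls_means(f1), ls_means(f2)
        np.testing.assert_allclose(m2["lsmean"], m1["lsmean"] + c, atol=1e-5)
        t1 = treatment_effects(f1, 6.0, "placebo")
        t2 = treatment_effects(f2, 6.0, "placebo")
        for a, b in zip(t1, t2):
            assert a.te == pytest.approx(b.te, abs=1e-5)


class TestLsMeans:
    def test_shape_is_arms_by_visits(self):
        fit = fit_mmrm(multi_visit_frame())
        table = ls_means(fit)
        assert len(table) == len(fit.arms) * len(fit.visit_weeks)
        assert set(table.columns) == {"arm", "visit_week", "lsmean", "se"}
        assert (table["se"] > 0).all()

    def test_mirrored_baselines_collapse_ls_means_to_raw_arm_means(self):
        """When baseline distributions are identical across arms, the adjusted
        means equal the observed arm means at each visit."""
        rng = np.random.default_rng(11)
        bases = rng.normal(25, 3, size=12)
        rows = []
        for arm, shift in (("placebo", 0.0), ("active", -3.0)):
            for i, b in enumerate(bases):
                for w, frac in ((3.0, 0.5), (6.0, 1.0)):
                    rows.append(
                        dict(subject_id=f"{arm}{i}", arm=arm, visit_week=w,
                             change_from_baseline=frac * (shift - 5) + rng.normal(0, 1)
                             + 0.1 * b,
                             baseline_total=b, weight=1.0)
                    )
        df = pd.DataFrame(rows)
        fit = fit_mmrm(df)
        table = ls_means(fit).set_index(["arm", "visit_week"])
        raw = df.groupby(["arm", "visit_week"])["change_from_baseline"].mean()
        for key in raw.index:
            assert table.loc[key, "lsmean"] == pytest.approx(raw.loc[key], abs=1e-6)

    def test_unscheduled_visit_rejected(self):
        fit = fit_mmrm(multi_visit_frame())
        with pytest.raises(MmrmError):
            ls_means(fit, 99.0)


def studentized_range_cdf_by_quadrature(q: float, k: int, df: float) -> float:
    """Independent quadrature oracle for the studentized range CDF."""

    def range_cdf_given_scale(s):
        integrand = lambda z: (
            k * stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (k - 1)
        )
        val, _ = integrate.quad(integrand, -8.5, 8.5, limit=200)
        return val

    logc = (df / 2) * np.log(df / 2) - gammaln(df / 2) + np.log(2.0)
    chi_scale_pdf = lambda s: np.exp(logc + (df - 1) * np.log(s) - df * s * s / 2)
    val, _ = integrate.quad(
        lambda s: chi_scale_pdf(s) * range_cdf_given_scale(s), 1e-9, 10, limit=200
    )
    return val


class TestTukey:
    def test_two_arms_reduce_to_plain_t_test(self):
        for t in (0.5, 1.8, 2.7):
            assert tukey_adjusted_p(t, 2, 60) == pytest.approx(
                2 * stats.t.sf(t, 60), rel=1e-12
            )

    def test_adjusted_never_below_unadjusted(self):
        for t in (0.2, 1.0, 2.0, 3.5):
            for k in (2, 3, 4):
                assert tukey_adjusted_p(t, k, 80) >= 2 * stats.t.sf(t, 80) - 1e-12

    def test_matches_quadrature_of_studentized_range_cdf(self):
        t, k, df = 2.5, 4, 100
        oracle = 1.0 - studentized_range_cdf_by_quadrature(np.sqrt(2) * t, k, df)
        assert tukey_adjusted_p(t, k, df) == pytest.approx(oracle, abs=1e-4)


class TestEffectSize:
    def test_absolute_ratio(self):
        assert effect_size(4.104, 7.990) == pytest.approx(0.514, abs=5e-4)
        assert effect_size(-0.466, 7.849) == pytest.approx(0.059, abs=5e-4)
        assert effect_size(0.0, 5.0) == 0.0

    def test_requires_positive_sd(self):
        with pytest.raises(ValueError):
            effect_size(1.0, 0.0)


def test_te_estimator_recovers_known_drug_effect_without_confounding():
    """All-drug-responder mixture, no placebo propensity: TE is unbiased."""
    delta, noise_sd = 8.0, 6.0
    design = TrialDesign(
        arms=(Arm("placebo", 0.0), Arm("active", delta)),
        n_per_arm=40,
        visit_weeks=(-1.0, 0.0, 3.0, 6.0),
        eos_week=6.0,
        class_mix=(ResponderClass(ClassLabel.DplusPminus, 1.0),),
        dropout_rate=0.0,
        noise_sd=noise_sd,
    )
    estimates = []
    for r in range(150):
        subjects = generate_trial(design, MADRS, 9000 + r)
        fit = fit_mmrm(prepare_long_dataset(subjects, None, 6.0),
                       df_method="between_within")
        estimates.append(treatment_effects(fit, 6.0, "placebo")[0].te)
    assert abs(np.mean(estimates) - delta) < 0.1 * noise_sd


class TestErrors:
    def test_single_arm_rejected(self):
        df = single_visit_frame().assign(arm="placebo")
        with pytest.raises(MmrmError):
            fit_mmrm(df)

    def test_nonpositive_weights_rejected(self):
        df = single_visit_frame()
        df.loc[0, "weight"] = 0.0
        with pytest.raises(MmrmError):
            fit_mmrm(df)

    def test_varying_weights_within_subject_rejected(self):
        df = multi_visit_frame()
        df.loc[0, "weight"] = df.loc[0, "weight"] + 1.0
        with pytest.raises(MmrmError):
            fit_mmrm(df)

    def test_comparisons_frame_schema(self):
        fit = fit_mmrm(multi_visit_frame())
        frame = comparisons_to_frame(treatment_effects(fit, 6.0, "placebo"))
        assert list(frame.columns) == ["Comparison", "TE", "StdErr", "P", "SD", "Effect_size"]
        assert len(frame) == 2
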