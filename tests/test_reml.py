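"""REML estimator: balanced-ANOVA oracle, cross-checks and BLUP behaviour."""
import numpy as np
import pandas as pd
import pytest

import halfsib as h
from halfsib.reml import HalfSibTrialModel, _fit_sparse_mme


def anova_components(df: pd.DataFrame, n_loc: int, n_seas: int, n_year: int,
                     n_rep: int) -> dict:
    """Closed-form expected-mean-squares estimators for the balanced design.

    Independent oracle: moment equations from the classical ANOVA strata of
    the crossed family × (location, season, year) model with replicates.
    """
    n = len(df)
    obs_per_fam = n_loc * n_seas * n_year * n_rep
    gm = df["value"].mean()
    fm = df.groupby("family")["value"].mean()
    F = len(fm)
    ms_f = obs_per_fam * fm.var(ddof=1)

    def inter_ms(fac, nlev):
        nobs = obs_per_fam // nlev
        cm = df.groupby(["family", fac])["value"].mean()
        facm = df.groupby(fac)["value"].mean()
        dev = (cm - fm.reindex(cm.index.get_level_values(0)).to_numpy()
               - facm.reindex(cm.index.get_level_values(1)).to_numpy() + gm)
        return nobs * (dev ** 2).sum() / ((F - 1) * (nlev - 1))

    ms_fl = inter_ms("location", n_loc)
    ms_fs = inter_ms("season", n_seas)
    ms_fy = inter_ms("year", n_year)

    ss_tot = ((df["value"] - gm) ** 2).sum()
    ss_f = obs_per_fam * ((fm - gm) ** 2).sum()
    parts = 0.0
    for fac, nlev in (("location", n_loc), ("season", n_seas), ("year", n_year)):
        facm = df.groupby(fac)["value"].mean()
        parts += (n // nlev) * ((facm - gm) ** 2).sum()
    ss_inter = (ms_fl * (F - 1) * (n_loc - 1) + ms_fs * (F - 1) * (n_seas - 1)
                + ms_fy * (F - 1) * (n_year - 1))
    df_res = (n - 1 - (F - 1) - (n_loc - 1) - (n_seas - 1) - (n_year - 1)
              - (F - 1) * (n_loc - 1 + n_seas - 1 + n_year - 1))
    ms_e = (ss_tot - ss_f - parts - ss_inter) / df_res

    c_l, c_s, c_y = (obs_per_fam // n_loc, obs_per_fam // n_seas,
                     obs_per_fam // n_year)
    s_fl = (ms_fl - ms_e) / c_l
    s_fs = (ms_fs - ms_e) / c_s
    s_fy = (ms_fy - ms_e) / c_y
    s_f = (ms_f - ms_e - c_l * s_fl - c_s * s_fs - c_y * s_fy) / obs_per_fam
    return {"family": s_f, "family:location": s_fl, "family:season": s_fs,
            "family:year": s_fy, "residual": ms_e}


@pytest.fixture(scope="module")
def interior_trial():
    """Balanced trial whose ANOVA solution is interior (all estimates > 0)."""
    vc = h.VarianceComponents(18000.0, 25000.0, 14000.0, 40000.0, 120000.0)
    design = h.TrialDesign(2, 3, 2, 3, 150)
    df = h.generate_trial(h.MockTrialSpec(
        design=design, components=vc, mean=3262.0, seed=7,
        fixed_effects={"location": [0.0, 180.0], "season": [0.0, -120.0, 90.0],
                       "year": [0.0, 70.0]}))
    return df, design


class TestOracleEquivalence:
    def test_balanced_reml_equals_anova(self, interior_trial):
        df, design = interior_trial
        oracle = anova_components(df, design.n_locations, design.n_seasons,
                                  design.n_years, design.n_reps)
        assert all(v > 0 for v in oracle.values())  # interior solution
        res = h.fit_reml(df)
        assert res.converged
        for term, truth in oracle.items():
            assert res.params[term] == pytest.approx(truth, rel=1e-6)

    def test_sparse_route_matches_block_route(self, interior_trial):
        df, _ = interior_trial
        block = h.fit_reml(df)
        sparse = _fit_sparse_mme(HalfSibTrialModel(df), 500, 1e-10, None)
        assert sparse.llf == pytest.approx(block.llf, abs=1e-5)
        for term, v in block.params.items():
            assert sparse.params[term] == pytest.approx(v, rel=1e-3)

    def test_mixedlm_cross_check(self, interior_trial):
        """statsmodels MixedLM (family-grouped variance components) agrees."""
        import statsmodels.formula.api as smf

        df, _ = interior_trial
        sub = df[df["family"] < 60].copy()
        md = smf.mixedlm(
            "value ~ C(location) + C(season) + C(year)", sub,
            groups="family", re_formula="1",
            vc_formula={"fl": "0 + C(location)", "fs": "0 + C(season)",
                        "fy": "0 + C(year)"})
        sm_fit = md.fit(reml=True)
        ours = h.fit_reml(sub)
        assert ours.params["residual"] == pytest.approx(sm_fit.scale, rel=1e-3)
        sm_vc = dict(zip(["fl", "fs", "fy"], sm_fit.vcomp))
        assert ours.params["family"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=5e-3)
        assert ours.params["family:location"] == pytest.approx(sm_vc["fl"], rel=5e-3)
        assert ours.params["family:season"] == pytest.approx(sm_vc["fs"], rel=5e-3)
        assert ours.params["family:year"] == pytest.approx(sm_vc["fy"], rel=5e-3)


class TestInvariances:
    def test_record_order_invariance(self, interior_trial):
        df, _ = interior_trial
        res1 = h.fit_reml(df)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        res2 = h.fit_reml(shuffled)
        for term, v in res1.params.items():
            assert res2.params[term] == pytest.approx(v, rel=1e-10)

    def test_pure_noise_family_variance_at_boundary(self):
        rng = np.random.default_rng(5)
        df = h.generate_trial(h.MockTrialSpec(
            design=h.TrialDesign(2, 2, 2, 2, 60),
            components=h.VarianceComponents(0, 0, 0, 0, 10000.0),
            mean=1000.0, seed=int(rng.integers(1 << 30))))
        res = h.fit_reml(df)
        assert res.params["family"] < 500.0  # essentially zero


class TestFamilyBlups:
    def test_shrinkage_towards_mean(self, interior_trial):
        df, _ = interior_trial
        res = h.fit_reml(df)
        raw_dev = df.groupby("family")["value"].mean() - df["value"].mean()
        eff = res.family_effects()
        assert eff.abs().mean() < raw_dev.abs().mean()
        assert eff.mean() == pytest.approx(0.0, abs=1.0)

    def test_zero_residual_limit_equals_raw_means(self):
        # interactions and residual ≈ 0: family means are measured exactly
        vc = h.VarianceComponents(10000.0, 0, 0, 0, 1.0)
        df = h.generate_trial(h.MockTrialSpec(
            design=h.TrialDesign(2, 2, 1, 2, 40), components=vc,
            mean=500.0, seed=2))
        res = h.fit_reml(df, terms=("family",))
        raw = df.groupby("family")["value"].mean()
        assert np.allclose(res.family_blups().to_numpy(), raw.to_numpy(),
                           atol=0.5)

    def test_blups_track_true_effects(self):
        vc = h.VarianceComponents(14170.0, 2222.0, 13406.0, 38511.0, 221768.0)
        df, true_eff = h.generate_trial(h.MockTrialSpec(
            design=h.TrialDesign(2, 3, 2, 3, 200), components=vc,
            mean=3262.0, seed=9), return_effects=True)
        res = h.fit_reml(df)
        r = np.corrcoef(res.family_effects().to_numpy(), true_eff)[0, 1]
        assert r > 0.5


class TestComponentExport:
    def test_round_trip_identity(self, interior_trial):
        df, _ = interior_trial
        res = h.fit_reml(df)
        vc = res.to_variance_components()
        assert vc.family == res.params["family"]
        assert vc.residual == res.params["residual"]

    def test_refuses_unconverged(self, interior_trial):
        df, _ = interior_trial
        res = h.fit_reml(df)
        res.converged = False
        with pytest.raises(ValueError):
            res.to_variance_components()


class TestFullPlotModel:
    def test_rep_row_col_terms(self):
        vc = h.VarianceComponents(14000.0, 8000.0, 12000.0, 10000.0, 50000.0)
        df = h.generate_trial(h.MockTrialSpec(
            design=h.TrialDesign(2, 2, 2, 2, 40), components=vc, mean=3000.0,
            seed=5, rep_variance=6000.0, row_variance=3000.0))
        res = h.fit_reml(df, terms=h.reml.ALL_TERMS[:6])  # through 'row'
        assert res.converged
        assert res.params["rep"] > 0
        assert res.params["residual"] == pytest.approx(50000.0, rel=0.5)

    def test_summary_renders(self, interior_trial):
        df, _ = interior_trial
        text = h.fit_reml(df).summary()
        assert "Variance components" in text and "family" in text


class TestValidation:
    def test_requires_two_families(self):
        df = pd.DataFrame({"family": [0, 0], "location": [0, 1],
                           "season": [0, 0], "year": [0, 0],
                           "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            HalfSibTrialModel(df)

    def test_rejects_nonfinite_response(self):
        df = pd.DataFrame({"family": [0, 1], "location": [0, 0],
                           "season": [0, 0], "year": [0, 0],
                           "value": [1.0, np.nan]})
        with pytest.raises(ValueError):
            HalfSibTrialModel(df)

    def test_rejects_duplicate_plots(self):
        df = pd.DataFrame({
            "family": [0, 1], "location": [0, 0], "season": [0, 0],
            "year": [0, 0], "rep": [0, 0], "row": [0, 0], "col": [0, 0],
            "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            HalfSibTrialModel(df, terms=("family", "rep"))

    def test_unknown_term(self):
        df = pd.DataFrame({"family": [0, 1], "location": [0, 0],
                           "season": [0, 0], "year": [0, 0],
                           "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            HalfSibTrialModel(df, terms=("family", "plot"))
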