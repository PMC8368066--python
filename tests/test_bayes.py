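import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from seminfer import bayes
from seminfer.discrimination import CAUSATIVES, NONCAUSATIVES

QUICK = dict(chains=2, draws=400, warmup=400)


def simulate_rows(seed, intercept=0.05, effects=None, verb_sd=0.02,
                  resid_sd=0.05, predictor="genre", levels=("cds", "ads", "wr")):
    """Rows from the generating model the regression assumes."""
    rng = np.random.default_rng(seed)
    effects = effects if effects is not None else {"cds": 0.0, "ads": -0.08,
                                                   "wr": -0.08}
    b = {v: rng.multivariate_normal(np.zeros(len(levels)),
                                    verb_sd**2 * np.eye(len(levels)))
         for v in CAUSATIVES}
    c = {v: rng.multivariate_normal(np.zeros(len(levels)),
                                    verb_sd**2 * np.eye(len(levels)))
         for v in NONCAUSATIVES}
    rows = []
    for li, level in enumerate(levels):
        for ci in CAUSATIVES:
            for nj in NONCAUSATIVES:
                y = (intercept + effects[level] + b[ci][0] + c[nj][0]
                     + (b[ci][li] + c[nj][li] if li > 0 else 0.0)
                     + rng.normal(0, resid_sd))
                rows.append({"response": y, predictor: level,
                             "caus": ci, "noncaus": nj})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def genre_fit():
    df = simulate_rows(seed=42)
    return df, bayes.fit_hierarchical(df, "genre", seed=1, **QUICK)


class TestFitHierarchical:
    def test_recovers_generating_fixed_effects(self, genre_fit):
        _, post = genre_fit
        s = post.summary()
        assert s.loc["intercept", "mean"] == pytest.approx(0.05, abs=0.03)
        assert s.loc["genre[ads]", "mean"] == pytest.approx(-0.08, abs=0.03)
        assert s.loc["sigma", "mean"] == pytest.approx(0.05, abs=0.015)

    def test_reference_level_is_cds(self, genre_fit):
        _, post = genre_fit
        assert post.fixed_names == ["intercept", "genre[ads]", "genre[wr]"]

    def test_null_response_concentrates_at_zero(self):
        df = simulate_rows(seed=3, intercept=0.0,
                           effects={"cds": 0, "ads": 0, "wr": 0},
                           verb_sd=0.0, resid_sd=1e-6)
        df["response"] = 0.0
        post = bayes.fit_hierarchical(df, "genre", seed=2, **QUICK)
        s = post.summary()
        for p in ("intercept", "genre[ads]", "genre[wr]"):
            assert abs(s.loc[p, "mean"]) < 1e-3
            assert 0.2 < s.loc[p, "prob_above_zero"] < 0.8

    def test_deterministic_given_seed(self):
        df = simulate_rows(seed=5, levels=("cds", "ads"))
        a = bayes.fit_hierarchical(df, "genre", seed=9, chains=1, draws=50,
                                   warmup=50)
        b = bayes.fit_hierarchical(df, "genre", seed=9, chains=1, draws=50,
                                   warmup=50)
        assert np.array_equal(a.draws["genre[ads]"], b.draws["genre[ads]"])

    def test_swapping_reference_negates_coefficient(self):
        df = simulate_rows(seed=6, levels=("cds", "ads"),
                           effects={"cds": 0.0, "ads": -0.08})
        fwd = bayes.fit_hierarchical(df, "genre", seed=4, reference="cds",
                                     **QUICK)
        rev = bayes.fit_hierarchical(df, "genre", seed=5, reference="ads",
                                     **QUICK)
        m_fwd = fwd.draws["genre[ads]"].mean()
        m_rev = rev.draws["genre[cds]"].mean()
        assert m_fwd == pytest.approx(-m_rev, abs=0.02)

    def test_single_level_predictor_rejected(self):
        df = simulate_rows(seed=7, levels=("cds",), effects={"cds": 0.0})
        with pytest.raises(bayes.FitError):
            bayes.fit_hierarchical(df, "genre", seed=0, chains=1, draws=10,
                                   warmup=10)

    def test_fixed_effects_agree_with_lme4_reference(self, genre_fit, tmp_path):
        df, post = genre_fit
        csv = tmp_path / "rows.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            d$genre <- relevel(factor(d$genre), ref='cds')
            m <- lmer(response ~ genre + (1 + genre | caus)
                      + (1 + genre | noncaus), data=d)
            cat(fixef(m), sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = [float(x) for x in out.stdout.strip().splitlines()]
        s = post.summary()
        mine = [s.loc["intercept", "mean"], s.loc["genre[ads]", "mean"],
                s.loc["genre[wr]", "mean"]]
        # weak priors: posterior means should sit on the REML estimates
        assert mine == pytest.approx(ref, abs=0.01)


class TestSummarize:
    def test_prob_above_zero_symmetric_draws(self):
        draws = np.random.default_rng(0).normal(size=(2, 2000))
        lo, hi = bayes.hpd_interval(draws, 0.90)
        assert lo == pytest.approx(-1.645, abs=0.12)
        assert hi == pytest.approx(1.645, abs=0.12)

    def test_all_positive_draws(self):
        x = np.abs(np.random.default_rng(1).normal(size=(1, 500))) + 0.1
        assert float((x > 0).mean()) == 1.0
        lo, hi = bayes.hpd_interval(x, 0.8)
        assert lo > 0

    def test_hpd_mass_covers_requested_fraction(self):
        x = np.random.default_rng(2).normal(size=5000)
        for mass in (0.8, 0.9):
            lo, hi = bayes.hpd_interval(x, mass)
            assert ((x >= lo) & (x <= hi)).mean() == pytest.approx(mass,
                                                                   abs=0.01)


class TestMeasurementError:
    def test_small_error_recovers_plain_fit(self):
        df = simulate_rows(seed=8, levels=("cds", "ads"))
        plain = bayes.fit_hierarchical(df, "genre", seed=3, **QUICK)
        me = bayes.measurement_error_variant(df, "genre", baseline_sd=1e-6,
                                             seed=3, **QUICK)
        assert me.draws["genre[ads]"].mean() == pytest.approx(
            plain.draws["genre[ads]"].mean(), abs=0.01)

    def test_larger_error_widens_intervals(self):
        # widening is only visible once the stated error dominates the
        # fixture's own noise; below that, known error merely relabels part
        # of the residual variance and the fixed-effect width is unchanged
        df = simulate_rows(seed=9, levels=("cds", "ads"), verb_sd=0.005,
                           resid_sd=0.005)
        widths = []
        for sd in (0.001, 0.03, 0.08):
            post = bayes.measurement_error_variant(
                df, "genre", baseline_sd=sd, seed=4, chains=2, draws=300,
                warmup=300)
            lo, hi = bayes.hpd_interval(post.draws["genre[ads]"], 0.90)
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_nonpositive_sd_rejected(self):
        df = simulate_rows(seed=10, levels=("cds", "ads"))
        with pytest.raises(ValueError):
            bayes.measurement_error_variant(df, "genre", baseline_sd=0.0)


class TestCompareModels:
    def test_identical_models_split_the_weight(self):
        df = simulate_rows(seed=11, levels=("cds", "ads"))
        a = bayes.fit_hierarchical(df, "genre", seed=6, name="a", **QUICK)
        b = bayes.fit_hierarchical(df, "genre", seed=6, name="b", **QUICK)
        comp = bayes.compare_models([a, b], seed=0)
        assert comp["weight"].sum() == pytest.approx(1.0)
        assert comp["weight"].min() == pytest.approx(0.5, abs=0.05)

    def test_true_model_dominates_null(self):
        df = simulate_rows(seed=12, levels=("cds", "ads"),
                           effects={"cds": 0.0, "ads": -0.3}, resid_sd=0.05)
        fit = bayes.fit_hierarchical(df, "genre", seed=8, name="genre", **QUICK)
        null = bayes.fit_hierarchical(df, None, seed=9, name="null", **QUICK)
        comp = bayes.compare_models([fit, null], seed=1)
        assert comp.loc["genre", "weight"] > 0.9

    def test_mismatched_data_rejected(self):
        df1 = simulate_rows(seed=13, levels=("cds", "ads"))
        fit1 = bayes.fit_hierarchical(df1, "genre", seed=1, chains=1, draws=50,
                                      warmup=50, name="a")
        fit2 = bayes.fit_hierarchical(df1.sample(100, random_state=0), "genre",
                                      seed=2,
                                      chains=1, draws=50, warmup=50, name="b")
        with pytest.raises(bayes.FitError):
            bayes.compare_models([fit1, fit2])
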