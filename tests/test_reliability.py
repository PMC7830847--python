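"""Provider reliability: the closed-form signal-to-noise ratio, its limits
and monotonicity, and variance-component recovery of the hierarchical
logistic fit (including an lme4 cross-check)."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from lungqi.reliability import (
    fit_hierarchical,
    indicator_reliability,
    provider_reliability,
    summarize_reliability,
)


def simulate_outcomes(n_providers, n_per, tau2, seed, p0=0.5, covariates=False):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(tau2), size=n_providers)
    rows = []
    for j in range(n_providers):
        x = rng.integers(0, 2, size=n_per) if covariates else np.zeros(n_per)
        p = expit(logit(p0) + u[j] + 0.5 * x)
        y = rng.random(n_per) < p
        for yi, xi in zip(y, x):
            rows.append({"provider": f"P{j:03d}", "outcome": int(yi), "sex": "M" if xi else "F"})
    return pd.DataFrame(rows)


def tau2_moments(df):
    """Method-of-moments oracle: between-provider variance of empirical
    logits minus the mean binomial sampling variance on the logit scale."""
    g = df.groupby("provider")["outcome"].agg(["sum", "size"])
    p = (g["sum"] + 0.5) / (g["size"] + 1.0)
    l = np.log(p / (1 - p))
    sampling = (1.0 / (g["size"] * p * (1 - p))).mean()
    return max(0.0, l.var(ddof=1) - sampling)


class TestProviderReliability:
    def test_closed_form_value(self):
        # tau_p^2 = 0.5 * 0.25^2 = 0.03125; noise = 0.25/100
        rel = provider_reliability(0.5, 0.5, 100)
        assert rel == pytest.approx(100 * 0.03125 / (0.03125 + 0.0025), abs=1e-9)
        assert rel == pytest.approx(92.59, abs=0.01)

    def test_zero_signal_gives_zero(self):
        assert provider_reliability(0.0, 0.3, 50) == 0.0

    def test_limit_to_100_with_caseload(self):
        rel = provider_reliability(0.5, 0.5, np.array([10, 100, 10_000, 10_000_000]))
        assert np.all(np.diff(rel) > 0)
        assert rel[-1] > 99.99

    def test_monotone_in_tau2_and_bounded(self):
        rels = [provider_reliability(t, 0.4, 30) for t in (0.05, 0.1, 0.5, 1.0, 5.0)]
        assert all(0 <= r <= 100 for r in rels)
        assert all(b > a for a, b in zip(rels, rels[1:]))

    def test_degenerate_proportion_undefined(self):
        assert np.isnan(provider_reliability(0.5, 0.0, 10))
        assert np.isnan(provider_reliability(0.5, 1.0, 10))

    def test_logit_scale_option(self):
        # naive ratio keeps tau2 unconverted
        rel = provider_reliability(0.5, 0.5, 100, scale="logit")
        assert rel == pytest.approx(100 * 0.5 / (0.5 + 0.0025), abs=1e-9)


class TestSummarize:
    def test_cutoff_inclusive(self):
        out = summarize_reliability([69.9, 70.0, 70.1], provider_ids=["a", "b", "c"])
        assert out["n_reliable"] == 2 and out["reliable_providers"] == ["b", "c"]

    def test_all_reliable(self):
        out = summarize_reliability([100.0] * 5)
        assert out["n_reliable"] == 5 and out["pct_reliable"] == 100.0


class TestHierarchicalFit:
    def test_null_variance_recovered(self):
        df = simulate_outcomes(60, 40, tau2=0.0, seed=1)
        fit = fit_hierarchical(df, covariates=())
        assert fit["tau2"] <= 0.05

    def test_tau2_half_recovered(self):
        df = simulate_outcomes(100, 100, tau2=0.5, seed=2)
        fit = fit_hierarchical(df, covariates=())
        assert 0.3 <= fit["tau2"] <= 0.7

    def test_matches_method_of_moments(self):
        df = simulate_outcomes(80, 80, tau2=0.4, seed=3)
        fit = fit_hierarchical(df, covariates=())
        assert fit["tau2"] == pytest.approx(tau2_moments(df), abs=0.12)

    def test_covariate_fit_recovers_variance(self):
        df = simulate_outcomes(80, 60, tau2=0.4, seed=4, covariates=True)
        fit = fit_hierarchical(df, covariates=("sex",))
        assert 0.2 <= fit["tau2"] <= 0.65
        assert fit["beta"].shape == (2,)  # intercept + sex dummy

    def test_single_provider_rejected(self):
        df = simulate_outcomes(1, 30, tau2=0.1, seed=5)
        with pytest.raises(ValueError):
            fit_hierarchical(df)

    def test_matches_lme4_reference(self):
        """Cross-check tau^2 against the independent glmer Laplace fit."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: the lme4 cross-check cannot run")
        df = simulate_outcomes(40, 30, tau2=0.5, seed=6)
        fit = fit_hierarchical(df, covariates=())
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            df.to_csv(csv, index=False)
            script = Path(td) / "fit.R"
            script.write_text(
                "suppressMessages(library(lme4))\n"
                f"d <- read.csv('{csv}')\n"
                "m <- glmer(outcome ~ 1 + (1|provider), data=d, family=binomial)\n"
                "cat(as.numeric(VarCorr(m)$provider[1]))\n"
            )
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=300
            )
            assert out.returncode == 0, out.stderr
            tau2_r = float(out.stdout.strip().split()[-1])
        assert fit["tau2"] == pytest.approx(tau2_r, rel=0.10, abs=0.02)


class TestIndicatorReliability:
    def test_end_to_end_summary(self):
        df = simulate_outcomes(50, 40, tau2=0.6, seed=7)
        out = indicator_reliability(df, covariates=())
        per = out["per_provider"]
        assert len(per) == 50
        assert per["reliability"].between(0, 100).all()
        assert (per["n"] == 40).all()
        assert out["summary"]["n_providers"] == 50

    def test_low_information_flagged(self):
        df = pd.concat([
            simulate_outcomes(30, 20, tau2=0.3, seed=8),
            pd.DataFrame([{"provider": "PX", "outcome": 1, "sex": "M"}]),
        ])
        out = indicator_reliability(df, covariates=())
        assert out["per_provider"].set_index("provider").loc["PX", "low_information"]
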