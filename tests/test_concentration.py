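"""Tests of the Poisson-gamma concentration model and its hierarchical fit."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from fecalflow.concentration import (
    GammaConcentration,
    HierarchicalPosterior,
    ReplicateSample,
    _split_rhat,
    draw_concentration,
    fit_hierarchical,
    marginal_loglik,
    read_counts_csv,
    replicate_loglik,
    write_counts_csv,
)
from fecalflow.synthetic import SyntheticDesign, gen_count_table


def sample(counts, amounts, stype="water", loc="a", sid="s"):
    return ReplicateSample(counts=tuple(counts), equiv_amounts=tuple(amounts),
                           sample_type=stype, location=loc, sample_id=sid)


class TestReplicateSample:
    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError):
            sample([-1, 2], [1.0, 1.0])
        with pytest.raises(ValueError):
            sample([1.5, 2], [1.0, 1.0])

    def test_rejects_nonpositive_amounts_and_length_mismatch(self):
        with pytest.raises(ValueError):
            sample([1, 2], [1.0, 0.0])
        with pytest.raises(ValueError):
            sample([1, 2], [1.0])

    def test_gamma_params_must_be_positive_finite(self):
        with pytest.raises(ValueError):
            GammaConcentration(0.0, 1.0)
        with pytest.raises(ValueError):
            GammaConcentration(1.0, math.inf)


class TestReplicateLoglik:
    def test_matches_independent_poisson_logpmf(self):
        s = sample([3, 0, 7], [1.0, 0.1, 2.0])
        c = 2.7
        expected = sum(
            stats.poisson.logpmf(k, c * v) for k, v in zip(s.counts, s.equiv_amounts)
        )
        assert replicate_loglik(s, c) == pytest.approx(expected, rel=1e-12)

    def test_zero_concentration_limits(self):
        assert replicate_loglik(sample([0, 0], [1.0, 0.5]), 0.0) == 0.0
        assert replicate_loglik(sample([1, 0], [1.0, 0.5]), 0.0) == -math.inf

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            replicate_loglik(sample([1], [1.0]), -0.1)


class TestMarginalLoglik:
    def test_single_replicate_reduces_to_negative_binomial(self):
        # marginalizing Poisson(cV) over c ~ Gamma(rho, lam) gives
        # NB(r=rho, p_success=1/(1 + lam*V)) for the count
        g = GammaConcentration(1.7, 4.2)
        for k, v in [(0, 1.0), (5, 1.0), (12, 0.25), (3, 10.0)]:
            got = marginal_loglik(sample([k], [v]), g)
            want = stats.nbinom.logpmf(k, g.shape, 1.0 / (1.0 + g.scale * v))
            assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("counts,amounts,rho,lam", [
        ([3, 1], [1.0, 0.1], 0.5, 20.0),
        ([0, 0, 0], [1.0, 1.0, 1.0], 2.0, 0.5),
        ([40, 4, 0], [1.0, 0.1, 0.01], 1.2, 30.0),
        ([7], [2.5], 0.3, 100.0),
    ])
    def test_quadrature_agrees_with_closed_form(self, counts, amounts, rho, lam):
        s = sample(counts, amounts)
        g = GammaConcentration(rho, lam)
        a = marginal_loglik(s, g, method="analytic")
        q = marginal_loglik(s, g, method="quadrature")
        assert q == pytest.approx(a, rel=1e-8)

    def test_normalizes_over_counts_single_replicate(self):
        g = GammaConcentration(0.8, 3.0)
        total = sum(
            math.exp(marginal_loglik(sample([k], [1.0]), g)) for k in range(500)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            marginal_loglik(sample([1], [1.0]), GammaConcentration(1, 1), method="mc")


class TestDrawConcentration:
    def test_mean_matches_gamma(self, rng):
        g = GammaConcentration(2.0, 5.0)
        draws = np.array([draw_concentration(g, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(g.mean, rel=0.05)
        assert (draws > 0).all()


class TestSplitRhat:
    def test_identical_stationary_chains_are_near_one(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert _split_rhat(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self, rng):
        chains = rng.standard_normal((4, 1000)) + np.array([[0.0], [0.0], [10.0], [10.0]])
        assert _split_rhat(chains) > 2.0


class TestHierarchicalFit:
    def test_recovers_truth_on_synthetic_counts(self):
        true = GammaConcentration(0.5, 200.0)
        design = SyntheticDesign(strata={("water", "siteA"): true},
                                 n_samples_per_stratum=150, seed=11)
        samples = gen_count_table(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = fit_hierarchical(samples, n_steps=1200, seed=3)
        rho_hat = post.rho_median("water")
        lam_hat = post.lam_median("siteA")
        assert 0.5 * true.shape <= rho_hat <= 2.0 * true.shape
        assert 0.5 * true.scale <= lam_hat <= 2.0 * true.scale
        # the mean concentration is well identified: the posterior product
        # tracks the realized empirical mean of this dataset
        empirical_mean = float(np.mean(
            [sum(s.counts) / sum(s.equiv_amounts) for s in samples]))
        mean_hat = float((post.draws["rho[water]"] * post.draws["lam[siteA]"]).median())
        assert mean_hat == pytest.approx(empirical_mean, rel=0.15)

    def test_posterior_csv_roundtrip(self, tmp_path):
        true = GammaConcentration(1.0, 10.0)
        design = SyntheticDesign(strata={("soil", "siteB"): true},
                                 n_samples_per_stratum=30, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = fit_hierarchical(gen_count_table(design), n_steps=300, seed=5)
        path = tmp_path / "post.csv"
        post.to_csv(path)
        back = HierarchicalPosterior.from_csv(path)
        assert back.sample_types == ("soil",)
        assert back.locations == ("siteB",)
        assert back.rho_median("soil") == pytest.approx(post.rho_median("soil"))
        lo, hi = post.interval("lam[siteB]")
        lo2, hi2 = back.interval("lam[siteB]")
        assert (lo2, hi2) == pytest.approx((lo, hi))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_hierarchical([])


class TestCountsCsv:
    def test_roundtrip(self, tmp_path):
        design = SyntheticDesign(
            strata={("water", "a"): GammaConcentration(1.0, 5.0),
                    ("soil", "b"): GammaConcentration(0.5, 40.0)},
            n_samples_per_stratum=3, seed=7)
        samples = gen_count_table(design)
        path = tmp_path / "counts.csv"
        write_counts_csv(samples, path)
        back = read_counts_csv(path)
        assert len(back) == len(samples)
        for a, b in zip(samples, back):
            assert a.counts == b.counts
            assert a.equiv_amounts == pytest.approx(b.equiv_amounts)
            assert (a.sample_type, a.location, a.sample_id) == (
                b.sample_type, b.location, b.sample_id)

    def test_invalid_tables_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("sample_id,sample_type,location,replicate,count,equiv_amount,unit\n"
                       "s1,water,a,1,-3,1.0,mL\n")
        with pytest.raises(ValueError, match="non-negative"):
            read_counts_csv(bad)
        bad.write_text("sample_id,sample_type,location,replicate,count,equiv_amount,unit\n"
                       "s1,water,a,1,3,0.0,mL\n")
        with pytest.raises(ValueError, match="positive"):
            read_counts_csv(bad)
        bad.write_text("sample_id,count\ns1,3\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_counts_csv(bad)

    def test_mixed_metadata_within_sample_rejected(self, tmp_path):
        bad = tmp_path / "mixed.csv"
        bad.write_text("sample_id,sample_type,location,replicate,count,equiv_amount,unit\n"
                       "s1,water,a,1,3,1.0,mL\n"
                       "s1,soil,a,2,2,1.0,mL\n")
        with pytest.raises(ValueError, match="mixes"):
            read_counts_csv(bad)
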