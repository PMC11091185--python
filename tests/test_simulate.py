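"""Synthetic-data generator: structure, determinism, and scenario behavior."""

import numpy as np
import pytest
from scipy import stats

import erspcm as E
from erspcm.pcm import ext_pcm_category_probs
from erspcm.scale import RatingScaleSpec


class TestCovariate:
    def test_two_countries_are_symmetric_points(self):
        x = E.generate_covariate(2, seed=5)
        assert np.isclose(x[0], -x[1])
        assert np.isclose(np.abs(x[0]), 1 / np.sqrt(2))  # SD with ddof=1 is 1

    @pytest.mark.parametrize("G", [2, 5, 45])
    def test_standardized_exactly(self, G):
        x = E.generate_covariate(G, seed=1)
        assert abs(x.mean()) < 1e-12
        assert abs(x.std(ddof=1) - 1) < 1e-12

    def test_deterministic(self):
        assert np.array_equal(E.generate_covariate(10, 42), E.generate_covariate(10, 42))

    def test_single_country_rejected(self):
        with pytest.raises(ValueError):
            E.generate_covariate(1, 0)


class TestSimulateDataset:
    def test_null_parameters_give_uniform_frequencies(self):
        """sigma=0, beta=0, tau=0: every category equally likely (+-3 SE)."""
        design = E.SimulationDesign(G=5, n_g=250, I=8, seed=9)
        truth = E.TrueParameters(
            beta0=0.0, sigma_u=0.0, sigma_theta=0.0, sigma_eta=0.0,
            mu_eta=np.zeros(5), tau=np.zeros((8, 8)),
        )
        ds, _ = E.simulate_dataset(design, truth)
        N = ds.responses.size
        assert N >= 10_000
        p = 1 / 9
        se = np.sqrt(p * (1 - p) / N)
        freqs = np.bincount(ds.responses.ravel(), minlength=10)[1:] / N
        assert np.all(np.abs(freqs - p) < 3 * se)

    def test_dominance_limit(self):
        """theta forced far above the thresholds: modal category is K everywhere."""
        design = E.SimulationDesign(G=3, n_g=50, I=4, seed=2)
        truth = E.TrueParameters(
            beta0=10.0, sigma_u=0.0, sigma_theta=0.0, sigma_eta=0.0,
            mu_eta=np.zeros(3), tau=np.zeros((4, 8)),
        )
        ds, _ = E.simulate_dataset(design, truth)
        for g in range(3):
            vals = ds.responses[ds.country == g].ravel()
            assert np.bincount(vals, minlength=10).argmax() == 9

    def test_seed_determinism(self):
        design = E.SimulationDesign(G=4, n_g=20, I=3, seed=77)
        a, ra = E.simulate_dataset(design)
        b, rb = E.simulate_dataset(design)
        assert np.array_equal(a.responses, b.responses)
        assert np.array_equal(ra["theta"], rb["theta"])

    def test_dimension_mismatch_rejected(self):
        design = E.SimulationDesign(G=4, n_g=10, I=3, seed=0)
        with pytest.raises(ValueError, match="mu_eta"):
            E.simulate_dataset(design, E.TrueParameters(mu_eta=np.zeros(7)))

    def test_ground_truth_closes_over_generation(self, rng):
        """The emitted record recomputes the exact cell probabilities."""
        design = E.SimulationDesign(G=3, n_g=15, I=4, seed=4)
        ds, rec = E.simulate_dataset(design)
        scale = design.scale
        for _ in range(20):
            p = int(rng.integers(ds.n_persons))
            i = int(rng.integers(ds.n_items))
            probs = ext_pcm_category_probs(
                rec["theta"][p], rec["eta"][p], rec["tau"][i], scale.s
            )
            assert abs(probs.sum() - 1) < 1e-12
            assert probs[ds.responses[p, i] - 1] > 0
        # regression structure closes too
        assert np.allclose(
            rec["mu_theta"],
            rec["beta0"] + rec["beta1"] * rec["x"] + rec["beta2"] * rec["x"] ** 2 + rec["u"],
        )

    def test_empirical_frequencies_converge_to_model_probabilities(self):
        """At one fixed parameter point, 1e5 cells match the closed form to 0.01."""
        design = E.SimulationDesign(G=2, n_g=6250, I=8, seed=13)
        tau = np.tile(np.linspace(-1, 1, 8), (8, 1))
        truth = E.TrueParameters(
            beta0=0.8, sigma_u=0.0, sigma_theta=0.0, sigma_eta=0.0,
            mu_eta=np.full(2, 0.4), tau=tau - tau.mean(),
        )
        ds, rec = E.simulate_dataset(design, truth)
        assert ds.responses.size >= 100_000
        expected = ext_pcm_category_probs(
            rec["mu_theta"][0], 0.4, rec["tau"][0], design.scale.s
        )
        # mu_theta includes u_g but sigma_u=0, and all items share tau
        freqs = np.bincount(ds.responses.ravel(), minlength=10)[1:] / ds.responses.size
        assert np.abs(freqs - expected).max() < 0.01


class TestConfoundScenario:
    def test_truth_records_no_quadratic_effect(self):
        design = E.SimulationDesign(G=10, n_g=20, I=3, seed=6)
        _, rec = E.confound_scenario(design, gamma2=-0.5)
        assert rec["beta1"] == 0.0
        assert rec["beta2"] == 0.0
        assert abs(rec["gamma2"]) == 0.5
        assert abs(np.sum(rec["mu_eta"])) < 1e-10

    def test_zero_gamma_reduces_to_null(self):
        design = E.SimulationDesign(G=6, n_g=10, I=2, seed=8)
        _, rec = E.confound_scenario(design, gamma2=0.0)
        assert np.allclose(rec["mu_eta"], 0.0)

    def test_extreme_share_tracks_squared_covariate(self):
        """gamma2>0: country extreme-response share rises with x^2 (bootstrap)."""
        design = E.SimulationDesign(G=30, n_g=200, I=8, seed=21)
        ds, rec = E.confound_scenario(design, gamma2=0.8)
        extreme = np.isin(ds.responses, [1, 2, 8, 9])
        share = np.array(
            [extreme[ds.country == g].mean() for g in range(30)]
        )
        x2 = rec["x"] ** 2
        rho = stats.spearmanr(share, x2).statistic
        assert rho > 0
        boot_rng = np.random.default_rng(0)
        boots = []
        for _ in range(1000):
            idx = boot_rng.integers(0, 30, 30)
            boots.append(stats.spearmanr(share[idx], x2[idx]).statistic)
        assert np.quantile(boots, 0.025) > 0


class TestFig1Presets:
    def test_case_labels(self):
        assert np.allclose(E.fig1_presets("A").mu_eta, 0.0)
        assert np.all(E.fig1_presets("B").mu_eta < 0)
        assert np.all(E.fig1_presets("C").mu_eta > 0)
        with pytest.raises(ValueError, match="unknown"):
            E.fig1_presets("D")

    def test_middle_vs_extreme_shares_at_equal_trait(self):
        """Closed-form probabilities at the preset values, theta held fixed."""
        s = RatingScaleSpec(9).s
        tau = np.zeros(8)
        shares = {}
        for case in "ABC":
            eta = float(E.fig1_presets(case).mu_eta[0])
            p = ext_pcm_category_probs(0.5, eta, tau, s)
            shares[case] = {
                "middle": p[3:6].sum(),  # categories 4-6
                "extreme": p[[0, 1, 7, 8]].sum(),  # categories 1,2,8,9
            }
        assert shares["B"]["middle"] > shares["A"]["middle"]
        assert shares["C"]["extreme"] > shares["A"]["extreme"]


def test_write_simulation_round_trips(tmp_path):
    design = E.SimulationDesign(G=3, n_g=5, I=2, seed=1)
    ds, rec = E.simulate_dataset(design)
    paths = E.write_simulation(ds, rec, tmp_path)
    back = E.read_and_validate(paths["responses"], paths["covariates"], K=9)
    assert np.array_equal(back.responses, ds.responses)
    assert np.array_equal(back.country, ds.country)
    # stored covariate is already standardized; re-standardization is a no-op
    assert np.allclose(back.x, ds.x)
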