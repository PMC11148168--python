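import numpy as np
import pandas as pd
import pytest

from pericell import (
    IsotopePattern,
    MidaConfig,
    MidaFit,
    MidaObservation,
    MolecularFormula,
    absolute_dnl,
    determine_n,
    fit_fp,
    natural_pattern,
    predict_observed,
    run_mida_table,
)
from pericell.errors import ConfigError, InvalidInputError


def _make_obs(f, p, n_sites, formula="C17H34O2", amount=None):
    mol = MolecularFormula.parse(formula)
    natural = natural_pattern(mol)
    pattern = predict_observed(f, p, n_sites, natural)
    return MidaObservation("sim", "fa", mol, pattern, amount)


class TestForwardModel:
    def test_no_synthesis_gives_natural_envelope(self, palmitate_natural):
        pred = predict_observed(0.0, 0.08, 14, palmitate_natural)
        assert pred.as_array() == pytest.approx(
            palmitate_natural.normalised().as_array(), abs=1e-12
        )

    def test_unlabelled_precursor_indistinguishable_from_old_pool(
        self, palmitate_natural
    ):
        pred = predict_observed(1.0, 0.0, 14, palmitate_natural)
        assert pred.as_array() == pytest.approx(
            palmitate_natural.normalised().as_array(), abs=1e-12
        )

    def test_forward_chain_matches_longhand_composition(self, palmitate_natural):
        """Binomial → convolution → mixture composed by hand reproduces
        predict_observed for the study condition f=0.25, p=0.08, N=14."""
        from math import comb

        p, f = 0.08, 0.25
        mprime = np.array(
            [comb(14, x) * p**x * (1 - p) ** (14 - x) for x in range(5)]
        )
        m = palmitate_natural.as_array()
        mn = np.array(
            [sum(mprime[i] * m[x - i] for i in range(x + 1)) for x in range(5)]
        )
        mix = f * mn + (1 - f) * m
        mix /= mix.sum()
        got = predict_observed(f, p, 14, palmitate_natural).as_array()
        assert got == pytest.approx(mix, abs=1e-12)

    def test_invalid_fraction_rejected(self, palmitate_natural):
        with pytest.raises(InvalidInputError):
            predict_observed(1.5, 0.08, 14, palmitate_natural)


class TestFitRoundTrip:
    @pytest.mark.parametrize("f", [0.05, 0.25, 0.5, 0.9])
    @pytest.mark.parametrize("p", [0.04, 0.08])
    @pytest.mark.parametrize("n_sites", [12, 14, 22])
    def test_noise_free_recovery_of_f_and_p(self, f, p, n_sites):
        fit = fit_fp(_make_obs(f, p, n_sites), n_sites)
        assert fit.converged
        assert fit.f == pytest.approx(f, abs=1e-5)
        assert fit.p == pytest.approx(p, abs=1e-5)
        assert fit.sse < 1e-12

    @pytest.mark.parametrize("n_sites", [12, 14, 22])
    def test_n_scan_recovers_true_site_number(self, n_sites):
        fit = determine_n(_make_obs(0.3, 0.08, n_sites))
        assert fit.n_sites == n_sites
        assert fit.p == pytest.approx(0.08, abs=1e-5)

    def test_natural_envelope_fits_zero_synthesis(self, palmitate_formula):
        natural = natural_pattern(palmitate_formula).normalised()
        obs = MidaObservation("blank", "palmitate", palmitate_formula, natural)
        fit = fit_fp(obs, 14)
        assert fit.f == pytest.approx(0.0, abs=1e-6)
        assert "unidentifiable" in fit.flags

    def test_unidentifiable_tie_breaks_to_smallest_n(self, palmitate_formula):
        natural = natural_pattern(palmitate_formula).normalised()
        obs = MidaObservation("blank", "palmitate", palmitate_formula, natural)
        cfg = MidaConfig(n_min=8, n_max=12)
        fit = determine_n(obs, cfg)
        assert "unidentifiable" in fit.flags
        assert fit.n_sites == 8  # no label information: tie rule picks n_min
        assert fit.f == 0.0

    def test_measured_control_pattern_overrides_theory(self, palmitate_formula):
        """A supplied unlabelled-control envelope takes precedence over
        the theoretical natural pattern; with a slightly perturbed
        control, fitting data generated from that control still
        round-trips exactly."""
        control = IsotopePattern((0.82, 0.16, 0.018, 0.0015, 0.0001))
        pattern = predict_observed(0.3, 0.08, 14, control)
        obs = MidaObservation("ctl", "palmitate", palmitate_formula, pattern)
        fit = fit_fp(obs, 14, natural=control)
        assert fit.f == pytest.approx(0.3, abs=1e-5)
        assert fit.p == pytest.approx(0.08, abs=1e-5)
        # against the theoretical envelope the same data do not fit exactly
        assert fit_fp(obs, 14).sse > fit.sse

    def test_fixed_p_mode_recovers_f_and_n(self):
        cfg = MidaConfig(fit_mode="fixed_p")
        fit = determine_n(_make_obs(0.4, 0.08, 14), cfg)
        assert fit.p == 0.08
        assert fit.n_sites == 14
        assert fit.f == pytest.approx(0.4, abs=1e-5)

    def test_optimiser_beats_grid_search_oracle(self):
        """The polished multistart fit must reach at least as low a
        residual as a brute-force 101×101 grid over (f, p)."""
        mol = MolecularFormula.parse("C17H34O2")
        natural = natural_pattern(mol)
        truth = predict_observed(0.25, 0.08, 14, natural).as_array()
        rng = np.random.default_rng(3)
        noisy = truth * rng.lognormal(0.0, 0.01, 5)
        obs = MidaObservation(
            "noisy", "palmitate", mol, IsotopePattern.from_array(noisy / noisy.sum())
        )
        fit = fit_fp(obs, 14)
        observed = obs.observed.as_array()
        best_grid = np.inf
        for f in np.linspace(0, 1, 101):
            for p in np.linspace(0, 0.99, 101):
                pred = predict_observed(f, p, 14, natural).as_array()
                best_grid = min(best_grid, float(np.sum((pred - observed) ** 2)))
        assert fit.sse <= best_grid + 1e-15


class TestConfigAndErrors:
    def test_unnormalised_observation_rejected(self, palmitate_formula):
        with pytest.raises(InvalidInputError):
            MidaObservation(
                "s", "fa", palmitate_formula, IsotopePattern((0.5, 0.3, 0.1, 0.0, 0.0))
            )

    def test_empty_n_range_rejected(self):
        with pytest.raises(ConfigError):
            MidaConfig(n_min=20, n_max=8)

    def test_bad_p_target_rejected(self):
        with pytest.raises(ConfigError):
            MidaConfig(p_target=0.0)

    def test_config_digest_stable(self):
        assert MidaConfig().digest() == MidaConfig().digest()
        assert MidaConfig().digest() != MidaConfig(p_target=0.05).digest()


class TestAbsoluteDnl:
    @pytest.mark.parametrize(
        "f,amount,expected", [(0.25, 40.0, 10.0), (0.0, 17.0, 0.0), (1.0, 7.5, 7.5)]
    )
    def test_product_of_fraction_and_pool(self, f, amount, expected):
        fit = MidaFit(f=f, p=0.08, n_sites=14, sse=0.0, converged=True)
        assert absolute_dnl(fit, amount) == pytest.approx(expected)

    def test_missing_amount_rejected(self):
        fit = MidaFit(f=0.5, p=0.08, n_sites=14, sse=0.0, converged=True)
        with pytest.raises(InvalidInputError):
            absolute_dnl(fit, None)


class TestBatch:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_batch_equals_single_calls(self):
        obs1 = _make_obs(0.25, 0.08, 14)
        obs2 = _make_obs(0.5, 0.08, 14)
        rows = []
        for i, obs in enumerate([obs1, obs2]):
            row = {"sample": f"s{i}", "fatty_acid": "palmitate",
                   "formula": "C17H34O2", "amount_nmol": 40.0}
            row.update({f"m{j}": v for j, v in enumerate(obs.observed.fractions)})
            rows.append(row)
        out = run_mida_table(self._table(rows))
        assert list(out["f"]) == pytest.approx([0.25, 0.5], abs=1e-5)
        assert list(out["n_sites"]) == [14, 14]
        assert list(out["dnl_nmol"]) == pytest.approx([10.0, 20.0], abs=1e-3)

    def test_raw_intensity_scaling_is_irrelevant(self):
        obs = _make_obs(0.3, 0.08, 14)
        row = {"sample": "s", "fatty_acid": "pa", "formula": "C17H34O2"}
        row.update({f"m{j}": v for j, v in enumerate(obs.observed.fractions)})
        scaled = dict(row)
        for j in range(5):
            scaled[f"m{j}"] = row[f"m{j}"] * 2.7e6
        out = run_mida_table(self._table([row, scaled]))
        assert out.loc[0, "f"] == pytest.approx(out.loc[1, "f"], abs=1e-9)
        assert out.loc[0, "p"] == pytest.approx(out.loc[1, "p"], abs=1e-9)

    def test_mixed_fatty_acids_use_their_own_formula(self):
        rows = []
        for name, formula in [("palmitate", "C17H34O2"), ("palmitoleate", "C17H32O2")]:
            obs = _make_obs(0.3, 0.08, 14, formula=formula)
            row = {"sample": "s", "fatty_acid": name, "formula": formula}
            row.update({f"m{j}": v for j, v in enumerate(obs.observed.fractions)})
            rows.append(row)
        out = run_mida_table(self._table(rows))
        assert out["f"].tolist() == pytest.approx([0.3, 0.3], abs=1e-5)
        assert out["n_sites"].tolist() == [14, 14]

    def test_failed_row_recorded_without_aborting_batch(self):
        good = _make_obs(0.3, 0.08, 14)
        row_good = {"sample": "ok", "fatty_acid": "pa", "formula": "C17H34O2"}
        row_good.update(
            {f"m{j}": v for j, v in enumerate(good.observed.fractions)}
        )
        row_bad = {"sample": "bad", "fatty_acid": "pa", "formula": "Xx17",
                   **{f"m{j}": 0.2 for j in range(5)}}
        out = run_mida_table(pd.DataFrame([row_bad, row_good]))
        assert out.loc[0, "error"] != ""
        assert out.loc[1, "error"] == ""
        assert out.loc[1, "f"] == pytest.approx(0.3, abs=1e-5)

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning):
            out = run_mida_table(pd.DataFrame(columns=["sample"]))
        assert out.empty
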