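"""Synthetic generator: determinism, moment matching, closed-form oracle."""

import math

import numpy as np
import pytest

from varchain import (
    ChainTopology,
    ClassParams,
    FrequencyParams,
    GeneratorConfig,
    Label,
    discretize_all,
    expected_confusion,
    generate,
    proposed_topology,
)
from varchain.features import feature_matrix
from varchain.simulate import (
    _poisson_binomial_tail,
    demo_clinvar_like_config,
    feature_one_probability,
    planted_chain_config,
    random_config,
)
from varchain.variants import ConfigurationError


def tiny_config(**overrides):
    base = dict(
        n_variants=500,
        prevalence_pathogenic=0.5,
        neutral=ClassParams(
            spp_call_probs=(0.2, 0.2, 0.2),
            exac=FrequencyParams(0.9, (1e-6, 1e-2)),
            common=FrequencyParams(0.9, (1e-6, 1e-2)),
            ndamage_probs=(0.4,) * 9,
        ),
        pathogenic=ClassParams(
            spp_call_probs=(0.9, 0.9, 0.9),
            exac=FrequencyParams(0.2, (1e-6, 1e-3)),
            common=FrequencyParams(0.2, (1e-6, 1e-3)),
            ndamage_probs=(0.8,) * 9,
        ),
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


class TestGenerate:
    def test_seed_determinism(self):
        a, la = generate(tiny_config())
        b, lb = generate(tiny_config())
        assert la == lb and a == b

    def test_prevalence_one_all_pathogenic(self):
        _, labels = generate(tiny_config(prevalence_pathogenic=1.0))
        assert set(labels) == {Label.PATHOGENIC}

    def test_zero_call_probs_force_spp_zero_for_neutrals(self):
        cfg = tiny_config(
            neutral=ClassParams(
                spp_call_probs=(0.0, 0.0, 0.0),
                exac=FrequencyParams(0.9, (1e-6, 1e-2)),
                common=FrequencyParams(0.9, (1e-6, 1e-2)),
                ndamage_probs=(0.4,) * 9,
            )
        )
        variants, labels = generate(cfg)
        fvs = discretize_all(variants)
        for fv, lab in zip(fvs, labels):
            if lab is Label.NEUTRAL:
                assert fv.values["SPP"] == 0

    def test_frequencies_respect_ranges(self):
        variants, _ = generate(tiny_config(n_variants=2000))
        for v in variants:
            for af in (v.exac_af, v.common_af):
                if af is not None:
                    assert 1e-6 <= af <= 1e-2

    def test_missingness_rates_match_within_binomial_error(self):
        cfg = tiny_config(n_variants=20_000,
                          missingness={"exac_af": 0.1, "damage": 0.05})
        variants, _ = generate(cfg)
        n = len(variants)
        frac_exac_extra = np.mean([v.exac_af is None for v in variants])
        # uncatalogued mass adds to missingness; bound from parameters
        p_uncat = 0.5 * (1 - 0.9) + 0.5 * (1 - 0.2)
        expect = 0.1 + 0.9 * p_uncat
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(frac_exac_extra - expect) < 4 * se
        from varchain.variants import Call

        dmg = [c for v in variants for c in v.damage_calls.values()]
        frac_missing = np.mean([c is Call.MISSING for c in dmg])
        se = math.sqrt(0.05 * 0.95 / len(dmg))
        assert abs(frac_missing - 0.05) < 4 * se

    def test_moment_matching_class_conditional_rates(self):
        cfg = tiny_config(n_variants=10_000)
        variants, labels = generate(cfg)
        fvs = discretize_all(variants)
        m = feature_matrix(fvs, proposed_topology().levels).astype(float)
        y = np.array([lab is Label.PATHOGENIC for lab in labels])
        for j, feat in enumerate(proposed_topology().levels):
            for mask, params in ((~y, cfg.neutral), (y, cfg.pathogenic)):
                p = feature_one_probability(cfg, params, feat)
                emp = m[mask, j].mean()
                se = math.sqrt(p * (1 - p) / mask.sum())
                assert abs(emp - p) < 3 * max(se, 1e-4), feat

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(prevalence_pathogenic=1.5)
        with pytest.raises(ConfigurationError):
            FrequencyParams(0.5, (1e-2, 1e-6))


class TestExpectedConfusion:
    def test_all_ones_detection_rate(self):
        cfg = tiny_config(
            pathogenic=ClassParams(
                spp_call_probs=(1.0, 1.0, 1.0),
                exac=FrequencyParams(0.0, (1e-6, 1e-6)),
                common=FrequencyParams(0.0, (1e-6, 1e-6)),
                ndamage_probs=(1.0,) * 9,
            )
        )
        exp = expected_confusion(cfg, proposed_topology())
        assert exp.rate_P_given_1 == pytest.approx(1.0)

    def test_single_level_equals_feature_rate(self):
        cfg = tiny_config()
        exp = expected_confusion(cfg, ChainTopology(("SPP",)))
        spp_n = 1 - (1 - 0.2) ** 3
        spp_p = 1 - (1 - 0.9) ** 3
        assert exp.rate_P_given_0 == pytest.approx(spp_n)
        assert exp.rate_P_given_1 == pytest.approx(spp_p)

    def test_rates_pair_sum_to_one(self):
        exp = expected_confusion(tiny_config(), proposed_topology())
        assert exp.rate_N_given_0 + exp.rate_P_given_0 == pytest.approx(1.0)
        assert exp.rate_N_given_1 + exp.rate_P_given_1 == pytest.approx(1.0)

    def test_agrees_with_simulation(self):
        cfg = random_config(seed=42, n_variants=50_000)
        variants, labels = generate(cfg)
        fvs = discretize_all(variants)
        m = feature_matrix(fvs, proposed_topology().levels)
        y = np.array([lab is Label.PATHOGENIC for lab in labels])
        pred = m.all(axis=1)
        exp = expected_confusion(cfg, proposed_topology())
        for mask, p in ((~y, exp.p_pathogenic_given_neutral),
                        (y, exp.p_pathogenic_given_pathogenic)):
            emp = pred[mask].mean()
            se = math.sqrt(p * (1 - p) / mask.sum())
            assert abs(emp - p) < 3 * max(se, 1e-4)

    def test_coupling_blocks_closed_form(self):
        cfg = tiny_config(exac_common_coupling=0.5)
        with pytest.raises(ConfigurationError, match="coupling"):
            expected_confusion(cfg, proposed_topology())
        # but generation still works and the coupling raises the ExAC-COMMON
        # association relative to the independent draw
        from varchain import phi_coefficient

        coupled, _ = generate(tiny_config(n_variants=5000,
                                          exac_common_coupling=0.9, seed=2))
        indep, _ = generate(tiny_config(n_variants=5000, seed=2))

        def phi_of(vs):
            fvs = discretize_all(vs)
            return phi_coefficient([fv.values["ExAC"] for fv in fvs],
                                   [fv.values["COMMON"] for fv in fvs])

        assert phi_of(coupled) > phi_of(indep)

    def test_unparameterized_feature_rejected(self):
        with pytest.raises(ConfigurationError):
            expected_confusion(tiny_config(), ChainTopology(("mystery",)))


class TestPoissonBinomial:
    def test_matches_binomial_closed_form(self):
        from scipy.stats import binom

        for p in (0.1, 0.5, 0.8):
            for k in (1, 5, 9):
                assert _poisson_binomial_tail((p,) * 9, k) == pytest.approx(
                    binom.sf(k - 1, 9, p))

    def test_unequal_probs_against_enumeration(self):
        import itertools

        probs = (0.2, 0.7, 0.5)
        for k in range(4):
            brute = sum(
                math.prod(p if b else 1 - p for p, b in zip(probs, bits))
                for bits in itertools.product((0, 1), repeat=3)
                if sum(bits) >= k
            )
            assert _poisson_binomial_tail(probs, k) == pytest.approx(brute)


class TestPresets:
    def test_demo_preset_lands_near_target_pattern(self):
        exp = expected_confusion(demo_clinvar_like_config(), proposed_topology())
        assert exp.rate_N_given_0 == pytest.approx(0.91, abs=0.02)
        assert exp.rate_P_given_1 == pytest.approx(0.92, abs=0.02)

    def test_planted_preset_orders_neutral_rates(self):
        cfg = planted_chain_config()
        rates = [feature_one_probability(cfg, cfg.neutral, f)
                 for f in proposed_topology().levels]
        assert rates == sorted(rates)
        assert len(set(np.round(rates, 6))) == 4
        path_rates = [feature_one_probability(cfg, cfg.pathogenic, f)
                      for f in proposed_topology().levels]
        assert all(r > 0.99 for r in path_rates)
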