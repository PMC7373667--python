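import dataclasses
import math
import time

import numpy as np
import pytest

from clotwave.io_formats import AssayCondition, Plasma, ValidationError
from clotwave.simulate import (
    ClotKinetics,
    condition_to_kinetics,
    default_model,
    simulate_condition_set,
    simulate_curve,
)
from clotwave.waveform import DetectionConfig, detect_lag, turbidity_params
from clotwave import reference

from .conftest import SAMPLING


def _cond(**kw):
    kw.setdefault("plasma", Plasma.FVIII_DEFICIENT)
    return AssayCondition(**kw)


class TestSimulateCurve:
    def test_no_aggregation_gives_flat_baseline(self):
        kin = ClotKinetics(lag_s=math.inf, max_rise_au=0.0, noise_sd_au=0.0)
        curve = simulate_curve(kin, SAMPLING, seed=0)
        np.testing.assert_array_equal(curve.absorbances, np.full(301, kin.baseline_au))

    def test_seed_determinism(self, pnp_kin):
        kin = dataclasses.replace(pnp_kin, noise_sd_au=0.003)
        a = simulate_curve(kin, SAMPLING, seed=7)
        b = simulate_curve(kin, SAMPLING, seed=7)
        c = simulate_curve(kin, SAMPLING, seed=8)
        np.testing.assert_array_equal(a.absorbances, b.absorbances)
        assert not np.array_equal(a.absorbances, c.absorbances)

    def test_lysis_decays_after_onset_only(self, pnp_kin):
        lysed = dataclasses.replace(pnp_kin, lysis_onset_s=960.0, lysis_rate_per_min=0.1)
        a = simulate_curve(pnp_kin, SAMPLING, seed=0).absorbances
        b = simulate_curve(lysed, SAMPLING, seed=0).absorbances
        t = simulate_curve(lysed, SAMPLING, seed=0).times
        np.testing.assert_array_equal(a[t <= 960], b[t <= 960])
        assert np.all(b[t > 972] < a[t > 972])
        # single-exponential tail
        tail = (t > 1200)
        ratio = (b[tail] - pnp_kin.baseline_au) / (a[tail] - pnp_kin.baseline_au)
        np.testing.assert_allclose(ratio, np.exp(-0.1 * (t[tail] - 960) / 60), rtol=1e-9)

    def test_invalid_sampling_rejected(self, pnp_kin):
        with pytest.raises(ValueError):
            simulate_curve(pnp_kin, (0.0, 3600.0), seed=0)
        with pytest.raises(ValueError):
            simulate_curve(pnp_kin, (12.0, 6.0), seed=0)


class TestConditionMapping:
    def test_pnp_maps_to_reference_kinetics(self):
        kin = condition_to_kinetics(_cond(plasma=Plasma.PNP))
        assert kin.lag_s == 600.0
        assert kin.rise_rate_au_per_min == 0.03
        assert kin.max_rise_au == 0.18

    def test_deficient_plasma_does_not_aggregate(self):
        kin = condition_to_kinetics(_cond())
        assert kin.max_rise_au == 0.0
        assert not kin.aggregates

    def test_low_dose_sia_onset_beyond_record(self):
        kin = condition_to_kinetics(_cond(sia_nM=10.0))
        assert kin.aggregates
        assert kin.lag_s >= 3600.0

    def test_detectable_single_agents_have_finite_lag(self):
        for kw in ({"sia_nM": 60.0}, {"apcc_mU_per_mL": 250.0}, {"rfviia_ug_per_mL": 5.25}):
            kin = condition_to_kinetics(_cond(**kw))
            assert kin.aggregates and kin.lag_s < 3300.0, kw

    def test_synergy_shortens_lag_below_either_single_agent(self):
        both = condition_to_kinetics(_cond(sia_nM=600.0, apcc_mU_per_mL=500.0))
        sia = condition_to_kinetics(_cond(sia_nM=600.0))
        apcc = condition_to_kinetics(_cond(apcc_mU_per_mL=500.0))
        assert both.lag_s < min(sia.lag_s, apcc.lag_s)
        assert both.rise_rate_au_per_min > max(sia.rise_rate_au_per_min,
                                               apcc.rise_rate_au_per_min)

    @pytest.mark.parametrize("agent,doses,background", [
        ("sia_nM", [0.0, 10.0, 60.0, 200.0, 600.0], {}),
        ("sia_nM", [0.0, 10.0, 60.0, 200.0, 600.0], {"apcc_mU_per_mL": 250.0}),
        ("apcc_mU_per_mL", [0.0, 25.0, 50.0, 250.0, 500.0, 1000.0], {}),
        ("apcc_mU_per_mL", [0.0, 25.0, 50.0, 250.0, 500.0, 1000.0], {"sia_nM": 200.0}),
        ("rfviia_ug_per_mL", [0.0, 0.88, 1.75, 5.25], {}),
        ("rfviia_ug_per_mL", [0.0, 0.88, 1.75, 5.25], {"sia_nM": 200.0}),
    ])
    def test_dose_monotonicity(self, agent, doses, background):
        """More agent never lengthens the latent lag nor slows the rate."""
        lags, rates = [], []
        for d in doses:
            kw = dict(background)
            kw[agent] = d
            kin = condition_to_kinetics(_cond(**kw))
            lags.append(kin.lag_s if kin.aggregates else math.inf)
            rates.append(kin.rise_rate_au_per_min if kin.aggregates else 0.0)
        assert all(b <= a + 1e-9 for a, b in zip(lags, lags[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_tpa_arm_gets_lysis_after_clot_completion(self):
        kin = condition_to_kinetics(_cond(plasma=Plasma.PNP, tpa_present=True))
        assert kin.lysis_rate_per_min > 0
        assert kin.lysis_onset_s == pytest.approx(kin.lag_s + kin.rise_duration_s)

    def test_negative_concentration_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            _cond(apcc_mU_per_mL=-5.0)


class TestConditionSet:
    def test_replicates_differ_only_by_noise(self):
        conds = [_cond(plasma=Plasma.PNP, replicate=i + 1) for i in range(3)]
        noisy = simulate_condition_set(conds, sampling=SAMPLING, seed=3)
        quiet_model = default_model(noise_sd_au=0.0)
        quiet = simulate_condition_set(conds, model=quiet_model, sampling=SAMPLING, seed=3)
        a0 = quiet[0][1].absorbances
        for _, curve in quiet[1:]:
            np.testing.assert_array_equal(curve.absorbances, a0)
        for (_, n), (_, q) in zip(noisy, quiet):
            resid = n.absorbances - q.absorbances
            assert 0 < np.std(resid) < 0.01

    def test_master_seed_determinism(self):
        conds = reference.condition_grid(replicates=1)
        a = simulate_condition_set(conds, sampling=SAMPLING, seed=5)
        b = simulate_condition_set(conds, sampling=SAMPLING, seed=5)
        for (_, ca), (_, cb) in zip(a, b):
            np.testing.assert_array_equal(ca.absorbances, cb.absorbances)

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_condition_set([], sampling=SAMPLING, seed=0)

    def test_full_grid_simulates_quickly(self):
        conds = reference.condition_grid(replicates=3)
        assert len(conds) == 180
        start = time.perf_counter()
        out = simulate_condition_set(conds, sampling=SAMPLING, seed=1)
        assert time.perf_counter() - start < 5.0
        assert len(out) == 180

    def test_grid_nd_rows_match_published_pattern(self):
        """FVIII-def, SIA 10, aPCC 25/50 and rFVIIa 0.88/1.75 come out ND."""
        cfg = DetectionConfig()
        model = default_model(noise_sd_au=0.0)
        nd_labels = set()
        for row in reference.REFERENCE_PANEL:
            kin = condition_to_kinetics(row.condition, model)
            curve = simulate_curve(kin, SAMPLING, seed=0)
            if turbidity_params(curve, cfg).nd:
                nd_labels.add(row.condition.label())
        expected = {row.condition.label() for row in reference.REFERENCE_PANEL if row.nd}
        assert nd_labels == expected
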