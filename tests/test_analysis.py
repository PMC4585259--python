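import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from naviph.analysis import (
    TAU_MAX,
    analyze_cohort,
    extract_period_stats,
    fit_exponential,
    kapp_from_inhibition,
    normalize_trace,
    paired_pH_test,
    reversibility,
    transition_recovery_ratio,
)
from naviph.errors import ConfigError, DataError
from naviph.io import AmplitudeTrace
from naviph.protocol import Protocol
from naviph.simulate import SimCohortConfig, class_preset, simulate_cohort

positive = st.floats(min_value=1e-3, max_value=1e6)


class TestKapp:
    def test_half_block_returns_the_concentration(self):
        assert kapp_from_inhibition(100.0, 0.5)[0] == pytest.approx(100.0)

    def test_single_concentration_case_from_printed_inhibitions(self):
        # 100 µM producing 42% inhibition: K = 100 * 0.58 / 0.42
        value, flags = kapp_from_inhibition(100.0, 0.42)
        assert value == pytest.approx(100.0 * 0.58 / 0.42)
        assert value == pytest.approx(138.1, abs=0.05)
        assert not flags

    def test_no_block_is_censored_not_a_number(self):
        value, flags = kapp_from_inhibition(100.0, 0.0)
        assert math.isnan(value) and "censored" in flags
        value, flags = kapp_from_inhibition(100.0, -0.2)
        assert math.isnan(value) and "censored" in flags

    def test_total_block_rejected(self):
        with pytest.raises(DataError):
            kapp_from_inhibition(100.0, 1.0)

    @given(k=positive, cc=positive)
    def test_inverts_reduced_hill_equation_exactly(self, k, cc):
        inh = cc / (cc + k)
        # the inversion is exact wherever the inhibition itself is
        # representable away from its endpoints
        if 1e-3 < inh < 1 - 1e-3:
            assert kapp_from_inhibition(cc, inh)[0] == pytest.approx(k, rel=1e-12)


class TestReversibility:
    def test_full_recovery(self):
        assert reversibility(1.0, 0.3, 1.0)[0] == pytest.approx(1.0)

    def test_no_recovery(self):
        assert reversibility(1.0, 0.3, 0.3)[0] == pytest.approx(0.0)

    def test_half_recovery(self):
        assert reversibility(1.0, 0.3, 0.65)[0] == pytest.approx(0.5)

    def test_undefined_when_no_inhibition(self):
        value, flags = reversibility(0.5, 0.6, 0.7)
        assert math.isnan(value) and "undefined" in flags

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_to_multiplicative_rescaling(self, scale):
        base = reversibility(1.0, 0.3, 0.65)[0]
        assert reversibility(scale, 0.3 * scale, 0.65 * scale)[0] == pytest.approx(base)


class TestNormalize:
    def _trace(self, amplitudes):
        n = len(amplitudes)
        return AmplitudeTrace(
            "c",
            pd.DataFrame(
                {
                    "time_s": np.arange(n) * 20.0,
                    "train_index": np.arange(n),
                    "period_index": 1,
                    "phase": "control",
                    "pH": 7.3,
                    "drug_on": False,
                    "amplitude": amplitudes,
                }
            ),
        )

    def test_divides_by_last_period1_control_amplitude(self):
        out = normalize_trace(self._trace([1.0, 1.5, 2.0]))
        assert list(out.data["amplitude"]) == [0.5, 0.75, 1.0]

    def test_idempotent_on_normalized_trace(self):
        once = normalize_trace(self._trace([1.0, 1.5, 2.0]))
        twice = normalize_trace(once)
        assert np.allclose(once.data["amplitude"], twice.data["amplitude"])

    def test_zero_reference_rejected(self):
        with pytest.raises(DataError):
            normalize_trace(self._trace([1.0, 0.5, 0.0]))

    def test_simulated_noiseless_cohort_reference_is_unity(self, noiseless_a_traces):
        for tr in noiseless_a_traces:
            out = normalize_trace(tr)
            ctrl = out.data[(out.data["period_index"] == 1) & (out.data["phase"] == "control")]
            assert ctrl["amplitude"].iloc[-1] == 1.0


class TestExponentialFit:
    def test_exact_recovery_on_train_grid(self):
        t = np.arange(10) * 20.0
        for tau in (5.0, 40.0, 150.0, 400.0):
            y = 0.4 + 0.6 * np.exp(-t / tau)
            fit = fit_exponential(t + 1000.0, y)
            assert fit.tau == pytest.approx(tau, rel=1e-6)
            assert fit.plateau == pytest.approx(0.4, abs=1e-6)

    def test_constant_data_flagged_unresolved(self):
        fit = fit_exponential(np.arange(10) * 20.0, np.full(10, 0.7))
        assert fit.tau == TAU_MAX
        assert fit.span == pytest.approx(0.0, abs=1e-9)
        assert "kinetics unresolved" in fit.flags

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ConfigError):
            fit_exponential([0.0, 20.0], [1.0, 0.5])

    def test_rising_recovery_curves_fit_too(self):
        t = np.arange(10) * 20.0
        y = 0.9 - 0.5 * np.exp(-t / 60.0)
        fit = fit_exponential(t, y)
        assert fit.tau == pytest.approx(60.0, rel=1e-6)
        assert fit.span == pytest.approx(-0.5, rel=1e-6)


class TestPeriodStats:
    def test_noiseless_class_a_inhibition_matches_steady_state(self, class_a, protocol):
        traces = simulate_cohort(class_a, SimCohortConfig(n_cells=2, noise_cv=0.0), protocol)
        ps = extract_period_stats(normalize_trace(traces[0]), 1)
        expected = class_a.conc / (class_a.conc + class_a.kd_site)
        assert 1.0 - ps.i / ps.c == pytest.approx(expected, rel=0.01)

    def test_constant_amplitude_trace_gives_c_equals_i_equals_w(self, protocol):
        sched = protocol.schedule()
        sched["amplitude"] = 0.8
        ps = extract_period_stats(AmplitudeTrace("c", sched), 1)
        assert ps.c == ps.i == ps.w == 0.8

    def test_drug_free_period_rejected(self, noiseless_a_traces):
        with pytest.raises(ConfigError):
            extract_period_stats(noiseless_a_traces[0], 3)

    def test_offset_tau_flagged_unreliable_at_low_recovery(self, protocol):
        # washout stuck at the inhibited level: recovery 0 < 0.1 floor
        sched = protocol.schedule()
        amp = np.ones(150)
        p1 = sched["period_index"] == 1
        amp[np.flatnonzero(p1 & sched["phase"].isin(["drug", "washout"]))] = 0.4
        sched["amplitude"] = amp
        ps = extract_period_stats(AmplitudeTrace("c", sched), 1)
        assert "offset unreliable" in ps.offset_flags


class TestTransitionRecovery:
    def _trace_with_section(self, protocol, amplitudes_by_slot):
        sched = protocol.schedule()
        sched["amplitude"] = amplitudes_by_slot
        return AmplitudeTrace("c", sched)

    def test_flat_section_gives_unity(self, protocol):
        tr = self._trace_with_section(protocol, np.full(150, 0.6))
        assert transition_recovery_ratio(tr, "neutral_to_acidic", protocol) == pytest.approx(1.0)

    def test_rising_section_ratio_is_arithmetic(self, protocol):
        amps = np.full(150, 0.6)
        # control phase of period 2 spans slots 30-39
        amps[30:40] = np.linspace(0.60, 0.75, 10)
        tr = self._trace_with_section(protocol, amps)
        assert transition_recovery_ratio(tr, "neutral_to_acidic", protocol) == pytest.approx(1.25)

    def test_unknown_transition_rejected(self, noiseless_a_traces):
        with pytest.raises(ConfigError):
            transition_recovery_ratio(noiseless_a_traces[0], "acidic_to_alkalic")

    def test_trap_escape_produces_acidification_induced_recovery(self, protocol):
        # a lipophilic-trap compound recovers on acidification; a fast
        # reversible compound shows a flat post-transition section
        for label, check in (("C", lambda r: r > 1.1), ("A", lambda r: abs(r - 1) < 0.05)):
            drug = class_preset(label)
            traces = simulate_cohort(drug, SimCohortConfig(n_cells=2, noise_cv=0.0), protocol)
            r = transition_recovery_ratio(normalize_trace(traces[0]), "neutral_to_acidic", protocol)
            assert check(r), (label, r)

    def test_invariant_to_proton_block_factor(self, protocol):
        drug = class_preset("C")
        ratios = []
        for pbf in (0.5, 0.724):
            cohort = SimCohortConfig(n_cells=2, noise_cv=0.0, proton_block_factor=pbf)
            traces = simulate_cohort(drug, cohort, protocol)
            ratios.append(
                transition_recovery_ratio(normalize_trace(traces[0]), "neutral_to_acidic", protocol)
            )
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-9)


class TestPairedTest:
    def test_identical_pairs_degenerate(self):
        p, flags = paired_pH_test([1, 1, 1, 1, 1], [1, 1, 1, 1, 1], "reversibility")
        assert p == 1.0 and "degenerate" in flags

    def test_constant_nonzero_differences_degenerate(self):
        p, flags = paired_pH_test([1, 1, 1, 1, 1], [2, 2, 2, 2, 2], "reversibility")
        assert p == 1.0 and "degenerate" in flags

    def test_matches_textbook_t_distribution(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.2, 5)
        b = a + rng.normal(0.2, 0.2, 5)
        p, _ = paired_pH_test(a, b, "reversibility")
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        expected = 2 * sps.t.sf(abs(t), df=len(d) - 1)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_log_transform_applied_for_affinity(self):
        a = [10.0, 100.0, 1000.0, 10.0, 100.0]
        b = [20.0, 200.0, 2000.0, 20.0, 200.0]
        # constant log-ratio: degenerate on the log scale
        p, flags = paired_pH_test(a, b, "affinity")
        assert "degenerate" in flags


class TestCohortSummaries:
    def test_geometric_mean_for_affinity(self, protocol):
        drug = class_preset("F")
        traces = simulate_cohort(drug, SimCohortConfig(seed=2), protocol)
        summ = analyze_cohort(traces, "F", drug.conc, protocol)
        percell = summ.per_cell
        neutral = percell[percell["ph_label"] == "neutral"]["kapp"].dropna()
        expected = math.exp(np.log(neutral).mean())
        assert summ.summary.loc["neutral", "kapp"] == pytest.approx(expected, rel=1e-9)

    def test_identical_neutral_periods_average_to_themselves(self, protocol):
        # noiseless traces: periods 1 and 5 carry slightly different residual
        # block, so assert on an explicitly symmetric synthetic cohort instead
        sched = protocol.schedule()
        amp = np.ones(150)
        for p in (1, 5):
            rows = (sched["period_index"] == p) & (sched["phase"] == "drug")
            amp[np.flatnonzero(rows)] = 0.5
        for p in (2, 4):
            rows = (sched["period_index"] == p) & (sched["phase"] == "drug")
            amp[np.flatnonzero(rows)] = 0.7
        sched["amplitude"] = amp
        traces = [AmplitudeTrace(f"c{i}", sched.copy()) for i in range(2)]
        summ = analyze_cohort(traces, "x", 100.0, protocol)
        single_period_kapp = kapp_from_inhibition(100.0, 0.5)[0]
        assert summ.summary.loc["neutral", "kapp"] == pytest.approx(single_period_kapp)

    def test_class_f_affinity_ordering_across_ph(self, protocol):
        drug = class_preset("F")
        traces = simulate_cohort(drug, SimCohortConfig(seed=4), protocol)
        summ = analyze_cohort(traces, "F", drug.conc, protocol).summary["kapp"]
        assert summ["alkalic"] < summ["neutral"] < summ["acidic"]

    def test_noiseless_presets_reproduce_qualitative_signatures(self, protocol):
        # scaled-down noiseless sweep across the class presets
        summaries = {}
        for label in "ABCDEFG":
            drug = class_preset(label)
            traces = simulate_cohort(drug, SimCohortConfig(n_cells=2, noise_cv=0.0), protocol)
            summaries[label] = analyze_cohort(traces, label, drug.conc, protocol).summary
        g = summaries
        assert g["A"]["reversibility"].min() > 0.9
        assert g["A"]["kapp"]["acidic"] / g["A"]["kapp"]["alkalic"] < 1.5
        assert g["B"]["kapp"]["acidic"] / g["B"]["kapp"]["alkalic"] > 2
        assert g["B"]["tau_onset"]["alkalic"] < g["B"]["tau_onset"]["acidic"]
        assert g["C"]["reversibility"]["alkalic"] < 0.15 <= 0.5 <= g["C"]["reversibility"]["acidic"]
        assert g["D"]["reversibility"]["acidic"] < 0.2 < 0.8 < g["D"]["reversibility"]["neutral"]
        assert g["E"]["kapp"]["neutral"] == min(g["E"]["kapp"])
        assert 2.5 <= g["F"]["kapp"]["neutral"] / g["F"]["kapp"]["alkalic"] <= 5.5
        ratios = (
            g["G"]["kapp"]["acidic"] / g["G"]["kapp"]["alkalic"],
            g["G"]["kapp"]["neutral"] / g["G"]["kapp"]["alkalic"],
            g["G"]["kapp"]["acidic"] / g["G"]["kapp"]["neutral"],
        )
        assert all(0.6 <= r <= 2.1 for r in ratios)

    def test_single_cell_rejected(self, noiseless_a_traces):
        with pytest.raises(ConfigError):
            analyze_cohort(noiseless_a_traces[:1], "A", 300.0)
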