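"""Synthetic TEVC generator: leak arithmetic, determinism, analytic
reversal, block ground truth and batch statistics."""

import math

import numpy as np
import pytest

from tevcperm.biophysics import PhysicalConstants, SolutionSpec, WoodhullParams
from tevcperm.permeability import estimate_reversal_potential
from tevcperm.simulate import (
    ChannelModel,
    ExperimentDesign,
    OocyteModel,
    Protocol,
    analytic_reversal_potential,
    generate_batch,
    simulate_application_sweep,
    simulate_ramp_sweep,
)
from tevcperm.traces import peak_current, percent_block, ramp_to_iv, segment_window

from conftest import make_application_protocol, make_ramp_protocol

ROOM = PhysicalConstants()


def blocked_channel(unblocked_at_hold: float, hold_mv: float = -70.0,
                    mg_mm: float = 0.5, **kw) -> ChannelModel:
    """Channel whose Woodhull parameters give a chosen unblocked fraction at
    the holding potential in `mg_mm` blocker (zdelta fixed at 1)."""
    kd_at_hold = mg_mm * unblocked_at_hold / (1.0 - unblocked_at_hold)
    kd0 = kd_at_hold * math.exp(-hold_mv * 1e-3 * ROOM.f_over_rt)
    defaults = dict(
        pca_over_pmono=2.3,
        max_conductance_scale=20.0,
        agonist_efficacy={"glycine": 1.0, "glutamate+glycine": 1.0},
        block=WoodhullParams(kd0=kd0, zdelta=1.0, blocker_conc=0.0),
    )
    defaults.update(kw)
    return ChannelModel(**defaults)


class TestRampSweep:
    def test_leak_only_trace_is_exactly_ohmic(self, nfr, ramp_protocol):
        channel = ChannelModel(max_conductance_scale=0.0)
        oocyte = OocyteModel(leak_conductance=1.0, leak_reversal=-20.0,
                             noise_sd=0.0)
        tr = simulate_ramp_sweep(channel, oocyte, ramp_protocol, nfr, seed=0)
        # 1 µS * (V + 20 mV) = (V + 20) nA
        assert np.allclose(tr.current, tr.command_voltage + 20.0, atol=1e-12)

    def test_identical_seed_bit_identical(self, gly_channel, nfr, ramp_protocol):
        oocyte = OocyteModel(noise_sd=10.0)
        a = simulate_ramp_sweep(gly_channel, oocyte, ramp_protocol, nfr, seed=42)
        b = simulate_ramp_sweep(gly_channel, oocyte, ramp_protocol, nfr, seed=42)
        assert np.array_equal(a.current, b.current)
        c = simulate_ramp_sweep(gly_channel, oocyte, ramp_protocol, nfr, seed=43)
        assert not np.array_equal(a.current, c.current)

    def test_noiseless_biionic_erev_matches_bisection_oracle(
        self, gly_channel, car4, quiet_oocyte, ramp_protocol
    ):
        truth = analytic_reversal_potential(gly_channel, car4, quiet_oocyte)
        tr = simulate_ramp_sweep(gly_channel, quiet_oocyte, ramp_protocol,
                                 car4, seed=0)
        est = estimate_reversal_potential(ramp_to_iv(tr))
        assert est == pytest.approx(truth, abs=0.1)

    def test_erev_targeted_by_permeability_choice(self, car4, quiet_oocyte,
                                                  ramp_protocol):
        """Choosing P_Ca/P_mono to put the analytic reversal at -30 mV is
        recovered by the downstream estimator within 0.1 mV."""
        # invert the biionic relation at -30 mV for the needed ratio
        u = -30.0 * 1e-3 * ROOM.f_over_rt
        x = math.exp(u)
        mono = quiet_oocyte.internal_concentrations["Mono"]
        ratio = mono * x * (x + 1) / (4.0 * 4.0)
        channel = ChannelModel(
            pca_over_pmono=ratio, max_conductance_scale=20.0,
            agonist_efficacy={"glycine": 1.0},
        )
        tr = simulate_ramp_sweep(channel, quiet_oocyte, ramp_protocol, car4, 0)
        est = estimate_reversal_potential(ramp_to_iv(tr))
        assert est == pytest.approx(-30.0, abs=0.1)

    def test_leak_does_not_move_subtracted_reversal(self, gly_channel, car4,
                                                    ramp_protocol):
        """Adding ohmic leak leaves the current at the channel's reversal
        unchanged after background subtraction (controls carry the leak)."""
        from tevcperm.traces import subtract_background

        quiet = OocyteModel(leak_conductance=0.0, noise_sd=0.0,
                            internal_concentrations={"Mono": 89.38, "Ca": 0.0})
        leaky = OocyteModel(leak_conductance=2.0, leak_reversal=-15.0,
                            noise_sd=0.0,
                            internal_concentrations={"Mono": 89.38, "Ca": 0.0})
        blank = SolutionSpec(label="4CaR",
                             ion_concentrations={"NMDG": 108.6, "Ca": 4.0})
        truth = analytic_reversal_potential(gly_channel, car4, quiet)
        ago = ramp_to_iv(simulate_ramp_sweep(gly_channel, leaky, ramp_protocol,
                                             car4, 0))
        ctrl = ramp_to_iv(simulate_ramp_sweep(
            ChannelModel(max_conductance_scale=0.0), leaky, ramp_protocol,
            blank, 0))
        sub = subtract_background(ago, ctrl, ctrl)
        assert estimate_reversal_potential(sub) == pytest.approx(truth, abs=0.1)

    def test_no_permeant_ion_rejected(self, gly_channel, ramp_protocol):
        empty = SolutionSpec(label="NMDG only",
                             ion_concentrations={"NMDG": 110.0})
        oocyte = OocyteModel(internal_concentrations={}, noise_sd=0.0)
        with pytest.raises(ValueError, match="permeant"):
            simulate_ramp_sweep(gly_channel, oocyte, ramp_protocol, empty, 0)

    def test_wrong_protocol_kind_rejected(self, gly_channel, nfr):
        proto = make_application_protocol([("NFR", 1.0)])
        with pytest.raises(ValueError):
            simulate_ramp_sweep(gly_channel, OocyteModel(), proto, nfr, 0)


def app_solutions():
    nfr = {"Na": 115.0, "K": 2.5, "Ca": 1.8}
    return {
        "NFR": SolutionSpec("NFR", nfr),
        "NFR+Gly": SolutionSpec("NFR+Gly", nfr, agonists={"glycine": 10.0}),
        "NFR+Gly+Mg": SolutionSpec("NFR+Gly+Mg", nfr,
                                   agonists={"glycine": 10.0},
                                   blockers={"Mg": 0.5}),
        "NFR+Glu/Gly": SolutionSpec(
            "NFR+Glu/Gly", nfr, agonists={"glutamate": 100.0, "glycine": 10.0}
        ),
    }


def app_protocol():
    return make_application_protocol(
        [("NFR", 2.0), ("NFR+Gly", 6.0), ("NFR+Gly+Mg", 6.0),
         ("NFR+Gly", 3.0), ("NFR", 2.0)],
        exchange_tau_s=0.2,
    )


def sweep_block(trace) -> float:
    base = trace.current[(trace.time >= 1.0) & (trace.time < 2.0)].mean()
    ctrl = peak_current(trace, segment_window(trace, 1), (0.0, 2.0))
    t2 = segment_window(trace, 2)
    mask = (trace.time >= t2[1] - 1.5) & (trace.time < t2[1])
    blocked = abs(trace.current[mask].mean() - base)
    return percent_block(ctrl, blocked)


class TestApplicationSweep:
    def test_unblocked_channel_shows_no_block(self, quiet_oocyte):
        channel = ChannelModel(
            pca_over_pmono=0.4, max_conductance_scale=5.0,
            agonist_efficacy={"glycine": 1.0}, block=None,
        )
        oocyte = OocyteModel(leak_conductance=0.0, noise_sd=0.02,
                             internal_concentrations={"Mono": 89.38, "Ca": 0.0})
        tr = simulate_application_sweep(channel, oocyte, app_protocol(),
                                        app_solutions(), seed=7)
        assert abs(sweep_block(tr)) < 3.0

    def test_known_woodhull_block_recovered(self):
        """Unblocked fraction 0.12 at the hold -> 88% block of the agonist
        response, the wild-type operating point."""
        channel = blocked_channel(0.12)
        oocyte = OocyteModel(leak_conductance=0.0, noise_sd=0.0,
                             internal_concentrations={"Mono": 89.38, "Ca": 0.0})
        tr = simulate_application_sweep(channel, oocyte, app_protocol(),
                                        app_solutions(), seed=0)
        assert sweep_block(tr) == pytest.approx(88.0, abs=1.0)

    def test_equal_efficacies_give_equal_peaks(self, quiet_oocyte):
        channel = ChannelModel(
            pca_over_pmono=0.4, max_conductance_scale=5.0,
            agonist_efficacy={"glycine": 0.8, "glutamate+glycine": 0.8},
        )
        proto = make_application_protocol(
            [("NFR", 2.0), ("NFR+Gly", 6.0), ("NFR", 3.0),
             ("NFR+Glu/Gly", 6.0), ("NFR", 2.0)],
            exchange_tau_s=0.2,
        )
        oocyte = OocyteModel(leak_conductance=0.0, noise_sd=0.05,
                             internal_concentrations={"Mono": 89.38, "Ca": 0.0})
        tr = simulate_application_sweep(channel, oocyte, proto,
                                        app_solutions(), seed=3)
        a = peak_current(tr, segment_window(tr, 1), (0.0, 2.0))
        b = peak_current(tr, segment_window(tr, 3), (0.0, 2.0))
        assert b == pytest.approx(a, rel=0.05)

    def test_undefined_solution_label_rejected(self, quiet_oocyte, gly_channel):
        proto = make_application_protocol([("NFR", 2.0), ("no-such", 2.0)])
        with pytest.raises(KeyError, match="no-such"):
            simulate_application_sweep(gly_channel, quiet_oocyte, proto,
                                       app_solutions(), seed=0)


def small_design(expression_cv=0.5, noise_sd=0.5) -> ExperimentDesign:
    sols = app_solutions()
    sols["4CaR+Gly"] = SolutionSpec(
        "4CaR+Gly", {"NMDG": 108.6, "Ca": 4.0}, agonists={"glycine": 10.0}
    )
    channel = ChannelModel(pca_over_pmono=2.3, max_conductance_scale=5.0,
                           agonist_efficacy={"glycine": 1.0})
    oocyte = OocyteModel(leak_conductance=0.2, noise_sd=noise_sd,
                         internal_concentrations={"Mono": 89.38, "Ca": 0.0})
    return ExperimentDesign(
        channel=channel, oocyte=oocyte, solutions=sols,
        ramp_sweeps=[(make_ramp_protocol(name="ramp"), "4CaR+Gly")],
        application_sweeps=[app_protocol()],
        expression_cv=expression_cv, condition="demo",
    )


class TestBatch:
    def test_cell_count_and_sweep_plan(self):
        batch = generate_batch(small_design(), n_cells=5, seed=1)
        assert len(batch) == 5
        for sweeps in batch.values():
            assert [s.metadata["protocol"] for s in sweeps] == [
                "ramp", "application"
            ]

    def test_same_seed_identical_batch(self):
        a = generate_batch(small_design(), n_cells=3, seed=11)
        b = generate_batch(small_design(), n_cells=3, seed=11)
        for cell in a:
            for ta, tb in zip(a[cell], b[cell]):
                assert np.array_equal(ta.current, tb.current)

    def test_single_sweep_reproducible_from_recorded_seed(self):
        design = small_design()
        batch = generate_batch(design, n_cells=2, seed=5)
        cell_id, sweeps = sorted(batch.items())[0]
        ramp = sweeps[0]
        from dataclasses import replace

        oocyte = replace(design.oocyte,
                         expression_scale=ramp.metadata["expression_scale"])
        redo = simulate_ramp_sweep(design.channel, oocyte,
                                   design.ramp_sweeps[0][0],
                                   design.solutions["4CaR+Gly"],
                                   ramp.metadata["seed"])
        assert np.array_equal(redo.current, ramp.current)

    def test_expression_cv_recovered_at_large_n(self):
        """Peak-current CV across 200 cells reflects the configured
        log-normal expression CV of 0.5."""
        design = small_design(expression_cv=0.5, noise_sd=0.0)
        batch = generate_batch(design, n_cells=200, seed=2)
        peaks = []
        for sweeps in batch.values():
            app = sweeps[1]
            peaks.append(peak_current(app, segment_window(app, 1), (0.0, 2.0)))
        peaks = np.asarray(peaks)
        cv = peaks.std(ddof=1) / peaks.mean()
        assert 0.4 <= cv <= 0.6

    def test_mean_peak_converges_to_expectation(self):
        """Law of large numbers: the batch mean peak approaches the unit-
        expression peak within 3 standard errors at n = 500."""
        design = small_design(expression_cv=0.5, noise_sd=0.0)
        batch = generate_batch(design, n_cells=500, seed=9)
        peaks = np.asarray([
            peak_current(s[1], segment_window(s[1], 1), (0.0, 2.0))
            for s in batch.values()
        ])
        from dataclasses import replace

        unit = replace(design.oocyte, expression_scale=1.0)
        ref = simulate_application_sweep(design.channel, unit,
                                         design.application_sweeps[0],
                                         design.solutions, seed=0)
        expected = peak_current(ref, segment_window(ref, 1), (0.0, 2.0))
        sem = peaks.std(ddof=1) / np.sqrt(peaks.size)
        assert abs(peaks.mean() - expected) <= 3 * sem

    def test_invalid_cell_count(self):
        with pytest.raises(ValueError):
            generate_batch(small_design(), n_cells=0, seed=1)
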