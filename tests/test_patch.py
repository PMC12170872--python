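"""Single-channel analysis: idealization, NPo, conductance, occurrence, Po(V)."""

import numpy as np
import pandas as pd
import pytest

from mitoquant import patch, synth
from mitoquant.core import SynthConfig
from mitoquant.patch import (
    PatchProtocol,
    Sweep,
    UnderdeterminedError,
    idealize,
)


def _square_pulse_sweep(
    amp_pA=-2.8, fs=10_000.0, dur_s=1.0, pulses=((0.2, 0.3), (0.5, 0.65))
):
    n = int(dur_s * fs)
    i = np.zeros(n)
    for t0, t1 in pulses:
        i[int(t0 * fs) : int(t1 * fs)] = amp_pA
    return Sweep(test_mV=-80.0, current_pA=i), pulses


class TestIdealize:
    def test_flat_noise_sweep_is_silent(self):
        rng = np.random.default_rng(0)
        sweep = Sweep(test_mV=-80.0, current_pA=rng.normal(0, 0.2, 20_000))
        ideal = idealize(sweep)
        assert ideal.silent
        assert ideal.open_time_total_s == 0.0
        assert ideal.dwell_s.sum() == pytest.approx(2.0)

    def test_noiseless_square_pulses_recover_exact_dwells(self):
        sweep, pulses = _square_pulse_sweep()
        ideal = idealize(sweep)
        assert ideal.n_levels == 1
        assert ideal.unitary_amp_pA == pytest.approx(-2.8, rel=0.05)
        open_dwells = ideal.dwell_s[ideal.levels == 1]
        expected = sorted(t1 - t0 for t0, t1 in pulses)
        assert np.allclose(sorted(open_dwells), expected, atol=2e-4)

    def test_time_conservation_is_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = rng.integers(5_000, 20_000)
            sweep = Sweep(
                test_mV=-80.0,
                current_pA=rng.normal(0, 0.2, n)
                + np.where(rng.random(n) < 0.3, -2.8, 0.0),
            )
            ideal = idealize(sweep)
            assert ideal.dwell_s.sum() == pytest.approx(n / 10_000.0, abs=1e-12)

    def test_open_fraction_recovered_at_snr_6p7(self, cfg):
        proto = PatchProtocol(test_mV=(-80.0,), dur_s=2.0)
        recs, truth = synth.make_patch_sweeps(
            cfg,
            protocol=proto,
            po_by_mV={-80.0: 0.3},
            noise_sd_frac=0.15,
            sweeps_per_potential=20,
        )
        est = np.mean(
            [idealize(s).open_time_total_s / 2.0 for s in recs[0].sweeps]
        )
        true = np.mean(
            [sw["true_open_frac"] for sw in truth["patches"][0]["sweeps"]]
        )
        assert est == pytest.approx(true, rel=0.10)

    def test_mean_current_oracle_matches_npo(self, cfg):
        proto = PatchProtocol(test_mV=(-80.0,), dur_s=5.0)
        recs, _ = synth.make_patch_sweeps(
            cfg, protocol=proto, po_by_mV={-80.0: 0.4}, sweeps_per_potential=8
        )
        ideal = [idealize(s) for s in recs[0].sweeps]
        npo_est = patch.npo(ideal)
        amp = np.nanmean([s.unitary_amp_pA for s in ideal])
        mean_current = np.mean([s.current_pA.mean() for s in recs[0].sweeps])
        assert mean_current / amp == pytest.approx(npo_est, rel=0.05)


class TestNpo:
    def test_always_closed_gives_zero(self):
        sweep = Sweep(test_mV=-80.0, current_pA=np.zeros(10_000))
        assert patch.npo([idealize(sweep)]) == 0.0

    def test_always_open_gives_one(self):
        # a brief closed stretch keeps the baseline estimable from the
        # all-points histogram (a precondition of the idealization)
        n = 20_000
        i = np.full(n, -2.8)
        i[:200] = 0.0
        ideal = idealize(Sweep(test_mV=-80.0, current_pA=i))
        assert patch.npo([ideal]) == pytest.approx(1.0, abs=0.02)

    def test_two_channels_sum_their_open_probability(self):
        proto = PatchProtocol(test_mV=(-80.0,), dur_s=10.0)
        recs, truth = synth.make_patch_sweeps(
            SynthConfig(seed=42),
            protocol=proto,
            po_by_mV={-80.0: 0.3},
            n_channels=2,
            sweeps_per_potential=6,
        )
        ideal = [idealize(s) for s in recs[0].sweeps]
        est = patch.npo(ideal)
        true = np.mean(
            [sw["true_level_time_frac"] for sw in truth["patches"][0]["sweeps"]]
        )
        assert est == pytest.approx(true, abs=0.05)
        assert est == pytest.approx(0.6, abs=0.1)

    def test_npo_estimator_bias_small_on_two_state_simulations(self):
        # short-horizon version of the bias bound; the long simulation
        # lives in the acceptance suite
        for po in (0.1, 0.5, 0.9):
            biases = []
            for seed in range(5):
                proto = PatchProtocol(test_mV=(-80.0,), dur_s=10.0)
                recs, truth = synth.make_patch_sweeps(
                    SynthConfig(seed=seed),
                    protocol=proto,
                    po_by_mV={-80.0: po},
                    sweeps_per_potential=3,
                )
                ideal = [idealize(s) for s in recs[0].sweeps]
                true = np.mean(
                    [sw["true_level_time_frac"] for sw in truth["patches"][0]["sweeps"]]
                )
                biases.append(patch.npo(ideal) - true)
            assert abs(np.mean(biases)) < 0.03


class TestOccurrence:
    def test_zero_active_patches(self):
        silent = [idealize(Sweep(test_mV=-80.0, current_pA=np.zeros(1000)))]
        assert patch.occurrence([silent] * 10) == 0.0

    def test_seven_of_fourteen_is_fifty_percent(self):
        sweep, _ = _square_pulse_sweep()
        active = [idealize(sweep)]
        silent = [idealize(Sweep(test_mV=-80.0, current_pA=np.zeros(1000)))]
        patches = [active] * 7 + [silent] * 7
        assert patch.occurrence(patches) == pytest.approx(50.0)

    def test_per_day_grouping(self):
        sweep, _ = _square_pulse_sweep()
        active = [idealize(sweep)]
        silent = [idealize(Sweep(test_mV=-80.0, current_pA=np.zeros(1000)))]
        overall, per_day = patch.occurrence(
            [active, silent, active, active],
            days=["d1", "d1", "d2", "d2"],
        )
        assert overall == pytest.approx(75.0)
        assert per_day["d1"] == pytest.approx(50.0)
        assert per_day["d2"] == pytest.approx(100.0)

    def test_half_silent_synthetic_set(self, cfg):
        proto = PatchProtocol(test_mV=(-80.0,), dur_s=1.0)
        recs, truth = synth.make_patch_sweeps(
            cfg,
            protocol=proto,
            po_by_mV={-80.0: 0.5},
            n_patches=12,
            sweeps_per_potential=2,
            frac_silent=0.5,
        )
        patches = [[idealize(s) for s in r.sweeps] for r in recs]
        assert patch.occurrence(patches) == pytest.approx(50.0, abs=10.0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty_set"):
            patch.occurrence([])


class TestConductance:
    def test_exact_line_recovers_35_pS(self):
        v = np.array([-60.0, -80.0, -100.0, -120.0])
        iv = pd.DataFrame({"test_mV": v, "unitary_amp_pA": 0.035 * v})
        gamma, ci = patch.conductance(iv, n_boot=50, seed=0)
        assert gamma == pytest.approx(35.0, abs=1e-12)

    def test_closed_form_slope_to_machine_precision(self):
        rng = np.random.default_rng(3)
        v = np.repeat([-60.0, -80.0, -100.0, -120.0], 5)
        i = 0.02 * v + rng.normal(0, 0.1, len(v))
        iv = pd.DataFrame({"test_mV": v, "unitary_amp_pA": i})
        gamma, _ = patch.conductance(iv, n_boot=10, seed=0)
        vm, im = v - v.mean(), i - i.mean()
        closed_form = (vm @ im) / (vm @ vm) * 1000.0
        assert gamma == pytest.approx(closed_form, rel=1e-12)

    def test_underdetermined_with_few_potentials(self):
        iv = pd.DataFrame(
            {"test_mV": [-80.0, -100.0], "unitary_amp_pA": [-2.8, -3.5]}
        )
        with pytest.raises(UnderdeterminedError):
            patch.conductance(iv)

    def test_silent_patch_exercises_underdetermined_path(self):
        silent = [
            idealize(Sweep(test_mV=v, current_pA=np.zeros(5000)))
            for v in (-60.0, -80.0, -100.0, -120.0)
        ]
        iv = patch.mean_unitary_amplitudes(silent)
        assert iv.empty
        with pytest.raises(UnderdeterminedError):
            patch.conductance(iv)

    def test_synthetic_recordings_recover_35_pS_within_2(self, cfg):
        recs, _ = synth.make_patch_sweeps(cfg, gamma_pS=35.0, sweeps_per_potential=5)
        ideal = [idealize(s) for s in recs[0].sweeps]
        gamma, _ = patch.conductance(
            patch.mean_unitary_amplitudes(ideal), n_boot=100, seed=0
        )
        assert gamma == pytest.approx(35.0, abs=2.0)


class TestPoVoltage:
    def test_po_is_npo_over_n(self):
        sweep, pulses = _square_pulse_sweep(dur_s=1.0, pulses=((0.0, 0.2),))
        ideal = idealize(sweep)
        df = patch.po_voltage([ideal])
        assert df.loc[0, "N"] == 1
        assert df.loc[0, "Po"] == pytest.approx(0.2, abs=0.01)

    def test_voltage_dependence_ordering_recovered(self, cfg):
        recs, truth = synth.make_patch_sweeps(cfg, sweeps_per_potential=10)
        ideal = [
            idealize(s, fs_hz=recs[0].fs_hz, filter_hz=recs[0].filter_hz)
            for s in recs[0].sweeps
        ]
        df = patch.po_voltage(ideal).sort_values("test_mV", ascending=False)
        assert df.attrs["po_increases_with_hyperpolarization"]
        est = dict(zip(df["test_mV"], df["Po"]))
        true_order = sorted(truth["po_by_mV"], key=truth["po_by_mV"].get)
        est_order = sorted(est, key=est.get)
        assert true_order == est_order

    def test_calcium_free_control_is_silent_everywhere(self, cfg):
        recs, _ = synth.make_patch_sweeps(
            cfg, po_by_mV={v: 0.0 for v in (-60.0, -80.0, -100.0, -120.0)},
            sweeps_per_potential=2,
        )
        ideal = [idealize(s) for s in recs[0].sweeps]
        assert all(s.silent for s in ideal)
        df = patch.po_voltage(ideal)
        assert df["Po"].isna().all()

    def test_zero_conductance_sweeps_are_pure_noise(self, cfg):
        recs, _ = synth.make_patch_sweeps(cfg, gamma_pS=0.0, sweeps_per_potential=2)
        ideal = [idealize(s) for s in recs[0].sweeps]
        assert all(s.silent for s in ideal)
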