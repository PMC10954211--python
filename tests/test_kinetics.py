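"""Machine-cycle simulation: conservation, anchors, ordering, calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from traptamer import kinetics as K
from traptamer import trace_analysis as ta


def lattice_sum(states):
    return states[:, :K._N_LATTICE].sum(axis=1)


class TestStemFreeEnergy:
    def test_empty_duplex_zero(self):
        assert K.stem_free_energy("") == 0.0
        assert K.stem_free_energy("G") == 0.0  # no stacks in a 1-bp duplex

    def test_gc_stem_more_stable_than_au(self):
        """Oracle: direct sum over the bundled table."""
        gc = K.stem_free_energy("GCGCG")
        au = K.stem_free_energy("AUAUA")
        assert gc < au
        expected_au = sum(K.NN_STACK[s] for s in ("AU", "UA", "AU", "UA"))
        assert au == pytest.approx(expected_au)

    def test_read_direction_symmetry(self):
        for seq in ("GGCGC", "GCAGC", "GAUC", "AAUU"):
            from traptamer.sequence_design import reverse_complement
            assert K.stem_free_energy(seq) == pytest.approx(
                K.stem_free_energy(reverse_complement(seq)))

    def test_non_complementary_duplex_rejected(self):
        with pytest.raises(ValueError):
            K.stem_free_energy("GGGG", bottom="GGGG")

    def test_lock_b_stem_more_stable(self, kparams):
        assert kparams.dG_stem_b < kparams.dG_stem_a
        assert kparams.branch_rate("B") < kparams.branch_rate("A")


class TestSchedule:
    def test_event_outside_horizon_rejected(self):
        with pytest.raises(ValueError):
            K.Schedule(((300.0, "key_a", 500.0),), horizon=200.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            K.Schedule(((0.0, "keyX", 500.0),), horizon=10.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            K.Schedule(((0.0, "dye", -1.0),), horizon=10.0)


class TestSimulate:
    def test_no_keys_baseline_flat(self, kparams):
        sched = K.Schedule(((0.0, "dye", 500.0),), horizon=100.0)
        trace = K.simulate(kparams, sched)
        assert trace["signal_au"].max() == pytest.approx(
            trace["signal_au"].min(), abs=1e-9)
        assert trace["signal_au"].iloc[0] == pytest.approx(kparams.baseline_au)

    def test_probability_conservation(self, kparams):
        _, _, states = K.simulate(kparams, K.reversibility_schedule(), key_type="key_t",
                                  return_states=True)
        assert np.abs(lattice_sum(states) - 1.0).max() < 1e-6

    def test_dye_mass_conservation(self, kparams):
        _, _, states = K.simulate(kparams, K.both_keys_schedule(),
                                  return_states=True)
        bound_idx = [K._sidx(a, b, 1, 1) for a in range(3) for b in range(3)]
        total = states[:, K._N_LATTICE + 4] + 100.0 * states[:, bound_idx].sum(axis=1)
        assert np.abs(total - 500.0).max() < 1e-6

    def test_key_mass_conservation(self, kparams):
        _, _, states = K.simulate(kparams, K.reversibility_schedule(with_rekey=False),
                                  key_type="key_t", return_states=True)
        t_added = 500.0
        holding = [K._sidx(a, b, f, d) for a in (1, 2) for b in range(3)
                   for f in range(2) for d in range(2)]
        free = states[:, K._N_LATTICE + 0]
        duplex = states[:, K._N_LATTICE + 5]
        bound = 100.0 * states[:, holding].sum(axis=1)
        total = free + duplex + bound
        # before the keys are added the total is 0; afterwards it is 500
        assert np.abs(total[-1] - t_added) < 1e-4

    def test_monotone_rise_with_keys_only(self, kparams):
        trace = K.simulate(kparams, K.both_keys_schedule())
        assert (np.diff(trace["signal_au"]) >= -1e-6).all()

    def test_zero_drive_stationary(self, kparams):
        sched = K.Schedule((), horizon=50.0)
        _, _, states = K.simulate(kparams, sched, return_states=True)
        assert np.abs(states - states[0]).max() < 1e-9

    def test_activation_83_percent_at_30min_5x_both_keys(self, kparams):
        trace = K.simulate(kparams, K.both_keys_schedule(horizon=240.0))
        act = K.activation_percent(trace, kparams)
        a30 = float(np.interp(30.0, trace["time_min"], act))
        assert a30 == pytest.approx(83.0, abs=5.0)

    def test_antikeys_return_to_baseline_within_25min(self, kparams):
        trace = K.simulate(kparams, K.reversibility_schedule(with_rekey=False),
                           key_type="key_t")
        assert K.time_to_baseline(trace, kparams) <= 25.0

    def test_max_rate_ordering_and_values(self, kparams):
        rates = {}
        for kt in ("plain", "key_t", "t_key"):
            tr = K.simulate(kparams, K.both_keys_schedule(horizon=240.0),
                            key_type=kt)
            rates[kt] = ta.max_rate(tr)
        assert rates["plain"] > rates["key_t"] > rates["t_key"]
        assert rates["plain"] == pytest.approx(847.0, rel=0.05)
        assert rates["key_t"] == pytest.approx(541.0, rel=0.05)
        assert rates["t_key"] == pytest.approx(443.0, rel=0.05)

    def test_on_off_timescales(self, kparams):
        """~80 min activation and ~10 min deactivation within 20%."""
        on = K._observable(("time_on",), kparams)
        tau = K._observable(("deactivation_tau",), kparams)
        assert on == pytest.approx(80.0, rel=0.20)
        assert tau == pytest.approx(10.0, rel=0.20)

    def test_halving_lock_b_branch_lowers_key_b_activation(self, kparams):
        rt = K.GAS_CONSTANT_KCAL * kparams.temperature
        slower = replace(kparams, dG_stem_b=kparams.dG_stem_b - rt * math.log(2))
        sched = K.Schedule(((0.0, "dye", 500.0), (0.0, "key_b", 500.0)),
                           horizon=120.0)
        s_fast = K.simulate(kparams, sched)["signal_au"].iloc[-1]
        s_slow = K.simulate(slower, sched)["signal_au"].iloc[-1]
        assert s_slow < s_fast

    def test_unrelated_antikeys_do_not_turn_off(self, kparams):
        inert = replace(kparams, k_antikey=0.0)
        tr = K.simulate(inert, K.reversibility_schedule(with_rekey=False), key_type="key_t")
        t = tr["time_min"].to_numpy()
        s = tr["signal_au"].to_numpy()
        peak = s[(t >= 80) & (t <= 85)].max()
        assert s[t > 110].min() > 0.8 * peak

    def test_or_rule_single_key_activates(self, kparams):
        sched = K.Schedule(((0.0, "dye", 500.0), (0.0, "key_a", 500.0)),
                           horizon=200.0)
        s_or = K.simulate(kparams, sched, design_rule="or")["signal_au"].iloc[-1]
        s_and = K.simulate(kparams, sched, design_rule="and")["signal_au"].iloc[-1]
        assert s_or > s_and

    def test_full_cycle_reactivates_to_similar_level(self, kparams):
        tr = K.simulate(kparams, K.reversibility_schedule(), key_type="key_t")
        t = tr["time_min"].to_numpy()
        s = tr["signal_au"].to_numpy()
        peak1 = s[(t >= 5) & (t <= 85)].max()
        trough = s[(t > 85) & (t <= 150)].min()
        peak2 = s[t > 150].max()
        assert trough < 0.1 * peak1
        assert peak2 == pytest.approx(peak1, rel=0.25)

    def test_invalid_arguments(self, kparams):
        with pytest.raises(ValueError):
            K.simulate(kparams, K.both_keys_schedule(), design_rule="xor")
        with pytest.raises(ValueError):
            K.simulate(kparams, K.both_keys_schedule(), key_type="fancy")


class TestCalibrate:
    def test_single_endpoint_target_converges(self, kparams):
        p = K.calibrate([(("activation_at", 200, "plain"), 100.0)],
                        free=("k_fold",), max_nfev=10)
        val = K._observable(("activation_at", 200, "plain"), p)
        assert val == pytest.approx(100.0, abs=2.0)

    def test_recovery_of_perturbed_branch_rate(self, kparams):
        """Self-consistency: simulate with known params, calibrate from a
        perturbed start, recover the identifiable parameter within 10%."""
        target = K._observable(("max_rate", "plain"), kparams)
        start = replace(kparams, k_branch=kparams.k_branch * 1.6)
        p = K.calibrate([(("max_rate", "plain"), target)],
                        start=start, free=("k_branch",), max_nfev=25)
        assert p.k_branch == pytest.approx(kparams.k_branch, rel=0.10)

    def test_infeasible_targets_raise_with_residuals(self, kparams):
        with pytest.raises(K.SimulationError, match="residuals"):
            K.calibrate([(("max_rate", "plain"), 1e9)],
                        free=("penalty_t_key",), max_nfev=5)
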