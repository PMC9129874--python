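"""Use-dependent photobleaching model: closed forms, orderings, convergence."""

import math

import numpy as np
import pytest

from iglu import (
    BleachProtocol,
    NoiseModel,
    PoolParams,
    PoolState,
    Segment,
    SynapseConfig,
    activation,
    detectability,
    evolve_pools,
    recovery_time,
    run_protocol,
)
from iglu.bleach import IMAGING_INTENSITY, state_at_end


def no_exchange_params(**kw):
    """Exchange disabled: isolates pure bleaching kinetics."""
    return PoolParams(
        tau_exchange={"evoked_site": math.inf, "synaptic_general": math.inf,
                      "reservoir": math.inf},
        **kw,
    )


class TestActivation:
    def test_perfusion_saturates_all_compartments(self):
        seg = Segment(duration=10.0, intensity=1.0, glutamate_perfusion=True)
        a = activation(PoolParams(), seg, 3.0)
        assert all(v == 1.0 for v in a.values())

    def test_dark_quiet_segment_sits_at_tonic_floor(self):
        seg = Segment(duration=10.0, intensity=0.0, spont_rate=0.0)
        a = activation(PoolParams(a_tonic=0.05), seg, 5.0)
        assert all(v == pytest.approx(0.05) for v in a.values())

    def test_stimulation_pulses_raise_evoked_site(self):
        p = PoolParams(a_tonic=0.0, event_activation=0.3, event_duration=0.1)
        seg = Segment(duration=10.0, intensity=1.0, stim_rate=5.0, spont_rate=0.0)
        # t=0.05: pulse started at t=0 still active (duration 0.1)
        assert activation(p, seg, 0.05)["evoked_site"] == pytest.approx(0.3)
        # t=0.15: pulse 0 expired, pulse at t=0 only; next starts at 0.2
        assert activation(p, seg, 0.15)["evoked_site"] == 0.0

    def test_overlapping_pulses_clamp_to_one(self):
        p = PoolParams(a_tonic=0.0, event_activation=0.6, event_duration=0.5)
        seg = Segment(duration=10.0, intensity=1.0, stim_rate=10.0, spont_rate=0.0)
        # 5 concurrent pulses x 0.6 >> 1
        assert activation(p, seg, 0.45)["evoked_site"] == 1.0


class TestEvolvePools:
    def test_pure_bleach_matches_exponential(self):
        """Full intensity, saturated activation, no exchange: u = exp(-k t)."""
        p = no_exchange_params(k_bleach=0.14)
        proto = BleachProtocol((Segment(duration=30.0, intensity=1.0,
                                        glutamate_perfusion=True),))
        traj = evolve_pools(PoolState(), p, proto, dt=0.01)
        end = traj.iloc[-1]
        expected = math.exp(-0.14 * 30.0)
        for c in ("u_evoked_site", "u_synaptic_general"):
            assert end[c] == pytest.approx(expected, rel=1e-6)

    def test_dark_relaxation_toward_reservoir(self):
        """I = 0: each compartment relaxes to u_res with its own tau."""
        p = PoolParams()
        start = PoolState(u={"evoked_site": 0.1, "synaptic_general": 0.1,
                             "reservoir": 1.0})
        proto = BleachProtocol((Segment(duration=50.0, intensity=0.0),))
        traj = evolve_pools(start, p, proto, dt=0.5)
        u = traj["u_synaptic_general"].to_numpy()
        assert np.all(np.diff(u) > -1e-12)  # monotone recovery
        t = traj["time_s"].to_numpy()
        expected = 1.0 - 0.9 * np.exp(-t / 10.0)
        assert np.allclose(u, expected, atol=1e-4)
        # evoked barely moves over 50 s with a 6 h exchange constant
        assert traj["u_evoked_site"].iloc[-1] < 0.11

    def test_use_dependence_no_activation_no_bleaching(self):
        p = PoolParams(a_tonic=0.0)
        proto = BleachProtocol((Segment(duration=120.0, intensity=1.0,
                                        spont_rate=0.0),))
        traj = evolve_pools(PoolState(), p, proto)
        assert np.allclose(traj[["u_evoked_site", "u_synaptic_general",
                                 "u_reservoir"]].to_numpy(), 1.0)

    def test_differential_bleaching_after_ten_minutes(self):
        proto = BleachProtocol((Segment(duration=600.0, intensity=1.0),))
        end = state_at_end(evolve_pools(PoolState(), PoolParams(), proto))
        assert end.u["evoked_site"] < end.u["synaptic_general"]
        assert end.u["evoked_site"] < 0.05  # evoked essentially gone
        assert end.u["synaptic_general"] > 0.3  # spontaneous pool replenished

    def test_monotone_dose_dependence(self):
        ends = []
        for dur in (30.0, 120.0, 600.0):
            proto = BleachProtocol((Segment(duration=dur, intensity=1.0),))
            ends.append(state_at_end(evolve_pools(PoolState(), PoolParams(), proto)))
        for a, b in zip(ends, ends[1:]):
            for c in ("evoked_site", "synaptic_general", "reservoir"):
                assert b.u[c] < a.u[c] + 1e-12

    def test_bounds_hold_along_trajectory(self):
        proto = BleachProtocol((
            Segment(duration=60.0, intensity=1.0, stim_rate=0.2),
            Segment(duration=60.0, intensity=0.0),
        ))
        traj = evolve_pools(PoolState(), PoolParams(), proto)
        u = traj[["u_evoked_site", "u_synaptic_general", "u_reservoir"]].to_numpy()
        assert np.all((u >= 0.0) & (u <= 1.0))

    def test_step_halving_converges(self):
        proto = BleachProtocol((Segment(duration=120.0, intensity=1.0),))
        e1 = state_at_end(evolve_pools(PoolState(), PoolParams(), proto, dt=0.5))
        e2 = state_at_end(evolve_pools(PoolState(), PoolParams(), proto, dt=0.25))
        for c in ("evoked_site", "synaptic_general", "reservoir"):
            assert abs(e1.u[c] - e2.u[c]) < 1e-4

    def test_rejects_too_coarse_dt(self):
        proto = BleachProtocol((Segment(duration=10.0, intensity=1.0),))
        with pytest.raises(ValueError, match="too coarse"):
            evolve_pools(PoolState(), PoolParams(), proto, dt=5.0)


class TestDetectability:
    def test_unbleached_detectable_at_good_snr(self):
        d = detectability(PoolState(), SynapseConfig(quantal_amp=8.0, amp_cv=0.0),
                          NoiseModel(sigma=1.0), k=3.0)
        assert d["evoked"]["detectable"] and d["spontaneous"]["detectable"]
        assert d["evoked"]["relative_amplitude"] == 1.0

    def test_fully_bleached_undetectable(self):
        state = PoolState(u={c: 0.0 for c in ("evoked_site", "synaptic_general")}
                          | {"reservoir": 1.0})
        d = detectability(state, SynapseConfig(quantal_amp=8.0), NoiseModel(sigma=0.0))
        assert not d["evoked"]["detectable"]
        assert not d["spontaneous"]["detectable"]

    def test_differential_detectability(self):
        state = PoolState(u={"evoked_site": 0.1, "synaptic_general": 0.8,
                             "reservoir": 1.0})
        d = detectability(state, SynapseConfig(quantal_amp=10.0, amp_cv=0.0),
                          NoiseModel(sigma=1.0), k=3.0)
        assert not d["evoked"]["detectable"]      # 1 < 3
        assert d["spontaneous"]["detectable"]     # 8 >= 3


class TestRunProtocol:
    def cfg(self):
        return SynapseConfig(quantal_amp=8.0, amp_cv=0.25)

    def test_zero_bleach_leaves_metrics_at_one(self):
        proto = BleachProtocol((Segment(duration=1.0, intensity=0.0, spont_rate=0.0),))
        rep = run_protocol(PoolParams(a_tonic=0.0), self.cfg(), NoiseModel(sigma=1.0),
                           proto, recovery_horizon=10.0)
        assert np.allclose(rep[["rel_pr", "rel_freq"]].to_numpy(), 1.0)

    def test_perfusion_deepens_spontaneous_bleach(self):
        base = (Segment(duration=240.0, intensity=1.0),
                Segment(duration=120.0, intensity=1.0),
                Segment(duration=240.0, intensity=1.0))
        perf = (base[0],
                Segment(duration=120.0, intensity=1.0, glutamate_perfusion=True),
                base[2])
        end = lambda segs: run_protocol(
            PoolParams(), self.cfg(), NoiseModel(sigma=1.0),
            BleachProtocol(segs), recovery_horizon=1.0,
        ).iloc[-1]
        without, with_perf = end(base), end(perf)
        assert with_perf["rel_amp_spont"] < without["rel_amp_spont"]
        # perfusion ablates spontaneous detection outright
        assert with_perf["rel_freq"] < 0.05
        assert without["rel_freq"] > 0.5

    def test_recovery_timescales_split_by_compartment(self):
        p = PoolParams()
        t_spont = recovery_time(p.tau_exchange["synaptic_general"], 0.9)
        t_evoked = recovery_time(p.tau_exchange["evoked_site"], 0.9)
        assert t_spont < 600.0       # minutes scale
        assert t_evoked > 3600.0     # hours scale

    def test_evoked_bleaches_faster_recovers_slower(self):
        proto = BleachProtocol((Segment(duration=600.0, intensity=1.0),))
        rep = run_protocol(PoolParams(), self.cfg(), NoiseModel(sigma=1.0), proto,
                           recovery_horizon=4 * 3600.0, record_every=60.0)
        i_end = rep["time_s"].searchsorted(600.0)
        assert rep["u_evoked"].iloc[i_end] < rep["u_spont"].iloc[i_end]
        # one hour into recovery: spontaneous back near its plateau, evoked not
        i_1h = rep["time_s"].searchsorted(600.0 + 3600.0)
        spont_gain = rep["u_spont"].iloc[i_1h] - rep["u_spont"].iloc[i_end]
        evoked_1h = rep["u_evoked"].iloc[i_1h]
        assert rep["rel_freq"].iloc[i_1h] > 0.5
        assert rep["rel_pr"].iloc[i_1h] < rep["rel_freq"].iloc[i_1h]
        assert evoked_1h < rep["u_spont"].iloc[i_1h]
        assert spont_gain > 0

    def test_imaging_intensity_bleaches_slowly(self):
        proto = BleachProtocol((Segment(duration=600.0, intensity=IMAGING_INTENSITY),))
        end = state_at_end(evolve_pools(PoolState(), PoolParams(), proto))
        assert 0.9 < end.u["evoked_site"] < 1.0  # slow but nonzero
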