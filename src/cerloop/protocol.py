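"""Eyelid-conditioning protocol: stimulus coding, trials, sessions.

The tone CS is carried by mossy fibers: a random 3% fire a brief
100-ms burst at CS onset (phasic CS fibers), another 3% fire at
80-100 Hz for the whole CS (tonic CS fibers), 5.2% are recurrent
collaterals carrying a rate copy of smoothed DCN output, and the rest
fire at background rates of 1-40 Hz.  All mossy-fiber activity is
stochastic: the target rate sets the per-ms spike probability.  The US
drives the climbing fibers at US onset; the probability of that US-evoked
spike is reduced in proportion to the ongoing virtual CR (nucleo-olivary
feedback), which gives learning a behavior-dependent equilibrium.

The virtual eyelid response is the averaged, causally smoothed activity
of the DCN cells, baseline-subtracted and scaled to millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ConfigurationError, SimConfig
from .network import Network, NumericalFailure
from .plasticity import (PlasticityConfig, apply_mf_dcn_plasticity,
                         apply_pf_plasticity_indexed, _eligible)

PHASIC_FRACTION = 0.03
TONIC_FRACTION = 0.03
COLLATERAL_FRACTION = 0.052

#: millimeters of virtual eyelid closure per Hz of smoothed DCN-rate
#: elevation; calibrated once on the trained ISI-500 run so the asymptotic
#: virtual CR approaches full closure (~6 mm), then frozen
EYELID_GAIN_MM_PER_HZ = 0.1
#: DCN-rate elevation (Hz) at which the US-evoked climbing-fiber spike is
#: fully suppressed at unit nucleo-olivary gain
NO_SUPPRESSION_SCALE_HZ = 60.0
DCN_SMOOTHING_TAU_MS = 40.0


@dataclass
class MossyFiberAssignment:
    """Per-mossy-fiber role and rate assignment."""

    roles: np.ndarray            # "background" | "phasic_cs" | "tonic_cs" | "dcn_collateral"
    background_hz: np.ndarray    # used outside the CS (phasic fibers: 0)
    tonic_cs_hz: np.ndarray      # CS rate of tonic fibers (0 elsewhere)
    phasic_rate_hz: float = 120.0
    phasic_burst_ms: float = 100.0
    collateral_gain: float = 1.0
    max_rate_hz: float = 150.0

    @property
    def n_mf(self) -> int:
        return len(self.roles)

    def counts(self) -> dict:
        vals, cnt = np.unique(self.roles, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def assign_mf_roles(config: SimConfig, seed: int) -> MossyFiberAssignment:
    """Randomly designate phasic-CS (3%), tonic-CS (3%) and DCN-collateral
    (5.2%) mossy fibers; counts are rounded to the nearest integer.
    Background rates are drawn uniformly from 1-40 Hz, tonic CS rates from
    80-100 Hz.  Phasic fibers are silent outside their burst."""
    n = config.n_mf
    n_ph = round(PHASIC_FRACTION * n)
    n_to = round(TONIC_FRACTION * n)
    n_co = round(COLLATERAL_FRACTION * n)
    if n_ph + n_to + n_co >= n:
        raise ConfigurationError("CS/collateral fractions exceed the population")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    roles = np.full(n, "background", dtype=object)
    roles[order[:n_ph]] = "phasic_cs"
    roles[order[n_ph:n_ph + n_to]] = "tonic_cs"
    roles[order[n_ph + n_to:n_ph + n_to + n_co]] = "dcn_collateral"
    bg = rng.uniform(1.0, 40.0, n)
    bg[roles == "phasic_cs"] = 0.0
    tonic = np.zeros(n)
    tonic[roles == "tonic_cs"] = rng.uniform(80.0, 100.0, n_to)
    return MossyFiberAssignment(roles=roles, background_hz=bg, tonic_cs_hz=tonic)


@dataclass
class TrialSpec:
    """One conditioning trial.  Times in ms; the CS co-terminates with the
    50-ms US, so CS duration is always ISI + US duration on paired trials."""

    trial_type: str = "paired"          # "paired" | "cs_alone"
    isi: float = 500.0
    us_duration: float = 50.0
    pre_cs: float = 200.0
    post: float = 150.0
    iti_s: float = 30.0

    def __post_init__(self) -> None:
        if self.trial_type not in ("paired", "cs_alone"):
            raise ConfigurationError(f"unknown trial type {self.trial_type!r}")

    @property
    def cs_duration(self) -> float:
        return self.isi + self.us_duration

    @property
    def cs_onset(self) -> int:
        return int(self.pre_cs)

    @property
    def us_onset(self) -> int:
        """Sample index of US onset (CS-alone trials keep the nominal time
        for analysis alignment; no US is delivered)."""
        return int(self.pre_cs + self.isi)

    @property
    def duration(self) -> int:
        return int(self.pre_cs + self.cs_duration + self.post)


@dataclass
class SessionSpec:
    """12 nine-trial blocks (108 trials); each block starts with a
    CS-alone trial followed by eight paired trials."""

    isi: float = 500.0
    n_blocks: int = 12
    trials_per_block: int = 9
    iti_range_s: tuple = (20.0, 40.0)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def trial_specs(self, rng: np.random.Generator) -> list[TrialSpec]:
        specs = []
        for b in range(self.n_blocks):
            for k in range(self.trials_per_block):
                specs.append(TrialSpec(
                    trial_type="cs_alone" if k == 0 else "paired",
                    isi=self.isi,
                    iti_s=float(rng.uniform(*self.iti_range_s)),
                ))
        return specs


@dataclass
class TrialRecord:
    """Everything logged for one trial, on a common 1-ms clock starting at
    trial onset (CS onset at sample ``spec.cs_onset``)."""

    spec: TrialSpec
    spike_times: dict                   # pop -> list of per-unit arrays (ms from CS onset)
    dcn_rate: np.ndarray                # smoothed DCN population rate (Hz)
    eyelid: np.ndarray                  # virtual eyelid position (mm)
    cf_times: list                      # per-CF spike times (ms from CS onset)
    seed_stamp: Optional[int] = None


def mf_drive(assignment: MossyFiberAssignment, trial: TrialSpec, t: int,
             dcn_feedback_rate: float = 0.0) -> np.ndarray:
    """Per-mossy-fiber spike probability for time step ``t`` of a trial.

    ``t`` is the sample index from trial onset; ``dcn_feedback_rate`` is
    the current smoothed DCN population rate (Hz) feeding the collateral
    fibers.  Probability = rate x dt (dt = 1 ms), capped at 1."""
    rates = mf_rates(assignment, trial, t, dcn_feedback_rate)
    return np.minimum(rates * 1e-3, 1.0)


def mf_rates(assignment: MossyFiberAssignment, trial: TrialSpec, t: int,
             dcn_feedback_rate: float = 0.0) -> np.ndarray:
    """Target firing rate (Hz) of every mossy fiber at step ``t``."""
    a = assignment
    rates = a.background_hz.copy()
    in_cs = trial.cs_onset <= t < trial.cs_onset + trial.cs_duration
    if in_cs:
        tonic = a.roles == "tonic_cs"
        rates[tonic] = a.tonic_cs_hz[tonic]
        if t < trial.cs_onset + a.phasic_burst_ms:
            rates[a.roles == "phasic_cs"] = a.phasic_rate_hz
    coll = a.roles == "dcn_collateral"
    rates[coll] = min(a.collateral_gain * max(dcn_feedback_rate, 0.0),
                      a.max_rate_hz)
    return rates


def dcn_output_to_eyelid(dcn_spike_trains, duration: Optional[int] = None,
                         tau: float = DCN_SMOOTHING_TAU_MS,
                         gain: float = EYELID_GAIN_MM_PER_HZ,
                         baseline_window: Optional[slice] = None) -> np.ndarray:
    """Convert DCN spike trains to the virtual eyelid trace (mm).

    The per-ms population rate (mean over cells, Hz) is smoothed with a
    causal exponential kernel (unit DC gain), the pre-trace baseline is
    subtracted, and the result is scaled to millimeters."""
    trains = [np.asarray(s, dtype=float) for s in dcn_spike_trains]
    if len(trains) == 0:
        raise ValueError("need at least one DCN spike train")
    if duration is None:
        duration = int(max((s.max() for s in trains if len(s)), default=0)) + 1
    counts = np.zeros(duration)
    for s in trains:
        idx = s.astype(int)
        idx = idx[(idx >= 0) & (idx < duration)]
        np.add.at(counts, idx, 1.0)
    rate = counts / len(trains) * 1000.0
    smoothed = smooth_causal_exponential(rate, tau)
    if baseline_window is None:
        baseline_window = slice(0, max(1, duration // 5))
    return gain * (smoothed - smoothed[baseline_window].mean())


def smooth_causal_exponential(x: np.ndarray, tau: float) -> np.ndarray:
    """Causal exponential smoother with unit DC gain (shift-invariant)."""
    from scipy.signal import lfilter
    a = np.exp(-1.0 / tau)
    y = lfilter([1.0 - a], [1.0, -a], np.asarray(x, dtype=float))
    return y


# ---------------------------------------------------------------------------
# trial / session execution
# ---------------------------------------------------------------------------

def _detect_bursts_raster(cells: np.ndarray, times: np.ndarray,
                          threshold: int, window: float):
    """Vectorized burst detection on (cell, time) spike pairs sorted
    cell-major.  Returns (burst_cells, burst_times)."""
    if len(cells) == 0:
        return cells[:0], times[:0]
    same = (cells[1:] == cells[:-1]) & ((times[1:] - times[:-1]) <= window)
    new = np.concatenate([[True], ~same])
    cid = np.cumsum(new) - 1
    sizes = np.bincount(cid)
    starts = np.flatnonzero(new)
    keep = sizes >= threshold
    return cells[starts[keep]], times[starts[keep]]


def run_trial(network: Network, assignment: MossyFiberAssignment,
              trial: TrialSpec, plasticity_on: bool = True,
              rng: Optional[np.random.Generator] = None,
              pconfig: Optional[PlasticityConfig] = None,
              eyelid_gain: float = EYELID_GAIN_MM_PER_HZ,
              record_pops=("pc", "bc", "sc", "dcn")) -> TrialRecord:
    """Run one trial: step the network over pre-CS + CS + post, log all
    spikes, update plastic weights at trial end if enabled."""
    cfg = network.config
    sim = network._sim
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if pconfig is None:
        pconfig = PlasticityConfig()
    T = trial.duration
    c = cfg.counts
    off = sim.offsets
    n_mf, n_cf = c["mf"], c["cf"]

    u_mf = rng.random((n_mf, T))
    u_cf = rng.random((n_cf, T))
    p_cf_spont = cfg.cf_spontaneous_hz * 1e-3

    # static part of the mossy-fiber rate schedule
    coll = assignment.roles == "dcn_collateral"
    static_rate = np.empty((n_mf, T))
    for t in range(T):
        static_rate[:, t] = mf_rates(assignment, trial, t, 0.0)
    static_p = np.minimum(static_rate * 1e-3, 1.0)

    raster = np.zeros((sim.n, T), dtype=bool)
    y_trace = np.empty(T)
    a_sm = np.exp(-1.0 / DCN_SMOOTHING_TAU_MS)
    y = 0.0
    ext = np.zeros(sim.n)
    dcn_sl = slice(off["dcn"], off["dcn"] + c["dcn"])
    deliver_us = trial.trial_type == "paired"
    us_t = trial.us_onset
    baseline_y = 0.0

    for t in range(T):
        ext[:] = 0.0
        p = static_p[:, t].copy()
        if coll.any():
            p[coll] = min(assignment.collateral_gain * max(y, 0.0),
                          assignment.max_rate_hz) * 1e-3
        ext[off["mf"]:off["mf"] + n_mf] = u_mf[:, t] < p
        cf_p = np.full(n_cf, p_cf_spont)
        if deliver_us and t == us_t:
            elevation = max(y - baseline_y, 0.0)
            p_us = 1.0 - cfg.nucleo_olivary_gain * elevation / NO_SUPPRESSION_SCALE_HZ
            cf_p = np.maximum(cf_p, np.clip(p_us, 0.0, 1.0))
        ext[off["cf"]:off["cf"] + n_cf] = u_cf[:, t] < cf_p
        try:
            spiked = sim.step(ext)
        except FloatingPointError as e:  # pragma: no cover
            raise NumericalFailure(f"trial failed at t={t}: {e}")
        raster[:, t] = spiked
        inst = raster[dcn_sl, t].sum() / c["dcn"] * 1000.0
        y = a_sm * y + (1 - a_sm) * inst
        y_trace[t] = y
        if t == trial.cs_onset - 1:
            baseline_y = y_trace[max(0, t - 100):t + 1].mean()
    sim.check_finite()

    cs_on = trial.cs_onset
    spike_times: dict = {}
    for pop in record_pops:
        sl = slice(off[pop], off[pop] + c[pop])
        units, ts = np.nonzero(raster[sl])
        spike_times[pop] = [ts[units == u].astype(float) - cs_on
                            for u in range(c[pop])]
    cf_units, cf_ts = np.nonzero(raster[off["cf"]:off["cf"] + n_cf])
    cf_times = [cf_ts[cf_units == u].astype(float) - cs_on for u in range(n_cf)]

    baseline = y_trace[max(0, cs_on - 100):cs_on].mean()
    # closure cannot be negative: below-baseline DCN output leaves the
    # (already open) eyelid at rest
    eyelid = np.maximum(eyelid_gain * (y_trace - baseline), 0.0)

    if plasticity_on:
        _apply_trial_plasticity(network, trial, raster, cf_times, y_trace, pconfig)

    return TrialRecord(spec=trial, spike_times=spike_times, dcn_rate=y_trace,
                       eyelid=eyelid, cf_times=cf_times)


def _apply_trial_plasticity(network: Network, trial: TrialSpec,
                            raster: np.ndarray, cf_times: list,
                            y_trace: np.ndarray,
                            pconfig: PlasticityConfig) -> None:
    sim = network._sim
    cfg = network.config
    c = cfg.counts
    off = sim.offsets
    cs_on = trial.cs_onset

    grc_sl = slice(off["grc"], off["grc"] + c["grc"])
    cells, times = np.nonzero(raster[grc_sl])
    b_cells, b_times = _detect_bursts_raster(
        cells, times.astype(float) - cs_on,
        pconfig.burst_threshold, pconfig.burst_window)

    cf_of_grc = network.cf_of_pc[network.pf_target_pc]

    if pconfig.locus in ("pf_pc_only", "both") and len(b_cells):
        def groups(syn):
            cf_id = cf_of_grc[syn]
            return [(cf_id == k, np.asarray(cf_times[k]))
                    for k in range(c["cf"])]
        w = apply_pf_plasticity_indexed(
            sim.pf_weights, b_cells, b_times, groups,
            _with_wmax(pconfig, cfg.pf_w_max))
        sim.set_pf_weights(w)

    if pconfig.locus in ("pf_mli_only", "both") and len(b_cells):
        pooled_cf = np.sort(np.concatenate([np.asarray(t) for t in cf_times])) \
            if len(cf_times) else np.empty(0)
        elig = _eligible(b_times, pooled_cf, pconfig.ltd_window)
        for key in (("grc", "bc"), ("grc", "sc")):
            ch, pos = sim._plastic_pos[key]
            w_edge = sim.W[ch].data[pos]
            src = network.projections[key].sources
            w0 = float(cfg.weights[key])
            w_max = 3.0 * w0
            delta = np.zeros(c["grc"])
            # inverted sign: potentiate granule->MLI inside the window
            np.add.at(delta, b_cells,
                      np.where(elig, pconfig.ltd_step, -pconfig.ltp_step) * w_max)
            sim.W[ch].data[pos] = np.clip(w_edge + delta[src], 0.0, w_max)

    if pconfig.dcn_ltd_step > 0 or pconfig.dcn_ltp_step > 0:
        pc_sl = slice(off["pc"], off["pc"] + c["pc"])
        pc_rate = smooth_causal_exponential(
            raster[pc_sl].sum(axis=0) / c["pc"] * 1000.0, 20.0)
        mf_act = raster[off["mf"]:off["mf"] + c["mf"]]
        w0 = float(cfg.weights[("mf", "dcn")])
        pc2 = _with_wmax(pconfig, cfg.pf_w_max)
        pc2.dcn_w_max = 4.0 * w0
        w = apply_mf_dcn_plasticity(sim.mf_dcn_weights, mf_act, pc_rate, pc2,
                                    mf_of_edge=sim._mfdcn_src)
        sim.set_mf_dcn_weights(w)


def _with_wmax(pconfig: PlasticityConfig, w_max: float) -> PlasticityConfig:
    import copy
    p = copy.copy(pconfig)
    p.w_max = w_max
    return p


def run_session(network: Network, session_spec: SessionSpec, seed: int,
                plasticity_on: bool = True,
                pconfig: Optional[PlasticityConfig] = None,
                assignment: Optional[MossyFiberAssignment] = None,
                eyelid_gain: float = EYELID_GAIN_MM_PER_HZ,
                record_pops=("pc", "bc", "sc", "dcn")):
    """Run one training session (108 trials in block order).

    The stimulus-noise RNG stream derives from ``seed`` only, independent
    of the wiring seed.  Returns ``(records, pf_weight_snapshot)``."""
    rng = np.random.default_rng(seed)
    if assignment is None:
        assignment = assign_mf_roles(network.config, seed=network.config.seed + 7)
    records = []
    for i, spec in enumerate(session_spec.trial_specs(rng)):
        rec = run_trial(network, assignment, spec, plasticity_on=plasticity_on,
                        rng=rng, pconfig=pconfig, eyelid_gain=eyelid_gain,
                        record_pops=record_pops)
        rec.seed_stamp = seed
        records.append(rec)
    return records, network.pf_weights.copy()
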