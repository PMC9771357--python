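"""Seeded synthetic-data generators with recorded ground truth.

These emulate the statistical structure of the real recordings so every
analysis stage is testable without downloads: coupled PC/MLI spike
trains whose PC rate decrease leads the MLI increase around the CR,
trial-structured eyelid traces with variable CR onset and amplitude,
depressing IPSC trains from a two-pool vesicle model, and photostim map
grids with spontaneous-event contamination.  Spike trains are
inhomogeneous Bernoulli processes on the 1-ms clock (thinning), with
per-spike coupling implemented as multiplicative rate modulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .physiology import IPSCTrain, MapGrid


# ---------------------------------------------------------------------------
# conditioning-session data (emulates the in vivo recordings)
# ---------------------------------------------------------------------------

@dataclass
class SessionGenSpec:
    """Conditions of one synthetic recording session."""

    n_trials: int = 100
    isi: float = 500.0
    cr_probability: float = 0.8
    cr_onset_mean_ms: float = 250.0
    cr_onset_sd_ms: float = 50.0
    cr_amplitude_mean_mm: float = 4.0
    cr_amplitude_sd_mm: float = 1.0
    pc_baseline_hz: float = 60.0
    pc_pause_depth: float = 0.7          # fractional rate decrease during CR
    mli_baseline_hz: float = 20.0
    mli_burst_height: float = 3.0        # fractional rate increase during CR
    pc_lead_ms: float = 50.0             # PC drop starts this long before MLI rise
    coupling_magnitude: float = 0.0      # per-PC-spike MLI rate suppression (0-1)
    coupling_lag_ms: float = 2.0
    coupling_duration_ms: float = 4.0
    rate_noise_sd: float = 0.15          # trial-wise multiplicative gain SD
    eyelid_noise_mm: float = 0.02
    pre_cs_ms: int = 200
    trace_len_ms: int = 2500
    baseline_epoch_ms: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cr_probability <= 1):
            raise ValueError("cr_probability must be in [0, 1]")
        if self.pc_baseline_hz <= 0 or self.mli_baseline_hz <= 0:
            raise ValueError("baseline rates must be positive")
        if self.cr_onset_mean_ms + 150 > self.isi + 100:
            # CR onsets must usually leave room for the post-onset window
            raise ValueError("CR onset distribution too close to the US")


def _sigmoid_rise(t: np.ndarray, onset: float, tau: float = 40.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - onset - 2 * tau) / tau))


def _bernoulli_train(rate_hz: np.ndarray, rng) -> np.ndarray:
    """Spike times (ms, float with sub-ms jitter) from per-ms rates."""
    p = np.clip(np.asarray(rate_hz) * 1e-3, 0, 1)
    hits = np.flatnonzero(rng.random(len(p)) < p)
    return hits + rng.random(len(hits))


def gen_session_data(spec: SessionGenSpec) -> dict:
    """Generate one session of coupled PC/MLI activity plus eyelid traces.

    Returns a dict with per-trial eyelid traces (mm, 1 kHz, CS onset at
    ``pre_cs_ms``), per-trial PC and MLI spike times (ms from CS onset),
    inter-trial 10-s baseline epochs carrying the per-spike inhibitory
    coupling, the CR table, and the ground-truth parameters."""
    rng = np.random.default_rng(spec.seed)
    T = spec.trace_len_ms
    cs_on = spec.pre_cs_ms
    us_on = cs_on + spec.isi
    t_rel = np.arange(T, dtype=float) - cs_on       # ms from CS onset

    eyelid, pc_trials, mli_trials = [], [], []
    cr_flags, cr_onsets, cr_amps = [], [], []
    pc_base_epochs, mli_base_epochs = [], []

    for _ in range(spec.n_trials):
        is_cr = rng.random() < spec.cr_probability
        onset = amp = np.nan
        lid = rng.normal(0.0, spec.eyelid_noise_mm, T)
        pc_rate = np.full(T, spec.pc_baseline_hz)
        mli_rate = np.full(T, spec.mli_baseline_hz)
        if is_cr:
            onset = float(np.clip(
                rng.normal(spec.cr_onset_mean_ms, spec.cr_onset_sd_ms),
                60.0, spec.isi - 60.0))
            amp = float(max(0.4, rng.normal(spec.cr_amplitude_mean_mm,
                                            spec.cr_amplitude_sd_mm)))
            shape = _sigmoid_rise(t_rel, onset)
            shape[t_rel < 0] = 0.0
            lid += amp * shape
            mli_start = onset - 20.0
            pc_start = mli_start - spec.pc_lead_ms
            gain_pc = max(0.1, rng.normal(1.0, spec.rate_noise_sd))
            gain_mli = max(0.1, rng.normal(1.0, spec.rate_noise_sd))
            pc_rate = spec.pc_baseline_hz * (
                1.0 - spec.pc_pause_depth * gain_pc * _sigmoid_rise(t_rel, pc_start))
            mli_rate = spec.mli_baseline_hz * (
                1.0 + spec.mli_burst_height * gain_mli * _sigmoid_rise(t_rel, mli_start))
        eyelid.append(lid)
        pc_trials.append(_bernoulli_train(np.maximum(pc_rate, 0), rng) - cs_on)
        mli_trials.append(_bernoulli_train(np.maximum(mli_rate, 0), rng) - cs_on)
        cr_flags.append(is_cr)
        cr_onsets.append(onset)
        cr_amps.append(amp)

        # inter-trial baseline epoch with optional per-spike coupling
        L = spec.baseline_epoch_ms
        pc_ep = _bernoulli_train(np.full(L, spec.pc_baseline_hz), rng)
        mod = np.ones(L)
        if spec.coupling_magnitude > 0:
            for s in pc_ep:
                a = int(s + spec.coupling_lag_ms)
                b = int(s + spec.coupling_lag_ms + spec.coupling_duration_ms)
                mod[a:min(b, L)] *= (1.0 - spec.coupling_magnitude)
        mli_ep = _bernoulli_train(spec.mli_baseline_hz * mod, rng)
        pc_base_epochs.append(np.sort(pc_ep))
        mli_base_epochs.append(np.sort(mli_ep))

    truth = {k: v for k, v in asdict(spec).items()}
    truth["cr_onsets"] = cr_onsets
    truth["cr_amplitudes"] = cr_amps
    return {
        "eyelid_mm": np.asarray(eyelid),
        "pc_trials": pc_trials,
        "mli_trials": mli_trials,
        "pc_baseline_epochs": pc_base_epochs,
        "mli_baseline_epochs": mli_base_epochs,
        "cr_flags": np.asarray(cr_flags),
        "cs_onset": cs_on,
        "us_onset": us_on,
        "ground_truth": truth,
    }


# ---------------------------------------------------------------------------
# IPSC trains from a two-pool vesicle model
# ---------------------------------------------------------------------------

@dataclass
class IPSCGenSpec:
    """Two-pool release model: a readily releasable pool of ``n_quanta``
    releasing a fraction per stimulus, replenished from an infinite
    reserve at a baseline rate plus an activity-dependent term (quanta per
    stimulus while the train is running -- mobilization accelerates with
    stimulation)."""

    n_quanta: int = 100
    release_fraction: float = 0.07
    mobilization_baseline_qps: float = 1.0     # quanta / s at rest
    mobilization_activity_qpstim: float = 3.5  # extra quanta per stimulus
    quantal_charge_pc: float = 0.10
    quantal_amp_pa: float = 18.0
    quantal_cv: float = 0.1
    frequency_hz: float = 50.0
    n_stimuli: int = 100
    stochastic_release: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.release_fraction <= 1):
            raise ValueError("release fraction must be in (0, 1]")
        if self.n_quanta < 1:
            raise ValueError("pool must hold at least one quantum")


def paper_matched_ipsc_spec(frequency_hz: float = 50.0, seed: int = 0) -> IPSCGenSpec:
    """Preset tuned to the reported PC->PC-MLI synapse: RRP ~100 quanta,
    release probability ~0.07, and steady-state IPSCs sustained at about
    half the initial amplitude across 10-100 Hz (activity-locked
    mobilization).  Emulates trial-averaged trains: release is the
    expected per-stimulus value, with quantal-size noise only."""
    return IPSCGenSpec(frequency_hz=frequency_hz, seed=seed,
                       stochastic_release=False)


def rrp_recovery_ipsc_spec(frequency_hz: float = 50.0, seed: int = 0) -> IPSCGenSpec:
    """Preset with deep pool depletion (high release fraction, slow
    mobilization), the regime where the cumulative-charge regression
    recovers the planted pool size accurately."""
    return IPSCGenSpec(release_fraction=0.3, mobilization_activity_qpstim=1.0,
                       mobilization_baseline_qps=1.0, quantal_cv=0.05,
                       frequency_hz=frequency_hz, seed=seed)


def gen_ipsc_trains(spec: IPSCGenSpec) -> tuple[IPSCTrain, dict]:
    """Simulate one stimulus train; returns the train and ground truth."""
    rng = np.random.default_rng(spec.seed)
    isi_s = 1.0 / spec.frequency_hz
    mob_per_stim = (spec.mobilization_baseline_qps * isi_s
                    + spec.mobilization_activity_qpstim)
    pool = float(spec.n_quanta)
    quanta_out = np.empty(spec.n_stimuli)
    for i in range(spec.n_stimuli):
        if spec.stochastic_release:
            rel = rng.binomial(max(int(round(pool)), 0), spec.release_fraction)
        else:
            rel = spec.release_fraction * pool
        rel = min(rel, pool)
        pool = min(pool - rel + mob_per_stim, float(spec.n_quanta))
        quanta_out[i] = rel
    noise = 1.0 + spec.quantal_cv * rng.standard_normal(spec.n_stimuli)
    charges = np.maximum(quanta_out * spec.quantal_charge_pc * noise, 0.0)
    amps = np.maximum(quanta_out * spec.quantal_amp_pa * noise, 0.0)
    times = np.arange(spec.n_stimuli) * (1000.0 / spec.frequency_hz)
    train = IPSCTrain(frequency_hz=spec.frequency_hz, stimulus_times_ms=times,
                      amplitudes_pa=amps, charges_pc=charges)
    truth = asdict(spec)
    truth["mobilization_quanta_per_stimulus"] = mob_per_stim
    truth["mobilization_quanta_per_s"] = mob_per_stim * spec.frequency_hz
    truth["expected_plateau"] = mob_per_stim / (spec.release_fraction * spec.n_quanta)
    return train, truth


# ---------------------------------------------------------------------------
# photostimulation maps
# ---------------------------------------------------------------------------

def gen_map_trials(planted_pixels: np.ndarray, spontaneous_rate: float,
                   n_repeats: int, seed: int,
                   response_probability: float = 0.9,
                   response_amp_pa: float = 40.0,
                   spontaneous_amp_pa: float = 25.0,
                   kind: str = "ipsc") -> tuple[MapGrid, dict]:
    """Planted-field photostimulation maps with spontaneous contamination.

    ``planted_pixels`` is a boolean 32x32 mask; planted pixels respond
    with ``response_probability`` per repeat; every pixel is additionally
    contaminated by a spontaneous suprathreshold event with probability
    ``spontaneous_rate`` per repeat."""
    planted = np.asarray(planted_pixels, dtype=bool)
    if planted.shape != (32, 32):
        raise ValueError("planted mask must be 32 x 32")
    rng = np.random.default_rng(seed)
    maps = np.zeros((n_repeats, 32, 32))
    for r in range(n_repeats):
        hit = planted & (rng.random((32, 32)) < response_probability)
        maps[r][hit] = response_amp_pa
        spont = rng.random((32, 32)) < spontaneous_rate
        maps[r][spont & ~hit] = spontaneous_amp_pa
    if kind == "spike":
        maps = (maps > 0).astype(float)
    truth = {"n_planted": int(planted.sum()),
             "response_probability": response_probability,
             "spontaneous_rate": spontaneous_rate}
    return MapGrid(maps, kind=kind), truth


# ---------------------------------------------------------------------------
# correlation-coefficient mixtures
# ---------------------------------------------------------------------------

def gen_mixture_sample(means=(-0.05, 0.43), sds=(0.15, 0.15),
                       weights=(0.9, 0.1), n: int = 800,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Labeled draws from a two-Gaussian mixture, clipped to [-1, 1]."""
    if not np.isclose(sum(weights), 1.0):
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(weights), size=n, p=weights)
    vals = rng.normal(np.asarray(means)[labels], np.asarray(sds)[labels])
    return np.clip(vals, -1.0, 1.0), labels


def write_ground_truth(path, truth: dict) -> None:
    """Persist a generator's ground truth as a JSON sidecar."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=default)
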