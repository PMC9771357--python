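"""Desk-scale simulation experiments: training batteries and the
analyses run on their output.

The reference desk-scale condition is a 1/6-granule-layer network (2,000
granule cells, full cortical-output and molecular-layer populations)
trained for 10 sessions of 108 trials.  The functions here train such
networks with and without PC->PC-MLI feedback and compute the
feedback-circuit statistics: per-MLI correlation of activity with the
virtual CR (and its two-Gaussian structure), the PC-vs-MLI lead-lag
distribution, acquisition curves, and parallel-fiber weight-change
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .behavior import CR_CRITERION_MM
from .config import SimConfig
from .network import Network, build_network
from .plasticity import PlasticityConfig, weight_change_summary
from .protocol import SessionSpec, assign_mf_roles, run_session
from .spikes import (RateTrace, cr_correlation, instantaneous_rate,
                     normalize_rate, pre_cr_fraction, session_average_cs_max)

DESK_SCALE = 1 / 6


@dataclass
class TrainingResult:
    net: Network
    records_last: list                 # full TrialRecords of the final session
    session_amplitudes: list           # mean paired-trial CR amplitude per session
    initial_weights: np.ndarray
    final_weights: np.ndarray
    isi: float


def train_network(isi: float = 500.0, feedback: bool = True,
                  n_sessions: int = 10, seed: int = 1,
                  scale: float = DESK_SCALE,
                  locus: str = "pf_pc_only",
                  pconfig: Optional[PlasticityConfig] = None) -> TrainingResult:
    """Train a fresh desk-scale network; deterministic in ``seed``."""
    cfg = SimConfig(seed=seed, scale_factor=scale, feedback_enabled=feedback)
    net = build_network(cfg)
    assignment = assign_mf_roles(cfg, seed=seed + 7)
    if pconfig is None:
        pconfig = PlasticityConfig(locus=locus)
    spec = SessionSpec(isi=isi)
    w0 = net.pf_weights.copy()
    amps = []
    records = None
    for s in range(n_sessions):
        pops = ("pc", "bc", "sc", "dcn") if s == n_sessions - 1 else ("dcn",)
        records, w_snap = run_session(net, spec, seed=seed * 1000 + s,
                                      pconfig=pconfig, assignment=assignment,
                                      record_pops=pops)
        us = records[1].spec.us_onset
        amps.append(float(np.mean([r.eyelid[us] for r in records
                                   if r.spec.trial_type == "paired"])))
    return TrainingResult(net=net, records_last=records,
                          session_amplitudes=amps,
                          initial_weights=w0, final_weights=net.pf_weights.copy(),
                          isi=isi)


# ---------------------------------------------------------------------------
# analyses on trained runs
# ---------------------------------------------------------------------------

def _trial_clock(rec):
    """(t_start, duration) of a trial record on the CS-onset clock."""
    return -float(rec.spec.pre_cs), rec.spec.duration


def mli_correlation_analysis(result: TrainingResult,
                             kernel_sd: float = 25.0) -> dict:
    """Per-MLI mean correlation with the virtual CR over the final
    session's CR trials, separated into PC-MLIs and other MLIs."""
    recs = result.records_last
    us = recs[0].spec.us_onset
    isi = result.isi
    t0, T = _trial_clock(recs[0])
    eyelid = [r.eyelid for r in recs]
    cr_flags = [r.eyelid[us] >= CR_CRITERION_MM for r in recs]

    pcmli = set(result.net.pcmli_indices.tolist())
    rows = []
    for pop, n in (("bc", result.net.config.n_bc), ("sc", result.net.config.n_sc)):
        for u in range(n):
            rates = [instantaneous_rate(r.spike_times[pop][u], duration=T,
                                        t_start=t0, kernel_sd=kernel_sd)
                     for r in recs]
            mx = session_average_cs_max(rates, cs_end_ms=isi + 50.0)
            if mx <= 0:
                continue
            normed = [normalize_rate(rt, "MLI", mli_session_cs_max_hz=mx)
                      for rt in rates]
            res = cr_correlation(normed, eyelid, cr_flags, us_onset_ms=isi)
            is_pcmli = pop == "bc" and u in pcmli
            rows.append((f"{pop}_{u}", res.mean_r, is_pcmli))
    r_all = np.array([r for _, r, _ in rows if np.isfinite(r)])
    labels = np.array([p for _, r, p in rows if np.isfinite(r)])
    return {"r": r_all, "is_pcmli": labels,
            "mean_r_pcmli": float(r_all[labels].mean()) if labels.any() else np.nan,
            "mean_r_other": float(r_all[~labels].mean()),
            "n_cr_trials": int(np.sum(cr_flags))}


def bimodality_bic(r_values: np.ndarray, random_state: int = 0) -> dict:
    """Compare one- vs two-component Gaussian fits of the correlation
    distribution by BIC (lower wins)."""
    from sklearn.mixture import GaussianMixture
    r = np.asarray(r_values, dtype=float).reshape(-1, 1)
    out = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=5,
                             random_state=random_state).fit(r)
        out[k] = {"bic": float(gm.bic(r)),
                  "means": np.sort(gm.means_.ravel()).tolist()}
    out["two_component_preferred"] = out[2]["bic"] < out[1]["bic"]
    return out


def leadlag_analysis(result: TrainingResult, kernel_sd: float = 25.0) -> np.ndarray:
    """Distribution of per-pair lead-lag differences on the final session.

    For every (PC, PC-MLI) pair: the fraction of the PC's full rate
    decrease (and the PC-MLI's full increase) completed at CR onset is
    computed per usable CR trial and averaged per unit; the pair value is
    the PC fraction minus the MLI fraction (positive = PC leads)."""
    from .behavior import EyelidTrace, cr_measures
    from .spikes import pre_cr_change_fraction
    recs = result.records_last
    isi = result.isi
    t0, T = _trial_clock(recs[0])
    us = recs[0].spec.us_onset
    pre = int(recs[0].spec.pre_cs)
    win = 150.0 if isi > 250 else 100.0

    onsets = {}
    for i, r in enumerate(recs):
        m = cr_measures(EyelidTrace(r.eyelid, cs_onset=pre, us_onset=us))
        if m.is_cr and m.onset_latency is not None \
                and 0 < m.onset_latency and m.onset_latency + win <= isi:
            onsets[i] = m.onset_latency
    if not onsets:
        return np.empty(0)

    net = result.net

    def unit_fractions(pop, unit, decreasing):
        vals = []
        for i, onset in onsets.items():
            rate = instantaneous_rate(recs[i].spike_times[pop][unit], T,
                                      t_start=t0, kernel_sd=kernel_sd)
            vals.append(pre_cr_change_fraction(rate, onset, isi, decreasing))
        return float(np.mean(vals))

    pc_frac = np.array([unit_fractions("pc", u, True)
                        for u in range(net.config.n_pc)])
    mli_frac = np.array([unit_fractions("bc", u, False)
                         for u in net.pcmli_indices])
    return (pc_frac[:, None] - mli_frac[None, :]).ravel()


def weight_change_comparison(result_fb: TrainingResult,
                             result_nofb: TrainingResult,
                             strong_ltd_fraction: float = 0.25) -> dict:
    """Fig-12-style comparison of net parallel-fiber weight changes with
    vs without feedback.  ``strong_ltd_fraction``: cutoff below which a
    change counts as strong LTD, as a fraction of the weight ceiling."""
    w_max = result_fb.net.config.pf_w_max
    bw = 0.05 * w_max
    lim = (-w_max, w_max)
    s_fb = weight_change_summary(result_fb.initial_weights,
                                 result_fb.final_weights, bw, lim)
    s_no = weight_change_summary(result_nofb.initial_weights,
                                 result_nofb.final_weights, bw, lim)
    cutoff = -strong_ltd_fraction * w_max
    return {
        "summary_fb": s_fb, "summary_nofb": s_no,
        "difference": s_fb.difference(s_no),
        "n_strong_ltd_fb": s_fb.n_below(cutoff),
        "n_strong_ltd_nofb": s_no.n_below(cutoff),
        "n_net_ltd_fb": int((s_fb.changes < -0.02 * w_max).sum()),
        "n_net_ltp_fb": int((s_fb.changes > 0.02 * w_max).sum()),
        "n_net_ltd_nofb": int((s_no.changes < -0.02 * w_max).sum()),
        "n_net_ltp_nofb": int((s_no.changes > 0.02 * w_max).sum()),
    }


def run_feedback_battery(seed: int = 1, n_sessions: int = 10,
                         scale: float = DESK_SCALE) -> dict:
    """Train the four desk-scale conditions (ISI 500 and 150, feedback on
    and off) and compute the feedback-circuit statistics on them."""
    from scipy import stats

    fb500 = train_network(isi=500.0, feedback=True, n_sessions=n_sessions,
                          seed=seed, scale=scale)
    no500 = train_network(isi=500.0, feedback=False, n_sessions=n_sessions,
                          seed=seed, scale=scale)
    fb150 = train_network(isi=150.0, feedback=True, n_sessions=n_sessions,
                          seed=seed, scale=scale)
    no150 = train_network(isi=150.0, feedback=False, n_sessions=n_sessions,
                          seed=seed, scale=scale)

    corr_fb = mli_correlation_analysis(fb500)
    corr_no = mli_correlation_analysis(no500)
    bic_fb = bimodality_bic(corr_fb["r"])
    bic_no = bimodality_bic(corr_no["r"])
    leadlag = leadlag_analysis(fb500)
    weights = weight_change_comparison(fb500, no500)

    return {
        "results": {"fb500": fb500, "no500": no500,
                    "fb150": fb150, "no150": no150},
        "corr_fb": corr_fb, "corr_no": corr_no,
        "bic_fb": bic_fb, "bic_no": bic_no,
        "skew_fb": float(stats.skew(corr_fb["r"])),
        "skew_no": float(stats.skew(corr_no["r"])),
        "leadlag": leadlag,
        "weights": weights,
        "amp150_fb": fb150.session_amplitudes[-1],
        "amp150_no": no150.session_amplitudes[-1],
        "amp500_fb": fb500.session_amplitudes[-1],
        "amp500_no": no500.session_amplitudes[-1],
    }
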