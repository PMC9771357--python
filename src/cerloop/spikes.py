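"""Single-unit spike-train analyses.

Kernel rate estimation (one-sided Gaussian, causal), PC/MLI rate
normalization, trial-wise correlation of unit rate with the conditioned
response, two-Gaussian mixture classification of those correlations with
a posterior-membership cutoff, spike/pause/burst-triggered
cross-correlograms with inter-spike-interval-shuffle nulls, the
lead-lag statistic (fraction of the full rate change completed before CR
onset, PC minus MLI), and trial grouping by CR onset or amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

Z_THRESHOLD = 3.34           # 95% two-sided, Bonferroni over 60 usable bins
CORRELOGRAM_WINDOW_MS = 30
DEFAULT_KERNEL_SD_MS = 25.0


class InsufficientDataError(ValueError):
    """Too few spikes/intervals/trials for the requested analysis."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Sorted spike times of one unit: per-trial times (ms from CS onset,
    negative allowed) plus optional inter-trial baseline epochs (each an
    array of times within the epoch, typically 10 s long)."""

    unit_id: str
    label: str = "unknown"            # "PC" | "MLI" | "unknown"
    trials: list = field(default_factory=list)
    baseline_epochs: list = field(default_factory=list)
    epoch_length_ms: float = 10_000.0

    def __post_init__(self) -> None:
        for arr in list(self.trials) + list(self.baseline_epochs):
            a = np.asarray(arr)
            if len(a) > 1 and np.any(np.diff(a) <= 0):
                raise ValueError("spike times must be strictly increasing")


@dataclass
class RateTrace:
    """Kernel-estimated instantaneous rate on the 1-ms clock."""

    rate: np.ndarray                  # Hz (dimensionless if normalized)
    t_start: float                    # time of sample 0, ms from CS onset
    kernel_sd: float = DEFAULT_KERNEL_SD_MS
    normalization: str = "none"       # none | pc_baseline | mli_cs_max
    normalizer: float = 1.0

    def time(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.rate))


@dataclass
class CorrelationResult:
    r_per_trial: np.ndarray
    mean_r: float
    n_cr_trials: int
    n_excluded: int = 0


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    skewness: float
    cutoff: Optional[float]
    membership_level: float
    assignments: np.ndarray            # 0 = low-mean, 1 = high-mean component
    degenerate: bool = False


@dataclass
class CorrelogramResult:
    lags: np.ndarray                   # ms, -30..30
    counts: np.ndarray
    norm_counts: np.ndarray            # counts / shuffle mean
    z: np.ndarray
    significant: bool
    trigger_type: str                  # spike | pause_start | burst_start
    lag0_excluded: bool = True
    n_triggers: int = 0


@dataclass
class LeadLagResult:
    delta_pc: float
    delta_mli: float
    difference: float
    post_window_ms: float


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def causal_gaussian_kernel(sd: float = DEFAULT_KERNEL_SD_MS) -> np.ndarray:
    """One-sided (causal) Gaussian kernel on the ms grid, unit area.

    Support starts at the spike: the kernel spreads each spike only
    *forward* in time, so responses to later events (e.g. the US) cannot
    leak backward into the CS period."""
    u = np.arange(0, int(np.ceil(5 * sd)) + 1)
    k = np.exp(-0.5 * (u / sd) ** 2)
    return k / k.sum()


def instantaneous_rate(spike_times, duration: int, t_start: float = 0.0,
                       kernel_sd: float = DEFAULT_KERNEL_SD_MS) -> RateTrace:
    """Causal kernel rate estimate (Hz) over ``duration`` ms.

    ``spike_times`` are ms relative to the same origin as ``t_start``
    (sample 0 of the output sits at ``t_start``).  The rate at time t
    depends only on spikes at or before t, and the rate integral over an
    unclipped window equals the spike count."""
    t = np.asarray(spike_times, dtype=float)
    binned = np.zeros(duration)
    idx = np.floor(t - t_start).astype(int)
    idx = idx[(idx >= 0) & (idx < duration)]
    np.add.at(binned, idx, 1.0)
    k = causal_gaussian_kernel(kernel_sd)
    rate = np.convolve(binned, k)[:duration] * 1000.0
    return RateTrace(rate=rate, t_start=t_start, kernel_sd=kernel_sd)


def normalize_rate(rate: RateTrace, label: str,
                   pc_baseline_hz: Optional[float] = None,
                   mli_session_cs_max_hz: Optional[float] = None) -> RateTrace:
    """Label-specific normalization.

    PCs are normalized by their pre-CS baseline rate (nominally measured
    over 1500 ms of pre-CS activity).  MLIs are normalized by the maximum,
    within the CS, of the unit's session-averaged rate -- so MLIs with 2x
    and 10x CR-related modulation contribute on equal (max 1) scales."""
    if label == "PC":
        if pc_baseline_hz is None:
            pre = rate.rate[rate.time() < 0]
            if len(pre) == 0:
                raise ValueError("no pre-CS samples to form a PC baseline")
            pc_baseline_hz = float(pre.mean())
        norm, mode = pc_baseline_hz, "pc_baseline"
    elif label == "MLI":
        if mli_session_cs_max_hz is None:
            raise ValueError("MLI normalization needs the session-average CS maximum")
        norm, mode = float(mli_session_cs_max_hz), "mli_cs_max"
    else:
        raise ValueError(f"unknown label {label!r}")
    if norm <= 0:
        raise ZeroDivisionError(f"normalizer for {label} is zero")
    return RateTrace(rate=rate.rate / norm, t_start=rate.t_start,
                     kernel_sd=rate.kernel_sd, normalization=mode,
                     normalizer=norm)


def session_average_cs_max(trial_rates: Sequence[RateTrace],
                           cs_onset_ms: float = 0.0,
                           cs_end_ms: float = 550.0) -> float:
    """Maximum, within the CS, of the session-averaged rate trace."""
    stack = np.stack([r.rate for r in trial_rates])
    mean = stack.mean(axis=0)
    t = trial_rates[0].time()
    in_cs = (t >= cs_onset_ms) & (t < cs_end_ms)
    return float(mean[in_cs].max())


# ---------------------------------------------------------------------------
# behavioral correlation
# ---------------------------------------------------------------------------

def cr_correlation(trial_rates: Sequence[RateTrace], eyelid_traces,
                   cr_flags, us_onset_ms: float,
                   window_start_ms: float = -150.0) -> CorrelationResult:
    """Zero-lag Pearson correlation of unit rate with eyelid position,
    per CR trial over [-150 ms, US onset), averaged across CR trials.

    ``eyelid_traces`` are per-trial arrays on the same clock as the rate
    traces (sample 0 at ``trial_rates[i].t_start``).  Trials with a
    zero-variance segment are excluded and counted."""
    rs, n_excluded = [], 0
    for rate, lid, is_cr in zip(trial_rates, eyelid_traces, cr_flags):
        if not is_cr:
            continue
        t = rate.time()
        sel = (t >= window_start_ms) & (t < us_onset_ms)
        x = rate.rate[sel]
        y = np.asarray(lid, dtype=float)[sel]
        if x.std() == 0 or y.std() == 0:
            n_excluded += 1
            continue
        x = x - x.mean()
        y = y - y.mean()
        rs.append(float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y))))
    rs = np.asarray(rs)
    mean_r = float(rs.mean()) if len(rs) else np.nan
    return CorrelationResult(rs, mean_r, len(rs), n_excluded)


def fit_two_gaussian_mixture(r_values, membership_level: float = 0.95,
                             cutoff_method: str = "posterior",
                             random_state: int = 0) -> MixtureFit:
    """Maximum-likelihood two-Gaussian fit to a sample of correlation
    coefficients, with the classification cutoff r*.

    ``cutoff_method="posterior"`` (default): r* is the smallest r at which
    the posterior membership in the higher-mean component reaches
    ``membership_level``.  ``cutoff_method="tail"``: r* is the point
    beyond which only 1 - level of the low-mean component's mass remains.
    """
    from sklearn.mixture import GaussianMixture
    r = np.asarray(r_values, dtype=float).reshape(-1, 1)
    if len(r) < 20:
        raise InsufficientDataError("need at least 20 correlation values")
    # EM on an unbalanced, overlapping mixture is initialization-
    # sensitive: try a spread of inits and keep the best-likelihood fit
    # whose components remain separated (guards against collapse)
    candidates = []
    for kw in (dict(n_init=10, init_params="random_from_data"),
               dict(n_init=1, means_init=[[np.percentile(r, 40)],
                                          [np.percentile(r, 97)]])):
        g = GaussianMixture(n_components=2, random_state=random_state,
                            max_iter=500, tol=1e-7, **kw).fit(r)
        candidates.append(g)
    def _sep(g):
        m = g.means_.ravel()
        s = np.sqrt(g.covariances_.ravel()).mean()
        return abs(m[1] - m[0]) / max(s, 1e-9)
    ok = [g for g in candidates if _sep(g) >= 1.5 and g.weights_.min() >= 0.01]
    pool = ok if ok else candidates
    gm = max(pool, key=lambda g: g.lower_bound_)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    skewness = float(stats.skew(r.ravel()))
    sep = abs(means[1] - means[0])
    degenerate = bool(weights.min() < 0.01 or sep < 0.5 * max(sds.mean(), 1e-6))
    cutoff = None
    if not degenerate:
        grid = np.linspace(means[0], means[1] + 6 * sds[1], 4001)
        if cutoff_method == "posterior":
            log_hi = np.log(weights[1]) + stats.norm.logpdf(grid, means[1], sds[1])
            log_lo = np.log(weights[0]) + stats.norm.logpdf(grid, means[0], sds[0])
            post_hi = 1.0 / (1.0 + np.exp(log_lo - log_hi))
            hit = np.flatnonzero(post_hi >= membership_level)
        elif cutoff_method == "tail":
            hit = np.flatnonzero(stats.norm.cdf(grid, means[0], sds[0])
                                 >= membership_level)
        else:
            raise ValueError(f"unknown cutoff_method {cutoff_method!r}")
        if len(hit):
            cutoff = float(grid[hit[0]])
    if cutoff is not None:
        assignments = (r.ravel() >= cutoff).astype(int)
    else:
        resp = gm.predict_proba(r)
        assignments = (resp[:, order[1]] >= 0.5).astype(int)
    return MixtureFit(means, sds, weights, skewness, cutoff,
                      membership_level, assignments, degenerate)


def classify_putative_pcmli(r_values, cutoff: float = 0.43) -> np.ndarray:
    """Putative PC-MLI labels: correlation at or above the cutoff."""
    return np.asarray(r_values, dtype=float) >= cutoff


# ---------------------------------------------------------------------------
# triggered cross-correlograms
# ---------------------------------------------------------------------------

def _bin_train(times: np.ndarray, length: int) -> np.ndarray:
    b = np.zeros(length, dtype=np.float32)
    idx = np.floor(times).astype(int)
    idx = idx[(idx >= 0) & (idx < length)]
    np.add.at(b, idx, 1.0)
    return b


def _lagged_counts(trigger_binned: np.ndarray, target_binned: np.ndarray,
                   window: int) -> np.ndarray:
    """counts[lag] = sum_t trigger[t] * target[t + lag], lag in [-w, w]."""
    T = len(target_binned)
    padded = np.zeros(T + 2 * window, dtype=np.float32)
    padded[window:window + T] = target_binned
    if trigger_binned.ndim == 1:
        trigger_binned = trigger_binned[None, :]
    n_lag = 2 * window + 1
    out = np.empty((trigger_binned.shape[0], n_lag), dtype=np.float64)
    for j in range(n_lag):
        out[:, j] = trigger_binned @ padded[j:j + T]
    return out


def _shuffle_isis(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the train's inter-spike intervals (preserves rate and the
    ISI marginal, destroys spike timing)."""
    if len(times) < 3:
        return times.copy()
    isis = np.diff(times)
    return times[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(isis))])


def _correlogram_core(trigger_epochs, target_epochs, epoch_len, n_shuffles,
                      rng, trigger_extractor):
    """Shared machinery: real and shuffled lagged counts accumulated over
    epochs.  ``trigger_extractor`` maps a raw trigger train to the event
    times the correlogram is aligned to."""
    w = CORRELOGRAM_WINDOW_MS
    L = int(epoch_len)
    counts = np.zeros(2 * w + 1)
    shuf = np.zeros((n_shuffles, 2 * w + 1))
    n_triggers = 0
    for trig, targ in zip(trigger_epochs, target_epochs):
        trig = np.asarray(trig, dtype=float)
        targ = np.asarray(targ, dtype=float)
        events = trigger_extractor(trig)
        n_triggers += len(events)
        tb = _bin_train(events, L)
        gb = _bin_train(targ, L)
        counts += _lagged_counts(tb, gb, w)[0]
        shuffled = np.empty((n_shuffles, L), dtype=np.float32)
        for s in range(n_shuffles):
            ev = trigger_extractor(_shuffle_isis(trig, rng))
            shuffled[s] = _bin_train(ev, L)
        shuf += _lagged_counts(shuffled, gb, w)
    return counts, shuf, n_triggers


def _finalize(counts, shuf, trigger_type, n_triggers,
              post_minus_pre_rule=False) -> CorrelogramResult:
    w = CORRELOGRAM_WINDOW_MS
    lags = np.arange(-w, w + 1, dtype=float)
    mean = shuf.mean(axis=0)
    sd = shuf.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(mean > 0, counts / mean, np.nan)
        z = np.where(sd > 0, (counts - mean) / sd, 0.0)
    usable = lags != 0
    sig_bins = (np.abs(z) >= Z_THRESHOLD) & usable
    if post_minus_pre_rule:
        significant = int(sig_bins[lags > 0].sum()) - int(sig_bins[lags < 0].sum()) >= 2
    else:
        significant = int(sig_bins.sum()) >= 2
    return CorrelogramResult(lags=lags, counts=counts, norm_counts=norm, z=z,
                             significant=bool(significant),
                             trigger_type=trigger_type, n_triggers=n_triggers)


def spike_triggered_correlogram(trigger: SpikeTrain, target: SpikeTrain,
                                n_shuffles: int = 200,
                                rng: Optional[np.random.Generator] = None
                                ) -> CorrelogramResult:
    """Cross-correlogram of target spikes around each trigger spike
    (1-ms bins, +-30 ms) over the 10-s pre-trial baseline epochs, with an
    ISI-shuffle null.  Significant iff at least two bins other than lag 0
    reach |Z| >= 3.34 (95% two-sided, Bonferroni over the 60 usable bins).
    The lag-0 bin is never interpreted (same-tetrode spike collisions)."""
    if rng is None:
        rng = np.random.default_rng(0)
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    if sum(len(e) for e in trigger.baseline_epochs) < 2:
        raise InsufficientDataError("fewer than 2 trigger spikes")
    counts, shuf, n_trig = _correlogram_core(
        trigger.baseline_epochs, target.baseline_epochs,
        trigger.epoch_length_ms, n_shuffles, rng, lambda t: t)
    return _finalize(counts, shuf, "spike", n_trig)


def select_extreme_isi_starts(times: np.ndarray, percentile: float,
                              largest: bool) -> np.ndarray:
    """Start times of the largest (pauses) or smallest (bursts)
    ``percentile`` fraction of inter-spike intervals.  The trigger count
    uses ceiling rounding and ties at the threshold ISI are all included;
    a selection that degenerates to every interval (constant-ISI train)
    yields no triggers."""
    times = np.asarray(times, dtype=float)
    isis = np.diff(times)
    n = len(isis)
    if n == 0:
        return times[:0]
    k = int(np.ceil(percentile * n))
    srt = np.sort(isis)
    thr = srt[-k] if largest else srt[k - 1]
    sel = isis >= thr if largest else isis <= thr
    if sel.all() and n > 1:
        return times[:0]                  # degenerate ties: no extremes exist
    return times[:-1][sel]


def event_triggered_correlogram(trigger: SpikeTrain, target: SpikeTrain,
                                event: str = "pause",
                                percentile: float = 0.35,
                                n_shuffles: int = 200,
                                rng: Optional[np.random.Generator] = None
                                ) -> CorrelogramResult:
    """Correlogram aligned to starts of PC pauses (largest ``percentile``
    fraction of inter-spike intervals) or bursts (smallest fraction),
    shuffle-normalized as for spike triggers.  Significance uses the
    post-vs-pre rule: at least two more significant bins after t=0 than
    before."""
    if event not in ("pause", "burst"):
        raise ValueError("event must be 'pause' or 'burst'")
    if rng is None:
        rng = np.random.default_rng(0)
    n_isi = sum(max(0, len(e) - 1) for e in trigger.baseline_epochs)
    if n_isi < 10:
        raise InsufficientDataError("fewer than 10 inter-spike intervals")
    extract = lambda t: select_extreme_isi_starts(t, percentile, event == "pause")
    counts, shuf, n_trig = _correlogram_core(
        trigger.baseline_epochs, target.baseline_epochs,
        trigger.epoch_length_ms, n_shuffles, rng, extract)
    if n_trig == 0:
        raise InsufficientDataError("no extreme-interval triggers (tied ISIs)")
    return _finalize(counts, shuf, f"{event}_start", n_trig,
                     post_minus_pre_rule=True)


# ---------------------------------------------------------------------------
# lead-lag statistic
# ---------------------------------------------------------------------------

def post_cr_window_ms(isi: float) -> float:
    """Post-CR-onset analysis window: 100 ms at ISI 250, 150 ms at the
    longer ISIs (500/700/750)."""
    return 100.0 if isi <= 250 else 150.0


def pre_cr_fraction(pc_rate: RateTrace, mli_rate: RateTrace,
                    cr_onset_ms: float, isi: float) -> LeadLagResult:
    """Fraction of the full PC decrease (and MLI increase) completed
    before CR onset; their difference is positive when the PC leads.

    The full change runs from the pre-CS baseline to the extremum within
    [CR onset, CR onset + window]; trials whose window would overlap the
    US are excluded (raises :class:`InsufficientDataError`)."""
    win = post_cr_window_ms(isi)
    d_pc = pre_cr_change_fraction(pc_rate, cr_onset_ms, isi, decreasing=True)
    d_mli = pre_cr_change_fraction(mli_rate, cr_onset_ms, isi, decreasing=False)
    return LeadLagResult(d_pc, d_mli, d_pc - d_mli, win)


def pre_cr_change_fraction(rate: RateTrace, cr_onset_ms: float, isi: float,
                           decreasing: bool) -> float:
    """Fraction of one unit's full rate change (baseline to extremum in
    the post-onset window) already completed at CR onset, clipped to
    [0, 1]; 0 is returned when the cell shows no change in the expected
    direction."""
    win = post_cr_window_ms(isi)
    if cr_onset_ms + win > isi:
        raise InsufficientDataError(
            "CR onset too close to the US for the post-onset window")
    t = rate.time()
    pre = rate.rate[t < 0]
    if len(pre) == 0:
        raise ValueError("rate trace lacks pre-CS samples")
    baseline = pre.mean()
    sel = (t >= cr_onset_ms) & (t <= cr_onset_ms + win)
    seg = rate.rate[sel]
    at_onset = rate.rate[min(np.searchsorted(t, cr_onset_ms), len(t) - 1)]
    if decreasing:
        full = baseline - seg.min()
        pre_change = baseline - at_onset
    else:
        full = seg.max() - baseline
        pre_change = at_onset - baseline
    if full <= 0:
        return 0.0
    return float(np.clip(pre_change / full, 0.0, 1.0))


# ---------------------------------------------------------------------------
# trial grouping
# ---------------------------------------------------------------------------

def group_trials(cr_values, traces, n_groups: int, cr_mask=None):
    """Divide CR trials into equal-count subgroups after sorting by CR
    onset or amplitude (``cr_values``); the remainder goes to the last
    group, and non-CR trials form their own group.

    ``traces`` maps name -> (n_trials, T) array; returns a list of dicts
    with trial indices, per-trace means, and pointwise 95% CIs."""
    cr_values = np.asarray(cr_values, dtype=float)
    n_trials = len(cr_values)
    if cr_mask is None:
        cr_mask = np.isfinite(cr_values)
    cr_idx = np.flatnonzero(cr_mask)
    if len(cr_idx) < n_groups:
        raise InsufficientDataError("fewer CR trials than groups")
    order = cr_idx[np.argsort(cr_values[cr_idx], kind="stable")]
    base = len(order) // n_groups
    groups = []
    start = 0
    for g in range(n_groups):
        size = base if g < n_groups - 1 else len(order) - base * (n_groups - 1)
        groups.append(order[start:start + size])
        start += size
    non_cr = np.flatnonzero(~np.asarray(cr_mask, dtype=bool))
    if len(non_cr):
        groups.append(non_cr)

    out = []
    for g, idx in enumerate(groups):
        entry = {"trials": idx,
                 "label": "non_cr" if (len(non_cr) and g == len(groups) - 1)
                 else f"group_{g}"}
        for name, arr in traces.items():
            sub = np.asarray(arr)[idx]
            mean = sub.mean(axis=0)
            sem = sub.std(axis=0, ddof=1) / np.sqrt(len(idx)) if len(idx) > 1 \
                else np.zeros_like(mean)
            entry[name] = {"mean": mean, "ci_low": mean - 1.96 * sem,
                           "ci_high": mean + 1.96 * sem}
        out.append(entry)
    return out


def compare_correlation_distributions(sim_r, real_r, n_draws: int = 1000,
                                      test: str = "ks",
                                      rng: Optional[np.random.Generator] = None):
    """Repeatedly draw from the simulated correlation values as many pairs
    as exist in the recorded sample and test each draw against the real
    distribution (paired t-test or two-sample Kolmogorov-Smirnov)."""
    if rng is None:
        rng = np.random.default_rng(0)
    sim_r = np.asarray(sim_r, dtype=float)
    real_r = np.asarray(real_r, dtype=float)
    pvals = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(sim_r, size=len(real_r), replace=True)
        if test == "t":
            pvals[i] = stats.ttest_rel(draw, real_r).pvalue
        elif test == "ks":
            pvals[i] = stats.ks_2samp(draw, real_r).pvalue
        else:
            raise ValueError("test must be 't' or 'ks'")
    return pvals


def classify_unit_heuristic(baseline_rate_hz: float,
                            has_complex_spikes: bool) -> str:
    """Convenience PC/MLI guess (non-canonical): high baseline rate with
    complex spikes suggests a Purkinje cell.  Real labels should come from
    the recording pipeline; this is only a fallback for unlabeled data."""
    return "PC" if (baseline_rate_hz > 40.0 and has_complex_spikes) else "MLI"
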