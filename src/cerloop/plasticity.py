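"""Learning rules of the model.

Two sites of plasticity:

* granule->PC parallel-fiber synapses: every *threshold burst* of a
  granule cell triggers LTD if the burst falls 100-300 ms before a
  climbing-fiber spike arriving at the target PC, and LTP otherwise;
* mossy-fiber->DCN synapses: LTD for synapses active during an abrupt
  pause of the PC population, LTP for synapses active during strong PC
  activity.

A *threshold burst* is a run of at least ``burst_threshold`` spikes whose
consecutive inter-spike intervals are all <= ``burst_window`` ms; the
burst time is the first spike of the run (for the default threshold of 2
this is exactly "two spikes within a 10-ms window").

An optional third locus (granule->MLI) applies the same timing rule with
inverted sign (potentiation inside the eligibility window), used for the
lead-lag model-comparison variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlasticityConfig:
    """Rule parameters.  ``ltd_step``/``ltp_step`` (and the DCN steps) are
    fractions of the corresponding weight ceiling ``w_max`` so the rule is
    invariant under the desk-scale weight rescaling."""

    ltd_window: tuple = (-300.0, -100.0)   # burst time relative to CF spike (ms)
    ltd_step: float = 0.012
    ltp_step: float = 0.0035
    w_max: float = 1.0
    burst_threshold: int = 2
    burst_window: float = 10.0
    # mossy-fiber -> DCN rule
    dcn_pause_criterion: float = 0.25      # fraction of baseline PC rate
    dcn_strong_criterion: float = 1.50
    dcn_window: float = 50.0               # minimum episode length (ms)
    dcn_ltd_step: float = 0.002
    dcn_ltp_step: float = 0.001
    dcn_w_max: float = 1.0
    locus: str = "pf_pc_only"              # pf_pc_only | pf_mli_only | both

    def __post_init__(self) -> None:
        lo, hi = self.ltd_window
        if not (lo < hi < 0):
            raise ValueError("ltd_window must satisfy start < end < 0")
        if self.ltd_step < self.ltp_step:
            raise ValueError("LTD step magnitude should exceed LTP step")
        if self.burst_window <= 0 or self.dcn_window <= 0:
            raise ValueError("windows must have positive length")
        if self.locus not in ("pf_pc_only", "pf_mli_only", "both"):
            raise ValueError(f"unknown plasticity locus {self.locus!r}")


def detect_bursts(spike_times: np.ndarray, threshold: int = 2,
                  window: float = 10.0) -> np.ndarray:
    """Burst onset times of a single sorted spike train."""
    t = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    if len(t) < threshold:
        return np.empty(0)
    # cluster boundaries where the gap exceeds the window
    new_cluster = np.concatenate([[True], np.diff(t) > window])
    cluster_id = np.cumsum(new_cluster) - 1
    sizes = np.bincount(cluster_id)
    starts = t[new_cluster]
    return starts[sizes >= threshold]


def _eligible(burst_t: np.ndarray, cf_times: np.ndarray,
              window: tuple) -> np.ndarray:
    """True where a CF spike falls within ``-window`` after the burst
    (burst at t is eligible iff some CF spike s has s-t in [100, 300] for
    the default window (-300, -100))."""
    cf = np.asarray(cf_times, dtype=float)
    if len(cf) == 0:
        return np.zeros(len(burst_t), dtype=bool)
    if np.any(np.diff(cf) < 0):
        raise ValueError("climbing-fiber spike times must be sorted")
    lo = np.searchsorted(cf, burst_t - window[1])   # t + 100
    hi = np.searchsorted(cf, burst_t - window[0], side="right")  # t + 300
    return hi > lo


def apply_pf_pc_plasticity(weights, granule_burst_times, cf_spike_times,
                           config: PlasticityConfig) -> np.ndarray:
    """Apply the timed LTD/LTP rule to parallel-fiber weights.

    Parameters
    ----------
    weights : array (n_synapses,)
    granule_burst_times : sequence of sorted burst-time arrays, one per synapse
    cf_spike_times : sorted array of climbing-fiber spike times shared by
        all synapses, or a sequence of per-synapse arrays
    """
    w = np.array(weights, dtype=float)
    if isinstance(cf_spike_times, np.ndarray) or len(cf_spike_times) == 0 \
            or np.isscalar(cf_spike_times[0]):
        shared_cf = True
        cf_spike_times = np.asarray(cf_spike_times, dtype=float)
    else:
        shared_cf = False
    ltd = config.ltd_step * config.w_max
    ltp = config.ltp_step * config.w_max
    for i, bursts in enumerate(granule_burst_times):
        b = np.asarray(bursts, dtype=float)
        if np.any(np.diff(b) < 0):
            raise ValueError("burst times must be sorted")
        if len(b) == 0:
            continue
        cf = cf_spike_times if shared_cf else cf_spike_times[i]
        elig = _eligible(b, np.asarray(cf, dtype=float), config.ltd_window)
        w[i] += -ltd * elig.sum() + ltp * (~elig).sum()
    return np.clip(w, 0.0, config.w_max)


def apply_pf_plasticity_indexed(weights: np.ndarray, burst_synapse: np.ndarray,
                                burst_time: np.ndarray, cf_times_of_synapse,
                                config: PlasticityConfig,
                                invert: bool = False) -> np.ndarray:
    """Vectorized rule application used by the trial loop.

    ``burst_synapse``/``burst_time`` are flat parallel arrays of burst
    events; ``cf_times_of_synapse`` is a callable mapping a synapse-index
    array to a list of groups ``(mask, cf_times)`` covering all events.
    ``invert=True`` swaps the LTD/LTP directions (granule->MLI locus).
    """
    w = np.array(weights, dtype=float)
    ltd = config.ltd_step * config.w_max
    ltp = config.ltp_step * config.w_max
    if invert:
        ltd, ltp = -ltp, -ltd
    delta = np.zeros_like(w)
    for mask, cf in cf_times_of_synapse(burst_synapse):
        if not mask.any():
            continue
        elig = _eligible(burst_time[mask], cf, config.ltd_window)
        contrib = np.where(elig, -ltd, ltp)
        np.add.at(delta, burst_synapse[mask], contrib)
    return np.clip(w + delta, 0.0, config.w_max)


def _episodes(mask: np.ndarray, min_len: int):
    """Yield (start, stop) of True runs of at least ``min_len`` samples."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_len:
            yield int(start), int(stop)


def apply_mf_dcn_plasticity(weights, mf_activity, pc_population_rate,
                            config: PlasticityConfig,
                            mf_of_edge=None) -> np.ndarray:
    """Pause/strong-activity gated LTD/LTP of mossy-fiber->DCN synapses.

    ``mf_activity`` is an (n_mf, T) 0/1 array on the ms clock,
    ``pc_population_rate`` a length-T rate trace (Hz).  ``mf_of_edge``
    maps each weight to its source mossy fiber (identity if omitted).
    The running baseline is the mean of the rate trace.
    """
    rate = np.asarray(pc_population_rate, dtype=float)
    act = np.asarray(mf_activity)
    w = np.array(weights, dtype=float)
    if mf_of_edge is None:
        mf_of_edge = np.arange(len(w))
    if config.dcn_window > len(rate):
        raise ValueError("criterion window longer than the record")
    baseline = rate.mean()
    if baseline <= 0:
        return w
    ltd = config.dcn_ltd_step * config.dcn_w_max
    ltp = config.dcn_ltp_step * config.dcn_w_max
    n_win = int(config.dcn_window)
    for crit, step in ((config.dcn_pause_criterion, -ltd),
                       (config.dcn_strong_criterion, +ltp)):
        mask = rate < crit * baseline if step < 0 else rate > crit * baseline
        for start, stop in _episodes(mask, n_win):
            active_mf = act[:, start:stop].any(axis=1)
            w[active_mf[mf_of_edge]] += step
    return np.clip(w, 0.0, config.dcn_w_max)


# ---------------------------------------------------------------------------
# weight-change summaries
# ---------------------------------------------------------------------------

@dataclass
class WeightChangeSummary:
    """Histogram of net per-synapse weight changes (final - initial)."""

    changes: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float = field(default=0.0)

    @property
    def cumulative(self) -> np.ndarray:
        """Monotone cumulative fraction of synapses per bin (ends at 1)."""
        return np.cumsum(self.counts) / self.counts.sum()

    def difference(self, other: "WeightChangeSummary") -> np.ndarray:
        """Bin-wise count difference (self - other); bins must match."""
        if not np.allclose(self.bin_edges, other.bin_edges):
            raise ValueError("summaries have different binning")
        return self.counts - other.counts

    def n_below(self, cutoff: float) -> int:
        """Number of synapses with net change below ``cutoff`` (strong LTD
        when cutoff is negative)."""
        return int((self.changes < cutoff).sum())


def weight_change_summary(initial_weights, final_weights,
                          bin_width: float = 0.05,
                          limits: tuple | None = None) -> WeightChangeSummary:
    """Histogram the net weight changes; LTD is negative, LTP positive."""
    w0 = np.asarray(initial_weights, dtype=float)
    w1 = np.asarray(final_weights, dtype=float)
    if w0.shape != w1.shape:
        raise ValueError("initial/final weight lists differ in length")
    changes = w1 - w0
    if limits is None:
        lim = max(np.abs(changes).max(), bin_width)
        lim = np.ceil(lim / bin_width) * bin_width
        limits = (-lim, lim)
    # bins centered so that zero change falls in the middle bin
    edges = np.arange(limits[0] - bin_width / 2, limits[1] + bin_width, bin_width)
    counts, edges = np.histogram(changes, bins=edges)
    return WeightChangeSummary(changes, edges, counts, bin_width)
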