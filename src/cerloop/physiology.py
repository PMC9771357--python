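"""In vitro synaptic-physiology analyses for the PC -> PC-MLI synapse.

Covers depression kinetics of IPSC trains, frequency (in)dependence of
the steady state, readily-releasable-pool (RRP) and vesicle-mobilization
estimation from cumulative synaptic charge, quantal metrics, IPSC
detection with latency/rise time, and optogenetic input-field /
footprint mapping with convergence estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

IPSC_DETECTION_THRESHOLD_PA = 15.0
IPSC_DETECTION_WINDOW_MS = (4.0, 24.0)
MAP_GRID = 32
MAP_PIXEL_UM = 16.0
PIXEL_AREA_UM2 = MAP_PIXEL_UM ** 2


@dataclass
class IPSCTrain:
    """One stimulus train: times, per-stimulus IPSC amplitudes (pA,
    magnitudes) and charges (pC)."""

    frequency_hz: float
    stimulus_times_ms: np.ndarray
    amplitudes_pa: np.ndarray
    charges_pc: Optional[np.ndarray] = None
    holding_mv: float = -40.0
    reversal_mv: float = -74.0

    def __post_init__(self) -> None:
        self.stimulus_times_ms = np.asarray(self.stimulus_times_ms, dtype=float)
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float)
        if (self.amplitudes_pa < 0).any():
            raise ValueError("amplitudes are magnitudes and must be >= 0")
        if self.charges_pc is not None:
            self.charges_pc = np.asarray(self.charges_pc, dtype=float)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_times_ms)


@dataclass
class DepressionFit:
    tau_stimuli: Optional[float]       # decay constant in units of stimulus number
    tau_ms: Optional[float]
    plateau: float                     # steady-state normalized amplitude
    residual_rms: float
    tau_identifiable: bool = True


@dataclass
class PoolEstimate:
    rrp_charge_pc: float
    rrp_quanta: Optional[float]
    mobilization_pc_per_stim: float
    mobilization_quanta_per_s: Optional[float]
    r_squared: float


@dataclass
class MapGrid:
    """32 x 32 photostimulation grid; ``responses`` has shape
    (n_repeats, 32, 32) holding IPSC amplitudes (pA) or spike flags."""

    responses: np.ndarray
    kind: str = "ipsc"                 # "ipsc" | "spike"
    pixel_um: float = MAP_PIXEL_UM

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3 or self.responses.shape[1:] != (MAP_GRID, MAP_GRID):
            raise ValueError(f"expected (n_repeats, {MAP_GRID}, {MAP_GRID}) responses")

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[0]


@dataclass
class FieldResult:
    pixels: np.ndarray                 # boolean 32 x 32 inclusion mask
    area_um2: float
    n_clusters: int
    detection_probability: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# depression kinetics and pool estimation
# ---------------------------------------------------------------------------

def fit_depression_train(train: IPSCTrain) -> DepressionFit:
    """Exponential-plus-plateau fit to the normalized IPSC amplitudes.

    Amplitudes are normalized to the first IPSC; the model is
    ``a_n = plateau + (1 - plateau) * exp(-n / tau)`` with n the stimulus
    index.  A flat train leaves tau unidentifiable (flagged)."""
    if train.n_stimuli < 20:
        raise ValueError("need at least 20 stimuli to fit depression")
    a0 = train.amplitudes_pa[0]
    if a0 <= 0:
        raise ValueError("first IPSC amplitude must be positive")
    y = train.amplitudes_pa / a0
    n = np.arange(len(y), dtype=float)
    spread = y.max() - y.min()
    if spread < 0.02:
        return DepressionFit(None, None, float(y.mean()),
                             float(np.sqrt(np.mean((y - y.mean()) ** 2))),
                             tau_identifiable=False)

    def model(n, plateau, amp, tau):
        return plateau + amp * np.exp(-n / tau)

    p0 = (max(y[-5:].mean(), 1e-3), y[0] - y[-5:].mean() or 0.5, len(y) / 5)
    try:
        popt, _ = optimize.curve_fit(
            model, n, y, p0=p0,
            bounds=([0, -2.0, 0.3], [np.inf, 2.0, 10.0 * len(y)]), maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"depression fit did not converge: {e}")
    plateau, amp, tau = popt
    resid = y - model(n, *popt)
    isi_ms = 1000.0 / train.frequency_hz
    return DepressionFit(float(tau), float(tau * isi_ms), float(plateau),
                         float(np.sqrt(np.mean(resid ** 2))))


def steady_state_analysis(fits: Sequence[DepressionFit],
                          frequencies_hz: Sequence[float]):
    """Regression of the steady-state (plateau) amplitude on stimulus
    frequency, with an F-test for a nonzero slope, plus the steady-state
    charge-transfer trend (plateau x frequency)."""
    freqs = np.asarray(frequencies_hz, dtype=float)
    plateaus = np.asarray([f.plateau for f in fits], dtype=float)
    if len(freqs) < 3:
        raise ValueError("need plateaus at >= 3 frequencies")
    slope, intercept, r, p_slope, stderr = stats.linregress(freqs, plateaus)
    transfer = plateaus * freqs
    t_slope, t_int, t_r, t_p, _ = stats.linregress(freqs, transfer)
    return {
        "plateau_slope": float(slope),
        "plateau_intercept": float(intercept),
        "plateau_slope_p": float(p_slope),     # F-test == t-test p for 1 df
        "charge_transfer": transfer,
        "charge_transfer_slope": float(t_slope),
        "charge_transfer_slope_p": float(t_p),
    }


def estimate_pool(train: IPSCTrain,
                  mean_quantal_charge_pc: Optional[float] = None,
                  n_tail: int = 20) -> PoolEstimate:
    """RRP size and mobilization rate from cumulative IPSC charge.

    Cumulative charge is plotted against stimulus number; the last
    ``n_tail`` points are fit by ordinary least squares.  The y-intercept
    estimates the RRP (charge released that mobilization cannot account
    for) and the slope the per-stimulus mobilization; dividing by the
    mean quantal charge converts to quanta, and slope x frequency gives
    quanta per second."""
    if train.n_stimuli < 2 * n_tail:
        raise ValueError(f"need at least {2 * n_tail} stimuli")
    charges = train.charges_pc
    if charges is None:
        raise ValueError("train has no charge measurements")
    cum = np.cumsum(charges)
    n = np.arange(1, len(cum) + 1, dtype=float)
    slope, intercept, r, p, stderr = stats.linregress(n[-n_tail:], cum[-n_tail:])
    rrp_q = mob_qs = None
    if mean_quantal_charge_pc:
        rrp_q = intercept / mean_quantal_charge_pc
        mob_qs = slope * train.frequency_hz / mean_quantal_charge_pc
    return PoolEstimate(float(intercept), rrp_q, float(slope), mob_qs,
                        float(r ** 2))


def quantal_metrics(evoked_amp_pa: float, spont_amp_pa: float,
                    holding_mv: float, reversal_mv: float = -74.0,
                    evoked_integral_qc: Optional[float] = None,
                    rrp_quanta: Optional[float] = None,
                    repeated_evoked_pa=None) -> dict:
    """Quantal content, release probability, synaptic conductance, CV.

    Quantal content is the evoked/spontaneous amplitude ratio; the
    release probability is the integral-based quantal content divided by
    the RRP size in quanta; conductance is amplitude over driving force.
    """
    if spont_amp_pa <= 0:
        raise ZeroDivisionError("spontaneous amplitude must be positive")
    if holding_mv == reversal_mv:
        raise ZeroDivisionError("holding potential equals reversal potential")
    out = {
        "quantal_content": evoked_amp_pa / spont_amp_pa,
        "conductance_ns": abs(evoked_amp_pa) / abs(holding_mv - reversal_mv),
    }
    if evoked_integral_qc is not None and rrp_quanta:
        out["release_probability"] = evoked_integral_qc / rrp_quanta
    if repeated_evoked_pa is not None:
        amps = np.asarray(repeated_evoked_pa, dtype=float)
        out["cv"] = float(amps.std(ddof=1) / amps.mean())
    return out


# ---------------------------------------------------------------------------
# IPSC detection
# ---------------------------------------------------------------------------

def detect_ipsc(current_pa: np.ndarray, flash_time_ms: float,
                dt_ms: float = 0.1,
                threshold_pa: float = IPSC_DETECTION_THRESHOLD_PA,
                window_ms: tuple = IPSC_DETECTION_WINDOW_MS) -> dict:
    """Detect a photostimulation-evoked IPSC and measure its kinetics.

    ``current_pa`` is the outward-positive IPSC magnitude trace sampled
    at ``dt_ms``.  An event is detected iff the maximum within
    [4, 24] ms after the flash reaches 15 pA.  Onset is the zero-crossing
    (with the pre-event baseline) of the line joining the 20% and 80%
    points of the rising phase; rise time is the 20->80% interval."""
    x = np.asarray(current_pa, dtype=float)
    t = np.arange(len(x)) * dt_ms
    lo, hi = flash_time_ms + window_ms[0], flash_time_ms + window_ms[1]
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        return {"detected": False}
    peak_idx_rel = int(np.argmax(x[sel]))
    peak_idx = np.flatnonzero(sel)[peak_idx_rel]
    peak = float(x[peak_idx])
    if peak < threshold_pa:
        return {"detected": False}
    base_sel = t < flash_time_ms
    baseline = float(x[base_sel].mean()) if base_sel.any() else 0.0
    amp = peak - baseline
    lvl20, lvl80 = baseline + 0.2 * amp, baseline + 0.8 * amp
    rise = x[:peak_idx + 1]
    i80 = int(np.flatnonzero(rise >= lvl80)[0])
    below20 = np.flatnonzero(rise[:i80 + 1] < lvl20)
    i20 = int(below20[-1]) + 1 if len(below20) else i80

    def crossing(level, i):
        """Linear-interpolated time at which the trace reaches ``level``
        just before sample ``i``."""
        if i == 0 or x[i] == x[i - 1]:
            return t[i]
        frac = (level - x[i - 1]) / (x[i] - x[i - 1])
        return t[i - 1] + frac * dt_ms

    t20, t80 = crossing(lvl20, i20), crossing(lvl80, i80)
    rise_time = t80 - t20
    # extrapolate the 20-80% line back to the baseline
    slope = (lvl80 - lvl20) / max(t80 - t20, dt_ms * 1e-6)
    onset = t20 - (lvl20 - baseline) / slope
    return {"detected": True, "amplitude_pa": amp,
            "latency_ms": onset - flash_time_ms, "rise_time_ms": rise_time,
            "peak_time_ms": float(t[peak_idx])}


# ---------------------------------------------------------------------------
# optogenetic maps
# ---------------------------------------------------------------------------

def _remove_single_pixel_islands(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop 4-connected components of size 1 (spontaneous-event
    artifacts); returns the cleaned mask and the remaining cluster count."""
    from scipy import ndimage
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros_like(mask, dtype=bool)
    clusters = 0
    for lab in range(1, n + 1):
        if sizes[lab] > 1:
            keep |= labels == lab
            clusters += 1
    return keep, clusters


def build_input_map(grid: MapGrid, detection_threshold_pa: float =
                    IPSC_DETECTION_THRESHOLD_PA,
                    min_probability: float = 0.5) -> FieldResult:
    """Input field of a recorded cell from repeated IPSC maps.

    A pixel is kept when its IPSC detection probability across repeats is
    at least 0.5; single-pixel islands (spontaneous activity) are then
    excluded, and the area is the pixel count times 256 um^2."""
    if grid.n_repeats < 2:
        import warnings
        warnings.warn("single repeat: detection probability cannot filter "
                      "spontaneous events", stacklevel=2)
    detected = grid.responses >= detection_threshold_pa if grid.kind == "ipsc" \
        else grid.responses > 0
    prob = detected.mean(axis=0)
    mask = prob >= min_probability
    mask, n_clusters = _remove_single_pixel_islands(mask)
    return FieldResult(mask, float(mask.sum() * PIXEL_AREA_UM2), n_clusters,
                       detection_probability=prob)


def build_footprint(grid: MapGrid) -> FieldResult:
    """Optical footprint of a ChR2-expressing PC: pixels where a spike was
    evoked (0-14 ms window, already encoded as flags) in *all* repeats."""
    if grid.n_repeats < 2:
        import warnings
        warnings.warn("single repeat: consistency criterion is vacuous",
                      stacklevel=2)
    mask = (grid.responses > 0).all(axis=0)
    mask, n_clusters = _remove_single_pixel_islands(mask)
    return FieldResult(mask, float(mask.sum() * PIXEL_AREA_UM2), n_clusters)


def convergence_estimate(field: FieldResult,
                         footprint_areas_um2: Sequence[float]) -> dict:
    """Convergence of presynaptic PCs onto the mapped cell: ratio of the
    input-field area to the mean single-PC footprint area."""
    fp = np.asarray(footprint_areas_um2, dtype=float)
    if len(fp) == 0 or fp.mean() <= 0:
        raise ZeroDivisionError("mean footprint area must be positive")
    if field.area_um2 <= 0:
        raise ValueError("empty input field")
    ratio = field.area_um2 / fp.mean()
    if 1.0 <= ratio <= 2.0:
        interpretation = "one to two converging PCs"
    else:
        interpretation = f"approximately {ratio:.1f} converging PCs"
    return {"ratio": float(ratio), "n_clusters": field.n_clusters,
            "interpretation": interpretation}
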