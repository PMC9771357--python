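"""Eyelid-trace processing: filtering, CR amplitude, criterion latency,
two-step CR-onset detection, velocity.

The same pipeline is applied to real (infrared-sensor) and virtual
(simulated) eyelid traces.  A CR is an anticipatory closure reaching the
0.3-mm criterion above the pre-CS baseline before US onset; CR amplitude
is the position above baseline at US onset, after truncating the trace at
US onset to exclude reflex (non-cerebellar) components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt

CR_CRITERION_MM = 0.3
SAMPLING_HZ = 1000.0


@dataclass
class EyelidTrace:
    """Eyelid position (mm) sampled at 1 kHz on the trial clock.

    The standard acquisition window is 2500 samples with CS onset at
    sample 200 (200 ms pre-CS); virtual traces may be shorter but keep the
    same pre-CS length."""

    samples: np.ndarray
    cs_onset: int = 200
    us_onset: int = 700

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not (0 < self.cs_onset < self.us_onset <= len(self.samples)):
            raise ValueError("CS/US onsets inconsistent with trace length")

    @property
    def pre_cs(self) -> np.ndarray:
        return self.samples[:self.cs_onset]

    def truncated(self) -> np.ndarray:
        """View ending just before US onset (for CR analysis)."""
        return self.samples[:self.us_onset]


@dataclass
class CRMeasures:
    is_cr: bool
    amplitude: float                       # mm above baseline at US onset
    baseline: float
    criterion_latency: Optional[float]     # ms from CS onset
    onset_latency: Optional[float]         # ms from CS onset


def preprocess_eyelid(raw, cs_onset: int = 200, us_onset: int = 700,
                      cutoff_hz: float = 50.0, order: int = 4) -> EyelidTrace:
    """Low-pass filter a raw 1-kHz eyelid trace (zero-phase Butterworth,
    default 50 Hz cutoff; eyelid kinematics live below ~20 Hz)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) <= cs_onset:
        raise ValueError("raw trace has wrong length")
    sos = butter(order, cutoff_hz, btype="low", fs=SAMPLING_HZ, output="sos")
    filtered = sosfiltfilt(sos, raw)
    return EyelidTrace(filtered, cs_onset=cs_onset, us_onset=us_onset)


def cr_measures(trace: EyelidTrace, criterion_mm: float = CR_CRITERION_MM,
                deflection_sd: float = 4.0, sustain_ms: int = 20,
                fit_ms: int = 20) -> CRMeasures:
    """CR amplitude, criterion latency, and two-step onset latency.

    Baseline is the mean of the pre-CS segment.  Amplitude is position
    minus baseline at US onset.  Criterion latency is the first crossing
    of baseline + 0.3 mm within the CS (before US onset).  Onset uses the
    two-step algorithm: (1) first sample in the CS exceeding baseline +
    ``deflection_sd`` pre-CS SDs and staying above for ``sustain_ms``;
    (2) a line fit to the following ``fit_ms`` samples, onset = its
    crossing with the baseline."""
    x = trace.samples
    baseline = float(trace.pre_cs.mean())
    sd = float(trace.pre_cs.std())
    us_idx = min(trace.us_onset, len(x) - 1)
    amplitude = float(x[us_idx] - baseline)
    # criterion crossing within the CS, truncated at US onset
    seg = trace.truncated()[trace.cs_onset:]
    above = np.flatnonzero(seg >= baseline + criterion_mm)
    is_cr = len(above) > 0
    criterion_latency = float(above[0]) if is_cr else None

    onset_latency = None
    if is_cr:
        thr = baseline + deflection_sd * max(sd, 1e-9)
        over = seg >= thr
        onset_idx = None
        run = 0
        for i, o in enumerate(over):
            run = run + 1 if o else 0
            if run >= sustain_ms:
                onset_idx = i - sustain_ms + 1
                break
        if onset_idx is None:
            hit = np.flatnonzero(over)
            onset_idx = int(hit[0]) if len(hit) else int(above[0])
        t_fit = np.arange(onset_idx, min(onset_idx + fit_ms, len(seg)))
        if len(t_fit) >= 2:
            slope, intercept = np.polyfit(t_fit, seg[t_fit], 1)
            if slope > 0:
                onset_latency = float((baseline - intercept) / slope)
            else:
                onset_latency = float(onset_idx)
        else:
            onset_latency = float(onset_idx)
        onset_latency = min(onset_latency, criterion_latency)
    return CRMeasures(is_cr=is_cr, amplitude=amplitude, baseline=baseline,
                      criterion_latency=criterion_latency,
                      onset_latency=onset_latency)


def eyelid_velocity(trace: EyelidTrace) -> np.ndarray:
    """Eyelid velocity (mm/s): centered finite differences, one-sided at
    the endpoints."""
    return np.gradient(trace.samples) * SAMPLING_HZ
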