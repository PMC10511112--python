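"""Forward models: from spike rasters to MEG- and BOLD-like predictions.

Two proxies connect simulated spiking activity to neuroimaging:

* **MEG**: source-localized activity is taken to reflect the *sum of
  spikes* in the populations underlying a region of interest (ROI).  ROIs
  may mix module populations (the temporal-cortex ROIs blend familiarity
  and declarative memory activity 60/40 and 45/55 because the generating
  structures are adjacent).  Traces are binned, mixture-weighted and
  smoothed; units are arbitrary — the predictions are qualitative.

* **BOLD**: the fMRI response is taken to be linearly related to
  *neurotransmitter usage*, computed here as |synaptic weight|-weighted
  filtered presynaptic activity summed over a module's incoming
  connections, then convolved with the canonical double-gamma hemodynamic
  response function and sampled at the scanner TR.

The two proxies dissociate: a condition with lower momentary activity but
longer duration can produce the *larger* BOLD response, because the slow
hemodynamic kernel integrates over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

__all__ = [
    "RoiMap", "HrfParams", "default_roi_map", "hrf_kernel",
    "meg_proxy", "epoch_average", "neurotransmitter_usage", "bold_proxy",
]


@dataclass
class RoiMap:
    """ROI name -> {population name: mixture weight}; weights sum to 1."""

    rois: dict

    def __post_init__(self) -> None:
        normed = {}
        for roi, mix in self.rois.items():
            total = float(sum(mix.values()))
            if total <= 0:
                raise ValueError(f"ROI {roi!r} has non-positive weights")
            normed[roi] = {k: v / total for k, v in mix.items()}
        self.rois = normed

    def __getitem__(self, roi: str) -> dict:
        return self.rois[roi]

    def __iter__(self):
        return iter(self.rois)


def default_roi_map() -> RoiMap:
    """The model's region mapping: visual parser -> occipital; mixed
    familiarity/declarative -> middle and superior temporal; representation
    buffer -> dorsolateral prefrontal; finger populations -> contralateral
    precentral."""
    return RoiMap({
        "visual": {"visual": 1.0},
        "familiarity": {"familiarity": 0.60, "declarative": 0.40},
        "retrieval": {"declarative": 0.55, "familiarity": 0.45},
        "representation": {"representation": 1.0},
        "left_motor": {"right_fingers": 1.0},
        "right_motor": {"left_fingers": 1.0},
    })


@dataclass
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (s)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0          # peak-to-undershoot amplitude ratio
    length: float = 32.0        # kernel support (covers the undershoot)
    tr: float = 1.5             # scanner sampling interval

    def __post_init__(self) -> None:
        if self.length <= self.undershoot_delay:
            raise ValueError("kernel length must cover the undershoot")


def hrf_kernel(params: HrfParams, dt: float) -> np.ndarray:
    """Double-gamma kernel sampled at dt; integrates to a positive value."""
    t = np.arange(0, params.length, dt)
    peak = gamma_dist.pdf(t, params.peak_delay / params.peak_disp,
                          scale=params.peak_disp)
    under = gamma_dist.pdf(t, params.undershoot_delay / params.undershoot_disp,
                           scale=params.undershoot_disp)
    h = peak - under / params.ratio
    area = h.sum() * dt
    if area <= 0:
        raise ValueError("kernel does not integrate to a positive value")
    return h / area


# ---------------------------------------------------------------------------
# MEG proxy
# ---------------------------------------------------------------------------

def meg_proxy(rasters: dict, roi_map: RoiMap, dt: float,
              bin_ms: float = 4.0, smoothing_ms: float = 20.0):
    """Sum-of-spikes ROI time courses.

    ``rasters`` maps population name -> (n_steps, n_neurons) binary spike
    array at resolution ``dt``.  Returns (roi -> trace, bin width s).
    Linear in the rasters; arbitrary units.
    """
    if not rasters:
        raise ValueError("no rasters")
    bin_steps = max(1, int(round(bin_ms / 1000.0 / dt)))
    summed = {}
    n_bins = None
    for name, rast in rasters.items():
        counts = np.asarray(rast).sum(axis=1)
        nb = len(counts) // bin_steps
        binned = counts[:nb * bin_steps].reshape(nb, bin_steps).sum(axis=1)
        summed[name] = binned
        n_bins = nb if n_bins is None else min(n_bins, nb)
    out = {}
    sigma_bins = smoothing_ms / bin_ms
    for roi in roi_map:
        mix = roi_map[roi]
        trace = np.zeros(n_bins)
        for pop, w in mix.items():
            if pop in summed:
                trace += w * summed[pop][:n_bins]
        if sigma_bins > 0:
            trace = gaussian_filter1d(trace, sigma_bins)
        out[roi] = trace
    return out, bin_steps * dt


def epoch_average(series: np.ndarray, times: np.ndarray, events: Sequence,
                  lock: str = "stimulus",
                  window: Optional[tuple] = None) -> dict:
    """Condition-averaged traces over correct trials only.

    ``events`` is a sequence of dicts with keys ``condition``, ``correct``,
    ``stimulus_time``, ``response_time``.  ``lock`` picks the alignment
    event; ``window`` is (start, end) in seconds relative to it (defaults:
    0..0.6 stimulus-locked, -0.4..0.1 response-locked).  A condition with
    no correct trials maps to None (absent, not zero).
    """
    if lock not in ("stimulus", "response"):
        raise ValueError(f"unknown lock {lock!r}")
    if window is None:
        window = (0.0, 0.6) if lock == "stimulus" else (-0.4, 0.1)
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    n_win = int(round((window[1] - window[0]) / dt))
    sums: dict = {}
    counts: dict = {}
    conditions = {ev["condition"] for ev in events}
    for ev in events:
        if not ev.get("correct", False):
            continue
        t0 = (ev["stimulus_time"] if lock == "stimulus"
              else ev.get("response_time"))
        if t0 is None:
            continue
        i0 = int(round((t0 + window[0] - times[0]) / dt))
        if i0 < 0 or i0 + n_win > len(series):
            continue
        seg = series[i0:i0 + n_win]
        c = ev["condition"]
        sums[c] = sums.get(c, 0) + seg
        counts[c] = counts.get(c, 0) + 1
    return {c: (sums[c] / counts[c] if c in counts else None)
            for c in conditions}


# ---------------------------------------------------------------------------
# BOLD proxy
# ---------------------------------------------------------------------------

def neurotransmitter_usage(rasters: dict, weight_coeffs: dict, dt: float,
                           synapse_tau: float = 0.005,
                           bin_ms: float = 10.0,
                           mode: str = "weighted") -> dict:
    """Per-module neurotransmitter-usage time series.

    For each module, usage(t) = sum over incoming synapses of |w_ij| times
    filtered presynaptic activity — transmitter release scales with
    presynaptic firing and synaptic strength.  ``weight_coeffs`` maps
    module -> list of (pre population name, per-pre-neuron coefficient
    vector sum_j |w_ij|).  ``mode="spikes"`` falls back to unweighted
    spike counts for sensitivity checks.  Non-negative, linear in rasters.
    """
    bin_steps = max(1, int(round(bin_ms / 1000.0 / dt)))
    a = np.exp(-dt / synapse_tau)
    out = {}
    for module, incoming in weight_coeffs.items():
        usage = None
        for pre_name, coeff in incoming:
            rast = np.asarray(rasters[pre_name], dtype=float)
            if mode == "spikes":
                contrib = rast.sum(axis=1) / dt
            else:
                filt = np.empty(rast.shape[0])
                acc = np.zeros(rast.shape[1])
                for k in range(rast.shape[0]):
                    acc = a * acc + (1 - a) * rast[k] / dt
                    filt[k] = acc @ np.abs(coeff)
                contrib = filt
            usage = contrib if usage is None else usage + contrib
        if usage is None:
            usage = np.zeros(0)
        nb = len(usage) // bin_steps
        out[module] = usage[:nb * bin_steps].reshape(
            nb, bin_steps).mean(axis=1)
    return out


def bold_proxy(usage: np.ndarray, params: HrfParams, dt: float,
               baseline: str = "first") -> np.ndarray:
    """Percent-signal-change-like BOLD trace at the TR grid.

    Convolves usage with the double-gamma kernel, resamples at TR, and
    subtracts the first sample (the first-scan baseline convention).
    """
    usage = np.asarray(usage, dtype=float)
    kernel = hrf_kernel(params, dt)
    conv = np.convolve(usage, kernel)[:len(usage) + len(kernel)] * dt
    stride = max(1, int(round(params.tr / dt)))
    trace = conv[::stride]
    if baseline == "first" and len(trace):
        trace = trace - trace[0]
    return trace
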