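"""Morlet-wavelet beta-burst detection and burst-rate quantification.

Beta bursts are transient (~100-200 ms) high-power events in the 15-29 Hz
band.  Each channel is convolved with complex Morlet wavelets

    w(t, f) = A * exp(-t**2 / (2 sigma_t**2)) * exp(2 i pi f t)

with ``sigma_t = m / (2 pi f)``, ``A = 1 / (sigma_t sqrt(2 pi))`` and
``m = 7`` cycles, at 15 evenly spaced frequencies spanning 15-29 Hz.  Power
is the squared magnitude of the convolved signal.  A burst is a regional
maximum of the trial's time-frequency power matrix whose power exceeds a
cutoff of ``threshold_factor x`` the median power of the electrode's entire
(edge-trimmed) time-frequency matrix, pooled over trials.  Because the
threshold is relative to the median, burst counts are invariant under
global amplitude scaling of the signal.

Burst rates are counted in behaviorally defined windows: on stop trials
from the stop-signal onset to the participant's SSRT estimate, on go trials
from the trial's current SSD over a window of identical length, and
baseline-normalised against the 500 ms pre-go period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from .eeg import EEGEpochs

__all__ = [
    "TFMatrix",
    "default_beta_freqs",
    "morlet_tf",
    "detect_bursts",
    "frontal_burst_rate",
    "burst_triggered_sensorimotor",
]

N_CYCLES = 7.0


def default_beta_freqs() -> np.ndarray:
    """15 evenly spaced frequencies spanning the beta band (15-29 Hz)."""
    return np.linspace(15.0, 29.0, 15)


@dataclass
class TFMatrix:
    """Wavelet power: (n_freqs, n_samples, n_trials) for one channel."""

    power: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    channel: str
    valid: np.ndarray  # bool over samples; False inside wavelet edge zones

    def median_power(self) -> float:
        """Median over the electrode's entire retained TF matrix (all trials)."""
        return float(np.median(self.power[:, self.valid, :]))


def _morlet_kernel(freq_hz: float, sfreq: float) -> np.ndarray:
    sigma_t = N_CYCLES / (2.0 * np.pi * freq_hz)       # seconds
    half = int(np.ceil(5.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    amp = 1.0 / (sigma_t * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * (t / sigma_t) ** 2) * \
        np.exp(2j * np.pi * freq_hz * t)


def morlet_tf(epochs: EEGEpochs, channel: str, freqs=None) -> TFMatrix:
    """Time-frequency power of one channel via complex Morlet convolution.

    Edge zones of width 3 sigma_t of the lowest frequency are flagged
    invalid; an epoch shorter than the longest wavelet raises.
    """
    if freqs is None:
        freqs = default_beta_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if epochs.sfreq < 2.0 * freqs.max():
        raise ValueError("sampling rate below Nyquist for requested frequencies")
    sig = epochs.channel(channel)           # (n_samples, n_trials)
    n_samples = sig.shape[0]

    longest = _morlet_kernel(freqs.min(), epochs.sfreq)
    if n_samples < len(longest):
        raise ValueError(
            f"epoch ({n_samples} samples) shorter than the {freqs.min():g} Hz "
            f"wavelet support ({len(longest)} samples)"
        )

    power = np.empty((len(freqs), n_samples, sig.shape[1]))
    x = sig.T  # (n_trials, n_samples)
    for i, f in enumerate(freqs):
        k = _morlet_kernel(f, epochs.sfreq)
        conv = fftconvolve(x, k[None, :], mode="same", axes=1)
        power[i] = np.abs(conv).T ** 2

    edge_ms = 3.0 * 1000.0 * N_CYCLES / (2.0 * np.pi * freqs.min())
    times = epochs.times_ms
    valid = (times >= times[0] + edge_ms) & (times <= times[-1] - edge_ms)
    return TFMatrix(power=power, freqs=freqs, times_ms=times,
                    channel=channel, valid=valid)


def _regional_maxima(mat: np.ndarray):
    """MATLAB-style regional maxima of a 2-D array.

    Returns (row, col) per maximum; plateau components are reduced to a
    single representative, ties broken by earliest column (time) then lowest
    row (frequency).
    """
    footprint = np.ones((3, 3), bool)
    is_peak = mat == ndimage.maximum_filter(mat, footprint=footprint,
                                            mode="nearest")
    labels, n_lab = ndimage.label(is_peak, structure=footprint)
    out = []
    if n_lab == 0:
        return out
    dil = ndimage.grey_dilation(mat, footprint=footprint, mode="nearest")
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        val = mat[rows[0], cols[0]]
        # Regional max: no strictly greater neighbour outside the plateau.
        border_max = dil[rows, cols].max()
        if border_max > val:
            continue
        order = np.lexsort((rows, cols))  # earliest time, then lowest freq
        out.append((rows[order[0]], cols[order[0]]))
    return out


def detect_bursts(tf: TFMatrix, threshold_factor: float = 2.0,
                  threshold: float | None = None) -> pd.DataFrame:
    """Detect bursts as supra-threshold regional maxima, per trial.

    ``threshold`` overrides the ``threshold_factor x median`` cutoff (used
    to share one electrode-wide threshold across subsets of trials).
    Returns a tidy frame (trial, channel, time_ms, freq_hz, power) sorted by
    time within trial.
    """
    if not np.all(np.isfinite(tf.power)):
        raise ValueError("TF power matrix contains non-finite values")
    if threshold is None:
        threshold = threshold_factor * tf.median_power()
    rows = []
    if not tf.valid.any():
        return pd.DataFrame(columns=["trial", "channel", "time_ms",
                                     "freq_hz", "power"])
    # Maxima are located on the full time axis and then filtered to the
    # valid (edge-trimmed) region, so the trim boundary itself cannot
    # manufacture spurious border maxima.
    for trial in range(tf.power.shape[2]):
        mat = tf.power[:, :, trial]
        for fi, ti in _regional_maxima(mat):
            p = mat[fi, ti]
            if p > threshold and tf.valid[ti]:
                rows.append((trial, tf.channel,
                             tf.times_ms[ti], tf.freqs[fi], p))
    df = pd.DataFrame(rows, columns=["trial", "channel", "time_ms",
                                     "freq_hz", "power"])
    return df.sort_values(["trial", "time_ms"], kind="stable",
                          ignore_index=True)


def _counts_in_windows(events: pd.DataFrame, n_trials: int,
                       lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Events per trial inside half-open per-trial windows [lo, hi)."""
    counts = np.zeros(n_trials)
    if len(events) == 0:
        return counts
    tr = events["trial"].to_numpy(dtype=int)
    t = events["time_ms"].to_numpy(dtype=float)
    inside = (t >= lo[tr]) & (t < hi[tr])
    np.add.at(counts, tr[inside], 1)
    return counts


def frontal_burst_rate(events: pd.DataFrame, trials: pd.DataFrame,
                       ssrt_ms: float,
                       baseline_window_ms: tuple = (-500.0, 0.0)) -> pd.DataFrame:
    """Frontal burst rates per trial type, baseline-normalised.

    Stop trials count bursts in [SSD, SSD + SSRT); go trials in
    [SSD_current, SSD_current + SSRT), where SSD_current is the staircase's
    held SSD for the trial.  Counts are divided by SSRT (in s) to give
    bursts/s, and the participant's baseline rate (from the pre-go window,
    same trial type) is subtracted.

    Returns one row per trial type: columns ``trial_type, n_trials,
    raw_rate, baseline_rate, normalized_rate``.
    """
    if not np.isfinite(ssrt_ms) or ssrt_ms <= 0:
        raise ValueError("SSRT estimate must be positive and finite")
    n = len(trials)
    ssd = trials["ssd_ms"].to_numpy(dtype=float)
    outcome = trials["outcome"].to_numpy()
    lo = ssd
    hi = ssd + ssrt_ms
    win_counts = _counts_in_windows(events, n, lo, hi)
    b_lo = np.full(n, baseline_window_ms[0])
    b_hi = np.full(n, baseline_window_ms[1])
    base_counts = _counts_in_windows(events, n, b_lo, b_hi)
    win_s = ssrt_ms / 1000.0
    base_s = (baseline_window_ms[1] - baseline_window_ms[0]) / 1000.0

    groups = {
        "successful_stop": outcome == "successful_stop",
        "failed_stop": outcome == "signal_respond",
        "go": np.isin(outcome, ("go_response", "go_omission")),
    }
    rows = []
    for name, mask in groups.items():
        if not mask.any():
            rows.append((name, 0, np.nan, np.nan, np.nan))
            continue
        raw = win_counts[mask].mean() / win_s
        base = base_counts[mask].mean() / base_s
        rows.append((name, int(mask.sum()), raw, base, raw - base))
    return pd.DataFrame(rows, columns=["trial_type", "n_trials", "raw_rate",
                                       "baseline_rate", "normalized_rate"])


def burst_triggered_sensorimotor(frontal_events: pd.DataFrame,
                                 sensorimotor_events: pd.DataFrame,
                                 trials: pd.DataFrame,
                                 ssrt_ms: float,
                                 window_ms: tuple = (-100.0, 100.0),
                                 half_width_ms: float = 25.0,
                                 step_ms: float = 2.0,
                                 baseline_window_ms: tuple = (-500.0, 0.0),
                                 seed=None) -> pd.DataFrame:
    """Sensorimotor burst-rate time course around the first frontal burst.

    Only Successful-stop trials enter.  Trials with at least one frontal
    burst in [SSD, SSD + SSRT) are time-locked to the first such burst;
    trials without one form the control condition, time-locked to a random
    time point in the same period.  At each sample point the sensorimotor
    burst rate in a +-``half_width_ms`` sliding window is averaged across
    trials and converted to percent change against the participant's mean
    pre-go sensorimotor baseline rate over the same trials.

    Returns a frame with columns ``lag_ms, pct_change, n_trials, condition``
    (condition is ``burst_locked`` or ``random_locked``); empty if no trial
    qualifies.
    """
    if not np.isfinite(ssrt_ms) or ssrt_ms <= 0:
        raise ValueError("SSRT estimate must be positive and finite")
    rng = np.random.default_rng(seed)
    ss = trials[trials["outcome"] == "successful_stop"]
    if len(ss) == 0:
        return pd.DataFrame(columns=["lag_ms", "pct_change", "n_trials",
                                     "condition"])
    lags = np.arange(window_ms[0], window_ms[1] + step_ms / 2, step_ms)

    fe_by_trial: dict[int, np.ndarray] = {
        int(k): np.sort(g["time_ms"].to_numpy(dtype=float))
        for k, g in frontal_events.groupby("trial")
    }
    locked_t0, locked_idx, control_t0, control_idx = [], [], [], []
    for _, row in ss.iterrows():
        tr = int(row["trial"])
        lo = float(row["ssd_ms"])
        hi = lo + ssrt_ms
        times = fe_by_trial.get(tr, np.empty(0))
        in_win = times[(times >= lo) & (times < hi)]
        if len(in_win):
            locked_t0.append(in_win[0])   # first frontal burst in the window
            locked_idx.append(tr)
        else:
            control_t0.append(rng.uniform(lo, hi))
            control_idx.append(tr)

    base_s = (baseline_window_ms[1] - baseline_window_ms[0]) / 1000.0
    n_total = int(trials["trial"].max()) + 1 if len(trials) else 0
    base_counts = _counts_in_windows(
        sensorimotor_events, n_total,
        np.full(n_total, baseline_window_ms[0]),
        np.full(n_total, baseline_window_ms[1]),
    )

    def timecourse(t0_list, trial_ids, condition):
        if not t0_list:
            return None
        t0 = np.asarray(t0_list)
        ids = np.asarray(trial_ids, dtype=int)
        sm = sensorimotor_events[sensorimotor_events["trial"].isin(ids)]
        tr = sm["trial"].to_numpy(dtype=int)
        t = sm["time_ms"].to_numpy(dtype=float)
        t0_of = dict(zip(ids.tolist(), t0.tolist()))
        rel = t - np.array([t0_of[int(x)] for x in tr]) if len(sm) else np.empty(0)
        rates = np.empty(len(lags))
        for i, lag in enumerate(lags):
            c = np.count_nonzero((rel >= lag - half_width_ms)
                                 & (rel < lag + half_width_ms))
            rates[i] = c / len(ids) / (2.0 * half_width_ms / 1000.0)
        base = base_counts[ids].mean() / base_s
        if base <= 0:
            pct = np.full(len(lags), np.nan)
        else:
            pct = 100.0 * (rates - base) / base
        return pd.DataFrame({"lag_ms": lags, "pct_change": pct,
                             "n_trials": len(ids), "condition": condition})

    parts = [timecourse(locked_t0, locked_idx, "burst_locked"),
             timecourse(control_t0, control_idx, "random_locked")]
    parts = [p for p in parts if p is not None]
    if not parts:
        return pd.DataFrame(columns=["lag_ms", "pct_change", "n_trials",
                                     "condition"])
    return pd.concat(parts, ignore_index=True)
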