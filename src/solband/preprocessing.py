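"""Signal conditioning and stance-phase normalization.

EMG envelope extraction follows the standard surface-EMG recipe: band-pass
30-300 Hz (2nd order Butterworth, zero-phase double pass), full-wave
rectification, low-pass 6 Hz (2nd order, double pass), then max-normalization
per muscle across the available trials.  Mechanics (GRF, torques) are
low-pass filtered at 8 Hz by the caller through :func:`butterworth_filter`.
Time-dependent variables are interpolated onto 101 points spanning the
stance phase (0-100 %stance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError, PeakDetectionError

EMG_BAND = (30.0, 300.0)  # Hz
EMG_LOWPASS = 6.0         # Hz
MECH_LOWPASS = 8.0        # Hz
STANCE_POINTS = 101
STANCE_GRF_THRESHOLD = 0.02  # fraction of bodyweight


@dataclass
class EnvelopeSet:
    """Normalized EMG envelopes for one trial.

    ``normalization_max`` stores, per channel, the raw-unit maximum the
    channel was divided by (shared across trials of one subject).
    """

    envelopes: np.ndarray          # (n_frames, n_channels)
    sampling_rate: float           # Hz
    normalization_max: np.ndarray | None = None  # (n_channels,) raw units


def butterworth_filter(series, sampling_rate, kind, cutoff, order=2,
                       zero_phase=True):
    """Butterworth-filter a 1-D or 2-D (frames x channels) series.

    ``kind`` is ``"lowpass"`` or ``"bandpass"``; ``cutoff`` a scalar or a
    (low, high) pair in Hz.  ``zero_phase=True`` applies forward-backward
    filtering (``filtfilt``), doubling the effective order and cancelling
    phase lag — the conventional "double pass".
    """
    x = np.asarray(series, dtype=float)
    nyq = sampling_rate / 2.0
    cut = np.atleast_1d(np.asarray(cutoff, dtype=float))
    if kind == "lowpass":
        if cut.size != 1:
            raise ParameterError("lowpass takes a scalar cutoff")
    elif kind == "bandpass":
        if cut.size != 2 or cut[0] >= cut[1]:
            raise ParameterError("bandpass takes an increasing (low, high) pair")
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise ParameterError(
            f"cutoff {cutoff} Hz outside (0, Nyquist={nyq:g}) Hz")
    sos = signal.butter(order, cut if cut.size > 1 else cut[0],
                        btype=kind, fs=sampling_rate, output="sos")
    if zero_phase:
        # default filtfilt padding: 3 * (2 * n_sections * 2 + 1)
        padlen = 3 * (2 * sos.shape[0] * 2 + 1)
        if x.shape[0] <= padlen:
            raise DataError(
                f"series length {x.shape[0]} too short for zero-phase "
                f"filtering (needs > {padlen} samples)")
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def emg_envelope(raw_emg, sampling_rate):
    """Extract the linear envelope of raw EMG (un-normalized).

    Band-pass 30-300 Hz -> full-wave rectify -> low-pass 6 Hz, all 2nd-order
    zero-phase Butterworth.  Filter ringing can push the result slightly
    negative near edges; values are clamped at 0 since activations are
    physically non-negative.
    """
    if sampling_rate <= 2 * EMG_BAND[1]:
        raise ParameterError(
            f"sampling_rate must exceed {2 * EMG_BAND[1]:g} Hz for the "
            f"{EMG_BAND[0]:g}-{EMG_BAND[1]:g} Hz band, got {sampling_rate:g}")
    band = butterworth_filter(raw_emg, sampling_rate, "bandpass", EMG_BAND)
    rect = np.abs(band)
    env = butterworth_filter(rect, sampling_rate, "lowpass", EMG_LOWPASS)
    return np.maximum(env, 0.0)


def normalize_envelopes(envelope_sets: list[EnvelopeSet]) -> list[EnvelopeSet]:
    """Divide each channel by its maximum across all supplied trials.

    After normalization at least one sample per channel (in some trial)
    equals 1.0 exactly.
    """
    if not envelope_sets:
        raise ParameterError("need at least one trial to normalize")
    n_ch = envelope_sets[0].envelopes.shape[1]
    for es in envelope_sets:
        if es.envelopes.shape[1] != n_ch:
            raise ParameterError("channel count differs across trials")
    gmax = np.max([es.envelopes.max(axis=0) for es in envelope_sets], axis=0)
    zero = np.flatnonzero(gmax <= 0)
    if zero.size:
        raise ParameterError(
            f"channel(s) {zero.tolist()} are identically zero across trials; "
            "cannot max-normalize")
    return [EnvelopeSet(es.envelopes / gmax, es.sampling_rate, gmax.copy())
            for es in envelope_sets]


def detect_grf_peaks(grf_vertical, min_prominence=None, bodyweight=None):
    """Locate the two characteristic peaks of the vertical GRF.

    Returns ``(i1, i2)``, the indices of the two highest local maxima
    (separated by at least one local minimum), with ``i1 < i2``.  Jitter is
    rejected with a minimum prominence of 5 % bodyweight (or 5 % of the
    series maximum when no bodyweight is given), overridable via
    ``min_prominence`` in the series' own units.
    """
    y = np.asarray(grf_vertical, dtype=float)
    if y.size < 5:
        raise ParameterError(f"series too short for peak detection ({y.size})")
    if min_prominence is None:
        ref = bodyweight if bodyweight is not None else y.max()
        min_prominence = 0.05 * ref
    peaks, _ = signal.find_peaks(y, prominence=min_prominence)
    if peaks.size < 2:
        raise PeakDetectionError(
            f"found {peaks.size} prominent local maxima, need 2")
    # rank by height, keep the two tallest, report in time order
    top = peaks[np.argsort(y[peaks])[-2:]]
    i1, i2 = int(top.min()), int(top.max())
    return i1, i2


def stance_window(grf_vertical, bodyweight,
                  threshold=STANCE_GRF_THRESHOLD) -> tuple[int, int]:
    """First and last frame (inclusive) where vertical GRF exceeds
    ``threshold`` x bodyweight — the stance phase, where joint contact
    forces are non-negligible."""
    above = np.flatnonzero(np.asarray(grf_vertical) > threshold * bodyweight)
    if above.size < 2:
        raise DataError("GRF never rises above the stance threshold")
    return int(above[0]), int(above[-1])


def resample_stance(series, stance_window):
    """Linearly interpolate frames [start, end] onto 101 evenly spaced points.

    Endpoints are preserved exactly; works on 1-D series or 2-D
    (frames x channels) arrays.
    """
    x = np.asarray(series, dtype=float)
    s, e = stance_window
    if not (0 <= s < e <= x.shape[0] - 1):
        raise ParameterError(
            f"stance window ({s}, {e}) outside series of {x.shape[0]} frames")
    grid = np.linspace(s, e, STANCE_POINTS)
    if x.ndim == 1:
        return np.interp(grid, np.arange(x.shape[0]), x)
    return np.column_stack(
        [np.interp(grid, np.arange(x.shape[0]), x[:, j])
         for j in range(x.shape[1])])


def select_representative_trial(trial_curves: list[np.ndarray]) -> int:
    """Pick the trial whose joint-angle curves best match the subject mean.

    ``trial_curves`` holds one (n_points x n_joints) array per trial, all on
    a common grid (typically hip/knee/ankle flexion over 101 stance points).
    Returns the index minimizing the sum over joints of the RMS deviation
    from the across-trial mean curve; ties break to the lowest index.
    """
    if not trial_curves:
        raise ParameterError("need at least one trial")
    stack = np.stack([np.atleast_2d(np.asarray(c, dtype=float).T).T
                      for c in trial_curves])  # (n_trials, n_points, n_joints)
    mean = stack.mean(axis=0)
    rms = np.sqrt(np.mean((stack - mean) ** 2, axis=1))  # (n_trials, n_joints)
    score = rms.sum(axis=1)
    return int(np.argmin(score))
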