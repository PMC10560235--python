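"""Signal conditioning, epoching and channel selection.

The preprocessing chain mirrors a standard intracranial pipeline: polyphase
anti-aliased downsampling, zero-phase notch filtering of line noise, removal
of the first principal component of high-frequency common-mode activity,
Kaiser-windowed FIR band-pass filtering, epoching with baseline correction,
per-timepoint ensemble normalisation for connectivity analysis, selection of
speech-responsive channels, and averaging of channels into ROIs.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from ecognet.containers import Epochs, Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Resampling and filtering
# ---------------------------------------------------------------------------

def resample(rec: Recording, target_fs: float) -> Recording:
    """Downsample with a polyphase Kaiser anti-alias filter.

    Only downsampling is supported. The output length is
    ``floor(n_times * target_fs / fs)`` so duration is preserved to within
    one sample, and tones below the new Nyquist keep their amplitude to ~1%.
    """
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec.copy_with(samples=rec.samples.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.samples, up, down, axis=1,
                               window=("kaiser", 5.0))
    n_out = math.floor(rec.n_times * target_fs / rec.fs)
    out = out[:, :n_out]
    return rec.copy_with(samples=out, fs=float(target_fs))


def notch_filter(rec: Recording, line_freq: float = 60.0,
                 width: float = 2.0) -> Recording:
    """Zero-phase IIR notch at the line frequency and its harmonics."""
    out = rec.samples.copy()
    nyq = rec.fs / 2.0
    f = line_freq
    while f < nyq:
        b, a = signal.iirnotch(f, f / width, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
        f += line_freq
    return rec.copy_with(samples=out)


def fir_bandpass(
    x: np.ndarray,
    low: float,
    high: float,
    fs: float,
    taps: int = 3624,
    kaiser_beta: float = 5.65,
) -> np.ndarray:
    """Zero-phase Kaiser-windowed FIR band-pass along the last axis.

    The default design (0.5-50 Hz, 3624 taps, beta = 5.65) gives a flat
    passband and a deep stopband; application is forward-backward
    (``filtfilt``) so the net phase response is zero and the magnitude
    response is squared.
    """
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= fs / 2:
        raise ValueError(f"high={high} must be below Nyquist ({fs / 2})")
    if taps < 3:
        raise ValueError("taps must be >= 3")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    taps = min(taps, max(3, n // 3 - 1))  # filtfilt needs padding room
    if low > 0:
        b = signal.firwin(taps, [low, high], pass_zero=False,
                          window=("kaiser", kaiser_beta), fs=fs)
    else:
        b = signal.firwin(taps, high, pass_zero=True,
                          window=("kaiser", kaiser_beta), fs=fs)
    return signal.filtfilt(b, [1.0], x, axis=-1)


def remove_first_pc(rec: Recording, hp_cutoff: float = 300.0) -> Recording:
    """Project out the first principal component of high-frequency activity.

    The covariance is computed from the ``> hp_cutoff`` high-passed data
    (where broadband artifacts such as amplifier or movement noise dominate)
    and its first principal direction is projected out of the *broadband*
    signal, so the output has zero variance along that direction in the
    high-passed band.
    """
    if rec.n_channels < 2:
        raise ValueError("first-PC removal needs at least 2 channels")
    if hp_cutoff >= rec.fs / 2:
        raise ValueError("hp_cutoff must be below Nyquist")
    sos = signal.butter(4, hp_cutoff, btype="highpass", fs=rec.fs,
                        output="sos")
    hf = signal.sosfiltfilt(sos, rec.samples, axis=1)
    cov = hf @ hf.T / hf.shape[1]
    w, v = np.linalg.eigh(cov)
    pc1 = v[:, -1]
    out = rec.samples - np.outer(pc1, pc1 @ rec.samples)
    return rec.copy_with(samples=out)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_and_baseline(
    rec: Recording,
    events: pd.DataFrame,
    window: tuple[float, float] = (-0.15, 0.8),
    baseline: tuple[float, float] | None = (-0.15, 0.0),
) -> Epochs:
    """Cut trials around event onsets and subtract the per-trial baseline mean.

    Sample windows are half-open ``[start, stop)`` with 0-based indexing:
    an epoch spans samples ``round(onset*fs) + round(w0*fs)`` up to (but not
    including) ``round(onset*fs) + round(w1*fs)``. Events too close to the
    recording edge are dropped with a logged warning.
    """
    i0 = int(round(window[0] * rec.fs))
    i1 = int(round(window[1] * rec.fs))
    n_samp = i1 - i0
    if n_samp <= 0:
        raise ValueError("empty epoch window")
    keep_rows, trials = [], []
    n_dropped = 0
    for idx, onset in enumerate(events["onset_s"].to_numpy(dtype=float)):
        s = int(round(onset * rec.fs))
        if s + i0 < 0 or s + i1 > rec.n_times:
            n_dropped += 1
            continue
        trials.append(rec.samples[:, s + i0 : s + i1])
        keep_rows.append(idx)
    if n_dropped:
        logger.warning("dropped %d event(s) too close to the recording edge",
                       n_dropped)
    data = (np.stack(trials) if trials
            else np.empty((0, rec.n_channels, n_samp)))
    ann = events.iloc[keep_rows].reset_index(drop=True)
    ep = Epochs(data, rec.fs, window[0], list(rec.labels), ann,
                baseline=baseline)
    if baseline is not None and ep.n_trials:
        mask = ep.time_mask(baseline)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        ep.data -= ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return ep


def normalize_trials_for_cgc(ep: Epochs, ddof: int = 1) -> Epochs:
    """Ensemble-normalise: at each (channel, time) remove the across-trial
    mean and divide by the across-trial standard deviation.

    This removes the stimulus-locked (deterministic) component so the
    connectivity analysis operates on the induced, trial-varying activity.
    """
    if ep.n_trials < 2:
        raise ValueError("ensemble normalisation needs >= 2 trials")
    mean = ep.data.mean(axis=0, keepdims=True)
    sd = ep.data.std(axis=0, ddof=ddof, keepdims=True)
    bad = np.argwhere(sd[0] == 0.0)
    if len(bad):
        ch, t = bad[0]
        raise ValueError(
            f"zero ensemble SD at channel {ep.labels[ch]!r}, sample {t} "
            f"(t = {ep.tmin + t / ep.fs:.4f} s)"
        )
    return ep.copy_with(data=(ep.data - mean) / sd)


# ---------------------------------------------------------------------------
# Channel selection and ROI averaging
# ---------------------------------------------------------------------------

def select_speech_responsive(
    ep: Epochs,
    response_window: tuple[float, float] = (0.0, 0.5),
    min_duration: float = 0.125,
    k_sd: float = 2.0,
    baseline: tuple[float, float] | None = None,
    sd_over: str = "time",
) -> tuple[list[str], pd.DataFrame]:
    """Select channels whose trial-averaged response exceeds baseline
    variability for long enough.

    A channel is selected when ``|mean response| > k_sd * baseline SD`` for a
    total of at least ``min_duration`` seconds within ``response_window``.
    ``sd_over`` chooses whether baseline SD is taken over time of the
    trial-averaged baseline (``"time"``, default) or over trials and time
    (``"both"``).

    Returns the selected labels and a per-channel report table.
    """
    if min_duration > response_window[1] - response_window[0]:
        raise ValueError("min_duration exceeds the response window")
    baseline = baseline or ep.baseline
    if baseline is None:
        raise ValueError("no baseline window available")
    bmask = ep.time_mask(baseline)
    rmask = ep.time_mask(response_window)
    avg = ep.data.mean(axis=0)  # channels x time
    if sd_over == "time":
        base_sd = avg[:, bmask].std(axis=1, ddof=1)
    elif sd_over == "both":
        base_sd = ep.data[:, :, bmask].std(axis=(0, 2), ddof=1)
    else:
        raise ValueError("sd_over must be 'time' or 'both'")
    base_mean = avg[:, bmask].mean(axis=1)
    above = (
        np.abs(avg[:, rmask] - base_mean[:, None])
        > k_sd * base_sd[:, None]
    )
    dur = above.sum(axis=1) / ep.fs
    selected = dur >= min_duration
    report = pd.DataFrame(
        {
            "channel": ep.labels,
            "baseline_sd": base_sd,
            "supra_duration_s": dur,
            "selected": selected,
        }
    )
    return [l for l, s in zip(ep.labels, selected) if s], report


def average_roi(ep: Epochs, roi_map: dict[str, str],
                order: list[str] | None = None) -> Epochs:
    """Average member channels into ROI-level epochs.

    ``roi_map`` maps channel label to ROI label; channels absent from the map
    are dropped. ``order`` fixes the ROI ordering (default: first appearance).
    """
    rois: dict[str, list[int]] = {}
    for i, lab in enumerate(ep.labels):
        roi = roi_map.get(lab)
        if roi is not None:
            rois.setdefault(roi, []).append(i)
    names = order if order is not None else list(rois)
    for roi in names:
        if not rois.get(roi):
            raise ValueError(f"ROI {roi!r} has no member channels")
    data = np.stack([ep.data[:, rois[r], :].mean(axis=1) for r in names],
                    axis=1)
    return ep.copy_with(data=data, labels=list(names))
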