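"""Evoked-response measures: ERSP, band courses, mismatch difference waves
and VOT peak latencies.

The event-related spectral perturbation (ERSP) is the trial-averaged
time-frequency power expressed in dB relative to the mean power in a
pre-stimulus baseline window, per frequency. Mismatch difference waves
contrast congruent minus incongruent trials after matching the two
conditions by VOT; peak measures track the latency shift of the early
negative and later positive auditory peaks along the VOT continuum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecognet.bands import BandSet, ERSP_BANDS
from ecognet.containers import Epochs
from ecognet.preprocess import fir_bandpass


@dataclass
class ERSP:
    """Event-related spectral perturbation in dB.

    ``values`` has shape (channels, frequencies, times); by construction the
    baseline-window mean is ~0 dB at every frequency.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple[float, float]
    labels: list[str]


def compute_ersp(
    ep: Epochs,
    freqs,
    baseline: tuple[float, float] = (-0.15, 0.0),
    n_cycles: float | np.ndarray = 7.0,
    average: str = "power",
) -> ERSP:
    """Morlet-wavelet ERSP relative to the pre-stimulus baseline.

    ``value = 10 log10(power / mean baseline power at that frequency)``,
    with power averaged across trials before the dB conversion
    (``average="power"``, default) or dB averaged across trials
    (``average="db"``).
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= ep.fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    times = ep.times
    bmask = ep.time_mask(baseline)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    power = tfr_array_morlet(
        ep.data, ep.fs, freqs, n_cycles=n_cycles, output="power",
        verbose="error",
    )  # (trials, channels, freqs, times)
    if average == "power":
        mean_pow = power.mean(axis=0)
        base = mean_pow[:, :, bmask].mean(axis=2, keepdims=True)
        if np.any(base <= 0):
            raise ValueError("zero baseline power")
        values = 10.0 * np.log10(mean_pow / base)
    elif average == "db":
        base = power[:, :, :, bmask].mean(axis=3, keepdims=True)
        if np.any(base <= 0):
            raise ValueError("zero baseline power")
        values = (10.0 * np.log10(power / base)).mean(axis=0)
    else:
        raise ValueError("average must be 'power' or 'db'")
    return ERSP(values, freqs, times, baseline, list(ep.labels))


def band_average(ersp: ERSP, bands: BandSet = ERSP_BANDS) -> dict[str, np.ndarray]:
    """Unweighted mean of ERSP dB values over in-band frequency bins.

    Returns ``{band: (channels x times) course}``. Bands with no bins in the
    frequency grid raise.
    """
    masks = bands.mask(ersp.freqs)
    out = {}
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"band {name!r} has no frequency bins in the grid")
        out[name] = ersp.values[:, m, :].mean(axis=1)
    return out


@dataclass
class DifferenceWave:
    """Congruent-minus-incongruent ERP difference after VOT matching."""

    values: np.ndarray  # channels x times
    times: np.ndarray
    n_congruent: int
    n_incongruent: int
    counts_per_step: pd.DataFrame | None = None
    labels: list[str] | None = None


def mismatch_difference(
    ep: Epochs,
    filter_spec: tuple[float, float, int, float] | None = (0.5, 50.0, 3624, 5.65),
) -> DifferenceWave:
    """Mismatch difference wave: congruent minus incongruent ERP.

    Trials must carry ``congruency`` labels. The two conditions are matched
    by VOT before subtraction (shortest with shortest, i.e. equal VOT steps
    pair up); unequal counts within any step raise with the offending counts.
    Per-condition ERPs are band-pass filtered with the Kaiser FIR
    specification ``(low, high, taps, beta)`` before the subtraction.
    """
    ann = ep.annotations
    if "congruency" not in ann.columns:
        raise ValueError("epochs lack congruency labels")
    cong = ann.index[ann["congruency"] == "congruent"].to_numpy()
    inc = ann.index[ann["congruency"] == "incongruent"].to_numpy()
    if len(cong) == 0 or len(inc) == 0:
        raise ValueError("both conditions must be non-empty")

    counts = (
        ann.loc[np.concatenate([cong, inc])]
        .groupby(["congruency", "vot_step"], observed=True)
        .size()
        .unstack("congruency", fill_value=0)
    )
    bad = counts[counts.get("congruent", 0) != counts.get("incongruent", 0)]
    if len(bad):
        raise ValueError(
            "conditions unbalanced after VOT matching:\n" + bad.to_string()
        )

    erp_c = ep.data[cong].mean(axis=0)
    erp_i = ep.data[inc].mean(axis=0)
    if filter_spec is not None:
        low, high, taps, beta = filter_spec
        erp_c = fir_bandpass(erp_c, low, high, ep.fs, taps, beta)
        erp_i = fir_bandpass(erp_i, low, high, ep.fs, taps, beta)
    return DifferenceWave(
        erp_c - erp_i, ep.times, len(cong), len(inc),
        counts.reset_index(), list(ep.labels),
    )


def vot_peak_measures(
    ep: Epochs,
    window_peak1: tuple[float, float] = (0.175, 0.325),
    window_peak2: tuple[float, float] = (0.275, 0.425),
) -> pd.DataFrame:
    """Peak latency/amplitude of the trial-averaged ERP per VOT step.

    Peak 1 is the most negative point of the channel- and trial-averaged ERP
    inside its search window; Peak 2 the most positive inside its window.
    Flat windows resolve ties to the earliest extremum and are flagged.
    """
    ann = ep.annotations
    if "vot_step" not in ann.columns:
        raise ValueError("epochs lack vot_step annotations")
    times = ep.times
    m1 = ep.time_mask(window_peak1)
    m2 = ep.time_mask(window_peak2)
    rows = []
    steps = sorted(
        int(s) for s in ann.loc[ann["trial_class"] == "experimental",
                                "vot_step"].unique()
    ) if "trial_class" in ann.columns else sorted(
        int(s) for s in ann["vot_step"].unique()
    )
    for step in steps:
        idx = ann.index[ann["vot_step"] == step].to_numpy()
        if len(idx) == 0:
            continue
        erp = ep.data[idx].mean(axis=(0, 1))  # average trials and channels
        seg1, t1 = erp[m1], times[m1]
        seg2, t2 = erp[m2], times[m2]
        i1 = int(np.argmin(seg1))
        i2 = int(np.argmax(seg2))
        rows.append(
            dict(
                vot_step=step,
                n_trials=len(idx),
                peak1_latency=float(t1[i1]),
                peak1_amplitude=float(seg1[i1]),
                peak1_tied=bool(np.sum(seg1 == seg1[i1]) > 1),
                peak2_latency=float(t2[i2]),
                peak2_amplitude=float(seg2[i2]),
                peak2_tied=bool(np.sum(seg2 == seg2[i2]) > 1),
            )
        )
    return pd.DataFrame(rows)


def latency_slope(peaks: pd.DataFrame, which: str = "peak1") -> float:
    """Least-squares slope of peak latency vs VOT step (seconds per step)."""
    x = peaks["vot_step"].to_numpy(dtype=float)
    y = peaks[f"{which}_latency"].to_numpy(dtype=float)
    return float(np.polyfit(x, y, 1)[0])
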