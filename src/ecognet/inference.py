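"""Surrogate and permutation inference for spectral conditional GC.

* :func:`phase_randomize` builds surrogates with the original per-channel
  amplitude spectra but i.i.d. uniform Fourier phases, destroying
  cross-channel dependence while preserving autocorrelation;
* :func:`surrogate_threshold` thresholds observed GC spectra at the
  ``1 - alpha`` quantile of a surrogate null (full re-identification per
  surrogate) and trims at zero;
* :func:`permutation_prepost` tests pre- vs post-condition band differences
  by trial-label permutation with full re-identification, controlling FDR
  across pairs and bands.

All iterations draw from per-iteration seeds spawned from the caller's seed,
so results are invariant to execution order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecognet.bands import BandSet, CGC_BANDS
from ecognet.containers import Epochs
from ecognet.ssgc import (
    CGCSpectrum,
    FactorizationError,
    spectral_cgc,
    subspace_identify,
)
from ecognet.stats import bh_fdr

logger = logging.getLogger(__name__)


def phase_randomize(ep: Epochs, seed: int | None = 0) -> Epochs:
    """Fourier phase-randomisation surrogate of every trial and channel.

    Per trial and channel independently, the FFT phases of the non-DC,
    non-Nyquist bins are replaced by i.i.d. uniform phases (DC and Nyquist
    stay real), so the amplitude spectrum — hence the autocorrelation — is
    preserved to machine precision while cross-channel dependence is
    destroyed in expectation.
    """
    rng = np.random.default_rng(seed)
    n = ep.n_times
    X = np.fft.rfft(ep.data, axis=2)
    n_bins = X.shape[2]
    has_nyquist = n % 2 == 0
    lo, hi = 1, n_bins - 1 if has_nyquist else n_bins
    if hi > lo:
        phases = rng.uniform(0.0, 2 * np.pi,
                             size=(ep.n_trials, ep.n_channels, hi - lo))
        X[:, :, lo:hi] = np.abs(X[:, :, lo:hi]) * np.exp(1j * phases)
    data = np.fft.irfft(X, n=n, axis=2)
    return ep.copy_with(data=data)


@dataclass
class SurrogateNull:
    """Empirical GC null from phase-randomised surrogates.

    ``values`` has shape (n_surrogates, channels, channels, frequencies);
    ``threshold`` is its ``1 - alpha`` quantile per (pair, frequency).
    """

    values: np.ndarray
    threshold: np.ndarray
    alpha: float
    n_surrogates: int
    seed: int | None
    n_redrawn: int = 0


def _fit_gc(ep: Epochs, order: int, freqs, horizon) -> np.ndarray:
    model = subspace_identify(ep, order, horizon=horizon)
    return spectral_cgc(model, freqs).values


def surrogate_threshold(
    observed: CGCSpectrum,
    ep: Epochs,
    order: int,
    n_surr: int = 2000,
    alpha: float = 0.05,
    seed: int | None = 0,
    horizon: int | None = None,
    max_redraws: int = 50,
) -> tuple[CGCSpectrum, SurrogateNull]:
    """Surrogate-threshold an observed GC spectrum.

    For each (ordered pair, frequency) cell, the threshold is the
    ``1 - alpha`` quantile of GC values computed by the full identification +
    GC pipeline on ``n_surr`` phase-randomised copies of ``ep`` (re-identified
    at the same model order as the observed fit); the output is
    ``max(observed - threshold, 0)``. A surrogate whose identification fails
    is redrawn (count logged).
    """
    if n_surr < 100:
        raise ValueError("n_surr must be >= 100")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_surr + max_redraws)
    c = len(observed.labels)
    null = np.empty((n_surr, c, c, len(observed.freqs)))
    n_redrawn = 0
    draw = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in range(n_surr):
            while True:
                if draw >= len(children):
                    raise FactorizationError(
                        "too many surrogate identification failures"
                    )
                child_seed = children[draw]
                draw += 1
                try:
                    surro = phase_randomize(ep, child_seed)
                    null[k] = _fit_gc(surro, order, observed.freqs, horizon)
                    break
                except (FactorizationError, np.linalg.LinAlgError):
                    n_redrawn += 1
    if n_redrawn:
        logger.info("redrew %d failed surrogate(s)", n_redrawn)
    thr = np.quantile(null, 1 - alpha, axis=0)
    out = np.maximum(observed.values - thr, 0.0)
    out[np.isnan(observed.values)] = np.nan
    return (
        CGCSpectrum(out, observed.freqs, list(observed.labels),
                    observed.conditioning),
        SurrogateNull(null, thr, alpha, n_surr, seed, n_redrawn),
    )


@dataclass
class EdgeChangeResult:
    """Pre/post permutation test of band-aggregated GC changes.

    ``table`` has one row per (ordered pair, band): observed pre and post
    band-mean GC, signed difference, permutation p (count / n_perm of null
    statistics at least as large), BH-FDR flag at ``q`` across pairs x bands,
    and the direction of change.
    """

    table: pd.DataFrame
    n_perm: int
    q: float
    seed: int | None
    gc_pre: CGCSpectrum
    gc_post: CGCSpectrum

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr_sig"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _band_stats(gc_a: np.ndarray, gc_b: np.ndarray, masks: dict) -> np.ndarray:
    """Per (pair, band): sum over in-band frequencies of |gc_a - gc_b|."""
    diff = np.abs(gc_a - gc_b)
    return np.stack([np.nansum(diff[:, :, m], axis=2) for m in masks.values()],
                    axis=-1)  # (c, c, n_bands)


def permutation_prepost(
    ep_pre: Epochs,
    ep_post: Epochs,
    order: int,
    bands: BandSet = CGC_BANDS,
    n_perm: int = 2000,
    q: float = 0.05,
    seed: int | None = 0,
    freqs=None,
    horizon: int | None = None,
) -> EdgeChangeResult:
    """Permutation test of pre- vs post-condition GC differences per band.

    The observed statistic per (ordered pair, band) is the sum over in-band
    frequencies of the absolute GC difference between conditions. The null is
    built by randomly reassigning trials to the two conditions (sizes
    preserved) and recomputing both GC spectra with full re-identification at
    the same model order. FDR across pairs x bands at level ``q``; the sign
    of a reported change is the sign of the (post - pre) band-mean.
    """
    if ep_pre.n_trials < 10 or ep_post.n_trials < 10:
        raise ValueError("need >= 10 trials per condition")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", RuntimeWarning,
                      stacklevel=2)
    from ecognet.ssgc import EnsembleMoments, _cap_horizon, default_freqs

    if freqs is None:
        freqs = default_freqs(min(50.0, ep_pre.fs / 2))
    freqs = np.asarray(freqs, dtype=float)
    masks = bands.mask(freqs)
    labels = list(ep_pre.labels)
    c = len(labels)
    fs = ep_pre.fs

    # one pooled moment stack serves the observed fit and every permutation
    pooled = np.concatenate([ep_pre.data, ep_post.data], axis=0)
    horizon = horizon or max(20, 2 * order)
    horizon = _cap_horizon(ep_pre, horizon)
    moments = EnsembleMoments(pooled, horizon)
    n_pre = ep_pre.n_trials
    n_tot = pooled.shape[0]
    idx_pre = np.arange(n_pre)
    idx_post = np.arange(n_pre, n_tot)

    def _gc(idx):
        model = moments.fit(order, fs, labels, idx=idx)
        return spectral_cgc(model, freqs).values

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gc_pre = _gc(idx_pre)
        gc_post = _gc(idx_post)
    obs = _band_stats(gc_pre, gc_post, masks)  # (c, c, n_bands)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_perm)
    null = np.empty((n_perm,) + obs.shape)
    total_gram, total_N = moments.sums()
    chunk = 64
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for start in range(0, n_perm, chunk):
            stop = min(start + chunk, n_perm)
            W = np.zeros((stop - start, n_tot))
            for k in range(start, stop):
                rng = np.random.default_rng(children[k])
                W[k - start, rng.permutation(n_tot)[:n_pre]] = 1.0
            gsums_a, Ns_a = moments.batched_sums(W)
            for k in range(start, stop):
                ga = spectral_cgc(
                    moments.fit(order, fs, labels,
                                gsum=gsums_a[k - start],
                                N=int(Ns_a[k - start])),
                    freqs,
                ).values
                gb = spectral_cgc(
                    moments.fit(order, fs, labels,
                                gsum=total_gram - gsums_a[k - start],
                                N=total_N - int(Ns_a[k - start])),
                    freqs,
                ).values
                null[k] = _band_stats(ga, gb, masks)

    band_names = list(bands)
    rows = []
    for j in range(c):
        for i in range(c):
            if i == j:
                continue
            for b, bname in enumerate(band_names):
                m = masks[bname]
                pre_mean = float(np.nanmean(gc_pre[j, i, m]))
                post_mean = float(np.nanmean(gc_post[j, i, m]))
                p = float(np.mean(null[:, j, i, b] >= obs[j, i, b]))
                rows.append(
                    dict(source=labels[j], target=labels[i], band=bname,
                         pre=pre_mean, post=post_mean,
                         delta=post_mean - pre_mean, p=p)
                )
    table = pd.DataFrame(rows)
    fdr = bh_fdr(table["p"].to_numpy(), q)
    table["p_adjusted"] = fdr.p_adjusted
    table["fdr_sig"] = fdr.reject
    table["direction"] = np.where(table["delta"] > 0, "increase", "decrease")
    return EdgeChangeResult(
        table, n_perm, q, seed,
        CGCSpectrum(gc_pre, freqs, labels),
        CGCSpectrum(gc_post, freqs, labels),
    )
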