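"""Shared fixtures: small ground-truth networks, rosters and an EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from ecognet.synth import (
    INTRAOP_DESIGN,
    Coupling,
    NetworkSpec,
    NodeDynamics,
    label_congruency,
    make_task_roster,
    simulate_network_trials,
)
from ecognet.preprocess import normalize_trials_for_cgc


@pytest.fixture(scope="session")
def chain_var():
    """3-channel VAR(1) chain 0 -> 1 -> 2 with correlated innovations."""
    A = np.zeros((1, 3, 3))
    A[0] = [[0.5, 0.0, 0.0], [0.6, 0.3, 0.0], [0.0, 0.6, 0.2]]
    Sigma = np.array([[1.0, 0.1, 0.0], [0.1, 1.0, 0.1], [0.0, 0.1, 1.0]])
    return A, Sigma


@pytest.fixture(scope="session")
def small_network():
    """3-node oscillator network with one directed coupling 0 -> 1."""
    return NetworkSpec(
        3,
        [NodeDynamics(10.0, 0.15), NodeDynamics(40.0, 0.1),
         NodeDynamics(6.0, 0.2)],
        [Coupling(0, 1, 0.5, 2, (31.0, 50.0))],
        noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def network_epochs(small_network):
    """Normalised trial ensemble simulated from the small network."""
    ep = simulate_network_trials(small_network, "pre", n_trials=60,
                                 n_samples=200, fs=100.0, seed=7)
    return normalize_trials_for_cgc(ep)


@pytest.fixture(scope="session")
def intraop_roster():
    return label_congruency(make_task_roster(INTRAOP_DESIGN, seed=3))


def write_minimal_edf(path, data: np.ndarray, fs: float) -> None:
    """Write a minimal single-record-per-second EDF file (test fixture)."""
    data = np.asarray(data, dtype=float)
    ns, n_samp = data.shape
    spr = int(fs)
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "fixture wants whole-second data"
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    pmax = np.where(pmax == pmin, pmin + 1.0, pmax)

    def pad(s, n):
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("test patient", 80), pad("test recording", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(ns), 4),
    ])
    fields = [
        ("".join(f"ch{k}".ljust(16) for k in range(ns)), 16),
        ("".join("".ljust(80) for _ in range(ns)), 80),
        ("".join("uV".ljust(8) for _ in range(ns)), 8),
        ("".join(f"{pmin[k]:.3f}"[:8].ljust(8) for k in range(ns)), 8),
        ("".join(f"{pmax[k]:.3f}"[:8].ljust(8) for k in range(ns)), 8),
        ("".join("-32768".ljust(8) for _ in range(ns)), 8),
        ("".join("32767".ljust(8) for _ in range(ns)), 8),
        ("".join("".ljust(80) for _ in range(ns)), 80),
        ("".join(str(spr).ljust(8) for _ in range(ns)), 8),
        ("".join("".ljust(32) for _ in range(ns)), 32),
    ]
    sig_hdr = b"".join(f[0].encode("ascii") for f in fields)
    digital = np.empty((ns, n_samp), dtype="<i2")
    for k in range(ns):
        scale = (pmax[k] - pmin[k]) / 65535.0
        digital[k] = np.round((data[k] - pmin[k]) / scale - 32768.0)
    with open(path, "wb") as f:
        f.write(hdr + sig_hdr)
        for r in range(n_rec):
            for k in range(ns):
                f.write(digital[k, r * spr : (r + 1) * spr].tobytes())
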