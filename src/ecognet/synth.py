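"""Synthetic data with known ground truth.

Everything downstream — preprocessing, evoked-response measures, state-space
Granger causality, surrogate/permutation inference, hub testing and
psychometric modeling — can be exercised on data generated here, where the
directed couplings, evoked templates and behavioral parameters are known
exactly.

The generator emulates three aspects of an intracranial speech-prediction
experiment:

* a **task roster** — a /b/-vs-/p/ word-pair design crossed with a 6-step
  voice-onset-time (VOT) continuum (0-40 ms) and a sentence bias, plus filler
  and catch trials;
* **network trial data** — multichannel trials from a network of damped
  stochastic oscillators (AR(2) nodes) with directed, lagged, band-limited
  couplings that may differ between a "pre" and a "post" condition;
* **evoked responses** — VOT-latency-shifted peaks, a congruency mismatch
  component and band-limited power effects, on top of trial noise; and
  **behavioral responses** from a Bernoulli/logistic psychometric model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ecognet.containers import Epochs

#: The 6-step VOT grid in milliseconds (even steps over the 0-40 ms range).
VOT_GRID_MS = (0.0, 8.0, 16.0, 24.0, 32.0, 40.0)

#: The seven /b/-/p/ word pairs of the extended task design.
WORD_PAIRS = (
    "bill/pill",
    "bad/pad",
    "bath/path",
    "back/pack",
    "bark/park",
    "bowl/pole",
    "beach/peach",
)

ROSTER_COLUMNS = [
    "trial_id",
    "trial_class",
    "word_pair",
    "bias",
    "vot_step",
    "vot_ms",
    "congruency",
    "phase",
]


class InvalidDesignError(ValueError):
    """Raised when the requested trial-roster design is inconsistent."""


class StabilityError(ValueError):
    """Raised when a network specification implies an unstable generator."""


# ---------------------------------------------------------------------------
# Task roster
# ---------------------------------------------------------------------------

def make_task_roster(
    design: dict,
    seed: int | None = None,
    phase: str = "pre",
) -> pd.DataFrame:
    """Build a balanced trial roster for the speech-prediction task.

    Parameters
    ----------
    design : dict
        Counts ``{"word_pairs": int, "vot_steps": int, "biases": int,
        "reps": int, "filler": int, "catch": int}``. Experimental rows number
        ``word_pairs * vot_steps * biases * reps`` with every
        (word pair, bias, VOT step) cell appearing exactly ``reps`` times.
    seed : int, optional
        Seed for the presentation-order shuffle. ``None`` leaves the roster
        in systematic order.
    phase : str
        Recording phase label attached to every row (``"pre"`` or ``"post"``).

    Returns
    -------
    pandas.DataFrame
        Roster with columns ``trial_id, trial_class, word_pair, bias,
        vot_step, vot_ms, congruency, phase``. Congruency is ``"n/a"`` until
        :func:`label_congruency` is applied.
    """
    d = {"word_pairs": 0, "vot_steps": 6, "biases": 2, "reps": 0,
         "filler": 0, "catch": 0}
    d.update(design)
    for k, v in d.items():
        if v < 0:
            raise InvalidDesignError(f"negative count for {k!r}: {v}")
    if d["word_pairs"] > 0 and d["reps"] <= 0:
        raise InvalidDesignError(
            "non-positive reps with nonzero word_pairs: the experimental "
            "cells cannot be filled"
        )
    if d["vot_steps"] > len(VOT_GRID_MS):
        raise InvalidDesignError(
            f"vot_steps={d['vot_steps']} exceeds the {len(VOT_GRID_MS)}-step grid"
        )

    pairs = [
        WORD_PAIRS[i] if i < len(WORD_PAIRS) else f"pair{i + 1}"
        for i in range(d["word_pairs"])
    ]
    biases = ["b", "p"][: d["biases"]]

    rows: list[dict] = []
    for wp in pairs:
        for bias in biases:
            for step in range(1, d["vot_steps"] + 1):
                for _ in range(d["reps"]):
                    rows.append(
                        dict(
                            trial_class="experimental",
                            word_pair=wp,
                            bias=bias,
                            vot_step=step,
                            vot_ms=VOT_GRID_MS[step - 1],
                        )
                    )
    for _ in range(d["filler"]):
        rows.append(
            dict(trial_class="filler", word_pair="filler", bias="n/a",
                 vot_step=0, vot_ms=np.nan)
        )
    for _ in range(d["catch"]):
        rows.append(
            dict(trial_class="catch", word_pair="catch", bias="n/a",
                 vot_step=0, vot_ms=np.nan)
        )

    roster = pd.DataFrame(rows, columns=["trial_class", "word_pair", "bias",
                                         "vot_step", "vot_ms"])
    if seed is not None and len(roster):
        rng = np.random.default_rng(seed)
        roster = roster.iloc[rng.permutation(len(roster))].reset_index(drop=True)
    roster.insert(0, "trial_id", np.arange(len(roster)))
    roster["congruency"] = "n/a"
    roster["phase"] = phase
    return roster[ROSTER_COLUMNS]


#: The extended (perioperative) design: 7 word pairs x 6 VOT x 2 bias x 6 reps
#: = 504 experimental trials, plus 126 filler and 63 catch trials (693 total).
EXTENDED_DESIGN = dict(word_pairs=7, vot_steps=6, biases=2, reps=6,
                       filler=126, catch=63)

#: The intraoperative design: 4 word pairs x 6 VOT x 2 bias x 6 reps = 288
#: experimental trials (24 per bias x VOT cell), plus 72 filler trials.
INTRAOP_DESIGN = dict(word_pairs=4, vot_steps=6, biases=2, reps=6,
                      filler=72, catch=0)


def label_congruency(roster: pd.DataFrame) -> pd.DataFrame:
    """Label experimental trials congruent/incongruent for the ERP contrast.

    A target word is *congruent* with the sentence bias when the bias predicts
    its endpoint of the VOT continuum: /b/-bias with the two shortest VOTs
    (steps 1-2) or /p/-bias with the two longest (steps 5-6). The reversed
    combinations are *incongruent*; the middle steps stay ``"n/a"`` and are
    excluded from the mismatch contrast.
    """
    out = roster.copy()
    exp = out["trial_class"] == "experimental"
    if exp.any() and (out.loc[exp, "bias"].isin(["b", "p"]) == False).any():  # noqa: E712
        raise ValueError("experimental rows must have bias 'b' or 'p'")
    bias = out["bias"]
    step = out["vot_step"]
    short = step.isin([1, 2])
    long = step.isin([5, 6])
    congruent = exp & ((bias.eq("b") & short) | (bias.eq("p") & long))
    incongruent = exp & ((bias.eq("b") & long) | (bias.eq("p") & short))
    out["congruency"] = "n/a"
    out.loc[congruent, "congruency"] = "congruent"
    out.loc[incongruent, "congruency"] = "incongruent"
    return out


def roster_to_tsv(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, sep="\t", index=False)


def roster_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Oscillator-network trial generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coupling:
    """A directed, lagged coupling ``source -> target``.

    ``gain`` is the VAR cross-coefficient applied to the lagged source sample;
    ``carrier_band`` records the frequency interval (Hz) the coupling is meant
    to act in. By default band limitation comes only from the source node's
    resonance; setting ``relay_damping`` routes the coupling through a
    noiseless damped-oscillator relay tuned to the carrier-band center, which
    confines the induced directed influence sharply to that band.
    """

    source: int
    target: int
    gain: float
    lag: int = 1
    carrier_band: tuple[float, float] | None = None
    relay_damping: float | None = None

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 sample")
        if not np.isfinite(self.gain):
            raise ValueError("coupling gain must be finite")
        if self.relay_damping is not None:
            if not 0.0 < self.relay_damping < 1.0:
                raise ValueError("relay_damping must lie in (0, 1)")
            if self.carrier_band is None:
                raise ValueError("a resonant relay needs a carrier_band")


@dataclass(frozen=True)
class NodeDynamics:
    """Damped stochastic oscillator (AR(2)) parameters for one node.

    The AR(2) poles sit at ``r * exp(+-i 2 pi f0 / fs)`` with ``r = 1 - damping``,
    so the node resonates at center frequency ``f0`` (Hz) with bandwidth set by
    ``damping`` in (0, 1).
    """

    f0: float
    damping: float

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")

    def ar2(self, fs: float) -> tuple[float, float]:
        r = 1.0 - self.damping
        theta = 2.0 * np.pi * self.f0 / fs
        return 2.0 * r * np.cos(theta), -(r**2)


@dataclass
class NetworkSpec:
    """Ground-truth specification of a coupled oscillator network.

    ``condition_deltas`` maps a condition name to coupling overrides: a listed
    ``Coupling`` replaces any existing coupling on the same (source, target);
    a gain of 0 removes the edge in that condition.
    """

    n_nodes: int
    node_dynamics: list[NodeDynamics]
    couplings: list[Coupling] = field(default_factory=list)
    noise_sd: float = 1.0
    condition_deltas: dict[str, list[Coupling]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.node_dynamics) != self.n_nodes:
            raise ValueError("node_dynamics must have one entry per node")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def couplings_for(self, condition: str) -> list[Coupling]:
        base = {(c.source, c.target): c for c in self.couplings}
        for c in self.condition_deltas.get(condition, []):
            if c.gain == 0.0:
                base.pop((c.source, c.target), None)
            else:
                base[(c.source, c.target)] = c
        return list(base.values())

    def var_coefficients(self, condition: str, fs: float) -> np.ndarray:
        """Stacked VAR coefficient matrices over the observed nodes.

        Only defined for direct (non-relay) couplings; relay-mediated
        couplings make the observed process VARMA (use
        :meth:`extended_var_coefficients`).
        """
        coup = self.couplings_for(condition)
        if any(c.relay_damping is not None for c in coup):
            raise ValueError(
                "relay-mediated couplings have no finite VAR representation "
                "over the observed nodes; use extended_var_coefficients"
            )
        p = max([2] + [c.lag for c in coup])
        A = np.zeros((p, self.n_nodes, self.n_nodes))
        for i, nd in enumerate(self.node_dynamics):
            a1, a2 = nd.ar2(fs)
            A[0, i, i] = a1
            A[1, i, i] = a2
        for c in coup:
            A[c.lag - 1, c.target, c.source] += c.gain
        return A

    def extended_var_coefficients(self, condition: str, fs: float
                                  ) -> tuple[np.ndarray, int]:
        """VAR coefficients over nodes plus one latent state per resonant
        relay; returns ``(A, n_extended)``. The first ``n_nodes`` rows are
        the observed channels; relay states are noiseless."""
        coup = self.couplings_for(condition)
        relays = [c for c in coup if c.relay_damping is not None]
        n_ext = self.n_nodes + len(relays)
        p = max([2] + [c.lag for c in coup])
        A = np.zeros((p, n_ext, n_ext))
        for i, nd in enumerate(self.node_dynamics):
            a1, a2 = nd.ar2(fs)
            A[0, i, i] = a1
            A[1, i, i] = a2
        r_idx = self.n_nodes
        for c in coup:
            if c.relay_damping is None:
                A[c.lag - 1, c.target, c.source] += c.gain
            else:
                f0 = 0.5 * (c.carrier_band[0] + c.carrier_band[1])
                a1, a2 = NodeDynamics(f0, c.relay_damping).ar2(fs)
                A[0, r_idx, r_idx] = a1
                A[1, r_idx, r_idx] = a2
                A[c.lag - 1, r_idx, c.source] = 1.0
                A[0, c.target, r_idx] = c.gain
                r_idx += 1
        return A, n_ext

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path=None) -> str | None:
        doc = dict(
            n_nodes=self.n_nodes,
            noise_sd=float(self.noise_sd),
            node_dynamics=[
                dict(f0=float(n.f0), damping=float(n.damping))
                for n in self.node_dynamics
            ],
            couplings=[_coupling_doc(c) for c in self.couplings],
            condition_deltas={
                k: [_coupling_doc(c) for c in v]
                for k, v in self.condition_deltas.items()
            },
        )
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as f:
            f.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "NetworkSpec":
        if isinstance(source, str) and "\n" in source:
            doc = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as f:
                doc = yaml.safe_load(f)
        return cls(
            n_nodes=doc["n_nodes"],
            noise_sd=doc.get("noise_sd", 1.0),
            node_dynamics=[NodeDynamics(**n) for n in doc["node_dynamics"]],
            couplings=[_coupling_from_doc(c) for c in doc.get("couplings", [])],
            condition_deltas={
                k: [_coupling_from_doc(c) for c in v]
                for k, v in doc.get("condition_deltas", {}).items()
            },
        )


def _coupling_doc(c: Coupling) -> dict:
    d = dict(source=c.source, target=c.target, gain=float(c.gain), lag=c.lag)
    if c.carrier_band is not None:
        d["carrier_band"] = [float(c.carrier_band[0]), float(c.carrier_band[1])]
    if c.relay_damping is not None:
        d["relay_damping"] = float(c.relay_damping)
    return d


def _coupling_from_doc(d: dict) -> Coupling:
    band = d.get("carrier_band")
    return Coupling(
        d["source"], d["target"], d["gain"], d.get("lag", 1),
        tuple(band) if band is not None else None,
        d.get("relay_damping"),
    )


def var_companion(A: np.ndarray) -> np.ndarray:
    """Companion matrix of a VAR with stacked coefficients (p, n, n)."""
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def check_stability(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix; raise if >= 1."""
    ev = np.linalg.eigvals(var_companion(A))
    rho = float(np.max(np.abs(ev)))
    if rho >= 1.0:
        worst = ev[np.argmax(np.abs(ev))]
        raise StabilityError(
            f"generator is unstable: companion root {worst:.4f} has "
            f"modulus {rho:.4f} >= 1"
        )
    return rho


def simulate_network_trials(
    spec: NetworkSpec,
    condition: str,
    n_trials: int,
    n_samples: int,
    fs: float,
    seed: int | None = 0,
    burn_in: int = 200,
) -> Epochs:
    """Simulate independent trials from the coupled-oscillator network.

    Trials are independent realisations of the stable VAR process implied by
    ``spec`` under ``condition``; a directed coupling j -> i produces nonzero
    ground-truth Granger causality j -> i concentrated near the source node's
    resonance, and absent couplings have ground-truth causality exactly zero.
    """
    A, n_ext = spec.extended_var_coefficients(condition, fs)
    check_stability(A)
    p = A.shape[0]
    n = spec.n_nodes
    rng = np.random.default_rng(seed)
    total = burn_in + n_samples
    noise = np.zeros((total, n_trials, n_ext))
    noise[:, :, :n] = rng.normal(0.0, spec.noise_sd,
                                 size=(total, n_trials, n))
    x = np.zeros((total, n_trials, n_ext))
    for t in range(total):
        acc = noise[t]
        for k in range(1, p + 1):
            if t - k >= 0:
                acc = acc + x[t - k] @ A[k - 1].T
        x[t] = acc
    data = np.moveaxis(x[burn_in:, :, :n], 0, -1)  # (n_trials, n, n_samples)
    ann = pd.DataFrame(
        {"trial_id": np.arange(n_trials), "phase": condition,
         "trial_class": "experimental"}
    )
    labels = [f"node{i}" for i in range(n)]
    return Epochs(data, fs, 0.0, labels, ann)


# ---------------------------------------------------------------------------
# Evoked-response generator
# ---------------------------------------------------------------------------

@dataclass
class PeakSpec:
    """One evoked peak: latency (s), amplitude (signed, uV), width (s) and a
    per-VOT-step latency shift (s per step, applied as step - 1)."""

    latency: float
    amplitude: float
    width: float = 0.04
    vot_slope: float = 0.0


@dataclass
class EvokedEffectSpec:
    """Ground truth for the evoked-trial generator.

    ``mismatch_amplitude`` maps phase -> amplitude (uV) of the extra component
    added to incongruent trials inside ``mismatch_window``; a scalar applies to
    all phases. ``band_power_effects`` maps phase -> list of
    ``(center frequency Hz, dB change)`` oscillatory power effects applied
    after stimulus onset.
    """

    peak1: PeakSpec = field(
        default_factory=lambda: PeakSpec(0.25, -8.0, 0.04, 0.008)
    )
    peak2: PeakSpec = field(
        default_factory=lambda: PeakSpec(0.35, 6.0, 0.05, 0.008)
    )
    mismatch_amplitude: float | dict = 4.0
    mismatch_window: tuple[float, float] = (0.27, 0.35)
    band_power_effects: dict = field(default_factory=dict)
    base_osc_amplitude: float = 1.0
    noise_sd: float = 5.0

    def mismatch_for(self, phase: str) -> float:
        if isinstance(self.mismatch_amplitude, dict):
            return float(self.mismatch_amplitude.get(phase, 0.0))
        return float(self.mismatch_amplitude)


def _gauss_bump(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def evoked_template(
    spec: EvokedEffectSpec, times: np.ndarray, vot_step: int, incongruent: bool,
    phase: str = "pre",
) -> np.ndarray:
    """Noise-free single-trial template (deterministic part of the generator)."""
    wave = np.zeros_like(times)
    for pk in (spec.peak1, spec.peak2):
        center = pk.latency + pk.vot_slope * (vot_step - 1)
        wave += pk.amplitude * _gauss_bump(times, center, pk.width)
    if incongruent:
        a, b = spec.mismatch_window
        center, width = 0.5 * (a + b), (b - a) / 4.0
        wave += spec.mismatch_for(phase) * _gauss_bump(times, center, width)
    return wave


def simulate_evoked_trials(
    roster: pd.DataFrame,
    spec: EvokedEffectSpec,
    fs: float = 500.0,
    window: tuple[float, float] = (-0.15, 0.8),
    seed: int | None = 0,
    n_channels: int = 1,
) -> Epochs:
    """Simulate evoked single trials for every roster row.

    Each trial is white noise plus the VOT-latency-shifted peak template, the
    mismatch component on incongruent trials, and phase-dependent band-limited
    oscillatory power after stimulus onset. The ensemble average converges to
    the template at rate ``noise_sd / sqrt(n)``.
    """
    n_samples = int(round((window[1] - window[0]) * fs))
    times = window[0] + np.arange(n_samples) / fs
    if not (window[0] <= spec.mismatch_window[0]
            and spec.mismatch_window[1] <= window[1]):
        raise ValueError("mismatch window lies outside the epoch window")
    rng = np.random.default_rng(seed)
    n_trials = len(roster)
    data = rng.normal(0.0, spec.noise_sd, size=(n_trials, n_channels, n_samples))
    post = times >= 0.0

    for t, row in enumerate(roster.itertuples(index=False)):
        phase = getattr(row, "phase", "pre")
        if row.trial_class == "experimental":
            wave = evoked_template(
                spec, times, int(row.vot_step),
                incongruent=(row.congruency == "incongruent"), phase=phase,
            )
            data[t] += wave[None, :]
        # band-limited oscillation with phase-dependent post-stimulus gain
        effects = spec.band_power_effects.get(phase, [])
        for f0, db_change in effects:
            ph0 = rng.uniform(0, 2 * np.pi)
            osc = spec.base_osc_amplitude * np.cos(2 * np.pi * f0 * times + ph0)
            gain = np.ones(n_samples)
            gain[post] = 10.0 ** (db_change / 20.0)
            data[t] += (osc * gain)[None, :]

    labels = [f"ch{i}" for i in range(n_channels)]
    return Epochs(data, fs, window[0], labels,
                  roster.reset_index(drop=True).copy(), baseline=(window[0], 0.0))


# ---------------------------------------------------------------------------
# Behavioral generator
# ---------------------------------------------------------------------------

@dataclass
class PsychometricParams:
    """Fixed effects of the Bernoulli /p/-response generator on the logit
    scale, with VOT centered (step - 3.5) and Bias/Disconnection coded +-0.5."""

    intercept: float = 0.0
    vot: float = 1.5
    bias: float = 1.0
    disconnection: float = 0.0
    vot_x_disconnection: float = 0.0
    bias_x_disconnection: float = 0.0

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "intercept": self.intercept,
                "vot_c": self.vot,
                "bias_c": self.bias,
                "disc_c": self.disconnection,
                "vot_c:disc_c": self.vot_x_disconnection,
                "bias_c:disc_c": self.bias_x_disconnection,
            }
        )


def behavior_design_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append centered/contrast-coded design columns to a response table."""
    out = table.copy()
    out["vot_c"] = out["vot_step"].astype(float) - 3.5
    out["bias_c"] = np.where(out["bias"].eq("p"), 0.5, -0.5)
    out["disc_c"] = np.where(out["phase"].eq("post"), 0.5, -0.5)
    return out


def simulate_behavior(
    roster: pd.DataFrame,
    params: PsychometricParams,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Bernoulli /p/-responses with a logit linear in centered VOT, bias,
    disconnection and the two disconnection interactions.

    Only experimental rows receive responses; the returned table keeps the
    roster columns and adds ``response`` (1 = /p/).
    """
    exp = roster[roster["trial_class"] == "experimental"]
    tab = behavior_design_columns(exp)
    logit = (
        params.intercept
        + params.vot * tab["vot_c"]
        + params.bias * tab["bias_c"]
        + params.disconnection * tab["disc_c"]
        + params.vot_x_disconnection * tab["vot_c"] * tab["disc_c"]
        + params.bias_x_disconnection * tab["bias_c"] * tab["disc_c"]
    ).to_numpy()
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-logit))
    rng = np.random.default_rng(seed)
    tab = tab.reset_index(drop=True)
    tab["response"] = (rng.uniform(size=len(tab)) < prob).astype(int)
    return tab
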