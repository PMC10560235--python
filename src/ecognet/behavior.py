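"""Psychometric modeling of /b/-vs-/p/ categorization and reliable change.

The phoneme-identification responses are modeled with a logistic fixed-effects
model on centered VOT, sentence bias (+-0.5) and disconnection phase (+-0.5)
plus the two disconnection interactions. The word-pair grouping structure is
honored through cluster-bootstrap standard errors (resampling word pairs with
replacement), approximating the inferential target of a by-word-pair
random-effects model without mixed-model machinery.

The reliable change index (RCI) rescales a pre/post score change by the
test-retest standard error of the difference (Jacobson-Truax form), with
|RCI| >= 1.96 flagged as a significant change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

COEF_NAMES = ["intercept", "vot_c", "bias_c", "disc_c",
              "vot_c:disc_c", "bias_c:disc_c"]


def design_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix with the study's factor coding.

    VOT is centered (step - 3.5), bias is /b/ = -0.5 and /p/ = +0.5,
    disconnection is pre = -0.5 and post = +0.5; the two interactions with
    disconnection complete the fixed effects.
    """
    vot_c = table["vot_step"].astype(float).to_numpy() - 3.5
    bias_c = np.where(table["bias"].eq("p"), 0.5, -0.5)
    disc_c = np.where(table["phase"].eq("post"), 0.5, -0.5)
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(table)),
            "vot_c": vot_c,
            "bias_c": bias_c,
            "disc_c": disc_c,
            "vot_c:disc_c": vot_c * disc_c,
            "bias_c:disc_c": bias_c * disc_c,
        }
    )
    y = table["response"].to_numpy(dtype=float)
    return X, y


def _fit_glm(X: pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, bool, object | None]:
    """IRLS logistic fit with a penalized fallback on separation."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
            params = np.asarray(res.params)
            if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 15:
                return params, False, res
        except Exception:
            pass
        # separation or non-convergence: small ridge penalty
        res_pen = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
        return np.asarray(res_pen.params), True, None


class PsychometricModel:
    """Logistic psychometric model of /p/-responses.

    Parameters
    ----------
    table : DataFrame
        Response table with columns ``response`` (1 = /p/), ``vot_step``,
        ``bias``, ``phase`` and ``word_pair``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"response", "vot_step", "bias", "phase", "word_pair"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"response table lacks columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "PsychometricModel":
        return cls(pd.read_csv(path, sep="\t"))

    def fit(
        self,
        se_method: str = "cluster",
        n_boot: int = 2000,
        seed: int | None = 0,
    ) -> "PsychometricResults":
        """Fit by IRLS; standard errors by bootstrap.

        ``se_method="cluster"`` resamples word pairs with replacement
        (approximating the by-word-pair grouping structure),
        ``"trial"`` resamples rows, ``"wald"`` uses the asymptotic GLM
        covariance. On complete separation a small ridge penalty is applied
        with a warning; with fewer than 2 word pairs, cluster SEs fall back
        to plain trial resampling with a warning.
        """
        X, y = design_matrix(self.table)
        params, penalized, glm_res = _fit_glm(X, y)
        if penalized:
            warnings.warn("separation detected: ridge-penalized fit used",
                          RuntimeWarning, stacklevel=2)

        pairs = self.table["word_pair"].unique()
        if se_method == "cluster" and len(pairs) < 2:
            warnings.warn("fewer than 2 word pairs: using trial bootstrap",
                          RuntimeWarning, stacklevel=2)
            se_method = "trial"

        if se_method == "wald":
            if glm_res is None:
                raise RuntimeError("Wald SEs unavailable for penalized fit")
            bse = np.asarray(glm_res.bse)
            boot = None
        else:
            rng = np.random.default_rng(seed)
            boot = np.empty((n_boot, len(COEF_NAMES)))
            groups = {p: self.table.index[self.table["word_pair"] == p].to_numpy()
                      for p in pairs}
            n = len(self.table)
            for b in range(n_boot):
                if se_method == "cluster":
                    chosen = rng.choice(pairs, size=len(pairs), replace=True)
                    idx = np.concatenate([groups[p] for p in chosen])
                elif se_method == "trial":
                    idx = rng.integers(0, n, size=n)
                else:
                    raise ValueError(
                        "se_method must be 'cluster', 'trial' or 'wald'"
                    )
                boot[b], _, _ = _fit_glm(X.iloc[idx], y[idx])
            bse = boot.std(axis=0, ddof=1)

        return PsychometricResults(
            self, pd.Series(params, index=COEF_NAMES),
            pd.Series(bse, index=COEF_NAMES), se_method, n_boot, penalized,
            boot,
        )


@dataclass
class PsychometricResults:
    """Fitted psychometric model: coefficients, SEs and Wald Z."""

    model: PsychometricModel
    params: pd.Series
    bse: pd.Series
    se_method: str
    n_boot: int
    penalized: bool
    boot_samples: np.ndarray | None = None

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        from scipy.stats import norm

        return pd.Series(2 * norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues,
             "p": self.pvalues}
        )
        head = (
            "Psychometric logistic model (IRLS; "
            f"{self.se_method} SEs, B={self.n_boot})"
        )
        if self.penalized:
            head += "  [ridge-penalized: separation]"
        return head + "\n" + tab.to_string(float_format=lambda v: f"{v:.4f}")


def psychometric_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Percent /p/-responses per (bias, VOT step, phase) with binomial SEM.

    Empty design cells are absent from the output rather than reported as
    zero.
    """
    rows = []
    for (bias, step, phase), g in table.groupby(["bias", "vot_step", "phase"],
                                                observed=True):
        n = len(g)
        p = g["response"].mean()
        rows.append(
            dict(bias=bias, vot_step=step, phase=phase, n=n,
                 percent_p=100.0 * p,
                 sem=100.0 * np.sqrt(p * (1 - p) / n))
        )
    return pd.DataFrame(rows)


@dataclass
class RCIResult:
    test: str
    pre: float
    post: float
    reliability: float
    norm_sd: float
    rci: float
    significant: bool


def reliable_change_index(
    pre: float, post: float, r: float, sd: float, test: str = ""
) -> RCIResult:
    """Jacobson-Truax reliable change index.

    ``RCI = (post - pre) / (sd * sqrt(2) * sqrt(1 - r))`` where ``r`` is the
    test-retest reliability and ``sd`` the normative standard deviation;
    |RCI| >= 1.96 flags a significant change between timepoints.
    """
    if not 0 < r < 1:
        raise ValueError("reliability must lie strictly in (0, 1)")
    if sd <= 0:
        raise ValueError("norm SD must be positive")
    rci = (post - pre) / (sd * np.sqrt(2.0) * np.sqrt(1.0 - r))
    return RCIResult(test, pre, post, r, sd, float(rci),
                     bool(abs(rci) >= 1.96))
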