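"""Canonical frequency-band definitions.

Two band sets are used: the connectivity analysis is restricted to 0-50 Hz
(theta, alpha, beta, gamma), while spectral-perturbation (ERSP) reporting
additionally splits gamma into low and high gamma.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandSet(Mapping):
    """An ordered, non-overlapping set of named frequency intervals in Hz.

    Band bounds are inclusive: a frequency bin belongs to a band when its
    center frequency lies in ``[lo, hi]``.
    """

    bands: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_hi = -float("inf")
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} has empty interval ({lo}, {hi})")
            if lo <= prev_hi:
                raise ValueError(f"band {name!r} overlaps the previous band")
            prev_hi = hi

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def mask(self, freqs) -> dict[str, "object"]:
        """Boolean in-band masks over a frequency grid (inclusive bounds)."""
        import numpy as np

        freqs = np.asarray(freqs, dtype=float)
        return {
            name: (freqs >= lo) & (freqs <= hi) for name, (lo, hi) in self.bands.items()
        }


#: Bands used for conditional Granger causality aggregation (analysis ceiling 50 Hz).
CGC_BANDS = BandSet(
    {
        "theta": (4.0, 8.0),
        "alpha": (9.0, 12.0),
        "beta": (13.0, 30.0),
        "gamma": (31.0, 50.0),
    }
)

#: Bands used for ERSP reporting. The low/high gamma split at 70 Hz follows the
#: common convention; only the high-gamma bounds are fixed by the study design.
ERSP_BANDS = BandSet(
    {
        "theta": (4.0, 8.0),
        "alpha": (9.0, 12.0),
        "beta": (13.0, 30.0),
        "low_gamma": (31.0, 69.0),
        "high_gamma": (70.0, 150.0),
    }
)
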