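"""Mechanical sensitivity and static weight bearing.

Two behavioral read-outs accompany the gait work:

* the 50% paw-withdrawal threshold from an adaptive up-down series of von
  Frey filament presentations (withdrawal -> next smaller filament, no
  withdrawal -> next larger), estimated as ``10**(Xf + k*delta)`` grams
  with Xf the log10 force of the final filament, delta the mean log10
  spacing of the filament set, and k a tabulated constant determined by
  the response pattern;
* hind-limb weight distribution from an incapacitance meter, the percent
  of total hind-limb weight borne on the right limb, averaged over trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "STANDARD_FILAMENTS_G",
    "UpDownSeries",
    "updown_threshold",
    "weight_distribution",
    "dixon_k",
    "DIXON_K",
]

#: Conventional rat von Frey series (grams-force), ascending.
STANDARD_FILAMENTS_G = (0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 15.0)

# k constants for the six-response patterns that terminate an up-down
# series (O = no withdrawal, step up; X = withdrawal, step down; the
# counted window starts one response before the first reversal, so the
# first two symbols always differ).  Values are maximum-likelihood
# estimates of the 50% point under a normal psychometric function whose
# spread equals one log-step, expressed in log-steps relative to the final
# filament — the construction behind the classical small-sample up-down
# tables.  They are antisymmetric under O<->X exchange.
DIXON_K: dict[str, float] = {
    "OXOOOO": -0.5470,
    "OXOOOX": -1.2501,
    "OXOOXO": 0.3720,
    "OXOOXX": -0.1687,
    "OXOXOO": 0.0215,
    "OXOXOX": -0.5000,
    "OXOXXO": 1.1687,
    "OXOXXX": 0.6108,
    "OXXOOO": -0.2959,
    "OXXOOX": -0.8313,
    "OXXOXO": 0.8313,
    "OXXOXX": 0.2959,
    "OXXXOO": 0.5000,
    "OXXXOX": -0.0431,
    "OXXXXO": 1.6034,
    "OXXXXX": 0.8931,
    "XOOOOO": -0.8931,
    "XOOOOX": -1.6034,
    "XOOOXO": 0.0431,
    "XOOOXX": -0.5000,
    "XOOXOO": -0.2959,
    "XOOXOX": -0.8313,
    "XOOXXO": 0.8313,
    "XOOXXX": 0.2959,
    "XOXOOO": -0.6108,
    "XOXOOX": -1.1687,
    "XOXOXO": 0.5000,
    "XOXOXX": -0.0215,
    "XOXXOO": 0.1687,
    "XOXXOX": -0.3720,
    "XOXXXO": 1.2501,
    "XOXXXX": 0.5470,
}


def dixon_k(pattern: str) -> float:
    """k constant for a terminated six-response up-down pattern."""
    try:
        return DIXON_K[pattern]
    except KeyError:
        raise KeyError(
            f"unknown up-down pattern {pattern!r}: expected six symbols from "
            "{O,X} whose first two differ"
        ) from None


@dataclass
class UpDownSeries:
    """One adaptive von Frey series for one paw.

    ``presentations`` is the ordered list of (filament gF, withdrawal?)
    pairs actually applied.  ``boundary`` records whether the staircase
    stepped off the bottom ('low') or top ('high') of the filament set
    before six countable responses accumulated.
    """

    presentations: list[tuple[float, bool]]
    filament_set: Sequence[float] = STANDARD_FILAMENTS_G
    cutoff_gF: float = 15.0
    boundary: str | None = None  # None, 'low', or 'high'

    def __post_init__(self) -> None:
        if len(self.filament_set) == 0:
            raise ValueError("empty filament set")
        fil = np.asarray(self.filament_set, float)
        if np.any(np.diff(fil) <= 0):
            raise ValueError("filament set must be strictly ascending")
        for f, _ in self.presentations:
            if not np.any(np.isclose(fil, f)):
                raise ValueError(f"filament {f} gF not in the configured set")

    @property
    def delta_log(self) -> float:
        """Mean log10 spacing of the filament set."""
        logs = np.log10(np.asarray(self.filament_set, float))
        return float((logs[-1] - logs[0]) / (len(logs) - 1))

    @property
    def min_assignable_gF(self) -> float:
        """Threshold assigned when the animal withdraws off the bottom of the set."""
        return float(10 ** (np.log10(self.filament_set[0]) - self.delta_log))

    def pattern(self) -> str:
        """O/X string of the six counted responses (from one before the first reversal)."""
        resp = [w for _, w in self.presentations]
        rev = next((i for i in range(1, len(resp)) if resp[i] != resp[i - 1]), None)
        if rev is None:
            raise ValueError("series has no reversal; terminated at a boundary")
        counted = resp[rev - 1 :]
        if len(counted) != 6:
            raise ValueError(
                f"unterminated series: {len(counted)} counted responses, need 6"
            )
        return "".join("X" if w else "O" for w in counted)


def updown_threshold(series: UpDownSeries) -> float:
    """50% paw-withdrawal threshold in grams-force for a terminated series.

    Boundary series return the extreme assignable values: the cutoff (top,
    conventionally 15 g) when the animal never withdraws off the top of the
    set, and one log-step below the smallest filament (~0.25 g for the
    standard set) when it withdraws off the bottom.
    """
    if series.boundary == "high":
        return series.cutoff_gF
    if series.boundary == "low":
        return series.min_assignable_gF
    pat = series.pattern()
    xf = np.log10(series.presentations[-1][0])
    thr = float(10 ** (xf + dixon_k(pat) * series.delta_log))
    return float(np.clip(thr, series.min_assignable_gF, series.cutoff_gF))


def weight_distribution(readings) -> float:
    """Percent of hind-limb weight borne on the right limb.

    ``readings`` is an (n_trials, 2) array-like of (left, right) scale
    readings in grams; each trial is converted to 100*right/(left+right)
    and the trial values are averaged.  A trial with zero total weight is
    an error.
    """
    arr = np.asarray(readings, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("readings must be an (n_trials, 2) array of (left, right)")
    if np.any(arr < 0):
        raise ValueError("negative scale reading")
    total = arr.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total weight in at least one trial")
    return float(np.mean(100.0 * arr[:, 1] / total))
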