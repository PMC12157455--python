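"""Normative model of bout length on the PRR task.

The PRR task is a patch-leaving problem: the progressive ratio is a
depleting patch, the reset delay a travel time.  With a work tempo of
``p`` presses/s, ratio ``n`` takes ``n / p`` seconds, so a bout of ``n``
ratios takes

    t_bout(n) = t_reset + n * t_handle + n(n+1) / (2 p)

seconds (reset delay, per-reward handling time, and the triangular sum of
ratio completion times), and yields ``n`` rewards — a bout-level reward
rate R_bout(n) = n / t_bout(n).  The rate-maximizing integer bout length
n_opt is found by brute force over n = 1..max_bout; its continuous-n
counterpart has the closed form n* = sqrt(2 p t_reset), independent of
handling time.  Handling-time independence is exact for the integer
optimum too: in the comparison R(n1) ≷ R(n2) the cross-multiplied handling
terms n1·n2·t_handle cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OptimalityParams",
    "OptimalityResult",
    "OptimalityGrid",
    "SearchBoundError",
    "ratio_time",
    "bout_time",
    "bout_rate",
    "optimal_bout_length",
    "continuous_optimum",
    "optimality_grid",
]

#: Relative tolerance below which two bout rates are considered tied;
#: ties are broken toward the smaller bout length (less effort, same rate).
TIE_RTOL = 1e-12


class SearchBoundError(ValueError):
    """The argmax landed on max_bout: the search bound was binding."""


@dataclass(frozen=True)
class OptimalityParams:
    """Inputs of the normative model.

    press_rate
        Active-lever work tempo p, presses/s (> 0).
    reset_delay_s
        Enforced delay t_reset after a reset press, s (> 0).
    handling_time_s
        Time t_handle to collect and consume each reward, s (default 2).
    max_bout
        Upper bound of the brute-force search over integer bout lengths.
    """

    press_rate: float
    reset_delay_s: float
    handling_time_s: float = 2.0
    max_bout: int = 1000

    def __post_init__(self) -> None:
        if self.press_rate <= 0:
            raise ValueError("press_rate must be > 0")
        if self.reset_delay_s <= 0:
            raise ValueError("reset_delay_s must be > 0")
        if self.handling_time_s < 0:
            raise ValueError("handling_time_s must be >= 0")
        if self.max_bout < 1:
            raise ValueError("max_bout must be >= 1")


@dataclass
class OptimalityResult:
    """Full R_bout curve plus its integer argmax."""

    params: OptimalityParams
    n: np.ndarray
    t_bout_s: np.ndarray
    r_bout: np.ndarray
    n_opt: int
    r_opt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n, "t_bout_s": self.t_bout_s,
                             "r_bout": self.r_bout})


def ratio_time(n: int, press_rate: float) -> float:
    """Time to complete ratio requirement ``n`` at ``press_rate`` presses/s."""
    if press_rate <= 0:
        raise ValueError("press_rate must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return n / press_rate


def bout_time(n: int, params: OptimalityParams) -> float:
    """Total time of a bout of ``n`` ratios, including the reset delay.

    Closed form of t_reset + n·t_handle + Σ_{k=1..n} k/p.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return (params.reset_delay_s
            + n * params.handling_time_s
            + n * (n + 1) / (2.0 * params.press_rate))


def bout_rate(n: int, params: OptimalityParams) -> float:
    """Bout-level reward rate R_bout(n) = n / t_bout(n), rewards/s."""
    return n / bout_time(n, params)


def optimal_bout_length(params: OptimalityParams) -> OptimalityResult:
    """Brute-force the integer bout length maximizing R_bout.

    Evaluates the full curve for n = 1..max_bout; ties within ``TIE_RTOL``
    relative tolerance resolve to the smaller n.  Raises
    :class:`SearchBoundError` if the argmax sits on the search bound.
    """
    n = np.arange(1, params.max_bout + 1, dtype=float)
    t = (params.reset_delay_s
         + n * params.handling_time_s
         + n * (n + 1) / (2.0 * params.press_rate))
    r = n / t
    r_max = float(r.max())
    tied = np.nonzero(r >= r_max * (1.0 - TIE_RTOL))[0]
    n_opt = int(n[tied[0]])
    if n_opt >= params.max_bout:
        raise SearchBoundError(
            f"argmax hit max_bout={params.max_bout}; increase the search bound"
        )
    return OptimalityResult(params=params, n=n.astype(int), t_bout_s=t,
                            r_bout=r, n_opt=n_opt, r_opt=float(r[tied[0]]))


def continuous_optimum(press_rate: float, reset_delay_s: float) -> float:
    """Continuous-n optimum of R_bout: sqrt(2 · press_rate · reset_delay).

    Stationarity of n / (T + h n + n(n+1)/(2p)) in real n gives
    T = n²/(2p); the handling term drops out.  Serves as the analytic
    oracle for the integer search (they agree to within one ratio).
    """
    if press_rate <= 0 or reset_delay_s <= 0:
        raise ValueError("press_rate and reset_delay_s must be > 0")
    return math.sqrt(2.0 * press_rate * reset_delay_s)


@dataclass
class OptimalityGrid:
    """n_opt and r_opt over a (reset delay × press rate) grid."""

    press_rates: np.ndarray
    reset_delays: np.ndarray
    handling_time_s: float
    n_opt: np.ndarray = field(repr=False)   # shape (delays, rates)
    r_opt: np.ndarray = field(repr=False)

    def slice_at_delay(self, reset_delay_s: float) -> pd.DataFrame:
        """1-D slice: n_opt and r_opt vs press rate at a fixed reset delay."""
        i = int(np.argmin(np.abs(self.reset_delays - reset_delay_s)))
        return pd.DataFrame({"press_rate": self.press_rates,
                             "n_opt": self.n_opt[i], "r_opt": self.r_opt[i]})

    def slice_at_rate(self, press_rate: float) -> pd.DataFrame:
        """1-D slice: n_opt and r_opt vs reset delay at a fixed press rate."""
        j = int(np.argmin(np.abs(self.press_rates - press_rate)))
        return pd.DataFrame({"reset_delay_s": self.reset_delays,
                             "n_opt": self.n_opt[:, j], "r_opt": self.r_opt[:, j]})

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, T in enumerate(self.reset_delays):
            for j, p in enumerate(self.press_rates):
                rows.append((T, p, self.n_opt[i, j], self.r_opt[i, j]))
        return pd.DataFrame(rows, columns=["reset_delay_s", "press_rate",
                                           "n_opt", "r_opt"])


def optimality_grid(
    press_rates,
    reset_delays,
    handling_time_s: float = 2.0,
    max_bout: int = 1000,
) -> OptimalityGrid:
    """Optimal bout length over a grid of press rates and reset delays.

    Element [i, j] is n_opt for (reset_delays[i], press_rates[j]).
    """
    press_rates = np.asarray(press_rates, dtype=float)
    reset_delays = np.asarray(reset_delays, dtype=float)
    n_opt = np.zeros((len(reset_delays), len(press_rates)), dtype=int)
    r_opt = np.zeros_like(n_opt, dtype=float)
    for i, T in enumerate(reset_delays):
        for j, p in enumerate(press_rates):
            res = optimal_bout_length(OptimalityParams(
                press_rate=float(p), reset_delay_s=float(T),
                handling_time_s=handling_time_s, max_bout=max_bout))
            n_opt[i, j] = res.n_opt
            r_opt[i, j] = res.r_opt
    return OptimalityGrid(press_rates=press_rates, reset_delays=reset_delays,
                          handling_time_s=handling_time_s, n_opt=n_opt, r_opt=r_opt)
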