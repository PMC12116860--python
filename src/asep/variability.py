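"""Within-person variability of daily ASEP and required food-record days.

A single day of food record is a noisy measurement of a person's habitual
ASEP.  Two classical designs quantify how many recording days are needed:

**Beaton's method** (absolute-deviation form).  For a maximum absolute
deviation ``a`` of the individual estimate from the true individual ASEP at
95% confidence::

    D_Beaton = ((1.96 / a) * s)**2

where ``s`` is the pooled intraindividual (within-person) standard
deviation of daily ASEP.  ``s`` is estimated as the d_i-weighted mean of
per-person standard deviations, each computed with the population divisor
d_i (the person's number of recorded days)::

    s_hat = sum_i(d_i * s_i) / sum_i(d_i)
    s_i   = sqrt(sum_day((ASEP_day,i - m_i)**2) / d_i)

Fully vegan records have s_i = 0 by definition (every day is exactly 0),
so vegans are excluded from pooling.

**Liu's method** (attenuation form).  Day-to-day variation shrinks an
observed correlation R towards zero by an error term ``e``; ``e`` can be
estimated from the correlation ``r`` between two single-day measurements of
the same person::

    e(r, n) = sqrt(1 / (1 + (1 - r) / (n * r)))

and the number of days needed to keep ``e`` above a floor (conventionally
0.9) is::

    D_Liu = (e**2 / (1 - e**2)) * (1 - r) / r

``r`` is the intraindividual correlation — between-person variance over
total variance — estimated here by enumerating every within-person
unordered day pair and correlating the symmetrized pair set (each pair in
both orders, removing the arbitrary ordering).

Day counts are returned as ``max(1, ceil(.))``: the ceiling is the
conservative reading of "days required to achieve" a precision target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, ParameterError

Z_95 = 1.96  # two-sided 95% normal quantile, as conventionally printed


# ---------------------------------------------------------------------------
# estimating the variance components


def _daily_frame(daily_asep) -> pd.DataFrame:
    """Normalize input to a (participant_id, daily_asep[, diet_category]) frame."""
    if isinstance(daily_asep, pd.DataFrame):
        if "daily_asep" not in daily_asep.columns:
            raise ParameterError("daily frame needs a 'daily_asep' column")
        return daily_asep
    # mapping participant -> sequence of daily values
    rows = [
        {"participant_id": pid, "daily_asep": float(v)}
        for pid, values in daily_asep.items()
        for v in values
    ]
    return pd.DataFrame(rows)


def _eligible(frame: pd.DataFrame, exclude_vegan: bool) -> pd.DataFrame:
    """Drop vegan participants (category tag, or all-zero daily series)."""
    if not exclude_vegan:
        return frame
    if "diet_category" in frame.columns and frame["diet_category"].notna().any():
        vegan = frame["diet_category"] == "vegan"
        return frame[~vegan]
    all_zero = frame.groupby("participant_id")["daily_asep"].transform(
        lambda v: bool((v == 0).all())
    )
    return frame[~all_zero]


def pooled_intraindividual_sd(
    daily_asep,
    exclude_vegan: bool = True,
) -> tuple[float, pd.Series]:
    """Pooled within-person SD of daily ASEP, s_hat, and per-person s_i.

    ``daily_asep`` is a long frame (``participant_id, daily_asep`` and
    optionally ``diet_category``) or a mapping participant -> daily values.
    Per-person SDs use the population divisor d_i; pooling weights are d_i.
    Participants with a single recorded day cannot contribute a deviation
    and are excluded, as are vegans.
    """
    frame = _eligible(_daily_frame(daily_asep), exclude_vegan)
    counts = frame.groupby("participant_id")["daily_asep"].count()
    keep = counts[counts >= 2].index
    frame = frame[frame["participant_id"].isin(keep)]
    if frame.empty:
        raise EstimationError(
            "no eligible participant with >= 2 recorded days for pooling"
        )
    per_sd = frame.groupby("participant_id")["daily_asep"].agg(
        lambda v: float(np.std(np.asarray(v, dtype=float), ddof=0))
    )
    d_i = frame.groupby("participant_id")["daily_asep"].count().astype(float)
    s_hat = float((d_i * per_sd).sum() / d_i.sum())
    return s_hat, per_sd.rename("s_asep_i")


def intraindividual_correlation(
    daily_asep,
    exclude_vegan: bool = True,
    method: str = "pearson",
) -> tuple[float, int]:
    """Intraindividual correlation r of paired daily ASEPs.

    Enumerates every within-person unordered day pair, symmetrizes the pair
    set (each pair entered in both orders) and computes the product-moment
    correlation over it (``method="spearman"`` rank-transforms first).
    Returns ``(r, n_pairs)`` with ``n_pairs`` counting unordered pairs.
    """
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown correlation method {method!r}")
    frame = _eligible(_daily_frame(daily_asep), exclude_vegan)
    x: list[float] = []
    y: list[float] = []
    n_pairs = 0
    for _, group in frame.groupby("participant_id", sort=True):
        values = np.asarray(group["daily_asep"], dtype=float)
        d = values.size
        for i in range(d):
            for j in range(i + 1, d):
                x.extend((values[i], values[j]))
                y.extend((values[j], values[i]))
                n_pairs += 1
    if n_pairs < 2:
        raise EstimationError("need >= 2 within-person day pairs to correlate")
    xa, ya = np.asarray(x), np.asarray(y)
    if method == "spearman":
        xa = stats.rankdata(xa)
        ya = stats.rankdata(ya)
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise EstimationError("pair correlation undefined: zero variance in pairs")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return r, n_pairs


# ---------------------------------------------------------------------------
# required-days formulas


def beaton_days(s: float, a: float, z: float = Z_95) -> int:
    """Required recording days for absolute deviation <= ``a`` at 95% confidence."""
    if a <= 0:
        raise ParameterError(f"deviation limit a must be > 0, got {a}")
    if s < 0:
        raise ParameterError(f"pooled SD must be >= 0, got {s}")
    return max(1, math.ceil((z * s / a) ** 2))


def liu_error_term(r: float, n_days: float) -> float:
    """Attenuation error term e for a correlation observed with ``n_days`` days."""
    if not 0 < r <= 1:
        raise ParameterError(f"intraindividual correlation must be in (0, 1], got {r}")
    if n_days < 1:
        raise ParameterError(f"n_days must be >= 1, got {n_days}")
    return math.sqrt(1.0 / (1.0 + (1.0 - r) / (n_days * r)))


def liu_days(r: float, e_limit: float = 0.9) -> int:
    """Required recording days so the attenuation error term stays above ``e_limit``."""
    if not 0 < r <= 1:
        raise ParameterError(f"intraindividual correlation must be in (0, 1], got {r}")
    if not 0 < e_limit < 1:
        raise ParameterError(f"e_limit must be in (0, 1), got {e_limit}")
    raw = (e_limit**2 / (1.0 - e_limit**2)) * (1.0 - r) / r
    return max(1, math.ceil(raw))


DEFAULT_A_GRID = (0.005, 0.01, 0.02, 0.05, 0.1)


def required_days_table(
    s: float | None = None,
    r: float | None = None,
    a_values: Iterable[float] = DEFAULT_A_GRID,
    e_limit: float = 0.9,
    z: float = Z_95,
) -> pd.DataFrame:
    """Table of day requirements across methods and precision targets."""
    rows = []
    if s is not None:
        for a in a_values:
            rows.append(
                {
                    "method": "beaton_absolute",
                    "parameter": a,
                    "days": beaton_days(s, a, z=z),
                    "confidence": 0.95,
                }
            )
    if r is not None:
        rows.append(
            {
                "method": "liu",
                "parameter": e_limit,
                "days": liu_days(r, e_limit),
                "confidence": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class VariabilityResults:
    """Estimates of ASEP day-to-day variability with derived day requirements."""

    s_hat: float
    per_individual_sd: pd.Series
    mean_asep: float
    cv_w: float
    r_i: float
    n_pairs: int
    n_participants: int
    pair_method: str = "pearson"

    def beaton_days(self, a: float, z: float = Z_95) -> int:
        return beaton_days(self.s_hat, a, z=z)

    def liu_error_term(self, n_days: float) -> float:
        return liu_error_term(self.r_i, n_days)

    def liu_days(self, e_limit: float = 0.9) -> int:
        return liu_days(self.r_i, e_limit)

    def required_days_table(
        self,
        a_values: Iterable[float] = DEFAULT_A_GRID,
        e_limit: float = 0.9,
        z: float = Z_95,
    ) -> pd.DataFrame:
        return required_days_table(
            s=self.s_hat, r=self.r_i, a_values=a_values, e_limit=e_limit, z=z
        )

    def summary(self) -> str:
        lines = [
            "ASEP variability estimates",
            "==========================",
            f"eligible participants (non-vegan, >=2 days): {self.n_participants}",
            f"pooled intraindividual SD  s_hat : {self.s_hat:.4f}",
            f"cohort mean ASEP           m     : {self.mean_asep:.4f}",
            f"within-person CV           CV_w  : {self.cv_w:.4f}",
            f"intraindividual correlation r    : {self.r_i:.4f} "
            f"({self.n_pairs} day pairs, {self.pair_method})",
            "",
            self.required_days_table().to_string(index=False),
        ]
        return "\n".join(lines)


class VariabilityModel:
    """Estimator of ASEP within-person variability from a daily-ASEP table.

    Parameters
    ----------
    daily_asep :
        Long frame with ``participant_id`` and ``daily_asep`` columns (one
        row per recorded day), optionally ``diet_category``; or a mapping
        participant -> sequence of daily values.
    exclude_vegan :
        Drop vegan participants (their within-person SD is 0 by definition
        and would bias the pooled estimate downward).  Default True.
    pair_method :
        ``"pearson"`` (default; the variance-decomposition framework is
        moment-based) or ``"spearman"`` for the day-pair correlation.
    """

    def __init__(
        self,
        daily_asep,
        exclude_vegan: bool = True,
        pair_method: str = "pearson",
    ) -> None:
        self.frame = _daily_frame(daily_asep)
        self.exclude_vegan = exclude_vegan
        self.pair_method = pair_method

    def fit(self) -> VariabilityResults:
        s_hat, per_sd = pooled_intraindividual_sd(
            self.frame, exclude_vegan=self.exclude_vegan
        )
        r_i, n_pairs = intraindividual_correlation(
            self.frame, exclude_vegan=self.exclude_vegan, method=self.pair_method
        )
        eligible = _eligible(self.frame, self.exclude_vegan)
        mean_asep = float(eligible["daily_asep"].mean())
        cv_w = s_hat / mean_asep if mean_asep > 0 else float("nan")
        return VariabilityResults(
            s_hat=s_hat,
            per_individual_sd=per_sd,
            mean_asep=mean_asep,
            cv_w=cv_w,
            r_i=r_i,
            n_pairs=n_pairs,
            n_participants=int(per_sd.size),
            pair_method=self.pair_method,
        )
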