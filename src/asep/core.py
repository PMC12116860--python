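"""The ASEP statistic: animal source energy percentage.

For a set of scored record entries, ASEP is the energy-weighted mean of the
item scores::

    ASEP = sum_i(E_i * ASWP_i) / sum_i(E_i)

where ``E_i`` is the energy derived from food item *i* and ``ASWP_i`` its
animal source weight proportion.  ASEP lies in [0, 1] (0–100%).  The same
formula serves one day or a whole recording period; the period value is the
energy-weighted mean of the daily values.

The module computes daily and period ASEP per participant, descriptive
cohort summaries per diet category, and the statistic for reference diets
given as food-group energy tables (e.g. the EAT-Lancet planetary health
diet, where 340 kcal of 2500 kcal/day come from animal-source food groups,
an ASEP of 14%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedAsepError, ValidationError
from .io import read_reference_diet


@dataclass
class AsepResult:
    """Daily and period ASEP for one participant."""

    participant_id: str
    daily_asep: dict[int, float]
    period_asep: float
    total_energy: float
    diet_category: str | None = None


def compute_asep(entries: pd.DataFrame) -> float:
    """ASEP of a collection of scored entries.

    ``entries`` must carry ``energy_kj`` and ``aswp`` columns (every entry
    already joined to its item score).  Raises
    :class:`~asep.exceptions.UndefinedAsepError` if total energy is zero.
    """
    energy = np.asarray(entries["energy_kj"], dtype=float)
    aswp = np.asarray(entries["aswp"], dtype=float)
    if (energy < 0).any():
        raise ValidationError("negative energy in scored entries")
    total = energy.sum()
    if total <= 0:
        raise UndefinedAsepError("ASEP undefined: total energy is zero")
    return float((energy * aswp).sum() / total)


def join_scores(records: pd.DataFrame, aswp_table: pd.DataFrame) -> pd.DataFrame:
    """Join record entries to their item scores by food code."""
    missing = set(records["food_code"]) - set(aswp_table["code"])
    if missing:
        some = sorted(missing)[:5]
        raise ValidationError(f"food codes without ASWP entry: {some}")
    cols = ["code", "aswp"] + (["asf_group"] if "asf_group" in aswp_table.columns else [])
    scored = records.merge(
        aswp_table[cols], left_on="food_code", right_on="code", how="left"
    ).drop(columns="code")
    return scored


def asep_by_participant(
    records: pd.DataFrame,
    aswp_table: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    drop_zero_energy_days: bool = True,
) -> tuple[pd.DataFrame, list[AsepResult]]:
    """Daily and period ASEP for every participant.

    Returns a long daily frame (``participant_id, day_index, daily_asep,
    day_energy_kj``, plus ``diet_category`` when known) and a list of
    :class:`AsepResult`.  Days with zero recorded energy — poor intake or
    missing data — are excluded from the daily series and flagged with a
    warning.
    """
    scored = join_scores(records, aswp_table)
    categories: dict[str, str] = {}
    if participants is not None and "diet_category" in participants.columns:
        categories = dict(
            zip(participants["participant_id"], participants["diet_category"])
        )

    day_groups = scored.groupby(["participant_id", "day_index"], sort=True)
    daily = day_groups.apply(
        lambda g: pd.Series(
            {
                "day_energy_kj": g["energy_kj"].sum(),
                "daily_asep": (
                    np.nan
                    if g["energy_kj"].sum() <= 0
                    else (g["energy_kj"] * g["aswp"]).sum() / g["energy_kj"].sum()
                ),
            }
        ),
        include_groups=False,
    ).reset_index()

    zero_days = daily[daily["day_energy_kj"] <= 0]
    if not zero_days.empty:
        warnings.warn(
            f"omitting {len(zero_days)} zero-energy recording day(s)", stacklevel=2
        )
        daily = daily[daily["day_energy_kj"] > 0]
    daily = daily.reset_index(drop=True)
    if categories:
        daily["diet_category"] = daily["participant_id"].map(categories)

    results: list[AsepResult] = []
    for pid, group in daily.groupby("participant_id", sort=True):
        total = float(group["day_energy_kj"].sum())
        if total <= 0:
            raise UndefinedAsepError(
                f"ASEP undefined for participant {pid!r}: no recorded energy"
            )
        period = float(
            (group["day_energy_kj"] * group["daily_asep"]).sum() / total
        )
        results.append(
            AsepResult(
                participant_id=pid,
                daily_asep=dict(
                    zip(group["day_index"].astype(int), group["daily_asep"])
                ),
                period_asep=period,
                total_energy=total,
                diet_category=categories.get(pid),
            )
        )
    return daily, results


def results_frame(results: list[AsepResult]) -> pd.DataFrame:
    """Tabulate period ASEP per participant."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "period_asep": [r.period_asep for r in results],
            "total_energy_kj": [r.total_energy for r in results],
            "n_days": [len(r.daily_asep) for r in results],
            "diet_category": [r.diet_category for r in results],
        }
    )


def cohort_summary(results: list[AsepResult] | pd.DataFrame) -> pd.DataFrame:
    """Median / min / max period ASEP per diet category and overall.

    Medians use the midpoint convention for even counts (numpy default).
    Empty categories are omitted with a warning.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    rows = []

    def _stats(label: str, values: pd.Series) -> dict:
        return {
            "diet_category": label,
            "n": int(values.size),
            "median_asep": float(np.median(values)),
            "min_asep": float(values.min()),
            "max_asep": float(values.max()),
        }

    rows.append(_stats("all", frame["period_asep"]))
    if frame["diet_category"].notna().any():
        for cat in ("vegan", "vegetarian", "omnivore"):
            values = frame.loc[frame["diet_category"] == cat, "period_asep"]
            if values.empty:
                warnings.warn(f"no participants in category {cat!r}; omitted", stacklevel=2)
                continue
            rows.append(_stats(cat, values))
    return pd.DataFrame(rows)


def reference_diet_asep(groups: pd.DataFrame | None = None, decimals: int = 0) -> float:
    """ASEP (in percent) of a reference diet given as food-group energies.

    ``groups`` needs ``energy_kcal`` and ``is_animal_source`` columns; with
    ``None`` the bundled EAT-Lancet planetary health diet table is used.
    Reported rounded to ``decimals`` (default: nearest whole percent).
    """
    if groups is None:
        groups = read_reference_diet()
    energy = np.asarray(groups["energy_kcal"], dtype=float)
    animal = np.asarray(groups["is_animal_source"], dtype=bool)
    total = energy.sum()
    if total <= 0:
        raise UndefinedAsepError("reference-diet ASEP undefined: zero total energy")
    pct = 100.0 * energy[animal].sum() / total
    return float(round(pct, decimals)) if decimals is not None else float(pct)
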