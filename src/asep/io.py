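"""Reading and writing the tabular inputs of an ASEP analysis.

Three plain-text tables drive an analysis:

``food_records.csv``
    one row per consumed food item per participant per recording day, with
    the energy derived from that item (``participant_id, day, food_code,
    energy_kj``).  The same item may appear several times on one day; its
    energies are additive.

``aswp_table.csv``
    the food-item dictionary mapping each ``code`` to its animal source
    weight proportion (ASWP) together with its origin class and how the
    proportion was assigned (``code, name, origin, aswp, aswp_basis``).

``participants.csv``
    optional participant metadata, in particular the diet category
    (``participant_id, diet_category``).

All files are UTF-8, comma-delimited by default (a ``delimiter`` argument
is accepted everywhere — food names contain commas in some exports).
Energies are kilojoules; pass ``energy_unit="kcal"`` to convert on read at
1 kcal = 4.184 kJ.  Extra columns are carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import FormatError, ParameterError, ValidationError

KJ_PER_KCAL = 4.184

ORIGINS = frozenset({"plant", "animal", "mixed", "generic"})
ASWP_BASES = frozenset(
    {
        "rule_pure_plant",
        "rule_pure_animal",
        "rule_dairy",
        "rule_meat_product",
        "calculated_recipe",
        "estimated_similar_product",
    }
)
DIET_CATEGORIES = ("vegan", "vegetarian", "omnivore")

RECORD_COLUMNS = ("participant_id", "day", "food_code", "energy_kj")
ASWP_COLUMNS = ("code", "name", "origin", "aswp", "aswp_basis")


@dataclass(frozen=True)
class FoodItem:
    """A food code with its animal source weight proportion (ASWP).

    ASWP is the fraction of the item's ingredient mass (excluding added
    water and trace ingredients) that is of animal origin; it is the weight
    attached to the item's energy in the ASEP statistic.
    """

    code: str
    name: str
    origin: str
    aswp: float
    aswp_basis: str

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"food item {self.code!r}: unknown origin {self.origin!r}"
            )
        if self.aswp_basis not in ASWP_BASES:
            raise ValidationError(
                f"food item {self.code!r}: unknown aswp_basis {self.aswp_basis!r}"
            )
        if not 0.0 <= self.aswp <= 1.0:
            raise ValidationError(
                f"food item {self.code!r}: aswp {self.aswp} outside [0, 1]"
            )
        if self.origin == "plant" and self.aswp != 0.0:
            raise ValidationError(
                f"food item {self.code!r}: plant origin requires aswp 0, got {self.aswp}"
            )
        if self.origin == "animal" and self.aswp != 1.0:
            raise ValidationError(
                f"food item {self.code!r}: animal origin requires aswp 1, got {self.aswp}"
            )


@dataclass(frozen=True)
class RecordEntry:
    """One consumed item on one day by one participant, with its energy (kJ)."""

    participant_id: str
    day_index: int
    food_code: str
    energy: float

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValidationError(
                f"record ({self.participant_id}, day {self.day_index}, "
                f"{self.food_code}): negative energy {self.energy}"
            )
        if self.day_index < 1:
            raise ValidationError(
                f"record ({self.participant_id}): day_index must be >= 1"
            )


@dataclass(frozen=True)
class Participant:
    participant_id: str
    diet_category: str | None = None
    n_days: int = 0

    def __post_init__(self) -> None:
        if self.diet_category is not None and self.diet_category not in DIET_CATEGORIES:
            raise ValidationError(
                f"participant {self.participant_id!r}: unknown diet category "
                f"{self.diet_category!r}"
            )


def _require_columns(frame: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_food_records(
    path,
    delimiter: str = ",",
    energy_unit: str = "kJ",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a food-record table.

    Returns ``(records, participants)``: the record rows (with ``day``
    renamed to ``day_index`` and energies in kJ) ordered deterministically
    by (participant, day, file row), and a participant frame with the
    derived number of distinct recording days ``n_days`` per participant.
    """
    if energy_unit not in ("kJ", "kcal"):
        raise ParameterError(f"energy_unit must be 'kJ' or 'kcal', got {energy_unit!r}")
    frame = pd.read_csv(path, sep=delimiter, dtype={"participant_id": str, "food_code": str})
    _require_columns(frame, RECORD_COLUMNS, path)

    day = pd.to_numeric(frame["day"], errors="coerce")
    bad_day = day.isna() | (day != day.round()) | (day < 1)
    if bad_day.any():
        row = int(frame.index[bad_day][0]) + 2  # 1-based, counting the header
        raise ValidationError(f"{path}: non-integer or non-positive day at file row {row}")
    energy = pd.to_numeric(frame["energy_kj"], errors="coerce")
    bad_energy = energy.isna() | (energy < 0)
    if bad_energy.any():
        row = int(frame.index[bad_energy][0]) + 2
        raise ValidationError(f"{path}: negative or non-numeric energy at file row {row}")

    records = frame.copy()
    records["day_index"] = day.astype(int)
    records["energy_kj"] = energy.astype(float)
    if energy_unit == "kcal":
        records["energy_kj"] = records["energy_kj"] * KJ_PER_KCAL
    records = records.drop(columns=["day"])
    records = records[["participant_id", "day_index", "food_code", "energy_kj"]
                      + [c for c in records.columns
                         if c not in ("participant_id", "day_index", "food_code", "energy_kj")]]
    records = (
        records.reset_index(names="_row")
        .sort_values(["participant_id", "day_index", "_row"], kind="stable")
        .drop(columns="_row")
        .reset_index(drop=True)
    )

    n_days = (
        records.groupby("participant_id", sort=True)["day_index"]
        .nunique()
        .rename("n_days")
        .reset_index()
    )
    return records, n_days


def write_food_records(records: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = records.rename(columns={"day_index": "day"})
    out.to_csv(path, sep=delimiter, index=False)


def read_aswp_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read the food-item ASWP dictionary, enforcing the item invariants.

    Returns a frame with one validated row per unique ``code``.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype={"code": str})
    _require_columns(frame, ASWP_COLUMNS, path)
    dupes = frame["code"][frame["code"].duplicated()]
    if not dupes.empty:
        raise ValidationError(f"{path}: duplicate food code {dupes.iloc[0]!r}")
    frame = frame.copy()
    frame["aswp"] = pd.to_numeric(frame["aswp"], errors="coerce")
    # row-wise validation reuses the dataclass invariants
    for idx, row in frame.iterrows():
        if pd.isna(row["aswp"]):
            raise ValidationError(f"{path}: non-numeric aswp at file row {idx + 2}")
        FoodItem(
            code=str(row["code"]),
            name=str(row["name"]),
            origin=str(row["origin"]),
            aswp=float(row["aswp"]),
            aswp_basis=str(row["aswp_basis"]),
        )
    return frame.reset_index(drop=True)


def write_aswp_table(items: pd.DataFrame, path, delimiter: str = ",") -> None:
    items.to_csv(path, sep=delimiter, index=False)


def read_participants(path, delimiter: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=delimiter, dtype={"participant_id": str})
    _require_columns(frame, ("participant_id",), path)
    if "diet_category" in frame.columns:
        bad = ~frame["diet_category"].isin(DIET_CATEGORIES) & frame["diet_category"].notna()
        if bad.any():
            raise ValidationError(
                f"{path}: unknown diet category "
                f"{frame.loc[bad, 'diet_category'].iloc[0]!r}"
            )
    if frame["participant_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate participant_id")
    return frame.reset_index(drop=True)


def write_participants(participants: pd.DataFrame, path, delimiter: str = ",") -> None:
    participants.to_csv(path, sep=delimiter, index=False)


def bundled_reference_diet_path() -> Path:
    """Path of the bundled EAT-Lancet planetary-health-diet energy table."""
    return Path(__file__).parent / "data" / "eat_lancet_reference_diet.csv"


def read_reference_diet(path=None, delimiter: str = ",") -> pd.DataFrame:
    """Read a reference-diet food-group energy table.

    Columns: ``group_name, energy_kcal, is_animal_source``.  With no path,
    the bundled EAT-Lancet planetary health diet table (2500 kcal/day, 340
    kcal of it from the seven animal-source food groups) is used.
    """
    if path is None:
        path = bundled_reference_diet_path()
    frame = pd.read_csv(path, sep=delimiter)
    _require_columns(frame, ("group_name", "energy_kcal", "is_animal_source"), path)
    if (pd.to_numeric(frame["energy_kcal"], errors="coerce") < 0).any():
        raise ValidationError(f"{path}: negative food-group energy")
    frame = frame.copy()
    frame["energy_kcal"] = pd.to_numeric(frame["energy_kcal"])
    frame["is_animal_source"] = frame["is_animal_source"].astype(bool)
    return frame
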