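"""Food-item scoring: assigning the animal source weight proportion (ASWP).

Every food item gets an ASWP in [0, 1] through a short, totally ordered
rule hierarchy:

1. purely plant-origin items score 0;
2. purely animal-origin items score 1;
3. dairy products (yogurts, cheeses, ice-creams) score 1 even when they
   contain small amounts of plant ingredients such as fruit or sugar;
4. sausages and cold cuts containing meat score 1 — their energy-yielding
   ingredients are almost exclusively animal-derived;
5. remaining mixed items get a calculated recipe proportion: the animal
   ingredient mass over the total ingredient mass, excluding added water
   (contributes no energy) and trace ingredients such as additives;
6. generic database codes ("cooking fat, average") use the same mass
   calculation on an ingredient estimate from similar products, recorded
   with an ``estimated_similar_product`` basis.

Proportions are mass-based, not energy-based; differing energy yields per
mass unit across ingredients are a documented limitation, not corrected.

The module also classifies participants into diet categories (vegan /
vegetarian / omnivore) from their scored records, optionally combined with
dietary-screener flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ParameterError, UndefinedProportionError, ValidationError

INGREDIENT_ORIGINS = frozenset({"plant", "animal", "water", "trace"})

ITEM_CATEGORIES = (
    "pure_plant",
    "pure_animal",
    "dairy_product",
    "meat_sausage_or_cold_cut",
    "mixed",
    "generic",
)

#: ASF subgroups that disqualify the vegetarian category.
RED_MEAT_OR_POULTRY = frozenset({"red_meat", "poultry"})


@dataclass(frozen=True)
class Ingredient:
    """One recipe ingredient with its mass (g) and origin class.

    Water and trace ingredients are excluded from proportion denominators:
    neither contributes to energy intake.
    """

    name: str
    mass: float
    origin: str

    def __post_init__(self) -> None:
        if self.origin not in INGREDIENT_ORIGINS:
            raise ValidationError(f"ingredient {self.name!r}: unknown origin {self.origin!r}")
        if self.mass < 0:
            raise ValidationError(f"ingredient {self.name!r}: negative mass {self.mass}")


@dataclass(frozen=True)
class ScoringRule:
    rule_id: str
    category: str
    assigned_aswp: float | str  # a fraction, or "calculated"
    priority: int


#: The default rule hierarchy, highest priority first.  The dairy and
#: meat-product blanket rules sit above the calculated-recipe rule; the
#: <10% plant-mass / >90% animal-energy justifications behind them are
#: asserted by the scoring scheme, not measured, so no numeric check is
#: applied here.
DEFAULT_RULES: tuple[ScoringRule, ...] = (
    ScoringRule("rule_pure_plant", "pure_plant", 0.0, 0),
    ScoringRule("rule_pure_animal", "pure_animal", 1.0, 1),
    ScoringRule("rule_dairy", "dairy_product", 1.0, 2),
    ScoringRule("rule_meat_product", "meat_sausage_or_cold_cut", 1.0, 3),
    ScoringRule("calculated_recipe", "mixed", "calculated", 4),
    ScoringRule("estimated_similar_product", "generic", "calculated", 5),
)


def recipe_proportion(ingredients: Iterable[Ingredient]) -> float:
    """Animal mass fraction of a recipe, excluding water and trace mass."""
    animal = 0.0
    denominator = 0.0
    for ing in ingredients:
        if not isinstance(ing, Ingredient):
            ing = Ingredient(*ing)
        if ing.origin in ("water", "trace"):
            continue
        denominator += ing.mass
        if ing.origin == "animal":
            animal += ing.mass
    if denominator <= 0:
        raise UndefinedProportionError(
            "recipe has zero non-water, non-trace ingredient mass"
        )
    return animal / denominator


def score_item(
    item_category: str,
    ingredients: Sequence[Ingredient] | None = None,
    rules: Sequence[ScoringRule] = DEFAULT_RULES,
) -> tuple[float, str]:
    """Assign ``(aswp, aswp_basis)`` to a food item.

    ``ingredients`` is required exactly when the category's rule computes a
    recipe proportion (``mixed`` and ``generic`` under the default rules).
    """
    if item_category not in ITEM_CATEGORIES:
        raise ParameterError(f"unknown item category {item_category!r}")
    for rule in sorted(rules, key=lambda r: r.priority):
        if rule.category != item_category:
            continue
        if rule.assigned_aswp == "calculated":
            if ingredients is None:
                raise ParameterError(
                    f"category {item_category!r} needs an ingredient list"
                )
            return recipe_proportion(ingredients), rule.rule_id
        return float(rule.assigned_aswp), rule.rule_id
    raise ParameterError(f"no scoring rule fires for category {item_category!r}")


def score_recipes(recipes: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format recipe table (code, ingredient, mass_g, origin).

    Returns one row per code with the calculated ASWP.
    """
    for col in ("code", "ingredient", "mass_g", "origin"):
        if col not in recipes.columns:
            raise ValidationError(f"recipes table: missing column {col!r}")
    rows = []
    for code, group in recipes.groupby("code", sort=True):
        ings = [
            Ingredient(str(r.ingredient), float(r.mass_g), str(r.origin))
            for r in group.itertuples()
        ]
        aswp, basis = score_item("mixed", ings)
        rows.append({"code": code, "aswp": aswp, "aswp_basis": basis})
    return pd.DataFrame(rows)


def classify_diet(
    scored_entries: pd.DataFrame,
    screener_flags: Mapping[str, bool] | None = None,
) -> str:
    """Classify one participant's diet from scored records and screener flags.

    ``scored_entries`` needs an ``aswp`` column (the entry's item score) and
    optionally ``asf_group`` naming the animal-source subgroup (``red_meat``,
    ``poultry``, ``fish``, ``egg``, ``dairy`` ...) and ``energy_kj``.  Rows
    with zero energy carry no consumption evidence and are ignored.

    Criteria: vegan — no animal-sourced products at all; vegetarian — no red
    meat or poultry (fish, eggs and dairy permitted, i.e. pesco-vegetarians
    are vegetarians); otherwise omnivore.  Record evidence and screener
    flags are combined by union: either source of animal-food use counts.
    """
    flags = dict(screener_flags or {})
    entries = scored_entries
    if "energy_kj" in entries.columns:
        entries = entries[entries["energy_kj"] > 0]

    any_asf = bool((entries["aswp"] > 0).any()) or flags.get("consumes_any_asf", False)
    if not any_asf:
        return "vegan"

    if "asf_group" in entries.columns:
        red = bool(entries["asf_group"].isin(RED_MEAT_OR_POULTRY).any())
    else:
        red = False
    red = red or flags.get("consumes_red_meat", False) or flags.get("consumes_poultry", False)
    return "omnivore" if red else "vegetarian"
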