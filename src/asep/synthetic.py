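"""Synthetic cohorts with the statistical structure the ASEP pipeline assumes.

The study data behind the method cannot be shared (individual-level dietary
and health records), so this module generates cohorts that emulate their
*statistical* structure — never their culinary detail:

* ~51 participants split vegan / vegetarian / omnivore (7 : 11 : 33);
* 3–4 recorded days each; daily energy within the observed cohort range;
* person-level mean ASEP drawn per category: vegans exactly 0,
  vegetarians in 0–0.20 with median 0.08, omnivores in 0.11–0.52 with
  median 0.33 (two-piece uniform distributions hit the stated medians and
  ranges exactly);
* within-person day-to-day ASEP variation targeting SD 0.08;
* nutrient intakes coupled to ASEP by a Gaussian copula on ranks at stated
  Spearman effect sizes, with marginals spanning observed intake ranges;
* an 872-feature log-normal metabolite matrix with 20 planted features
  (15 positive, 5 negative) strongly rank-correlated with ASEP.

Daily ASEP targets are i.i.d. normal draws around the person's latent
mean, censored to [0, 1]; the generating SD is calibrated so the pooled
population-divisor SD estimator — the estimator the 0.08 target refers
to — is centred on the target.  Each recording day is then realized as
8–15 record entries whose energy-weighted item scores hit the day's
target ASEP *exactly*: two balancer items (one pure-animal, one
pure-plant) absorb a closed-form energy split after decoy items are
placed, so downstream recovery tests can be sharp (1e-9) rather than
statistical.  The ground truth records realized values and the analytic
censored-normal moments per person.

Everything is deterministic given the seed (single generator, fixed
iteration order), and ``generate_cohort`` returns the ground truth needed
by parameter-recovery tests alongside the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .io import write_aswp_table, write_food_records, write_participants

#: Spearman effect-size targets for nutrient intakes vs period ASEP,
#: with (min, median, max) marginal anchors on the observed intake scales.
DEFAULT_NUTRIENT_TARGETS: dict[str, dict] = {
    "protein_e_pct": {"rho": 0.55, "marginal": (10.1, 15.5, 21.3)},
    "safa_e_pct": {"rho": 0.80, "marginal": (4.9, 10.7, 17.9)},
    "pufa_e_pct": {"rho": -0.80, "marginal": (3.0, 6.2, 12.4)},
    "fibre_g_mj": {"rho": -0.80, "marginal": (1.7, 3.5, 6.2)},
    "cholesterol_mg_mj": {"rho": 0.70, "marginal": (0.1, 18.6, 51.9)},
    "folate_ug_d": {"rho": -0.80, "marginal": (94.0, 175.0, 505.0)},
}

ANIMAL_SUBGROUPS = ("dairy", "red_meat", "poultry", "fish", "egg")
VEGETARIAN_ALLOWED = ("dairy", "fish", "egg")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the study design."""

    n_participants: int = 51
    category_weights: tuple[float, float, float] = (7, 11, 33)  # vegan, vegetarian, omnivore
    days_per_participant: int = 4
    three_day_fraction: float = 4 / 51
    vegetarian_mean: tuple[float, float, float] = (0.0, 0.08, 0.20)  # min, median, max
    omnivore_mean: tuple[float, float, float] = (0.11, 0.33, 0.52)
    within_sd: float = 0.08
    n_food_items: int = 60
    origin_fractions: tuple[float, float, float] = (0.68, 0.23, 0.09)  # plant, animal, mixed
    daily_energy_kj: tuple[float, float] = (3386.0, 8115.0)
    entries_per_day: tuple[int, int] = (8, 15)
    nutrient_targets: dict = field(default_factory=lambda: dict(DEFAULT_NUTRIENT_TARGETS))
    n_metabolites: int = 872
    n_planted: int = 20
    n_planted_negative: int = 5
    planted_abs_rho: tuple[float, float] = (0.78, 0.92)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if any(w < 0 for w in self.category_weights) or sum(self.category_weights) <= 0:
            raise ParameterError("category_weights must be non-negative, not all zero")
        for name, (lo, med, hi) in (
            ("vegetarian_mean", self.vegetarian_mean),
            ("omnivore_mean", self.omnivore_mean),
        ):
            if not (0 <= lo <= med <= hi <= 1):
                raise ParameterError(f"{name}: need 0 <= min <= median <= max <= 1")
        if not 0 <= self.within_sd < 0.5:
            raise ParameterError("within_sd must be in [0, 0.5)")
        if self.n_planted > self.n_metabolites:
            raise ParameterError("cannot plant more features than exist")
        if self.n_planted_negative > self.n_planted:
            raise ParameterError("n_planted_negative exceeds n_planted")
        lo, hi = self.planted_abs_rho
        if not 0 < lo <= hi < 1:
            raise ParameterError("planted_abs_rho must satisfy 0 < lo <= hi < 1")


@dataclass
class SyntheticCohort:
    """Generated input tables plus the ground truth used by recovery tests."""

    food_items: pd.DataFrame
    records: pd.DataFrame
    participants: pd.DataFrame
    nutrients: pd.DataFrame | None
    metabolites: pd.DataFrame | None
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_food_records(self.records, out / "food_records.csv")
        write_aswp_table(self.food_items, out / "aswp_table.csv")
        write_participants(self.participants, out / "participants.csv")
        if self.nutrients is not None:
            self.nutrients.to_csv(out / "nutrients.csv", index=False)
        if self.metabolites is not None:
            self.metabolites.to_csv(out / "metabolites.csv", index=False)
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _two_piece_uniform(rng: np.random.Generator, lo: float, med: float, hi: float) -> float:
    """Draw from a distribution with the given min, median and max exactly."""
    u = rng.uniform()
    if u < 0.5:
        return lo + 2 * u * (med - lo)
    return med + (2 * u - 1) * (hi - med)


def _category_counts(n: int, weights) -> tuple[int, int, int]:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts
    for idx in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[idx] += 1
    return tuple(int(c) for c in counts)


def _make_item_bank(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n_plant = max(1, round(spec.origin_fractions[0] * spec.n_food_items))
    n_animal = max(len(ANIMAL_SUBGROUPS), round(spec.origin_fractions[1] * spec.n_food_items))
    n_mixed = max(1, spec.n_food_items - n_plant - n_animal)
    rows = []
    for i in range(n_plant):
        rows.append(
            {
                "code": f"P{i + 1:03d}",
                "name": f"plant item {i + 1}",
                "origin": "plant",
                "aswp": 0.0,
                "aswp_basis": "rule_pure_plant",
                "asf_group": "",
            }
        )
    for i in range(n_animal):
        subgroup = ANIMAL_SUBGROUPS[i % len(ANIMAL_SUBGROUPS)]
        basis = "rule_dairy" if subgroup == "dairy" else "rule_pure_animal"
        rows.append(
            {
                "code": f"A{i + 1:03d}",
                "name": f"{subgroup.replace('_', ' ')} item {i + 1}",
                "origin": "animal",
                "aswp": 1.0,
                "aswp_basis": basis,
                "asf_group": subgroup,
            }
        )
    for i in range(n_mixed):
        rows.append(
            {
                "code": f"M{i + 1:03d}",
                "name": f"mixed item {i + 1}",
                "origin": "mixed",
                "aswp": float(rng.uniform(0.1, 0.9)),
                "aswp_basis": "calculated_recipe",
                "asf_group": "",
            }
        )
    return pd.DataFrame(rows)


def _c4(d: int) -> float:
    """Unbiasing constant: E[sample SD] = c4 * sigma for d normal draws."""
    from scipy.special import gammaln

    return float(
        np.sqrt(2.0 / (d - 1)) * np.exp(gammaln(d / 2.0) - gammaln((d - 1) / 2.0))
    )


def _generating_sigma(s_target: float, d: int) -> float:
    """Day-level SD so the population-divisor pooled-SD estimator targets
    ``s_target``.

    The pooled estimate uses per-person SDs with the population divisor d,
    whose expectation for i.i.d. normal days is c4(d) * sqrt((d-1)/d) *
    sigma; the study's pooled value is that same estimator, so emulating
    "pooled SD about s_target" means inflating the generating sigma by the
    inverse factor.
    """
    if d < 2:
        return s_target
    return s_target / (_c4(d) * np.sqrt((d - 1) / d))


def _censored_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of clip(N(mu, sigma^2), 0, 1) — the day-level law."""
    if sigma == 0:
        return mu, 0.0
    alpha = (0.0 - mu) / sigma
    beta = (1.0 - mu) / sigma
    p_lo = stats.norm.cdf(alpha)
    p_hi = stats.norm.sf(beta)
    p_mid = max(1.0 - p_lo - p_hi, 0.0)
    if p_mid > 0:
        mid = stats.truncnorm(alpha, beta, loc=mu, scale=sigma)
        m_mid, v_mid = mid.mean(), mid.var()
    else:  # pragma: no cover - degenerate all-censored case
        m_mid, v_mid = mu, 0.0
    mean = p_lo * 0.0 + p_hi * 1.0 + p_mid * m_mid
    second = p_hi * 1.0 + p_mid * (v_mid + m_mid**2)
    return float(mean), float(second - mean**2)


def _daily_targets(
    rng: np.random.Generator, mu: float, d: int, s_target: float
) -> tuple[np.ndarray, float]:
    """Daily ASEP targets: i.i.d. normal days around latent mean ``mu``,
    censored to [0, 1].

    Days are independent given the person (no artificial within-person
    correlation), so the day-pair correlation estimator is unbiased for
    the between/total variance ratio of the generating process.  Returns
    (targets, realized population SD about the realized mean).
    """
    if s_target == 0 or d < 1:
        return np.full(d, mu), 0.0
    sigma = _generating_sigma(s_target, d)
    targets = np.clip(mu + sigma * rng.standard_normal(d), 0.0, 1.0)
    realized = float(np.sqrt(((targets - targets.mean()) ** 2).mean()))
    return targets, realized


def _realize_day(
    rng: np.random.Generator,
    target: float,
    energy: float,
    n_rows: int,
    plant_codes: np.ndarray,
    animal_pool: pd.DataFrame,
    mixed_pool: pd.DataFrame,
    animal_balancer: str,
) -> list[tuple[str, float]]:
    """Record rows for one day whose energy-weighted score equals ``target``.

    Two balancer rows (one pure-animal, one pure-plant) take a closed-form
    energy split after the decoy rows are placed; decoys are shrunk until
    the split is feasible, which always terminates because with zero decoy
    animal contribution the split is target*energy <= balancer energy.
    """
    n_decoys = n_rows - 2
    shares = rng.dirichlet(np.ones(n_rows)) * energy
    decoy_energy = shares[:n_decoys].copy()
    plant_balancer = str(rng.choice(plant_codes))

    decoy_items: list[tuple[str, float]] = []  # (code, aswp)
    for _ in range(n_decoys):
        u = rng.uniform()
        if u < 0.6 * target and len(animal_pool):
            row = animal_pool.iloc[rng.integers(len(animal_pool))]
            decoy_items.append((str(row["code"]), float(row["aswp"])))
        elif u < 0.6 * target + 0.1 and len(mixed_pool) and target > 0:
            row = mixed_pool.iloc[rng.integers(len(mixed_pool))]
            decoy_items.append((str(row["code"]), float(row["aswp"])))
        else:
            decoy_items.append((str(rng.choice(plant_codes)), 0.0))

    for attempt in range(60):
        if attempt == 5:  # all-plant decoys: makes the split feasible for sure
            decoy_items = [
                (str(rng.choice(plant_codes)), 0.0) for _ in decoy_items
            ]
        weighted = sum(e * w for e, (_, w) in zip(decoy_energy, decoy_items))
        balancer_energy = energy - decoy_energy.sum()
        x = target * energy - weighted
        if -1e-12 <= x <= balancer_energy + 1e-12:
            x = min(max(x, 0.0), balancer_energy)
            break
        decoy_energy *= 0.5
    else:  # pragma: no cover - loop always breaks by construction
        raise RuntimeError("day realization failed to converge")

    rows = [
        (code, float(e))
        for (code, _), e in zip(decoy_items, decoy_energy)
        if e > 0
    ]
    if x > 0:
        rows.append((animal_balancer, float(x)))
    if balancer_energy - x > 0:
        rows.append((plant_balancer, float(balancer_energy - x)))
    return rows


def _copula_column(
    rng: np.random.Generator, z_scores: np.ndarray, rho_spearman: float
) -> np.ndarray:
    """Latent standard-normal column rank-coupled to ``z_scores`` at the
    target Spearman rho (Pearson rho on the latent scale via 2 sin(pi rho/6))."""
    rho_g = 2.0 * np.sin(np.pi * rho_spearman / 6.0)
    eps = rng.standard_normal(z_scores.size)
    return rho_g * z_scores + np.sqrt(1.0 - rho_g**2) * eps


def _two_piece_quantile(u: np.ndarray, lo: float, med: float, hi: float) -> np.ndarray:
    return np.where(u < 0.5, lo + 2 * u * (med - lo), med + (2 * u - 1) * (hi - med))


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (tables + ground truth).

    ``seed`` overrides ``spec.seed``.  Regeneration with the same spec and
    seed reproduces byte-identical tables.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    items = _make_item_bank(spec, rng)
    plant_codes = items.loc[items["origin"] == "plant", "code"].to_numpy()
    animal_items = items[items["origin"] == "animal"]
    mixed_items = items[items["origin"] == "mixed"]
    veg_pool = animal_items[animal_items["asf_group"].isin(VEGETARIAN_ALLOWED)]
    meat_pool = animal_items[animal_items["asf_group"].isin(("red_meat", "poultry"))]

    n_vegan, n_veget, n_omni = _category_counts(spec.n_participants, spec.category_weights)
    categories = ["vegan"] * n_vegan + ["vegetarian"] * n_veget + ["omnivore"] * n_omni

    n_three = int(round(spec.three_day_fraction * spec.n_participants))
    three_day_ids = set(
        rng.choice(spec.n_participants, size=min(n_three, spec.n_participants), replace=False).tolist()
    )

    record_rows: list[dict] = []
    participant_rows: list[dict] = []
    truth_people: list[dict] = []
    for p_idx, category in enumerate(categories):
        pid = f"S{p_idx + 1:03d}"
        d = spec.days_per_participant - (1 if p_idx in three_day_ids else 0)
        if category == "vegan":
            mu = 0.0
            targets, s_real = np.zeros(d), 0.0
            day_mean, day_var = 0.0, 0.0
        else:
            anchors = spec.vegetarian_mean if category == "vegetarian" else spec.omnivore_mean
            mu = _two_piece_uniform(rng, *anchors)
            targets, s_real = _daily_targets(rng, mu, d, spec.within_sd)
            day_mean, day_var = _censored_normal_moments(
                mu, _generating_sigma(spec.within_sd, d)
            )

        if category == "omnivore":
            balancer = str(meat_pool.iloc[rng.integers(len(meat_pool))]["code"])
            pool = animal_items
        elif category == "vegetarian":
            balancer = str(veg_pool.iloc[rng.integers(len(veg_pool))]["code"])
            pool = veg_pool
        else:
            balancer, pool = "", animal_items.iloc[:0]

        day_energies = rng.uniform(*spec.daily_energy_kj, size=d)
        for day in range(1, d + 1):
            n_rows = int(rng.integers(spec.entries_per_day[0], spec.entries_per_day[1] + 1))
            if category == "vegan":
                shares = rng.dirichlet(np.ones(n_rows)) * day_energies[day - 1]
                day_rows = [
                    (str(rng.choice(plant_codes)), float(e)) for e in shares if e > 0
                ]
            else:
                day_rows = _realize_day(
                    rng,
                    float(targets[day - 1]),
                    float(day_energies[day - 1]),
                    n_rows,
                    plant_codes,
                    pool,
                    mixed_items,
                    balancer,
                )
            for code, e in day_rows:
                record_rows.append(
                    {
                        "participant_id": pid,
                        "day_index": day,
                        "food_code": code,
                        "energy_kj": e,
                    }
                )

        period = float(np.average(targets, weights=day_energies)) if d else 0.0
        participant_rows.append(
            {
                "participant_id": pid,
                "diet_category": category,
                "n_days": d,
                # screener truth: what a dietary questionnaire would report
                "consumes_any_asf": category != "vegan",
                "consumes_red_meat": category == "omnivore",
                "consumes_poultry": False,
            }
        )
        truth_people.append(
            {
                "participant_id": pid,
                "diet_category": category,
                "true_mean_asep": float(mu),
                "day_level_mean": day_mean,  # analytic mean of the censored day law
                "day_level_var": day_var,  # analytic within-person day variance
                "daily_asep": [float(t) for t in targets],
                "realized_within_sd": s_real,
                "n_days": d,
                "period_asep": period,
            }
        )

    records = pd.DataFrame(record_rows)
    participants = pd.DataFrame(participant_rows)

    # --- variance-component ground truth over non-vegan participants
    nonveg = [t for t in truth_people if t["diet_category"] != "vegan"]
    period_asep = pd.Series(
        {t["participant_id"]: t["period_asep"] for t in truth_people}
    ).sort_index()
    if nonveg:
        day_means = np.array([t["day_level_mean"] for t in nonveg])
        day_vars = np.array([t["day_level_var"] for t in nonveg])
        d_w = np.array([t["n_days"] for t in nonveg], dtype=float)
        s_real = np.array([t["realized_within_sd"] for t in nonveg])
        # between/within decomposition of the generating process itself:
        # days are i.i.d. given the person, so the pair-correlation
        # estimand is var(person day-level means) over total day variance
        sigma2_b = float(np.var(day_means))
        sigma2_w = float(np.average(day_vars, weights=d_w))
        pooled_sd = float(np.average(s_real, weights=d_w))
        icc = sigma2_b / (sigma2_b + sigma2_w) if (sigma2_b + sigma2_w) > 0 else float("nan")
    else:
        sigma2_b = sigma2_w = pooled_sd = icc = float("nan")

    # --- nutrient intakes coupled to period ASEP
    n = spec.n_participants
    ranks = stats.rankdata(period_asep.to_numpy())
    z = stats.norm.ppf(ranks / (n + 1))
    z = (z - z.mean()) / z.std() if z.std() > 0 else z
    nutrients = pd.DataFrame({"participant_id": period_asep.index})
    for name in sorted(spec.nutrient_targets):
        cfg = spec.nutrient_targets[name]
        latent = _copula_column(rng, z, cfg["rho"])
        u = stats.norm.cdf(latent)
        nutrients[name] = _two_piece_quantile(u, *cfg["marginal"])

    # --- metabolite matrix with planted features
    m = spec.n_metabolites
    feature_ids = [f"M{i + 1:04d}" for i in range(m)]
    planted_idx = np.sort(rng.choice(m, size=spec.n_planted, replace=False))
    signs = np.ones(spec.n_planted)
    neg_pick = rng.choice(spec.n_planted, size=spec.n_planted_negative, replace=False)
    signs[neg_pick] = -1.0
    abs_rho = rng.uniform(*spec.planted_abs_rho, size=spec.n_planted)
    rho_s = np.zeros(m)
    rho_s[planted_idx] = signs * abs_rho

    rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)
    eps = rng.standard_normal((n, m))
    latent = z[:, None] * rho_g[None, :] + np.sqrt(1.0 - rho_g**2)[None, :] * eps
    log_mu = rng.uniform(2.0, 8.0, size=m)
    log_sd = rng.uniform(0.3, 0.8, size=m)
    abundance = np.exp(log_mu[None, :] + log_sd[None, :] * latent)
    metabolites = pd.DataFrame(abundance, columns=feature_ids)
    metabolites.insert(0, "participant_id", period_asep.index.to_numpy())

    truth = {
        "seed": int(spec.seed if seed is None else seed),
        "participants": truth_people,
        "sigma2_between": sigma2_b,
        "sigma2_within": sigma2_w,
        "pooled_within_sd": pooled_sd,
        "icc": icc,
        "within_sd_target": spec.within_sd,
        "nutrient_targets": {k: v["rho"] for k, v in spec.nutrient_targets.items()},
        "planted_features": [
            {"feature_id": feature_ids[i], "rho": float(rho_s[i])} for i in planted_idx
        ],
    }
    return SyntheticCohort(
        food_items=items,
        records=records,
        participants=participants,
        nutrients=nutrients,
        metabolites=metabolites,
        truth=truth,
    )


def worked_example_tables() -> SyntheticCohort:
    """A fixed 4-participant, 2-day, 6-item cohort with hand-checkable ASEPs.

    Period ASEPs: E01 (vegetarian) 0.375, E02 (vegan) 0.0,
    E03 (omnivore) 0.42, E04 (vegetarian) 0.40.  E03's first day is the
    hand-summed example (300*1 + 100*0.4 + 600*0) / 1000 = 0.34, and its
    period value is (340 + 500) / 2000 = 0.42.
    """
    items = pd.DataFrame(
        [
            ("A1", "oat drink", "plant", 0.0, "rule_pure_plant", ""),
            ("A2", "yogurt", "animal", 1.0, "rule_dairy", "dairy"),
            ("A3", "beef stew", "animal", 1.0, "rule_pure_animal", "red_meat"),
            ("A4", "margarine", "mixed", 0.4, "calculated_recipe", ""),
            ("A5", "rye bread", "plant", 0.0, "rule_pure_plant", ""),
            ("A6", "salmon soup", "animal", 1.0, "rule_pure_animal", "fish"),
        ],
        columns=["code", "name", "origin", "aswp", "aswp_basis", "asf_group"],
    )
    records = pd.DataFrame(
        [
            ("E01", 1, "A2", 500.0), ("E01", 1, "A1", 500.0),
            ("E01", 2, "A2", 250.0), ("E01", 2, "A5", 750.0),
            ("E02", 1, "A1", 600.0), ("E02", 1, "A5", 400.0),
            ("E02", 2, "A5", 1000.0),
            ("E03", 1, "A3", 300.0), ("E03", 1, "A4", 100.0), ("E03", 1, "A1", 600.0),
            ("E03", 2, "A6", 500.0), ("E03", 2, "A5", 500.0),
            ("E04", 1, "A4", 1000.0),
            ("E04", 2, "A2", 400.0), ("E04", 2, "A5", 600.0),
        ],
        columns=["participant_id", "day_index", "food_code", "energy_kj"],
    )
    participants = pd.DataFrame(
        {
            "participant_id": ["E01", "E02", "E03", "E04"],
            "diet_category": ["vegetarian", "vegan", "omnivore", "vegetarian"],
            "n_days": [2, 2, 2, 2],
        }
    )
    truth = {
        "participants": [
            {"participant_id": "E01", "period_asep": 0.375, "daily_asep": [0.5, 0.25]},
            {"participant_id": "E02", "period_asep": 0.0, "daily_asep": [0.0, 0.0]},
            {"participant_id": "E03", "period_asep": 0.42, "daily_asep": [0.34, 0.5]},
            {"participant_id": "E04", "period_asep": 0.4, "daily_asep": [0.4, 0.4]},
        ]
    }
    return SyntheticCohort(
        food_items=items,
        records=records,
        participants=participants,
        nutrients=None,
        metabolites=None,
        truth=truth,
    )
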