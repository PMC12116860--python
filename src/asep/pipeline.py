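"""End-to-end analysis: records -> ASEP -> variability -> screens -> clusters.

``run_full_analysis`` wires the stages in analysis order and writes a fixed
artifact set plus a run manifest (configuration, package version, seed and
input checksums) so a run is reproducible and auditable.  Reruns on
identical inputs produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .core import asep_by_participant, cohort_summary, results_frame
from .exceptions import AsepError
from .io import read_aswp_table, read_food_records, read_participants
from .screen import CorrelationScreen
from .variability import DEFAULT_A_GRID, VariabilityModel

log = logging.getLogger("asep")

ARTIFACTS = (
    "asep.csv",
    "cohort_summary.csv",
    "days_required.csv",
    "screen_intakes.csv",
    "screen_metabolites.csv",
    "top20.csv",
    "clusters.nwk",
    "manifest.json",
)


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    records: str
    aswp: str
    participants: str | None = None
    nutrients: str | None = None
    metabolites: str | None = None
    out_dir: str = "asep_out"
    delimiter: str = ","
    energy_unit: str = "kJ"
    a_values: tuple[float, ...] = DEFAULT_A_GRID
    e_limit: float = 0.9
    z: float = 1.96
    methods: tuple[str, ...] = ("beaton", "liu")
    m_intakes: int = 12
    m_metabolites: int = 872
    alpha: float = 0.05
    k: int = 20
    pair_method: str = "pearson"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _screen_block(
    table_path: str,
    asep: pd.Series,
    m: int,
    alpha: float,
    k: int,
    delimiter: str,
):
    frame = pd.read_csv(table_path, sep=delimiter, dtype={"participant_id": str})
    frame = frame.set_index("participant_id")
    screen = CorrelationScreen(frame, asep, m_for_bonferroni=m, alpha=alpha, k=k)
    return screen.fit()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage the inputs support; returns {artifact name: path}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, str] = {}
    inputs = {
        name: path
        for name, path in (
            ("records", config.records),
            ("aswp", config.aswp),
            ("participants", config.participants),
            ("nutrients", config.nutrients),
            ("metabolites", config.metabolites),
        )
        if path
    }

    stage = "read inputs"
    try:
        records, derived = read_food_records(
            config.records, delimiter=config.delimiter, energy_unit=config.energy_unit
        )
        aswp_table = read_aswp_table(config.aswp, delimiter=config.delimiter)
        participants = (
            read_participants(config.participants, delimiter=config.delimiter)
            if config.participants
            else derived
        )
        counts = aswp_table["origin"].value_counts()
        log.info(
            "read %d record rows, %d participants; %d food items (%d plant / %d animal / %d mixed-or-generic)",
            len(records),
            participants["participant_id"].nunique(),
            len(aswp_table),
            counts.get("plant", 0),
            counts.get("animal", 0),
            counts.get("mixed", 0) + counts.get("generic", 0),
        )

        stage = "asep"
        daily, results = asep_by_participant(records, aswp_table, participants)
        per_participant = results_frame(results)
        per_participant.to_csv(out / "asep.csv", index=False)
        produced["asep.csv"] = str(out / "asep.csv")

        summary = cohort_summary(results)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        produced["cohort_summary.csv"] = str(out / "cohort_summary.csv")
        log.info("ASEP computed for %d participants", len(per_participant))

        stage = "variability"
        fit = VariabilityModel(daily, pair_method=config.pair_method).fit()
        days = fit.required_days_table(
            a_values=config.a_values, e_limit=config.e_limit, z=config.z
        )
        keep = {"beaton": "beaton_absolute", "liu": "liu"}
        wanted = [keep[m] for m in config.methods]
        days = days[days["method"].isin(wanted)]
        days.to_csv(out / "days_required.csv", index=False)
        produced["days_required.csv"] = str(out / "days_required.csv")
        log.info(
            "variability: s_hat=%.4f r=%.3f over %d pairs", fit.s_hat, fit.r_i, fit.n_pairs
        )

        asep_vector = per_participant.set_index("participant_id")["period_asep"]
        if config.nutrients:
            stage = "screen intakes"
            res = _screen_block(
                config.nutrients, asep_vector, config.m_intakes, config.alpha,
                config.k, config.delimiter,
            )
            res.table.to_csv(out / "screen_intakes.csv", index=False)
            produced["screen_intakes.csv"] = str(out / "screen_intakes.csv")
            log.info("intake screen: %d significant", res.n_significant)

        if config.metabolites:
            stage = "screen metabolites"
            res = _screen_block(
                config.metabolites, asep_vector, config.m_metabolites, config.alpha,
                config.k, config.delimiter,
            )
            res.table.to_csv(out / "screen_metabolites.csv", index=False)
            produced["screen_metabolites.csv"] = str(out / "screen_metabolites.csv")
            top = res.top()
            top.to_csv(out / "top20.csv", index=False)
            produced["top20.csv"] = str(out / "top20.csv")
            if len(top) >= 2:
                res.cluster_top().write_newick(out / "clusters.nwk")
                produced["clusters.nwk"] = str(out / "clusters.nwk")
            log.info(
                "metabolite screen: %d significant, top %d exported",
                res.n_significant,
                len(top),
            )
    except AsepError as err:
        raise type(err)(f"stage '{stage}' failed: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.seed,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()},
        "artifacts": sorted(produced),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    produced["manifest.json"] = str(out / "manifest.json")
    return produced
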