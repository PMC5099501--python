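"""End-to-end pipeline orchestration and artifact emission.

Stage order: generate (or load) -> link -> derive -> aggregate -> correlate
-> report.  Every emitted number is recomputable from the emitted
intermediate CSVs; a JSON manifest records the configuration hash, seed and
per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregate import aggregate_plans, plan_membership, state_summaries
from .attributes import derive_all
from .config import WorldConfig
from .linkage import (AttributeWeights, LinkSet, build_specialty_map,
                      calibrate_threshold, link_directories,
                      match_insurance_names)
from .mappings import DEFAULT_SPECIALTY_CATEGORIES
from .model import PlanQualityAnalysis, PlanQualityResults
from .synthdata import SyntheticWorld, generate_world

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    started: str
    finished: str = ""
    counts: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2)


def linkage_report(links: LinkSet, truth_pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Accepted-pair counts and score summary; precision/recall/F1 given truth."""
    scores = links.accepted["score"]
    rows = [
        ("n_scored_pairs", float(len(links.scored_pairs))),
        ("n_accepted", float(len(links.accepted))),
        ("threshold", float(links.threshold)),
        ("accepted_score_mean", float(scores.mean()) if len(scores) else float("nan")),
        ("accepted_score_min", float(scores.min()) if len(scores) else float("nan")),
    ]
    if truth_pairs is not None and len(truth_pairs):
        truth = set(zip(truth_pairs["npi"], truth_pairs["site_id"]))
        accepted = set(zip(links.accepted["npi"], links.accepted["site_id"]))
        tp = len(truth & accepted)
        precision = tp / len(accepted) if accepted else 0.0
        recall = tp / len(truth)
        f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
        rows += [("precision", precision), ("recall", recall), ("f1", f1)]
    return pd.DataFrame(rows, columns=["metric", "value"])


def analyze_world(
    world: SyntheticWorld,
    links: LinkSet | str | None = None,
    weights: AttributeWeights | None = None,
    calibrate: bool = False,
    min_members: int = 5,
    min_plans_per_state: int = 10,
    min_insurance_similarity: float = 0.5,
    compute_cost: bool = True,
    referral_norm: str = "none",
) -> tuple[pd.DataFrame, dict, pd.DataFrame, PlanQualityResults, LinkSet | None]:
    """Run link -> derive -> aggregate -> correlate on a synthetic world.

    ``links`` may be a precomputed :class:`LinkSet`, the string ``"truth"``
    to use the generator's ground-truth identity pairs directly, or None to
    run the linkage stage (optionally recalibrating the threshold on truth).
    Returns ``(attrs, membership, aggregates, results, links)``.
    """
    if links == "truth":
        accepted = world.truth_links.copy()
        accepted["score"] = 1.0
        links = None
    else:
        if links is None:
            weights = weights or AttributeWeights()
            links = link_directories(world.cms_providers, world.site_providers, weights)
            if calibrate and len(world.truth_links):
                cal = calibrate_threshold(links.scored_pairs, world.truth_links)
                logger.info("calibrated threshold %.3f (F1=%.3f)", cal.threshold, cal.f1)
                weights.threshold = cal.threshold
                links = link_directories(world.cms_providers, world.site_providers, weights)
        accepted = links.accepted

    smap = build_specialty_map(world.specialty_counts(), DEFAULT_SPECIALTY_CATEGORIES)
    attrs = derive_all(
        world.cms_providers, world.site_providers, world.hospitals,
        world.hospital_scores, world.charges, world.referrals, accepted, smap,
        referral_norm=referral_norm, compute_cost=compute_cost)

    # accepted-insurer strings of linked profiles -> plan names
    linked_site = world.site_providers.merge(accepted[["npi", "site_id"]], on="site_id")
    raw_strings = sorted({s for ins in linked_site["insurers"].dropna()
                          for s in str(ins).split(";") if s})
    mapping, unmapped = match_insurance_names(
        raw_strings, world.plans["plan_name"].tolist(),
        min_similarity=min_insurance_similarity)
    if unmapped:
        logger.info("%d insurer strings unmapped", len(unmapped))
    provider_insurers = linked_site[["npi", "insurers"]].rename(
        columns={"npi": "provider_id"})
    membership = plan_membership(world.plans, provider_insurers, mapping)

    model = PlanQualityAnalysis.from_tables(
        world.plans, attrs, membership, min_members=min_members,
        min_plans_per_state=min_plans_per_state)
    results = model.fit()
    return attrs, membership, model.plan_aggregates, results, links


def run_pipeline(
    config: WorldConfig | str | Path,
    outdir: str | Path,
    overwrite: bool = False,
    calibrate: bool = False,
    min_members: int = 5,
    min_plans_per_state: int = 10,
    input_dir: str | Path | None = None,
) -> Path:
    """Run the full pipeline from a config and write all artifacts.

    With ``input_dir`` given, the generation stage is skipped and the five
    input table families are loaded from CSVs there (ground-truth sidecars
    optional — absent truth simply disables the precision/recall rows of
    the linkage report and threshold calibration).  Emits the input tables,
    the linkage report, the provider attribute table, plan aggregates,
    correlation and plan-type tables, per-state summaries and a JSON run
    manifest.
    """
    if not isinstance(config, WorldConfig):
        config = WorldConfig.from_yaml(config)
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16],
        seed=config.seed, software_version=__version__,
        started=datetime.now(timezone.utc).isoformat())

    if input_dir is not None:
        logger.info("stage load: reading input tables from %s", input_dir)
        world = SyntheticWorld.read(input_dir, config=config)
    else:
        logger.info("stage generate: %d providers, %d plans", config.n_providers,
                    config.n_plans)
        world = generate_world(config)
    world.write(outdir / "inputs")

    have_truth = len(world.truth_links) > 0
    attrs, membership, aggregates, results, links = analyze_world(
        world, calibrate=calibrate and have_truth, min_members=min_members,
        min_plans_per_state=min_plans_per_state)

    linkage_report(links, world.truth_links if have_truth else None).to_csv(
        outdir / "linkage_report.csv", index=False)
    attrs.to_csv(outdir / "provider_attributes.csv", index=False)
    aggregates.to_csv(outdir / "plan_aggregates.csv", index=False)
    results.attribute_correlations.to_csv(
        outdir / "attribute_correlations.csv", index=False)
    results.statewise_correlations.to_csv(
        outdir / "statewise_correlations.csv", index=False)
    results.plan_type_stats.to_csv(outdir / "plan_type_stats.csv", index=False)
    if results.condition_correlations is not None:
        results.condition_correlations.to_csv(
            outdir / "condition_correlations.csv", index=False)
    if len(world.populations):
        state_summaries(world.plans, world.cms_providers, world.populations).to_csv(
            outdir / "state_summaries.csv", index=False)
    else:
        logger.info("no population table supplied; state summaries skipped")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")

    manifest.counts = {
        "providers_generated": len(world.cms_providers),
        "site_profiles": len(world.site_providers),
        "pairs_scored": len(links.scored_pairs),
        "links_accepted": len(links.accepted),
        "plans_aggregated": len(aggregates),
        "plans_in_analysis": int(aggregates["in_analysis"].sum()),
        "correlations_emitted": (
            len(results.attribute_correlations)
            + len(results.statewise_correlations)
            + (len(results.condition_correlations)
               if results.condition_correlations is not None else 0)),
    }
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return outdir
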