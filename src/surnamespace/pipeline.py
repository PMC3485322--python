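"""Two-stage surname-space pipeline with config, manifests and determinism.

Computing pairwise relatedness for every surname pair at the finest spatial
resolution is both expensive and noisy (tiny units make chance co-occurrence
likely).  The pipeline therefore runs in two stages:

1. **Coarse stage** — aggregate counts to functional micro-regions, compute
   concentration sets and the pairwise measure there, and inspect the
   rank-size distribution of values to pick a link threshold.  Surnames
   incident to the strongest links become *candidates*.
2. **Fine stage** — restrict to candidates, drop the largest units (noise
   from big-city mixing), recompute everything at the fine level, and build
   the thresholded network.

A run is fully described by a :class:`RunConfig`; a :class:`RunManifest`
echoes the config, counts every filtering step, and checksums every output,
so that identical config + seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .concentration import concentration_sets, location_quotients, max_lq_region
from .errors import ConfigError, ValidationError
from .io_model import (
    SurnameCountTable,
    aggregate_to,
    exclude_regions,
    filter_feminine,
    filter_min_bearers,
    read_counts,
    read_mapping,
)
from .network import build_network, export_graph, network_stats
from .relatedness import (
    LinkRecord,
    ProximityMatrix,
    dice_symmetric_all,
    jaccard_all,
    rank_size,
    top_links,
)

logger = logging.getLogger(__name__)

MEASURES = {"jaccard": jaccard_all, "dice_sym": dice_symmetric_all}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to re-run a surname-space analysis.

    Defaults follow the reference design for a country-scale register:
    analysis restricted to surnames with >= 50 bearers, stage-1 links at 60%
    of the maximum observed value, stage-2 links at an absolute Dice
    threshold of 0.23, display cuts of 100 (coarse) and 150 (fine) bearers.
    """

    counts_path: str | None = None
    mapping_path: str | None = None
    regions_path: str | None = None
    output_dir: str = "surnamespace_out"
    measure: str = "dice_sym"
    feminine_suffixes: tuple[str, ...] = ("á",)
    min_bearers_analysis: int = 50
    min_bearers_stage1_display: int = 100
    min_bearers_stage2_display: int = 150
    stage1_link_mode: str = "fraction_of_max"  # or "threshold"
    stage1_link_param: float = 0.60
    stage2_threshold: float = 0.23
    excluded_regions: tuple[str, ...] = ()
    candidate_rule: str = "fraction_of_max"  # threshold | top_k | fraction_of_max | target_count
    candidate_param: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ConfigError(f"unknown measure {self.measure!r}; choose from {sorted(MEASURES)}")
        if not (0 < self.stage2_threshold <= 1):
            raise ConfigError("stage2_threshold must be in (0, 1]")
        if self.stage1_link_mode == "fraction_of_max" and not (0 < self.stage1_link_param <= 1):
            raise ConfigError("stage-1 fraction-of-max must be in (0, 1]")
        for name in ("min_bearers_analysis", "min_bearers_stage1_display", "min_bearers_stage2_display"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feminine_suffixes"] = list(self.feminine_suffixes)
        d["excluded_regions"] = list(self.excluded_regions)
        return d


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from YAML, with keyword overrides (CLI flags)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("feminine_suffixes", "excluded_regions"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class StageOneResult:
    proximity: ProximityMatrix
    rank_size: pd.DataFrame
    derived_threshold: float
    counts: dict[str, int]
    table: SurnameCountTable = field(repr=False)


@dataclass
class StageTwoResult:
    proximity: ProximityMatrix
    network: nx.Graph
    stats: dict
    counts: dict[str, int]
    table: SurnameCountTable = field(repr=False)


def _prepare(table: SurnameCountTable, config: RunConfig) -> tuple[SurnameCountTable, dict[str, int]]:
    counts = {"surnames_in": table.n_surnames, "records_in": len(table)}
    table = filter_feminine(table, config.feminine_suffixes)
    counts["surnames_after_feminine_filter"] = table.n_surnames
    table = filter_min_bearers(table, config.min_bearers_analysis)
    counts["surnames_after_min_bearers"] = table.n_surnames
    return table, counts


def stage_one(config: RunConfig, table: SurnameCountTable | None = None) -> StageOneResult:
    """Coarse pass: filter, aggregate, concentrate, measure, rank-size."""
    if table is None:
        if not config.counts_path:
            raise ConfigError("counts_path required when no table is passed")
        table = read_counts(config.counts_path)
    table, counts = _prepare(table, config)
    if len(table) == 0:
        raise ValidationError("no surnames survive the stage-1 filters")
    if config.mapping_path:
        table = aggregate_to(table, read_mapping(config.mapping_path))
    counts["regions_stage1"] = table.n_regions
    if table.n_surnames < 2:
        raise ValidationError("fewer than 2 surnames after stage-1 filtering")

    conc = concentration_sets(location_quotients(table))
    prox = MEASURES[config.measure](conc)
    counts["stage1_pairs_stored"] = prox.n_stored

    if config.stage1_link_mode == "fraction_of_max":
        derived = config.stage1_link_param * prox.max_value
    elif config.stage1_link_mode == "threshold":
        derived = config.stage1_link_param
    else:
        raise ConfigError(f"unknown stage1_link_mode {config.stage1_link_mode!r}")
    rs = rank_size(prox, floor=0.5 * prox.max_value if prox.n_stored else 0.0)
    logger.info("stage 1: %d surnames, max %s = %.3f, derived d = %.3f",
                table.n_surnames, config.measure, prox.max_value, derived)
    return StageOneResult(proximity=prox, rank_size=rs, derived_threshold=derived, counts=counts, table=table)


def select_candidates(
    prox: ProximityMatrix,
    rule: str = "fraction_of_max",
    param: float | int = 0.60,
) -> set[str]:
    """Surnames incident to the qualifying stage-1 links.

    rule="threshold"        links with value >= param;
    rule="fraction_of_max"  links with value >= param * max;
    rule="top_k"            the param strongest links (ties included);
    rule="target_count"     searches the link threshold so the incident
                            surname count comes as close as possible to
                            param (ties always included; if the target falls
                            between achievable counts the nearest is used and
                            a warning logged).
    """
    if rule in ("threshold", "fraction_of_max", "top_k"):
        links = top_links(prox, rule, param)
        return {s for rec in links for s in (rec.surname_i, rec.surname_j)}
    if rule != "target_count":
        raise ConfigError(f"unknown candidate rule {rule!r}")
    target = int(param)
    if target <= 0:
        raise ValidationError("target candidate count must be positive")
    df = prox.to_dataframe()  # descending value
    if df.empty:
        return set()
    # walk distinct values downward, tracking incident-surname counts
    best_cut, best_count, seen = None, 0, set()
    for value in df["value"].unique():  # already descending
        chunk = df.loc[df["value"] == value]
        seen.update(chunk["surname_i"])
        seen.update(chunk["surname_j"])
        count = len(seen)
        if best_cut is None or abs(count - target) < abs(best_count - target):
            best_cut, best_count = float(value), count
        if count >= target:
            break
        prev_count = count
    if best_count != target:
        logger.warning(
            "target candidate count %d not exactly achievable; using threshold %.4f with %d candidates",
            target, best_cut, best_count,
        )
    links = top_links(prox, "threshold", best_cut)
    return {s for rec in links for s in (rec.surname_i, rec.surname_j)}


def stage_two(
    config: RunConfig,
    candidates: set[str],
    table: SurnameCountTable | None = None,
) -> StageTwoResult:
    """Fine pass: restrict to candidates, drop excluded units, rebuild the
    concentration sets and measure at fine resolution, threshold the network."""
    if not candidates:
        raise ValidationError("candidate set is empty")
    if table is None:
        if not config.counts_path:
            raise ConfigError("counts_path required when no table is passed")
        table = read_counts(config.counts_path)
    table = filter_feminine(table, config.feminine_suffixes)
    present = set(table.df["surname"].unique())
    missing = candidates - present
    if missing:
        logger.warning("%d candidate(s) absent from the fine-level table", len(missing))
    table = SurnameCountTable(table.df.loc[table.df["surname"].isin(candidates)])
    if config.excluded_regions:
        table = exclude_regions(table, config.excluded_regions)
    if table.n_surnames < 2:
        raise ValidationError("fewer than 2 candidates with fine-level records")
    counts = {
        "candidates_requested": len(candidates),
        "candidates_found": len(candidates & present),
        "surnames_stage2": table.n_surnames,
        "regions_stage2_raw": table.n_regions,
    }

    lq = location_quotients(table)
    conc = concentration_sets(lq)
    # fine units where no candidate concentrates carry no signal; count them
    import numpy as np

    col_occ = np.asarray(conc.indicator.sum(axis=0)).ravel()
    counts["regions_without_concentrated_candidate"] = int((col_occ == 0).sum())
    counts["regions_stage2_effective"] = int((col_occ > 0).sum())

    prox = MEASURES[config.measure](conc)
    counts["stage2_pairs_stored"] = prox.n_stored

    totals = table.surname_totals
    display = set(totals.index[totals >= config.min_bearers_stage2_display])
    links = [
        rec
        for rec in top_links(prox, "threshold", config.stage2_threshold)
        if rec.surname_i in display and rec.surname_j in display
    ]
    attribution = max_lq_region(lq, counts=table)
    node_attrs = {
        s: {"bearers": int(totals[s]), "attribution_region": attribution.get(s, "none")}
        for s in totals.index
    }
    net = build_network(links, node_attrs=node_attrs, d=config.stage2_threshold)
    counts["network_nodes"] = net.number_of_nodes()
    counts["network_links"] = net.number_of_edges()
    stats = (
        network_stats(net).rounded()
        if net.number_of_nodes()
        else {"n": 0, "m": 0, "c": None, "rho": None}
    )
    return StageTwoResult(proximity=prox, network=net, stats=stats, counts=counts, table=table)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    coarse_table: SurnameCountTable | None = None,
    fine_table: SurnameCountTable | None = None,
) -> dict:
    """Run both stages end-to-end, write all artifacts, return the manifest.

    Outputs under ``config.output_dir``: stage-1/2 proximity CSVs, rank-size
    CSV, candidate list, GraphML + edge/node CSVs, a stats JSON and a
    manifest JSON.  All outputs are deterministically ordered; the manifest
    contains no timestamps, so identical config + inputs give byte-identical
    files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if fine_table is None and coarse_table is not None and not config.mapping_path:
        fine_table = coarse_table

    s1 = stage_one(config, table=coarse_table)
    candidates = select_candidates(s1.proximity, config.candidate_rule, config.candidate_param)
    if not candidates:
        raise ValidationError("stage-1 candidate selection produced no surnames")
    s2 = stage_two(config, candidates, table=fine_table if fine_table is not None else coarse_table)

    files: dict[str, Path] = {}
    files["stage1_proximity"] = out / "stage1_proximity.csv"
    s1.proximity.to_dataframe().to_csv(files["stage1_proximity"], index=False, encoding="utf-8")
    files["stage1_rank_size"] = out / "stage1_rank_size.csv"
    s1.rank_size.to_csv(files["stage1_rank_size"], index=False, encoding="utf-8")
    files["candidates"] = out / "candidates.txt"
    files["candidates"].write_text("\n".join(sorted(candidates)) + "\n", encoding="utf-8")
    files["stage2_proximity"] = out / "stage2_proximity.csv"
    s2.proximity.to_dataframe().to_csv(files["stage2_proximity"], index=False, encoding="utf-8")
    if s2.network.number_of_nodes():
        files["network_graphml"] = out / "network.graphml"
        export_graph(s2.network, files["network_graphml"], "graphml")
        files["network_edges"] = out / "network_edges.csv"
        export_graph(s2.network, files["network_edges"], "edgelist")
        files["network_nodes"] = out / "network_nodes.csv"
        export_graph(s2.network, files["network_nodes"], "nodetable")

    stats_payload = {
        "stage1": {"derived_threshold": round(s1.derived_threshold, 12), **s1.counts},
        "candidates": len(candidates),
        "stage2": {**s2.counts},
        "network": s2.stats,
    }
    files["stats"] = out / "stats.json"
    files["stats"].write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )

    manifest = {
        "software": {"name": "surnamespace", "version": __version__},
        "config": config.to_dict(),
        "counts": {"stage1": s1.counts, "stage2": s2.counts},
        "derived": {
            "stage1_threshold": round(s1.derived_threshold, 12),
            "stage2_threshold": config.stage2_threshold,
            "n_candidates": len(candidates),
        },
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(files.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    logger.info("pipeline complete: %d candidates, network n=%d m=%d",
                len(candidates), s2.counts["network_nodes"], s2.counts["network_links"])
    return manifest
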