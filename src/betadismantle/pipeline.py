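"""One-command analysis pipeline.

Runs the whole distance-matrix analysis on community CSVs (or a
synthetic dataset generated on the fly): beta-diversity partition and
summary means, Mantel correlograms of both components against
geographic distance, NMDS of the Jaccard matrix, per-predictor MRM
tables and hierarchical partitioning, per guild.  All randomness flows
from one root seed split per guild and stage, so a report re-run with
the same config is numerically identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .betadiv import (
    BetaPartition,
    beta_partition_matrix,
    bray_curtis_matrix,
    haversine_matrix,
    scalar_distance_matrix,
)
from .core_io import (
    BetadismantleError,
    CommunityMatrix,
    DistanceMatrix,
    DomainError,
    SiteAttributes,
    drop_empty_sites,
    read_community_table,
    read_site_attributes,
    write_distance_matrix,
)
from .inference import HPResult, hierarchical_partition, mrm_table
from .ordination import NMDSResult, nmds
from .spatial import CorrelogramResult, mantel_correlogram
from .synthetic_data import (
    SyntheticConfig,
    fixture_config,
    generate_dataset,
    paper_like_config,
)

__all__ = ["AnalysisReport", "GuildReport", "run_analysis", "load_config",
           "PREDICTOR_NAMES", "build_predictors"]

logger = logging.getLogger("betadismantle")

PREDICTOR_NAMES = ("DIST", "TEMP", "RAIN", "FOR", "AREA", "IMP")

DEFAULTS = {
    "predictors": list(PREDICTOR_NAMES),
    "n_perm": 999,
    "alpha": 0.05,
    "n_classes": None,  # None = Sturges' rule on the pair count
    "nmds_k": 2,
    "nmds_starts": 4,
    "drop_empty_sites": True,
    "seed": 0,
}


class ConfigError(BetadismantleError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML/JSON mapping")
    return cfg


def build_predictors(
    attrs: SiteAttributes,
    forest: CommunityMatrix,
    names: list[str],
) -> dict[str, DistanceMatrix]:
    """Construct the predictor distance matrices for one site set.

    DIST = great-circle centroid distance; TEMP/RAIN = absolute climate
    differences; FOR = Bray-Curtis on forest-type areas; AREA/IMP =
    absolute differences of log forest area / log import value.
    """
    unknown = [n for n in names if n not in PREDICTOR_NAMES]
    if unknown:
        raise ConfigError(f"unknown predictors {unknown}; choose from {PREDICTOR_NAMES}")
    sites = attrs.site_ids
    out: dict[str, DistanceMatrix] = {}
    for name in names:
        if name == "DIST":
            out[name] = haversine_matrix(attrs)
        elif name == "TEMP":
            out[name] = scalar_distance_matrix(attrs.column("temp"), sites)
        elif name == "RAIN":
            out[name] = scalar_distance_matrix(attrs.column("rain"), sites)
        elif name == "AREA":
            out[name] = scalar_distance_matrix(
                attrs.column("forest_area"), sites, transform="log")
        elif name == "IMP":
            out[name] = scalar_distance_matrix(
                attrs.column("import_value"), sites, transform="log")
        elif name == "FOR":
            idx = [forest.site_ids.index(s) for s in sites]
            sub = CommunityMatrix(
                site_ids=sites,
                species_ids=list(forest.species_ids),
                values=forest.values[idx],
                mode="abundance",
                guild_tag=forest.guild_tag,
            )
            out[name] = bray_curtis_matrix(sub)
    return out


@dataclass
class GuildReport:
    guild: str
    dropped_sites: list[str]
    partition: BetaPartition
    mean_beta_rich: float
    mean_beta_3: float
    correlograms: dict[str, CorrelogramResult]  # keys: beta_rich, beta_3
    nmds: NMDSResult
    mrm: dict[str, pd.DataFrame]  # keys: beta_rich, beta_3
    hp: dict[str, HPResult]


@dataclass
class AnalysisReport:
    guilds: dict[str, GuildReport]
    provenance: dict
    out_dir: Path | None


def _stage_rng(root: np.random.SeedSequence, *key: str) -> np.random.Generator:
    # stable across processes (unlike hash()) so reports are reproducible
    h = zlib.crc32("/".join(key).encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(root.entropy), h]))


def _load_inputs(cfg: dict):
    if "synthetic" in cfg:
        s = dict(cfg["synthetic"])
        preset = s.pop("preset", "paper-like")
        seed = s.pop("seed", cfg.get("seed", DEFAULTS["seed"]))
        if preset == "paper-like":
            sc = paper_like_config(seed=seed)
        elif preset == "fixture":
            sc = fixture_config(seed=seed)
        else:
            raise ConfigError(f"unknown synthetic preset {preset!r}")
        if "n_sites" in s:
            sc.n_sites = int(s.pop("n_sites"))
        if s:
            raise ConfigError(f"unknown synthetic options {sorted(s)}")
        ds = generate_dataset(sc, seed=seed)
        return ds.attributes, ds.communities, ds.forest
    try:
        inputs = cfg["inputs"]
        attrs = read_site_attributes(inputs["attributes"])
        forest = read_community_table(inputs["forest"], mode="abundance")
        communities = {
            name: read_community_table(path, mode="incidence", guild_tag=name)
            for name, path in inputs["communities"].items()
        }
    except KeyError as exc:
        raise ConfigError(f"missing config key: {exc}")
    return attrs, communities, forest


def _analyse_guild(
    name: str,
    cm: CommunityMatrix,
    attrs: SiteAttributes,
    forest: CommunityMatrix,
    cfg: dict,
    root: np.random.SeedSequence,
) -> GuildReport:
    dropped: list[str] = []
    if cfg["drop_empty_sites"]:
        cm, dropped = drop_empty_sites(cm)
        if dropped:
            logger.info("guild %s: dropped empty sites %s", name, dropped)
    attrs_g = attrs.reorder(cm.site_ids, allow_extra=True)
    predictors = build_predictors(attrs_g, forest, list(cfg["predictors"]))

    part = beta_partition_matrix(cm)
    d_geo = haversine_matrix(attrs_g)

    components = {"beta_rich": part.beta_rich, "beta_3": part.beta_3}
    correlograms, mrm_tables, hp_results = {}, {}, {}
    for comp, dm in components.items():
        correlograms[comp] = mantel_correlogram(
            dm, d_geo,
            n_classes=cfg["n_classes"],
            n_perm=cfg["n_perm"],
            alpha=cfg["alpha"],
            seed=_stage_rng(root, name, comp, "correlogram"),
        )
        mrm_tables[comp] = mrm_table(
            dm, predictors, n_perm=cfg["n_perm"],
            seed=_stage_rng(root, name, comp, "mrm"),
        )
        hp_results[comp] = hierarchical_partition(dm, predictors)

    nmds_res = nmds(
        part.beta_cc,
        k=cfg["nmds_k"],
        n_starts=cfg["nmds_starts"],
        seed=int(_stage_rng(root, name, "nmds").integers(2**31)),
    )
    return GuildReport(
        guild=name,
        dropped_sites=dropped,
        partition=part,
        mean_beta_rich=part.mean_beta_rich,
        mean_beta_3=part.mean_beta_3,
        correlograms=correlograms,
        nmds=nmds_res,
        mrm=mrm_tables,
        hp=hp_results,
    )


def _write_report(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for name, g in report.guilds.items():
        gdir = out_dir / name
        gdir.mkdir(exist_ok=True)
        write_distance_matrix(g.partition.beta_cc, gdir / "beta_cc.csv")
        write_distance_matrix(g.partition.beta_rich, gdir / "beta_rich.csv")
        write_distance_matrix(g.partition.beta_3, gdir / "beta_3.csv")
        for comp in ("beta_rich", "beta_3"):
            g.correlograms[comp].to_csv(gdir / f"correlogram_{comp}.csv")
            g.mrm[comp].to_csv(gdir / f"mrm_{comp}.csv", index=False,
                               float_format="%.10g")
            g.hp[comp].table.to_csv(gdir / f"hp_{comp}.csv", index=False,
                                    float_format="%.10g")
        g.nmds.write_coords(gdir / "nmds_coords.csv")
        summary_rows.append({
            "guild": name,
            "n_sites": g.partition.beta_cc.n,
            "dropped_sites": ";".join(g.dropped_sites),
            "mean_beta_rich": g.mean_beta_rich,
            "mean_beta_3": g.mean_beta_3,
            "nmds_stress": g.nmds.stress,
        })
    pd.DataFrame(summary_rows).to_csv(out_dir / "summary.csv", index=False,
                                      float_format="%.10g")
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)


def run_analysis(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> AnalysisReport:
    """Run the full pipeline from a config mapping or YAML path.

    The config names either input CSVs (``inputs:`` with ``communities``,
    ``attributes`` and ``forest``) or a ``synthetic:`` block, plus the
    predictor set, ``n_perm``, ``alpha``, ``n_classes`` and ``seed``.
    Writes all tables under ``out_dir`` when given.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULTS, **config}
    if out_dir is None:
        out_dir = cfg.get("output_dir")

    log_handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        log_handlers.append(logging.FileHandler(Path(out_dir) / "run.log", mode="w"))
    logger.setLevel(logging.INFO)
    for h in log_handlers:
        logger.addHandler(h)
    try:
        attrs, communities, forest = _load_inputs(cfg)
        root = np.random.SeedSequence(int(cfg["seed"]))
        guilds = {}
        for name, cm in communities.items():
            logger.info("analysing guild %s (%d sites, %d species)",
                        name, cm.n_sites, cm.n_species)
            try:
                guilds[name] = _analyse_guild(name, cm, attrs, forest, cfg, root)
            except BetadismantleError as exc:
                raise type(exc)(f"[guild {name}] {exc}") from exc
        provenance = {
            "package": "betadismantle",
            "version": __version__,
            "config": {k: v for k, v in cfg.items()},
            "seed": cfg["seed"],
            "numpy": np.__version__,
        }
        report = AnalysisReport(guilds=guilds, provenance=provenance,
                                out_dir=Path(out_dir) if out_dir else None)
        if out_dir is not None:
            _write_report(report, Path(out_dir))
            logger.info("report written to %s", out_dir)
        return report
    finally:
        for h in log_handlers:
            logger.removeHandler(h)
            h.close()
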