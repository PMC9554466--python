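"""End-to-end pipeline: filter -> rarefy -> classify -> per-subcommunity
assembly analyses, with a manifest and deterministic per-stage seeding.

The pipeline operates on a community table plus sample metadata — read
from files or produced by the synthetic generator — and writes every
artifact (TSV/CSV/JSON) into a run directory. One master seed drives the
whole run; each stage derives its own substream from a stable hash of
(master seed, stage name), so stages are reproducible independently of
execution order.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables as tio
from .tables import SampleMetadata
from .classify import classify_regional, classify_local
from .niche import niche_breadth, community_bcom
from .distances import (bray_curtis, geographic_distance,
                        single_covariate_distance, ddr_fit, permanova)
from .nullmodel import beta_deviation
from .ncm import fit_ncm
from .mrm import forward_select, vpa_two_sets, hierarchical_partition
from .pathmodel import PathSpec, fit_path_model
from .simulate import SimConfig, mixed_scenario

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

SOIL_VARS = ("SM", "pH", "TSN", "SAN", "TSP", "TOC")
CLIMATE_VARS = ("MAT", "aridity")
PLANT_VARS = ("PLC", "SLA", "LCN", "LNP", "PHight", "Cwidth", "richness")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run (frozen copy written per run)."""

    output_dir: str = "run"
    community_table: str | None = None   # TSV path; None -> simulate
    metadata: str | None = None          # CSV path
    depth: int = 9080
    min_reads: int = 8
    reps: int = 999                      # null-model replicates
    permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    subcommunities: tuple[str, ...] = ("abundant", "rare")
    collinearity_threshold: float = 0.6
    sim: SimConfig | None = None         # generator settings when simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subcommunities"] = list(self.subcommunities)
        return d


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed and stage name."""
    h = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master, h]).generate_state(1)[0] % (2**31))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _grouped_env_distances(covariates: pd.DataFrame, retained: list[str]):
    """Per-variable standardized distances, bucketed into predictor groups."""
    dists = single_covariate_distance(covariates[retained])
    groups: dict[str, dict] = {"soil": {}, "climate": {}, "plant": {}}
    for name, dm in dists.items():
        if name in SOIL_VARS:
            groups["soil"][name] = dm
        elif name in CLIMATE_VARS:
            groups["climate"][name] = dm
        elif name in PLANT_VARS:
            groups["plant"][name] = dm
    return dists, {k: v for k, v in groups.items() if v}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in fixed order and write artifacts + manifest.

    Returns the run directory. On stage failure a ``FAILED`` marker naming
    the stage and error is left in the directory and the exception
    re-raised; completed artifacts are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": []}
    t_start = time.time()

    def record(stage: str, t0: float, *paths: Path) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     "seed": stage_seed(config.seed, stage)}
        manifest["artifacts"].extend(str(p.relative_to(out)) for p in paths)

    current = "setup"
    try:
        # ------------------------------------------------------------ input
        current = "input"
        t0 = time.time()
        if config.community_table is not None:
            table = tio.read_community_table(config.community_table)
            meta_frame = pd.read_csv(config.metadata)
            meta = SampleMetadata(meta_frame)
        else:
            sim = config.sim or SimConfig(seed=stage_seed(config.seed, "simulate"),
                                          depth=config.depth)
            table, meta = mixed_scenario(sim)
            manifest["sim"] = sim.to_dict()
        meta = meta.aligned_to(table)
        p_table = out / "community_raw.tsv"
        tio.write_community_table(table, p_table)
        meta.frame.to_csv(out / "metadata.csv", index=False)
        record("input", t0, p_table, out / "metadata.csv")

        # ----------------------------------------------------- filter/rarefy
        current = "filter_rarefy"
        t0 = time.time()
        table = tio.filter_low_count_taxa(table, config.min_reads)
        # rarefy to the configured depth, capped at the post-filter minimum
        # (the conventional "rarefy to the shallowest sample")
        eff_depth = int(min(config.depth, table.depth.min()))
        manifest["rarefaction_depth"] = eff_depth
        table = tio.rarefy(table, eff_depth, seed=stage_seed(config.seed, "rarefy"))
        p_rare = out / "community_rarefied.tsv"
        tio.write_community_table(table, p_rare)
        record("filter_rarefy", t0, p_rare)

        # ---------------------------------------------------------- classify
        current = "classify"
        t0 = time.time()
        rel = tio.relative_abundance(table)
        cls = classify_regional(rel)
        p_cls = out / "classification.tsv"
        cls.frame.to_csv(p_cls, sep="\t")
        classify_local(rel).to_csv(out / "local_labels.tsv", sep="\t")
        record("classify", t0, p_cls, out / "local_labels.tsv")

        # -------------------------------------------------------- covariates
        current = "covariates"
        t0 = time.time()
        cov_names = [c for c in (*SOIL_VARS, *CLIMATE_VARS, *PLANT_VARS)
                     if c in meta.frame.columns]
        cov = meta.covariates(cov_names)
        pruned = tio.collinearity_prune(cov, config.collinearity_threshold)
        (out / "collinearity.json").write_text(pruned.to_json())
        geo = geographic_distance(meta)
        geo.to_frame().to_csv(out / "distance_geographic_km.tsv", sep="\t")
        env_dists, env_groups = _grouped_env_distances(cov, pruned.retained)
        plant_bc = None
        if meta.plant_composition is not None:
            plant_bc = bray_curtis(meta.plant_composition)
            plant_bc.kind = "plant_bray_curtis"
        record("covariates", t0, out / "collinearity.json",
               out / "distance_geographic_km.tsv")

        # --------------------------------------------- per-subcommunity loop
        veg = meta.frame["vegetation_type"].to_numpy()
        summary: dict = {}
        for sub in config.subcommunities:
            current = f"subcommunity:{sub}"
            t0 = time.time()
            taxa = cls.taxa(sub) if sub != "all" else list(table.taxon_ids)
            if not taxa:
                summary[sub] = {"n_taxa": 0, "skipped": "no taxa in class"}
                continue
            sub_table = table.subset_taxa(taxa)
            # samples holding no reads of this subcommunity cannot enter
            # pairwise analyses; drop them (recorded in the summary)
            occupied = [s for s, dep in zip(sub_table.sample_ids, sub_table.depth)
                        if dep > 0]
            n_dropped = sub_table.n_samples - len(occupied)
            if len(occupied) < 5:
                summary[sub] = {"n_taxa": sub_table.n_taxa,
                                "skipped": "fewer than 5 occupied samples"}
                continue
            sub_table = sub_table.subset_samples(occupied)
            geo_s = geo.subset(occupied)
            env_groups_s = {g: {k: dm.subset(occupied) for k, dm in grp.items()}
                            for g, grp in env_groups.items()}
            veg_s = meta.frame.set_index("sample_id").loc[
                occupied, "vegetation_type"].to_numpy()
            plant_bc_s = plant_bc.subset(occupied) if plant_bc is not None else None
            sdir = out / sub
            sdir.mkdir(exist_ok=True)
            tio.write_community_table(sub_table, sdir / "community.tsv")

            b = niche_breadth(sub_table)
            bcom = community_bcom(sub_table, b)
            b.to_csv(sdir / "levins_b.tsv", sep="\t")
            bcom.to_csv(sdir / "bcom.tsv", sep="\t")

            bc = bray_curtis(sub_table)
            bc.to_frame().to_csv(sdir / "bray_curtis.tsv", sep="\t")

            dev = beta_deviation(sub_table, reps=config.reps,
                                 seed=stage_seed(config.seed, f"nulldev:{sub}"))
            dev.pairs.to_csv(sdir / "beta_deviation.csv", index=False)
            _write_json(sdir / "beta_deviation_provenance.json",
                        {"reps": dev.reps, "seed": dev.seed,
                         "pool_hash": int(zlib.crc32(sub_table.counts.sum(0).tobytes()))})

            # subcommunity depths vary after subsetting the rarefied table;
            # use the mean subset depth as the neutral community size
            try:
                ncm = fit_ncm(sub_table, N=int(round(sub_table.depth.mean())))
                _write_json(sdir / "ncm.json", ncm.to_dict())
                ncm.taxa.to_csv(sdir / "ncm_taxa.csv", index=False)
                ncm_m, ncm_r2 = ncm.m, ncm.r2
            except ValueError as err:  # e.g. degenerate occupancy
                _write_json(sdir / "ncm.json", {"error": str(err)})
                ncm_m = ncm_r2 = float("nan")

            ddr = ddr_fit(bc, geo_s, permutations=0)
            _write_json(sdir / "ddr.json", vars(ddr))

            try:
                perma = permanova(bc, veg_s, permutations=config.permutations,
                                  seed=stage_seed(config.seed, f"permanova:{sub}"))
                _write_json(sdir / "permanova_vegetation.json", vars(perma))
                perma_p = perma.p_value
            except ValueError as err:  # e.g. a vegetation type left with 1 sample
                _write_json(sdir / "permanova_vegetation.json", {"error": str(err)})
                perma_p = float("nan")

            # MRM + VPA + HP on the beta-deviation matrix
            dev_m = dev.deviation_matrix()
            space_set = {"geo_km": geo_s}
            env_set = {
                name: dm for g in env_groups_s.values() for name, dm in g.items()
            }
            selected, final = forward_select(
                dev_m, {**space_set, **env_set}, alpha=config.alpha,
                permutations=config.permutations,
                seed=stage_seed(config.seed, f"mrm:{sub}"),
            )
            mrm_doc = {"selected": selected}
            if final is not None:
                mrm_doc.update(r2=final.r2, model_p=final.model_p,
                               coefficients=final.coefficients.to_dict(),
                               coef_p=final.coef_p.to_dict())
            _write_json(sdir / "mrm_forward_selection.json", mrm_doc)

            vpa = vpa_two_sets(dev_m, space_set, env_set)
            _write_json(sdir / "vpa.json", vars(vpa))
            hp = hierarchical_partition(dev_m, {"space": space_set, **env_groups_s})
            _write_json(sdir / "hierarchical_partitioning.json",
                        {"contributions": hp.contributions, "r2_full": hp.r2_full})

            # path model: space -> (soil, climate, plant) -> deviation
            path_data = pd.DataFrame({"space": geo_s.condensed()})
            for gname, g in env_groups_s.items():
                stacked = np.vstack([dm.condensed() for dm in g.values()])
                path_data[gname] = stacked.mean(axis=0)
            if plant_bc_s is not None and sub == "rare":
                path_data["plant_composition"] = plant_bc_s.condensed()
            path_data["fungal_deviation"] = dev_m.condensed()
            edges = [("space", g) for g in env_groups] + \
                    [(g, "fungal_deviation") for g in env_groups] + \
                    [("space", "fungal_deviation")]
            if "plant_composition" in path_data:
                edges += [("space", "plant_composition"),
                          ("plant_composition", "fungal_deviation")]
            pfit = fit_path_model(PathSpec(edges=edges), path_data)
            _write_json(sdir / "path_model.json", pfit.to_dict())

            summary[sub] = {
                "n_taxa": sub_table.n_taxa,
                "n_samples": sub_table.n_samples,
                "n_samples_dropped": n_dropped,
                "mean_deviation": float(np.nanmean(dev.deviations)),
                "ncm_m": ncm_m, "ncm_r2": ncm_r2,
                "ddr_slope_per_km": ddr.slope,
                "mean_bcom": float(bcom.mean()),
                "vpa": vpa.fractions(),
                "hp": hp.contributions,
                "path_r2": pfit.outcome_r2,
                "permanova_p": perma_p,
            }
            record(f"subcommunity:{sub}", t0)

        current = "finalize"
        _write_json(out / "summary.json", summary)
        manifest["total_seconds"] = round(time.time() - t_start, 3)
        manifest["n_samples"] = table.n_samples
        manifest["n_taxa_after_filter"] = table.n_taxa
        _write_json(out / "manifest.json", manifest)
        return out
    except Exception as exc:  # leave a marker, keep partial outputs
        (out / "FAILED").write_text(f"stage={current}\n{type(exc).__name__}: {exc}\n")
        raise
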