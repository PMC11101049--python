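"""End-to-end orchestration of the metacommunity analysis.

Stages: spatial basis construction → per-species five-subset forward
selection → deviance partitioning → Moran's I → cross-species trait
models → per-lake elevation analyses. Each stage is also callable on
its own; :func:`run_all` chains them and writes the result tables
(CSV), a machine-readable ``summary.json``, and the configuration used
(YAML) for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spatial, traits as traits_mod, trait_models
from .glm import SelectedModel, forward_select
from .moran import morans_i
from .partition import SUBSETS, partition, partition_table

log = logging.getLogger("metanema")

__all__ = ["RunConfig", "SpatialStage", "build_spatial", "species_models",
           "partition_species", "moran_table", "run_all"]

NON_ENV_COLS = ("lake_id", "lat", "lon", "altitude_m")


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    lakes_csv: str = "lakes.csv"
    counts_csv: str = "counts.csv"
    morphometry_csv: str | None = "morphometry.csv"
    outdir: str = "results"
    cut_large: float = 25000.0
    cut_small: float = 1000.0
    alpha: float = 0.05
    delta_criterion: float = 4.0
    boundary_eps: float = 1e-10
    min_lakes: int = 4
    min_adults: int = 6
    seed: int = 0
    mcmc: bool = False
    removal_analyses: bool = True

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


@dataclass
class SpatialStage:
    coords: spatial.PlanarCoords
    distances: spatial.DistanceMatrix
    threshold: float
    basis: spatial.SpatialBasis
    connectivity: spatial.ConnectivityMatrix


def build_spatial(lakes: pd.DataFrame, cut_large: float = 25000.0,
                  cut_small: float = 1000.0) -> SpatialStage:
    """Coordinates → distances → MST threshold → PCNM → connectivity."""
    coords = spatial.project_to_cartesian(lakes)
    d = spatial.distance_matrix(coords)
    t = spatial.mst_threshold(d)
    basis = spatial.classify_scale(spatial.pcnm(d, t), cut_large=cut_large, cut_small=cut_small)
    w = spatial.connectivity(d, t)
    return SpatialStage(coords=coords, distances=d, threshold=t, basis=basis, connectivity=w)


def _design_pool(lakes: pd.DataFrame, stage: SpatialStage) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """All candidate columns plus the subset → column-name map."""
    env_cols = [c for c in lakes.columns if c not in NON_ENV_COLS]
    env = lakes.set_index("lake_id")[env_cols].astype(float)
    alt = lakes.set_index("lake_id")[["altitude_m"]].astype(float)
    pcnms = stage.basis.frame()
    pool = pd.concat([pcnms, env, alt], axis=1)
    subsets = {label: list(stage.basis.axes_for_scale(label).columns)
               for label in ("large", "medium", "small")}
    subsets["environment"] = env_cols
    subsets["altitude"] = ["altitude_m"]
    return pool, subsets


def species_models(y: np.ndarray, pool: pd.DataFrame, subsets: dict[str, list[str]],
                   species: str, alpha: float = 0.05, eps: float = 1e-10) -> dict[str, SelectedModel]:
    """Run forward selection within each of the five predictor subsets."""
    out = {}
    for name in SUBSETS:
        out[name] = forward_select(y, pool[subsets[name]], species=species,
                                   subset_name=name, alpha=alpha, eps=eps)
    return out


def partition_species(presence: pd.DataFrame, pool: pd.DataFrame, subsets: dict[str, list[str]],
                      species_list: list[str], alpha: float = 0.05,
                      eps: float = 1e-10):
    """Selections and adjusted-D² partitions for every species."""
    selections, partitions, rows = {}, [], []
    for sp in species_list:
        y = presence[sp].to_numpy(dtype=float)
        sel = species_models(y, pool, subsets, sp, alpha=alpha, eps=eps)
        selections[sp] = sel
        partitions.append(partition(sp, sel, y, pool, eps=eps))
        for name in SUBSETS:
            rows.append({"species": sp, "subset": name,
                         "selected": ";".join(sel[name].selected),
                         "adj_d2": sel[name].fit.adj_d2 * 100.0})
    return selections, partition_table(partitions), pd.DataFrame(rows)


def moran_table(presence: pd.DataFrame, w: spatial.ConnectivityMatrix,
                species_list: list[str]) -> pd.DataFrame:
    rows = []
    for sp in species_list:
        r = morans_i(presence[sp].to_numpy(dtype=float), w, species=sp)
        rows.append({"taxon": sp, "I": r.observed, "expected": r.expected,
                     "sd": r.sd, "p": r.p_value})
    return pd.DataFrame(rows).set_index("taxon")


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())

    lakes = spatial.load_lakes(config.lakes_csv)
    counts = pd.read_csv(config.counts_csv, dtype={"lake_id": str, "taxon": str})
    if counts.empty:
        raise ValueError("species counts table is empty")
    morph = pd.read_csv(config.morphometry_csv) if config.morphometry_csv else None

    stage = build_spatial(lakes, cut_large=config.cut_large, cut_small=config.cut_small)
    log.info("spatial basis: %d retained axes, threshold %.2f km", stage.basis.n_axes, stage.threshold)

    traits = traits_mod.species_filters(
        traits_mod.species_traits(counts, morph), min_lakes=config.min_lakes,
        min_adults=config.min_adults)
    for taxon, row in traits.iterrows():
        if not row["model_eligible"]:
            log.info("excluded from distribution models: %s (freq=%d, adults=%d)",
                     taxon, row["freq"], row["adults"])
    traits.to_csv(outdir / "species_traits.csv")

    lake_ids = list(lakes["lake_id"])
    presence = traits_mod.presence_matrix(counts, lake_ids)
    eligible = [t for t in traits.index[traits["model_eligible"]] if t in presence.columns]
    if not eligible:
        raise ValueError("no species pass the analysis filters")

    pool, subsets = _design_pool(lakes, stage)
    selections, partitions, selection_report = partition_species(
        presence, pool, subsets, eligible, alpha=config.alpha, eps=config.boundary_eps)
    selection_report.to_csv(outdir / "selection_report.csv", index=False)
    partitions.to_csv(outdir / "deviance_partition.csv")
    audit = [dataclasses.asdict(rec) for sp in eligible
             for name in SUBSETS for rec in selections[sp][name].audit]
    with open(outdir / "selection_audit.jsonl", "w") as fh:
        for rec in audit:
            fh.write(json.dumps(rec) + "\n")

    moran = moran_table(presence, stage.connectivity, eligible)
    moran.to_csv(outdir / "moran.csv")

    cross = trait_models.cross_species_zoib(
        traits.loc[eligible], partitions, criterion="dic" if config.mcmc else "bic",
        delta=config.delta_criterion, mcmc=config.mcmc, seed=config.seed)
    cross_df = pd.DataFrame([{"trait": r.trait, "subset": r.subset, "chosen": r.choice.chosen,
                              **{f"crit_{k}": v for k, v in r.choice.values.items()},
                              "rho": r.rho, "p": r.p, "n_clamped": r.n_clamped}
                             for r in cross])
    cross_df.to_csv(outdir / "cross_species_zoib.csv", index=False)

    gam_rows = []
    for trait_col in ("afp", "ofp", "body_ug"):
        tr = traits.loc[eligible, trait_col]
        fits = {"full": trait_models.gam_moran(moran["I"], tr)}
        if config.removal_analyses:
            side = "max" if trait_col == "body_ug" else "min"
            fits["extreme_removed"] = trait_models.gam_moran(
                moran["I"], tr, remove=trait_models.most_extreme(tr.dropna(), side))
        for variant, f in fits.items():
            gam_rows.append({"trait": trait_col, "variant": variant, "edf": f.edf,
                             "adj_d2_pct": f.adj_d2 * 100.0, "bic": f.bic, "bic_null": f.bic_null,
                             "parametric_p": f.parametric_p, "nonparametric_p": f.nonparametric_p,
                             "chisq_p": f.chisq_p, "n": f.n})
    gam_df = pd.DataFrame(gam_rows)
    gam_df.to_csv(outdir / "gam_moran.csv", index=False)

    abund = trait_models.abundance_checks(counts, partitions, moran["I"], n_lakes=len(lake_ids))
    abund.to_csv(outdir / "abundance_checks.csv", index=False)

    lake_summary = traits_mod.lake_trait_summary(counts, traits, min_adults=config.min_adults)
    lake_summary.to_csv(outdir / "lake_traits.csv")
    elev = trait_models.elevation_zoib(lake_summary, lakes, criterion="dic" if config.mcmc else "bic",
                                       delta=config.delta_criterion, mcmc=config.mcmc,
                                       seed=config.seed)
    elev.to_csv(outdir / "elevation_zoib.csv", index=False)

    summary = {
        "n_lakes": len(lake_ids),
        "n_taxa": int(len(traits)),
        "n_eligible": len(eligible),
        "mst_threshold_km": stage.threshold,
        "n_pcnm_retained": int(stage.basis.n_axes),
        "scale_counts": {lab: int(stage.basis.scale_label.count(lab))
                         for lab in ("large", "medium", "small")},
        "n_moran_significant": int((moran["p"] < 0.05).sum()),
        "total_adj_d2_range": [float(partitions["total"].min()), float(partitions["total"].max())],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"summary": summary, "traits": traits, "partitions": partitions, "moran": moran,
            "cross_species": cross_df, "gam": gam_df, "elevation": elev,
            "selection_report": selection_report, "spatial": stage}
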