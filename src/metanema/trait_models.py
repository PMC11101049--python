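"""Cross-species and per-lake trait analyses.

Relates each species' female proportion and body size to the deviance
fractions explained by the spatial/environmental predictor subsets and
to its Moran's I:

* zero-one-inflated beta regression of unshared adj-D² (divided by 100)
  on the trait, with the Δ≥4 information-criterion rule and a Spearman
  rank correlation as a complementary check;
* a Gaussian df-4 smoothing-spline GAM of Moran's I on the trait;
* Spearman screens of species abundance against the deviance fractions
  and Moran's I;
* per-lake female proportion and relative body size against altitude
  (zoib again, for comparability across analyses).

Covariates are standardized before entering the zoib fits (the spanned
model space, hence the selection, is invariant to affine maps of the
covariate; the optimizer conditioning is not). Negative unshared
fractions — legal outputs of deviance partitioning — are clamped to 0
before the zoib, whose support is [0, 1]; the count of clamped values
is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import GamFit, gam_fit
from .zoib import ModelChoice, select_zoib

__all__ = ["spearman", "cross_species_zoib", "gam_moran", "abundance_checks",
           "elevation_zoib", "most_extreme"]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p (average ranks, t approximation).

    Missing pairs are dropped; a constant vector is rejected (ranks
    carry no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("unequal lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def most_extreme(values: pd.Series, side: str) -> str:
    """Index label of the extreme observation (``min`` or ``max``)."""
    if side == "min":
        return values.idxmin()
    if side == "max":
        return values.idxmax()
    raise ValueError("side must be 'min' or 'max'")


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


@dataclass
class TraitSubsetResult:
    """One trait × predictor-subset comparison."""

    trait: str
    subset: str
    choice: ModelChoice
    rho: float
    p: float
    n_clamped: int


def cross_species_zoib(traits: pd.DataFrame, partitions: pd.DataFrame,
                       trait_cols: tuple[str, ...] = ("afp", "ofp", "body_ug"),
                       subsets: tuple[str, ...] = ("large", "medium", "small", "environment"),
                       criterion: str = "bic", delta: float = 4.0,
                       mcmc: bool = False, seed: int = 0) -> list[TraitSubsetResult]:
    """zoib + Spearman of each unshared adj-D² column on each trait.

    ``partitions`` columns ``unshared_<subset>`` are percent values;
    they are divided by 100 and negatives clamped to 0. Altitude is not
    offered as a subset here (its unshared fraction is dropped from the
    comparative stage).
    """
    common = traits.index.intersection(partitions.index)
    results = []
    for subset in subsets:
        raw = partitions.loc[common, f"unshared_{subset}"].to_numpy(dtype=float) / 100.0
        n_clamped = int((raw < 0).sum())
        if n_clamped:
            warnings.warn(f"{subset}: {n_clamped} negative unshared value(s) clamped to 0", stacklevel=2)
        y = np.clip(raw, 0.0, 1.0)
        for trait in trait_cols:
            x = traits.loc[common, trait].to_numpy(dtype=float)
            choice = select_zoib(y, _standardize(x), criterion=criterion, delta=delta,
                                 mcmc=mcmc, seed=seed)
            rho, p = spearman(x, raw)  # ranks use the unclamped fractions
            results.append(TraitSubsetResult(trait=trait, subset=subset, choice=choice,
                                             rho=rho, p=p, n_clamped=n_clamped))
    return results


def gam_moran(moran_i: pd.Series, trait: pd.Series, target_df: float = 4.0,
              remove: str | None = None) -> GamFit:
    """df-4 spline GAM of Moran's I on a trait, optionally after
    removing one species (e.g. the most extreme trait value)."""
    df = pd.concat([moran_i.rename("I"), trait.rename("x")], axis=1).dropna()
    if remove is not None:
        df = df.drop(index=remove)
    return gam_fit(df["I"].to_numpy(), df["x"].to_numpy(), target_df=target_df)


def abundance_checks(counts: pd.DataFrame, partitions: pd.DataFrame,
                     moran_i: pd.Series, n_lakes: int) -> pd.DataFrame:
    """Spearman screen: abundance summaries vs deviance fractions and I.

    Abundance per species is summarised as the mean over occupied lakes
    (zeros excluded), the mean over all lakes (zeros included), and the
    per-lake maximum. Each is correlated with every unshared adj-D²
    column and with Moran's I.
    """
    species = partitions.index
    grp = counts[counts["abundance"] > 0].groupby("taxon")["abundance"]
    summaries = pd.DataFrame({
        "mean_excl_zero": grp.sum() / grp.count(),
        "mean_incl_zero": grp.sum() / n_lakes,
        "max": grp.max(),
    }).reindex(species)
    targets = {c: partitions[c] for c in partitions.columns if c.startswith("unshared_")}
    targets["moran_i"] = moran_i.reindex(species)
    rows = []
    for aname, avals in summaries.items():
        for tname, tvals in targets.items():
            rho, p = spearman(avals.to_numpy(dtype=float),
                              tvals.reindex(species).to_numpy(dtype=float))
            rows.append({"abundance": aname, "target": tname, "rho": rho, "p": p})
    return pd.DataFrame(rows)


def elevation_zoib(lake_summary: pd.DataFrame, lakes: pd.DataFrame,
                   columns: tuple[str, ...] = ("afp_mean_across_species", "fp_abundance_weighted",
                                               "size_relative_mean_across_species",
                                               "size_relative_abundance_weighted"),
                   criterion: str = "bic", delta: float = 4.0,
                   mcmc: bool = False, seed: int = 0) -> pd.DataFrame:
    """Per-lake traits against altitude: zoib Δ-rule plus Spearman.

    Rows with missing trait values (lakes failing the adult-count
    eligibility rules) are dropped per column; the n used and the
    altitudinal range covered are reported with each result.
    """
    alt = lakes.set_index("lake_id")["altitude_m"]
    rows = []
    for col in columns:
        y = lake_summary[col].dropna()
        x = alt.reindex(y.index).to_numpy(dtype=float)
        yv = np.clip(y.to_numpy(dtype=float), 0.0, 1.0)
        choice = select_zoib(yv, _standardize(x), criterion=criterion, delta=delta,
                             mcmc=mcmc, seed=seed)
        rho, p = spearman(x, yv)
        rows.append({"trait": col, "n_lakes": len(yv),
                     "alt_min": float(x.min()), "alt_max": float(x.max()),
                     "chosen": choice.chosen,
                     **{f"crit_{k}": v for k, v in choice.values.items()},
                     "rho": rho, "p": p})
    return pd.DataFrame(rows)
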