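"""Species trait tables: occurrence, abundance, sex counts, body mass.

The central objects are a long-format counts table
(``lake_id, taxon, abundance, adults, females``) and a morphometry table
(``taxon, L_um, a_um``) from which per-species traits are derived:

* frequency of occurrence (number of lakes occupied),
* AFP — average female proportion (mean of per-lake proportions over
  lakes where adults of the species were found),
* OFP — overall female proportion (pooled females / pooled adults),
* body mass B in μg by Andrássy's formula B = L·a²/(1.6·10⁶).

Female proportion is a colonization trait here: parthenogenetic species
(female proportion near 1) can found a population from a single
immigrant, so a high female proportion is expected to relax dispersal
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "andrassy_mass",
    "species_traits",
    "female_proportions",
    "species_filters",
    "lake_trait_summary",
    "presence_matrix",
]


def andrassy_mass(length_um: float, diam_um: float) -> float:
    """Nematode fresh weight (μg) from length and greatest diameter (μm)."""
    if length_um <= 0 or diam_um <= 0:
        raise ValueError("length and diameter must be positive")
    return length_um * diam_um**2 / 1.6e6


def _validate_counts(counts: pd.DataFrame) -> None:
    for col in ("lake_id", "taxon", "abundance", "adults", "females"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    bad = counts[(counts["females"] > counts["adults"]) | (counts["adults"] > counts["abundance"])]
    if len(bad):
        raise ValueError(f"count ordering violated (females ≤ adults ≤ abundance) for: "
                         f"{bad[['lake_id', 'taxon']].values.tolist()[:5]}")
    if (counts[["abundance", "adults", "females"]] < 0).any().any():
        raise ValueError("negative counts")


def female_proportions(counts: pd.DataFrame, taxon: str) -> tuple[float, float]:
    """(AFP, OFP) for one taxon from the long counts table.

    AFP averages per-lake proportions over lakes with ≥1 adult of the
    taxon; OFP pools counts across lakes. NaN (flagged missing) if the
    taxon has no adults anywhere.
    """
    sub = counts[(counts["taxon"] == taxon) & (counts["adults"] >= 1)]
    if len(sub) == 0 or sub["adults"].sum() == 0:
        return float("nan"), float("nan")
    afp = float((sub["females"] / sub["adults"]).mean())
    ofp = float(sub["females"].sum() / sub["adults"].sum())
    return afp, ofp


def species_traits(counts: pd.DataFrame, morphometry: pd.DataFrame | None = None,
                   exclude: set[str] | frozenset[str] = frozenset()) -> pd.DataFrame:
    """Per-species trait table (one row per taxon).

    Columns: freq, abundance, adults, afp, ofp, body_ug, excluded.
    ``exclude`` marks taxa carried in the data model but omitted from
    statistical treatment (e.g. parasitic families not determined to
    species, indeterminate individuals). Body mass comes from a
    ``body_ug`` column in ``morphometry`` when present, else from
    Andrássy's formula on ``L_um``/``a_um``.
    """
    _validate_counts(counts)
    present = counts[counts["abundance"] > 0]
    rows = []
    for taxon, grp in present.groupby("taxon", sort=True):
        afp, ofp = female_proportions(counts, taxon)
        rows.append({
            "taxon": taxon,
            "freq": int((grp["abundance"] > 0).sum()),
            "abundance": int(grp["abundance"].sum()),
            "adults": int(grp["adults"].sum()),
            "afp": afp,
            "ofp": ofp,
            "excluded": taxon in exclude,
        })
    traits = pd.DataFrame(rows).set_index("taxon")
    if morphometry is not None:
        morph = morphometry.set_index("taxon")
        if "body_ug" in morph.columns:
            traits["body_ug"] = morph["body_ug"].reindex(traits.index)
        else:
            traits["body_ug"] = [
                andrassy_mass(morph.loc[t, "L_um"], morph.loc[t, "a_um"]) if t in morph.index else np.nan
                for t in traits.index
            ]
    else:
        traits["body_ug"] = np.nan
    return traits


def species_filters(traits: pd.DataFrame, min_lakes: int = 4, min_adults: int = 6) -> pd.DataFrame:
    """Eligibility flags for downstream analyses.

    ``model_eligible``: distribution models and Moran's I require
    occupancy of ≥ ``min_lakes`` lakes AND ≥ ``min_adults`` adults
    overall. ``fp_eligible``: female-proportion statistics require only
    the adult minimum. Excluded taxa fail both.
    """
    out = traits.copy()
    ok = ~out["excluded"]
    out["model_eligible"] = ok & (out["freq"] >= min_lakes) & (out["adults"] >= min_adults)
    out["fp_eligible"] = ok & (out["adults"] >= min_adults)
    return out


def lake_trait_summary(counts: pd.DataFrame, traits: pd.DataFrame, min_adults: int = 6) -> pd.DataFrame:
    """Per-lake community trait summary.

    * ``afp_mean_across_species``: mean of per-species female
      proportions at the lake, over species with ≥ ``min_adults``
      adults *in that lake* (missing if none qualifies);
    * ``fp_abundance_weighted``: pooled females/adults over all species
      at the lake, missing unless the lake holds ≥ ``min_adults``
      adults in total;
    * ``size_mean_across_species`` / ``size_abundance_weighted``: body
      mass (μg) averaged over species present, unweighted or weighted
      by abundance;
    * ``size_relative_*``: the two size summaries divided by their
      maximum across lakes, so the largest lake scores exactly 1 (this
      is what makes body size admissible in a zero-one-inflated beta
      regression).
    """
    _validate_counts(counts)
    excl = set(traits.index[traits["excluded"]]) if "excluded" in traits.columns else set()
    use = counts[(counts["abundance"] > 0) & ~counts["taxon"].isin(excl)].copy()
    size = traits["body_ug"] if "body_ug" in traits.columns else pd.Series(dtype=float)
    rows = []
    for lake, grp in use.groupby("lake_id", sort=True):
        qual = grp[grp["adults"] >= min_adults]
        afp_mean = float((qual["females"] / qual["adults"]).mean()) if len(qual) else np.nan
        tot_ad = grp["adults"].sum()
        fp_w = float(grp["females"].sum() / tot_ad) if tot_ad >= min_adults else np.nan
        sizes = size.reindex(grp["taxon"]).to_numpy(dtype=float)
        ab = grp["abundance"].to_numpy(dtype=float)
        ok = np.isfinite(sizes)
        s_mean = float(np.mean(sizes[ok])) if ok.any() else np.nan
        s_w = float(np.sum(sizes[ok] * ab[ok]) / np.sum(ab[ok])) if ok.any() else np.nan
        rows.append({"lake_id": lake, "afp_mean_across_species": afp_mean,
                     "fp_abundance_weighted": fp_w,
                     "size_mean_across_species": s_mean,
                     "size_abundance_weighted": s_w})
    out = pd.DataFrame(rows).set_index("lake_id")
    for col in ("size_mean_across_species", "size_abundance_weighted"):
        mx = out[col].max()
        out[col.replace("size", "size_relative")] = out[col] / mx if mx > 0 else np.nan
    return out


def presence_matrix(counts: pd.DataFrame, lake_ids: list[str]) -> pd.DataFrame:
    """Lakes × taxa 0/1 presence matrix aligned to ``lake_ids`` order."""
    _validate_counts(counts)
    pres = (counts.pivot_table(index="lake_id", columns="taxon", values="abundance",
                               aggfunc="sum", fill_value=0) > 0).astype(int)
    return pres.reindex(lake_ids, fill_value=0)
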