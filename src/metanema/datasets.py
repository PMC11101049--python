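"""Bundled reference tables from a 75-lake Pyrenean nematode survey.

``species_survey`` is the published species-level summary: frequency of
occurrence, total abundance, adult count, average and overall female
proportion (AFP/OFP), Andrássy body mass (μg), and — for the 20 species
meeting the ≥4-lakes/≥6-adults analysis filters — Moran's I under the
MST-threshold binary connectivity (``moran_sig`` marks the four species
significant at P < 0.05). Mermithidae (parasitic, not determined to
species) and indeterminate individuals are carried but flagged
``excluded``.

``deviance_partition`` is the matching species × fraction table of the
adjusted-D² partition (percent): total, shared, and the unshared
fractions of the five predictor subsets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["species_survey", "deviance_partition", "analysis_set", "EXCLUDED_TAXA"]

EXCLUDED_TAXA = frozenset({"Mermithidae", "Indeterminate"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("metanema.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def species_survey() -> pd.DataFrame:
    """Species-level survey summary, indexed by taxon."""
    df = _read("species_survey.csv").set_index("taxon")
    df["excluded"] = df.index.isin(EXCLUDED_TAXA)
    return df


def deviance_partition() -> pd.DataFrame:
    """Adjusted-D² partition (percent) for the 20 analysed species."""
    return _read("deviance_partition.csv").set_index("species")


def analysis_set(min_lakes: int = 4, min_adults: int = 6) -> pd.DataFrame:
    """The survey rows passing the distribution-model filters."""
    df = species_survey()
    keep = (~df["excluded"]) & (df["freq"] >= min_lakes) & (df["adults"] >= min_adults)
    return df[keep]
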