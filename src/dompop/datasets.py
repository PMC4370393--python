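"""Loaders for the packaged study tables of the *Lilium regale* ISSR survey.

Three small fixtures ship with the package: the eight sampling sites with
their coordinates and sample sizes, the ten-primer marker panel summary, and
the published population-by-population matrix holding Nei's unbiased genetic
distance below the diagonal and pairwise Fst above it.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core import DistanceMatrix, PopulationSite, parse_dms

__all__ = [
    "POPULATION_ORDER",
    "load_sampling_sites",
    "load_primer_table",
    "load_nei_distances",
    "load_pairwise_fst",
]

#: Population order used by the study's diversity and distance tables.
POPULATION_ORDER = ("YMF", "FHB", "SDG", "SEG", "XV", "TF", "WZT", "SP")


def _read(name: str) -> pd.DataFrame:
    with resources.files("dompop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_sampling_sites() -> list[PopulationSite]:
    """The eight sampled populations with decimal-degree coordinates."""
    df = _read("sampling_sites.csv")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            PopulationSite(
                name=row.population,
                site=row.site,
                longitude=parse_dms(row.longitude),
                latitude=parse_dms(row.latitude),
                altitude=None if pd.isna(row.altitude_m) else float(row.altitude_m),
                n_sampled=int(row.n_sampled),
            )
        )
    return sites


def load_primer_table() -> pd.DataFrame:
    """Published per-primer marker summary (10 ISSR primers, 180 bands)."""
    return _read("primer_table.csv")


def _load_halves() -> tuple[DistanceMatrix, DistanceMatrix]:
    df = _read("population_distances.csv").set_index("population")
    labels = list(df.index)
    vals = df.to_numpy(dtype=float)
    lower = np.tril(np.nan_to_num(vals), k=-1)
    upper = np.triu(np.nan_to_num(vals), k=1)
    nei = DistanceMatrix(labels, lower + lower.T, units="nei-distance")
    fst = DistanceMatrix(labels, upper + upper.T, units="fst")
    return nei, fst


def load_nei_distances() -> DistanceMatrix:
    """Nei's unbiased genetic distances among the 8 populations."""
    return _load_halves()[0]


def load_pairwise_fst() -> DistanceMatrix:
    """Pairwise Fst among the 8 populations."""
    return _load_halves()[1]
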