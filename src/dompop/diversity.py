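"""Within-population genetic diversity from dominant-marker band data.

Allele-frequency based statistics use the square-root null-allele estimate
q = sqrt(1 - band frequency): Nei's gene diversity h = 1 - p^2 - q^2, the
effective number of alleles Ne = 1/(p^2 + q^2) = 1/(1 - h), and Shannon's
information index I = -p ln p - q ln q. The observed number of alleles at a
locus is 2 when both band states occur, else 1. Expected heterozygosity is
computed on band states (haploid coding) with the small-sample correction
n/(n-1), the convention of dominant-data diversity software; it therefore
exceeds the allele-based h at polymorphic loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, BinaryMarkerMatrix
from .informativeness import _entropy2, null_allele_frequency

__all__ = [
    "locus_diversity",
    "observed_alleles",
    "expected_heterozygosity_band",
    "population_diversity",
]


def locus_diversity(q):
    """Per-locus (h, Ne, I) from the null-allele frequency q."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    p = 1.0 - q
    h = 1.0 - p**2 - q**2
    ne = 1.0 / (p**2 + q**2)
    i = _entropy2(p)
    return h, ne, i


def observed_alleles(band_freq):
    """2 if both band states occur (0 < band frequency < 1), else 1."""
    bf = np.asarray(band_freq, dtype=float)
    return np.where((bf > 0) & (bf < 1), 2, 1)


def expected_heterozygosity_band(band_freq, n: int):
    """Unbiased band-state gene diversity (n/(n-1)) * (1 - fb^2 - (1-fb)^2)."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    bf = np.asarray(band_freq, dtype=float)
    return (n / (n - 1.0)) * (1.0 - bf**2 - (1.0 - bf) ** 2)


def _scope_stats(m: BinaryMarkerMatrix, rows: np.ndarray | None) -> dict[str, float]:
    sub = m.calls if rows is None else m.calls[rows]
    n = sub.shape[0]
    scored = (sub != MISSING).sum(axis=0)
    if (scored == 0).any():
        raise ValueError("locus with no scored calls in scope")
    bf = (sub == 1).sum(axis=0) / scored
    q = null_allele_frequency(bf)
    h, ne, i = locus_diversity(q)
    # per-individual harmonic alternatives are not used: all-loci arithmetic
    # means, monomorphic loci contributing zeros, as in POPGENE-style reports
    return {
        "n": n,
        "mean_observed_alleles": float(observed_alleles(bf).mean()),
        "mean_effective_alleles": float(ne.mean()),
        "nei_h": float(h.mean()),
        "shannon_I": float(i.mean()),
        "He_band": float(expected_heterozygosity_band(bf, n).mean()),
    }


def population_diversity(m: BinaryMarkerMatrix) -> pd.DataFrame:
    """Per-population diversity plus ``Mean`` and pooled ``Species`` rows.

    ``Mean`` is the unweighted mean over populations; ``Species`` treats all
    individuals as one population. Requires >= 2 individuals per population.
    """
    records: dict[str, dict[str, float]] = {}
    for pop in m.population_labels:
        rows = m.population_rows(pop)
        if rows.size < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        records[pop] = _scope_stats(m, rows)
    df = pd.DataFrame.from_dict(records, orient="index")
    mean_row = df.drop(columns=["n"]).mean()
    species = _scope_stats(m, None)
    df.loc["Mean"] = {"n": df["n"].mean(), **mean_row.to_dict()}
    df.loc["Species"] = species
    df.index.name = "population"
    return df
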