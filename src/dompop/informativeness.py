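"""Per-locus and per-primer marker informativeness statistics.

For a dominant biallelic locus the observable is the band frequency; under
Hardy-Weinberg equilibrium the band-absence frequency equals q^2, so the
null-allele frequency is estimated as q = sqrt(1 - band frequency) and the
dominant-allele frequency as p = 1 - q. The polymorphic information content
is PIC = 1 - p^2 - q^2 = 2pq (maximal 0.5 at q = 0.5, i.e. band frequency
0.75); the marker index of a primer is its mean PIC times its number of
polymorphic loci; Shannon's H' is the two-state band entropy
-p ln p - (1-p) ln(1-p) evaluated at the band frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMarkerMatrix, PrimerPanel

__all__ = [
    "null_allele_frequency",
    "band_frequency",
    "pic",
    "marker_index",
    "percent_polymorphic",
    "shannon_band",
    "PrimerReport",
    "primer_report",
]


def null_allele_frequency(band_freq):
    """Estimate the recessive (null) allele frequency q = sqrt(1 - band_freq).

    Follows from band absence being the null homozygote under HWE: the
    frequency of band-absent individuals is q^2.
    """
    bf = np.asarray(band_freq, dtype=float)
    if np.any((bf < 0) | (bf > 1)):
        raise ValueError("band frequency must lie in [0, 1]")
    return np.sqrt(1.0 - bf)


def band_frequency(m: BinaryMarkerMatrix, locus: str, population: str | None = None) -> float:
    """Proportion of non-missing calls showing the band at ``locus``.

    ``population=None`` pools all individuals; otherwise the scope is one
    population.
    """
    j = m.locus_ids.index(locus)
    rows = None if population is None else m.population_rows(population)
    return float(m.band_frequencies(rows)[j])


def pic(band_freq):
    """Polymorphic information content 1 - p^2 - q^2 of a dominant locus."""
    q = null_allele_frequency(band_freq)
    p = 1.0 - q
    return 1.0 - p**2 - q**2


def percent_polymorphic(n_polymorphic: int, n_total: int) -> float:
    """Percentage of polymorphic loci, truncated to one decimal place.

    Truncation (not rounding) is the printing convention of the classic
    dominant-marker reports this mirrors: 21/22 prints 95.4, 15/16 prints
    93.7, 176/180 prints 97.7.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return np.floor(1000.0 * n_polymorphic / n_total) / 10.0


def marker_index(mean_pic: float, n_polymorphic: int) -> float:
    """Marker index MI = mean PIC x number of polymorphic loci."""
    if n_polymorphic < 0:
        raise ValueError("n_polymorphic must be >= 0")
    return float(mean_pic) * n_polymorphic


def _entropy2(p):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0) + np.where(
            p < 1, -(1 - p) * np.log1p(-p), 0.0
        )
    return terms


def shannon_band(band_freq):
    """Two-state Shannon entropy of band presence/absence at frequency p."""
    bf = np.asarray(band_freq, dtype=float)
    if np.any((bf < 0) | (bf > 1)):
        raise ValueError("band frequency must lie in [0, 1]")
    out = _entropy2(bf)
    return float(out) if np.isscalar(band_freq) or out.ndim == 0 else out


@dataclass(frozen=True)
class PrimerReport:
    """Marker summary for one primer (one row of a panel report)."""

    primer: str
    n_bands: int
    n_polymorphic: int
    percent_polymorphic: float
    mean_pic: float
    mi: float
    mean_shannon: float


def _is_polymorphic(bf: np.ndarray, rule: str) -> np.ndarray:
    if rule == "strict":
        return (bf > 0.0) & (bf < 1.0)
    if rule == "95%":
        return (bf >= 0.05) & (bf <= 0.95)
    if rule == "99%":
        return (bf >= 0.01) & (bf <= 0.99)
    raise ValueError(f"unknown polymorphism rule {rule!r}")


def primer_report(
    m: BinaryMarkerMatrix,
    panel: PrimerPanel | None = None,
    polymorphism_rule: str = "strict",
) -> pd.DataFrame:
    """Per-primer marker statistics plus an unweighted ``average`` row.

    Per-primer mean PIC and mean H' are unweighted means over that primer's
    loci; a locus counts as polymorphic when its pooled band frequency is
    strictly inside (0, 1) (default rule). The ``average`` row is the
    unweighted arithmetic mean over primers.
    """
    if panel is None:
        if not m.primer_of:
            raise ValueError("matrix has no primer assignment and no panel given")
        panel = PrimerPanel.from_locus_map(m.primer_of)
    locus_index = {l: j for j, l in enumerate(m.locus_ids)}
    unknown = [l for l in m.locus_ids if l not in panel.primer_of()]
    if unknown:
        raise ValueError(f"loci not covered by panel: {unknown[:5]}")

    bf = m.band_frequencies()
    pic_all = pic(bf)
    h_all = _entropy2(bf)
    poly = _is_polymorphic(bf, polymorphism_rule)

    rows = []
    for primer in panel.primers:
        loci = panel.loci_of[primer]
        if not loci:
            raise ValueError(f"primer {primer!r} has no loci")
        jj = np.array([locus_index[l] for l in loci])
        n_poly = int(poly[jj].sum())
        mean_pic = float(pic_all[jj].mean())
        rows.append(
            PrimerReport(
                primer=primer,
                n_bands=len(jj),
                n_polymorphic=n_poly,
                percent_polymorphic=100.0 * n_poly / len(jj),
                mean_pic=mean_pic,
                mi=marker_index(mean_pic, n_poly),
                mean_shannon=float(h_all[jj].mean()),
            )
        )
    df = pd.DataFrame(rows)
    avg = df.drop(columns=["primer"]).mean()
    df.loc[len(df)] = ["average", *avg.tolist()]
    return df
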