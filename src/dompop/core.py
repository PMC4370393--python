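"""Core data containers and I/O for dominant presence/absence marker data.

Dominant markers (ISSR, AFLP, RAPD) are scored per individual and locus as
band present (1) or absent (0). A heterozygote and a dominant homozygote both
show the band, so the observable primitive is the band frequency; allele
frequencies are inferred downstream under Hardy-Weinberg assumptions.

The on-disk matrix dialect is a delimited table with header
``id,pop,<locus1>,...`` and one row per individual; missing calls use a
configurable token (default ``-9``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "BinaryMarkerMatrix",
    "PopulationSite",
    "DistanceMatrix",
    "PrimerPanel",
    "read_matrix",
    "write_matrix",
    "write_structure_export",
    "parse_dms",
    "format_dms",
]

#: Sentinel stored in ``BinaryMarkerMatrix.calls`` for a missing call.
MISSING: int = -1


class MatrixParseError(ValueError):
    """Raised when a marker-matrix file cannot be parsed or validated."""


@dataclass
class BinaryMarkerMatrix:
    """Individuals x loci presence/absence calls with population labels.

    Parameters
    ----------
    calls : ndarray of int8, shape (n_individuals, n_loci)
        0 = band absent, 1 = band present, :data:`MISSING` = missing call.
    individual_ids : sequence of str
        Unique labels, one per row.
    populations : sequence of str
        Population label of each individual (row-aligned).
    locus_ids : sequence of str
        Unique labels, one per column.
    primer_of : mapping locus -> primer label, optional
        Groups loci by the primer that amplified them.
    """

    calls: np.ndarray
    individual_ids: list[str]
    populations: list[str]
    locus_ids: list[str]
    primer_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.populations = [str(x) for x in self.populations]
        self.locus_ids = [str(x) for x in self.locus_ids]
        n, L = self.calls.shape
        if n < 2 or L < 1:
            raise ValueError("need at least 2 individuals and 1 locus")
        if len(self.individual_ids) != n or len(self.populations) != n:
            raise ValueError("individual labels misaligned with call matrix")
        if len(self.locus_ids) != L:
            raise ValueError("locus labels misaligned with call matrix")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary call {self.calls[i, j]} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.primer_of is not None:
            missing = [l for l in self.locus_ids if l not in self.primer_of]
            if missing:
                raise ValueError(f"loci without primer assignment: {missing[:5]}")

    # -- convenience -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_rows(self, pop: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``pop``."""
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def subset_populations(self, pops: Sequence[str]) -> "BinaryMarkerMatrix":
        rows = np.concatenate([self.population_rows(p) for p in pops])
        return BinaryMarkerMatrix(
            calls=self.calls[rows],
            individual_ids=[self.individual_ids[i] for i in rows],
            populations=[self.populations[i] for i in rows],
            locus_ids=list(self.locus_ids),
            primer_of=dict(self.primer_of) if self.primer_of else None,
        )

    def band_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-locus proportion of non-missing calls equal to 1."""
        sub = self.calls if rows is None else self.calls[rows]
        present = (sub == 1).sum(axis=0)
        scored = (sub != MISSING).sum(axis=0)
        if (scored == 0).any():
            j = int(np.flatnonzero(scored == 0)[0])
            raise ValueError(f"locus {self.locus_ids[j]!r} has no scored calls in scope")
        return present / scored

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMarkerMatrix):
            return NotImplemented
        return (
            np.array_equal(self.calls, other.calls)
            and self.individual_ids == other.individual_ids
            and self.populations == other.populations
            and self.locus_ids == other.locus_ids
            and (self.primer_of or None) == (other.primer_of or None)
        )


@dataclass(frozen=True)
class PopulationSite:
    """A sampled population with geographic metadata (decimal degrees)."""

    name: str
    site: str = ""
    longitude: float = float("nan")
    latitude: float = float("nan")
    altitude: float | None = None
    n_sampled: int = 1

    def __post_init__(self) -> None:
        if np.isfinite(self.latitude) and abs(self.latitude) > 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if np.isfinite(self.longitude) and abs(self.longitude) > 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        if self.n_sampled < 1:
            raise ValueError("n_sampled must be >= 1")


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix with a units tag.

    ``units`` records what the entries are (e.g. ``"nei-distance"``, ``"fst"``,
    ``"km"``, ``"squared-band-differences"``); it is metadata only.
    """

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and label-aligned")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains missing entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        # store exactly symmetric values so downstream algebra is clean
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (i>j) order."""
        idx = np.tril_indices(len(self.labels), k=-1)
        return self.values[idx]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        perm = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(perm, perm)], self.units)


@dataclass(frozen=True)
class PrimerPanel:
    """Assignment of loci to the primers that amplified them."""

    primers: tuple[str, ...]
    sequences: Mapping[str, str]
    loci_of: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.primers)) != len(self.primers):
            raise ValueError("primer names not unique")
        seen: dict[str, str] = {}
        for primer in self.primers:
            for locus in self.loci_of.get(primer, ()):
                if locus in seen:
                    raise ValueError(
                        f"locus {locus!r} assigned to both {seen[locus]!r} and {primer!r}"
                    )
                seen[locus] = primer

    @classmethod
    def from_locus_map(
        cls, primer_of: Mapping[str, str], sequences: Mapping[str, str] | None = None
    ) -> "PrimerPanel":
        loci: dict[str, list[str]] = {}
        for locus, primer in primer_of.items():
            loci.setdefault(primer, []).append(locus)
        primers = tuple(loci)
        return cls(
            primers=primers,
            sequences=dict(sequences or {p: "" for p in primers}),
            loci_of={p: tuple(v) for p, v in loci.items()},
        )

    def primer_of(self) -> dict[str, str]:
        return {l: p for p in self.primers for l in self.loci_of[p]}


# ---------------------------------------------------------------------------
# matrix file dialect
# ---------------------------------------------------------------------------

_DELIMS = {"csv": ",", "tsv": "\t"}


def read_matrix(
    path: str | Path, dialect: str = "csv", missing_code: str = "-9"
) -> BinaryMarkerMatrix:
    """Read a presence/absence matrix from a delimited text file.

    The header row is ``id,pop,<locus ids...>``; every following row is one
    individual. Tokens other than ``0``, ``1`` and ``missing_code`` raise
    :class:`MatrixParseError` naming the offending cell.
    """
    sep = _DELIMS[dialect]
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    if len(header) < 3 or header[0] != "id" or header[1] != "pop":
        raise MatrixParseError(f"{path}: header must start with 'id{sep}pop'")
    locus_ids = header[2:]
    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(sep)
        if len(fields) != len(header):
            raise MatrixParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        ids.append(fields[0])
        pops.append(fields[1])
        row: list[int] = []
        for locus, tok in zip(locus_ids, fields[2:]):
            tok = tok.strip()
            if tok == missing_code:
                row.append(MISSING)
            elif tok in ("0", "1"):
                row.append(int(tok))
            else:
                raise MatrixParseError(
                    f"{path}:{lineno}: non-binary token {tok!r} at locus {locus!r}"
                )
        rows.append(row)
    try:
        return BinaryMarkerMatrix(
            calls=np.array(rows, dtype=np.int8),
            individual_ids=ids,
            populations=pops,
            locus_ids=locus_ids,
        )
    except ValueError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc


def write_matrix(
    m: BinaryMarkerMatrix,
    path: str | Path,
    dialect: str = "csv",
    missing_code: str = "-9",
) -> None:
    """Write a matrix in the dialect read by :func:`read_matrix`."""
    sep = _DELIMS[dialect]
    out = [sep.join(["id", "pop", *m.locus_ids])]
    for i, (ind, pop) in enumerate(zip(m.individual_ids, m.populations)):
        toks = [missing_code if c == MISSING else str(int(c)) for c in m.calls[i]]
        out.append(sep.join([ind, pop, *toks]))
    Path(path).write_text("\n".join(out) + "\n")


def write_structure_export(m: BinaryMarkerMatrix, path: str | Path) -> None:
    """Write the matrix in STRUCTURE's haploid one-row-per-individual format.

    Each band is coded as one haploid biallelic locus: one allele column per
    locus with values 1 (band) / 0 (no band) and -9 for missing. The second
    column is the integer population index (1-based, order of first
    appearance).
    """
    pop_index = {p: k + 1 for k, p in enumerate(m.population_labels)}
    lines = []
    for i, (ind, pop) in enumerate(zip(m.individual_ids, m.populations)):
        toks = ["-9" if c == MISSING else str(int(c)) for c in m.calls[i]]
        lines.append(" ".join([ind, str(pop_index[pop]), *toks]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d+)\s*[°d]\s*(\d+)\s*[′'m]\s*(\d+(?:\.\d+)?)\s*[″"s]?\s*([NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_dms(coordinate: str, hemisphere: str | None = None) -> float:
    """Convert a degrees-minutes-seconds string to signed decimal degrees.

    The hemisphere letter may be embedded (``103°45′31″E``) or passed
    separately; S and W negate the value.
    """
    match = _DMS_RE.match(coordinate)
    if not match:
        raise ValueError(f"malformed DMS coordinate: {coordinate!r}")
    deg, minutes, seconds, hemi = match.groups()
    hemi = hemisphere or hemi
    if hemi not in ("N", "S", "E", "W"):
        raise ValueError(f"missing or invalid hemisphere in {coordinate!r}")
    minutes_f, seconds_f = float(minutes), float(seconds)
    if not (0 <= minutes_f < 60 and 0 <= seconds_f < 60):
        raise ValueError(f"minutes/seconds out of [0,60) in {coordinate!r}")
    value = float(deg) + minutes_f / 60.0 + seconds_f / 3600.0
    return -value if hemi in ("S", "W") else value


def format_dms(decimal: float, axis: str = "lat") -> str:
    """Format decimal degrees as a DMS string (inverse of :func:`parse_dms`).

    Seconds are rounded to the nearest integer, matching field-survey
    precision; ``axis`` selects the hemisphere letters (lat -> N/S,
    lon -> E/W).
    """
    hemi = ("N", "S") if axis == "lat" else ("E", "W")
    letter = hemi[0] if decimal >= 0 else hemi[1]
    mag = abs(decimal)
    deg = int(mag)
    rem = (mag - deg) * 60.0
    minutes = int(rem)
    seconds = round((rem - minutes) * 60.0)
    if seconds == 60:  # carry from rounding
        seconds = 0
        minutes += 1
    if minutes == 60:
        minutes = 0
        deg += 1
    return f"{deg}°{minutes}′{seconds}″{letter}"
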