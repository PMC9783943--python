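"""Occurrence/site tables, elevation banding, and species elevational ranges.

The data model mirrors a light-trap survey along a mountain transect:
sites sit at (jittered) elevations on a transect grid, occurrence records
are per-species capture tallies at a site, and downstream analyses consume
either pooled abundance vectors (one per altitude area) or per-species
elevational ranges.

Conventions
-----------
* Elevation bands are half-open ``[lower, lower + width)`` except the last
  band, which is closed at its upper edge, so the band grid partitions the
  domain exactly.
* Altitude areas follow the same half-open-left convention.
* A *singleton* is a species represented by a single collected individual
  (one specimen in total, not one site); singletons carry no information
  about range width and are excluded from range analyses when requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "OccurrenceRecord",
    "ElevationBandSpec",
    "AltitudeAreaSpec",
    "SpeciesRange",
    "AbundanceVector",
    "ConfigurationError",
    "ReferentialIntegrityError",
    "read_sites",
    "read_occurrences",
    "write_sites",
    "write_occurrences",
    "species_ranges",
    "ranges_to_frame",
    "pool_by_area",
    "vectors_to_frame",
    "assign_band",
]


class ConfigurationError(ValueError):
    """A table is missing a required column or violates a structural invariant."""


class ReferentialIntegrityError(ValueError):
    """An occurrence row references a site that is not in the site table."""


@dataclass(frozen=True)
class SiteRecord:
    """One trapping site: a replicate at a transect, at a measured elevation."""

    site_id: str
    transect_id: str
    replicate: int
    elevation_m: float

    def __post_init__(self) -> None:
        if self.elevation_m <= 0:
            raise ValueError(
                f"site {self.site_id!r}: elevation must be positive, got {self.elevation_m}"
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    """One capture tally: ``count`` individuals of ``species_id`` at ``site_id``."""

    species_id: str
    site_id: str
    count: int
    elevation_m: float

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.count < 1:
            raise ValueError(
                f"occurrence of {self.species_id!r} at {self.site_id!r}: count must be >= 1"
            )


@dataclass(frozen=True)
class ElevationBandSpec:
    """Regular elevation bands: ``n_bands`` bands of ``width_m`` from ``origin_m``.

    Bands are half-open ``[lower, lower + width)`` except the last, which is
    closed at its upper edge.  The default (900 m origin, 200 m width, 7
    bands) reproduces the seven 200-m sections from 900 m to 2300 m used in
    band-based range analyses.
    """

    origin_m: float = 900.0
    width_m: float = 200.0
    n_bands: int = 7

    def __post_init__(self) -> None:
        if self.width_m <= 0:
            raise ValueError("band width must be positive")
        if self.n_bands < 1:
            raise ValueError("need at least one band")

    @property
    def top_m(self) -> float:
        return self.origin_m + self.n_bands * self.width_m

    def edges(self) -> np.ndarray:
        """Band edges, length ``n_bands + 1``."""
        return self.origin_m + self.width_m * np.arange(self.n_bands + 1)

    def midpoints(self) -> np.ndarray:
        """Arithmetic mid-elevation of each band."""
        return self.origin_m + self.width_m * (np.arange(self.n_bands) + 0.5)


@dataclass(frozen=True)
class AltitudeAreaSpec:
    """Contiguous altitude areas defined by ordered break elevations.

    Defaults follow the vertical vegetation zones of a temperate mountain:
    800–1300 m (deciduous broad-leaved forest, low), 1300–1800 m (coniferous
    forest, mid), 1800–2300 m (alpine shrub, high).  Areas are half-open
    ``[a, b)`` except the last, closed at its upper break.
    """

    breaks_m: tuple[float, ...] = (800.0, 1300.0, 1800.0, 2300.0)
    labels: tuple[str, ...] = ("low", "mid", "high")

    def __post_init__(self) -> None:
        if len(self.breaks_m) < 2:
            raise ValueError("need at least two breaks")
        if any(b <= a for a, b in zip(self.breaks_m, self.breaks_m[1:])):
            raise ValueError("breaks must be strictly increasing")
        if len(self.labels) != len(self.breaks_m) - 1:
            raise ValueError("need one label per area")

    def assign(self, elevation_m: float) -> str:
        """Label of the area containing ``elevation_m``; raises if outside."""
        lo, hi = self.breaks_m[0], self.breaks_m[-1]
        if not (lo <= elevation_m <= hi):
            raise ValueError(
                f"elevation {elevation_m} m outside area domain [{lo}, {hi}]"
            )
        idx = int(np.searchsorted(self.breaks_m, elevation_m, side="right")) - 1
        idx = min(idx, len(self.labels) - 1)  # top break closes the last area
        return self.labels[idx]


@dataclass(frozen=True)
class SpeciesRange:
    """Observed elevational range of one species (min/max over its site elevations)."""

    species_id: str
    min_elev_m: float
    max_elev_m: float
    range_size_m: float
    midpoint_m: float
    n_records: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.min_elev_m > self.max_elev_m:
            raise ValueError(f"{self.species_id}: min > max elevation")


@dataclass
class AbundanceVector:
    """Species -> individual-count tally for one pooled assemblage."""

    assemblage_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    def as_array(self) -> np.ndarray:
        """Counts as a positive integer array (order: sorted species id)."""
        return np.array([self.counts[k] for k in sorted(self.counts)], dtype=np.int64)


# ---------------------------------------------------------------------------
# Readers / writers

_SITE_COLUMNS = {
    "site": "site_id",
    "transect": "transect_id",
    "replicate": "replicate",
    "elevation": "elevation_m",
}
_OCC_COLUMNS = {"species": "species_id", "site": "site_id", "count": "count"}


def _require_columns(df: pd.DataFrame, mapping: Mapping[str, str], path: Path) -> None:
    missing = [c for c in mapping.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_sites(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[SiteRecord]:
    """Read a site table (CSV with header) into :class:`SiteRecord` objects.

    ``columns`` remaps logical names (site/transect/replicate/elevation) to
    the file's header names.  Duplicate (transect, replicate) pairs are a
    configuration error; non-numeric elevations are reported with their line
    number.
    """
    path = Path(path)
    names = dict(_SITE_COLUMNS)
    if columns:
        names.update(columns)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, names, path)

    records: list[SiteRecord] = []
    for i, row in df.iterrows():
        raw = row[names["elevation"]]
        try:
            elev = float(raw)
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"{path}, line {i + 2}: non-numeric elevation {raw!r}"
            ) from None
        records.append(
            SiteRecord(
                site_id=str(row[names["site"]]),
                transect_id=str(row[names["transect"]]),
                replicate=int(row[names["replicate"]]),
                elevation_m=elev,
            )
        )

    seen: dict[tuple[str, int], str] = {}
    for rec in records:
        key = (rec.transect_id, rec.replicate)
        if key in seen:
            raise ConfigurationError(
                f"{path}: duplicate (transect, replicate) pair {key} "
                f"(sites {seen[key]!r} and {rec.site_id!r})"
            )
        seen[key] = rec.site_id
    return records


def read_occurrences(
    path: str | Path,
    sites: Sequence[SiteRecord],
    columns: Mapping[str, str] | None = None,
) -> list[OccurrenceRecord]:
    """Read an occurrence table and join site elevations.

    Zero-count rows are dropped with a logged warning; site ids that do not
    resolve in ``sites`` raise :class:`ReferentialIntegrityError` listing all
    offenders.
    """
    path = Path(path)
    names = dict(_OCC_COLUMNS)
    if columns:
        names.update(columns)
    df = pd.read_csv(path, dtype={names["species"]: str, names["site"]: str})
    _require_columns(df, names, path)

    elev_by_site = {s.site_id: s.elevation_m for s in sites}
    unknown = sorted(set(df[names["site"]]) - set(elev_by_site))
    if unknown:
        raise ReferentialIntegrityError(
            f"{path}: occurrence rows reference unknown site id(s): {unknown}"
        )

    records: list[OccurrenceRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        count = int(row[names["count"]])
        if count < 1:
            n_dropped += 1
            continue
        site = str(row[names["site"]])
        records.append(
            OccurrenceRecord(
                species_id=str(row[names["species"]]),
                site_id=site,
                count=count,
                elevation_m=elev_by_site[site],
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d zero-count occurrence row(s)", path, n_dropped)
    return records


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "transect_id": s.transect_id,
                "replicate": s.replicate,
                "elevation_m": s.elevation_m,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)


def write_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "site_id": r.site_id,
                "count": r.count,
                "elevation_m": r.elevation_m,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived quantities


def species_ranges(
    records: Sequence[OccurrenceRecord], exclude_singletons: bool = True
) -> list[SpeciesRange]:
    """Per-species elevational ranges over actual site elevations.

    With ``exclude_singletons`` set, species whose *total* individual count is
    one are removed before range computation: a single specimen fixes a point,
    not a range.
    """
    if not records:
        raise ValueError("species_ranges: no occurrence records")

    by_species: dict[str, list[OccurrenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)

    out: list[SpeciesRange] = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        total = sum(r.count for r in recs)
        if exclude_singletons and total == 1:
            continue
        elevs = [r.elevation_m for r in recs]
        lo, hi = min(elevs), max(elevs)
        out.append(
            SpeciesRange(
                species_id=sp,
                min_elev_m=lo,
                max_elev_m=hi,
                range_size_m=hi - lo,
                midpoint_m=(hi + lo) / 2.0,
                n_records=len(recs),
                n_sites=len({r.site_id for r in recs}),
            )
        )
    return out


def ranges_to_frame(ranges: Sequence[SpeciesRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "min_elev_m": r.min_elev_m,
                "max_elev_m": r.max_elev_m,
                "range_size_m": r.range_size_m,
                "midpoint_m": r.midpoint_m,
                "n_records": r.n_records,
                "n_sites": r.n_sites,
            }
            for r in ranges
        ]
    )


def pool_by_area(
    records: Sequence[OccurrenceRecord], areas: AltitudeAreaSpec | None = None
) -> list[AbundanceVector]:
    """Pool occurrence tallies into one :class:`AbundanceVector` per altitude area.

    Total individuals are conserved: the per-area ``n`` values sum to the sum
    of record counts.  A record whose elevation falls outside every area is an
    error.
    """
    areas = areas or AltitudeAreaSpec()
    vectors = {label: AbundanceVector(assemblage_id=label) for label in areas.labels}
    for rec in records:
        try:
            label = areas.assign(rec.elevation_m)
        except ValueError as exc:
            raise ValueError(
                f"record ({rec.species_id!r} at {rec.site_id!r}): {exc}"
            ) from None
        vec = vectors[label]
        vec.counts[rec.species_id] = vec.counts.get(rec.species_id, 0) + rec.count
    return [vectors[label] for label in areas.labels]


def vectors_to_frame(vectors: Sequence[AbundanceVector]) -> pd.DataFrame:
    rows = [
        {"assemblage_id": v.assemblage_id, "species_id": sp, "count": c}
        for v in vectors
        for sp, c in sorted(v.counts.items())
    ]
    return pd.DataFrame(rows, columns=["assemblage_id", "species_id", "count"])


def assign_band(elevation_m: float, spec: ElevationBandSpec | None = None) -> int:
    """Index of the band containing ``elevation_m``.

    Elevations below the origin clamp to band 0 with a logged warning (the
    survey may start slightly below the first printed section); elevations
    above the top edge are an error.  The top edge itself closes the last
    band.
    """
    spec = spec or ElevationBandSpec()
    if elevation_m > spec.top_m:
        raise ValueError(
            f"elevation {elevation_m} m above band domain top {spec.top_m} m"
        )
    if elevation_m < spec.origin_m:
        logger.warning(
            "elevation %.1f m below band origin %.1f m; clamped to band 0",
            elevation_m,
            spec.origin_m,
        )
        return 0
    idx = int((elevation_m - spec.origin_m) // spec.width_m)
    return min(idx, spec.n_bands - 1)  # top edge closes the last band
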