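"""Readers and writers for every external format the tool touches.

Input formats
-------------
* occurrence tables: tab-separated with header ``species``/``latitude``/
  ``longitude`` (case-insensitive), or the GBIF archive dialect
  (tab-delimited, columns ``species``/``decimalLatitude``/``decimalLongitude``,
  extra columns ignored);
* operational-unit definitions: one unit per line,
  ``name<TAB>lon,lat lon,lat ...<TAB>min:max`` where the third field is an
  optional elevation/depth band in metres (negative = depth), or a GeoJSON
  FeatureCollection of polygons with a ``name`` property;
* elevation rasters: ESRI ASCII grid (6-line header, row 0 = northernmost);
* dated phylogenies: Newick, one tree per line, ultrametric.

Output formats: NEXUS (STANDARD data, SYMBOLS="01"), tab-separated summary
tables, GeoJSON point export.

Every reader keeps a row-level account: accepted + rejected (by reason)
always equals the number of input rows.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GeometryError, GeoPoint, PolygonDef
from .tree import Tree, TreeError, check_ultrametric, parse_newick


class FormatError(ValueError):
    """Fatal format problem (missing header columns, duplicate unit names...)."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One geo-referenced observation."""

    species: str
    point: GeoPoint
    source_row: int  # 1-based line number, for diagnostics


@dataclass
class ReadLog:
    """Row-level accounting for a reader: accepted + rejected = input rows."""

    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)
    details: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def reject(self, row: int, reason: str) -> None:
        self.rejected[reason] += 1
        self.details.append((row, reason))


@dataclass(frozen=True)
class OperationalUnit:
    """A named polygon, optionally intersected with an elevation/depth band.

    The band is ``(min_m, max_m)`` in metres a.s.l.; negative values denote
    depth. Band semantics are lower-inclusive, upper-exclusive: [min_m, max_m).
    """

    name: str
    polygon: PolygonDef
    elevation_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.elevation_band is not None:
            lo, hi = self.elevation_band
            if lo > hi:
                raise FormatError(
                    f"unit {self.name!r}: elevation band min {lo} > max {hi}"
                )


# ---------------------------------------------------------------------------
# occurrence tables


def _collapse_ws(s: str) -> str:
    return " ".join(s.split())


def _read_occurrence_table(
    path, species_col: str, lat_col: str, lon_col: str
) -> tuple[list[OccurrenceRecord], ReadLog]:
    records: list[OccurrenceRecord] = []
    log = ReadLog()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header row") from None
        cols = {c.strip().lower(): i for i, c in enumerate(header)}
        try:
            i_sp = cols[species_col.lower()]
            i_lat = cols[lat_col.lower()]
            i_lon = cols[lon_col.lower()]
        except KeyError as e:
            raise FormatError(
                f"{path}: required column {e.args[0]!r} missing from header "
                f"(have: {', '.join(header)})"
            ) from None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) <= max(i_sp, i_lat, i_lon):
                log.reject(lineno, "too few columns")
                continue
            species = _collapse_ws(row[i_sp])
            lat_s = row[i_lat].strip()
            lon_s = row[i_lon].strip()
            if not species:
                log.reject(lineno, "missing species")
                continue
            if not lat_s or not lon_s:
                log.reject(lineno, "missing coordinate")
                continue
            try:
                lat = float(lat_s)
                lon = float(lon_s)
            except ValueError:
                log.reject(lineno, "unparseable coordinate")
                continue
            if not np.isfinite(lat) or not np.isfinite(lon):
                log.reject(lineno, "unparseable coordinate")
                continue
            if not -90.0 <= lat <= 90.0:
                log.reject(lineno, "latitude out of range")
                continue
            records.append(
                OccurrenceRecord(species, GeoPoint(lon, lat), lineno)
            )
            log.accepted += 1
    return records, log


def read_occurrences_tsv(path) -> tuple[list[OccurrenceRecord], ReadLog]:
    """Read a tab-separated occurrence table (species/latitude/longitude).

    Longitudes outside [-180, 180] are normalized; rows with missing or
    unparseable coordinates, out-of-range latitudes, or blank species are
    skipped and counted by reason in the returned :class:`ReadLog`.
    """
    return _read_occurrence_table(path, "species", "latitude", "longitude")


def read_occurrences_gbif(path) -> tuple[list[OccurrenceRecord], ReadLog]:
    """Read a GBIF-archive occurrence table (tab-delimited; extra columns
    ignored; columns species/decimalLatitude/decimalLongitude required)."""
    return _read_occurrence_table(
        path, "species", "decimalLatitude", "decimalLongitude"
    )


# ---------------------------------------------------------------------------
# operational units


def _parse_band(token: str, name: str) -> tuple[float, float]:
    parts = token.split(":")
    if len(parts) != 2:
        raise FormatError(
            f"unit {name!r}: elevation band must be 'min:max', got {token!r}"
        )
    try:
        lo, hi = float(parts[0]), float(parts[1])
    except ValueError:
        raise FormatError(
            f"unit {name!r}: unparseable elevation band {token!r}"
        ) from None
    return (lo, hi)


def read_units(path) -> list[OperationalUnit]:
    """Read unit definitions: ``name TAB lon,lat pairs TAB optional min:max``.

    Lines starting with '#' and blank lines are skipped. Duplicate unit
    names are fatal.
    """
    units: list[OperationalUnit] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'name<TAB>coordinates', got "
                    f"{line!r}"
                )
            name = _collapse_ws(fields[0])
            if not name:
                raise FormatError(f"{path}:{lineno}: empty unit name")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate unit name {name!r}")
            seen.add(name)
            ring = []
            for tok in fields[1].split():
                pair = tok.split(",")
                if len(pair) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: bad coordinate pair {tok!r} "
                        "(expected 'lon,lat')"
                    )
                try:
                    ring.append((float(pair[0]), float(pair[1])))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable coordinate pair {tok!r}"
                    ) from None
            band = None
            if len(fields) >= 3 and fields[2].strip():
                band = _parse_band(fields[2].strip(), name)
            try:
                poly = PolygonDef(name, ring)
            except GeometryError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            units.append(OperationalUnit(name, poly, band))
    return units


def read_units_geojson(path) -> list[OperationalUnit]:
    """Read polygon units from a GeoJSON FeatureCollection.

    Each feature must be a single-ring Polygon with a ``name`` property;
    an optional ``elevation_band`` property ``[min_m, max_m]`` is honoured.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    units: list[OperationalUnit] = []
    seen: set[str] = set()
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        name = _collapse_ws(str(props.get("name", "")))
        if not name:
            raise FormatError(f"{path}: feature {i} has no 'name' property")
        if name in seen:
            raise FormatError(f"{path}: duplicate unit name {name!r}")
        seen.add(name)
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(
                f"{path}: feature {name!r}: only Polygon geometries are "
                f"supported, got {geom.get('type')!r}"
            )
        rings = geom.get("coordinates") or []
        if len(rings) != 1:
            raise FormatError(
                f"{path}: feature {name!r}: exactly one ring expected "
                "(holes are not supported)"
            )
        band = None
        if props.get("elevation_band") is not None:
            lo, hi = props["elevation_band"]
            band = (float(lo), float(hi))
        units.append(OperationalUnit(name, PolygonDef(name, rings[0]), band))
    return units


def write_units(units: list[OperationalUnit], path) -> None:
    """Write units in the tab-separated dialect read by :func:`read_units`."""
    with open(path, "w", encoding="utf-8") as fh:
        for u in units:
            coords = " ".join(
                f"{lo:.10g},{la:.10g}"
                for lo, la in zip(u.polygon.lons, u.polygon.lats)
            )
            line = f"{u.name}\t{coords}"
            if u.elevation_band is not None:
                line += f"\t{u.elevation_band[0]:.10g}:{u.elevation_band[1]:.10g}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# elevation rasters (ESRI ASCII grid)


@dataclass
class ElevationGrid:
    """An ESRI-ASCII-style raster; ``values[0]`` is the northernmost row."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float
    values: np.ndarray  # shape (nrows, ncols)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise FormatError(
                f"grid dimensions {self.values.shape} do not match declared "
                f"nrows={self.nrows}, ncols={self.ncols}"
            )
        if self.cellsize <= 0:
            raise FormatError("cellsize must be positive")


_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_elevation_ascii(path) -> ElevationGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    idx = 0
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + (
            "nodata_value",
        ):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}: malformed header line {lines[idx]!r}"
                ) from None
            idx += 1
        else:
            break
    for key in _ASC_HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    data = " ".join(lines[idx:]).split()
    if len(data) != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows * ncols} values, found {len(data)}"
        )
    values = np.array(data, dtype=float).reshape(nrows, ncols)
    return ElevationGrid(
        ncols, nrows, header["xllcorner"], header["yllcorner"],
        header["cellsize"], nodata, values,
    )


def write_elevation_ascii(grid: ElevationGrid, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def sample_elevation(grid: ElevationGrid, p: GeoPoint) -> float | None:
    """Nearest-cell elevation at a point, or None outside the extent / nodata.

    A coordinate exactly on a cell boundary belongs to the cell to its
    north-east (larger column index, smaller row index), which is what plain
    floor indexing gives with row 0 at the north.
    """
    col = int(np.floor((p.lon - grid.xllcorner) / grid.cellsize))
    row_from_south = int(np.floor((p.lat - grid.yllcorner) / grid.cellsize))
    row = grid.nrows - 1 - row_from_south
    if not (0 <= col < grid.ncols and 0 <= row < grid.nrows):
        return None
    v = grid.values[row, col]
    if v == grid.nodata or not np.isfinite(v):
        return None
    return float(v)


# ---------------------------------------------------------------------------
# NEXUS / tables / GeoJSON output


def _safe_name(s: str) -> str:
    return "_".join(str(s).split())


def write_nexus(presence: pd.DataFrame, path) -> None:
    """Write a presence/absence matrix as NEXUS STANDARD data (SYMBOLS "01").

    Rows are taxa in input order; one character per operational unit, with
    unit names recorded in CHARSTATELABELS. Internal whitespace in names is
    replaced by underscores.
    """
    if presence.empty:
        raise FormatError("cannot write an empty presence matrix")
    taxa = [_safe_name(s) for s in presence.index]
    chars = [_safe_name(c) for c in presence.columns]
    width = max(len(t) for t in taxa) + 2
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"\tDIMENSIONS NTAX={len(taxa)};\n")
        fh.write("\tTAXLABELS\n")
        for t in taxa:
            fh.write(f"\t\t{t}\n")
        fh.write("\t;\nEND;\n\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write(f"\tDIMENSIONS NCHAR={len(chars)};\n")
        fh.write('\tFORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
        fh.write("\tCHARSTATELABELS\n")
        fh.write(
            ",\n".join(f"\t\t{i + 1} {c}" for i, c in enumerate(chars))
        )
        fh.write("\n\t;\n")
        fh.write("\tMATRIX\n")
        for taxon, (_, row) in zip(taxa, presence.iterrows()):
            states = "".join(str(int(v)) for v in row)
            fh.write(f"\t\t{taxon:<{width}}{states}\n")
        fh.write("\t;\nEND;\n")


def write_tables(counts: pd.DataFrame, stats: dict, path_prefix) -> None:
    """Write the count matrix and summary statistics as TSV files.

    Produces ``<prefix>_counts.tsv``, ``<prefix>_species_per_area.tsv`` and
    ``<prefix>_relative_occurrence.tsv`` with deterministic row/column order.
    """
    prefix = str(path_prefix)
    counts.to_csv(prefix + "_counts.tsv", sep="\t", index_label="species")
    spa = stats["species_per_area"]
    spa.rename("n_species").to_frame().to_csv(
        prefix + "_species_per_area.tsv", sep="\t", index_label="unit"
    )
    stats["relative_occurrence"].to_csv(
        prefix + "_relative_occurrence.tsv", sep="\t", index_label="species"
    )


def export_points_geojson(
    records: list[OccurrenceRecord], memberships: list[list[str]], path
) -> int:
    """Export occurrences that fall inside at least one unit as GeoJSON points.

    Each feature carries the species name and the list of containing units.
    Returns the number of features written.
    """
    feats = []
    for rec, units in zip(records, memberships):
        if not units:
            continue
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [rec.point.lon, rec.point.lat],
                },
                "properties": {"species": rec.species, "units": list(units)},
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": feats},
            fh, indent=None, separators=(",", ":"), sort_keys=True,
        )
        fh.write("\n")
    return len(feats)


# ---------------------------------------------------------------------------
# trees


def read_newick(path) -> list[Tree]:
    """Read one or many dated trees (one Newick string per line).

    Every tree must be rooted, fully dated (branch lengths present) and
    ultrametric to a relative tolerance of 1e-6; violations are fatal and
    name the offending tip pair.
    """
    trees: list[Tree] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = parse_newick(line)
                check_ultrametric(tree)
            except TreeError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            trees.append(tree)
    if not trees:
        raise FormatError(f"{path}: no trees found")
    return trees
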