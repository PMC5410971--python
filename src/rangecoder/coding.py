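"""The core coding engine: occurrences -> unit membership -> count and
presence matrices -> summary statistics.

An occurrence belongs to an operational unit iff it falls inside the unit's
polygon (boundary inclusive) and, where the unit carries an elevation band,
its sampled elevation e satisfies min_m <= e < max_m. The half-open band
makes two units split at the same altitude a partition: a point at exactly
1000 m belongs to the 1000:6000 highland unit, not the 0:1000 lowland one.

Species may be members of several (overlapping) units; any reduction to a
single state per species happens downstream in :mod:`rangecoder.phylo`.
Species order in every output is first appearance in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ElevationGrid, OccurrenceRecord, OperationalUnit, sample_elevation
from .geometry import points_in_polygon


class CodingError(ValueError):
    """Configuration problem in the coding stage."""


@dataclass
class MembershipTable:
    """Per-occurrence unit membership, plus a run log."""

    records: list[OccurrenceRecord]
    unit_names: list[str]
    memberships: list[list[str]]  # parallel to records; may be empty lists
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def assign_units(
    records: list[OccurrenceRecord],
    units: list[OperationalUnit],
    grid: ElevationGrid | None = None,
) -> MembershipTable:
    """Assign every occurrence to the units that contain it.

    ``grid`` is required iff any unit has an elevation band. Occurrences
    whose elevation cannot be sampled (outside the raster, or nodata) are
    excluded from banded units only; the count is reported in the log.
    """
    names = [u.name for u in units]
    if len(set(names)) != len(names):
        raise CodingError("unit names must be unique")
    banded = [u for u in units if u.elevation_band is not None]
    if banded and grid is None:
        raise CodingError(
            f"units {[u.name for u in banded]} have elevation bands but no "
            "elevation grid was supplied"
        )

    lons = np.array([r.point.lon for r in records], dtype=float)
    lats = np.array([r.point.lat for r in records], dtype=float)

    elev: np.ndarray | None = None
    if banded:
        elev = np.array(
            [
                np.nan if (e := sample_elevation(grid, r.point)) is None else e
                for r in records
            ],
            dtype=float,
        )

    memberships: list[list[str]] = [[] for _ in records]
    n_missing_elev_exclusions = 0
    for u in units:
        inside = points_in_polygon(lons, lats, u.polygon)
        if u.elevation_band is not None:
            lo, hi = u.elevation_band
            missing = inside & np.isnan(elev)
            n_missing_elev_exclusions += int(missing.sum())
            with np.errstate(invalid="ignore"):
                inside = inside & ~np.isnan(elev) & (elev >= lo) & (elev < hi)
        for i in np.flatnonzero(inside):
            memberships[i].append(u.name)

    log = {
        "n_records": len(records),
        "n_units": len(units),
        "n_missing_elevation_exclusions": n_missing_elev_exclusions,
        "n_unassigned": sum(1 for m in memberships if not m),
    }
    return MembershipTable(records, names, memberships, log)


def build_counts(membership: MembershipTable) -> pd.DataFrame:
    """Species x unit occurrence counts.

    Rows follow first appearance of each species in the input; species whose
    occurrences fall in no unit keep an all-zero row. An occurrence inside
    several overlapping units contributes once to each of their columns.
    """
    species_order: list[str] = []
    seen: set[str] = set()
    for r in membership.records:
        if r.species not in seen:
            seen.add(r.species)
            species_order.append(r.species)
    counts = pd.DataFrame(
        0, index=pd.Index(species_order, name="species"),
        columns=membership.unit_names, dtype=int,
    )
    sp_idx = {s: i for i, s in enumerate(species_order)}
    u_idx = {u: i for i, u in enumerate(membership.unit_names)}
    arr = counts.to_numpy()
    for rec, units in zip(membership.records, membership.memberships):
        i = sp_idx[rec.species]
        for u in units:
            arr[i, u_idx[u]] += 1
    counts.iloc[:, :] = arr
    return counts


def threshold_presence(counts: pd.DataFrame, t: int = 1) -> pd.DataFrame:
    """0/1 presence coding: 1 iff the count reaches the threshold t (>= 1)."""
    if t < 1:
        raise CodingError(f"presence threshold must be >= 1, got {t}")
    presence = (counts >= t).astype(int)
    presence.attrs["threshold"] = t
    return presence


def summary_stats(counts: pd.DataFrame) -> dict:
    """The three summary statistics derived from the count matrix.

    * ``species_per_area``: number of species with >= 1 occurrence per unit;
    * ``occ_per_species_per_area``: the count matrix itself;
    * ``relative_occurrence``: each species' counts divided by its total
      (all-zero species stay 0 in every unit and are listed in the log).
    """
    species_per_area = (counts >= 1).sum(axis=0)
    species_per_area.name = "species_per_area"
    totals = counts.sum(axis=1)
    zero_species = list(counts.index[totals == 0])
    denom = totals.replace(0, 1)
    relative = counts.div(denom, axis=0)
    return {
        "species_per_area": species_per_area,
        "occ_per_species_per_area": counts,
        "relative_occurrence": relative,
        "zero_occurrence_species": zero_species,
    }


#: Coexistence matrices are meant for visual inspection of small data sets.
COEXISTENCE_MAX_SPECIES = 40


def coexistence_matrix(presence: pd.DataFrame, unit: str) -> pd.DataFrame:
    """Species x species joint-presence indicator within one unit.

    Refuses data sets of 40 or more species (the matrix is intended for
    small-set inspection); symmetric, with diagonal equal to presence.
    """
    n = len(presence.index)
    if n >= COEXISTENCE_MAX_SPECIES:
        raise CodingError(
            f"coexistence matrix is only computed for data sets of fewer than "
            f"{COEXISTENCE_MAX_SPECIES} species (got {n})"
        )
    if unit not in presence.columns:
        raise CodingError(f"unknown unit {unit!r}")
    v = presence[unit].to_numpy(dtype=int)
    return pd.DataFrame(
        np.outer(v, v), index=presence.index, columns=presence.index
    )


def flag_outliers(counts: pd.DataFrame, t: int) -> list[tuple[str, str, int]]:
    """Species/unit pairs whose count is positive but below the threshold.

    These are candidate outlier localities (e.g. a lat/lon swap placing a
    single record in the wrong polygon).
    """
    out: list[tuple[str, str, int]] = []
    arr = counts.to_numpy()
    for i, s in enumerate(counts.index):
        for j, u in enumerate(counts.columns):
            c = int(arr[i, j])
            if 1 <= c < t:
                out.append((s, u, c))
    return out
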