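"""Community data assembly: trap-year aggregation, prevalence filtering
and trait coding.

The sampling unit throughout is the trap-year: the annual aggregate of one
light trap's weekly samples. Species are filtered by prevalence (fraction
of trap-years with presence) before modelling, since very rare species
carry little statistical information for a multivariate fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOST_GROUPS = (
    "herbaceous",
    "graminoid",
    "dwarf_shrub",
    "deciduous",
    "conifer",
    "other",
)
#: Reference level for the host-group indicator coding.
HOST_REFERENCE = "herbaceous"

#: Wing-span bin edges (mm): a singleton wingless bin, four interior bins,
#: and a singleton top bin for anything above the last edge.
WING_BIN_EDGES = (17.9, 24.1, 30.3, 36.5, 43.0)


@dataclass
class CommunityTable:
    """Trap-year by species count matrix with unit metadata.

    ``counts`` is indexed by (site, year) with one column per species;
    ``effort_days``, ``zone`` and coordinates align with its index.
    """

    counts: pd.DataFrame
    effort_days: pd.Series
    zone: pd.Series
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate (site, year) rows")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.effort_days.to_numpy() < 1).any():
            raise ValueError("effort_days must be >= 1")

    @property
    def species(self) -> list:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        """Presence-absence view (count > 0)."""
        return self.counts.gt(0)

    def prevalence(self) -> pd.Series:
        """Fraction of trap-years in which each species is present."""
        return self.presence().mean(axis=0)


def aggregate_to_trap_year(
    weekly_counts: pd.DataFrame,
    effort: pd.DataFrame | None = None,
    days_per_sample: int = 7,
) -> pd.DataFrame:
    """Aggregate weekly records to trap-year sums.

    ``weekly_counts`` needs columns (site, year, week, species, count); the
    result has one row per (site, year) with per-species sums and an
    ``effort_days`` column. Effort defaults to ``days_per_sample`` times
    the number of distinct sampling weeks, unless an explicit per
    (site, year) ``effort`` frame with an ``effort_days`` column is given.
    """
    req = {"site", "year", "week", "species", "count"}
    if not req.issubset(weekly_counts.columns):
        raise ValueError(f"weekly records need columns {sorted(req)}")
    if (weekly_counts["count"] < 0).any():
        raise ValueError("negative weekly counts")

    sums = (
        weekly_counts.groupby(["site", "year", "species"])["count"]
        .sum()
        .unstack(fill_value=0)
    )
    sums.columns.name = None
    if effort is not None:
        eff = effort.set_index(["site", "year"])["effort_days"]
        eff = eff.reindex(sums.index)
        if eff.isna().any():
            raise ValueError("effort table missing some trap-years")
    else:
        eff = (
            weekly_counts.groupby(["site", "year"])["week"].nunique()
            * days_per_sample
        )
    out = sums.copy()
    out["effort_days"] = eff
    return out.reset_index()


def prevalence_filter(
    table: CommunityTable, threshold: float = 0.10
) -> tuple[list, dict]:
    """Keep species present in strictly more than ``threshold`` of trap-years.

    Returns the kept species list and a report with the retained fraction
    of occurrences and of total abundance.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if table.counts.empty:
        raise ValueError("empty community table")
    prev = table.prevalence()
    kept = [s for s in table.species if prev[s] > threshold]
    pres = table.presence().to_numpy()
    cnts = table.counts.to_numpy()
    keep_mask = np.array([s in set(kept) for s in table.species])
    total_occ = pres.sum()
    total_ab = cnts.sum()
    report = {
        "n_species_total": len(table.species),
        "n_species_kept": len(kept),
        "retained_occurrence_fraction": (
            float(pres[:, keep_mask].sum() / total_occ) if total_occ else np.nan
        ),
        "retained_abundance_fraction": (
            float(cnts[:, keep_mask].sum() / total_ab) if total_ab else np.nan
        ),
    }
    return kept, report


def filter_table(table: CommunityTable, species: list) -> CommunityTable:
    """Restrict a community table to a species subset."""
    return CommunityTable(
        counts=table.counts[species].copy(),
        effort_days=table.effort_days,
        zone=table.zone,
        coords=table.coords,
    )


def assign_wing_bins(traits: pd.DataFrame) -> pd.DataFrame:
    """Attach ordinal wing-span bins (1..6) to a trait table.

    Bin 1 is the wingless group (W = 0); bins 2-5 follow the interior
    edges 17.9 / 24.1 / 30.3 / 36.5 / 43 mm; bin 6 holds anything above
    the last edge. Spans falling between 0 and the first edge are assigned
    to the nearest bin with a warning.
    """
    if (traits["wing_span"] < 0).any():
        raise ValueError("wing_span must be >= 0")
    w = traits["wing_span"].to_numpy(dtype=float)
    bins = np.empty(len(w), dtype=int)
    lo = WING_BIN_EDGES[0]
    n_gap = 0
    for i, wi in enumerate(w):
        if wi == 0:
            bins[i] = 1
        elif wi <= lo:
            # outside every bin: nearest is the wingless singleton or bin 2
            bins[i] = 1 if wi < lo / 2 else 2
            n_gap += 1
        elif wi > WING_BIN_EDGES[-1]:
            bins[i] = 6
        else:
            bins[i] = 2 + int(np.searchsorted(WING_BIN_EDGES, wi) - 1)
    if n_gap:
        warnings.warn(
            f"{n_gap} wing spans below the first bin edge assigned to the "
            "nearest bin",
            stacklevel=2,
        )
    out = traits.copy()
    out["wing_bin"] = bins
    return out


def encode_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Species-level trait design matrix.

    Columns: intercept, standardized wing span (continuous), and five
    host-group indicators with ``herbaceous`` as the reference level.
    """
    bad = set(traits["host_group"]) - set(HOST_GROUPS)
    if bad:
        raise ValueError(f"unknown host groups: {sorted(bad)}")
    w = traits["wing_span"].to_numpy(dtype=float)
    sd = w.std()
    wz = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
    out = pd.DataFrame(index=traits.index)
    out["trait_intercept"] = 1.0
    out["trait_wing_span"] = wz
    for g in HOST_GROUPS:
        if g == HOST_REFERENCE:
            continue
        out[f"trait_host_{g}"] = (traits["host_group"] == g).astype(float)
    return out
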