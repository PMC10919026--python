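"""MAG quality tiers, GTDB-based novelty calls and taxon aggregation.

Quality tiers follow the usual completeness/contamination gates, with the
boundary semantics applied literally: *high* requires completeness
strictly above 90% and contamination strictly below 5%; *medium* is
anything not high with completeness at least 50% and contamination below
10%; the rest is discarded.

Novelty calls read the GTDB-Tk classification string alone: a named
species means a known species; an empty species under a named genus flags
a candidate novel species, and so on up the ranks.  Where order and family
are both unassigned the call is ``novel_higher`` rather than guessing a
rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GTDB_RANKS, MagRecord, parse_gtdb_string

TIERS = ("high", "medium", "discarded")
NOVELTIES = (
    "known_species", "novel_species", "novel_genus", "novel_family",
    "novel_higher", "unclassified",
)

UNASSIGNED_SENTINEL = "(unassigned at rank)"


@dataclass(frozen=True)
class QualityTier:
    mag_id: str
    tier: str


@dataclass(frozen=True)
class NoveltyCall:
    mag_id: str
    lowest_assigned_rank: str
    novelty: str


def tier_for(completeness_pct: float, contamination_pct: float) -> str:
    """Quality tier from completeness/contamination, boundaries strict as stated."""
    if completeness_pct > 90 and contamination_pct < 5:
        return "high"
    if completeness_pct >= 50 and contamination_pct < 10:
        return "medium"
    return "discarded"


def tier_mags(
    mags: Sequence[MagRecord],
) -> tuple[list[QualityTier], dict[tuple[str, str], int]]:
    """Tier every MAG; also return counts per (host_sample, tier)."""
    tiers = [QualityTier(m.mag_id, tier_for(m.completeness_pct, m.contamination_pct))
             for m in mags]
    summary: dict[tuple[str, str], int] = {}
    for mag, qt in zip(mags, tiers):
        key = (mag.host_sample, qt.tier)
        summary[key] = summary.get(key, 0) + 1
    return tiers, summary


def call_novelty(mag: MagRecord) -> NoveltyCall:
    """Classify a MAG's taxonomic novelty from its GTDB string."""
    ranks = parse_gtdb_string(mag.gtdb_string)
    lowest = "none"
    for rank in GTDB_RANKS:
        if ranks[rank]:
            lowest = rank
    if mag.gtdb_string == "unclassified" or not ranks["domain"]:
        novelty = "unclassified"
        lowest = "none"
    elif ranks["species"]:
        novelty = "known_species"
    elif ranks["genus"]:
        novelty = "novel_species"
    elif ranks["family"]:
        novelty = "novel_genus"
    elif ranks["order"]:
        novelty = "novel_family"
    else:
        novelty = "novel_higher"
    return NoveltyCall(mag.mag_id, lowest, novelty)


def tier_table(mags: Sequence[MagRecord]) -> pd.DataFrame:
    tiers, _ = tier_mags(mags)
    return pd.DataFrame(
        {
            "mag_id": [m.mag_id for m in mags],
            "host_sample": [m.host_sample for m in mags],
            "completeness_pct": [m.completeness_pct for m in mags],
            "contamination_pct": [m.contamination_pct for m in mags],
            "tier": [t.tier for t in tiers],
        }
    )


def novelty_table(mags: Sequence[MagRecord]) -> pd.DataFrame:
    calls = [call_novelty(m) for m in mags]
    return pd.DataFrame(
        {
            "mag_id": [m.mag_id for m in mags],
            "gtdb_classification": [m.gtdb_string for m in mags],
            "lowest_assigned_rank": [c.lowest_assigned_rank for c in calls],
            "novelty": [c.novelty for c in calls],
        }
    )


def aggregate_by_taxon(
    profiles: Mapping[str, Iterable],
    mags: Sequence[MagRecord],
    rank: str,
) -> pd.DataFrame:
    """Summarise per-MAG densities by taxon at one rank.

    *profiles* maps mag_id → iterable of DensityRecords (any level).  The
    output holds, per (taxon, key), the number of MAGs in the taxon, the
    mean and max density, and the per-MAG listing.  MAGs with an empty rank
    are grouped under a sentinel label.
    """
    if rank not in GTDB_RANKS[1:6]:  # phylum .. genus
        raise ValueError(f"rank must be one of {GTDB_RANKS[1:6]}, got {rank!r}")
    by_id = {m.mag_id: m for m in mags}
    unknown = [mag_id for mag_id in profiles if mag_id not in by_id]
    if unknown:
        raise ValueError(f"profiled MAG(s) absent from metadata: {', '.join(unknown)}")
    rows = []
    for mag_id, records in profiles.items():
        taxon = parse_gtdb_string(by_id[mag_id].gtdb_string)[rank] or UNASSIGNED_SENTINEL
        for r in records:
            rows.append(
                {"taxon": taxon, "key": r.key, "level": r.level, "mag_id": mag_id,
                 "density": r.density}
            )
    if not rows:
        return pd.DataFrame(
            columns=["taxon", "key", "level", "n_mags", "mean_density", "max_density",
                     "per_mag"]
        )
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["taxon", "key", "level"], sort=True)
        .agg(
            n_mags=("mag_id", "nunique"),
            mean_density=("density", "mean"),
            max_density=("density", "max"),
            per_mag=(
                "mag_id",
                lambda s: ";".join(sorted(s.unique())),
            ),
        )
        .reset_index()
    )
    return out
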