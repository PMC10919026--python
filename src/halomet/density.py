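"""Gene densities per function and per cluster, and cross-sample comparisons.

The central statistic is the gene density: number of annotated genes
divided by the assembled size in megabase pairs (genes/Mbp).  Metagenomes
are normalised by their total assembled contig size; each MAG by its own
assembly size, the self-consistent analog of the metagenome definition.
Densities are kept at full precision; a display-rounded value (default 2
decimals, matching how such values are conventionally printed) travels
alongside.

Cross-sample comparisons are binary set algebra on presence (a function or
cluster is present when at least one gene is annotated): intersections,
unions, pairwise shares and the shared fraction |∩| / |∪|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog import Catalog
from .screening import SampleProfile, ScreeningError


class DensityError(ValueError):
    pass


@dataclass(frozen=True)
class DensityRecord:
    """Gene density of one function (EC) or cluster in one sample."""

    sample_id: str
    key: str
    level: str  # "function" or "cluster"
    n_genes: int
    density: float
    density_display: float


def _record(sample_id, key, level, n_genes, size_mbp, decimals) -> DensityRecord:
    density = n_genes / size_mbp
    return DensityRecord(sample_id, key, level, n_genes, density, round(density, decimals))


def function_density(
    profile: SampleProfile,
    catalog: Optional[Catalog] = None,
    dense: bool = False,
    decimals: int = 2,
) -> list[DensityRecord]:
    """Per-EC gene densities for one sample, sorted by EC.

    By default only functions with at least one gene are emitted; with
    ``dense=True`` (requires *catalog*) every catalog EC appears, zeros
    included.
    """
    if profile.size_mbp <= 0:
        raise DensityError(f"{profile.sample_id}: size_mbp must be positive")
    if dense:
        if catalog is None:
            raise DensityError("dense export requires the catalog")
        keys = sorted(catalog.ecs)
    else:
        keys = sorted(profile.counts)
    return [
        _record(profile.sample_id, ec, "function", profile.counts.get(ec, 0),
                profile.size_mbp, decimals)
        for ec in keys
    ]


def cluster_density(
    profile: SampleProfile, catalog: Catalog, decimals: int = 2
) -> list[DensityRecord]:
    """Per-cluster gene densities for one sample; every cluster emitted.

    A cluster's gene count is the sum over its member ECs; an EC belonging
    to several clusters contributes its full count to each of them (cluster
    totals are therefore not additive across clusters and are never summed).
    """
    if profile.size_mbp <= 0:
        raise DensityError(f"{profile.sample_id}: size_mbp must be positive")
    if profile.catalog_checksum and profile.catalog_checksum != catalog.checksum:
        raise ScreeningError(
            f"profile {profile.sample_id} was screened against a different catalog"
        )
    records = []
    for cl in catalog.clusters:
        n = sum(profile.counts.get(ec, 0) for ec in cl.member_ecs)
        records.append(
            _record(profile.sample_id, cl.cluster_id, "cluster", n,
                    profile.size_mbp, decimals)
        )
    return records


@dataclass
class ComparisonReport:
    """Presence/absence set algebra across two or more samples."""

    sample_ids: list[str]
    level: str
    presence: dict[str, set[str]]
    intersection: set[str]
    union: set[str]
    pairwise_shared: dict[tuple[str, str], set[str]]

    @property
    def shared_fraction(self) -> float:
        """|intersection over all samples| / |union| (0 for an empty union)."""
        return len(self.intersection) / len(self.union) if self.union else 0.0

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "level": self.level,
            "presence": {s: sorted(v) for s, v in self.presence.items()},
            "intersection": sorted(self.intersection),
            "union": sorted(self.union),
            "pairwise_shared": {
                f"{a}|{b}": sorted(v) for (a, b), v in self.pairwise_shared.items()
            },
            "n_intersection": len(self.intersection),
            "n_union": len(self.union),
            "shared_fraction": self.shared_fraction,
        }


def _compare_sets(presence: dict[str, set[str]], level: str) -> ComparisonReport:
    sample_ids = list(presence)
    sets = list(presence.values())
    intersection = set.intersection(*sets) if sets else set()
    union = set.union(*sets) if sets else set()
    pairwise = {
        (a, b): presence[a] & presence[b] for a, b in combinations(sample_ids, 2)
    }
    return ComparisonReport(sample_ids, level, presence, intersection, union, pairwise)


def compare_samples(
    profiles: Sequence[SampleProfile],
    level: str = "function",
    catalog: Optional[Catalog] = None,
) -> ComparisonReport:
    """Shared/unique functions or clusters across samples.

    Presence is binary (n_genes >= 1).  At cluster level the catalog is
    required to resolve memberships.  All profiles must have been screened
    against the same catalog.
    """
    if len(profiles) < 2:
        raise DensityError("compare_samples needs at least two profiles")
    checksums = {p.catalog_checksum for p in profiles if p.catalog_checksum}
    if len(checksums) > 1:
        raise ScreeningError("profiles were screened against different catalogs")
    if level == "function":
        presence = {p.sample_id: set(p.counts) for p in profiles}
    elif level == "cluster":
        if catalog is None:
            raise DensityError("cluster-level comparison requires the catalog")
        presence = {
            p.sample_id: {
                cl.cluster_id
                for cl in catalog.clusters
                if any(p.counts.get(ec, 0) for ec in cl.member_ecs)
            }
            for p in profiles
        }
    else:
        raise DensityError(f"unknown comparison level {level!r}")
    return _compare_sets(presence, level)


def shared_taxa(
    taxon_tables: Mapping[str, Iterable[str]], level: str = "taxon"
) -> tuple[ComparisonReport, pd.DataFrame]:
    """Set algebra on per-sample taxon label lists at one rank.

    Labels are normalised (strip + case-fold) before comparison.  Returns
    the comparison report plus a chord-diagram-ready long table with one
    row per (sample, taxon) and a mask naming every sample sharing that
    taxon.  An empty sample is tolerated with a warning and treated as an
    empty set.
    """
    presence: dict[str, set[str]] = {}
    for sample, labels in taxon_tables.items():
        cleaned = {" ".join(str(x).split()).casefold() for x in labels}
        cleaned.discard("")
        if not cleaned:
            warnings.warn(f"sample {sample!r} has no taxon labels; treated as empty set")
        presence[sample] = cleaned
    report = _compare_sets(presence, level)
    rows = []
    for sample in report.sample_ids:
        for taxon in sorted(presence[sample]):
            mask = "|".join(s for s in report.sample_ids if taxon in presence[s])
            rows.append({"sample": sample, "taxon": taxon, "shared_with_mask": mask})
    table = pd.DataFrame(rows, columns=["sample", "taxon", "shared_with_mask"])
    return report, table
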