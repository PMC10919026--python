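"""Match annotated EC numbers against the catalog, per sample.

Counting is per (feature, EC): a feature carrying two distinct catalog ECs
contributes one gene to each of the two functions, while duplicate
identical ECs on one feature count once.  In practice the upstream
annotator assigns at most one EC per feature, so this choice only affects
rare bifunctional annotations.  Feature type is not restricted — EC
presence alone gates counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import Catalog, CatalogError
from .io import AnnotationTable


class ScreeningError(ValueError):
    pass


@dataclass
class SampleProfile:
    """Per-sample gene counts over the catalog functions.

    ``counts`` maps catalog EC → number of features carrying it (only ECs
    with at least one gene are stored); ``size_mbp`` is the assembled size
    in megabase pairs, the denominator of every density downstream.
    """

    sample_id: str
    sample_kind: str
    size_mbp: float
    counts: dict[str, int] = field(default_factory=dict)
    catalog_checksum: str = ""

    @property
    def n_functions(self) -> int:
        """Distinct catalog functions with at least one annotated gene."""
        return len(self.counts)

    @property
    def n_target_genes(self) -> int:
        """Total annotated genes over all catalog functions."""
        return sum(self.counts.values())


def screen(table: AnnotationTable, catalog: Catalog) -> SampleProfile:
    """Tally catalog functions annotated in one sample.

    Each feature contributes 1 to every distinct catalog EC it carries;
    features without a catalog EC contribute nothing.
    """
    counts: dict[str, int] = {}
    catalog_ecs = catalog.ecs
    for feat in table.features:
        for ec in feat.ec_numbers & catalog_ecs:
            counts[ec] = counts.get(ec, 0) + 1
    return SampleProfile(
        sample_id=table.sample_id,
        sample_kind=table.sample_kind,
        size_mbp=table.size_bp / 1e6,
        counts=counts,
        catalog_checksum=catalog.checksum,
    )


@dataclass
class Ec42Split:
    """Counts of the direct (carbon–halogen bond forming/breaking) subset,
    partitioned by role and, within dehalogenases, by mechanism."""

    halogenase: dict[str, int]
    dehalogenase: dict[str, int]
    hydrolytic: dict[str, int]
    non_hydrolytic: dict[str, int]

    def total_direct(self) -> int:
        return sum(self.halogenase.values()) + sum(self.dehalogenase.values())


def split_ec42(profile: SampleProfile, catalog: Catalog) -> Ec42Split:
    """Partition a profile's direct-subset counts by role and mechanism.

    Auxiliary ECs are excluded from all four outputs; hydrolytic plus
    non-hydrolytic reproduce the dehalogenase counts exactly.  Raises if the
    profile was screened against a different catalog or carries unknown ECs.
    """
    if profile.catalog_checksum and profile.catalog_checksum != catalog.checksum:
        raise ScreeningError(
            f"profile {profile.sample_id} was screened against a different catalog"
        )
    halogenase: dict[str, int] = {}
    dehalogenase: dict[str, int] = {}
    hydrolytic: dict[str, int] = {}
    non_hydrolytic: dict[str, int] = {}
    for ec, n in profile.counts.items():
        fn = catalog.get(ec)
        if fn is None:
            raise ScreeningError(
                f"profile {profile.sample_id} contains EC {ec} unknown to the catalog"
            )
        if fn.role == "halogenase":
            halogenase[ec] = n
        elif fn.role == "dehalogenase":
            dehalogenase[ec] = n
            if fn.mechanism == "hydrolytic":
                hydrolytic[ec] = n
            else:
                non_hydrolytic[ec] = n
    return Ec42Split(halogenase, dehalogenase, hydrolytic, non_hydrolytic)
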