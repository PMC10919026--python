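"""Join per-MAG densities and taxonomy onto a phylogenetic tree.

Emits annotation datasets for external tree renderers: one multi-value bar
dataset per requested track (total catalog density, halogenase density,
hydrolytic dehalogenase density, any cluster, ...) in the iTOL simple-bar
text dialect, a color-strip dataset for the taxonomic order, and a plain
long-format TSV twin for renderer independence.  Leaf order is never
touched; leaves with a configurable reference prefix (external reference
genomes included in tree building) are passed through untouched and
flagged; a MAG without a computed profile gets value 0 with a missing
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .catalog import Catalog
from .density import cluster_density, function_density
from .io import MagRecord, TreeData, parse_gtdb_string
from .screening import SampleProfile, split_ec42

#: Core density tracks always available for a screened MAG.
BASE_TRACKS = (
    "total", "halogenase", "dehalogenase", "hydrolytic", "non_hydrolytic",
)

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94",
)


class TreeAnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class TrackRow:
    leaf: str
    value: float
    missing: bool
    is_reference: bool


@dataclass
class AnnotationBundle:
    """Per-track rows in leaf order plus a taxonomy color strip."""

    tracks: dict[str, list[TrackRow]]
    colorstrip: list[tuple[str, str, str]]  # (leaf, color, label)
    leaf_order: list[str]


def compute_tracks(profile: SampleProfile, catalog: Catalog) -> dict[str, float]:
    """All density tracks for one screened MAG: the base role/mechanism
    splits plus one track per cluster id."""
    size = profile.size_mbp
    split = split_ec42(profile, catalog)
    tracks = {
        "total": profile.n_target_genes / size,
        "halogenase": sum(split.halogenase.values()) / size,
        "dehalogenase": sum(split.dehalogenase.values()) / size,
        "hydrolytic": sum(split.hydrolytic.values()) / size,
        "non_hydrolytic": sum(split.non_hydrolytic.values()) / size,
    }
    for rec in cluster_density(profile, catalog):
        tracks[rec.key] = rec.density
    return tracks


def annotate_tree(
    tree: TreeData,
    mag_tracks: Mapping[str, Mapping[str, float]],
    mags: Sequence[MagRecord],
    tracks: Sequence[str],
    ref_prefix: str = "Ref",
) -> AnnotationBundle:
    """Build the annotation bundle for *tracks* over every tree leaf.

    *mag_tracks* maps mag_id → track → value (see :func:`compute_tracks`).
    Every requested track must exist for at least one MAG; unknown tracks
    raise, listing what is available.
    """
    available: set[str] = set()
    for values in mag_tracks.values():
        available.update(values)
    unknown = [t for t in tracks if t not in available]
    if unknown:
        raise TreeAnnotationError(
            f"track(s) not computed: {', '.join(unknown)}; "
            f"available: {', '.join(sorted(available))}"
        )
    by_id = {m.mag_id: m for m in mags}
    bundle_tracks: dict[str, list[TrackRow]] = {}
    for track in tracks:
        rows = []
        for leaf in tree.leaf_labels:
            is_ref = leaf.startswith(ref_prefix)
            values = mag_tracks.get(leaf)
            if is_ref:
                rows.append(TrackRow(leaf, 0.0, missing=False, is_reference=True))
            elif values is None or track not in values:
                rows.append(TrackRow(leaf, 0.0, missing=True, is_reference=False))
            else:
                rows.append(TrackRow(leaf, values[track], missing=False,
                                     is_reference=False))
        bundle_tracks[track] = rows

    orders = sorted(
        {
            parse_gtdb_string(m.gtdb_string)["order"] or "(unassigned)"
            for m in mags
        }
    )
    colors = {o: _PALETTE[i % len(_PALETTE)] for i, o in enumerate(orders)}
    strip = []
    for leaf in tree.leaf_labels:
        mag = by_id.get(leaf)
        if mag is None:
            label = "(reference)" if leaf.startswith(ref_prefix) else "(unknown)"
            strip.append((leaf, "#dddddd", label))
        else:
            order = parse_gtdb_string(mag.gtdb_string)["order"] or "(unassigned)"
            strip.append((leaf, colors[order], order))
    return AnnotationBundle(bundle_tracks, strip, list(tree.leaf_labels))


# -- writers ------------------------------------------------------------------

def write_itol_bar(
    bundle: AnnotationBundle, track: str, path: str | Path, color: str = "#2ca02c"
) -> None:
    """iTOL simple-bar dataset for one track (header block + TAB rows)."""
    if track not in bundle.tracks:
        raise TreeAnnotationError(
            f"track {track!r} not in bundle; available: "
            f"{', '.join(sorted(bundle.tracks))}"
        )
    lines = [
        "DATASET_SIMPLEBAR",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{track}",
        f"COLOR\t{color}",
        "DATA",
    ]
    for row in bundle.tracks[track]:
        lines.append(f"{row.leaf}\t{repr(row.value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_itol_colorstrip(bundle: AnnotationBundle, path: str | Path) -> None:
    """iTOL color-strip dataset for the taxonomic order of each leaf."""
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        "DATASET_LABEL\ttaxonomic_order",
        "COLOR\t#7f7f7f",
        "DATA",
    ]
    for leaf, color, label in bundle.colorstrip:
        lines.append(f"{leaf}\t{color}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_long_tsv(bundle: AnnotationBundle, path: str | Path) -> None:
    """Renderer-independent long-format twin of the whole bundle."""
    lines = ["leaf\ttrack\tvalue\tmissing\tis_reference"]
    for track in bundle.tracks:
        for row in bundle.tracks[track]:
            lines.append(
                f"{row.leaf}\t{track}\t{repr(row.value)}\t{int(row.missing)}"
                f"\t{int(row.is_reference)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
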