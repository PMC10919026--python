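"""Readers and writers for annotation tables, MAG metadata, trees and results.

Input formats are the ones the upstream tools emit: Prokka feature tables
(tab-separated, header ``locus_tag ftype length_bp gene EC_number COG
product``), Prokka GFF3 (attribute spelling ``eC_number``), a MAG metadata
TSV carrying assembly size, CheckM completeness/contamination and the
GTDB-Tk classification string, and Newick trees.  Assembly size is supplied
out-of-band rather than summed from gene spans because gene densities are
normalised by the total assembled contig size.

All result writers emit plain TSV/JSON; density columns are serialised at
full precision (``repr`` of the float, which round-trips exactly) next to a
display-rounded column.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from gffutils.feature import feature_from_line

GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
SAMPLE_KINDS = ("metagenome", "mag")

_EC_SPLIT_RE = re.compile(r"[,\s]+")


class AnnotationFormatError(ValueError):
    """An input file does not conform to its declared format."""


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene feature."""

    locus_tag: str
    ftype: str
    length_bp: int
    ec_numbers: frozenset[str] = field(default_factory=frozenset)
    product: str = ""


@dataclass
class AnnotationTable:
    """Parsed per-sample gene features with optional EC assignments."""

    sample_id: str
    sample_kind: str
    size_bp: int
    features: list[FeatureRecord]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise AnnotationFormatError("sample_id must be non-empty")
        if self.sample_kind not in SAMPLE_KINDS:
            raise AnnotationFormatError(
                f"sample_kind must be one of {SAMPLE_KINDS}, got {self.sample_kind!r}"
            )
        if self.size_bp <= 0:
            raise AnnotationFormatError(
                f"{self.sample_id}: size_bp must be positive, got {self.size_bp}"
            )


@dataclass(frozen=True)
class MagRecord:
    """MAG metadata: assembly size, quality estimates and GTDB classification."""

    mag_id: str
    host_sample: str
    size_bp: int
    completeness_pct: float
    contamination_pct: float
    gtdb_string: str

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise AnnotationFormatError(f"{self.mag_id}: size_bp must be positive")
        if not 0 <= self.completeness_pct <= 100:
            raise AnnotationFormatError(
                f"{self.mag_id}: completeness {self.completeness_pct} outside [0, 100]"
            )
        if self.contamination_pct < 0:
            raise AnnotationFormatError(
                f"{self.mag_id}: contamination {self.contamination_pct} negative"
            )
        validate_gtdb_string(self.gtdb_string, context=self.mag_id)


def validate_gtdb_string(s: str, context: str = "") -> None:
    """Require the literal ``unclassified`` or exactly 7 prefixed rank fields."""
    if s == "unclassified":
        return
    fields = s.split(";")
    where = f"{context}: " if context else ""
    if len(fields) != 7:
        raise AnnotationFormatError(
            f"{where}malformed GTDB string {s!r}: expected 7 ';'-separated fields "
            f"or the literal 'unclassified', got {len(fields)} fields"
        )
    for fld, prefix in zip(fields, GTDB_PREFIXES):
        if not fld.startswith(prefix):
            raise AnnotationFormatError(
                f"{where}malformed GTDB string {s!r}: field {fld!r} lacks prefix {prefix!r}"
            )


def parse_gtdb_string(s: str) -> dict[str, str]:
    """Split a GTDB classification string into a rank → name mapping.

    Empty ranks (prefix with nothing after it) map to ``""``; the literal
    ``unclassified`` maps every rank to ``""``.
    """
    validate_gtdb_string(s)
    if s == "unclassified":
        return {rank: "" for rank in GTDB_RANKS}
    return {
        rank: fld[len(prefix):]
        for rank, prefix, fld in zip(GTDB_RANKS, GTDB_PREFIXES, s.split(";"))
    }


def strip_digit_grouping(text: str) -> int:
    """Normalise a dot/comma-grouped integer (e.g. ``"784.246.579"``) to an int.

    Only for explicitly flagged inputs; plain readers accept bare integers.
    """
    cleaned = text.replace(".", "").replace(",", "").replace(" ", "")
    if not cleaned.isdigit():
        raise AnnotationFormatError(f"cannot parse grouped integer {text!r}")
    return int(cleaned)


# -- Prokka feature tables ----------------------------------------------------

_PROKKA_REQUIRED = ("locus_tag", "ftype", "length_bp", "EC_number")


def _split_ecs(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(tok for tok in _EC_SPLIT_RE.split(cell) if tok)


def read_prokka_tsv(
    path: str | Path, sample_id: str, sample_kind: str, size_bp: int
) -> AnnotationTable:
    """Read a Prokka feature table (.tsv dialect) into an AnnotationTable.

    The EC_number cell may hold several ECs separated by commas or
    whitespace; an empty cell yields an empty set.  Rows are preserved in
    file order.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise AnnotationFormatError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in _PROKKA_REQUIRED if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    dupes = frame["locus_tag"][frame["locus_tag"].duplicated()].unique().tolist()
    if dupes:
        raise AnnotationFormatError(f"{path}: duplicate locus_tag(s): {', '.join(dupes)}")
    features = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        try:
            length = int(getattr(row, "length_bp"))
        except ValueError:
            raise AnnotationFormatError(
                f"{path}: line {idx}: non-integer length_bp {getattr(row, 'length_bp')!r}"
            ) from None
        if length <= 0:
            raise AnnotationFormatError(
                f"{path}: line {idx}: non-positive length_bp {length}"
            )
        features.append(
            FeatureRecord(
                locus_tag=getattr(row, "locus_tag"),
                ftype=getattr(row, "ftype"),
                length_bp=length,
                ec_numbers=_split_ecs(getattr(row, "EC_number")),
                product=getattr(row, "product", ""),
            )
        )
    return AnnotationTable(sample_id, sample_kind, size_bp, features)


# -- Prokka GFF3 --------------------------------------------------------------

def read_gff3(
    path: str | Path, sample_id: str, sample_kind: str, size_bp: int
) -> AnnotationTable:
    """Read a Prokka GFF3 into an AnnotationTable equivalent to the TSV reader.

    Features are identified by the ``locus_tag`` (fallback ``ID``) attribute
    and ECs by Prokka's ``eC_number`` attribute.  Coordinates are 1-based
    inclusive and are used only to derive the feature length.  A trailing
    ``##FASTA`` section is ignored.
    """
    features: list[FeatureRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: unparseable GFF3 record: {exc}"
                ) from exc
            if feat.start is None or feat.end is None:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: feature without coordinates"
                )
            if feat.start > feat.end:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: start {feat.start} > end {feat.end}"
                )
            attrs = feat.attributes
            locus = (attrs.get("locus_tag") or attrs.get("ID") or [None])[0]
            if locus is None:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: feature lacks locus_tag/ID attribute"
                )
            if locus in seen:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: duplicate locus_tag {locus!r}"
                )
            seen.add(locus)
            ecs = frozenset(
                tok for cell in attrs.get("eC_number", []) for tok in _split_ecs(cell)
            )
            features.append(
                FeatureRecord(
                    locus_tag=locus,
                    ftype=feat.featuretype,
                    length_bp=feat.end - feat.start + 1,
                    ec_numbers=ecs,
                    product=(attrs.get("product") or [""])[0],
                )
            )
    return AnnotationTable(sample_id, sample_kind, size_bp, features)


# -- MAG metadata -------------------------------------------------------------

_MAG_REQUIRED = (
    "mag_id", "host_sample", "size_bp", "completeness_pct", "contamination_pct",
    "gtdb_classification",
)


def read_mag_metadata(path: str | Path) -> list[MagRecord]:
    """Read the MAG metadata TSV (one row per MAG); invariants enforced."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise AnnotationFormatError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in _MAG_REQUIRED if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records = []
    for row in frame.itertuples(index=False):
        try:
            records.append(
                MagRecord(
                    mag_id=row.mag_id,
                    host_sample=row.host_sample,
                    size_bp=int(row.size_bp),
                    completeness_pct=float(row.completeness_pct),
                    contamination_pct=float(row.contamination_pct),
                    gtdb_string=row.gtdb_classification,
                )
            )
        except ValueError as exc:
            if isinstance(exc, AnnotationFormatError):
                raise
            raise AnnotationFormatError(f"{path}: {row.mag_id}: {exc}") from exc
    dupes = frame["mag_id"][frame["mag_id"].duplicated()].unique().tolist()
    if dupes:
        raise AnnotationFormatError(f"{path}: duplicate mag_id(s): {', '.join(dupes)}")
    return records


# -- trees --------------------------------------------------------------------

@dataclass
class TreeData:
    """A parsed tree plus its leaf labels (file order) and match report."""

    tree: dendropy.Tree
    leaf_labels: list[str]
    unmatched_leaves: list[str]
    missing_mags: list[str]


def read_tree(path: str | Path, mag_ids: Optional[Iterable[str]] = None) -> TreeData:
    """Parse a Newick tree; optionally cross-check leaves against MAG ids.

    Leaves absent from the metadata and metadata MAGs absent from the tree
    are reported (never fatal — reference leaves are legitimate).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise AnnotationFormatError(f"{path}: unparseable Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if mag_ids is None:
        unmatched, missing = [], []
    else:
        mag_set = set(mag_ids)
        unmatched = [lbl for lbl in labels if lbl not in mag_set]
        missing = sorted(mag_set - set(labels))
    return TreeData(tree, labels, unmatched, missing)


# -- result writers -----------------------------------------------------------

def _fmt_full(x: float) -> str:
    return repr(float(x))


def write_function_counts(profile, catalog, path: str | Path) -> None:
    """Per-sample function-count table (sample_id, ec, enzyme_name, role,
    mechanism, n_genes), sorted by EC."""
    rows = []
    for ec in sorted(profile.counts):
        fn = catalog.get(ec)
        rows.append(
            {
                "sample_id": profile.sample_id,
                "ec": ec,
                "enzyme_name": fn.name if fn else "",
                "role": fn.role if fn else "",
                "mechanism": fn.mechanism if fn else "",
                "n_genes": profile.counts[ec],
            }
        )
    pd.DataFrame(
        rows, columns=["sample_id", "ec", "enzyme_name", "role", "mechanism", "n_genes"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


_DENSITY_COLUMNS = ["sample_id", "key", "level", "n_genes", "density", "density_display"]


def write_density_long(records: Sequence, path: str | Path) -> None:
    """Long-format density table; full-precision plus display-rounded column."""
    with open(path, "w") as fh:
        fh.write("\t".join(_DENSITY_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.sample_id, r.key, r.level, str(r.n_genes),
                     _fmt_full(r.density), str(r.density_display)]
                )
                + "\n"
            )


def read_density_long(path: str | Path) -> pd.DataFrame:
    """Re-read a long-format density table at full precision."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "key": str, "level": str, "n_genes": int,
               "density": float, "density_display": float},
        float_precision="round_trip",
    )


def write_density_matrix(records: Sequence, path: str | Path) -> None:
    """Matrix export: rows = ECs or clusters, columns = samples, full precision."""
    samples = sorted({r.sample_id for r in records})
    keys = sorted({r.key for r in records})
    values = {(r.key, r.sample_id): r.density for r in records}
    with open(path, "w") as fh:
        fh.write("key\t" + "\t".join(samples) + "\n")
        for key in keys:
            cells = [_fmt_full(values.get((key, s), 0.0)) for s in samples]
            fh.write(key + "\t" + "\t".join(cells) + "\n")


def write_json(payload: dict, path: str | Path) -> None:
    """Deterministic JSON writer used for reports and run manifests."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
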