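"""Synthetic holobiont-microbiome fixtures with planted ground truth.

Generates the same file formats the readers consume — annotation feature
tables, MAG metadata, a Newick tree — with known per-EC gene densities
planted per sample, so every pipeline stage (screen → density → tier →
novelty → compare) can be checked against ground truth without any
download.  Densities, not absolute counts, are the planted quantities,
because density is the pipeline's central statistic.

Two count models: ``exact`` places exactly ``round(density × size_mbp)``
genes of each planted EC (deterministic recovery is then exact), while
``poisson`` draws the count from a Poisson with that mean, emulating the
sampling noise of assembled metagenomes.  Decoy features — genes without
an EC, with a partial EC, or with a complete EC guaranteed absent from the
catalog — exercise the screening filter without ever perturbing a catalog
count.

All randomness flows through the spec seed; a fixed seed yields
byte-identical output bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .catalog import Catalog, load_catalog
from .io import AnnotationTable, FeatureRecord, MagRecord
from .mags import call_novelty, tier_for


class SimulationError(ValueError):
    pass


#: GTDB strings the MAG generator draws from: the bacterial orders reported
#: as enriched in halogen-metabolism functions in macroalgal microbiomes,
#: represented at several novelty levels, plus an unclassifiable entry.
DEFAULT_TAXON_POOL = (
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhodobacterales;f__Rhodobacteraceae;g__Sulfitobacter;s__Sulfitobacter pontiacus",
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhodobacterales;f__Rhodobacteraceae;g__Sulfitobacter;s__",
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhizobiales;f__Stappiaceae;g__;s__",
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Caulobacterales;f__Hyphomonadaceae;g__Hyphomonas;s__",
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Geminicoccales;f__Geminicoccaceae;g__;s__",
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Sphingomonadales;f__Sphingomonadaceae;g__Sphingomonas;s__",
    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Granulosicoccales;f__Granulosicoccaceae;g__Granulosicoccus;s__",
    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas;s__Pseudomonas aeruginosa",
    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__UBA10353;f__;g__;s__",
    "d__Bacteria;p__Myxococcota;c__UBA9160;o__UBA9160;f__;g__;s__",
    "d__Bacteria;p__Actinobacteriota;c__Acidimicrobiia;o__Microtrichales;f__Microtrichaceae;g__;s__",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Flavobacteriales;f__Flavobacteriaceae;g__Maribacter;s__",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__;f__;g__;s__",
    "unclassified",
)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    kind: str  # "metagenome" or "mag"
    size_bp: int


@dataclass
class BackgroundSpec:
    """Decoy features per sample: no-EC, partial-EC and non-catalog-EC genes."""

    n_decoys: int = 50
    decoy_ec_class: int = 9  # EC top-level class reserved for decoys


@dataclass
class MagBlockSpec:
    """MAG metadata generation: quality mix, taxon pool, boundary cases."""

    n_mags: int = 0
    host_samples: tuple[str, ...] = ()
    p_high: float = 0.2
    p_medium: float = 0.7
    taxon_pool: tuple[str, ...] = DEFAULT_TAXON_POOL
    #: explicit (completeness, contamination) pairs applied to the first
    #: MAGs, for boundary-case testing (e.g. completeness exactly 90.0)
    boundary_cases: tuple[tuple[float, float], ...] = ()


@dataclass
class SimulationSpec:
    seed: int
    samples: list[SampleSpec]
    planted: dict[tuple[str, str], float]  # (sample_id, ec) -> genes/Mbp
    count_model: str = "exact"
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    mag_block: MagBlockSpec = field(default_factory=MagBlockSpec)

    def validate(self, catalog: Catalog) -> None:
        if self.count_model not in ("exact", "poisson"):
            raise SimulationError(f"unknown count_model {self.count_model!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate sample_id in spec")
        for s in self.samples:
            if s.size_bp <= 0:
                raise SimulationError(f"{s.sample_id}: size_bp must be positive")
        for (sample_id, ec), density in self.planted.items():
            if sample_id not in ids:
                raise SimulationError(f"planted EC for unknown sample {sample_id!r}")
            if ec not in catalog:
                raise SimulationError(f"planted EC {ec} not in catalog")
            if density < 0:
                raise SimulationError(f"planted density for {ec} negative")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "samples": [
                {"sample_id": s.sample_id, "kind": s.kind, "size_bp": s.size_bp}
                for s in self.samples
            ],
            "planted": [
                {"sample_id": sid, "ec": ec, "density": d}
                for (sid, ec), d in self.planted.items()
            ],
            "count_model": self.count_model,
            "background": {
                "n_decoys": self.background.n_decoys,
                "decoy_ec_class": self.background.decoy_ec_class,
            },
            "mag_block": {
                "n_mags": self.mag_block.n_mags,
                "host_samples": list(self.mag_block.host_samples),
                "p_high": self.mag_block.p_high,
                "p_medium": self.mag_block.p_medium,
                "taxon_pool": list(self.mag_block.taxon_pool),
                "boundary_cases": [list(b) for b in self.mag_block.boundary_cases],
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationSpec":
        bg = doc.get("background", {})
        mb = doc.get("mag_block", {})
        return cls(
            seed=int(doc["seed"]),
            samples=[
                SampleSpec(d["sample_id"], d.get("kind", "metagenome"), int(d["size_bp"]))
                for d in doc["samples"]
            ],
            planted={
                (d["sample_id"], d["ec"]): float(d["density"])
                for d in doc.get("planted", [])
            },
            count_model=doc.get("count_model", "exact"),
            background=BackgroundSpec(
                n_decoys=int(bg.get("n_decoys", 50)),
                decoy_ec_class=int(bg.get("decoy_ec_class", 9)),
            ),
            mag_block=MagBlockSpec(
                n_mags=int(mb.get("n_mags", 0)),
                host_samples=tuple(mb.get("host_samples", ())),
                p_high=float(mb.get("p_high", 0.2)),
                p_medium=float(mb.get("p_medium", 0.7)),
                taxon_pool=tuple(mb.get("taxon_pool", DEFAULT_TAXON_POOL)),
                boundary_cases=tuple(
                    (float(a), float(b)) for a, b in mb.get("boundary_cases", ())
                ),
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GroundTruth:
    """What was planted, per sample and per MAG."""

    count_model: str
    samples: dict[str, dict]  # sample_id -> {size_bp, per_ec: {ec: {...}}}
    mags: dict[str, dict]  # mag_id -> {tier, novelty, ...}

    def to_dict(self) -> dict:
        return {
            "count_model": self.count_model,
            "samples": self.samples,
            "mags": self.mags,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(doc["count_model"], doc["samples"], doc["mags"])


@dataclass
class Bundle:
    """In-memory simulation output plus the files written (if any)."""

    tables: dict[str, AnnotationTable]
    mags: list[MagRecord]
    newick: str
    ground_truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


# -- feature generation -------------------------------------------------------

def _decoy_ec(rng: np.random.Generator, ec_class: int, catalog: Catalog) -> str:
    while True:
        ec = f"{ec_class}.{rng.integers(1, 100)}.{rng.integers(1, 100)}.{rng.integers(1, 100)}"
        if ec not in catalog:
            return ec


def _sample_features(
    spec: SimulationSpec,
    sample: SampleSpec,
    catalog: Catalog,
    rng: np.random.Generator,
) -> tuple[list[FeatureRecord], dict[str, int]]:
    size_mbp = sample.size_bp / 1e6
    planted_counts: dict[str, int] = {}
    for (sid, ec), density in sorted(spec.planted.items()):
        if sid != sample.sample_id:
            continue
        mean = density * size_mbp
        if spec.count_model == "exact":
            count = int(round(mean))
        else:
            count = int(rng.poisson(mean))
        planted_counts[ec] = count
    features: list[FeatureRecord] = []
    for ec in sorted(planted_counts):
        fn = catalog.get(ec)
        for _ in range(planted_counts[ec]):
            features.append(
                FeatureRecord(
                    locus_tag="",  # assigned after shuffling
                    ftype="CDS",
                    length_bp=int(rng.integers(150, 4500)),
                    ec_numbers=frozenset([ec]),
                    product=fn.name if fn else "planted gene",
                )
            )
    for _ in range(spec.background.n_decoys):
        kind = rng.random()
        if kind < 0.5:
            ecs: frozenset[str] = frozenset()
            product = "hypothetical protein"
        elif kind < 0.85:
            ecs = frozenset([_decoy_ec(rng, spec.background.decoy_ec_class, catalog)])
            product = "decoy enzyme"
        else:
            ecs = frozenset()  # partial EC strings never reach the catalog anyway
            product = "putative hydrolase"
            ecs = frozenset(["3.8.1.-"])
        features.append(
            FeatureRecord("", "CDS", int(rng.integers(150, 4500)), ecs, product)
        )
    order = rng.permutation(len(features))
    shuffled = [features[i] for i in order]
    final = [
        FeatureRecord(
            locus_tag=f"{sample.sample_id}_{i + 1:05d}",
            ftype=f.ftype,
            length_bp=f.length_bp,
            ec_numbers=f.ec_numbers,
            product=f.product,
        )
        for i, f in enumerate(shuffled)
    ]
    return final, planted_counts


def _draw_quality(
    mb: MagBlockSpec, index: int, rng: np.random.Generator
) -> tuple[float, float]:
    if index < len(mb.boundary_cases):
        return mb.boundary_cases[index]
    u = rng.random()
    if u < mb.p_high:
        return (
            float(np.round(90.0 + rng.random() * 10.0, 2)),  # (90, 100]
            float(np.round(rng.random() * 4.9, 2)),
        )
    if u < mb.p_high + mb.p_medium:
        return (
            float(np.round(50.0 + rng.random() * 39.9, 2)),
            float(np.round(rng.random() * 9.9, 2)),
        )
    return (
        float(np.round(rng.random() * 49.0, 2)),
        float(np.round(rng.random() * 20.0, 2)),
    )


def _random_bifurcating_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Random topology by successive joins; branch lengths U(0.01, 0.5)."""
    nodes = [lbl for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        bl_a = 0.01 + rng.random() * 0.49
        bl_b = 0.01 + rng.random() * 0.49
        joined = f"({a}:{bl_a:.6f},{b}:{bl_b:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    return nodes[0] + ";"


# -- top-level ----------------------------------------------------------------

def simulate(
    spec: SimulationSpec,
    catalog: Optional[Catalog] = None,
    out_dir: str | Path | None = None,
) -> Bundle:
    """Run the generator; optionally write the file bundle under *out_dir*.

    Files written: ``<sample_id>.tsv`` per sample (feature-table dialect),
    ``mags.tsv`` and ``tree.nwk`` when the MAG block is non-empty, and
    ``ground_truth.json``.
    """
    if catalog is None:
        catalog = load_catalog()
    spec.validate(catalog)
    rng = np.random.default_rng(spec.seed)

    tables: dict[str, AnnotationTable] = {}
    gt_samples: dict[str, dict] = {}
    for sample in spec.samples:
        features, planted_counts = _sample_features(spec, sample, catalog, rng)
        tables[sample.sample_id] = AnnotationTable(
            sample.sample_id, sample.kind, sample.size_bp, features
        )
        size_mbp = sample.size_bp / 1e6
        gt_samples[sample.sample_id] = {
            "kind": sample.kind,
            "size_bp": sample.size_bp,
            "per_ec": {
                ec: {
                    "target_density": spec.planted[(sample.sample_id, ec)],
                    "count": count,
                    "density": count / size_mbp,
                }
                for ec, count in sorted(planted_counts.items())
            },
        }

    # MAG metadata: sample entries of kind "mag" first, then metadata-only MAGs
    mag_ids = [s.sample_id for s in spec.samples if s.kind == "mag"]
    extra = spec.mag_block.n_mags - len(mag_ids)
    taken, counter = set(mag_ids), 0
    while extra > 0:
        counter += 1
        name = f"MAG{counter:03d}"
        if name not in taken:
            mag_ids.append(name)
            taken.add(name)
            extra -= 1
    hosts = spec.mag_block.host_samples or tuple(
        s.sample_id for s in spec.samples if s.kind == "metagenome"
    ) or ("S1",)
    mags: list[MagRecord] = []
    gt_mags: dict[str, dict] = {}
    sizes_by_id = {s.sample_id: s.size_bp for s in spec.samples}
    for i, mag_id in enumerate(mag_ids):
        comp, cont = _draw_quality(spec.mag_block, i, rng)
        gtdb = spec.mag_block.taxon_pool[
            int(rng.integers(0, len(spec.mag_block.taxon_pool)))
        ]
        mag = MagRecord(
            mag_id=mag_id,
            host_sample=hosts[i % len(hosts)],
            size_bp=int(sizes_by_id.get(mag_id, rng.integers(1_500_000, 8_000_000))),
            completeness_pct=comp,
            contamination_pct=cont,
            gtdb_string=gtdb,
        )
        mags.append(mag)
        gt_mags[mag_id] = {
            "host_sample": mag.host_sample,
            "completeness_pct": comp,
            "contamination_pct": cont,
            "gtdb": gtdb,
            "tier": tier_for(comp, cont),
            "novelty": call_novelty(mag).novelty,
        }

    newick = _random_bifurcating_newick(mag_ids, rng) if mag_ids else ""
    ground_truth = GroundTruth(spec.count_model, gt_samples, gt_mags)
    bundle = Bundle(tables, mags, newick, ground_truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample_id, table in tables.items():
            p = out / f"{sample_id}.tsv"
            write_annotation_tsv(table, p)
            bundle.paths[f"annotations/{sample_id}"] = p
        if mags:
            p = out / "mags.tsv"
            write_mag_metadata_tsv(mags, p)
            bundle.paths["mag_metadata"] = p
            p = out / "tree.nwk"
            p.write_text(newick + "\n")
            bundle.paths["tree"] = p
        p = out / "ground_truth.json"
        with open(p, "w") as fh:
            json.dump(ground_truth.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        bundle.paths["ground_truth"] = p
    return bundle


# -- serializers (fixture writers in the reader dialects) ---------------------

_TSV_HEADER = ["locus_tag", "ftype", "length_bp", "gene", "EC_number", "COG", "product"]


def write_annotation_tsv(table: AnnotationTable, path: str | Path) -> None:
    """Serialise an AnnotationTable in the feature-table TSV dialect."""
    lines = ["\t".join(_TSV_HEADER)]
    for f in table.features:
        ecs = ",".join(sorted(f.ec_numbers))
        lines.append(
            "\t".join([f.locus_tag, f.ftype, str(f.length_bp), "", ecs, "", f.product])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_gff3(table: AnnotationTable, path: str | Path) -> None:
    """Serialise an AnnotationTable as GFF3 (the paired-dialect twin).

    Features are laid head-to-tail on one synthetic contig so that
    ``end - start + 1`` reproduces each feature's length exactly.
    """
    lines = ["##gff-version 3"]
    cursor = 1
    for f in table.features:
        start, end = cursor, cursor + f.length_bp - 1
        cursor = end + 101
        attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
        for ec in sorted(f.ec_numbers):
            attrs.append(f"eC_number={ec}")
        if f.product:
            attrs.append(f"product={f.product}")
        lines.append(
            "\t".join(
                ["contig_1", "sim", f.ftype, str(start), str(end), ".", "+", "0",
                 ";".join(attrs)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_mag_metadata_tsv(mags: Sequence[MagRecord], path: str | Path) -> None:
    lines = [
        "\t".join(
            ["mag_id", "host_sample", "size_bp", "completeness_pct",
             "contamination_pct", "gtdb_classification"]
        )
    ]
    for m in mags:
        lines.append(
            "\t".join(
                [m.mag_id, m.host_sample, str(m.size_bp), repr(m.completeness_pct),
                 repr(m.contamination_pct), m.gtdb_string]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- recovery -----------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Pipeline outputs vs planted ground truth."""

    count_model: str
    per_sample: dict[str, dict]
    per_mag: dict[str, dict]

    @property
    def counts_exact(self) -> bool:
        return all(d["counts_match"] for d in self.per_sample.values())

    @property
    def densities_exact(self) -> bool:
        return all(d["densities_match"] for d in self.per_sample.values())

    @property
    def labels_exact(self) -> bool:
        return all(
            d["tier_match"] and d["novelty_match"] for d in self.per_mag.values()
        )

    def to_dict(self) -> dict:
        return {
            "count_model": self.count_model,
            "counts_exact": self.counts_exact,
            "densities_exact": self.densities_exact,
            "labels_exact": self.labels_exact,
            "per_sample": self.per_sample,
            "per_mag": self.per_mag,
        }


def recovery_check(
    ground_truth: GroundTruth,
    profiles: dict[str, "object"],
    tiers: Optional[dict[str, str]] = None,
    novelties: Optional[dict[str, str]] = None,
) -> RecoveryReport:
    """Compare screened profiles (and optional tier/novelty calls) with the
    planted truth.

    For the exact count model agreement is expected to be exact; for the
    Poisson model the per-sample relative density error is reported, not
    asserted — it is bounded by Poisson sampling noise.
    """
    per_sample: dict[str, dict] = {}
    for sample_id, truth in ground_truth.samples.items():
        profile = profiles.get(sample_id)
        planted = {ec: d["count"] for ec, d in truth["per_ec"].items() if d["count"] > 0}
        recovered = dict(profile.counts) if profile is not None else {}
        size_mbp = truth["size_bp"] / 1e6
        rel_errors = {}
        for ec, d in truth["per_ec"].items():
            target = d["target_density"]
            got = recovered.get(ec, 0) / size_mbp
            rel_errors[ec] = abs(got - target) / target if target > 0 else 0.0
        densities_match = all(
            recovered.get(ec, 0) / size_mbp == d["density"]
            for ec, d in truth["per_ec"].items()
        )
        per_sample[sample_id] = {
            "counts_match": recovered == planted,
            "densities_match": densities_match,
            "n_planted_ecs": len(planted),
            "n_recovered_ecs": len(recovered),
            "max_rel_density_error_vs_target": max(rel_errors.values(), default=0.0),
        }
    per_mag: dict[str, dict] = {}
    for mag_id, truth in ground_truth.mags.items():
        per_mag[mag_id] = {
            "tier_match": tiers is None or tiers.get(mag_id) == truth["tier"],
            "novelty_match": novelties is None
            or novelties.get(mag_id) == truth["novelty"],
        }
    return RecoveryReport(ground_truth.count_model, per_sample, per_mag)
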