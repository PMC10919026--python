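"""Curated halogen-metabolism enzyme catalog.

The reference model is a catalog of enzyme functions, each identified by a
complete four-field EC number, that participate in the microbial metabolism
of organohalogens.  Functions carry a *role* — ``halogenase`` or
``dehalogenase`` for enzymes directly forming or breaking carbon–halogen
bonds (the "direct" subset), ``auxiliary`` for enzymes acting upstream or
downstream of the halogenation/dehalogenation step — a *mechanism* flag for
dehalogenases (hydrolytic carbon–halogen hydrolases of the EC 3.8.1.x family
vs everything else), a pathway *direction*, and memberships in named
function clusters grouped by the halogenated molecule degraded or the
halometabolite produced.

The packaged catalog reproduces the published structure: 161 functions of
which 42 are direct (16 halogenases + 26 dehalogenases) and 119 auxiliary,
organised into 32 clusters (23 degradative, 9 biosynthetic).  Entries in EC
class 8 (unassigned in the real EC system) are synthetic placeholders that
keep the counts faithful where the underlying curation is not public; they
are labelled as such in their names and in the catalog version string.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

ROLES = ("halogenase", "dehalogenase", "auxiliary")
MECHANISMS = ("hydrolytic", "non_hydrolytic", "not_applicable")
DIRECTIONS = ("halogenation", "dehalogenation")
CLUSTER_DIRECTIONS = ("degradative", "biosynthetic")

#: EC prefix of the carbon–halogen hydrolases ("hydrolytic dehalogenases").
HYDROLYTIC_PREFIX = "3.8.1."

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

#: Published structure of the reference catalog, used by
#: :func:`validate_published_counts`.
EXPECTED_COUNTS = {
    "total": 161,
    "direct": 42,
    "halogenase": 16,
    "dehalogenase": 26,
    "auxiliary": 119,
    "clusters_degradative": 23,
    "clusters_biosynthetic": 9,
}


class CatalogError(ValueError):
    """A catalog file or in-memory catalog violates a structural invariant."""


def is_complete_ec(ec: str) -> bool:
    """True iff *ec* is a complete four-field EC number (all fields numeric)."""
    return bool(_EC_RE.match(ec))


@dataclass(frozen=True)
class HalogenFunction:
    """One catalog entry: a halogen-metabolism enzyme function."""

    ec: str
    name: str
    role: str
    mechanism: str
    direction: str
    cluster_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_direct(self) -> bool:
        """Whether the enzyme itself forms or breaks a carbon–halogen bond."""
        return self.role in ("halogenase", "dehalogenase")

    def validate(self) -> None:
        if not is_complete_ec(self.ec):
            raise CatalogError(
                f"partial or malformed EC number {self.ec!r} ({self.name!r}): "
                "only complete a.b.c.d EC numbers are admitted"
            )
        if self.role not in ROLES:
            raise CatalogError(f"{self.ec}: unknown role {self.role!r}")
        if self.mechanism not in MECHANISMS:
            raise CatalogError(f"{self.ec}: unknown mechanism {self.mechanism!r}")
        if self.direction not in DIRECTIONS:
            raise CatalogError(f"{self.ec}: unknown direction {self.direction!r}")
        if self.role == "dehalogenase":
            expected = (
                "hydrolytic" if self.ec.startswith(HYDROLYTIC_PREFIX) else "non_hydrolytic"
            )
            if self.mechanism != expected:
                raise CatalogError(
                    f"{self.ec}: dehalogenase mechanism must be {expected!r} "
                    f"(EC {'does' if expected == 'hydrolytic' else 'does not'} "
                    f"start with {HYDROLYTIC_PREFIX!r}), got {self.mechanism!r}"
                )
            if self.direction != "dehalogenation":
                raise CatalogError(f"{self.ec}: dehalogenase with direction {self.direction!r}")
        else:
            if self.mechanism != "not_applicable":
                raise CatalogError(
                    f"{self.ec}: mechanism {self.mechanism!r} only applies to dehalogenases"
                )
            if self.role == "halogenase" and self.direction != "halogenation":
                raise CatalogError(f"{self.ec}: halogenase with direction {self.direction!r}")


@dataclass(frozen=True)
class FunctionCluster:
    """A named group of catalog ECs sharing a degraded-molecule or
    produced-metabolite category."""

    cluster_id: str
    name: str
    direction: str
    member_ecs: frozenset[str]

    def validate(self) -> None:
        if self.direction not in CLUSTER_DIRECTIONS:
            raise CatalogError(
                f"cluster {self.cluster_id}: unknown direction {self.direction!r}"
            )
        if not self.member_ecs:
            raise CatalogError(f"cluster {self.cluster_id}: empty member set")


class Catalog:
    """A validated halogen-function catalog plus its cluster scheme.

    Structural invariants (unique complete ECs, resolved cluster members,
    role/mechanism/direction consistency, no mixed-direction clusters) are
    enforced at construction; the published counts are *reported*, not
    enforced, by :func:`validate_published_counts`, so user-supplied catalogs of
    any size are accepted.
    """

    def __init__(
        self,
        functions: Iterable[HalogenFunction],
        clusters: Iterable[FunctionCluster] = (),
        version: str = "unversioned",
    ):
        self.functions: tuple[HalogenFunction, ...] = tuple(functions)
        self.clusters: tuple[FunctionCluster, ...] = tuple(clusters)
        self.version = version
        self._by_ec: dict[str, HalogenFunction] = {}
        self._by_cluster: dict[str, FunctionCluster] = {}
        self._validate()
        payload = self.version + "|" + ",".join(sorted(self._by_ec))
        #: Content fingerprint used to detect profiles screened against
        #: different catalogs.
        self.checksum: str = hashlib.sha1(payload.encode()).hexdigest()

    def _validate(self) -> None:
        for fn in self.functions:
            fn.validate()
            if fn.ec in self._by_ec:
                raise CatalogError(f"duplicate EC number {fn.ec} in catalog")
            self._by_ec[fn.ec] = fn
        for cl in self.clusters:
            cl.validate()
            if cl.cluster_id in self._by_cluster:
                raise CatalogError(f"duplicate cluster id {cl.cluster_id}")
            self._by_cluster[cl.cluster_id] = cl
            member_dir = (
                "dehalogenation" if cl.direction == "degradative" else "halogenation"
            )
            for ec in cl.member_ecs:
                fn = self._by_ec.get(ec)
                if fn is None:
                    raise CatalogError(
                        f"cluster {cl.cluster_id} references EC {ec} absent from catalog"
                    )
                if fn.direction != member_dir:
                    raise CatalogError(
                        f"cluster {cl.cluster_id} ({cl.direction}) contains EC {ec} "
                        f"with pathway direction {fn.direction}"
                    )
        # function.cluster_ids must mirror the cluster rosters
        membership: dict[str, set[str]] = {ec: set() for ec in self._by_ec}
        for cl in self.clusters:
            for ec in cl.member_ecs:
                membership[ec].add(cl.cluster_id)
        for fn in self.functions:
            if set(fn.cluster_ids) != membership[fn.ec]:
                raise CatalogError(
                    f"{fn.ec}: cluster_ids {sorted(fn.cluster_ids)} inconsistent with "
                    f"cluster rosters {sorted(membership[fn.ec])}"
                )

    # -- queries -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.functions)

    def __contains__(self, ec: str) -> bool:
        return ec in self._by_ec

    @property
    def ecs(self) -> frozenset[str]:
        return frozenset(self._by_ec)

    @property
    def direct_ecs(self) -> frozenset[str]:
        return frozenset(fn.ec for fn in self.functions if fn.is_direct)

    def get(self, ec: str) -> Optional[HalogenFunction]:
        return self._by_ec.get(ec)

    def cluster(self, cluster_id: str) -> FunctionCluster:
        try:
            return self._by_cluster[cluster_id]
        except KeyError:
            raise CatalogError(f"unknown cluster id {cluster_id!r}") from None

    def role_counts(self) -> dict[str, int]:
        counts = {role: 0 for role in ROLES}
        for fn in self.functions:
            counts[fn.role] += 1
        return counts


def lookup(catalog: Catalog, ec: str) -> Optional[HalogenFunction]:
    """Exact-match a complete EC number against the catalog.

    Matching is exact string equality on the four-field EC; there is no
    wildcard or prefix matching (family labels such as "3.8.1.X" are
    narrative, not matchable).  Raises :class:`CatalogError` for a
    syntactically partial EC; returns ``None`` when absent.
    """
    if not is_complete_ec(ec):
        raise CatalogError(f"cannot look up partial EC number {ec!r}")
    return catalog.get(ec)


# -- loading -----------------------------------------------------------------

def _packaged_catalog_path():
    return resources.files("halomet.data").joinpath("catalog.json")


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load a catalog from JSON; with no *path*, load the packaged catalog.

    The file must carry top-level keys ``version``, ``functions`` (objects
    with keys ec, name, role, mechanism, direction, cluster_ids) and
    ``clusters`` (objects with keys cluster_id, name, direction, member_ecs).
    All structural invariants are checked; errors name the offending entry.
    """
    if path is None:
        raw = _packaged_catalog_path().read_text()
    else:
        raw = Path(path).read_text()
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"catalog file is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise CatalogError("catalog file must hold a JSON object")
    for key in ("functions", "clusters"):
        if key not in doc or not isinstance(doc[key], list):
            raise CatalogError(f"catalog file missing list-valued key {key!r}")
    try:
        functions = [
            HalogenFunction(
                ec=str(e["ec"]),
                name=str(e.get("name", "")),
                role=str(e["role"]),
                mechanism=str(e["mechanism"]),
                direction=str(e["direction"]),
                cluster_ids=frozenset(e.get("cluster_ids", ())),
            )
            for e in doc["functions"]
        ]
        clusters = [
            FunctionCluster(
                cluster_id=str(e["cluster_id"]),
                name=str(e.get("name", "")),
                direction=str(e["direction"]),
                member_ecs=frozenset(str(m) for m in e["member_ecs"]),
            )
            for e in doc["clusters"]
        ]
    except KeyError as exc:
        raise CatalogError(f"catalog entry missing required key {exc}") from exc
    return Catalog(functions, clusters, version=str(doc.get("version", "unversioned")))


# -- published-structure report ----------------------------------------------

@dataclass(frozen=True)
class CountCheck:
    name: str
    expected: int
    observed: int

    @property
    def passed(self) -> bool:
        return self.expected == self.observed


@dataclass
class ValidationReport:
    """Observed vs published catalog structure, check by check."""

    checks: list[CountCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def observed(self, name: str) -> int:
        return next(c.observed for c in self.checks if c.name == name)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {"name": c.name, "expected": c.expected, "observed": c.observed,
                 "passed": c.passed}
                for c in self.checks
            ],
        }

    def __str__(self) -> str:
        width = max(len(c.name) for c in self.checks)
        lines = [
            f"{c.name:<{width}}  expected {c.expected:>4}  observed {c.observed:>4}  "
            f"{'PASS' if c.passed else 'FAIL'}"
            for c in self.checks
        ]
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def validate_published_counts(catalog: Catalog) -> ValidationReport:
    """Report the catalog's structure against the published counts.

    Seven checks: total functions (161), direct subset (42), halogenases
    (16), dehalogenases (26), auxiliaries (119), degradative clusters (23),
    biosynthetic clusters (9).  Report-only: failures never block loading.
    """
    roles = catalog.role_counts()
    observed = {
        "total": len(catalog),
        "direct": roles["halogenase"] + roles["dehalogenase"],
        "halogenase": roles["halogenase"],
        "dehalogenase": roles["dehalogenase"],
        "auxiliary": roles["auxiliary"],
        "clusters_degradative": sum(
            1 for cl in catalog.clusters if cl.direction == "degradative"
        ),
        "clusters_biosynthetic": sum(
            1 for cl in catalog.clusters if cl.direction == "biosynthetic"
        ),
    }
    checks = [
        CountCheck(name, EXPECTED_COUNTS[name], observed[name]) for name in EXPECTED_COUNTS
    ]
    return ValidationReport(checks)


# -- TSV curation round-trip --------------------------------------------------

_TSV_COLUMNS = ["ec", "name", "role", "mechanism", "direction", "cluster_ids"]


def functions_to_tsv(catalog: Catalog, path: str | Path) -> None:
    """Export the function table for curation (one function per row;
    cluster_ids semicolon-delimited)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for fn in catalog.functions:
            writer.writerow(
                [fn.ec, fn.name, fn.role, fn.mechanism, fn.direction,
                 ";".join(sorted(fn.cluster_ids))]
            )


def functions_from_tsv(path: str | Path) -> list[HalogenFunction]:
    """Re-import a curated function table written by :func:`functions_to_tsv`."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _TSV_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise CatalogError(f"function TSV missing columns: {', '.join(missing)}")
        return [
            HalogenFunction(
                ec=row["ec"],
                name=row["name"],
                role=row["role"],
                mechanism=row["mechanism"],
                direction=row["direction"],
                cluster_ids=frozenset(
                    x for x in row["cluster_ids"].split(";") if x
                ),
            )
            for row in reader
        ]
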