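"""Core data model and file IO.

Containers for the four kinds of inputs the pipeline consumes — curated
gene catalogs, named gene-set collections (GMT), interactome graphs
(SIF-style TSV), and two-group expression experiments — plus the small
set-algebra helpers that split a catalog against a pathway.

Gene identity is handled uniformly: symbols are matched case-insensitively
and stored upper-case; no alias resolution is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "PATHWAY_COMMONS_TYPES",
    "CatalogEntry",
    "GeneCatalog",
    "GeneSet",
    "GeneSetCollection",
    "Edge",
    "Interactome",
    "ExpressionExperiment",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "read_interactions",
    "write_interactions",
    "read_catalog",
    "read_expression",
    "split_catalog",
]

#: The four directed interaction types retained from Pathway-Commons-style
#: interaction tables when building the directed regulatory graph.
PATHWAY_COMMONS_TYPES = frozenset(
    {
        "controls-state-change-of",
        "controls-expression-of",
        "controls-transport-of",
        "controls-phosphorylation-of",
    }
)


def normalize_symbol(symbol: str) -> str:
    """Upper-case, stripped gene symbol (the package-wide gene identity)."""
    return str(symbol).strip().upper()


def normalize_symbols(symbols: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_symbol(s) for s in symbols)


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    gene: str
    n_studies: int
    source_ids: tuple[str, ...] = ()


@dataclass
class GeneCatalog:
    """Literature-curated disease genes with per-gene study counts.

    Invariants: symbols unique after case normalization; every entry backed
    by at least one study.
    """

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        normd = []
        seen: set[str] = set()
        for e in self.entries:
            g = normalize_symbol(e.gene)
            if g in seen:
                raise ValueError(f"duplicate catalog gene after normalization: {g}")
            if int(e.n_studies) < 1:
                raise ValueError(f"n_studies must be >= 1 for {g}")
            seen.add(g)
            normd.append(CatalogEntry(g, int(e.n_studies), tuple(e.source_ids)))
        self.entries = normd

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries)

    def n_multi_study(self) -> int:
        """Number of genes supported by more than one study."""
        return sum(1 for e in self.entries if e.n_studies > 1)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "gene": [e.gene for e in self.entries],
                "n_studies": [e.n_studies for e in self.entries],
                "source_ids": [";".join(e.source_ids) for e in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.entries)


def read_catalog(path: str | Path) -> GeneCatalog:
    """Read a catalog TSV with columns ``gene`` and ``n_studies``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "n_studies" not in cols:
        raise ValueError(f"catalog file {path} must have columns gene, n_studies")
    entries = []
    for _, row in df.iterrows():
        src = ()
        if "source_ids" in cols and isinstance(row.get(cols["source_ids"]), str):
            src = tuple(s for s in row[cols["source_ids"]].split(";") if s)
        entries.append(CatalogEntry(row[cols["gene"]], int(row[cols["n_studies"]]), src))
    return GeneCatalog(entries)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    genes: frozenset[str]
    category: Optional[str] = None


@dataclass
class GeneSetCollection:
    """Named gene sets with optional category labels (e.g. KEGG main classes)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, GeneSet] = {}
        for name, gs in self.sets.items():
            genes = normalize_symbols(gs.genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = GeneSet(genes, gs.category)
        self.sets = clean

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        categories: Optional[Mapping[str, str]] = None,
    ) -> "GeneSetCollection":
        categories = categories or {}
        return cls(
            {
                name: GeneSet(frozenset(genes), categories.get(name))
                for name, genes in sets.items()
            }
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are collapsed; a repeated set name or a
    line with fewer than three fields is a parse error naming the line.
    The description field doubles as the category label when non-empty and
    not a URL (the common GMT convention).
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = normalize_symbols(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            category = desc if desc and not desc.startswith(("http://", "https://")) else None
            sets[name] = GeneSet(genes, category)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            gs = collection.sets[name]
            desc = gs.category if gs.category else "na"
            fh.write("\t".join([name, desc, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    type: str
    directed: bool


@dataclass
class Interactome:
    """Gene–gene interaction graph.

    Edges carry a free-text type label and a directedness flag. Undirected
    edges are canonicalized to lexicographic endpoint order and duplicate
    (source, target, type, directed) tuples are collapsed, so the edge list
    is a set in disguise. Self-loops are retained (they are reported by
    :meth:`summary` and ignored by cross-set statistics downstream).
    """

    nodes: set[str]
    edges: list[Edge]

    def __post_init__(self) -> None:
        nodes = {normalize_symbol(n) for n in self.nodes}
        seen: set[tuple] = set()
        edges: list[Edge] = []
        for e in self.edges:
            s, t = normalize_symbol(e.source), normalize_symbol(e.target)
            if not e.directed and t < s:
                s, t = t, s
            key = (s, t, e.type, bool(e.directed))
            if key in seen:
                continue
            seen.add(key)
            nodes.add(s)
            nodes.add(t)
            edges.append(Edge(s, t, e.type, bool(e.directed)))
        self.nodes = nodes
        self.edges = edges

    @property
    def n_self_loops(self) -> int:
        return sum(1 for e in self.edges if e.source == e.target)

    def summary(self) -> dict:
        return {
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "n_directed": sum(1 for e in self.edges if e.directed),
            "n_undirected": sum(1 for e in self.edges if not e.directed),
            "n_self_loops": self.n_self_loops,
            "types": sorted({e.type for e in self.edges}),
        }


def read_interactions(
    path: str | Path,
    allowed_types: Iterable[str] = (),
    directed: bool = False,
) -> Interactome:
    """Read a SIF-dialect TSV (``source<TAB>type<TAB>target``) into a graph.

    Rows whose interaction type is not in ``allowed_types`` are dropped;
    an empty ``allowed_types`` keeps every type. ``directed`` sets the
    directedness flag of every retained edge (Pathway-Commons-style tables
    are directed; high-confidence interactome tables are not).
    """
    allowed = frozenset(allowed_types)
    edges: list[Edge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected source<TAB>type<TAB>target"
                )
            source, itype, target = fields[0], fields[1], fields[2]
            if allowed and itype not in allowed:
                continue
            edges.append(Edge(source, target, itype, directed))
    return Interactome(nodes=set(), edges=edges)


def write_interactions(g: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in sorted(g.edges, key=lambda e: (e.source, e.target, e.type)):
            fh.write(f"{e.source}\t{e.type}\t{e.target}\n")


# ---------------------------------------------------------------------------
# Expression experiments
# ---------------------------------------------------------------------------


@dataclass
class ExpressionExperiment:
    """Genes × samples log2-scale expression with two-group labels.

    ``values``: DataFrame indexed by gene symbol, columns are sample ids.
    ``groups``: Series mapping sample id to a group label; testing
    operations require exactly two levels.
    ``detection_p``: optional per-cell detection p-values aligned with
    ``values`` (beadarray-style platforms).
    """

    values: pd.DataFrame
    groups: pd.Series
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        if self.detection_p is not None:
            dp = self.detection_p.copy()
            dp.index = [normalize_symbol(g) for g in dp.index]
            if list(dp.index) != list(self.values.index) or list(dp.columns) != list(
                self.values.columns
            ):
                raise ValueError("detection_p not aligned with values")
            self.detection_p = dp

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    def require_two_groups(self) -> tuple[str, str]:
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(f"need exactly two group levels, found {levels}")
        return levels[0], levels[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionExperiment":
        keep = [g for g in self.values.index if g in set(genes)]
        dp = self.detection_p.loc[keep] if self.detection_p is not None else None
        return ExpressionExperiment(self.values.loc[keep], self.groups, dp)

    def to_tsv(self, matrix_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.groups.rename("group").to_frame().to_csv(groups_path, sep="\t")


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    detection_p_path: Optional[str | Path] = None,
) -> ExpressionExperiment:
    """Read a genes × samples TSV plus a sample→group TSV (columns sample, group)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", index_col=0)
    groups = gdf.iloc[:, 0].astype(str)
    dp = None
    if detection_p_path is not None:
        dp = pd.read_csv(detection_p_path, sep="\t", index_col=0)
    return ExpressionExperiment(values, groups, dp)


# ---------------------------------------------------------------------------
# Catalog / pathway splitting
# ---------------------------------------------------------------------------


def split_catalog(
    catalog: GeneCatalog | Iterable[str], pathway: Iterable[str]
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition catalog genes into pathway members (ds) and the rest (olc).

    ``ds`` = catalog ∩ pathway, ``olc`` = catalog \\ pathway; the two are
    disjoint by construction and their union is the catalog. An empty side
    triggers a warning because downstream set-pair tests degenerate.
    """
    cat_genes = catalog.genes if isinstance(catalog, GeneCatalog) else normalize_symbols(catalog)
    path_genes = normalize_symbols(pathway)
    ds = frozenset(cat_genes & path_genes)
    olc = frozenset(cat_genes - path_genes)
    if not ds:
        warnings.warn("pathway is disjoint from the catalog: ds side is empty")
    if not olc:
        warnings.warn("pathway covers the whole catalog: olc side is empty")
    return ds, olc


def to_json(obj, path: str | Path) -> None:
    """Serialize a result dataclass dict to JSON (stable key order)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
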