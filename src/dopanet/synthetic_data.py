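"""Synthetic inputs with the statistical structure the analyses assume.

Every generator draws from a stream derived from a single spec-level seed
(seed + a per-generator tag), so each stage is independently reproducible
and the whole pipeline is bit-stable under a fixed seed.

The generators emulate, at desk scale:

* a scale-free interactome (preferential attachment) with interaction-type
  labels drawn from the four retained Pathway-Commons types plus decoys,
  and optional planted cross-set edges (the set-pair enrichment signal);
* two-group microarray-like log2 intensity matrices with per-cell
  detection p-values, planted differentially expressed sets whose member
  shifts alternate in sign (so a direction-agnostic set test is required
  to see them), and within-set co-regulation through a shared latent
  factor;
* a curated-catalog sampler whose per-gene study counts follow a
  geometric law (most genes reported once, a long tail of multi-study
  genes);
* confocal-like myelin stacks: a bright horizontal band with known column
  coverage and thickness, per-slice intensity jitter, Gaussian blur and
  Gaussian noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from skimage.filters import gaussian as _gaussian_blur

from .io_model import (
    CatalogEntry,
    Edge,
    ExpressionExperiment,
    GeneCatalog,
    GeneSetCollection,
    Interactome,
    PATHWAY_COMMONS_TYPES,
)
from .myelin_quant import MyelinStack

__all__ = [
    "SyntheticSpec",
    "BACKGROUND_LEVEL",
    "SIGNAL_LEVEL",
    "make_interactome",
    "plant_cross_edges",
    "make_expression",
    "make_catalog",
    "make_myelin_image",
    "default_thresholds",
    "true_coverage_percent",
    "expression_gene_names",
]

#: Image intensity of unlabelled tissue and of the myelin band (arbitrary
#: fluorescence units on a 0–1 scale).
BACKGROUND_LEVEL = 0.1
SIGNAL_LEVEL = 0.8

DECOY_TYPES = ("in-complex-with", "interacts-with")


@dataclass
class SyntheticSpec:
    """Sizes and effect parameters for all generators (one seed rules all)."""

    seed: int = 0
    # expression
    n_genes: int = 500
    n_samples_per_group: int = 10
    delta: float = 1.5  # standardized case-group shift of planted genes
    rho: float = 0.0  # within-set correlation via a shared latent factor
    baseline_mean: float = 8.0  # log2 intensity center
    baseline_sd: float = 1.0  # between-gene baseline spread
    # interactome
    n_nodes: int = 500
    attachment: int = 3  # preferential-attachment edges per new node
    planted_cross_edges: int = 30
    # catalog
    n_catalog_genes: int = 100
    multi_study_p: float = 0.65  # geometric success prob for n_studies
    # image
    image_width: int = 250
    image_height: int = 64
    n_slices: int = 10
    coverage_fraction: float = 0.6
    thickness_px: int = 5
    noise_sd: float = 0.03
    blur_sigma: float = 1.0
    slice_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_group", "n_nodes", "n_catalog_genes",
                     "image_width", "image_height", "n_slices", "thickness_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must lie in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")

    def rng(self, tag: str) -> np.random.Generator:
        """Named substream: seed combined with a stable hash of the tag."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), zlib.crc32(tag.encode())])
        )


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------


def make_interactome(spec: SyntheticSpec, directed: bool = False) -> Interactome:
    """Preferential-attachment graph with random interaction-type labels.

    Produces exactly (n_nodes − attachment) × attachment edges. When
    ``directed`` each edge gets a random orientation.
    """
    if spec.n_nodes < 2:
        raise ValueError("need at least two nodes")
    rng = spec.rng("interactome")
    G = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment, seed=int(rng.integers(2**31))
    )
    types = list(PATHWAY_COMMONS_TYPES) + list(DECOY_TYPES)
    edges = []
    for u, v in sorted(G.edges()):
        ty = types[int(rng.integers(len(types)))]
        if directed and rng.integers(2):
            u, v = v, u
        edges.append(Edge(f"N{u:04d}", f"N{v:04d}", ty, directed))
    nodes = {f"N{i:04d}" for i in range(spec.n_nodes)}
    return Interactome(nodes=nodes, edges=edges)


def plant_cross_edges(
    g: Interactome,
    set_a: Iterable[str],
    set_b: Iterable[str],
    k: int,
    seed: Optional[int] = None,
) -> Interactome:
    """Add exactly ``k`` new undirected cross-set edges, uniformly at random."""
    from .io_model import normalize_symbols

    sa = sorted(normalize_symbols(set_a))
    sb = sorted(normalize_symbols(set_b))
    existing = set()
    for e in g.edges:
        existing.add((e.source, e.target))
        existing.add((e.target, e.source))
    candidates = [
        (a, b) for a in sa for b in sb if a != b and (a, b) not in existing
    ]
    if k > len(candidates):
        raise ValueError(
            f"cannot plant {k} cross edges; only {len(candidates)} absent pairs"
        )
    rng = np.random.default_rng(seed)
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)]
    new_edges = list(g.edges) + [
        Edge(a, b, "interacts-with", False) for a, b in chosen
    ]
    return Interactome(nodes=set(g.nodes), edges=new_edges)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def expression_gene_names(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]


def make_expression(
    spec: SyntheticSpec,
    planted_sets: Optional[GeneSetCollection | Mapping[str, Iterable[str]]] = None,
    share_factor: bool = False,
    anticorrelated: Iterable[str] = (),
) -> ExpressionExperiment:
    """Two-group microarray-like log2 intensities with planted structure.

    Baseline per gene ~ N(baseline_mean, baseline_sd²); unit-variance
    within-gene noise. Genes of each planted set receive (i) a case-group
    shift of ``delta`` standard deviations with alternating sign along the
    set, and (ii) a shared per-sample latent factor with loading √rho
    (noise scaled by √(1−rho) to keep unit variance). ``share_factor``
    makes all planted sets load on one common factor; set names listed in
    ``anticorrelated`` load negatively. Detection p-values decrease
    monotonically with intensity (p = 10^−(y−5), clipped to (0, 1]).
    """
    if planted_sets is None:
        sets: dict[str, frozenset[str]] = {}
    elif isinstance(planted_sets, GeneSetCollection):
        sets = {name: planted_sets[name].genes for name in planted_sets}
    else:
        sets = {name: frozenset(g.upper() for g in gs) for name, gs in planted_sets.items()}
    genes = expression_gene_names(spec)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, members in sets.items():
        unknown = sorted(set(members) - set(genes))
        if unknown:
            raise ValueError(f"planted set {name!r} has genes outside the matrix: {unknown}")

    anticorrelated = set(anticorrelated)
    n = spec.n_samples_per_group
    samples = [f"ctrl_{i:02d}" for i in range(1, n + 1)] + [
        f"case_{i:02d}" for i in range(1, n + 1)
    ]
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples, name="group")
    case = np.array([False] * n + [True] * n)

    rng = spec.rng("expression")
    mu = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.n_genes)
    Y = mu[:, None] + rng.standard_normal((spec.n_genes, 2 * n))

    shared = rng.standard_normal(2 * n) if share_factor else None
    assigned: set[int] = set()
    for name in sorted(sets):
        members = sorted(sets[name])
        idx = [gene_pos[g] for g in members if gene_pos[g] not in assigned]
        assigned.update(idx)
        if not idx:
            continue
        factor = shared if shared is not None else rng.standard_normal(2 * n)
        load = -1.0 if name in anticorrelated else 1.0
        if spec.rho > 0:
            noise = rng.standard_normal((len(idx), 2 * n))
            Y[idx, :] = (
                mu[idx, None]
                + np.sqrt(spec.rho) * load * factor[None, :]
                + np.sqrt(1 - spec.rho) * noise
            )
        signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(idx))])
        Y[np.ix_(idx, np.flatnonzero(case))] += spec.delta * signs[:, None]

    values = pd.DataFrame(Y, index=genes, columns=samples)
    detection_p = pd.DataFrame(
        np.clip(10.0 ** (-(Y - 5.0)), 1e-16, 1.0), index=genes, columns=samples
    )
    return ExpressionExperiment(values, groups, detection_p)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


def make_catalog(
    spec: SyntheticSpec,
    collection: GeneSetCollection,
    enriched_set: Optional[str] = None,
    excess: int = 0,
) -> GeneCatalog:
    """Sample a curated catalog, optionally over-drawing one gene set.

    ``n_catalog_genes`` genes are drawn uniformly without replacement from
    the collection's universe, then ``excess`` additional distinct genes
    from ``enriched_set`` are forced in. Study counts follow a geometric
    law (success probability ``multi_study_p``), giving the many-singleton
    evidence distribution typical of literature curation.
    """
    rng = spec.rng("catalog")
    universe = sorted(collection.all_genes())
    if spec.n_catalog_genes > len(universe):
        raise ValueError("catalog larger than the collection universe")
    chosen = {
        universe[i]
        for i in rng.choice(len(universe), size=spec.n_catalog_genes, replace=False)
    }
    if excess:
        if enriched_set is None or enriched_set not in collection.sets:
            raise ValueError("excess draws require a valid enriched_set name")
        pool = sorted(collection[enriched_set].genes - chosen)
        if excess > len(pool):
            raise ValueError("excess exceeds the remaining genes of the enriched set")
        extra = [pool[i] for i in rng.choice(len(pool), size=excess, replace=False)]
        chosen.update(extra)
    entries = [
        CatalogEntry(g, int(rng.geometric(spec.multi_study_p))) for g in sorted(chosen)
    ]
    return GeneCatalog(entries)


# ---------------------------------------------------------------------------
# Myelin image stacks
# ---------------------------------------------------------------------------


def _band_layout(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Column runs of the myelin band totalling coverage_fraction × width."""
    W = spec.image_width
    cov_px = int(round(spec.coverage_fraction * W))
    if cov_px <= 0:
        return []
    if cov_px >= W:
        return [(0, W)]
    free = W - cov_px
    if free < 8 or cov_px < 10:
        s = int(rng.integers(0, free + 1))
        return [(s, s + cov_px)]
    len1 = cov_px // 2
    len2 = cov_px - len1
    gap = 8 + int(rng.integers(0, free - 8 + 1))
    s1 = int(rng.integers(0, free - gap + 1))
    return [(s1, s1 + len1), (s1 + len1 + gap, s1 + len1 + gap + len2)]


def make_myelin_image(spec: SyntheticSpec) -> MyelinStack:
    """Synthetic mbp:eGFP-like z-stack with known coverage and thickness.

    A horizontal band of ``thickness_px`` rows spans column runs covering
    ``coverage_fraction`` of the width (one interior gap when geometry
    allows). Each of ``n_slices`` slices gets multiplicative intensity
    jitter, Gaussian blur (``blur_sigma``) and additive Gaussian noise
    (``noise_sd``).
    """
    rng = spec.rng("image")
    H, W = spec.image_height, spec.image_width
    runs = _band_layout(spec, rng)
    truth = np.full((H, W), BACKGROUND_LEVEL)
    r0 = (H - spec.thickness_px) // 2
    for s, e in runs:
        truth[r0 : r0 + spec.thickness_px, s:e] = SIGNAL_LEVEL
    slices = []
    for _ in range(spec.n_slices):
        jit = 1.0 + rng.normal(0.0, spec.slice_jitter_sd)
        sl = BACKGROUND_LEVEL + (truth - BACKGROUND_LEVEL) * jit
        if spec.blur_sigma > 0:
            sl = _gaussian_blur(sl, sigma=spec.blur_sigma, preserve_range=True)
        if spec.noise_sd > 0:
            sl = sl + rng.normal(0.0, spec.noise_sd, size=sl.shape)
        slices.append(np.clip(sl, 0.0, None))
    return MyelinStack(np.stack(slices))


def default_thresholds() -> tuple[float, float]:
    """Midpoint lower threshold between tissue background and band signal."""
    return (BACKGROUND_LEVEL + SIGNAL_LEVEL) / 2.0, float("inf")


def true_coverage_percent(spec: SyntheticSpec) -> float:
    """Ground-truth coverage after rounding the band to whole pixels."""
    cov_px = min(int(round(spec.coverage_fraction * spec.image_width)), spec.image_width)
    return 100.0 * cov_px / spec.image_width
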