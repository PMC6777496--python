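"""Kappa-based fuzzy clustering of annotation terms.

Terms are compared pairwise with Cohen's kappa computed over a gene universe:
for terms i and j the 2x2 agreement table counts genes annotated by both (a),
by exactly one (b, c) and by neither (d), and

    kappa = (Po - Pe) / (1 - Pe),
    Po = (a + d) / T,
    Pe = ((a + b)(a + c) + (c + d)(b + d)) / T^2.

Pairs sharing fewer than ``min_gene_overlap`` genes are treated as unrelated
(kappa forced to 0).  Candidate seeds are grown around every term from its
kappa neighbours, kept when large enough and internally tight, and merged
whenever two groups share at least ``linkage_threshold`` of the smaller
group's members.  The heuristic mirrors the DAVID functional annotation
clustering tool with its published defaults (overlap 5, seed sizes 5,
linkage 0.5, kappa 0.20), but the merge order is made fully deterministic:
highest sharing fraction first, ties by smaller merged size, then by
lexicographically smallest member tuple.

After clustering, members failing the enrichment FDR cutoff are pruned and
each surviving cluster is summarised (representative term, gene union,
enrichment score = -log10 geometric mean of member raw p-values, mean fold
enrichment).  A deterministic squarified treemap layout is provided for
reporting, with rectangle area proportional to a cluster's gene-union size.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ConfigurationError, log_filter
from .enrichment import EnrichmentResult, TermAnnotation


@dataclass
class ClusteringParams:
    """Fuzzy-clustering tuning knobs (defaults follow the source heuristic)."""

    min_gene_overlap: int = 5
    initial_seed_size: int = 5
    final_cluster_size: int = 5
    linkage_threshold: float = 0.5
    kappa_threshold: float = 0.20
    membership_fraction: float = 0.5

    def __post_init__(self):
        for name in ("min_gene_overlap", "initial_seed_size", "final_cluster_size"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")
        for name in ("linkage_threshold", "kappa_threshold", "membership_fraction"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1]")


@dataclass
class TermCluster:
    """A fuzzy cluster of annotation terms with summary statistics."""

    cluster_id: str
    member_terms: frozenset
    representative_label: str
    gene_union: frozenset
    enrichment_score: float
    mean_fold_enrichment: float

    @property
    def n_terms(self) -> int:
        return len(self.member_terms)


def cohen_kappa(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa from a 2x2 agreement table; 0 when chance agreement is 1."""
    total = a + b + c + d
    if total == 0:
        raise ValueError("empty agreement table")
    po = (a + d) / total
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / total**2
    if math.isclose(pe, 1.0):
        warnings.warn("degenerate constant annotation pair; kappa set to 0")
        return 0.0
    return (po - pe) / (1 - pe)


def kappa_matrix(
    terms: Sequence[TermAnnotation],
    universe: Iterable[str],
    params: ClusteringParams | None = None,
) -> pd.DataFrame:
    """Symmetric term-by-term kappa matrix over the gene universe.

    Off-diagonal entries for pairs sharing fewer than ``min_gene_overlap``
    genes are 0; the diagonal is 1.
    """
    params = params or ClusteringParams()
    genes = sorted(set(universe))
    if not genes:
        raise ValueError("empty gene universe")
    index = {g: i for i, g in enumerate(genes)}
    ids = [t.term_id for t in terms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate term ids")
    total = len(genes)

    m = np.zeros((len(terms), total), dtype=np.int64)
    for row, term in enumerate(terms):
        cols = [index[g] for g in term.genes if g in index]
        if len(cols) != len(term.genes):
            missing = sorted(set(term.genes) - set(genes))[:5]
            raise ValueError(f"term {term.term_id!r} has genes outside universe (e.g. {missing})")
        m[row, cols] = 1

    sizes = m.sum(axis=1)
    a = m @ m.T
    b = sizes[:, None] - a
    c = sizes[None, :] - a
    d = total - a - b - c
    po = (a + d) / total
    pe = ((a + b) * (a + c) + (c + d) * (b + d)).astype(float) / total**2
    degenerate = np.isclose(pe, 1.0)
    if degenerate.any():
        warnings.warn("degenerate constant annotation pair(s); kappa set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(degenerate, 0.0, (po - pe) / (1 - pe))
    kappa[a < params.min_gene_overlap] = 0.0
    np.fill_diagonal(kappa, 1.0)
    return pd.DataFrame(kappa, index=ids, columns=ids)


def form_seeds(kappa: pd.DataFrame, params: ClusteringParams | None = None) -> list[frozenset]:
    """Initial candidate groups: each term plus its kappa neighbours.

    A seed is kept when it reaches ``initial_seed_size`` members and at least
    ``membership_fraction`` of its internal pairs meet the kappa threshold;
    duplicates are removed.
    """
    params = params or ClusteringParams()
    ids = list(kappa.index)
    values = kappa.to_numpy()
    tight = values >= params.kappa_threshold
    seeds: set[frozenset] = set()
    for i in range(len(ids)):
        members = [j for j in range(len(ids)) if j == i or tight[i, j]]
        if len(members) < params.initial_seed_size:
            continue
        n_pairs = len(members) * (len(members) - 1) // 2
        n_tight = sum(
            1 for j, k in itertools.combinations(members, 2) if tight[j, k]
        )
        if n_pairs and n_tight / n_pairs >= params.membership_fraction:
            seeds.add(frozenset(ids[j] for j in members))
    return sorted(seeds, key=lambda s: tuple(sorted(s)))


def _merge_key(x: frozenset, y: frozenset) -> tuple:
    shared = len(x & y) / min(len(x), len(y))
    merged = tuple(sorted(x | y))
    return (-shared, len(merged), merged)


def merge_clusters(
    seeds: Sequence[frozenset], params: ClusteringParams | None = None
) -> list[frozenset]:
    """Iteratively merge groups sharing >= ``linkage_threshold`` of the smaller.

    The merge order is deterministic (see module docstring); groups smaller
    than ``final_cluster_size`` are discarded at the end.
    """
    params = params or ClusteringParams()
    groups = sorted(set(seeds), key=lambda s: tuple(sorted(s)))
    while True:
        best = None
        for x, y in itertools.combinations(groups, 2):
            if len(x & y) / min(len(x), len(y)) >= params.linkage_threshold:
                key = _merge_key(x, y)
                if best is None or key < best[0]:
                    best = (key, x, y)
        if best is None:
            break
        _, x, y = best
        groups = [g for g in groups if g is not x and g is not y]
        groups.append(x | y)
        groups = sorted(set(groups), key=lambda s: tuple(sorted(s)))
    final = [g for g in groups if len(g) >= params.final_cluster_size]
    log_filter("clustering.merge_clusters", len(seeds), len(final))
    return sorted(final, key=lambda s: tuple(sorted(s)))


def prune_and_summarize(
    clusters: Sequence[frozenset],
    results: Mapping[str, EnrichmentResult],
    terms_by_id: Mapping[str, TermAnnotation],
    params: ClusteringParams | None = None,
    alpha: float = 0.05,
    keep_small: bool = False,
) -> list[TermCluster]:
    """Drop members with FDR > alpha, then summarise surviving clusters.

    Clusters falling below ``final_cluster_size`` after pruning are dropped
    unless ``keep_small``.  The representative label is the member with the
    lowest raw p (ties: larger gene set, then lexicographic term id).
    """
    params = params or ClusteringParams()
    summaries: list[TermCluster] = []
    for cluster in clusters:
        for term in cluster:
            if term not in results:
                raise KeyError(f"no enrichment result for term {term!r}")
            if term not in terms_by_id:
                raise KeyError(f"no annotation for term {term!r}")
        members = sorted(t for t in cluster if results[t].fdr <= alpha)
        if not members:
            continue
        if len(members) < params.final_cluster_size and not keep_small:
            continue
        rep = min(
            members,
            key=lambda t: (results[t].p_raw, -len(terms_by_id[t].genes), t),
        )
        log_p = [math.log10(results[t].p_raw) for t in members]
        summaries.append(
            TermCluster(
                cluster_id="",
                member_terms=frozenset(members),
                representative_label=rep,
                gene_union=frozenset().union(*(terms_by_id[t].genes for t in members)),
                enrichment_score=-float(np.mean(log_p)),
                mean_fold_enrichment=float(
                    np.mean([results[t].fold_enrichment for t in members])
                ),
            )
        )
    summaries.sort(key=lambda c: (-c.enrichment_score, c.representative_label))
    for i, cluster in enumerate(summaries, start=1):
        cluster.cluster_id = f"C{i:02d}"
    return summaries


def cluster_terms(
    terms: Sequence[TermAnnotation],
    results: Mapping[str, EnrichmentResult],
    universe: Iterable[str],
    params: ClusteringParams | None = None,
    alpha: float = 0.05,
    keep_small: bool = False,
) -> list[TermCluster]:
    """Full pipeline: kappa matrix -> seeds -> merge -> prune + summarise.

    Raw p-values drive the clustering itself; the FDR cutoff is applied only
    afterwards, pruning non-significant members from the formed clusters.
    """
    params = params or ClusteringParams()
    kappa = kappa_matrix(terms, universe, params)
    seeds = form_seeds(kappa, params)
    merged = merge_clusters(seeds, params)
    terms_by_id = {t.term_id: t for t in terms}
    return prune_and_summarize(merged, results, terms_by_id, params, alpha, keep_small)


# --- treemap -----------------------------------------------------------------


def _worst_ratio(row: list[float], length: float) -> float:
    total = sum(row)
    side = total / length
    return max(max(r / side, side / r) for r in (x / length for x in row))


def squarify_layout(
    sizes: Sequence[float], x: float, y: float, dx: float, dy: float
) -> list[tuple[float, float, float, float]]:
    """Squarified treemap rectangles for ``sizes`` (already area-normalised).

    Sizes must be positive and sum to dx*dy; rectangles are laid out row by
    row against the shorter side, keeping aspect ratios near 1.  The layout
    is deterministic in the input order.
    """
    sizes = [float(s) for s in sizes]
    if not sizes:
        return []
    if len(sizes) == 1:
        return [(x, y, dx, dy)]
    row: list[float] = [sizes[0]]
    rest = sizes[1:]
    length = min(dx, dy)
    while rest and _worst_ratio(row + [rest[0]], length) <= _worst_ratio(row, length):
        row.append(rest.pop(0))
    total = sum(row)
    rects = []
    if dx >= dy:  # lay the row vertically along the left edge
        width = total / dy
        cy = y
        for s in row:
            rects.append((x, cy, width, s / width))
            cy += s / width
        remainder = (x + width, y, dx - width, dy)
    else:  # horizontally along the top edge
        height = total / dx
        cx = x
        for s in row:
            rects.append((cx, y, s / height, height))
            cx += s / height
        remainder = (x, y + height, dx, dy - height)
    if rest:
        rects.extend(squarify_layout(rest, *remainder))
    return rects


def treemap_table(
    clusters: Sequence[TermCluster], width: float = 100.0, height: float = 100.0
) -> pd.DataFrame:
    """One rectangle per cluster, area proportional to gene-union size.

    Clusters are ordered by area descending, ties broken by label, so the
    layout is deterministic.
    """
    ordered = sorted(
        clusters, key=lambda c: (-len(c.gene_union), c.representative_label)
    )
    sizes = np.array([len(c.gene_union) for c in ordered], dtype=float)
    if len(sizes) == 0:
        return pd.DataFrame(
            columns=["cluster_id", "label", "gene_union_size", "x", "y", "dx", "dy"]
        )
    if (sizes <= 0).any():
        raise ValueError("clusters with empty gene unions cannot be drawn")
    scaled = sizes / sizes.sum() * width * height
    rects = squarify_layout(list(scaled), 0.0, 0.0, width, height)
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in ordered],
            "label": [c.representative_label for c in ordered],
            "gene_union_size": sizes.astype(int),
            "x": [r[0] for r in rects],
            "y": [r[1] for r in rects],
            "dx": [r[2] for r in rects],
            "dy": [r[3] for r in rects],
        }
    )


def treemap_figure(clusters: Sequence[TermCluster], path: str) -> None:
    """Render the treemap to an image file via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = treemap_table(clusters)
    fig, ax = plt.subplots(figsize=(10, 7))
    cmap = plt.get_cmap("tab20")
    for i, row in table.iterrows():
        ax.add_patch(
            plt.Rectangle(
                (row.x, row.y), row.dx, row.dy,
                facecolor=cmap(i % 20), edgecolor="white",
            )
        )
        if row.dx * row.dy > 100:
            ax.text(
                row.x + row.dx / 2, row.y + row.dy / 2,
                f"{row.label}\n({row.gene_union_size})",
                ha="center", va="center", fontsize=7, wrap=True,
            )
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.invert_yaxis()
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
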