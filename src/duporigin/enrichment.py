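"""Functional profiling of duplicate classes.

Fold-enrichment profiles over a panel of large biological-process GO terms
summarise what each duplicate class does relative to the pooled duplicate
population; profiles are compared by 1 − Pearson r and grouped by
average-linkage hierarchical clustering.  Class-versus-trait enrichment
(essential genes, PPI participation) uses Fisher's exact test with a
class-appropriate background — in particular, PPI tests are restricted to the
screened gene population from which the interactome was derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "FunctionalProfile",
    "EnrichmentResult",
    "ClusterResult",
    "select_go_terms",
    "fold_enrichment_profile",
    "cluster_profiles",
    "fisher_enrichment",
    "ppi_enrichment",
]


@dataclass
class FunctionalProfile:
    origin_class: str
    terms: tuple[str, ...]
    fold_enrichments: np.ndarray  # aligned to terms; NaN where undefined


@dataclass(frozen=True)
class EnrichmentResult:
    group: str
    trait: str
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    fold_enrichment: float
    untestable: bool = False


@dataclass
class ClusterResult:
    classes: tuple[str, ...]        # input order
    distance: np.ndarray            # condensed-form square matrix (1 - r)
    linkage: np.ndarray             # scipy average-linkage matrix
    leaf_order: tuple[str, ...]     # deterministic rotated dendrogram order
    matrix: pd.DataFrame            # heat-map matrix, rows in leaf order
    newick: str


def select_go_terms(
    annotations: pd.DataFrame,
    namespaces: pd.DataFrame | Mapping[str, str],
    namespace: str = "biological_process",
    min_genes: int = 300,
) -> list[str]:
    """Terms of one namespace annotating strictly more than ``min_genes`` genes.

    ``annotations`` is a two-column (gene, term) table, assumed pre-propagated
    up the ontology; returned terms are sorted by gene count descending, ties
    by term id.
    """
    if isinstance(namespaces, pd.DataFrame):
        ns = dict(zip(namespaces["term"], namespaces["namespace"]))
    else:
        ns = dict(namespaces)
    df = annotations.drop_duplicates(["gene", "term"])
    counts = df.groupby("term")["gene"].nunique()
    counts = counts[[ns.get(t) == namespace for t in counts.index]]
    counts = counts[counts > min_genes]
    return sorted(counts.index, key=lambda t: (-counts[t], t))


def fold_enrichment_profile(
    class_genes: Iterable[str],
    pooled_genes: Iterable[str],
    terms: Sequence[str],
    annotations: pd.DataFrame,
    origin_class: str = "",
) -> FunctionalProfile:
    """Per-term ratio of class term fraction to pooled term fraction.

    Terms annotating no pooled gene have an undefined ratio and are flagged
    with NaN.
    """
    cls = set(class_genes)
    pool = set(pooled_genes)
    if not cls <= pool:
        raise ValueError("class genes must be a subset of the pooled genes")
    if not pool:
        raise ValueError("pooled gene set is empty")
    by_term = annotations.groupby("term")["gene"].agg(set)
    fe = np.empty(len(terms))
    for i, t in enumerate(terms):
        genes_t = by_term.get(t, set())
        pool_frac = len(genes_t & pool) / len(pool)
        if pool_frac == 0:
            fe[i] = np.nan
            continue
        cls_frac = len(genes_t & cls) / len(cls) if cls else 0.0
        fe[i] = cls_frac / pool_frac
    return FunctionalProfile(origin_class, tuple(terms), fe)


def _rotated_leaf_order(Z: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Dendrogram leaf order with deterministic rotation: at every merge the
    subtree whose lexicographically smallest label is smaller goes left."""
    n = len(labels)

    def leaves(node: int) -> list[str]:
        if node < n:
            return [labels[node]]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        l, r = leaves(left), leaves(right)
        return l + r if min(l) <= min(r) else r + l

    return leaves(n + len(Z) - 1)


def _newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        l, r = int(Z[i - n, 0]), int(Z[i - n, 1])
        h = Z[i - n, 2]
        heights[i] = h
        kids = sorted(
            [(node(l), h - heights[l]), (node(r), h - heights[r])],
            key=lambda kv: kv[0],
        )
        inner = ",".join(f"{name}:{bl:.6g}" for name, bl in kids)
        return f"({inner})"

    return node(n + len(Z) - 1) + ";"


def cluster_profiles(profiles: Sequence[FunctionalProfile]) -> ClusterResult:
    """Average-linkage clustering of functional profiles at distance 1 − r."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    terms = profiles[0].terms
    if any(p.terms != terms for p in profiles):
        raise ValueError("profiles must share one term list")
    X = np.vstack([p.fold_enrichments for p in profiles])
    if np.isnan(X).any():
        raise ValueError("profiles contain undefined (NaN) fold enrichments")
    for p, row in zip(profiles, X):
        if row.std() == 0:
            raise ValueError(f"profile {p.origin_class!r} is constant; correlation undefined")
    labels = tuple(p.origin_class for p in profiles)
    dist = 1.0 - np.corrcoef(X)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = _rotated_leaf_order(Z, labels)
    mat = pd.DataFrame(X, index=labels, columns=terms).loc[order]
    return ClusterResult(labels, dist, Z, tuple(order), mat, _newick(Z, labels))


def fisher_enrichment(
    class_genes: Iterable[str],
    trait_genes: Iterable[str],
    background_genes: Iterable[str],
    group: str = "",
    trait: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of a class x trait 2x2 table.

    Fold enrichment is the trait fraction in the class over the trait
    fraction in the background.
    """
    bg = set(background_genes)
    if not bg:
        raise ValueError("background gene set is empty")
    cls = set(class_genes) & bg
    trt = set(trait_genes) & bg
    if set(class_genes) - bg or set(trait_genes) - bg:
        raise ValueError("class and trait genes must be subsets of the background")
    a = len(cls & trt)
    b = len(cls - trt)
    c = len(trt - cls)
    d = len(bg) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if cls and trt:
        fe = (a / len(cls)) / (len(trt) / len(bg))
    else:
        fe = float("nan")
    return EnrichmentResult(group, trait, ((a, b), (c, d)), float(odds), float(p), fe)


def ppi_enrichment(
    class_genes: Iterable[str],
    ppi_genes: Iterable[str],
    screened_genes: Iterable[str],
    group: str = "",
) -> EnrichmentResult:
    """PPI-participation enrichment restricted to the screened background.

    Interactome screens assay only a subset of the genome; comparing PPI
    membership against the whole genome would conflate screen coverage with
    connectivity, so the background is the screened population and class
    genes are intersected with it first.
    """
    screened = set(screened_genes)
    cls = set(class_genes) & screened
    ppi = set(ppi_genes) & screened
    if not cls:
        return EnrichmentResult(group, "ppi", ((0, 0), (len(ppi), len(screened) - len(ppi))),
                                float("nan"), float("nan"), float("nan"), untestable=True)
    return EnrichmentResult(
        group, "ppi",
        *_strip(fisher_enrichment(cls, ppi, screened, group=group, trait="ppi")),
    )


def _strip(res: EnrichmentResult):
    return res.contingency, res.odds_ratio, res.p_value, res.fold_enrichment


def plot_profile_heatmap(result: ClusterResult, path) -> None:
    """Save the clustered fold-enrichment heat map (rows in dendrogram order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.25 * result.matrix.shape[1]), 3 + 0.3 * len(result.matrix)))
    im = ax.imshow(result.matrix.values, aspect="auto", cmap="RdBu_r", vmin=0, vmax=2)
    ax.set_yticks(range(len(result.matrix)), result.matrix.index)
    ax.set_xticks(range(result.matrix.shape[1]), result.matrix.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="fold enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
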