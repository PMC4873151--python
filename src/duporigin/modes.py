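"""Duplicate-mode classification: WGD, tandem, proximal, dispersed.

The classifier follows the standard exclusion order used throughout the plant
comparative-genomics literature: a homolog pair is a WGD pair if it is an
anchor in a colinear block; otherwise it is tandem when the two genes are
adjacent in gene order, proximal when separated by at most ``local_window``
(default 10) annotated genes on the same chromosome, and dispersed otherwise.
Gene-level modes use the precedence wgd > tandem > proximal > dispersed, and
redundancy among local/dispersed pairs is reduced by keeping, per gene, only
the pair with the smallest Ks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .colinearity import ColinearBlock, GenomeLayout

__all__ = [
    "MODE_PRECEDENCE",
    "HomologPair",
    "filter_pairs",
    "classify_pairs",
    "reduce_redundancy",
    "classify_genes",
    "attribute_wgd_events",
    "wgd_pair_set",
]

log = logging.getLogger(__name__)

MODE_PRECEDENCE = ("wgd", "tandem", "proximal", "dispersed")


@dataclass(frozen=True)
class HomologPair:
    """A duplicate gene pair with optional divergence estimates."""

    gene_a: str
    gene_b: str
    evalue_proxy: float | None = None
    ks: float | None = None
    ka: float | None = None

    @property
    def omega(self) -> float | None:
        if self.ks is None or self.ka is None or self.ks <= 0:
            return None
        return self.ka / self.ks


def pairs_to_frame(pairs: Iterable) -> pd.DataFrame:
    """Normalise pair input (HomologPair objects, tuples, or a DataFrame)."""
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        rows = []
        for p in pairs:
            if isinstance(p, HomologPair):
                rows.append((p.gene_a, p.gene_b, p.evalue_proxy, p.ks, p.ka))
            else:
                t = tuple(p) + (None,) * (5 - len(p))
                rows.append(t[:5])
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue", "ks", "ka"])
    for col in ("evalue", "ks", "ka"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["gene_a"] == df["gene_b"]).any():
        raise ValueError("self pairs (gene_a == gene_b) are not allowed")
    return df


def filter_pairs(pairs, evalue_max: float = 1e-10, top_k: int = 5) -> pd.DataFrame:
    """BLAST-style ingestion filter: E-value cutoff and top-k non-self matches.

    Applied per gene on the E-value column when present (smallest E first,
    ties by partner id); pairs kept for either member survive.  Mirrors the
    standard 'top five non-self matches and E < 1e-10' population definition.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    df = pairs_to_frame(pairs)
    if df["evalue"].notna().any():
        df = df[df["evalue"] < evalue_max]
    keep: set[int] = set()
    long = pd.concat(
        [
            df.assign(gene=df["gene_a"], partner=df["gene_b"]),
            df.assign(gene=df["gene_b"], partner=df["gene_a"]),
        ]
    )
    sort_col = "evalue" if df["evalue"].notna().any() else "ks"
    long = long.sort_values([sort_col, "partner"], kind="mergesort", na_position="last")
    for _, grp in long.groupby("gene", sort=False):
        keep.update(grp.index[:top_k])
    return df.loc[sorted(keep)].reset_index(drop=True)


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def wgd_pair_set(blocks: Iterable[ColinearBlock]) -> set[tuple[str, str]]:
    """Unordered anchor-pair set from intra-genome colinear blocks."""
    return {_canon(a.gene_a, a.gene_b) for b in blocks for a in b.anchors}


def classify_pairs(
    pairs,
    layout: GenomeLayout,
    wgd_anchor_pairs: Iterable[tuple[str, str]] | Iterable[ColinearBlock],
    local_window: int = 10,
) -> pd.DataFrame:
    """Assign each homolog pair a mode: wgd / tandem / proximal / dispersed.

    ``wgd_anchor_pairs`` may be a set of unordered gene-id pairs or a list of
    intra-genome colinear blocks.
    """
    if local_window < 1:
        raise ValueError("local_window must be >= 1")
    df = pairs_to_frame(pairs)
    wgd: Iterable = wgd_anchor_pairs
    wgd_list = list(wgd) if not isinstance(wgd, (set, frozenset)) else wgd
    if wgd_list and isinstance(next(iter(wgd_list)), ColinearBlock):
        anchor_set = wgd_pair_set(wgd_list)
    else:
        anchor_set = {_canon(a, b) for a, b in wgd_list}

    missing = [g for g in pd.concat([df["gene_a"], df["gene_b"]]).unique() if g not in layout.rank]
    if missing:
        raise KeyError(f"genes missing from layout: {missing[:5]}{'...' if len(missing) > 5 else ''}")

    modes = []
    for ga, gb in zip(df["gene_a"], df["gene_b"]):
        if _canon(ga, gb) in anchor_set:
            modes.append("wgd")
            continue
        if layout.chrom[ga] == layout.chrom[gb]:
            d = abs(layout.rank[ga] - layout.rank[gb])
            if d == 1:
                modes.append("tandem")
                continue
            if 2 <= d <= local_window:
                modes.append("proximal")
                continue
        modes.append("dispersed")
    out = df.copy()
    out["mode"] = modes
    return out


def reduce_redundancy(
    pair_modes: pd.DataFrame,
    modes: Sequence[str] = ("tandem", "proximal", "dispersed"),
) -> pd.DataFrame:
    """Smallest-Ks representative pair per gene within each reduced mode.

    Ties break toward the lexicographically smaller partner id, making the
    result independent of input order.  Genes whose candidate pairs all lack
    Ks are dropped from the representatives with a logged warning.
    """
    df = pair_modes[pair_modes["mode"].isin(modes)]
    long = pd.concat(
        [
            df.assign(gene=df["gene_a"], partner=df["gene_b"]),
            df.assign(gene=df["gene_b"], partner=df["gene_a"]),
        ],
        ignore_index=True,
    )
    has_ks = long["ks"].notna()
    n_bad_genes = 0
    reps = []
    for (gene, mode), grp in long.groupby(["gene", "mode"], sort=True):
        g = grp[grp["ks"].notna()]
        if g.empty:
            n_bad_genes += 1
            continue
        best = g.sort_values(["ks", "partner"], kind="mergesort").iloc[0]
        reps.append((gene, mode, best["partner"], best["ks"], best["ka"], best["evalue"]))
    if n_bad_genes:
        log.warning("reduce_redundancy: %d (gene, mode) groups had no Ks and were dropped", n_bad_genes)
    return pd.DataFrame(reps, columns=["gene", "mode", "partner", "ks", "ka", "evalue"])


def classify_genes(pair_modes: pd.DataFrame, representatives: pd.DataFrame | None = None) -> pd.DataFrame:
    """Gene-level mode labels (precedence wgd > tandem > proximal > dispersed).

    Returns one row per labeled gene with its mode and, where available, the
    representative (smallest-Ks) partner for that mode.
    """
    rank = {m: i for i, m in enumerate(MODE_PRECEDENCE)}
    long = pd.concat(
        [
            pair_modes.assign(gene=pair_modes["gene_a"], partner=pair_modes["gene_b"]),
            pair_modes.assign(gene=pair_modes["gene_b"], partner=pair_modes["gene_a"]),
        ],
        ignore_index=True,
    )
    long["prec"] = long["mode"].map(rank)
    idx = long.groupby("gene", sort=True)["prec"].idxmin()
    genes = long.loc[idx, ["gene", "mode"]].reset_index(drop=True)
    if representatives is not None and not representatives.empty:
        reps = representatives.set_index(["gene", "mode"])
        rep_partner, rep_ks = [], []
        for gene, mode in zip(genes["gene"], genes["mode"]):
            if (gene, mode) in reps.index:
                row = reps.loc[(gene, mode)]
                rep_partner.append(row["partner"])
                rep_ks.append(row["ks"])
            else:
                sub = long[(long["gene"] == gene) & (long["mode"] == mode)]
                sub = sub.sort_values(["ks", "partner"], kind="mergesort", na_position="last")
                rep_partner.append(sub.iloc[0]["partner"])
                rep_ks.append(sub.iloc[0]["ks"])
        genes["partner"] = rep_partner
        genes["ks"] = rep_ks
    return genes


def mode_counts(gene_modes: pd.DataFrame) -> pd.Series:
    """Gene counts per mode; sums to the number of labeled genes."""
    return gene_modes["mode"].value_counts().reindex(MODE_PRECEDENCE, fill_value=0)


def attribute_wgd_events(
    gene_modes: pd.DataFrame,
    intra_blocks: Sequence[ColinearBlock],
    ks_by_pair: Mapping[tuple[str, str], float],
    event_ks_ranges: Mapping[str, tuple[float, float]],
) -> dict[str, str]:
    """Attribute WGD-mode genes to named polyploidy events by block median Ks.

    Real-data attribution of blocks to specific WGD rounds is consumed as an
    input label column when available; this helper covers simulated or
    label-free input by matching each block's median anchor Ks against
    configured per-event Ks ranges.  Returns gene -> event name for anchors of
    attributable blocks.
    """
    out: dict[str, str] = {}
    for b in intra_blocks:
        ks = [
            ks_by_pair[k]
            for a in b.anchors
            if (k := _canon(a.gene_a, a.gene_b)) in ks_by_pair
        ]
        if not ks:
            continue
        med = float(np.median(ks))
        for event, (lo, hi) in event_ks_ranges.items():
            if lo <= med < hi:
                for a in b.anchors:
                    out.setdefault(a.gene_a, event)
                    out.setdefault(a.gene_b, event)
                break
    return out
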