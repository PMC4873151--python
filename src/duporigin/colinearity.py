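"""Colinear (synteny) block detection by dynamic-programming anchor chaining.

A colinear block is a run of homologous gene pairs ("anchors") whose gene-order
ranks increase together on both chromosomes (or increase on one and decrease on
the other, for an inverted block).  Blocks are chained with a hard rank-gap cap
and unit anchor weights, which mirrors the behaviour practitioners expect from
MCScanX at its default parameters (min_block_size=5, max_gap=25) while keeping
the algorithm explicit and exhaustively testable.

The module also reads and writes the MCScanX ``.collinearity`` text dialect so
externally computed blocks can be used interchangeably with the internal
chainer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnchorPair",
    "ColinearBlock",
    "GenomeLayout",
    "anchors_from_pairs",
    "chain_anchors",
    "colinear_gene_sets",
    "is_colinear_with",
    "read_collinearity",
    "write_collinearity",
]


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair placed on the dot-plot coordinate system."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 1.0


@dataclass
class ColinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    score: float

    def genes_a(self) -> list[str]:
        return [a.gene_a for a in self.anchors]

    def genes_b(self) -> list[str]:
        return [a.gene_b for a in self.anchors]


@dataclass
class GenomeLayout:
    """Ordered gene layout of one genome: the dot-plot coordinate system.

    ``chromosomes`` maps chromosome name to the ordered list of gene ids;
    ``rank``/``chrom`` are derived lookups.  ``strand``/``tss`` are optional
    per-gene annotations used by promoter-window plumbing.
    """

    species: str
    chromosomes: dict[str, list[str]]
    strand: dict[str, str] = field(default_factory=dict)
    tss: dict[str, int] = field(default_factory=dict)
    rank: dict[str, int] = field(init=False)
    chrom: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.rank = {}
        self.chrom = {}
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g in self.rank:
                    raise ValueError(f"gene {g!r} appears twice in layout of {self.species}")
                self.rank[g] = i
                self.chrom[g] = chrom

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.chromosomes.values() for g in genes]

    def __len__(self) -> int:
        return len(self.rank)


# ---------------------------------------------------------------------------
# Anchor construction
# ---------------------------------------------------------------------------

def anchors_from_pairs(
    pairs: Iterable[tuple],
    layout_a: GenomeLayout,
    layout_b: GenomeLayout,
) -> list[AnchorPair]:
    """Place homolog pairs ``(gene_a, gene_b[, score])`` onto layouts.

    For a self-comparison (``layout_a is layout_b``) self pairs are dropped and
    the unordered pair is kept once, oriented so (chrom_a, rank_a) <=
    (chrom_b, rank_b).
    """
    self_cmp = layout_a is layout_b
    out: dict[tuple, AnchorPair] = {}
    for pair in pairs:
        ga, gb = pair[0], pair[1]
        score = float(pair[2]) if len(pair) > 2 else 1.0
        if ga not in layout_a.rank:
            raise KeyError(f"anchor gene {ga!r} missing from layout {layout_a.species}")
        if gb not in layout_b.rank:
            raise KeyError(f"anchor gene {gb!r} missing from layout {layout_b.species}")
        if self_cmp:
            if ga == gb:
                continue
            ka = (layout_a.chrom[ga], layout_a.rank[ga])
            kb = (layout_b.chrom[gb], layout_b.rank[gb])
            if kb < ka:
                ga, gb, ka, kb = gb, ga, kb, ka
            key = (ga, gb)
        else:
            key = (ga, gb)
        anc = AnchorPair(
            ga, gb, layout_a.chrom[ga], layout_b.chrom[gb],
            layout_a.rank[ga], layout_b.rank[gb], score,
        )
        prev = out.get(key)
        if prev is None or anc.score > prev.score:
            out[key] = anc
    return sorted(out.values(), key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))


def _collapse_tandem(anchors: list[AnchorPair]) -> list[AnchorPair]:
    """Drop anchors outscored by another anchor at the same rank_a (or rank_b).

    Mirrors MCScanX tandem collapsing: a tandem array matching one partner
    must not inflate block scores with stacked anchors at a single rank.
    Score ties are all kept — a chain is strictly increasing on both axes, so
    at most one of them can enter any block, and the chaining DP (not an
    arbitrary pre-filter) decides which placement is consistent with the
    surrounding diagonal.
    """
    for axis in ("rank_a", "rank_b"):
        best: dict[int, float] = {}
        for a in anchors:
            k = getattr(a, axis)
            if k not in best or a.score > best[k]:
                best[k] = a.score
        anchors = [a for a in anchors if a.score >= best[getattr(a, axis)]]
    return sorted(anchors, key=lambda x: (x.rank_a, x.rank_b))


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _local_stack_components(anchors: list[AnchorPair], window: int) -> list[int]:
    """Group anchors that are alternative placements of one local duplicate
    stack: anchors sharing a gene and lying within ``window`` ranks on the
    other axis (a tandem/proximal array matching one locus).  A chain may use
    at most one anchor per component, which is the chaining-time equivalent of
    MCScanX's collapse of tandem arrays to a single representative."""
    n = len(anchors)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for key, other in (("gene_a", "rank_b"), ("gene_b", "rank_a")):
        by_gene: dict[str, list[int]] = {}
        for i, a in enumerate(anchors):
            by_gene.setdefault(getattr(a, key), []).append(i)
        for lst in by_gene.values():
            for x in range(len(lst)):
                for y in range(x + 1, len(lst)):
                    i, j = lst[x], lst[y]
                    if abs(getattr(anchors[i], other) - getattr(anchors[j], other)) <= window:
                        union(i, j)
    return [find(i) for i in range(n)]


def _best_chain(
    anchors: list[AnchorPair], orientation: str, max_gap: int,
    comp: list[int] | None = None,
) -> tuple[list[int], tuple[int, int, int]]:
    """Best unit-weight chain under the gap cap for one orientation.

    Returns (indices of chain members, key) where key = (score, -sum_a, -sum_b)
    so larger keys are better: among equal-score chains the one with the
    lexicographically smallest (sum of rank_a, sum of rank_b) wins.
    """
    sign = 1 if orientation == "same" else -1
    idx = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    n = len(idx)
    # per node: chain length, summed ranks, predecessor
    length = [1] * n
    sum_a = [0] * n
    sum_b = [0] * n
    pred = [-1] * n
    for ii in range(n):
        a = anchors[idx[ii]]
        sum_a[ii], sum_b[ii] = a.rank_a, a.rank_b
        best_key = None
        for jj in range(ii - 1, -1, -1):
            b = anchors[idx[jj]]
            da = a.rank_a - b.rank_a
            if da > max_gap:
                # sorted by rank_a: all earlier nodes are at least this far
                break
            if da <= 0:
                continue
            db = (a.rank_b - b.rank_b) * sign
            if db <= 0 or db > max_gap:
                continue
            if comp is not None and comp[idx[ii]] == comp[idx[jj]]:
                continue
            key = (length[jj], -(sum_a[jj] + a.rank_a), -(sum_b[jj] + a.rank_b))
            if best_key is None or key > best_key:
                best_key = key
                pred[ii] = jj
        if pred[ii] >= 0:
            jj = pred[ii]
            length[ii] = length[jj] + 1
            sum_a[ii] += sum_a[jj]
            sum_b[ii] += sum_b[jj]
    if n == 0:
        return [], (0, 0, 0)
    best_end = max(range(n), key=lambda ii: (length[ii], -sum_a[ii], -sum_b[ii]))
    chain = []
    ii = best_end
    while ii >= 0:
        chain.append(idx[ii])
        ii = pred[ii]
    chain.reverse()
    return chain, (length[best_end], -sum_a[best_end], -sum_b[best_end])


def chain_anchors(
    pairs: Sequence,
    layout_a: GenomeLayout,
    layout_b: GenomeLayout,
    min_block_size: int = 5,
    max_gap: int = 25,
    self_exclude_window: int = 10,
) -> list[ColinearBlock]:
    """Chain anchors into maximal-score non-overlapping colinear blocks.

    ``pairs`` may be ``AnchorPair`` objects or ``(gene_a, gene_b[, score])``
    tuples resolved against the layouts.  Per chromosome pair, best chains are
    extracted greedily (highest chain score first, deterministic tie-break) and
    their anchors removed until no chain of ``min_block_size`` anchors remains.

    In a self-comparison, pairs within ``self_exclude_window`` gene ranks on
    the same chromosome are local (tandem/proximal) duplicates, not syntenic
    anchors; they are dropped before chaining so that runs of tandem arrays
    cannot masquerade as duplicated blocks along the diagonal.
    """
    if min_block_size < 2:
        raise ValueError("min_block_size must be >= 2")
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if pairs and not isinstance(pairs[0], AnchorPair):
        anchors = anchors_from_pairs(pairs, layout_a, layout_b)
    else:
        anchors = list(pairs)
    if layout_a is layout_b:
        anchors = [
            a for a in anchors
            if a.chrom_a != a.chrom_b or abs(a.rank_a - a.rank_b) > self_exclude_window
        ]

    by_cp: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        by_cp.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[ColinearBlock] = []
    for (ca, cb) in sorted(by_cp):
        remaining = _collapse_tandem(by_cp[(ca, cb)])
        while True:
            comp = _local_stack_components(remaining, self_exclude_window)
            cands = []
            for orient in ("same", "inverted"):
                chain, key = _best_chain(remaining, orient, max_gap, comp)
                cands.append((key, 0 if orient == "same" else 1, orient, chain))
            cands.sort(key=lambda c: (tuple(-k for k in c[0]), c[1]))
            key, _, orient, chain = cands[0]
            if key[0] < min_block_size:
                break
            members = [remaining[i] for i in chain]
            blocks.append(ColinearBlock(ca, cb, members, orient, float(key[0])))
            # a rank used by a block cannot re-anchor within this chromosome
            # pair: tandem/proximal copies of chained genes would otherwise
            # build shadow diagonals offset by a few ranks
            used_a = {m.rank_a for m in members}
            used_b = {m.rank_b for m in members}
            remaining = [a for a in remaining
                         if a.rank_a not in used_a and a.rank_b not in used_b]
    return blocks


# ---------------------------------------------------------------------------
# Block queries
# ---------------------------------------------------------------------------

def colinear_gene_sets(blocks: Iterable[ColinearBlock]) -> dict[str, list[tuple[str, int]]]:
    """Map every anchor gene (either side) to its (partner, block index) list."""
    out: dict[str, list[tuple[str, int]]] = {}
    for bi, block in enumerate(blocks):
        for a in block.anchors:
            out.setdefault(a.gene_a, []).append((a.gene_b, bi))
            out.setdefault(a.gene_b, []).append((a.gene_a, bi))
    return out


def is_colinear_with(gene: str, blocks_vs_outgroup) -> bool:
    """True iff ``gene`` is an anchor in at least one block of the comparison.

    ``blocks_vs_outgroup`` may be a block list or a precomputed gene set/map.
    """
    if isinstance(blocks_vs_outgroup, (set, frozenset, dict)):
        return gene in blocks_vs_outgroup
    return any(gene == a.gene_a or gene == a.gene_b for b in blocks_vs_outgroup for a in b.anchors)


def anchor_gene_set(blocks: Iterable[ColinearBlock], side: str = "a") -> set[str]:
    """Set of anchor genes on one side ('a', 'b') or both ('both')."""
    out: set[str] = set()
    for b in blocks:
        for a in b.anchors:
            if side in ("a", "both"):
                out.add(a.gene_a)
            if side in ("b", "both"):
                out.add(a.gene_b)
    return out


# ---------------------------------------------------------------------------
# MCScanX ".collinearity" dialect
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"^##\s*Alignment\s+(\S+):\s*score=(\S+)\s+e_value=(\S+)\s+N=(\d+)\s+(\S+)&(\S+)\s+(plus|minus)"
)


def write_collinearity(blocks: Sequence[ColinearBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("############### Parameters ###############\n")
        fh.write(f"# Number of collinear blocks: {len(blocks)}\n")
        for i, b in enumerate(blocks):
            strand = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {i}: score={b.score:.1f} e_value=0 N={len(b.anchors)} "
                f"{b.chrom_a}&{b.chrom_b} {strand}\n"
            )
            for j, a in enumerate(b.anchors):
                fh.write(f"{i:3d}-{j:3d}:\t{a.gene_a}\t{a.gene_b}\t0\n")


def read_collinearity(
    path,
    layout_a: GenomeLayout | None = None,
    layout_b: GenomeLayout | None = None,
) -> list[ColinearBlock]:
    """Read MCScanX-dialect blocks.  Layouts, when given, supply anchor ranks;
    otherwise ranks are the in-block order (sufficient for gene-set queries)."""
    blocks: list[ColinearBlock] = []
    current: ColinearBlock | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = _HEADER_RE.match(line)
            if m:
                current = ColinearBlock(
                    chrom_a=m.group(5), chrom_b=m.group(6), anchors=[],
                    orientation="same" if m.group(7) == "plus" else "inverted",
                    score=float(m.group(2)),
                )
                blocks.append(current)
                continue
            if line.startswith("#") or not line.strip():
                continue
            if current is None:
                continue
            fields = re.split(r"[\t ]+", line.split(":", 1)[-1].strip())
            if len(fields) < 2:
                continue
            ga, gb = fields[0], fields[1]
            ra = layout_a.rank[ga] if layout_a else len(current.anchors)
            rb = layout_b.rank[gb] if layout_b else len(current.anchors)
            current.anchors.append(AnchorPair(ga, gb, current.chrom_a, current.chrom_b, ra, rb))
    return blocks
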