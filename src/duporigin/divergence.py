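"""Divergence measures for duplicate gene pairs.

Covers four axes on which duplicate classes are compared:

* **Coding divergence** — Ks age distributions (histogram + Gaussian KDE) with
  secondary-peak detection, and Welch t comparisons of Ks / Ka / Ka-Ks between
  classes.  A secondary local maximum of the dispersed-duplicate Ks density at
  high Ks is the signature of a burst of ancient relocations on top of the
  L-shaped steady-state single-gene process.
* **Expression divergence** — 1 − Pearson r between expression profiles.
* **Regulation divergence** — Jaccard distance between the motif (PWM) hit
  sets of the two promoters, with a simple log-odds promoter scanner and the
  −600/+200 promoter-window convention as optional plumbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal, stats

log = logging.getLogger(__name__)

__all__ = [
    "KsDistribution",
    "ks_distribution",
    "detect_secondary_peak",
    "GroupComparison",
    "compare_groups",
    "expression_divergence",
    "regulation_divergence",
    "promoter_window",
    "scan_pwms",
    "load_jaspar_pwms",
    "load_meme_pwms",
]


# ---------------------------------------------------------------------------
# Ks distributions
# ---------------------------------------------------------------------------

@dataclass
class KsDistribution:
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_excluded: int


def ks_distribution(values: Iterable[float], bin_width: float = 0.05, cap: float = 3.0) -> KsDistribution:
    """Histogram + Silverman-bandwidth Gaussian KDE of a Ks sample.

    Values above ``cap`` (saturation guard) are excluded with a logged count.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if (v < 0).any():
        raise ValueError("Ks values must be non-negative")
    n_excl = int((v > cap).sum())
    v = v[v <= cap]
    if n_excl:
        log.info("ks_distribution: excluded %d values above cap %.3g", n_excl, cap)
    edges = np.arange(0.0, cap + bin_width, bin_width)
    if v.size == 0:
        log.warning("ks_distribution: empty input")
        return KsDistribution(v, edges, np.zeros(len(edges) - 1, int),
                              np.linspace(0, cap, 512), np.zeros(512), float("nan"), n_excl)
    # right-closed bins (e_i, e_{i+1}]; zero falls in the first bin
    idx = np.clip(np.searchsorted(edges, v, side="left") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    grid = np.linspace(0.0, cap, 512)
    if v.size > 1 and v.std() > 0:
        kde = stats.gaussian_kde(v, bw_method="silverman")
        density = kde(grid)
        bw = float(kde.factor * v.std(ddof=1))
    else:
        density = np.zeros_like(grid)
        bw = float("nan")
    return KsDistribution(v, edges, counts, grid, density, bw, n_excl)


def detect_secondary_peak(
    dist: KsDistribution,
    search_range: tuple[float, float] = (1.5, 2.2),
    prominence_frac: float = 0.05,
) -> float | None:
    """Location of the most prominent density maximum inside ``search_range``.

    Returns None when no local maximum in the range reaches the prominence
    threshold (``prominence_frac`` of the global density maximum); a strictly
    decreasing (L-shaped) density therefore yields None.
    """
    lo, hi = search_range
    if lo >= hi:
        raise ValueError("search_range must satisfy lo < hi")
    if dist.density.size == 0 or not np.any(dist.density > 0):
        return None
    prom = prominence_frac * float(dist.density.max())
    peaks, props = signal.find_peaks(dist.density, prominence=prom)
    if peaks.size == 0:
        return None
    locs = dist.grid[peaks]
    mask = (locs > lo) & (locs < hi)
    if not mask.any():
        return None
    best = np.argmax(props["prominences"][mask])
    return float(locs[mask][best])


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float


def compare_groups(group_a: Iterable[float], group_b: Iterable[float], metric: str = "ks") -> GroupComparison:
    """Welch (unequal-variance) two-sample t-test between two value groups."""
    a = np.asarray([x for x in group_a if x is not None and np.isfinite(x)], dtype=float)
    b = np.asarray([x for x in group_b if x is not None and np.isfinite(x)], dtype=float)
    for name, v in (("a", a), ("b", b)):
        if v.size < 2:
            raise ValueError(f"group {name} needs >= 2 finite values")
        if v.std(ddof=1) == 0:
            raise ValueError(f"group {name} has zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(metric, float(a.mean()), float(b.mean()), a.size, b.size,
                           float(res.statistic), float(res.df), float(res.pvalue))


# ---------------------------------------------------------------------------
# Expression and regulation divergence
# ---------------------------------------------------------------------------

def expression_divergence(a: Sequence[float], b: Sequence[float]) -> float:
    """1 − Pearson r between two equal-length expression profiles (in [0, 2]).

    Profiles shorter than 3 conditions raise; a zero-variance profile makes
    the correlation undefined and returns NaN (flagged missing).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if av.size < 3:
        raise ValueError("profiles must have length >= 3")
    if av.std() == 0 or bv.std() == 0:
        log.warning("expression_divergence: zero-variance profile; returning NaN")
        return float("nan")
    r = np.corrcoef(av, bv)[0, 1]
    return float(1.0 - r)


def regulation_divergence(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard distance 1 − |a ∩ b| / |a ∪ b| between promoter motif hit sets.

    Both sets empty -> NaN (flagged missing).
    """
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        log.warning("regulation_divergence: both hit sets empty; returning NaN")
        return float("nan")
    return 1.0 - len(sa & sb) / len(union)


# ---------------------------------------------------------------------------
# Promoter windows and PWM scanning (optional plumbing)
# ---------------------------------------------------------------------------

def promoter_window(
    tss: int,
    strand: str,
    upstream: int = 600,
    downstream: int = 200,
    seq_length: int | None = None,
) -> tuple[int, int, bool]:
    """Half-open promoter interval around a TSS, strand-aware.

    The window spans ``upstream`` bp 5' of the TSS and ``downstream`` bp 3' of
    it (800 bp total by default).  Returns (start, end, clipped).
    """
    if tss is None:
        raise ValueError("tss is required")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"invalid strand {strand!r}")
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if seq_length is not None and end > seq_length:
        end, clipped = seq_length, True
    return start, end, clipped


_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _logodds(matrix: np.ndarray, pseudo: float = 1e-6) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != 4:
        raise ValueError("PWM must be a 4 x width matrix (rows A, C, G, T)")
    col = m.sum(axis=0)
    if not np.allclose(col[col > 0], 1.0, atol=1e-3):
        m = m / np.where(col == 0, 1.0, col)
    return np.log2((m + pseudo) / 0.25)


def _best_score(seq: str, lom: np.ndarray) -> float:
    w = lom.shape[1]
    if len(seq) < w:
        return -np.inf
    idx = np.fromiter((_BASES.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))
    best = -np.inf
    for off in range(len(seq) - w + 1):
        window = idx[off:off + w]
        s = 0.0
        for j, bi in enumerate(window):
            s += lom[bi, j] if bi >= 0 else 0.0  # N scores as background
        best = max(best, s)
    return best


def scan_pwms(
    sequence: str,
    pwms: Iterable[tuple[str, np.ndarray]],
    score_threshold_frac: float = 0.8,
) -> set[str]:
    """Motif hit set for a promoter sequence by log-odds scanning.

    A motif is reported when its best log-odds score over both strands reaches
    ``score_threshold_frac`` of the motif's maximum achievable score (uniform
    background).  Ambiguous bases (N) contribute the background score 0; a
    sequence of all N therefore never reaches a positive threshold.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    rc = seq.translate(_COMP)[::-1]
    hits: set[str] = set()
    for pwm_id, matrix in pwms:
        lom = _logodds(matrix)
        max_score = float(lom.max(axis=0).sum())
        if max_score <= 0:
            continue
        thr = score_threshold_frac * max_score
        if _best_score(seq, lom) >= thr or _best_score(rc, lom) >= thr:
            hits.add(pwm_id)
    return hits


def _motifs_to_pwms(motifs) -> list[tuple[str, np.ndarray]]:
    out = []
    for m in motifs:
        name = m.matrix_id if getattr(m, "matrix_id", None) else m.name
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append((name, counts / counts.sum(axis=0)))
    return out


def load_jaspar_pwms(path) -> list[tuple[str, np.ndarray]]:
    """Parse JASPAR-format PWMs into (id, 4 x w column-stochastic matrix)."""
    from Bio import motifs

    with open(path) as fh:
        return _motifs_to_pwms(motifs.parse(fh, "jaspar"))


def load_meme_pwms(path) -> list[tuple[str, np.ndarray]]:
    """Parse MEME minimal-format PWMs."""
    from Bio import motifs

    with open(path) as fh:
        return _motifs_to_pwms(motifs.parse(fh, "minimal"))


def plot_ks_distributions(dists: dict[str, KsDistribution], path) -> None:
    """Overlay Ks densities of several duplicate classes and save the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, d in dists.items():
        if d.density.size:
            ax.plot(d.grid, d.density, label=f"{label} (n={d.values.size})")
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
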