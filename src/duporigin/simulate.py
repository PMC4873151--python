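"""Forward-in-time gene-order evolution on a species ladder.

The generator emulates the genome history that colinearity-ladder dating is
designed to read: an ancestral genome evolves along a caterpillar species tree
(a focal lineage plus ordered outgroups), undergoes a genome triplication on
the stem above the nearest polyploid outgroup, suffers elevated post-polyploidy
gene loss (fractionation), experiences a burst of per-gene relocations in a
configurable time window after the triplication, and accumulates steady
single-gene duplications (tandem / proximal / transposed) with high constant
turnover.  Ks between duplicates follows a strict molecular clock
(Ks = 2 mu T) with multiplicative lognormal noise, and Ka = omega * Ks with
omega drawn per pair.

Every event is logged, and per-gene ground truth (birth mechanism, birth time,
relocation history, observable duplicate class) is emitted for the focal
genome, so classification pipelines can be scored against the generating
process.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .colinearity import GenomeLayout
from .epochs import DEFAULT_LADDER, EpochLadder

__all__ = [
    "RateConfig",
    "ClockConfig",
    "OmegaConfig",
    "SimEvent",
    "SimConfig",
    "SimResult",
    "ConfigError",
    "SimulationError",
    "simulate",
    "emit_homolog_pairs",
    "emit_cross_pairs",
    "AnnotationConfig",
    "generate_annotations",
    "write_fixture",
    "load_fixture",
    "pair_divergence",
]

SINGLE_DUP_KINDS = ("tandem", "proximal", "transposed")
POLYPLOIDY_KINDS = ("wgd", "triplication")


class ConfigError(ValueError):
    pass


class SimulationError(RuntimeError):
    def __init__(self, msg, event_log=None):
        super().__init__(msg)
        self.event_log = event_log


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateConfig:
    """Per-gene per-My event rates.

    Gene loss applies only to genes with at least one surviving same-family
    copy in the same genome (the last copy of a family cannot be lost), at
    ``loss_base`` except: polyploidy-descended copies lose at
    ``loss_polyploidy`` within ``polyploidy_loss_window`` My after the event
    (fractionation), and single-gene duplicate copies turn over at the higher
    constant ``loss_single_dup`` (the source of the L-shaped local-duplicate
    age distribution).  Relocation runs at ``relocation_base`` except inside
    ``burst_window`` (Mya) on polyploid lineages, where ``relocation_burst``
    applies.

    A ``constrained_fraction`` of ancestral gene lineages is dosage-constrained
    (gene-balance retention): their loss rates are scaled by
    ``constrained_loss_mult`` and the property is inherited by all copies and
    orthologs, so fractionation is correlated across lineages, as observed in
    real post-polyploid genomes, rather than independent.
    """

    loss_base: float = 0.002
    loss_polyploidy: float = 0.015
    polyploidy_loss_window: float = 40.0
    loss_single_dup: float = 0.008
    constrained_fraction: float = 0.3
    constrained_loss_mult: float = 0.15
    relocation_base: float = 0.001
    relocation_burst: float = 0.01
    burst_window: tuple[float, float] = (107.0, 148.0)
    tandem_dup: float = 0.002
    proximal_dup: float = 0.001
    transposed_dup: float = 0.001

    def validate(self, root_age: float) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "burst_window":
                lo, hi = v
                if not (0 <= lo < hi <= root_age):
                    raise ConfigError(f"burst_window {v} must be a sub-interval of [0, {root_age}]")
            elif v < 0:
                raise ConfigError(f"rate {f.name} must be >= 0, got {v}")
        if not (0 <= self.constrained_fraction <= 1):
            raise ConfigError("constrained_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ClockConfig:
    """Ks clock: Ks = 2 * mu * T * lognormal(sigma); mu in Ks/My per lineage."""

    mu: float = 0.0075
    sigma: float = 0.15


@dataclass(frozen=True)
class OmegaConfig:
    """Ka/Ks per pair drawn lognormal around ``median`` (purifying selection)."""

    median: float = 0.2
    sigma: float = 0.5


@dataclass(frozen=True)
class SimEvent:
    time: float
    kind: str  # 'triplication' | 'wgd'
    lineage: str = "focal_path"

    def __post_init__(self):
        if self.kind not in POLYPLOIDY_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    n_ancestral_genes: int = 2000
    n_chromosomes: int = 10
    focal: str = "At"
    ladder: EpochLadder = DEFAULT_LADDER
    events: tuple[SimEvent, ...] = (SimEvent(126.0, "triplication"),)
    rates: RateConfig = RateConfig()
    clock: ClockConfig = ClockConfig()
    omega: OmegaConfig = OmegaConfig()
    seed: int = 0

    def validate(self) -> None:
        if self.n_ancestral_genes < 1 or self.n_chromosomes < 1:
            raise ConfigError("need at least one gene and one chromosome")
        if len(self.ladder.outgroups) < 1:
            raise ConfigError("tree needs at least two leaves (focal + one outgroup)")
        root = self.ladder.root_age
        self.rates.validate(root)
        split_of = dict(self.ladder.outgroups)
        for ev in self.events:
            if ev.lineage == "focal_path":
                if not (0 < ev.time < root):
                    raise ConfigError(f"event at {ev.time} Mya is outside the focal path (0, {root})")
            elif ev.lineage in split_of:
                if not (0 < ev.time < split_of[ev.lineage]):
                    raise ConfigError(
                        f"event at {ev.time} Mya is outside the {ev.lineage} branch (0, {split_of[ev.lineage]})"
                    )
            else:
                raise ConfigError(f"event lineage {ev.lineage!r} is not in the tree")


# ---------------------------------------------------------------------------
# Internal state
# ---------------------------------------------------------------------------

class _Registry:
    """Global gene genealogy across all genomes."""

    def __init__(self):
        self.counter = 0
        self.family: dict[str, int] = {}
        self.parent: dict[str, str | None] = {}
        self.btime: dict[str, float] = {}        # branch-off time from parent node (Mya)
        self.birth_time: dict[str, float] = {}   # real lineage birth time (clones inherit)
        self.event_kind: dict[str, str] = {}     # separating event kind at btime
        self.lineage_kind: dict[str, str] = {}   # real birth mechanism (clones inherit)
        self.strand: dict[str, str] = {}
        self.relocations: dict[str, list[float]] = {}
        self.loss_mult: dict[str, float] = {}

    def new_gene(self, family, parent, btime, birth_time, event_kind, lineage_kind, strand,
                 loss_mult: float | None = None) -> str:
        g = f"g{self.counter:07d}"
        self.counter += 1
        self.family[g] = family
        self.parent[g] = parent
        self.btime[g] = btime
        self.birth_time[g] = birth_time
        self.event_kind[g] = event_kind
        self.lineage_kind[g] = lineage_kind
        self.strand[g] = strand
        if loss_mult is None:
            loss_mult = self.loss_mult[parent] if parent is not None else 1.0
        self.loss_mult[g] = loss_mult
        return g


class _Genome:
    def __init__(self, label: str, chroms: list[list[str]], poly_events=(), fam_count=None):
        self.label = label
        self.chroms = chroms
        self.poly_events: list[float] = list(poly_events)
        if fam_count is None:
            fam_count = Counter()
        self.fam_count = fam_count

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chroms)

    def genes(self):
        for c in self.chroms:
            yield from c


def _pick_slot(genome: _Genome, rng) -> tuple[int, int]:
    """Uniform insertion slot over the genome (chromosome index, list index)."""
    total = genome.n_genes + len(genome.chroms)
    u = int(rng.integers(total))
    for ci, c in enumerate(genome.chroms):
        if u <= len(c):
            return ci, u
        u -= len(c) + 1
    return len(genome.chroms) - 1, len(genome.chroms[-1])


def _pick_gene(genome: _Genome, rng) -> tuple[str, int, int]:
    u = int(rng.integers(genome.n_genes))
    for ci, c in enumerate(genome.chroms):
        if u < len(c):
            return c[u], ci, u
        u -= len(c)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genomes: dict[str, GenomeLayout]
    families: dict[str, int]
    truth: pd.DataFrame
    event_log: pd.DataFrame
    lineage_initial: dict[str, int]
    registry: _Registry = field(repr=False, default=None)

    @property
    def gamma_time(self) -> float | None:
        times = [e.time for e in self.config.events
                 if e.lineage == "focal_path" and e.kind in POLYPLOIDY_KINDS]
        return max(times) if times else None


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

_MAX_SLICE_MY = 5.0


def _loss_rate_class(reg: _Registry, genome: _Genome, g: str, active_poly: tuple, rates: RateConfig) -> str:
    if genome.fam_count[reg.family[g]] < 2:
        return "none"
    if reg.lineage_kind[g] in SINGLE_DUP_KINDS:
        return "single"
    if any(reg.birth_time[g] >= e for e in active_poly):
        return "poly"
    return "base"


def _evolve_slice(genome, reg, rates, t_hi, t_lo, rng, log_rows):
    """Continuous events on (t_lo, t_hi]; rates constant within the slice."""
    dt = t_hi - t_lo
    n = genome.n_genes
    if n == 0 or dt <= 0:
        return
    lo_w, hi_w = rates.burst_window
    mid = (t_hi + t_lo) / 2
    in_burst = genome.poly_events and lo_w <= mid <= hi_w
    reloc_rate = rates.relocation_burst if in_burst else rates.relocation_base
    active_poly = tuple(e for e in genome.poly_events
                        if e - rates.polyploidy_loss_window <= mid <= e)

    # class totals weighted by per-gene retention multipliers
    n_class: dict[str, float] = Counter()
    for g in genome.genes():
        cls = _loss_rate_class(reg, genome, g, active_poly, rates)
        n_class[cls] += reg.loss_mult[g] if cls in ("base", "poly") else 1
    loss_rates = {"base": rates.loss_base, "poly": rates.loss_polyploidy, "single": rates.loss_single_dup}

    events: list[tuple[float, str]] = []
    for kind, rate, count in (
        ("relocation", reloc_rate, n),
        ("tandem", rates.tandem_dup, n),
        ("proximal", rates.proximal_dup, n),
        ("transposed", rates.transposed_dup, n),
    ):
        k = rng.poisson(rate * dt * count)
        events += [(float(t), kind) for t in t_lo + rng.random(k) * dt]
    for cls, rate in loss_rates.items():
        k = rng.poisson(rate * dt * n_class[cls])
        events += [(float(t), f"loss:{cls}") for t in t_lo + rng.random(k) * dt]

    events.sort(key=lambda e: -e[0])  # apply oldest first
    for t, kind in events:
        if genome.n_genes == 0:
            break
        if kind.startswith("loss:"):
            cls = kind.split(":", 1)[1]
            for _ in range(60):  # rejection-sample a gene of the drawn rate class
                g, ci, gi = _pick_gene(genome, rng)
                if _loss_rate_class(reg, genome, g, active_poly, rates) != cls:
                    continue
                if cls in ("base", "poly") and rng.random() >= reg.loss_mult[g]:
                    continue
                genome.chroms[ci].pop(gi)
                genome.fam_count[reg.family[g]] -= 1
                log_rows.append((t, genome.label, "loss", g, ""))
                break
        elif kind == "relocation":
            g, ci, gi = _pick_gene(genome, rng)
            genome.chroms[ci].pop(gi)
            cj, slot = _pick_slot(genome, rng)
            genome.chroms[cj].insert(slot, g)
            reg.relocations.setdefault(g, []).append(t)
            log_rows.append((t, genome.label, "relocation", g, f"{ci}->{cj}"))
        elif kind in ("tandem", "proximal", "transposed"):
            g, ci, gi = _pick_gene(genome, rng)
            new = reg.new_gene(reg.family[g], g, t, t, kind, kind, reg.strand[g])
            if kind == "tandem":
                cj, slot = ci, gi + 1
            elif kind == "proximal":
                d = int(rng.integers(2, 11))
                right_ok = gi + d <= len(genome.chroms[ci])
                left_ok = gi + 1 - d >= 0
                if right_ok and (not left_ok or rng.random() < 0.5):
                    cj, slot = ci, gi + d
                elif left_ok:
                    cj, slot = ci, gi + 1 - d
                else:
                    cj, slot = ci, min(gi + d, len(genome.chroms[ci]))
            else:
                cj, slot = _pick_slot(genome, rng)
            genome.chroms[cj].insert(slot, new)
            genome.fam_count[reg.family[g]] += 1
            log_rows.append((t, genome.label, f"birth:{kind}", new, f"parent={g}"))


def _apply_polyploidy(genome, reg, ev: SimEvent, rng, log_rows):
    n_copies = 2 if ev.kind == "triplication" else 1
    # new subgenome chromosomes preserve ancestral gene order and are appended;
    # later relocations, not the event itself, do the shuffling
    new_chroms = []
    for c in list(genome.chroms):
        for _ in range(n_copies):
            copy = []
            for g in c:
                new = reg.new_gene(reg.family[g], g, ev.time, ev.time, ev.kind, ev.kind, reg.strand[g])
                copy.append(new)
                genome.fam_count[reg.family[g]] += 1
                log_rows.append((ev.time, genome.label, f"birth:{ev.kind}", new, f"parent={g}"))
            new_chroms.append(copy)
    genome.chroms.extend(new_chroms)
    genome.poly_events.append(ev.time)
    log_rows.append((ev.time, genome.label, ev.kind, "", f"n_chrom={len(genome.chroms)}"))


def _evolve_branch(genome, reg, cfg: SimConfig, t_hi, t_lo, branch_events, rng, log_rows):
    """Evolve one branch from t_hi down to t_lo (Mya), applying discrete events."""
    evs = sorted([e for e in branch_events if t_lo < e.time <= t_hi], key=lambda e: -e.time)
    cuts = {t_lo, t_hi}
    for w in cfg.rates.burst_window:
        if t_lo < w < t_hi:
            cuts.add(w)
    t = t_hi
    for ev in evs + [None]:
        t_stop = ev.time if ev is not None else t_lo
        # fractionation-window edges depend on events already applied
        seg_cuts = set()
        for e_time in genome.poly_events:
            edge = e_time - cfg.rates.polyploidy_loss_window
            if t_stop < edge < t:
                seg_cuts.add(edge)
        pts = sorted({t, t_stop} | {c for c in cuts if t_stop < c < t} | seg_cuts, reverse=True)
        for a, b in zip(pts, pts[1:]):
            # bounded slices keep Poisson counts honest as gene number drifts
            n_sub = max(1, int(np.ceil((a - b) / _MAX_SLICE_MY)))
            for k in range(n_sub):
                s_hi = a - (a - b) * k / n_sub
                s_lo = a - (a - b) * (k + 1) / n_sub
                _evolve_slice(genome, reg, cfg.rates, s_hi, s_lo, rng, log_rows)
        if ev is not None:
            _apply_polyploidy(genome, reg, ev, rng, log_rows)
        t = t_stop


def _clone_genome(genome, reg, label: str, split_time: float) -> _Genome:
    chroms = []
    for c in genome.chroms:
        copy = []
        for g in c:
            new = reg.new_gene(
                reg.family[g], g, split_time, reg.birth_time[g], "speciation",
                reg.lineage_kind[g], reg.strand[g],
            )
            copy.append(new)
        chroms.append(copy)
    return _Genome(label, chroms, genome.poly_events, Counter(genome.fam_count))


def simulate(config: SimConfig) -> SimResult:
    """Run the forward simulation; deterministic for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    reg = _Registry()
    log_rows: list[tuple] = []
    root = config.ladder.root_age

    # ancestral genome: families 0..n-1 spread contiguously over chromosomes
    n, k = config.n_ancestral_genes, config.n_chromosomes
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    chroms, fam = [], 0
    for s in sizes:
        c = []
        for _ in range(s):
            strand = "+" if rng.random() < 0.5 else "-"
            mult = (config.rates.constrained_loss_mult
                    if rng.random() < config.rates.constrained_fraction else 1.0)
            c.append(reg.new_gene(fam, None, root, root, "ancestral", "ancestral", strand,
                                  loss_mult=mult))
            fam += 1
        chroms.append(c)
    genome = _Genome(config.focal, chroms, [], Counter({f: 1 for f in range(n)}))

    by_lineage: dict[str, list[SimEvent]] = {}
    for ev in config.events:
        by_lineage.setdefault(ev.lineage, []).append(ev)

    lineage_initial = {config.focal: genome.n_genes}
    finals: dict[str, _Genome] = {}
    t = root
    for sp, t_split in reversed(config.ladder.outgroups):
        _evolve_branch(genome, reg, config, t, t_split, by_lineage.get("focal_path", ()), rng, log_rows)
        out = _clone_genome(genome, reg, sp, t_split)
        lineage_initial[sp] = out.n_genes
        _evolve_branch(out, reg, config, t_split, 0.0, by_lineage.get(sp, ()), rng, log_rows)
        finals[sp] = out
        t = t_split
    _evolve_branch(genome, reg, config, t, 0.0, by_lineage.get("focal_path", ()), rng, log_rows)
    finals[config.focal] = genome

    event_log = pd.DataFrame(log_rows, columns=["time", "lineage", "kind", "gene", "detail"])
    if genome.n_genes == 0:
        raise SimulationError("focal genome lost all genes", event_log)

    layouts = {}
    for sp, g in finals.items():
        layouts[sp] = GenomeLayout(
            sp,
            {f"{sp}_c{i}": list(c) for i, c in enumerate(g.chroms) if c},
            strand={x: reg.strand[x] for c in g.chroms for x in c},
        )

    result = SimResult(config, layouts, dict(reg.family), pd.DataFrame(), event_log,
                       lineage_initial, registry=reg)
    result.truth = _build_truth(result)
    return result


# ---------------------------------------------------------------------------
# Genealogy and truth labels
# ---------------------------------------------------------------------------

def pair_divergence(result_or_reg, a: str, b: str) -> tuple[float, str]:
    """Divergence time (Mya) and separating-event kind for two same-family genes.

    The separating event is the duplication (or speciation) at which the two
    lineages parted: the most recent common ancestor's child with the larger
    branch-off time on the two descent paths.
    """
    reg = result_or_reg.registry if isinstance(result_or_reg, SimResult) else result_or_reg
    if a == b:
        raise ValueError("a pair needs two distinct genes")
    chain = []
    x = a
    while x is not None:
        chain.append(x)
        x = reg.parent[x]
    pos = {g: i for i, g in enumerate(chain)}
    x, prev_b = b, None
    while x not in pos:
        prev_b = x
        x = reg.parent[x]
        if x is None:
            raise ValueError(f"{a!r} and {b!r} share no ancestor (different families)")
    cands = []
    if pos[x] > 0:
        cands.append(chain[pos[x] - 1])
    if prev_b is not None:
        cands.append(prev_b)
    sep = max(cands, key=lambda g: reg.btime[g])
    return reg.btime[sep], reg.event_kind[sep]


_MODE_RANK = {"wgd": 0, "tandem": 1, "proximal": 2, "dispersed": 3}


def _build_truth(result: SimResult) -> pd.DataFrame:
    reg = result.registry
    cfg = result.config
    layout = result.genomes[cfg.focal]
    lo_w, hi_w = cfg.rates.burst_window
    t_gamma = result.gamma_time

    by_family: dict[int, list[str]] = {}
    for g in layout.genes:
        by_family.setdefault(reg.family[g], []).append(g)

    rows = []
    for g in layout.genes:
        partners = [p for p in by_family[reg.family[g]] if p != g]
        relocs = sorted(reg.relocations.get(g, []), reverse=True)
        last_rel = min(relocs) if relocs else np.nan  # most recent = smallest Mya

        # Observable expected mode.  WGD-ness is a property of descent: the
        # pair must have been separated by a polyploidy event, with both
        # members still at positions laid down by that event (present at or
        # born by the event, never relocated since).  Local modes are
        # positional by definition, so they are read off the final layout.
        is_wgd = False
        for p in partners:
            t_div, kind = pair_divergence(reg, g, p)
            if kind not in POLYPLOIDY_KINDS:
                continue
            if any(r < t_div for r in relocs):
                continue
            if any(r < t_div for r in reg.relocations.get(p, [])):
                continue
            if reg.birth_time[g] >= t_div and reg.birth_time[p] >= t_div:
                is_wgd = True
                break
        min_dr = None
        for p in partners:
            if layout.chrom[p] == layout.chrom[g]:
                dr = abs(layout.rank[p] - layout.rank[g])
                min_dr = dr if min_dr is None else min(min_dr, dr)
        if not partners:
            expected = "singleton"
        elif is_wgd:
            expected = "wgd"
        elif min_dr == 1:
            expected = "tandem"
        elif min_dr is not None and min_dr <= 10:
            expected = "proximal"
        else:
            expected = "dispersed"

        if not partners:
            origin = "singleton"
        elif expected == "wgd":
            origin = "gamma"
        elif expected in ("tandem", "proximal"):
            origin = expected
        else:
            origin = "dispersed_other"
            if (
                relocs
                and t_gamma is not None
                and reg.birth_time[g] >= t_gamma
                and last_rel < t_gamma
                and lo_w <= last_rel <= hi_w
            ):
                origin = "relocated_gamma"
            elif reg.lineage_kind[g] == "transposed" and not relocs:
                origin = "transposed"
        rows.append(
            (
                g, reg.family[g], layout.chrom[g], layout.rank[g],
                reg.lineage_kind[g], reg.birth_time[g],
                len(relocs), last_rel, len(partners), expected, origin,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "family", "chrom", "rank", "birth_kind", "birth_time",
            "n_relocations", "last_relocation", "n_partners", "expected_mode", "truth_origin",
        ],
    )


# ---------------------------------------------------------------------------
# Homolog-pair emission
# ---------------------------------------------------------------------------

def _pair_rng(result: SimResult, tag: str):
    # crc32, not hash(): stable across processes
    h = zlib.crc32(tag.encode())
    return np.random.default_rng((result.config.seed * 1_000_003 + h % 999_983) % 2**31)


def emit_homolog_pairs(
    result: SimResult, species: str, top_k: int = 5, ks_cap: float = 3.0
) -> pd.DataFrame:
    """Within-genome same-family pairs with clock Ks, Ka and an E-value proxy.

    Per gene at most ``top_k`` partners with the smallest Ks and Ks < ks_cap
    are kept (a detectability cap standing in for a BLAST E-value cutoff); the
    returned unordered pair list is symmetric-closed and deduplicated.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if species not in result.genomes:
        raise KeyError(species)
    reg = result.registry
    rng = _pair_rng(result, f"pairs:{species}")
    clock, om = result.config.clock, result.config.omega
    layout = result.genomes[species]

    by_family: dict[int, list[str]] = {}
    for g in layout.genes:
        by_family.setdefault(reg.family[g], []).append(g)

    per_gene: dict[str, list[tuple[float, str, float, float]]] = {}
    seen = set()
    records = {}
    for fam, genes in by_family.items():
        if len(genes) < 2:
            continue
        genes = sorted(genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                t_div, _ = pair_divergence(reg, a, b)
                noise = float(np.exp(rng.normal(0.0, clock.sigma))) if clock.sigma > 0 else 1.0
                ks = 2.0 * clock.mu * t_div * noise
                omega = float(np.exp(rng.normal(np.log(om.median), om.sigma))) if om.sigma > 0 else om.median
                ka = omega * ks
                ev = 10.0 ** (-max(0.0, 180.0 * (1.0 - ks / 3.5)))
                records[(a, b)] = (ks, ka, ev)
                per_gene.setdefault(a, []).append((ks, b))
                per_gene.setdefault(b, []).append((ks, a))
    keep: set[tuple[str, str]] = set()
    for g, cands in per_gene.items():
        cands = sorted((ks, p) for ks, p in cands if ks < ks_cap)
        for ks, p in cands[:top_k]:
            keep.add((g, p) if g <= p else (p, g))
    rows = [(a, b, records[(a, b)][2], records[(a, b)][0], records[(a, b)][1]) for a, b in sorted(keep)]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue", "ks", "ka"])


def emit_cross_pairs(
    result: SimResult, species_a: str, species_b: str, ks_cap: float | None = None
) -> pd.DataFrame:
    """Cross-genome same-family homolog pairs (colinearity anchors)."""
    reg = result.registry
    la, lb = result.genomes[species_a], result.genomes[species_b]
    by_family: dict[int, list[str]] = {}
    for g in lb.genes:
        by_family.setdefault(reg.family[g], []).append(g)
    mu = result.config.clock.mu
    rows = []
    for ga in la.genes:
        for gb in by_family.get(reg.family[ga], ()):
            if ks_cap is not None:
                t_div, _ = pair_divergence(reg, ga, gb)
                if 2.0 * mu * t_div >= ks_cap:
                    continue
            rows.append((ga, gb))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationConfig:
    """Synthetic functional annotations conditioned on truth origin classes.

    Multipliers scale a class's probability of carrying a trait (essentiality,
    PPI participation, favored GO terms) relative to the base rate; expression
    correlation and motif-set overlap decay with pair divergence time with
    timescales ``expr_tau`` / ``reg_tau`` (My).
    """

    n_go_terms: int = 40
    n_bp_terms: int = 34
    terms_per_gene: float = 3.0
    n_favored_terms: int = 6
    go_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"gamma": 1.5, "relocated_gamma": 1.5, "tandem": 0.6}
    )
    essential_base: float = 0.12
    essential_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"relocated_gamma": 1.8, "gamma": 1.0, "tandem": 0.6,
                                 "proximal": 0.6, "transposed": 0.5}
    )
    screen_fraction: float = 0.55
    ppi_base: float = 0.3
    ppi_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"gamma": 1.3, "relocated_gamma": 1.0, "tandem": 0.6,
                                 "proximal": 0.6, "transposed": 0.6}
    )
    ppi_mean_degree: float = 2.0
    expr_n_conditions: int = 20
    expr_tau: float = 250.0
    reg_universe: int = 155
    reg_base_mean: float = 8.0
    reg_tau: float = 180.0
    reg_gain: float = 2.0

    def validate(self):
        for m in (self.go_multipliers, self.essential_multipliers, self.ppi_multipliers):
            if any(v < 0 for v in m.values()):
                raise ConfigError("multipliers must be >= 0")


@dataclass
class AnnotationBundle:
    go: pd.DataFrame                 # gene, term
    go_namespaces: pd.DataFrame      # term, namespace
    essential: pd.DataFrame          # gene, essential (0/1)
    ppi_edges: pd.DataFrame          # gene_a, gene_b
    screened: list[str]
    expression: pd.DataFrame         # genes x conditions
    pwm_hits: dict[str, set[str]]


def _family_expression(reg, genes, tau, n_cond, rng):
    """Multivariate-normal profiles with cov exp(-2 t_div / tau) (OU on the
    gene genealogy): young pairs correlate more than old ones."""
    k = len(genes)
    cov = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            t, _ = pair_divergence(reg, genes[i], genes[j])
            cov[i, j] = cov[j, i] = np.exp(-2.0 * t / tau)
    for jitter in (1e-9, 1e-6, 1e-3):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(k))
            break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover - covariance is PSD by construction
        L = np.linalg.cholesky(cov + 0.1 * np.eye(k))
    return L @ rng.standard_normal((k, n_cond))


def _family_pwm_sets(reg, genes, cfg: AnnotationConfig, universe, rng):
    """Evolve motif sets along the family genealogy: per My, each motif is
    retained with rate 1/reg_tau of loss, and novel motifs arrive at
    reg_gain/reg_tau per My.  Age-0 copies share their parent's exact set."""

    nodes = set(genes)
    for g in genes:
        x = reg.parent[g]
        while x is not None and x not in nodes:
            nodes.add(x)
            x = reg.parent[x]
    checkpoints: dict[str, list[tuple[float, frozenset]]] = {}

    def set_at(node: str, t: float) -> frozenset:
        cps = checkpoints[node]
        base_t, base_s = cps[-1]
        for ct, cs in cps:
            if ct >= t:
                base_t, base_s = ct, cs
        s = sorted(base_s)  # sorted iteration keeps rng consumption deterministic
        dt = base_t - t
        if dt > 0:
            keep = np.exp(-dt / cfg.reg_tau)
            s = [m for m in s if rng.random() < keep]
            n_gain = rng.poisson(cfg.reg_gain * dt / cfg.reg_tau)
            for _ in range(n_gain):
                s.append(universe[int(rng.integers(len(universe)))])
        out = frozenset(s)
        cps.append((t, out))
        cps.sort(key=lambda c: -c[0])
        return out

    order = sorted(nodes, key=lambda g: (-reg.btime[g], g))
    for g in order:
        par = reg.parent[g]
        if par is None or par not in checkpoints:
            size = 1 + rng.poisson(cfg.reg_base_mean)
            s = frozenset(universe[i] for i in rng.choice(len(universe), min(size, len(universe)), replace=False))
            checkpoints[g] = [(reg.btime[g], s)]
        else:
            checkpoints[g] = [(reg.btime[g], set_at(par, reg.btime[g]))]
    return {g: set(set_at(g, 0.0)) for g in genes}


def generate_annotations(
    result: SimResult, ann_config: AnnotationConfig | None = None, seed: int = 0
) -> AnnotationBundle:
    cfg = ann_config or AnnotationConfig()
    cfg.validate()
    rng = np.random.default_rng((result.config.seed * 7_368_787 + seed) % 2**31)
    reg = result.registry
    truth = result.truth.set_index("gene")
    genes = list(truth.index)
    origin = truth["truth_origin"]

    # GO terms with Zipf-like sizes; favored terms boosted per class
    terms = [f"T{i:04d}" for i in range(cfg.n_go_terms)]
    ns = pd.DataFrame(
        {"term": terms,
         "namespace": ["biological_process" if i < cfg.n_bp_terms else "molecular_function"
                       for i in range(cfg.n_go_terms)]}
    )
    base_w = 1.0 / (np.arange(cfg.n_go_terms) + 1.0) ** 0.6
    go_rows = []
    for g in genes:
        mult = cfg.go_multipliers.get(origin[g], 1.0)
        w = base_w.copy()
        w[: cfg.n_favored_terms] *= mult
        w /= w.sum()
        k = min(rng.poisson(cfg.terms_per_gene), cfg.n_go_terms)
        if k:
            for ti in rng.choice(cfg.n_go_terms, size=k, replace=False, p=w):
                go_rows.append((g, terms[ti]))
    go = pd.DataFrame(go_rows, columns=["gene", "term"])

    ess_p = np.array([min(1.0, cfg.essential_base * cfg.essential_multipliers.get(origin[g], 1.0))
                      for g in genes])
    essential = pd.DataFrame({"gene": genes, "essential": (rng.random(len(genes)) < ess_p).astype(int)})

    screened = [g for g in genes if rng.random() < cfg.screen_fraction]
    part_p = {g: min(1.0, cfg.ppi_base * cfg.ppi_multipliers.get(origin[g], 1.0)) for g in screened}
    participants = [g for g in screened if rng.random() < part_p[g]]
    edges = []
    if len(participants) >= 2:
        shuffled = list(participants)
        rng.shuffle(shuffled)
        for i in range(0, len(shuffled) - 1, 2):
            edges.append((shuffled[i], shuffled[i + 1]))
        n_extra = rng.poisson(max(0.0, cfg.ppi_mean_degree - 1.0) * len(participants) / 2)
        for _ in range(n_extra):
            i, j = rng.choice(len(participants), 2, replace=False)
            edges.append((participants[i], participants[j]))
    ppi_edges = pd.DataFrame(sorted({(min(a, b), max(a, b)) for a, b in edges if a != b}),
                             columns=["gene_a", "gene_b"])

    by_family: dict[int, list[str]] = {}
    for g in genes:
        by_family.setdefault(reg.family[g], []).append(g)
    expr = np.empty((len(genes), cfg.expr_n_conditions))
    index_of = {g: i for i, g in enumerate(genes)}
    universe = [f"PWM{i:03d}" for i in range(cfg.reg_universe)]
    pwm_hits: dict[str, set[str]] = {}
    for fam, fgenes in sorted(by_family.items()):
        fgenes = sorted(fgenes)
        X = _family_expression(reg, fgenes, cfg.expr_tau, cfg.expr_n_conditions, rng)
        for g, row in zip(fgenes, X):
            expr[index_of[g]] = row
        pwm_hits.update(_family_pwm_sets(reg, fgenes, cfg, universe, rng))
    expression = pd.DataFrame(expr, index=genes,
                              columns=[f"cond{i:02d}" for i in range(cfg.expr_n_conditions)])
    return AnnotationBundle(go, ns, essential, ppi_edges, screened, expression, pwm_hits)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def _layout_to_bed(layout: GenomeLayout) -> pd.DataFrame:
    rows = []
    for chrom, cgenes in layout.chromosomes.items():
        for i, g in enumerate(cgenes):
            rows.append((chrom, i, i + 1, g, 0, layout.strand.get(g, "+")))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "score", "strand"])


def bed_to_layout(df: pd.DataFrame, species: str) -> GenomeLayout:
    chroms: dict[str, list[str]] = {}
    strand = {}
    for _, r in df.sort_values(["chrom", "start"]).iterrows():
        chroms.setdefault(r["chrom"], []).append(r["gene"])
        strand[r["gene"]] = r.get("strand", "+")
    return GenomeLayout(species, chroms, strand=strand)


def write_fixture(result: SimResult, annotations: AnnotationBundle | None, outdir) -> None:
    """Write a complete plain-text fixture that round-trips through the
    pipeline's readers (BED-like gene tables, TSV pair/Ks tables, ladder,
    truth labels, annotation TSVs)."""
    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    for sp, layout in sorted(result.genomes.items()):
        _layout_to_bed(layout).to_csv(os.path.join(outdir, f"genes_{sp}.bed"),
                                      sep="\t", index=False, header=False)
    emit_homolog_pairs(result, cfg.focal).to_csv(
        os.path.join(outdir, f"pairs_{cfg.focal}.tsv"), sep="\t", index=False)
    for sp, _ in cfg.ladder.outgroups:
        emit_cross_pairs(result, cfg.focal, sp).to_csv(
            os.path.join(outdir, f"pairs_{cfg.focal}_{sp}.tsv"), sep="\t", index=False)
    cfg.ladder.to_tsv(os.path.join(outdir, "ladder.tsv"))
    result.truth.to_csv(os.path.join(outdir, f"truth_{cfg.focal}.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(config_to_dict(cfg), fh, indent=1, sort_keys=True)
    if annotations is not None:
        a = annotations
        a.go.to_csv(os.path.join(outdir, "go.tsv"), sep="\t", index=False)
        a.go_namespaces.to_csv(os.path.join(outdir, "go_namespaces.tsv"), sep="\t", index=False)
        a.essential.to_csv(os.path.join(outdir, "essential.tsv"), sep="\t", index=False)
        a.ppi_edges.to_csv(os.path.join(outdir, "ppi_edges.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "ppi_screened.txt"), "w") as fh:
            fh.write("\n".join(a.screened) + ("\n" if a.screened else ""))
        a.expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t",
                            index=True, index_label="gene")
        rows = [(g, m) for g in sorted(a.pwm_hits) for m in sorted(a.pwm_hits[g])]
        pd.DataFrame(rows, columns=["gene", "pwm_id"]).to_csv(
            os.path.join(outdir, "pwm_hits.tsv"), sep="\t", index=False)


@dataclass
class FixtureBundle:
    focal: str
    layouts: dict[str, GenomeLayout]
    pairs: pd.DataFrame
    cross_pairs: dict[str, pd.DataFrame]
    ladder: EpochLadder
    truth: pd.DataFrame | None
    annotations: AnnotationBundle | None


def load_fixture(indir) -> FixtureBundle:
    with open(os.path.join(indir, "config.json")) as fh:
        cfg = json.load(fh)
    focal = cfg["focal"]
    ladder = EpochLadder.from_tsv(os.path.join(indir, "ladder.tsv"))
    layouts = {}
    for fn in sorted(os.listdir(indir)):
        if fn.startswith("genes_") and fn.endswith(".bed"):
            sp = fn[len("genes_"):-len(".bed")]
            df = pd.read_csv(os.path.join(indir, fn), sep="\t", header=None,
                             names=["chrom", "start", "end", "gene", "score", "strand"])
            layouts[sp] = bed_to_layout(df, sp)
    pairs = pd.read_csv(os.path.join(indir, f"pairs_{focal}.tsv"), sep="\t")
    cross = {}
    for sp, _ in ladder.outgroups:
        p = os.path.join(indir, f"pairs_{focal}_{sp}.tsv")
        if os.path.exists(p):
            cross[sp] = pd.read_csv(p, sep="\t")
    truth_path = os.path.join(indir, f"truth_{focal}.tsv")
    truth = pd.read_csv(truth_path, sep="\t") if os.path.exists(truth_path) else None

    ann = None
    if os.path.exists(os.path.join(indir, "go.tsv")):
        go = pd.read_csv(os.path.join(indir, "go.tsv"), sep="\t")
        ns = pd.read_csv(os.path.join(indir, "go_namespaces.tsv"), sep="\t")
        ess = pd.read_csv(os.path.join(indir, "essential.tsv"), sep="\t")
        ppi = pd.read_csv(os.path.join(indir, "ppi_edges.tsv"), sep="\t")
        with open(os.path.join(indir, "ppi_screened.txt")) as fh:
            screened = [l.strip() for l in fh if l.strip()]
        expr = pd.read_csv(os.path.join(indir, "expression.tsv"), sep="\t", index_col="gene")
        hits_df = pd.read_csv(os.path.join(indir, "pwm_hits.tsv"), sep="\t")
        hits: dict[str, set[str]] = {g: set() for g in expr.index}
        for g, m in zip(hits_df["gene"], hits_df["pwm_id"]):
            hits.setdefault(g, set()).add(m)
        ann = AnnotationBundle(go, ns, ess, ppi, screened, expr, hits)
    return FixtureBundle(focal, layouts, pairs, cross, ladder, truth, ann)


def config_to_dict(cfg: SimConfig) -> dict:
    d = {
        "n_ancestral_genes": cfg.n_ancestral_genes,
        "n_chromosomes": cfg.n_chromosomes,
        "focal": cfg.focal,
        "ladder": {"outgroups": [[s, t] for s, t in cfg.ladder.outgroups],
                   "distal": list(cfg.ladder.distal)},
        "events": [asdict(e) for e in cfg.events],
        "rates": asdict(cfg.rates),
        "clock": asdict(cfg.clock),
        "omega": asdict(cfg.omega),
        "seed": cfg.seed,
    }
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    rates = dict(d.get("rates", {}))
    if "burst_window" in rates:
        rates["burst_window"] = tuple(rates["burst_window"])
    return SimConfig(
        n_ancestral_genes=d.get("n_ancestral_genes", 2000),
        n_chromosomes=d.get("n_chromosomes", 10),
        focal=d.get("focal", "At"),
        ladder=EpochLadder(
            tuple((s, float(t)) for s, t in d["ladder"]["outgroups"]),
            tuple(d["ladder"].get("distal", ())),
        ) if "ladder" in d else DEFAULT_LADDER,
        events=tuple(SimEvent(**e) for e in d.get("events", [])),
        rates=RateConfig(**rates),
        clock=ClockConfig(**d.get("clock", {})),
        omega=OmegaConfig(**d.get("omega", {})),
        seed=int(d.get("seed", 0)),
    )
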