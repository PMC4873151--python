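"""Epoch dating of dispersed duplicates by colinearity against an outgroup ladder.

A dispersed duplicate that still shows colinearity conservation with an
outgroup must have reached its current position before the focal lineage and
that outgroup diverged.  Scanning an ordered ladder of outgroups therefore
brackets each duplicate's creation (relocation) time: a gene colinear with
outgroup *i* but not with outgroup *i+1* was placed during the epoch between
the two divergences.  Per-epoch retention rates (retained duplicates per My)
expose bursts of gene relocation, and time windows on the epochs separate
recently transposed duplicates from duplicates relocated shortly after an
ancient polyploidy (the "relocated gamma" class of core eudicots).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRE_LADDER",
    "ORIGIN_CLASSES",
    "EpochLadder",
    "DEFAULT_LADDER",
    "assign_epochs",
    "retention_rates",
    "call_origins",
    "relocated_fraction",
    "gamma_set_no_recent_wgd",
]

PRE_LADDER = -1  # sentinel epoch index: colinear with the farthest outgroup

ORIGIN_CLASSES = (
    "alpha", "beta", "gamma", "wgd",
    "tandem", "proximal",
    "transposed", "relocated_gamma", "dispersed_other",
)


@dataclass(frozen=True)
class EpochLadder:
    """Ordered outgroups (nearest to farthest) with divergence times in Mya.

    ``distal`` optionally names outgroups used only as distal exclusions (for
    the no-recent-WGD gamma-set estimation), not as ladder rungs.
    """

    outgroups: tuple[tuple[str, float], ...]
    distal: tuple[str, ...] = ()

    def __post_init__(self):
        times = [t for _, t in self.outgroups]
        if not times:
            raise ValueError("ladder must contain at least one outgroup")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("ladder divergence times must be strictly increasing")
        if any(t <= 0 for t in times):
            raise ValueError("divergence times must be positive")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.outgroups)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.outgroups)

    def time_of(self, species: str) -> float:
        for s, t in self.outgroups:
            if s == species:
                return t
        raise KeyError(species)

    @property
    def epochs(self) -> list[tuple[float, float]]:
        """Half-open intervals [t_i, t_{i+1}); one epoch per outgroup."""
        bounds = (0.0,) + self.times
        return [(bounds[i], bounds[i + 1]) for i in range(len(self.outgroups))]

    @property
    def root_age(self) -> float:
        return self.times[-1]

    # -- TSV round trip ----------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "EpochLadder":
        df = pd.read_csv(path, sep="\t")
        if "role" not in df.columns:
            df["role"] = "ladder"
        lad = df[df["role"] == "ladder"].sort_values("divergence_mya")
        distal = tuple(df.loc[df["role"] == "distal_exclusion", "species"])
        return cls(tuple(zip(lad["species"], lad["divergence_mya"].astype(float))), distal)

    def to_tsv(self, path) -> None:
        rows = [(s, t, "ladder") for s, t in self.outgroups]
        rows += [(s, np.nan, "distal_exclusion") for s in self.distal]
        pd.DataFrame(rows, columns=["species", "divergence_mya", "role"]).to_csv(
            path, sep="\t", index=False
        )


#: The core-eudicot focal ladder: A. lyrata, B. rapa, C. papaya, T. cacao,
#: P. trichocarpa, V. vinifera, S. tuberosum, and the monocot O. sativa.
DEFAULT_LADDER = EpochLadder(
    (
        ("Al", 5.0), ("Br", 16.0), ("Cp", 72.0), ("Tc", 90.0),
        ("Pt", 107.0), ("Vv", 113.0), ("St", 125.0), ("Os", 148.0),
    )
)


def assign_epochs(
    genes: Iterable[str],
    ladder: EpochLadder,
    colinearity_per_outgroup: Mapping[str, set | Mapping],
) -> pd.DataFrame:
    """Date genes by their deepest colinear outgroup.

    ``colinearity_per_outgroup`` maps ladder species to the set of focal genes
    colinear with that outgroup.  The deepest (farthest) colinear outgroup
    wins; non-nested patterns (colinear with a distal but not a proximal
    outgroup, possible through lineage-specific block loss) are resolved the
    same way.  Genes colinear with the farthest outgroup predate the ladder
    and receive the ``PRE_LADDER`` sentinel epoch index.
    """
    if not ladder.outgroups:
        raise ValueError("empty ladder")
    missing = [s for s in ladder.species if s not in colinearity_per_outgroup]
    if missing:
        raise KeyError(f"colinearity missing for ladder outgroups: {missing}")
    sets = [colinearity_per_outgroup[s] for s in ladder.species]
    n = len(ladder.outgroups)
    rows = []
    for g in genes:
        deepest = -1
        for i in range(n - 1, -1, -1):
            if g in sets[i]:
                deepest = i
                break
        if deepest == n - 1:
            epoch = PRE_LADDER
            sp = ladder.species[deepest]
        elif deepest == -1:
            epoch = 0
            sp = None
        else:
            epoch = deepest + 1
            sp = ladder.species[deepest]
        rows.append((g, epoch, sp))
    return pd.DataFrame(rows, columns=["gene", "epoch_index", "deepest_colinear_outgroup"])


def retention_rates(assignments: pd.DataFrame, ladder: EpochLadder) -> pd.DataFrame:
    """Retained dispersed duplicates per My, per epoch (sentinels excluded)."""
    epochs = ladder.epochs
    counts = (
        assignments.loc[assignments["epoch_index"] != PRE_LADDER, "epoch_index"]
        .value_counts()
        .to_dict()
    )
    rows = []
    for i, (lo, hi) in enumerate(epochs):
        length = hi - lo
        if length <= 0:
            raise ValueError(f"epoch {i} has non-positive length")
        c = int(counts.get(i, 0))
        rows.append((i, lo, hi, length, c, c / length))
    return pd.DataFrame(rows, columns=["epoch_index", "start_mya", "end_mya", "length_my", "count", "rate_per_my"])


def default_windows(ladder: EpochLadder) -> dict[str, tuple[float, float]]:
    """Default origin-class time windows on an 8-rung core-eudicot ladder.

    transposed: duplicates younger than the second outgroup split (epochs 0-1);
    relocated_gamma: the two epochs between the 5th and 7th outgroup splits
    (the post-triplication relocation window).  The oldest epoch is left out
    of both windows: duplicates dated there may predate the triplication.
    """
    t = ladder.times
    if len(t) < 7:
        raise ValueError("default windows require a ladder of >= 7 outgroups; pass windows explicitly")
    return {"transposed": (0.0, t[1]), "relocated_gamma": (t[4], t[6])}


def call_origins(
    gene_modes: pd.DataFrame,
    assignments: pd.DataFrame,
    ladder: EpochLadder,
    windows: Mapping[str, tuple[float, float]] | None = None,
    wgd_events: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene origin class from mode labels plus epoch assignments.

    Dispersed genes fall into transposed / relocated_gamma / dispersed_other
    according to whether their epoch interval is contained in a class window;
    pre-ladder genes and genes in uncovered epochs are dispersed_other.
    Non-dispersed genes keep their mode-derived origin; WGD genes may be
    sub-attributed to named events (alpha/beta/gamma) via ``wgd_events``.
    """
    if windows is None:
        windows = default_windows(ladder)
    wins = sorted(windows.items(), key=lambda kv: kv[1])
    for (na, (a_lo, a_hi)), (nb, (b_lo, b_hi)) in zip(wins, wins[1:]):
        if b_lo < a_hi:
            raise ValueError(f"origin windows {na!r} and {nb!r} overlap")
    epochs = ladder.epochs
    epoch_of = dict(zip(assignments["gene"], assignments["epoch_index"]))
    rows = []
    for _, row in gene_modes.iterrows():
        g, mode = row["gene"], row["mode"]
        if mode == "wgd":
            origin = (wgd_events or {}).get(g, "wgd")
        elif mode in ("tandem", "proximal"):
            origin = mode
        else:  # dispersed
            e = epoch_of.get(g)
            origin = "dispersed_other"
            if e is not None and e != PRE_LADDER:
                lo, hi = epochs[int(e)]
                for name, (wlo, whi) in windows.items():
                    if wlo <= lo and hi <= whi:
                        origin = name
                        break
        rows.append((g, mode, origin))
    return pd.DataFrame(rows, columns=["gene", "mode", "origin"])


def relocated_fraction(n_gamma: int, n_relocated_gamma: int) -> float:
    """Percentage of surviving polyploidy-born duplicates found relocated.

    100 * relocated / (in-place + relocated), rounded half-up to one decimal
    (e.g. (802, 4763) -> 85.6).
    """
    if n_gamma < 0 or n_relocated_gamma < 0:
        raise ValueError("counts must be non-negative")
    total = n_gamma + n_relocated_gamma
    if total == 0:
        raise ZeroDivisionError("relocated_fraction undefined for zero counts")
    pct = Decimal(100 * n_relocated_gamma) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gamma_set_no_recent_wgd(
    intra_anchor_genes: set[str],
    colinearity_per_outgroup: Mapping[str, set],
    dispersed_genes: Iterable[str],
    mid_species: Sequence[str],
    distal_species: Sequence[str],
) -> tuple[set[str], set[str]]:
    """Gamma / relocated-gamma gene sets for a lineage with no recent WGD.

    In a genome without lineage-specific polyploidy, intra-genome colinear
    genes descend from the ancient triplication — except recent segmental
    duplicates, which are excluded by requiring colinearity with at least one
    outgroup.  Relocated-gamma genes are dispersed duplicates colinear with at
    least one designated mid-ladder outgroup and with none of the designated
    distal outgroups (monocots).
    """
    for s in list(mid_species) + list(distal_species):
        if s not in colinearity_per_outgroup:
            raise KeyError(f"designated outgroup {s!r} has no colinearity data")
    any_outgroup = set()
    for s, genes in colinearity_per_outgroup.items():
        any_outgroup |= set(genes)
    gamma = {g for g in intra_anchor_genes if g in any_outgroup}
    mid = set()
    for s in mid_species:
        mid |= set(colinearity_per_outgroup[s])
    distal = set()
    for s in distal_species:
        distal |= set(colinearity_per_outgroup[s])
    relocated = {g for g in dispersed_genes if g in mid and g not in distal}
    return gamma, relocated
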