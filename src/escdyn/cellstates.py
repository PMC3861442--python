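"""Coarse-graining of trajectories into discrete cell states.

Copy numbers are banded per gene (half-open intervals, boundary counts go
up) and a label is formed from the band indices plus the histone codes of
the gatekeeper genes (Nanog and the three lineage genes by default).  The
lambda weight attached to each band feeds the two-dimensional projection of
the landscape module (closeness to the trophectoderm / primitive endoderm
lineages).  Dwell segments, state occupancies and the filtered transition
diagram follow the sojourn-and-jump character of the simulated dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
import pandas as pd

__all__ = [
    "LevelScheme",
    "CellStateLabel",
    "TransitionDiagram",
    "default_scheme",
    "discretize",
    "label_trajectory",
    "dwell_segments",
    "occupancy_table",
    "build_diagram",
]


@dataclass(frozen=True)
class GeneBands:
    """Copy-number band edges, display names and lambda weights of one gene."""

    edges: tuple[float, ...]  # interior thresholds, strictly increasing
    names: tuple[str, ...]  # one per band (len(edges) + 1); "" = silent
    lambdas: tuple[float, ...]  # non-decreasing weights, one per band

    def __post_init__(self):
        if list(self.edges) != sorted(self.edges) or len(set(self.edges)) != len(self.edges):
            raise ValueError("band edges must be strictly increasing")
        if len(self.names) != len(self.edges) + 1 or len(self.lambdas) != len(self.names):
            raise ValueError("need one name and one lambda per band")
        if list(self.lambdas) != sorted(self.lambdas):
            raise ValueError("lambda weights must be non-decreasing")

    def band(self, count) -> np.ndarray | int:
        return np.searchsorted(self.edges, count, side="right")


@dataclass(frozen=True)
class LevelScheme:
    """Banding of all genes plus the choice of histone codes in the label."""

    bands: dict[str, GeneBands]
    histone_genes: tuple[str, ...] = ("Nanog", "Cdx2", "Gata6", "Gcnf")

    def gene_order(self):
        return tuple(self.bands)


def default_scheme() -> LevelScheme:
    """The banding used to define cell states and the projection weights.

    Nanog alone gets four bands (no expression, LN, MN, HN); high bands of
    the lineage genes carry the full weight 4 so that the projection
    separates the trophectoderm (Cdx2, Gcnf) and primitive endoderm (Gata6,
    Gcnf) directions.
    """
    return LevelScheme(
        bands={
            "Sox2": GeneBands((10, 200), ("", "LS", "S"), (0, 2, 4)),
            "Oct4": GeneBands((20, 200), ("", "LO", "O"), (0, 2, 4)),
            "Nanog": GeneBands(
                (40, 400, 4000), ("", "LN", "MN", "HN"), (0, 1, 2, 4)
            ),
            "Cdx2": GeneBands((20, 200), ("", "LC", "C"), (0, 2, 4)),
            "Gata6": GeneBands((100,), ("", "Ga"), (0, 4)),
            "Gcnf": GeneBands((100,), ("", "Gc"), (0, 4)),
        }
    )


@dataclass(frozen=True)
class CellStateLabel:
    """Discrete cell state: band index per gene plus histone codes."""

    bands: tuple[int, ...]
    histones: tuple[int, ...]  # per histone_genes entry, count of active alleles
    name: str

    def __str__(self):
        return self.name


def _label_name(scheme: LevelScheme, bands) -> str:
    parts = []
    for g, b in zip(scheme.gene_order(), bands):
        nm = scheme.bands[g].names[b]
        if nm:
            parts.append(nm)
    return "-".join(parts) if parts else "null"


def discretize(snapshot_counts, histone_counts, scheme: LevelScheme) -> CellStateLabel:
    """Label one snapshot.

    ``snapshot_counts`` maps gene -> copy number; ``histone_counts`` maps
    gene -> number of alleles with an active histone code.
    """
    bands = tuple(
        int(scheme.bands[g].band(snapshot_counts[g])) for g in scheme.gene_order()
    )
    hist = tuple(int(histone_counts.get(g, 0)) for g in scheme.histone_genes)
    return CellStateLabel(bands, hist, _label_name(scheme, bands))


def label_trajectory(traj, scheme: LevelScheme) -> np.ndarray:
    """Vector of state keys (tuples) for every snapshot of a trajectory."""
    order = scheme.gene_order()
    T = len(traj.times)
    bands = np.empty((T, len(order)), dtype=np.int16)
    for j, g in enumerate(order):
        bands[:, j] = scheme.bands[g].band(traj.gene_counts(g))
    lay = traj.layout
    hcols = []
    for g in scheme.histone_genes:
        gi = traj.gene_names.index(g)
        loci = [li for li in range(traj.hist.shape[1]) if lay.locus_gene[li] == gi]
        hcols.append(traj.hist[:, loci].sum(axis=1).astype(np.int16))
    hmat = np.stack(hcols, axis=1) if hcols else np.empty((T, 0), dtype=np.int16)
    keys = np.empty(T, dtype=object)
    full = np.concatenate([bands, hmat], axis=1)
    for t in range(T):
        keys[t] = tuple(int(x) for x in full[t])
    return keys


def key_to_label(key, scheme: LevelScheme) -> CellStateLabel:
    ng = len(scheme.gene_order())
    bands, hist = tuple(key[:ng]), tuple(key[ng:])
    return CellStateLabel(bands, hist, _label_name(scheme, bands))


def dwell_segments(traj, scheme: LevelScheme) -> list[tuple]:
    """(state key, entry time, exit time) with equal consecutive labels merged.

    Segment durations sum to the trajectory duration; each snapshot is taken
    to represent the recording interval that follows it, and the final
    segment is closed at the last snapshot time plus one interval.
    """
    keys = label_trajectory(traj, scheme)
    if len(keys) < 2:
        raise ValueError("need at least two snapshots to form segments")
    dt = float(traj.times[1] - traj.times[0])
    out = []
    i = 0
    pos = 0
    for key, grp in groupby(keys):
        n = sum(1 for _ in grp)
        t0 = float(traj.times[pos])
        t1 = float(traj.times[pos + n - 1]) + dt
        out.append((key, t0, t1))
        pos += n
        i += 1
    return out


def occupancy_table(ensemble, scheme: LevelScheme) -> pd.Series:
    """Fraction of total dwell time spent in each state, descending.

    Sums to one; the rank-ordered values are the occupancy spectrum used to
    pick the retention threshold of the transition diagram.
    """
    tot: dict = {}
    grand = 0.0
    for traj in ensemble.trajectories:
        for key, t0, t1 in dwell_segments(traj, scheme):
            tot[key] = tot.get(key, 0.0) + (t1 - t0)
            grand += t1 - t0
    s = pd.Series(tot) / grand
    return s.sort_values(ascending=False)


@dataclass
class TransitionDiagram:
    """Retained states with occupancies and dwell-time-derived rates."""

    states: pd.DataFrame  # index: state key; columns: name, occupancy
    edges: pd.DataFrame  # from, to, count, tau_s, rate_per_day
    occ_threshold: float
    link_count_threshold: int
    scheme: LevelScheme | None = None

    @property
    def state_keys(self):
        return list(self.states.index)

    def rate(self, a, b) -> float:
        m = self.edges[(self.edges["from"] == a) & (self.edges["to"] == b)]
        return float(m["rate_per_day"].iloc[0]) if len(m) else 0.0

    def write(self, prefix: str) -> None:
        self.states.to_csv(f"{prefix}.states.tsv", sep="\t")
        self.edges.to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)


def build_diagram(
    ensemble,
    scheme: LevelScheme | None = None,
    occ_threshold: float = 0.01,
    link_count_threshold: int = 600,
) -> TransitionDiagram:
    """Filtered transition diagram of an ensemble.

    States with occupancy below ``occ_threshold`` are dropped; passages
    through dropped states are projected out, so a path A -> (rare) -> A
    appears as a self-return edge on A.  The waiting time tau_ij is the
    total dwell time spent in state i divided by the number of observed
    i -> j transitions (the continuous-time Markov-chain rate estimator);
    the reported rate is W_ij = 1/tau_ij.  Edges observed no more than
    ``link_count_threshold`` times are discarded.
    """
    if occ_threshold < 0 or link_count_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    scheme = scheme or default_scheme()
    occ = occupancy_table(ensemble, scheme)
    kept = set(occ[occ >= occ_threshold].index) if occ_threshold > 0 else set(occ.index)
    if not kept:
        raise ValueError(
            f"no state reaches occupancy {occ_threshold}; max is {occ.max():.3g}"
        )
    counts: dict = {}
    dwell: dict = {}
    for traj in ensemble.trajectories:
        segs = [s for s in dwell_segments(traj, scheme)]
        retained = [(k, t0, t1) for (k, t0, t1) in segs if k in kept]
        for k, t0, t1 in retained:
            dwell[k] = dwell.get(k, 0.0) + (t1 - t0)
        for (a, *_), (b, *_) in zip(retained, retained[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    rows = []
    for (a, b), c in counts.items():
        if c <= link_count_threshold:
            continue
        tau = dwell[a] / c
        rows.append(
            {
                "from": a,
                "to": b,
                "count": c,
                "tau_s": tau,
                "rate_per_day": 86_400.0 / tau,
            }
        )
    edges = pd.DataFrame(
        rows, columns=["from", "to", "count", "tau_s", "rate_per_day"]
    )
    if len(edges) == 0:
        raise ValueError(
            "no edge exceeds the link threshold "
            f"({link_count_threshold}); diagram would be empty"
        )
    keys = sorted(kept, key=lambda k: -occ[k])
    states = pd.DataFrame(
        {
            "name": [key_to_label(k, scheme).name for k in keys],
            "occupancy": [occ[k] for k in keys],
        },
        index=pd.Index(keys, tupleize_cols=False, name="state"),
    )
    return TransitionDiagram(
        states=states,
        edges=edges,
        occ_threshold=occ_threshold,
        link_count_threshold=link_count_threshold,
        scheme=scheme,
    )
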