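"""Exact stochastic simulation of the network (Gillespie direct method).

`run_trajectory` simulates one cell: a burn-in performed under the ESC
culture condition (so every cell starts from the self-renewing steady state)
followed by the recorded window under the requested culture mode.
`run_ensemble` runs independent cells with per-cell seeds derived from a base
seed, so results do not depend on scheduling or worker count.

A pure-Python single step (`gillespie_step`) over the domain objects is also
provided; the production path is the compiled kernel in `_kernel`, which the
test suite cross-checks channel by channel against the `kinetics` functions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import kinetics
from ._kernel import ModelLayout, build_layout, rate_arrays, run_ssa
from .network import ParameterSet, RegulatoryNetwork
from .state import CellStateVector, LocusState, pluripotent_state, state_to_arrays

__all__ = [
    "DAY",
    "Trajectory",
    "Ensemble",
    "initial_state",
    "gillespie_step",
    "run_trajectory",
    "run_ensemble",
    "relaxation_experiment",
]

DAY = 86_400.0  # seconds


@lru_cache(maxsize=32)
def _layout_for(network: RegulatoryNetwork) -> ModelLayout:
    return build_layout(network)


def _params_hash(network: RegulatoryNetwork, params: ParameterSet) -> str:
    text = repr(network) + repr(sorted(params.__dict__.items(), key=str))
    return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class Trajectory:
    """Snapshots of one simulated cell at a fixed recording interval."""

    times: np.ndarray  # seconds, 0 at the start of the recorded window
    counts: np.ndarray  # int64 [T, G]
    ta: np.ndarray  # int8 [T, L], value/2 on the 0..1 scale
    hist: np.ndarray  # int8 [T, L]
    bound_mask: np.ndarray  # uint8 [T, L]
    gene_names: tuple[str, ...]
    seed: int
    params_hash: str
    layout: ModelLayout = field(repr=False, default=None)

    def gene_counts(self, gene: str) -> np.ndarray:
        return self.counts[:, self.gene_names.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for i, g in enumerate(self.gene_names):
            cols[f"n_{g}"] = self.counts[:, i]
        lay = self.layout
        for li in range(self.ta.shape[1]):
            if lay is not None:
                g = lay.gene_names[lay.locus_gene[li]]
                a = lay.locus_allele[li]
                tag = f"{g}.{a}"
            else:
                tag = str(li)
            cols[f"ta_{tag}"] = self.ta[:, li] / 2.0
            cols[f"hist_{tag}"] = self.hist[:, li]
            cols[f"bound_{tag}"] = self.bound_mask[:, li]
        return pd.DataFrame(cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Ensemble:
    """Independent trajectories sharing one configuration."""

    trajectories: list[Trajectory]
    duration: float
    culture_mode: str
    params_hash: str

    @property
    def n_cells(self) -> int:
        return len(self.trajectories)

    def pooled_counts(self, gene: str) -> np.ndarray:
        """All post-burn-in snapshots of one gene, pooled over cells."""
        return np.concatenate([t.gene_counts(gene) for t in self.trajectories])

    def counts_at(self, gene: str, time_s: float) -> np.ndarray:
        """One sample per cell at the snapshot closest to ``time_s``."""
        out = np.empty(self.n_cells, dtype=np.int64)
        for i, t in enumerate(self.trajectories):
            k = int(np.argmin(np.abs(t.times - time_s)))
            out[i] = t.gene_counts(gene)[k]
        return out


def initial_state(
    network: RegulatoryNetwork, params: ParameterSet
) -> CellStateVector:
    """The pluripotent initial condition (SON on, lineage genes silent)."""
    return pluripotent_state(network, params)


# ---------------------------------------------------------------------------
# pure-Python reference step
# ---------------------------------------------------------------------------

def list_channels(
    state: CellStateVector, network: RegulatoryNetwork, params: ParameterSet
):
    """Active reaction channels as (description, propensity, apply) triples.

    Channels with zero propensity are omitted.  Used by the reference
    stepper and by tests; the compiled kernel implements the same set.
    """
    chans = []

    def add(desc, a, apply):
        if a > 0.0:
            chans.append((desc, a, apply))

    for spec in network.genes:
        g = spec.name

        def deg(s, g=g):
            s.counts[g] -= 1

        add(("degrade", g), kinetics.degradation_propensity(g, state.counts, params), deg)
        for ai, locus in enumerate(state.loci[g]):
            sites = spec.sites()
            # synthesis is applied by the stepper itself (needs the rng
            # for the Poisson burst draw), marked with a sentinel
            a_syn = kinetics.synthesis_propensity(locus, spec, params)
            add(("synthesize", g, ai), a_syn, ("burst", g))
            for si, site in enumerate(sites):
                if locus.bound[si]:
                    def unb(s, g=g, ai=ai, si=si):
                        ls = s.loci[g][ai]
                        b = list(ls.bound)
                        b[si] = 0
                        ls.bound = tuple(b)

                    add(("unbind", g, ai, si), kinetics.unbinding_propensity(site, params), unb)
                else:
                    def bnd(s, g=g, ai=ai, si=si):
                        ls = s.loci[g][ai]
                        b = list(ls.bound)
                        b[si] = 1
                        ls.bound = tuple(b)

                    add(("bind", g, ai, si), kinetics.binding_propensity(site, state.counts, params), bnd)

            def set_ta(v, g=g, ai=ai):
                def f(s):
                    s.loci[g][ai].ta = v
                return f

            def set_h(v, g=g, ai=ai):
                def f(s):
                    s.loci[g][ai].histone = v
                return f

            add(("ta1", g, ai), kinetics.ta_step1_propensity(locus, spec, params), set_ta(0.5))
            add(("ta2", g, ai), kinetics.ta_step2_propensity(locus, spec, params), set_ta(1.0))
            add(("tadiss", g, ai), kinetics.ta_dissolution_propensity(locus, spec, params), set_ta(0.0))
            add(("hist_on", g, ai), kinetics.histone_on_propensity(locus, spec, params), set_h(1))
            add(("hist_off", g, ai), kinetics.histone_off_propensity(locus, spec, params), set_h(0))
    return chans


def gillespie_step(
    state: CellStateVector,
    network: RegulatoryNetwork,
    params: ParameterSet,
    rng: np.random.Generator,
):
    """One exact SSA step on the domain objects.

    Returns ``(state, dt)`` with the state advanced in place; raises
    ``RuntimeError`` when no channel is active (absorbing state), in which
    case the caller advances time to its horizon.
    """
    chans = list_channels(state, network, params)
    if not chans:
        raise RuntimeError("absorbing state: total propensity is zero")
    props = np.array([a for _, a, _ in chans])
    A = props.sum()
    dt = rng.exponential(1.0 / A)
    idx = rng.choice(len(chans), p=props / A)
    _, _, apply = chans[idx]
    if isinstance(apply, tuple) and apply[0] == "burst":
        state.counts[apply[1]] += int(rng.poisson(params.b_mean))
    else:
        apply(state)
    state.t += dt
    return state, dt


# ---------------------------------------------------------------------------
# compiled path
# ---------------------------------------------------------------------------

def _cell_seeds(base_seed: int, cell_index: int) -> tuple[int, int]:
    """Burn-in and main-phase kernel seeds for one cell.

    Streams are split with ``np.random.SeedSequence([base_seed, cell])`` so
    ensembles are reproducible cell by cell.
    """
    ss = np.random.SeedSequence([int(base_seed), int(cell_index)])
    a, b = ss.generate_state(2)
    return int(a % (2**31)), int(b % (2**31))


def _kernel_args(layout: ModelLayout, rates: dict):
    sox2 = layout.gene_names.index("Sox2") if "Sox2" in layout.gene_names else -1
    oct4 = layout.gene_names.index("Oct4") if "Oct4" in layout.gene_names else -1
    return (
        layout.locus_gene, layout.locus_site0, layout.locus_nsites,
        layout.site_locus, layout.site_tf, layout.site_dimer, layout.site_role,
        layout.complex_rule, layout.simplified,
        layout.tf_sites_flat, layout.tf_sites_start,
        rates["g_syn"], rates["inv_gamma"], rates["b_mean"], rates["k_deg"],
        rates["h0"], rates["f_unbind"], rates["K_dimer"],
        rates["kf1"], rates["kf1b"], rates["kf1r"], rates["kf2"],
        rates["kdis"], rates["ron"], rates["ronb"], rates["roff"],
        layout.nanog_index, sox2, oct4,
    )


def run_trajectory(
    network: RegulatoryNetwork,
    params: ParameterSet,
    duration: float,
    burn_in: float = 10 * DAY,
    seed: int = 0,
    record_dt: float = 1000.0,
    initial: CellStateVector | None = None,
    _cell_index: int = 0,
) -> Trajectory:
    """Simulate one cell and record snapshots every ``record_dt`` seconds.

    The burn-in is always run with the ESC-condition histone rates so the
    recorded window starts from the self-renewing steady state; the recorded
    window itself uses ``params.culture_mode``.  Bit-identical for a given
    seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if burn_in < 0 or record_dt <= 0:
        raise ValueError("burn_in must be >= 0 and record_dt > 0")
    layout = _layout_for(network)
    counts, bound, ta, hist = state_to_arrays(
        initial if initial is not None else pluripotent_state(network, params),
        layout,
    )
    seed_burn, seed_main = _cell_seeds(seed, _cell_index)
    L = layout.n_loci
    empty = np.empty(0, dtype=np.float64)
    e_i = np.empty((0, layout.n_genes), dtype=np.int64)
    e_b = np.empty((0, L), dtype=np.int8)
    e_m = np.empty((0, L), dtype=np.uint8)
    if burn_in > 0:
        burn_rates = rate_arrays(network, params, force_esc=True)
        run_ssa(
            counts, bound, ta, hist, 0.0, burn_in,
            empty, e_i, e_b, e_b, e_m, 0,
            *_kernel_args(layout, burn_rates), seed_burn,
        )
    rec_t = np.arange(0.0, duration + 0.5 * record_dt, record_dt)
    rec_t = rec_t[rec_t <= duration]
    T = len(rec_t)
    rec_counts = np.zeros((T, layout.n_genes), dtype=np.int64)
    rec_ta = np.zeros((T, L), dtype=np.int8)
    rec_hist = np.zeros((T, L), dtype=np.int8)
    rec_bound = np.zeros((T, L), dtype=np.uint8)
    rates = rate_arrays(network, params)
    run_ssa(
        counts, bound, ta, hist, 0.0, duration,
        rec_t, rec_counts, rec_ta, rec_hist, rec_bound, 0,
        *_kernel_args(layout, rates), seed_main,
    )
    return Trajectory(
        times=rec_t,
        counts=rec_counts,
        ta=rec_ta,
        hist=rec_hist,
        bound_mask=rec_bound,
        gene_names=layout.gene_names,
        seed=seed,
        params_hash=_params_hash(network, params),
        layout=layout,
    )


def run_ensemble(
    network: RegulatoryNetwork,
    params: ParameterSet,
    n_cells: int,
    duration: float,
    base_seed: int = 0,
    burn_in: float = 10 * DAY,
    record_dt: float = 1000.0,
    initial: CellStateVector | None = None,
) -> Ensemble:
    """``n_cells`` independent trajectories, seeds split from ``base_seed``."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    trajs = [
        run_trajectory(
            network, params, duration,
            burn_in=burn_in, seed=base_seed, record_dt=record_dt,
            initial=initial, _cell_index=i,
        )
        for i in range(n_cells)
    ]
    return Ensemble(
        trajectories=trajs,
        duration=duration,
        culture_mode=params.culture_mode,
        params_hash=trajs[0].params_hash,
    )


def _low_nanog_state(network, params) -> CellStateVector:
    """Pluripotent state pushed into the low-Nanog branch (TA unformed)."""
    st = pluripotent_state(network, params)
    spec = network["Nanog"]
    sites = spec.sites()
    low = int(round(params.synth_rate("Nanog") * params.b_mean
                    / (params.k_deg * params.gamma_synth)))
    st.counts["Nanog"] = low
    for ls in st.loci["Nanog"]:
        ls.ta = 0.0
        bound = list(ls.bound)
        for i, s in enumerate(sites):
            if s.is_dimer:
                bound[i] = 0
        ls.bound = tuple(bound)
    return st


def relaxation_experiment(
    network: RegulatoryNetwork,
    params: ParameterSet,
    n_cells: int,
    start_state: str = "HN",
    times=(0.0, 1 * DAY, 5 * DAY),
    base_seed: int = 0,
    record_dt: float = 1000.0,
):
    """Relaxation of a sorted sub-population back to the full distribution.

    Starts every cell either in the high-Nanog (``"HN"``: complete TA,
    steady-level copies) or low-Nanog (``"LN"``: unformed TA, partial-TA
    copy level) branch, simulates the ESC condition with no burn-in, and
    returns ``{time_s: ExpressionHistogram}`` for Nanog at the requested
    times.
    """
    from .scoring import histogram_from_samples

    if start_state not in ("HN", "LN"):
        raise ValueError("start_state must be 'HN' or 'LN'")
    init = (
        pluripotent_state(network, params)
        if start_state == "HN"
        else _low_nanog_state(network, params)
    )
    horizon = max(times)
    ens = run_ensemble(
        network, params, n_cells, max(horizon, record_dt),
        base_seed=base_seed, burn_in=0.0, record_dt=record_dt, initial=init,
    )
    return {
        t: histogram_from_samples(ens.counts_at("Nanog", t), gene="Nanog")
        for t in times
    }
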