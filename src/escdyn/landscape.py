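"""Epigenetic landscape and non-equilibrium curl fluxes.

The transition rates of a coarse-grained diagram are fitted to the
transition-state form W_ij = k0 * exp(-(F_dagger_ij - F_i)), with F a
dimensionless free-energy-like depth per state and F_dagger a saddle height
per undirected link.  On a diagram with loops the fit is inconsistent along
each loop unless a curl flux J_a (one signed unknown per independent loop)
is added, giving one equation per observed directed link:

    exp(-F_i) * W_ij / k0  =  exp(-F_dagger_ij)  +  sum_a sigma_a(i->j) J_a

with sigma the orientation sign of the loop through that link.  One F is
gauge-fixed to zero; links whose reverse transition was never observed have
their saddle pinned at F_dagger = F_j + F_max (a barrier high enough to
suppress the reverse move on the simulated timescale), which keeps the
system square.  A detailed-balance diagram yields all J = 0 and
F = -ln(stationary probability) up to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EquationSystem",
    "LandscapeSolution",
    "Projection2D",
    "LandscapeError",
    "find_loops",
    "equation_system",
    "solve_landscape",
    "project_states",
    "DEFAULT_AXIS_WEIGHTS",
]


class LandscapeError(RuntimeError):
    """Raised on non-convergence; carries the best iterate and residual."""

    def __init__(self, msg, solution=None):
        super().__init__(msg)
        self.solution = solution


def _rates_from_diagram(diagram) -> dict[tuple, float]:
    """{(i, j): W_ij} from a TransitionDiagram or a plain mapping."""
    if hasattr(diagram, "edges") and isinstance(diagram.edges, pd.DataFrame):
        return {
            (r["from"], r["to"]): float(r["rate_per_day"])
            for _, r in diagram.edges.iterrows()
            if r["from"] != r["to"]  # self-returns carry no landscape info
        }
    return {k: float(v) for k, v in dict(diagram).items() if k[0] != k[1]}


def find_loops(diagram) -> list[list]:
    """Independent cycle basis of the undirected support graph.

    The basis size is E - N + C (edges minus nodes plus connected
    components); a tree-like diagram has none.
    """
    W = _rates_from_diagram(diagram)
    G = nx.Graph()
    for (i, j) in W:
        G.add_edge(i, j)
    loops = []
    for comp in nx.connected_components(G):
        loops.extend(nx.cycle_basis(G.subgraph(comp)))
    return loops


@dataclass
class EquationSystem:
    """Bookkeeping of the landscape fit before solving."""

    states: list
    undirected_edges: list[tuple]
    one_way_edges: list[tuple]  # (observed_from, observed_to)
    loops: list[list]
    n_variables: int  # F per state + F_dagger per two-way edge + J per loop
    n_equations: int  # one per observed directed edge
    W: dict[tuple, float] = field(repr=False, default_factory=dict)

    @property
    def n_unknowns_after_gauge(self) -> int:
        return self.n_variables - 1


def equation_system(diagram) -> EquationSystem:
    """Enumerate variables and equations of the transition-state fit.

    Variables are the state depths F, one saddle height per reversible
    undirected link, and one curl flux per independent loop; one-way links
    contribute an equation but their saddle is pinned (not a variable).
    After gauge-fixing one F the system is square exactly when the loop
    count is E - N + C.
    """
    W = _rates_from_diagram(diagram)
    und = sorted({frozenset(e) for e in W}, key=lambda s: sorted(map(str, s)))
    und = [tuple(sorted(e, key=str)) for e in und]
    one_way = [
        (i, j) for (i, j) in W if (j, i) not in W
    ]
    loops = find_loops(diagram)
    states = sorted({s for e in W for s in e}, key=str)
    two_way = len(und) - len(one_way)
    return EquationSystem(
        states=states,
        undirected_edges=und,
        one_way_edges=one_way,
        loops=loops,
        n_variables=len(states) + two_way + len(loops),
        n_equations=len(W),
        W=W,
    )


@dataclass
class LandscapeSolution:
    F: dict  # state -> depth (gauge state at 0)
    F_sharp: dict  # frozenset({i, j}) -> saddle height
    J: list[float]  # one per loop, order of `loops`
    loops: list[list]
    gauge_state: object
    k0: float
    F_max: float
    capped_edges: list[tuple]
    residual_norm: float
    n_variables: int
    n_equations: int

    def edge_flux(self, i, j) -> float:
        """Net curl flux carried by the directed link i -> j
        (sum of loop fluxes signed by orientation)."""
        return float(
            sum(
                sig * J
                for loop, J in zip(self.loops, self.J)
                if (sig := _loop_sign(loop, i, j))
            )
        )

    def to_frames(
        self, flux_thresholds: tuple[float, float] = (0.01, 0.1)
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node and edge tables; edges carry the flux magnitude class
        (thin / middle / thick) cut at ``flux_thresholds``."""
        nodes = pd.DataFrame(
            {"state": list(self.F), "F": list(self.F.values())}
        ).set_index("state")
        lo, hi = flux_thresholds
        rows = []
        for e, v in self.F_sharp.items():
            i, j = sorted(e, key=str)
            flux = self.edge_flux(i, j)
            mag = abs(flux)
            cls = "thin" if mag < lo else ("middle" if mag < hi else "thick")
            rows.append(
                {"i": i, "j": j, "F_sharp": v, "flux": flux, "flux_class": cls}
            )
        return nodes, pd.DataFrame(rows)


def _loop_sign(loop, i, j) -> int:
    k = len(loop)
    for a in range(k):
        u, v = loop[a], loop[(a + 1) % k]
        if (u, v) == (i, j):
            return 1
        if (u, v) == (j, i):
            return -1
    return 0


def solve_landscape(
    diagram,
    k0: float | None = None,
    F_max: float | None = None,
    gauge_state=None,
    tol: float = 1e-10,
    max_iter: int = 500,
    damping: float = 0.5,
) -> LandscapeSolution:
    """Fit state depths, saddle heights and loop curl fluxes to the rates.

    ``k0`` is the attempt-frequency scale; the default (the largest observed
    rate) makes every saddle at least as high as its states.  Solved by
    damped Newton iteration on the square system described in the module
    docstring, with a least-squares fallback for non-square components.
    """
    sys_ = equation_system(diagram)
    W = sys_.W
    if not W:
        raise ValueError("diagram has no transitions between distinct states")
    if any(w <= 0 for w in W.values()):
        raise ValueError("all retained rates must be positive")
    k0 = float(k0 if k0 is not None else max(W.values()))
    states = sys_.states
    if gauge_state is None:
        if hasattr(diagram, "states") and isinstance(diagram.states, pd.DataFrame):
            gauge_state = diagram.states["occupancy"].idxmax()
        else:
            gauge_state = states[0]
    one_way = set(sys_.one_way_edges)
    one_way_und = {frozenset(e) for e in one_way}
    two_way_edges = [e for e in sys_.undirected_edges if frozenset(e) not in one_way_und]
    loops = sys_.loops

    # variable indexing
    f_idx = {s: k for k, s in enumerate(s for s in states if s != gauge_state)}
    nF = len(f_idx)
    e_idx = {frozenset(e): nF + k for k, e in enumerate(two_way_edges)}
    nE = len(two_way_edges)
    j_idx0 = nF + nE
    nvar = nF + nE + len(loops)
    directed = sorted(W, key=str)

    # spanning-tree initial guess for F
    G = nx.Graph(frozenset(e) for e in W)
    F0 = {gauge_state: 0.0}
    for parent, child in nx.bfs_edges(G, gauge_state):
        wf = W.get((parent, child))
        wr = W.get((child, parent))
        if wf and wr:
            F0[child] = F0[parent] + np.log(wf / wr)
        elif wf:
            F0[child] = F0[parent] - 1.0
        else:
            F0[child] = F0[parent] + 1.0
    Fs0 = {}
    for (i, j) in two_way_edges:
        a = F0[i] + np.log(k0 / W[(i, j)]) if (i, j) in W else np.inf
        b = F0[j] + np.log(k0 / W[(j, i)]) if (j, i) in W else np.inf
        Fs0[frozenset((i, j))] = min(a, b) if np.isinf(max(a, b)) else 0.5 * (a + b)
    if F_max is None:
        barriers = [
            v - min(F0[i], F0[j])
            for (i, j) in two_way_edges
            for v in [Fs0[frozenset((i, j))]]
        ]
        F_max = (max(barriers) if barriers else np.log(k0 / min(W.values()))) + 2.0

    # sigma table per directed edge
    sig = np.zeros((len(directed), len(loops)))
    for r, (i, j) in enumerate(directed):
        for a, loop in enumerate(loops):
            sig[r, a] = _loop_sign(loop, i, j)

    x = np.zeros(nvar)
    for s, k in f_idx.items():
        x[k] = F0[s]
    for e, k in e_idx.items():
        x[e_idx[e]] = Fs0[e]

    def unpack(x):
        F = {gauge_state: 0.0}
        for s, k in f_idx.items():
            F[s] = x[k]
        Fs = {}
        for e in two_way_edges:
            Fs[frozenset(e)] = x[e_idx[frozenset(e)]]
        for (i, j) in one_way:
            Fs[frozenset((i, j))] = F[j] + F_max
        J = x[j_idx0:]
        return F, Fs, J

    def residual_and_jac(x):
        F, Fs, J = unpack(x)
        r = np.zeros(len(directed))
        Jac = np.zeros((len(directed), nvar))
        for row, (i, j) in enumerate(directed):
            e = frozenset((i, j))
            lhs = np.exp(-F[i]) * W[(i, j)] / k0
            bar = np.exp(-Fs[e])
            r[row] = lhs - bar - float(sig[row] @ J)
            if i in f_idx:
                Jac[row, f_idx[i]] = -lhs
            if e in e_idx:
                Jac[row, e_idx[e]] = bar
            elif j in f_idx:
                # pinned saddle F_j + F_max follows the destination depth
                Jac[row, f_idx[j]] += bar
            Jac[row, j_idx0:] = -sig[row]
        return r, Jac

    square = len(directed) == nvar
    best = None
    for it in range(max_iter):
        r, Jac = residual_and_jac(x)
        nrm = float(np.max(np.abs(r))) if len(r) else 0.0
        if best is None or nrm < best[0]:
            best = (nrm, x.copy())
        if nrm < tol:
            break
        if square:
            try:
                dx = np.linalg.solve(Jac, -r)
            except np.linalg.LinAlgError:
                dx = np.linalg.lstsq(Jac, -r, rcond=None)[0]
        else:
            dx = np.linalg.lstsq(Jac, -r, rcond=None)[0]
        step = np.linalg.norm(dx)
        if step > 10.0:  # keep exp() in range early on
            dx *= 10.0 / step
        x = x + damping * dx
    else:
        nrm, x = best
        if square and nrm >= tol:
            F, Fs, J = unpack(x)
            sol = _make_solution(
                F, Fs, J, loops, gauge_state, k0, F_max, one_way, nrm,
                sys_.n_variables, sys_.n_equations,
            )
            raise LandscapeError(
                f"landscape solve did not converge (residual {nrm:.3g})", sol
            )
    r, _ = residual_and_jac(x)
    nrm = float(np.max(np.abs(r))) if len(r) else 0.0
    F, Fs, J = unpack(x)
    return _make_solution(
        F, Fs, J, loops, gauge_state, k0, F_max, one_way, nrm,
        sys_.n_variables, sys_.n_equations,
    )


def _make_solution(F, Fs, J, loops, gauge, k0, F_max, one_way, nrm, nvar, neq):
    return LandscapeSolution(
        F=F,
        F_sharp=Fs,
        J=[float(j) for j in J],
        loops=loops,
        gauge_state=gauge,
        k0=k0,
        F_max=F_max,
        capped_edges=sorted(one_way, key=str),
        residual_norm=nrm,
        n_variables=nvar,
        n_equations=neq,
    )


#: default composition of the lineage-closeness axes from band weights
DEFAULT_AXIS_WEIGHTS = {
    "q_TE": {"Cdx2": 1.0, "Gcnf": 0.5},
    "q_PE": {"Gata6": 1.0, "Gcnf": 0.5},
}


@dataclass
class Projection2D:
    coords: pd.DataFrame  # index: state key; columns q_TE, q_PE

    def __getitem__(self, state):
        row = self.coords.loc[[state]]
        return float(row["q_TE"].iloc[0]), float(row["q_PE"].iloc[0])


def project_states(
    state_keys, scheme, axis_weights: dict | None = None
) -> Projection2D:
    """Project cell states onto the (trophectoderm, primitive endoderm) plane.

    Each coordinate is a linear combination of the per-gene band lambda
    weights; the defaults place the ESC states near the origin and pull
    Cdx2- and Gata6-dominant states along their own axes, with Gcnf
    contributing half weight to both.
    """
    weights = axis_weights or DEFAULT_AXIS_WEIGHTS
    order = scheme.gene_order()
    rows = []
    for key in state_keys:
        lam = {
            g: scheme.bands[g].lambdas[key[k]] for k, g in enumerate(order)
        }
        rows.append(
            {
                ax: sum(c * lam.get(g, 0.0) for g, c in comp.items())
                for ax, comp in weights.items()
            }
        )
    coords = pd.DataFrame(
        rows, index=pd.Index(list(state_keys), tupleize_cols=False, name="state")
    )
    return Projection2D(coords)
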