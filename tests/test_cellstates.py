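"""Discretization, dwell segments, occupancies, transition diagrams."""

import numpy as np
import pytest

from escdyn.cellstates import (
    GeneBands,
    build_diagram,
    default_scheme,
    discretize,
    dwell_segments,
    occupancy_table,
)


class _StubLayout:
    def __init__(self, gene_names, locus_gene):
        self.gene_names = tuple(gene_names)
        self.locus_gene = np.asarray(locus_gene)
        self.locus_allele = np.zeros(len(locus_gene), dtype=int)
        self.n_loci = len(locus_gene)


class _StubTraj:
    """A fake trajectory built directly from count/histone arrays."""

    def __init__(self, times, counts, gene_names, hist=None):
        self.times = np.asarray(times, dtype=float)
        self.counts = np.asarray(counts)
        self.gene_names = tuple(gene_names)
        L = len(gene_names)
        self.hist = (
            np.asarray(hist)
            if hist is not None
            else np.zeros((len(times), L), dtype=np.int8)
        )
        self.layout = _StubLayout(gene_names, list(range(L)))

    def gene_counts(self, gene):
        return self.counts[:, self.gene_names.index(gene)]


class _StubEnsemble:
    def __init__(self, trajs):
        self.trajectories = trajs

    @property
    def n_cells(self):
        return len(self.trajectories)


GENES6 = ("Sox2", "Oct4", "Nanog", "Cdx2", "Gata6", "Gcnf")


def _snap(sox2=0, oct4=0, nanog=0, cdx2=0, gata6=0, gcnf=0):
    return dict(Sox2=sox2, Oct4=oct4, Nanog=nanog, Cdx2=cdx2, Gata6=gata6, Gcnf=gcnf)


class TestDiscretize:
    def test_all_zero_counts_lowest_bands(self):
        lab = discretize(_snap(), {}, default_scheme())
        assert lab.bands == (0, 0, 0, 0, 0, 0)
        assert lab.name == "null"

    def test_high_nanog_lands_in_top_band(self):
        lab = discretize(_snap(nanog=5000), {}, default_scheme())
        assert lab.bands[2] == 3
        assert "HN" in lab.name

    def test_boundary_count_goes_up(self):
        # half-open bands [lower, upper): exactly 400 joins the third band
        lab = discretize(_snap(nanog=400), {}, default_scheme())
        assert lab.bands[2] == 2
        lab399 = discretize(_snap(nanog=399), {}, default_scheme())
        assert lab399.bands[2] == 1

    def test_esc_state_name(self):
        lab = discretize(
            _snap(sox2=400, oct4=400, nanog=5000), {"Nanog": 1}, default_scheme()
        )
        assert lab.name == "S-O-HN"

    def test_histone_codes_distinguish_states(self):
        s = default_scheme()
        a = discretize(_snap(nanog=100), {"Nanog": 1}, s)
        b = discretize(_snap(nanog=100), {"Nanog": 0}, s)
        assert a.bands == b.bands and a.histones != b.histones

    def test_bad_band_definitions_rejected(self):
        with pytest.raises(ValueError):
            GeneBands((10, 10), ("", "a", "b"), (0, 1, 2))
        with pytest.raises(ValueError):
            GeneBands((10,), ("", "a"), (2, 1))


class TestDwellSegments:
    def _traj(self, nanog_values, dt=100.0):
        T = len(nanog_values)
        counts = np.zeros((T, 6), dtype=int)
        counts[:, 2] = nanog_values
        return _StubTraj(np.arange(T) * dt, counts, GENES6)

    def test_constant_trajectory_single_segment(self):
        segs = dwell_segments(self._traj([50] * 10), default_scheme())
        assert len(segs) == 1
        key, t0, t1 = segs[0]
        assert (t0, t1) == (0.0, 1000.0)

    def test_alternating_labels_three_segments(self):
        segs = dwell_segments(self._traj([50, 5000, 50]), default_scheme())
        assert len(segs) == 3

    def test_durations_sum_to_total(self):
        vals = [50, 50, 5000, 500, 500, 500, 50, 5000]
        segs = dwell_segments(self._traj(vals), default_scheme())
        total = sum(t1 - t0 for _, t0, t1 in segs)
        assert total == pytest.approx(len(vals) * 100.0)


class TestOccupancy:
    def test_single_state_ensemble(self):
        ens = _StubEnsemble(
            [_StubTraj([0, 1, 2], np.zeros((3, 6), dtype=int), GENES6)]
        )
        occ = occupancy_table(ens, default_scheme())
        assert len(occ) == 1 and occ.iloc[0] == pytest.approx(1.0)

    def test_two_cells_half_half_and_sums_to_one(self):
        a = np.zeros((4, 6), dtype=int)
        b = np.zeros((4, 6), dtype=int)
        b[:, 2] = 5000
        ens = _StubEnsemble(
            [_StubTraj(range(4), a, GENES6), _StubTraj(range(4), b, GENES6)]
        )
        occ = occupancy_table(ens, default_scheme())
        assert occ.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(occ.values, [0.5, 0.5])


def _two_state_paths(rng, k_ab, k_ba, n_paths, horizon, dt):
    """Sampled telegraph trajectories (Nanog 50 <-> 5000) with known rates."""
    trajs = []
    times = np.arange(0.0, horizon, dt)
    for _ in range(n_paths):
        state = rng.integers(0, 2)
        t, switch_times, states = 0.0, [], []
        while t < horizon:
            rate = k_ab if state == 0 else k_ba
            stay = rng.exponential(1.0 / rate)
            switch_times.append(t + stay)
            states.append(state)
            t += stay
            state = 1 - state
        # sample on the grid
        vals = np.empty(len(times), dtype=int)
        idx = 0
        for i, tt in enumerate(times):
            while switch_times[idx] <= tt:
                idx += 1
            vals[i] = 50 if states[idx] == 0 else 5000
        counts = np.zeros((len(times), 6), dtype=int)
        counts[:, 2] = vals
        trajs.append(_StubTraj(times, counts, GENES6))
    return _StubEnsemble(trajs)


class TestDiagram:
    def test_telegraph_rates_recovered(self, rng):
        k_ab, k_ba = 2e-4, 1e-4  # 1/s
        ens = _two_state_paths(rng, k_ab, k_ba, n_paths=60, horizon=2e5, dt=200.0)
        dia = build_diagram(
            ens, default_scheme(), occ_threshold=0.0, link_count_threshold=0
        )
        lo = next(k for k in dia.state_keys if k[2] == 1)
        hi = next(k for k in dia.state_keys if k[2] == 3)
        w_ab = dia.rate(lo, hi) / 86_400.0
        w_ba = dia.rate(hi, lo) / 86_400.0
        # ~1200 transitions per direction: 3 sigma is ~9% relative
        assert w_ab == pytest.approx(k_ab, rel=0.1)
        assert w_ba == pytest.approx(k_ba, rel=0.1)

    def test_occupancy_threshold_zero_keeps_all(self, rng):
        ens = _two_state_paths(rng, 2e-4, 1e-4, 10, 5e4, 200.0)
        dia = build_diagram(ens, default_scheme(), 0.0, 0)
        assert len(dia.states) == 2

    def test_raising_link_threshold_only_removes_edges(self, rng):
        ens = _two_state_paths(rng, 2e-4, 1e-4, 20, 1e5, 200.0)
        d1 = build_diagram(ens, default_scheme(), 0.0, 0)
        d2 = build_diagram(ens, default_scheme(), 0.0, 100)
        e1 = {(r["from"], r["to"]) for _, r in d1.edges.iterrows()}
        e2 = {(r["from"], r["to"]) for _, r in d2.edges.iterrows()}
        assert e2 <= e1

    def test_empty_diagram_raises_with_diagnostic(self, rng):
        ens = _two_state_paths(rng, 2e-4, 1e-4, 4, 2e4, 200.0)
        with pytest.raises(ValueError, match="link threshold"):
            build_diagram(ens, default_scheme(), 0.0, 10**6)

    def test_dropped_states_become_self_returns(self):
        # A -> rare -> A must appear as a self-edge on A
        vals = [50] * 40 + [500] + [50] * 40
        counts = np.zeros((81, 6), dtype=int)
        counts[:, 2] = vals
        trajs = [_StubTraj(np.arange(81) * 100.0, counts, GENES6)] * 5
        dia = build_diagram(
            _StubEnsemble(trajs), default_scheme(),
            occ_threshold=0.5, link_count_threshold=0,
        )
        assert len(dia.states) == 1
        (a,) = dia.state_keys
        assert dia.rate(a, a) > 0


def test_markov_chain_rate_recovery_converges(rng):
    """On a 3-state chain with known generator the dwell-based estimator
    recovers every retained rate within 20% at n = 500 paths."""
    Q = {
        (0, 1): 3e-4, (1, 0): 1.5e-4,
        (1, 2): 2e-4, (2, 1): 2.5e-4,
        (0, 2): 1e-4, (2, 0): 1e-4,
    }
    levels = {0: 20, 1: 200, 2: 5000}  # Nanog bands 0, 1, 3
    times = np.arange(0.0, 4e4, 100.0)
    trajs = []
    for _ in range(500):
        s = int(rng.integers(0, 3))
        t = 0.0
        sw, states = [], []
        while t < times[-1] + 100.0:
            out = {j: q for (i, j), q in Q.items() if i == s}
            tot = sum(out.values())
            stay = rng.exponential(1.0 / tot)
            sw.append(t + stay)
            states.append(s)
            t += stay
            r = rng.random() * tot
            acc = 0.0
            for j, q in out.items():
                acc += q
                if r < acc:
                    s = j
                    break
        vals = np.empty(len(times), dtype=int)
        idx = 0
        for i, tt in enumerate(times):
            while sw[idx] <= tt:
                idx += 1
            vals[i] = levels[states[idx]]
        counts = np.zeros((len(times), 6), dtype=int)
        counts[:, 2] = vals
        trajs.append(_StubTraj(times, counts, GENES6))
    dia = build_diagram(
        _StubEnsemble(trajs), default_scheme(), occ_threshold=0.0,
        link_count_threshold=0,
    )
    key = {0: None, 1: None, 2: None}
    for k in dia.state_keys:
        band = k[2]
        key[{0: 0, 1: 1, 3: 2}[band]] = k
    for (i, j), q in Q.items():
        w = dia.rate(key[i], key[j]) / 86_400.0
        assert w == pytest.approx(q, rel=0.2), f"rate {i}->{j}"
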