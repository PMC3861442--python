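"""Flat-array model layout and the numba SSA kernel.

The Gillespie direct method is exact but event counts reach ~1e6 per
simulated cell-day, so the inner loop is compiled with numba.  The kernel
keeps one propensity per reaction channel and after each event recomputes
only the channels whose inputs changed (counts -> degradation and the bind
channels of that TF; a site flip -> that site and its locus's TA/histone
channels; a TA or histone move -> the affected locus channels).  Channel
selection is two-level: first over category sums, then within the category
slice.  Running floating-point sums are refreshed from scratch every 2^14
events to cancel drift.

Channel order: degradation (per gene) | synthesis (per locus) | bind (per
site) | unbind (per site) | TA step1 | TA step2 | TA dissolution | histone on
| histone off (each per locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import ParameterSet, RegulatoryNetwork


__all__ = ["ModelLayout", "build_layout", "rate_arrays", "run_ssa"]


@dataclass
class ModelLayout:
    """Static structure of a compiled network (no rates)."""

    gene_names: tuple[str, ...]
    nanog_index: int  # -1 when the network has no Nanog
    locus_gene: np.ndarray  # int32[L]
    locus_allele: np.ndarray  # int32[L]
    locus_site0: np.ndarray  # int32[L]
    locus_nsites: np.ndarray  # int32[L]
    site_locus: np.ndarray  # int32[S]
    site_tf: np.ndarray  # int32[S] gene index of binding TF
    site_dimer: np.ndarray  # int8[S]
    site_role: np.ndarray  # int8[S] 0 act / 1 rep / 2 secondary
    complex_rule: np.ndarray  # int8[G]
    simplified: np.ndarray  # int8[G] (no repressor sites)
    tf_sites_flat: np.ndarray  # int32, site indices grouped by TF gene
    tf_sites_start: np.ndarray  # int32[G+1]

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_loci(self) -> int:
        return len(self.locus_gene)

    @property
    def n_sites(self) -> int:
        return len(self.site_locus)

    def channel_offsets(self) -> tuple[int, ...]:
        """Start offsets of the nine channel categories plus the total."""
        G, L, S = self.n_genes, self.n_loci, self.n_sites
        off = [0, G, G + L, G + L + S, G + L + 2 * S]
        for _ in range(5):
            off.append(off[-1] + L)
        return tuple(off)


def build_layout(network: RegulatoryNetwork) -> ModelLayout:
    names = network.gene_names
    gidx = {g: i for i, g in enumerate(names)}
    locus_gene, locus_allele, locus_site0, locus_nsites = [], [], [], []
    s_locus, s_tf, s_dimer, s_role = [], [], [], []
    for spec in network.genes:
        sites = spec.sites()
        for a in range(spec.n_alleles):
            li = len(locus_gene)
            locus_gene.append(gidx[spec.name])
            locus_allele.append(a)
            locus_site0.append(len(s_locus))
            locus_nsites.append(len(sites))
            for s in sites:
                s_locus.append(li)
                s_tf.append(gidx[s.tf_gene])
                s_dimer.append(1 if s.is_dimer else 0)
                s_role.append(s.role)
    s_tf_arr = np.asarray(s_tf, dtype=np.int32)
    tf_flat, tf_start = [], [0]
    for g in range(len(names)):
        idx = np.nonzero(s_tf_arr == g)[0]
        tf_flat.extend(int(i) for i in idx)
        tf_start.append(len(tf_flat))
    return ModelLayout(
        gene_names=names,
        nanog_index=gidx.get("Nanog", -1),
        locus_gene=np.asarray(locus_gene, dtype=np.int32),
        locus_allele=np.asarray(locus_allele, dtype=np.int32),
        locus_site0=np.asarray(locus_site0, dtype=np.int32),
        locus_nsites=np.asarray(locus_nsites, dtype=np.int32),
        site_locus=np.asarray(s_locus, dtype=np.int32),
        site_tf=s_tf_arr,
        site_dimer=np.asarray(s_dimer, dtype=np.int8),
        site_role=np.asarray(s_role, dtype=np.int8),
        complex_rule=np.asarray(
            [1 if g.histone_complex_rule else 0 for g in network.genes],
            dtype=np.int8,
        ),
        simplified=np.asarray(
            [1 if g.simplified_rules else 0 for g in network.genes],
            dtype=np.int8,
        ),
        tf_sites_flat=np.asarray(tf_flat, dtype=np.int32),
        tf_sites_start=np.asarray(tf_start, dtype=np.int32),
    )


def rate_arrays(
    network: RegulatoryNetwork, params: ParameterSet, force_esc: bool = False
) -> dict[str, np.ndarray | float]:
    """Per-gene rate vectors with overrides and culture mode resolved.

    ``force_esc`` applies the ESC histone silencing of lineage genes
    regardless of ``params.culture_mode`` (used for the burn-in phase).
    """
    p = params.replace(culture_mode="esc") if force_esc else params
    names = network.gene_names

    def vec(name):
        return np.asarray(
            [params.for_gene(g, name) for g in names], dtype=np.float64
        )

    return {
        "g_syn": np.asarray(
            [params.synth_rate(g) for g in names], dtype=np.float64
        ),
        "inv_gamma": 1.0 / params.gamma_synth,
        "b_mean": params.b_mean,
        "k_deg": params.k_deg,
        "h0": params.h0_bind,
        "f_unbind": params.f_unbind,
        "K_dimer": params.K_dimer,
        "kf1": vec("k_ta_form1"),
        "kf1b": vec("k_ta_form1_basal"),
        "kf1r": vec("k_ta_form1_rep"),
        "kf2": vec("k_ta_form2"),
        "kdis": vec("k_ta_diss"),
        "ron": np.asarray(
            [p.effective_r_on(g) for g in names], dtype=np.float64
        ),
        "ronb": np.asarray(
            [p.effective_r_on_basal(g) for g in names], dtype=np.float64
        ),
        "roff": vec("r_off"),
    }


# ---------------------------------------------------------------------------
# numba section
# ---------------------------------------------------------------------------

_REFRESH_EVERY = 1 << 14


@njit(cache=True, inline="always")
def _monomer(n, Kd):
    if Kd <= 0.0 or n <= 0:
        return float(n)
    # conjugate form of the positive root, stable for Kd*n -> 0
    return 2.0 * n / (1.0 + np.sqrt(1.0 + 8.0 * Kd * n))


@njit(cache=True, inline="always")
def _dimer(n, Kd):
    return 0.5 * (n - _monomer(n, Kd))


@njit(cache=True)
def _locus_flags(li, bound, locus_site0, locus_nsites, site_role, site_tf,
                 site_dimer, sox2_i, oct4_i):
    """(any_act, all_act, any_rep, any_sec, complex_ok) for one locus."""
    s0 = locus_site0[li]
    n = locus_nsites[li]
    any_act = False
    all_act = True
    any_rep = False
    any_sec = False
    oct4_b = False
    partner_b = False  # Sox2 or Nanog-dimer activator bound
    for k in range(s0, s0 + n):
        b = bound[k] == 1
        r = site_role[k]
        if r == 0:
            if b:
                any_act = True
                if site_dimer[k] == 1:
                    partner_b = True
                elif site_tf[k] == oct4_i:
                    oct4_b = True
                elif site_tf[k] == sox2_i:
                    partner_b = True
            else:
                all_act = False
        elif r == 1:
            if b:
                any_rep = True
        else:
            if b:
                any_sec = True
    return any_act, all_act, any_rep, any_sec, (oct4_b and partner_b)


@njit(cache=True)
def _channel_prop(c, counts, bound, ta, hist,
                  off0, off1, off2, off3, off4, off5, off6, off7, off8, off9,
                  locus_gene, locus_site0, locus_nsites,
                  site_locus, site_tf, site_dimer, site_role,
                  complex_rule, simplified,
                  g_syn, inv_gamma, k_deg, h0, f_unbind, Kd,
                  kf1, kf1b, kf1r, kf2, kdis, ron, ronb, roff,
                  nanog_i, sox2_i, oct4_i):
    if c < off1:  # degradation
        g = c
        if g == nanog_i:
            return k_deg * _monomer(counts[g], Kd)
        return k_deg * counts[g]
    if c < off2:  # synthesis
        li = c - off1
        t = ta[li]
        if t == 0:
            return 0.0
        g = locus_gene[li]
        if t == 2:
            return g_syn[g]
        return g_syn[g] * inv_gamma
    if c < off3:  # bind
        s = c - off2
        if bound[s] == 1:
            return 0.0
        if site_dimer[s] == 1:
            return h0 * _dimer(counts[nanog_i], Kd)
        return h0 * counts[site_tf[s]]
    if c < off4:  # unbind
        s = c - off3
        if bound[s] == 1:
            return f_unbind
        return 0.0
    if c < off5:  # TA step 1
        li = c - off4
        if ta[li] != 0 or hist[li] == 0:
            return 0.0
        g = locus_gene[li]
        any_act, _, any_rep, _, _ = _locus_flags(
            li, bound, locus_site0, locus_nsites, site_role, site_tf,
            site_dimer, sox2_i, oct4_i)
        if any_rep:
            return kf1r[g]
        if any_act:
            return kf1[g]
        return kf1b[g]
    if c < off6:  # TA step 2
        li = c - off5
        if ta[li] != 1:
            return 0.0
        g = locus_gene[li]
        _, all_act, any_rep, _, _ = _locus_flags(
            li, bound, locus_site0, locus_nsites, site_role, site_tf,
            site_dimer, sox2_i, oct4_i)
        if not all_act:
            return 0.0
        if simplified[g] == 0 and any_rep:
            return 0.0
        return kf2[g]
    if c < off7:  # TA dissolution
        li = c - off6
        if ta[li] == 0:
            return 0.0
        return kdis[locus_gene[li]]
    if c < off8:  # histone on
        li = c - off7
        if hist[li] != 0:
            return 0.0
        g = locus_gene[li]
        any_act, _, any_rep, any_sec, cplx = _locus_flags(
            li, bound, locus_site0, locus_nsites, site_role, site_tf,
            site_dimer, sox2_i, oct4_i)
        if any_rep or any_sec:
            return 0.0
        ok = cplx if complex_rule[g] == 1 else any_act
        if ok:
            return ron[g]
        if not any_act:
            return ronb[g]
        return 0.0
    # histone off
    li = c - off8
    if hist[li] != 1:
        return 0.0
    g = locus_gene[li]
    any_act, _, any_rep, any_sec, _ = _locus_flags(
        li, bound, locus_site0, locus_nsites, site_role, site_tf,
        site_dimer, sox2_i, oct4_i)
    if any_act:
        return 0.0
    if simplified[g] == 1:
        return roff[g]
    if any_rep or any_sec:
        return roff[g]
    return 0.0


@njit(cache=True)
def run_ssa(counts, bound, ta, hist, t_start, t_end,
            rec_t, rec_counts, rec_ta, rec_hist, rec_bound, rec_start,
            locus_gene, locus_site0, locus_nsites,
            site_locus, site_tf, site_dimer, site_role,
            complex_rule, simplified,
            tf_sites_flat, tf_sites_start,
            g_syn, inv_gamma, b_mean, k_deg, h0, f_unbind, Kd,
            kf1, kf1b, kf1r, kf2, kdis, ron, ronb, roff,
            nanog_i, sox2_i, oct4_i, seed):
    """Advance one cell from t_start to t_end, recording snapshots.

    Snapshots are taken at every entry of ``rec_t`` (absolute times within
    [t_start, t_end]) into the ``rec_*`` arrays starting at row
    ``rec_start``.  State arrays are modified in place; returns the number
    of executed events.
    """
    np.random.seed(seed)
    G = len(g_syn)
    L = len(locus_gene)
    S = len(site_locus)
    off = np.empty(10, dtype=np.int64)
    off[0] = 0
    off[1] = G
    off[2] = G + L
    off[3] = G + L + S
    off[4] = G + L + 2 * S
    for i in range(5, 10):
        off[i] = off[i - 1] + L
    C = off[9]
    props = np.zeros(C, dtype=np.float64)
    cat_sum = np.zeros(9, dtype=np.float64)

    def _refresh():
        for cat in range(9):
            s = 0.0
            for c in range(off[cat], off[cat + 1]):
                props[c] = _channel_prop(
                    c, counts, bound, ta, hist,
                    off[0], off[1], off[2], off[3], off[4], off[5], off[6],
                    off[7], off[8], off[9],
                    locus_gene, locus_site0, locus_nsites,
                    site_locus, site_tf, site_dimer, site_role,
                    complex_rule, simplified,
                    g_syn, inv_gamma, k_deg, h0, f_unbind, Kd,
                    kf1, kf1b, kf1r, kf2, kdis, ron, ronb, roff,
                    nanog_i, sox2_i, oct4_i)
                s += props[c]
            cat_sum[cat] = s

    def _update(c):
        new = _channel_prop(
            c, counts, bound, ta, hist,
            off[0], off[1], off[2], off[3], off[4], off[5], off[6],
            off[7], off[8], off[9],
            locus_gene, locus_site0, locus_nsites,
            site_locus, site_tf, site_dimer, site_role,
            complex_rule, simplified,
            g_syn, inv_gamma, k_deg, h0, f_unbind, Kd,
            kf1, kf1b, kf1r, kf2, kdis, ron, ronb, roff,
            nanog_i, sox2_i, oct4_i)
        cat = 0
        for i in range(1, 9):
            if c >= off[i]:
                cat = i
        cat_sum[cat] += new - props[c]
        props[c] = new

    def _count_changed(g):
        _update(g)  # degradation channel
        for k in range(tf_sites_start[g], tf_sites_start[g + 1]):
            _update(off[2] + tf_sites_flat[k])

    def _record(k):
        for g in range(G):
            rec_counts[rec_start + k, g] = counts[g]
        for li in range(L):
            rec_ta[rec_start + k, li] = ta[li]
            rec_hist[rec_start + k, li] = hist[li]
            mask = 0
            for s in range(locus_site0[li], locus_site0[li] + locus_nsites[li]):
                if bound[s] == 1:
                    mask |= 1 << (s - locus_site0[li])
            rec_bound[rec_start + k, li] = mask

    _refresh()
    t = t_start
    krec = 0
    nrec = len(rec_t)
    n_events = 0
    while True:
        A = cat_sum.sum()
        if A <= 0.0:
            # absorbing state: emit remaining snapshots and stop
            while krec < nrec:
                _record(krec)
                krec += 1
            break
        t_next = t - np.log(np.random.random()) / A
        stop = t_next if t_next < t_end else t_end
        while krec < nrec and rec_t[krec] <= stop:
            _record(krec)
            krec += 1
        if t_next >= t_end:
            break
        t = t_next
        # two-level channel selection
        r = np.random.random() * A
        cat = 8
        acc = 0.0
        for i in range(9):
            if r < acc + cat_sum[i]:
                cat = i
                break
            acc += cat_sum[i]
        c = off[cat + 1] - 1
        for cc in range(off[cat], off[cat + 1]):
            acc += props[cc]
            if r < acc:
                c = cc
                break
        # apply
        if c < off[1]:  # degradation
            g = c
            if counts[g] > 0:
                counts[g] -= 1
            _count_changed(g)
        elif c < off[2]:  # synthesis burst
            li = c - off[1]
            g = locus_gene[li]
            counts[g] += np.random.poisson(b_mean)
            _count_changed(g)
        elif c < off[3]:  # bind
            s = c - off[2]
            bound[s] = 1
            li = site_locus[s]
            _update(c)
            _update(off[3] + s)
            _update(off[4] + li)
            _update(off[5] + li)
            _update(off[7] + li)
            _update(off[8] + li)
        elif c < off[4]:  # unbind
            s = c - off[3]
            bound[s] = 0
            li = site_locus[s]
            _update(off[2] + s)
            _update(c)
            _update(off[4] + li)
            _update(off[5] + li)
            _update(off[7] + li)
            _update(off[8] + li)
        elif c < off[5]:  # TA 0 -> 1/2
            li = c - off[4]
            ta[li] = 1
            _update(off[1] + li)
            _update(off[4] + li)
            _update(off[5] + li)
            _update(off[6] + li)
        elif c < off[6]:  # TA 1/2 -> 1
            li = c - off[5]
            ta[li] = 2
            _update(off[1] + li)
            _update(off[4] + li)
            _update(off[5] + li)
            _update(off[6] + li)
        elif c < off[7]:  # TA dissolution -> 0
            li = c - off[6]
            ta[li] = 0
            _update(off[1] + li)
            _update(off[4] + li)
            _update(off[5] + li)
            _update(off[6] + li)
        elif c < off[8]:  # histone on
            li = c - off[7]
            hist[li] = 1
            _update(off[4] + li)
            _update(off[7] + li)
            _update(off[8] + li)
        else:  # histone off
            li = c - off[8]
            hist[li] = 0
            _update(off[4] + li)
            _update(off[7] + li)
            _update(off[8] + li)
        n_events += 1
        if n_events % _REFRESH_EVERY == 0:
            _refresh()
    return n_events


def all_propensities(layout: ModelLayout, rates, counts, bound, ta, hist):
    """Propensity of every channel for a given flat state (test hook)."""
    off = layout.channel_offsets()
    C = off[-1]
    offs = list(off)
    out = np.zeros(C, dtype=np.float64)
    for c in range(C):
        out[c] = _channel_prop(
            c, counts, bound, ta, hist,
            offs[0], offs[1], offs[2], offs[3], offs[4], offs[5], offs[6],
            offs[7], offs[8], offs[9],
            layout.locus_gene, layout.locus_site0, layout.locus_nsites,
            layout.site_locus, layout.site_tf, layout.site_dimer,
            layout.site_role, layout.complex_rule, layout.simplified,
            rates["g_syn"], rates["inv_gamma"], rates["k_deg"], rates["h0"],
            rates["f_unbind"], rates["K_dimer"],
            rates["kf1"], rates["kf1b"], rates["kf1r"], rates["kf2"],
            rates["kdis"], rates["ron"], rates["ronb"], rates["roff"],
            layout.nanog_index,
            layout.gene_names.index("Sox2") if "Sox2" in layout.gene_names else -1,
            layout.gene_names.index("Oct4") if "Oct4" in layout.gene_names else -1,
        )
    return out
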