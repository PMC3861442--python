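"""Per-cell state containers.

A cell is described per gene per allele by the binding occupancy of every
site, the transcription-apparatus (TA) level and the histone code, together
with integer protein copy numbers.  The TA level is three-valued:
0 (unformed), 1/2 (partial, synthesis at reduced rate) and 1 (complete).
Internally the TA level is stored as an int in {0, 1, 2} (value = ta/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import RegulatoryNetwork

__all__ = ["LocusState", "CellStateVector", "TA_LEVELS"]

#: admissible TA values on the 0..1 scale
TA_LEVELS = (0.0, 0.5, 1.0)

_TA_CODE = {0.0: 0, 0.5: 1, 1.0: 2}


@dataclass
class LocusState:
    """Epigenetic state of a single allele of one gene."""

    bound: tuple[int, ...]  # occupancy per site, same order as GeneSpec.sites()
    ta: float = 0.0  # in {0, 1/2, 1}
    histone: int = 0  # 0 repressive, 1 active

    def __post_init__(self):
        if self.ta not in _TA_CODE:
            raise ValueError(f"ta must be one of {TA_LEVELS}, got {self.ta}")
        if self.histone not in (0, 1):
            raise ValueError("histone must be 0 or 1")
        if any(b not in (0, 1) for b in self.bound):
            raise ValueError("bound entries must be 0 or 1")

    @property
    def ta_code(self) -> int:
        return _TA_CODE[self.ta]


@dataclass
class CellStateVector:
    """Full state of one simulated cell.

    ``loci[gene]`` is a list with one :class:`LocusState` per allele; a
    silenced Nanog allele is simply absent.  ``counts`` are whole-cell
    protein copy numbers.
    """

    loci: dict[str, list[LocusState]]
    counts: dict[str, int]
    t: float = 0.0
    frozen_loci: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for g, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"count of {g} must be a non-negative int")


def pluripotent_state(network: RegulatoryNetwork, params) -> CellStateVector:
    """The pluripotent initial condition.

    SON loci start with active histone code, complete TA and all activator
    sites occupied, and copy numbers at the deterministic steady level
    ``n_alleles * g_full * b_mean / k_deg``; lineage loci start fully silent
    with zero copies.
    """
    loci: dict[str, list[LocusState]] = {}
    counts: dict[str, int] = {}
    per_allele = params.b_mean / params.k_deg  # times synth rate below
    for spec in network.genes:
        g = spec.name
        sites = spec.sites()
        son = spec.histone_complex_rule
        n_all = spec.n_alleles
        if son:
            bound = tuple(1 if s.role == 0 else 0 for s in sites)
            loci[g] = [
                LocusState(bound=bound, ta=1.0, histone=1)
                for _ in range(n_all)
            ]
            counts[g] = int(round(n_all * params.synth_rate(g) * per_allele))
        else:
            bound = tuple(0 for _ in sites)
            loci[g] = [
                LocusState(bound=bound, ta=0.0, histone=0)
                for _ in range(n_all)
            ]
            counts[g] = 0
    return CellStateVector(loci=loci, counts=counts, t=0.0)


def state_to_arrays(state: CellStateVector, layout) -> tuple[np.ndarray, ...]:
    """Pack a CellStateVector into the flat arrays used by the SSA kernel."""
    counts = np.zeros(len(layout.gene_names), dtype=np.int64)
    for i, g in enumerate(layout.gene_names):
        counts[i] = state.counts.get(g, 0)
    bound = np.zeros(layout.n_sites, dtype=np.int8)
    ta = np.zeros(layout.n_loci, dtype=np.int8)
    hist = np.zeros(layout.n_loci, dtype=np.int8)
    for li in range(layout.n_loci):
        g = layout.gene_names[layout.locus_gene[li]]
        a = layout.locus_allele[li]
        alleles = state.loci.get(g, [])
        if a >= len(alleles):
            continue  # silenced allele stays all-zero
        ls = alleles[a]
        ta[li] = ls.ta_code
        hist[li] = ls.histone
        s0 = layout.locus_site0[li]
        for k, b in enumerate(ls.bound):
            bound[s0 + k] = b
    return counts, bound, ta, hist
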