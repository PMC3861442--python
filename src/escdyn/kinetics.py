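"""Reaction propensities.

Pure functions mapping a locus/cell state to the rate of every reaction
channel: burst synthesis, degradation, TF binding/unbinding, the two-step
formation and one-step dissolution of the transcription apparatus (TA), and
the histone-code switch.  All functions are side-effect free; the SSA kernel
implements the same rules on flat arrays and is cross-checked against these
functions in the test suite.

Rules
-----
* Binding is linear in the copy number of the binding TF; any Nanog site uses
  the dimer count from the fast dimerization equilibrium.
* Degradation is linear in copy number; Nanog degrades through its monomer.
* TA step 1 (0 -> 1/2) requires an active histone code and is graded by what
  is bound: repressor bound (repressed rate) > nothing bound (basal) >
  activator bound (full), with the repressor branch taking precedence.
* TA step 2 (1/2 -> 1) requires every activator site occupied; on loci that
  have repressors it is additionally blocked while a repressor is bound.
* Histone activation requires bound activators that are not opposed by any
  repressor; on the SON loci the activator condition is the complex rule
  (Oct4 with Sox2, or Oct4 with the Nanog dimer).  An unbound locus retains a
  basal activation rate.  Histone repression requires a bound repressor and
  no bound activator; repressor-free loci (Sox2, Gcnf) instead repress at the
  basal rate whenever no activator is bound.
* The secondary Oct4 site of the Nanog locus is invisible to the TA rules and
  counts as a repressor in both histone rules.
"""

from __future__ import annotations

import math

from .network import (
    ACTIVATOR,
    REPRESSOR,
    SECONDARY,
    GeneSpec,
    ParameterSet,
)
from .state import LocusState

__all__ = [
    "dimer_partition",
    "binding_propensity",
    "unbinding_propensity",
    "ta_step1_propensity",
    "ta_step2_propensity",
    "ta_dissolution_propensity",
    "histone_on_propensity",
    "histone_off_propensity",
    "synthesis_propensity",
    "degradation_propensity",
]


def dimer_partition(n_total: float, K: float) -> tuple[float, float]:
    """Split a total Nanog copy number into (dimer, monomer) counts.

    Dimerization is treated as infinitely fast, so the monomer count m solves
    the equilibrium system  d = K m^2,  2 d + m = n_total  in closed form
    (positive root of 2K m^2 + m - n_total = 0).  Real-valued outputs.
    """
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    if K < 0:
        raise ValueError("K must be non-negative")
    if K == 0.0 or n_total == 0.0:
        return 0.0, float(n_total)
    # conjugate form of the positive root, stable for K*n -> 0
    m = 2.0 * n_total / (1.0 + math.sqrt(1.0 + 8.0 * K * n_total))
    d = 0.5 * (n_total - m)
    return d, m


def _tf_copies(site, counts, params: ParameterSet) -> float:
    if site.is_dimer:
        d, _ = dimer_partition(counts.get("Nanog", 0), params.K_dimer)
        return d
    return float(counts.get(site.tf_gene, 0))


def binding_propensity(site, counts, params: ParameterSet) -> float:
    """h0_bind times the copy number of the binding TF (dimer for Nanog)."""
    return params.h0_bind * _tf_copies(site, counts, params)


def unbinding_propensity(site, params: ParameterSet) -> float:
    """Constant unbinding rate, independent of copy numbers."""
    return params.f_unbind


def _bound_roles(locus: LocusState, gene: GeneSpec):
    sites = gene.sites()
    act = [locus.bound[i] for i, s in enumerate(sites) if s.role == ACTIVATOR]
    rep = [locus.bound[i] for i, s in enumerate(sites) if s.role == REPRESSOR]
    sec = [locus.bound[i] for i, s in enumerate(sites) if s.role == SECONDARY]
    return sites, act, rep, sec


def ta_step1_propensity(
    locus: LocusState, gene: GeneSpec, params: ParameterSet
) -> float:
    """Rate of the first TA-formation step (ta 0 -> 1/2)."""
    if locus.ta != 0.0:
        return 0.0
    if locus.histone == 0:
        return 0.0
    _, act, rep, _ = _bound_roles(locus, gene)
    g = gene.name
    if any(rep):  # repression dominant over activation
        return params.for_gene(g, "k_ta_form1_rep")
    if any(act):
        return params.for_gene(g, "k_ta_form1")
    return params.for_gene(g, "k_ta_form1_basal")


def ta_step2_propensity(
    locus: LocusState, gene: GeneSpec, params: ParameterSet
) -> float:
    """Rate of TA completion (ta 1/2 -> 1): all activator sites occupied."""
    if locus.ta != 0.5:
        return 0.0
    _, act, rep, _ = _bound_roles(locus, gene)
    if not all(act):
        return 0.0
    if not gene.simplified_rules and any(rep):
        return 0.0
    return params.for_gene(gene.name, "k_ta_form2")


def ta_dissolution_propensity(
    locus: LocusState, gene: GeneSpec, params: ParameterSet
) -> float:
    """TA dissolution: both partial and complete TA resolve to 0 directly."""
    if locus.ta == 0.0:
        return 0.0
    return params.for_gene(gene.name, "k_ta_diss")


def _son_complex_bound(locus: LocusState, gene: GeneSpec) -> bool:
    # activator order on SON loci is (Sox2, Oct4, Nanog-dimer)
    sites = gene.sites()
    by_tf = {
        s.tf: locus.bound[i] for i, s in enumerate(sites) if s.role == ACTIVATOR
    }
    oct4 = bool(by_tf.get("Oct4", 0))
    return oct4 and (bool(by_tf.get("Sox2", 0)) or bool(by_tf.get("Nanog2", 0)))


def histone_on_propensity(
    locus: LocusState, gene: GeneSpec, params: ParameterSet
) -> float:
    """Histone activation rate (histone 0 -> 1), culture-mode aware."""
    if locus.histone != 0:
        return 0.0
    _, act, rep, sec = _bound_roles(locus, gene)
    if any(rep) or any(sec):
        return 0.0
    if gene.histone_complex_rule:
        activated = _son_complex_bound(locus, gene)
    else:
        activated = any(act)
    if activated:
        return params.effective_r_on(gene.name)
    if not any(act):  # nothing bound at all: basal activation
        return params.effective_r_on_basal(gene.name)
    return 0.0


def histone_off_propensity(
    locus: LocusState, gene: GeneSpec, params: ParameterSet
) -> float:
    """Histone repression rate (histone 1 -> 0)."""
    if locus.histone != 1:
        return 0.0
    _, act, rep, sec = _bound_roles(locus, gene)
    if any(act):
        return 0.0
    if gene.simplified_rules:
        # no repressor sites exist: basal repression when unprotected
        return params.for_gene(gene.name, "r_off")
    if any(rep) or any(sec):
        return params.for_gene(gene.name, "r_off")
    return 0.0


def synthesis_propensity(
    locus: LocusState, gene: GeneSpec, params: ParameterSet
) -> float:
    """Burst-synthesis rate of one allele: g (complete TA), g/gamma
    (partial), 0 (unformed); each firing adds Poisson(b_mean) copies."""
    if locus.ta == 0.0:
        return 0.0
    g = params.synth_rate(gene.name)
    return g if locus.ta == 1.0 else g / params.gamma_synth


def degradation_propensity(
    gene_name: str, counts, params: ParameterSet
) -> float:
    """First-order decay; Nanog decays through its monomer pool."""
    n = counts.get(gene_name, 0)
    if gene_name == "Nanog":
        _, m = dimer_partition(n, params.K_dimer)
        return params.k_deg * m
    return params.k_deg * n
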