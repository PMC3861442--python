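"""Gene network, parameter sets and their validation.

The default network couples the core pluripotency factors of mouse embryonic
stem cells -- Sox2, Oct4 and Nanog (SON) -- to the lineage-trigger genes Cdx2
(trophectoderm), Gata6 (primitive endoderm) and Gcnf.  Each locus carries an
ordered list of activator and repressor binding sites; Nanog always acts
through its dimer, and the Nanog locus carries a secondary Oct4 site that is
read only by the histone-code reactions (excess Oct4 represses Nanog).

Rates are grouped in :class:`ParameterSet`.  The key dimensionless quantities
are the adiabaticities -- the ratio of each switching process's rate to the
protein degradation rate ``k_deg``: transcription-factor binding must be fast
(adiabatic), the histone code slow (non-adiabatic), and the transcription
apparatus (TA) of the Nanog locus sits near the cell-cycle frequency, which is
what generates the bimodal Nanog distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "GENES",
    "NANOG_DIMER",
    "Site",
    "GeneSpec",
    "RegulatoryNetwork",
    "ParameterSet",
    "AdiabaticityReport",
    "build_default_network",
    "validate_parameters",
]

#: canonical gene order used throughout the package
GENES = ("Sox2", "Oct4", "Nanog", "Cdx2", "Gata6", "Gcnf")

#: TF identifier denoting the Nanog homodimer (all chromatin contacts of
#: Nanog are made by the dimer)
NANOG_DIMER = "Nanog2"

# site roles
ACTIVATOR = 0
REPRESSOR = 1
SECONDARY = 2  # repressor read only by the histone-code reactions


@dataclass(frozen=True)
class Site:
    """A single TF binding site on a locus."""

    tf: str  # gene name of the binding factor, or NANOG_DIMER
    role: int  # ACTIVATOR / REPRESSOR / SECONDARY

    @property
    def tf_gene(self) -> str:
        return "Nanog" if self.tf == NANOG_DIMER else self.tf

    @property
    def is_dimer(self) -> bool:
        return self.tf == NANOG_DIMER


@dataclass(frozen=True)
class GeneSpec:
    """Wiring of one gene locus.

    ``histone_complex_rule`` marks loci whose histone activation requires an
    Oct4--Sox2 or Oct4--Nanog pair bound (the SON loci).
    ``secondary_oct4_repressor`` marks the Nanog locus, whose extra Oct4 site
    acts repressively in the histone-code reactions only.
    """

    name: str
    activator_sites: tuple[str, ...] = ()
    repressor_sites: tuple[str, ...] = ()
    histone_complex_rule: bool = False
    secondary_oct4_repressor: bool = False
    n_alleles: int = 2
    # per-gene rate overrides may also be attached here for bookkeeping; the
    # resolved values live in ParameterSet.gene_overrides (excluded from
    # equality/hash so networks stay usable as cache keys)
    rate_overrides: Mapping[str, float] = field(
        default_factory=dict, compare=False
    )

    def sites(self) -> tuple[Site, ...]:
        """Ordered binding sites: activators first, then repressors.

        On a locus with ``secondary_oct4_repressor`` the Oct4 entry of the
        repressor list becomes a SECONDARY site (histone-code reactions only).
        """
        out = [Site(tf, ACTIVATOR) for tf in self.activator_sites]
        for tf in self.repressor_sites:
            if self.secondary_oct4_repressor and tf == "Oct4":
                out.append(Site(tf, SECONDARY))
            else:
                out.append(Site(tf, REPRESSOR))
        return tuple(out)

    @property
    def simplified_rules(self) -> bool:
        """True for loci with no repressor sites (Sox2, Gcnf).

        These use the reduced TA-completion and histone-repression rules
        (no repressor condition; basal histone repression when no activator
        is bound).
        """
        return len(self.repressor_sites) == 0


@dataclass(frozen=True)
class RegulatoryNetwork:
    genes: tuple[GeneSpec, ...]

    def __post_init__(self):
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in network")

    def __getitem__(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def with_gene(self, spec: GeneSpec) -> "RegulatoryNetwork":
        """Return a copy with one gene replaced."""
        return RegulatoryNetwork(
            tuple(spec if g.name == spec.name else g for g in self.genes)
        )


def build_default_network(nanog_alleles: int = 1) -> RegulatoryNetwork:
    """The six-gene ESC core network.

    By default only one Nanog allele is dynamic (allelic silencing in
    Lif-cultured ESCs); pass ``nanog_alleles=2`` for the variant in which both
    alleles work independently, which produces a three-peak Nanog
    distribution.
    """
    if nanog_alleles not in (1, 2):
        raise ValueError("nanog_alleles must be 1 or 2")
    son_act = ("Sox2", "Oct4", NANOG_DIMER)
    genes = (
        GeneSpec("Sox2", son_act, (), histone_complex_rule=True),
        GeneSpec("Oct4", son_act, ("Cdx2", "Gcnf"), histone_complex_rule=True),
        GeneSpec(
            "Nanog",
            son_act,
            ("Oct4", "Gata6", "Gcnf"),
            histone_complex_rule=True,
            secondary_oct4_repressor=True,
            n_alleles=nanog_alleles,
        ),
        GeneSpec("Cdx2", ("Cdx2",), ("Oct4", "Gata6")),
        GeneSpec("Gata6", ("Gata6",), (NANOG_DIMER, "Cdx2")),
        GeneSpec("Gcnf", ("Cdx2", "Gata6", "Gcnf"), ()),
    )
    return RegulatoryNetwork(genes)


# culture modes
ESC = "esc"
DIFFERENTIATION = "differentiation"

#: genes whose histone code is kept repressive by the Lif/c-Myc axis in the
#: self-renewing (ESC) culture condition
LINEAGE_GENES = ("Cdx2", "Gata6", "Gcnf")


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants of the model (units: 1/s unless noted).

    Per-gene deviations from the common values live in ``gene_overrides``
    (``{gene: {field: value}}``); the shipped defaults pin the Nanog TA
    dissolution at the cell-cycle frequency and slow its completion, which
    is the slow-switching regime behind the bimodal Nanog distribution.
    """

    g_full: float = 0.02  # synthesis rate with complete TA [1/s]
    gamma_synth: float = 10.0  # complete/partial TA synthesis ratio (>= 1)
    b_mean: float = 5.0  # mean burst size [copies/burst]
    k_deg: float = 1.0e-4  # protein degradation [1/s]
    h0_bind: float = 1.0e-4  # binding rate per TF copy [1/(s*copy)]
    f_unbind: float = 1.0e-2  # unbinding rate [1/s]
    K_dimer: float = 0.01  # Nanog dimerization constant [1/copies]
    k_ta_form1: float = 1.0e-3  # TA first step, activator bound
    k_ta_form1_basal: float = 1.0e-4  # TA first step, nothing bound
    k_ta_form1_rep: float = 1.0e-5  # TA first step, repressor bound
    k_ta_form2: float = 1.0e-3  # TA completion (all activators bound)
    k_ta_diss: float = 1.0e-3  # TA dissolution (1 or 1/2 -> 0)
    r_on: float = 5.0e-6  # histone code -> active
    r_on_basal: float = 5.0e-6  # histone code -> active, no TF bound
    r_off: float = 5.0e-6  # histone code -> repressive
    culture_mode: str = ESC
    oct4_synth_factor: float = 1.0  # Oct4 depletion multiplier (1, 0.25, 0.1)
    gene_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    #: fields that admit per-gene overrides
    _OVERRIDABLE = frozenset(
        {
            "k_ta_form1",
            "k_ta_form1_basal",
            "k_ta_form1_rep",
            "k_ta_form2",
            "k_ta_diss",
            "r_on",
            "r_on_basal",
            "r_off",
            "g_full",
        }
    )

    def for_gene(self, gene: str, name: str) -> float:
        """Rate ``name`` resolved for ``gene`` (override-aware)."""
        ov = self.gene_overrides.get(gene, {})
        if name in ov:
            return float(ov[name])
        return float(getattr(self, name))

    def effective_r_on(self, gene: str) -> float:
        """Histone-activation rate after applying the culture condition.

        In ESC culture the Lif/c-Myc axis keeps the histone code of the
        lineage genes repressive, which is encoded as r_on = 0 for Cdx2,
        Gata6 and Gcnf.
        """
        if self.culture_mode == ESC and gene in LINEAGE_GENES:
            return 0.0
        return self.for_gene(gene, "r_on")

    def effective_r_on_basal(self, gene: str) -> float:
        if self.culture_mode == ESC and gene in LINEAGE_GENES:
            return 0.0
        return self.for_gene(gene, "r_on_basal")

    def synth_rate(self, gene: str) -> float:
        g = self.for_gene(gene, "g_full")
        if gene == "Oct4":
            g *= self.oct4_synth_factor
        return g

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def with_override(self, gene: str, **rates: float) -> "ParameterSet":
        ov = {k: dict(v) for k, v in self.gene_overrides.items()}
        ov.setdefault(gene, {}).update(rates)
        return replace(self, gene_overrides=ov)


#: cell-cycle frequency of mouse ESCs, 1/day expressed in 1/s; the lowest
#: biologically allowed TA dissolution rate
CELL_CYCLE_RATE = 1.16e-5


def default_parameters(
    culture_mode: str = ESC, slow_nanog: bool = True
) -> ParameterSet:
    """The shipped parameter set.

    With ``slow_nanog`` (the default) every TA rate of the Nanog locus is
    pinned at the cell-cycle frequency (adiabaticity ~0.1, non-adiabatic),
    reproducing the bimodal Nanog distribution; without it Nanog switches as
    fast as the other genes (adiabaticity 10) and the distribution collapses
    to a single peak.  In differentiation culture the Cdx2 histone-activation
    rate is kept one order of magnitude below the other lineage genes.
    """
    overrides: dict[str, dict[str, float]] = {
        "Cdx2": {"r_on": 5.0e-7, "r_on_basal": 5.0e-7},
    }
    if slow_nanog:
        overrides["Nanog"] = {
            "k_ta_form1": 1.0e-4,
            "k_ta_form1_basal": 1.0e-5,
            "k_ta_form1_rep": 1.0e-6,
            "k_ta_form2": 2.0e-5,
            "k_ta_diss": CELL_CYCLE_RATE,
        }
    return ParameterSet(culture_mode=culture_mode, gene_overrides=overrides)


@dataclass(frozen=True)
class AdiabaticityReport:
    """Process rates relative to protein turnover (pure derived ratios)."""

    pi_bind: float
    pi_ta: Mapping[str, float]
    pi_hist: Mapping[str, float]

    @classmethod
    def from_parameters(
        cls, params: ParameterSet, network: RegulatoryNetwork
    ) -> "AdiabaticityReport":
        k = params.k_deg
        return cls(
            pi_bind=params.f_unbind / k,
            pi_ta={
                g: params.for_gene(g, "k_ta_diss") / k
                for g in network.gene_names
            },
            pi_hist={
                g: params.for_gene(g, "r_off") / k for g in network.gene_names
            },
        )


def validate_parameters(
    params: ParameterSet,
    network: RegulatoryNetwork | None = None,
    copy_number_window: tuple[float, float] = (1e2, 1e4),
) -> list[str]:
    """Check a parameter set against the model's timescale ordering.

    Returns a list of human-readable violations (empty when the set is
    admissible); never raises, so parameter scans can probe bad regions.
    Checks: non-negativity, gamma_synth >= 1, b_mean > 0, the conditional
    TA-formation ordering (k_ta_form1 >= basal >= repressed), adiabatic TF
    binding (pi_bind > 1), non-adiabatic histone code (pi_hist < 1 per gene)
    and the steady copy-number scale 2*g_full*b_mean/k_deg inside a
    plausibility window.
    """
    if network is None:
        network = build_default_network()
    v: list[str] = []
    rate_fields = (
        "g_full",
        "b_mean",
        "k_deg",
        "h0_bind",
        "f_unbind",
        "K_dimer",
        "k_ta_form1",
        "k_ta_form1_basal",
        "k_ta_form1_rep",
        "k_ta_form2",
        "k_ta_diss",
        "r_on",
        "r_on_basal",
        "r_off",
    )
    for name in rate_fields:
        if getattr(params, name) < 0:
            v.append(f"negative rate: {name}")
    if params.gamma_synth < 1:
        v.append("gamma_synth < 1: partial TA cannot outproduce complete TA")
    if params.b_mean <= 0:
        v.append("b_mean must be positive")
    if params.k_deg <= 0:
        v.append("k_deg must be positive")
        return v  # ratios below are meaningless

    rep = AdiabaticityReport.from_parameters(params, network)
    if rep.pi_bind <= 1:
        v.append(
            f"binding not adiabatic: f_unbind/k_deg = {rep.pi_bind:.3g} <= 1"
        )
    for g in network.gene_names:
        if rep.pi_hist[g] >= 1:
            v.append(
                "histone code not non-adiabatic for "
                f"{g}: r_off/k_deg = {rep.pi_hist[g]:.3g} >= 1"
            )
        k1 = params.for_gene(g, "k_ta_form1")
        kb = params.for_gene(g, "k_ta_form1_basal")
        kr = params.for_gene(g, "k_ta_form1_rep")
        if not (k1 >= kb >= kr):
            v.append(
                f"TA formation ordering violated for {g}: "
                f"expected k_ta_form1 >= basal >= repressed, "
                f"got {k1:.3g}, {kb:.3g}, {kr:.3g}"
            )
    scale = 2.0 * params.g_full * params.b_mean / params.k_deg
    lo, hi = copy_number_window
    if not (lo <= scale <= hi):
        v.append(
            f"steady copy-number scale 2*g_full*b_mean/k_deg = {scale:.3g} "
            f"outside [{lo:g}, {hi:g}]"
        )
    return v
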