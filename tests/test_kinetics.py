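"""Propensity rules, the dimer equilibrium, and kernel/reference agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from escdyn import kinetics
from escdyn._kernel import all_propensities, build_layout, rate_arrays
from escdyn.network import build_default_network, default_parameters
from escdyn.state import LocusState


class TestDimerPartition:
    def test_no_molecules(self):
        assert kinetics.dimer_partition(0, 0.5) == (0.0, 0.0)

    def test_no_dimerization(self):
        assert kinetics.dimer_partition(123, 0.0) == (0.0, 123.0)

    def test_exact_quadratic_case(self):
        d, m = kinetics.dimer_partition(100, 0.01)
        assert m == pytest.approx(50.0)
        assert d == pytest.approx(25.0)
        assert 2 * d + m == pytest.approx(100.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            kinetics.dimer_partition(-1, 0.1)
        with pytest.raises(ValueError):
            kinetics.dimer_partition(1, -0.1)

    @settings(derandomize=True, max_examples=200)
    @given(
        n=st.floats(min_value=0.0, max_value=1e6),
        K=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_mass_conserved_and_equilibrium(self, n, K):
        d, m = kinetics.dimer_partition(n, K)
        assert d >= 0 and m >= 0
        assert 2 * d + m == pytest.approx(n, rel=1e-9, abs=1e-9)
        assert d == pytest.approx(K * m * m, rel=1e-7, abs=1e-7)

    @pytest.mark.parametrize("n,K", [(7, 0.3), (1000, 1e-4), (5, 2.0)])
    def test_agrees_with_bisection_oracle(self, n, K):
        m_oracle = brentq(lambda m: 2 * K * m * m + m - n, 0.0, float(n))
        _, m = kinetics.dimer_partition(n, K)
        assert m == pytest.approx(m_oracle, rel=1e-9)


@pytest.fixture(scope="module")
def net():
    return build_default_network()


@pytest.fixture(scope="module")
def params():
    return default_parameters()


def _locus(spec, bound_tfs=(), ta=0.0, hist=0, roles=None):
    sites = spec.sites()
    bound = tuple(
        1 if (s.tf, s.role) in bound_tfs or (s.tf, None) in bound_tfs else 0
        for s in sites
    )
    return LocusState(bound=bound, ta=ta, histone=hist)


class TestBinding:
    def test_zero_copies_zero_rate(self, net, params):
        site = net["Cdx2"].sites()[1]  # Oct4 repressor site
        assert kinetics.binding_propensity(site, {"Oct4": 0}, params) == 0.0

    def test_linear_in_copy_number(self, net, params):
        site = net["Cdx2"].sites()[1]
        p = params.replace(h0_bind=2e-5)
        assert kinetics.binding_propensity(site, {"Oct4": 500}, p) == pytest.approx(0.01)

    def test_nanog_site_uses_dimer_count(self, net, params):
        site = next(s for s in net["Sox2"].sites() if s.is_dimer)
        p = params.replace(K_dimer=0.01)
        a = kinetics.binding_propensity(site, {"Nanog": 100}, p)
        assert a == pytest.approx(p.h0_bind * 25.0)

    def test_unbinding_constant(self, net, params):
        site = net["Sox2"].sites()[0]
        assert kinetics.unbinding_propensity(site, params) == params.f_unbind


class TestTARules:
    def test_step1_requires_active_histone(self, net, params):
        spec = net["Oct4"]
        loc = _locus(spec, {("Sox2", 0), ("Oct4", 0), ("Nanog2", 0)}, ta=0.0, hist=0)
        assert kinetics.ta_step1_propensity(loc, spec, params) == 0.0

    def test_step1_basal_when_nothing_bound(self, net, params):
        spec = net["Oct4"]
        loc = _locus(spec, set(), ta=0.0, hist=1)
        assert kinetics.ta_step1_propensity(loc, spec, params) == (
            params.for_gene("Oct4", "k_ta_form1_basal")
        )

    def test_step1_repressor_branch_dominates(self, net, params):
        spec = net["Oct4"]
        loc = _locus(spec, {("Sox2", 0), ("Cdx2", 1)}, ta=0.0, hist=1)
        assert kinetics.ta_step1_propensity(loc, spec, params) == (
            params.for_gene("Oct4", "k_ta_form1_rep")
        )

    def test_step1_ignores_secondary_oct4_site(self, net, params):
        spec = net["Nanog"]
        sites = spec.sites()
        bound = tuple(1 if s.role in (0, 2) else 0 for s in sites)
        loc = LocusState(bound=bound, ta=0.0, histone=1)
        assert kinetics.ta_step1_propensity(loc, spec, params) == (
            params.for_gene("Nanog", "k_ta_form1")
        )

    def test_step2_needs_every_activator(self, net, params):
        spec = net["Oct4"]
        full = _locus(spec, {("Sox2", 0), ("Oct4", 0), ("Nanog2", 0)}, ta=0.5, hist=1)
        assert kinetics.ta_step2_propensity(full, spec, params) == (
            params.for_gene("Oct4", "k_ta_form2")
        )
        partial = _locus(spec, {("Sox2", 0), ("Oct4", 0)}, ta=0.5, hist=1)
        assert kinetics.ta_step2_propensity(partial, spec, params) == 0.0

    def test_step2_gcnf_ignores_repressors_it_lacks(self, net, params):
        spec = net["Gcnf"]
        loc = _locus(spec, {("Cdx2", 0), ("Gata6", 0), ("Gcnf", 0)}, ta=0.5)
        assert kinetics.ta_step2_propensity(loc, spec, params) == (
            params.for_gene("Gcnf", "k_ta_form2")
        )

    def test_dissolution_from_both_levels_single_step(self, net, params):
        spec = net["Sox2"]
        for ta in (0.5, 1.0):
            loc = _locus(spec, set(), ta=ta, hist=1)
            assert kinetics.ta_dissolution_propensity(loc, spec, params) == (
                params.for_gene("Sox2", "k_ta_diss")
            )
        assert kinetics.ta_dissolution_propensity(
            _locus(spec, set(), ta=0.0), spec, params
        ) == 0.0


class TestHistoneRules:
    def test_repressor_blocks_activation(self, net, params):
        spec = net["Nanog"]
        loc = _locus(spec, {("Sox2", 0), ("Oct4", 0), ("Gata6", 1)}, hist=0)
        assert kinetics.histone_on_propensity(loc, spec, params) == 0.0

    def test_son_complex_rule_needs_oct4(self, net, params):
        spec = net["Oct4"]
        only_sox2 = _locus(spec, {("Sox2", 0)}, hist=0)
        assert kinetics.histone_on_propensity(only_sox2, spec, params) == 0.0
        pair = _locus(spec, {("Sox2", 0), ("Oct4", 0)}, hist=0)
        assert kinetics.histone_on_propensity(pair, spec, params) == (
            params.effective_r_on("Oct4")
        )

    def test_esc_mode_silences_lineage_activation(self, net):
        p = default_parameters(culture_mode="esc")
        spec = net["Gata6"]
        loc = _locus(spec, {("Gata6", 0)}, hist=0)
        assert kinetics.histone_on_propensity(loc, spec, p) == 0.0
        d = default_parameters(culture_mode="differentiation")
        assert kinetics.histone_on_propensity(loc, spec, d) > 0.0

    def test_repression_needs_repressor_and_no_activator(self, net, params):
        spec = net["Cdx2"]
        oct4_only = _locus(spec, {("Oct4", 1)}, hist=1)
        assert kinetics.histone_off_propensity(oct4_only, spec, params) == (
            params.for_gene("Cdx2", "r_off")
        )
        with_act = _locus(spec, {("Oct4", 1), ("Cdx2", 0)}, hist=1)
        assert kinetics.histone_off_propensity(with_act, spec, params) == 0.0

    def test_secondary_oct4_counts_as_histone_repressor(self, net, params):
        spec = net["Nanog"]
        sites = spec.sites()
        bound = tuple(1 if s.role == 2 else 0 for s in sites)
        loc = LocusState(bound=bound, ta=0.0, histone=1)
        assert kinetics.histone_off_propensity(loc, spec, params) == (
            params.for_gene("Nanog", "r_off")
        )
        loc_on = LocusState(bound=bound, ta=0.0, histone=0)
        assert kinetics.histone_on_propensity(loc_on, spec, params) == 0.0

    def test_repressor_free_locus_represses_basally(self, net, params):
        spec = net["Sox2"]
        naked = _locus(spec, set(), hist=1)
        assert kinetics.histone_off_propensity(naked, spec, params) == (
            params.for_gene("Sox2", "r_off")
        )
        active = _locus(spec, {("Sox2", 0)}, hist=1)
        assert kinetics.histone_off_propensity(active, spec, params) == 0.0


class TestSynthesisDegradation:
    def test_synthesis_levels(self, net, params):
        spec = net["Sox2"]
        assert kinetics.synthesis_propensity(_locus(spec, set(), ta=0.0), spec, params) == 0.0
        full = kinetics.synthesis_propensity(_locus(spec, set(), ta=1.0), spec, params)
        half = kinetics.synthesis_propensity(_locus(spec, set(), ta=0.5), spec, params)
        assert full == params.synth_rate("Sox2")
        assert half == pytest.approx(full / params.gamma_synth)

    def test_gamma_one_removes_partial_penalty(self, net):
        p = default_parameters().replace(gamma_synth=1.0)
        spec = net["Sox2"]
        assert kinetics.synthesis_propensity(
            _locus(spec, set(), ta=0.5), spec, p
        ) == kinetics.synthesis_propensity(_locus(spec, set(), ta=1.0), spec, p)

    def test_oct4_depletion_factor(self, net):
        p = default_parameters().replace(oct4_synth_factor=0.25)
        spec = net["Oct4"]
        assert kinetics.synthesis_propensity(
            _locus(spec, set(), ta=1.0), spec, p
        ) == pytest.approx(0.25 * p.for_gene("Oct4", "g_full"))

    def test_degradation_linear_and_monomer_based_for_nanog(self, params):
        assert kinetics.degradation_propensity("Sox2", {"Sox2": 0}, params) == 0.0
        assert kinetics.degradation_propensity(
            "Sox2", {"Sox2": 1000}, params
        ) == pytest.approx(1000 * params.k_deg)
        p = params.replace(K_dimer=0.01)
        assert kinetics.degradation_propensity(
            "Nanog", {"Nanog": 100}, p
        ) == pytest.approx(50 * p.k_deg)


def test_kernel_propensities_match_reference_on_random_states(net, params, rng):
    """The compiled kernel and the pure-Python rules agree channel by channel."""
    from escdyn.simulate import list_channels
    from escdyn.state import CellStateVector, state_to_arrays

    layout = build_layout(net)
    rates = rate_arrays(net, params)
    for trial in range(25):
        loci = {}
        counts = {}
        for spec in net.genes:
            counts[spec.name] = int(rng.integers(0, 3000))
            sites = spec.sites()
            loci[spec.name] = [
                LocusState(
                    bound=tuple(int(b) for b in rng.integers(0, 2, len(sites))),
                    ta=float(rng.choice([0.0, 0.5, 1.0])),
                    histone=int(rng.integers(0, 2)),
                )
                for _ in range(spec.n_alleles)
            ]
        cell = CellStateVector(loci=loci, counts=counts)
        arrays = state_to_arrays(cell, layout)
        kprops = all_propensities(layout, rates, *arrays)
        ref = sorted(
            (a for _, a, _ in list_channels(cell, net, params)), reverse=True
        )
        kp = sorted((float(x) for x in kprops if x > 0), reverse=True)
        assert len(ref) == len(kp)
        np.testing.assert_allclose(kp, ref, rtol=1e-12)
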