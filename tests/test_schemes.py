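"""Structure and invariants of the enzyme-state reaction graphs."""

import pytest
from hypothesis import given, strategies as st

import aakin.schemes as sch
from aakin.schemes import (RateSet, SchemeError, build_pp_exchange_scheme,
                           build_scheme, build_single_turnover_scheme,
                           dissociation_constant)

ALL_VARIANTS = [sch.CLASS1_MONOMER, sch.CLASS1_TRNA_REQUIRED,
                sch.CLASS2_FLIPFLOP, sch.PP_EXCHANGE, sch.SINGLE_TURNOVER]


class TestCounts:
    def test_class1_has_16_states_and_48_parameters(self):
        s = build_scheme(sch.CLASS1_MONOMER)
        assert len(s.states) == 16
        assert {x.label for x in s.states} == {f"S{i}" for i in range(16)}
        assert s.n_parameters == 48

    def test_pp_exchange_has_6_states_and_12_parameters(self):
        s = build_pp_exchange_scheme()
        assert len(s.states) == 6
        assert {x.label for x in s.states} == {f"S{i}" for i in range(6)}
        assert s.n_parameters == 12

    def test_single_turnover_has_8_parameters_from_adenylate_state(self):
        s = build_single_turnover_scheme()
        assert s.n_parameters == 8
        assert s.start_label == "S5"
        kinds = {st_.kind for st_ in s.steps}
        assert kinds == {"binding", "transfer", "release"}


@pytest.mark.parametrize("variant", ALL_VARIANTS)
class TestGraphInvariants:
    def test_validates_and_fully_reachable(self, variant):
        s = build_scheme(variant)
        s.validate()
        assert s.reachable_from_start() == {x.label for x in s.states}

    def test_every_step_is_reversible(self, variant):
        """Each kinetic step carries a forward and backward rate slot."""
        s = build_scheme(variant)
        rates = RateSet({x.id: (1.0, 1.0) for x in s.steps})
        assert rates.n_parameters == s.n_parameters
        for x in s.steps:
            kf, kb = rates[x.id]
            assert kf >= 0 and kb >= 0

    def test_site_exclusivity(self, variant):
        """A site never holds two tRNA forms or two adenosine ligands."""
        for state in build_scheme(variant).states:
            for site in state.composition:
                assert len(site & {"R", "R*"}) <= 1
                assert len(site & {"T", "M", "D"}) <= 1


class TestVariantStructure:
    def test_trna_required_has_no_trna_free_activation(self):
        s = build_scheme(sch.CLASS1_TRNA_REQUIRED, trna_required=True)
        for step in s.steps:
            if step.kind == "activation":
                comp = s.state(step.from_state).ligand_multiset()
                assert comp["R"] >= 1, \
                    "adenylate may only form with tRNA on the enzyme"

    def test_dual_ppi_release_paths(self):
        """PPi can leave before or after transfer (S10->S11->S13 and
        S10->S12->S13)."""
        s = build_scheme(sch.CLASS1_MONOMER)
        edges = {(x.from_state, x.to_state) for x in s.steps}
        assert {("S10", "S11"), ("S11", "S13")} <= edges
        assert {("S10", "S12"), ("S12", "S13")} <= edges

    def test_atp_binds_before_product_release_path(self):
        s = build_scheme(sch.CLASS1_MONOMER)
        step = s.step("atp_bind_p")
        assert (step.from_state, step.to_state) == ("S14", "S15")
        assert s.state("S15").ligand_multiset() == {"T": 1, "R*": 1}

    def test_pp_scheme_is_trna_free_restriction_of_class1(self):
        full = build_scheme(sch.CLASS1_MONOMER)
        pp = build_pp_exchange_scheme()
        for state in pp.states:
            assert state.composition == full.state(state.label).composition
            assert "R" not in state.ligand_multiset()
        full_ids = {x.id for x in full.steps}
        assert {x.id for x in pp.steps} <= full_ids

    def test_single_turnover_is_induced_subgraph_of_class1(self):
        full = build_scheme(sch.CLASS1_MONOMER)
        sub = build_single_turnover_scheme()
        keep = {x.label for x in sub.states}
        induced = {x.id for x in full.steps
                   if x.from_state in keep and x.to_state in keep}
        assert {x.id for x in sub.steps} == induced

    def test_flipflop_retains_site1_product_until_site2_activation(self):
        s = build_scheme(sch.CLASS2_FLIPFLOP)
        # no direct product release from the ER*/ state S14
        for step in s.steps:
            if step.releases == sch.AATRNA:
                comp = s.state(step.from_state).composition
                site2 = comp[1]
                assert "D" in site2, \
                    "site-1 aa-tRNA leaves only after site-2 activation"

    def test_full_cycle_pool_stoichiometry(self):
        """One catalytic cycle consumes ATP + AA + tRNA and releases
        PPi + AMP + aa-tRNA."""
        s = build_scheme(sch.CLASS1_MONOMER)
        cycle = ["aa_bind", "atp_bind_a", "act", "ppi_rel", "trna_bind_d",
                 "tran", "amp_rel", "prod_rel"]
        net = {}
        for sid in cycle:
            step = s.step(sid)
            if step.consumes:
                net[step.consumes] = net.get(step.consumes, 0) - 1
            if step.releases:
                net[step.releases] = net.get(step.releases, 0) + 1
        assert net == {sch.AA: -1, sch.ATP: -1, sch.TRNA: -1,
                       sch.PPI: 1, sch.AMP: 1, sch.AATRNA: 1}


class TestErrors:
    def test_unknown_variant_rejected(self):
        with pytest.raises(SchemeError):
            build_scheme("class3_trimer")

    def test_trna_required_with_flipflop_rejected(self):
        with pytest.raises(SchemeError):
            build_scheme(sch.CLASS2_FLIPFLOP, trna_required=True)

    def test_canonical_enzyme_variant_enforced(self):
        rates = RateSet({x.id: (1.0, 1.0)
                         for x in build_scheme(sch.CLASS1_MONOMER).steps})
        with pytest.raises(SchemeError):
            sch.EnzymeModel("argRS", "I", sch.CLASS1_MONOMER, rates)

    def test_flipflop_assignment(self):
        assert sch.canonical_variant("hisRS") == (sch.CLASS2_FLIPFLOP, False)
        assert sch.canonical_variant("metRS") == (sch.CLASS2_FLIPFLOP, False)
        assert sch.canonical_variant("tyrRS") == (sch.CLASS1_MONOMER, False)
        assert sch.canonical_variant("gluRS") == (sch.CLASS1_TRNA_REQUIRED, True)


class TestDissociationConstant:
    def test_thrRS_threonine_example(self):
        rates = RateSet({"aa_bind": (0.024, 3.2)})
        assert dissociation_constant(rates, "aa_bind") == pytest.approx(133.33, rel=1e-3)

    def test_irreversible_binding_gives_zero(self):
        assert dissociation_constant(RateSet({"x": (1.0, 0.0)}), "x") == 0.0

    def test_zero_on_rate_is_an_error(self):
        with pytest.raises(ValueError):
            dissociation_constant(RateSet({"x": (0.0, 1.0)}), "x")

    @given(kf=st.floats(1e-6, 1e6), kb=st.floats(0.0, 1e6))
    def test_kd_times_kf_recovers_kb(self, kf, kb):
        rates = RateSet({"x": (kf, kb)})
        assert dissociation_constant(rates, "x") * kf == pytest.approx(kb, rel=1e-12)
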