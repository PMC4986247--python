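"""Model definition contracts: completeness, rate laws, transport, decay."""

import numpy as np
import pytest

import ddrsim
from ddrsim.model import (HALF_LIVES_H, CellState, ModelLoadError, ModelSpec,
                          build_default_model, resting_state, rhs,
                          transport_terms)
from tests.conftest import random_states


class TestBuildDefaultModel:
    def test_three_compartments_present(self, spec):
        comps = {s.compartment for s in spec.species}
        assert comps == {"extracellular", "cytoplasm", "nucleus"}

    def test_core_species_inventory(self, spec):
        required = ["atm_n", "atma_n", "mrn_n", "chk2_n", "p53_n", "p53a_n",
                    "mdm2_c", "mdm2_n", "mdm2pp_n", "wip1_mrna_c", "wip1_n",
                    "mir16_c", "ksrp_n", "creb_n", "nfkb_c", "ikb_c",
                    "ikk_c", "a20_c", "p21_mrna_c", "p21_n", "bax_mrna_c",
                    "bax_c"]
        for name in required:
            assert name in spec.index, name

    def test_deleted_parameter_is_load_error_naming_symbol(self, spec):
        broken = spec.to_dict()
        del broken["parameters"]["k_act_atm"]
        with pytest.raises(ModelLoadError, match="k_act_atm"):
            ModelSpec.from_dict(broken)

    def test_undeclared_species_is_load_error(self, spec):
        broken = spec.to_dict()
        broken["reactions"][0]["stoich"][0][0] = "ghost_species"
        with pytest.raises(ModelLoadError, match="ghost_species"):
            ModelSpec.from_dict(broken)

    def test_degradation_rates_match_half_lives(self, spec):
        # rate = ln2 / t_half, recomputed independently from the table
        for pname, t_half_h in HALF_LIVES_H.items():
            expected = np.log(2.0) / (t_half_h * 3600.0)
            assert spec.parameters[pname] == pytest.approx(expected,
                                                           rel=1e-12)

    def test_all_rate_parameters_nonnegative(self, spec):
        for p, v in spec.parameters.items():
            assert v >= 0, p

    def test_yaml_round_trip_is_lossless(self, spec, tmp_path):
        path = tmp_path / "model.yaml"
        spec.to_yaml(path)
        back = ModelSpec.from_yaml(path)
        assert back.to_dict() == spec.to_dict()
        assert back.spec_hash() == spec.spec_hash()


class TestRhs:
    def test_resting_point_is_fixed_point(self, spec, rest):
        from ddrsim.engine import mean_field_rhs

        y, g, d = rest
        res = mean_field_rhs(spec.pack(), y, g, d, 0.0, 0.0, 0.0)
        # molecules/s residual, tiny relative to typical fluxes (~1/s)
        assert np.abs(res).max() < 1e-6

    def test_empty_cell_only_constitutive_sources(self, spec):
        state = CellState(t=0.0, y=np.zeros(spec.n_species),
                          genes={g.name: 0 for g in spec.genes},
                          dsb=0, receptors_active=0)
        dy = rhs(state, spec)
        const_targets = set()
        for r in spec.reactions:
            if r.kind == "const":
                for sname, c in r.stoich:
                    const_targets.add(spec.index[sname])
        for i, v in enumerate(dy):
            if i in const_targets:
                assert v > 0
            else:
                assert v == 0.0

    def test_negative_level_rejected(self, spec):
        y = np.zeros(spec.n_species)
        y[3] = -1.0
        state = CellState(t=0.0, y=y, genes={g.name: 0 for g in spec.genes})
        with pytest.raises(ValueError, match="negative"):
            rhs(state, spec)

    def test_transcription_linear_in_allele_count(self, spec, rest_state):
        """Doubling the Wip1 allele count doubles the gene-dependent part
        of the Wip1 mRNA synthesis term."""
        i_mrna = spec.index["wip1_mrna_c"]
        contributions = []
        for alleles in (0, 1, 2):
            st = CellState(t=0.0, y=rest_state.y.copy(),
                           genes={**rest_state.genes, "wip1": alleles},
                           dsb=rest_state.dsb)
            contributions.append(rhs(st, spec)[i_mrna])
        d1 = contributions[1] - contributions[0]
        d2 = contributions[2] - contributions[0]
        assert d1 > 0
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_dsb_count_drives_atm_pathway(self, spec, rest_state):
        st0 = CellState(t=0.0, y=rest_state.y.copy(),
                        genes=dict(rest_state.genes), dsb=0)
        st1 = CellState(t=0.0, y=rest_state.y.copy(),
                        genes=dict(rest_state.genes), dsb=200)
        i = spec.index["mrn_act_n"]
        assert rhs(st1, spec)[i] > rhs(st0, spec)[i]


class TestTransport:
    def test_antisymmetry_single_term(self, spec, rest_state):
        """p53 nuclear import appears as -k*L in cytoplasm, +k*L nucleus."""
        tr = transport_terms(rest_state, spec)
        r = next(x for x in spec.reactions
                 if x.name == "p53 nuclear import")
        k = spec.parameters[r.k]
        L = rest_state.y[spec.index["p53_c"]]
        only = spec.copy()
        only.reactions = [x for x in only.reactions if x.transport]
        # the full transport contribution to p53_c is the sum of its
        # transport terms; check the import flux appears with both signs
        flux = k * L
        ic, in_ = spec.index["p53_c"], spec.index["p53_n"]
        assert tr[ic] == pytest.approx(-flux)
        assert tr[in_] == pytest.approx(+flux)

    def test_transport_conserves_mass_over_random_states(self, spec):
        """Summing transport contributions of a shuttled species over its
        compartments cancels exactly, for 100 random states."""
        shuttled = {}
        for r in spec.reactions:
            if r.transport:
                for sname, c in r.stoich:
                    shuttled.setdefault(r.name, []).append(spec.index[sname])
        for state in random_states(spec, 100, seed=3):
            tr = transport_terms(state, spec)
            for name, idxs in shuttled.items():
                assert abs(sum(tr[i] for i in idxs)) < 1e-9, name

    def test_zero_transport_decouples_compartments(self, spec, rest_state):
        notr = spec.copy()
        zeroed = {r.k for r in notr.reactions if r.transport}
        for p in zeroed:
            notr.parameters[p] = 0.0
        full = rhs(rest_state, notr)
        local = rhs(rest_state, notr, skip_transport=True)
        np.testing.assert_allclose(full, local, rtol=0, atol=1e-12)


class TestDecayConsistency:
    @pytest.mark.parametrize("pname,species", [
        ("k_deg_wip1", "wip1_n"),
        ("k_deg_mir16", "mir16_c"),
        ("k_deg_p53m", "p53_mrna_c"),
    ])
    def test_pure_decay_halves_in_half_life(self, spec, pname, species):
        """With all synthesis off, a species halves in ln2/k within 1 %
        using the engine's step size."""
        from ddrsim.engine import EngineConfig, simulate_cell
        from ddrsim.protocols import Protocol

        dead = spec.copy()
        i = dead.index[species]
        # strip every reaction except this species' first-order decays
        dead.reactions = [
            r for r in dead.reactions
            if r.kind == "lin" and r.s1 == species and r.k == pname
            and all(sn == species and c < 0 for sn, c in r.stoich)]
        assert dead.reactions, pname
        for g in dead.genes:
            dead.parameters[g.basal] = 0.0
        dead.parameters["k_dsb_bg"] = 0.0
        dead._resting = None

        t_half = np.log(2.0) / dead.parameters[pname]
        y0 = np.zeros(dead.n_species)
        y0[i] = 1.0e4
        cfg = EngineConfig(dt=0.1, save_every=max(0.1, round(t_half / 100)),
                           seed=0)
        prot = Protocol(name="decay", burn_in=0.0, horizon=t_half)
        traj = simulate_cell(dead, prot, cfg, y0=y0,
                             genes0=np.zeros(dead.n_genes, dtype=np.int64),
                             dsb0=0)
        final = traj.y[-1, i]
        assert final == pytest.approx(5.0e3, rel=1e-2)


class TestCellState:
    def test_gene_values_outside_alleles_rejected(self, spec, rest_state):
        bad = CellState(t=0.0, y=rest_state.y.copy(),
                        genes={**rest_state.genes, "wip1": 3})
        with pytest.raises(ValueError, match="wip1"):
            bad.validate()

    def test_negative_discrete_counts_rejected(self, spec, rest_state):
        bad = CellState(t=0.0, y=rest_state.y.copy(),
                        genes=dict(rest_state.genes), dsb=-1)
        with pytest.raises(ValueError):
            bad.validate()
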