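"""Event-channel propensity contracts and Markov-chain stationarity."""

import numpy as np
import pytest

from ddrsim.genes import (ContractViolation, dsb_channels,
                          gene_activation_propensity,
                          gene_deactivation_propensity,
                          tnf_receptor_channels)
from ddrsim.model import CellState
from tests.conftest import random_states


def _state(spec, rest_state, **kw):
    st = CellState(t=0.0, y=rest_state.y.copy(),
                   genes=dict(rest_state.genes),
                   dsb=rest_state.dsb,
                   receptors_active=rest_state.receptors_active)
    for k, v in kw.items():
        setattr(st, k, v)
    return st


class TestGeneActivation:
    def test_zero_regulators_no_basal_gives_zero(self, spec, rest_state):
        sv = spec.copy()
        gene = next(g for g in sv.genes if g.name == "wip1")
        sv.parameters[gene.basal] = 0.0
        st = _state(sv, rest_state)
        st.y[:] = 0.0
        st.genes["wip1"] = 0
        assert gene_activation_propensity(gene, st, sv) == 0.0

    def test_saturated_gene_has_zero_activation(self, spec, rest_state):
        gene = next(g for g in spec.genes if g.name == "wip1")
        st = _state(spec, rest_state)
        st.genes["wip1"] = 2
        assert gene_activation_propensity(gene, st, spec) == 0.0

    def test_wip1_activation_linear_in_p53(self, spec, rest_state):
        """Doubling active p53 doubles the p53-dependent component."""
        gene = next(g for g in spec.genes if g.name == "wip1")
        ip53 = spec.index["p53a_n"]
        st = _state(spec, rest_state)
        st.genes["wip1"] = 0

        st.y[ip53] = 0.0
        base = gene_activation_propensity(gene, st, spec)
        st.y[ip53] = 5000.0
        a1 = gene_activation_propensity(gene, st, spec)
        st.y[ip53] = 10000.0
        a2 = gene_activation_propensity(gene, st, spec)
        assert (a2 - base) == pytest.approx(2 * (a1 - base), rel=1e-12)

    def test_wip1_nfkb_arm_self_inhibited(self, spec, rest_state):
        """The NF-kB contribution shrinks as Wip1 protein rises; the
        p53 contribution is unaffected."""
        gene = next(g for g in spec.genes if g.name == "wip1")
        st = _state(spec, rest_state)
        st.genes["wip1"] = 0
        inf, iw = spec.index["nfkb_n"], spec.index["wip1_n"]
        st.y[inf] = 2.0e4

        st.y[iw] = 0.0
        hi = gene_activation_propensity(gene, st, spec)
        st.y[iw] = 1.0e6
        lo = gene_activation_propensity(gene, st, spec)
        assert lo < hi
        # with NF-kB removed, Wip1 level no longer matters
        st.y[inf] = 0.0
        st.y[iw] = 0.0
        a = gene_activation_propensity(gene, st, spec)
        st.y[iw] = 1.0e6
        b = gene_activation_propensity(gene, st, spec)
        assert a == pytest.approx(b, rel=1e-12)

    def test_chk2_activation_carries_p53_inhibition_factor(self, spec,
                                                           rest_state):
        """Chk2 activation rises with p53 at low levels but the
        p53-dependent inhibition bends it below linearity."""
        gene = next(g for g in spec.genes if g.name == "chk2")
        ip53 = spec.index["p53a_n"]
        st = _state(spec, rest_state)
        st.genes["chk2"] = 0
        st.y[ip53] = 0.0
        base = gene_activation_propensity(gene, st, spec)
        st.y[ip53] = 1000.0
        a1 = gene_activation_propensity(gene, st, spec)
        st.y[ip53] = 2000.0
        a2 = gene_activation_propensity(gene, st, spec)
        assert a1 > base
        assert (a2 - base) < 2 * (a1 - base)   # sub-linear

    def test_negative_regulator_rejected(self, spec, rest_state):
        gene = next(g for g in spec.genes if g.name == "wip1")
        st = _state(spec, rest_state)
        st.genes["wip1"] = 0
        st.y[spec.index["p53a_n"]] = -5.0
        with pytest.raises(ContractViolation):
            gene_activation_propensity(gene, st, spec)


class TestGeneDeactivation:
    def test_linear_in_active_alleles_and_regulator_independent(
            self, spec, rest_state):
        gene = next(g for g in spec.genes if g.name == "wip1")
        st = _state(spec, rest_state)
        st.genes["wip1"] = 0
        assert gene_deactivation_propensity(gene, st, spec) == 0.0
        st.genes["wip1"] = 1
        d1 = gene_deactivation_propensity(gene, st, spec)
        st.genes["wip1"] = 2
        d2 = gene_deactivation_propensity(gene, st, spec)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)
        st.y[:] *= 7.0   # deactivation is spontaneous: levels irrelevant
        assert gene_deactivation_propensity(gene, st, spec) == d2


class TestDsbChannels:
    def test_quiet_limit(self, spec, rest_state):
        sv = spec.copy()
        sv.parameters["k_dsb_bg"] = 0.0
        st = _state(sv, rest_state, dsb=0)
        ind, rep = dsb_channels(0.0, st, sv)
        assert ind == 0.0 and rep == 0.0

    def test_delivery_window_and_poisson_dispersion(self, spec, rest_state):
        """An acute dose d gives ~Poisson(dsb_per_gy * d) break counts:
        10 Gy at 1 Gy/min means exactly 600 s of elevated induction."""
        from ddrsim.protocols import make_protocol

        prot = make_protocol("ir_only", dose=10.0)
        assert prot.ir_duration == pytest.approx(600.0)

        sv = spec.copy()
        sv.parameters["k_dsb_bg"] = 0.0
        sv.parameters["vmax_repair"] = 0.0   # count induction only
        st = _state(sv, rest_state, dsb=0)
        rate_gy_s = 10.0 / 600.0
        ind, _ = dsb_channels(rate_gy_s, st, sv)
        lam = ind * 600.0
        assert lam == pytest.approx(sv.parameters["dsb_per_gy"] * 10.0)

        rng = np.random.default_rng(5)
        draws = rng.poisson(lam, size=1000)
        assert np.mean(draws) == pytest.approx(lam, rel=0.05)
        assert np.var(draws) == pytest.approx(np.mean(draws), rel=0.15)

    def test_repair_proportional_to_load_at_low_counts(self, spec,
                                                       rest_state):
        st1 = _state(spec, rest_state, dsb=1)
        st2 = _state(spec, rest_state, dsb=2)
        _, r1 = dsb_channels(0.0, st1, spec)
        _, r2 = dsb_channels(0.0, st2, spec)
        km = spec.parameters["km_repair"]
        assert r2 / r1 == pytest.approx(2 * (km + 1) / (km + 2), rel=1e-12)


class TestReceptorChannels:
    def test_zero_tnf_and_saturation(self, spec, rest_state):
        st = _state(spec, rest_state, receptors_active=0)
        act, deact = tnf_receptor_channels(0.0, st, spec)
        assert act == 0.0 and deact == 0.0
        st.receptors_active = int(spec.parameters["n_receptors"])
        act, _ = tnf_receptor_channels(10.0, st, spec)
        assert act == 0.0

    def test_stationary_fraction_matches_two_state_chain(self, spec,
                                                         rest_state):
        """Long-run active fraction at constant TNF equals a/(a+d) per
        receptor (binomial closed form), via direct simulation of the
        receptor channel alone."""
        tnf = 10.0
        a = spec.parameters["k_rec_on"] * tnf
        d = spec.parameters["k_rec_off"]
        expect = a / (a + d)

        n_rec = int(spec.parameters["n_receptors"])
        rng = np.random.default_rng(11)
        st = _state(spec, rest_state, receptors_active=0)
        t, t_end = 0.0, 3.0e5
        occ_time = 0.0
        weight = 0.0
        burn = 5.0e4
        while t < t_end:
            act, deact = tnf_receptor_channels(tnf, st, spec)
            total = act + deact
            tau = rng.exponential(1.0 / total)
            if t > burn:
                occ_time += st.receptors_active * min(tau, t_end - t)
                weight += min(tau, t_end - t)
            if rng.random() * total < act:
                st.receptors_active += 1
            else:
                st.receptors_active -= 1
            t += tau
        frac = occ_time / weight / n_rec
        assert frac == pytest.approx(expect, abs=0.02)


class TestPropensityProperties:
    def test_all_propensities_nonnegative_over_random_states(self, spec):
        for st in random_states(spec, 50, seed=9):
            for gene in spec.genes:
                assert gene_activation_propensity(gene, st, spec) >= 0
                assert gene_deactivation_propensity(gene, st, spec) >= 0
            ind, rep = dsb_channels(0.01, st, spec)
            assert ind >= 0 and rep >= 0
            a, d = tnf_receptor_channels(5.0, st, spec)
            assert a >= 0 and d >= 0

    def test_gene_toggle_stationary_occupancy_matches_chain(self):
        """Empirical allele occupancy converges to the analytic 3-state
        chain stationary law (chi-square GOF over ~1e5 events)."""
        from scipy import stats as sps

        from ddrsim.fixtures import make_gene_toggle

        a, d = 3.0e-3, 1.5e-3
        toy = make_gene_toggle(a, d)
        p = a / (a + d)
        expect = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])

        # exact SSA on the 3-state chain, occupancy measured in time
        rng = np.random.default_rng(21)
        g, t = 0, 0.0
        occ = np.zeros(3)
        n_events = 0
        while n_events < 100_000:
            act = a * (2 - g)
            dea = d * g
            tot = act + dea
            tau = rng.exponential(1.0 / tot)
            occ[g] += tau
            g = g + 1 if rng.random() * tot < act else g - 1
            n_events += 1
        frac = occ / occ.sum()
        chi2 = occ.sum() * np.sum((frac - expect) ** 2 / expect)
        # time-weighted occupancy: compare fractions loosely
        np.testing.assert_allclose(frac, expect, atol=0.02)
        assert toy.analytic["mean_state"] == pytest.approx(2 * p)
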