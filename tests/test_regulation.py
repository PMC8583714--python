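"""Fuzzy controller: inference, neighborhood kernel and state updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosim import Geometry, build_mesh
from dosim.regulation import (RegulationInput, RegulationOutput, RuleBase,
                              apply_regulation, evaluate_rules,
                              neighborhood_aggregate, perfusion_source_field)


def make_input(**kw):
    base = dict(eps_dil=0.0, gamma_dist=0.0, perfusion=0.0, c_cart=0.0,
                c_bone=0.0, neighbor_perfusion=0.0, neighbor_bone=0.0)
    base.update(kw)
    return RegulationInput(**{k: np.atleast_1d(float(v))
                              for k, v in base.items()})


class TestNeighborhoodAggregate:
    def test_uniform_field(self):
        mesh = build_mesh(Geometry(12, 16, 4.0, 0.0, 4.0), 0.5)
        out = neighborhood_aggregate(mesh, np.full(mesh.n_elements, 100.0), 0.5)
        np.testing.assert_allclose(out, 100.0)

    def test_all_neighbors_zero(self):
        mesh = build_mesh(Geometry(12, 16, 4.0, 0.0, 4.0), 0.5)
        f = np.zeros(mesh.n_elements)
        f[5] = 100.0  # the element itself is excluded from its own average
        out = neighborhood_aggregate(mesh, f, 0.5)
        far = np.ones(mesh.n_elements, bool)
        cen = mesh.centroids()
        far &= np.linalg.norm(cen - cen[5], axis=1) > 1.5
        assert np.all(out[far] == 0.0)

    def test_cortex_seeds_gap_edge(self):
        """Cortex at 100 % perfusion feeds only the gap-adjacent elements."""
        mesh = build_mesh(Geometry(12, 16, 1.0, 30.0, 8.0), 0.5)
        perf = np.where(mesh.region == 2, 0.0, 100.0)
        src = perfusion_source_field(mesh, perf)
        agg = neighborhood_aggregate(mesh, src, 0.5)
        cal = mesh.callus
        z = mesh.centroids()[cal, 1] - 30.0
        edge = z < 0.75
        mid = np.abs(z - 4.0) < 1.0
        assert agg[cal][edge].min() > 10.0
        assert np.allclose(agg[cal][mid], 0.0)

    def test_invalid_sigma(self):
        mesh = build_mesh(Geometry(12, 16, 4.0, 0.0, 4.0), 1.0)
        with pytest.raises(ValueError):
            neighborhood_aggregate(mesh, np.zeros(mesh.n_elements), 0.0)


class TestEvaluateRules:
    def test_favorable_window_forms_bone(self, rules):
        out = evaluate_rules(make_input(eps_dil=1.0, gamma_dist=5.0,
                                        perfusion=90.0, neighbor_bone=80.0,
                                        neighbor_perfusion=80.0), rules)
        assert out.d_bone[0] > 0
        assert not out.destroyed[0]

    def test_destructive_state(self, rules):
        out = evaluate_rules(make_input(eps_dil=5.0, gamma_dist=35.0), rules)
        assert out.destroyed[0]
        assert out.d_perfusion[0] <= 0

    def test_quiescent_state(self, rules):
        out = evaluate_rules(make_input(), rules)
        assert out.d_perfusion[0] == 0
        assert out.d_cart[0] == 0
        assert out.d_bone[0] == 0
        assert not out.destroyed[0]

    def test_no_spontaneous_generation(self, rules):
        """No perfusion anywhere nearby: bone cannot appear."""
        out = evaluate_rules(make_input(eps_dil=1.0, gamma_dist=8.0,
                                        perfusion=0.0, neighbor_perfusion=0.0,
                                        neighbor_bone=0.0), rules)
        assert out.d_bone[0] == 0
        assert out.d_perfusion[0] == 0

    def test_bone_rate_monotone_in_perfusion(self, rules):
        rates = []
        for p in np.linspace(0, 100, 21):
            out = evaluate_rules(make_input(eps_dil=1.0, gamma_dist=8.0,
                                            perfusion=p, neighbor_bone=80.0,
                                            neighbor_perfusion=80.0), rules)
            rates.append(out.d_bone[0])
        assert np.all(np.diff(rates) >= -1e-12)

    def test_destruction_dominance(self, rules):
        """Beyond the disruptive thresholds nothing anabolic happens."""
        for eps, gam in [(4.0, 25.0), (6.0, 35.0), (10.0, 50.0)]:
            out = evaluate_rules(make_input(eps_dil=eps, gamma_dist=gam,
                                            perfusion=90.0, c_cart=50.0,
                                            neighbor_perfusion=90.0,
                                            neighbor_bone=90.0), rules)
            assert out.destroyed[0]
            assert out.d_bone[0] <= 0
            assert out.d_perfusion[0] <= 0

    def test_weak_stimulus_grows_slower(self, rules):
        """Very low distortion stimulates less than the moderate band."""
        weak = evaluate_rules(make_input(eps_dil=1.0, gamma_dist=1.0,
                                         perfusion=90.0, neighbor_bone=80.0,
                                         neighbor_perfusion=80.0), rules)
        strong = evaluate_rules(make_input(eps_dil=1.0, gamma_dist=8.0,
                                           perfusion=90.0, neighbor_bone=80.0,
                                           neighbor_perfusion=80.0), rules)
        assert 0 < weak.d_bone[0] < strong.d_bone[0]

    def test_chondrogenesis_band(self, rules):
        out = evaluate_rules(make_input(eps_dil=1.0, gamma_dist=18.0), rules)
        assert out.d_cart[0] > 0

    def test_rule_base_roundtrip(self, rules):
        clone = RuleBase.from_dict(rules.to_dict())
        inp = make_input(eps_dil=1.0, gamma_dist=8.0, perfusion=90.0,
                         neighbor_bone=80.0, neighbor_perfusion=80.0)
        a = evaluate_rules(inp, rules)
        b = evaluate_rules(inp, clone)
        np.testing.assert_allclose(a.d_bone, b.d_bone)
        np.testing.assert_allclose(a.d_perfusion, b.d_perfusion)


class TestApplyRegulation:
    def _out(self, n=1, d_perf=0.0, d_cart=0.0, d_bone=0.0, destroyed=False):
        return RegulationOutput(
            d_perfusion=np.full(n, d_perf), d_cart=np.full(n, d_cart),
            d_bone=np.full(n, d_bone),
            destroyed=np.full(n, destroyed, dtype=bool))

    def test_bone_bookkeeping(self):
        conc = np.array([[50.0, 0.0, 50.0, 0.0]])
        new, _ = apply_regulation(conc, np.array([80.0]), self._out(d_bone=10.0))
        np.testing.assert_allclose(new[0], [40.0, 0.0, 60.0, 0.0])

    def test_destruction_resets_element(self):
        conc = np.array([[10.0, 30.0, 60.0, 0.0]])
        new, perf = apply_regulation(conc, np.array([90.0]),
                                     self._out(destroyed=True))
        np.testing.assert_allclose(new[0], [100.0, 0.0, 0.0, 0.0])
        assert perf[0] == 0.0

    def test_cartilage_calcifies_to_bone(self):
        """Repeated calcification converts the cartilage stock into bone."""
        conc = np.array([[60.0, 40.0, 0.0, 0.0]])
        perf = np.array([90.0])
        for _ in range(4):
            conc, perf = apply_regulation(conc, perf,
                                          self._out(d_cart=-10.0, d_bone=10.0))
        # all 40 % cartilage has become bone; connective tissue untouched
        np.testing.assert_allclose(conc[0], [60.0, 0.0, 40.0, 0.0], atol=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        cart0=st.floats(0, 50), bone0=st.floats(0, 50),
        d_perf=st.floats(-10, 10), d_cart=st.floats(-10, 10),
        d_bone=st.floats(-10, 10), perf0=st.floats(0, 100))
    def test_conservation_and_bounds(self, cart0, bone0, d_perf, d_cart,
                                     d_bone, perf0):
        conn0 = 100.0 - cart0 - bone0
        conc = np.array([[conn0, cart0, bone0, 0.0]])
        new, perf = apply_regulation(
            conc, np.array([perf0]),
            self._out(d_perf=d_perf, d_cart=d_cart, d_bone=d_bone))
        assert new.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(new >= -1e-9)
        assert 0.0 <= perf[0] <= 100.0

    def test_invalid_concentrations_rejected(self):
        with pytest.raises(ValueError):
            apply_regulation(np.array([[50.0, 0.0, 30.0, 0.0]]),
                             np.array([0.0]), self._out())
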