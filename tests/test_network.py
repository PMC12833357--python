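"""Connectivity: in-degree rule, nearest-neighbor wiring, weights,
enhancement, full network construction."""

import numpy as np
import pandas as pd
import pytest

from tcnet import tables
from tcnet.network import (NetworkConfig, PopulationLayout, apply_enhancement,
                           build_network, connect, in_degree)

# every printed in-degree for the default 75-25 layout
TABLE1 = {
    ("RS", "RS"): 11, ("RS", "IB"): 4, ("RS", "NRS"): 4, ("RS", "LTS"): 3,
    ("IB", "IB"): 11, ("IB", "RS"): 11, ("IB", "NRS"): 11, ("IB", "LTS"): 9,
    ("NRS", "NRS"): 11, ("NRS", "RS"): 11, ("NRS", "IB"): 11,
    ("NRS", "LTS"): 9, ("NRS", "TC"): 16, ("NRS", "RE"): 16,
    ("LTS", "RS"): 11, ("LTS", "IB"): 11, ("LTS", "NRS"): 11,
    ("TC", "RE"): 11, ("TC", "NRS"): 21, ("TC", "IB"): 21, ("TC", "RS"): 21,
    ("TC", "LTS"): 21, ("RE", "RE"): 11, ("RE", "TC"): 11,
}


class TestInDegree:
    def test_reproduces_all_24_published_entries(self):
        layout = PopulationLayout.default()
        for (pre, post), expected in TABLE1.items():
            base = tables.base_radius(pre, post)
            got = in_degree(base, layout.counts[pre], layout.counts[post])
            assert got == expected, f"{pre}->{post}: {got} != {expected}"

    @pytest.mark.parametrize("n_ib,n_rs", [(95, 5), (5, 95), (50, 50)])
    def test_alternate_compositions_stay_in_bounds(self, n_ib, n_rs):
        layout = PopulationLayout.default(n_ib, n_rs)
        for pre, n_pre in layout.counts.items():
            for post, n_post in layout.counts.items():
                base = tables.base_radius(pre, post)
                n = in_degree(base, n_pre, n_post)
                assert 1 <= n <= min(base, n_pre)


class TestConnect:
    def test_interior_re_cell_receives_exact_in_degree_and_weight(self):
        net = build_network(NetworkConfig())
        proj = net.projection("RE", "RE", "GABA_A")
        edges = proj.edges
        inbound = edges[edges[:, 0] == 50]
        assert len(inbound) == 11
        assert proj.weight == pytest.approx(0.2 / 11)
        assert 50 not in inbound[:, 1]  # no self-edge

    def test_edge_cells_keep_full_in_degree(self):
        pos = np.arange(100) / 99.0
        edges = connect(pos, pos, 11, same_class=True)
        counts = np.bincount(edges[:, 0], minlength=100)
        assert (counts == 11).all()
        assert len(edges) == 100 * 11

    def test_ties_break_toward_lower_index(self):
        pre = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        post = np.array([0.5])
        edges = connect(pre, post, 3)
        # cell at 0.5 is nearest; 0.25 and 0.75 tie, both taken; next tie
        # (0.0 vs 1.0) resolves to index 0
        assert sorted(edges[:, 1]) == [1, 2, 3]
        edges = connect(pre, post, 4)
        assert sorted(edges[:, 1]) == [0, 1, 2, 3]

    def test_oversubscribed_in_degree_rejected(self):
        pos = np.arange(5) / 4.0
        with pytest.raises(ValueError):
            connect(pos, pos, 5, same_class=True)


class TestEnhancement:
    def test_stated_factors_scale_frontocortical_projections(self):
        tab = apply_enhancement(tables.synapse_table(), (7.0, 5.0, 3.0))
        def g(pre, post):
            m = (tab["pre"] == pre) & (tab["post"] == post)
            return float(tab.loc[m, "gbar"].iloc[0])
        assert g("IB", "IB") == pytest.approx(0.3 * 7)
        assert g("IB", "NRS") == pytest.approx(0.05 * 5)
        assert g("NRS", "IB") == pytest.approx(0.3 * 3)
        # everything else untouched
        assert g("NRS", "NRS") == pytest.approx(2.0)

    def test_unit_factors_are_identity(self):
        tab = apply_enhancement(tables.synapse_table(), (1.0, 1.0, 1.0))
        pd.testing.assert_frame_equal(tab, tables.synapse_table())

    def test_factors_below_one_rejected(self):
        with pytest.raises(ValueError):
            apply_enhancement(tables.synapse_table(), (0.5, 1.0, 1.0))


class TestBuildNetwork:
    def test_default_network_has_475_cells_and_full_projection_set(self):
        net = build_network(NetworkConfig())
        assert net.n_cells == 475
        assert len(net.projections) == 28
        # RE->TC carries both GABA_A and GABA_B
        net.projection("RE", "TC", "GABA_A")
        net.projection("RE", "TC", "GABA_B")
        # LTS->pyramids carry both receptor types
        for post in ("RS", "IB", "NRS"):
            net.projection("LTS", post, "GABA_A")
            net.projection("LTS", post, "GABA_B")

    def test_alternate_composition_total_conserved(self):
        net = build_network(NetworkConfig(n_ib=50, n_rs=50))
        assert net.layout.counts["IB"] == 50
        assert net.layout.counts["RS"] == 50
        assert net.n_cells == 475

    def test_lts_receives_no_inhibition_and_thalamus_no_lts_input(self):
        net = build_network(NetworkConfig())
        for p in net.projections:
            if p.post_class == "LTS":
                assert p.synapse.receptor == "AMPA"
            if p.post_class in ("TC", "RE"):
                assert p.pre_class in ("NRS", "TC", "RE")
            assert (p.pre_class, p.post_class) != ("LTS", "LTS")

    def test_inbound_weight_sum_equals_gbar(self):
        """Weight normalization: summed inbound conductance for one
        projection equals gbar regardless of in-degree."""
        net = build_network(NetworkConfig(enhancement=(7.0, 5.0, 3.0)))
        for p in net.projections:
            inbound = (p.edges[:, 0] == 0).sum()
            total = inbound * p.weight
            expected = p.synapse.g_effective
            assert total == pytest.approx(expected, rel=1e-9), \
                f"{p.pre_class}->{p.post_class}"

    def test_mutation_scales_only_cortical_pyramidal_gaba_a(self):
        net = build_network(NetworkConfig(cortical_gaba_fraction=0.1))
        for p in net.projections:
            if p.synapse.receptor == "GABA_A" and p.post_class in ("RS", "IB", "NRS"):
                assert p.synapse.gaba_scale == pytest.approx(0.1)
            else:
                assert p.synapse.gaba_scale == 1.0

    def test_allo_transforms_every_gaba_a_and_only_gaba_a(self):
        net = build_network(NetworkConfig(allo=True))
        ref = build_network(NetworkConfig())
        for p, q in zip(net.projections, ref.projections):
            if p.synapse.receptor == "GABA_A":
                assert p.synapse.variant == "post-ALLO"
                assert p.synapse.alpha == pytest.approx(q.synapse.alpha * 1.58)
            else:
                assert p.synapse.variant == "Control"
                assert p.synapse.alpha == q.synapse.alpha

    def test_build_is_deterministic(self):
        a = build_network(NetworkConfig(n_ib=95, n_rs=5)).edge_table()
        b = build_network(NetworkConfig(n_ib=95, n_rs=5)).edge_table()
        pd.testing.assert_frame_equal(a, b)


class TestTableIO:
    def test_roundtrip(self, tmp_path):
        paths = tables.write_tables(tmp_path)
        back = tables.read_synapse_table(paths[0])
        pd.testing.assert_frame_equal(back, tables.synapse_table())

    def test_parameter_matrix_shape(self):
        m = tables.parameter_matrix("gbar")
        assert m.loc["NRS", "RE"] == pytest.approx(2.4)
        assert np.isnan(m.loc["RE", "RS"])
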