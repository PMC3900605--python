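"""Generators: reproducibility and the statistical structure they promise."""

import dendropy
import numpy as np
import pytest

from phagekit.kinetics import TiterSeries
from phagekit.simulate import (
    ADSORPTION_DESIGN,
    ONE_STEP_DESIGN,
    AdsorptionParams,
    CommunityConfig,
    OneStepParams,
    SeriesDesign,
    pairwise_identity,
    simulate_collapsed_assembly,
    simulate_marker_families,
    simulate_phage_community,
    simulate_titer_series,
)
from phagekit.congruence import random_binary_tree
from phagekit.trees import alignment_distance_matrix, nj_tree


class TestCommunity:
    def test_zero_within_rate_gives_identical_group_members(self):
        cfg = CommunityConfig(
            within_rate=0.0, between_rate=0.3, accessory_turnover=0.0, seed=1
        )
        truth = simulate_phage_community(cfg)
        for gname in ("GA", "GB", "GC"):
            members = [g for g in truth.genomes if truth.group_of(g.id) == gname]
            assert all(m.sequence == members[0].sequence for m in members)

    def test_within_identity_exceeds_between_identity(self):
        truth = simulate_phage_community(
            CommunityConfig(within_rate=0.05, between_rate=0.45, seed=7)
        )
        within, between = [], []
        ingroup = [g for g in truth.genomes if g.id != "outgroup"]
        for i in range(len(ingroup)):
            for j in range(i + 1, len(ingroup)):
                ident = pairwise_identity(ingroup[i].sequence, ingroup[j].sequence)
                same = truth.group_of(ingroup[i].id) == truth.group_of(ingroup[j].id)
                (within if same else between).append(ident)
        assert np.mean(within) > np.mean(between)

    def test_rejects_between_rate_not_above_within(self):
        with pytest.raises(ValueError, match="between_rate"):
            CommunityConfig(within_rate=0.2, between_rate=0.2)

    def test_fixed_seed_reproduces_bit_identical_output(self):
        a = simulate_phage_community(CommunityConfig(seed=3))
        b = simulate_phage_community(CommunityConfig(seed=3))
        assert [g.sequence for g in a.genomes] == [g.sequence for g in b.genomes]
        assert a.group_labels == b.group_labels

    def test_outgroup_has_its_own_label_and_tree_has_all_leaves(self, community):
        assert community.group_labels["outgroup"] == "outgroup"
        leaves = {l.taxon.label for l in community.generating_tree.leaf_node_iter()}
        assert leaves == {g.id for g in community.genomes}


class TestCollapsedAssembly:
    def test_zero_reads_gives_all_zero_coverage(self):
        _, prof, _ = simulate_collapsed_assembly(30000, 2000, 0, 400, seed=0)
        assert np.all(prof.depth == 0)

    def test_repeat_region_carries_about_double_depth(self):
        _, prof, truth = simulate_collapsed_assembly(30000, 2000, 20000, 400, seed=1)
        inside = prof.depth[truth.ltr_start - 1 : truth.ltr_end].mean()
        outside = prof.depth[truth.ltr_end :].mean()
        assert 1.8 <= inside / outside <= 2.2

    def test_repeat_interior_is_flat_doubling_not_a_spike(self):
        _, prof, truth = simulate_collapsed_assembly(30000, 2000, 20000, 400, seed=1)
        rl = truth.read_length
        interior = prof.depth[truth.ltr_start - 1 + rl : truth.ltr_end - rl]
        outside = prof.depth[truth.ltr_end + rl : -rl]
        ratio = np.median(interior) / np.median(outside)
        assert 1.85 <= ratio <= 2.15
        # flat: interior quartiles stay near the interior median
        q1, q3 = np.percentile(interior, [25, 75])
        assert (q3 - q1) / np.median(interior) < 0.3

    def test_rejects_reads_longer_than_repeat(self):
        with pytest.raises(ValueError, match="read_length"):
            simulate_collapsed_assembly(30000, 2000, 100, 2500, seed=0)
        with pytest.raises(ValueError, match="ltr_length"):
            simulate_collapsed_assembly(30000, 16000, 100, 400, seed=0)


class TestMarkers:
    def test_zero_rate_gives_identical_sequences(self):
        tree = random_binary_tree([f"t{i}" for i in range(6)], seed=1)
        fams = simulate_marker_families(tree, 2, 100, 0.0, seed=0)
        for fam in fams:
            seqs = list(fam.values())
            assert all(s == seqs[0] for s in seqs)

    def test_nj_recovers_generating_topology_at_high_site_count(self):
        tree = random_binary_tree([f"t{i}" for i in range(8)], seed=5)
        fams = simulate_marker_families(tree, 2, 2000, 0.05, seed=2)
        tns = dendropy.TaxonNamespace()
        ref = dendropy.Tree.get(
            data=tree.as_string(schema="newick"), schema="newick", taxon_namespace=tns
        )
        for fam in fams:
            nj = nj_tree(alignment_distance_matrix(fam))
            nj2 = dendropy.Tree.get(
                data=nj.as_string(schema="newick"), schema="newick", taxon_namespace=tns
            )
            rf = dendropy.calculate.treecompare.symmetric_difference(ref, nj2)
            assert rf == 0

    def test_markers_from_different_topologies_disagree(self):
        labels = [f"t{i}" for i in range(8)]
        t1 = random_binary_tree(labels, seed=1)
        t2 = random_binary_tree(labels, seed=9)
        f1 = simulate_marker_families(t1, 1, 2000, 0.05, seed=3)[0]
        f2 = simulate_marker_families(t2, 1, 2000, 0.05, seed=4)[0]
        tns = dendropy.TaxonNamespace()
        trees = []
        for fam in (f1, f2):
            nj = nj_tree(alignment_distance_matrix(fam))
            trees.append(
                dendropy.Tree.get(
                    data=nj.as_string(schema="newick"), schema="newick",
                    taxon_namespace=tns,
                )
            )
        assert dendropy.calculate.treecompare.symmetric_difference(*trees) > 0


class TestTiterSeries:
    def test_noise_free_adsorption_matches_closed_form(self):
        params = AdsorptionParams(p0=1e6, k=6.44e-9, b=3e8)
        design = SeriesDesign(times=(0, 1, 2), replicates=1, cv=0.0)
        s = simulate_titer_series("adsorption", params, design, seed=0)
        ratio = s.pfu[0, 2] / s.pfu[0, 0]
        assert ratio == pytest.approx(np.exp(-6.44e-9 * 3e8 * 2), rel=1e-12)
        assert ratio == pytest.approx(0.0210, abs=2e-4)

    def test_noise_free_one_step_plateau_equals_burst_times_initial(self):
        params = OneStepParams(burst=100.0)
        design = SeriesDesign(times=tuple(range(0, 81, 10)), replicates=1, cv=0.0)
        total, _ = simulate_titer_series("one_step", params, design, seed=0)
        assert total.pfu[0, -1] / total.pfu[0, 0] == pytest.approx(100.0)

    def test_fixed_seed_regenerates_identically(self):
        a = simulate_titer_series("adsorption", AdsorptionParams(), ADSORPTION_DESIGN, seed=5)
        b = simulate_titer_series("adsorption", AdsorptionParams(), ADSORPTION_DESIGN, seed=5)
        assert np.array_equal(a.pfu, b.pfu)
        t1 = simulate_titer_series("one_step", OneStepParams(), ONE_STEP_DESIGN, seed=5)
        t2 = simulate_titer_series("one_step", OneStepParams(), ONE_STEP_DESIGN, seed=5)
        assert np.array_equal(t1[0].pfu, t2[0].pfu)
        assert np.array_equal(t1[1].pfu, t2[1].pfu)

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            AdsorptionParams(k=-1e-9)
        with pytest.raises(ValueError):
            OneStepParams(burst=-5)

    def test_series_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TiterSeries(times=[0, 0, 1], pfu=[[1, 1, 1]])
        with pytest.raises(ValueError, match="positive"):
            TiterSeries(times=[0, 1], pfu=[[1, 0]])
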