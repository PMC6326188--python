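"""Superposition, contacts, rewiring, proximity and summary statistics."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ssapdiv import (AlignmentMap, ContactNetwork, PreferenceProfile,
                     build_contacts, compare_contacts,
                     divergence_binned_summary, ensemble_contact_frequency,
                     network_proximity_test, sequence_divergence, site_entropy,
                     srmsd, superpose)
from ssapdiv.io_formats import Residue, SiteRecord, StructureModel, ValidationError
from ssapdiv.synthetic_data import generate_toy_structure


def _transformed(model, R, t):
    residues = [Residue(r.number, r.aa,
                        {n: R @ xyz + t for n, xyz in r.atoms.items()})
                for r in model.residues]
    return StructureModel(model.structure_id + "_t", model.chain_id, residues)


class TestSuperpose:
    def test_identical_structures(self):
        st = generate_toy_structure(15, "helix", seed=0)
        res = superpose(st, st)
        assert res.alignment.n_pairs == 15
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        assert res.paired_ca_distances.max() < 1e-9
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_recovers_known_rotation(self):
        st = generate_toy_structure(20, "two_helix_bundle", seed=1)
        R = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        moved = _transformed(st, R, t)
        res = superpose(st, moved)
        # the fit maps B onto A, so the recovered rotation is Rᵀ
        np.testing.assert_allclose(res.rotation, R.T, atol=1e-6)
        assert res.paired_ca_distances.max() < 1e-6

    def test_displaced_residue_unpaired(self):
        st = generate_toy_structure(15, "helix", seed=2)
        moved = _transformed(st, np.eye(3), np.zeros(3))
        for name in moved.residues[7].atoms:
            moved.residues[7].atoms[name] = moved.residues[7].atoms[name] + \
                np.array([30.0, 0.0, 0.0])
        res = superpose(st, moved)
        assert 7 in res.alignment.unpaired_b
        assert res.alignment.n_pairs == 14

    def test_too_few_atoms_rejected(self):
        st = generate_toy_structure(4, "helix", seed=3)
        tiny = StructureModel("t", "A", st.residues[:2])
        with pytest.raises(ValidationError):
            superpose(tiny, st)


class TestSrmsd:
    def test_mean_of_distances(self):
        assert srmsd(AlignmentMap([(0, 0, 1.0), (1, 1, 3.0)])) == pytest.approx(2.0)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValidationError):
            srmsd(AlignmentMap([]))

    def test_matches_mean_oracle(self, rng):
        d = rng.uniform(0, 3.5, size=25)
        am = AlignmentMap([(i, i, float(x)) for i, x in enumerate(d)])
        assert srmsd(am) == pytest.approx(float(np.mean(d)), abs=1e-12)

    def test_rigid_motion_invariance(self):
        """Applying one rigid transform to both structures leaves the
        superposition-derived sRMSD unchanged."""
        a = generate_toy_structure(18, "two_helix_bundle", seed=4)
        b = generate_toy_structure(18, "two_helix_bundle", seed=4)
        for i, res in enumerate(b.residues):  # small deterministic deformation
            shift = np.array([0.2 * math.sin(i), 0.2 * math.cos(i), 0.1])
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + shift
        base = srmsd(superpose(a, b).alignment)
        R = Rotation.from_euler("zyx", [17, 123, -55], degrees=True).as_matrix()
        t = np.array([-4.0, 9.0, 1.0])
        moved = srmsd(superpose(_transformed(a, R, t), _transformed(b, R, t)).alignment)
        assert moved == pytest.approx(base, abs=1e-6)


def _two_residue_structure(d, sidechain=True):
    """Two residues whose closest atoms (CB side chains or backbone O/N) are
    exactly ``d`` Å apart; Cα atoms are kept far apart."""
    r1 = Residue(1, "A", {"CA": np.array([0.0, 0.0, 0.0]),
                          "CB": np.array([0.0, 0.0, 2.0])})
    if sidechain:
        r2 = Residue(2, "A", {"CA": np.array([10.0, 0.0, 0.0]),
                              "CB": np.array([0.0, d, 2.0])})
    else:
        r1.atoms["O"] = np.array([5.0, 0.0, 0.0])
        r2 = Residue(2, "A", {"CA": np.array([20.0, 0.0, 0.0]),
                              "N": np.array([5.0, d, 0.0])})
    return StructureModel("pair", "A", [r1, r2])


class TestContacts:
    def test_sidechain_threshold_inclusive(self):
        assert _contact_present(_two_residue_structure(3.4), "sidechain_3p5")
        assert not _contact_present(_two_residue_structure(3.6), "sidechain_3p5")

    def test_backbone_contact_only_in_allatom_dialect(self):
        st = _two_residue_structure(3.3, sidechain=False)
        assert _contact_present(st, "allatom_3p5")
        assert not _contact_present(st, "sidechain_3p5")

    def test_glycine_contributes_no_sidechain_atoms(self):
        st = _two_residue_structure(3.0)
        st.residues[1].aa = "G"
        del st.residues[1].atoms["CB"]
        assert not _contact_present(st, "sidechain_3p5")

    def test_exclude_sequential_option(self):
        st = _two_residue_structure(3.0)
        net = build_contacts(st, "sidechain_3p5", exclude_sequential=True)
        assert net.n_edges == 0

    def test_ensemble_frequency(self):
        base = _two_residue_structure(3.0)
        apart = _two_residue_structure(5.0)
        net = ensemble_contact_frequency([base, base, base, apart],
                                         "sidechain_3p5")
        assert net.edges[(0, 1)] == pytest.approx(0.25 * 3)
        single = ensemble_contact_frequency([base], "sidechain_3p5")
        assert single.edges == build_contacts(base, "sidechain_3p5").edges

    def test_ensemble_equals_mean_of_indicators(self):
        models = [generate_toy_structure(12, "helix", seed=s) for s in range(3)]
        # same geometry, different sequences: perturb coordinates per model
        for k, m in enumerate(models):
            for res in m.residues:
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + 0.3 * k
        # rebuild with identical sequence so residue identity matches
        net = ensemble_contact_frequency(models, "allatom_3p5")
        indicators = {}
        for m in models:
            for e in build_contacts(m, "allatom_3p5").edges:
                indicators[e] = indicators.get(e, 0) + 1
        for e, c in indicators.items():
            assert net.edges[e] == pytest.approx(c / 3)

    def test_inconsistent_numbering_rejected(self):
        a = generate_toy_structure(8, "helix", seed=0)
        b = generate_toy_structure(9, "helix", seed=0)
        with pytest.raises(ValidationError, match="numbering"):
            ensemble_contact_frequency([a, b], "allatom_3p5")


def _contact_present(st, dialect):
    return (0, 1) in build_contacts(st, dialect).edges


def _net(edges, nodes=None):
    e = {tuple(sorted(p)): 1.0 for p in edges}
    n = set(nodes) if nodes is not None else {x for p in e for x in p}
    return ContactNetwork(n, e, "allatom_3p5")


class TestCompareContacts:
    def test_worked_counts_close_pair(self):
        """Totals (gained 16, lost 23, conserved 118) pool to a rewired
        fraction of 0.248, i.e. 25% of contacts lost or gained."""
        cmp_res = _comparison_from_counts(16, 23, 118)
        assert cmp_res.totals == (2 * 16, 2 * 23, 2 * 118)
        assert round(100 * cmp_res.pooled_rewired_fraction) == 25

    def test_worked_counts_divergent_pair(self):
        cmp_res = _comparison_from_counts(31, 36, 105)
        assert round(100 * cmp_res.pooled_rewired_fraction) == 39

    def test_identical_networks_fully_conserved(self):
        net = _net([(0, 1), (1, 2), (2, 3)])
        aln = AlignmentMap.identity(4)
        res = compare_contacts(net, net, aln, "AAAA", "AAAA")
        assert all(sc.f_r == 0.0 for sc in res.per_site if sc.f_r is not None)
        assert res.totals[0] == res.totals[1] == 0

    def test_fr_symmetric_under_homolog_swap(self):
        na = _net([(0, 1), (1, 2)], nodes=range(4))
        nb = _net([(0, 1), (2, 3)], nodes=range(4))
        aln = AlignmentMap.identity(4)
        fwd = compare_contacts(na, nb, aln, "AAAA", "AAAA")
        rev = compare_contacts(nb, na, aln, "AAAA", "AAAA")
        for f, r in zip(fwd.per_site, rev.per_site):
            assert f.f_r == r.f_r
            assert f.gained == r.lost and f.lost == r.gained

    def test_unaligned_neighbors_counted_or_ignored(self):
        na = _net([(0, 1), (0, 2)], nodes=range(3))
        nb = _net([(0, 1)], nodes=range(3))
        aln = AlignmentMap([(0, 0, 0.0), (1, 1, 0.0)], unpaired_a=[2],
                           unpaired_b=[2])
        counted = compare_contacts(na, nb, aln, "AAA", "AAA", unaligned="count")
        assert counted.per_site[0].f_r == pytest.approx(0.5)  # contact to 2 lost
        ignored = compare_contacts(na, nb, aln, "AAA", "AAA", unaligned="ignore")
        assert ignored.per_site[0].f_r == 0.0

    def test_site_class_tracks_substitution(self):
        net = _net([(0, 1)])
        aln = AlignmentMap.identity(2)
        res = compare_contacts(net, net, aln, "AC", "AW")
        assert res.per_site[0].site_class == "conserved_aa"
        assert res.per_site[1].site_class == "substituted"


def _comparison_from_counts(gained, lost, conserved):
    """Build a network pair realizing exact pooled gained/lost/conserved
    counts, using disjoint edges so every edge is counted at two sites."""
    edges_c = [(4 * k, 4 * k + 1) for k in range(conserved)]
    off = 4 * conserved
    edges_l = [(off + 4 * k, off + 4 * k + 1) for k in range(lost)]
    off2 = off + 4 * lost
    edges_g = [(off2 + 4 * k, off2 + 4 * k + 1) for k in range(gained)]
    n_nodes = off2 + 4 * gained + 2
    na = _net(edges_c + edges_l, nodes=range(n_nodes))
    nb = _net(edges_c + edges_g, nodes=range(n_nodes))
    aln = AlignmentMap.identity(n_nodes)
    seq = "A" * n_nodes
    return compare_contacts(na, nb, aln, seq, seq)


class TestSequenceDivergence:
    @pytest.mark.parametrize("seq_b, expected", [
        ("ACDEFGHIKL", 0.0),
        ("WWWWWWWWWW", 1.0),
        ("WCDEFGHIKW", 0.2),
    ])
    def test_fraction_of_mismatches(self, seq_b, expected):
        aln = AlignmentMap.identity(10)
        assert sequence_divergence(aln, "ACDEFGHIKL", seq_b) == pytest.approx(expected)

    def test_three_of_ten(self):
        aln = AlignmentMap.identity(10)
        assert sequence_divergence(aln, "AAAAAAAAAA", "CCCAAAAAAA") == pytest.approx(0.3)


class TestNetworkProximity:
    def test_path_graph_hand_countable(self):
        net = _net([(0, 1), (1, 2), (2, 3), (3, 4)])
        observed, _null, _p = network_proximity_test(net, {0}, {4}, n_random=10,
                                                     rng=np.random.default_rng(0))
        assert observed == 4.0

    def test_query_inside_anchor_minimal_p(self):
        net = _net([(i, i + 1) for i in range(9)])
        observed, null, p = network_proximity_test(net, {3}, {3, 4}, n_random=200,
                                                   rng=np.random.default_rng(1))
        assert observed == 0.0
        assert p == pytest.approx(1 / 201)

    def test_dijkstra_matches_brute_force_enumeration(self, rng):
        """Weighted shortest paths on small random graphs vs exhaustive
        simple-path enumeration."""
        for trial in range(5):
            gen = np.random.default_rng(trial)
            n = 7
            g = nx.gnp_random_graph(n, 0.5, seed=trial)
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(gen.uniform(0.1, 1.0))
            src, dst = 0, n - 1
            if not nx.has_path(g, src, dst):
                continue
            best = min(
                sum(g.edges[a, b]["weight"] for a, b in zip(path, path[1:]))
                for path in nx.all_simple_paths(g, src, dst))
            best = min(best, math.inf)
            dj = nx.dijkstra_path_length(g, src, dst)
            assert dj == pytest.approx(best, abs=1e-12)

    def test_size_validation(self):
        net = _net([(0, 1)])
        with pytest.raises(ValidationError):
            network_proximity_test(net, {0, 1}, {0, 1}, n_random=5)


class TestBinnedSummary:
    def test_constant_values_zero_width_ci(self, rng):
        recs = [(0.05, 2.0), (0.07, 2.0), (0.15, 2.0)]
        df = divergence_binned_summary(recs, n_boot=200, rng=rng)
        row0 = df.iloc[0]
        assert row0["mean"] == 2.0
        assert row0["ci_lo"] == row0["ci_hi"] == 2.0

    def test_singleton_bin_degenerate_ci(self, rng):
        df = divergence_binned_summary([(0.35, 7.0)], n_boot=100, rng=rng)
        row = df.iloc[3]
        assert row["n"] == 1
        assert row["mean"] == row["ci_lo"] == row["ci_hi"] == 7.0

    def test_empty_bins_reported_not_raised(self, rng):
        df = divergence_binned_summary([(0.95, 1.0)], n_boot=100, rng=rng)
        assert df.iloc[0]["n"] == 0
        assert math.isnan(df.iloc[0]["mean"])

    def test_bootstrap_ci_coverage(self):
        """95% percentile-bootstrap CI covers the true mean ≈95% of the time
        for Gaussian bins (coverage simulated over 400 trials)."""
        gen = np.random.default_rng(77)
        hits = 0
        trials = 400
        for _ in range(trials):
            vals = gen.normal(0.0, 1.0, size=40)
            recs = [(0.5, v) for v in vals]
            df = divergence_binned_summary(recs, n_boot=400, rng=gen)
            row = df.iloc[5]
            hits += row["ci_lo"] <= 0.0 <= row["ci_hi"]
        assert hits / trials == pytest.approx(0.95, abs=0.03)

    def test_deterministic_under_seed(self):
        recs = [(0.1 * (i % 10), float(i)) for i in range(50)]
        d1 = divergence_binned_summary(recs, n_boot=500, rng=np.random.default_rng(5))
        d2 = divergence_binned_summary(recs, n_boot=500, rng=np.random.default_rng(5))
        assert d1.equals(d2)


class TestSiteEntropy:
    def test_reference_values(self):
        values = np.zeros((3, 20))
        values[0, :] = 1 / 20
        values[1, 4] = 1.0
        values[2, 0] = values[2, 1] = 0.5
        prof = PreferenceProfile("e", [SiteRecord(i, i + 1, "A") for i in range(3)],
                                 values)
        h = site_entropy(prof)
        assert h[0] == pytest.approx(math.log2(20), abs=1e-12)
        assert h[1] == 0.0
        assert h[2] == pytest.approx(1.0, abs=1e-12)
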