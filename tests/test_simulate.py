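import math

import numpy as np
import pytest
from scipy import stats

from introtrio.census import census, minority_asymmetry_test
from introtrio.records import Topology, TopologyCensus
from introtrio.simulate import (
    DEFAULT_SCHEME,
    SimGene,
    SimNode,
    SimParams,
    attach_supports,
    census_from_topology_indices,
    estimate_gamma,
    expected_topology_probs,
    simulate_alignment,
    simulate_dataset,
    simulate_genealogy,
    simulate_topologies,
    to_newick,
    triplet_record_from_sim,
    write_dataset,
)
from introtrio.trees import _parse_newick, extract_rooted_triplet


class TestSimParams:
    @pytest.mark.parametrize("kw", [
        dict(tau_m=1.0),               # pulse older than the A-B split
        dict(tau_ab=2.0),              # split older than the ingroup root
        dict(gamma=1.2),
        dict(gamma=0.7, ghost_gamma=0.5),
        dict(rate=0.0),
        dict(ghost_gamma=0.2, tau_ghost_join=1.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SimParams(**kw)

    def test_head_start_durations(self):
        p = SimParams()
        assert p.T1 == pytest.approx(p.tau_abc - p.tau_ab)
        assert p.T2 == pytest.approx(p.tau_abc - p.tau_m)
        assert p.T2b == pytest.approx(p.tau_ab - p.tau_m)


class TestGenealogies:
    def test_clock_like_without_rate_noise(self):
        params = SimParams(rate_noise_sigma=0.0, gamma=0.3)
        rng = np.random.default_rng(1)
        for i in range(50):
            g = simulate_genealogy(params, rng, gene_id=f"g{i}")
            for pair, t in g.coal_times.items():
                assert g.tip_dist[pair] == pytest.approx(
                    2.0 * t * params.rate, abs=1e-12
                )

    def test_complete_pulse_with_long_head_start_is_mostly_bc(self):
        params = SimParams(gamma=1.0, tau_ab=2.5, tau_abc=3.0, tau_m=0.1,
                           tau_out=5.0, n_genes=2000, seed=2)
        genes = simulate_dataset(params)
        frac_bc = np.mean([g.true_topology is Topology.BC for g in genes])
        assert frac_bc > 0.9

    def test_full_simulator_matches_closed_form(self):
        params = SimParams(gamma=0.3, n_genes=20000, seed=9)
        genes = simulate_dataset(params)
        counts = np.zeros(3)
        for g in genes:
            counts[(Topology.AB, Topology.BC, Topology.AC).index(g.true_topology)] += 1
        obs = counts / len(genes)
        exp = np.array(expected_topology_probs(params))
        se = np.sqrt(exp * (1 - exp) / len(genes))
        assert np.all(np.abs(obs - exp) < 3.5 * se)

    def test_vectorized_topologies_match_closed_form_with_ghost(self):
        params = SimParams(gamma=0.2, ghost_gamma=0.2, n_genes=1,
                           tau_ghost_join=2.0, seed=0)
        rng = np.random.default_rng(13)
        idx = simulate_topologies(params, 50000, rng)
        cens = census_from_topology_indices(idx)
        exp = np.array(expected_topology_probs(params))
        obs = np.array(cens.proportions())
        se = np.sqrt(exp * (1 - exp) / 50000)
        assert np.all(np.abs(obs - exp) < 3.5 * se)

    def test_introgressed_genes_have_shorter_bc_distance(self):
        params = SimParams(gamma=0.5, n_genes=2000, seed=4)
        genes = simulate_dataset(params)
        bc = frozenset(("B", "C"))
        d_intro = [g.tip_dist[bc] for g in genes if g.introgressed]
        d_none = [g.tip_dist[bc] for g in genes if not g.introgressed]
        assert stats.mannwhitneyu(d_intro, d_none,
                                  alternative="less").pvalue < 0.01

    def test_resistant_genes_follow_species_history(self):
        params = SimParams(gamma=1.0, n_genes=100, seed=5)
        genes = simulate_dataset(params, n_resistant=40)
        assert all(not g.introgressed for g in genes[:40])
        assert all(g.resistant for g in genes[:40])
        assert all(g.introgressed for g in genes[40:])


class TestNewickRoundTrip:
    def test_emitted_trees_reparse_without_loss(self, scheme):
        params = SimParams(gamma=0.3, n_genes=30, seed=6,
                           support_bootstraps=20, aln_length=300)
        genes = simulate_dataset(params, with_supports=True)
        for g in genes:
            gt = _parse_newick(to_newick(g), g.gene_id)
            rec = extract_rooted_triplet(gt, scheme)
            direct = triplet_record_from_sim(g)
            assert rec.topology is direct.topology
            assert rec.d_ab == pytest.approx(direct.d_ab, rel=1e-6)
            assert rec.d_ac == pytest.approx(direct.d_ac, rel=1e-6)
            assert rec.d_bc == pytest.approx(direct.d_bc, rel=1e-6)
            assert rec.support == pytest.approx(direct.support)


def _two_tip_gene(t_total):
    """Stub genealogy with two tips separated by branch length t_total."""
    a = SimNode(name="A")
    b = SimNode(name="B")
    root = SimNode(height=1.0, children=[a, b])
    a.length = t_total / 2
    b.length = t_total / 2
    return SimGene(gene_id="g", root=root, true_topology=Topology.AB,
                   observed_pair=Topology.AB, introgressed=False, ghost=False,
                   direction="")


class TestJC69Alignments:
    def test_zero_length_tree_gives_identical_sequences(self):
        gene = _two_tip_gene(0.0)
        aln = simulate_alignment(gene, SimParams(aln_length=500),
                                 np.random.default_rng(0))
        seqs = list(aln.sequences.values())
        assert seqs[0] == seqs[1]

    def test_saturation_limit_identity_near_one_quarter(self):
        gene = _two_tip_gene(25.0)
        aln = simulate_alignment(gene, SimParams(aln_length=100000),
                                 np.random.default_rng(1))
        s1 = aln.sequences[DEFAULT_SCHEME.taxon_a]
        s2 = aln.sequences[DEFAULT_SCHEME.taxon_b]
        ident = np.mean([a == b for a, b in zip(s1, s2)])
        assert ident == pytest.approx(0.25, abs=0.01)

    def test_p_distance_matches_jc_expectation(self):
        t = 0.2
        gene = _two_tip_gene(t)
        L = 100000
        aln = simulate_alignment(gene, SimParams(aln_length=L),
                                 np.random.default_rng(2))
        seqs = list(aln.sequences.values())
        p_obs = np.mean([a != b for a, b in zip(*seqs)])
        p_exp = 0.75 * (1 - math.exp(-4 * t / 3))
        assert abs(p_obs - p_exp) < 4 * math.sqrt(p_exp * (1 - p_exp) / L)

    def test_alignment_length_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_alignment(_two_tip_gene(0.1), SimParams(aln_length=0),
                               np.random.default_rng(0))


class TestSupports:
    def test_long_informative_genes_get_high_support(self):
        # long internal branch (strong sorting) and plenty of signal
        params = SimParams(gamma=0.0, tau_ab=0.5, tau_abc=2.0, tau_m=0.25,
                           tau_out=4.0, rate=0.05, aln_length=2000,
                           support_bootstraps=50, n_genes=30, seed=7)
        genes = simulate_dataset(params, with_supports=True)
        sorted_genes = [g for g in genes if g.true_topology is Topology.AB]
        assert np.median([g.support for g in sorted_genes]) >= 90

    def test_single_column_alignment_is_uninformative(self):
        params = SimParams(aln_length=1, support_bootstraps=40, n_genes=40,
                           seed=8)
        genes = simulate_dataset(params, with_supports=True)
        supports = np.array([g.support for g in genes])
        assert supports.min() < 60  # far from uniformly confident

    def test_zero_bootstraps_means_unknown(self):
        params = SimParams(support_bootstraps=0, n_genes=2, seed=9,
                           aln_length=100)
        genes = simulate_dataset(params, with_alignments=True,
                                 with_supports=False)
        gene = genes[0]
        assert attach_supports(gene, params, np.random.default_rng(0)) is None

    def test_identical_sequences_tie_flagged(self):
        gene = simulate_genealogy(SimParams(), np.random.default_rng(10))
        params = SimParams(aln_length=50, support_bootstraps=20)
        gene.alignment = None
        # zero-length branches -> identical sequences -> all distances tie
        for node in _walk(gene.root):
            node.length = 0.0
        gene.alignment = simulate_alignment(gene, params,
                                            np.random.default_rng(3))
        attach_supports(gene, params, np.random.default_rng(4))
        assert gene.support_tie


def _walk(node):
    yield node
    for ch in node.children:
        yield from _walk(ch)


class TestEstimateGamma:
    def test_symmetric_census_lands_on_boundary(self):
        cens = TopologyCensus(700, 150, 150)
        gamma_hat, t1_hat, _ = estimate_gamma(cens, T2=1.0)
        assert gamma_hat == 0.0
        assert t1_hat > 0

    def test_null_census_estimates_near_zero(self):
        params = SimParams(gamma=0.0, seed=11)
        rng = np.random.default_rng(11)
        cens = census_from_topology_indices(
            simulate_topologies(params, 10000, rng)
        )
        gamma_hat, _, _ = estimate_gamma(cens, T2=params.T2,
                                         T2b=params.T2b,
                                         via_ab_frac=params.pulse_via_ab_ancestor)
        assert gamma_hat < 0.02

    def test_recovery_of_simulated_gamma(self):
        params = SimParams(gamma=0.3, seed=12)
        rng = np.random.default_rng(12)
        cens = census_from_topology_indices(
            simulate_topologies(params, 10000, rng)
        )
        gamma_hat, t1_hat, _ = estimate_gamma(
            cens, T2=params.T2, T2b=params.T2b,
            via_ab_frac=params.pulse_via_ab_ancestor,
        )
        assert gamma_hat == pytest.approx(0.3, abs=0.05)
        assert t1_hat == pytest.approx(params.T1, abs=0.15)

    def test_empty_census_errors(self):
        with pytest.raises(ValueError):
            estimate_gamma(TopologyCensus(0, 0, 0), T2=1.0)


class TestDatasetWriter:
    def test_writes_trees_truth_params_and_alignments(self, tmp_path):
        params = SimParams(n_genes=5, seed=13, aln_length=60,
                           support_bootstraps=10)
        genes = simulate_dataset(params, with_supports=True)
        write_dataset(genes, tmp_path, params)
        assert (tmp_path / "trees.tsv").read_text().count("\n") == 5
        truth = (tmp_path / "truth.tsv").read_text().splitlines()
        assert len(truth) == 6  # header + genes
        assert (tmp_path / "params.json").exists()
        assert len(list((tmp_path / "alignments").glob("*.fasta"))) == 5
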