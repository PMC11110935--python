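import math

import numpy as np
import pytest

from introtrio.records import Topology, TripletRecord, TripletRejection
from introtrio.trees import (
    GeneAlignment,
    MissingBranchLengthError,
    TaxonScheme,
    TreeParseError,
    UnresolvableRootError,
    _parse_newick,
    extract_rooted_triplet,
    midpoint_root,
    parse_support,
    patristic_distance,
    read_alignments,
    read_tree_collection,
    total_tree_length,
)


def _tree(nwk, gene_id="g1"):
    return _parse_newick(nwk, gene_id)


class TestReadTreeCollection:
    def test_tsv_parse_with_support(self, tmp_path):
        f = tmp_path / "trees.tsv"
        f.write_text("g1\t((A:1,B:1)90:1,(C:2,D:1):1);\n")
        (gt,) = read_tree_collection(f)
        assert gt.gene_id == "g1"
        assert set(gt.tip_labels) == {"A", "B", "C", "D"}
        rec = extract_rooted_triplet(gt, TaxonScheme("A", "B", "C", "D"))
        assert isinstance(rec, TripletRecord)
        assert rec.support == 90.0

    def test_missing_support_is_unknown(self, tmp_path):
        f = tmp_path / "trees.tsv"
        f.write_text("g1\t((A:1,B:1):1,(C:2,D:1):1);\n")
        (gt,) = read_tree_collection(f)
        rec = extract_rooted_triplet(gt, TaxonScheme("A", "B", "C", "D"))
        assert rec.support is None

    def test_malformed_newick_names_gene(self, tmp_path):
        f = tmp_path / "trees.tsv"
        f.write_text("g1\t((A:1,B\n")
        with pytest.raises(TreeParseError, match="g1"):
            read_tree_collection(f)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        f = tmp_path / "trees.tsv"
        f.write_text("g1\t(A:1,B:1);\ng1\t(A:1,C:1);\n")
        with pytest.raises(TreeParseError, match="duplicate"):
            read_tree_collection(f)

    def test_directory_input(self, tmp_path):
        (tmp_path / "gX.nwk").write_text("((A:1,B:1):1,C:2);\n")
        trees = read_tree_collection(tmp_path)
        assert [t.gene_id for t in trees] == ["gX"]

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeParseError, match="g1"):
            _tree("((A:1,A:1):1,C:2);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeParseError, match="negative"):
            _tree("((A:1,B:-0.5):1,C:2);")


class TestSupportParsing:
    def test_proportion_rescaled_with_warning(self):
        with pytest.warns(UserWarning, match="proportion"):
            assert parse_support("0.95") == 95.0

    @pytest.mark.parametrize("label,expected", [("87", 87.0), ("0", 0.0),
                                                ("", None), (None, None),
                                                ("nodeA", None)])
    def test_plain_values(self, label, expected):
        assert parse_support(label) == expected


class TestDistances:
    @pytest.mark.parametrize("pair,expected", [
        (("A", "B"), 3.0), (("A", "C"), 8.0), (("B", "C"), 9.0), (("A", "A"), 0.0),
    ])
    def test_patristic_examples(self, pair, expected):
        gt = _tree("((A:1,B:2):3,C:4);")
        assert patristic_distance(gt, *pair) == pytest.approx(expected)
        assert patristic_distance(gt, pair[1], pair[0]) == pytest.approx(expected)

    def test_missing_tip_errors(self):
        with pytest.raises(ValueError, match="not in tree"):
            patristic_distance(_tree("((A:1,B:2):3,C:4);"), "A", "Z")

    def test_missing_length_is_error_not_zero(self):
        gt = _tree("((A:1,B):3,C:4);")
        assert not gt.has_branch_lengths
        with pytest.raises(MissingBranchLengthError):
            patristic_distance(gt, "A", "B")

    @pytest.mark.parametrize("nwk,expected", [
        ("((A:1,B:2):3,C:4);", 10.0),
        ("A:5;", 5.0),
        ("((A:0,B:0):0,C:0);", 0.0),
    ])
    def test_total_tree_length(self, nwk, expected):
        assert total_tree_length(_tree(nwk)) == pytest.approx(expected)


class TestMidpointRoot:
    def test_longest_path_midpoint_selects_long_pendant(self):
        # pendants 0.5/0.1/0.1: longest path 0.6, midpoint 0.3 from A on A's edge
        rooted, out = midpoint_root(_tree("(A:0.5,B:0.1,C:0.1);"))
        assert out == "A"
        assert set(rooted.tip_labels) == {"A", "B", "C"}

    def test_tie_breaks_lexicographically(self):
        _, out = midpoint_root(_tree("(C:0.2,B:0.2,A:0.2);"))
        assert out == "A"

    def test_zero_length_star_unresolvable(self):
        with pytest.raises(UnresolvableRootError):
            midpoint_root(_tree("(A:0,B:0,C:0);"))


class TestExtractRootedTriplet:
    SCHEME = TaxonScheme("Pa", "Pk", "Pe", "Oh")

    def test_context_rooted_pair_and_support(self):
        gt = _tree("(((Pa:1,Pk:1)95:1,Pe:2):1,(Oh:3,Mc:3):1);")
        rec = extract_rooted_triplet(gt, self.SCHEME)
        assert rec.topology is Topology.AB
        assert rec.support == 95.0
        assert rec.d_ab == pytest.approx(2.0)
        assert rec.d_ac == pytest.approx(4.0)
        assert rec.provenance == "context-rooted"

    def test_copy_number_rejection(self):
        gt = _tree("(((Pa1:1,Pa2:1):1,(Pk:1,Pe:1):1):1,Oh:3);")
        rej = extract_rooted_triplet(gt, self.SCHEME)
        assert isinstance(rej, TripletRejection)
        assert rej.reason == "copy-number"

    def test_no_context_falls_back_to_midpoint(self):
        gt = _tree("((Pa:1,Pk:1):1,Pe:2);")
        rec = extract_rooted_triplet(gt, self.SCHEME, fallback_midpoint=True)
        assert rec.provenance == "midpoint"
        # Pe has the longest pendant -> midpoint outgroup -> pair is Pa-Pk
        assert rec.topology is Topology.AB

    def test_no_context_without_fallback_rejected(self):
        gt = _tree("((Pa:1,Pk:1):1,Pe:2);")
        rej = extract_rooted_triplet(gt, self.SCHEME, fallback_midpoint=False)
        assert rej.reason == "no-context"

    def test_zero_internal_edge_unresolved(self):
        gt = _tree("(((Pa:1,Pk:1):0,Pe:1):0,Oh:3);")
        rec = extract_rooted_triplet(gt, self.SCHEME)
        assert rec.topology is Topology.UNRESOLVED

    def test_decorated_trees_always_recover_focal_clade(self):
        # focal clade ((Pa,Pk),Pe) buried under arbitrary outside decorations:
        # every context tip must vote AB
        rng = np.random.default_rng(77)
        for _ in range(40):
            core = "((Pa:1,Pk:1)88:1,Pe:2)"
            n_extra = int(rng.integers(1, 6))
            for i in range(n_extra):
                left = rng.random() < 0.5
                ln = round(float(rng.uniform(0.5, 3.0)), 3)
                core = (
                    f"(X{i}:{ln},{core}:1)" if left else f"({core}:1,X{i}:{ln})"
                )
            rec = extract_rooted_triplet(_tree(core + ";"), self.SCHEME)
            assert isinstance(rec, TripletRecord)
            assert rec.topology is Topology.AB
            assert rec.support == 88.0

    def test_distances_match_direct_patristic(self):
        gt = _tree("(((Pa:0.3,Pk:0.1)77:0.2,Pe:0.4):0.1,Oh:1.5);")
        rec = extract_rooted_triplet(gt, self.SCHEME)
        assert rec.d_ab == pytest.approx(patristic_distance(gt, "Pa", "Pk"))
        assert rec.d_ac == pytest.approx(patristic_distance(gt, "Pa", "Pe"))
        assert rec.d_bc == pytest.approx(patristic_distance(gt, "Pk", "Pe"))
        assert rec.total_length == pytest.approx(
            0.5 * (rec.d_ab + rec.d_ac + rec.d_bc)
        )


class TestReadAlignments:
    def _write(self, tmp_path, name, rows):
        f = tmp_path / f"{name}.fasta"
        f.write_text("".join(f">{lab}\n{seq}\n" for lab, seq in rows))

    def test_valid_alignment(self, tmp_path, scheme):
        self._write(tmp_path, "g1", [("Pa", "ACGT"), ("Pk", "ACGA"),
                                     ("Pe", "ACTT"), ("Oh", "ACGT")])
        alns, rejected = read_alignments(tmp_path, scheme)
        assert len(alns) == 1 and not rejected
        assert alns[0].length == 4
        assert alns[0].row_for_role(scheme, "O") == "ACGT"

    def test_missing_outgroup_rejected(self, tmp_path, scheme):
        self._write(tmp_path, "g1", [("Pa", "ACGT"), ("Pk", "ACGA"),
                                     ("Pe", "ACTT")])
        alns, rejected = read_alignments(tmp_path, scheme)
        assert not alns
        assert rejected[0].reason == "missing outgroup"

    def test_ragged_rejected(self, tmp_path, scheme):
        self._write(tmp_path, "g1", [("Pa", "ACGT"), ("Pk", "ACG"),
                                     ("Pe", "ACTT"), ("Oh", "ACGT")])
        alns, rejected = read_alignments(tmp_path, scheme)
        assert rejected[0].reason == "ragged"


class TestTaxonScheme:
    def test_labels_must_be_distinct(self):
        with pytest.raises(ValueError):
            TaxonScheme("Pa", "Pa", "Pe", "Oh")

    def test_ambiguous_prefix_raises(self):
        s = TaxonScheme("P", "Pa", "Pe", "Oh")
        with pytest.raises(ValueError, match="multiple"):
            s.assign("Pa_gene1")

    def test_prefix_assignment(self, scheme):
        assert scheme.assign("Pa_scaf1") == "A"
        assert scheme.assign("Oh_x") == "O"
        assert scheme.assign("Mc_x") is None
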