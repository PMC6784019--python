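"""Cysteine frameworks, superfamily classification, connectivity, logos."""

import math

import pytest

from knotminer.framework import (
    SuperfamilyDefinition,
    classify_superfamily,
    cluster_frameworks,
    consensus_logo_matrix,
    extract_framework,
    validate_connectivity,
)

X = "A"  # any non-cysteine residue


class TestExtractFramework:
    @pytest.mark.parametrize(
        "mature, canonical, n_cys",
        [
            ("ACAACAACCAAC", "C-C-CC-C", 5),
            ("CC", "CC", 2),
            ("CCC", "CCC", 3),
            ("CAC", "C-C", 2),
            ("AAAA", "", 0),
        ],
    )
    def test_canonical_patterns(self, mature, canonical, n_cys):
        fw = extract_framework(mature)
        assert fw.canonical == canonical
        assert fw.n_cys == n_cys

    def test_positions_and_spacings(self):
        fw = extract_framework("ACAACAACCAAC")
        assert fw.positions == [1, 4, 7, 8, 11]
        assert fw.spacings == [2, 2, 0, 2]

    def test_canonical_reconstructible_from_positions(self):
        """Adjacency in canonical == zero gaps in spacings (fixed point)."""
        for mature in ("CCACC", "ACACCCA", "CAACAAC", "CCCC"):
            fw = extract_framework(mature)
            rebuilt = "C"
            for gap in fw.spacings:
                rebuilt += "C" if gap == 0 else "-C"
            assert rebuilt == fw.canonical or (not fw.positions and not rebuilt)


class TestClassify:
    def test_table_patterns(self, sf_defs):
        ten = extract_framework("ACAACAACCAAC" + "AACAACAACAACAAC")
        assert ten.canonical == "C-C-CC-C-C-C-C-C-C"
        assert classify_superfamily(ten, sf_defs).superfamily == "SF8"
        six = extract_framework("ACAACAACAACCAAC")
        assert six.canonical == "C-C-C-CC-C"
        assert classify_superfamily(six, sf_defs).superfamily == "SF2"

    def test_unknown_pattern_is_novel(self, sf_defs):
        fw = extract_framework("CCCC")
        assert classify_superfamily(fw, sf_defs).novel

    def test_length_violation_warns_but_classifies(self, sf_defs):
        fw = extract_framework("CACAACCAC")  # SF1 pattern, length 9 != 54
        cls = classify_superfamily(fw, sf_defs)
        assert cls.superfamily == "SF1"
        assert any("length" in w for w in cls.warnings)

    def test_duplicate_canonicals_rejected(self, sf_defs):
        dupe = SuperfamilyDefinition(name="SFX", canonical="C-C-CC-C", n_cys=5)
        with pytest.raises(ValueError, match="duplicate"):
            classify_superfamily(extract_framework("CC"), list(sf_defs) + [dupe])

    def test_definition_consistency_enforced(self):
        with pytest.raises(ValueError):
            SuperfamilyDefinition(name="bad", canonical="C-C", n_cys=3)


class TestCluster:
    def test_partition_by_pattern(self):
        fws = [extract_framework(s) for s in ("CAC", "CAAC", "CCA", "ACC")]
        groups = cluster_frameworks(fws)
        assert set(groups) == {"C-C", "CC"}
        assert len(groups["C-C"]) == 2 and len(groups["CC"]) == 2

    def test_permutation_invariant_partition(self):
        seqs = ["CAC", "CCA", "CAAC", "ACC", "CACAC"]
        fws = [extract_framework(s, peptide_ref=s) for s in seqs]
        a = cluster_frameworks(fws)
        b = cluster_frameworks(fws[::-1])
        assert {k: sorted(f.peptide_ref for f in v) for k, v in a.items()} == {
            k: sorted(f.peptide_ref for f in v) for k, v in b.items()
        }

    def test_degenerate_inputs(self):
        assert cluster_frameworks([]) == {}
        same = [extract_framework("CAC") for _ in range(3)]
        assert len(cluster_frameworks(same)) == 1


class TestConnectivity:
    def test_three_bridge_pattern_valid(self):
        res = validate_connectivity(6, [(1, 4), (2, 5), (3, 6)])
        assert res.valid and res.free == []

    def test_free_cysteine_reported(self):
        res = validate_connectivity(5, [(2, 3), (4, 5)])
        assert res.valid and res.free == [1]

    def test_reuse_and_range_and_self_pairs_invalid(self):
        assert not validate_connectivity(6, [(1, 2), (2, 3)]).valid
        assert not validate_connectivity(4, [(1, 5)]).valid
        assert not validate_connectivity(4, [(2, 2)]).valid

    def test_shipped_scheme_annotations_validate(self, sf_defs):
        for d in sf_defs:
            if d.connectivity:
                res = validate_connectivity(d.n_cys, d.connectivity)
                assert res.valid
                if d.free_cysteines:
                    assert res.free == sorted(d.free_cysteines)


class TestConsensusLogo:
    def test_conserved_column_has_full_information(self):
        cm = consensus_logo_matrix(["C", "C", "C"])
        assert cm.columns[0] == {"C": 1.0}
        assert cm.information[0] == pytest.approx(math.log2(20))

    def test_uniform_distinct_column(self):
        cm = consensus_logo_matrix(list("ACDEFGHIKL"))
        assert cm.information[0] == pytest.approx(math.log2(20) - math.log2(10))

    def test_gaps_excluded_and_sum_to_one(self):
        cm = consensus_logo_matrix(["AC", "-C", "GC"])
        assert sum(cm.columns[0].values()) == pytest.approx(1.0)
        assert cm.columns[0] == pytest.approx({"A": 0.5, "G": 0.5})

    def test_empty_and_ragged_error(self):
        with pytest.raises(ValueError):
            consensus_logo_matrix([])
        with pytest.raises(ValueError, match="ragged"):
            consensus_logo_matrix(["AA", "A"])

    def test_information_bounds(self):
        cm = consensus_logo_matrix(["ACDC", "ACDA", "GCDC", "TCDG"])
        for info in cm.information:
            assert 0.0 <= info <= math.log2(20) + 1e-12
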