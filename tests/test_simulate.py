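"""Synthetic-data generator: planted truth, determinism, digestion rules."""

import numpy as np
import pytest

from knotminer.framework import extract_framework
from knotminer.mass import peptide_mass, oxidized_mods
from knotminer.precursor import segment_precursor
from knotminer.simulate import (
    GeneratorConfig,
    generate_precursor_gene,
    generate_transcriptome,
    simulate_bundle,
    simulate_maldi,
    simulate_tryptic_fragments,
    tryptic_peptides,
    write_bundle,
)
from knotminer.translate import read_transcript_fasta, transcript_orfs


class TestGene:
    def test_sf1_gene_realizes_pattern_and_length(self, sf_by_name):
        rng = np.random.default_rng(3)
        _, truth = generate_precursor_gene(sf_by_name["SF1"], rng)
        fw = extract_framework(truth.mature)
        assert fw.canonical == "C-C-CC-C"
        assert fw.n_cys == 5
        assert len(truth.mature) == 54

    def test_same_seed_same_transcript(self, sf_by_name):
        a = generate_precursor_gene(sf_by_name["SF3"], np.random.default_rng(9))
        b = generate_precursor_gene(sf_by_name["SF3"], np.random.default_rng(9))
        assert a[0].sequence == b[0].sequence
        assert a[1].mature == b[1].mature

    def test_segmentation_recovers_planted_truth(self, sf_by_name):
        rng = np.random.default_rng(12)
        _, truth = generate_precursor_gene(sf_by_name["SF6"], rng)
        p = segment_precursor(truth.protein)
        assert (p.signal, p.propeptide, p.mature) == (
            truth.signal, truth.propeptide, truth.mature,
        )

    def test_propeptide_ends_in_processing_quadruplet(self, sf_defs):
        rng = np.random.default_rng(4)
        for sf in sf_defs:
            _, truth = generate_precursor_gene(sf, rng)
            assert truth.propeptide[-1] == "R"
            assert "E" in truth.propeptide[-4:-1]

    def test_impossible_length_range_errors(self, sf_by_name):
        sf = sf_by_name["SF8"]
        squeezed = type(sf)(
            name="tiny", canonical=sf.canonical, n_cys=sf.n_cys,
            length_range=(5, 8),
        )
        with pytest.raises(ValueError, match="length range"):
            generate_precursor_gene(squeezed, np.random.default_rng(0))


class TestTranscriptome:
    def test_uniform_mix_realizes_all_patterns(self):
        mix = {f"SF{i}": 1 / 8 for i in range(1, 9)}
        cfg = GeneratorConfig(n_toxin_genes=24, superfamily_mix=mix, seed=5)
        _, truth = generate_transcriptome(cfg)
        patterns = {extract_framework(g.mature).canonical for g in truth.genes}
        assert len(patterns) == 8

    def test_tpm_sums_to_one_million(self):
        cfg = GeneratorConfig(n_toxin_genes=10, seed=6)
        transcripts, _ = generate_transcriptome(cfg)
        total = sum(t.abundance for t in transcripts)
        assert total == pytest.approx(1e6, abs=1e-3)

    def test_zero_toxin_genes_gives_decoys_only(self):
        cfg = GeneratorConfig(n_toxin_genes=0, decoy_fraction=0.0, seed=1)
        transcripts, truth = generate_transcriptome(cfg)
        assert transcripts == [] and truth.genes == []

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(superfamily_mix={"SF1": 0.5})


class TestMaldi:
    def test_full_amidation_yields_exact_pairs(self):
        cfg = GeneratorConfig(
            n_toxin_genes=8, amidation_fraction=1.0, mass_noise_sd=0.0, seed=2
        )
        _, truth = generate_transcriptome(cfg)
        observed = simulate_maldi(truth, cfg)
        assert len(observed) == 16
        for g in truth.genes:
            assert g.amidated
            assert g.mass_acid - g.mass_amide == pytest.approx(0.98402)

    def test_noise_free_masses_equal_calculator(self):
        cfg = GeneratorConfig(n_toxin_genes=6, mass_noise_sd=0.0, seed=8)
        _, truth = generate_transcriptome(cfg)
        observed = simulate_maldi(truth, cfg)
        theoretical = {
            round(peptide_mass(g.mature, oxidized_mods(g.mature)), 6)
            for g in truth.genes
        } | {
            round(peptide_mass(g.mature, oxidized_mods(g.mature, amide=True)), 6)
            for g in truth.genes
        }
        assert {round(o.neutral_mass, 6) for o in observed} <= theoretical

    def test_same_seed_identical_lists(self):
        cfg = GeneratorConfig(n_toxin_genes=5, mass_noise_sd=0.2, seed=13)
        _, t1 = generate_transcriptome(cfg)
        _, t2 = generate_transcriptome(cfg)
        m1 = [o.neutral_mass for o in simulate_maldi(t1, cfg)]
        m2 = [o.neutral_mass for o in simulate_maldi(t2, cfg)]
        assert m1 == m2


class TestTrypticDigest:
    def test_no_cleavage_before_proline(self):
        spans = tryptic_peptides("AKPGK", missed_cleavages=0)
        assert spans == [(0, 5)]

    def test_reported_fragment_among_products(self):
        mature = "IFECVFSCDIEKEGKPCKPKG"
        spans = tryptic_peptides(mature, missed_cleavages=2)
        products = {mature[s:e] for s, e in spans}
        assert "IFECVFSCDIEK" in products

    def test_zero_missed_cleavages_have_no_internal_sites(self):
        seq = "AKCDEFKRGHPKLMR"
        for s, e in tryptic_peptides(seq, missed_cleavages=0):
            pep = seq[s:e]
            for i, aa in enumerate(pep[:-1]):
                if aa in "KR":
                    assert pep[i + 1] == "P"

    def test_fragment_truth_spans_match_sequences(self):
        cfg = GeneratorConfig(n_toxin_genes=4, seed=3)
        _, truth = generate_transcriptome(cfg)
        frags = simulate_tryptic_fragments(truth, cfg)
        by_id = {f.id: f for f in frags}
        for ft in truth.fragments:
            gene = truth.gene(ft.gene_id)
            assert by_id[ft.fragment_id].sequence == gene.mature[ft.start : ft.end]

    def test_flank_dot_notation(self):
        cfg = GeneratorConfig(n_toxin_genes=2, seed=3)
        _, truth = generate_transcriptome(cfg)
        frags = simulate_tryptic_fragments(truth, cfg)
        assert all(f.dot_notation.count(".") == 2 for f in frags)


class TestBundleIO:
    def test_write_and_reread_roundtrip(self, tmp_path, small_bundle):
        paths = write_bundle(small_bundle, tmp_path)
        transcripts = read_transcript_fasta(paths["transcripts"])
        assert [t.id for t in transcripts] == [
            t.id for t in small_bundle.transcripts
        ]
        assert all(t.abundance is not None for t in transcripts)

    def test_bundle_is_deterministic(self, small_bundle):
        again = simulate_bundle(small_bundle.config)
        assert [t.sequence for t in again.transcripts] == [
            t.sequence for t in small_bundle.transcripts
        ]
        assert [o.neutral_mass for o in again.observed] == [
            o.neutral_mass for o in small_bundle.observed
        ]
        assert [f.sequence for f in again.fragments] == [
            f.sequence for f in small_bundle.fragments
        ]

    def test_planted_orf_recoverable(self, small_bundle):
        ok = 0
        for g in small_bundle.truth.genes:
            t = next(
                x for x in small_bundle.transcripts if x.id == g.transcript_id
            )
            proteins = {o.protein for o in transcript_orfs(t, min_len=40)}
            ok += g.protein in proteins
        assert ok == len(small_bundle.truth.genes)
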