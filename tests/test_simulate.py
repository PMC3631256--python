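"""Tests for the synthetic corpus generator: planted disorder levels,
biased back-translation, copula coupling, outlier planting and
reproducibility."""

import io
import warnings

import numpy as np
import pytest
from Bio.Seq import Seq

from virodisorder.composition import fourfold_site_composition
from virodisorder.disorder import DisorderProfile, PredictorSpec
from virodisorder.genome_io import parse_genome_records
from virodisorder.simulate import (
    BlockRelaxationWarning,
    DISORDER_POOL,
    FamilyTruth,
    ORDER_POOL,
    back_translate,
    default_config,
    load_config,
    save_config,
    simulate_corpus,
    synth_protein,
    write_corpus,
)

from conftest import scaled_config

SPEC = PredictorSpec()


class TestDefaultConfig:
    def test_at_least_twelve_analysis_families(self):
        config = default_config()
        analysis = [f for f in config if f.baltimore_type != "satellite"]
        assert len(analysis) >= 12

    def test_mean_disorder_spans_three_to_thirty(self):
        targets = [f.target_mean_d for f in default_config()]
        assert min(targets) <= 3.5 and max(targets) >= 28.0

    def test_sizes_span_2kb_to_100kb_plus(self):
        sizes = [np.exp(f.mean_log_size) for f in default_config()]
        assert min(sizes) <= 2500 and max(sizes) >= 100_000

    def test_correlations_of_both_signs(self):
        rhos = [f.size_disorder_rho for f in default_config()]
        assert any(r > 0.2 for r in rhos) and any(r < -0.2 for r in rhos)

    def test_all_major_baltimore_types_present(self):
        types = {f.baltimore_type for f in default_config()}
        for t in ("dsDNA", "ssDNA", "dsRNA", "ssRNAp", "ssRNAn", "ssRNA-RT", "dsDNA-RT"):
            assert t in types

    def test_one_satellite_and_one_outlier_family(self):
        config = default_config()
        assert sum(f.baltimore_type == "satellite" for f in config) == 1
        assert sum(f.plant_outliers for f in config) == 1

    def test_config_round_trip(self, tmp_path):
        path = tmp_path / "families.cfg"
        config = default_config()
        save_config(config, path)
        assert load_config(path) == config

    def test_invalid_parameters_rejected(self):
        base = default_config()[0].__dict__
        with pytest.raises(ValueError):
            FamilyTruth(**{**base, "size_disorder_rho": 1.5})
        with pytest.raises(ValueError):
            FamilyTruth(**{**base, "n_genomes": 0})
        with pytest.raises(ValueError):
            FamilyTruth(**{**base, "composition_bias": (0.0, 0.0, 0.0, 0.0)})


class TestSynthProtein:
    def test_zero_fraction_is_ordered(self, rng):
        seq = synth_protein(400, 0.0, rng)
        assert set(seq) <= set(ORDER_POOL)
        prof = DisorderProfile.from_sequence("p", seq, SPEC)
        assert prof.percent_disorder < 10.0

    def test_unit_fraction_is_disordered(self, rng):
        seq = synth_protein(400, 1.0, rng)
        assert set(seq) <= set(DISORDER_POOL)
        prof = DisorderProfile.from_sequence("p", seq, SPEC)
        assert prof.percent_disorder > 90.0

    def test_half_fraction_recovers_within_five_points(self, rng):
        ds = []
        for _ in range(30):
            seq = synth_protein(600, 0.5, rng)
            ds.append(DisorderProfile.from_sequence("p", seq, SPEC).percent_disorder)
        assert np.mean(ds) == pytest.approx(50.0, abs=5.0)

    def test_short_protein_warns_about_relaxed_blocks(self, rng):
        with pytest.warns(BlockRelaxationWarning):
            synth_protein(60, 0.5, rng)

    def test_length_is_exact(self, rng):
        for length in (25, 100, 999):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", BlockRelaxationWarning)
                assert len(synth_protein(length, 0.3, rng)) == length

    def test_below_window_errors(self, rng):
        with pytest.raises(ValueError):
            synth_protein(10, 0.5, rng)

    def test_invalid_fraction_errors(self, rng):
        with pytest.raises(ValueError):
            synth_protein(100, 1.2, rng)


class TestBackTranslate:
    def test_translation_round_trip(self, rng):
        protein = synth_protein(300, 0.4, rng)
        cds = back_translate(protein, (1, 1, 1, 1), rng)
        assert str(Seq(cds).translate()) == protein

    def test_extreme_c_bias_picks_c_ending_codons(self, rng):
        cds = back_translate("A" * 200, (1e-9, 1.0, 1e-9, 1e-9), rng)
        assert set(cds[i : i + 3] for i in range(0, len(cds), 3)) == {"GCC"}

    def test_uniform_bias_is_uniform_at_fourfold_sites(self, rng):
        protein = "".join(rng.choice(list("APTVGRL"), size=12000))
        cds = back_translate(protein, (1, 1, 1, 1), rng)
        comp = fourfold_site_composition([cds])
        for attr in "acgt":
            assert getattr(comp, attr) == pytest.approx(0.25, abs=0.02)

    def test_biased_composition_tracks_weights(self, rng):
        protein = "A" * 12000  # four-fold box, all third bases synonymous
        cds = back_translate(protein, (0.1, 0.5, 0.2, 0.2), rng)
        comp = fourfold_site_composition([cds])
        assert comp.c == pytest.approx(0.5, abs=0.02)
        assert comp.a == pytest.approx(0.1, abs=0.02)

    def test_unknown_residue_errors(self, rng):
        with pytest.raises(ValueError, match="no codon"):
            back_translate("AX", (1, 1, 1, 1), rng)

    def test_bad_weights_error(self, rng):
        with pytest.raises(ValueError):
            back_translate("A", (1, 1, 1), rng)


class TestSimulateCorpus:
    def test_counts_and_accessions(self, small_corpus):
        config = scaled_config(8)
        assert len(small_corpus.genomes) == sum(f.n_genomes for f in config)
        accessions = [g.accession for g in small_corpus.genomes]
        assert len(set(accessions)) == len(accessions)

    def test_bit_reproducible(self):
        cfg = scaled_config(3)
        a = simulate_corpus(cfg, seed=7)
        b = simulate_corpus(cfg, seed=7)
        assert [g.segments for g in a.genomes] == [g.segments for g in b.genomes]
        assert a.realised.equals(b.realised)

    def test_different_seeds_differ(self):
        cfg = scaled_config(2)
        a = simulate_corpus(cfg, seed=1)
        b = simulate_corpus(cfg, seed=2)
        assert a.genomes[0].segments != b.genomes[0].segments

    def test_family_streams_independent(self):
        """Dropping a family leaves the remaining families' genomes unchanged."""
        cfg = scaled_config(3)
        full = simulate_corpus(cfg, seed=5)
        reduced = simulate_corpus(cfg[:1] + cfg[2:], seed=5)
        full_first = [g.segments for g in full.genomes if g.family == cfg[0].family]
        red_first = [g.segments for g in reduced.genomes if g.family == cfg[0].family]
        assert full_first == red_first

    def test_outliers_planted_exactly_four(self, small_corpus):
        flagged = small_corpus.realised[small_corpus.realised.outlier != ""]
        assert len(flagged) == 4
        assert sorted(flagged.outlier) == ["deficit", "deficit", "excess", "excess"]
        assert set(flagged.family) == {"Phycosimviridae"}

    def test_no_outliers_when_disabled(self):
        corpus = simulate_corpus(scaled_config(5), seed=3, include_outliers=False)
        assert (corpus.realised.outlier == "").all()

    def test_translations_match_extracted_cds(self, small_corpus):
        rec = small_corpus.genomes[0]
        for feat in rec.primary_cds()[:3]:
            nt = feat.extract(rec.segments[feat.segment])
            translated = str(Seq(nt[: 3 * len(feat.translation)]).translate())
            assert translated == feat.translation

    def test_genome_size_matches_drawn_size(self, small_corpus):
        for rec in small_corpus.genomes[:20]:
            assert rec.genome_size == len(rec.segments[0])
            covered = max(e for f in rec.primary_cds() for (_, e) in f.intervals)
            assert covered <= rec.genome_size

    def test_polyproteins_present_in_large_genomes(self, small_corpus):
        polys = [
            rec
            for rec in small_corpus.genomes
            if any(f.is_mat_peptide for f in rec.cds)
        ]
        assert polys, "no polyproteins generated"
        rec = polys[0]
        parents = {f.parent_protein_id for f in rec.cds if f.is_mat_peptide}
        for pid in parents:
            assert len(rec.mat_peptides(pid)) >= 2

    def test_round_trip_through_genbank_is_warning_free(self, tmp_path):
        corpus = simulate_corpus(scaled_config(2), seed=9)
        paths = write_corpus(corpus, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            parsed = parse_genome_records(paths["genbank"])
        assert len(parsed) == len(corpus.genomes)
        by_acc = {r.accession: r for r in parsed}
        for rec in corpus.genomes:
            back = by_acc[rec.accession]
            assert back.segments == rec.segments
            assert len(back.primary_cds()) == len(rec.primary_cds())

    def test_family_mean_disorder_near_target(self):
        """Crude end-to-end check: the most and least disordered families
        separate in the right direction (full-precision recovery is an
        acceptance-level property)."""
        cfg = [f for f in scaled_config(6) if f.family in ("Nanosimviridae", "Circosimviridae")]
        corpus = simulate_corpus(cfg, seed=4)
        by_family = {}
        for rec in corpus.genomes:
            profs = [
                DisorderProfile.from_sequence(pid, seq, SPEC) for pid, seq in rec.proteins
            ]
            d = np.mean([p.percent_disorder for p in profs])
            by_family.setdefault(rec.family, []).append(d)
        assert np.mean(by_family["Circosimviridae"]) > np.mean(by_family["Nanosimviridae"]) + 10
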