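"""Tests for GenBank parsing, annotation QC and survey-set assembly."""

import numpy as np
import pytest
from Bio.Seq import Seq

from virodisorder.genome_io import (
    CdsFeature,
    GenomeRecord,
    ParseError,
    SurveySet,
    apply_metadata,
    build_survey_set,
    merge_segment_groups,
    parse_genome_records,
    peptide_spans,
    qc_residue_vs_genome,
    read_corpus_tables,
    write_corpus_tables,
)


def genbank_text(accession: str, seq: str, feature_lines: list[str]) -> str:
    """Hand-format a GenBank record (independent of any writer)."""
    lines = [
        f"LOCUS       {accession:<23} {len(seq):>9} bp    DNA     linear   VRL 01-JAN-2000",
        "DEFINITION  synthetic test virus.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
        "KEYWORDS    .",
        "SOURCE      synthetic test virus",
        "  ORGANISM  synthetic test virus",
        "            Viruses.",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
    ]
    lines.extend(feature_lines)
    lines.append("ORIGIN      ")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        parts = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def coding(protein: str) -> str:
    """A deterministic back-translation using each residue's first codon."""
    table = {}
    for x in "TCAG":
        for y in "TCAG":
            for z in "TCAG":
                aa = str(Seq(x + y + z).translate())
                table.setdefault(aa, x + y + z)
    return "".join(table[aa] for aa in protein)


PROT99 = "MKT" * 33
CDS300 = coding(PROT99) + "TAA"  # 300 nt including the stop


class TestParsing:
    def test_single_cds_record(self, tmp_path):
        seq = "G" * 15 + CDS300 + "C" * 15
        path = tmp_path / "one.gbk"
        path.write_text(
            genbank_text("TV0001", seq, [
                "     CDS             16..315",
                '                     /product="test protein"',
                '                     /protein_id="TV0001_p1"',
            ])
        )
        (rec,) = parse_genome_records(path)
        assert rec.genome_size == len(seq)
        assert len(rec.proteins) == 1
        pid, prot = rec.proteins[0]
        assert pid == "TV0001_p1" and prot == PROT99 and len(prot) == 99

    def test_polyprotein_with_mat_peptides(self, tmp_path):
        seq = "G" * 15 + CDS300 + "C" * 15
        feats = [
            "     CDS             16..315",
            '                     /protein_id="TV0002_pp"',
            "     mat_peptide     16..105",
            '                     /product="pep1"',
            "     mat_peptide     106..225",
            '                     /product="pep2"',
            "     mat_peptide     226..312",
            '                     /product="pep3"',
        ]
        path = tmp_path / "poly.gbk"
        path.write_text(genbank_text("TV0002", seq, feats))
        (rec,) = parse_genome_records(path)
        assert len(rec.proteins) == 1
        peptides = rec.mat_peptides("TV0002_pp")
        assert len(peptides) == 3
        total_pep = sum(len(p.translation) for p in peptides)
        assert total_pep <= len(rec.proteins[0][1])
        spans = peptide_spans(rec, rec.primary_cds()[0])
        assert spans[0][0] == 0 and spans[-1][1] == 99
        # cleaved peptides tile the parent protein
        assert "".join(s for _, _, s in spans) == PROT99

    def test_minus_strand_and_join(self, tmp_path):
        fwd = coding("MKTAY") + "TAA"
        rc = str(Seq(fwd).reverse_complement())
        seq = "A" * 12 + rc + "G" * 12
        feats = [f"     CDS             complement({13}..{12 + len(rc)})"]
        path = tmp_path / "minus.gbk"
        path.write_text(genbank_text("TV0003", seq, feats))
        (rec,) = parse_genome_records(path)
        assert rec.proteins[0][1] == "MKTAY"

        part1 = coding("MKT")
        part2 = coding("AYW") + "TAA"
        seq2 = "C" * 10 + part1 + "T" * 7 + part2 + "C" * 5
        feats2 = [f"     CDS             join(11..{10 + len(part1)},{18 + len(part1)}..{17 + len(part1) + len(part2)})"]
        path2 = tmp_path / "join.gbk"
        path2.write_text(genbank_text("TV0004", seq2, feats2))
        (rec2,) = parse_genome_records(path2)
        assert rec2.proteins[0][1] == "MKTAYW"

    def test_translation_conflict_warns_but_keeps_annotation(self, tmp_path):
        seq = "G" * 15 + CDS300 + "C" * 15
        wrong = "W" * 99
        feats = [
            "     CDS             16..315",
            f'                     /translation="{wrong}"',
        ]
        path = tmp_path / "conflict.gbk"
        path.write_text(genbank_text("TV0005", seq, feats))
        with pytest.warns(UserWarning, match="conflicts"):
            (rec,) = parse_genome_records(path)
        assert rec.proteins[0][1] == wrong  # deposited annotation kept
        assert rec.parse_warnings

    def test_feature_beyond_sequence_is_parse_error_naming_locus(self, tmp_path):
        seq = "G" * 50
        path = tmp_path / "bad.gbk"
        path.write_text(genbank_text("TV0006", seq, ["     CDS             16..999"]))
        with pytest.raises(ParseError, match="TV0006"):
            parse_genome_records(path)

    def test_empty_input_errors(self, tmp_path):
        path = tmp_path / "empty.gbk"
        path.write_text("")
        with pytest.raises(ParseError):
            parse_genome_records(path)

    def test_clean_translation_matches_deposited(self, tmp_path):
        # deposited /translation identical to in-house translation: no warnings
        seq = "G" * 15 + CDS300 + "C" * 15
        feats = [
            "     CDS             16..315",
            f'                     /translation="{PROT99}"',
        ]
        path = tmp_path / "clean.gbk"
        path.write_text(genbank_text("TV0007", seq, feats))
        (rec,) = parse_genome_records(path)
        assert not rec.parse_warnings


class TestSegmentsAndMetadata:
    def test_segment_group_merges_records(self, tmp_path):
        seq1 = "G" * 15 + CDS300 + "C" * 15
        seq2 = "A" * 10 + coding("MW") + "TAA" + "T" * 10
        text = genbank_text("SEG1", seq1, ["     CDS             16..315"]) + genbank_text(
            "SEG2", seq2, [f"     CDS             11..{10 + 9}"]
        )
        path = tmp_path / "seg.gbk"
        path.write_text(text)
        records = parse_genome_records(path)
        meta = {
            "SEG1": {"family": "FamX", "baltimore_type": "ssRNAn", "host_category": "Plants", "segment_group": "VIRUS1"},
            "SEG2": {"family": "FamX", "baltimore_type": "ssRNAn", "host_category": "Plants", "segment_group": "VIRUS1"},
        }
        merged = apply_metadata(records, meta)
        assert len(merged) == 1
        genome = merged[0]
        assert genome.accession == "VIRUS1"
        assert genome.genome_size == len(seq1) + len(seq2)
        assert len(genome.proteins) == 2
        assert genome.family == "FamX"

    def test_without_grouping_each_record_stands_alone(self):
        recs = [GenomeRecord("A", segments=["ACGT"]), GenomeRecord("B", segments=["ACGT"])]
        assert len(merge_segment_groups(recs, {})) == 2

    def test_unknown_baltimore_type_rejected(self):
        with pytest.raises(ValueError, match="Baltimore"):
            GenomeRecord("X", baltimore_type="ssRNA")


def _mk_genome(accession, family, size, residues, btype="dsDNA"):
    rec = GenomeRecord(accession, family=family, baltimore_type=btype, genome_size=size)
    rec.proteins = [(f"{accession}_p1", "A" * residues)]
    return rec


class TestQc:
    def test_planted_outliers_flagged_exactly(self, rng):
        genomes = []
        for i in range(50):
            size = int(10 ** rng.uniform(3.3, 5.3))
            residues = max(50, int(size / 3 * rng.uniform(0.9, 1.1)))
            genomes.append(_mk_genome(f"G{i}", "F", size, residues))
        excess = _mk_genome("EXTRA", "F", 30000, 10 * 10000)
        deficit = _mk_genome("MISSING", "F", 30000, 1000)
        flags = qc_residue_vs_genome(genomes + [excess, deficit])
        assert flags["EXTRA"] == "excess_residues"
        assert flags["MISSING"] == "deficit_residues"
        assert all(v == "ok" for k, v in flags.items() if k not in ("EXTRA", "MISSING"))

    def test_clean_set_has_zero_flags_by_direct_mad_oracle(self, rng):
        genomes = []
        for i in range(50):
            size = int(10 ** rng.uniform(3.3, 5.3))
            residues = max(50, int(size / 3 * rng.uniform(0.9, 1.1)))
            genomes.append(_mk_genome(f"G{i}", "F", size, residues))
        flags = qc_residue_vs_genome(genomes, k=3.0)
        assert all(v == "ok" for v in flags.values())
        # oracle: residuals of an ideal slope-1 log-log law stay inside 3 MAD
        x = np.log10([g.genome_size for g in genomes])
        y = np.log10([g.n_residues for g in genomes])
        resid = y - x  # slope 1, intercept absorbed by median
        resid -= np.median(resid)
        mad = np.median(np.abs(resid))
        assert np.max(np.abs(resid)) <= 3 * 1.4826 * mad + 0.05

    def test_too_few_genomes_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            qc_residue_vs_genome([_mk_genome("A", "F", 1000, 300)] * 5)


class TestSurveySet:
    def _families(self, n_a=11, n_b=10):
        genomes = [_mk_genome(f"A{i}", "FamA", 10000, 3000) for i in range(n_a)]
        genomes += [_mk_genome(f"B{i}", "FamB", 10000, 3000) for i in range(n_b)]
        return genomes

    def test_family_size_rule_is_strictly_greater(self):
        survey = build_survey_set(self._families(), min_family_size=10)
        fams = {g.family for g in survey.family_level_genomes()}
        assert fams == {"FamA"}
        # both families remain in the all-virus analysis list
        assert len(survey.genomes) == 21

    def test_satellites_excluded(self):
        genomes = self._families()
        sats = [_mk_genome(f"S{i}", "Sat", 1500, 400, btype="satellite") for i in range(5)]
        survey = build_survey_set(genomes + sats)
        assert all(survey.exclusions[s.accession] == "satellite" for s in sats)
        assert len(survey.exclusions) == 5

    def test_flag_family_policy_removes_whole_family(self):
        genomes = self._families()
        flags = {"A0": "excess_residues"}
        survey = build_survey_set(genomes, flags, qc_policy="flag-family")
        assert all(g.family != "FamA" for g in survey.genomes)
        assert survey.exclusions["A5"] == "qc_outlier"

    def test_flag_genome_policy_removes_only_the_genome(self):
        survey = build_survey_set(self._families(), {"A0": "excess_residues"}, qc_policy="flag-genome")
        assert "A0" in survey.exclusions and len(survey.exclusions) == 1

    def test_partition_invariant(self):
        genomes = self._families()
        genomes.append(_mk_genome("S0", "Sat", 1500, 400, btype="satellite"))
        survey = build_survey_set(genomes, {"B3": "deficit_residues"}, qc_policy="flag-genome")
        assert len(survey.genomes) + len(survey.exclusions) == len(genomes)

    def test_excluded_genome_in_analysis_list_rejected(self):
        g = _mk_genome("A", "F", 1000, 300)
        with pytest.raises(ValueError):
            SurveySet([g], {"A": "satellite"})


class TestRoundTrip:
    def test_corpus_tables_round_trip(self, tmp_path, small_corpus):
        records = small_corpus.genomes[:10]
        tsv, fasta = tmp_path / "meta.tsv", tmp_path / "prot.fasta"
        write_corpus_tables(records, tsv, fasta)
        back = read_corpus_tables(tsv, fasta)
        assert [r.accession for r in back] == [r.accession for r in records]
        for orig, new in zip(records, back):
            assert new.family == orig.family
            assert new.baltimore_type == orig.baltimore_type
            assert new.genome_size == orig.genome_size
            assert new.proteins == orig.proteins
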