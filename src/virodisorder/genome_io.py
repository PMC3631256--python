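"""Reading annotated viral genome records and assembling the survey set.

Genomes enter as multi-record GenBank flat files plus a metadata table
(accession, family, Baltimore genome type, host category, optional
segment group).  Parsing extracts coding-sequence features, translates
them (or trusts the deposited ``/translation``), and attaches mature
peptide (``mat_peptide``) annotations to their parent polyprotein by
coordinate containment.

Quality control follows the survey design: genomes whose annotated
residue count departs grossly from the genome-size trend (over- or
under-annotated records) are flagged on a robust log–log fit, satellite
viruses are excluded outright, and small families are kept in whole-set
analyses but dropped from family-level tables.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats as sps

__all__ = [
    "BALTIMORE_TYPES",
    "EXCLUSION_REASONS",
    "CdsFeature",
    "GenomeRecord",
    "SurveySet",
    "ParseError",
    "parse_genome_records",
    "read_metadata",
    "apply_metadata",
    "merge_segment_groups",
    "qc_residue_vs_genome",
    "build_survey_set",
    "write_corpus_tables",
    "read_corpus_tables",
    "peptide_spans",
]

BALTIMORE_TYPES = frozenset(
    {"ssDNA", "dsDNA", "ssRNAp", "ssRNAn", "dsRNA", "ssRNA-RT", "dsDNA-RT", "satellite"}
)
EXCLUSION_REASONS = frozenset({"satellite", "qc_outlier", "small_family"})


class ParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted."""


@dataclass
class CdsFeature:
    """One coding feature on a genome segment.

    Coordinates are 0-based half-open on the segment's deposited strand;
    ``intervals`` lists the exon/part intervals of a ``join`` location in
    coding (5'→3') order.  ``mat_peptide`` features are stored with
    ``is_mat_peptide=True`` and point at their parent polyprotein.
    """

    segment: int
    intervals: list[tuple[int, int]]
    strand: int = 1
    product: str = ""
    protein_id: str = ""
    is_mat_peptide: bool = False
    parent_protein_id: str | None = None
    translation: str | None = None
    frame_warning: bool = False

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start >= end:
                raise ValueError(f"{self.protein_id}: empty interval [{start}, {end})")
        ordered = self.intervals if self.strand >= 0 else self.intervals[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if e1 > s2:
                raise ValueError(f"{self.protein_id}: overlapping or unordered intervals")
        if self.coding_length % 3 != 0:
            self.frame_warning = True

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def extract(self, segment_seq: str) -> str:
        """Spliced coding-strand nucleotide sequence of this feature."""
        parts = [segment_seq[s:e] for s, e in self.intervals]
        seq = "".join(parts)
        if self.strand < 0:
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class GenomeRecord:
    """One viral genome: metadata, segments, annotation and proteome."""

    accession: str
    family: str = ""
    baltimore_type: str = ""
    host_category: str = ""
    segments: list[str] = field(default_factory=list)
    cds: list[CdsFeature] = field(default_factory=list)
    proteins: list[tuple[str, str]] = field(default_factory=list)
    genome_size: int | None = None
    parse_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_size is None:
            self.genome_size = sum(len(s) for s in self.segments)
        if self.baltimore_type and self.baltimore_type not in BALTIMORE_TYPES:
            raise ValueError(
                f"{self.accession}: unknown Baltimore type {self.baltimore_type!r}"
            )

    @property
    def n_residues(self) -> int:
        """Total annotated residues, counting each protein once.

        Mature peptides are annotation on the polyprotein, not extra
        proteome mass, so only non-``mat_peptide`` products count.
        """
        return sum(len(seq) for _, seq in self.proteins)

    @property
    def is_satellite(self) -> bool:
        return self.baltimore_type == "satellite"

    def coding_sequences(self) -> list[str]:
        """Spliced coding-strand nucleotide sequences (one per protein CDS)."""
        out = []
        for feat in self.cds:
            if feat.is_mat_peptide:
                continue
            out.append(feat.extract(self.segments[feat.segment]))
        return out

    def primary_cds(self) -> list[CdsFeature]:
        return [f for f in self.cds if not f.is_mat_peptide]

    def mat_peptides(self, parent_protein_id: str) -> list[CdsFeature]:
        return [
            f
            for f in self.cds
            if f.is_mat_peptide and f.parent_protein_id == parent_protein_id
        ]


def _translate(nt: str) -> str:
    prot = str(Seq(nt).translate(table=1))
    return prot[:-1] if prot.endswith("*") else prot


def _feature_intervals(feature) -> list[tuple[int, int]]:
    return [(int(part.start), int(part.end)) for part in feature.location.parts]


def parse_genome_records(source) -> list[GenomeRecord]:
    """Parse a multi-record GenBank flat file into :class:`GenomeRecord` s.

    One genome per LOCUS (use :func:`merge_segment_groups` afterwards for
    segmented viruses).  CDS translations come from the ``/translation``
    qualifier when present; otherwise the feature is translated from its
    coordinates with the standard genetic code.  A deposited translation
    that conflicts with the in-house one is kept, with a warning recorded
    on the genome.  ``mat_peptide`` features are attached to the CDS that
    contains them.
    """
    records: list[GenomeRecord] = []
    last_locus = "<none>"
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        for rec in SeqIO.parse(handle, "genbank"):
            last_locus = rec.name or rec.id
            records.append(_convert_record(rec))
    except ParseError:
        raise
    except Exception as exc:  # malformed flat file
        raise ParseError(f"malformed GenBank record after LOCUS {last_locus}: {exc}") from exc
    finally:
        if close:
            handle.close()
    if not records:
        raise ParseError("no GenBank records found in input")
    return records


def _convert_record(rec) -> GenomeRecord:
    seq = str(rec.seq).upper().replace("U", "T")
    genome = GenomeRecord(accession=rec.name or rec.id, segments=[seq])
    cds_feats: list[CdsFeature] = []
    mat_feats: list[CdsFeature] = []
    n_unnamed = 0

    for feature in rec.features:
        if feature.type not in ("CDS", "mat_peptide"):
            continue
        try:
            intervals = _feature_intervals(feature)
            strand = feature.location.strand or 1
        except Exception as exc:
            raise ParseError(f"LOCUS {genome.accession}: bad feature location: {exc}") from exc
        for start, end in intervals:
            if start < 0 or end > len(seq):
                raise ParseError(
                    f"LOCUS {genome.accession}: feature [{start}, {end}) outside sequence"
                )
        product = feature.qualifiers.get("product", [""])[0]
        pid = feature.qualifiers.get("protein_id", [""])[0]
        if feature.type == "CDS":
            if not pid:
                n_unnamed += 1
                pid = f"{genome.accession}_p{n_unnamed}"
            feat = CdsFeature(0, intervals, strand, product, pid)
            own = _translate(feat.extract(seq))
            deposited = feature.qualifiers.get("translation", [None])[0]
            if deposited is not None:
                if deposited != own:
                    msg = f"{pid}: deposited translation conflicts with coordinates"
                    warnings.warn(msg, stacklevel=3)
                    genome.parse_warnings.append(msg)
                feat.translation = deposited
            else:
                feat.translation = own
            cds_feats.append(feat)
        else:
            mat_feats.append(CdsFeature(0, intervals, strand, product, pid, is_mat_peptide=True))

    for mp in mat_feats:
        parent = None
        for feat in cds_feats:
            if feat.strand == mp.strand and feat.start <= mp.start and mp.end <= feat.end:
                parent = feat
                break
        if parent is None:
            genome.parse_warnings.append(
                f"mat_peptide [{mp.start}, {mp.end}) has no containing CDS; dropped"
            )
            continue
        mp.parent_protein_id = parent.protein_id
        mp.translation = _translate(mp.extract(seq))
        if not mp.protein_id:
            mp.protein_id = f"{parent.protein_id}_mp{len(genome.mat_peptides(parent.protein_id)) + 1}"
        genome.cds.append(mp)

    genome.cds = cds_feats + [f for f in genome.cds if f.is_mat_peptide]
    genome.proteins = [(f.protein_id, f.translation or "") for f in cds_feats]
    return genome


def read_metadata(path) -> dict[str, dict[str, str]]:
    """Read the accession metadata TSV into a mapping keyed by accession."""
    meta: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["accession"]] = row
    return meta


def apply_metadata(
    records: Sequence[GenomeRecord], metadata: Mapping[str, Mapping[str, str]]
) -> list[GenomeRecord]:
    """Attach family / Baltimore type / host to parsed records and merge
    segment groups where the metadata supplies a ``segment_group`` key."""
    groups: dict[str, str] = {}
    for rec in records:
        row = metadata.get(rec.accession)
        if row is None:
            raise KeyError(f"no metadata for accession {rec.accession}")
        if row.get("baltimore_type") and row["baltimore_type"] not in BALTIMORE_TYPES:
            raise ValueError(
                f"{rec.accession}: unknown Baltimore type {row['baltimore_type']!r}"
            )
        rec.family = row.get("family", "") or rec.family
        rec.baltimore_type = row.get("baltimore_type", "") or rec.baltimore_type
        rec.host_category = row.get("host_category", "") or rec.host_category
        group = row.get("segment_group") or ""
        if group:
            groups[rec.accession] = group
    return merge_segment_groups(records, groups)


def merge_segment_groups(
    records: Sequence[GenomeRecord], groups: Mapping[str, str]
) -> list[GenomeRecord]:
    """Merge multi-segment viruses into single genomes.

    Records sharing a group key become one :class:`GenomeRecord` whose
    accession is the group key and whose genome size is the summed
    segment length; records without a key stay as they are (matching how
    per-record genome counting works when no grouping is known).
    """
    merged: dict[str, GenomeRecord] = {}
    out: list[GenomeRecord] = []
    for rec in records:
        key = groups.get(rec.accession)
        if not key:
            out.append(rec)
            continue
        if key not in merged:
            combined = GenomeRecord(
                accession=key,
                family=rec.family,
                baltimore_type=rec.baltimore_type,
                host_category=rec.host_category,
            )
            merged[key] = combined
            out.append(combined)
        combined = merged[key]
        offset = len(combined.segments)
        combined.segments.append(rec.segments[0])
        combined.genome_size = sum(len(s) for s in combined.segments)
        for feat in rec.cds:
            feat.segment = offset
            combined.cds.append(feat)
        combined.proteins.extend(rec.proteins)
        combined.parse_warnings.extend(rec.parse_warnings)
    return out


def qc_residue_vs_genome(
    genomes: Sequence[GenomeRecord], k: float = 3.0
) -> dict[str, str]:
    """Flag genomes whose annotated residue count defies the size trend.

    Fits log10(residues) against log10(genome size) by Siegel repeated-
    median regression (robust to the very outliers it must detect) and
    flags genomes whose residual exceeds ``k`` scaled median absolute
    deviations as ``excess_residues`` or ``deficit_residues``; all other
    genomes map to ``ok``.
    """
    if len(genomes) < 10:
        raise ValueError(
            "residue-vs-size QC needs at least 10 genomes; skip QC for smaller sets"
        )
    usable = [g for g in genomes if g.n_residues > 0 and g.genome_size > 0]
    x = np.log10([g.genome_size for g in usable])
    y = np.log10([g.n_residues for g in usable])
    slope, intercept = sps.siegelslopes(y, x)
    resid = y - (intercept + slope * x)
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    cutoff = k * 1.4826 * mad
    flags: dict[str, str] = {g.accession: "ok" for g in genomes}
    for g, r in zip(usable, resid):
        if r - med > cutoff:
            flags[g.accession] = "excess_residues"
        elif med - r > cutoff:
            flags[g.accession] = "deficit_residues"
    return flags


@dataclass
class SurveySet:
    """The analysed genome set plus the excluded records and why.

    ``genomes`` is the all-virus analysis list (satellites and QC
    casualties removed).  Families at or below ``min_family_size``
    members stay in ``genomes`` for whole-set analyses but are omitted
    from :meth:`family_level_genomes`, mirroring a survey that keeps all
    genomes overall while tabulating only well-populated families.
    """

    genomes: list[GenomeRecord]
    exclusions: dict[str, str]
    min_family_size: int = 10

    def __post_init__(self) -> None:
        bad = set(self.exclusions.values()) - EXCLUSION_REASONS
        if bad:
            raise ValueError(f"unknown exclusion reasons: {sorted(bad)}")
        kept = {g.accession for g in self.genomes}
        if kept & set(self.exclusions):
            raise ValueError("excluded genome present in analysis list")

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.genomes:
            sizes[g.family] = sizes.get(g.family, 0) + 1
        return sizes

    def family_level_genomes(self) -> list[GenomeRecord]:
        """Genomes belonging to families with more than ``min_family_size``
        members (strictly greater)."""
        sizes = self.family_sizes()
        return [g for g in self.genomes if sizes[g.family] > self.min_family_size]


def build_survey_set(
    genomes: Sequence[GenomeRecord],
    flags: Mapping[str, str] | None = None,
    min_family_size: int = 10,
    qc_policy: str = "flag-family",
) -> SurveySet:
    """Apply the survey inclusion rules.

    Satellites are excluded.  QC-flagged genomes are excluded either
    individually (``qc_policy="flag-genome"``) or together with their
    whole family (``"flag-family"``, the default: a family whose
    annotation cannot be trusted for one member is suspect throughout).
    Small families remain in the returned set but are separated out by
    :meth:`SurveySet.family_level_genomes`.
    """
    if qc_policy not in ("flag-family", "flag-genome"):
        raise ValueError(f"unknown qc_policy {qc_policy!r}")
    flags = flags or {}
    flagged_families = {
        g.family for g in genomes if flags.get(g.accession, "ok") != "ok" and g.family
    }
    exclusions: dict[str, str] = {}
    kept: list[GenomeRecord] = []
    for g in genomes:
        if g.is_satellite:
            exclusions[g.accession] = "satellite"
        elif flags.get(g.accession, "ok") != "ok":
            exclusions[g.accession] = "qc_outlier"
        elif qc_policy == "flag-family" and g.family in flagged_families:
            exclusions[g.accession] = "qc_outlier"
        else:
            kept.append(g)
    return SurveySet(kept, exclusions, min_family_size)


# ---------------------------------------------------------------------------
# plain-text corpus round trip (metadata TSV + protein FASTA)

def write_corpus_tables(
    records: Sequence[GenomeRecord], tsv_path, fasta_path
) -> None:
    """Serialise a genome set to a metadata TSV plus a protein FASTA."""
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "family", "baltimore_type", "host_category", "genome_size", "n_proteins"]
        )
        for rec in records:
            writer.writerow(
                [rec.accession, rec.family, rec.baltimore_type, rec.host_category,
                 rec.genome_size, len(rec.proteins)]
            )
    with open(fasta_path, "w") as fh:
        for rec in records:
            for pid, seq in rec.proteins:
                fh.write(f">{pid} {rec.accession}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def read_corpus_tables(tsv_path, fasta_path) -> list[GenomeRecord]:
    """Inverse of :func:`write_corpus_tables` (sequences and annotation
    beyond the proteome are not round-tripped)."""
    by_accession: dict[str, GenomeRecord] = {}
    order: list[str] = []
    with open(tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rec = GenomeRecord(
                accession=row["accession"],
                family=row["family"],
                baltimore_type=row["baltimore_type"],
                host_category=row["host_category"],
                genome_size=int(row["genome_size"]),
            )
            by_accession[rec.accession] = rec
            order.append(rec.accession)
    for fasta in SeqIO.parse(str(fasta_path), "fasta"):
        accession = fasta.description.split()[1]
        by_accession[accession].proteins.append((fasta.id, str(fasta.seq)))
    return [by_accession[a] for a in order]


def peptide_spans(
    record: GenomeRecord, parent: CdsFeature
) -> list[tuple[int, int, str]]:
    """Residue intervals of a polyprotein's mature peptides on the parent.

    Returns ``(start_aa, end_aa, sequence)`` triples, 0-based half-open
    in parent protein coordinates.  Only single-interval parents and
    peptides are supported (the common case for polyproteins).
    """
    spans = []
    p_start, p_end = parent.intervals[0]
    for mp in record.mat_peptides(parent.protein_id):
        m_start, m_end = mp.intervals[0]
        if parent.strand >= 0:
            nt_off = m_start - p_start
        else:
            nt_off = p_end - m_end
        if nt_off % 3 != 0:
            raise ValueError(
                f"{mp.protein_id}: mature peptide not in frame with parent"
            )
        aa_start = nt_off // 3
        aa_len = mp.coding_length // 3
        spans.append((aa_start, aa_start + aa_len, mp.translation or ""))
    spans.sort()
    return spans
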