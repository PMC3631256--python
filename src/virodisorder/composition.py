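"""Nucleotide composition and gene-overlap statistics for viral genomes.

Two composition summaries are computed per genome: the base fractions of
the deposited genome strand over all sites, and the base fractions at
four-fold degenerate synonymous third codon positions pooled over all
coding sequences.  The four-fold sites are free of protein-level
selection, so their composition isolates the mutational/compositional
pressure acting on the genome; comparing the two site classes is what
lets a survey separate "composition drives disorder" from "selection on
disorder drives composition".

The overlap fraction measures how much of the gene-bearing genome is
shared between two or more coding sequences (strand-agnostic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "BaseComposition",
    "GenomeCompositionSummary",
    "base_composition",
    "fourfold_codon_set",
    "fourfold_site_composition",
    "overlap_fraction",
    "normalise_nucleotides",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def normalise_nucleotides(seq: str) -> str:
    """Uppercase and normalise U to T so RNA genomes need no special cases."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class BaseComposition:
    """Fractions of A, C, G, T over a pool of unambiguous sites."""

    a: float
    c: float
    g: float
    t: float
    n_sites: int
    n_ambiguous: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}

    @classmethod
    def from_counts(cls, counts: Sequence[int], n_ambiguous: int = 0) -> "BaseComposition":
        counts = np.asarray(counts, dtype=np.int64)
        n = int(counts.sum())
        if n == 0:
            raise ValueError("no unambiguous sites")
        frac = counts / n
        return cls(frac[0], frac[1], frac[2], frac[3], n, n_ambiguous)


def _count_bases(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.array(
        [int((arr == ord(b)).sum()) for b in BASES], dtype=np.int64
    )


def base_composition(seq: str) -> BaseComposition:
    """Base fractions of a nucleotide sequence (deposited strand).

    Ambiguity codes (N etc.) are excluded from the denominator and
    reported in ``n_ambiguous``.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = normalise_nucleotides(seq)
    counts = _count_bases(s)
    n_ambiguous = len(s) - int(counts.sum())
    if counts.sum() == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return BaseComposition.from_counts(counts, n_ambiguous)


def _standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


STANDARD_CODE = _standard_code()


def fourfold_codon_set(genetic_code: Mapping[str, str] | None = None) -> frozenset[str]:
    """Dinucleotide codon prefixes that are four-fold degenerate.

    A prefix ``XY`` qualifies when ``XYA``, ``XYC``, ``XYG`` and ``XYT``
    all encode the same amino acid and none is a stop.  For the standard
    code these are the eight boxes Ala/Arg4/Gly/Leu4/Pro/Ser4/Thr/Val.
    """
    code = STANDARD_CODE if genetic_code is None else dict(genetic_code)
    if len(code) != 64:
        missing = 64 - len(code)
        raise ValueError(f"genetic code table is incomplete ({missing} codons missing)")
    prefixes = set()
    for x in BASES:
        for y in BASES:
            aas = {code[x + y + z] for z in BASES}
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(x + y)
    return frozenset(prefixes)


def fourfold_site_composition(
    cds_list: Iterable[str], genetic_code: Mapping[str, str] | None = None
) -> BaseComposition:
    """Composition of third positions of four-fold degenerate codons.

    Third-position bases are pooled genome-wide across all supplied
    in-frame coding sequences.  Coding sequences whose length is not a
    multiple of 3 are skipped with a warning; codons containing
    ambiguity codes are skipped entirely.
    """
    prefixes = fourfold_codon_set(genetic_code)
    prefix_mask = np.zeros(16, dtype=bool)
    for p in prefixes:
        prefix_mask[4 * _BASE_INDEX[p[0]] + _BASE_INDEX[p[1]]] = True

    # ASCII -> base index lookup; 255 marks anything but A/C/G/T
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i

    counts = np.zeros(4, dtype=np.int64)
    n_cds = 0
    for cds in cds_list:
        seq = normalise_nucleotides(str(cds))
        if len(seq) % 3 != 0:
            warnings.warn(
                f"coding sequence length {len(seq)} not divisible by 3; skipped",
                stacklevel=2,
            )
            continue
        n_cds += 1
        if not seq:
            continue
        codons = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].reshape(-1, 3)
        clean = (codons < 4).all(axis=1)  # skip codons with ambiguity codes
        codons = codons[clean]
        if codons.size == 0:
            continue
        keep = prefix_mask[4 * codons[:, 0].astype(np.int64) + codons[:, 1]]
        counts += np.bincount(codons[keep, 2], minlength=4).astype(np.int64)
    if counts.sum() == 0:
        if n_cds == 0:
            raise ValueError("no usable coding sequences supplied")
        raise ValueError("coding sequences contain no four-fold degenerate codons")
    return BaseComposition.from_counts(counts)


def overlap_fraction(
    cds: Sequence,
    genome_size: int | None = None,
    denominator: str = "covered",
) -> float:
    """Fraction of gene-bearing positions covered by two or more CDS.

    ``cds`` may contain :class:`~virodisorder.genome_io.CdsFeature`
    objects or plain ``(segment, start, end)`` / ``(start, end)`` tuples;
    coverage is a strand-agnostic union over intervals, accumulated per
    segment.  The numerator counts positions covered at least twice.  By
    default the denominator is the number of positions covered at least
    once; ``denominator="genome"`` divides by ``genome_size`` instead.
    """
    if denominator not in ("covered", "genome"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    intervals: list[tuple[object, int, int]] = []
    for feat in cds:
        if hasattr(feat, "intervals"):
            seg = getattr(feat, "segment", 0)
            for start, end in feat.intervals:
                intervals.append((seg, start, end))
        elif len(feat) == 3:
            intervals.append((feat[0], int(feat[1]), int(feat[2])))
        else:
            intervals.append((0, int(feat[0]), int(feat[1])))
    if not intervals:
        return 0.0

    # sweep-line depth per segment
    covered = 0
    multi = 0
    by_segment: dict[object, list[tuple[int, int]]] = {}
    for seg, start, end in intervals:
        by_segment.setdefault(seg, []).append((start, 1))
        by_segment[seg].append((end, -1))
    for events in by_segment.values():
        events.sort()
        depth = 0
        prev = None
        for pos, delta in events:
            if prev is not None and pos > prev:
                if depth >= 1:
                    covered += pos - prev
                if depth >= 2:
                    multi += pos - prev
            depth += delta
            prev = pos
    if denominator == "genome":
        if not genome_size or genome_size <= 0:
            raise ValueError("genome_size required for denominator='genome'")
        return multi / genome_size
    return multi / covered if covered else 0.0


@dataclass
class GenomeCompositionSummary:
    """Per-genome composition at both site classes plus gene overlap."""

    accession: str
    total: BaseComposition
    fourfold: BaseComposition | None
    overlap_fraction: float
    n_fourfold_codons: int

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"accession": self.accession}
        row.update({k: v for k, v in self.total.as_dict().items()})
        if self.fourfold is not None:
            row.update({f"{k}4": v for k, v in self.fourfold.as_dict().items()})
        else:
            row.update({f"{k}4": float("nan") for k in BASES})
        row["n_fourfold_codons"] = self.n_fourfold_codons
        row["overlap_fraction"] = self.overlap_fraction
        return row


def summarise_genome_composition(
    accession: str,
    segments: Sequence[str],
    coding_sequences: Sequence[str],
    cds_features: Sequence,
    genome_size: int | None = None,
    genetic_code: Mapping[str, str] | None = None,
    overlap_denominator: str = "covered",
) -> GenomeCompositionSummary:
    """Assemble the full composition summary for one genome.

    Total composition is computed on the deposited strand of every
    segment pooled; four-fold composition on each CDS's coding strand.
    Genomes whose CDS yield no four-fold codons get a missing four-fold
    block rather than an error, so one peculiar genome cannot abort a
    survey.
    """
    total = base_composition("".join(segments))
    try:
        ff = fourfold_site_composition(coding_sequences, genetic_code)
        n_ff = ff.n_sites
    except ValueError:
        ff = None
        n_ff = 0
    ov = overlap_fraction(cds_features, genome_size, overlap_denominator)
    return GenomeCompositionSummary(accession, total, ff, ov, n_ff)
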