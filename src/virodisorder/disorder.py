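"""Per-residue intrinsic disorder scoring and percent-disorder statistics.

The predictor estimates, for every residue, the mean pairwise interaction
energy between that residue and its sequence neighbours inside a sliding
window, and maps the energy through a monotone decreasing logistic
calibration onto a disorder score in [0, 1].  Low estimated interaction
energy (little capacity to form stabilising contacts) yields a high
disorder score.  The packaged energy table is an additive quadratic form
built from a published amino-acid disorder-propensity scale (TOP-IDP);
it reproduces the architecture of energy-estimation predictors such as
IUPred, and the interface accepts externally computed per-residue score
files so that output of any third-party predictor can be substituted.

Percent disorder is accumulated at three levels:

* per protein:  ``D_i = 100 * (# residues with score >= S_Th) / L_i``
* per genome:   pooled over all proteins (equivalently, the residue-length
  weighted mean of the ``D_i``)
* per polyprotein: both on the intact precursor and on its cleaved
  mature peptides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "DISORDER_PROPENSITY",
    "PredictorSpec",
    "DisorderProfile",
    "GenomeDisorderSummary",
    "predict_scores",
    "call_disordered",
    "percent_disorder_protein",
    "percent_disorder_genome",
    "polyprotein_disorder_two_ways",
    "read_score_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# TOP-IDP disorder propensity scale (Campen et al. 2008): positive values
# promote disorder, negative values promote order.
DISORDER_PROPENSITY: Mapping[str, float] = {
    "A": 0.060, "C": -0.020, "D": 0.192, "E": 0.736, "F": -0.697,
    "G": 0.166, "H": 0.303, "I": -0.486, "K": 0.586, "L": -0.326,
    "M": -0.397, "N": 0.007, "P": 0.987, "Q": 0.318, "R": 0.180,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}

AMBIGUOUS_RESIDUES = frozenset("XBZJUO*")


def _default_energy_table() -> np.ndarray:
    """Symmetric 20x20 pairwise energy table.

    The pair energy of residues (a, b) is the negated mean of their
    disorder propensities: pairs of order-promoting residues have high
    (stabilising) interaction energy, pairs of disorder-promoting
    residues low energy.
    """
    p = np.array([DISORDER_PROPENSITY[aa] for aa in AMINO_ACIDS])
    return -0.5 * (p[:, None] + p[None, :])


@dataclass(frozen=True)
class PredictorSpec:
    """Parameters of the built-in windowed pairwise-energy predictor.

    Attributes
    ----------
    name:
        Identifier recorded in output headers.
    window:
        Odd window width in residues; the energy of residue *r* averages
        pair energies with all residues within ``(window - 1) // 2``
        positions (the window truncates at the termini, no padding).
    energy_table:
        Symmetric 20x20 array indexed by :data:`AMINO_ACIDS`.
    calibration_midpoint, calibration_scale:
        Logistic calibration ``score = 1 / (1 + exp((E - midpoint)/scale))``;
        ``scale`` must be positive so the map is monotone decreasing in
        the energy.
    neutral_score:
        Score assigned to ambiguity codes (X, B, Z, J, U, O); they are
        also excluded from their neighbours' windows.
    """

    name: str = "pairwise-energy-v1"
    window: int = 25
    energy_table: np.ndarray = field(default_factory=_default_energy_table)
    calibration_midpoint: float = 0.0
    calibration_scale: float = 0.1
    neutral_score: float = 0.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")
        tab = np.asarray(self.energy_table, dtype=float)
        if tab.shape != (20, 20):
            raise ValueError("energy_table must be 20x20")
        if not np.allclose(tab, tab.T, atol=1e-12):
            raise ValueError("energy_table must be symmetric")
        if self.calibration_scale <= 0:
            raise ValueError("calibration_scale must be positive")
        object.__setattr__(self, "energy_table", tab)

    def calibrate(self, energy: np.ndarray) -> np.ndarray:
        """Map windowed energies to disorder scores in [0, 1]."""
        z = (np.asarray(energy, dtype=float) - self.calibration_midpoint) / self.calibration_scale
        return 1.0 / (1.0 + np.exp(z))


DEFAULT_PREDICTOR = PredictorSpec()


def _encode(sequence: str) -> np.ndarray:
    """Map a protein sequence to integer indices; -1 marks ambiguity codes."""
    seq = sequence.upper()
    idx = np.empty(len(seq), dtype=np.int64)
    for i, aa in enumerate(seq):
        j = _AA_INDEX.get(aa, -1)
        if j < 0 and aa not in AMBIGUOUS_RESIDUES:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        idx[i] = j
    return idx


def predict_scores(sequence: str, spec: PredictorSpec = DEFAULT_PREDICTOR) -> np.ndarray:
    """Per-residue disorder scores for one protein.

    The energy of residue *r* is the mean of ``energy_table[a_r, a_j]``
    over all valid residues *j* with ``|j - r| <= (window - 1) // 2``
    (including *r* itself).  The window truncates at the termini; when the
    window exceeds the sequence it degenerates to the whole sequence.
    Ambiguity codes receive ``spec.neutral_score`` and do not contribute
    to neighbouring windows.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    idx = _encode(sequence)
    n = idx.size
    half = (spec.window - 1) // 2
    valid = idx >= 0

    # Row-gathered energies: contrib[a, j] = E(a, residue_j); ambiguous
    # positions contribute zero and are excluded from the denominator.
    contrib = np.where(valid[None, :], spec.energy_table[:, np.where(valid, idx, 0)], 0.0)
    csum = np.concatenate([np.zeros((20, 1)), np.cumsum(contrib, axis=1)], axis=1)
    ccount = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])

    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    counts = ccount[hi] - ccount[lo]

    scores = np.full(n, spec.neutral_score, dtype=float)
    rows = idx[valid]
    sums = csum[rows, hi[valid]] - csum[rows, lo[valid]]
    denom = counts[valid]
    # a valid residue always counts itself, so denom >= 1
    energies = sums / denom
    scores[valid] = spec.calibrate(energies)
    return scores


def call_disordered(
    scores: Sequence[float], threshold: float = 0.5, strict_gt: bool = False
) -> np.ndarray:
    """Binary disorder calls from per-residue scores.

    A residue is called disordered when its score reaches the threshold
    ``S_Th`` (inclusive by default: a score exactly at the threshold is
    disordered; ``strict_gt=True`` switches to a strict comparison).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    s = np.asarray(scores, dtype=float)
    return s > threshold if strict_gt else s >= threshold


def percent_disorder_protein(calls: Sequence[bool]) -> float:
    """Percent disorder ``D_i`` of one protein from its binary calls."""
    c = np.asarray(calls, dtype=bool)
    if c.size == 0:
        raise ValueError("no residues")
    return 100.0 * int(c.sum()) / c.size


@dataclass
class DisorderProfile:
    """Per-residue disorder scores and calls for one protein."""

    protein_id: str
    scores: np.ndarray
    threshold: float = 0.5
    strict_gt: bool = False
    calls: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValueError(f"{self.protein_id}: empty score vector")
        self.calls = call_disordered(self.scores, self.threshold, self.strict_gt)

    @property
    def length(self) -> int:
        """Residue count ``L_i``."""
        return self.scores.size

    @property
    def n_disordered(self) -> int:
        return int(self.calls.sum())

    @property
    def percent_disorder(self) -> float:
        """``D_i`` in [0, 100]."""
        return percent_disorder_protein(self.calls)

    @classmethod
    def from_sequence(
        cls,
        protein_id: str,
        sequence: str,
        spec: PredictorSpec = DEFAULT_PREDICTOR,
        threshold: float = 0.5,
        strict_gt: bool = False,
    ) -> "DisorderProfile":
        return cls(protein_id, predict_scores(sequence, spec), threshold, strict_gt)


@dataclass
class GenomeDisorderSummary:
    """Pooled percent disorder for one genome's proteome."""

    accession: str
    n_proteins: int
    total_residues: int
    disordered_residues: int
    per_protein: list[DisorderProfile]

    @property
    def percent_disorder(self) -> float:
        """Genome-level ``D``: pooled disordered residues over pooled length."""
        return 100.0 * self.disordered_residues / self.total_residues


def percent_disorder_genome(
    profiles: Sequence[DisorderProfile], accession: str = ""
) -> GenomeDisorderSummary:
    """Pool residues across a genome's proteins.

    ``D`` is the ratio of disordered residues to total residues across the
    whole proteome — algebraically identical to the residue-length
    weighted mean of the per-protein ``D_i``, never the unweighted mean.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no disorder profiles supplied")
    total = sum(p.length for p in profiles)
    dis = sum(p.n_disordered for p in profiles)
    return GenomeDisorderSummary(accession, len(profiles), total, dis, profiles)


def polyprotein_disorder_two_ways(
    parent: str,
    peptides: Sequence[tuple],
    spec: PredictorSpec = DEFAULT_PREDICTOR,
    threshold: float = 0.5,
    strict_gt: bool = False,
) -> tuple[float, float]:
    """Percent disorder of a polyprotein, intact and after cleavage.

    Parameters
    ----------
    parent:
        Amino-acid sequence of the uncleaved precursor.
    peptides:
        Mature peptides as ``(start, end)`` residue intervals on the
        parent (0-based half-open), optionally ``(start, end, sequence)``
        in which case the sequence is checked against the parent slice.

    Returns
    -------
    (D_whole, D_cleaved):
        ``D_whole`` scores the intact precursor over all its residues;
        ``D_cleaved`` scores every peptide independently and pools
        disordered counts over the total cleaved length.  Surveys default
        to ``D_whole``.
    """
    if not peptides:
        raise ValueError("no peptides supplied")
    spans: list[tuple[int, int]] = []
    for pep in peptides:
        start, end = int(pep[0]), int(pep[1])
        if not (0 <= start < end <= len(parent)):
            raise ValueError(f"peptide interval [{start}, {end}) outside parent of length {len(parent)}")
        if len(pep) > 2 and pep[2] is not None and parent[start:end] != str(pep[2]):
            raise ValueError(
                f"peptide sequence does not match parent slice [{start}, {end})"
            )
        spans.append((start, end))

    whole = DisorderProfile.from_sequence("whole", parent, spec, threshold, strict_gt)
    d_whole = whole.percent_disorder

    dis = 0
    total = 0
    for start, end in spans:
        prof = DisorderProfile.from_sequence(
            f"pep_{start}_{end}", parent[start:end], spec, threshold, strict_gt
        )
        dis += prof.n_disordered
        total += prof.length
    return d_whole, 100.0 * dis / total


def read_score_table(path) -> dict[str, np.ndarray]:
    """Read externally computed per-residue scores.

    Expects a TSV with columns ``protein_id``, ``position`` (1-based) and
    ``score``; returns one dense score vector per protein.  Positions must
    form a gap-free 1..L range per protein.
    """
    per_protein: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pid = row["protein_id"]
            per_protein.setdefault(pid, {})[int(row["position"])] = float(row["score"])
    out: dict[str, np.ndarray] = {}
    for pid, by_pos in per_protein.items():
        length = max(by_pos)
        if sorted(by_pos) != list(range(1, length + 1)):
            raise ValueError(f"{pid}: score positions are not a gap-free 1..L range")
        out[pid] = np.array([by_pos[i] for i in range(1, length + 1)])
    return out
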