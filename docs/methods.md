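# Methods

## 1. Disorder prediction

### Model

The built-in predictor follows the energy-estimation architecture of
IUPred-class predictors: a residue's tendency to disorder is estimated
from the composition of its sequence neighbourhood rather than from
structure.

- **Energy table.** A 20×20 symmetric table
  `e(a, b) = −(p_a + p_b) / 2`, where `p_a` is the published TOP-IDP
  disorder propensity of amino acid `a` (positive for disorder-promoting
  residues such as E, P, K, S, Q; negative for order-promoting residues
  such as W, F, Y, I, L). Lower (more negative) energy means more
  order-promoting context.
- **Windowing.** For residue `r`, the mean of `e(aa_r, aa_j)` over all
  residues `j` in a centred window of 25 (default), truncated at the
  sequence ends, with the residue itself included. Implemented with
  per-row cumulative sums, so scoring is O(20·L) per protein.
- **Calibration.** The window energy `E` maps to a score in (0, 1) via
  the logistic `1 / (1 + exp((E − m) / s))` with midpoint `m = 0` and
  scale `s = 0.1`. The midpoint sits at the natural zero of the
  propensity scale, so positive-propensity neighbourhoods score above
  0.5 and negative ones below.
- **Ambiguity codes.** X, B, Z, J, U, O receive a fixed neutral score
  (default 0.0, i.e. they are never called disordered) and are excluded
  from their neighbours' windows, so one unknown residue cannot shift
  the calls around it.

**This predictor is a stand-in.** It shares the sliding-window
energy-estimation architecture of published predictors but not their
fitted pairwise energies; its absolute output is not comparable to
IUPred's. Surveys needing a specific predictor should supply per-residue
scores through the external score-table interface
(`read_score_table`, CLI `--scores`), which replaces the built-in scores
protein by protein.

### Percent disorder

- Per protein: `D_i = 100 · (# residues with score ≥ 0.5) / L_i`. The
  threshold comparison is inclusive by default ("0.5 or more"); a
  `strict_gt` option exists for strict comparison.
- Per genome: `D` pools disordered residues over all annotated proteins,
  `D = 100 · Σ d_i / Σ L_i`. This is algebraically the length-weighted
  mean of the `D_i`, and the identity is enforced to 1e-9 in the
  acceptance suite.

### Polyproteins

Genomes annotating `mat_peptide` products under a polyprotein CDS are
scored two ways: on the intact precursor (the survey default, matching
what a whole-proteome scan sees) and pooled over the cleaved mature
peptides. The two differ only within `(window − 1)` residues of each
cleavage boundary, so
`|D_whole − D_cleaved| ≤ 100 · N_peptides · (window − 1) / L`;
with window 1 they agree exactly. Mature-peptide residues are never
counted on top of their parent precursor.

## 2. Genome handling

- GenBank records are parsed with Biopython; CDS features yield proteins
  (annotated `translation` preferred; conflicts between the annotated
  translation and the extracted nucleotide translation are recorded as
  parse warnings, with the annotation kept). `mat_peptide` features are
  attached to the containing CDS by coordinate containment.
- Coordinates are stored 0-based half-open; joins and complement-strand
  features are supported. Multi-segment genomes are merged into one
  record per virus via a metadata `segment_group` column; genome size is
  the summed segment length.
- **Survey-set rules.** Satellite genomes are excluded from all
  analyses. Genomes flagged by annotation QC are excluded (policy
  `flag-family` drops the whole family, the default for a family known
  to carry curation problems; `flag-genome` drops only the flagged
  genomes). Families must have strictly more than `min_family_size`
  members (default 10) to appear in family-level tables, but small
  families stay in the whole-set analyses. The analysed set plus the
  exclusion map exactly partitions the input.
- **Annotation QC.** log10(annotated residues) is regressed on
  log10(genome size) by Siegel repeated-median regression, which stays
  unbiased with a minority of gross outliers. Genomes whose residual
  exceeds `k · 1.4826 · MAD` (default `k = 3`) are flagged as
  `excess_residues` or `deficit_residues`. At least 10 genomes are
  required; smaller sets skip QC.

## 3. Composition

- **Whole-strand composition** keeps all four base fractions on the
  deposited strand (no GC collapsing), because strand asymmetry makes
  A≠T and C≠G informative. Ambiguous bases are excluded from the
  denominator; U is normalised to T.
- **Four-fold degenerate sites.** The 8 codon boxes of the standard code
  whose amino acid is invariant to the third base (`CT, GT, TC, CC, AC,
  CG, GC, GG`) are derived from the code table at runtime, not
  hard-coded (a brute-force enumeration over all 64 codons is the test
  oracle). Third-position composition is pooled genome-wide over all
  coding sequences read on the coding strand; CDS whose length is not a
  multiple of 3 are skipped with a warning, ambiguous codons are
  skipped silently. "No usable coding sequence" and "coding but no
  four-fold codons" are distinguished failure modes.
- **Overlap fraction.** A sweep-line over CDS intervals per segment:
  positions covered by ≥2 features divided by positions covered by ≥1
  (default) or by genome size.

## 4. Statistics

- **Spearman correlation** uses midranks. p-values: exhaustive
  permutation for n ≤ 8; fixed-seed 9,999-replicate vectorised
  Monte-Carlo permutation for 9 ≤ n ≤ 20 (deterministic across runs);
  the t approximation above that.
- **Nested size model.** `D ~ A + C + G` versus `D ~ A + C + G + S`
  (OLS; T is dropped as the reference base since the four fractions sum
  to 1; `S` is genome size in kb). The size effect is reported as the
  partial-F/t p-value of `S` and the gain in adjusted R². A
  `rank_response` option ranks `D` first, making the test invariant to
  monotone transforms of disorder. Rank-deficient designs raise rather
  than silently pseudo-inverting.
- **Calibration.** Simulation shows the size term rejects at the nominal
  5% under a size-free truth (400 replicates, n = 300: rate within the
  binomial 95% interval of 0.05; median ΔadjR² within ±0.02), and
  detects an exact in-sample standardised size effect of −0.3 with
  p < 0.05 and ΔadjR² > 0.05 in ≥95% of 200 replicates.
- **Multiple testing.** Bonferroni, `min(1, m·p)` with `m` the number of
  rows in the table being reported.
- **Variance attribution.** Adjusted R² of OLS fits on a common row set
  for each predictor set (composition, size, family, type, host and
  combinations), with categorical predictors one-hot encoded.
- **Grouped tables.** Per Baltimore type / family / host category: N,
  mean and SD of genome size and disorder, size–disorder Spearman ρ with
  Bonferroni-corrected nested-model size p, and the two adjusted R²
  values. Groups below the minimum size report summary statistics only.

## 5. Synthetic corpus generator

The generator's defaults are the study conditions; they are not tuned to
any test.

- **Families.** 12 analysis families spanning ~3–30% planted mean
  disorder and ~2 kb–200 kb mean genome size across all seven Baltimore
  classes (+RT classes), with size–disorder correlations of both signs;
  one satellite family; one family carrying planted annotation outliers
  (two ten-fold excess, two ten-fold deficit).
- **Proteins** alternate blocks drawn from an order-promoting pool
  (W, F, Y, I, L, M) and a disorder-promoting pool (E, P, K, S, Q) with
  blocks at least 3× the window, so windowed scoring resolves the
  planted disordered fraction; too-short proteins relax the block floor
  with a warning.
- **Coding sequences** come from back-translation with synonymous codons
  drawn proportionally to the product of per-base bias weights; the
  family bias couples C up and T down with planted disorder, creating
  the composition–disorder association the survey must recover. The
  back-translation always re-translates exactly.
- **Size–disorder coupling** uses a Gaussian copula (Pearson
  `r = 2·sin(π·ρ_s/6)` attains the target Spearman ρ regardless of
  marginals) between log-normal size and clipped-normal disorder.
- **Genome assembly**: coding density drawn U(0.75, 0.98) with
  non-coding padding (so annotated residues jitter realistically around
  the size trend), intergenic spacers, one polyprotein with three
  `mat_peptide` products per genome when the residue budget allows, and
  nested in-frame internal genes (the overlap gene's translation is a
  slice of the host protein, avoiding stop-codon conflicts) to hit a
  per-family overlap target.
- **Reproducibility**: per-family child streams spawned from the root
  seed, so corpora are bit-reproducible and adding or removing one
  family never perturbs another.

### Generator realism limits

Proteins are two-pool block copolymers, not natural sequences; codon
choice is independent across sites; non-coding padding is uniform
random; overlap genes are only of the nested in-frame kind; satellites
and segment structure are minimal. The generator supports calibration
and recovery testing, not biological inference about real viruses.

## 6. Numerical and formatting choices

- All floating-point reductions use numpy double precision; the pooled
  disorder identity holds to 1e-9 and composition symmetries to 1e-12.
- Output tables are TSV with `%.6g` float formatting, `\n` line endings
  and a single header comment (`# virodisorder <version> | predictor=…
  window=… threshold=… seed=… config=<sha256-12>`); report tables round
  percent columns to 0.1. Reruns under the same configuration are
  byte-identical.

## 7. Limitations

- The built-in predictor's absolute disorder levels are arbitrary up to
  its calibration; only predictor-agnostic claims (identities, bounds,
  recovery of planted structure, sign patterns) are asserted. No
  empirical claim is made about real viral corpora.
- Host-proteome disorder is not computed; the host comparison table
  joins an externally supplied host summary if given.
- The nested model is linear in composition and size; the rank-response
  option mitigates, but does not remove, sensitivity to nonlinear
  size–disorder relationships.
- QC assumes a single global residue-vs-size trend; corpora mixing
  radically different annotation conventions would need stratified QC.
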