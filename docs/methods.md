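# Methods

## Coordinate conventions

All coordinates are 0-based half-open in transcript space; positions
within a CDS are also expressed in "CDS frame" (nucleotides from the
start codon). The CDS includes one terminal stop codon, which is excluded
from the derived protein; `N` bases translate to `X` and `X` positions
are dropped from residue counts rather than imputed. Peak intervals are
collapsed to their midpoint, `floor((start + end)/2)` — the peak-calling
summit is not available in a generic peak table, and the midpoint is the
assumption-free choice.

## Synthetic data generator

The generator produces data with the statistical structure the analysis
assumes, plus a truth ledger for every planted feature.

* **Transcripts.** Coding lengths uniform in 300–900 nt plus one stop
  codon; 5′/3′ UTRs of 30–100 / 30–150 nt. Poisson(2) glutamate/lysine
  tracts of 6–12 aa are placed without overlap (resampled up to 100
  times, then an error); all other codons are uniform over the 61 sense
  codons.
* **Coverage.** Per-nucleotide P-site counts are NB(μ_g, k) with
  gene-level means μ_g log-normal around 10 reads/nt (σ_log = 0.6 — the
  spread deliberately straddles the ≥ 1 coverage filter) and size k = 5.
  Replicates are independent draws sharing means. Pauses are
  single-nucleotide multiplicative elevations (default 10×) at the first
  nucleotide of a codon 1–3 codons downstream of a tract end, matching
  nucleotide-resolution calling. In the knockdown condition the elevation
  is attenuated to `1 + (factor − 1)·attenuation` (default attenuation
  0.2). Optional per-library depth factors and a gene-level knockdown
  shift (`gene_shift_factor` applied to a random `gene_shift_fraction` of
  genes) support the normalization and coherence-filter studies; a shift
  of *every* gene is mathematically indistinguishable from library depth
  and would be removed by normalization, which is why the shift is
  fractional.
* **Footprints.** Each P-site count emits a read of uniform random length
  26–34 nt whose 5′ end sits `true_offsets[L]` nucleotides upstream
  (canonical ~12 nt at length 30). On top of this the generator emits a
  start-codon initiation pileup (Poisson((init_peak_factor − 1)·gene
  mean), default 8×): real ribosome profiling has a strong initiation
  peak, and the metagene offset calibration *depends* on it — flat
  coverage gives the 5′-end histogram a step rather than a peak and makes
  argmax calibration ill-posed. The pileup exists only at the footprint
  stage, so coverage-based statistics stay clean NB; read totals
  reconcile as `reads + clipped = coverage + initiation reads`.
* **Peaks.** One peak per tract, centered 1–3 codons downstream of the
  tract end; a configurable fraction is drawn to fail the >8-fold /
  p < 10⁻⁵ filter (half by fold, half by p-value).
* **Spectra.** Per-protein ER fraction `0.5 + bias·(u − 0.5)`,
  log-normal abundance, Bernoulli interactor flag; Poisson counts per
  pool/compartment/replicate over two experiments, with a mock-bead pool
  of mean `mock_background` and non-interactor mRNP background at mock
  level split by compartment.

What the generator does **not** emulate: sequencing error, UMI
duplication, rRNA contamination, alignment multimapping, codon-level
periodicity of elongation, positional autocorrelation of coverage, and
compositional bias of real transcriptomes. Passing tests therefore show
the statistics are implemented and calibrated as specified — not that the
pipeline is robust to those real-data artifacts.

## Pause detection

Per gene *and per replicate*: trim the `floor(0.05·L)` largest and
smallest positions (ties broken leftmost-first; vectors under 20
positions lose nothing), fit NB by method of moments (μ = m̄,
k = m̄²/(s² − m̄); Poisson fallback when s² ≤ m̄; all-zero vectors are
degenerate with all p-values 1), and compute the inclusive tail
P(X ≥ x) for every position — including the trimmed ones, which must
remain testable. A maximum-likelihood estimator is available via
`estimator="mle"`.

**Trimming correction.** Trimming clips the distribution's own tails, so
the retained-sample moments understate the spread and plug-in tail
p-values become anti-conservative (measured: ~5× too many combined
p < 10⁻³ on null data). `correct_trimmed_fit` solves for the NB whose
asymptotic *trimmed* moments — quantile integrals ∫Q(u)du over
u ∈ [0.05, 0.95], which weight boundary mass points of the discrete
distribution fractionally, exactly as count-based trimming does — match
the observed trimmed moments. This restores the dispersion estimate
(k̂ ≈ 5.05 at truth 5) and null calibration (7×10⁻⁴ below 10⁻³,
against a 2×10⁻³ bound).

Replicate p-values are combined with Fisher's method; zero p-values are
floored at 10⁻³⁰⁰ and logged. The call threshold, combined p < 10⁻⁷, is
strict. Per-replicate fits (rather than one pooled fit) keep the
combined p-values a product of independent replicate evidence.

**Known limitation.** At the 10⁻⁷ tail itself, plug-in parameter noise
(k̂ relative error ~15% at ~600 retained positions) is exponentially
amplified; null runs of ~10⁶ positions typically show 0–2 calls rather
than uniformly zero. Dispersion shrinkage across genes would stabilize
this but is a different estimator than the one implemented.

## Differential pausing

Libraries are normalized by median-of-ratios size factors against a
geometric-mean pseudo-reference (total-count fallback below 10
all-nonzero genes). The site test is an NB likelihood-ratio test
(group-mean model vs shared-mean model, χ²₁) at a common dispersion
shared across all sites. The dispersion is estimated by Cox–Reid
adjusted profile likelihood: the naive profile likelihood is biased low
because each fitted group mean absorbs residual degrees of freedom, which
inflated null type-I error to ~0.11; the CR adjustment (−½ log of the
mean's Fisher information per site and group) brings the estimate to the
truth and type-I error to ~0.055 at α = 0.05. Fold changes are
log2((mean_kd + ½)/(mean_ctrl + ½)) on normalized group means — the ½
pseudo-count keeps zeros finite. The dispersion floor is 10⁻⁸.

Gene-level differential occupancy applies the same LRT to summed CDS
counts with BH across genes (differential at FDR ≤ 0.05). The coherence
filter then classifies each site: FDR > 0.05 → `not_significant`;
significant in a non-differential gene → `retained`; significant in a
differential gene → `removed_coherence` iff
|log2FC_site − log2FC_gene| < 0.8, else `retained`.

**Power note.** At dispersion 0.2 with 3 vs 3 replicates, the per-site
log2FC standard error is ≈ 0.55, so a pure 2-fold gene-level shift is
near the detection boundary: the sites that do reach FDR significance are
selected for exaggerated fold changes and often land outside the ±0.8
coherence window. The coherence filter's *logic* is exercised directly by
unit tests; the end-to-end gene-shift study reports the fraction removed
as measured.

## Context enrichment

Anchors are peak-center codons (UTR centers are excluded and counted) or
pause-site codons (P-site codon; anchoring at an offset codon is possible
but not the default). The background is the residue composition of the
anchor-bearing transcripts' own CDSs, which controls for target
composition; a proteome-wide frequency vector can be supplied instead.
Enrichment is log2((f + ε)/(g + ε)) with ε = 10⁻⁴. The permutation null
redraws each anchor uniformly within its own transcript's codon range,
preserving per-transcript anchor counts; it yields per-cell empirical
two-sided p-values with the +1 correction, a per-cell 95% envelope, and
the distribution of the profile-wide max |enrichment| for family-wise
comparisons. Reported enrichment is a log2 ratio (not a z-score); the
choice is recorded here because ratio, log-ratio and z-score conventions
all appear in the literature.

## Fractionation proteomics

Presence: count > 0 in ≥ 2 of 3 replicates (per pool; the RNA-dependent
and ribosome-bound pools count an experiment as sufficient). Oligo-dT:
presence in every experiment *and* summed counts ≥ 2× the matched mock
total in every experiment; a zero mock total becomes a ½ pseudo-count
(logged) so strong enrichment over an empty mock is not discarded.
Percent ER excludes experiments where ER + cytosol = 0 and averages the
rest; all-zero proteins yield NaN. The curated-contaminant exclusion list
is user-supplied; the number of removed proteins is reported.

## Problem sizes and tolerances

The verification studies use: 1700 genes (~1.03×10⁶ CDS positions) × 3
replicates for null calibration; 60 genes for pause and differential
recovery; 10⁴ sites for site-test calibration; ~500+ anchors with 500
permutations for the planted-signal enrichment study and 20 runs × 200
permutations for the uniform null; 30 genes for offset recovery. Oracle
agreements are checked to 10⁻¹² (Fisher vs χ² tail) and 10⁻¹⁰ (NB tail
vs brute-force summation). The full verification run completes in about
a minute on one CPU.

## Open design choices, resolved

* "Normalized CDS coverage ≥ 1" is read as mean P-site count per CDS
  nucleotide, applied across all libraries of both conditions; an RPKM
  variant (`filter_genes_rpkm`) is provided since expression filters are
  stated both ways in the field.
* Exceedance is inclusive, P(X ≥ x) — the standard discrete convention;
  x = 0 then always gives p = 1.
* Offset ties break toward the smaller offset; the search window 8–16 nt
  brackets the canonical ~12 nt 5′-to-P-site distance.
* Histidine counts as neutral in the charge classes (mostly uncharged at
  cytosolic pH).
* Peak significance uses strict inequalities (> 8-fold, < 10⁻⁵), and the
  pause threshold is strict (< 10⁻⁷).
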