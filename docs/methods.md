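# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data model behind the tests, and the
design choices made where the underlying procedure was open to
interpretation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tumour-only somatic SNV calling and TMB

Variants called from a targeted tumour panel without a matched normal mix
somatic mutations, germline polymorphisms and artifacts. The cascade applies
independent, order-free predicates; a record is somatic iff it fails none:

| filter | predicate (fails when) | default |
| --- | --- | --- |
| depth | `depth < min_depth` | 100 |
| call quality | `call_quality < min_quality` | 40 |
| uncalled-base fraction | `nc_fraction >= max_nc_snv` (SNVs only) | 0.03 |
| strand bias | `strand_bias > strand_bias_cut` (more negative = less biased) | −80 |
| allele frequency | `vaf < min_vaf` | 0.05 |
| germline | `pop_maf_enf > 0` **and** `vaf ∈ [0.40, 0.60] ∪ (0.80, 1]` | — |

TMB is the retained somatic SNV count divided by the panel footprint in
megabases (default 0.524 Mb, the targeted regions of the 170-gene panel the
defaults model). Only SNVs count: panel indel calls carry a high
false-positive rate and contribute little to ovarian-cancer mutational load,
so indels stay in the audit trail (`NOT_SNV`) but never in TMB.

Boundary conventions are exactly as listed (99 fails / 100 passes; VAF 0.05
passes; NC 0.03 fails; strand bias −80 passes). The germline VAF windows are
closed at [0.40, 0.60] and strict above 0.80; both bounds are configurable
because the bracket convention is not fixed by the rule's usual prose
statement. By default a positive population MAF only excludes variants
*inside* the VAF windows — a strict reading of the two-sentence rule — while
`maf_always_excludes=True` gives the biologically conservative alternative.
An absent population annotation is `None`, never 0: absence from the
database is evidence *for* somatic status. Records missing a metric fail
closed with a distinct `MISSING_METRIC` reason (fail-open configurable),
preferring reproducibility over permissiveness. The
`count_only_nonsynonymous` toggle restricts TMB to non-synonymous SNVs
(oncoprint convention); the default counts all somatic SNVs. Manual
read-level review is a human step and is not modelled.

## Expression normalisation and signature scores

The three-step chain mirrors the standard nCounter scheme, fully specified
so no external software is needed:

1. **Positive controls** — each sample scaled by (cohort mean of per-sample
   positive-control geometric means) / (sample's positive-control geometric
   mean).
2. **Background** — per-sample floor at mean + 2·SD of negative-control
   probes (sample SD; floor clamped at ≥ 1 count so log₁₀ ≥ 0); endogenous
   and housekeeping values below the floor are raised to it. Controls are
   not floored.
3. **Housekeeping** — the k most stable HK genes (ascending coefficient of
   variation of log₁₀ values across samples, ties alphabetical; default
   k = 10) define a per-sample geometric mean, and each sample is scaled so
   that geomean hits the target level.

**Anchoring choice.** In the full `normalize()` chain the housekeeping
target is a *fixed reference level* (500 counts, configurable), not the
cohort mean. Because the HK step is the last per-sample scaling, dividing by
the sample's current HK geomean cancels every upstream per-sample and global
factor, making normalised expression — and therefore signature scores —
exactly invariant to per-sample multiplicative factors on the raw counts
(lane/loading effects). A cohort-mean anchor cannot have this property: it
leaves a residual global factor `mean_s(posGM_s·f_s)/mean_s(posGM_s)` that
shifts all log-scale scores together. `hk_normalize()` called directly still
defaults to the cohort-mean (lane-relative) convention. The only residual
non-invariance is the background floor's 1-count clamp, which can engage for
extreme (> 5-fold) global intensity shifts.

A signature score is the arithmetic mean of log₁₀ normalised expression over
the signature's genes present in the matrix; scoring refuses to proceed
(naming the missing genes) when coverage drops below 80% (configurable).
The packaged IFN-γ (6 genes), Expanded-immune (18) and T-cell-inflamed (18)
sets are data, not code — transcribed into YAML and editable.

Differential expression uses Welch's t-test on log₁₀ values (Mann–Whitney
selectable); the fold change is the linear-scale ratio of group geometric
means. Flags follow the volcano convention — `up` iff FC > 2 and p < 0.05,
`down` iff FC < 0.5 and p < 0.05 — on raw p-values, with Benjamini–Hochberg
q-values reported alongside but not gating (cohorts of four per group leave
no power after correction; the q column makes the cost explicit). Genes
constant across both groups get p = 1 with a warning. Heatmap preparation
z-scores each gene row across samples ("standardised by the sample mean";
plain centring via `zscore=False`) and orders rows and columns by
average-linkage Euclidean agglomeration with deterministic, input-order tie
breaking.

## ELISPOT reactivity

The specific-spot statistic is `mean(target replicates) − 2·mean(medium
replicates)` (arithmetic mean; median selectable). The doubled background
term makes the statistic conservative: a product whose target wells merely
match background scores −mean(medium) < 0. Positivity is strict:
specific > 30 spots per 5×10⁴ effectors. Negative values are reported as-is,
never clipped.

HLA-I restriction and CD137 upregulation are shown qualitatively in the kind
of experiment modelled here, so their numeric criteria are declared package
conventions, configurable and logged: blockade must remove ≥ 50% of the
specific signal (and the unblocked signal must be positive); the CD137 call
requires co-culture percent ≥ 2× the alone-condition percent and ≥ 1%
absolute. Tumour specificity requires positivity against autologous tumour
but not against the unrelated line. All three are flags: a patient is TR iff
*any* fraction's product is positive against autologous tumour, so a
positive but non-HLA-restricted PD-1⁻ response is flagged yet still counts
toward TR, and the CD137 readout confirms but never overrides the ELISPOT
label.

## Tissue quantification

Cytometry counts arrive pre-gated along a declared tree; the loader enforces
child ≤ parent at every edge. Frequencies are 100·count(node)/count(reference)
with the reference either the immediate parent or any named ancestor (e.g.
the living-cell root). An empty reference yields a *missing* frequency, not
0% — empty parents carry no information.

Multiplex-IF summaries are the unweighted arithmetic mean of per-field
percentages (default 20 fields per compartment), deliberately **not** the
pooled-count ratio: the two differ whenever field totals vary, and the
field-averaged convention weights each field equally regardless of
cellularity. FOXP3 is quantified but excluded from TR-vs-NTR comparisons by
default. Group comparisons delegate to the exact tests below, carrying the
figure-convention metadata (two-tailed / 95% for cytometry, one-tailed / 90%
with Monte Carlo estimation for IF).

## Exact small-sample tests

With ≤ 10 patients per group, p-values come from full enumeration, not
asymptotics. The Mann–Whitney U null distribution is taken over all
C(nx+ny, nx) assignments of the observed pooled multiset (mid-ranks for
ties); the Wilcoxon signed-rank distribution over all 2ⁿ sign assignments,
with zero differences dropped (the original convention). Two-tailed
p = P(|T − μ| ≥ |t_obs − μ|). Implementation: a subset-sum dynamic program
over doubled mid-ranks — integer arithmetic, so every p is an exact ratio of
arrangement counts; the test suite cross-checks against literal
`itertools` enumeration and scipy's exact methods. Note the two-tailed
convention differs from scipy's doubled-smaller-tail rule only when tied
ranks make the achievable tail sets asymmetric. Groups larger than 12 fall
back (with a warning) to seeded Monte Carlo using the add-one estimator
p̂ = (1 + #extreme)/(1 + n_perm) — itself a valid permutation p-value, never
zero — with a normal-approximation 95% CI; default n_perm = 10⁵.

At n = 5 vs 5 the smallest achievable two-tailed Mann–Whitney p is 2/252 and
the smallest paired Wilcoxon p at n = 5 is 2/32 = 0.0625 — exact floors that
frame what "significant" can mean at this cohort size.

## TMB ∨ GEP stratification

A patient is predicted TR iff TMB > tmb_cut **or** GEP > gep_cut. The rule
is deliberately disjunctive: mutational load (antigen quantity) and the
T-cell-inflamed profile (microenvironment permissiveness) capture different
routes to reactivity, and either suffices. Cuts are explicit configuration —
no canonical thresholds exist at this scale — with `suggest_cuts` as an
explicitly exploratory concordance-maximising helper that is never applied
silently. Missing biomarkers short-circuit (a patient high on the observed
one is predicted TR); patients missing both are excluded with a warning.
Concordance is (TP+TN)/n over labelled patients.

## Synthetic cohort model

`synth` generates every pipeline input from one seeded spec; the defaults
are the study conditions, not tuning knobs:

- **Cohort**: 10 patients, 5 TR (P01, P02, P04, P05, P06) / 5 NTR; per-patient
  somatic SNV counts (P01…P10) = (2, 8, 0, 0, 6, 7, 1, 2, 2, 1), chosen so the
  TMB distribution over 0.524 Mb has median 3.8, minimum 0 and maximum
  15.3 SNVs/Mb with the largest loads in the TR group. TR splits into a
  TMB-high sub-scenario (P02, P05, P06) and a GEP-high one (P01, P04) so the
  OR rule is genuinely needed end-to-end.
- **Variants**: somatic SNVs with clean metrics, VAF ~ U[0.05, 0.35], MAF
  absent; 30 germline SNVs per patient with VAF in the heterozygous/homozygous
  windows and MAF ~ U[0.001, 0.40]; 5 artifacts each violating exactly one
  named site filter. By construction the cascade's recall and precision on
  this data are exactly 1; real data add borderline metric values, shared
  artifacts and subclonal germline contamination that this model omits, so
  perfect recovery here validates the logic, not real-world accuracy.
- **Expression**: negative-binomial counts (dispersion size 20; HK size 200),
  per-sample lognormal size factors (σ = 0.2) shared by all probes, a
  geometric positive-control ladder, Poisson negatives (mean 2). Signature
  genes carry their published symbols at base mean 150 and are shifted by
  Δlog₁₀ = 0.5 in TR samples (0.15 in the TMB-high sub-scenario, so their GEP
  stays below the cut); 4 healthy-control samples are unshifted.
- **ELISPOT**: Poisson replicates (3 per condition); medium λ = 10, reactive
  target λ = 150, non-reactive λ = 10, blocked-reactive λ = 15, unrelated
  λ = 10, positive control λ = 500. Reactivity is confined to the PD-1ʰⁱ
  fraction of TR patients. At these rates the specific-spot statistic
  separates reactive (≈ 130) from non-reactive (≈ −10) by many standard
  deviations, hence the ≥ 99% product-level classification accuracy the
  acceptance checks measure.
- **Gating / IF**: binomial chains down the gating tree with group-specific
  probabilities (TR tumours richer in CD8⁺, PD-1ʰⁱ and CD137⁺ cells);
  multinomial per-field counts (20 fields/compartment, ≈ 1000 cells/field)
  with epithelial CD137⁺PD-1⁺CD8⁺ probability 0.004 (TR) vs 0.0004 (NTR) —
  a "nearly null" population, as in the tissue data this emulates.
- **Seeding**: each stage draws from `SeedSequence([master, stage_code,
  patient_index])`, with optional per-stage overrides, so changing one
  stage's seed leaves all other outputs byte-identical.

Generator-consistent stratification cuts are midpoints between the generated
low and high biomarker modes (largest value outside a high sub-scenario vs
smallest within it).

## Problem sizes and numerics

The default test and acceptance workloads — one 10-patient cohort per seed,
1,000 simulated ELISPOT products, 100 replicate 4v4 expression cohorts for
the shift-recovery property, 60 IF-direction cohorts, exhaustive
Mann–Whitney checks to pooled n = 8 — were chosen as the smallest sizes at
which each property is sharply testable; all run in seconds on one core.
Degenerate inputs are defined, not crashed: empty variant lists give TMB 0;
constant genes give p = 1 with a warning; single-sample matrices skip column
clustering; empty gating parents report missing frequencies.

## Known limitations

- Tumour-only filtering cannot distinguish rare germline variants (absent
  from the population database) from somatic ones; panel TMB over 0.524 Mb
  is a noisy, upward-biased surrogate for exome TMB.
- The normalisation chain assumes housekeeping genes are unaffected by the
  biology under study; the CV-based stability ranking is simple and
  deterministic but not a pairwise-stability (geNorm-style) analysis.
- HLA-restriction and CD137 thresholds are declared conventions, not
  community standards.
- Stratification cuts are cohort-relative; nothing here validates them
  prospectively.
- The synthetic generator draws independent genes, fields and wells; it has
  no gene–gene correlation, spatial field structure, batch effects or
  plate-position artifacts.
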