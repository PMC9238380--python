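# Methods

This note documents the models, conventions and numerical choices behind
`gutstab`, and what the synthetic cohort does and does not emulate.

## The analysis model

The study design is a double-blind, parallel-group, repeated-measures
dietary intervention: two arms (high-protein HPD, high-carbohydrate HCD),
each subject sampled at three time points (pre/mid/post), each stool
sample profiled in three compartments — 16S-derived bacterial genera,
free viral particles (FVP) and norfloxacin-induced prophages (IV) — plus
viral orthologous group (VOG) gene abundances from metagenomes. The
performance endpoint is time-trial-to-exhaustion (TTE) seconds at 95% of
maximal sustainable effort, expressed per subject as percent change from
the pre-intervention baseline.

### Diversity metrics

All taxonomic metrics operate at genus level. Alpha diversity is
summarised by richness (count of non-zero features), Fisher's log-series
α — the unique positive root of S = α·ln(1 + N/α), solved by Brent's
method to relative tolerance 1e-10 after bracketing by doubling (the
objective is increasing in α, so a sign change is guaranteed whenever
S < N; S ≥ N is reported as an unbounded-α error) — and Simpson
dominance Σpᵢ². Beta diversity uses Bray-Curtis for taxonomic tables and,
for functional gene composition, the Canberra distance averaged over the
pairs with xᵢ + yᵢ > 0. That normalisation (by the non-zero pair count,
not the vector length) matches the convention of vegan's `vegdist`, keeps
the distance in [0, 1] and makes it invariant to joint rescaling.
Features absent from both samples contribute to neither metric.

Bray-Curtis is computed on the table's values as given (`on="counts"`,
the default) with `on="proportions"` normalising each sample first. The
source analysis does not state which basis it used; counts are the
default because that is what `vegdist` does with a raw table, and both
paths are tested. No rarefaction or library-size normalisation is applied
before distance computation (also unstated upstream); callers can convert
to proportions explicitly.

### Ordination and permutation inference

PCoA is classical metric scaling: eigendecomposition of the
Gower-centred −½ J D² J. Axes with eigenvalue above 1e-9 (relative to the
spectrum's magnitude) carry scores eigenvector·√eigenvalue; negative
eigenvalues — routine for Bray-Curtis input — are reported in the
spectrum but excluded from scores and from the explained-variance
denominator. No correction is applied by default; `correction="cailliez"`
adds the smallest constant making the off-diagonal distances Euclidean
(largest real eigenvalue of the standard 2n×2n companion problem). Axis
signs are fixed by making each axis's largest-magnitude score positive so
plots reproduce; the stability statistic is a range and therefore
sign-invariant regardless.

PERMANOVA partitions squared dissimilarities: SS_total = Σd²/n over all
pairs, SS_within accumulates each group's pairwise d²/n_g, and
pseudo-F = (SS_among/(a−1)) / (SS_within/(n−a)). The p-value is the
add-one permutation estimate (1 + #{F* ≥ F}) / (1 + n_perm), which can
never reach 0 and has floor 1/(n_perm+1). With strata, group labels are
shuffled independently *within* each stratum and never across — with
subject as stratum and time point as the tested factor, time labels
permute within each subject, the repeated-measures restriction. A stratum
whose samples all share one group label cannot contribute exchange; it is
kept (its permutation is a no-op) and a warning is recorded. Pairwise
PERMANOVA tests each unordered group pair on its sub-matrix and reports
Bonferroni-adjusted p alongside raw p.

ANOSIM ranks all n(n−1)/2 distances jointly (average ranks on ties) and
reports R = (mean between-group rank − mean within-group rank)/(M/2),
permutation-tested the same way. Because R depends on distances only
through ranks, it is invariant to monotone transforms. The upstream
report quotes an ANOSIM "R²"; ANOSIM conventionally yields R, and that is
what this package computes and labels. Kruskal-Wallis uses the rank-sum H
with tie correction and a χ² reference distribution.

### The stability statistic

Per-kingdom tables are converted to proportions, kingdom-prefixed and
stacked over the samples common to all kingdoms. Because every kingdom
block of every sample sums to 1, each block contributes exactly 2 to any
pair's Bray-Curtis denominator, so the combined table's Bray-Curtis is
algebraically the arithmetic mean of the per-kingdom (proportion-basis)
Bray-Curtis matrices — asserted to 1e-12 in tests.

"Subject variance" is read as: one value per subject, the **range**
(max − min) of that subject's scores on the first principal coordinate
across its time points. "Average" applies when summarising an arm, not
within a subject — this matches a per-subject point in a box plot.
Between-subject variance is the companion per-subject value: the mean
absolute PC1 difference between the subject's samples and all samples of
*other* subjects in the same arm. Other readings (e.g. mean pairwise
dissimilarity without ordination) exist; these were chosen because they
yield one number per subject in the same ordination units. The PCoA for
stability is computed per diet arm on that arm's combined-kingdom
Bray-Curtis matrix (not globally), since the stability comparison is made
within each intervention; `per_arm_ordination=False` gives the joint
alternative.

### Responder stratification

Per-subject TTE percent change is 100·(TTE_t − TTE_pre)/TTE_pre; group
curves use the same formula on arm-mean TTE. Responders are the subjects
whose mid-intervention change exceeds the arm's expected change in the
arm-characteristic direction: improved more than expected under HCD,
reduced more than expected under HPD. "Expected" is the fitted value at
mid of a least-squares line of percent change against time-point index
pooled over the arm's subjects (degenerating to the arm's mean mid change
when only mid data are supplied). Because the line passes through the
arm's own mean, a uniformly shifted arm puts every subject on one side;
the rule then falls back to a median split on mid change (strictly
above/below the median, so an even arm with distinct changes splits
4/4). `method="median"` forces that split, `method="residual"` disables
the fallback. An arm whose subjects all share one change value is
unclassifiable and raises.

The stability-performance association is, per arm, a Kruskal-Wallis test
of within-subject variance between responder classes plus a Spearman
correlation of within-subject variance against mid TTE change. With 8
subjects per arm these tests are deliberately coarse; the package reports
them with exact inputs rather than pretending to more resolution.

### VOG functional analysis

When a query sequence aligns to several VOG targets the hierarchical
preference keeps: actual classification over putative, then greatest
V.score, then lowest E.score, then — a determinism tie-break not present
upstream — the lexicographically smallest target id. Selection is a
function of the hit *set*: shuffling input rows cannot change it. V.score
and E.score are treated as opaque ordered reals (higher- and
lower-is-better respectively). Functional richness and dominance reuse
the alpha-diversity definitions on VOG abundance vectors; percent change
from baseline divides by the subject's pre-intervention value and is
undefined (error) when that baseline is zero. Class grouping pools genes
by a user-supplied two-column mapping, sending unmapped genes to
"unclassified" and conserving totals exactly; the bundled illustrative
labels (structure / metabolism / replication / unclassified) mirror the
granularity of a typical high-level viral gene classification and are not
a curated ontology.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
at the emulated study's scale — it is the package's test bed, not a
sequencing simulator.

* **Baselines.** Each subject draws a baseline composition from a
  symmetric Dirichlet with per-feature concentration
  `subject_specificity` (default 0.3). Small values give strongly
  individual communities, reproducing the "samples cluster by
  participant" structure that dominates real gut data.
* **Temporal stability.** Each time point's composition is
  Dirichlet(κᵢ·baseline). κᵢ is the subject's stability: at κ → ∞ the
  community pins to its baseline (within-subject Bray-Curtis collapses to
  multinomial noise), at small κ it wanders. Default κ values are
  log-spaced over [10, 300] across each arm's subjects, giving every arm
  the same spread of stable and unstable individuals.
* **Diet effects.** The arm's multipliers act on named features at the
  mid time point only, then the composition renormalises — communities
  revert at post, matching the observed recovery. Defaults: Sk1virus ×4
  (FVP and IV) and Leuconostoc ×3 under HPD; Ruminococcus ×2 and
  Collinsella ×2 under HCD. Feature names are labels on abstract units,
  chosen for demonstration configs; no real taxonomy is simulated.
* **Counts.** Multinomial at a fixed per-kingdom library size: FVP 234
  and IV 187 (the reported per-sample read means), bacterial 30000 and
  VOG 20000 (this package's own choices of a plausible amplicon /
  mapped-gene depth — the corresponding real values are unspecified).
  Library-size variation can be introduced via the config but is off by
  default.
* **Performance.** Pre and post TTE vary by `tte_noise` (2%) around a
  subject baseline drawn from the arm's printed mean ± SD (HPD
  128.3 ± 29.3 s, HCD 182.2 ± 44.4 s). The mid percent change is
  arm_effect + β·(log κᵢ − arm mean log κ) + N(0, σ), with arm effects
  −23.3 (HPD) and +6.5 (HCD) and default (β, σ) = (6, 3). g(κ) = log κ
  keeps the link bounded across orders of magnitude of κ; centring within
  the arm keeps the arm's expected mean change equal to its prescribed
  effect, so simulated group curves land on the reference pattern while
  higher-κ subjects still fare relatively better. With β = 0 the
  microbiome and performance are independent — the null configuration
  used for calibration tests.

Everything is a pure function of (config, seed): per-subject random
streams are derived from the seed with fixed spawn keys, so tables are
identical regardless of the order in which kingdoms are generated.

**What passing tests do not show.** The generator draws features
independently within the Dirichlet (no ecological interactions or
phage-host coupling), uses fixed library sizes, three exact time points
with no dropout, and noise-free compositional shifts apart from sampling.
Recovery of the stability-performance link here demonstrates the
*pipeline's* correctness and calibration, not that real cohorts of this
size would yield significant associations.

## Numerical choices and degenerate inputs

* Eigenvalue positivity cutoff 1e-9 (relative); proportion columns must
  sum to 1 within 1e-9; the combined-table Bray-Curtis identity is exact
  to machine precision.
* A distance matrix of all zeros ordinates to zero scores everywhere;
  PC1 is then an all-zero series and every subject's variance is 0.
* Bray-Curtis and Canberra raise on an all-zero sample pair (undefined
  denominator); `to_proportions` raises on an all-zero column.
* ANOSIM returns R = 0 with a warning when every distance is tied.
* Subjects with fewer than two scored samples are excluded from subject
  variance with a logged warning, never silently.
* TSV writers emit floats as %.17g and readers parse with round-trip
  precision, so a write/read cycle is value-exact and pipeline reruns are
  byte-identical (checksummed in the manifest).

## Problem sizes

The default demo pipeline and the test suite use the emulated study's
scale (16 subjects, 48 samples, three kingdoms) for end-to-end runs, a
4-subject-per-arm cohort with reduced feature counts for replicated
Monte-Carlo checks (50 replicates for κ-monotonicity, 100–200 seeded
datasets for null calibration), and 199–999 permutations for individual
tests; these sizes give stable rates while keeping the whole suite quick
on a single CPU.

## Known limitations

* Bray-Curtis basis (counts vs proportions) and pre-distance
  normalisation upstream are unstated; both are exposed as options and
  the defaults documented above.
* Whether the upstream per-time-point regression was fitted per arm or
  pooled is ambiguous; this package fits per arm.
* The responder residual rule is sensitive to the time points supplied;
  the median split is the reproducible anchor (4/4 on an 8-subject arm).
* Between-subject variance has several defensible definitions; only the
  one documented above is implemented.
* The VOG class mapping is illustrative; real analyses should supply
  their own curated mapping file.
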