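# Methods

This note documents the models, parameter choices and numerical
conventions behind vinekit, and what the synthetic-data validation does
and does not establish about real array data.

## Candidate filtering and marker selection

Candidates arrive as VCF records with QUAL, per-sample GT and DP. The
filter chain flags, independently and idempotently:

- `low_qual` — QUAL < 100. A missing QUAL (`.`) is recorded as absent and
  does **not** trigger the flag; absence of evidence is not low quality.
- `indel`, `multiallelic` — only biallelic SNVs are probe candidates.
- `low_depth` — by default the site fails when **any called sample** has
  DP < 8, matching per-sample DP semantics of common callers; a `mean`
  mode compares mean depth over called samples instead.
- `high_missing` — missing genotype fraction strictly greater than 20%.
- `at_cg` — A/T and C/G polymorphisms, indistinguishable on a
  single-colour strand-ambiguous assay.
- `proximity` — another polymorphism within 35 nt (|Δpos| ≤ 35,
  inclusive) on the same chromosome. Proximity is computed **before** and
  **against all** polymorphisms, including ones later rejected, because a
  probe does not care why its interfering neighbour was eventually
  dropped. A variant is within the window of some other variant iff it is
  within the window of its nearest neighbour, so a single pass over
  per-chromosome sorted positions is exact; the test suite checks it
  against the quadratic all-pairs scan.

Quota selection fills each (species, chromosome) cell with
min(quota, available) markers: 130 per chromosome for the cultivated
pool, 40 per chromosome per wild species. Chromosomes configured as
R-locus carriers receive an additional pool of 60 markers attached to the
**chromosome**, not to a species; the pool is distributed round-robin
across the wild species present there (alphabetical order), each species
continuing down its own ranking. Within a cell the ranking is: descending
recommendation score (absent scores last); inside a score tie, greedy
maximization of the minimum distance to already selected markers (the
first pick of an empty cell is the smallest position); remaining ties by
position, then marker id. Every rule is deterministic, so re-runs are
byte-identical.

## Curation

Sample QC: call rate = called/markers, observed heterozygosity =
n_AB/n_called (undefined for all-no-call samples, which fail outright).
The default call-rate threshold is 0.85 — the value used for multi-species
panels, where species-specific probe design inflates missingness.

Marker QC: MAF from allele counts, min(p, 1−p) with
p = (2·n_AA + n_AB)/(2·n_called); no-calls excluded from all
denominators. Status precedence LOW_CALL_RATE > EXTRA_CLASS_SUSPECT >
MONO > PASS. Intensity-cluster classes of the vendor software cannot be
reproduced from exported calls; the enum is a declared call-level proxy,
with EXTRA_CLASS_SUSPECT (all three genotype classes present at MAF below
the floor) standing in for spurious-cluster detection. No claim of
equivalence with intensity-based classification is made.

Mendelian marker filter: per marker, error rate = incompatible
transmissions / evaluable transmissions pooled over all confirmed duos
(opposing homozygotes; both members called) and trios (biparental
impossibility; all three called). Markers above 3% are removed. The
filter is stateless; iteration is orchestrated by the kinship module.

## Kinship

Duo/trio inference is pure incompatibility counting — no likelihood or
IBD model. Conventions:

- The duo denominator excludes markers with a no-call in either member;
  the trio denominator requires all three called.
- Directional heterozygous mismatches: `het_mismatch_A1A2` counts markers
  where the first-listed sample is AB and the second homozygous;
  swapping the pair swaps the two counters. This directional convention
  is the package's documented reading; only the orientation, not the
  total, depends on it.
- Trio incompatibility closed form: offspring AA is impossible iff either
  parent is BB (symmetrically for BB); offspring AB is impossible iff
  both parents are homozygous for the same allele. The tests verify exact
  agreement with brute-force gamete-pairing enumeration over all 27
  genotype combinations.
- Duplicate detection reports unordered pairs with call discordance
  (both called, calls differ) at or below a cutoff (default 10). Before
  relationship analysis one member of each duplicate pair is dropped
  (lexicographically first retained).
- **Plastid markers are excluded from duo/trio statistics.** Chloroplast
  loci are haploid and maternally inherited, so a father–offspring duo
  with different chlorotypes shows opposing homozygotes there by
  construction, not by error. The CLI accepts marker metadata to perform
  this exclusion.

Threshold policy: all pairs are screened at an initial duo-error
threshold (percent). If pedigree-declared parent–offspring pairs exceed
it, the threshold is raised to the maximum error observed among known
pairs, so that every expected true pair is captured. The same relaxation
is applied to trios: the trio threshold rises to the maximum error
observed among pedigree-declared trios whose parents are both candidate
parents. This symmetric rule is a design choice of this package: with
high-error markers still present, expected trios can exceed a fixed cut
even though every one of them is genuine, and the relaxation preserves
them exactly as the duo relaxation preserves known pairs.

Iterative curation alternates inference and the 3% Mendelian filter until
no marker is removed (or an iteration cap, default 10, with a warning).
Only candidates that are **also pedigree-declared** enter the filter's
confirmed set, so coincidentally low-error pairs (full siblings can fall
below the threshold) do not contaminate marker filtering.

The relationship-class ordination standardizes the four duo variables
over pairs with a primary pedigree class (PO/FS/GP/HS/UN) and fits the
PCA on those pairs only; OTHER pairs are projected with the fitted
centering/scaling/rotation as supplementary individuals, so their large
and heterogeneous variance cannot distort the axes. Per-axis variable
contributions are squared loadings × 100 (summing to 100 per axis); each
axis is sign-fixed so its largest-|loading| variable is positive.

## Diversity and concordance

The genotype PCA codes calls as B-dosage 0/1/2, drops markers with
MAF < 0.05, mean-imputes no-calls per marker (keeping small panels
intact rather than dropping samples), centers, and decomposes by SVD with
the same sign convention. Variance fractions are relative to the total
variance of the centered matrix, hence non-increasing and summing to ≤ 1.

Platform concordance discards, per sample, markers with a no-call on
either platform. The default **zygosity** mode scores agreement of the
{hom, het} class — A/B allele assignment is platform-specific, so exact
call identity is not meaningful across platforms without harmonization.
The **strict** mode requires identical calls and can first harmonize each
marker by swapping hom codes on the second platform when that strictly
increases agreement.

## Chlorotypes

Plastid haplotypes are built from homozygous calls (AA→A, BB→B); a
heterozygous plastid call is treated as a technical artifact — masked and
counted per sample — not as heteroplasmy. Markers monomorphic across the
called panel are non-discriminating; typing uses the discriminating
positions only, so a no-call at a monomorphic position does not block
typing. Types are labelled Type1..TypeK by descending panel frequency
(ties lexicographic); the numbering is panel-relative, and mapping to any
published chlorotype nomenclature is a user-supplied table. Maternal
verdicts: *confirmed* (parents differ, offspring matches the recorded
mother), *inconclusive* (identical parental types), *excluded* (offspring
contradicts the recorded mother — matching only the recorded father, or
neither parent), *unassessable* (a member untyped).

## The trait-rule engine

Rules are data: (markers, predicate, predicted class, optional
applicability subset). Evaluation is two-sided — predicate true must meet
the predicted class, predicate false must not — with observed labels
passed through an explicit class-collapse map (e.g. OIV-225 codes
{5,6}→colored, {1,2}→non-colored). Samples lacking the phenotype or
carrying a no-call at a required marker are not evaluable; duplicate
mates can be excluded from panel-level counts. The flower-sex panel
combines a female-sterility marker set and a male-sterility marker set
into one call per sample (male / female / hermaphrodite / conflict /
unknown), with conflicts flagged and excluded from accuracy.

## The synthetic panel

The generator emulates a grapevine breeding/diversity panel; its defaults
are the package's study conditions.

**Population structure.** Five founder populations under a
Balding–Nichols model: per marker an ancestral frequency p ~ U(0.05,
0.95), then a per-population frequency from Beta(p(1−F)/F, (1−p)(1−F)/F).
Defaults: a cultivated cluster (30 founders, F = 0.05), a sylvestris-like
cluster (6, F = 0.15) and three divergent wild clusters (2 each,
F = 0.35–0.45). Markers are array-like and vinifera-ascertained by
construction, so wild clusters show lower observed heterozygosity — the
ascertainment bias seen on real multi-species arrays.

**Pedigree.** 14 founder couples × 5 offspring, one half-sib cross, one
second-generation cross (grandparent and avuncular pairs), two
interspecific crosses: 76 offspring, 152 parent–offspring duos and 76
trios among 120 samples — the relationship density of a breeding parental
panel. Transmission is Mendelian per marker with no linkage (the kinship
statistics use none). Couple size matters for the Mendelian filter's
statistics: one erroneous parent call is shared by all of that parent's
transmissions, so large couples let a single clean-marker error cascade
past the 3% threshold, while very small couples starve the filter of
independent offspring-side evidence; five offspring per couple balances
the two.

**Noise.** Two distinct processes. The panel-wide genotyping error
(default 0.5% per call) is a symmetric single-step perturbation —
hom→het, het→either hom — the smallest model producing both opposing
homozygotes and heterozygous mismatches. Planted *failing markers*
(default 100) instead model probeset cluster collapse: 10% of their calls
are wrong and homozygous (a het falls into a hom cluster, a hom into the
opposite one), the characteristic failure of a degraded array probeset.
Missingness is 3% base, +3% for wild-cluster samples, all applied to
nuclear non-candidate markers; one wild founder is planted at 80% call
rate to exercise sample QC.

**Exemptions.** Plastid markers receive neither error nor missingness,
and trait-candidate markers receive no error and no missingness either:
the planted trait loci are fully penetrant and the chlorotype logic is
deterministic, so their validation isolates the rule/typing logic itself.
The no-call and heterozygous-plastid code paths are exercised by
dedicated unit tests on crafted inputs instead.

**Duplicates.** Two founders are cloned after error and before
missingness with exactly six discordant calls (planted at positions
called in the source), mimicking somatic variants; missingness then hits
both copies independently.

**Chlorotypes.** Three haplotypes over six plastid SNPs, the first SNP
monomorphic; founders draw a haplotype (frequencies 0.5/0.3/0.2),
offspring copy the mother, duplicates copy their source. Plastid calls
are reported homozygous, never heterozygous.

**Trait loci.** Flower sex is one locus with alleles M (female-sterile →
male), H (hermaphrodite) and F (male-sterile → female; female = FF). Nine
sex markers tag the locus: four carry B with M, five carry B with F.
Seed parents are constrained to hermaphrodite diplotypes, so M and F
never co-occur and the combined call logic is exact. "Recombination" is
planted at one marker of each set (7 and 1 samples) by overwriting calls
to contradict the phenotype, leaving exactly 7 of 9 markers fully
predictive. Berry colour, seedlessness and muscat are dominant-B loci
transmitted through the pedigree, with phenotypes derived
deterministically from the true genotypes (males bear no fruit and get no
berry phenotypes). Two methoxypyrazine haplotype vectors over 11 markers
are planted in two disjoint founder groups; everyone else is homozygous
reference there.

**Streams and determinism.** Random-number streams are split per concern
(markers, founders, transmission, traits, plastid, failing markers,
error, duplicates, missingness, candidate VCF) from one seed, so toggling
one process does not shift the others; a fixed seed reproduces the panel
byte-identically.

**Candidate VCF.** Per (species, chromosome) cell the generator plants
330 clean biallelic SNVs plus ten records failing each single filter and
five proximal pairs 20 nt apart, on a 1 kb grid so nothing is
accidentally proximal; the truth record lists the flags each record must
receive.

## What the synthetic validation shows — and does not

Passing the planted-truth suite establishes that the counting kernels,
thresholds and orchestration behave exactly as specified under a model
where markers are independent, populations are Balding–Nichols-shaped,
errors are independent across calls, and trait loci are fully penetrant.
Real panels violate each of these: linkage disequilibrium correlates
markers, error is probeset- and cluster-structured, phenotypes are
incompletely penetrant and partially misrecorded, and pedigrees contain
errors. Recovery rates measured here are therefore upper bounds on
real-data behaviour, not estimates of it; headline counts from any real
array experiment (numbers of PASS markers, concordance percentages,
numbers of relationships) depend on that experiment's data and are not
reproduced by this package.

## Problem sizes

The default panel is 120 samples × ~5,000 markers (19 autosome-like
chromosomes × 262 markers, 23 trait candidates, 6 plastid SNPs) and the
default candidate pool ~38,000 records — sizes chosen so the complete
validation workflow, including brute-force oracle cross-checks, runs in
seconds on a single CPU while keeping every per-cell quota saturated and
every recovery statistic well-powered.
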