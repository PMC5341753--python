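# Methods

## Disease model and rationale

The pipeline targets risk alleles that are (i) rare in reference
populations (≤ 2% allele frequency), (ii) shared identically by
descent within a family (a single founder origin per family), and
(iii) moderately penetrant, so that within a carrier family only a
fraction of affected men — typically 40–65% here — carry the allele,
and some unaffected relatives do.  These assumptions shape every
statistic: enrichment is measured against *probands* rather than all
sequenced men (one affected man per family, so multiplex families do
not multiply-count alleles), segregation asks only that ≥ 1 sequenced
affected man per family carries the variant, and the carrier-frequency
metric deliberately uses the *full affected roster* (genotyped or not)
as denominator, which is what lets families with a single sequenced
case contribute information.

## Kinship and family statistics

Kinship uses the standard recursion (founders mutually unrelated;
φ(a,a) = ½(1 + φ(father, mother)); otherwise recurse on the deeper
individual).  Relationship degree is derived numerically as
`round(−log₂ φ) − 1`, which classifies looped/inbred pedigrees by
their kinship value rather than by path lists; the "largest set of
sequenced cases that are pairwise second-degree or more distant" uses
φ ≤ 1/8 and exhaustive subset enumeration (exact for the ≤ 12
sequenced cases supported).  Sequencing-candidate selection ranks
affected men by aggressive disease, then early onset (≤ 65 y), then
chooses the subset maximizing total pairwise relationship degree; the
subset search is exhaustive rather than greedy so the "most distantly
related" criterion is globally optimal, with id-lexicographic
tie-breaks for reproducibility.

## Carrier-bound inference

For each carrier family the candidate haplotype set is the
intersection of sequenced carriers' founder-label pairs: one label
(resolved) or two (a single carrier cannot be resolved).  An empty
intersection — possible with recombination between the variant and
the haplotype scaffold, or two mutation origins — is flagged
`inconsistent` and falls back to the union of carrier labels
(configurable to drop such families instead).  Bounds count roster
members whose pair contains each candidate; affected men missing from
the haplotype map stay in the denominator but cannot enter the
numerator (warned).  Homozygous carriers contribute both labels.  Min
and max fractions are averaged *unweighted* across carrier families
and reported as percentages to one decimal.

Because the true carrier haplotype is always a member of the candidate
set whenever the sequenced carriers are truthful heterozygotes, the
bounds bracket the true affected-carrier fraction by construction;
the test suite verifies this bracketing and the equivalence with
brute-force enumeration over all consistent single-haplotype
assignments on 1,000 simulated family replicates.

## Thresholds

All printed thresholds are inclusive (≥/≤) exactly as stated by the
design: population frequency ≤ 0.02; frequency ratio ≥ 2 with ≥ 3
segregating families; selection criteria ≥ 6 families, ratio ≥ 4 with
max average carrier frequency ≥ 40%, min average ≥ 50%, max average
≥ 67%.  Two deliberate exceptions follow the source conventions: the
gene-list alternate filter uses a *strict* < 2% population frequency,
and post-genotyping QC removes call rates strictly *below* 70% and
control carrier frequencies strictly *above* 2%.  The frequency-ratio
denominator is the *maximum* of the available European reference
frequencies (conservative: minimizes the ratio); `min` or a single
population are available behind a switch.  A variant absent from both
European references gets an infinite ratio (it passes any finite
threshold) and is flagged.

## QC semantics

Variant QC applies its three rules in a fixed order — call rate,
control carrier frequency, family count — attributing each removal to
the first failing rule.  Membership in the removed set is
order-independent (tested); only the attribution depends on order.
"Frequency in controls" is interpreted as *carrier* frequency among
study controls, switchable to allele frequency.

## Association statistics

Dominant coding throughout (carriers of ≥ 1 alternate allele vs
homozygous reference).  Logistic fits are maximum likelihood via
statsmodels with Wald CIs; age enters as a continuous covariate by
default.  Perfect-separation cases (an empty carrier cell) raise a
typed error directing the caller to Fisher's exact test — the same
fallback the stratified analysis automates when a study stratum has
no control carriers.  The polytomous model is a multinomial logistic
fit with controls as reference and per-stratum Wald intervals.

Meta-analysis is **fixed-effect inverse-variance** pooling of study
log-ORs with SEs recovered from the printed 95% CIs as
`(ln U − ln L)/(2·1.959964)`.  Fixed-effect (not random-effects)
pooling is used because it reproduces the published combined estimates
from the published per-study intervals; a DerSimonian–Laird
alternative is out of scope beyond test comparisons.  Pooled results
are reported to two decimals; CI-rounding in the inputs leaves about
±0.02 of slack (±0.03 where the input CIs are widest relative to the
estimate).

Fisher's exact test exposes three conventions: `two_sided`
(minimum-likelihood), `one_sided`, and `point` — the hypergeometric
probability of the observed table itself.  The published
family-history stratified P values match the *point* convention
(0.032 and 0.183 on the pooled tables; the one/two-sided conventions
give 0.037/0.077 and 0.280/0.518), so `point` is the default where
the pipeline mirrors that fallback; the discrepancy is documented
rather than resolved.

The risk-allele count score sums dominant indicators over a variant
set, restricted to subjects genotyped for *every* variant in the set
(complete-case); categories are 0 / 1 / 2–3 / ≥ 1 with odds ratios
versus the zero category.  The co-occurrence analysis compares
double-carriers against zero-carriers between cases and controls and
reports the observed double-carrier case count against the
independence expectation `n_cases·f1·f2`.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: 75 families drawn from
the published family-size (3–4: 5, 5–6: 30, 7–8: 22, 9–10: 15,
11–18: 3), mean-diagnosis-age (50–79.5 in five bins) and
sequenced-case (1: 44, 2: 2, 3: 13, 4: 8, 5: 7, 6: 1) marginals,
three families of non-European ancestry, 11 reference populations,
and two cohorts of 1,265/1,230 and 4,222/2,899 cases/controls with
14%/8% first-degree family history and 20% aggressive disease among
cases.  Ages are normal(65, 8) truncated to [40, 90]; family
diagnosis ages are recentred so the realized family mean equals the
drawn bin value.  Pedigrees are three generations (founding couple,
2–4 married children, 2–4 grandchildren per branch), which yields the
avuncular and cousin pairs the "distantly related" statistics need.

Penetrance is implicit: a planted variant is assigned to the founder
haplotype whose affected-carrier fraction is closest to a target
drawn from U[0.40, 0.65], leaving affection status untouched.  By
default the choice is restricted to haplotypes carried by at least
one sequenced affected man, so planting in k families guarantees k
segregating families (warned when the nearest achievable fraction is
more than 0.25 from the target).  Cohort carrier status is Bernoulli
with the planted control frequency and the odds-ratio-shifted case
frequency; variants are independent of each other and of age.

Not emulated: linkage disequilibrium and recombination (haplotypes
are variant-local; a Poisson recombination stress mode is the only
exception), genotyping error and allelic dropout, population
substructure within cohorts, age-dependent penetrance, and
ascertainment bias in family recruitment.  Passing tests therefore
demonstrate the correctness and calibration of the *computations*
under the stated model, not robustness to those real-data
complications — in particular, the co-occurrence test inherits the
susceptibility to hidden population substructure that the design
itself flags.

## Numerical and testing choices

Problem sizes in the test and acceptance suites were chosen as the
smallest that make the statistical checks sharp: 1,000 family
replicates for carrier-bound bracketing; 500 cohort replicates of
n = 7,000 for planted-OR recovery (|mean log-OR bias| < 0.05);
1,000–2,000 null cohorts of n = 2,000 for the 5% type-I error band
(0.035, 0.065); 100 random tables for the logistic-vs-closed-form
oracle at 1e-6.  The co-occurrence null calibration is checked as
sub-uniformity (P(p ≤ α) ≤ α plus a binomial band) rather than a
Kolmogorov–Smirnov uniformity test because the double-carrier counts
are small and the exact p-value is heavily discrete.  Kinship is
verified against exact enumeration over inheritance vectors (4^k
configurations for k non-founders) on a battery of ≤ 8-member
pedigrees including half-sib, looped and lineal structures; the
distant-set statistic against Bron–Kerbosch maximum cliques.

## Known limitations

Degree classification of inbred relationships is a numeric convention,
not genealogy.  The frequency-ratio denominator choice ("max" of the
European panels) is one of several defensible readings and is
switchable.  Carrier bounds assume the haplotype scaffold is correct;
real phased haplotypes carry reconstruction error the synthetic truth
does not.  The validation statistics assume unrelated cohort
subjects; no kinship correction is applied there.
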