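# Methods

This note documents the models behind `rookery`, the choices that were
genuinely open when the package was designed, and what its tests do and do
not demonstrate.

## Data model and missing data

The universal input is an aligned set of mtDNA control-region sequences over
`{A,C,G,T,N,-}` plus a population map assigning each sequence to a nesting
unit at up to three nested levels (rookery → island → beach), with
per-unit coordinates. Literature compilations of control-region fragments
differ in length, so missing data are unavoidable; `N` and `-` are treated
identically as missing. Distance-based statistics (π, Φ_ST, mismatch) use
pairwise-complete sites: each sequence pair is compared only where both
carry a called base. The rectangular-matrix statistics (Tajima's D, Fu's
Fs) instead drop columns containing any missing value, since their
variance constants assume a complete matrix.

Haplotype identity is exact string equality over the non-missing sites of
both sequences. A sequence whose observed sites are compatible with more
than one complete haplotype joins the most frequent one (ties broken by the
lexicographically smaller haplotype). The rule is deterministic and
frequency-parsimonious; it will occasionally merge a truly distinct rare
haplotype that differs only at its unsequenced sites, which is the
unavoidable cost of any non-probabilistic assignment.

Trimming uses 0-based half-open windows. The default window producing the
674-bp consensus from the 780-bp long fragment is a centred convention
(offset 53), exposed as `STUDY_TRIM_WINDOW`; the true genomic offset of the
consensus region is not determined by anything in the data model, so the
window is configuration, not a claim.

## Differentiation statistics

F_ST and Φ_ST are computed as one-level AMOVA variance-component ratios
σ²_a/(σ²_a+σ²_w). "Frequency" mode uses the identity distance between
distinct haplotypes (conventional haplotype-frequency F_ST); "distance"
mode uses raw pairwise nucleotide differences as the squared distance
(Φ_ST). Frequency mode is the default for the cross-scale tables. Negative
estimates are reported as computed; they are clamped to zero only where
averages of F_ST are formed (the East–West gradient), because averaging raw
negatives biases a gradient test downward.

Permutation p-values permute individuals among the two units and use the
`(k+1)/(n_perm+1)` rule, so a p-value of exactly 0 is never reported; the
default permutation count is 10,000 and a seed is a mandatory API argument.
Worth knowing: with identity distances on small tables the permutation
distribution is coarsely discrete and the p-value is conservative in the
tails; with nucleotide distances the statistic is effectively continuous
and the p-value is uniform under exchangeability (this is verified by a
Kolmogorov–Smirnov test over 500 null replicates in the acceptance suite).

The exact test of differentiation is a Metropolis walk over haplotype × 2
contingency tables with fixed margins and the multivariate hypergeometric
stationary law; the reported p is the chain fraction of tables no more
probable than the observed one (Fisher's tail definition). Default chain
length 10⁵ after 10⁴ burn-in. For small tables the estimate is checked
against exhaustive enumeration (and, for 2×2 tables, the enumeration
equals Fisher's two-sided exact test).

The hierarchical AMOVA uses the standard three-level nested
sums-of-squares decomposition with unequal-size coefficients; the F_CT
p-value permutes whole units among groups, preserving group sizes. With
few units the permutation space is tiny (permuting 4 units over 2 groups
has 6 distinct outcomes), so F_CT p-values at that scale are bounded away
from 0 — one reason hierarchical grouping tests are often uninformative at
basin scale.

The multiple-testing correction is Benjamini–Yekutieli step-up with the
harmonic-sum penalty c(m) = Σ 1/i, the "modified FDR" conventional in
population-genetic test batteries; it is implemented directly (and
property-tested against the statsmodels implementation). The Mantel test
is one-sided positive by default, the isolation-by-distance convention.

## Neutrality and demography statistics

Tajima's D uses the canonical a₁…e₂ constants. Its p-value is two-tailed
against a null of constant-size coalescent genealogies conditioned on the
observed number of segregating sites S (S mutations placed multinomially by
branch length, 1000 simulations by default) — conditioning on S rather than
on θ̂ matches common practice in the software this statistic is usually
reported from.

Fu's Fs is ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ̂, n) under the Ewens
sampling formula, θ̂ the mean pairwise difference count. The probability is
computed by the sequential (Chinese-restaurant) recursion, which is exactly
the unsigned-Stirling/rising-factorial formula but stable for large n; a
log-space variant covers extreme tails, and k_obs = 1 yields S′ = 1, i.e. a
+∞ sentinel that the table writers serialise but exclude from significance
assessment. Significance defaults: α = 0.05 for D, SSD and raggedness,
α = 0.02 for Fs (its null is strongly skewed).

The mismatch analysis fits the sudden-expansion expected distribution — a
τ-truncated geometric (parameter θ₁) plus a Poisson(τ)-shifted geometric
(parameter θ₀) — to the observed pairwise-difference histogram by bounded
L-BFGS-B least squares over (τ, θ₀, θ₁) with θ₁ ≥ θ₀ ≥ 0 enforced via
reparameterisation, moment-based starting values (τ₀ = mean difference
count) and 10 jittered restarts at tolerance 1e-12. SSD and raggedness
p-values come from a parametric bootstrap: coalescent samples are simulated
under the fitted piecewise history in mutational time and refitted
(default 100 bootstrap replicates). Raggedness uses a pinned boundary
convention — classes 0..d with d = max observed difference + 1, the
frequency of class d defined as 0, and the sum of squared successive
differences starting at i = 0 with x₋₁ = 0 — so a flat two-class histogram
(0.5, 0.5) scores exactly 0.5. This includes the leading term that some
formulations omit; the convention is fixed here to make the statistic
testable to machine precision.

## Structured coalescent and mutation model

The simulator is haploid/matrilineal throughout: within a deme of size N a
lineage pair coalesces at rate 1/N per generation, E[T₂] = N and θ = 2Nμ.
This differs by a factor of two from autosomal diploid conventions; all
built-in calibrations and the island-model law below use the haploid
scaling consistently. Events are backward in time: a split moves all
lineages of the derived deme into its source; an admixture pulse moves each
lineage of the destination into the pulse source independently with the
admixture fraction. Times are continuous; between events the next
coalescence (or, in the island-model variant, migration) is drawn from the
exponential race across demes.

Priors for the built-in scenarios: deme sizes uniform integers 100–500;
branching-time windows t1 = [80,100], t2 = [2000,3999], t3 = [4000,5999],
t4 = [6000,8999], t5 = [9000,10000] generations; at the 50-year generation
time of the study species the t1 window places the youngest (Mediterranean)
founding 4000–5000 years before present. Realized event times are redrawn
until strictly increasing in listed order; the windows are disjoint by
construction so rejection is rare. The mutation-rate prior is uniform on
[10⁻⁷, 10⁻³] per site per generation; a log-uniform alternative is provided
because a linear-uniform prior over four orders of magnitude puts ~90% of
its mass in the top decade, where 674-site control-region data are fully
saturated. Transition/transversion ratio κ defaults to 2.

Mutation is exact finite-sites K2P: each branch's substitution process is
the K2P continuous-time Markov chain (Poisson events with
transition:transversion odds κ:2), sampled per site from the closed-form
transition matrix. In the 0..3 base encoding (purines 0/1, pyrimidines
2/3) the three possible state changes are XOR masks independent of the
parent state, so per-branch changes are drawn as one vectorised block and
composed down the tree with a single XOR per node — this is what makes
reference tables of tens of thousands of rows practical on one CPU.

The two-deme island-model variant used as a joint oracle parameterises
migration by M = Nm, the total number of lineages exchanged between the
demes per generation (both directions combined), i.e. a per-lineage rate of
M/2N. With that convention the exact two-deme haploid coalescent gives
within- and cross-deme pair coalescence times 2N and 2N + N/M, hence an
equilibrium fixation index of exactly 1/(1+2M) — the form familiar from
organelle island-model theory. (Under the alternative convention in which
each lineage migrates at rate m, the same algebra gives 1/(1+4Nm); the
parameterisation here was chosen so the package states one law and
simulates it exactly.)

## The five colonization scenarios

S5 is fixed by the narrative it implements: Brazil founded from the
haplogroup-I ancestor at t5, Cabo Verde from Brazil at t4, USA/Mexico from
Cabo Verde at t3; the Mediterranean founded last (t1) and only from the
haplogroup-II ancestor, whose carriers then disperse to USA/Mexico and from
there to Cabo Verde as admixture pulses. The pulse times have no stated
windows, so they are placed in sub-windows below t1 ([60,79] and [40,59]
generations) preserving the narrated order, with fractions uniform on
(0.05, 0.5). The haplogroup ancestors split 50,000 generations ago (fixed),
deep enough that inter-haplogroup divergence at control-region-like
mutation rates reaches the observed ~34-point-mutation magnitude.

S1–S4 are this package's reconstructions of the competing hypotheses (their
event-level details are not published in an accessible form): S1, a
USA/Mexico-source model; S2, a stepping-stone model with Cabo Verde as the
central hub; S3, a Brazil-ancestral single wave with no recent gene flow;
S4, two waves without return dispersal. Because two of the competing models
are source/sink *gene-flow* models and the scenario engine (like comparable
ABC simulators) has no continuous migration, their source character is
encoded as recent admixture pulses from the source deme — the standard
workaround. This choice also matters for identifiability: with deme sizes
≤ 500 and founding times ≥ 2000 generations, lineage sorting between demes
is essentially complete, so haplotype-identity F_ST saturates and carries
no information about the *order* of ancient foundings; what the summary
statistics can distinguish is the recent-event structure (who exchanged
lineages with whom in the last ~100 generations) and the within-deme
signature of haplogroup admixture. The five scenarios differ exactly
there, by design.

## ABC engine

Summary statistics are all pairwise frequency-mode F_ST values among
sampled demes, in canonical sorted-deme order, with undefined (monomorphic)
pairs imputed as 0 and flagged; an extended set appends per-deme haplotype
diversity and mean within-deme pairwise distance per site. The extended set
is used for the recovery and coverage experiments because identity-based
F_ST alone is blind to the haplogroup-admixture signature (an admixed deme
shows inflated π at unchanged haplotype-identity distances) — the same
reasoning that makes the observed system's high-π demes diagnostic.

Rejection uses Euclidean distance on median/MAD-normalised statistics
(zero-MAD statistics excluded, ties broken by row index). Model choice fits
an unpenalised multinomial logistic regression of scenario identity on the
normalised statistics within the retained set and reads the posterior
probability at the observed vector; fit quality per retained-set size is
McFadden's pseudo-R², with confidence bands from bootstrap resampling of
the retained set (500 resamples by default), and the selected scenario is
flagged as clear when its band does not overlap the runner-up's at the
largest retained-set size. Complete separation or a single-scenario
retained set falls back to within-set frequencies, flagged. The polytomous
weighting used by some ABC packages is not implemented; the fit is the
plain multinomial likelihood.

Posterior parameters use the classic local-linear adjustment with
Epanechnikov weights; strictly positive parameters are adjusted on the log
scale so the adjustment cannot leave the support. In a two-deme split
model the derived deme's size is cleanly identified by its within-deme
diversity, whereas the root deme's size doubles as the ancestral size and
is only weakly identified — its interval coverage sits at the edge of
nominal, a known limitation worth remembering when reading posterior
tables for the root deme.

Reference tables default to 100,000 rows at desk scale (the study-scale
analysis this mirrors used 4,000,000); tables are TSV with a header line
carrying the statistic names and scenario ids, rebuildable exactly from
`(seed, row index)`.

## Synthetic-data generator

The generator emulates the features the statistics feed on: two haplogroup
founders separated by exactly 34 point mutations at uniformly chosen sites;
star-like within-haplogroup scatter (each non-founder haplotype carries
1 + Poisson(1.5) private substitutions); archipelago-wide haplotype
frequencies drawn from a Dirichlet with concentration 0.2 (producing the
1–2 dominant haplotypes per unit seen in real frequency spectra); island
frequencies re-drawn around the archipelago frequencies at concentration 60
(weak but non-zero among-island structure); one island with haplogroup-II
mixture 0.7 (the admixed, high-π island); and one beach re-drawn at
concentration 4 (the isolated beach detectable at local scale). Default
total sample size is 565 over six islands and three beaches, chosen so the
full statistical battery runs in seconds.

What the generator does *not* emulate: real haplotype genealogies within
haplogroups (scatter is star-like, not coalescent), sequencing error,
length heterogeneity and indel structure of real compilations,
sample-size imbalance at the basin scale (thousands versus dozens), or
temporal structure across nesting seasons. Tests passing on generated data
therefore demonstrate the correctness and calibration of the statistics
and the end-to-end plumbing — not that any particular biological
conclusion would be recovered from real data.

## Experiment sizes in the acceptance suite

The acceptance tests re-derive every guarantee at sizes chosen to keep the
full suite in minutes on one CPU: coalescent moments from 5,000–10,000
genealogies; null-calibration from 500 replicates at 99 permutations or
3,000-step chains; scenario recovery from a 50,000-row reference table
(10,000 rows per scenario, 20 samples per deme) against 50 pseudo-observed
datasets per scenario, each classified from its 4,000 nearest rows;
parameter coverage from a 15,000-row table and 50 runs; island-model
equilibrium from 400 replicate datasets per migration level, compared as a
pooled variance-component ratio with a bootstrap standard error.
Pseudo-observed datasets for the recovery experiment are drawn with prior
parameter values but a fixed mutation rate of 34/(2·50000·674) per site per
generation — the rate at which the built-in deep haplogroup split
accumulates the calibrated 34-point-mutation divergence — so that
recovery is assessed in the data regime the scenarios describe rather than
in the saturated regime that dominates the linear-uniform rate prior.

## Known limitations

- No recombination (appropriate for mtDNA) and no selection.
- No continuous migration in colonization scenarios (pulses only); the
  island-model variant with continuous migration exists for calibration.
- The exact test's chain p-value carries Monte-Carlo error; for tables
  with ≲10⁵ configurations the exhaustive enumerator is available and
  preferable.
- Frequency-mode F_ST saturates under complete lineage sorting; use
  distance mode (Φ_ST) when divergence times, not recent exchange, are the
  quantity of interest.
- The mismatch bootstrap refits with fewer restarts than the primary fit
  (3 versus 10); p-values near a rejection boundary deserve a rerun at
  higher settings.
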