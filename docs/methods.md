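# Methods

This note documents the models and estimators implemented in
`flocknet`, the choices made where the design was genuinely open, and
what the bundled simulator does and does not emulate.

## Data model

Genotypes are unordered diploid allele pairs (positive integer codes,
typically fragment lengths) per animal per locus, with an internal
missing sentinel distinct from 0 so that a literal allele code `0` in an
input file can never pass silently. Herd and animal identifiers are
opaque strings. The herd label carried into every analysis is the herd
of **birth**: animals whose birth herd is unknown are kept in the table
but excluded from herd-level statistics. Exchange records are directed
pairs of herds; every network metric uses the undirected view (one edge
as soon as any exchange is reported in either direction), with the
directed records retained only for reporting.

## Diversity statistics

* **Ho** is the fraction of heterozygous typed individuals; **He** is
  Nei's unbiased gene diversity (2n/(2n−1))(1 − Σpᵢ²) with n the typed
  individuals at the locus. Monomorphic loci report Ho = He = 0 and
  Fis = NA. Multi-locus unit summaries are unweighted means over
  polymorphic loci — the weighting is not identifiable from breed-level
  reports, and the unweighted mean is the convention of the F-statistics
  literature.
* **Fis** is the Weir–Cockerham small-sample f, computed from the
  within-population variance components b and c summed over alleles
  (f = 1 − Σc/Σ(b+c)). A naive 1 − Ho/He variant is available via
  `fis_method="naive"` for cross-checks.
* **Allelic richness** uses hypergeometric rarefaction to a common gene
  count g, by default the smallest (unit, locus) gene count — the
  convention that makes richness comparable across unequal samples.
  Computed in log-gamma space for stability.
* **Hardy–Weinberg exact test.** Conditioning on the allele counts,
  random mating makes every arrangement of the 2N genes into N
  individual slot-pairs equally likely. The sampler is therefore a
  uniform random-transposition walk on gene arrangements (pick two
  animals, swap one allele copy each; every proposal accepted); the
  marginal over genotype tables is exactly the conditional
  distribution, and the p-value is the stationary probability of tables
  no more probable than the observed one (probability test). The
  chain's defaults mirror the classical toolchain (100 batches × 5000
  iterations, dememorization 10 000); the Monte-Carlo standard error is
  the across-batch standard error. During development this design was
  validated two ways: against full enumeration for two alleles, and by
  requiring the p-value distribution under simulated random-mating data
  to be uniform — the latter check caught, and the current formulation
  fixes, a subtle double-counting of table multiplicities that a
  Metropolis ratio on count tables would introduce on this state space.
* **Null alleles** are screened with Brookfield's estimator 1,
  r = (He − Ho)/(1 + He), flagged when r exceeds a configurable
  threshold (default 0.05) with Ho < He. This is a deliberate
  simplification: only the binary suspicion outcome feeds downstream
  marker-exclusion decisions, so the full Micro-checker machinery
  (stutter/large-allele diagnostics) is out of scope.

## Differentiation

* **Fst** is the Weir–Cockerham (1984) θ: per-allele, per-locus variance
  components a (between populations), b (between individuals within
  populations), c (within individuals), combined as
  θ = ΣΣa / ΣΣ(a+b+c) over alleles and loci. Loci monomorphic across
  all units are skipped. The standard deviation is the classic delete-1
  jackknife over loci, sd = √[((L−1)/L) Σ(θ₍₋ᵢ₎ − θ̄)²], requiring at
  least three informative loci.
* **Reynolds distance.** Pairwise herd coancestry θ̂ uses a moment
  estimator derived from the pure-drift model that motivates the
  Reynolds–Weir–Cockerham (1983) least-squares estimator: per locus,
  numerator = ½[Σᵤ(p₁ᵤ−p₂ᵤ)² − ĥ₁/(2n₁) − ĥ₂/(2n₂)] and denominator =
  numerator + (ĥ₁+ĥ₂)/2, where ĥᵢ is the unbiased gene diversity; loci
  are combined by summing numerators and denominators. The reported
  distance is D_r = −ln(1−θ̂), the form linear in drift time; θ̂ itself
  is available via `kind="theta"`. Negative θ̂ is truncated at 0 before
  the log; a pair's distance uses only loci typed in both herds. No
  bit-compatibility with any legacy implementation is claimed — the
  estimator is documented here and cross-checked against an
  independently coded version of the same moment conditions.
* Herd-level matrices include only herds with ≥5 genotyped animals by
  default (`min_animals`), the usual survey threshold below which herd
  allele frequencies are too noisy.

## Admixture clustering

The model is the admixture model with **independent** allele
frequencies: cluster k carries frequencies ~ Dirichlet(λ=1) per locus,
individual i a membership vector qᵢ ~ Dirichlet(α) (symmetric), and
each allele copy an independent latent origin. This is a deliberate
deviation from the correlated-frequency F-model of the classical
software: the extra hierarchy is unnecessary for the strongly drifted,
desk-scale scenarios this package validates on, and the downstream
q̄-threshold rule is agnostic to the prior. α is updated by a
Gaussian-proposal Metropolis step (sd 0.25) under a uniform prior on
(0, 10]. The reported q is the posterior mean over post-burn-in sweeps;
lnP is the conventional mean(lnL) − var(lnL)/2 estimator of the model
log-probability, computed from the complete-data log-likelihood
Σ log(Σₖ qᵢₖ Pₖₗₐ). Same seed, same parameters ⇒ bit-identical output.

Default chain lengths are 10 000 burn-in + 10 000 sweeps (the classical
10⁵/10⁵ is configurable); the validation suites use a few hundred
sweeps, which the recovery experiments below show is ample at the
simulated separation levels. Runs at one K are label-aligned by greedy
matching on q-column correlation before averaging. ΔK follows the
second-difference criterion on lnP means over replicate runs,
ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd[L(K)], endpoints NA, sd = 0
reported as +inf with a warning. argmax ΔK is a *suggestion* exposed as
`best_k`; the cluster count actually used downstream is always a user
decision, since second-difference criteria are known to favor the top
level of hierarchical structure (often K = 2).

Herd assignment: q̄(herd) is the unweighted mean of member q vectors;
a herd joins the genetic group of its best cluster iff max q̄ ≥ 0.7
(boundary inclusive), ties at or above threshold resolve to the lowest
cluster index, otherwise the herd is UNASSIGNED.

## Networks and the Mantel test

AD = 2e/n holds bit-exactly for every emitted graph and stratum. SPL
matrices come from breadth-first search; geodesic counts from the BFS
predecessor recurrence σ(s,v) = Σᵤ σ(s,u). The per-SPL stratum for
distance d is built from the pair set P_d: its vertices are the herds
in at least one pair of P_d, its edges the edges of the analysis graph
induced on those vertices. This construction is fixed and documented
because published per-stratum edge/herd counts for d ≥ 2 are not
reproducible from text descriptions alone; the d = 1 stratum provably
equals the full analysis graph whenever no herd is isolated.

The Mantel statistic is the Pearson correlation over the strict upper
triangle; the null distribution permutes rows and columns of one matrix
jointly; p = (hits + 1)/(n_perm + 1) so p is never 0, default 10⁵
permutations, seeded. The default tail is one-sided (positive
association), matching the directional hypothesis that exchange
partners are genetically closer; two-sided is available. Herd selection
before the test: ≥ `min_animals` genotyped **and** membership in the
largest connected component of the exchange graph restricted to
qualifying herds (isolated islets would contribute infinite SPL).
SPL enters the correlation untransformed.

## Donor tiering

Tier 1: genotyped candidates, assigned by their own q with the same 0.7
threshold (at the individual level — a reuse of the herd rule, config
settable); unassigned genotyped animals remain tier 1. Tier 2:
ungenotyped candidates with genotyped parents (preferred) or, failing
that, genotyped grandparents; the putative group is the relatives'
common group, and any disagreement or unassigned relative yields
UNASSIGNED — conservative by design. Tier 3: network-only candidates
take their natal herd's group, or if that herd is unassigned, the
majority group among its direct exchange partners, ties ⇒ UNASSIGNED.
The majority-partner rule is this package's own deterministic stand-in
for a step whose published description is informal; it uses only
network information. Ranking is tier-ascending and round-robin across
groups within a tier, so per-group counts in any prefix differ by at
most one. Candidates with no evidence at all are reported as
uncharacterizable, never dropped.

## The simulator

`simulate_scenario` is a forward-time Wright–Fisher model on a herd
network: founder allele frequencies per locus ~ symmetric Dirichlet
(default 8 alleles, 19 loci); each generation every herd's gene pool is
mixed with a `migration_rate` fraction of one uniformly chosen network
neighbor's pool, then resampled as 2N genes (default N = 20 diploids).
The final generation is sampled into 5–15 diploid genotypes per herd
(uniform), matching field-survey sampling depth. The exchange-record
table is the network's edge list; optional islet components exercise
the isolation filter; optional ungenotyped offspring of sampled parents
exercise the pedigree tier. Multi-group scenarios draw one independent
founder pool per group — strong, unambiguous separation — rather than
hierarchically drifting group pools from a global ancestor.

What it does **not** emulate: overlapping generations, named-animal
movement (migration acts on gene pools), mutation (off by default at
these timescales), genotyping error, and unequal herd census sizes.
Passing recovery tests therefore demonstrate estimator correctness and
pipeline wiring under the stated drift model, not robustness to those
real-data complications.

Verified simulator properties: allele-frequency trajectories are
martingales (mean final frequency within 0.02 of founder over 500
replicate herds); heterozygosity decays as (1 − 1/2N)ᵗ within 10% at
t = 50, N = 20; zero migration at long times gives herd Fst > 0.2 and
heavy migration on a complete graph gives Fst < 0.02.

## Validation scales and numerical choices

The validation suites run at deliberately small problem sizes chosen as
the smallest scales at which each property is decisively testable:
oracle-equivalence checks use 200 random graphs (n ≤ 12) against
Floyd–Warshall, exhaustive path enumeration at n ≤ 10, full 4!
enumeration for the Mantel null, and direct subset enumeration for
rarefaction; calibration uses 500 independent-matrix Mantel replicates
(type-I error within [0.03, 0.07] at the 5% level) and 300 HWE
replicates (Kolmogorov–Smirnov uniformity at the 1% level); recovery
uses ten 3-population drift scenarios (ΔK argmax = 3 in ≥ 8),
and a 5-point average-degree grid with 20 replicates per point for the
connectivity-vs-differentiation trend. Gibbs chains in these suites run
200–400 recorded sweeps, which the ΔK tables show is far past decisive
at the simulated separation (ΔK at the true K exceeds the runners-up by
one to two orders of magnitude).

Tolerances: estimator-vs-oracle comparisons assert agreement within
1e-10; Monte-Carlo comparisons use 2–3 standard errors; q simplex sums
are enforced to 1e-9. Degenerate inputs (monomorphic loci, empty herds,
all-missing cells) yield NA or documented skips, never silent zeros.

## Known limitations

Reynolds θ̂ is a moment estimator, not a replica of any specific legacy
binary; ΔK inherits the well-known K = 2 attraction of second-difference
criteria; the Gibbs sampler has no correlated-frequency prior and no
linkage model, so it will under-resolve weakly diverged populations
that the F-model can separate; and network edges are unweighted —
exchange volumes, when known, are not modeled.
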