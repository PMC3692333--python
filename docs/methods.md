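# Methods

## The simulated pedigree

Each replicate is a three-generation family built from a panel of L
autosomal STR loci. Founders (paternal grandparents I and J, the mother F,
the aunt's partner N, the father's second partner S, the half-sibling
scenario's mother J2, and a random man X) are drawn under Hardy–Weinberg
equilibrium: both alleles at each locus are independent draws from the
locus's allele-frequency distribution. Every child receives one uniformly
chosen allele from each parent, independently across loci. Mutation is
deliberately not modelled: a child allele always exists verbatim in a
parent, so the true father can never be excluded, and the non-exclusion
rates isolate the contribution of allele sharing between relatives.

The pedigree realizes seven alleged-father relationships against a tested
child: the true father E (child of I×J), the child's full sibling C, the
grandfather I, the paternal uncle K, the cousin R (son of the father's
sister D), a random man X — all tested against child B of E×F — and the
child's half brother W (child of E×S), tested against child M of E×J2 so
that alleged father and child share exactly one parent. Maternal
grandparents and additional random persons appear in no pairing and are
not simulated. Expected identity-by-descent sharing (k0, k1, k2) is
(¼,½,¼) for siblings, (½,½,0) for grandparent, uncle and half sibling,
(¾,¼,0) for cousins and (1,0,0) for the random man; the test suite checks
the simulated per-locus sharing against exhaustive-enumeration
probabilities built from these coefficients.

Randomness follows one master `numpy.random.SeedSequence`; it spawns one
child stream per family, so family i is identical regardless of how many
families are simulated after it, and each family consumes draws in a fixed
order (one uniform block for founders, one transmission block per child
generation).

## Exclusion rules and the non-conformity tables

Duo (motherless) exclusion at a locus is the standard no-shared-allele
rule. Trio exclusion derives the obligate paternal allele set from mother
and child — child aa → {a}; child ab with the mother carrying exactly one
of them → the other; child ab with the mother carrying both → {a, b} — and
excludes an alleged father carrying none of it. Because the obligate set
is a subset of the child's alleles, a duo exclusion always implies a trio
exclusion, so per-pair trio mismatch counts dominate duo counts and trio
non-exclusion rates can only be lower. A mother–child incompatibility is
impossible without mutation and is treated as a pipeline error, never as
an exclusion.

Per pair, the number k of excluded loci is histogrammed over k = 0..L
(row I), accumulated (row II — the number of pairs that would *not* be
excluded if up to k mismatches were tolerated, e.g. attributed to
mutation), and converted to rates (row III). The accumulative rate uses
the Agresti–Coull (modified Wald) estimator in its "add two successes and
two failures" form: center p̃ = (x+2)/(n+4), half-width z·√(p̃(1−p̃)/n)
with z the exact 0.975 standard-normal quantile (≈1.959964) at the default
α = 0.05. This hybrid — adjusted center, Wald standard error over the raw
trial count — is the variant that reproduces published tables of this
design cell-for-cell at two printed decimals; it differs from the fully
adjusted z²-form only in the third decimal at n = 10 000. The adjusted
center is strictly positive at x = 0, which is why a zero-count cell
reports 0.02 ± 0.03% rather than 0. Reported cells are rounded half-up to
two decimals; unrounded values are retained internally and in the JSON
dump.

## Paternity indices

The per-locus paternity index compares P(child | tested man is the father)
with P(child | a random man is the father). Both hypotheses share the
maternal transmission factor, so duo and trio cases reduce to one
two-transmission formula: for child {a,b}, P = M(a)·Q(b) + M(b)·Q(a) (and
M(a)·Q(a) for a homozygote), where M is the maternal distribution — the
mother's transmission probabilities in a trio, the population frequencies
for the untyped duo mother — and Q is the paternal one (tested man's
transmission probabilities in the numerator, population frequencies in the
denominator). This reproduces the familiar closed forms (child aa, father
aa → 1/p_a; child ab, father ab → (p_a+p_b)/(4 p_a p_b); trio child ab,
mother aa, father bb → 1/p_b) and yields PI = 0 exactly on the loci the
exclusion rules flag.

The combined LR is the product over loci; a single zero factor annihilates
it, so pairs with any non-matching locus are summarized only through the
exclusion tables and never enter Log LR summaries — their non-excluded
count therefore equals the k = 0 histogram cell. Log LR is base 10.
Summaries report min, max and mean over non-excluded pairs with a t-based
confidence half-width of the mean, t₁₋α/₂(n−1)·s/√n (undefined for n < 2;
with n = 2 the t quantile 12.706 makes the interval deliberately wide).
The posterior probability of paternity W = 100·LR·π/(LR·π + 1 − π) uses
prior π = 0.5 by default (the conventional neutral prior, under which all
published Log LR ↔ W pairs interconvert); it is exposed as a parameter.

## Synthetic frequency panels

Real forensic frequency tables are population-specific and usually not
redistributable, so the generator produces stand-ins with the statistical
character of an Identifiler-style panel: per locus, an allele count drawn
uniformly from 8–15 and frequencies from a symmetric Dirichlet with
concentration 1, floored at 10⁻⁴ and renormalized. The floor keeps every
random-man denominator finite. Across seeds this yields mean expected
heterozygosity ≈ 0.8, in the range of real 15-locus panels. The defaults
are exposed as parameters; a user-supplied CSV (`locus,allele,frequency`)
replaces the generator everywhere.

What the synthetic panel does *not* emulate: the actual allele spectra of
any real population, linkage or linkage disequilibrium between loci,
population substructure (no θ/co-ancestry correction), silent alleles, or
mutation. Consequently the package reproduces published *rates* only in
ordering and rough magnitude under synthetic panels — e.g. sibling duo
non-exclusion near 15–19% and random-man near 0.02–0.04% — while the exact
published figures require the original population's frequency table, which
can be supplied as input. The report *arithmetic* (cumulative counts,
interval cells, LR conversions and summaries) is frequency-independent and
is verified cell-for-cell against the reference tabulations bundled in
`parentsim.reference`.

## Study sizes and numerics

The default study — 10 000 families, 15 loci, 7 relationships × 2 modes —
runs in a few seconds: family simulation loops over per-family substreams
while all exclusion and PI evaluation is vectorized over the population.
The test suite's Monte Carlo checks use 10 000 replicates with 3-standard-
error bands (≈99.7% coverage per check) against enumeration oracles at
2–4-allele loci. Allele labels are opaque tokens throughout; no arithmetic
is ever done on repeat counts. Probabilities and LRs are computed in
double precision; with L = 15 and frequencies ≥ 10⁻⁴ the combined LR stays
far from overflow (log₁₀ LR ≤ ~60 in the worst constructed case, ≤ ~16 in
practice).

## Known limitations

* No mutation model: one observed mismatch in real casework may be a
  mutation rather than a true exclusion; the cumulative rows quantify the
  false-inclusion cost of tolerating k mismatches but the package takes no
  position on a mutation-aware decision rule.
* Duo/trio only: no deficiency cases with other typed relatives, no
  X/Y-chromosomal or mitochondrial markers.
* Independence across loci and Hardy–Weinberg within loci are assumed
  exactly as simulated; real populations deviate through substructure and
  relatedness of founders.
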