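# Methods

## Kinship: the Reverse Parentage Index

The per-locus statistic compares two hypotheses for an observed trio
(mother AB, father CD, child BC): the couple drawn at random from the
population with the child their biological offspring, versus three
unrelated random draws. Writing T for the Mendelian transmission
probability of the child's genotype given the parents (each parental
allele transmitted with probability 0.5) and HW(child) for the child's
Hardy–Weinberg genotype probability (2·p_a·p_b heterozygous, p_a²
homozygous),

    RPI = [P(AB)·P(CD)·T] / [P(AB)·P(CD)·HW(child)] = T / HW(child).

The implementation computes T by enumerating the four equally likely
parental gamete pairs, and evaluates the ratio in its cancelled form, so
the result is exactly invariant to the frequencies of alleles carried only
by the parents (this invariance is property-tested). For the AB×CD→BC
configuration the closed form 0.25/(2·p_B·p_C) is recovered to 1e-12.

Assumptions: loci are unlinked and combined by multiplication; no mutation
term, no silent alleles, no θ-correction for population substructure. The
amelogenin sex marker is never included in the product — it gets a
dedicated X/Y transmission check (mother must be X/X; a son's Y must come
from the father). Loci with any missing member genotype are excluded from
the product and reported, never imputed: in practice such gaps are filled
by retyping (e.g. a second skeletal element), which is an upstream data
decision, not a statistical one.

The posterior ("kinship probability") uses the Essen-Möller form
W = CRPI·π/(CRPI·π + 1 − π) with a configurable prior, default π = 0.5.
The conversion and the prior are package choices; likelihood-ratio users
can ignore W entirely.

## Alu presence/absence calls and congruence

Two amplification strategies are reconciled per sample per locus:

* FAP (flanking primers): the long amplicon (presence allele, ~450–500 bp
  here) and the short one (absence allele, one Alu insert shorter) are
  each either seen or not seen on the gel.
* IAP (one flanking primer + an Alu-subfamily-internal primer): a
  ~118–194 bp amplicon that proves at least one presence allele but says
  nothing about the second allele.

The reconciliation truth table is total over all inputs. For ancient
samples a single FAP band yields "+" (`P_any`) or "−" (`A_only`), never a
definite homozygote, because dropout preferentially removes the long
presence fragment; modern-DNA samples are called at face value (PP/AA).
An absence-only FAP result plus an IAP band is the combined-result
heterozygote ("CR"): the absence allele seen directly, the presence allele
proven by the short amplicon. A totally failed FAP with an IAP band yields
`P_any`. A depleted extract behaves as an untested IAP, but a resulting
missing call carries the depletion as its reason.

Calls expand to compatibility sets — the genotypes they could represent:
PA→{PA}, PP→{PP}, AA→{AA}, P_any→{PP,PA}, and A_only→{AA} in `strict`
mode or {AA,PA} in `dropout_tolerant` mode. Trio congruence is an
existential check over the ≤27 genotype triples, verified in tests against
an independently written transmitted-insert-count enumerator; it is
monotone in set inclusion, so strict congruence implies dropout-tolerant
congruence. Classification uses strict mode: a locus is `definite` when
all three members yield a call and the trio is congruent, `incongruent`
when complete but conflicting, `incomplete` when a member is missing, and
`not_investigated` when the missing call stems from a depleted extract.
A missing member takes precedence over a conflict.

Note a deliberate asymmetry in strict mode: an absence-only result is read
as {AA} (the short absence fragment is trusted), while a presence-only
result stays {PP,PA} (absence of the *short* band is informative, but the
"+" convention does not commit to zygosity). Consequently the incongruence
signature that triggers internal-primer retesting is a presence-bearing
child with absence-only parents — an insert cannot appear de novo — while
an absence-only child among ancient parents is never, by itself,
incongruent.

## The packaged fixtures

The worked-example trio ships as verbatim transcriptions of the published
consensus STR tables (13 autosomal systems + amelogenin; the daughter's
D16S639/D2S1338/D19S433 genotypes stem from a second bone of the same
individual, recorded in a `source_bone` column; the "D16S639" spelling is
kept verbatim with an optional alias map to D16S539). The 30-locus Alu
observation fixture encodes only what the study's running text states —
22 loci definite from FAP alone, IAP rescues at Alu_3/14/19/20,
combined-result heterozygotes at Alu_16/26/27, Alu_2/7 incongruent,
Alu_4/25 extract-depleted — with synthetic congruent band patterns at loci
whose genotypes were never printed; the file says so in its header. The
frequency table is synthetic (European-plausible values, incomplete per
locus by design); the study's own frequencies came from an online database
whose version is unknown, so the headline posterior is asserted as an
order-of-magnitude property (CRPI > 10⁴, W > 0.9999), not as the printed
percentage.

## Degradation model and simulator

Amplification success is modelled as at least one intact template spanning
the amplicon: with N0 effective templates at length → 0 fragmented at rate
λ per bp, p_amplify(L) = 1 − exp(−N0·e^(−λL)). This two-parameter curve is
the simplest that reproduces the qualitative behaviour of degraded-DNA
PCR: ~150 bp amplicons are safe, 200–300 bp become unreliable, ~500 bp
succeed only in well-preserved material. Presets (package defaults, with
p(150), p(500) shown): `well_preserved` N0=150, λ=0.006 (1.00, 0.999);
`moderate` N0=38, λ=0.008 (1.00, ~0.50); `poor` N0=60, λ=0.012 (1.00,
~0.14). The moderate tier was pinned to p(150) > 0.99 and p(500) ≈ 0.5;
the poor tier still amplifies internal-primer-sized fragments reliably,
which is exactly what makes the short-amplicon rescue strategy work.

The simulator draws parental genotypes from Hardy–Weinberg (STR allele
frequencies per locus from a flat Dirichlet, α = 5; insertion frequency
0.3 per Alu locus by default) and a child by uniform gamete choice, so the
truth is Mendelian by construction. Every allele amplifies independently
with p_amplify at its amplicon length: presence/absence alleles at the
locus's FAP lengths, the internal-primer probe at the IAP length, STR
alleles at a locus base length (100–220 bp) plus 4 bp per repeat. Defaults
mirror the motivating study scale: 13 STR systems, 30 Alu loci, presence
amplicons 450–500 bp, inserts 280–330 bp, IAP amplicons 118–194 bp, one
well-preserved, one moderate and one poor sample. Randomness comes from
per-(stream, sample, locus) `numpy` `SeedSequence` sub-streams, so adding
loci never perturbs earlier draws and equal seeds give byte-identical
output files.

What the simulator does *not* emulate: PCR stutter, cytosine-deamination
miscoding, contamination mixtures, amplification competition between
alleles, or inhibitor effects. Passing end-to-end tests therefore shows
the pipeline's logic is sound under idealised per-allele Bernoulli
dropout, not that real aDNA error modes are handled.

## Fitting the degradation parameters

`fit_degradation` maximises the Bernoulli log-likelihood
Σ[y·log p(L) + (1−y)·log(1−p(L))] over (log N0, λ): a coarse grid
(log10 N0 ∈ [0,6] × λ ∈ [0,0.05]) locates the basin, Nelder-Mead refines
to 1e-8 in log-likelihood; probabilities are clipped to [1e-12, 1−1e-12]
for numerical safety. Preconditions (≥20 observations spanning ≥100 bp)
reject data that cannot constrain two parameters; all-success or
all-failure data sets a boundary flag and returns no point estimate, since
λ is then unidentifiable. Recovery at the simulator's study scale
(200 observations, lengths 100–600 bp, N0=50, λ=0.01) lands λ within ±30%
in well over 80% of replicates.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp without waste: 1,000 random trios for oracle
equivalence (tolerance 1e-12, pure float arithmetic), 10,000 loci for
Hardy–Weinberg and calibration checks (3 binomial SE), 100 replicates of
200 observations for parameter recovery, 2,500 loci × 3 samples at fixed
amplicon lengths (500/180/150 bp) for dropout calibration. Ties and
degenerate inputs: homozygous-child transmission is counted once (the
gamete enumeration has no symmetric double-count); unordered genotypes are
canonicalised lexicographically at construction; allele labels are opaque
strings throughout, so microvariants like "30.2" survive verbatim.

## Known limitations

Single-trio pedigrees only — no multi-generation likelihoods, mutation
models, or X-linked indices. No probabilistic genotype calling from band
intensities: observations are binary. The incongruent/definite accounting
of the fixture reproduces the counts stated in the study's text, but the
per-locus band patterns behind the 19 undocumented definite loci are
synthetic placeholders, not data.
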