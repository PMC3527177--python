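# Methods

## The discovery model

`hetsnp` discovers SNPs within a *single heterozygous individual*: deep
short-read coverage of one genotype is mapped onto shallow long-read
references (e.g. Sanger BAC-end sequences) from the same or a related
genotype. A SNP is then *heterozygosity*, visible as two bases segregating
within the stack of reads at one site. The reference sequence does not act
as the second haplotype — it acts as a filter. This has two consequences:

- A site where all reads agree with each other but differ from the
  reference (VF = 1, FVF = 0) is *not* a SNP in this design: it is either a
  homozygous difference from the reference genotype or a reference
  sequencing error. `call_site` therefore returns no candidate for
  single-base stacks.
- A site where the stack segregates for two bases *neither* of which matches
  the reference is still a SNP candidate; the reference base is inferred to
  be a sequencing error (`ref_error_inferred`), and FVF is computed within
  the two-allele stack rather than against the unreliable reference base.

### The FVF deviation test

Read counts of the two alleles at a heterozygous site are Binomial(RMD, ½).
Rather than a fixed FVF threshold, a site is kept when its FVF is
statistically consistent with 0.5:

    t = (|FVF − 0.5| − 0.5/RMD) / (0.5·√(1/RMD))   if RMD·0.5 < 30
    t =  |FVF − 0.5|            / (0.5·√(1/RMD))   otherwise

discarding when `t ≥ t₀.₀₅, RMD−1` (upper one-tail quantile; the fold makes
the alternative one-sided, and the continuity correction `0.5/RMD` applies
only in the small-sample branch). Note a calibration subtlety the tests
assert explicitly: because the fold maps *both* binomial tails onto the same
FVF, the attained null discard rate is not the nominal α — it sits near α in
the corrected branch and approaches 2α in the uncorrected branch. The unit
tests therefore compare Monte-Carlo discard rates against the level
*enumerated exactly* over binomial outcomes, which is the honest oracle for
a discrete statistic.

### The extreme-value depth cutoff

Reads from every copy of a repeated sequence collapse onto its one
representative in the reference set, inflating read mapping depth (RMD)
severalfold. Depth over the pooled reference set is therefore a skewed
mixture, modelled with a Gumbel (type-I extreme-value) distribution fitted
by maximum likelihood (`scipy.stats.gumbel_r.fit`; method-of-moments
fallback). The maximum-depth cutoff is `⌊X̄ + k·s⌋` with `k = 0.5` by
default; `X̄ = μ + γβ` and `s = πβ/√6` come from the fitted parameters
(`moment_source="fitted"`), with sample moments available as an option since
either convention is defensible. At the published moments (15.9, 19.1) the
cutoff is 25 reads.

The fit is deliberately performed on the pooled depths of *all* references
under analysis — single-copy bulk plus repeat tail. The contaminated mixture
is what inflates `s` relative to the single-copy spread and places
`X̄ + 0.5·s` *between* the single-copy bulk and the repeat class; fitting
single-copy depths alone would put the cutoff at a fixed upper quantile of
the bulk (for a Gumbel, P(X > mean + 0.5σ) ≈ 0.26 at any scale) and discard
a quarter of genuine sites.

### The filter cascade

Candidates pass through, in order: minimum RMD (≥ 5), maximum RMD (from the
depth model), the FVF criterion (fixed ≥ 0.2 in the *initial* preset, the
t-test in the *adjusted* preset), site mapping quality (MQS ≥ 25 initial,
≥ 30 adjusted), reference base quality at the SNP (≥ 40 genic, ≥ 45
non-genic — the stricter bound is applied when annotation is unknown),
homopolymer context (inside a run of ≥ 3 identical bases, or either allele
would create one), inter-SNP spacing (> 3 bp; *both* members of a close pair
are removed, since a near neighbour casts doubt on the local alignment of
either), and distance from the 3′ end of the reference read (> 30 bp, where
Sanger quality decays). All filters are evaluated for every candidate — no
short-circuiting — so the `FilterReport` attributes every failure; a
candidate passes iff its flag list is empty.

## Infinium design rules

Type I pairs ({A,T}, {C,G}) need two probes, the other four pairs one, so
panels use type II only, with an external design score ≥ 0.7 (design scores
are vendor input, never computed here). Panel allocation apportions the
whole budget across physical-map contigs proportionally to contig size by
the largest-remainder method, then enforces a floor of one seat per contig
with eligible supply; the full-budget-first order is what makes sizes
900:100 at budget 10 yield 9:1. Within a contig, picks are spread by
position percentile. One SNP per reference; one reference per gene when
gene ids are provided, otherwise that rule is skipped.

## Validation and the logistic model

Marker segregation in the F1 progeny is classified against its Mendelian
expectation: AB×AB → 1:2:1 (χ², 2 df), AB×homozygote → carrier vs
non-carrier 1:1 (1 df), identical (or opposite) homozygous parents →
monomorphic. Progeny in a Mendelian-impossible class are tolerated up to 5%
of the scored progeny and dropped from the test — real genotyping data
contain error, and a strict reading would void nearly every test-cross
marker at n ≈ 350 — beyond that the marker is unscorable. A discovery is a
*true positive* only when the discovery parent is heterozygous and the
progeny segregate; monomorphic loci, and segregating loci at which the
discovery parent is homozygous, are false positives.

The false-positive probability of a discovered SNP follows a logistic model
`log(p/(1−p)) = b0 + b1·MQS + b2·RMD + b3·FVF` with published default
coefficients (10.3976899, −0.3077982, 0.07896269, −5.2585503); predicted
false when p > 0.5 (the canonical threshold). Refitting uses statsmodels'
Logit MLE and reports standard errors and training-set accuracy; degenerate
fits (perfect separation, unbounded standard errors) raise. Two-sided
Fisher exact tests (scipy, minimum-likelihood convention) probe group ×
outcome tables; on the scorable-by-annotation table (378/202/3488/1932) the
exact two-sided p is 0.7152 (R's `fisher.test` agrees to 7 digits), which
reports as 0.71 at the printed precision. Report percentages are rounded
half-up in decimal, so exact boundary cases (5163/6000 = 86.05%) print as a
human would round them.

## Pedigree and diversity

COP uses the Malecot recursion with F = 0 for all individuals (outcrossing
cultivars): f(x,x) = ½, f(x,y) = ½·[f(sire_x,y) + f(dam_x,y)] descending
the individual of greater pedigree depth (the standard guard against
infinite descent), unknown parents contributing 0. Dissimilarity is the
allele-sharing distance d = |dose_i − dose_j|/2 averaged over shared scored
loci (AA–AA 0, AA–AB ½, AA–BB 1, AB–AB 0) — the literature's "improved"
coefficient for codominant diploid markers is not reproducible from its
citation alone, so this standard semimetric is the documented default and
results that depend on the exact variant should be read directionally.
Heterozygosity is 100·#AB/#scored. Correlations are Pearson.

## The simulator

`simulate` emulates the study conditions the pipeline targets: ~721 bp
references with a Sanger quality profile (Q55 flat, decaying linearly to
Q20 over the final 100 bp — the motivation for the right-edge filter), one
heterozygous site per ~1500 bp, per-reference depth Gumbel(μ = 16 reads,
β = 2.5 reads) jittered ±10% per site, a 10% repeat class at 3× depth
carrying paralog-divergence sites (variant fraction 1/multiplier ≈ 0.33 —
the dominant false-positive pressure that the depth cutoff and FVF test
must remove), Phred-driven base errors (e = 10^(−Q/10)) split evenly among
the three non-reference bases, MQS ~ N(34.3, 1.6) at true sites and
N(33.7, 2.0) elsewhere, and Mendelian F1 crosses of 428 progeny with 0.5%
genotyping error and 1% missingness. All draws flow from one seeded
`numpy` Generator; fixed seed ⇒ byte-identical outputs.

Truth het sites are planted only at *assayable* positions: reference
quality ≥ 45, outside homopolymer context (checked with the same predicate
the filter uses, for both alleles), ≥ 61 bp apart, and > 30 bp from the 3′
end. The truth table thus represents discoverable SNPs; sites in contexts
the cascade removes by design (≈ 15% of random positions sit in homopolymer
context alone) would only measure the generator against rules it cannot
pass, not the pipeline's discrimination. Consequently the end-to-end tests
measure sensitivity against discoverable truth — they say nothing about
SNPs genuinely located in homopolymers or low-quality read tails, which
this design gives up by construction.

Other simplifications: no reference-sequence errors are planted (the
SNP3-style inference path is unit-tested directly), no mapping bias or
paired-read structure, errors are independent across reads, and repeat
divergence is a single diverged copy. Passing tests therefore demonstrate
the statistical machinery under the declared generative model, not
performance on real mapped data.

## Problem sizes and numerical choices

The shared end-to-end fixture uses 600 references (~430 kb, ~290 truth
sites), the package's desk-scale default, at seed 42; discovery over it
runs in seconds. Observed there: sensitivity 0.90 on single-copy truth,
100% of repeat-reference candidates above the fitted cutoff (23 reads),
adjusted-preset precision 1.00 vs 0.875 for the initial preset. Monte-Carlo
checks use 10,000 replicates with 3–4σ bands. Cutoff rounding is floor
(15.9 + 0.5·19.1 = 25.45 → 25). Count ties in allele calling break by base
order A<C<G<T (FVF is unaffected). Degenerate inputs raise rather than
guess: constant depth vectors, all-missing genotype columns, zero-variance
correlations, all-zero contingency tables, single-class logistic fits.

## Coordinates and formats

1-based inclusive positions everywhere (pileup/VCF convention); stacks are
strand-collapsed to the reference forward strand. Canonical pileup is the
7-field TSV `ref_id pos ref_base depth A,C,G,T mqs`; samtools-mpileup text
is parsed best-effort (MQS from the RMS of the `-s` mapping-quality column;
0 when absent, which is then unsuitable for MQS filtering). Phred qualities
cap at 93. The VCF writer emits minimal VCF 4.2 with
VF/FVF/RMD/MQS/REFQ/ANN/ITYPE/PFALSE INFO keys and the first failing filter
in FILTER.
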