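# Methods

This note records the models, conventions and numerical choices behind
pnpskit, what the synthetic-data generator does and does not emulate, and the
known limitations.

## pN/pS with covered-site denominators

pN/pS compares the rate of nonsynonymous polymorphism to synonymous
polymorphism.  Counting "rates" requires a denominator in *sites*, and a
site is only informative where sequencing depth was high enough to have
detected a SNP; a low-coverage position can look monomorphic even when it is
not.  Both numerator and denominator are therefore depth-conditioned:

* **Numerators.** Biallelic SNPs inside an annotated CDS are classified
  synonymous/nonsynonymous by substituting the alternate base into the
  reference codon and comparing translations under the standard genetic
  code.  Effects are judged against the reference codon even when another
  variant falls in the same codon (no haplotype-aware multi-nucleotide
  resolution).  Substitutions that create or destroy a stop codon are
  nonsynonymous.
* **Denominators.** Each CDS position carries Nei–Gojobori (1986) fractional
  weights: the synonymous weight of a position is the fraction of its three
  possible single-base changes that preserve the amino acid (changes to a
  stop count as nonsynonymous); weights sum to 3 per codon and to 183 over
  the 61 sense codons.  A position contributes its weights only when its
  depth is ≥ `min_depth` (default 20, inclusive) in the focal sample
  (per-individual mode) or in every sample of a mask set (all-individuals
  mode).  Exclusion is per nucleotide, not per codon.

Quality filtering mirrors the same logic at the SNP level: a site is kept
only when every required sample has DP ≥ 20 and GQ ≥ 30 and the site QUAL is
≥ 30, all inclusive; missing genotypes fail.

For class-level tables the covered-site mask defaults to the *adults* whose
genotypes define the class.  A pooled-offspring sample, typically sequenced
far shallower, would otherwise collapse the denominator to its own covered
set; per-individual covered-site totals make this interaction obvious.

## The shared-ratio likelihood-ratio test

Model each class's counts as two Poisson processes with exposures S_N and
S_S (the covered-site totals) and rates λ·r and λ, where r is pN/pS.
Conditioning on the total SNP count n = nN + nS profiles out λ and leaves

    nN ~ Binomial(n, π(r)),   π(r) = r·S_N / (r·S_N + S_S).

The alternative hypothesis gives each class its own r, with the closed-form
MLE r̂ = (nN/S_N)/(nS/S_S); the null imposes one shared r, maximised
numerically on the log scale with a bounded 1-D search bracketing both
per-class MLEs by ±5 log units (`scipy.optimize.minimize_scalar`,
`xatol = 1e-12`).  The statistic 2·(ℓ_alt − ℓ_null), clipped at 0, is
referred to χ² with 1 df.  When the two classes share the same S_N/S_S the
test reduces exactly to the 2×2 G-test of independence, which the test suite
uses as an oracle.  Type-I error at α = 0.05 is calibrated by simulation at
realistic count magnitudes (2,000 null datasets; accepted band 3–7%).
A class with zero synonymous SNPs makes r unidentifiable and is an error;
pN/pS itself is reported missing (not 0 or ∞) when nS = 0.

## Exact tests

* **Sex ratio** — two-sided exact binomial against p₀ = 1/2, two-sided by
  the minimum-likelihood rule (sum P(X = x) over outcomes no more likely
  than the observed, with a 1e-7 relative tolerance), via
  `scipy.stats.binomtest`.
* **Per-individual pN/pS comparison** — exact two-sample Mann–Whitney:
  the null distribution of U is enumerated over all C(nA+nB, nA) rank
  assignments and the two-sided p is 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.
  Ties across groups are an error rather than silently approximated; the
  enumeration refuses more than ~2·10⁶ assignments.  This is the correct
  reading of the analysis often mislabelled an "unpaired Wilcoxon signed
  rank test" — a signed-rank test cannot be unpaired.

## Ploidy from allele balance

At a heterozygous SNP the reference-read fraction concentrates near 1/2 in
diploids and near 1/3 or 2/3 in triploids (one or two of three copies).  The
operational rule sums, over heterozygous biallelic sites with reads (ref r,
alt a, n = r + a), the log-likelihoods of

    diploid:   Binomial(n, 1/2)
    triploid:  ½·Binomial(n, 1/3) + ½·Binomial(n, 2/3)

and calls the larger, requiring ≥ `min_sites` (default 100) heterozygous
sites, otherwise `undetermined`.  Equal log-likelihoods break to diploid.
This is a deterministic stand-in for inspecting the allele-balance histogram
(also exported, fixed 0.02-wide bins on [0, 1], right-open except the last).
The mixture is symmetric and raw-binomial: neither overdispersion nor the
reference-allele bias that makes real assemblies' 1/3 peak taller than the
2/3 peak is modelled.  Real data slightly displaced from 1/2 by alignment
bias will still be called correctly as long as the displacement is small
against the 1/2-vs-1/3 separation.

## Genotype-identity (clonality) and SNP classes

Identity summaries count biallelic SNPs at which every listed sample has the
same sorted allele multiset; records with any missing call among the listed
samples leave both numerator and denominator.  A diploid `0/1` and a
triploid `0/0/1` are deliberately *not* identical (multisets differ), which
cannot trigger in single-species comparisons but guards cross-species
misuse.

Class membership is strict genotype-pattern matching over the clonal
*adults* (the offspring pool is excluded — it duplicates its mother and
would double-count her mutations):

* candidate novel: ≥ 1 adult `0/0/0`, ≥ 1 adult `0/0/1`, nothing else;
* ancestral identical: every adult exactly `0/0/1`;
* low frequency (diploid set): exactly one `0/1`, all others `0/0`.

Any third pattern (e.g. `0/1/1`) disqualifies a site, keeping genotyping
noise out of the novel class at some cost in sensitivity.  Polarity is by
the homozygous genotype: sites where the majority is `0/0/1` and the
minority `0/0/0` still qualify as candidate novel.  Note that ancestral
heterozygosity whose single-copy allele was chosen as the assembly reference
appears as `0/1/1`, so the ancestral-identical class captures only the
`0/0/1` polarity — roughly half of ancestral sites under an unbiased
assembler; this matches how the class is defined in practice and does not
bias its pN/pS.

## Pairwise dN/dS (NG86 + Jukes–Cantor)

A deliberately simple divergence utility for simulator-scale work, not a
replacement for maximum-likelihood codon models: NG86 site counts averaged
over the two sequences; per-codon differences resolved by averaging
synonymous/nonsynonymous step counts over all substitution orderings (2 or 6
paths), with paths through stop codons allowed and any stop-touching step
counted nonsynonymous; proportions corrected with d = −(3/4)·ln(1 − 4p/3),
undefined (reported missing) at p ≥ 3/4.  dN/dS is missing when dS is 0 or
undefined.  All fields are symmetric in the two inputs.

## The synthetic study generator

`pnpskit.simulate` produces a complete two-species study — VCF, reference
CDS FASTA + coordinate table, per-base depth table, sample sheet and a truth
table — as a deterministic function of one seed.

Generative model, asexual species (AAB triploid clone, default 4 adults +
a pooled-offspring sample copying adult 1 exactly):

* random sense-codon transcripts (ATG start, terminal stop outside the CDS);
* progenitor haplotype B differs from A at Bernoulli(d) CDS sites
  (default d = 0.005); the assembly reference base at each such site is
  drawn from the two alleles with equal probability (so both allele-balance
  peaks appear), except that a choice creating an internal stop in the
  reference is rejected — ORF-predicted references contain none;
* novel mutations: each haploid CDS site of each adult mutates with
  probability μ (default 2×10⁻⁵), giving single-adult `0/0/1` sites;
* selection is a retention filter: nonsynonymous proposals survive with
  probability f (novel, default 0.2), f_ancestral (progenitor divergence,
  default 0.1) or f_sexual (segregating sites, default 0.1); synonymous
  proposals always survive.  Because proposals are uniform single-base
  changes and NG86 sites are defined as mutant fractions, the expected
  pN/pS of a class equals its retention probability — the anchor for the
  recovery tests.

Sexual species: segregating sites at density 0.001 per CDS site before
thinning, alternate-allele count drawn (default uniformly) from 1..2N−1, and
genotypes assigned by sampling allele slots without replacement.

Read support: DP ~ NegativeBinomial(mean 60, size 30) per call, reference
allele depth ~ Binomial(DP, reference copies / ploidy), GQ and site QUAL
constant at 60.  The depth table covers every CDS position so covered-site
denominators are computable at monomorphic positions too.

What is *not* emulated: read-level data (no FASTQ), caller error models
(GQ is a constant, so filter plumbing is tested but not error calibration),
assembler reference-allele bias (the 1/3 vs 2/3 peak asymmetry of real
RNA-seq assemblies), allelic expression imbalance, gene conversion,
recombination, or a population-genetic fixation process (selection is a
one-shot retention filter).  Passing recovery tests therefore demonstrates
that the pipeline's arithmetic and filtering are correct under the stated
model, not that the model captures every artifact of real transcriptome
genotyping.

At the defaults (2,000 transcripts × 150 codons, d = 0.005, μ = 2×10⁻⁵)
the clone carries ≈ 1,400 ancestral heterozygous SNPs and ≈ 20 retained
novel mutations per adult, so the expected all-adults identical fraction is
≈ 0.94–0.95 — the same regime as real clonal isopod data.  These defaults
are the package's standing study conditions; the recovery suite runs at this
scale (≈ 15 s) and the LRT calibration uses 2,000 simulated count datasets.

## Numerical and interface conventions

* Coordinates are 1-based inclusive transcript coordinates everywhere; no
  genome coordinates exist (the reference is a transcriptome).
* Genotypes are sorted allele-index multisets; `0/1/0` ≡ `0/0/1`.
* Only single-base SNP records are read from VCF; indels/MNPs are skipped
  with a warning.  Genotype arity differing from the declared ploidy is a
  hard error naming the sample and site; `./.`-style calls are missing.
* Threshold comparisons are inclusive (≥) throughout.
* Report rounding: pN/pS to 4 decimals, frequencies to 3 significant
  figures, χ² to 1 decimal, p to 2–3 significant figures.
* Positions absent from the depth table have depth 0.

## Known limitations

* The NG86 equal-pathway site definition is one convention among several
  (transition/transversion-weighted or ML site definitions would shift
  denominators by a few percent); it is used consistently for numerators
  and denominators, which is what pN/pS ratios require.
* The LRT's χ²(1) reference is asymptotic; at very small counts (a handful
  of SNPs per class) the calibration band test, not the asymptotics,
  is the evidence of validity.
* The ploidy rule only distinguishes 2n from 3n and assumes unbiased
  sequencing of both alleles.
* The dN/dS utility is a counting stand-in; comparisons with
  likelihood-based codon-model estimates should expect systematic
  differences at high divergence.
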