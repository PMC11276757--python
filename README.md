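# pnpskit

Tools for asking whether purifying selection is less effective in asexual
lineages, using SNP data from a triploid apomictic (clonally parthenogenetic)
population and a diploid sexual relative — the study design used for the
terrestrial isopods *Trichoniscus pusillus* (triploid, parthenogenic) and
*Hyloniscus riparius* (diploid, outcrossing).

In an apomictic clone, offspring are genetic copies of their mother, so a new
mutation stays heterozygous forever and the usual divergence-based dN/dS test
misses it.  The package instead works with polymorphism: it partitions SNPs
by their genotype pattern across clonal adults into

* **candidate novel** sites — some adults `0/0/0`, the others `0/0/1`:
  heterozygous mutations that arose *after* the origin of the clone;
* **ancestral identical** sites — every adult `0/0/1`: heterozygosity
  inherited from the hybrid (AAB) founding of the lineage;

and, in the sexual species, **low-frequency** sites (a singleton alternate
allele) as the matched comparison class.  For each class it computes

    pN = (nonsynonymous SNPs) / (covered nonsynonymous sites)
    pS = (synonymous SNPs)    / (covered synonymous sites)

with Nei–Gojobori (1986) fractional site counts restricted to positions with
sequencing depth ≥ 20 in the required samples, and tests whether two classes
share one pN/pS ratio with a likelihood-ratio test: conditional on a class's
total SNP count n = nN + nS,

    nN ~ Binomial(n, π(r)),   π(r) = r·S_N / (r·S_N + S_S),

where S_N, S_S are the covered-site totals and r = pN/pS.  The alternative
fits one r per class (closed form), the null a shared r (1-D maximisation),
and 2Δℓ is referred to χ²(1).  Around this core sit the supporting stages:
VCF/FASTA/TSV input with triploid-aware genotype parsing, the depth/GQ/QUAL
quality filters, allele-balance ploidy inference (the 1/3–2/3 vs 1/2 read
ratio signature), clonality (genotype-identity) summaries, an exact binomial
sex-ratio test, an exact Mann–Whitney comparison of per-individual pN/pS, a
pairwise NG86 + Jukes–Cantor dN/dS utility, and a fully seeded synthetic
study generator with truth labels.

## Worked example

Published per-class counts `(nN, nS, S_N, S_S)` can be fed to the statistics
directly.  Comparing a clonal lineage's candidate-novel class
`(12, 17, 1 593 394, 434 906)` against the sexual species' low-frequency
class `(388, 1209, 881 978, 237 763)`:

```
$ pnpskit lrt --a 12 17 1593394 434906 --b 388 1209 881978 237763
{
  "ratio_a": 0.1927,
  "ratio_b": 0.0865,
  "ratio_shared": 0.088,
  "chi2": 4.1,
  "df": 1,
  "p": 0.0423
}
```

The novel-mutation class has pN/pS ≈ 0.19 — roughly twice the 0.087 of
comparable rare variants in the sexual species — and the shared-ratio null is
rejected (χ² = 4.1, p = 0.042): purifying selection has removed a smaller
share of nonsynonymous variants among the clone's post-origin mutations.
A 7-female / 4-male field sample is meanwhile fully compatible with a 1:1
sex ratio:

```
$ pnpskit sexratio --female 7 --male 4
p = 0.549 (exact binomial)
```

The same analysis runs end-to-end on simulated data:

```
$ pnpskit simulate --seed 42 --out sim --n-transcripts 300 \
    --cds-length-codons 100 --divergence 0.01 --mut-rate 1e-4
$ pnpskit report --sample-sheet sim/samples.tsv \
    --dataset "triclone=sim/triclone.vcf,sim/triclone_cds.fasta,sim/triclone_cds.tsv,sim/triclone_depth.tsv" \
    --dataset "dipsex=sim/dipsex.vcf,sim/dipsex_cds.fasta,sim/dipsex_cds.tsv,sim/dipsex_depth.tsv" \
    --outdir report --pool-mother triclone=TPU_A1 --seed 1
```

`report/ploidy_calls.tsv` then shows every clonal sample called triploid
from its allele-balance likelihoods (e.g. `TPU_A1 ... -1838.903 -949.803
triploid`; the diploid samples carry too few heterozygous SNPs at this toy
scale for a call and are reported `undetermined`), and
`report/table5_classes.tsv` gives the per-class pN/pS rows, e.g. candidate
novel SNPs at 0.1908 vs identical SNPs at 0.1254 for seed 42, with the LRT
results in `report/tests.json`.

## Layout

| module | contents |
|---|---|
| `pnpskit.io` | VCF (GT/DP/AD/GQ, diploid + triploid), CDS FASTA + coordinate table, depth table, sample sheet; quality filters |
| `pnpskit.codon` | genetic code, NG86 site counting, SNP effect classification, covered-site totals |
| `pnpskit.ploidy` | allele-balance profiles, binomial-mixture ploidy calls |
| `pnpskit.clonality` | genotype-identity fractions, marker subsets |
| `pnpskit.partition` | candidate-novel / ancestral-identical / low-frequency / per-individual-het classes |
| `pnpskit.selection` | pN/pS summaries, the shared-ratio LRT, exact binomial and rank-sum tests |
| `pnpskit.dnds` | pairwise NG86 + Jukes–Cantor dN/dS |
| `pnpskit.simulate` | seeded two-species synthetic study generator with truth labels |
| `pnpskit.pipeline`, `pnpskit.cli` | report orchestration and the `pnpskit` command |

See `docs/methods.md` for the models, conventions and their limitations.
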