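# hetsnp

Genome-wide SNP discovery from mapped short-read stacks in **heterozygous
(outcrossing) organisms**, for projects that have no reference genome — only a
shallow set of long reads (e.g. Sanger BAC-end sequences) and deep short-read
coverage of a *single* heterozygous individual.

In a single diploid, a true SNP is heterozygosity: two bases segregating
within the stack of reads mapped to one site, each at expected frequency 0.5.
Sequencing and mapping errors instead produce a minor variant near frequency
0. `hetsnp` separates the two regimes and carries the result through assay
design and genotyping-based validation:

- **Variant statistics** — variant frequency `VF` (fraction of reads differing
  from the reference base) and its folded form `FVF = min(VF, 1 − VF)`; a
  *t*-test of `FVF` against the heterozygous expectation 0.5,
  `t = (|FVF − 0.5| − 0.5/RMD) / (0.5·√(1/RMD))` for small stacks
  (`RMD·0.5 < 30`; uncorrected otherwise), judged against `t₀.₀₅, RMD−1`.
- **Extreme-value depth model** — a Gumbel fit to per-site read depth; sites
  above `⌊X̄ + k·s⌋` (default `k = 0.5`) are treated as collapsed repeats.
- **Filter cascade** — minimum/maximum depth, FVF test, mapping quality,
  reference base quality (stricter for non-genic references), homopolymer
  context, inter-SNP spacing, and the low-quality 3′ end of Sanger reads,
  with per-filter accounting.
- **Infinium assay design** — type I (`A/T`, `C/G`) vs type II classification,
  probe-spacing screen, and panel selection (one SNP per reference, ≥ 1 per
  physical-map contig, contig allocations proportional to size).
- **Validation** — 1:2:1 / 1:1 / monomorphic segregation classification in an
  F1 population, true/false-positive labeling, Fisher exact group tests, and
  a logistic model `log(p/(1−p)) = b0 + b1·MQS + b2·RMD + b3·FVF` of the
  false-positive probability.
- **Pedigree & diversity** — Malecot coefficient of parentage, marker
  heterozygosity, allele-sharing dissimilarity, correlations.
- **Simulator** — synthetic references, pileups, crosses and pedigrees with
  known truth, so the whole pipeline is testable offline.

## Worked example

```sh
hetsnp simulate --seed 1 --n-refs 40 --het-site-rate 0.005 --outdir demo
hetsnp discover --fasta demo/refs.fasta --qual demo/refs.qual \
    --pileup demo/pileup.tsv --annotation demo/annotation.tsv \
    --preset adjusted --outdir demo/out
```

prints

```
simulated 40 references, 128 true het sites -> demo
229 candidates, 108 passed -> demo/out
```

i.e. the simulator planted 128 heterozygous sites on ~29 kb of reference;
calling every two-allele stack yields 229 candidates (true sites plus error
and paralog sites on repeat references), and the adjusted cascade — depth
cutoff from the fitted Gumbel model, FVF *t*-test, MQS ≥ 30 — retains 108, almost
all of them true sites (`demo/out/filter_report.tsv` attributes every
rejection; `demo/out/snps.vcf` carries VF/FVF/RMD/MQS per record and the
first failing filter in `FILTER`).

The same operations are importable:

```python
>>> from hetsnp import depth_cutoff, fvf_deviation_test
>>> depth_cutoff(15.9, 19.1, 0.5)    # mean 15.9 reads, SD 19.1 reads
25
>>> t, discard = fvf_deviation_test(0.2, 25)   # FVF 0.2 in a 25-read stack
>>> round(t, 3), discard
(2.8, True)                                    # deviates from 0.5 -> discard
```

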