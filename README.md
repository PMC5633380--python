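# ecckit

Detection and simulation toolkit for **extrachromosomal circular DNA
(eccDNA)** in paired-end sequencing data.

Eukaryotic genomes shed circular DNA molecules — excised exons, repeat
units, mobile-element intermediates — that are invisible to standard
linear-genome analyses. Experiments enrich for these circles biochemically
(exonuclease V digestion of linear DNA, or CsCl–ethidium-bromide density
banding) and fragment them with Tn5 tagmentase for sequencing. `ecckit`
implements the downstream computational method for such experiments, for
genomicists analyzing circle-enriched libraries against matched
total-genomic controls:

1. **Single-cut circle signature.** Tn5 duplicates 9 bp of target sequence
   at every insertion. A circle cut exactly once linearizes with the same
   9-mer at both ends, so an inward-facing read pair satisfies
   `R1[0:9] == revcomp(R2[0:9])`. The per-library fraction of such pairs,
   and its fold over a genomic control, quantifies circle capture directly
   from FASTQ — no alignment needed (chance rate 4⁻⁹ ≈ 3.8×10⁻⁶ per pair).
2. **k-mer repeat classification.** Reads are placed over the genome
   through a canonical k-mer index (k = 31) and classified from their full
   placement set: *unique*; *focal repeat* (all placements on one
   chromosome within 300 kb); *intrachromosomal repeat* (one chromosome,
   span > 300 kb); *dispersed repeat* (multiple chromosomes). Unique and
   focal reads retain a usable genomic position (placement, or span
   midpoint).
3. **Binned enrichment calling.** With per-bin counts s_i (sample, total S)
   and c_i (control, total C), a bin is called eccDNA-enriched when a
   Wilson-interval lower bound on the fold `(s_i/S)/(c_i/C)` reaches the
   minimum fold (4 by default) **and** the exact two-tailed binomial
   p-value (X ~ Bin(S, c_i/C), minimum-likelihood tails) passes a
   Bonferroni-corrected α = 0.05. The circular mitochondrial chromosome
   serves as an internal control, and replicate agreement is summarized as
   Pearson r of log₁₀ binned coverage.
4. **Topology-aware simulator.** Reference genomes with planted repeat
   families and planted circles, plus a mechanistic Tn5 model (Poisson cut
   process, 9-bp duplications, attenuated single-cut regime for circles,
   Bernoulli removal of linear molecules) — so the entire method is
   testable end to end without external data.

## Worked example

Plant two 2-kb circles at 10 copies in a 400-kb genome with a 14-kb
circular mitochondrion, simulate an enriched library (99.9% linear
removal) and a matched control, and call enriched 1-kb bins
(`python examples/enrichment_calls.py`):

```
chrI:100000-101000  fold=7.8 robust>=7.3  p=0.00e+00
chrI:101000-102000  fold=7.8 robust>=7.3  p=0.00e+00
chrI:300000-301000  fold=7.7 robust>=7.3  p=0.00e+00
chrI:301000-302000  fold=7.9 robust>=7.4  p=0.00e+00
chrM:0-1000  fold=8.0 robust>=6.6  p=0.00e+00
...
mitochondrial internal-control fold: 8.5
```

Every significant bin falls inside a planted circle or on the
mitochondrion: the four circle bins are exactly the planted loci, and the
mitochondrial fold (8.5×) confirms genuine circle enrichment of the
library as a whole. The signature-level view
(`python examples/signature_detection.py`) shows the same at the read
level — a library with 5% singly cut circles reports a 4.94% duplication
fraction, 82-fold over its linear control.

The other examples cover the direct-repeat excision model used to build
reference circles (`excision_model.py`: a 378-bp spacer between two 34-bp
repeats excises as a 412-bp circle from a 3446-bp plasmid, leaving
3034 bp) and read classification over planted repeat families
(`repeat_classification.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
ecckit simulate --out-dir sim --chrom-length 200000 --mito-length 14000 \
    --circle chr1:100000-102000:10 --depth 20000 --epsilon 0.999
ecckit detect-signature --r1 sim/sample_R1.fastq --r2 sim/sample_R2.fastq -o sig.tsv
ecckit classify --r1 ... --r2 ... --reference sim/reference.fasta --out-dir cls
ecckit enrich --sample-r1 ... --control-r1 ... --reference ... --out-dir calls
ecckit report --bins-a calls_rep1/bins.tsv --bins-b calls_rep2/bins.tsv
```

Every command accepts `--config file` (flat `key = value`; flags override)
and writes its resolved configuration and a checksummed manifest into the
output directory, so runs are reproducible byte for byte under a fixed
seed.

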