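# occutarget

Transcription factors such as GATA1 and PU.1, the master regulators of the
erythroid and myeloid lineages, bind the promoters of ribosomal protein (RP)
genes — including genes mutated in Diamond-Blackfan Anemia — and their
occupancy tracks with RP gene expression during terminal erythroid
differentiation. `occutarget` is a small, tested toolkit for the
computational side of that kind of study:

- **TSS-window occupancy scoring.** For each gene, the *Total Gene Score*
  (TGS) is the ChIP signal within a fixed window around the transcription
  start site: for read datasets, the number of reads whose midpoint falls in
  `[TSS − w, TSS + w)` (default `w = 10 kb`); for peak datasets (ENCODE
  narrowPeak), the summed `signalValue` of peaks whose summit falls in the
  window (or the peak count, `--peak-count`). Scores are normalized to the
  dataset mean over a gene universe, and **target genes** are those with
  normalized TGS strictly greater than 1 — i.e. above the dataset mean.
  TSS-centered reads-per-million density profiles (default ±1.5 kb, 50 bp
  bins) are provided for visualization.
- **Promoter motif scanning.** IUPAC consensus scanning (defaults:
  `WGATAR` for GATA factors, `RRGGAA` for the PU.1 ETS core) on both
  strands, with positions reported in the ATG-anchored promoter frame:
  the base 5′ of the start codon is −1, the A of the ATG is +1, and there
  is no position 0. A site mutagenesis helper designs mutant probes
  (transversions at invariant consensus bases) that abolish a binding site.
- **ChIP-qPCR calculus.** Fold enrichment versus input with a reference
  amplicon, `fold = 2^(ΔCt_input − ΔCt_IP)` where
  `ΔCt = Ct(target) − Ct(reference)`, and `2^(−ΔΔCt)` relative expression
  against a calibrator sample. Replicates are summarized by mean Ct with
  dispersion over all replicate combinations.
- **Occupancy–expression association.** Per differentiation stage, the
  RPKM distributions of occupied versus non-occupied genes are compared by
  a one-sided Wilcoxon rank-sum test (occupied greater), exact by full
  enumeration for small tie-free samples, tie-corrected normal
  approximation otherwise. Consecutive-stage `log2` fold-change profiling
  (pseudocount 0.1) summarizes the expression decline.
- **Synthetic data.** Seeded generators produce every input the pipeline
  consumes — annotations, Poisson-background reads with point-source
  enrichment planted at occupied TSSs, companion narrowPeak records,
  expression matrices with a planted occupied-gene shift and
  species-specific decline timing, and promoters with motifs planted at
  known ATG-relative positions — so every analysis path can be validated
  against known ground truth.

## Worked example

Simulate a study (200 genes, 15% occupied by the factor, 40 enrichment
reads per occupied TSS over a 5·10⁻⁴ reads/bp background), score
occupancy, and test the expression association:

```bash
occutarget simulate --seed 7 --outdir demo
occutarget score --reads demo/reads.bed --genes demo/ann.tsv -o demo/scores.tsv
head -4 demo/scores.tsv
```

```
gene_id	raw_tgs	normalized_tgs	is_target
g001	10	0.636335	0
g002	14	0.890869	0
g003	14	0.890869	0
```

Gene `g001` has 10 reads in its ±10 kb TSS window, 0.64× the dataset mean,
so it is not called a target; 37 of the 200 genes score above the mean and
are called targets (the 30 planted occupied genes plus 7 background genes
that fluctuate above the mean).

```bash
occutarget scan --fasta demo/promoter.fa --atg-index 1000 -o demo/hits.tsv
cat demo/hits.tsv
```

```
pattern	seq_index	strand	match	promoter_pos
GATA1	306	+	TGATAA	-694
PU1	291	+	GAGGAA	-709
PU1	347	+	GAGGAA	-653
```

The planted GATA site is recovered at −694 and the two ETS sites at
−709/−653 relative to the ATG.

```bash
occutarget associate --expr demo/expr_mouse.tsv \
    --targets <(grep "	1$" demo/scores.tsv | cut -f1) -o demo/assoc.tsv
cat demo/assoc.tsv
```

```
stage	n_occupied	n_nonoccupied	median_occupied	median_nonoccupied	W	p_one_sided	method
ProE	37	163	58.7007	33.9132	4768	0.000482646	normal
Baso	37	163	15.6182	7.79753	5066	1.12737e-05	normal
Poly	37	163	10.2002	3.86994	5392	7.05796e-08	normal
Ortho	37	163	4.69754	3.01117	4825	0.000250903	normal
```

At every stage the occupied stratum has the higher median RPKM and the
one-sided rank-sum p-value is well below 0.01 — the planted +1 log2
occupancy effect is detected throughout the simulated differentiation,
despite the overall stage-wise expression decline.

`occutarget run` composes the whole pipeline from a YAML config or flags
and writes a `manifest.json` recording the version, config hash and
per-stage record counts; `occutarget qpcr` and `occutarget profile` cover
the ChIP-qPCR and density-profile analyses.

## File formats

| format | use |
|---|---|
| BED (≥3 col, 0-based half-open) | aligned reads |
| ENCODE narrowPeak (10 col) | called peaks; `signalValue` col 7, summit offset col 10 (−1 = absent) |
| FASTA | promoter sequences (output wrapped at 60 columns) |
| `annotation` TSV | `gene_id  gene_name  chrom  strand  tss  is_rp  is_dba` (TSS 0-based) |
| `expression` TSV | `gene_id` then one RPKM column per ordered stage |
| `qpcr` TSV | `sample  amplicon  ct`, one row per technical replicate |

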