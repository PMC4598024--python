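# Methods

## Occupancy scoring

The Total Gene Score of gene *g* for a read dataset is

    TGS(g) = #{ reads r : midpoint(r) ∈ [tss_g − w, tss_g + w) }

with half-width *w* = 10,000 bp by default and a half-open window, so a
read midpoint exactly at `tss + w` is excluded while one at `tss − w` is
included. Reads are assigned by their midpoint because it is robust to
read length and symmetric around the binding site; 5′-end assignment is
available (`read_assignment="five_prime"`) for workflows that counted read
starts. Windows extending past coordinate 0 are truncated at 0 rather
than dropping the gene. Reads on other chromosomes contribute nothing.

For peak datasets the same window receives the summed `signalValue` of
peaks whose *summit* (narrowPeak column 10; midpoint fallback when the
summit is absent) lies inside it. Because "the sum of peaks in a window"
can equally mean a count, both interpretations are exposed
(`use_count=True` / `--peak-count`); summed signal is the default since it
preserves peak strength.

Scores are normalized by the mean raw TGS over a *gene universe* —
by default all scored genes, but intended to be the expressed-gene set of
the cell type when one is available, which is why `normalize_tgs` takes an
explicit universe argument. Target genes are defined by normalized
TGS > 1, strictly: a gene exactly at the dataset mean is not a target.
Target calls are therefore invariant under any uniform positive rescaling
of the raw scores, and the mean of normalized scores over the universe is
1 by construction (tested to 1e−12).

Density profiles count read midpoints in fixed bins over TSS ± 1,500 bp
(50 bp bins by default; the bin width must divide the window), scaled to
reads per million by the library size, and are reported 5′→3′ with respect
to the gene, i.e. reversed for minus-strand genes.

## Motif scanning and the ATG frame

Consensus patterns are IUPAC strings compiled to per-position allowed-base
sets; an `N` in the *sequence* matches nothing, so ambiguous bases never
create hits. Scanning reports every match — overlapping and nested hits
included — on the plus strand and, by default, matches of the
reverse-complemented pattern (minus-strand sites), each identified by the
0-based index of its 5′-most plus-strand base.

Promoter positions use the coordinate frame anchored at the translation
start codon: the A of the ATG is +1, the base 5′ of it is −1, and no
position 0 exists. `to_promoter_coords` / `from_promoter_coords` are exact
inverses over this frame. The defaults `WGATAR` (GATA factors) and
`RRGGAA` (purine-flanked ETS core for PU.1) are configuration, not ground
truth: consensus definitions vary across prediction tools, and any IUPAC
string can be supplied per scan.

Site mutagenesis (`mutate_site`) emulates mutant EMSA probe design: it
searches for the smallest set of non-degenerate (invariant) pattern
positions whose transversion leaves no hit of the pattern overlapping the
original site, and only if no in-site combination suffices does it also
break overlapping occurrences at their own invariant cores. Degenerate
positions are never touched, and a fully degenerate pattern raises.

## qPCR calculus

ChIP enrichment of a target amplicon versus input is
`E^(ΔCt_input − ΔCt_IP)` with `ΔCt = Ct(target) − Ct(reference)` and
amplification efficiency `E = 2.0` (one doubling per cycle) unless a
standard-curve-derived efficiency is supplied. Referencing both IP and
input to the same amplicon makes the result invariant to any constant Ct
offset within a sample, and swapping IP and input inverts the fold exactly.
Relative expression is `E^(−ΔΔCt)` against a calibrator sample.
Technical replicates enter as the mean Ct; the reported dispersion is the
standard deviation of the fold over the full Cartesian product of
replicate combinations, which is exact and cheap at qPCR scale (≤ 3⁴
combinations for triplicates).

## Rank-sum association

Per stage, expression (RPKM) of occupied genes is compared with
non-occupied genes by a one-sided Wilcoxon rank-sum test with the
alternative fixed as "occupied greater" — the directional claim under
study. Ties receive midranks. For tie-free pooled samples with
n1 + n2 ≤ 20 the p-value is exact: the null distribution of the occupied
group's rank sum is obtained by dynamic programming over subset sums,
which is identical to enumerating all C(n1+n2, n2) rank assignments.
Larger or tied samples use the normal approximation with tie-corrected
variance

    Var(W) = n1·n2/12 · ( (n+1) − Σ(t³ − t) / (n(n−1)) )

and a 0.5 continuity correction. The cutoff of 20 keeps the exact path
instantaneous while the approximation is already within 0.01 of exact at
n1 = n2 = 10 (tested). p-values are reported per stage with no
multiple-testing correction, as stage panels are interpreted individually;
this is noted in the output. Stage-wise fold changes are
`log2((RPKM_next + ε)/(RPKM_prev + ε))` with pseudocount ε = 0.1 to keep
zero RPKM finite; ε is configurable and ε = 0 is permitted when all
denominators are positive.

## Synthetic data: what it emulates, and what it does not

The generators produce data with the minimal statistical structure each
analysis assumes, under fixed default conditions chosen once:

- **Genome/annotation**: one 6 Mb chromosome, 200 genes with pairwise TSS
  spacing ≥ 25 kb (so ±10 kb windows rarely overlap), random strands, 30%
  flagged as RP genes and 15% designated occupied.
- **ChIP reads**: uniform background at 5·10⁻⁴ reads/bp (≈ 10 background
  reads per 20 kb window) plus Poisson(40) extra reads per occupied TSS
  placed Normal(TSS, σ = 300 bp), mimicking a point-source factor binding
  footprint; 36 bp reads. Companion narrowPeak records carry the planted
  read count as signal with the summit at the TSS, so the read-based and
  peak-based scoring paths can be validated against the same truth. Under
  these rates the occupied/background window-count ratio is ≈ 5:1, and
  mean-normalized target calling recovers the planted set with
  sensitivity and specificity ≥ 0.9.
- **Expression**: per (gene, stage), log2 RPKM ~ Normal(5, 1) + 1.0 for
  occupied genes + a per-stage decline offset; the "mouse" schedule
  (0, −2, −3, −3.5) drops hardest at the first stage pair and the "human"
  schedule (0, −0.5, −2.5, −3.5) at later pairs, emulating the
  early-versus-late decline timing difference between the species'
  erythroid differentiation. Schedules are parameters, not hard-coded
  biology.
- **Promoter**: a 1,200 nt sequence with the ATG at index 1,000, carrying
  a planted `WGATAR` realization at −694 and `RRGGAA` realizations at −709
  and −653 — a synthetic reconstruction of a GATA/ETS-bearing RP gene
  proximal promoter. Chance background matches of the planted patterns
  are removed by deterministic single-base edits outside the planted
  spans, so scans recover exactly the planted sites. One subtlety: a
  pyrimidine-only background excludes purine-requiring motifs on the plus
  strand, but its minus strand is purine-rich, so pattern-exclusion
  arguments hold per strand, not globally.

All generators are deterministic per seed, with independent seeded streams
per generator, so bundles are reproducible component-wise.

What the synthetic data does **not** model: fragment-length/shift effects,
GC and mappability bias, duplicate reads, replicate structure,
input-chromatin background structure, overdispersed (non-log-normal)
expression noise, and correlated gene neighborhoods. Passing tests
therefore demonstrate the correctness of the scoring, scanning and testing
machinery under the stated generative assumptions — not robustness to
every artifact of real ChIP-seq or RNA-seq data.

## Numerical and design choices

- Window membership and coordinate conventions are half-open everywhere;
  1-based report formats are converted at the I/O boundary only.
- Fast interval counting uses sorted positions with binary search; its
  equivalence to naive all-pairs containment is asserted in tests on
  planted instances.
- Pipeline outputs format floats with 6 significant digits so repeated
  runs on identical inputs are byte-identical; round-trip I/O writers use
  full float precision instead.
- The association requires both strata non-empty at every stage and
  refuses target sets covering all (or no) genes, rather than returning a
  degenerate p-value.
- Null calibration of the association pipeline (no planted shift) is part
  of the test suite: the one-sided test rejects at ≈ the nominal 5% rate
  over 500 seeded simulations.
- Problem sizes in the test suite (200 genes / ~4,200 reads; 500-run null
  calibration at 160 genes) were chosen to make the full suite run in a
  few seconds while keeping every statistical check well-powered.

## Known limitations

- TGS counts each read once per gene; a read within two genes' windows
  (possible when TSSs are < 2w apart) contributes to both, by design.
- The exact rank-sum path requires tie-free data; tied small samples fall
  back to the approximation rather than implementing the exact
  tied-permutation distribution.
- Percent-of-input ChIP quantification and efficiency calibration from
  standard curves are out of scope; enrichment is fold-over-input.
- Peak calling itself is out of scope: peaks are consumed, never called.
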