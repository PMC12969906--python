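# Methods

`acescan` analyses organophosphate/carbamate resistance conferred by the
*ace-1* gene of *Anopheles sinensis*: the G119S point mutation and the
heterogeneous gene duplication (one susceptible plus one resistant copy on
the same chromosome) that creates permanent heterozygotes. This note
records the models implemented, the parameters that matter, and the
choices made where the design was genuinely open.

## Codon-119 genotyping

Sanger consensus amplicons are anchored to a fixed 193 bp reference by
exact matching of the two 10-mers flanking codon 119, tried on both
strands; IUPAC ambiguity codes in the query match any compatible base. A
tie between strands, or a non-unique flank hit, is reported as
`no_anchor`. Anchoring by exact flank match instead of alignment keeps
the caller fully deterministic, which a 193 bp fixed amplicon permits.

The observed codon is expanded position-wise into base sets and resolved
against the three known alleles — GGC and GGT (glycine, susceptible G
class) and AGC (serine, resistant S) — as the unique unordered pair whose
position-wise union reproduces the observed sets. Codons ambiguous at
**more than one position** (e.g. `RGY`) are rejected as `unresolvable`
even when a single known-allele pair could explain them: a consensus
sequence carries no phase information, so the double peaks could equally
pair into a haplotype outside the known allele set. Homozygotes for an
unknown codon (e.g. `GGA`) are likewise `unresolvable`.

The bundled reference amplicon is a synthetic stand-in sequence (the
assay's true amplicon is defined by its primers and is not redistributed
here); it is constructed so that both codon flanks occur exactly once
across both strands, which the anchoring contract requires.

## Exact Hardy–Weinberg test

Counts are reduced to allele counts with GGT pooled into the G class.
Conditional on allele counts (nG, nS), the probability of h heterozygotes
among n diploids is

    P(h) = n! nG! nS! 2^h / [(2n)! nGG! h! nSS!]

evaluated in log space with `gammaln` over every admissible h (same
parity as nS, up to min(nG, nS)). The two-sided p-value sums all
configurations whose probability does not exceed the observed one, with a
relative tolerance of 1e−12 on the comparison so that ties survive
floating-point noise; a single admissible configuration short-circuits to
p = 1 exactly. The test suite cross-checks the whole enumeration against
an exact-rational factorial oracle for small n.

Heterozygote excess is judged against the Levene finite-sample
expectation E[h] = nG·nS/(2n−1), not the asymptotic 2npq.

Allele-frequency heterogeneity across populations uses the Pearson
chi-square on the K×2 table of (G-class, S) allele counts without
continuity correction (`scipy.stats.chi2_contingency`), df = K−1.

## The packaged survey table

`acescan/data/guizhou_genotype_table.csv` carries the printed genotype
percentages of the 12-population Guizhou survey; counts are reconstructed
as `round(n·%/100)` and validated to sum to n (all 12 rows reconstruct
exactly). Two quirks are handled deliberately:

- The CH row's printed allele column is internally inconsistent with its
  own genotype column; allele frequencies are therefore always derived
  from genotype counts (giving S = 67% for CH), which is the only reading
  consistent with the pooled S frequency of 50.36% and the heterogeneity
  chi-square of 128.02.
- The survey's "Average" row is the mean of the *rounded printed*
  percentages (63.5% heterozygotes); the count-derived unweighted mean is
  63.43%. `summarize()` reports the count-derived value; the tests assert
  both readings.
- The single GGT carrier is modeled as one GGT/GGT homozygote in ZJ (2
  GGT alleles of 100), the only configuration matching the printed 2%
  GGT allele frequency.

## AChE1 residual activity

The kit equation collapses to activity (U/g) = 2255·ΔA/W with
ΔA = OD_total − OD_inhibitory and W the tissue mass in grams. The
long-form constant (ε, path length, volumes, reaction time) is accepted
symbolically and overrides 2255 when fully specified, but the component
values that collapse to 2255 are not published, so the long form cannot
be validated against it. Negative ΔA is clipped to 0 and flagged —
residual activity is physically nonnegative. Population comparisons use
the Welch t-test by default (small groups with no variance-equality
guarantee); the pooled-variance form and a Bonferroni option (off by
default, matching the original analysis) are available.

## DOC-ratio duplication scan

Per-base depth tables (samtools-depth TSV; absent positions are implicit
zeros) are averaged in non-overlapping 100 bp windows (the window step is
configurable; non-overlapping tiling is the default because nothing in
the three-step procedure requires overlap and it is the cheaper choice).
A trailing partial window is dropped. Each sample's windows are divided
by that sample's genome-wide **median per-base depth** before the
resistant/sensitive ratio is taken; this removes library-size
differences, makes `copy_estimate = mean_ratio` an identity, and means a
*global* depth doubling produces ratio 1 — only a local duplication
shifts the track. Windows with zero normalized sensitive depth are
masked.

A locus is called duplicated when the mean unmasked window ratio over its
span is ≥ 1.5 (midway between the 1- and 2-copy expectations) **and** the
single-copy control locus (vgsc, on a separate contig) has mean ratio
inside [0.75, 1.25]; a failing control vetoes the call regardless of the
locus signal. Both thresholds are exposed as parameters. Coordinates are
1-based inclusive in depth files and window records, 0-based half-open in
`Span`/BED.

Out of scope, as for the original desk analysis: read mapping, breakpoint
resolution (the *ace-1* contig, 41,288 bp, has no resolved chromosomal
placement), and inferring the S/R composition of the duplicated copies
from coverage alone.

## Double-standard-curve qPCR

Each gene's tenfold dilution series is fitted by OLS of Cq on log10
relative concentration (level k ⇒ 10^−k, undiluted = 1); efficiency
E = 10^(−1/slope) − 1, flagged invalid outside (0, 1.1] or for
non-negative slope. Unknown concentrations are read off each gene's own
curve, c = 10^((Cq − intercept)/slope); a sample's copy number is the
mean over replicate well pairs of the target/reference concentration
ratio (arithmetic by default, matching "mean number of copies";
geometric optionally). Because the reference gene (rps7) is single-copy,
the ratio is the target copy number per haploid genome with no absolute
calibration. Plates are analysed independently (no inter-plate
calibrator) and melting-curve QC is reduced to an optional boolean per
well.

## Synthetic data generator

The generator produces every input the pipeline consumes and defines the
conditions under which the stochastic stages are validated:

- **Genotypes**: P(GG) = (1−p)² + Fpq, P(GS) = 2pq(1−F),
  P(SS) = p² + Fpq, clamped to [0, 1] and renormalized. Heterozygote
  excess is parameterized by a single inbreeding-style coefficient F < 0
  rather than an explicit duplication-genetics model — the survey
  quantifies excess only through HWE deviation. GGT substitution (rate
  `p_ggt` per G allele) is restricted to GG homozygotes because a
  GGT/AGC consensus (`RGY`) is unphaseable by design of the caller, and
  the only GGT carrier observed in the field was a homozygote.
- **Amplicons**: the reference with the codon replaced by the IUPAC
  consensus of the allele pair; optional uniform substitution error
  (default 0) outside the codon.
- **Coverage**: per-base Poisson(λ), default λ = 30 on a 41,288 bp
  target contig and a 35,000 bp control contig (the control contig's true
  length is not published; 35 kb is an arbitrary same-order choice), with
  a 4 kb span at relative copy 2 in resistant pools. A negative-binomial
  option adds overdispersion; Poisson is the default since no coverage
  noise model is published.
- **qPCR**: Cq = intercept + slope·log10(conc) with
  slope = −1/log10(1+E); standards noiseless by default, unknowns with
  N(0, σ) Cq noise, σ = 0.1; default efficiencies 0.97/0.99, 5 dilution
  levels, 4 replicates, unknown baseline concentration 0.1 (inside the
  standard range).
- **Activity**: OD_inhibitory inverted from the target activity through
  the kit equation, multiplicative lognormal noise at the given CV
  (default 10%), OD_total baseline 1.0, W = 0.1 g.

Every generator is deterministic under a fixed seed (byte-identical
files). The bundled scenario (`GUIZHOU_SCENARIO`) mirrors the survey:
12 populations at the surveyed S frequencies with F < 0 for the six
heterozygote-excess populations, one copy-2 resistant pool against a
single-copy sensitive pool, duplicated and single-copy qPCR populations,
and a sensitive reference with ~2.5× the residual activity of the
mutated populations (plus one population, HX, indistinguishable from the
reference).

What passing these simulations does *not* show: recovery of the real
WGS DOC ratios (2.25 for CH/LP etc.), the published activity t
statistics, or per-population field copy numbers — those require the
deposited raw data. The generator has no read-level error model, no GC
or mappability bias in coverage, and no between-replicate plate effects;
real data would stress all three.

## Problem sizes and runtime choices

The test suite validates the stochastic stages at the scale the analysis
itself uses: full-length contigs (41,288 + 35,000 bp) at 30×, 100-seed
replicate batteries for the DOC caller, 200-replicate batteries for HWE
parameter recovery and qPCR error, 20-sample qPCR populations. The whole
suite runs in well under a minute on one CPU; `scripts/acceptance.py`
recomputes its four headline quantities in seconds.

## Known limitations

- The exact HWE test enumerates all configurations; fine for per-locus
  sample sizes here (n ≤ a few thousand), not meant for genome-scale
  scans.
- Duplication calling assumes a single contiguous duplicated span and a
  trustworthy single-copy control; it does not segment, and cannot
  distinguish a homogeneous amplification from a heterogeneous (S+R)
  duplication — that distinction needs genotype and copy-number evidence
  together.
- The percent-to-count reconstruction is exact for the packaged table but
  will reject tables whose printed percentages do not round back to n.
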