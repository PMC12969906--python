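# acescan

Analysis pipeline for organophosphate/carbamate resistance mediated by
the *ace-1* gene in *Anopheles sinensis* field populations.

Resistance to these insecticide classes rests on two mechanisms at the
same locus: the G119S substitution in acetylcholinesterase-1 (codon
alleles GGC/GGT = susceptible glycine, AGC = resistant serine) and a
*heterogeneous duplication* — one susceptible and one resistant *ace-1*
copy on the same chromosome — which creates permanent heterozygotes and
shows up as heterozygote excess, a doubled read-depth ratio, and a qPCR
copy number near 2. `acescan` implements the full desk analysis:

- **Genotyping** — codon-119 calls from Sanger consensus amplicons,
  heterozygotes arriving as IUPAC ambiguity codes (`RGC` = GGC/AGC).
- **Population genetics** — genotype/allele frequencies; the exact
  Hardy–Weinberg test by full enumeration, two-sided p summing all
  heterozygote configurations no more probable than the observed one,

      P(h | nG, nS) = n! nG! nS! 2^h / [(2n)! n_GG! h! n_SS!]

  with excess judged against the Levene expectation nG·nS/(2n−1); and
  the K×2 Pearson χ² for allele-frequency heterogeneity.
- **AChE1 residual activity** — the kit equation
  activity (U/g) = 2255·ΔA/W, with Welch t-tests against a sensitive
  reference population.
- **CNV by depth-of-coverage ratio** — 100 bp window means from
  per-base depth tables, median-of-genome normalization per sample,
  resistant/sensitive ratio tracks, and duplication calls gated on a
  single-copy control locus (*vgsc*).
- **qPCR copy number** — the double-standard-curve method: each gene
  (*ace-1*, single-copy *rps7*) read off its own tenfold-dilution curve
  (slope = −1/log₁₀(1+E)), copy number = target/reference concentration
  ratio.
- **Synthetic data** — seeded generators for every input (FASTA, depth
  TSV, qPCR and OD plates), so the whole pipeline is testable without
  sequencing data.

## Worked example

The package ships the 12-population Guizhou survey genotype table.
Reconstructing counts from the printed percentages and summarizing:

```python
from acescan import popgen

tables = popgen.load_guizhou_counts()
s = popgen.summarize(tables)
print(s["n_total"], round(s["pooled_pct_S"], 2), s["n_hwe_deviant"])
het = popgen.heterogeneity_chi2(tables)
print(round(het.chi2, 2), het.df)
by_pop = {t.population: t for t in tables}
print(round(popgen.hwe_exact(by_pop["LD"]).p_exact, 3))
```

prints

```
551 50.36 6
128.02 11
0.06
```

551 mosquitoes genotyped; pooled resistant-allele frequency 50.36%; six
populations deviate from Hardy–Weinberg equilibrium (all toward
heterozygote excess — the duplication signature); allele frequencies are
strongly heterogeneous across populations (χ² = 128.02, df = 11); the LD
population's exact HWE p is 0.060.

The same stages run from the shell on files:

```sh
acescan simulate all --seed 11 --out sim/         # synthetic survey bundle
acescan genotype sim/amplicons.fasta --out genotypes.csv
acescan popgen genotypes.csv --from-genotypes --out-json popgen.json
acescan cnv sim/depth_resistant.tsv sim/depth_sensitive.tsv \
        --bed sim/loci.bed --out-json cnv.json
acescan qpcr sim/qpcr_plate.csv --out qpcr.csv --summary-out qpcr.json
acescan report --popgen-json popgen.json --cnv-json cnv.json \
        --qpcr-json qpcr.json --out-json report.json --out-md report.md
```

On the bundled scenario the CNV stage reports a mean DOC ratio ≈ 2.0
over the duplicated span with the control locus ≈ 1.0 (`is_duplicated:
true`), and the qPCR stage estimates mean copy ≈ 2 for the duplicated
populations and ≈ 1 for the sensitive reference.

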