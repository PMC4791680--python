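# mapsat

Development of **informative microsatellite markers** for a non-model species
from scaffolds obtained by mapping its shotgun reads against a related model
species' genome. Unlike markers from anonymous cloning protocols, markers
developed this way come with genomic context: the reference chromosome they
sit on, the distance to the nearest exon, and the protein-coding genes within
reach of a selective sweep.

The package is aimed at molecular ecologists and population geneticists who
have (or can cheaply produce) a reference-mapped consensus for their study
species and want polymorphic, well-characterized SSR panels — plus the
bookkeeping to decide which markers are effectively neutral and which are
gene-linked.

## What it computes

- **Repeat screening** (`repeat_screen`): maximal perfect tandem repeats of a
  configurable unit length (default tetranucleotide, ≥ 8 whole copies) in
  scaffolds above a length cutoff (default 1 Mbp). Motifs are grouped into
  rotation/reverse-complement classes: `canonical_motif("CTTT") == "AAAG"`.
- **Marker design prep** (`marker_design`): flank extraction, designability
  under primer constraints (primers 20–24 bp, T_m 57 °C in 54–65 °C, product
  ≤ 450 bp), universal M13R/CAG 5′ tags, and stratified random panel
  selection (2–5 loci per chromosome group, exclusions supported). Primer3
  thermodynamics are deliberately not reimplemented; the module prepares its
  inputs.
- **Gene linkage** (`gene_linkage`): distance from each locus to the nearest
  exon, genes within ±100 kbp, and a **dual-evidence filter**: a gene counts
  as linked only if it appears both in the annotation window and among the
  translated-homology (BLASTX, E ≤ 10⁻⁶) hits of the same region, with
  predicted genes (`Gm#`, `LOC#`, `#Rik`) and microRNAs (`Mir#`) excluded.
- **Genotype QC** (`marker_qc`): per locus N, allele count N_A, size range,
  observed heterozygosity H_O, Nei's unbiased expected heterozygosity
  H_E = 2N/(2N−1)·(1 − Σpᵢ²), an **exact Hardy–Weinberg probability test**
  (Levene distribution, full enumeration with Monte Carlo fallback), and
  null-allele frequency estimates (Chakraborty (H_E−H_O)/(H_E+H_O);
  Brookfield-1 (H_E−H_O)/(1+H_E)).
- **Cross-species amplification** (`cross_amp`): per-species success rates
  per locus and locus counts at rate thresholds (80 %/40 % conventions).
- **Synthetic data** (`fixtures`): seeded generators with recorded ground
  truth (planted repeats, annotation, Hardy–Weinberg genotypes with null
  alleles), plus a bundled reference panel of 24 polymorphic tetranucleotide
  loci characterized in the Taiwan field mouse (*Apodemus semotus*).

I/O: FASTA, GFF3, 12-column BLAST tabular, genotype CSV, GenePop (3-digit
allele codes), BED/TSV. All internal coordinates are 0-based half-open;
conversions happen only at file boundaries.

## Worked example

```python
from mapsat.fixtures import make_scaffolds, make_genotypes
from mapsat.io_formats import write_fasta, write_genotype_csv, write_bed

records, truth = make_scaffolds(
    1, 50_000, [("AAAG", 10, 10_000), ("AGAT", 9, 30_000)], seed=1)
write_fasta(records, "demo.fa")
table, _ = make_genotypes(24, [({100: 0.5, 104: 0.3, 108: 0.2}, 0.0, 0.0)], seed=4)
write_genotype_csv(table, "demo_geno.csv")
```

```console
$ mapsat scan demo.fa --min-scaffold-len 0 --bed demo.bed
scanned 1 scaffolds (0 below length cutoff): 2 loci
  AAAG  1
  AGAT  1
$ mapsat qc demo_geno.csv --seed 1 --out qc.tsv
1 loci: mean N_A 3.0, mean H_E 0.627, mean H_O 0.750, 1 in HWE at alpha=0.05
```

`scan` recovered exactly the two planted repeats and reported their canonical
motif classes. `qc` found 3 alleles at the simulated locus; H_E ≈ 0.627 is
Nei's unbiased estimate from the 48 sampled allele copies, H_O = 0.75 is the
heterozygote fraction, and the exact HWE test (method `enumeration` in
`qc.tsv`, p ≈ 0.485) does not reject random mating — as expected for
genotypes drawn at Hardy–Weinberg proportions with no null allele.

The bundled 24-locus reference panel aggregates the same way:

```python
>>> import mapsat
>>> from mapsat.fixtures import table1_fixture
>>> s = mapsat.summarize_panel(table1_fixture())
>>> round(s.mean_na, 1), round(s.mean_he, 3), round(s.mean_ho, 3), s.n_in_hwe
(7.4, 0.689, 0.599, 18)
```

i.e. a mean of 7.4 alleles per locus, mean H_E 0.689 against mean H_O 0.599
(a modest heterozygote deficit), and 18 of 24 loci consistent with
Hardy–Weinberg equilibrium at α = 0.05.

## Layout

```
src/mapsat/
  io_formats.py     FASTA / GFF3 / BLAST tabular / genotype CSV / GenePop / BED
  repeat_screen.py  canonical motifs, perfect-repeat finder, scaffold screen
  marker_design.py  flanks, designability, tags, stratified panel selection
  gene_linkage.py   nearest-exon distance, ±100 kbp windows, dual-evidence filter
  marker_qc.py      H_O / H_E, exact HWE test, null-allele estimators
  cross_amp.py      amplification success rates and threshold counts
  fixtures.py       seeded synthetic generators + bundled reference panel
  cli.py            `mapsat` command group (scan / design / link / qc / genepop / crossamp)
```

See `docs/methods.md` for the statistical model, numerical choices and known
limitations.
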