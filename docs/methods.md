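# Methods

## Problem setting

Shotgun reads from a study species mapped against a related model genome give
a fragmented consensus ("scaffolds", named after the reference chromosomes
they derive from, with N runs where mapping failed). Scaffolds are screened
for microsatellites; because each locus inherits a position in the reference
genome, its annotation context — nearest exon, genes within a window — comes
for free. That context is what makes a marker "informative": it can be chosen
to be near-neutral (far from genes) or deliberately gene-linked (e.g. near a
QTL of interest).

## Repeat model

A locus is a **maximal run of exact copies** of a fixed-length unit (period
p, default 4) with at least `min_repeats` whole copies (default 8). No
mismatches or indels: imperfect-repeat detection is out of scope, matching
the common SSR-mining convention. Conventions, chosen for determinism and
oracle-checkability:

- a run is reported once, anchored at its **leftmost** start; the reported
  motif is the unit read at that position (its rotation/reverse-complement
  class representative is the `canonical` label);
- partial trailing copies neither count toward `n_repeats` nor extend the
  reported interval;
- units that are homopolymers (e.g. `AAAA` at p = 4) are rejected for p > 1 —
  they are period-1 repeats in disguise;
- any N (or other ambiguity character, normalized to N on input) breaks a
  run.

The finder is a vectorized scan of the self-match mask `seq[i] == seq[i+p]`;
its contract is checked in the tests against two independent reference
implementations (a positional brute force and a regex backreference oracle
with a maximality post-check).

Scaffold screening considers only scaffolds **strictly longer** than
`min_scaffold_len` (default 1 Mbp): short mapped fragments yield loci whose
chromosome assignment is unreliable.

## Marker design preparation

Thermodynamic primer picking (Primer3) is intentionally not reimplemented.
The module prepares its inputs and enforces the constraints that determine
whether a design attempt is worth making:

| parameter | default | meaning |
|---|---|---|
| `primer_len_min/max` | 20 / 24 bp | primer length window |
| `tm_opt (tm_min–tm_max)` | 57 °C (54–65) | melting temperature window, recorded for the design run |
| `max_product` | 450 bp | amplicon ceiling (fragment-analysis range) |
| `flank_len` | 200 bp | flank offered on each side of the repeat |
| `max_n_fraction` | 0.2 | tolerated N fraction per flank |

A candidate is designable iff each flank holds ≥ 24 contiguous non-N bases,
each flank's N fraction is ≤ 0.2, and `repeat + 2·primer_len_min ≤
max_product`. The N-fraction ceiling is this package's choice — mapped
consensi carry gap runs in flanks and no standard value exists; 0.2 keeps
flanks that Primer3 can realistically use while discarding gap-riddled ones.
`flank_len` = 200 bp makes a 450 bp product reachable for repeats up to
~410 bp.

Universal 5′ tags for three-primer fluorescent genotyping are M13R
(`GGAAACAGCTATGACCAT`, 18 bp) and CAG (`CAGTCGGGCGTCATCA`, 16 bp); a tag adds
its full length to the expected product.

Panel selection is stratified sampling: per chromosome group, a uniformly
drawn number k ∈ {k_min … min(k_max, available)} of designable loci without
replacement (defaults 2–5), with group exclusions (e.g. sex chromosomes, or
groups known to misbehave). Groups are visited in sorted label order so a
fixed seed gives a fixed panel.

## Gene linkage

Distances use scaffold-coordinate geometry on 0-based half-open intervals:
0 when intervals overlap, else the gap between closest ends. The convention
is stated because common usage is ambiguous; strand is recorded but ignored.
Nearest-exon queries fall back from exon children to CDS records to the gene
span when annotation lacks sub-features (logged).

The gene window is anchored on the repeat interval and extends `half_width`
(default 100 kbp — the distance over which a selective sweep plausibly drags
linked variation) on each side; a gene belongs to the window if its interval
intersects it. The homology side of the evidence is a translated search of
the same region against the model species' proteins, pre-filtered at
E ≤ 10⁻⁶ (inclusive at the boundary). A gene is **linked** only when present
on both sides after removing predicted/uncharacterized genes (`Gm<digit>`,
`LOC<digit>`, suffix `Rik`) and microRNAs (`Mir<digit>`): translated search
cannot recover those classes, so counting them would make the two evidence
sources structurally inconsistent.

Gene identity across the two sources is the symbol, compared
case-insensitively after stripping a trailing separator+digits isoform
suffix. This normalization is a package choice (hit descriptions and
annotation attributes rarely agree byte-for-byte) and is deliberately
conservative: it never merges two distinct stems.

## Genotype statistics

- **H_O**: heterozygous fraction of genotyped individuals.
- **H_E**: Nei's (1978) small-sample-corrected expected heterozygosity
  `2N/(2N−1)·(1 − Σpᵢ²)`, matching the estimator of the standard genotype
  analysis programs; the uncorrected form is available via `unbiased=False`.
  Allele frequencies are kept as exact rationals so they sum to 1 identically.
- **Exact HWE test**: conditional on allele counts, genotype configurations
  follow the Levene distribution
  `P({n_ij}) = N!·Πa_k!·2^h / ((2N)!·Πn_ij!)`;
  the p-value is the total probability of configurations no more probable
  than the observed one (log-space comparison with a 1e-9 tolerance so
  numerically tied configurations count as tied). Full enumeration is used
  while the configuration count stays ≤ 10⁵ (a lazy enumerator aborts past
  the cap); beyond that, Monte Carlo shuffling of the 2N allele copies with
  the `(1 + hits)/(1 + reps)` estimator (default 100 000 reps, seed required
  at the CLI). The method and rep count are always recorded. Degenerate loci
  (one allele, or fewer than two genotypes) report p = 1.
- **Null alleles**: Chakraborty `r = (H_E−H_O)/(H_E+H_O)` (undefined when
  both are 0) and Brookfield-1 `r = (H_E−H_O)/(1+H_E)`. Negative estimates
  are floored at 0 with the raw value retained — a negative raw value is
  itself informative (heterozygote excess).
- Missing genotypes are dropped locus-wise, never imputed, so N varies by
  locus. No multiple-testing correction is applied to per-locus HWE p-values
  (panel characterization conventionally reports raw values); loci "in HWE"
  are counted at α = 0.05.

## Synthetic data and what it does (not) show

`make_scaffolds` draws i.i.d. uniform ACGT background, plants repeats and
N-gap runs, then enforces boundary hygiene (the base left of a planted run
must not continue the unit periodicity; the base to the right must not start
a partial copy) and rejection-checks the whole scaffold so the recorded truth
is provably exhaustive at the screened (period, min_repeats). It does **not**
emulate real genomic base composition, repeat clustering, or imperfect
repeats — passing recall/precision 1.0 shows the detector implements its
contract, not that real genomes are this clean.

`make_annotation` packs non-overlapping fixed-length gene models with evenly
spaced exons and a controlled fraction of predicted-gene symbols; real gene
length/spacing distributions are not modelled.

`make_genotypes` draws two alleles per individual from a visible+null pool at
Hardy–Weinberg proportions: null/null becomes missing, null/visible an
apparent visible homozygote — the classic null-allele signature, and exactly
the model underlying the Chakraborty estimator (so recovery tests validate
the estimator under its own assumptions). Independent technical dropout is
added via `missing_rate`.

The bundled reference panel (24 polymorphic tetranucleotide loci in
*Apodemus semotus*, 24 individuals, per-locus N between 9 and 24) ships as a
per-locus summary table; `summarize_panel` recomputes only the panel-level
aggregates (mean N_A 7.4, mean H_E 0.689, mean H_O 0.599, 18 loci in HWE)
from those rows.

## Problem sizes

The self-checks are sized to run on one CPU in seconds to a few minutes:
repeat-finder oracle equivalence on 200 random 600 bp sequences across
periods 2–6 (two-letter alphabets make spontaneous repeats common enough to
exercise every code path); interval-query equivalence on 150 random
instances of ≤ 60 features; HWE type-I calibration on 10 000 simulated
diallelic panels of N = 24 in the test suite (2 000 in the acceptance
script); H_E recovery at N = 500 and null-allele recovery over 200
replicates of N = 100.

## Known limitations

- Perfect repeats only; compound and interrupted microsatellites are not
  reported as single loci.
- The dual-evidence filter matches on normalized symbols, so annotation
  sources using database accessions without symbols will under-link unless a
  symbol can be parsed from the hit title.
- The exact-test enumeration cap makes highly polymorphic loci (N_A ≳ 10 at
  N ≈ 24) take the Monte Carlo path; p-values there carry sampling noise of
  order `1/√reps`.
- `select_panel` groups by a user-supplied label; the package does not infer
  chromosome assignments from scaffold names.
- Cross-amplification success is an input label (a wet-lab judgement), never
  computed from traces.
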