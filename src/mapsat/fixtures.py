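"""Seeded synthetic data with recorded ground truth.

Every pipeline stage can be exercised without any external download: scaffold
sequences with planted tandem repeats and N-gap runs (emulating a consensus
mapped against a related reference genome), gene annotation with a controlled
fraction of predicted-gene symbols, and diploid genotype panels drawn at
Hardy-Weinberg proportions with optional null alleles.

A bundled reference panel — the published characterization of 24 polymorphic
tetranucleotide microsatellite loci in the Taiwan field mouse (*Apodemus
semotus*), genotyped in 24 individuals — is exposed by :func:`table1_fixture`
for panel-aggregate computations.
"""

from __future__ import annotations

import importlib.resources
import logging
import string
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, SequenceRecord
from .repeat_screen import RepeatLocus, canonical_motif, find_perfect_repeats

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedRepeat:
    scaffold_index: int
    motif: str
    n_repeats: int
    position: int

    @property
    def end(self) -> int:
        return self.position + len(self.motif) * self.n_repeats


def _coerce_planted(planted_repeats: Iterable) -> list[PlantedRepeat]:
    out = []
    for item in planted_repeats:
        if isinstance(item, PlantedRepeat):
            out.append(item)
            continue
        if len(item) == 3:
            motif, n_rep, pos = item
            scaf = 0
        else:
            motif, n_rep, pos, scaf = item
        out.append(PlantedRepeat(scaffold_index=scaf, motif=str(motif),
                                 n_repeats=int(n_rep), position=int(pos)))
    return out


def make_scaffolds(
    n_scaffolds: int,
    length: int,
    planted_repeats: Iterable = (),
    gap_runs: Iterable = (),
    seed: int | None = 0,
    period: int = 4,
    min_repeats: int = 8,
    max_attempts: int = 50,
) -> tuple[list[SequenceRecord], list[RepeatLocus]]:
    """Scaffolds of i.i.d. uniform ACGT background with planted features.

    ``planted_repeats`` entries are ``(motif, n_repeats, position)`` tuples,
    optionally with a fourth scaffold-index element (default 0).  ``gap_runs``
    entries are ``(position, length)`` (optionally ``+ scaffold index``) N
    runs emulating mapping gaps.  Returns ``(records, truth)`` where truth is
    the exact list of RepeatLocus objects planted.

    The background is rejection-checked: after planting, a repeat screen at
    ``(period, min_repeats)`` must recover exactly the truth set, so the truth
    is exhaustive.  Backgrounds that spawn an accidental repeat (or extend a
    planted one) are regenerated from the seeded stream, up to
    ``max_attempts`` times.  Deterministic for a fixed seed.
    """
    planted = _coerce_planted(planted_repeats)
    gaps = []
    for item in gap_runs:
        if len(item) == 2:
            pos, glen = item
            scaf = 0
        else:
            pos, glen, scaf = item
        gaps.append((int(pos), int(glen), int(scaf)))

    # feasibility: planted repeats non-overlapping, inside scaffolds, separated
    per_scaffold: dict[int, list[PlantedRepeat]] = {}
    for p in planted:
        if not (0 <= p.scaffold_index < n_scaffolds):
            raise ValueError(f"scaffold index {p.scaffold_index} out of range")
        if p.position < 0 or p.end > length:
            raise ValueError(f"planted repeat at {p.position} does not fit in {length} bp")
        per_scaffold.setdefault(p.scaffold_index, []).append(p)
    for scaf, items in per_scaffold.items():
        items.sort(key=lambda p: p.position)
        for a, b in zip(items, items[1:]):
            if b.position < a.end + len(a.motif):
                raise ValueError(
                    f"planted repeats on scaffold {scaf} overlap or touch: "
                    f"{a.position}-{a.end} and {b.position}-{b.end}"
                )
    for pos, glen, scaf in gaps:
        if pos < 0 or pos + glen > length:
            raise ValueError("gap run does not fit in scaffold")
        for p in per_scaffold.get(scaf, []):
            if pos < p.end and pos + glen > p.position:
                raise ValueError("gap run overlaps a planted repeat")

    truth: list[RepeatLocus] = []
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    for i in range(n_scaffolds):
        name = f"scaffold_{i+1}"
        wanted = []
        for p in per_scaffold.get(i, []):
            wanted.append(
                RepeatLocus(
                    scaffold_id=name,
                    start=p.position,
                    end=p.end,
                    motif=p.motif,
                    canonical=canonical_motif(p.motif),
                    period=len(p.motif),
                    n_repeats=p.n_repeats,
                )
            )
        for attempt in range(max_attempts):
            arr = rng.choice(_BASES, size=length)
            seq = bytearray(arr.tobytes())
            for pos, glen, scaf in gaps:
                if scaf == i:
                    seq[pos : pos + glen] = b"N" * glen
            for p in per_scaffold.get(i, []):
                seq[p.position : p.end] = (p.motif * p.n_repeats).encode()
            # boundary hygiene: the base left of a planted run must not equal
            # the motif base one period in (which would shift the leftmost
            # start), and the base right of the run must not begin a partial
            # extra copy.  N already breaks a run and is left alone.
            forbidden: dict[int, set[int]] = {}
            for p in per_scaffold.get(i, []):
                if p.position > 0:
                    forbidden.setdefault(p.position - 1, set()).add(ord(p.motif[-1]))
                if p.end < length:
                    forbidden.setdefault(p.end, set()).add(ord(p.motif[0]))
            for pos_b, bad in forbidden.items():
                if seq[pos_b] != ord("N") and seq[pos_b] in bad:
                    allowed = [b for b in _BASES.tolist() if b not in bad]
                    seq[pos_b] = int(rng.choice(allowed))
            record = SequenceRecord(id=name, sequence=seq.decode())
            found = find_perfect_repeats(record, period=period, min_repeats=min_repeats)
            expected = sorted(
                [l for l in wanted if l.period == period and l.n_repeats >= min_repeats],
                key=lambda l: (l.start, l.end),
            )
            if [(l.start, l.end) for l in found] == [(l.start, l.end) for l in expected]:
                records.append(record)
                truth.extend(wanted)
                break
        else:
            raise RuntimeError(
                f"could not generate clean background for {name} in {max_attempts} attempts"
            )
    return records, truth


_SYMBOL_PREFIXES = [
    "Abc", "Bmp", "Cdk", "Dlg", "Eif", "Fgf", "Gab", "Hox", "Itg", "Jak",
    "Kcn", "Lrp", "Map", "Nrx", "Olf", "Pkd", "Rab", "Sox", "Tmem", "Ubr",
]


def _random_symbol(rng: np.random.Generator) -> str:
    return f"{rng.choice(_SYMBOL_PREFIXES)}{rng.integers(1, 100)}"


def _predicted_symbol(rng: np.random.Generator) -> str:
    kind = rng.integers(0, 4)
    num = rng.integers(100, 100000)
    if kind == 0:
        return f"Gm{num}"
    if kind == 1:
        return f"LOC{num}"
    if kind == 2:
        return f"Mir{rng.integers(1, 5000)}"
    stem = "".join(rng.choice(list(string.digits + "ABCDEF"), size=10))
    return f"{stem}Rik"


def make_annotation(
    scaffolds: Sequence[SequenceRecord],
    n_genes: int,
    exons_per_gene: int = 3,
    predicted_fraction: float = 0.0,
    seed: int | None = 0,
    gene_length: int = 20_000,
) -> tuple[list, pd.DataFrame]:
    """Random non-overlapping gene models with exon children on the scaffolds.

    A ``predicted_fraction`` of symbols is drawn from the predicted-gene
    classes (Gm#/LOC#/Mir#/...Rik).  Returns ``(features, truth)`` where truth
    is a DataFrame of (gene_id, symbol, scaffold, start, end, predicted).
    Raises when the requested genes cannot be packed without overlap.
    """
    from .gene_linkage import GeneFeature

    if not 0.0 <= predicted_fraction <= 1.0:
        raise ValueError("predicted_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    per_scaffold = [max(1, len(s.sequence) // (2 * gene_length)) for s in scaffolds]
    capacity = sum(per_scaffold)
    if n_genes > capacity:
        raise ValueError(f"cannot pack {n_genes} genes of {gene_length} bp; capacity {capacity}")

    features: list[GeneFeature] = []
    rows = []
    n_predicted = int(round(predicted_fraction * n_genes))
    predicted_flags = [True] * n_predicted + [False] * (n_genes - n_predicted)
    rng.shuffle(predicted_flags)
    gi = 0
    scaffold_cycle = sorted(range(len(scaffolds)), key=lambda i: -len(scaffolds[i].sequence))
    used: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(scaffolds))}
    while gi < n_genes:
        placed = False
        for si in scaffold_cycle:
            if gi >= n_genes:
                break
            s = scaffolds[si]
            if len(s.sequence) < gene_length:
                continue
            for _ in range(200):
                start = int(rng.integers(0, len(s.sequence) - gene_length + 1))
                end = start + gene_length
                if all(end <= a or start >= b for a, b in used[si]):
                    used[si].append((start, end))
                    placed = True
                    break
            else:
                continue
            predicted = predicted_flags[gi]
            symbol = _predicted_symbol(rng) if predicted else _random_symbol(rng)
            gene_id = f"gene{gi:04d}"
            # exon children: evenly spaced blocks inside the gene span
            step = gene_length // exons_per_gene
            exons = [
                (start + k * step, start + k * step + max(50, step // 4))
                for k in range(exons_per_gene)
            ]
            exons = [(a, min(b, end)) for a, b in exons]
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    symbol=symbol,
                    scaffold_id=s.id,
                    start=start,
                    end=end,
                    strand="+" if rng.integers(0, 2) else "-",
                    exons=exons,
                    kind="gene",
                    biotype="miRNA" if symbol.startswith("Mir") else "protein_coding",
                )
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "symbol": symbol,
                    "scaffold": s.id,
                    "start": start,
                    "end": end,
                    "predicted": predicted,
                }
            )
            gi += 1
        if not placed:
            raise ValueError("could not place all genes without overlap")
    return features, pd.DataFrame(rows)


def write_gff3(features: Sequence, path) -> None:
    """Write GeneFeature objects as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id};Name={f.symbol}"
            if f.biotype:
                attrs += f";gene_biotype={f.biotype}"
            fh.write(
                f"{f.scaffold_id}\tmapsat\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            for k, (a, b) in enumerate(f.exons, start=1):
                fh.write(
                    f"{f.scaffold_id}\tmapsat\texon\t{a + 1}\t{b}\t.\t{f.strand}\t.\t"
                    f"ID={f.gene_id}.exon{k};Parent={f.gene_id}\n"
                )


@dataclass(frozen=True)
class GenotypeTruth:
    locus_id: str
    allele_freqs: dict
    null_freq: float
    missing_rate: float

    @property
    def expected_het(self) -> float:
        """True expected heterozygosity of the *visible* allele pool."""
        return 1.0 - sum(float(p) ** 2 for p in self.allele_freqs.values())


def make_genotypes(
    n_samples: int,
    loci_specs: Sequence[tuple],
    seed: int | None = 0,
) -> tuple[GenotypeTable, list[GenotypeTruth]]:
    """Diploid panel drawn at Hardy-Weinberg proportions, with null alleles.

    ``loci_specs`` entries are ``(allele_freqs, null_freq, missing_rate)``
    where allele_freqs maps allele size -> frequency (summing, with
    ``null_freq``, to 1 over the visible+null pool).  Each individual draws
    two alleles independently from the pool; null/null genotypes are recorded
    as missing, null/visible as an apparent visible homozygote — the classic
    null-allele signature of inflated homozygosity.  ``missing_rate`` adds
    independent technical dropout.
    """
    rng = np.random.default_rng(seed)
    records = []
    truths = []
    for li, (freqs, null_freq, missing_rate) in enumerate(loci_specs):
        if not 0.0 <= null_freq < 1.0:
            raise ValueError("null_freq must lie in [0, 1)")
        visible = sorted(freqs)
        probs = np.array([float(freqs[a]) for a in visible], dtype=float)
        total = probs.sum() + null_freq
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"locus {li}: frequencies sum to {total}, not 1")
        pool = visible + [None]
        p = np.concatenate([probs, [null_freq]])
        p = p / p.sum()
        locus_id = f"locus_{li+1}"
        truths.append(
            GenotypeTruth(
                locus_id=locus_id,
                allele_freqs={a: float(freqs[a]) / probs.sum() for a in visible},
                null_freq=float(null_freq),
                missing_rate=float(missing_rate),
            )
        )
        for si in range(n_samples):
            sample = f"sample_{si+1:03d}"
            i, j = rng.choice(len(pool), size=2, p=p)
            a, b = pool[int(i)], pool[int(j)]
            if (a is None and b is None) or rng.random() < missing_rate:
                records.append((sample, locus_id, None, None))
            elif a is None:
                records.append((sample, locus_id, b, b))
            elif b is None:
                records.append((sample, locus_id, a, a))
            else:
                records.append((sample, locus_id, a, b))
    return GenotypeTable.from_records(records), truths


def table1_fixture() -> pd.DataFrame:
    """The bundled 24-locus reference panel as a per-locus summary table.

    Columns: locus, chromosome, motif, motif_repeats, primer_f, primer_r, n,
    size_min, size_max, n_alleles, he, ho, p_hwe, hwe_deviation, linked_gene.
    Suitable for :func:`mapsat.marker_qc.summarize_panel`, which recomputes
    the panel-level aggregates from these rows.
    """
    ref = importlib.resources.files("mapsat").joinpath("data/asemotus_panel.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df
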