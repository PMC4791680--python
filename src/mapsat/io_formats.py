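"""Readers and writers for the external formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open; conversion to and
from the 1-based inclusive conventions of GFF3 and BLAST happens only here, at
the file boundary, so downstream interval arithmetic is unambiguous.

Formats handled: FASTA (scaffolds), GFF3 (gene/exon annotation), 12-column
BLAST tabular output (translated homology hits), a simple genotype CSV
(sample,locus,allele1,allele2) and the GenePop diploid format with 3-digit
allele codes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .gene_linkage import GeneFeature

log = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 1e-6

# IUPAC ambiguity codes other than N (plus U) are normalized to N: mapped
# consensus sequences can contain them but the repeat screen cannot use them.
_AMBIGUITY_CODES = "RYSWKMBDHVU"
_AMBIGUITY_TO_N = str.maketrans({c: "N" for c in _AMBIGUITY_CODES})
_ALLOWED = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologyHit:
    """One hit from a 12-column tabular homology search report.

    Positions are kept exactly as the producer wrote them (1-based inclusive);
    ``gene_symbol`` is parsed from the subject identifier/description when one
    can be recognized.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    gene_symbol: str | None = None


@dataclass
class GenotypeTable:
    """Sample x locus diploid genotype calls with missing data allowed.

    ``calls[(sample, locus)]`` is an unordered allele pair stored sorted
    ascending, or None for missing.  Allele labels are integer fragment sizes.
    """

    samples: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], tuple[int, int] | None]

    def calls_at(self, locus: str) -> list[tuple[int, int]]:
        """Non-missing genotypes at a locus, in sample order."""
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out = []
        for s in self.samples:
            g = self.calls.get((s, locus))
            if g is not None:
                out.append(g)
        return out

    @staticmethod
    def normalize_pair(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int | None, int | None]]
    ) -> "GenotypeTable":
        """Build from (sample, locus, allele1, allele2) rows; None = missing."""
        samples: list[str] = []
        loci: list[str] = []
        calls: dict = {}
        for sample, locus, a1, a2 in records:
            if sample not in samples:
                samples.append(sample)
            if locus not in loci:
                loci.append(locus)
            if a1 is None or a2 is None:
                calls[(sample, locus)] = None
            else:
                calls[(sample, locus)] = cls.normalize_pair(int(a1), int(a2))
        return cls(samples=samples, loci=loci, calls=calls)


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into uppercase, N-normalized sequence records.

    Lowercase input is uppercased; IUPAC ambiguity codes other than N are
    mapped to N (count logged).  Duplicate ids raise; an empty file returns an
    empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_substituted = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = seq.translate(_AMBIGUITY_TO_N)
        n_substituted += sum(1 for a, b in zip(seq, cleaned) if a != b)
        bad = set(cleaned) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {rec.id}: invalid sequence characters {sorted(bad)}"
            )
        records.append(SequenceRecord(id=rec.id, sequence=cleaned))
    if n_substituted:
        log.info("normalized %d ambiguity characters to N", n_substituted)
    if not records:
        log.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    bio = (_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _validate_gff3_lines(path) -> None:
    """Pre-pass giving line-numbered errors for structural GFF3 defects."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) < start ({start})"
                )


def read_gff3(path) -> list[GeneFeature]:
    """Read gene/exon(/CDS) annotation from GFF3 into GeneFeature objects.

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention.  Exon (or, failing that, CDS) children are attached
    to their parent genes; exons/CDS whose Parent does not resolve to a gene
    are dropped with a logged count.  Genes lacking any usable identifier are
    likewise dropped and counted.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    genes: dict[str, GeneFeature] = {}
    n_dropped = 0
    for g in db.features_of_type("gene"):
        attrs = g.attributes
        gene_id = g.id or (attrs.get("ID") or [None])[0]
        symbol = (attrs.get("Name") or attrs.get("gene_name") or [gene_id])[0]
        if not gene_id:
            n_dropped += 1
            continue
        biotype = (attrs.get("gene_biotype") or attrs.get("biotype") or [None])[0]
        genes[gene_id] = GeneFeature(
            gene_id=gene_id,
            symbol=symbol or gene_id,
            scaffold_id=g.seqid,
            start=g.start - 1,
            end=g.end,
            strand=g.strand if g.strand in "+-" else "?",
            exons=[],
            kind="gene",
            biotype=biotype,
        )
    # attach exon children; fall back to CDS for genes with no exon records
    attached: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genes}
    cds_fallback: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genes}
    for ftype, store in (("exon", attached), ("CDS", cds_fallback)):
        for child in db.features_of_type(ftype):
            parents = child.attributes.get("Parent") or []
            hit = False
            for pid in parents:
                gid = _resolve_gene(db, pid, genes)
                if gid is not None:
                    store[gid].append((child.start - 1, child.end))
                    hit = True
            if not hit:
                n_dropped += 1
    for gid, feat in genes.items():
        ivs = attached[gid] or cds_fallback[gid]
        feat.exons = sorted(set(ivs))
    if n_dropped:
        log.info("dropped %d feature(s) without a resolvable gene", n_dropped)
    return list(genes.values())


def _resolve_gene(db, feature_id: str, genes: dict) -> str | None:
    """Walk Parent links from an id up to a known gene id (mRNA -> gene etc.)."""
    seen = set()
    current = feature_id
    while current and current not in seen:
        if current in genes:
            return current
        seen.add(current)
        try:
            feat = db[current]
        except gffutils.FeatureNotFoundError:
            return None
        parents = feat.attributes.get("Parent") or []
        current = parents[0] if parents else None
    return None


def read_blast_tab(path, max_evalue: float = DEFAULT_MAX_EVALUE) -> list[HomologyHit]:
    """Read 12-column tabular homology hits, dropping weak ones.

    Hits with E-value strictly greater than ``max_evalue`` are excluded
    (boundary hits at exactly the threshold are retained).  An optional 13th
    column, when present, is treated as the subject title and mined for a gene
    symbol; otherwise the symbol is taken from the subject id.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 (or 13) columns, got {len(cols)}"
                )
            try:
                evalue = float(cols[10])
                hit = HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    evalue=evalue,
                    bitscore=float(cols[11]),
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_start=int(cols[8]),
                    subject_end=int(cols[9]),
                    gene_symbol=_parse_gene_symbol(
                        cols[1], cols[12] if len(cols) == 13 else None
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed hit line") from exc
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value")
            if evalue <= max_evalue:
                hits.append(hit)
    return hits


def _parse_gene_symbol(subject_id: str, title: str | None) -> str | None:
    """Best-effort gene symbol from a subject id or title.

    Recognizes ``GN=Sym`` tags and ``(Sym)`` parentheticals in titles, and
    pipe-delimited ids (``sp|P12345|Sym``) where the last segment is used.
    """
    import re

    if title:
        m = re.search(r"GN=(\S+)", title)
        if m:
            return m.group(1)
        m = re.search(r"\(([A-Za-z0-9_.-]+)\)\s*$", title.strip())
        if m:
            return m.group(1)
        return title.strip().split()[0] if title.strip() else None
    if "|" in subject_id:
        seg = [s for s in subject_id.split("|") if s]
        return seg[-1] if seg else None
    return subject_id or None


def read_genotype_csv(path) -> GenotypeTable:
    """Read a genotype CSV with columns sample,locus,allele1,allele2.

    Blank allele cells mean a missing call (both must be blank together).
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample", "locus", "allele1", "allele2"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected header with columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            a1, a2 = row["allele1"].strip(), row["allele2"].strip()
            if (a1 == "") != (a2 == ""):
                raise ValueError(f"{path}:{lineno}: half-missing genotype")
            if a1 == "":
                records.append((row["sample"], row["locus"], None, None))
            else:
                records.append((row["sample"], row["locus"], int(a1), int(a2)))
    return GenotypeTable.from_records(records)


def write_genotype_csv(table: GenotypeTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "locus", "allele1", "allele2"])
        for s in table.samples:
            for l in table.loci:
                g = table.calls.get((s, l))
                if g is None:
                    writer.writerow([s, l, "", ""])
                else:
                    writer.writerow([s, l, g[0], g[1]])


MISSING_GENEPOP = "000000"


def write_genepop(table: GenotypeTable, path, title: str = "mapsat genotype export") -> dict:
    """Write a GenePop file with 3-digit allele codes; returns the allele map.

    Alleles at each locus are rank-coded 001..k in ascending size order;
    missing calls become 000000.  The size->code mapping is written alongside
    as ``<path>.alleles.tsv`` and returned as
    ``{locus: {allele_size: code}}``.  A locus with more than 999 distinct
    alleles cannot be encoded and raises.
    """
    mapping: dict[str, dict[int, int]] = {}
    for locus in table.loci:
        sizes = sorted(
            {a for s in table.samples
             for a in (table.calls.get((s, locus)) or ())}
        )
        if len(sizes) > 999:
            raise ValueError(f"locus {locus}: {len(sizes)} alleles exceed 3-digit codes")
        mapping[locus] = {size: rank for rank, size in enumerate(sizes, start=1)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for sample in table.samples:
            codes = []
            for locus in table.loci:
                g = table.calls.get((sample, locus))
                if g is None:
                    codes.append(MISSING_GENEPOP)
                else:
                    m = mapping[locus]
                    codes.append(f"{m[g[0]]:03d}{m[g[1]]:03d}")
            fh.write(f"{sample} ,  " + " ".join(codes) + "\n")
    map_path = str(path) + ".alleles.tsv"
    with open(map_path, "w") as fh:
        fh.write("locus\tallele_size\tcode\n")
        for locus in table.loci:
            for size, rank in mapping[locus].items():
                fh.write(f"{locus}\t{size}\t{rank:03d}\n")
    return mapping


def write_bed(loci: Iterable, path) -> None:
    """Write repeat loci as BED4 (name = canonical motif x repeat count)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.scaffold_id}\t{l.start}\t{l.end}\t{l.canonical}x{l.n_repeats}\n")


def read_bed_loci(path) -> list[tuple[str, int, int, str]]:
    """Read BED3/4 intervals back as (scaffold, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            out.append((cols[0], int(cols[1]), int(cols[2]),
                        cols[3] if len(cols) > 3 else ""))
    return out
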