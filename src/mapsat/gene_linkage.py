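"""Gene-linkage annotation of microsatellite loci.

A marker is "informative" when its genomic neighbourhood is known: the distance
to the nearest exon, and the protein-coding genes falling in a window extending
100 kbp on either side of the repeat (the scale over which a selective sweep can
drag neutral loci along).  A gene is accepted as *linked* only under dual
evidence: it must be present in the annotation window AND recovered by a
translated homology search (BLASTX) of the same region, the annotation acting
as a filter against homology false positives.  Predicted/uncharacterized genes
(Gm#, LOC#, #Rik) and microRNAs (Mir#) are excluded: translated search cannot
recover them, so they can never satisfy both evidence sources.

Coordinates throughout are 0-based half-open on scaffold coordinates; strand is
carried but ignored for distance geometry.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

DEFAULT_WINDOW_HALF_WIDTH = 100_000

_PREDICTED_PATTERNS = (
    re.compile(r"^Gm\d"),    # predicted gene models
    re.compile(r"^LOC\d"),   # uncharacterized loci
    re.compile(r"^Mir\d"),   # microRNA
    re.compile(r"Rik$"),     # RIKEN cDNA clones
)

_ISOFORM_SUFFIX = re.compile(r"[._-]\d+$")


@dataclass
class GeneFeature:
    """A gene (or sub-feature) interval with identifier and symbol.

    ``exons`` holds child exon intervals (0-based half-open) clipped within the
    gene span.  ``kind`` distinguishes gene / exon / cds records where both are
    kept as top-level features.
    """

    gene_id: str
    symbol: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "?"
    exons: list[tuple[int, int]] = field(default_factory=list)
    kind: str = "gene"
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class LinkageReport:
    """Per-locus annotation: nearest exon and windowed, dual-filtered genes."""

    locus_id: str
    nearest_exon_distance: int | None
    genes_in_window: list[tuple[str, int]]     # (symbol, signed distance bp)
    linked_genes: list[str]                    # subset passing the dual filter
    window_half_width: int = DEFAULT_WINDOW_HALF_WIDTH


def normalize_gene_symbol(symbol: str) -> str:
    """Normalize a gene symbol for cross-source comparison.

    Homology-hit descriptions and annotation attributes differ in case and
    often carry isoform suffixes (``Nrxn1-2``, ``NRXN1.1``); comparison is
    case-insensitive after stripping a trailing separator+digits suffix.
    """
    return _ISOFORM_SUFFIX.sub("", symbol.strip()).casefold()


def _interval(locus) -> tuple[str, int, int]:
    """Accept a RepeatLocus-like object or a (scaffold_id, start, end) triple."""
    if hasattr(locus, "start"):
        return locus.scaffold_id, locus.start, locus.end
    scaffold_id, start, end = locus
    return scaffold_id, start, end


def exon_intervals(feature: GeneFeature) -> list[tuple[int, int]]:
    """Exon intervals of a gene, falling back to CDS records then the gene span.

    Annotation without exon children still supports distance queries via the
    gene's own interval; the fallback is logged once per call site via DEBUG.
    """
    if feature.exons:
        return feature.exons
    log.debug("feature %s has no exon children; using %s span", feature.gene_id, feature.kind)
    return [(feature.start, feature.end)]


def nearest_feature_distance(locus, features: Iterable[GeneFeature]) -> int | None:
    """Distance in bp from a locus to the nearest exon among ``features``.

    Distance is 0 when intervals overlap, otherwise the gap between the closest
    ends under half-open arithmetic.  Only features on the locus's scaffold
    count; returns None when there are none.  Uses sorted endpoints + bisection
    so large annotations stay cheap.
    """
    scaffold_id, start, end = _interval(locus)
    intervals: list[tuple[int, int]] = []
    for feat in features:
        if feat.scaffold_id != scaffold_id:
            continue
        intervals.extend(exon_intervals(feat))
    if not intervals:
        return None
    intervals.sort()
    starts = [iv[0] for iv in intervals]
    # prefix maximum of ends lets us answer "closest end among intervals
    # starting left of the locus" in O(1) after the sort
    prefix_max_end = []
    running = -1
    for _, e in intervals:
        running = max(running, e)
        prefix_max_end.append(running)
    best: int | None = None
    idx = bisect_left(starts, end)
    if idx < len(intervals):
        best = starts[idx] - end  # nearest interval lying to the right
    if idx > 0:
        max_end = prefix_max_end[idx - 1]
        d = 0 if max_end > start else start - max_end
        best = d if best is None else min(best, d)
    return best


def genes_in_window(
    locus,
    features: Iterable[GeneFeature],
    half_width: int = DEFAULT_WINDOW_HALF_WIDTH,
) -> list[tuple[GeneFeature, int]]:
    """Genes whose interval intersects the locus's +-``half_width`` window.

    The window is ``[start - half_width, end + half_width)`` clipped at zero.
    Signed distance: 0 if the gene overlaps the locus, negative if the gene is
    upstream (left, lower coordinates), positive downstream.  Sorted by
    ``abs(distance)``, ties broken by (distance, symbol) for determinism.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    scaffold_id, start, end = _interval(locus)
    win_lo = max(0, start - half_width)
    win_hi = end + half_width
    tree = IntervalTree()
    for feat in features:
        if feat.scaffold_id != scaffold_id or feat.kind != "gene":
            continue
        tree.addi(feat.start, feat.end, feat)
    hits: list[tuple[GeneFeature, int]] = []
    for iv in tree.overlap(win_lo, win_hi):
        feat = iv.data
        if feat.end <= start:
            dist = feat.end - start          # upstream: negative
        elif feat.start >= end:
            dist = feat.start - end          # downstream: positive
        else:
            dist = 0
        hits.append((feat, dist))
    hits.sort(key=lambda t: (abs(t[1]), t[1], t[0].symbol))
    return hits


def exclude_predicted(symbols: Iterable[str]) -> list[str]:
    """Drop predicted/uncharacterized gene symbols and microRNAs.

    Removes symbols matching Gm<digit>..., LOC<digit>..., Mir<digit>... or
    ending in "Rik" (case-sensitive letterforms).  ``Gmppa`` survives: Gm must
    be followed by a digit to denote a predicted model.
    """
    return [s for s in symbols if not any(p.search(s) for p in _PREDICTED_PATTERNS)]


def dual_evidence_filter(window_genes: Sequence, homology_hits: Iterable) -> list[str]:
    """Genes supported by both annotation window and homology evidence.

    ``window_genes`` may be GeneFeature objects, (GeneFeature, distance) pairs
    or bare symbols; ``homology_hits`` may be HomologyHit objects or bare
    symbols.  Predicted genes are removed first; the intersection is computed
    on normalized symbols, and window order is preserved.
    """
    def _symbol(g) -> str:
        if isinstance(g, str):
            return g
        if isinstance(g, tuple):
            g = g[0]
        return g.symbol

    hit_symbols = set()
    for h in homology_hits:
        sym = h if isinstance(h, str) else getattr(h, "gene_symbol", None)
        if sym:
            hit_symbols.add(normalize_gene_symbol(sym))

    kept = exclude_predicted([_symbol(g) for g in window_genes])
    return [s for s in kept if normalize_gene_symbol(s) in hit_symbols]


def build_linkage_report(
    locus,
    features: Sequence[GeneFeature],
    homology_hits: Iterable,
    half_width: int = DEFAULT_WINDOW_HALF_WIDTH,
) -> LinkageReport:
    """Annotate one locus: nearest exon, windowed genes, dual-evidence subset."""
    scaffold_id, start, end = _interval(locus)
    locus_id = getattr(locus, "locus_id", f"{scaffold_id}:{start}-{end}")
    window = genes_in_window(locus, features, half_width)
    return LinkageReport(
        locus_id=locus_id,
        nearest_exon_distance=nearest_feature_distance(locus, features),
        genes_in_window=[(f.symbol, d) for f, d in window],
        linked_genes=dual_evidence_filter(window, homology_hits),
        window_half_width=half_width,
    )


def linkage_summary(
    reports: Sequence[LinkageReport], bin_width: int = 10_000
) -> tuple[dict, dict]:
    """Summaries of nearest-exon distances and linked-gene counts.

    Returns ``(distance_hist, gene_count_hist)``.  ``distance_hist`` maps bin
    lower edge (bp) -> fraction of loci, with a ``"no_feature"`` category for
    loci whose scaffold carries no annotation.  ``gene_count_hist`` maps
    {0, 1, 2, "3+"} -> fraction of loci over the dual-filtered gene counts.
    Fractions in each histogram sum to 1 over categorized loci.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not reports:
        return {}, {}
    dist_counts: dict = {}
    for r in reports:
        if r.nearest_exon_distance is None:
            key = "no_feature"
        else:
            key = (r.nearest_exon_distance // bin_width) * bin_width
        dist_counts[key] = dist_counts.get(key, 0) + 1
    n = len(reports)
    dist_hist = {k: c / n for k, c in sorted(
        dist_counts.items(), key=lambda kv: (isinstance(kv[0], str), kv[0]))}

    count_counts = {0: 0, 1: 0, 2: 0, "3+": 0}
    for r in reports:
        c = len(r.linked_genes)
        count_counts[c if c < 3 else "3+"] += 1
    gene_count_hist = {k: v / n for k, v in count_counts.items()}
    return dist_hist, gene_count_hist
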