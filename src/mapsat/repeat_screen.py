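"""Perfect tandem-repeat (microsatellite/SSR) detection in scaffold sequences.

The screening model mirrors the classic SSR-mining tools: a locus is a maximal
run of *exact* copies of a short unit (default period 4, "tetra" motifs) with at
least a minimum number of whole tandem copies (default 8).  Imperfect repeats
(mismatches, indels) are out of scope by design.

Motifs are grouped into equivalence classes under rotation and reverse
complement (``AAAG``, ``AGAA`` and ``CTTT`` are the same microsatellite), with
:func:`canonical_motif` giving the class representative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset(b"ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical representative of a repeat unit's equivalence class.

    The class contains every rotation of ``motif`` and every rotation of its
    reverse complement; the representative is the lexicographically smallest
    member.  Canonicalization is idempotent and identical for all members of a
    class, so it can be used to group loci by motif (e.g. ``GAAA`` -> ``AAAG``,
    ``CTTT`` -> ``AAAG``).

    Raises
    ------
    ValueError
        If the motif is empty or contains characters outside {A,C,G,T}
        (ambiguity codes, including N, have no well-defined class).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    rc = reverse_complement(motif)
    candidates = (
        [motif[i:] + motif[:i] for i in range(len(motif))]
        + [rc[i:] + rc[:i] for i in range(len(rc))]
    )
    return min(candidates)


@dataclass(frozen=True, order=True)
class RepeatLocus:
    """A perfect tandem repeat on a scaffold.

    Coordinates are 0-based half-open; ``sequence[start:end]`` equals ``motif``
    repeated ``n_repeats`` times.  Partial trailing copies are never included.
    """

    scaffold_id: str
    start: int
    end: int
    motif: str
    canonical: str
    period: int
    n_repeats: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % self.period != 0:
            raise ValueError("locus length must be a whole number of units")
        if (self.end - self.start) // self.period != self.n_repeats:
            raise ValueError("n_repeats inconsistent with coordinates")

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


def _is_homopolymer(motif: str) -> bool:
    return len(set(motif)) == 1


def find_perfect_repeats(record, period: int = 4, min_repeats: int = 8) -> list[RepeatLocus]:
    """Find every maximal perfect tandem repeat of the given period.

    A run is reported once, anchored at its leftmost start; the reported motif
    is the unit read at that position.  A run is maximal: it cannot be extended
    on either side by a full or partial unit copy without breaking exactness.
    ``n_repeats`` counts whole copies only.  Runs whose unit is a homopolymer
    (period-1 repeats in disguise, e.g. ``AAAA``) and runs touching N or any
    other ambiguity character are excluded.

    Parameters
    ----------
    record
        Object with ``id`` and ``sequence`` attributes (e.g.
        :class:`mapsat.io_formats.SequenceRecord`).
    period
        Repeat unit length (>= 1, default 4 for tetranucleotide motifs).
    min_repeats
        Minimum number of whole tandem copies (>= 2, default 8).
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    seq = record.sequence
    n = len(seq)
    if n < period * min_repeats:
        return []

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    # match[j] is True when position j and j+period carry the same valid base;
    # a maximal block of True of length L spans a repeated region of L+period bp.
    match = (arr[:-period] == arr[period:]) & valid[:-period] & valid[period:]

    loci: list[RepeatLocus] = []
    # block boundaries of consecutive True values
    padded = np.concatenate(([False], match, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        run_len = int(e - s)
        n_copies = (run_len + period) // period
        if n_copies < min_repeats:
            continue
        start = int(s)
        motif = seq[start : start + period]
        if period > 1 and _is_homopolymer(motif):
            continue
        loci.append(
            RepeatLocus(
                scaffold_id=record.id,
                start=start,
                end=start + n_copies * period,
                motif=motif,
                canonical=canonical_motif(motif),
                period=period,
                n_repeats=n_copies,
            )
        )
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


@dataclass
class ScreenResult:
    """Loci found by a scaffold screen plus a scan summary."""

    loci: list[RepeatLocus]
    n_scaffolds_scanned: int
    n_scaffolds_skipped: int
    loci_per_motif: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)


def screen_scaffolds(
    records: Iterable,
    min_scaffold_len: int = 1_000_000,
    period: int = 4,
    min_repeats: int = 8,
) -> ScreenResult:
    """Screen scaffolds longer than ``min_scaffold_len`` for perfect repeats.

    Only records with length strictly greater than ``min_scaffold_len`` are
    scanned (the screening convention is "scaffolds longer than" the cutoff).
    Results are concatenated in input order; per-canonical-motif counts are
    accumulated and logged.
    """
    if min_scaffold_len < 0:
        raise ValueError("min_scaffold_len must be >= 0")
    loci: list[RepeatLocus] = []
    scanned = skipped = 0
    per_motif: Counter = Counter()
    for rec in records:
        if len(rec.sequence) <= min_scaffold_len:
            skipped += 1
            continue
        scanned += 1
        found = find_perfect_repeats(rec, period=period, min_repeats=min_repeats)
        loci.extend(found)
        per_motif.update(l.canonical for l in found)
    log.info(
        "screened %d scaffolds (%d below %d bp skipped): %d loci, %d motif classes",
        scanned, skipped, min_scaffold_len, len(loci), len(per_motif),
    )
    return ScreenResult(loci=loci, n_scaffolds_scanned=scanned,
                        n_scaffolds_skipped=skipped, loci_per_motif=per_motif)
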