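"""Turn repeat loci into primer-ready marker candidates.

This module prepares everything a thermodynamic primer-design run (Primer3)
needs — flanking sequence, designability constraints, product-size accounting,
universal 5' tags — without reimplementing the thermodynamics.  A candidate is
*designable* when both flanks can host a primer (enough contiguous unambiguous
sequence) and the amplicon can stay within the product-size ceiling.

Tags: genotyping with a third, fluorescently labelled primer uses a universal
extension on one locus-specific primer — M13R (GGAAACAGCTATGACCAT, 18 bp) or
CAG (CAGTCGGGCGTCATCA, 16 bp).  The tag adds its full length to the amplicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .repeat_screen import RepeatLocus

log = logging.getLogger(__name__)

TAG_SEQUENCES: dict[str, str] = {
    "M13R": "GGAAACAGCTATGACCAT",
    "CAG": "CAGTCGGGCGTCATCA",
}


@dataclass(frozen=True)
class PrimerParams:
    """Constraints handed to the downstream primer-design run.

    Defaults: primers 20-24 bp, optimum melting temperature 57 C within
    54-65 C, amplicon at most 450 bp, 200 bp of flank offered on each side.
    """

    primer_len_min: int = 20
    primer_len_max: int = 24
    tm_opt: float = 57.0
    tm_min: float = 54.0
    tm_max: float = 65.0
    max_product: int = 450
    flank_len: int = 200
    max_n_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("require tm_min <= tm_opt <= tm_max")
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("require primer_len_min <= primer_len_max")


@dataclass(frozen=True)
class MarkerCandidate:
    """A repeat locus plus its flanks and design verdict."""

    locus: RepeatLocus
    left_flank: str
    right_flank: str
    designable: bool = True
    reason: str = ""
    max_product_size: int = 450
    tag: str = "none"
    expected_product_range: tuple[int, int] | None = None

    @property
    def repeat_length(self) -> int:
        return len(self.locus)


def extract_flanks(record, locus: RepeatLocus, flank_len: int = 200) -> MarkerCandidate:
    """Extract up-to-``flank_len`` bp flanks around a locus.

    Flanks are clipped at the scaffold ends; clipping is recorded in the
    reason string, and a clipped flank shorter than the longest allowed primer
    makes the candidate not designable outright.
    """
    if locus.scaffold_id != record.id:
        raise ValueError(f"locus {locus.locus_id} is not on scaffold {record.id}")
    seq = record.sequence
    if locus.start < 0 or locus.end > len(seq):
        raise ValueError(f"locus {locus.locus_id} lies outside scaffold {record.id}")
    left = seq[max(0, locus.start - flank_len): locus.start]
    right = seq[locus.end: locus.end + flank_len]
    reasons = []
    params = PrimerParams()
    designable = True
    if len(left) < flank_len:
        reasons.append(f"left flank clipped to {len(left)} bp")
    if len(right) < flank_len:
        reasons.append(f"right flank clipped to {len(right)} bp")
    if len(left) < params.primer_len_max:
        designable = False
        reasons.append("left flank too short")
    if len(right) < params.primer_len_max:
        designable = False
        reasons.append("right flank too short")
    return MarkerCandidate(
        locus=locus,
        left_flank=left,
        right_flank=right,
        designable=designable,
        reason="; ".join(reasons),
    )


def _longest_clean_run(flank: str) -> int:
    best = cur = 0
    for ch in flank:
        if ch == "N":
            cur = 0
        else:
            cur += 1
            best = max(best, cur)
    return best


def designability_check(candidate: MarkerCandidate, params: PrimerParams | None = None) -> MarkerCandidate:
    """Apply primer-placement and product-size constraints.

    Designable iff (a) each flank holds at least ``primer_len_max`` contiguous
    non-N bases, (b) the N fraction of each flank is at most
    ``max_n_fraction``, and (c) the repeat plus two minimum-length primers fits
    within ``max_product``.  The check is monotone in ``max_product``.
    """
    params = params or PrimerParams()
    reasons = [candidate.reason] if candidate.reason else []
    ok = candidate.designable
    for side, flank in (("left", candidate.left_flank), ("right", candidate.right_flank)):
        if _longest_clean_run(flank) < params.primer_len_max:
            ok = False
            reasons.append(f"{side} flank lacks {params.primer_len_max} contiguous non-N bases")
        if flank and flank.count("N") / len(flank) > params.max_n_fraction:
            ok = False
            reasons.append(f"{side} flank ambiguity")
    min_product = candidate.repeat_length + 2 * params.primer_len_min
    if min_product > params.max_product:
        ok = False
        reasons.append(
            f"minimum product {min_product} bp exceeds {params.max_product} bp"
        )
    product_range = (
        (min_product, min(params.max_product,
                          candidate.repeat_length + 2 * params.primer_len_max
                          + 2 * (params.flank_len - params.primer_len_max)))
        if ok
        else None
    )
    return replace(
        candidate,
        designable=ok,
        reason="; ".join(reasons),
        max_product_size=params.max_product,
        expected_product_range=product_range,
    )


def add_tag(primer_seq: str, tag_name: str) -> str:
    """Prepend a universal tag to a primer's 5' end.

    Downstream product-size accounting must add ``len(TAG_SEQUENCES[tag])`` to
    the expected amplicon, since the tag is incorporated into the product.
    """
    if tag_name not in TAG_SEQUENCES:
        raise ValueError(
            f"unknown tag {tag_name!r}; known tags: {sorted(TAG_SEQUENCES)}"
        )
    return TAG_SEQUENCES[tag_name] + primer_seq


def tag_candidate(candidate: MarkerCandidate, tag_name: str) -> MarkerCandidate:
    """Record a tag choice on a candidate, shifting its expected product range."""
    if tag_name not in TAG_SEQUENCES:
        raise ValueError(f"unknown tag {tag_name!r}")
    shift = len(TAG_SEQUENCES[tag_name])
    rng = candidate.expected_product_range
    return replace(
        candidate,
        tag=tag_name,
        expected_product_range=None if rng is None else (rng[0] + shift, rng[1] + shift),
    )


def select_panel(
    candidates: Sequence[MarkerCandidate],
    group_of: Callable | Mapping,
    k_min: int = 2,
    k_max: int = 5,
    exclude_groups: Iterable[str] = (),
    seed: int | None = None,
) -> list[MarkerCandidate]:
    """Stratified random panel: ``k_min``..``k_max`` designable loci per group.

    ``group_of`` maps a candidate's locus to a group label (e.g. the reference
    chromosome its scaffold corresponds to); excluded groups (such as a
    problematic chromosome or the sex chromosomes) contribute nothing.  Within
    each non-excluded group the panel takes a uniformly drawn number
    ``k ~ U{k_min .. min(k_max, available)}`` of designable candidates, sampled
    without replacement; groups with fewer than ``k_min`` candidates contribute
    everything they have (warning logged).  Deterministic for a fixed seed:
    groups are visited in sorted label order.
    """
    if k_min > k_max:
        raise ValueError("require k_min <= k_max")
    lookup = group_of if callable(group_of) else (lambda locus: group_of[locus])
    excluded = set(exclude_groups)
    groups: dict[str, list[MarkerCandidate]] = {}
    for cand in candidates:
        if not cand.designable:
            continue
        label = lookup(cand.locus)
        groups.setdefault(label, []).append(cand)
    rng = np.random.default_rng(seed)
    panel: list[MarkerCandidate] = []
    for label in sorted(groups, key=str):
        if label in excluded:
            continue
        avail = groups[label]
        if len(avail) < k_min:
            log.warning(
                "group %s has only %d designable candidate(s) (< %d); taking all",
                label, len(avail), k_min,
            )
            panel.extend(avail)
            continue
        hi = min(k_max, len(avail))
        k = int(rng.integers(k_min, hi + 1))
        idx = rng.choice(len(avail), size=k, replace=False)
        panel.extend(avail[i] for i in sorted(idx))
    return panel
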