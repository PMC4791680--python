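"""Genotype-panel quality statistics for microsatellite markers.

Per locus: sample size N, allele count N_A, allele size range, observed
heterozygosity H_O, Nei's (1978) unbiased expected heterozygosity

    H_E = 2N/(2N-1) * (1 - sum_i p_i^2),

an exact Hardy-Weinberg probability test, and two null-allele frequency
estimators driven by the heterozygote deficit:

    Chakraborty  r = (H_E - H_O) / (H_E + H_O)
    Brookfield-1 r = (H_E - H_O) / (1 + H_E)

The HWE test conditions on the observed allele counts.  Under the null every
assignment of the 2N allele copies into N genotypes is equally likely, giving
the Levene distribution over genotype-count configurations ``{n_ij}``:

    P({n_ij}) = N! * prod_k a_k! * 2^h / ( (2N)! * prod_{i<=j} n_ij! )

with ``a_k`` the allele counts and ``h`` the number of heterozygotes.  The
p-value is the total probability of configurations no more probable than the
observed one — computed by full enumeration when the configuration space is
small, otherwise by Monte Carlo shuffling of the allele copies.

Missing genotypes are excluded locus-wise (never imputed), so N varies across
loci in a panel.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable

log = logging.getLogger(__name__)

DEFAULT_HWE_REPS = 100_000
DEFAULT_ENUMERATION_CAP = 100_000
DEFAULT_ALPHA = 0.05

_LOG_PROB_TOL = 1e-9  # configurations within this log-tolerance count as "<= observed"


@dataclass(frozen=True)
class HweResult:
    p_value: float
    method: str               # "enumeration", "monte_carlo" or "degenerate"
    reps: int | None = None   # Monte Carlo samples, when applicable


@dataclass(frozen=True)
class NullAlleleEstimate:
    """Null-allele frequency estimates; negatives floored at 0, raw kept."""

    chakraborty: float | None
    brookfield1: float
    chakraborty_raw: float | None
    brookfield1_raw: float


@dataclass
class LocusSummary:
    locus_id: str
    n: int
    size_range: tuple[int, int]
    n_alleles: int
    h_obs: float
    h_exp: float
    p_hwe: float
    hwe_method: str
    null_chakraborty: float | None
    null_brookfield1: float | None


@dataclass
class PanelSummary:
    loci: list[LocusSummary]
    mean_na: float
    mean_he: float
    mean_ho: float
    n_in_hwe: int
    alpha: float = DEFAULT_ALPHA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [l.locus_id for l in self.loci],
                "n": [l.n for l in self.loci],
                "size_min": [l.size_range[0] for l in self.loci],
                "size_max": [l.size_range[1] for l in self.loci],
                "n_alleles": [l.n_alleles for l in self.loci],
                "he": [l.h_exp for l in self.loci],
                "ho": [l.h_obs for l in self.loci],
                "p_hwe": [l.p_hwe for l in self.loci],
                "hwe_method": [l.hwe_method for l in self.loci],
                "null_chakraborty": [l.null_chakraborty for l in self.loci],
                "null_brookfield1": [l.null_brookfield1 for l in self.loci],
            }
        )


def allele_stats(table: GenotypeTable, locus: str):
    """(N, allele frequency map, size range, N_A) for one locus.

    Frequencies are exact rationals over the 2N observed allele copies, so
    they sum to 1 identically.  Raises on an all-missing locus.
    """
    calls = table.calls_at(locus)
    if not calls:
        raise ValueError(f"locus {locus}: no genotyped individuals")
    counts: Counter = Counter()
    for a, b in calls:
        counts[a] += 1
        counts[b] += 1
    n = len(calls)
    freqs = {allele: Fraction(c, 2 * n) for allele, c in sorted(counts.items())}
    sizes = sorted(counts)
    return n, freqs, (sizes[0], sizes[-1]), len(counts)


def observed_het(table: GenotypeTable, locus: str) -> float:
    """Fraction of genotyped individuals that are heterozygous."""
    calls = table.calls_at(locus)
    if not calls:
        raise ValueError(f"locus {locus}: no genotyped individuals")
    return sum(1 for a, b in calls if a != b) / len(calls)


def unbiased_expected_het(freqs: Mapping, n: int, unbiased: bool = True) -> float:
    """Nei's (1978) unbiased expected heterozygosity.

    H_E = 2N/(2N-1) * (1 - sum p_i^2).  For N == 1 the correction factor is
    undefined-ish (2N/(2N-1) = 2) and the uncorrected gene diversity is
    returned with a warning.  Set ``unbiased=False`` for the raw
    1 - sum p_i^2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = float(sum(freqs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {total}, not 1")
    gene_diversity = 1.0 - float(sum(Fraction(p) ** 2 if isinstance(p, Fraction) else p * p
                                     for p in freqs.values()))
    if not unbiased:
        return gene_diversity
    if n == 1:
        warnings.warn("N=1: small-sample correction unavailable, returning 1 - sum p^2")
        return gene_diversity
    return (2 * n) / (2 * n - 1) * gene_diversity


def _genotype_counts(calls: Sequence[tuple[int, int]]) -> Counter:
    return Counter(tuple(sorted(g)) for g in calls)


def _log_levene_const(allele_counts: Sequence[int], n: int) -> float:
    two_n = 2 * n
    return (
        math.lgamma(n + 1)
        + sum(math.lgamma(a + 1) for a in allele_counts)
        - math.lgamma(two_n + 1)
    )


def _log_prob_config(config: Mapping[tuple[int, int], int], const: float) -> float:
    h = sum(c for (a, b), c in config.items() if a != b)
    return const + h * math.log(2) - sum(
        math.lgamma(c + 1) for c in config.values()
    )


def _enumerate_configs(allele_counts: Sequence[int], cap: int | None):
    """Yield all genotype-count configurations consistent with allele counts.

    A configuration maps allele index pairs (i <= j) to genotype counts.
    Raises ``OverflowError`` once more than ``cap`` configurations are seen —
    the caller then falls back to Monte Carlo.
    """
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    n_emitted = 0

    def recurse(idx: int, remaining: list[int], current: dict):
        nonlocal n_emitted
        if idx == len(pairs):
            if all(r == 0 for r in remaining):
                n_emitted += 1
                if cap is not None and n_emitted > cap:
                    raise OverflowError("configuration space exceeds cap")
                yield dict(current)
            return
        i, j = pairs[idx]
        if i == j:
            max_n = remaining[i] // 2
        else:
            max_n = min(remaining[i], remaining[j])
        # prune: once allele i's pairs are exhausted its remainder must be 0
        last_for_i = (j == k - 1)
        for cnt in range(max_n + 1):
            remaining[i] -= 2 * cnt if i == j else cnt
            if i != j:
                remaining[j] -= cnt
            if cnt:
                current[(i, j)] = cnt
            if not (last_for_i and remaining[i] != 0):
                yield from recurse(idx + 1, remaining, current)
            if cnt:
                del current[(i, j)]
            remaining[i] += 2 * cnt if i == j else cnt
            if i != j:
                remaining[j] += cnt

    yield from recurse(0, list(allele_counts), {})


def hwe_exact_enumeration(calls: Sequence[tuple[int, int]],
                          cap: int | None = DEFAULT_ENUMERATION_CAP) -> float:
    """Exact HWE p-value by full enumeration of the Levene distribution."""
    n = len(calls)
    alleles = sorted({a for g in calls for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    counts = Counter()
    for a, b in calls:
        counts[a] += 1
        counts[b] += 1
    allele_counts = [counts[a] for a in alleles]
    const = _log_levene_const(allele_counts, n)
    obs = Counter((index[min(a, b)], index[max(a, b)]) for a, b in calls)
    log_obs = _log_prob_config(obs, const)
    p = 0.0
    for config in _enumerate_configs(allele_counts, cap):
        lp = _log_prob_config(config, const)
        if lp <= log_obs + _LOG_PROB_TOL:
            p += math.exp(lp)
    return min(p, 1.0)


def hwe_monte_carlo(calls: Sequence[tuple[int, int]], reps: int,
                    seed: int | np.random.Generator | None) -> float:
    """Monte Carlo HWE p-value: shuffle the 2N allele copies into genotypes.

    The observed configuration is included in the sample, giving the standard
    (1 + #{P <= P_obs}) / (1 + reps) estimator, which never returns 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(calls)
    alleles = sorted({a for g in calls for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    pool = np.array([index[a] for g in calls for a in g], dtype=np.int64)
    allele_counts = np.bincount(pool, minlength=k)
    const = _log_levene_const(allele_counts.tolist(), n)
    obs = Counter((index[min(a, b)], index[max(a, b)]) for a, b in calls)
    log_obs = _log_prob_config(obs, const)

    # lgamma lookup for genotype counts 0..n
    lgam = np.array([math.lgamma(c + 1) for c in range(n + 1)])
    log2 = math.log(2)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(pool)
        a = perm[0::2]
        b = perm[1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        h = int((lo != hi).sum())
        flat = lo * k + hi
        cnt = np.bincount(flat, minlength=k * k)
        lp = const + h * log2 - float(lgam[cnt].sum())
        if lp <= log_obs + _LOG_PROB_TOL:
            hits += 1
    return (1 + hits) / (1 + reps)


def hwe_test(
    table: GenotypeTable,
    locus: str,
    reps: int = DEFAULT_HWE_REPS,
    seed: int | np.random.Generator | None = None,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> HweResult:
    """Exact probability test of Hardy-Weinberg proportions at one locus.

    Full enumeration when the conditional configuration space has at most
    ``enumeration_cap`` members, otherwise Monte Carlo with ``reps`` shuffles
    of the allele copies.  Degenerate loci (fewer than 2 genotypes or a single
    allele) return p = 1.
    """
    calls = table.calls_at(locus)
    alleles = {a for g in calls for a in g}
    if len(calls) < 2 or len(alleles) < 2:
        return HweResult(p_value=1.0, method="degenerate")
    try:
        p = hwe_exact_enumeration(calls, cap=enumeration_cap)
        return HweResult(p_value=p, method="enumeration")
    except OverflowError:
        p = hwe_monte_carlo(calls, reps=reps, seed=seed)
        return HweResult(p_value=p, method="monte_carlo", reps=reps)


def null_allele_estimates(h_exp: float, h_obs: float) -> NullAlleleEstimate:
    """Null-allele frequency from the heterozygote deficit.

    Chakraborty: r = (H_E - H_O)/(H_E + H_O); undefined (None) when both are 0.
    Brookfield-1: r = (H_E - H_O)/(1 + H_E).  Negative estimates (H_O > H_E)
    are floored at 0, with the raw value retained.
    """
    for name, v in (("h_exp", h_exp), ("h_obs", h_obs)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if h_exp + h_obs == 0:
        chak_raw = None
    else:
        chak_raw = (h_exp - h_obs) / (h_exp + h_obs)
    brook_raw = (h_exp - h_obs) / (1.0 + h_exp)
    return NullAlleleEstimate(
        chakraborty=None if chak_raw is None else max(chak_raw, 0.0),
        brookfield1=max(brook_raw, 0.0),
        chakraborty_raw=chak_raw,
        brookfield1_raw=brook_raw,
    )


def summarize_locus(
    table: GenotypeTable,
    locus: str,
    reps: int = DEFAULT_HWE_REPS,
    seed: int | np.random.Generator | None = None,
) -> LocusSummary:
    n, freqs, size_range, n_alleles = allele_stats(table, locus)
    ho = observed_het(table, locus)
    he = unbiased_expected_het(freqs, n)
    hwe = hwe_test(table, locus, reps=reps, seed=seed)
    nulls = null_allele_estimates(he, ho)
    return LocusSummary(
        locus_id=locus,
        n=n,
        size_range=size_range,
        n_alleles=n_alleles,
        h_obs=ho,
        h_exp=he,
        p_hwe=hwe.p_value,
        hwe_method=hwe.method,
        null_chakraborty=nulls.chakraborty,
        null_brookfield1=nulls.brookfield1,
    )


def summarize_panel(
    table,
    alpha: float = DEFAULT_ALPHA,
    reps: int = DEFAULT_HWE_REPS,
    seed: int | np.random.Generator | None = None,
) -> PanelSummary:
    """Panel-level summary: per-locus statistics plus aggregate means.

    ``table`` is either a GenotypeTable (everything is computed from
    genotypes) or a precomputed per-locus DataFrame with columns
    ``locus, n, size_min, size_max, n_alleles, he, ho, p_hwe`` — in that case
    only the panel-level aggregates (mean N_A, mean H_E, mean H_O, loci in
    HWE at ``alpha``) are recomputed from the given rows.
    """
    if isinstance(table, pd.DataFrame):
        if table.empty:
            raise ValueError("empty locus summary table")
        loci = [
            LocusSummary(
                locus_id=str(row["locus"]),
                n=int(row["n"]),
                size_range=(int(row["size_min"]), int(row["size_max"])),
                n_alleles=int(row["n_alleles"]),
                h_obs=float(row["ho"]),
                h_exp=float(row["he"]),
                p_hwe=float(row["p_hwe"]),
                hwe_method=str(row.get("hwe_method", "reported")),
                null_chakraborty=None,
                null_brookfield1=None,
            )
            for _, row in table.iterrows()
        ]
    else:
        if not table.loci:
            raise ValueError("genotype table contains no loci")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        loci = [summarize_locus(table, l, reps=reps, seed=rng) for l in table.loci]
    return PanelSummary(
        loci=loci,
        mean_na=float(np.mean([l.n_alleles for l in loci])),
        mean_he=float(np.mean([l.h_exp for l in loci])),
        mean_ho=float(np.mean([l.h_obs for l in loci])),
        n_in_hwe=sum(1 for l in loci if l.p_hwe >= alpha),
        alpha=alpha,
    )
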