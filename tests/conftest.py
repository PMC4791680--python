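import numpy as np
import pytest

from mapsat.io_formats import GenotypeTable, SequenceRecord


@pytest.fixture
def small_scaffold():
    """10 kb deterministic scaffold with one planted AAAG x 10 repeat at 5000."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=10_000))
    seq = seq[:5000] + "AAAG" * 10 + seq[5040:]
    return SequenceRecord(id="s1", sequence=seq)


@pytest.fixture
def hw_table():
    """24-sample table at one diallelic locus, roughly at HW proportions."""
    rng = np.random.default_rng(7)
    records = []
    for i in range(24):
        a, b = rng.choice([120, 124], size=2, p=[0.6, 0.4])
        records.append((f"s{i}", "locA", int(a), int(b)))
    return GenotypeTable.from_records(records)


def brute_force_repeats(seq: str, period: int, min_repeats: int):
    """Independent reference repeat finder: leftmost maximal exact runs.

    A start qualifies when its unit is clean ACGT and non-homopolymer, the run
    holds >= min_repeats whole copies, and the run cannot be extended left by
    one character at the same period (leftmost anchoring).
    """
    out = []
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    for s in range(n - period * min_repeats + 1):
        unit = seq[s:s + period]
        if not all(valid[s:s + period]):
            continue
        if period > 1 and len(set(unit)) == 1:
            continue
        if s > 0 and s - 1 + period < n and valid[s - 1] and valid[s - 1 + period] \
                and seq[s - 1] == seq[s - 1 + period]:
            continue  # extendable left: not the leftmost start
        k = 1
        while seq[s + k * period: s + (k + 1) * period] == unit:
            k += 1
        if k >= min_repeats:
            out.append((s, s + k * period, unit))
    return sorted(out)
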