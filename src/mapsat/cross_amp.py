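"""Cross-species amplification bookkeeping.

Primers designed in one species are tested on panels of related species; each
(species, sample, locus) cell is an externally scored success/failure call (a
product of the expected size without smearing), or untested.  This module only
aggregates: per-(species, locus) success rates and, per species, the number of
loci amplifying at or above given rate thresholds (the conventional 80% and
40% cutoffs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

DEFAULT_THRESHOLDS = (0.8, 0.4)

SUCCESS, FAILURE, UNTESTED = "success", "failure", "untested"


@dataclass
class AmplificationMatrix:
    """Per (species, sample, locus) amplification outcomes.

    Backed by a tidy DataFrame with columns ``species, sample, locus, result``
    where result is "success"/"failure"; untested cells are simply absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species", "sample", "locus", "result"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        bad = set(self.data["result"]) - {SUCCESS, FAILURE}
        if bad:
            raise ValueError(f"unknown result values: {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        # input order preserved (drop_duplicates keeps first occurrence)
        return list(self.data["species"].drop_duplicates())

    @property
    def loci(self) -> list[str]:
        return list(self.data["locus"].drop_duplicates())

    @classmethod
    def from_csv(cls, path) -> "AmplificationMatrix":
        """Read a CSV with columns species,sample,locus,success (0/1, blank = untested)."""
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"species", "sample", "locus", "success"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected columns {sorted(required)}")
            for lineno, row in enumerate(reader, start=2):
                cell = row["success"].strip()
                if cell == "":
                    continue  # untested
                if cell not in {"0", "1"}:
                    raise ValueError(f"{path}:{lineno}: success must be 0, 1 or blank")
                rows.append(
                    {
                        "species": row["species"],
                        "sample": row["sample"],
                        "locus": row["locus"],
                        "result": SUCCESS if cell == "1" else FAILURE,
                    }
                )
        return cls(pd.DataFrame(rows, columns=["species", "sample", "locus", "result"]))


def success_rate(matrix: AmplificationMatrix, species: str, locus: str) -> float | None:
    """Successes / tested for one (species, locus); None when nothing was tested."""
    sub = matrix.data[(matrix.data["species"] == species) & (matrix.data["locus"] == locus)]
    if sub.empty:
        return None
    return float((sub["result"] == SUCCESS).mean())


def loci_at_threshold(matrix: AmplificationMatrix, species: str, threshold: float) -> int:
    """Number of loci with success rate >= threshold in one species.

    Comparison is inclusive ("80% or better"); loci never tested in that
    species are excluded even at threshold 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    count = 0
    for locus in matrix.loci:
        rate = success_rate(matrix, species, locus)
        if rate is not None and rate >= threshold:
            count += 1
    return count


def species_table(
    matrix: AmplificationMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-species locus counts at each threshold, ranked by transferability.

    Rows are sorted by the count at the highest threshold, descending, with
    ties broken by species input order; columns are labelled ``n_ge_<pct>``.
    """
    if not matrix.species:
        raise ValueError("matrix contains no species")
    thresholds = sorted(thresholds, reverse=True)
    rows = []
    for order, sp in enumerate(matrix.species):
        row = {"species": sp, "_order": order}
        for t in thresholds:
            row[f"n_ge_{int(round(t * 100))}"] = loci_at_threshold(matrix, sp, t)
        rows.append(row)
    df = pd.DataFrame(rows)
    top = f"n_ge_{int(round(thresholds[0] * 100))}"
    df = df.sort_values([top, "_order"], ascending=[False, True], kind="stable")
    return df.drop(columns="_order").reset_index(drop=True)


def write_species_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
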