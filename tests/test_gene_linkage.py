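"""Interval geometry, predicted-gene exclusion and the dual-evidence filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapsat.gene_linkage import (
    GeneFeature,
    LinkageReport,
    build_linkage_report,
    dual_evidence_filter,
    exclude_predicted,
    genes_in_window,
    linkage_summary,
    nearest_feature_distance,
    normalize_gene_symbol,
)


def _gene(symbol, start, end, scaffold="s1", exons=None):
    return GeneFeature(
        gene_id=symbol.lower(), symbol=symbol, scaffold_id=scaffold,
        start=start, end=end, exons=exons if exons is not None else [(start, end)],
    )


def brute_nearest(locus, features):
    scaffold, start, end = locus
    best = None
    for f in features:
        if f.scaffold_id != scaffold:
            continue
        for a, b in (f.exons or [(f.start, f.end)]):
            if a < end and b > start:
                d = 0
            elif b <= start:
                d = start - b
            else:
                d = a - end
            best = d if best is None or d < best else best
    return best


def brute_window(locus, features, hw):
    scaffold, start, end = locus
    lo, hi = max(0, start - hw), end + hw
    out = []
    for f in features:
        if f.scaffold_id != scaffold or f.kind != "gene":
            continue
        if f.start < hi and f.end > lo:
            out.append(f.symbol)
    return sorted(out)


class TestNearestFeatureDistance:
    def test_gap_to_the_left(self):
        d = nearest_feature_distance(("s1", 1000, 1040), [_gene("A", 500, 900)])
        assert d == 100

    def test_overlap_is_zero(self):
        d = nearest_feature_distance(("s1", 1000, 1040), [_gene("A", 1020, 1100)])
        assert d == 0

    def test_no_feature_on_scaffold(self):
        d = nearest_feature_distance(("s1", 0, 10), [_gene("A", 5, 9, scaffold="s2")])
        assert d is None

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n_feat = int(rng.integers(1, 40))
            feats = []
            for i in range(n_feat):
                s = int(rng.integers(0, 100_000))
                e = s + int(rng.integers(1, 5_000))
                scaffold = f"s{rng.integers(1, 4)}"
                feats.append(_gene(f"G{i}", s, e, scaffold=scaffold))
            ls = int(rng.integers(0, 100_000))
            locus = (f"s{rng.integers(1, 4)}", ls, ls + int(rng.integers(1, 200)))
            assert nearest_feature_distance(locus, feats) == brute_nearest(locus, feats)


class TestGenesInWindow:
    def test_upstream_gene_signed_distance(self):
        gene = _gene("A", 150_000, 160_000)
        locus = ("s1", 210_000, 210_040)
        ((feat, dist),) = genes_in_window(locus, [gene], half_width=100_000)
        assert feat.symbol == "A" and dist == -50_000

    def test_gene_beyond_window_excluded(self):
        gene = _gene("A", 0, 10_000)
        locus = ("s1", 160_000, 160_040)  # gap 150 kbp
        assert genes_in_window(locus, [gene], half_width=100_000) == []

    def test_gene_straddling_window_edge_included(self):
        gene = _gene("A", 50_000, 120_000)
        locus = ("s1", 210_000, 210_040)  # window starts at 110 000
        hits = genes_in_window(locus, [gene], half_width=100_000)
        assert [f.symbol for f, _ in hits] == ["A"]

    def test_sorted_by_abs_distance(self):
        feats = [_gene("Far", 0, 100), _gene("Near", 900, 1000), _gene("On", 1190, 1300)]
        locus = ("s1", 1200, 1240)
        hits = genes_in_window(locus, feats, half_width=10_000)
        assert [f.symbol for f, _ in hits] == ["On", "Near", "Far"]

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            feats = [
                _gene(
                    f"G{i}",
                    s := int(rng.integers(0, 500_000)),
                    s + int(rng.integers(1, 30_000)),
                    scaffold=f"s{rng.integers(1, 3)}",
                )
                for i in range(int(rng.integers(1, 50)))
            ]
            ls = int(rng.integers(0, 500_000))
            locus = (f"s{rng.integers(1, 3)}", ls, ls + 40)
            hw = int(rng.integers(0, 120_000))
            got = sorted(f.symbol for f, _ in genes_in_window(locus, feats, hw))
            assert got == brute_window(locus, feats, hw)


class TestExcludePredicted:
    def test_label_classes(self):
        symbols = ["Gm123", "Nrxn1", "LOC456", "Mir21", "2410004B18Rik"]
        assert exclude_predicted(symbols) == ["Nrxn1"]

    def test_gm_requires_digit(self):
        assert exclude_predicted(["Gmppa"]) == ["Gmppa"]
        assert exclude_predicted(["LOCKED1"]) == ["LOCKED1"]
        assert exclude_predicted(["Mirage"]) == ["Mirage"]

    def test_empty(self):
        assert exclude_predicted([]) == []


class TestDualEvidenceFilter:
    def test_set_intersection(self):
        assert dual_evidence_filter(["A", "B", "C"], ["B", "C", "D"]) == ["B", "C"]

    def test_predicted_excluded_before_intersection(self):
        assert dual_evidence_filter(["Gm123", "B"], ["Gm123", "B"]) == ["B"]

    def test_empty_hits(self):
        assert dual_evidence_filter(["A", "B"], []) == []

    def test_symbol_normalization_bridges_sources(self):
        assert dual_evidence_filter(["Nrxn1"], ["NRXN1-2"]) == ["Nrxn1"]
        assert normalize_gene_symbol("Abc1.3") == normalize_gene_symbol("ABC1")

    @given(
        st.lists(st.sampled_from(["Aa1", "Bb2", "Cc3", "Dd4", "Gm99", "Mir7"]), max_size=6),
        st.lists(st.sampled_from(["Aa1", "Bb2", "Cc3", "Dd4", "Gm99", "Mir7"]), max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_contained_in_both_inputs(self, window, hits):
        out = dual_evidence_filter(window, hits)
        norm = {normalize_gene_symbol(s) for s in hits}
        assert set(out) <= set(window)
        assert all(normalize_gene_symbol(s) in norm for s in out)


class TestLinkageSummary:
    def _report(self, locus_id, dist, linked):
        return LinkageReport(
            locus_id=locus_id, nearest_exon_distance=dist,
            genes_in_window=[(s, 0) for s in linked], linked_genes=linked,
        )

    def test_distance_mass_below_100kb(self):
        reports = [self._report(f"l{i}", 5_000 * i, []) for i in range(7)]  # all < 100 kbp
        reports += [self._report(f"m{i}", 150_000 + i, []) for i in range(3)]
        dist_hist, _ = linkage_summary(reports, bin_width=10_000)
        below = sum(v for k, v in dist_hist.items() if isinstance(k, int) and k < 100_000)
        assert below == pytest.approx(0.7)

    def test_gene_count_fractions(self):
        linked_sets = [[]] * 2 + [["a"]] * 5 + [["a", "b"]] * 2 + [["a", "b", "c", "d"]]
        reports = [self._report(f"l{i}", 0, ls) for i, ls in enumerate(linked_sets)]
        _, counts = linkage_summary(reports)
        assert counts == {0: 0.2, 1: 0.5, 2: 0.2, "3+": 0.1}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        reports = [
            self._report(
                f"l{i}",
                None if rng.random() < 0.2 else int(rng.integers(0, 300_000)),
                ["x"] * int(rng.integers(0, 5)),
            )
            for i in range(57)
        ]
        dist_hist, counts = linkage_summary(reports)
        assert sum(dist_hist.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(counts.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_input(self):
        assert linkage_summary([]) == ({}, {})


def test_build_linkage_report_end_to_end():
    feats = [
        _gene("Nrxn1", 150_000, 170_000, exons=[(150_000, 151_000)]),
        _gene("Gm999", 200_000, 205_000),
        _gene("Far9", 900_000, 910_000),
    ]
    locus = ("s1", 210_000, 210_040)
    report = build_linkage_report(locus, feats, ["Nrxn1", "Gm999", "Far9"])
    assert report.nearest_exon_distance == 5_000  # gene span fallback for Gm999
    assert [s for s, _ in report.genes_in_window] == ["Gm999", "Nrxn1"]
    assert report.linked_genes == ["Nrxn1"]
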