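import itertools

import numpy as np
import pandas as pd
import pytest

from skipquant.dedup_quant import (
    BarcodeWhitelist,
    classify_molecules,
    condition_ratio,
    correct_barcode,
    dedup,
    per_cluster_summary,
    read_annotations,
)
from skipquant.exon_model import JunctionSpec
from skipquant.read_scan import HitRecord


def _hit(read_id, barcode, umi, junction):
    return HitRecord(read_id, barcode, umi, junction, 0, "sense")


WL = BarcodeWhitelist(["AAAA", "CCCC", "GGTT"])


class TestCorrectBarcode:
    def test_exact_member_is_identity(self):
        assert correct_barcode("AAAA", WL) == "AAAA"

    def test_unique_hamming1_neighbour(self):
        # brute-force oracle over the 3-entry whitelist
        raw = "AAAT"
        oracle = [w for w in WL if sum(a != b for a, b in zip(raw, w)) <= 1]
        assert oracle == ["AAAA"]
        assert correct_barcode(raw, WL) == "AAAA"

    def test_ambiguous_neighbour_returns_none(self):
        wl = BarcodeWhitelist(["AAAA", "AAAC"])
        # AAAG is at Hamming 1 from both entries
        assert correct_barcode("AAAG", wl) is None

    def test_no_neighbour_returns_none(self):
        assert correct_barcode("TTTT", WL) is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            correct_barcode("AAA", WL)

    def test_exhaustive_hamming1_against_brute_force(self):
        # every 4-mer over a small alphabet, checked against direct scan
        wl = BarcodeWhitelist(["ACGT", "ACGG", "TTTT"])
        for raw in map("".join, itertools.product("ACGT", repeat=4)):
            near = [w for w in wl if sum(a != b for a, b in zip(raw, w)) <= 1]
            expected = raw if raw in wl else (near[0] if len(near) == 1 else None)
            assert correct_barcode(raw, wl) == expected


class TestDedup:
    def test_pure_pcr_duplicates_collapse_to_one_molecule(self):
        hits = [_hit(f"r{i}", "AAAA", "GGGG", "j1") for i in range(5)]
        table, stats = dedup(hits)
        assert len(table) == 1
        assert table["support"].iloc[0] == 5
        assert stats.molecules_out == 1
        assert stats.reads_in == 5

    def test_directional_hamming1_merge(self):
        hits = (
            [_hit(f"a{i}", "AAAA", "GGGG", "j1") for i in range(3)]
            + [_hit("b0", "AAAA", "GGGC", "j1")]
        )
        exact, _ = dedup(hits, umi_collapse="exact")
        assert len(exact) == 2
        merged, stats = dedup(hits, umi_collapse="hamming1")
        assert len(merged) == 1
        assert merged["umi"].iloc[0] == "GGGG"  # higher support wins
        assert merged["support"].iloc[0] == 4
        assert stats.umis_merged == 1

    def test_equal_support_tie_merges_into_lexicographically_smaller(self):
        hits = [_hit("a", "AAAA", "GGGC", "j1"), _hit("b", "AAAA", "GGGG", "j1")]
        merged, _ = dedup(hits, umi_collapse="hamming1")
        assert list(merged["umi"]) == ["GGGC"]

    def test_whitelist_correction_and_discard(self):
        wl = BarcodeWhitelist(["AAAA", "CCCC"])
        hits = [
            _hit("r1", "AAAA", "GGGG", "j1"),  # exact
            _hit("r2", "AAAT", "GGGG", "j1"),  # corrects to AAAA, same molecule
            _hit("r3", "TTTT", "GGGG", "j1"),  # uncorrectable, discarded
        ]
        table, stats = dedup(hits, whitelist=wl)
        assert len(table) == 1
        assert table["support"].iloc[0] == 2
        assert stats.reads_discarded_barcode == 1

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        hits = [
            _hit(
                f"r{i}",
                "".join(rng.choice(bases, 4)),
                "".join(rng.choice(bases, 4)),
                rng.choice(["j1", "j2"]),
            )
            for i in range(200)
        ]
        table, _ = dedup(hits, umi_collapse="hamming1")
        rehits = [
            _hit(f"m{i}", row.barcode, row.umi, row.junction)
            for i, row in enumerate(table.itertuples())
        ]
        table2, _ = dedup(rehits, umi_collapse="hamming1")
        left = table[["barcode", "umi", "junction"]].reset_index(drop=True)
        right = table2[["barcode", "umi", "junction"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_collapse_tightening_is_monotone(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        hits = [
            _hit(
                f"r{i}",
                rng.choice(["AAAA", "CCCC"]),
                "".join(rng.choice(bases, 3)),
                "j1",
            )
            for i in range(300)
        ]
        exact, _ = dedup(hits, umi_collapse="exact")
        ham, _ = dedup(hits, umi_collapse="hamming1")
        assert len(ham) <= len(exact) <= len(hits)


SPECS = [JunctionSpec(22, 23), JunctionSpec(23, 24), JunctionSpec(22, 24)]


class TestClassifyMolecules:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["barcode", "umi", "junction", "support"])

    def test_canonical_junctions_count_unskipped(self):
        mt = self._table(
            [("b1", "U1", "e22-e23", 1), ("b1", "U2", "e23-e24", 1)]
        )
        out = classify_molecules(mt, SPECS)
        row = out.set_index("barcode").loc["b1"]
        assert (row.unskipped, row.skipped, row.ambiguous) == (2, 0, 0)

    def test_skip_junction_counts_skipped(self):
        mt = self._table([("b1", "U1", "e22-e24", 1)])
        row = classify_molecules(mt, SPECS).set_index("barcode").loc["b1"]
        assert (row.unskipped, row.skipped, row.ambiguous) == (0, 1, 0)

    def test_same_umi_in_both_classes_is_ambiguous(self):
        mt = self._table(
            [("b1", "U1", "e22-e23", 1), ("b1", "U1", "e22-e24", 1)]
        )
        row = classify_molecules(mt, SPECS).set_index("barcode").loc["b1"]
        assert (row.unskipped, row.skipped, row.ambiguous) == (0, 0, 1)

    def test_unknown_junction_label_raises(self):
        mt = self._table([("b1", "U1", "e1-e2", 1)])
        with pytest.raises(ValueError, match="unknown junction"):
            classify_molecules(mt, SPECS)


class TestPerClusterSummary:
    def _ann(self):
        return pd.DataFrame(
            {
                "barcode": ["b1", "b2", "b3", "b4"],
                "sample": ["s1"] * 4,
                "condition": ["mdx"] * 3 + ["WT"],
                "cluster": ["myonuclei"] * 3 + ["myonuclei"],
            }
        )

    def test_positive_fraction_over_all_annotated_nuclei(self):
        mt = pd.DataFrame(
            [("b1", "U1", "e22-e24", 1)],
            columns=["barcode", "umi", "junction", "support"],
        )
        summary, unmatched = per_cluster_summary(
            mt, self._ann(), junctions=["e22-e24"], specs=SPECS
        )
        row = summary[
            (summary.condition == "mdx") & (summary.junction == "e22-e24")
        ].iloc[0]
        assert row.n_nuclei == 3
        assert row.n_positive == 1
        assert row.percent_positive == pytest.approx(33.33)
        wt = summary[summary.condition == "WT"].iloc[0]
        assert wt.n_positive == 0 and wt.percent_positive == 0.0
        assert unmatched == set()

    def test_unannotated_barcode_reported_and_excluded(self):
        mt = pd.DataFrame(
            [("zz", "U1", "e22-e24", 1)],
            columns=["barcode", "umi", "junction", "support"],
        )
        summary, unmatched = per_cluster_summary(
            mt, self._ann(), junctions=["e22-e24"], specs=SPECS
        )
        assert unmatched == {"zz"}
        assert (summary.n_positive == 0).all()

    def test_restrict_limits_denominator(self):
        ann = self._ann()
        ann.loc[2, "cluster"] = "fibroblast"
        mt = pd.DataFrame(
            [("b1", "U1", "e22-e24", 1)],
            columns=["barcode", "umi", "junction", "support"],
        )
        summary, _ = per_cluster_summary(
            mt, ann, restrict={"myonuclei"}, junctions=["e22-e24"], specs=SPECS
        )
        row = summary[summary.condition == "mdx"].iloc[0]
        assert row.n_nuclei == 2
        assert row.percent_positive == pytest.approx(50.0)

    def test_ambiguous_pairs_excluded_from_positivity(self):
        mt = pd.DataFrame(
            [("b1", "U1", "e22-e23", 1), ("b1", "U1", "e22-e24", 1)],
            columns=["barcode", "umi", "junction", "support"],
        )
        summary, _ = per_cluster_summary(
            mt, self._ann(), junctions=["e22-e23", "e22-e24"], specs=SPECS
        )
        assert (summary.n_positive == 0).all()


class TestConditionRatio:
    def _summary(self, pa, na, pb, nb):
        return pd.DataFrame(
            {
                "condition": ["treated", "untreated"],
                "cluster": ["myonuclei"] * 2,
                "junction": ["e22-e24"] * 2,
                "n_nuclei": [na, nb],
                "n_positive": [pa, pb],
                "percent_positive": [100 * pa / na, 100 * pb / nb],
                "n_molecules": [pa, pb],
            }
        )

    def test_tenfold_ratio(self):
        # 0.8% vs 0.08%
        s = self._summary(8, 1000, 2, 2500)
        ratio, inf = condition_ratio(s, "e22-e24", "treated", "untreated")
        assert ratio == pytest.approx(10.0)
        assert not inf

    def test_equal_percentages_give_one(self):
        s = self._summary(5, 100, 5, 100)
        ratio, _ = condition_ratio(s, "e22-e24", "treated", "untreated")
        assert ratio == pytest.approx(1.0)

    def test_zero_denominator_is_flagged_infinite(self):
        s = self._summary(5, 100, 0, 100)
        ratio, inf = condition_ratio(s, "e22-e24", "treated", "untreated")
        assert inf and ratio == float("inf")

    def test_missing_condition_raises(self):
        s = self._summary(5, 100, 5, 100)
        with pytest.raises(ValueError, match="WT"):
            condition_ratio(s, "e22-e24", "WT", "untreated")


def test_read_annotations_rejects_duplicates(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "barcode\tsample\tcondition\tcluster\n"
        "b1\ts1\tWT\tmyonuclei\nb1\ts1\tWT\tmyonuclei\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_annotations(path)
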