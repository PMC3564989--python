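"""Per-gene feature integration: counting, APA, evasion, interval assignment."""

import numpy as np
import pandas as pd
import pytest

from rbpkit.features import (
    build_feature_table,
    count_isoforms,
    count_mirna_families,
    count_phospho_residues,
    count_regulators,
    detect_apa,
    intersect_sites_with_utrs,
    mirna_evasion,
    utr_length_per_gene,
)
from rbpkit.io import FormatError


def gene_model(rows):
    return pd.DataFrame(rows, columns=["gene_id", "protein_id"]).assign(
        transcript_id=lambda d: d.protein_id
    )


class TestIsoforms:
    def test_distinct_count(self):
        gm = gene_model([("g", "a1"), ("g", "a2")])
        assert count_isoforms(gm)["g"] == 2

    def test_duplicates_collapse(self):
        gm = gene_model([("g", "a1"), ("g", "a1")])
        assert count_isoforms(gm)["g"] == 1

    def test_multi_isoform_fraction_on_seven_genes(self):
        rows = [(f"g{i}", f"g{i}.p1") for i in range(7)]
        rows += [("g0", "g0.p2"), ("g3", "g3.p2"), ("g3", "g3.p3")]
        counts = count_isoforms(gene_model(rows))
        assert (counts >= 2).sum() / len(counts) == pytest.approx(2 / 7)


class TestRegulators:
    BINDINGS = pd.DataFrame(
        [
            ("A", "TF", "g"),
            ("B", "TF", "g"),
            ("A", "TF", "g"),  # duplicate row must not double-count
            ("R1", "RBP", "g"),
            ("R1", "RBP", "h"),
        ],
        columns=["regulator_id", "regulator_class", "target_gene_id"],
    )

    def test_distinct_regulators(self):
        assert count_regulators(self.BINDINGS, "TF")["g"] == 2

    def test_absent_gene_not_listed(self):
        assert "zzz" not in count_regulators(self.BINDINGS, "TF")

    def test_class_filter(self):
        rbp = count_regulators(self.BINDINGS, "RBP")
        assert rbp["g"] == 1 and "g" in rbp.index
        assert "g" not in count_regulators(self.BINDINGS, "CLIP")

    def test_unknown_class_label_rejected(self):
        bad = self.BINDINGS.assign(regulator_class="mystery")
        with pytest.raises(FormatError):
            count_regulators(bad, "TF")
        with pytest.raises(ValueError):
            count_regulators(self.BINDINGS, "mystery")


class TestUTRLength:
    UTRS = pd.DataFrame(
        [("g", "g.u1", 100), ("g", "g.u2", 215), ("h", "h.u1", 50)],
        columns=["gene_id", "utr_id", "length"],
    )

    def test_longest_policy(self):
        assert utr_length_per_gene(self.UTRS, "longest")["g"] == 215

    def test_single_utr_any_policy(self):
        for policy in ("longest", "shortest"):
            assert utr_length_per_gene(self.UTRS, policy)["h"] == 50

    def test_per_utr_multiset(self):
        per = utr_length_per_gene(self.UTRS, "per_utr")
        assert per == {"g": [100, 215], "h": [50]}
        assert sum(len(v) for v in per.values()) == 3

    def test_nonpositive_length_rejected(self):
        bad = self.UTRS.copy()
        bad.loc[0, "length"] = 0
        with pytest.raises(FormatError):
            utr_length_per_gene(bad)


class TestMiRNAFamilies:
    UTRS = pd.DataFrame(
        [("g", "g.u1", 100), ("g", "g.u2", 200)],
        columns=["gene_id", "utr_id", "length"],
    )

    def test_distinct_family_union(self):
        preds = pd.DataFrame(
            [("g.u1", "fam-a", 2), ("g.u1", "fam-b", 1), ("g.u2", "fam-a", 1)],
            columns=["utr_id", "mirna_family", "n_sites"],
        )
        assert count_mirna_families(preds, self.UTRS)["g"] == 2

    def test_gene_without_predictions(self):
        preds = pd.DataFrame(columns=["utr_id", "mirna_family", "n_sites"])
        assert "g" not in count_mirna_families(preds, self.UTRS)

    def test_orphan_utr_id_rejected(self):
        preds = pd.DataFrame(
            [("ghost.u1", "fam-a", 1)], columns=["utr_id", "mirna_family", "n_sites"]
        )
        with pytest.raises(FormatError, match="ghost.u1"):
            count_mirna_families(preds, self.UTRS)

    def test_zero_site_rows_rejected_at_load(self, tmp_path):
        from rbpkit.io import read_target_predictions

        path = tmp_path / "targets.tsv"
        path.write_text("utr_id\tmirna_family\tn_sites\ng.u1\tfam-a\t0\n")
        with pytest.raises(FormatError):
            read_target_predictions(path)


class TestAPA:
    def test_two_distinct_ends(self):
        utrs = pd.DataFrame(
            [
                ("g", "g.u1", 100, "chrI", 0, 100, "+"),
                ("g", "g.u2", 250, "chrI", 0, 250, "+"),
            ],
            columns=["gene_id", "utr_id", "length", "chrom", "start", "end", "strand"],
        )
        out = detect_apa(utrs)
        assert out.loc["g", "n_utrs"] == 2 and bool(out.loc["g", "uses_apa"])

    def test_single_utr_no_apa(self):
        utrs = pd.DataFrame(
            [("g", "g.u1", 100)], columns=["gene_id", "utr_id", "length"]
        )
        out = detect_apa(utrs)
        assert out.loc["g", "n_utrs"] == 1 and not bool(out.loc["g", "uses_apa"])

    def test_identical_end_records_deduplicated(self):
        utrs = pd.DataFrame(
            [
                ("g", "g.u1", 100, "chrI", 0, 100, "+"),
                ("g", "g.u1b", 100, "chrI", 0, 100, "+"),
            ],
            columns=["gene_id", "utr_id", "length", "chrom", "start", "end", "strand"],
        )
        out = detect_apa(utrs)
        assert out.loc["g", "n_utrs"] == 1 and not bool(out.loc["g", "uses_apa"])

    def test_minus_strand_distinctness_uses_start(self):
        # same interval end, different starts: on the minus strand the
        # 3' end is the start coordinate, so these are two isoforms
        utrs = pd.DataFrame(
            [
                ("g", "g.u1", 100, "chrI", 400, 500, "-"),
                ("g", "g.u2", 300, "chrI", 200, 500, "-"),
            ],
            columns=["gene_id", "utr_id", "length", "chrom", "start", "end", "strand"],
        )
        assert detect_apa(utrs).loc["g", "n_utrs"] == 2


class TestEvasion:
    def test_hand_derived_fixture(self, evasion_fixture):
        utrs, preds, expected = evasion_fixture
        out = mirna_evasion(preds, utrs)
        assert out == expected
        evading_fraction = len(out) / utrs["gene_id"].nunique()
        assert evading_fraction == pytest.approx(1 / 3)

    def test_family_in_every_utr_not_evadable(self, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        assert "gY" not in mirna_evasion(preds, utrs)

    def test_single_utr_gene_never_evades(self, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        assert "gZ" not in mirna_evasion(preds, utrs)

    def test_evadable_subset_of_targeting_families(self, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        families = count_mirna_families(preds, utrs)
        for gene, evadable in mirna_evasion(preds, utrs).items():
            assert len(evadable) <= families[gene]


class TestIntervalIntersection:
    def make(self, rows, id_col):
        cols = ["chrom", "start", "end", id_col, "strand"]
        df = pd.DataFrame(rows, columns=cols)
        if id_col == "utr_id":
            df["gene_id"] = df["utr_id"].str.split(".").str[0]
            df["length"] = df["end"] - df["start"]
        return df

    def test_overlapping_same_strand_assigned(self):
        sites = self.make([("chrI", 100, 120, "s1", "+")], "name")
        utrs = self.make([("chrI", 110, 300, "g.u1", "+")], "utr_id")
        out = intersect_sites_with_utrs(sites, utrs)
        assert out.to_dict("records") == [{"utr_id": "g.u1", "site_id": "s1"}]

    def test_opposite_strand_not_assigned(self):
        sites = self.make([("chrI", 110, 300, "s1", "-")], "name")
        utrs = self.make([("chrI", 110, 300, "g.u1", "+")], "utr_id")
        assert intersect_sites_with_utrs(sites, utrs).empty

    def test_adjacent_half_open_not_assigned(self):
        sites = self.make([("chrI", 100, 110, "s1", "+")], "name")
        utrs = self.make([("chrI", 110, 200, "g.u1", "+")], "utr_id")
        assert intersect_sites_with_utrs(sites, utrs).empty

    def test_degenerate_interval_rejected(self):
        sites = self.make([("chrI", 110, 110, "s1", "+")], "name")
        utrs = self.make([("chrI", 110, 200, "g.u1", "+")], "utr_id")
        with pytest.raises(FormatError):
            intersect_sites_with_utrs(sites, utrs)

    def test_agrees_with_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_sites, n_utrs = rng.integers(1, 101, size=2)
            def draw(n, prefix):
                starts = rng.integers(0, 2000, size=n)
                lengths = rng.integers(1, 150, size=n)
                return pd.DataFrame(
                    {
                        "chrom": rng.choice(["chrI", "chrII"], size=n),
                        "start": starts,
                        "end": starts + lengths,
                        "name": [f"{prefix}{i}" for i in range(n)],
                        "strand": rng.choice(["+", "-"], size=n),
                    }
                )
            sites = draw(n_sites, "s")
            utrs = draw(n_utrs, "u").rename(columns={"name": "utr_id"})
            got = set(
                map(tuple, intersect_sites_with_utrs(sites, utrs)[["utr_id", "site_id"]].values)
            )
            expected = {
                (u.utr_id, s.name)
                for u in utrs.itertuples()
                for s in sites.itertuples()
                if u.chrom == s.chrom
                and u.strand == s.strand
                and max(u.start, s.start) < min(u.end, s.end)
            }
            assert got == expected


class TestPhospho:
    GM = gene_model([("g", "P1"), ("g", "P2"), ("h", "Q1")])

    def test_duplicate_residues_counted_once(self):
        sites = pd.DataFrame(
            [("P1", 12), ("P1", 12), ("P1", 47)], columns=["protein_id", "residue_index"]
        )
        assert count_phospho_residues(sites, self.GM)["g"] == 2

    def test_isoforms_combined_nonredundantly(self):
        sites = pd.DataFrame(
            [("P1", 12), ("P2", 47)], columns=["protein_id", "residue_index"]
        )
        assert count_phospho_residues(sites, self.GM)["g"] == 2

    def test_no_sites_no_entry(self):
        sites = pd.DataFrame(columns=["protein_id", "residue_index"])
        assert "g" not in count_phospho_residues(sites, self.GM)

    def test_orphan_protein_rejected(self):
        sites = pd.DataFrame([("ZZ", 5)], columns=["protein_id", "residue_index"])
        with pytest.raises(FormatError, match="ZZ"):
            count_phospho_residues(sites, self.GM)


class TestFeatureTable:
    def test_one_row_per_gene_with_explicit_missing(self, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        gm = gene_model([(g, f"{g}.p1") for g in ("gX", "gY", "gZ", "gNoUTR")])
        table = build_feature_table(gm, utrs=utrs, predictions=preds)
        assert len(table) == 4
        row = table.set_index("gene_id").loc["gNoUTR"]
        assert pd.isna(row["utr_len"]) and pd.isna(row["n_utrs"])
        assert pd.isna(row["n_mirna_families"])
        assert row["n_tfs"] == 0 and row["n_phospho_residues"] == 0
        # no detection reference supplied: detection is unannotated, not False
        assert pd.isna(row["detected_in_ms"])

    def test_annotated_gene_without_predictions_is_zero(self, evasion_fixture):
        utrs, _, _ = evasion_fixture
        preds = pd.DataFrame([("gX.u1", "fam-a", 1)], columns=["utr_id", "mirna_family", "n_sites"])
        gm = gene_model([(g, f"{g}.p1") for g in ("gX", "gY", "gZ")])
        table = build_feature_table(gm, utrs=utrs, predictions=preds).set_index("gene_id")
        assert table.loc["gY", "n_mirna_families"] == 0  # annotated, none observed
        assert table.loc["gX", "n_evadable_families"] == 1

    def test_round_trip_through_tsv(self, tmp_path, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        gm = gene_model([(g, f"{g}.p1") for g in ("gX", "gY", "gZ")])
        table = build_feature_table(
            gm, utrs=utrs, predictions=preds, gene_sets={"demo": {"gX"}}
        )
        path = tmp_path / "features.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(table.columns)
        assert back["gene_id"].tolist() == table["gene_id"].tolist()
        assert back.set_index("gene_id")["n_mirna_families"].to_dict() == {
            "gX": 1, "gY": 1, "gZ": 1,
        }

    def test_gene_set_outside_universe_warns(self, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        gm = gene_model([("gX", "gX.p1")])
        with pytest.warns(UserWarning, match="outside"):
            build_feature_table(gm, gene_sets={"demo": {"gX", "ghost"}})


class TestNonredundancy:
    """Repeating any input row never changes any count."""

    def test_duplicated_rows_are_idempotent(self, evasion_fixture):
        utrs, preds, _ = evasion_fixture
        gm = gene_model([(g, f"{g}.p1") for g in ("gX", "gY", "gZ")])
        bindings = pd.DataFrame(
            [("A", "TF", "gX"), ("R", "RBP", "gX")],
            columns=["regulator_id", "regulator_class", "target_gene_id"],
        )
        phospho = pd.DataFrame([("gX.p1", 3)], columns=["protein_id", "residue_index"])

        def build(mult):
            return build_feature_table(
                pd.concat([gm] * mult, ignore_index=True),
                utrs=pd.concat([utrs] * mult, ignore_index=True),
                predictions=pd.concat([preds] * mult, ignore_index=True),
                bindings=pd.concat([bindings] * mult, ignore_index=True),
                phospho=pd.concat([phospho] * mult, ignore_index=True),
            )

        pd.testing.assert_frame_equal(build(1), build(3))
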