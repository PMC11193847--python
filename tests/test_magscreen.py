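"""MAG quality filtering, BAKO screening, taxonomy and BAMD set logic."""

import numpy as np
import pandas as pd
import pytest

from rumenba.magscreen import (DEFAULT_BAKO_CATALOG, MagRecord, ScreenSummary,
                               build_bamd, filter_mags, normalize_species_name,
                               quality_score, screen_bakos, screen_isolates,
                               set_analysis, summarize_proportions,
                               taxonomy_breakdown)


def make_mag(mag_id="M1", completeness=95.0, contamination=2.0,
             taxonomy="d__Bacteria;p__X;c__Y;o__Z;f__Fam;g__Gen;s__Gen sp1",
             kos=()):
    return MagRecord(mag_id=mag_id, completeness=completeness,
                     contamination=contamination, taxonomy=taxonomy,
                     ko_set=frozenset(kos),
                     gene_count_per_ko={k: 1 for k in kos})


class TestQualityScore:
    @pytest.mark.parametrize("comp,cont,expected", [
        (90, 2, 80), (100, 0, 100), (80, 10, 30)])
    def test_formula(self, comp, cont, expected):
        assert quality_score(comp, cont) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quality_score(101, 0)
        with pytest.raises(ValueError):
            quality_score(-1, 0)
        with pytest.raises(ValueError):
            quality_score(90, -2)


class TestFilter:
    def test_strict_boundary_semantics(self):
        mags = [make_mag("a", 81.0, 9.0), make_mag("b", 80.0, 5.0),
                make_mag("c", 95.0, 10.0)]
        kept = filter_mags(mags)
        assert [m.mag_id for m in kept] == ["a"]

    def test_inclusive_mode_keeps_boundary(self):
        mags = [make_mag("b", 80.0, 5.0), make_mag("c", 95.0, 10.0)]
        assert len(filter_mags(mags, inclusive=True)) == 2

    def test_all_pass_identity_and_idempotence(self):
        mags = [make_mag(f"m{i}", 90 + i, 1.0) for i in range(5)]
        once = filter_mags(mags)
        assert once == mags
        assert filter_mags(once) == once

    def test_empty_catalog(self):
        assert filter_mags([]) == []

    def test_duplicate_ids_deduplicated(self):
        mags = [make_mag("a", 90, 1), make_mag("a", 95, 1)]
        kept = filter_mags(mags)
        assert len(kept) == 1 and kept[0].completeness == 90

    def test_survivor_count_matches_row_by_row_recheck(self):
        rng = np.random.default_rng(5)
        mags = [make_mag(f"m{i}", float(np.clip(rng.normal(85, 8), 0, 100)),
                         float(rng.exponential(4)))
                for i in range(5000)]
        kept = filter_mags(mags)
        oracle = sum(1 for m in mags
                     if m.completeness > 80 and m.contamination < 10)
        assert len(kept) == oracle


class TestScreen:
    def test_single_ko_carrier_counted_once(self):
        mags = [make_mag("a", kos=["K07007"]), make_mag("b", kos=[])]
        s = screen_bakos(mags)
        assert s.bamag_ids == {"a"}
        assert s.per_ko_mag_count == {"K07007": 1}

    def test_non_carrier_excluded(self):
        s = screen_bakos([make_mag("x", kos=["K99999"])])
        assert s.bamag_ids == set() and s.n_filtered_mags == 1

    def test_species_level_bamags_tracked(self):
        named = make_mag("a", kos=["K01442"])
        unnamed = MagRecord("b", 95, 1, "d__Bacteria;p__X;c__Y;o__Z;f__F;g__G;s__",
                            frozenset(["K01442"]), {"K01442": 1})
        s = screen_bakos([named, unnamed])
        assert s.bamag_species_ids == {"a"}

    def test_counts_match_set_intersection_oracle(self):
        rng = np.random.default_rng(9)
        kos = sorted(DEFAULT_BAKO_CATALOG.ko_ids)
        mags = []
        for i in range(2000):
            carried = [k for k in kos if rng.random() < 0.3]
            counts = {k: int(rng.integers(1, 4)) for k in carried}
            mags.append(MagRecord(f"m{i}", 95, 1,
                                  "d__Bacteria;p__;c__;o__;f__;g__;s__",
                                  frozenset(carried), counts))
        s = screen_bakos(mags)
        bako = set(kos)
        oracle_bamags = {m.mag_id for m in mags if m.ko_set & bako}
        assert s.bamag_ids == oracle_bamags
        for ko in kos:
            n_mag = sum(1 for m in mags if ko in m.ko_set)
            n_gene = sum(m.gene_count_per_ko.get(ko, 0) for m in mags)
            assert s.per_ko_mag_count.get(ko, 0) == n_mag
            assert s.per_ko_gene_count.get(ko, 0) == n_gene
        assert s.total_bako_genes == sum(s.per_ko_gene_count.values())


class TestProportions:
    def test_published_mag_level_percentages(self):
        s = ScreenSummary.from_counts(
            per_ko_mag_count={"K07007": 3013}, per_ko_gene_count={"K07007": 4623},
            n_bamags=3585, n_filtered_mags=3954)
        df = summarize_proportions(s)
        mag_row = df[(df.level == "mag") & (df.ko == "K07007")].iloc[0]
        assert mag_row["printed"] == "84%"
        gene_row = df[(df.level == "gene") & (df.ko == "K07007")].iloc[0]
        assert gene_row["value"] == pytest.approx(100.0)

    def test_single_ko_carried_by_all(self):
        s = ScreenSummary.from_counts({"K01442": 50}, {"K01442": 50}, 50, 100)
        df = summarize_proportions(s)
        assert df[df.level == "mag"].iloc[0]["value"] == pytest.approx(100.0)
        frac = df[df.level == "bamag_fraction"].iloc[0]
        assert frac["value"] == pytest.approx(50.0)

    def test_zero_denominator_rejected(self):
        s = ScreenSummary(set(), set(), {}, {}, 10)
        with pytest.raises(ValueError):
            summarize_proportions(s)


class TestTaxonomy:
    def test_single_family(self):
        mags = [make_mag(f"m{i}") for i in range(4)]
        assert taxonomy_breakdown(mags, "family") == {"Fam": 1.0}

    def test_empty_species_goes_to_unlabeled(self):
        rec = MagRecord("a", 95, 1, "d__Bacteria;p__X;c__Y;o__Z;f__F;g__G;s__",
                        frozenset(), {})
        assert taxonomy_breakdown([rec], "species") == {"unlabeled": 1.0}

    def test_fractions_sum_to_one_and_match_tally(self):
        rng = np.random.default_rng(2)
        fams = ["Lachnospiraceae", "Bacteroidaceae", "Acutalibacteraceae", ""]
        mags = []
        for i in range(500):
            f = fams[rng.integers(0, len(fams))]
            mags.append(MagRecord(
                f"m{i}", 95, 1,
                f"d__Bacteria;p__X;c__Y;o__Z;f__{f};g__G;s__S",
                frozenset(), {}))
        comp = taxonomy_breakdown(mags, "family")
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
        for f in fams:
            key = f if f else "unlabeled"
            oracle = sum(1 for m in mags if m.rank("family") == (f or "")) / 500
            assert comp.get(key, 0.0) == pytest.approx(oracle)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            taxonomy_breakdown([make_mag()], "kingdom")


class TestIsolates:
    def test_duplicate_organisms_merged(self):
        table = pd.DataFrame({"organism_id": ["o1", "o1", "o2"],
                              "ko_id": ["K01442", "K03453", "K99999"]})
        res = screen_isolates(table)
        assert res["n_organisms"] == 2
        assert res["carriers"] == {"o1"}
        assert res["non_carriers"] == {"o2"}
        assert res["per_ko_organism_count"] == {"K01442": 1, "K03453": 1}

    def test_no_bako_goes_to_none_partition(self):
        table = pd.DataFrame({"organism_id": ["o1"], "ko_id": ["K00001"]})
        res = screen_isolates(table)
        assert res["carriers"] == set() and res["non_carriers"] == {"o1"}

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(4)
        kos = sorted(DEFAULT_BAKO_CATALOG.ko_ids) + ["K12345"]
        rows = [(f"org{rng.integers(0, 80)}", kos[rng.integers(0, len(kos))])
                for _ in range(600)]
        table = pd.DataFrame(rows, columns=["organism_id", "ko_id"])
        res = screen_isolates(table)
        sets = table.groupby("organism_id")["ko_id"].agg(set)
        bako = DEFAULT_BAKO_CATALOG.ko_ids
        assert res["carriers"] == set(sets.index[sets.apply(
            lambda s: bool(s & bako))])
        for ko in bako:
            oracle = int(sets.apply(lambda s: ko in s).sum())
            assert res["per_ko_organism_count"].get(ko, 0) == oracle

    def test_malformed_ko_rows_rejected_with_count(self):
        table = pd.DataFrame({"organism_id": ["o1", "o1"],
                              "ko_id": ["K01442", "notako"]})
        res = screen_isolates(table)
        assert res["n_rejected_rows"] == 1 and res["carriers"] == {"o1"}


class TestBamd:
    def test_disjoint_union(self):
        bamd = build_bamd({"A one", "B two", "C three"}, {"D four", "E five"})
        assert len(bamd) == 5

    def test_alias_collapse_via_name_map(self):
        bamd = build_bamd({"Prevotella sp900314947"},
                          {"Prevotella brunnea"},
                          name_map={"prevotella sp900314947":
                                    "prevotella brunnea"})
        assert bamd == {"prevotella brunnea"}

    def test_conflicting_map_rejected(self):
        with pytest.raises(ValueError, match="conflict"):
            build_bamd({"x"}, set(), name_map={"A b": "c d", "a B": "e f"})

    def test_candidatus_stripped_and_sp_names_distinct(self):
        assert normalize_species_name("Candidatus Foo bar") == "foo bar"
        assert normalize_species_name("Foo sp. 1") != \
            normalize_species_name("Foo sp. 2")

    def test_planted_aliases_match_manual_union(self):
        rng = np.random.default_rng(8)
        gtdb = {f"genus{i} species{i}" for i in range(40)}
        aliased = {f"genus{i} species{i}": f"ncbi{i} name{i}"
                   for i in range(0, 40, 4)}
        isolates = {f"ncbi{i} name{i}" for i in range(0, 40, 8)} | \
                   {f"other{j} sp{j}" for j in range(5)}
        bamd = build_bamd(gtdb, isolates, name_map=aliased)
        manual = {aliased.get(g, g) for g in gtdb} | set(isolates)
        assert bamd == {n.lower() for n in manual}


class TestSetAnalysis:
    def test_dfm_union(self):
        res = set_analysis(set(), set(), ({"a", "b"}, {"b", "c"}, set()))
        assert res["dfm_s"] == {"a", "b", "c"}

    def test_disjoint_bamd_gives_empty_intersection(self):
        res = set_analysis({"x"}, {"x"}, ({"a"}, {"b"}, {"c"}))
        assert res["dfm_with_bako"] == set()
        assert res["t_bamd"] == {"x"}

    def test_venn_counts_match_membership_check(self):
        rng = np.random.default_rng(12)
        universe = [f"sp{i}" for i in range(200)]
        bamd = set(rng.choice(universe, 100, replace=False))
        detected = set(rng.choice(universe, 50, replace=False))
        lists = tuple(set(rng.choice(universe, 10, replace=False))
                      for _ in range(3))
        res = set_analysis(bamd, detected, lists)
        dfm = lists[0] | lists[1] | lists[2]
        assert res["venn"]["n_dfm_s"] == len(dfm)
        assert res["venn"]["n_t_bamd"] == sum(1 for s in universe
                                              if s in bamd and s in detected)
        assert res["venn"]["n_dfm_with_bako"] == sum(
            1 for s in universe if s in dfm and s in bamd)
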