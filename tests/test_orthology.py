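"""Orthogroup set logic, comparator preprocessing, and duplication epochs."""

import numpy as np
import pandas as pd
import pytest

from macdev import (
    OrthogroupTable,
    PlatformSpec,
    SampleDesign,
    classify_comparator,
    classify_paralog_divergence,
    duplication_epoch,
    generate_orthogroups,
    identify_recent_genes,
    intersect_programs,
    phylo_profile,
    preprocess_comparator,
    union_inclusion_exclusion,
)

SPECIES = ["oxy", "sterkiella", "tet", "para", "human"]


def og_from(groups: dict) -> OrthogroupTable:
    return OrthogroupTable(groups)


class TestParalogClassification:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([True, True], "all_specific"),
            ([True, False], "mixed"),
            ([False, False], "none"),
        ],
    )
    def test_class_rules(self, flags, expected):
        genes = [f"oxy_g{i}" for i in range(len(flags))]
        og = og_from({"OG1": {"oxy": genes}})
        calls = dict(zip(genes, flags))
        result = classify_paralog_divergence(og, calls, "oxy")
        assert result.classes["OG1"] == expected

    def test_oversize_excluded(self):
        genes = [f"oxy_g{i}" for i in range(20)]
        og = og_from({"OG1": {"oxy": genes}})
        result = classify_paralog_divergence(og, {g: True for g in genes}, "oxy")
        assert result.classes["OG1"] == "excluded_oversize"
        assert result.summary["considered"] == 0

    def test_classes_partition_everything(self):
        og, truth = generate_orthogroups(
            SPECIES, 200,
            {"all_specific": 0.1, "mixed": 0.2, "none": 0.6, "oversize": 0.1},
            seed=5,
        )
        result = classify_paralog_divergence(og, truth.gene_specific, "oxy")
        assert set(result.classes) == set(og.groups)
        valid = {"all_specific", "mixed", "none", "excluded_oversize"}
        assert set(result.classes.values()) <= valid

    def test_planted_counts_recovered_exactly(self):
        # emulates the reported scale: 50 fully specific + 183 mixed of 2169
        n = 2169
        og, truth = generate_orthogroups(
            SPECIES, n,
            {"all_specific": 50 / n, "mixed": 183 / n,
             "none": (n - 233) / n, "oversize": 0.0},
            seed=1,
        )
        result = classify_paralog_divergence(og, truth.gene_specific, "oxy")
        assert result.summary["considered"] == 2169
        assert result.summary["specific_containing"] == 233
        assert result.summary["all_specific"] == 50
        assert result.summary["mixed"] == 183

    def test_all_none_mix_gives_zero_specific(self):
        og, truth = generate_orthogroups(SPECIES, 50, {"none": 1.0}, seed=2)
        result = classify_paralog_divergence(og, truth.gene_specific, "oxy")
        assert result.summary["specific_containing"] == 0

    def test_missing_focal_species_rejected(self):
        og = og_from({"OG1": {"tet": ["t1"]}})
        with pytest.raises(ValueError):
            classify_paralog_divergence(og, {}, "oxy")


def _comparator_design():
    return SampleDesign(
        {
            "veg1": ("vegetative", 1),
            "veg2": ("vegetative", 2),
            "starv1": ("starvation", 1),
            "dev1": ("conj_early", 1),
            "dev2": ("conj_late", 1),
        }
    )


class TestComparatorPipeline:
    def test_probe_collapse_geometric_mean(self):
        design = _comparator_design()
        matrix = pd.DataFrame(
            {s: [4.0, 16.0] for s in design.sample_ids}, index=["p1", "p2"]
        )
        platform = PlatformSpec(
            floor=0.0, control_conditions=("vegetative",),
            probe_map={"p1": "gene", "p2": "gene"},
        )
        rel = preprocess_comparator(matrix, platform, design)
        # geometric mean of (4, 16) = 8 -> log2 = 3; centred by control mean
        assert rel.shape == (1, 5)
        assert np.allclose(rel.to_numpy(), 0.0)  # constant gene centres to 0

    def test_probe_collapse_order_invariant(self):
        design = _comparator_design()
        m1 = pd.DataFrame({s: [4.0, 16.0] for s in design.sample_ids}, index=["p1", "p2"])
        m2 = m1.iloc[::-1]
        platform = PlatformSpec(
            floor=0.0, control_conditions=("vegetative",),
            probe_map={"p1": "gene", "p2": "gene"},
        )
        assert preprocess_comparator(m1, platform, design).equals(
            preprocess_comparator(m2, platform, design)
        )

    def test_floor_removes_dim_genes(self):
        design = _comparator_design()
        # all samples at 2^6.9: below a floor of 7 everywhere -> removed
        matrix = pd.DataFrame(
            {s: [2.0**6.9, 2.0**7.1] for s in design.sample_ids},
            index=["dim", "bright"],
        )
        platform = PlatformSpec(floor=7.0, control_conditions=("vegetative",))
        rel = preprocess_comparator(matrix, platform, design)
        assert list(rel.index) == ["bright"]

    def test_unknown_probes_listed(self):
        design = _comparator_design()
        matrix = pd.DataFrame({s: [4.0] for s in design.sample_ids}, index=["mystery"])
        platform = PlatformSpec(
            floor=0.0, control_conditions=("vegetative",), probe_map={"p1": "g"}
        )
        with pytest.raises(ValueError, match="mystery"):
            preprocess_comparator(matrix, platform, design)

    @pytest.mark.parametrize(
        "dev,veg,starv,expected",
        [
            (np.log2(3.2), 0.0, 0.0, True),
            (np.log2(3.2), np.log2(3.2), 0.0, False),  # equals vegetative
            (np.log2(2.0), 0.0, 0.0, False),
        ],
    )
    def test_three_fold_rule_against_both_controls(self, dev, veg, starv, expected):
        design = _comparator_design()
        values = {
            "veg1": veg, "veg2": veg, "starv1": starv, "dev1": dev, "dev2": 0.0
        }
        rel = pd.DataFrame([values], index=["g"])
        calls = classify_comparator(
            rel, design,
            dev_conditions=("conj_early", "conj_late"),
            control_conditions=("starvation", "vegetative"),
        )
        assert bool(calls.loc["g", "specific"]) is expected


class TestIntersectPrograms:
    def _planted(self):
        groups = {}
        focal_calls, tet_calls, para_calls = {}, {}, {}
        # 3 orthogroups specific in focal+tet, 2 in focal+para, 1 in all three
        plan = [("t", 3), ("p", 2), ("tp", 1), ("none", 4)]
        i = 0
        for kind, count in plan:
            for _ in range(count):
                og_id = f"OG{i}"
                groups[og_id] = {
                    "oxy": [f"oxy_{i}"], "tet": [f"tet_{i}"], "para": [f"para_{i}"]
                }
                focal_calls[f"oxy_{i}"] = kind != "none"
                tet_calls[f"tet_{i}"] = kind in ("t", "tp")
                para_calls[f"para_{i}"] = kind in ("p", "tp")
                i += 1
        return og_from(groups), focal_calls, {"tet": tet_calls, "para": para_calls}

    def test_planted_intersections_and_union(self):
        og, focal, comps = self._planted()
        report = intersect_programs(og, focal, comps, "oxy")
        assert report.counts["tet"] == 4  # 3 + the shared one
        assert report.counts["para"] == 3
        assert report.counts["both"] == 1
        assert report.counts["union"] == union_inclusion_exclusion(4, 3, 1) == 6

    def test_no_comparator_hits_gives_zero_union(self):
        og, focal, comps = self._planted()
        empty = {sp: {g: False for g in c} for sp, c in comps.items()}
        report = intersect_programs(og, focal, empty, "oxy")
        assert report.counts["union"] == 0

    def test_required_presence_validated(self):
        og, focal, comps = self._planted()
        with pytest.raises(ValueError):
            intersect_programs(og, focal, comps, "oxy", required_presence=["yeti"])


class TestPhyloProfile:
    def test_presence_rows(self):
        og = og_from(
            {
                "OG1": {"oxy": ["a"], "tet": ["t"], "human": ["h"]},
                "OG2": {"oxy": ["b"]},
            }
        )
        presence, counts = phylo_profile(og, ["a", "b"], "oxy")
        assert presence.loc["oxy"].all()
        assert counts["human"] == 1
        assert counts["tet"] == 1
        assert presence.loc["human", "OG2"] == False  # noqa: E712


class TestRecentGenes:
    def _og(self):
        return og_from(
            {
                "OG1": {"oxy": ["a"], "sterkiella": ["s1"]},
                "OG2": {"oxy": ["b"], "sterkiella": ["s2"], "human": ["h"]},
                "OG3": {"oxy": ["c"]},
            }
        )

    def test_sister_only_groups_qualify(self):
        genes, ogs = identify_recent_genes(
            self._og(), {"a": True, "b": True, "c": True}, "oxy",
            ["sterkiella"], ["human"],
        )
        assert genes == ["a"] and ogs == ["OG1"]

    def test_anti_monotone_in_exclusions(self):
        og = self._og()
        calls = {"a": True, "b": True, "c": True}
        base, _ = identify_recent_genes(og, calls, "oxy", ["sterkiella"], [])
        narrowed, _ = identify_recent_genes(og, calls, "oxy", ["sterkiella"], ["human"])
        assert set(narrowed) <= set(base)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            identify_recent_genes(self._og(), {}, "oxy", ["x"], ["x"])


SPECIES_TREE = "((((oxy,sterkiella),tetmemena),urostyla),euplotes);"


class TestDuplicationEpoch:
    def test_pre_radiation_duplication(self):
        # both paralog clades span all stichotrichs but not the outgroup:
        # duplication after the outgroup split, before the radiation
        gene_tree = (
            "(((oxy|a1,(sterkiella|s1,tetmemena|t1)),urostyla|u1),"
            "((oxy|a2,(sterkiella|s2,tetmemena|t2)),urostyla|u2));"
        )
        epoch = duplication_epoch(gene_tree, SPECIES_TREE, ["a1", "a2"], "oxy")
        assert epoch.status == "resolved"
        assert epoch.after == ("euplotes",)
        assert set(epoch.before) == {"oxy", "sterkiella", "tetmemena", "urostyla"}

    def test_recent_duplication_focal_only_clades(self):
        gene_tree = "((oxy|a1,oxy|a2),sterkiella|s1);"
        epoch = duplication_epoch(gene_tree, SPECIES_TREE, ["a1", "a2"], "oxy")
        assert epoch.status == "resolved"
        assert epoch.before == ("oxy",)
        assert epoch.after == ("sterkiella",)

    def test_hand_worked_four_species_case(self):
        # clade 1: oxy+sterkiella; clade 2: oxy only -> LCA(oxy, sterkiella)
        gene_tree = "((oxy|a1,sterkiella|s1),(oxy|a2));"
        epoch = duplication_epoch(gene_tree, SPECIES_TREE, ["a1", "a2"], "oxy")
        assert set(epoch.before) == {"oxy", "sterkiella"}
        assert epoch.after == ("tetmemena",)

    def test_leaf_order_and_paralog_order_invariance(self):
        a = "((oxy|a1,sterkiella|s1),(oxy|a2));"
        b = "((oxy|a2),(sterkiella|s1,oxy|a1));"
        e1 = duplication_epoch(a, SPECIES_TREE, ["a1", "a2"], "oxy")
        e2 = duplication_epoch(b, SPECIES_TREE, ["a2", "a1"], "oxy")
        assert (e1.before, e1.after) == (e2.before, e2.after)

    def test_unresolved_with_single_paralog(self):
        gene_tree = "((oxy|a1,sterkiella|s1),tetmemena|t1);"
        epoch = duplication_epoch(gene_tree, SPECIES_TREE, ["a1"], "oxy")
        assert epoch.status == "unresolved"
        assert epoch.describe() == "unresolved"


class TestOrthogroupTable:
    def test_duplicate_gene_across_groups_rejected(self):
        with pytest.raises(ValueError):
            og_from({"OG1": {"oxy": ["a"]}, "OG2": {"oxy": ["a"]}})

    def test_table_round_trip(self):
        og = og_from({"OG1": {"oxy": ["a", "b"], "tet": ["t"]}})
        again = OrthogroupTable.from_table(og.to_table())
        assert again.groups == og.groups

    def test_orthofinder_csv_dialect(self, tmp_path):
        path = tmp_path / "Orthogroups.csv"
        path.write_text(
            "\toxy\ttet\n"
            "OG0000000\toxy_a, oxy_b\ttet_a\n"
            "OG0000001\toxy_c\t\n"
        )
        og = OrthogroupTable.from_orthofinder_csv(path)
        assert og.members("OG0000000", "oxy") == ["oxy_a", "oxy_b"]
        assert og.members("OG0000001", "tet") == []
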