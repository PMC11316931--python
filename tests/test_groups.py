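import numpy as np
import pandas as pd
import pytest

from hologuild.differential import fold_change_quartiles, wilcoxon_bh
from hologuild.groups import (FunctionalGroup, build_mtb_group, build_mtp_group,
                              build_mtt_group, compare_groups, export_sankey)
from hologuild.tables import AnnotationMap, FeatureTable, normalize_cpm


def _panel(n_samples=18):
    samples = [f"s{i}" for i in range(n_samples)]
    half = n_samples // 2
    groups = pd.Series(["efficient"] * half + ["inefficient"] * half, index=samples)
    return samples, groups


def _ann(fids, species="Selenomonas bovis", family="Selenomonadaceae",
         categories=("COG:G",), origin=None, similarity=None):
    tax = pd.DataFrame({"species": species, "family": family},
                       index=pd.Index(fids, name="feature_id"))
    cats = {f: frozenset(categories) for f in fids}
    met = None
    if origin is not None:
        met = pd.DataFrame({"origin": [origin.get(f, "microbiota") for f in fids],
                            "similarity": [similarity.get(f, 300.0) for f in fids]},
                           index=pd.Index(fids, name="feature_id"))
    return AnnotationMap(tax, cats, met)


class TestMTTGroup:
    def _table(self, rows, fids):
        samples, groups = _panel()
        ab = pd.DataFrame(rows, index=pd.Index(fids, name="feature_id"),
                          columns=samples, dtype=float)
        return FeatureTable("MTT", ab, groups)

    def test_cpm_exactly_five_excluded(self):
        # Two features; f0's efficient-group mean CPM is exactly 5 after
        # normalization (5 vs 999995 per sample), strongly differential.
        up = [5.0] * 9 + [1.0] * 9
        filler = [999995.0] * 9 + [999999.0] * 9
        t = self._table([up, filler], ["f0", "f1"])
        g = build_mtt_group(t, _ann(["f0", "f1"]))
        assert "f0" not in g.provenance

    def test_all_below_cpm_empty_group(self):
        rows = [[1.0] * 9 + [0.5] * 9, [1e6] * 18]
        t = self._table(rows, ["f0", "bulk"])
        ann = _ann(["f0", "bulk"])
        g = build_mtt_group(t, ann, cpm_min=5e5)
        assert len(g) <= 1  # the small feature can never enter

    def test_planted_species_recovered(self, feature_panel):
        tables, anns, fcr, truth = feature_panel
        g = build_mtt_group(tables["MTT"], anns["MTT"])
        planted = set(truth.planted_species["MTT"])
        assert len(g.species & planted) / len(planted) >= 0.8

    def test_down_features_never_included(self, feature_panel):
        tables, anns, _, truth = feature_panel
        g = build_mtt_group(tables["MTT"], anns["MTT"])
        down = {f for f, s in truth.differential_feature_ids["MTT"].items() if s < 0}
        assert not (set(g.provenance) & down)


class TestMTPGroup:
    def test_q3_q4_membership(self, feature_panel):
        tables, anns, _, truth = feature_panel
        diff = fold_change_quartiles(wilcoxon_bh(tables["MTP"]))
        g = build_mtp_group(tables["MTP"], anns["MTP"], diff)
        chosen = set(g.provenance)
        assert chosen == set(diff.index[diff["quartile"].isin(("Q3", "Q4"))])
        q2 = set(diff.index[diff["quartile"] == "Q2"])
        assert not (chosen & q2)

    def test_missing_quartiles_rejected(self, feature_panel):
        tables, anns, _, _ = feature_panel
        diff = wilcoxon_bh(tables["MTP"])  # quartile column still empty
        with pytest.raises(ValueError, match="quartile"):
            build_mtp_group(tables["MTP"], anns["MTP"], diff)

    def test_no_upper_quartiles_empty_group(self):
        samples, groups = _panel()
        ab = pd.DataFrame(np.ones((4, 18)), index=[f"f{i}" for i in range(4)],
                          columns=samples)
        t = FeatureTable("MTP", ab, groups)
        diff = wilcoxon_bh(t)
        diff["quartile"] = "Q1"
        g = build_mtp_group(t, _ann(list(ab.index)), diff)
        assert len(g) == 0


class TestMTBGroup:
    def _mtb(self, similarity, origin="microbiota", prevalence=18):
        samples, groups = _panel()
        up = np.array([40.0] * 9 + [10.0] * 9)
        row = np.where(np.arange(18) < prevalence, up, 0.0)
        ab = pd.DataFrame([row, np.ones(18)], index=["m0", "m1"], columns=samples)
        t = FeatureTable("MTB", ab, groups)
        ann = _ann(["m0", "m1"], origin={"m0": origin, "m1": "others"},
                   similarity={"m0": similarity, "m1": 300.0})
        fcr = pd.Series(np.r_[np.random.default_rng(0).normal(5.8, 0.1, 9),
                              np.random.default_rng(1).normal(7.0, 0.1, 9)],
                        index=samples)
        return t, ann, fcr

    def test_similarity_exactly_200_excluded(self):
        t, ann, fcr = self._mtb(similarity=200.0)
        assert "m0" not in build_mtb_group(t, ann, fcr).provenance

    def test_similarity_over_200_included(self):
        t, ann, fcr = self._mtb(similarity=200.5)
        assert "m0" in build_mtb_group(t, ann, fcr).provenance

    def test_host_origin_excluded_despite_statistics(self):
        t, ann, fcr = self._mtb(similarity=300.0, origin="host")
        assert "m0" not in build_mtb_group(t, ann, fcr).provenance

    def test_prevalence_exactly_half_excluded(self):
        t, ann, fcr = self._mtb(similarity=300.0, prevalence=9)
        assert "m0" not in build_mtb_group(t, ann, fcr).provenance

    def test_planted_metabolites_recovered(self, feature_panel):
        tables, anns, fcr, truth = feature_panel
        g = build_mtb_group(tables["MTB"], anns["MTB"], fcr)
        qualifying = set(truth.mtb_qualifying_ids)
        got = set(g.provenance)
        assert len(got & qualifying) / len(qualifying) >= 0.9

    def test_missing_origin_annotation_required(self, feature_panel):
        tables, anns, fcr, _ = feature_panel
        bare = AnnotationMap(anns["MTB"].taxonomy, anns["MTB"].categories, None)
        with pytest.raises(ValueError, match="origin"):
            build_mtb_group(tables["MTB"], bare, fcr)


class TestCompareAndExport:
    def _group(self, layer, species):
        members = {(s, "fam") for s in species}
        prov = {f"{layer}_{i}": {"species": s, "family": "fam", "categories": ["COG:G"]}
                for i, s in enumerate(species)}
        return FunctionalGroup(layer, members, set(), prov)

    def test_set_arithmetic(self, feature_panel):
        tables, _, _, _ = feature_panel
        groups = {"MTT": self._group("MTT", ["a", "b", "c"]),
                  "MTP": self._group("MTP", ["b", "c", "d"]),
                  "MTB": self._group("MTB", ["c"])}
        venn, _ = compare_groups(groups, tables, n_perm=0, seed=0)
        assert venn["MTT&MTP"] == 2
        assert venn["MTT&MTP&MTB"] == 1
        assert venn["MTT_unique"] == 1

    def test_identical_groups_full_overlap(self, feature_panel):
        tables, _, _, _ = feature_panel
        g = self._group("MTT", ["x", "y"])
        groups = {"MTT": g, "MTP": FunctionalGroup("MTP", g.members, set(), g.provenance),
                  "MTB": FunctionalGroup("MTB", g.members, set(), g.provenance)}
        venn, _ = compare_groups(groups, tables, n_perm=0, seed=0)
        assert venn["MTT&MTP&MTB"] == 2
        assert venn["MTT_unique"] == 0

    def test_sankey_single_feature(self):
        g = FunctionalGroup("MTP", {("sp", "fam")}, {("sp", "COG:G")},
                            {"f1": {"species": "sp", "family": "fam",
                                    "categories": ["COG:G"]}})
        links = export_sankey(g)
        assert len(links) == 2
        assert set(links["weight"]) == {1}

    def test_sankey_weight_conservation(self, feature_panel):
        tables, anns, fcr, _ = feature_panel
        g = build_mtb_group(tables["MTB"], anns["MTB"], fcr)
        links = export_sankey(g)
        fam_links = links[links["level"] == "species-family"]
        for sp in g.species:
            supporting = sum(1 for info in g.provenance.values()
                             if info["species"] == sp)
            assert fam_links[fam_links["source"] == sp]["weight"].sum() == supporting

    def test_group_permanova_detects_planted_signal(self, feature_panel):
        tables, anns, fcr, _ = feature_panel
        from hologuild.differential import fold_change_quartiles, wilcoxon_bh
        diff = fold_change_quartiles(wilcoxon_bh(tables["MTP"]))
        groups = {"MTP": build_mtp_group(tables["MTP"], anns["MTP"], diff)}
        _, perma = compare_groups(groups, tables, n_perm=199, seed=5)
        res = perma["MTP"]
        assert res.p_perm <= 0.05
        assert res.effect_size_log2 == pytest.approx(
            np.log2(res.pseudo_F / res.q), abs=1e-12)
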