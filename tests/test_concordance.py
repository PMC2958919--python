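import numpy as np
import pandas as pd
import pytest

from aflpdelim.concordance import (
    DiscordanceEvent,
    MonophylyReport,
    Thresholds,
    assess_monophyly,
    classify_discordance,
    coalescence_depth_profile,
    species_map_from_tips,
)
from aflpdelim.io_formats import SpecimenTable, parse_newick_tree
from aflpdelim.synthetic_data import simulate_coalescent_tree


def brute_force_status(tree, species_of):
    """Oracle: enumerate every clade; a species is monophyletic iff its tip
    set is exactly some clade's leaf set."""
    tips_by_sp = {}
    for leaf in tree.tree.leaf_node_iter():
        tips_by_sp.setdefault(species_of[leaf.taxon.label], set()).add(
            leaf.taxon.label)
    clades = []
    for node in tree.tree.preorder_node_iter():
        clades.append({l.taxon.label for l in node.leaf_iter()})
    return {sp: tips in clades or len(tips) == 1
            for sp, tips in tips_by_sp.items()}


class TestMonophyly:
    def test_clean_split_is_monophyletic(self):
        t = parse_newick_tree("((A_1:1,A_2:1):1,(B_1:1,B_2:1):1);")
        rep = assess_monophyly(t, species_map_from_tips(t.tip_labels()))
        assert rep.status == {"A": "monophyletic", "B": "monophyletic"}

    def test_interleaved_topology_forces_nonmonophyly(self):
        t = parse_newick_tree("((A_1:1,B_1:1):1,(A_2:1,B_2:1):1);")
        rep = assess_monophyly(t, species_map_from_tips(t.tip_labels()))
        assert rep.status["A"] != "monophyletic"
        assert rep.status["B"] != "monophyletic"
        assert rep.intruders["A"] == ["B_1", "B_2"]

    def test_paraphyly_vs_polyphyly(self):
        # B nested inside A as one clade: A paraphyletic
        t = parse_newick_tree("(((B_1:1,B_2:1):1,A_1:2):1,A_2:3);")
        rep = assess_monophyly(t, species_map_from_tips(t.tip_labels()))
        assert rep.status["A"] == "paraphyletic"
        assert rep.status["B"] == "monophyletic"

    def test_matches_brute_force_clade_enumeration(self):
        rng = np.random.default_rng(1)
        for s in range(12):
            t = simulate_coalescent_tree([3, 3, 2], [50.0, 120.0],
                                         pop_sizes=30.0, seed=s + 1)
            sp = species_map_from_tips(t.tip_labels())
            rep = assess_monophyly(t, sp)
            oracle = brute_force_status(t, sp)
            for species, is_mono in oracle.items():
                assert (rep.status[species] == "monophyletic") == is_mono

    def test_unmapped_tip_rejected(self):
        t = parse_newick_tree("((A_1:1,A_2:1):1,B_1:2);")
        with pytest.raises(ValueError, match="maps to no"):
            assess_monophyly(t, {"A_1": "A", "A_2": "A"})

    def test_specimen_table_mapping(self):
        t = parse_newick_tree("((x1:1,x2:1):1,y1:2);")
        meta = SpecimenTable(pd.DataFrame({
            "specimen_id": ["x1", "x2", "y1"],
            "species_label": ["X", "X", "Y"],
        }))
        rep = assess_monophyly(t, meta)
        assert rep.status == {"X": "monophyletic", "Y": "monophyletic"}


class TestDepthProfile:
    def test_hand_constructed_relative_depth(self):
        # A_2 rejoins heterospecific lineages at 9/10 of the root height
        t = parse_newick_tree("(((A_1:1,B_1:1):8,A_2:9):1,B_2:10);")
        sp = species_map_from_tips(t.tip_labels())
        evs = coalescence_depth_profile(t, sp, "A")
        by_tip = {tuple(e.tips): e.relative_depth for e in evs}
        assert by_tip[("A_2",)] == pytest.approx(0.9)
        assert by_tip[("B_1",)] == pytest.approx(0.1)

    def test_zero_length_attachment_has_zero_depth(self):
        t = parse_newick_tree("(((A_1:0,B_1:0):5,A_2:5):1,B_2:6);")
        sp = species_map_from_tips(t.tip_labels())
        evs = coalescence_depth_profile(t, sp, "B")
        assert min(e.relative_depth for e in evs) == pytest.approx(0.0)

    def test_scale_invariance(self):
        base = "(((A_1:1,B_1:1):8,A_2:9):1,B_2:10);"
        scaled = "(((A_1:3,B_1:3):24,A_2:27):3,B_2:30);"
        sp = {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
        d1 = [e.relative_depth for e in coalescence_depth_profile(
            parse_newick_tree(base), sp, "A")]
        d2 = [e.relative_depth for e in coalescence_depth_profile(
            parse_newick_tree(scaled), sp, "A")]
        assert d1 == pytest.approx(d2)

    def test_monophyletic_species_has_no_events(self):
        t = parse_newick_tree("((A_1:1,A_2:1):1,(B_1:1,B_2:1):1);")
        sp = species_map_from_tips(t.tip_labels())
        assert coalescence_depth_profile(t, sp, "A") == []

    def test_zero_root_height_rejected(self):
        t = parse_newick_tree("((A_1:0,B_1:0):0,(A_2:0,B_2:0):0);")
        sp = species_map_from_tips(t.tip_labels())
        with pytest.raises(ValueError, match="root height"):
            coalescence_depth_profile(t, sp, "A")

    def test_outgroup_excluded_from_normalization(self):
        # without exclusion the distant outgroup doubles the root height
        t = parse_newick_tree("((((A_1:1,B_1:1):8,A_2:9):1,B_2:10):10,OUT_1:20);")
        sp = species_map_from_tips(t.tip_labels())
        evs = coalescence_depth_profile(t, sp, "A", exclude=["OUT_1"])
        assert max(e.relative_depth for e in evs) == pytest.approx(0.9)

    def test_introgression_shallower_than_deep_divergence_control(self):
        # paired simulation: same species tree with and without a recent
        # total introgression pulse; the pulse must shift discordant
        # coalescences toward the tips
        intro, control = [], []
        for s in range(1, 20):
            for pulse, sink in ((1.0, intro), (None, control)):
                kw = dict(species_sizes=[5, 5, 2],
                          divergence_times=[400.0, 20_000.0],
                          pop_sizes=100.0, seed=s)
                if pulse is not None:
                    kw["introgression"] = ("S1", "S2", 1.0, pulse)
                t = simulate_coalescent_tree(**kw)
                sp = species_map_from_tips(t.tip_labels())
                rep = assess_monophyly(t, sp)
                for species in ("S1", "S2"):
                    if rep.status[species] != "monophyletic":
                        sink.extend(e.relative_depth for e in
                                    coalescence_depth_profile(t, sp, species))
        assert intro and control
        assert np.median(intro) < np.median(control)


class TestClassification:
    def _mono(self):
        return MonophylyReport(
            {"deep_sp": "paraphyletic", "shallow_sp": "paraphyletic",
             "ok_sp": "monophyletic"},
            {"deep_sp": ["x_1"], "shallow_sp": ["y_1"], "ok_sp": []},
            {"deep_sp": [], "shallow_sp": [], "ok_sp": []},
        )

    def test_decision_table(self):
        rep = classify_discordance(
            self._mono(),
            {"deep_sp": [0.9], "shallow_sp": [0.05]},
            {"deep_sp": 0.004, "shallow_sp": 0.139},
        )
        labels = dict(zip(rep.table["species"], rep.table["label"]))
        assert labels["deep_sp"] == "incomplete-lineage-sorting"
        assert labels["shallow_sp"] == "recent-divergence-or-introgression"
        assert labels["ok_sp"] == "concordant"

    def test_conflicting_criteria_are_ambiguous(self):
        rep = classify_discordance(
            self._mono(),
            {"deep_sp": [0.9], "shallow_sp": [0.05]},
            {"deep_sp": 0.5, "shallow_sp": 0.001},
        )
        labels = dict(zip(rep.table["species"], rep.table["label"]))
        assert labels["deep_sp"] == "ambiguous"
        assert labels["shallow_sp"] == "ambiguous"

    def test_missing_admixture_results_flagged(self):
        rep = classify_discordance(self._mono(), {"deep_sp": [0.9],
                                                  "shallow_sp": [0.2]}, None)
        rows = rep.table.set_index("species")
        assert rows.loc["deep_sp", "label"] == "ambiguous"
        assert "admixture" in rows.loc["deep_sp", "reason"]

    def test_pure_function_same_inputs_same_labels(self):
        args = (self._mono(), {"deep_sp": [0.9], "shallow_sp": [0.05]},
                {"deep_sp": 0.004, "shallow_sp": 0.139})
        assert classify_discordance(*args).table.equals(
            classify_discordance(*args).table)

    def test_thresholds_configurable_and_reported(self):
        rep = classify_discordance(
            self._mono(), {"deep_sp": [0.4], "shallow_sp": [0.05]},
            {"deep_sp": 0.004, "shallow_sp": 0.139},
            thresholds=Thresholds(depth=0.3, admixture=0.2),
        )
        labels = dict(zip(rep.table["species"], rep.table["label"]))
        assert labels["deep_sp"] == "incomplete-lineage-sorting"
        assert labels["shallow_sp"] == "ambiguous"
        assert rep.thresholds.depth == 0.3

    def test_accepts_report_dataframe_for_admixture(self):
        adf = pd.DataFrame({"foreign_ancestry": [0.01, 0.139]})
        rep = classify_discordance(self._mono(),
                                   {"deep_sp": [0.9], "shallow_sp": [0.05]},
                                   {"deep_sp": adf, "shallow_sp": adf})
        rows = rep.table.set_index("species")
        assert rows.loc["shallow_sp", "label"] == "recent-divergence-or-introgression"
        assert rows.loc["deep_sp", "foreign_ancestry"] == pytest.approx(0.139)

    def test_events_accepted_as_objects_or_floats(self):
        ev = [DiscordanceEvent(["x_1"], 0.9)]
        r1 = classify_discordance(self._mono(), {"deep_sp": ev, "shallow_sp": [0.05]},
                                  {"deep_sp": 0.0, "shallow_sp": 0.3})
        r2 = classify_discordance(self._mono(), {"deep_sp": [0.9], "shallow_sp": [0.05]},
                                  {"deep_sp": 0.0, "shallow_sp": 0.3})
        assert r1.table.equals(r2.table)
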