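"""Threshold estimation and hierarchical classification."""

import itertools

import numpy as np
import pytest

from tmaturity import (
    EventTable, InsufficientEventsError, ThresholdSet, builtin_trees,
    classify_events, estimate_thresholds, simulate_tube, transform,
)
from tmaturity.gating import estimate_threshold_1d
from tmaturity.panels import PANEL, canonical_marker


class TestThresholds:
    def test_balanced_mixture_valley(self):
        """50:50 N(0, 0.4) + N(2.5, 0.4): the density valley is at 1.25."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.0, 0.4, 10_000),
                            rng.normal(2.5, 0.4, 10_000)])
        cut, how = estimate_threshold_1d(x)
        assert how == "valley"
        assert cut == pytest.approx(1.25, abs=0.15)

    def test_rare_positive_population_still_found(self):
        """A 0.5% positive shoulder is a real mode, not noise."""
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(1.0, 0.4, 20_000),
                            rng.normal(3.5, 0.4, 100)])
        cut, how = estimate_threshold_1d(x)
        assert how == "valley"
        assert 2.0 < cut < 3.2

    def test_unimodal_falls_back_to_quantile(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 0.4, 5_000)
        cut, how = estimate_threshold_1d(x)
        assert how == "quantile-fallback"
        assert cut > np.median(x)

    def test_duplication_invariance(self):
        """Duplicating every event leaves the cutoff bit-identical."""
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0.0, 0.4, 3_000),
                            rng.normal(2.5, 0.4, 3_000)])
        cut1, _ = estimate_threshold_1d(x)
        cut2, _ = estimate_threshold_1d(np.concatenate([x, x]))
        assert cut1 == cut2

    def test_insufficient_events_error(self, nbs_profile):
        table = transform(simulate_tube(nbs_profile, "2", 2000))
        within = np.zeros(table.n_events, dtype=bool)
        within[:100] = True
        with pytest.raises(InsufficientEventsError):
            estimate_thresholds(table, ["CD27"], within=within)

    def test_estimates_on_simulated_tube(self, nbs_profile):
        """Cutoffs land between the negative and positive components."""
        table = transform(simulate_tube(nbs_profile, "2", 20_000))
        t_mask = np.isin(table.event_labels.astype(str),
                         ["debris", "nonT"], invert=True)
        ts = estimate_thresholds(table, ["CD27", "CD45RA", "CD197"],
                                 within=t_mask)
        for m in ("CD27", "CD45RA", "CD197"):
            assert 1.8 < ts[m] < 3.2, m
            assert ts.provenance[m] == "valley"


def tube2_event_table(rows, branch="CD4"):
    """Events on tube 2 channels with explicit CD27/CD45RA/CD197 signs."""
    channels = list(PANEL["2"].channels)
    idx = {c.marker: j for j, c in enumerate(channels)}
    data = np.zeros((len(rows), len(channels)))
    data[:, idx["CD3"]] = 1.0
    data[:, idx[branch]] = 1.0
    data[:, idx["CD8" if branch == "CD4" else "CD4"]] = -1.0
    for i, (cd27, ra, r7) in enumerate(rows):
        data[i, idx["CD27"]] = cd27
        data[i, idx["CD45RA"]] = ra
        data[i, idx["CD197"]] = r7
    return EventTable(data, channels, {"tube_id": "2",
                                       "transform_state": "transformed"})


def zero_thresholds(tree):
    return ThresholdSet({m: 0.0 for m in tree.markers},
                        {m: "user" for m in tree.markers})


EXPECTED_TUBE2 = {
    (1, 1, 1): "TN", (1, 1, -1): "LTEMRA", (1, -1, 1): "TCM",
    (1, -1, -1): "TEM", (-1, 1, -1): "HTEMRA", (-1, -1, -1): "TD",
    (-1, 1, 1): "unclassified_CD27neg_CCR7pos_RApos",
    (-1, -1, 1): "unclassified_CD27neg_CCR7pos_RAneg",
}


class TestClassification:
    @pytest.mark.parametrize("branch", ["CD4", "CD8"])
    def test_truth_table_all_eight_combos(self, branch):
        """Brute force over CD27 x CD45RA x CD197: six named subsets plus the
        two explicit unclassified buckets; identical logic on both branches."""
        combos = list(itertools.product([1, -1], repeat=3))
        tree = builtin_trees()["2"]
        table = tube2_event_table(combos, branch)
        labels = classify_events(table, tree, zero_thresholds(tree),
                                 np.ones(len(combos), dtype=bool))
        leaf_names = [f"{b}_{branch}" for b in
                      ("TN", "TCM", "TEM", "LTEMRA", "HTEMRA", "TD",
                       "unclassified_CD27neg_CCR7pos_RApos",
                       "unclassified_CD27neg_CCR7pos_RAneg")]
        for i, combo in enumerate(combos):
            hit = [n for n in leaf_names if labels[n][i]]
            assert hit == [f"{EXPECTED_TUBE2[combo]}_{branch}"], combo

    def test_tie_is_negative(self):
        """Intensity exactly at the cutoff counts as negative."""
        tree = builtin_trees()["2"]
        table = tube2_event_table([(0, 1, 1)])  # CD27 exactly at cutoff 0
        labels = classify_events(table, tree, zero_thresholds(tree),
                                 np.ones(1, dtype=bool))
        assert not labels["TN_CD4"][0]
        assert labels["unclassified_CD27neg_CCR7pos_RApos_CD4"][0]

    def test_partition_and_conservation(self, nbs_profile):
        """{TN,TCM,TEM,LTEMRA} exactly partition CD27+; CD27- splits into
        H-TEMRA, TD and the two unclassified buckets."""
        tree = builtin_trees()["2"]
        table = transform(simulate_tube(nbs_profile, "2", 25_000))
        primary = np.isin(table.event_labels.astype(str),
                          ["debris", "nonT"], invert=True)
        thresholds = estimate_thresholds(table, tree.markers, within=primary)
        labels = classify_events(table, tree, thresholds, primary)
        for x in ("CD4", "CD8"):
            pos = labels[f"CD27pos_{x}"].sum()
            neg = labels[f"CD27neg_{x}"].sum()
            quartet = sum(labels[f"{b}_{x}"].sum()
                          for b in ("TN", "TCM", "TEM", "LTEMRA"))
            assert quartet == pos
            rest = sum(labels[f"{b}_{x}"].sum()
                       for b in ("HTEMRA", "TD",
                                 "unclassified_CD27neg_CCR7pos_RApos",
                                 "unclassified_CD27neg_CCR7pos_RAneg"))
            assert rest == neg
            assert pos + neg == labels[x].sum()

    def test_missing_threshold_marker_raises(self):
        tree = builtin_trees()["2"]
        table = tube2_event_table([(1, 1, 1)])
        with pytest.raises(Exception, match="CD197|threshold"):
            classify_events(table, tree,
                            ThresholdSet({"CD27": 0.0}, {"CD27": "user"}),
                            np.ones(1, dtype=bool))


class TestBuiltinTrees:
    def test_five_trees_cover_the_panel(self):
        trees = builtin_trees()
        assert set(trees) == set(PANEL)
        for tid, tree in trees.items():
            tube_markers = {canonical_marker(m) for m in PANEL[tid].markers}
            assert set(tree.markers) <= tube_markers

    def test_key_definitions(self):
        trees = builtin_trees()
        tscm = next(s for s in trees["3"].subsets if s.name == "TSCM_CD4")
        assert set(tscm.requirements) == {("CD27", "+"), ("CD45RA", "+"),
                                          ("CD95", "+")}
        rte = next(s for s in trees["1"].subsets if s.name == "RTE_CD4")
        assert rte.parent == "CD4"
        assert set(rte.requirements) == {("CD31", "+"), ("CD45RA", "+")}
        nk = next(s for s in trees["trucount"].subsets if s.name == "NK")
        assert set(nk.requirements) == {("CD3", "-"), ("CD16/56", "+")}
        assert trees["trucount"].primary_mode == "cd45_ssc"
        assert all(trees[t].primary_mode == "cd3_ssc" for t in "1234")

    def test_cd4_cd8_symmetry(self):
        """The CD8 branch mirrors the CD4 branch subset-for-subset."""
        tree = builtin_trees()["2"]
        cd4 = {s.name[:-4]: s.requirements for s in tree.subsets
               if s.name.endswith("_CD4")}
        cd8 = {s.name[:-4]: s.requirements for s in tree.subsets
               if s.name.endswith("_CD8")}
        assert cd4 == cd8

    def test_yaml_round_trip(self):
        tree = builtin_trees()["3"]
        from tmaturity.gating import GateTree
        assert GateTree.from_yaml(tree.to_yaml()) == tree
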