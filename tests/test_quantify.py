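"""Bead-anchored absolute counts, the proportion chain, and tube merging."""

import numpy as np
import pytest

from tmaturity import (
    ConfigurationError, DataError, EventTable, Channel, MergeError,
    absolute_lymphocyte_count, builtin_trees, merge_tubes, subset_statistics,
)
from tmaturity.quantify import SubsetStat, TubeResult
from tmaturity.synthetic import GroupPreset, make_subject_profile, simulate_tube
from tmaturity.preprocess import gate_beads, transform

from _oracles import bead_count_mc_oracle


def counting_table(beads=50_000, volume=50.0):
    return EventTable(np.empty((0, 1)), [Channel("FITC-A", "FITC", "CD3")],
                      {"tube_id": "trucount", "beads_per_tube": beads,
                       "stained_volume_ul": volume})


class TestBeadFormula:
    def test_ratio_arithmetic(self):
        """10,000 cells : 10,000 beads at 50,000 beads / 50 ul = 1,000/ul."""
        assert absolute_lymphocyte_count(counting_table(), 10_000, 10_000) \
            == pytest.approx(1000.0)

    def test_zero_lymphocytes(self):
        assert absolute_lymphocyte_count(counting_table(), 0, 5_000) == 0.0

    def test_zero_beads_is_diagnostic_error(self):
        with pytest.raises(DataError, match="bead"):
            absolute_lymphocyte_count(counting_table(), 100, 0)

    def test_missing_metadata(self):
        t = EventTable(np.empty((0, 1)), [Channel("FITC-A", "FITC", "CD3")])
        with pytest.raises(ConfigurationError):
            absolute_lymphocyte_count(t, 100, 100)

    def test_recovers_generator_truth_over_seeds(self, nbs_preset):
        """Simulated counting tubes recover the known 1,330 cells/ul within
        5% on average (40 acquisition replicates; scaled from 100)."""
        d = nbs_preset.to_dict()
        d["dispersion"] = 0.0
        preset = GroupPreset.from_dict(d)
        estimates = []
        for i in range(40):
            prof = make_subject_profile(preset, i, seed=13)
            table = transform(simulate_tube(prof, "trucount", 30_000))
            labels = table.event_labels.astype(str)
            beads = int(gate_beads(table).sum())
            lymph = int(np.isin(labels, ["debris", "bead", "other_leukocytes"],
                                invert=True).sum())
            estimates.append(absolute_lymphocyte_count(table, lymph, beads))
        assert np.mean(estimates) == pytest.approx(1330.0, rel=0.05)
        np.testing.assert_allclose(estimates, 1330.0, rtol=0.10)

    def test_matches_monte_carlo_volume_oracle(self):
        """The closed-form ratio agrees with a per-event acquisition
        simulation on 20 random fixtures (within 1%)."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            conc = rng.uniform(500, 4000)
            volume = rng.uniform(40, 110)
            beads = int(rng.uniform(20_000, 60_000))
            alpha = rng.uniform(0.05, 0.2)
            oracle = bead_count_mc_oracle(conc, volume, beads, alpha, rng)
            assert oracle == pytest.approx(conc, rel=0.01)


def synthetic_labels(n_primary=10_000, n_parent=4_000, n_subset=1_000):
    tree = builtin_trees()["2"]
    n = n_primary
    labels = {name: np.zeros(n, dtype=bool)
              for name in ["T"] + [s.name for s in tree.subsets]}
    labels["T"][:] = True
    labels["CD4"][:n_parent] = True
    labels["TN_CD4"][:n_subset] = True
    return tree, labels


class TestProportionChain:
    def test_hand_arithmetic(self):
        """4,000 of 10,000 primary events in the parent, 1,000 in the subset,
        primary gate worth 2,000 cells/ul -> 25% and 200 cells/ul."""
        tree, labels = synthetic_labels()
        res = subset_statistics(labels, tree, lymph_abs=2000.0,
                                primary_abs=2000.0)
        st = res.stats["TN_CD4"]
        assert st.pct_of_parent == pytest.approx(25.0)
        assert st.abs_count == pytest.approx(200.0)

    def test_subset_equal_to_parent(self):
        tree, labels = synthetic_labels(8_000, 8_000, 0)
        labels["TN_CD4"] = labels["CD4"].copy()
        res = subset_statistics(labels, tree, 1500.0, primary_abs=1500.0)
        assert res.stats["TN_CD4"].pct_of_parent == pytest.approx(100.0)
        assert res.stats["TN_CD4"].abs_count == pytest.approx(
            res.stats["CD4"].abs_count if "CD4" in res.stats
            else 1500.0 * 8_000 / 8_000)

    def test_empty_parent_reported_missing_not_zero(self):
        tree, labels = synthetic_labels(1000, 0, 0)
        with pytest.warns(UserWarning, match="empty"):
            res = subset_statistics(labels, tree, 1000.0)
        assert res.stats["TN_CD4"].pct_of_parent is None

    def test_scale_equivariance(self):
        """Doubling the anchor doubles every absolute count, leaves % alone."""
        tree, labels = synthetic_labels()
        r1 = subset_statistics(labels, tree, 1000.0, primary_abs=1000.0)
        r2 = subset_statistics(labels, tree, 2000.0, primary_abs=2000.0)
        for name in r1.stats:
            assert r2.stats[name].abs_count == pytest.approx(
                2 * r1.stats[name].abs_count)
            assert r2.stats[name].pct_of_parent == r1.stats[name].pct_of_parent

    def test_conservation_of_absolute_counts(self, nbs_profile):
        """TN+TCM+TEM+LTEMRA absolute counts equal the CD27+ parent's within
        float tolerance (they partition it)."""
        from tmaturity.gating import classify_events, estimate_thresholds
        tree = builtin_trees()["2"]
        table = transform(simulate_tube(nbs_profile, "2", 25_000))
        primary = np.isin(table.event_labels.astype(str), ["debris", "nonT"],
                          invert=True)
        thr = estimate_thresholds(table, tree.markers, within=primary)
        labels = classify_events(table, tree, thr, primary)
        res = subset_statistics(labels, tree, 700.0, primary_abs=700.0)
        quartet = sum(res.stats[f"{b}_CD4"].abs_count
                      for b in ("TN", "TCM", "TEM", "LTEMRA"))
        cd27pos = res.tallies["CD27pos_CD4"] / res.primary_events * 700.0
        assert quartet == pytest.approx(cd27pos, rel=1e-12)

    def test_low_confidence_flag(self):
        tree, labels = synthetic_labels(10_000, 30, 10)
        res = subset_statistics(labels, tree, 1000.0)
        assert res.stats["TN_CD4"].low_confidence


def tube_result(tube_id, names, lymph_abs=None):
    stats = {n: SubsetStat(10, 100, 10.0, 50.0, False, tube_id) for n in names}
    return TubeResult(tube_id, stats, {n: 10 for n in names}, 1000,
                      lymph_abs=lymph_abs)


class TestMergeTubes:
    def test_full_merge_has_all_families(self, nbs_preset):
        from tmaturity.pipeline import RunConfig, process_subject_tables
        from tmaturity.synthetic import iter_cohort
        profile, tables = next(iter_cohort(nbs_preset, seed=3, n_events=12_000))
        cfg = RunConfig(presets=(nbs_preset,), seed=3, n_events=12_000)
        res = process_subject_tables(profile.subject_id, profile.group,
                                     tables, cfg)
        expected = {"lymphocytes", "T", "B", "NK", "CD4", "CD8"}
        for x in ("CD4", "CD8"):
            expected |= {f"{b}_{x}" for b in
                         ("RTE", "TN", "TSCM", "TCM", "TEM", "LTEMRA",
                          "HTEMRA", "TEMRA", "TD", "CD57", "KLRG1", "PD1")}
        assert expected <= set(res.stats)

    def test_duplicate_subset_is_merge_error(self):
        tubes = {"trucount": tube_result("trucount", ["T"], lymph_abs=1200.0),
                 "1": tube_result("1", ["RTE_CD4"]),
                 "2": tube_result("2", ["RTE_CD4"]),
                 "3": tube_result("3", []), "4": tube_result("4", [])}
        with pytest.raises(MergeError, match="RTE_CD4"):
            merge_tubes(tubes, "s1", "nbs")

    def test_missing_counting_tube_fatal(self):
        with pytest.raises(ConfigurationError, match="counting"):
            merge_tubes({"1": tube_result("1", ["RTE_CD4"])}, "s1")

    def test_missing_panel_tube_degrades_with_warning(self, caplog):
        tubes = {"trucount": tube_result("trucount", ["T"], lymph_abs=1200.0),
                 "1": tube_result("1", ["RTE_CD4"]),
                 "2": tube_result("2", ["TN_CD4"]),
                 "3": tube_result("3", ["TSCM_CD4"])}
        with caplog.at_level("WARNING"):
            res = merge_tubes(tubes, "s1", "nbs")
        assert "4" in caplog.text
        assert "TN_CD4" in res.stats and "CD57_CD4" not in res.stats
        assert res.lymph_abs == 1200.0
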