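"""Synthetic-cohort generator: determinism, median calibration, tube
structure, bead and debris composition."""

import dataclasses

import numpy as np
import pytest

from tmaturity import (
    ConfigurationError, GroupPreset, default_spillover,
    make_subject_profile, simulate_cohort, simulate_tube, subset_truth_mask,
)
from tmaturity.panels import TUBE_IDS
from tmaturity.synthetic import (
    MIN_EVENTS_PER_TUBE, POS_MEAN, NEG_MEAN, iter_cohort,
)

MID = 0.5 * (POS_MEAN + NEG_MEAN)  # transformed-scale positivity midpoint


def zero_dispersion(preset, **over):
    d = preset.to_dict()
    d["dispersion"] = 0.0
    d.update(over)
    return GroupPreset.from_dict(d)


class TestProfiles:
    def test_seed_determinism(self, nbs_preset):
        """Identical (seed, subject) -> identical SubjectProfile."""
        a = make_subject_profile(nbs_preset, 3, seed=7)
        b = make_subject_profile(nbs_preset, 3, seed=7)
        assert a == b
        c = make_subject_profile(nbs_preset, 3, seed=8)
        assert a != c

    def test_zero_dispersion_hits_medians_exactly(self, nbs_preset):
        p0 = zero_dispersion(nbs_preset)
        prof = make_subject_profile(p0, 0, seed=1)
        assert prof.lymph_abs_true == p0.median_lymph_abs
        assert prof.composition_true["leuko"]["lymphocytes"] == pytest.approx(
            p0.median_lymph_pct / 100, abs=1e-12)
        for key in ("TN_CD4", "TD_CD4", "TSCM_CD8", "CD57_CD4", "RTE_CD8"):
            assert prof.true_fraction(key) == pytest.approx(
                p0.pct(key) / 100, abs=1e-9)

    def test_median_recovery_monte_carlo(self, nbs_preset):
        """Medians of drawn truths converge to preset medians (<=5% relative)
        at the default dispersion.  Scaled to 4,000 subjects."""
        n = 4000
        p = GroupPreset.from_dict({**nbs_preset.to_dict(), "n_subjects": n})
        profs = [make_subject_profile(p, i, seed=11) for i in range(n)]
        checks = {"TN_CD4": 11.6, "TCM_CD4": 28.6, "TD_CD4": 13.0,
                  "TSCM_CD4": 2.1, "CD57_CD4": 5.9, "KLRG1_CD8": 88.0,
                  "RTE_CD4": 6.6, "HTEMRA_CD8": 20.6, "T": 52.7, "NK": 32.3}
        for name, median in checks.items():
            got = float(np.median([pr.true_fraction(name) for pr in profs])) * 100
            assert got == pytest.approx(median, rel=0.05), name
        lymph = float(np.median([pr.lymph_abs_true for pr in profs]))
        assert lymph == pytest.approx(1330.0, rel=0.05)

    def test_invalid_presets_rejected(self, nbs_preset):
        with pytest.raises(ConfigurationError):
            GroupPreset.from_dict({**nbs_preset.to_dict(), "dispersion": -1})
        bad = nbs_preset.to_dict()
        bad["subset_median_pct"] = {**bad["subset_median_pct"], "TN_CD4": 120.0}
        with pytest.raises(ConfigurationError):
            GroupPreset.from_dict(bad)
        sums = nbs_preset.to_dict()
        sums["subset_median_pct"] = {**sums["subset_median_pct"],
                                     "T": 60.0, "B": 30.0, "NK": 30.0}
        with pytest.raises(ConfigurationError, match="sum"):
            GroupPreset.from_dict(sums)
        with pytest.raises(ConfigurationError):
            make_subject_profile(nbs_preset, 46, seed=1)  # index out of range


class TestTubes:
    def test_tube2_channel_layout(self, nbs_profile):
        table = simulate_tube(nbs_profile, "2", 1000)
        assert table.markers == ["FSC", "SSC", "CD27", "CD197", "CD3", "CD4",
                                 "CD8", "CD45RA"]

    def test_event_determinism(self, nbs_profile):
        a = simulate_tube(nbs_profile, "3", 2000, default_spillover())
        b = simulate_tube(nbs_profile, "3", 2000, default_spillover())
        np.testing.assert_array_equal(a.data, b.data)
        assert list(a.event_labels) == list(b.event_labels)

    def test_empty_class_produces_no_events(self, nbs_preset):
        """A subset with true fraction 0 never emits events."""
        prof = make_subject_profile(zero_dispersion(nbs_preset), 0, seed=1)
        comp = {k: dict(v) for k, v in prof.composition_true.items()}
        block = comp["tube2_CD4"]
        freed = block.pop("TD_CD4")
        block["TD_CD4"] = 0.0
        block["TEM_CD4"] += freed
        prof = dataclasses.replace(prof, composition_true=comp)
        table = simulate_tube(prof, "2", 50_000)
        assert np.count_nonzero(table.event_labels == "TD_CD4") == 0

    def test_tn_half_fraction_recovered_at_100k(self, nbs_preset):
        """TN_CD4 true fraction 0.5 -> empirical fraction of events above the
        CD27/CD45RA/CD197 positivity midpoints among CD3+CD4+ is 0.5 +- 0.01."""
        over = dict(nbs_preset.to_dict()["subset_median_pct"])
        over.update({"TN_CD4": 50.0, "TCM_CD4": 20.0, "TEM_CD4": 15.0,
                     "LTEMRA_CD4": 5.0, "HTEMRA_CD4": 3.0, "TD_CD4": 5.0})
        p = zero_dispersion(nbs_preset, subset_median_pct=over)
        prof = make_subject_profile(p, 0, seed=2)
        table = simulate_tube(prof, "2", 100_000)
        t = np.arcsinh(table.data / 150.0)
        cd4 = subset_truth_mask(table.event_labels, "CD4")
        pos = np.ones(table.n_events, dtype=bool)
        for m in ("CD27", "CD45RA", "CD197"):
            pos &= t[:, table.marker_index(m)] > MID
        frac = pos[cd4].mean()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_counting_tube_composition(self, nbs_profile):
        table = simulate_tube(nbs_profile, "trucount", 30_000)
        labels = table.event_labels
        beads = np.count_nonzero(labels == "bead")
        # Poisson around beads_per_tube * acquired fraction: thousands of
        # beads, never zero, never the majority
        assert 1000 < beads < table.n_events / 2
        assert table.meta["beads_per_tube"] == 50_000
        assert table.meta["stained_volume_ul"] == 50.0
        # lymphocyte share of leukocyte-like events tracks the subject truth
        lymph = subset_truth_mask(labels, "lymphocytes").sum()
        leuko = lymph + np.count_nonzero(labels == "other_leukocytes")
        truth = nbs_profile.composition_true["leuko"]["lymphocytes"]
        assert lymph / leuko == pytest.approx(truth, rel=0.05)

    def test_tube_consistency_cd4_cd8_ratio(self, nbs_profile):
        """One latent state feeds all tubes: the true CD4:CD8 ratio agrees
        across every tube's event labels."""
        ratios = []
        for tid in TUBE_IDS:
            table = simulate_tube(nbs_profile, tid, 60_000)
            cd4 = subset_truth_mask(table.event_labels, "CD4").sum()
            cd8 = subset_truth_mask(table.event_labels, "CD8").sum()
            ratios.append(cd4 / cd8)
        expected = (nbs_profile.composition_true["T"]["CD4"]
                    / nbs_profile.composition_true["T"]["CD8"])
        np.testing.assert_allclose(ratios, expected, rtol=0.05)

    def test_rejects_unknown_tube_and_bad_n(self, nbs_profile):
        with pytest.raises(ConfigurationError):
            simulate_tube(nbs_profile, "9", 100)
        with pytest.raises(ConfigurationError):
            simulate_tube(nbs_profile, "1", 0)


class TestCohortFiles:
    def test_file_count_and_manifest(self, tmp_path, nbs_preset, control_preset):
        rows = simulate_cohort(nbs_preset, control_preset, seed=5,
                               out_dir=tmp_path, fmt="fcs",
                               n_events=MIN_EVENTS_PER_TUBE, n_subjects=2)
        assert len(rows) == 2 * 2 * 5  # 20 event files for 2 subjects/arm
        manifest = (tmp_path / "manifest.csv").read_text().strip().splitlines()
        assert len(manifest) == 21  # header + 20 rows
        assert len(list((tmp_path / "events").iterdir())) == 20
        groups = {r["group"] for r in rows}
        assert groups == {"nbs", "control"}

    def test_seed_reproducibility_byte_identical(self, tmp_path, nbs_preset):
        for d in ("a", "b"):
            simulate_cohort(nbs_preset, None, seed=9, out_dir=tmp_path / d,
                            fmt="csv", n_events=MIN_EVENTS_PER_TUBE,
                            n_subjects=1)
        assert ((tmp_path / "a" / "manifest.csv").read_bytes()
                == (tmp_path / "b" / "manifest.csv").read_bytes())
        assert ((tmp_path / "a" / "truth" / "nbs_001.csv").read_bytes()
                == (tmp_path / "b" / "truth" / "nbs_001.csv").read_bytes())

    def test_acquisition_floor_enforced(self, tmp_path, nbs_preset):
        with pytest.raises(ConfigurationError, match="floor"):
            simulate_cohort(nbs_preset, None, seed=1, out_dir=tmp_path,
                            n_events=5000, n_subjects=1)

    def test_default_arm_sizes(self, nbs_preset, control_preset):
        """Shipped presets describe two arms of 46 subjects each."""
        assert nbs_preset.n_subjects == 46
        assert control_preset.n_subjects == 46
        ids = [prof.subject_id for prof, _ in iter_cohort(
            nbs_preset, seed=1, n_events=1000, n_subjects=2)]
        assert ids == ["nbs_001", "nbs_002"]
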