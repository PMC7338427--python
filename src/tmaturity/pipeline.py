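"""End-to-end orchestration: simulate or load events, preprocess, gate,
quantify, and compare the two arms, as one reproducible run.

A run is described by a :class:`RunConfig` with exactly one input source —
a cohort manifest on disk, or simulation presets — and is deterministic
given the config (fixed seed, per-subject thresholds).  Per-stage errors
propagate annotated with subject, tube and stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ConfigurationError, DataError
from .cohort_stats import compare_cohorts
from .events_io import EventTable, parse_spillover_keyword, read_events
from .gating import ThresholdSet, builtin_trees, classify_events, \
    estimate_threshold_1d, estimate_thresholds
from .panels import TUBE_IDS
from .preprocess import TransformSpec, compensate, gate_beads, gate_primary, \
    transform
from .quantify import SubjectResult, SubsetStat, absolute_lymphocyte_count, \
    merge_tubes, subset_statistics
from .synthetic import DEFAULT_EVENTS_PER_TUBE, SpilloverMatrix, \
    default_spillover, iter_cohort

__all__ = ["RunConfig", "run_subject", "run_cohort"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run.

    Exactly one of ``manifest`` (path to a cohort manifest CSV) or
    ``presets`` (one or two :class:`GroupPreset` arms to simulate) must be
    given; ``seed`` is mandatory when simulating.  ``spill`` may be
    ``None`` (no compensation), ``"default"`` (the shipped matrix),
    ``"fcs-keyword"`` (read per file), or an explicit
    :class:`SpilloverMatrix`.
    """

    manifest: str | Path | None = None
    presets: tuple = ()
    seed: int | None = None
    n_events: int = DEFAULT_EVENTS_PER_TUBE
    spill: object = "default"
    transform_spec: TransformSpec = field(default_factory=TransformSpec)
    threshold_mode: str = "per-subject"
    n_subjects: int | None = None       # per-arm override (simulation only)
    out_dir: str | Path | None = None
    write_labels: bool = False

    def __post_init__(self) -> None:
        if (self.manifest is None) == (not self.presets):
            raise ConfigurationError(
                "exactly one input source: manifest OR presets")
        if self.presets and self.seed is None:
            raise ConfigurationError("seed is required when simulating")
        if self.threshold_mode not in ("per-subject", "pooled"):
            raise ConfigurationError(
                f"unknown threshold_mode {self.threshold_mode!r}")
        if len(self.presets) > 2:
            raise ConfigurationError("at most two simulation arms")

    # -- config identity -------------------------------------------------
    def to_dict(self) -> dict:
        spill = self.spill
        if isinstance(spill, SpilloverMatrix):
            spill = {"channels": list(spill.channels),
                     "matrix": spill.matrix.tolist()}
        return {
            "manifest": str(self.manifest) if self.manifest else None,
            "presets": [p.to_dict() for p in self.presets],
            "seed": self.seed, "n_events": self.n_events, "spill": spill,
            "transform": {"method": self.transform_spec.method,
                          "cofactor": self.transform_spec.cofactor,
                          "overrides": dict(self.transform_spec.overrides)},
            "threshold_mode": self.threshold_mode,
            "n_subjects": self.n_subjects,
            "write_labels": self.write_labels,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_spill(config: RunConfig, table: EventTable):
    if config.spill is None:
        return None
    if isinstance(config.spill, SpilloverMatrix):
        return config.spill
    if config.spill == "default":
        return default_spillover()
    if config.spill == "fcs-keyword":
        kw = table.meta.get("spillover_keyword")
        if kw is None:
            raise ConfigurationError(
                f"tube {table.meta.get('tube_id')!r} carries no $SPILLOVER keyword")
        names, m = parse_spillover_keyword(kw)
        return SpilloverMatrix(m, tuple(names))
    raise ConfigurationError(f"unknown spill source {config.spill!r}")


def _process_tube(table: EventTable, tube_id: str, tree, config: RunConfig,
                  pooled_thresholds: ThresholdSet | None = None):
    """Preprocess + gate + classify one tube.  Returns the pieces the
    quantification stage needs."""
    stage = "compensate"
    try:
        if table.transform_state == "raw":
            spill = _resolve_spill(config, table)
            if spill is not None:
                table = compensate(table, spill)
        stage = "transform"
        if table.transform_state != "transformed":
            table = transform(table, config.transform_spec)
        stage = "gate_beads"
        beads = gate_beads(table) if tube_id == "trucount" else None
        stage = "gate_primary"
        primary = gate_primary(table, tree.primary_mode)
        if beads is not None:
            primary &= ~beads
        stage = "estimate_thresholds"
        if pooled_thresholds is not None:
            thresholds = pooled_thresholds
        else:
            thresholds = estimate_thresholds(table, tree.markers, within=primary)
        stage = "classify"
        labels = classify_events(table, tree, thresholds, primary)
    except Exception as exc:
        raise DataError(f"tube {tube_id} stage {stage}: {exc}") from exc
    return table, beads, primary, thresholds, labels


def _leukocyte_gate(table: EventTable, beads: np.ndarray):
    """CD45+ non-bead events (the denominator of the lymphocyte %).

    Unlike marker positivity, this gate specifically separates CD45-
    debris from everything cellular, so the cutoff is the valley directly
    above the *lowest* CD45 density mode (distinct leukocyte lineages may
    form several brighter modes).  With a single mode no debris is
    discernible and every non-bead event counts as a leukocyte.
    """
    from ._density import find_modes_1d, smoothed_density_1d

    cd45 = table.column("CD45")[~beads]
    centers, dens, _ = smoothed_density_1d(cd45)
    modes = find_modes_1d(dens)
    if len(modes) >= 2:
        a, b = modes[0], modes[1]
        cutoff = float(centers[a + int(np.argmin(dens[a:b + 1]))])
    else:
        cutoff = -np.inf
    leuko = (table.column("CD45") > cutoff) & ~beads
    return leuko, cutoff


def process_subject_tables(subject_id: str, group: str, tables: dict,
                           config: RunConfig,
                           pooled: dict | None = None) -> SubjectResult:
    """Run preprocess -> gate -> quantify for one subject's five tubes."""
    missing = [t for t in TUBE_IDS if t not in tables]
    if missing:
        raise DataError(f"subject {subject_id}: missing tube "
                        + ", ".join(repr(m) for m in missing))
    trees = builtin_trees()
    tube_results: dict = {}
    thresholds_used: dict = {}

    # counting tube first: it anchors every absolute count
    tid = "trucount"
    table, beads, primary, thresholds, labels = _process_tube(
        tables[tid], tid, trees[tid], config,
        pooled.get(tid) if pooled else None)
    thresholds_used[tid] = thresholds
    try:
        leuko, _ = _leukocyte_gate(table, beads)
        lymph_abs = absolute_lymphocyte_count(
            table, int(primary.sum()), int(beads.sum()))
    except Exception as exc:
        raise DataError(f"subject {subject_id} tube {tid} stage quantify: "
                        f"{exc}") from exc
    tres = subset_statistics(labels, trees[tid], lymph_abs, primary_abs=lymph_abs)
    tres.lymph_abs = lymph_abs
    n_leuko = int(leuko.sum())
    tres.stats["lymphocytes"] = SubsetStat(
        n_events=int(primary.sum()), n_parent=n_leuko,
        pct_of_parent=(100.0 * primary.sum() / n_leuko) if n_leuko else None,
        abs_count=lymph_abs, low_confidence=n_leuko < 50, tube_id=tid)
    tube_results[tid] = tres
    t_abs = tres.stats["T"].abs_count

    for tid in ("1", "2", "3", "4"):
        table, _, primary, thresholds, labels = _process_tube(
            tables[tid], tid, trees[tid], config,
            pooled.get(tid) if pooled else None)
        thresholds_used[tid] = thresholds
        tube_results[tid] = subset_statistics(
            labels, trees[tid], lymph_abs, primary_abs=t_abs)
        log.info("subject=%s tube=%s events=%d primary=%d", subject_id, tid,
                 table.n_events, tube_results[tid].primary_events)

    result = merge_tubes(tube_results, subject_id, group)
    if config.out_dir is not None:
        _write_subject_artifacts(result, thresholds_used, Path(config.out_dir))
    return result


def _write_subject_artifacts(result: SubjectResult, thresholds: dict,
                             out: Path) -> None:
    sub = out / "subjects"
    sub.mkdir(parents=True, exist_ok=True)
    rows = [{"tube_id": tid, "marker": m, "cutoff": ts.cutoffs[m],
             "provenance": ts.provenance[m]}
            for tid, ts in thresholds.items() for m in ts.cutoffs]
    pd.DataFrame(rows).to_csv(sub / f"{result.subject_id}_thresholds.csv",
                              index=False)
    tally_rows = [{"tube_id": tid, "gate": g, "n_events": n}
                  for tid, tallies in result.tube_tallies.items()
                  for g, n in tallies.items()]
    pd.DataFrame(tally_rows).to_csv(sub / f"{result.subject_id}_tallies.csv",
                                    index=False)


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def _iter_subjects(config: RunConfig):
    """Yield (subject_id, group, tables) from whichever source is configured."""
    if config.presets:
        for preset in config.presets:
            spill = config.spill
            spill_mat = default_spillover() if spill == "default" else (
                spill if isinstance(spill, SpilloverMatrix) else None)
            for profile, tables in iter_cohort(preset, config.seed,
                                               config.n_events, spill_mat,
                                               config.n_subjects):
                yield profile.subject_id, profile.group, tables
        return
    manifest = pd.read_csv(config.manifest)
    base = Path(config.manifest).parent
    for subject_id, grp in manifest.groupby("subject_id", sort=True):
        tables = {str(row.tube_id): read_events(base / row.events_path)
                  for row in grp.itertuples()}
        yield str(subject_id), str(grp["group"].iloc[0]), tables


def _pooled_thresholds(config: RunConfig, per_tube_sample: int = 4000) -> dict:
    """Cohort-pooled thresholds: one cutoff per marker per tube, estimated
    from primary-gated events pooled across subjects."""
    trees = builtin_trees()
    pools: dict = {tid: {m: [] for m in trees[tid].markers} for tid in TUBE_IDS}
    for subject_id, _, tables in _iter_subjects(config):
        for tid in TUBE_IDS:
            tree = trees[tid]
            table, beads, primary, _, _ = _process_tube(
                tables[tid], tid, tree, config,
                pooled_thresholds=ThresholdSet({m: 0.0 for m in tree.markers}))
            idx = np.flatnonzero(primary)[:per_tube_sample]
            for m in tree.markers:
                pools[tid][m].append(table.column(m)[idx])
    out = {}
    for tid, by_marker in pools.items():
        cutoffs, prov = {}, {}
        for m, chunks in by_marker.items():
            cutoffs[m], prov[m] = estimate_threshold_1d(np.concatenate(chunks))
        out[tid] = ThresholdSet(cutoffs, prov)
    return out


def run_subject(config: RunConfig, subject_id: str) -> SubjectResult:
    """Process a single subject end to end (all five tubes)."""
    for sid, group, tables in _iter_subjects(config):
        if sid == subject_id:
            return process_subject_tables(sid, group, tables, config)
    raise ConfigurationError(f"subject {subject_id!r} not found in input source")


def run_cohort(config: RunConfig):
    """Process every subject and compare the arms.

    Returns ``(results_by_group, comparison, run_manifest)`` where
    ``comparison`` is the :func:`compare_cohorts` table (None for a
    single-arm run).  Aborts if more than 20% of subjects fail.
    """
    t0 = time.time()
    pooled = _pooled_thresholds(config) if config.threshold_mode == "pooled" \
        else None
    results: dict[str, list[SubjectResult]] = {}
    failures: list[tuple[str, str]] = []
    n_total = 0
    for subject_id, group, tables in _iter_subjects(config):
        n_total += 1
        try:
            res = process_subject_tables(subject_id, group, tables, config,
                                         pooled)
            results.setdefault(group, []).append(res)
        except Exception as exc:  # noqa: BLE001 - summarised and re-raised
            log.error("subject %s failed: %s", subject_id, exc)
            failures.append((subject_id, str(exc)))
    if n_total == 0:
        raise ConfigurationError("input source yielded no subjects")
    if len(failures) > 0.2 * n_total:
        summary = "; ".join(f"{s}: {m}" for s, m in failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{n_total} subjects failed - aborting ({summary})")
    for subject_id, msg in failures:
        warnings.warn(f"subject {subject_id} failed and was skipped: {msg}",
                      stacklevel=2)

    groups = list(results)
    comparison = None
    if len(groups) == 2:
        comparison = compare_cohorts(results[groups[0]], results[groups[1]])

    run_manifest = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "version": __version__, "n_subjects": {g: len(v)
                                               for g, v in results.items()},
        "n_failed": len(failures), "runtime_s": round(time.time() - t0, 2),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [row for rs in results.values() for r in rs for row in r.to_rows()]
        pd.DataFrame(rows).to_csv(out / "subject_results.csv", index=False)
        if comparison is not None:
            comparison.to_csv(out / "cohort_comparison.csv", index=False)
        (out / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")
    return results, comparison, run_manifest
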