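"""Per-subject quantification: bead-based absolute counts and the
proportion chain.

The counting tube contains a known number of beads in a known stained
volume; the absolute lymphocyte concentration is

    lymph_abs = (lymph_events / bead_events) * beads_per_tube / volume_ul

(cells/ul).  Every other absolute count follows the proportion chain: the
subset's share of its tube's primary gate times the absolute size of that
primary gate, anchored to the bead-derived lymphocyte count.  Percentages
are reported relative to each subset's immediate parent gate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError, DataError, MergeError
from .events_io import EventTable
from .gating import GateTree

__all__ = [
    "SubsetStat", "TubeResult", "SubjectResult",
    "absolute_lymphocyte_count", "subset_statistics", "merge_tubes",
    "MIN_PARENT_EVENTS",
]

log = logging.getLogger(__name__)

#: Gates with fewer parent events than this are flagged low-confidence.
MIN_PARENT_EVENTS = 50


@dataclass(frozen=True)
class SubsetStat:
    """Relative and absolute size of one subset for one subject."""

    n_events: int
    n_parent: int
    pct_of_parent: float | None      # None when the parent gate is empty
    abs_count: float | None          # cells/ul
    low_confidence: bool
    tube_id: str

    def rounded(self) -> tuple:
        """(pct to one decimal, abs to nearest cell/ul) - reporting precision."""
        pct = None if self.pct_of_parent is None else round(self.pct_of_parent, 1)
        ab = None if self.abs_count is None else round(self.abs_count)
        return pct, ab


@dataclass
class TubeResult:
    """Quantification of one tube: subset stats plus raw gate tallies."""

    tube_id: str
    stats: dict                      # subset name -> SubsetStat (reported only)
    tallies: dict                    # every gate -> event count
    primary_events: int
    lymph_abs: float | None = None   # counting tube only


@dataclass
class SubjectResult:
    """Merged per-subject output across all tubes."""

    subject_id: str
    group: str
    lymph_abs: float
    stats: dict = field(default_factory=dict)
    tube_tallies: dict = field(default_factory=dict)

    def pct(self, subset: str) -> float | None:
        return self.stats[subset].pct_of_parent

    def abs_count(self, subset: str) -> float | None:
        return self.stats[subset].abs_count

    def to_rows(self) -> list:
        rows = []
        for name, st in self.stats.items():
            pct, ab = st.rounded()
            rows.append({"subject_id": self.subject_id, "group": self.group,
                         "subset": name, "tube_id": st.tube_id,
                         "n_events": st.n_events, "n_parent": st.n_parent,
                         "pct_of_parent": pct, "abs_count": ab,
                         "low_confidence": st.low_confidence})
        return rows


def absolute_lymphocyte_count(trucount_table: EventTable, lymph_events: int,
                              bead_events: int) -> float:
    """Bead-ratio absolute lymphocyte count (cells/ul) from the counting tube."""
    meta = trucount_table.meta
    beads_per_tube = meta.get("beads_per_tube")
    volume = meta.get("stained_volume_ul")
    if beads_per_tube is None or volume is None:
        raise ConfigurationError(
            "counting tube metadata must include beads_per_tube and "
            "stained_volume_ul")
    if bead_events <= 0:
        raise DataError(
            f"no bead events detected in tube {meta.get('tube_id', '?')!r}; "
            "cannot anchor absolute counts (check bead gate and staining)")
    if lymph_events < 0:
        raise DataError("negative lymphocyte event count")
    return lymph_events / bead_events * beads_per_tube / volume


def subset_statistics(labels: dict, tree: GateTree, lymph_abs: float,
                      primary_abs: float | None = None) -> TubeResult:
    """Relative and absolute subset sizes from classified event masks.

    ``labels`` is the output of :func:`tmaturity.gating.classify_events`.
    ``pct_of_parent`` is ``100 * subset / parent``; the absolute count is
    the subset's share of the tube's primary gate times ``primary_abs``
    (the absolute size of the primary gate in cells/ul — ``lymph_abs``
    itself for the lymphocyte-gated counting tube, the T-cell absolute
    count for CD3-gated panel tubes).  An empty parent yields a missing
    (None) percentage with a warning, never a silent zero.
    """
    if tree.primary_name not in labels:
        raise ConfigurationError(
            f"labels lack the primary gate {tree.primary_name!r}")
    anchor = lymph_abs if primary_abs is None else primary_abs
    tallies = {name: int(np.count_nonzero(mask)) for name, mask in labels.items()}
    n_primary = tallies[tree.primary_name]
    stats: dict = {}
    for s in tree.subsets:
        n = tallies[s.name]
        n_parent = tallies[s.parent]
        if n_parent == 0:
            warnings.warn(
                f"parent gate {s.parent!r} of {s.name!r} is empty in tube "
                f"{tree.tube_id}; percentage reported as missing", stacklevel=2)
            pct = None
        else:
            pct = 100.0 * n / n_parent
        ab = (n / n_primary * anchor) if n_primary > 0 else None
        if not s.report:
            continue
        stats[s.name] = SubsetStat(
            n_events=n, n_parent=n_parent, pct_of_parent=pct, abs_count=ab,
            low_confidence=n_parent < MIN_PARENT_EVENTS, tube_id=tree.tube_id)
    return TubeResult(tube_id=tree.tube_id, stats=stats, tallies=tallies,
                      primary_events=n_primary)


def merge_tubes(tube_results: dict, subject_id: str, group: str = "") -> SubjectResult:
    """Union the per-tube results of one subject into a single record.

    The counting tube is mandatory (it anchors ``lymph_abs``); a missing
    panel tube degrades gracefully with a warning.  The same reported
    subset arriving from two tubes is an error — tube-specific definitions
    (e.g. CCR7-based vs CD95-based RA+ effectors) are deliberately kept
    distinct and must never collide.
    """
    if "trucount" not in tube_results:
        raise ConfigurationError(
            f"subject {subject_id!r}: counting tube result missing; absolute "
            "counts cannot be anchored")
    tru = tube_results["trucount"]
    if tru.lymph_abs is None:
        raise ConfigurationError("counting-tube result lacks lymph_abs")
    missing = [tid for tid in ("1", "2", "3", "4") if tid not in tube_results]
    if missing:
        log.warning("subject %s: missing tube(s) %s; their subsets will be absent",
                    subject_id, ", ".join(missing))
    result = SubjectResult(subject_id=subject_id, group=group,
                           lymph_abs=tru.lymph_abs)
    for tid, tres in sorted(tube_results.items()):
        result.tube_tallies[tid] = dict(tres.tallies)
        for name, stat in tres.stats.items():
            if name in result.stats:
                raise MergeError(
                    f"subset {name!r} produced by both tube "
                    f"{result.stats[name].tube_id!r} and tube {tid!r}")
            result.stats[name] = stat
    return result
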