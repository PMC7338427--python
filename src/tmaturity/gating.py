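"""Declarative hierarchical gating of T-cell maturation subsets.

Subset phenotypes follow the standard maturation scheme on CD27, CD45RA,
CD197 (CCR7) and CD95:

* TN (naive): CD27+ CD45RA+ CD197+
* TSCM (stem-cell-like memory): CD27+ CD45RA+ CD95+
* TCM (central memory): CD27+ CD45RA- CD197+
* TEM (effector memory): CD27+ CD45RA- CD197-
* L-TEMRA (low-differentiated RA+ effector): CD27+ CD45RA+ CD197-
* H-TEMRA (high-differentiated RA+ effector): CD27- CD45RA+ CD197-
* TEMRA (CD95-defined RA+ effector): CD27- CD45RA+ CD95+
* TD (terminally differentiated): CD27- CD45RA- CD197-
* RTE (recent thymic emigrants, CD4 branch): CD31+ CD45RA+
* senescence/exhaustion: CD57+, KLRG1+, PD1(CD279)+ on the whole CD4+/CD8+
  populations

The CD27- CD45RA+/- CD197+ phenotypes carry no standard name; they are kept
as explicit ``unclassified_CD27neg_CCR7pos_*`` buckets so that event
conservation can be asserted.  The CD4 and CD8 branches use identical logic.

Positivity convention (fixed): intensity strictly greater than the cutoff is
positive; an exact tie is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._density import find_modes_1d, smoothed_density_1d
from ._errors import ConfigurationError, InsufficientEventsError
from .events_io import EventTable, resolve_marker
from .panels import PANEL, canonical_marker

__all__ = [
    "SubsetDef", "GateTree", "ThresholdSet",
    "estimate_thresholds", "estimate_threshold_1d", "classify_events",
    "builtin_trees", "MIN_GATE_EVENTS",
]

log = logging.getLogger(__name__)

#: Fewer primary-gate events than this and threshold estimation refuses.
MIN_GATE_EVENTS = 500


@dataclass(frozen=True)
class SubsetDef:
    """One subset: a parent reference plus (marker, polarity) requirements.

    ``parent`` is either another subset name or the tree's primary-gate
    name.  ``report=False`` marks structural nodes (per-tube CD4/CD8 gates,
    CD27 branches) that are not part of the merged per-subject output.
    """

    name: str
    parent: str
    requirements: tuple[tuple[str, str], ...]
    report: bool = True

    def __post_init__(self) -> None:
        markers = [m for m, _ in self.requirements]
        if len(set(markers)) != len(markers):
            raise ConfigurationError(f"duplicate marker in subset {self.name!r}")
        if any(pol not in ("+", "-") for _, pol in self.requirements):
            raise ConfigurationError(f"polarity must be '+'/'-' in {self.name!r}")


@dataclass(frozen=True)
class GateTree:
    """Ordered subset hierarchy for one tube, rooted at the primary gate."""

    tube_id: str
    primary_name: str          # e.g. "lymphocytes" or "T"
    primary_mode: str          # "cd45_ssc" | "cd3_ssc"
    subsets: tuple[SubsetDef, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.subsets]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate subset names in tube {self.tube_id}")
        known = {self.primary_name}
        for s in self.subsets:
            if s.parent not in known:
                raise ConfigurationError(
                    f"subset {s.name!r} references undefined parent {s.parent!r}")
            known.add(s.name)
        if self.tube_id in PANEL:
            tube_markers = {canonical_marker(m) for m in PANEL[self.tube_id].markers}
            for s in self.subsets:
                for m, _ in s.requirements:
                    if canonical_marker(m) not in tube_markers:
                        raise ConfigurationError(
                            f"subset {s.name!r} uses marker {m!r} absent from "
                            f"tube {self.tube_id}")

    @property
    def markers(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.subsets:
            for m, _ in s.requirements:
                cm = canonical_marker(m)
                if cm not in seen:
                    seen.append(cm)
        return tuple(seen)

    def parent_of(self, name: str) -> str:
        for s in self.subsets:
            if s.name == name:
                return s.parent
        raise KeyError(name)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tube_id": self.tube_id,
            "primary_name": self.primary_name,
            "primary_mode": self.primary_mode,
            "subsets": [
                {"name": s.name, "parent": s.parent,
                 "requirements": [[m, p] for m, p in s.requirements],
                 "report": s.report}
                for s in self.subsets
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateTree":
        return cls(
            tube_id=str(d["tube_id"]),
            primary_name=d["primary_name"],
            primary_mode=d["primary_mode"],
            subsets=tuple(
                SubsetDef(s["name"], s["parent"],
                          tuple((m, p) for m, p in s["requirements"]),
                          bool(s.get("report", True)))
                for s in d["subsets"]
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GateTree":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class ThresholdSet:
    """Per-marker positivity cutoffs on the transformed scale.

    ``provenance[marker]`` records how each cutoff was obtained:
    ``"valley"`` (bimodal density), ``"quantile-fallback"`` (unimodal) or
    ``"user"``.
    """

    cutoffs: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, c in self.cutoffs.items():
            if not np.isfinite(c):
                raise ConfigurationError(f"non-finite cutoff for {m!r}")
            self.provenance.setdefault(m, "user")

    def __getitem__(self, marker: str) -> float:
        return self.cutoffs[canonical_marker(marker)]

    def __contains__(self, marker: str) -> bool:
        return canonical_marker(marker) in self.cutoffs


def estimate_threshold_1d(values: np.ndarray) -> tuple[float, str]:
    """Positivity cutoff for one marker from its transformed intensities.

    Bimodal density: the cutoff is the deepest valley between the two
    highest well-separated modes.  Unimodal: fall back to the midpoint of
    the mode and the 99.5th percentile, flagged ``"quantile-fallback"``.
    """
    values = np.asarray(values, dtype=float)
    centers, dens, _ = smoothed_density_1d(values)
    modes = find_modes_1d(dens)
    if len(modes) >= 2:
        top_two = sorted(sorted(modes, key=lambda i: dens[i])[-2:])
        a, b = top_two
        valley = a + int(np.argmin(dens[a:b + 1]))
        return float(centers[valley]), "valley"
    mode_x = float(centers[modes[0]]) if modes else float(np.median(values))
    q995 = float(np.quantile(values, 0.995))
    return 0.5 * (mode_x + q995), "quantile-fallback"


def estimate_thresholds(table: EventTable, markers, within=None) -> ThresholdSet:
    """Estimate positivity cutoffs for ``markers`` on a transformed table.

    ``within`` restricts estimation to a boolean event mask (normally the
    primary gate, mirroring per-sample manual gate placement).  Requires at
    least :data:`MIN_GATE_EVENTS` events in the mask.
    """
    if table.transform_state != "transformed":
        raise ConfigurationError("estimate_thresholds() expects a transformed table")
    mask = np.ones(table.n_events, dtype=bool) if within is None else np.asarray(within)
    n = int(mask.sum())
    if n < MIN_GATE_EVENTS:
        raise InsufficientEventsError(
            f"only {n} events in the primary gate of tube "
            f"{table.meta.get('tube_id', '?')!r} (< {MIN_GATE_EVENTS})")
    cutoffs, prov = {}, {}
    for marker in markers:
        cm = canonical_marker(marker)
        vals = table.data[mask, resolve_marker(table, cm)]
        cut, how = estimate_threshold_1d(vals)
        cutoffs[cm] = cut
        prov[cm] = how
        if how != "valley":
            log.debug("threshold for %s on tube %s: %s at %.3f", cm,
                      table.meta.get("tube_id"), how, cut)
    return ThresholdSet(cutoffs, prov)


def classify_events(table: EventTable, tree: GateTree, thresholds: ThresholdSet,
                    primary_mask: np.ndarray) -> dict:
    """Classify every event through ``tree`` against ``thresholds``.

    Returns ``{subset_name: boolean mask}`` including the primary gate under
    ``tree.primary_name``.  An event belongs to a subset iff it satisfies
    the whole parent chain and every (marker, polarity) requirement;
    intensity strictly above the cutoff is positive, a tie is negative.
    Masks may overlap across subsets (e.g. TN and the senescence gates).
    """
    for m in tree.markers:
        if m not in thresholds:
            raise ConfigurationError(
                f"thresholds missing marker {m!r} required by tube {tree.tube_id}")
    primary_mask = np.asarray(primary_mask, dtype=bool)
    if primary_mask.shape != (table.n_events,):
        raise ConfigurationError("primary_mask length mismatch")
    labels: dict = {tree.primary_name: primary_mask}
    for s in tree.subsets:
        mask = labels[s.parent].copy()
        for marker, pol in s.requirements:
            col = table.data[:, resolve_marker(table, marker)]
            positive = col > thresholds[marker]
            mask &= positive if pol == "+" else ~positive
        labels[s.name] = mask
    return labels


# ---------------------------------------------------------------------------
# built-in gate trees
# ---------------------------------------------------------------------------

def _maturation_subsets(x: str) -> list[SubsetDef]:
    """Tube-2 maturation scheme for one branch (x = "CD4" | "CD8")."""
    return [
        SubsetDef(f"CD27pos_{x}", x, (("CD27", "+"),), report=False),
        SubsetDef(f"CD27neg_{x}", x, (("CD27", "-"),), report=False),
        SubsetDef(f"TN_{x}", x, (("CD27", "+"), ("CD45RA", "+"), ("CD197", "+"))),
        SubsetDef(f"TCM_{x}", x, (("CD27", "+"), ("CD45RA", "-"), ("CD197", "+"))),
        SubsetDef(f"TEM_{x}", x, (("CD27", "+"), ("CD45RA", "-"), ("CD197", "-"))),
        SubsetDef(f"LTEMRA_{x}", x, (("CD27", "+"), ("CD45RA", "+"), ("CD197", "-"))),
        SubsetDef(f"HTEMRA_{x}", x, (("CD27", "-"), ("CD45RA", "+"), ("CD197", "-"))),
        SubsetDef(f"TD_{x}", x, (("CD27", "-"), ("CD45RA", "-"), ("CD197", "-"))),
        SubsetDef(f"unclassified_CD27neg_CCR7pos_RApos_{x}", x,
                  (("CD27", "-"), ("CD45RA", "+"), ("CD197", "+"))),
        SubsetDef(f"unclassified_CD27neg_CCR7pos_RAneg_{x}", x,
                  (("CD27", "-"), ("CD45RA", "-"), ("CD197", "+"))),
    ]


def builtin_trees() -> dict:
    """The five shipped gate trees, keyed by tube id.

    The counting tube gates lymphocytes on CD45/SSC and yields the basic
    subsets (T, B, NK, CD4, CD8); panel tubes 1-4 gate T cells on CD3/SSC
    and yield the maturation, stem-memory and senescence/exhaustion
    subsets, identically for the CD4 and CD8 branches.
    """
    structural_branches = [
        SubsetDef("CD4", "T", (("CD4", "+"),), report=False),
        SubsetDef("CD8", "T", (("CD8", "+"),), report=False),
    ]
    trees = {
        "trucount": GateTree("trucount", "lymphocytes", "cd45_ssc", (
            SubsetDef("T", "lymphocytes", (("CD3", "+"),)),
            SubsetDef("B", "lymphocytes", (("CD19", "+"),)),
            SubsetDef("NK", "lymphocytes", (("CD3", "-"), ("CD16/56", "+"))),
            SubsetDef("CD4", "T", (("CD4", "+"),)),
            SubsetDef("CD8", "T", (("CD8", "+"),)),
        )),
        "1": GateTree("1", "T", "cd3_ssc", tuple(structural_branches + [
            SubsetDef("RTE_CD4", "CD4", (("CD31", "+"), ("CD45RA", "+"))),
            SubsetDef("RTE_CD8", "CD8", (("CD31", "+"), ("CD45RA", "+"))),
        ])),
        "2": GateTree("2", "T", "cd3_ssc", tuple(
            structural_branches
            + _maturation_subsets("CD4") + _maturation_subsets("CD8"))),
        "3": GateTree("3", "T", "cd3_ssc", tuple(structural_branches + [
            SubsetDef("TSCM_CD4", "CD4",
                      (("CD27", "+"), ("CD45RA", "+"), ("CD95", "+"))),
            SubsetDef("TEMRA_CD4", "CD4",
                      (("CD27", "-"), ("CD45RA", "+"), ("CD95", "+"))),
            SubsetDef("TSCM_CD8", "CD8",
                      (("CD27", "+"), ("CD45RA", "+"), ("CD95", "+"))),
            SubsetDef("TEMRA_CD8", "CD8",
                      (("CD27", "-"), ("CD45RA", "+"), ("CD95", "+"))),
        ])),
        "4": GateTree("4", "T", "cd3_ssc", tuple(structural_branches + [
            SubsetDef("CD57_CD4", "CD4", (("CD57", "+"),)),
            SubsetDef("KLRG1_CD4", "CD4", (("KLRG1", "+"),)),
            SubsetDef("PD1_CD4", "CD4", (("CD279", "+"),)),
            SubsetDef("CD57_CD8", "CD8", (("CD57", "+"),)),
            SubsetDef("KLRG1_CD8", "CD8", (("KLRG1", "+"),)),
            SubsetDef("PD1_CD8", "CD8", (("CD279", "+"),)),
        ])),
    }
    return trees
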