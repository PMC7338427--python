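"""Antibody panel definitions for the five-tube T-cell maturation assay.

The assay uses four 6-colour maturation tubes plus one bead-containing
(Trucount-style) tube for absolute counts.  Every tube carries forward and
side scatter plus six fluorescence detectors (FITC, PE, PerCP, APC,
APC-Cy7, PE-Cy7).  The marker layout per tube is fixed by the assay design:

=========  =======  ========  =======  ======  ========  ========
tube       FITC     PE        PerCP    APC     APC-Cy7   PE-Cy7
=========  =======  ========  =======  ======  ========  ========
trucount   CD3      CD16/56   CD45     CD19    CD8       CD4
1          CD45RO   CD31      CD3      CD4     CD8       CD45RA
2          CD27     CD197     CD3      CD4     CD8       CD45RA
3          CD27     CD8       CD3      CD95    CD4       CD45RA
4          KLRG1    CD8       CD3      CD57    CD4       CD279
=========  =======  ========  =======  ======  ========  ========

Markers are stored under canonical names; :data:`MARKER_ALIASES` maps the
common synonyms (CCR7 = CD197, PD1 = CD279, the CD16/CD56 composite) onto
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Channel",
    "TubeDef",
    "PANEL",
    "TUBE_IDS",
    "FLUOR_CHANNELS",
    "SCATTER_CHANNELS",
    "MARKER_ALIASES",
    "canonical_marker",
]

#: Detector (channel id) order shared by every tube.
SCATTER_CHANNELS: tuple[str, ...] = ("FSC-A", "SSC-A")
FLUOR_CHANNELS: tuple[str, ...] = (
    "FITC-A", "PE-A", "PerCP-A", "APC-A", "APC-Cy7-A", "PE-Cy7-A",
)

#: Synonym -> canonical marker name.  The CD16/CD56 composite antibody is
#: treated as a single channel ("CD16/56").
MARKER_ALIASES: dict[str, str] = {
    "CCR7": "CD197",
    "PD1": "CD279",
    "PD-1": "CD279",
    "CD16/CD56": "CD16/56",
    "CD16+CD56": "CD16/56",
    "CD16+56": "CD16/56",
}


def canonical_marker(name: str) -> str:
    """Map a marker name or known alias onto its canonical form (case-insensitive)."""
    key = name.strip()
    for alias, target in MARKER_ALIASES.items():
        if key.casefold() == alias.casefold():
            return target
    return key


@dataclass(frozen=True)
class Channel:
    """One detector: instrument channel id, fluorochrome, and the marker it carries."""

    name: str           # e.g. "FITC-A"
    fluorochrome: str   # e.g. "FITC"; "" for scatter
    marker: str         # e.g. "CD27"; "FSC"/"SSC" for scatter


@dataclass(frozen=True)
class TubeDef:
    """A stained tube: its id, channel layout and staining metadata."""

    tube_id: str
    channels: tuple[Channel, ...]
    stained_volume_ul: float
    beads_per_tube: int | None = None
    extras: dict = field(default_factory=dict, compare=False)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(c.marker for c in self.channels)

    @property
    def fluor_markers(self) -> tuple[str, ...]:
        return tuple(c.marker for c in self.channels if c.name in FLUOR_CHANNELS)


def _tube(tube_id: str, fluor_markers: list[str], volume: float,
          beads: int | None = None) -> TubeDef:
    chans = [Channel("FSC-A", "", "FSC"), Channel("SSC-A", "", "SSC")]
    for cid, marker in zip(FLUOR_CHANNELS, fluor_markers):
        chans.append(Channel(cid, cid[:-2], marker))
    return TubeDef(tube_id, tuple(chans), volume, beads)


#: Default bead load of the counting tube (lot-dependent in practice).
DEFAULT_BEADS_PER_TUBE = 50_000

PANEL: dict[str, TubeDef] = {
    "trucount": _tube("trucount", ["CD3", "CD16/56", "CD45", "CD19", "CD8", "CD4"],
                      volume=50.0, beads=DEFAULT_BEADS_PER_TUBE),
    "1": _tube("1", ["CD45RO", "CD31", "CD3", "CD4", "CD8", "CD45RA"], volume=100.0),
    "2": _tube("2", ["CD27", "CD197", "CD3", "CD4", "CD8", "CD45RA"], volume=100.0),
    "3": _tube("3", ["CD27", "CD8", "CD3", "CD95", "CD4", "CD45RA"], volume=100.0),
    "4": _tube("4", ["KLRG1", "CD8", "CD3", "CD57", "CD4", "CD279"], volume=100.0),
}

TUBE_IDS: tuple[str, ...] = tuple(PANEL)
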