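"""Spillover compensation, intensity transforms and the primary lymphocyte/
T-cell gate.

The manual steps of clinical gating (scatter-based lymphocyte gate on
CD45/SSC, T-cell gate on CD3/SSC) are replaced by a deterministic,
parameter-light density surrogate: a smoothed 2-D histogram is segmented
into basins of attraction of its modes, and the basin of the marker-bright,
low-side-scatter mode is retained.  This is a stand-in for, not a
reconstruction of, instrument-software gates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._density import density_grid_2d, grid_basins, merge_shallow_basins
from ._errors import ConfigurationError, NumericError
from .events_io import EventTable, resolve_marker

__all__ = [
    "TransformSpec", "DEFAULT_COFACTOR", "compensate", "transform",
    "gate_primary", "gate_beads", "BEAD_CUTOFF", "PRIMARY_MARKER_FLOOR",
]

log = logging.getLogger(__name__)

#: Default arcsinh cofactor for digital flow cytometers.  The CyTOF
#: convention (cofactor 5) is far too aggressive for fluorescence data;
#: 150 places the transition region at typical autofluorescence levels.
DEFAULT_COFACTOR = 150.0

#: Transformed-scale level above which (on every fluorescence channel
#: simultaneously) an event is called a counting bead.  Beads are engineered
#: to be brighter than any cellular positive on all detectors.
BEAD_CUTOFF = 6.0

#: Minimum transformed CD45/CD3 signal for a density mode to be a credible
#: leukocyte/T-cell cluster; modes below it are debris.
PRIMARY_MARKER_FLOOR = 2.0


@dataclass(frozen=True)
class TransformSpec:
    """Per-channel monotone transform specification.

    method : ``"arcsinh"`` (default) or ``"logicle"`` (a display-scale
        approximation, ``arcsinh(x/cofactor)/ln 10``; decades rather than
        natural units).
    cofactor : shared positive cofactor.
    overrides : optional marker -> cofactor map.
    """

    method: str = "arcsinh"
    cofactor: float = DEFAULT_COFACTOR
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("arcsinh", "logicle"):
            raise ConfigurationError(f"unknown transform method {self.method!r}")
        if not self.cofactor > 0 or any(v <= 0 for v in self.overrides.values()):
            raise ConfigurationError("transform cofactors must be > 0")

    def apply(self, x: np.ndarray, marker: str | None = None) -> np.ndarray:
        c = self.overrides.get(marker, self.cofactor)
        t = np.arcsinh(np.asarray(x, dtype=float) / c)
        return t / np.log(10.0) if self.method == "logicle" else t

    def invert(self, t: np.ndarray, marker: str | None = None) -> np.ndarray:
        c = self.overrides.get(marker, self.cofactor)
        t = np.asarray(t, dtype=float)
        if self.method == "logicle":
            t = t * np.log(10.0)
        return c * np.sinh(t)


def compensate(table: EventTable, spill) -> EventTable:
    """Remove fluorescence spillover by inverting the mixing matrix.

    The spillover convention follows the worked identity
    ``observed = true @ S.T`` (``S[i, j]`` = fraction of channel *j* signal
    received by detector *i*), so compensation solves ``S x = observed`` per
    event.  Scatter channels are untouched.

    Requires ``transform_state == "raw"``; the result is ``"compensated"``.
    """
    if table.transform_state != "raw":
        raise ConfigurationError(
            f"compensate() needs raw data, got {table.transform_state!r}")
    S = np.asarray(getattr(spill, "matrix", spill), dtype=float)
    fluor = table.fluor_indices
    if S.shape != (len(fluor), len(fluor)):
        raise ConfigurationError(
            f"spillover is {S.shape} but tube has {len(fluor)} fluorescence channels")
    data = table.data.copy()
    try:
        comp = np.linalg.solve(S, data[:, fluor].T).T
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"singular spillover matrix: {exc}") from exc
    data[:, fluor] = comp
    return table.with_data(data, transform_state="compensated")


def transform(table: EventTable, spec: TransformSpec | None = None) -> EventTable:
    """Apply the monotone per-channel transform (event order preserved)."""
    if table.transform_state == "transformed":
        raise ConfigurationError("table is already transformed")
    spec = spec or TransformSpec()
    data = np.empty_like(table.data)
    for j, ch in enumerate(table.channels):
        data[:, j] = spec.apply(table.data[:, j], ch.marker)
    return table.with_data(data, transform_state="transformed")


def gate_beads(table: EventTable, cutoff: float = BEAD_CUTOFF) -> np.ndarray:
    """Boolean mask of counting-bead events (transformed table).

    Beads sit in a dedicated extreme region: above ``cutoff`` on *every*
    fluorescence channel simultaneously, where no cell reaches.
    """
    if table.transform_state != "transformed":
        raise ConfigurationError("gate_beads() expects a transformed table")
    fluor = table.data[:, table.fluor_indices]
    if fluor.shape[1] == 0:
        return np.zeros(table.n_events, dtype=bool)
    return fluor.min(axis=1) > cutoff


def gate_primary(table: EventTable, mode: str = "cd45_ssc",
                 marker_floor: float = PRIMARY_MARKER_FLOOR,
                 bins: int = 128) -> np.ndarray:
    """Primary gate: the marker-bright, low-SSC density cluster.

    mode ``"cd45_ssc"`` gates lymphocytes on CD45 vs side scatter (counting
    tube); ``"cd3_ssc"`` gates T cells on CD3 vs side scatter (panel tubes).

    Algorithm (deterministic given the table): smoothed 2-D histogram of
    (marker, SSC); local density maxima are candidate populations; maxima
    with marker signal below ``marker_floor`` (debris) are discarded, as are
    high-SSC maxima (granulocytes/monocytes, beads); among the remaining
    low-SSC modes the one with the highest marker signal wins, and its full
    basin of attraction is returned as a boolean event mask.
    """
    if mode not in ("cd45_ssc", "cd3_ssc"):
        raise ConfigurationError(f"unknown primary gate mode {mode!r}")
    if table.transform_state != "transformed":
        raise ConfigurationError("gate_primary() expects a transformed table")
    marker = "CD45" if mode == "cd45_ssc" else "CD3"
    x = table.data[:, resolve_marker(table, marker)]
    y = table.data[:, resolve_marker(table, "SSC")]
    if table.n_events == 0:
        return np.zeros(0, dtype=bool)

    H, xc, yc, ex, ey = density_grid_2d(x, y, bins=bins)
    # steepest-ascent basins, then watershed-merge shoulders whose saddle
    # stays above half the smaller peak (one population, not two)
    basins = merge_shallow_basins(H, grid_basins(H))
    roots = np.unique(basins)
    n1 = H.shape[1]
    heights = H.ravel()[roots]
    keep = heights >= 0.005 * H.max()
    roots, heights = roots[keep], heights[keep]
    mode_x = xc[roots // n1]
    mode_y = yc[roots % n1]

    # credible cell clusters: marker-positive but below the bead region
    cand = (mode_x >= marker_floor) & (mode_x < BEAD_CUTOFF)
    if not np.any(cand):
        log.warning("gate_primary(%s): no marker-positive density mode; empty gate",
                    mode)
        return np.zeros(table.n_events, dtype=bool)
    y_span = yc[-1] - yc[0]
    low_ssc = mode_y <= mode_y[cand].min() + 0.15 * y_span
    cand &= low_ssc
    order = np.lexsort((mode_y, -mode_x))  # highest marker, ties -> lowest SSC
    chosen = next(i for i in order if cand[i])
    chosen_root = roots[chosen]

    ix = np.clip(np.searchsorted(ex, x, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ey, y, side="right") - 1, 0, bins - 1)
    return basins[ix * n1 + iy] == chosen_root
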