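"""Synthetic cytometry cohort generator with known ground truth.

Emulates the study design the pipeline targets: two arms of 46 subjects,
five stained tubes per subject (four 6-colour maturation tubes plus one
bead-containing counting tube), >= 15,000 events per tube.  Each subject is
a latent state (absolute lymphocyte count, nested subset composition)
drawn around the arm's preset medians — log-normal for counts, logit-normal
for fractions, one shared dispersion — and every tube of that subject is
simulated from the same latent state, so cross-tube quantities (e.g. the
CD4:CD8 ratio) are consistent by construction.

Fluorescence is a two-component model per marker on the arcsinh scale
(negative ~ N(1.0, 0.4), positive ~ N(3.5, 0.4); separation 2.5 units).
Debris is dim on the gating marker with broad scatter; non-lymphocyte
leukocytes in the counting tube are CD45-dim with high side scatter;
counting beads occupy an extreme region, brighter than any cellular
positive on every fluorescence detector.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit, logit

from ._errors import ConfigurationError
from .events_io import EventTable, write_events
from .panels import FLUOR_CHANNELS, PANEL, TUBE_IDS, TubeDef

__all__ = [
    "GroupPreset", "SubjectProfile", "SpilloverMatrix", "MarkerModel",
    "load_preset", "default_spillover", "make_subject_profile",
    "simulate_tube", "iter_cohort", "simulate_cohort", "subset_truth_mask",
    "DEFAULT_EVENTS_PER_TUBE", "MIN_EVENTS_PER_TUBE",
]

DEFAULT_EVENTS_PER_TUBE = 30_000
#: Acquisition floor: at least this many events per tube in a cohort run.
MIN_EVENTS_PER_TUBE = 15_000

#: Default debris load (lyse-no-wash preparations always carry debris).
DEFAULT_DEBRIS_FRACTION = 0.10

# -- fluorescence model (arcsinh-transformed scale) -------------------------
NEG_MEAN, POS_MEAN, MARKER_SD = 1.0, 3.5, 0.4   # pos - neg = 2.5 units
CD45_LYMPH_MEAN = 3.8     # lymphocytes are CD45-bright
CD45_LEUKO_MEAN = 2.8     # granulocytes/monocytes are CD45-dim
DEBRIS_FLUOR = (0.3, 0.3)
BEAD_FLUOR = (7.0, 0.15)

#: (FSC mean, FSC sd, SSC mean, SSC sd) per population class, arcsinh scale.
_SCATTER = {
    "lymph": (2.5, 0.20, 1.6, 0.22),
    "leuko": (3.0, 0.25, 3.2, 0.28),
    "debris": (1.2, 0.50, 1.5, 0.70),
    "bead": (2.0, 0.10, 3.0, 0.12),
}

from .preprocess import DEFAULT_COFACTOR  # single source for the raw scale


@dataclass(frozen=True)
class MarkerModel:
    """Two-component fluorescence model for one marker (transformed scale)."""

    neg_mean: float = NEG_MEAN
    neg_sd: float = MARKER_SD
    pos_mean: float = POS_MEAN
    pos_sd: float = MARKER_SD

    def __post_init__(self) -> None:
        if not self.pos_mean > self.neg_mean:
            raise ConfigurationError("marker model requires pos_mean > neg_mean")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: subset_median_pct keys whose parent is the T gate.
_T_CHILDREN = ("CD4", "CD8")
#: maturation combo bases per tube (suffixes _CD4/_CD8 added per branch)
_TUBE2_NAMED = ("TN", "TCM", "TEM", "LTEMRA", "HTEMRA", "TD")
_TUBE2_UNCLASSIFIED = ("unclassified_CD27neg_CCR7pos_RApos",
                       "unclassified_CD27neg_CCR7pos_RAneg")


@dataclass(frozen=True)
class GroupPreset:
    """Cohort-arm parameters: the printed medians plus a dispersion.

    ``subset_median_pct`` values are percentages of the subset's *parent*
    (T/B/NK of lymphocytes; CD4/CD8 of T; maturation subsets of CD4/CD8).
    ``dispersion`` is the shared logit-scale (fractions) / log-scale
    (counts) standard deviation of inter-subject variation.
    """

    name: str
    median_lymph_abs: float
    median_lymph_pct: float
    subset_median_pct: dict
    dispersion: float = 0.25
    n_subjects: int = 46

    def __post_init__(self) -> None:
        if not self.dispersion >= 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.median_lymph_abs > 0:
            raise ConfigurationError("median_lymph_abs must be > 0")
        for key, val in {"median_lymph_pct": self.median_lymph_pct,
                         **self.subset_median_pct}.items():
            if not 0.0 <= val <= 100.0:
                raise ConfigurationError(f"{key}={val} outside [0, 100]")
        for label, keys in self._sibling_blocks().items():
            total = sum(self.subset_median_pct.get(k, 0.0) for k in keys)
            if total > 100.0 + 1e-9:
                raise ConfigurationError(
                    f"sibling medians of {label} sum to {total:.2f}% > 100%")

    @staticmethod
    def _sibling_blocks() -> dict:
        blocks = {"basic": ["T", "B", "NK"], "T": ["CD4", "CD8"]}
        for x in ("CD4", "CD8"):
            blocks[f"tube2_{x}"] = [f"{b}_{x}" for b in _TUBE2_NAMED]
            blocks[f"tube3_{x}"] = [f"TSCM_{x}", f"TEMRA_{x}"]
        return blocks

    def pct(self, key: str) -> float:
        try:
            return self.subset_median_pct[key]
        except KeyError as exc:
            raise ConfigurationError(
                f"preset {self.name!r} lacks median for {key!r}") from exc

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"name": self.name, "n_subjects": self.n_subjects,
                "median_lymph_abs": self.median_lymph_abs,
                "median_lymph_pct": self.median_lymph_pct,
                "dispersion": self.dispersion,
                "subset_median_pct": dict(self.subset_median_pct)}

    @classmethod
    def from_dict(cls, d: dict) -> "GroupPreset":
        return cls(name=str(d["name"]),
                   median_lymph_abs=float(d["median_lymph_abs"]),
                   median_lymph_pct=float(d["median_lymph_pct"]),
                   subset_median_pct={k: float(v)
                                      for k, v in d["subset_median_pct"].items()},
                   dispersion=float(d.get("dispersion", 0.25)),
                   n_subjects=int(d.get("n_subjects", 46)))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_preset(name_or_path) -> GroupPreset:
    """Load a shipped preset (``"nbs"`` | ``"control"``) or a YAML file path."""
    text = None
    if isinstance(name_or_path, str) and name_or_path in ("nbs", "control"):
        text = (resources.files("tmaturity") / "presets"
                / f"{name_or_path}.yaml").read_text()
    else:
        text = Path(name_or_path).read_text()
    return GroupPreset.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# spillover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpilloverMatrix:
    """Square leak-coefficient matrix over the fluorescence detectors.

    ``matrix[i, j]`` is the fraction of channel *j*'s true signal received
    by detector *i* (diagonal 1); an observed event row is
    ``true @ matrix.T``.
    """

    matrix: np.ndarray
    channels: tuple = FLUOR_CHANNELS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.channels)
        if m.shape != (n, n):
            raise ConfigurationError("spillover matrix shape mismatch")
        if not np.allclose(np.diag(m), 1.0):
            raise ConfigurationError("spillover diagonal must be 1")
        off = m[~np.eye(n, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 0.5):
            raise ConfigurationError("off-diagonal spillover must be in [0, 0.5)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ConfigurationError("spillover matrix is singular")


def default_spillover() -> SpilloverMatrix:
    """Plausible spectral-neighbour spillover for the 6-detector layout."""
    idx = {c: i for i, c in enumerate(FLUOR_CHANNELS)}
    S = np.eye(len(FLUOR_CHANNELS))
    leaks = {  # (receiving detector, source channel): coefficient
        ("PE-A", "FITC-A"): 0.10,
        ("FITC-A", "PE-A"): 0.02,
        ("PerCP-A", "PE-A"): 0.08,
        ("PerCP-A", "FITC-A"): 0.01,
        ("PE-A", "PerCP-A"): 0.01,
        ("APC-Cy7-A", "APC-A"): 0.06,
        ("APC-A", "APC-Cy7-A"): 0.01,
        ("PE-Cy7-A", "PE-A"): 0.03,
        ("PE-A", "PE-Cy7-A"): 0.02,
        ("PE-Cy7-A", "APC-Cy7-A"): 0.04,
    }
    for (recv, src), c in leaks.items():
        S[idx[recv], idx[src]] = c
    return SpilloverMatrix(S)


# ---------------------------------------------------------------------------
# subject profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """One subject's latent truth, shared by all five tubes."""

    subject_id: str
    group: str
    lymph_abs_true: float              # cells/ul
    composition_true: dict             # block -> {name: fraction of parent}
    marker_model: dict                 # marker -> MarkerModel
    debris_fraction: float
    rng_seed: tuple                    # entropy prefix for per-tube streams

    def true_fraction(self, name: str) -> float:
        """Look up a named fraction-of-parent anywhere in the composition."""
        for block in self.composition_true.values():
            if name in block:
                return block[name]
        raise KeyError(name)


def _group_key(name: str) -> int:
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def _draw_block(medians_pct: dict, sigma: float, rng) -> dict:
    """Joint draw of a partition: logit-normal per sibling, renormalised."""
    keys = list(medians_pct)
    m = np.array([medians_pct[k] for k in keys]) / 100.0
    m = np.clip(m, 1e-6, 1 - 1e-6)
    if sigma > 0:
        w = expit(logit(m) + sigma * rng.standard_normal(len(m)))
    else:
        w = m
    w = w / w.sum()
    return dict(zip(keys, w))


def _draw_marginal(median_pct: float, sigma: float, rng) -> float:
    m = np.clip(median_pct / 100.0, 1e-6, 1 - 1e-6)
    if sigma == 0:
        return float(m)
    return float(expit(logit(m) + sigma * rng.standard_normal()))


def _composition_blocks(preset: GroupPreset) -> dict:
    """Preset medians arranged into complete partitions (percent, sum 100)."""
    p = preset.pct
    blocks: dict = {}
    basic = {"T": p("T"), "B": p("B"), "NK": p("NK")}
    basic["other"] = max(100.0 - sum(basic.values()), 0.2)
    blocks["lymph"] = basic
    tblk = {"CD4": p("CD4"), "CD8": p("CD8")}
    tblk["DN"] = max(100.0 - sum(tblk.values()), 0.2)
    blocks["T"] = tblk
    for x in ("CD4", "CD8"):
        rte = p(f"RTE_{x}")
        rest = max(100.0 - rte, 0.3) / 3.0
        blocks[f"tube1_{x}"] = {f"RTE_{x}": rte,
                                f"CD31posRAneg_{x}": rest,
                                f"CD31negRApos_{x}": rest,
                                f"CD31negRAneg_{x}": rest}
        named = {f"{b}_{x}": p(f"{b}_{x}") for b in _TUBE2_NAMED}
        rem = max(100.0 - sum(named.values()), 0.2) / 2.0
        named.update({f"{u}_{x}": rem for u in _TUBE2_UNCLASSIFIED})
        blocks[f"tube2_{x}"] = named
        t3 = {f"TSCM_{x}": p(f"TSCM_{x}"), f"TEMRA_{x}": p(f"TEMRA_{x}")}
        share = max(100.0 - sum(t3.values()), 0.6) / 6.0
        for combo in ("CD27posRAposCD95neg", "CD27posRAnegCD95pos",
                      "CD27posRAnegCD95neg", "CD27negRAposCD95neg",
                      "CD27negRAnegCD95pos", "CD27negRAnegCD95neg"):
            t3[f"{combo}_{x}"] = share
        blocks[f"tube3_{x}"] = t3
    return blocks


def default_marker_model() -> dict:
    """Shared two-component model; CD45 positives are lymphocyte-bright."""
    model = {m: MarkerModel() for tube in PANEL.values() for m in tube.fluor_markers}
    model["CD45"] = MarkerModel(pos_mean=CD45_LYMPH_MEAN)
    return model


def make_subject_profile(preset: GroupPreset, subject_index: int,
                         seed: int) -> SubjectProfile:
    """Draw one subject's latent state around the preset medians.

    Deterministic given ``(seed, preset.name, subject_index)``; the median
    of every drawn quantity over many subjects converges to its preset
    median (log-normal counts, logit-normal fractions are median-preserving;
    partition renormalisation perturbs medians only at O(dispersion^2)).
    """
    if not 0 <= subject_index < preset.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} out of range for n={preset.n_subjects}")
    entropy = (int(seed), _group_key(preset.name), int(subject_index))
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    sigma = preset.dispersion

    lymph_abs = preset.median_lymph_abs * float(np.exp(sigma * rng.standard_normal())) \
        if sigma > 0 else preset.median_lymph_abs
    f_lymph = _draw_marginal(preset.median_lymph_pct, sigma, rng)

    comp: dict = {"leuko": {"lymphocytes": f_lymph,
                            "other_leukocytes": 1.0 - f_lymph}}
    for block_name, medians in _composition_blocks(preset).items():
        comp[block_name] = _draw_block(medians, sigma, rng)
    for x in ("CD4", "CD8"):
        comp[f"tube4_{x}"] = {
            f"{m}_{x}": _draw_marginal(preset.pct(f"{m}_{x}"), sigma, rng)
            for m in ("CD57", "KLRG1", "PD1")}

    return SubjectProfile(
        subject_id=f"{preset.name}_{subject_index + 1:03d}",
        group=preset.name,
        lymph_abs_true=lymph_abs,
        composition_true=comp,
        marker_model=default_marker_model(),
        debris_fraction=DEFAULT_DEBRIS_FRACTION,
        rng_seed=entropy,
    )


# ---------------------------------------------------------------------------
# event simulation
# ---------------------------------------------------------------------------

# base-name -> phenotype, per tube family
_TUBE1_PHENO = {
    "RTE": {"CD31": "+", "CD45RA": "+", "CD45RO": "-"},
    "CD31posRAneg": {"CD31": "+", "CD45RA": "-", "CD45RO": "+"},
    "CD31negRApos": {"CD31": "-", "CD45RA": "+", "CD45RO": "-"},
    "CD31negRAneg": {"CD31": "-", "CD45RA": "-", "CD45RO": "+"},
}
_TUBE2_PHENO = {
    "TN": {"CD27": "+", "CD45RA": "+", "CD197": "+"},
    "TCM": {"CD27": "+", "CD45RA": "-", "CD197": "+"},
    "TEM": {"CD27": "+", "CD45RA": "-", "CD197": "-"},
    "LTEMRA": {"CD27": "+", "CD45RA": "+", "CD197": "-"},
    "HTEMRA": {"CD27": "-", "CD45RA": "+", "CD197": "-"},
    "TD": {"CD27": "-", "CD45RA": "-", "CD197": "-"},
    "unclassified_CD27neg_CCR7pos_RApos": {"CD27": "-", "CD45RA": "+", "CD197": "+"},
    "unclassified_CD27neg_CCR7pos_RAneg": {"CD27": "-", "CD45RA": "-", "CD197": "+"},
}


def _tube3_pheno(base: str) -> dict:
    if base == "TSCM":
        return {"CD27": "+", "CD45RA": "+", "CD95": "+"}
    if base == "TEMRA":
        return {"CD27": "-", "CD45RA": "+", "CD95": "+"}
    # names like CD27posRAnegCD95pos
    return {"CD27": "+" if "CD27pos" in base else "-",
            "CD45RA": "+" if "RApos" in base else "-",
            "CD95": "+" if "CD95pos" in base else "-"}


def _split_branch(name: str) -> tuple[str, str]:
    for x in ("CD4", "CD8"):
        if name.endswith(f"_{x}"):
            return name[:-len(x) - 1], x
    return name, ""


def _tube4_combos(marginals: dict, x: str):
    """Product-law combos over the three senescence/exhaustion markers."""
    markers = ("CD57", "KLRG1", "PD1")
    fracs = [marginals[f"{m}_{x}"] for m in markers]
    for bits in itertools.product((True, False), repeat=3):
        frac = 1.0
        pheno = {}
        tokens = []
        for m, f, on in zip(markers, fracs, bits):
            frac *= f if on else (1.0 - f)
            pheno["CD279" if m == "PD1" else m] = "+" if on else "-"
            tokens.append(f"{m}{'pos' if on else 'neg'}")
        yield "_".join(tokens), frac, pheno


def _populations(profile: SubjectProfile, tube: TubeDef):
    """(labels, weights, class, phenotype) for one tube; weights sum to 1
    for panel tubes and are expected event counts' relative rates for the
    counting tube (handled by the caller)."""
    comp = profile.composition_true
    d = profile.debris_fraction
    pops: list[tuple[str, float, str, dict]] = []
    if tube.tube_id == "trucount":
        lymph, t = comp["lymph"], comp["T"]
        pheno = {
            "T_CD4": {"CD3": "+", "CD4": "+"},
            "T_CD8": {"CD3": "+", "CD8": "+"},
            "T_DN": {"CD3": "+"},
            "B": {"CD19": "+"},
            "NK": {"CD16/56": "+"},
            "other_lymph": {},
        }
        leaf = {"T_CD4": lymph["T"] * t["CD4"], "T_CD8": lymph["T"] * t["CD8"],
                "T_DN": lymph["T"] * t["DN"], "B": lymph["B"], "NK": lymph["NK"],
                "other_lymph": lymph["other"]}
        for name, frac in leaf.items():
            pops.append((name, frac, "lymph", pheno[name]))
        return pops
    T = comp["lymph"]["T"]
    t = comp["T"]
    pops.append(("debris", d, "debris", {}))
    pops.append(("nonT", (1 - d) * (1 - T), "lymph", {}))
    pops.append(("T_DN", (1 - d) * T * t["DN"], "lymph", {"CD3": "+"}))
    for x in ("CD4", "CD8"):
        base_pheno = {"CD3": "+", x: "+"}
        share = (1 - d) * T * t[x]
        if tube.tube_id == "4":
            for combo, frac, pheno in _tube4_combos(comp[f"tube4_{x}"], x):
                pops.append((f"{combo}_{x}", share * frac, "lymph",
                             {**base_pheno, **pheno}))
        else:
            pheno_map = _TUBE1_PHENO if tube.tube_id == "1" else (
                _TUBE2_PHENO if tube.tube_id == "2" else None)
            for name, frac in comp[f"tube{tube.tube_id}_{x}"].items():
                base, _ = _split_branch(name)
                pheno = _tube3_pheno(base) if tube.tube_id == "3" else pheno_map[base]
                pops.append((name, share * frac, "lymph", {**base_pheno, **pheno}))
    return pops


def _channel_params(tube: TubeDef, pops, marker_model: dict):
    """Mean/sd matrices (n_pop x n_channels) on the transformed scale."""
    n_pop, n_ch = len(pops), len(tube.channels)
    M = np.empty((n_pop, n_ch))
    S = np.empty((n_pop, n_ch))
    for i, (_, _, cls, pheno) in enumerate(pops):
        fsc_m, fsc_s, ssc_m, ssc_s = _SCATTER[cls]
        for j, ch in enumerate(tube.channels):
            if ch.marker == "FSC":
                M[i, j], S[i, j] = fsc_m, fsc_s
            elif ch.marker == "SSC":
                M[i, j], S[i, j] = ssc_m, ssc_s
            elif cls == "bead":
                M[i, j], S[i, j] = BEAD_FLUOR
            elif cls == "debris":
                M[i, j], S[i, j] = DEBRIS_FLUOR
            else:
                try:
                    mm = marker_model[ch.marker]
                except KeyError as exc:
                    raise ConfigurationError(
                        f"tube {tube.tube_id} marker {ch.marker!r} absent from "
                        "the subject marker model") from exc
                if ch.marker == "CD45":
                    if cls == "leuko":
                        M[i, j], S[i, j] = CD45_LEUKO_MEAN, mm.pos_sd
                    else:
                        M[i, j], S[i, j] = mm.pos_mean, mm.pos_sd
                elif pheno.get(ch.marker) == "+":
                    M[i, j], S[i, j] = mm.pos_mean, mm.pos_sd
                else:
                    M[i, j], S[i, j] = mm.neg_mean, mm.neg_sd
    return M, S


def simulate_tube(profile: SubjectProfile, tube: TubeDef | str,
                  n_events: int = DEFAULT_EVENTS_PER_TUBE,
                  spill: SpilloverMatrix | None = None) -> EventTable:
    """Simulate one stained tube for one subject.

    Panel tubes draw exactly ``n_events`` events from the debris/lymphocyte
    mixture.  The counting tube treats ``n_events`` as the expected total
    and draws each component (lymphocyte leaves, other leukocytes, debris,
    beads) as an independent Poisson at the acquired fraction, which keeps
    the cell:bead ratio an unbiased estimator of the true concentration.
    Returns a raw-scale :class:`EventTable` carrying per-event ground-truth
    labels; deterministic given the profile and tube.
    """
    if isinstance(tube, str):
        try:
            tube = PANEL[tube]
        except KeyError as exc:
            raise ConfigurationError(f"unknown tube {tube!r}") from exc
    if n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    tube_index = TUBE_IDS.index(tube.tube_id)
    rng = np.random.default_rng(
        np.random.SeedSequence(tuple(profile.rng_seed) + (tube_index,)))

    pops = _populations(profile, tube)
    names = [p[0] for p in pops]
    weights = np.array([p[1] for p in pops], dtype=float)

    if tube.tube_id == "trucount":
        f_l = profile.composition_true["leuko"]["lymphocytes"]
        d = profile.debris_fraction
        beads_per_tube = tube.beads_per_tube or 0
        n_leuko_tube = profile.lymph_abs_true * tube.stained_volume_ul / f_l
        acquired = n_events / (n_leuko_tube / (1 - d) + beads_per_tube)
        # lymphocyte leaves are fractions of the lymphocyte compartment
        rates = np.concatenate([
            weights * (acquired * n_leuko_tube * f_l),
            [acquired * n_leuko_tube * (1 - f_l),        # other leukocytes
             acquired * n_leuko_tube * d / (1 - d),      # debris
             acquired * beads_per_tube],                 # beads
        ])
        pops = pops + [("other_leukocytes", 0.0, "leuko", {}),
                       ("debris", 0.0, "debris", {}),
                       ("bead", 0.0, "bead", {})]
        names = [p[0] for p in pops]
        counts = rng.poisson(rates)
    else:
        counts = rng.multinomial(n_events, weights / weights.sum())

    idx = np.repeat(np.arange(len(pops)), counts)
    M, S = _channel_params(tube, pops, profile.marker_model)
    t_scale = rng.normal(M[idx], S[idx])
    raw = DEFAULT_COFACTOR * np.sinh(t_scale)

    if spill is not None:
        order = [i for i, ch in enumerate(tube.channels)
                 if ch.name in spill.channels]
        perm = [spill.channels.index(tube.channels[i].name) for i in order]
        Ssp = spill.matrix[np.ix_(perm, perm)]
        raw[:, order] = raw[:, order] @ Ssp.T

    meta = {"tube_id": tube.tube_id, "stained_volume_ul": tube.stained_volume_ul,
            "transform_state": "raw"}
    if tube.beads_per_tube is not None:
        meta["beads_per_tube"] = tube.beads_per_tube
    return EventTable(raw, list(tube.channels), meta,
                      event_labels=np.array(names, dtype=object)[idx])


def subset_truth_mask(event_labels: np.ndarray, subset: str) -> np.ndarray:
    """Ground-truth membership mask for a gate-tree subset.

    Maps generator labels onto tree subset names: leaf subsets match by
    name, senescence/exhaustion subsets by marker token, basic subsets by
    their counting-tube populations.
    """
    labels = np.asarray(event_labels, dtype=object)
    as_str = labels.astype(str)
    if subset == "lymphocytes":
        return ~np.isin(as_str, ("debris", "bead", "other_leukocytes", "nonT"))
    if subset == "T":
        return np.char.startswith(as_str.astype("U"), "T_") | subset_truth_mask(
            labels, "CD4") | subset_truth_mask(labels, "CD8")
    if subset in ("B", "NK"):
        return as_str == subset
    if subset in ("CD4", "CD8"):
        return (as_str == f"T_{subset}") | np.char.endswith(
            as_str.astype("U"), f"_{subset}")
    base, branch = _split_branch(subset)
    if base in ("CD57", "KLRG1", "PD1") and branch:
        return (np.char.find(as_str.astype("U"), f"{base}pos") >= 0) & np.char.endswith(
            as_str.astype("U"), f"_{branch}")
    return as_str == subset


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def iter_cohort(preset: GroupPreset, seed: int,
                n_events: int = DEFAULT_EVENTS_PER_TUBE,
                spill: SpilloverMatrix | None = None,
                n_subjects: int | None = None):
    """Yield ``(profile, {tube_id: EventTable})`` per subject, in memory."""
    n = preset.n_subjects if n_subjects is None else n_subjects
    for i in range(n):
        profile = make_subject_profile(preset, i, seed)
        tables = {tid: simulate_tube(profile, tid, n_events, spill)
                  for tid in TUBE_IDS}
        yield profile, tables


def _write_truth_sidecar(profile: SubjectProfile, path: Path) -> None:
    lines = ["block,name,value",
             f"scalar,lymph_abs_true,{profile.lymph_abs_true:.10g}",
             f"scalar,debris_fraction,{profile.debris_fraction:.10g}"]
    for block, entries in profile.composition_true.items():
        for name, val in entries.items():
            lines.append(f"{block},{name},{val:.10g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def simulate_cohort(preset_a: GroupPreset, preset_b: GroupPreset | None,
                    seed: int, out_dir, fmt: str = "fcs",
                    n_events: int = DEFAULT_EVENTS_PER_TUBE,
                    spill: SpilloverMatrix | None = None,
                    n_subjects: int | None = None):
    """Write a full two-arm (or one-arm) cohort to ``out_dir``.

    Produces ``events/<subject>_tube<ID>.<fmt>`` per tube, a ground-truth
    sidecar CSV per subject, and ``manifest.csv`` (subject, group, tube,
    file path, truth path).  Fully reproducible by seed: manifests and
    sidecars are byte-identical across runs.  Returns the manifest rows as
    a list of dicts.
    """
    if n_events < MIN_EVENTS_PER_TUBE:
        raise ConfigurationError(
            f"cohort acquisition floor is {MIN_EVENTS_PER_TUBE} events/tube")
    if fmt not in ("fcs", "csv"):
        raise ConfigurationError(f"unknown event format {fmt!r}")
    out = Path(out_dir)
    try:
        (out / "events").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    rows = []
    for preset in [p for p in (preset_a, preset_b) if p is not None]:
        for profile, tables in iter_cohort(preset, seed, n_events, spill,
                                           n_subjects):
            truth_rel = f"truth/{profile.subject_id}.csv"
            _write_truth_sidecar(profile, out / truth_rel)
            for tid, table in tables.items():
                rel = f"events/{profile.subject_id}_tube{tid}.{fmt}"
                write_events(table, out / rel, fmt)
                rows.append({"subject_id": profile.subject_id,
                             "group": profile.group, "tube_id": tid,
                             "events_path": rel, "truth_path": truth_rel})
    header = "subject_id,group,tube_id,events_path,truth_path"
    body = "\n".join(",".join(r[k] for k in header.split(",")) for r in rows)
    (out / "manifest.csv").write_text(header + "\n" + body + "\n", encoding="utf-8")
    return rows
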