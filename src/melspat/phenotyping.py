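"""Gate-based intensity rescaling, hierarchical phenotype calling, and tumor
differentiation states.

Raw per-cell marker intensities are rescaled per (specimen, marker) with a
two-segment piecewise-linear map anchored at the gate: [min, gate] -> [0, 0.5]
and [gate, max] -> [0.5, 1], clipping outside [min, max].  After rescaling,
values strictly above 0.5 mark a cell as positive for the marker.

Phenotypes are called by matching each cell's binarized marker pattern against
an ordered rule hierarchy (deepest matching rule wins).  SOX10+ tumor cells are
further assigned one of four differentiation states from the binarized
MART1/SOX9/NGFR pattern: melanocytic, transitional, mesenchymal, NC-like.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CellTable

TUMOR_STATES = ("melanocytic", "transitional", "mesenchymal", "NC-like")


class ConfigurationError(ValueError):
    """Hierarchy/state-map references a marker absent from the data."""


@dataclasses.dataclass(frozen=True)
class Gate:
    """Per (specimen, marker) rescaling anchors: observed min m, gate g, max M."""

    specimen_id: str
    marker: str
    gate: float
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not (self.vmin <= self.gate <= self.vmax):
            raise ValueError(
                f"gate for ({self.specimen_id}, {self.marker}) must satisfy "
                f"min <= gate <= max, got ({self.vmin}, {self.gate}, {self.vmax})")


class GateSet:
    """One :class:`Gate` per (specimen, marker) pair."""

    def __init__(self, gates: Sequence[Gate]):
        self._gates: dict[tuple[str, str], Gate] = {}
        for g in gates:
            key = (g.specimen_id, g.marker)
            if key in self._gates:
                raise ValueError(f"duplicate gate for {key}")
            self._gates[key] = g

    def __getitem__(self, key: tuple[str, str]) -> Gate:
        return self._gates[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._gates

    def __iter__(self):
        return iter(self._gates.values())

    @classmethod
    def from_tsv(cls, path) -> "GateSet":
        df = pd.read_csv(path, sep="\t")
        return cls([Gate(str(r.specimen), str(r.marker), float(r.gate),
                         float(r.min), float(r.max))
                    for r in df.itertuples()])

    def to_tsv(self, path) -> None:
        pd.DataFrame([{"specimen": g.specimen_id, "marker": g.marker,
                       "gate": g.gate, "min": g.vmin, "max": g.vmax}
                      for g in self]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_percentiles(cls, table: CellTable,
                         gates: Mapping[tuple[str, str], float],
                         lo: float = 0.1, hi: float = 99.9) -> "GateSet":
        """Build a GateSet from user gate values, anchoring min/max at
        per-specimen-marker intensity percentiles (default 0.1 / 99.9) to
        resist outliers."""
        out = []
        for (spec, marker), gate in gates.items():
            vals = table.data.loc[table.data["specimen_id"] == spec, marker]
            vmin = float(np.percentile(vals, lo))
            vmax = float(np.percentile(vals, hi))
            out.append(Gate(spec, marker, float(np.clip(gate, vmin, vmax)),
                            vmin, vmax))
        return cls(out)


def rescale_by_gate(values, gate: Gate) -> np.ndarray:
    """Two-segment piecewise-linear rescale: gate -> 0.5, clipped to [0, 1].

    A degenerate channel (min == max) maps everything to 0 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if gate.vmin == gate.vmax:
        warnings.warn(
            f"degenerate channel ({gate.specimen_id}, {gate.marker}): "
            "min == max, all values rescaled to 0", stacklevel=2)
        return np.zeros_like(v)
    lo = gate.gate - gate.vmin
    hi = gate.vmax - gate.gate
    out = np.empty_like(v)
    below = v <= gate.gate
    if lo > 0:
        out[below] = 0.5 * (v[below] - gate.vmin) / lo
    else:  # gate == min: everything at/below the gate sits at the boundary
        out[below] = 0.5
    if hi > 0:
        out[~below] = 0.5 + 0.5 * (v[~below] - gate.gate) / hi
    else:
        out[~below] = 1.0
    return np.clip(out, 0.0, 1.0)


def rescale_table(table: CellTable, gates: GateSet) -> CellTable:
    """Rescale every marker of every specimen; result stored in ``rescaled``."""
    out = table.copy()
    rescaled = pd.DataFrame(index=out.data.index, columns=out.markers,
                            dtype=float)
    for spec, idx in out.data.groupby("specimen_id").groups.items():
        for marker in out.markers:
            key = (str(spec), marker)
            if key not in gates:
                raise ConfigurationError(f"no gate for {key}")
            rescaled.loc[idx, marker] = rescale_by_gate(
                out.data.loc[idx, marker].to_numpy(), gates[key])
    out.rescaled = rescaled
    return out


@dataclasses.dataclass(frozen=True)
class PhenotypeRule:
    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]
    parent: str | None = None


class PhenotypeHierarchy:
    """Ordered phenotype rules plus the SOX10+ tumor-state map.

    Cells are matched to the *deepest* rule (most ancestors) whose
    positive/negative marker requirements all hold; unmatched cells become
    "unclassified".  ``state_map`` maps the (MART1, SOX9, NGFR) sign triple of
    a SOX10+ tumor cell to a differentiation state and must cover all 8
    combinations.
    """

    def __init__(self, rules: Sequence[PhenotypeRule],
                 state_map: Mapping[tuple[bool, bool, bool], str] | None = None,
                 tumor_label: str = "tumor"):
        self.rules = list(rules)
        self.tumor_label = tumor_label
        labels = {r.label for r in self.rules}
        self._depth: dict[str, int] = {}
        for r in self.rules:
            if r.parent is not None and r.parent not in labels:
                raise ConfigurationError(
                    f"rule {r.label!r} has unknown parent {r.parent!r}")
        for r in self.rules:
            d, seen, cur = 0, {r.label}, r.parent
            while cur is not None:
                if cur in seen:
                    raise ConfigurationError(f"cycle in hierarchy at {cur!r}")
                seen.add(cur)
                d += 1
                cur = next(p.parent for p in self.rules if p.label == cur)
            self._depth[r.label] = d
        self.state_map = dict(state_map or DEFAULT_STATE_MAP)
        missing = {(m, s, n) for m in (True, False) for s in (True, False)
                   for n in (True, False)} - set(self.state_map)
        if missing:
            raise ConfigurationError(
                f"tumor state map must cover all 8 sign combinations; "
                f"missing {sorted(missing)}")

    @property
    def markers(self) -> list[str]:
        out: list[str] = []
        for r in self.rules:
            for m in r.positive + r.negative:
                if m not in out:
                    out.append(m)
        return out

    def depth(self, label: str) -> int:
        return self._depth[label]

    def effective_requirements(self, rule: PhenotypeRule) -> tuple[set, set]:
        """Positive/negative markers required by the rule and all its ancestors."""
        pos, neg = set(rule.positive), set(rule.negative)
        cur = rule.parent
        while cur is not None:
            parent = next(r for r in self.rules if r.label == cur)
            pos |= set(parent.positive)
            neg |= set(parent.negative)
            cur = parent.parent
        return pos, neg


#: Default tumor-state map for SOX10+ cells, keyed by (MART1, SOX9, NGFR)
#: positivity.  MART1+ alone -> melanocytic; MART1+ with SOX9 or NGFR ->
#: transitional; MART1- SOX9+ (NGFR-) -> mesenchymal; MART1- NGFR+ -> NC-like.
#: The fully-negative triple is melanocytic by default (SOX10+ lineage with no
#: dedifferentiation marker); the map is user-overridable.
DEFAULT_STATE_MAP: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "melanocytic",
    (True, True, False): "transitional",
    (True, False, True): "transitional",
    (True, True, True): "transitional",
    (False, True, False): "mesenchymal",
    (False, False, True): "NC-like",
    (False, True, True): "NC-like",
    (False, False, False): "melanocytic",
}


def default_hierarchy() -> PhenotypeHierarchy:
    """The built-in phenotype hierarchy for the simulator's 9-marker panel."""
    rules = [
        PhenotypeRule("immune", ("CD45",), ()),
        PhenotypeRule("tumor", ("SOX10",), ("CD45",)),
        PhenotypeRule("epithelial", ("panCK",), ("SOX10", "CD45")),
        PhenotypeRule("endothelial", ("CD31",), ("SOX10", "CD45", "panCK")),
        PhenotypeRule("stromal", (), ("SOX10", "CD45", "panCK", "CD31")),
        PhenotypeRule("T cell", ("CD3",), (), parent="immune"),
        PhenotypeRule("macrophage", ("CD163",), ("CD3",), parent="immune"),
    ]
    return PhenotypeHierarchy(rules)


def binarize(table: CellTable, threshold: float = 0.5) -> pd.DataFrame:
    """Positive calls per marker: rescaled value strictly above the threshold."""
    if table.rescaled is None:
        raise ConfigurationError("cell table has no rescaled intensities")
    return table.rescaled > threshold


def call_phenotypes(table: CellTable,
                    hierarchy: PhenotypeHierarchy | None = None) -> CellTable:
    """Assign one phenotype per cell from binarized staining patterns."""
    hierarchy = hierarchy or default_hierarchy()
    pos = binarize(table)
    for m in hierarchy.markers:
        if m not in pos.columns:
            raise ConfigurationError(
                f"hierarchy references marker {m!r} absent from the table")
    labels = pd.Series("unclassified", index=table.data.index, dtype=object)
    depths = pd.Series(-1, index=table.data.index, dtype=int)
    for rule in hierarchy.rules:
        req_pos, req_neg = hierarchy.effective_requirements(rule)
        match = pd.Series(True, index=table.data.index)
        for m in req_pos:
            match &= pos[m]
        for m in req_neg:
            match &= ~pos[m]
        d = hierarchy.depth(rule.label)
        take = match & (d > depths)
        labels[take] = rule.label
        depths[take] = d
    out = table.copy()
    out.data["phenotype"] = labels.to_numpy()
    return out


def assign_tumor_states(table: CellTable,
                        hierarchy: PhenotypeHierarchy | None = None) -> CellTable:
    """Assign differentiation states to SOX10+ tumor cells.

    Cells whose phenotype is the hierarchy's tumor label get a ``tumor_state``
    from the (MART1, SOX9, NGFR) binarized triple; all other cells get NA.
    """
    hierarchy = hierarchy or default_hierarchy()
    if "phenotype" not in table.data.columns:
        raise ConfigurationError("call_phenotypes must run before tumor states")
    pos = binarize(table)
    for m in ("MART1", "SOX9", "NGFR"):
        if m not in pos.columns:
            raise ConfigurationError(f"tumor state map needs marker {m!r}")
    out = table.copy()
    is_tumor = out.data["phenotype"] == hierarchy.tumor_label
    states = pd.Series(pd.NA, index=out.data.index, dtype=object)
    triples = zip(pos["MART1"], pos["SOX9"], pos["NGFR"])
    lookup = hierarchy.state_map
    states[is_tumor] = [lookup[t] for t, keep in zip(triples, is_tumor) if keep]
    out.data["tumor_state"] = states.to_numpy()
    return out


def state_of(mart1: bool, sox9: bool, ngfr: bool,
             state_map: Mapping[tuple[bool, bool, bool], str] | None = None) -> str:
    """State of a single SOX10+ cell from its binarized marker triple."""
    return dict(state_map or DEFAULT_STATE_MAP)[(mart1, sox9, ngfr)]
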