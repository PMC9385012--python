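"""Gate primitives and threshold-derivation rules.

Gates are axis-aligned regions with half-open bounds ``[lo, hi)`` so an
event on an exact boundary belongs to exactly one side.  Thresholds come
from control acquisitions: the viability and CD45 cutoffs from the unstained
tube, marker positivity cutoffs from fluorescence-minus-one (FMO) tubes, and
the scatter gate from a bead calibration run.  A hierarchy of gates is
evaluated top-down; child membership is always a subset of the parent's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    CalibrationError,
    GateTreeError,
    InsufficientEventsError,
)
from .fcs_io import EventTable, inverse_transform_channel

__all__ = [
    "Gate",
    "GateNode",
    "GatingResult",
    "size_gate_from_beads",
    "doublet_gate",
    "threshold_from_control",
    "evaluate_hierarchy",
    "population_frequency",
    "channel_mfi",
    "save_gate_tree",
    "load_gate_tree",
    "DEFAULT_CONTROL_QUANTILE",
    "INSTRUMENT_MAX",
]

#: FMO positivity quantile: stringent enough to reproduce per-mille-scale
#: background while still estimable from ~1e4-1e5 control events.
DEFAULT_CONTROL_QUANTILE = 0.9995
#: top ADC channel of the emulated instrument; the scatter gate excludes it
INSTRUMENT_MAX = 262_144.0

GATE_KINDS = ("interval", "rectangle", "threshold_above", "threshold_below", "ratio_band")


@dataclass(frozen=True)
class Gate:
    """One axis-aligned gate.

    kind / channels / bounds semantics:

    - ``interval``: 1 channel, bounds ``(lo, hi)`` — keep lo <= x < hi
    - ``rectangle``: 2 channels, bounds ``(xlo, xhi, ylo, yhi)``
    - ``threshold_above``: 1 channel, bounds ``(thr,)`` — keep x >= thr
    - ``threshold_below``: 1 channel, bounds ``(thr,)`` — keep x < thr
    - ``ratio_band``: 2 channels (num, den), bounds ``(lo, hi)`` on num/den
    """

    kind: str
    channels: tuple[str, ...]
    bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if not all(np.isfinite(self.bounds)):
            raise ValueError("gate bounds must be finite")
        n_ch = {"interval": 1, "rectangle": 2, "threshold_above": 1,
                "threshold_below": 1, "ratio_band": 2}[self.kind]
        n_b = {"interval": 2, "rectangle": 4, "threshold_above": 1,
               "threshold_below": 1, "ratio_band": 2}[self.kind]
        if len(self.channels) != n_ch or len(self.bounds) != n_b:
            raise ValueError(f"{self.kind} gate needs {n_ch} channels / {n_b} bounds")
        if self.kind in ("interval", "ratio_band") and self.bounds[0] > self.bounds[1]:
            raise ValueError("interval bounds must be ordered")
        if self.kind == "rectangle" and (
            self.bounds[0] > self.bounds[1] or self.bounds[2] > self.bounds[3]
        ):
            raise ValueError("rectangle bounds must be ordered")

    def membership(self, table: EventTable) -> np.ndarray:
        """Boolean membership of every event (half-open bounds)."""
        for ch in self.channels:
            if not table.has_channel(ch):
                raise GateTreeError(f"gate channel {ch!r} missing from tube")
        if self.kind == "interval":
            x = table.channel(self.channels[0])
            return (x >= self.bounds[0]) & (x < self.bounds[1])
        if self.kind == "rectangle":
            x = table.channel(self.channels[0])
            y = table.channel(self.channels[1])
            return (
                (x >= self.bounds[0]) & (x < self.bounds[1])
                & (y >= self.bounds[2]) & (y < self.bounds[3])
            )
        if self.kind == "threshold_above":
            return table.channel(self.channels[0]) >= self.bounds[0]
        if self.kind == "threshold_below":
            return table.channel(self.channels[0]) < self.bounds[0]
        num = table.channel(self.channels[0])
        den = table.channel(self.channels[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den != 0, num / den, np.inf)
        return (ratio >= self.bounds[0]) & (ratio < self.bounds[1])


@dataclass(frozen=True)
class GateNode:
    name: str
    gate: Gate
    parent: str = "root"


class GatingResult:
    """Per-event membership for every node of a gating hierarchy."""

    def __init__(
        self,
        memberships: dict[str, np.ndarray],
        parents: dict[str, str],
    ) -> None:
        self.memberships = memberships
        self.parents = parents
        self.counts = {name: int(m.sum()) for name, m in memberships.items()}

    def membership(self, name: str) -> np.ndarray:
        return self.memberships[name]

    def count(self, name: str) -> int:
        return self.counts[name]

    def is_ancestor(self, ancestor: str, node: str) -> bool:
        while node != ancestor:
            if node == "root":
                return False
            node = self.parents[node]
        return True


# ---------------------------------------------------------------------------
# Threshold / gate derivation
# ---------------------------------------------------------------------------

def _bead_clusters(
    fsc: np.ndarray, k: int, n_iter: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """1-D k-means on log FSC with quantile initialization (deterministic)."""
    x = np.log(np.clip(fsc, 1.0, None))
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        edges = (centers[:-1] + centers[1:]) / 2.0
        labels = np.digitize(x, edges)
        new = np.array([
            x[labels == j].mean() if np.any(labels == j) else centers[j]
            for j in range(k)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return labels, centers


def size_gate_from_beads(
    beads: EventTable,
    diameters_um: Sequence[float],
    lo_um: float = 5.0,
    hi_um: float = 30.0,
    instrument_max: float = INSTRUMENT_MAX,
) -> Gate:
    """Derive the FSC/SSC size-exclusion rectangle from a bead run.

    The FSC-A lower bound is the 1st percentile of the ``lo_um`` bead
    cluster, the upper bound the 99th percentile of the ``hi_um`` cluster —
    keeping intact cells while cutting small debris.  The SSC upper bound
    excludes the instrument's top channel, where aggregates pile up.
    """
    diameters = sorted(diameters_um)
    if lo_um not in diameters or hi_um not in diameters:
        raise CalibrationError("bead run must include the lo and hi diameters")
    k = len(diameters)
    fsc = beads.channel("FSC-A")
    if len(fsc) < 50 * k:
        raise CalibrationError("too few bead events for calibration")
    labels, centers = _bead_clusters(fsc, k)
    spreads = np.array([
        np.std(np.log(np.clip(fsc[labels == j], 1.0, None))) for j in range(k)
    ])
    gaps = np.diff(centers)
    if k > 1 and np.any(gaps < 4.0 * np.maximum(spreads[:-1], spreads[1:])):
        raise CalibrationError("bead diameter clusters are not distinct")

    lo_cluster = fsc[labels == diameters.index(lo_um)]
    hi_cluster = fsc[labels == diameters.index(hi_um)]
    if len(lo_cluster) < 20 or len(hi_cluster) < 20:
        raise CalibrationError("missing required bead cluster")
    fsc_lo = float(np.percentile(lo_cluster, 1))
    fsc_hi = float(np.percentile(hi_cluster, 99))
    return Gate(
        "rectangle", ("FSC-A", "SSC-A"),
        (fsc_lo, fsc_hi, 0.0, float(instrument_max) - 1.0),
    )


def doublet_gate(
    table: EventTable, k: float = 4.0, min_events: int = 50
) -> Gate:
    """Singlet gate: FSC-H/FSC-A ratio within median +/- k x MAD.

    Doublets carry roughly the summed area of the pair but a pulse height
    near the larger event's, so their ratio falls well below the singlet
    band.  MAD is floored so an all-identical input retains every event.
    """
    if table.n_events < min_events:
        raise InsufficientEventsError(
            f"doublet gate needs >= {min_events} events, got {table.n_events}"
        )
    fsc_a = table.channel("FSC-A")
    fsc_h = table.channel("FSC-H")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_a != 0, fsc_h / fsc_a, np.inf)
    ratio = ratio[np.isfinite(ratio)]
    med = float(np.median(ratio))
    mad = float(np.median(np.abs(ratio - med)))
    mad = max(mad, 1e-6 * max(abs(med), 1.0))
    return Gate(
        "ratio_band", ("FSC-H", "FSC-A"),
        (med - k * mad, med + k * mad),
    )


def threshold_from_control(
    control: EventTable | np.ndarray,
    channel: str | None = None,
    q: float = DEFAULT_CONTROL_QUANTILE,
    min_events: int = 1000,
) -> float:
    """Positivity threshold: the ``q``-quantile of a control's channel.

    The control carries only background (autofluorescence) in this channel —
    the unstained tube for viability/CD45, an FMO tube for an antibody — so
    events above the returned value in a stained tube are called positive.
    Monotone in ``q``.
    """
    values = control.channel(channel) if isinstance(control, EventTable) else np.asarray(control)
    if len(values) < min_events:
        raise InsufficientEventsError(
            f"control threshold needs >= {min_events} events, got {len(values)}"
        )
    if not (0.0 <= q <= 1.0):
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.quantile(values, q))


# ---------------------------------------------------------------------------
# Hierarchy evaluation and summaries
# ---------------------------------------------------------------------------

def evaluate_hierarchy(
    table: EventTable, nodes: Sequence[GateNode]
) -> GatingResult:
    """Evaluate a gate tree top-down; child AND parent at every node.

    ``root`` (all events) is implicit.  Nodes may appear in any order as
    long as the tree is acyclic; a parent that is never defined raises.
    """
    names = {"root"} | {n.name for n in nodes}
    for n in nodes:
        if n.parent not in names:
            raise GateTreeError(f"node {n.name!r} has dangling parent {n.parent!r}")
        if n.name == "root":
            raise GateTreeError("'root' is reserved")
    memberships: dict[str, np.ndarray] = {
        "root": np.ones(table.n_events, dtype=bool)
    }
    parents: dict[str, str] = {"root": "root"}
    pending = list(nodes)
    while pending:
        progressed = False
        remaining = []
        for node in pending:
            if node.parent in memberships:
                own = node.gate.membership(table)
                memberships[node.name] = own & memberships[node.parent]
                parents[node.name] = node.parent
                progressed = True
            else:
                remaining.append(node)
        if not progressed:
            raise GateTreeError("gate tree contains a cycle")
        pending = remaining
    return GatingResult(memberships, parents)


def population_frequency(
    result: GatingResult, node: str, denominator_node: str = "root"
) -> float:
    """Population size as a percentage of an ancestor node.

    Returns NaN (undefined) when the denominator is empty; the node must be
    the denominator node or one of its descendants, so numerator > 0 with a
    zero denominator is impossible and raises.
    """
    if not result.is_ancestor(denominator_node, node):
        raise GateTreeError(
            f"{node!r} is not a descendant of denominator {denominator_node!r}"
        )
    num = result.count(node)
    den = result.count(denominator_node)
    if den == 0:
        if num > 0:  # membership is conjunctive, so this cannot happen
            raise GateTreeError("hierarchy violation: child exceeds empty parent")
        return float("nan")
    return 100.0 * num / den


def channel_mfi(
    table: EventTable, membership: np.ndarray, channel: str
) -> float:
    """Mean fluorescence intensity of member events on the raw scale.

    Transformed channels are mapped back to raw intensities before
    averaging; an empty membership yields NaN (undefined).
    """
    if not np.any(membership):
        return float("nan")
    raw = inverse_transform_channel(table, channel)
    return float(np.mean(raw[membership]))


# ---------------------------------------------------------------------------
# Plain-text gate tree serialization
# ---------------------------------------------------------------------------

def save_gate_tree(nodes: Iterable[GateNode], path: str | Path) -> None:
    """Write a gate tree as tab-separated text (one node per line)."""
    lines = ["# name\tparent\tkind\tchannels\tbounds"]
    for n in nodes:
        lines.append(
            "\t".join([
                n.name, n.parent, n.gate.kind,
                ",".join(n.gate.channels),
                ",".join(repr(b) for b in n.gate.bounds),
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_gate_tree(path: str | Path) -> list[GateNode]:
    nodes = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, parent, kind, channels, bounds = line.split("\t")
        nodes.append(
            GateNode(
                name=name,
                parent=parent,
                gate=Gate(
                    kind,
                    tuple(channels.split(",")),
                    tuple(float(b) for b in bounds.split(",")),
                ),
            )
        )
    return nodes
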