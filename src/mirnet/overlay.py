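"""Binding score tables to network nodes: hit definition and node styling."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

from mirnet.annotation_io import ScoreTable, normalize_mirna_id
from mirnet.network_build import MiRNANetwork

logger = logging.getLogger(__name__)

Direction = Literal["greater", "less", "two-sided-absolute"]

#: semi-transparency applied to unmeasured / filtered-out nodes
DEFAULT_UNMEASURED_ALPHA = 0.25
NEUTRAL_COLOR = (200, 200, 200)


@dataclass(frozen=True)
class HitRule:
    """Predicate turning a score column into a hit call.

    ``direction`` selects ``value > threshold``, ``value < threshold`` or
    ``|value| > threshold``.  An optional expression filter restricts the
    measured set to rows whose ``expression_column`` value exceeds
    ``expression_threshold`` (e.g. median reads > 10).
    """

    value_column: str
    threshold: float
    direction: Direction = "greater"
    expression_column: str | None = None
    expression_threshold: float = 0.0

    def describe(self) -> str:
        op = {"greater": ">", "less": "<", "two-sided-absolute": "|x| >"}[self.direction]
        desc = f"{self.value_column} {op} {self.threshold:g}"
        if self.expression_column is not None:
            desc += f" among {self.expression_column} > {self.expression_threshold:g}"
        return desc

    def passes(self, value: float) -> bool:
        if math.isnan(value):
            return False
        if self.direction == "greater":
            return value > self.threshold
        if self.direction == "less":
            return value < self.threshold
        return abs(value) > self.threshold


@dataclass
class HitSet:
    """Measured ids and the subset passing the hit predicate."""

    measured_ids: set[str]
    hit_ids: set[str]
    predicate_description: str

    def __post_init__(self) -> None:
        assert self.hit_ids <= self.measured_ids, "hits must be a subset of measured ids"

    @property
    def n_measured(self) -> int:
        return len(self.measured_ids)

    @property
    def n_hits(self) -> int:
        return len(self.hit_ids)


def define_hits(scores: ScoreTable, rule: HitRule, network: MiRNANetwork | None = None) -> HitSet:
    """Apply a :class:`HitRule` to a score table.

    measured = rows with a non-missing value in the rule's column that pass
    the expression filter (if any); hits = measured rows passing the
    comparison.  When a network is supplied, both sets are intersected with
    its nodes and score rows absent from the network are reported (never
    silently dropped).
    """
    if rule.value_column not in scores.data.columns:
        raise ValueError(
            f"unknown score column {rule.value_column!r}; available: {scores.column_names}"
        )
    node_lookup: dict[str, str] | None = None
    if network is not None:
        node_lookup = {normalize_mirna_id(n): n for n in network.graph.nodes}
    measured: set[str] = set()
    hits: set[str] = set()
    off_network = 0
    for mirna_id in scores.data.index:
        value = float(scores.data.at[mirna_id, rule.value_column])
        if math.isnan(value):
            continue
        if rule.expression_column is not None:
            expr = float(scores.data.at[mirna_id, rule.expression_column])
            if math.isnan(expr) or expr <= rule.expression_threshold:
                continue
        elif scores.expression_mask is not None and not bool(
            scores.expression_mask.get(mirna_id, False)
        ):
            continue
        node_id = mirna_id
        if node_lookup is not None:
            node_id = node_lookup.get(normalize_mirna_id(mirna_id))
            if node_id is None:
                off_network += 1
                continue
        measured.add(node_id)
        if rule.passes(value):
            hits.add(node_id)
    if not measured:
        raise ValueError(
            f"no measured rows for rule '{rule.describe()}'"
            + (" on this network" if network is not None else "")
        )
    if off_network:
        logger.warning("%d measured score row(s) not present in the network", off_network)
    logger.info("hit rule '%s': %d hits of %d measured", rule.describe(), len(hits), len(measured))
    return HitSet(measured, hits, rule.describe())


@dataclass
class NodeStyle:
    node_id: str
    fill_value: float  # NaN when unmeasured
    color: tuple[int, int, int]
    alpha: float


@dataclass(frozen=True)
class ColorScale:
    """Diverging two-gradient color map (default green-white-red).

    Values are interpolated linearly on each half of [vmin, vmid, vmax];
    out-of-range values clamp to the end colors.
    """

    vmin: float
    vmid: float
    vmax: float
    low_color: tuple[int, int, int] = (0, 140, 60)
    mid_color: tuple[int, int, int] = (255, 255, 255)
    high_color: tuple[int, int, int] = (200, 30, 30)
    unmeasured_alpha: float = DEFAULT_UNMEASURED_ALPHA
    neutral_color: tuple[int, int, int] = NEUTRAL_COLOR

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError(f"degenerate color scale: vmin {self.vmin} >= vmax {self.vmax}")
        if not self.vmin <= self.vmid <= self.vmax:
            raise ValueError("vmid must lie within [vmin, vmax]")

    def color_for(self, value: float) -> tuple[int, int, int]:
        if math.isnan(value):
            return self.neutral_color
        if value <= self.vmin:
            return self.low_color
        if value >= self.vmax:
            return self.high_color
        if value < self.vmid:
            t = (value - self.vmin) / (self.vmid - self.vmin) if self.vmid > self.vmin else 1.0
            a, b = self.low_color, self.mid_color
        else:
            t = (value - self.vmid) / (self.vmax - self.vmid) if self.vmax > self.vmid else 0.0
            a, b = self.mid_color, self.high_color
        return tuple(round(a[i] + t * (b[i] - a[i])) for i in range(3))  # type: ignore[return-value]


def style_nodes(
    network: MiRNANetwork,
    scores: ScoreTable,
    value_column: str,
    scale: ColorScale,
    measured_ids: set[str] | None = None,
) -> list[NodeStyle]:
    """Per-node rendering attributes for a score overlay.

    Measured nodes get interpolated colors at full opacity; unmeasured or
    filtered-out nodes (e.g. below the expression cutoff) get the neutral
    color at the scale's semi-transparent alpha.  Pass ``measured_ids``
    (typically ``HitSet.measured_ids``) to apply an expression filter;
    otherwise any node with a non-missing value counts as measured.
    """
    styles: list[NodeStyle] = []
    for node_id in sorted(network.graph.nodes):
        value = scores.value(node_id, value_column)
        is_measured = not math.isnan(value)
        if measured_ids is not None:
            is_measured = is_measured and node_id in measured_ids
        if is_measured:
            styles.append(NodeStyle(node_id, value, scale.color_for(value), 1.0))
        else:
            styles.append(
                NodeStyle(node_id, math.nan, scale.neutral_color, scale.unmeasured_alpha)
            )
    return styles
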