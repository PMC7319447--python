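"""Graph, table and figure export: GraphML, a JSON graph dialect, TSV
tables, and deterministic static SVG rendering."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import networkx as nx

from mirnet.enrichment_stats import GlobalTestResult, LocalTestResult
from mirnet.network_build import GenomicCluster, MiRNANetwork
from mirnet.overlay import ColorScale, NodeStyle


def network_to_json_dict(network: MiRNANetwork) -> dict:
    nodes = [
        {"id": n, **{k: v for k, v in network.graph.nodes[n].items()}}
        for n in sorted(network.graph.nodes)
    ]
    edges = sorted([sorted(e) for e in network.graph.edges])
    return {
        "rule_name": network.rule_name,
        "threshold": network.threshold,
        "species_code": network.species_code,
        "nodes": nodes,
        "edges": edges,
    }


def write_network_json(network: MiRNANetwork, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        json.dump(network_to_json_dict(network), out, indent=1, sort_keys=True)
        out.write("\n")


def read_network_json(path: str | Path) -> MiRNANetwork:
    with open(path, "rt", encoding="utf-8") as handle:
        doc = json.load(handle)
    g = nx.Graph()
    for node in doc["nodes"]:
        attrs = {k: v for k, v in node.items() if k != "id"}
        g.add_node(node["id"], **attrs)
    g.add_edges_from(doc["edges"])
    return MiRNANetwork(
        rule_name=doc["rule_name"],
        threshold=doc["threshold"],
        species_code=doc["species_code"],
        graph=g,
    )


def write_network_graphml(network: MiRNANetwork, path: str | Path) -> None:
    g = network.graph.copy()
    g.graph["rule_name"] = network.rule_name
    g.graph["threshold"] = -1.0 if network.threshold is None else float(network.threshold)
    g.graph["species_code"] = network.species_code
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> MiRNANetwork:
    g = nx.read_graphml(str(path))
    threshold = g.graph.get("threshold")
    if threshold is not None and float(threshold) < 0:
        threshold = None
    return MiRNANetwork(
        rule_name=g.graph.get("rule_name", "custom"),
        threshold=None if threshold is None else float(threshold),
        species_code=g.graph.get("species_code", "unknown"),
        graph=nx.Graph(g),
    )


def clusters_to_tsv(clusters: Sequence[GenomicCluster], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("cluster_id\tmembers\tchrom\tspan_bp\tsize\n")
        for c in clusters:
            out.write(
                f"{c.cluster_id}\t{','.join(sorted(c.member_ids))}\t{c.chrom}\t{c.span_bp}\t{c.size}\n"
            )


def components_to_tsv(components: Sequence[set[str]], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("component_id\tsize\tmembers\n")
        for i, comp in enumerate(components, start=1):
            out.write(f"component_{i:03d}\t{len(comp)}\t{','.join(sorted(comp))}\n")


LOCAL_TSV_COLUMNS = (
    "group_id",
    "n_nodes",
    "n_hits",
    "n_cluster",
    "k_hits",
    "background_p",
    "pvalue",
    "pvalue_BH",
)


def local_results_to_tsv(results: Sequence[LocalTestResult], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("\t".join(LOCAL_TSV_COLUMNS) + "\n")
        for r in results:
            bh = "" if r.pvalue_bh is None else f"{r.pvalue_bh:.6g}"
            out.write(
                f"{r.group_id}\t{r.n_nodes}\t{r.n_hits}\t{r.n_cluster}\t{r.k_hits}\t"
                f"{r.background_p:.6g}\t{r.pvalue:.6g}\t{bh}\n"
            )


def global_result_to_json(result: GlobalTestResult, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        json.dump(dataclasses.asdict(result), out, indent=1, sort_keys=True)
        out.write("\n")


def styles_to_tsv(styles: Sequence[NodeStyle], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("node_id\tfill_value\tcolor_hex\talpha\n")
        for s in styles:
            value = "" if s.fill_value != s.fill_value else f"{s.fill_value:.6g}"
            out.write(f"{s.node_id}\t{value}\t{_hex(s.color)}\t{s.alpha:g}\n")


def _hex(color: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def render_svg(
    network: MiRNANetwork,
    styles: Sequence[NodeStyle],
    layout_seed: int = 0,
    scale: ColorScale | None = None,
    width: int = 900,
    height: int = 700,
    node_radius: float = 6.0,
    labels: bool = False,
    layout_iterations: int = 50,
) -> str:
    """Render the network to a standalone SVG string.

    The layout is a seeded Fruchterman-Reingold iteration with a fixed
    iteration budget, so the same inputs and seed give a byte-identical
    document.  Node fill and opacity come from the supplied styles; a
    color-scale legend with the anchor values is drawn when ``scale`` is
    given.
    """
    style_map = {s.node_id: s for s in styles}
    missing = set(network.graph.nodes) - set(style_map)
    if missing:
        raise ValueError(f"styles missing for {len(missing)} node(s), e.g. {sorted(missing)[:3]}")
    margin = 40.0
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    if network.graph.number_of_nodes() > 0:
        pos = nx.spring_layout(
            network.graph, seed=layout_seed, iterations=layout_iterations
        )
        xs = [p[0] for p in pos.values()]
        ys = [p[1] for p in pos.values()]
        span_x = (max(xs) - min(xs)) or 1.0
        span_y = (max(ys) - min(ys)) or 1.0

        def to_canvas(p):
            x = margin + (p[0] - min(xs)) / span_x * (width - 2 * margin)
            y = margin + (p[1] - min(ys)) / span_y * (height - 2 * margin - 60)
            return x, y

        for u, v in sorted(map(sorted, network.graph.edges)):
            xu, yu = to_canvas(pos[u])
            xv, yv = to_canvas(pos[v])
            lines.append(
                f'<line x1="{xu:.2f}" y1="{yu:.2f}" x2="{xv:.2f}" y2="{yv:.2f}" '
                'stroke="#999999" stroke-width="0.8"/>'
            )
        for node in sorted(network.graph.nodes):
            x, y = to_canvas(pos[node])
            s = style_map[node]
            lines.append(
                f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{node_radius:g}" '
                f'fill="{_hex(s.color)}" fill-opacity="{s.alpha:g}" '
                'stroke="#333333" stroke-width="0.5"/>'
            )
            if labels:
                lines.append(
                    f'<text x="{x + node_radius + 2:.2f}" y="{y + 3:.2f}" '
                    f'font-size="8" font-family="sans-serif">{node}</text>'
                )
    if scale is not None:
        lines.extend(_legend_svg(scale, x=margin, y=height - 40.0, width=200.0))
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def _legend_svg(scale: ColorScale, x: float, y: float, width: float) -> list[str]:
    lines = []
    n_steps = 40
    step_w = width / n_steps
    for i in range(n_steps):
        value = scale.vmin + (i + 0.5) / n_steps * (scale.vmax - scale.vmin)
        lines.append(
            f'<rect x="{x + i * step_w:.2f}" y="{y:.2f}" width="{step_w + 0.5:.2f}" '
            f'height="12" fill="{_hex(scale.color_for(value))}"/>'
        )
    for anchor, frac in ((scale.vmin, 0.0), (scale.vmid, None), (scale.vmax, 1.0)):
        if frac is None:
            frac = (scale.vmid - scale.vmin) / (scale.vmax - scale.vmin)
        lines.append(
            f'<text x="{x + frac * width:.2f}" y="{y + 24:.2f}" font-size="10" '
            f'font-family="sans-serif" text-anchor="middle">{anchor:g}</text>'
        )
    return lines
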