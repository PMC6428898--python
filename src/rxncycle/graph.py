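"""Bipartite regulatory graphs for Cytoscape-compatible inspection.

Reaction-to-state edges (produce, consume, synthesise, degrade) show what
each reaction does; state-to-reaction edges (source, contingency) show how
states gate reactions, optionally through Boolean gate nodes.  The
simplified view omits neutral states and their incident edges, which removes
non-informative cycles.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .core import (
    Modifier,
    RxnconSystem,
    RxnconError,
    StateKind,
    is_gate_id,
    is_global_id,
)

NODE_TYPES = ("reaction", "state", "gate", "global")


def regulatory_graph(system: RxnconSystem, simplified: bool = False) -> nx.MultiDiGraph:
    """Build the typed bipartite reaction/state graph of a system."""
    system._require_finalised()
    g = nx.MultiDiGraph()

    def ensure_state_node(sid: str) -> None:
        if g.has_node(sid):
            return
        g.add_node(sid, ntype="global" if is_global_id(sid) else "state")

    neutral_ids = {
        str(s) for s in system.states if s.kind is not StateKind.GLOBAL and s.is_neutral
    }
    for r in system.reactions:
        g.add_node(r.id, ntype="reaction")
        sk = system.skeletons[r.id]
        for s in sorted(sk.produced, key=str):
            ensure_state_node(str(s))
            g.add_edge(r.id, str(s), etype="produce")
        for s in sorted(sk.consumed, key=str):
            ensure_state_node(str(s))
            g.add_edge(r.id, str(s), etype="consume")
            g.add_edge(str(s), r.id, etype="source")
        for s in sorted(sk.synthesised, key=str):
            ensure_state_node(str(s))
            g.add_edge(r.id, str(s), etype="synthesise")
        for s in sorted(sk.degraded, key=str):
            ensure_state_node(str(s))
            g.add_edge(r.id, str(s), etype="degrade")
    for gid, gate in system.gates.items():
        g.add_node(gid, ntype="gate")
        for child in gate.children:
            if is_gate_id(child):
                g.add_node(child, ntype="gate")
            else:
                ensure_state_node(child)
            g.add_edge(child, gid, etype="boolean-membership")
    for row in system.contingencies:
        if row.modifier.is_boolean_membership:
            continue
        if is_gate_id(row.effector):
            g.add_node(row.effector, ntype="gate")
        else:
            ensure_state_node(row.effector)
        if is_global_id(row.target):
            ensure_state_node(row.target)
        g.add_edge(row.effector, row.target, etype=f"contingency-{row.modifier.value}")
    if simplified:
        # synthesis/degradation of a neutral state is shown on a
        # component-presence node instead, so every reaction keeps at least
        # one produce/synthesise/degrade edge in the simplified view
        retarget = []
        for u, v, data in g.edges(data=True):
            if data["etype"] in ("synthesise", "degrade") and v in neutral_ids:
                comps = system_state_components(system, v)
                retarget.extend((u, comp, data["etype"]) for comp in comps)
        g.remove_nodes_from([n for n in list(g.nodes) if n in neutral_ids])
        seen = set()
        for u, comp, etype in retarget:
            if (u, comp, etype) in seen:
                continue
            seen.add((u, comp, etype))
            if not g.has_node(comp):
                g.add_node(comp, ntype="state")
            g.add_edge(u, comp, etype=etype)
    return g


def system_state_components(system: RxnconSystem, state_id: str) -> tuple[str, ...]:
    from .core import parse_state

    return parse_state(state_id).components


def edge_census(graph: nx.MultiDiGraph) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, _, data in graph.edges(data=True):
        counts[data["etype"]] = counts.get(data["etype"], 0) + 1
    return counts


def write_graph(graph: nx.MultiDiGraph, path: str | Path, fmt: str | None = None) -> Path:
    """Serialise to GraphML or XGMML with node/edge type attributes."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path, infer_numeric_types=False)
    elif fmt == "xgmml":
        path.write_text(_to_xgmml(graph))
    else:
        raise RxnconError(f"unknown graph format {fmt!r} (use graphml or xgmml)")
    return path


def read_graphml(path: str | Path) -> nx.MultiDiGraph:
    return nx.read_graphml(path, force_multigraph=True)


def _to_xgmml(graph: nx.MultiDiGraph) -> str:
    from lxml import etree

    root = etree.Element(
        "graph",
        label="regulatory-graph",
        directed="1",
        nsmap={None: "http://www.cs.rpi.edu/XGMML"},
    )
    ids = {n: str(i) for i, n in enumerate(graph.nodes)}
    for n, data in graph.nodes(data=True):
        node = etree.SubElement(root, "node", id=ids[n], label=str(n))
        etree.SubElement(
            node, "att", name="ntype", value=str(data.get("ntype", "")), type="string"
        )
    for u, v, data in graph.edges(data=True):
        edge = etree.SubElement(
            root, "edge", source=ids[u], target=ids[v], label=f"{u}->{v}"
        )
        etree.SubElement(
            edge, "att", name="etype", value=str(data.get("etype", "")), type="string"
        )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def is_bipartite_with_gates(graph: nx.MultiDiGraph) -> bool:
    """Check the reaction-side/state-side alternation after contracting
    gate nodes (gates sit on the state-to-reaction side of the graph)."""
    side = {}
    for n, data in graph.nodes(data=True):
        ntype = data.get("ntype")
        if ntype == "reaction":
            side[n] = "reaction"
        elif ntype in ("state", "global"):
            side[n] = "state"
    for u, v, data in graph.edges(data=True):
        su, sv = side.get(u), side.get(v)
        if su is None or sv is None:  # gate endpoint: alternation via gates is free
            continue
        if su == sv:
            return False
    return True
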