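"""DOT export of bridge graphs and solutions.

Interval connections are drawn as solid black arcs, reference connections
dotted, bridge connections red with their support as label.  Extremity nodes
are laid out chromosome by chromosome in reference order so the intervals line
up.  With a solution, every edge is annotated with its traversal count f and
unused bridge edges are dashed.
"""

from __future__ import annotations

from .graph import BRIDGE, BridgeGraph, INTERVAL, REFERENCE
from .reconstruct import Solution
from .segments import Extremity


def _node_id(e: Extremity) -> str:
    return f"{e.side.lower()}_{e.chrom}_{e.index}"


def _label(e: Extremity) -> str:
    return f"{e.side.lower()}{e.index}"


def to_dot(g: BridgeGraph, sol: Solution | None = None) -> str:
    """Render the graph (optionally with a fitted solution overlay) as DOT text."""
    em = sol.multiplicities if sol is not None else None
    lines = [
        "digraph bridge_graph {",
        "  rankdir=LR;",
        '  node [shape=plaintext, fontsize=11];',
    ]
    for chrom in g.segmentation.chromosomes:
        lines.append(f'  subgraph "cluster_{chrom}" {{')
        lines.append(f'    label="{chrom}";')
        lines.append("    rank=same;")
        for j in range(1, len(g.segmentation.chromosomes[chrom]) + 1):
            for side in ("T", "H"):
                e = Extremity(chrom, j, side)
                lines.append(f'    {_node_id(e)} [label="{_label(e)}"];')
        lines.append("  }")

    for c in g.connections:
        attrs = []
        if c.kind == INTERVAL:
            attrs.append("color=black")
            attrs.append("penwidth=2")
            label = f"CN={c.weight:g}"
        elif c.kind == REFERENCE:
            attrs.append("style=dotted")
            label = ""
        else:
            attrs.append("color=red")
            label = f"{c.weight:g}"
        if em is not None:
            f = em.f(c)
            label = (label + " " if label else "") + f"f={f}"
            if c.kind == BRIDGE and f == 0:
                attrs.append("style=dashed")
        if label:
            attrs.append(f'label="{label}"')
        attrs.append("dir=both")  # a connection is a pair of antiparallel edges
        lines.append(f"  {_node_id(c.u)} -> {_node_id(c.v)} [{', '.join(attrs)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
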