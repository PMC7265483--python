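"""Burr-projection geometry.

An antler's branching structure is projected onto the circular cross-section
of the burr.  Every branch segment carries a cross-section circle; arc
positions on a circle of circumference ``C`` live in ``[0, C)`` with modular
arithmetic.  Inside a :class:`TineTree` all positions are stored normalized
(fractions of the local circumference, origin at the segment's attachment
crotch); physical circumferences are retained so inputs can be given in
length units.

Per fork, the input geometry supplies two arc positions on the stem circle
just below the fork: the *ridge* (lateral end of the fork crotch) and the
*groove boundary* (its medial end).  These two points are the fork's two burr
marks once carried down, they bound the window through which the branching
child's grooves descend, and the prorating of a point over an overlapping
proximal tine is centred on the groove boundary
(:func:`remap_across_tine`).

Projection to the burr composes, fork by fork, order-preserving affine arc
maps that unroll each child circle onto its window.  Because each map is
affine and anchored at the crotch, deleting an overlapping proximal tine and
pushing its fork record through the map (:func:`delete_tine`) leaves every
more-distal branching direction and fork mark at exactly the same point on
the burr — the design goal of the prorated projection.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

__all__ = [
    "opposite_point",
    "remap_across_tine",
    "inverse_remap_across_tine",
    "TineNode",
    "TineTree",
    "BurrDiagram",
    "project_to_burr",
    "project_fork",
    "compute_zones",
    "build_diagram",
    "render_diagram",
    "delete_tine",
    "mirror_angle",
]


# ---------------------------------------------------------------------------
# arc primitives
# ---------------------------------------------------------------------------

def opposite_point(ridge: float, circumference: float) -> float:
    """Point dividing the circumference in two, opposite ``ridge``.

    This is the branching direction of a tine on its own cross-section: the
    point half a circumference away from the fork.
    """
    if circumference <= 0:
        raise ValueError("circumference must be positive")
    return (ridge + circumference / 2.0) % circumference


def remap_across_tine(
    alpha_before: float,
    ridge: float,
    boundary: float,
    circumference: float,
) -> float:
    """Prorate a point over an overlapping proximal tine.

    A descending point at ``alpha_before`` on the arc between the fork
    ``ridge`` and the ``groove boundary`` is moved to ``alpha_after`` on the
    arc between the ridge's opposite point and the boundary, preserving the
    proportion x : y = X : Y where x, y are the arc lengths ridge->alpha and
    alpha->boundary, and X, Y the corresponding lengths opposite->alpha_after
    and alpha_after->boundary.  The ridge maps to the opposite point, the
    groove boundary is the fixed point, and the map is strictly monotone and
    continuous in between.  The degenerate zero-width interval (ridge on the
    boundary) collapses to the boundary.
    """
    C = float(circumference)
    if C <= 0:
        raise ValueError("circumference must be positive")
    alpha, ridge, boundary = alpha_before % C, ridge % C, boundary % C
    opp = opposite_point(ridge, C)

    d_alpha = (alpha - ridge) % C
    d_bound = (boundary - ridge) % C
    if d_bound == 0.0:  # ridge coincides with the groove boundary
        return boundary
    if d_alpha <= d_bound:  # alpha on the +arc from ridge to boundary
        sign, x, y = 1.0, d_alpha, d_bound - d_alpha
    else:  # alpha on the -arc
        sign, x, y = -1.0, (ridge - alpha) % C, (alpha - boundary) % C
    total = x + y
    if total == 0.0:
        return boundary
    # target arc runs from the opposite point to the boundary, on the side
    # corresponding to the carrying arc (direction -sign from the opposite).
    target_len = (sign * (opp - boundary)) % C
    X = x * target_len / total
    return (opp - sign * X) % C


def inverse_remap_across_tine(
    alpha_after: float,
    ridge: float,
    boundary: float,
    circumference: float,
) -> float:
    """Inverse of :func:`remap_across_tine` on the + carrying arc."""
    C = float(circumference)
    alpha, ridge, boundary = alpha_after % C, ridge % C, boundary % C
    opp = opposite_point(ridge, C)
    d_bound = (boundary - ridge) % C
    target_len = (opp - boundary) % C
    if target_len == 0.0:
        return ridge
    X = (opp - alpha) % C
    if X > target_len:
        raise ValueError("alpha_after outside the opposite->boundary arc")
    return (ridge + X / target_len * d_bound) % C


def mirror_angle(angle_deg: float) -> float:
    """Mirror a burr angle across the anterior-posterior axis (left<->right)."""
    return (360.0 - angle_deg) % 360.0


# ---------------------------------------------------------------------------
# tine trees
# ---------------------------------------------------------------------------

@dataclass
class Fork:
    """Fork geometry on the stem circle just below the bifurcation.

    ``ridge`` and ``boundary`` are normalized arc positions (fractions of the
    local circumference) of the lateral and medial crotch ends; the window
    ``[ridge, boundary]`` carries the first child's grooves.  Non-wrapping
    (``0 <= ridge <= boundary < 1``); the root fork's ridge anchors the burr
    coordinate origin and must be 0.
    """

    ridge: float
    boundary: float


@dataclass
class TineNode:
    """One branch segment: an element (or the unnamed base) and its geometry."""

    code: str
    category: str = "tine"
    length: float = 1.0
    diameter: float = 0.3
    circumference: float = 1.0
    fork: Fork | None = None
    children: list["TineNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class TineTree:
    """Rooted branching structure of one antler.

    The root is the antler base at the burr.  Every internal node bifurcates;
    trifurcations are encoded as two nested forks.  Lengths, diameters and
    circumferences are positive; fork records are validated non-wrapping.
    """

    def __init__(self, root: TineNode, side: str = "left",
                 skull_marks: dict[str, float] | None = None):
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.root = root
        self.side = side
        self.skull_marks = dict(skull_marks or {})
        self._validate()
        self._index: dict[str, TineNode] = {}
        self._parent: dict[int, TineNode | None] = {id(root): None}
        for node in self.walk():
            for child in node.children:
                self._parent[id(child)] = node
            if node.code != "base":
                if node.code in self._index:
                    raise ValueError(f"duplicate element code {node.code!r}")
                self._index[node.code] = node

    def _validate(self) -> None:
        stack = [(self.root, True)]
        while stack:
            node, is_root = stack.pop()
            if node.length <= 0 or node.diameter <= 0 or node.circumference <= 0:
                raise ValueError(f"{node.code}: lengths, diameters and "
                                 "circumferences must be positive")
            if node.children:
                if len(node.children) != 2:
                    raise ValueError(f"{node.code}: every fork must bifurcate")
                if node.fork is None:
                    raise ValueError(f"{node.code}: internal node lacks fork record")
                f = node.fork
                if not (0.0 <= f.ridge <= f.boundary < 1.0):
                    raise ValueError(
                        f"{node.code}: fork record must satisfy "
                        "0 <= ridge <= boundary < 1 (non-wrapping window)")
                if is_root and f.ridge != 0.0:
                    raise ValueError("root fork ridge must be 0 (coordinate origin)")
                if not is_root and f.ridge == 0.0:
                    raise ValueError(
                        f"{node.code}: non-root fork ridge must be strictly "
                        "positive (the stem retains a zone)")
                for child in node.children:
                    stack.append((child, False))
            elif node.fork is not None:
                raise ValueError(f"{node.code}: leaf carries a fork record")

    # -- traversal -------------------------------------------------------

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def elements(self) -> list[str]:
        return [n.code for n in self.walk() if n.code != "base"]

    def node(self, code: str) -> TineNode:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"element {code!r} not in tine tree") from None

    def parent(self, node: TineNode) -> TineNode | None:
        return self._parent[id(node)]

    def child_index(self, node: TineNode) -> int:
        parent = self.parent(node)
        return -1 if parent is None else parent.children.index(node)

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_json(cls, text_or_dict) -> "TineTree":
        data = json.loads(text_or_dict) if isinstance(text_or_dict, str) else text_or_dict

        def node_from(d):
            fork = d.get("fork")
            return TineNode(
                code=d["code"], category=d.get("category", "tine"),
                length=float(d.get("length", 1.0)),
                diameter=float(d.get("diameter", 0.3)),
                circumference=float(d.get("circumference", 1.0)),
                fork=Fork(float(fork["ridge"]), float(fork["boundary"])) if fork else None,
                children=[node_from(c) for c in d.get("children", [])],
            )

        return cls(node_from(data["root"]), side=data.get("side", "left"),
                   skull_marks={k: float(v) for k, v in data.get("skull_marks", {}).items()})

    def to_json(self) -> str:
        def dump(node):
            d = {"code": node.code, "category": node.category,
                 "length": node.length, "diameter": node.diameter,
                 "circumference": node.circumference}
            if node.fork:
                d["fork"] = {"ridge": node.fork.ridge, "boundary": node.fork.boundary}
            if node.children:
                d["children"] = [dump(c) for c in node.children]
            return d

        return json.dumps({"side": self.side, "skull_marks": self.skull_marks,
                           "root": dump(self.root)}, indent=1)


# ---------------------------------------------------------------------------
# projection chain
# ---------------------------------------------------------------------------

def _region(tree: TineTree, node: TineNode) -> tuple[float, float]:
    """Burr arc [start, start+length) carrying this segment's grooves.

    Computed by composing, root-down, the affine unroll of each child circle
    onto its window: child 0 onto [ridge, boundary], child 1 onto
    [boundary, 1) of the parent's region.
    """
    chain: list[tuple[TineNode, int]] = []
    cur = node
    while True:
        parent = tree.parent(cur)
        if parent is None:
            break
        chain.append((parent, parent.children.index(cur)))
        cur = parent
    start, length = 0.0, 1.0
    for parent, idx in reversed(chain):
        f = parent.fork
        if idx == 0:
            start, length = (start + f.ridge * length) % 1.0, (f.boundary - f.ridge) * length
        else:
            start, length = (start + f.boundary * length) % 1.0, (1.0 - f.boundary) * length
    return start, length


def _to_burr(tree: TineTree, node: TineNode, local: float) -> float:
    start, length = _region(tree, node)
    return (start + (local % 1.0) * length) % 1.0


def _angle(tree: TineTree, frac: float) -> float:
    # Local geometry is measured in the antler's own anatomical handedness
    # (origin at the crotch, increasing toward the lateral side), so left and
    # right antlers project onto directly comparable angles; use
    # :func:`mirror_angle` when converting viewer-absolute measurements.
    return (frac % 1.0) * 360.0


def project_to_burr(tree: TineTree, element: str) -> float:
    """Burr angle (degrees) of an element's branching direction.

    For a terminal element this is the opposite point of its fork crotch on
    its own cross-section, carried through every intervening fork; for a beam
    that forks distally it is the centre of the arc its own grooves retain at
    the burr.  Angles follow the left-antler convention (right antlers are
    mirrored).
    """
    node = tree.node(element)
    if node.is_leaf:
        # opposite point of the crotch (local origin) on the element's circle
        local = opposite_point(0.0, 1.0)
        return _angle(tree, _to_burr(tree, node, local))
    # beam with a distal fork: midpoint of the retained arc [0, ridge)
    return _angle(tree, _to_burr(tree, node, node.fork.ridge / 2.0))


def project_fork(tree: TineTree, fork_id: str) -> tuple[float, float]:
    """Burr angles (lateral, medial) of one fork's two marks.

    ``fork_id`` is ``"A/B"`` where A and B are the fork's child codes.  The
    two marks are the images of the fork's ridge and groove boundary; they
    coincide when the ridge lies on the boundary.
    """
    node = _fork_node(tree, fork_id)
    lat = _to_burr(tree, node, node.fork.ridge)
    med = _to_burr(tree, node, node.fork.boundary)
    return _angle(tree, lat), _angle(tree, med)


def _fork_node(tree: TineTree, fork_id: str) -> TineNode:
    for node in tree.walk():
        if node.children and _fork_name(node) == fork_id:
            return node
    raise KeyError(f"unknown fork {fork_id!r}")


def _fork_name(node: TineNode) -> str:
    return f"{node.children[0].code}/{node.children[1].code}"


def compute_zones(tree: TineTree) -> dict[str, list[tuple[float, float]]]:
    """Angular zones of all elements; the intervals partition the circle.

    Each fork's two marks subdivide the stem's region: the window between
    them goes to the branching child, the arc beyond the medial mark to the
    continuing child, and the stem itself retains the arc before the lateral
    mark.  Intervals are reported in degrees, split at 360 where they wrap.
    """
    zones: dict[str, list[tuple[float, float]]] = {}
    for node in tree.walk():
        if node.code == "base" and node.is_leaf:
            raise ValueError("empty antler has no zones")
        start, length = _region(tree, node)
        if node.is_leaf:
            lo, hi = start, start + length
        else:
            lo, hi = start, start + node.fork.ridge * length
        if node.code != "base":
            zones[node.code] = _arc_to_intervals(tree, lo, hi)
    return zones


def _arc_to_intervals(tree: TineTree, lo: float, hi: float) -> list[tuple[float, float]]:
    if hi - lo <= 0:
        return []
    a, b = (lo % 1.0) * 360.0, ((lo % 1.0) + (hi - lo)) * 360.0
    if b <= 360.0:
        return [(a, b)]
    return [(a, 360.0), (0.0, b - 360.0)]


# ---------------------------------------------------------------------------
# diagram
# ---------------------------------------------------------------------------

@dataclass
class BurrDiagram:
    """The circular burr-cross-section summary of one antler.

    Dots are branching directions, paired marks are fork positions, painted
    zones partition the circle, the hierarchy string nests element codes by
    branching order, and skull marks relate everything to the skull.
    """

    branching_directions: dict[str, float]
    fork_positions: dict[str, tuple[float, float]]
    zones: dict[str, list[tuple[float, float]]]
    hierarchy: str
    skull_marks: dict[str, float]
    side: str = "left"

    def elements(self) -> list[str]:
        return sorted(self.branching_directions)

    def validate(self) -> None:
        total = sum(hi - lo for arcs in self.zones.values() for lo, hi in arcs)
        if self.zones and abs(total - 360.0) > 1e-6:
            raise ValueError(f"zones do not partition the circle (sum {total})")
        in_hierarchy = set(_codes_in_hierarchy(self.hierarchy))
        if set(self.branching_directions) != in_hierarchy:
            raise ValueError("branching directions and hierarchy disagree")
        for code, angle in self.branching_directions.items():
            if not any(lo - 1e-9 <= angle <= hi + 1e-9
                       for lo, hi in self.zones.get(code, [])):
                raise ValueError(f"direction of {code} lies outside its zone")

    def to_json(self) -> str:
        return json.dumps({
            "side": self.side,
            "branching_directions": {k: round(v, 2) for k, v in self.branching_directions.items()},
            "fork_positions": {k: [round(a, 2), round(b, 2)]
                               for k, (a, b) in self.fork_positions.items()},
            "zones": {k: [[round(a, 2), round(b, 2)] for a, b in v]
                      for k, v in self.zones.items()},
            "hierarchy": self.hierarchy,
            "skull_marks": {k: round(v, 2) for k, v in self.skull_marks.items()},
        }, indent=1)


def _codes_in_hierarchy(hierarchy: str) -> list[str]:
    out, token = [], ""
    for ch in hierarchy:
        if ch in "(),":
            if token and token != "base":
                out.append(token)
            token = ""
        else:
            token += ch
    if token and token != "base":
        out.append(token)
    return out


def _hierarchy(node: TineNode) -> str:
    label = "" if node.code == "base" else node.code
    if node.is_leaf:
        return label
    return f"{label}({_hierarchy(node.children[0])},{_hierarchy(node.children[1])})"


def build_diagram(tree: TineTree, skull_marks: dict[str, float] | None = None,
                  side: str | None = None) -> BurrDiagram:
    """Assemble the full burr diagram for one antler.

    ``skull_marks`` (index code -> burr angle in this antler's own anatomical
    handedness) override any marks stored on the tree.  Because all geometry
    is recorded in the antler's own handedness, a right antler and its
    mirror-image left twin yield identical diagrams — the right antler is
    thereby presented in the left-antler convention.
    """
    side = side or tree.side
    marks = dict(tree.skull_marks)
    if skull_marks:
        marks.update(skull_marks)
    marks = {k: v % 360.0 for k, v in marks.items()}

    directions, forks = {}, {}
    if tree.root.is_leaf and tree.root.code == "base":
        return BurrDiagram({}, {}, {}, "base", marks, side=side)
    for node in tree.walk():
        if node.code != "base":
            directions[node.code] = project_to_burr(tree, node.code)
        if node.children:
            forks[_fork_name(node)] = project_fork(tree, _fork_name(node))
    zones = compute_zones(tree)
    diagram = BurrDiagram(directions, forks, zones, _hierarchy(tree.root),
                          marks, side=side)
    diagram.validate()
    return diagram


def delete_tine(tree: TineTree, element: str) -> TineTree:
    """Remove a branching tine; distal projections are unchanged.

    The deleted element must be the first (window) child of its fork.  Its
    sibling's fork record is pushed forward through the fork's unroll map, so
    every branching direction and fork mark distal to the deleted tine comes
    down to the same point on the burr — the invariance the prorated
    projection is designed to guarantee.
    """
    target = tree.node(element)
    parent = tree.parent(target)
    if parent is None or parent.children[0] is not target:
        raise ValueError(f"{element!r} is not a deletable window-side tine")
    if tree.parent(parent) is None:
        raise ValueError("cannot delete a tine of the first fork: its ridge "
                         "anchors the burr coordinate origin")
    if not target.is_leaf:
        raise ValueError(f"{element!r} has distal structure; delete its tips first")

    def clone(node: TineNode) -> TineNode:
        return TineNode(node.code, node.category, node.length, node.diameter,
                        node.circumference,
                        Fork(node.fork.ridge, node.fork.boundary) if node.fork else None,
                        [clone(c) for c in node.children])

    new_root = clone(tree.root)

    def find(node, path):
        if not path:
            return node
        return find(node.children[path[0]], path[1:])

    # path to the parent fork in the clone
    path = []
    cur = target
    while tree.parent(cur) is not None:
        p = tree.parent(cur)
        path.append(p.children.index(cur))
        cur = p
    path = list(reversed(path))[:-1]
    new_parent = find(new_root, path)

    sib = new_parent.children[1]
    beta = new_parent.fork.boundary

    def push(a: float) -> float:  # continuation unroll: [0,1) -> [beta, 1)
        return beta + a * (1.0 - beta)

    merged = TineNode(new_parent.code, new_parent.category,
                      new_parent.length + sib.length, new_parent.diameter,
                      new_parent.circumference,
                      Fork(push(sib.fork.ridge), push(sib.fork.boundary))
                      if sib.fork else None,
                      sib.children)
    grandparent = find(new_root, path[:-1])
    grandparent.children[path[-1]] = merged
    return TineTree(new_root, side=tree.side, skull_marks=tree.skull_marks)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_PALETTE = ["#e5704c", "#66a61e", "#7570b3", "#e7a838", "#1b9e77", "#d95f88",
            "#8c6d31", "#4c78a8", "#b2df8a", "#a6761d", "#e41a1c", "#80b1d3"]


def _pol(cx, cy, r, angle_deg):
    # diagram drawn with 0 deg at the top, increasing clockwise
    rad = math.radians(angle_deg - 90.0)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def render_diagram(diagram: BurrDiagram, size: int = 360) -> str:
    """Render the diagram as an SVG document (string).

    Large circle = burr cross-section, dots = branching directions, short
    orthogonal ticks = fork positions, painted sectors = zones, centre dot =
    antler base, outer labels = skull indices.
    """
    cx = cy = size / 2.0
    r = size * 0.32
    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg",
                     width=str(size), height=str(size))
    for i, (code, arcs) in enumerate(sorted(diagram.zones.items())):
        colour = _PALETTE[i % len(_PALETTE)]
        for lo, hi in arcs:
            if hi - lo <= 0:
                continue
            x1, y1 = _pol(cx, cy, r, lo)
            x2, y2 = _pol(cx, cy, r, hi)
            large = "1" if hi - lo > 180.0 else "0"
            d = (f"M {cx:.2f} {cy:.2f} L {x1:.2f} {y1:.2f} "
                 f"A {r:.2f} {r:.2f} 0 {large} 1 {x2:.2f} {y2:.2f} Z")
            ET.SubElement(svg, "path", d=d, fill=colour, opacity="0.35",
                          **{"class": f"zone zone-{code}"})
    ET.SubElement(svg, "circle", cx=str(cx), cy=str(cy), r=f"{r:.2f}",
                  fill="none", stroke="black", attrib={"stroke-width": "1.5"})
    for fork_id, (lat, med) in diagram.fork_positions.items():
        for angle in (lat, med):
            x1, y1 = _pol(cx, cy, r * 0.93, angle)
            x2, y2 = _pol(cx, cy, r * 1.07, angle)
            ET.SubElement(svg, "line", x1=f"{x1:.2f}", y1=f"{y1:.2f}",
                          x2=f"{x2:.2f}", y2=f"{y2:.2f}", stroke="black",
                          **{"class": f"fork fork-{fork_id.replace('/', '-')}"})
    for code, angle in diagram.branching_directions.items():
        x, y = _pol(cx, cy, r, angle)
        ET.SubElement(svg, "circle", cx=f"{x:.2f}", cy=f"{y:.2f}", r="4",
                      fill="black", **{"class": f"dot dot-{code}"})
        tx, ty = _pol(cx, cy, r * 0.82, angle)
        label = ET.SubElement(svg, "text", x=f"{tx:.2f}", y=f"{ty:.2f}",
                              attrib={"font-size": "11", "text-anchor": "middle"})
        label.text = code
    for code, angle in diagram.skull_marks.items():
        x, y = _pol(cx, cy, r * 1.18, angle)
        mark = ET.SubElement(svg, "text", x=f"{x:.2f}", y=f"{y:.2f}",
                             attrib={"font-size": "10", "text-anchor": "middle",
                                     "fill": "#555"})
        mark.text = code
        x1, y1 = _pol(cx, cy, r * 1.08, angle)
        x2, y2 = _pol(cx, cy, r * 1.12, angle)
        ET.SubElement(svg, "line", x1=f"{x1:.2f}", y1=f"{y1:.2f}",
                      x2=f"{x2:.2f}", y2=f"{y2:.2f}", stroke="#555")
    ET.SubElement(svg, "circle", cx=str(cx), cy=str(cy), r="3", fill="black",
                  **{"class": "base"})
    return ET.tostring(svg, encoding="unicode")
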