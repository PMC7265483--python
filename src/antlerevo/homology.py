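"""Diagram signatures and interspecific homology of antler elements.

Homology is decided symbolically: two elements in two diagrams are homologous
when they occupy the same position in the diagram — the same ordinal
relations to skull indices, other branching directions and fork marks, the
same branching-hierarchy depth, and the same fork partner.  Raw angles never
enter the verdict, so it is invariant under rotation of a whole diagram and
under uniform scaling of the geometry.

Directional predicates (anterior/posterior/medial/lateral) encode on which
side of a reference mark an element lies: the signed circular displacement
from the reference to the element, named by the compass pole nearest the
reference.  The compass is diagram-intrinsic, anchored on the skull indices:
the anterior pole is the supraorbital ridge (SR), the lateral pole the
temporal ridge (TR), the posterior pole the nerve-field boundary (BN) and
the medial pole opposite TR.  A mark just past the temporal ridge in the
increasing-angle direction is therefore "posterior to TR", one just short of
it "anterior to TR", mirroring how such positions are stated anatomically.
Qualified statements ("slightly lateral") collapse onto the unqualified
predicate; near-antipodal pairs carry no stable side and yield no
directional predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .projection import BurrDiagram

__all__ = [
    "ElementSignature",
    "extract_signature",
    "match_elements",
    "consensus_signature",
    "classify_category",
    "DEFAULT_TOLERANCE_DEG",
]

DEFAULT_TOLERANCE_DEG = 5.0

#: moving in the increasing-angle direction sweeps anterior -> lateral ->
#: posterior -> medial; the tuple gives the (+, -) direction names at each pole
_DIRECTIONS = {
    "anterior": ("lateral", "medial"),
    "lateral": ("posterior", "anterior"),
    "posterior": ("medial", "lateral"),
    "medial": ("anterior", "posterior"),
}


def _circdist(a: float, b: float) -> float:
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def _signed(a: float, b: float) -> float:
    """Signed displacement from b to a in (-180, 180]."""
    return ((a - b + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class ElementSignature:
    """Symbolic position of one element on a burr diagram."""

    element: str
    relations: frozenset[tuple[str, str]]  # (predicate, reference mark)
    hierarchy_depth: int
    hierarchy_partner: str | None
    reference_marks: frozenset[str]
    tolerance_deg: float = DEFAULT_TOLERANCE_DEG

    def restricted(self, marks: frozenset[str]) -> frozenset[tuple[str, str]]:
        return frozenset(r for r in self.relations if r[1] in marks)


def _axes(diagram: BurrDiagram) -> dict[str, float]:
    marks = diagram.skull_marks
    anterior = marks.get("SR", 0.0)
    lateral = marks.get("TR", (anterior + 90.0) % 360.0)
    posterior = marks.get("BN", (anterior + 180.0) % 360.0)
    return {
        "anterior": anterior,
        "lateral": lateral,
        "posterior": posterior,
        "medial": (lateral + 180.0) % 360.0,
    }


def _landmarks(diagram: BurrDiagram) -> dict[str, float]:
    """All reference marks of a diagram: dots, fork marks, skull indices."""
    out: dict[str, float] = {}
    for code, angle in diagram.branching_directions.items():
        out[f"dir:{code}"] = angle
    for fork, (lat, med) in diagram.fork_positions.items():
        out[f"fork:{fork}:lat"] = lat
        out[f"fork:{fork}:med"] = med
    for code, angle in diagram.skull_marks.items():
        out[f"skull:{code}"] = angle
    return out


def _depth_and_partner(diagram: BurrDiagram, element: str) -> tuple[int, str | None]:
    """Fork count from the antler base, and the code bifurcating against it."""
    text = diagram.hierarchy
    idx = _find_code(text, element)
    depth = 0
    partner_span = None
    # walk outward counting enclosing parentheses; the partner is the other
    # member of the innermost enclosing pair
    opens = []
    spans = _paren_spans(text)
    for (start, end, comma) in spans:
        if start < idx[0] and idx[1] <= end:
            opens.append((start, end, comma))
    if not opens:
        return 0, None
    depth = len(opens)
    start, end, comma = max(opens, key=lambda s: s[0])
    if idx[0] > comma:
        partner_span = (start + 1, comma)
    else:
        partner_span = (comma + 1, end)
    partner_text = text[partner_span[0]:partner_span[1]]
    partner = partner_text.split("(")[0].strip(",)") or None
    return depth, partner


def _find_code(text: str, code: str) -> tuple[int, int]:
    i = 0
    while i < len(text):
        j = text.find(code, i)
        if j < 0:
            break
        before = text[j - 1] if j else "("
        after = text[j + len(code)] if j + len(code) < len(text) else ")"
        if before in "(), " and after in "(),":
            return j, j + len(code)
        i = j + 1
    raise KeyError(f"element {code!r} not in hierarchy {text!r}")


def _paren_spans(text: str) -> list[tuple[int, int, int]]:
    """(open, close, top-level comma) index triples for each paren pair."""
    stack, spans = [], []
    commas: dict[int, int] = {}
    for i, ch in enumerate(text):
        if ch == "(":
            stack.append(i)
        elif ch == ",":
            if stack:
                commas.setdefault(stack[-1], i)
        elif ch == ")":
            start = stack.pop()
            spans.append((start, i, commas.get(start, start)))
    return spans


def extract_signature(diagram: BurrDiagram, element: str,
                      tolerance_deg: float = DEFAULT_TOLERANCE_DEG) -> ElementSignature:
    """Extract the symbolic signature of one element from a diagram."""
    if element not in diagram.branching_directions:
        raise KeyError(f"element {element!r} not in diagram")
    theta = diagram.branching_directions[element]
    axes = _axes(diagram)
    landmarks = _landmarks(diagram)
    own = f"dir:{element}"
    relations: set[tuple[str, str]] = set()
    for name, angle in landmarks.items():
        if name == own:
            continue
        d = _signed(theta, angle)
        if abs(d) <= tolerance_deg:
            relations.add(("coincides_with", name))
            continue
        if 180.0 - abs(d) <= tolerance_deg:
            continue  # antipodal: no stable side
        pole = min(axes, key=lambda p: _circdist(angle, axes[p]))
        label = _DIRECTIONS[pole][0 if d > 0 else 1]
        relations.add((f"{label}_to", name))
    depth, partner = _depth_and_partner(diagram, element)
    return ElementSignature(
        element=element,
        relations=frozenset(relations),
        hierarchy_depth=depth,
        hierarchy_partner=partner,
        reference_marks=frozenset(n for n in landmarks if n != own),
        tolerance_deg=tolerance_deg,
    )


def match_elements(sig_a: ElementSignature, sig_b: ElementSignature
                   ) -> tuple[str, list[str]]:
    """Compare two signatures; ``("homologous", [])`` or the violations.

    Ordinal relations are compared restricted to reference marks available in
    both diagrams; hierarchy depth and fork partner must also agree.  A mark
    that yielded no predicate in one of the two signatures sat in its
    uninformative near-antipodal band and is excluded from the comparison.
    """
    violations: list[str] = []
    shared = (sig_a.reference_marks & sig_b.reference_marks
              & {ref for _, ref in sig_a.relations}
              & {ref for _, ref in sig_b.relations})
    rel_a, rel_b = sig_a.restricted(shared), sig_b.restricted(shared)
    for pred, ref in sorted(rel_a - rel_b):
        violations.append(f"{sig_a.element} {pred} {ref} (first only)")
    for pred, ref in sorted(rel_b - rel_a):
        violations.append(f"{sig_b.element} {pred} {ref} (second only)")
    if sig_a.hierarchy_depth != sig_b.hierarchy_depth:
        violations.append(
            f"hierarchy depth {sig_a.hierarchy_depth} != {sig_b.hierarchy_depth}")
    if sig_a.hierarchy_partner != sig_b.hierarchy_partner:
        violations.append(
            f"fork partner {sig_a.hierarchy_partner} != {sig_b.hierarchy_partner}")
    return ("homologous" if not violations else "not_homologous", violations)


def consensus_signature(signatures: list[ElementSignature],
                        weights: list[float] | None = None) -> ElementSignature:
    """Majority-rule species signature over specimen signatures.

    A relation is kept when it holds in more than half the total weight; ties
    follow the largest-weight specimen set.
    """
    if not signatures:
        raise ValueError("no signatures to form a consensus from")
    if weights is None:
        weights = [1.0] * len(signatures)
    total = sum(weights)
    counts: dict[tuple[str, str], float] = {}
    for sig, w in zip(signatures, weights):
        for rel in sig.relations:
            counts[rel] = counts.get(rel, 0.0) + w
    heaviest = signatures[max(range(len(signatures)), key=lambda i: weights[i])]
    kept = frozenset(
        rel for rel, w in counts.items()
        if w > total / 2.0 or (w == total / 2.0 and rel in heaviest.relations)
    )
    marks: set[str] = set()
    for sig in signatures:
        marks |= sig.reference_marks
    return ElementSignature(
        element=signatures[0].element,
        relations=kept,
        hierarchy_depth=heaviest.hierarchy_depth,
        hierarchy_partner=heaviest.hierarchy_partner,
        reference_marks=frozenset(marks),
        tolerance_deg=signatures[0].tolerance_deg,
    )


def classify_category(length: float, basal_diameter: float) -> str:
    """Tines and beams are longer than twice their basal diameter; shorter
    projections are processes.  The boundary is strict."""
    if length <= 0 or basal_diameter <= 0:
        raise ValueError("length and basal diameter must be positive")
    return "tine_or_beam" if length > 2.0 * basal_diameter else "process"
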