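"""The 16 five-part stimulus objects and synthetic test fixtures.

Every stimulus shares a common elongated body (``P0``) at the origin and
draws one of two interchangeable parts at each of four fixed locations:
``L1``: P1/P2 at voxel (0,-1,0), ``L2``: P3/P4 at (1,0,0), ``L3``: P5/P6
at (-1,1,0), and ``L4``: P7/P8 nested one level deeper at (0,1,0) under
L3's node.  A stimulus is therefore summarized by a 4-bit *list-of-parts
code*; 2^4 = 16 objects.

The exact geometry of the original multi-part "Fribble" parts is not
publicly available; the templates here are simplified box primitives
inside the part's bounding cube.  They are chosen so that the
qualitative part relations the model's behavior depends on hold by
construction: P8 is the smallest part and nearly a subset of P7
(confusable pair), while all other part pairs are clearly distinct.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .grammar import Node, ObjectRepresentation, canonical_key

Code = tuple[int, int, int, int]

#: Variable-location metadata: (level-1 voxel, (part if bit 0, part if bit 1)).
#: L4's entry is the nested voxel under L3's S node.
LOCATIONS = (
    ((0, -1, 0), ("P1", "P2")),
    ((1, 0, 0), ("P3", "P4")),
    ((-1, 1, 0), ("P5", "P6")),
    ((0, 1, 0), ("P7", "P8")),
)

# ---------------------------------------------------------------------------
# part templates
#
# Templates are lists of axis-aligned boxes in part-local coordinates
# (workspace edge w = 1), all inside the part bounding cube
# [-1/6, 1/6]^3 except P0, the elongated body (length 0.9 along y,
# half-width 0.12).  Shapes are simple extrusions chosen so that each
# interchangeable pair differs grossly, P8 is the smallest part, and P7
# differs from P8 only by extra plate thickness that protrudes into free
# space above the object -- which keeps the pair confusable yet leaves
# both forward models a strictly nonzero trace of the difference.

_H = 1.0 / 6.0  # half-edge of the part bounding cube


def _box(lo, hi) -> np.ndarray:
    return np.array([lo, hi], dtype=float)


PART_TEMPLATES: dict[str, np.ndarray] = {
    # common body: a tall column through the object center
    "P0": np.array([[[-0.12, -0.45, -0.12], [0.12, 0.45, 0.12]]]),
    # Each of P1..P6 fills a grossly different *sector* of the part cube
    # (half-cube slabs in different orientations, mirrored diagonal cube
    # pairs), so that replacing one part by another empties whole ray
    # corridors and image regions rather than nudging surfaces by a few
    # hundredths -- the contrast both forward models rely on.
    # upper half of the cube in z
    "P1": np.stack([_box((-_H, -_H, 0.0), (_H, _H, _H))]),
    # lower half of the cube in z
    "P2": np.stack([_box((-_H, -_H, -_H), (_H, _H, 0.0))]),
    # high-x half of the cube
    "P3": np.stack([_box((0.0, -_H, -_H), (_H, _H, _H))]),
    # low-x half of the cube
    "P4": np.stack([_box((-_H, -_H, -_H), (0.0, _H, _H))]),
    # thick corner column toward +x,+z (single convex block; unions of
    # smaller blocks proved too easy for inference to mis-decompose)
    "P5": np.stack([_box((-_H / 3, -_H, -_H / 3), (_H, _H, _H))]),
    # the opposite corner column, toward -x,-z
    "P6": np.stack([_box((-_H, -_H, -_H), (_H / 3, _H, _H / 3))]),
    # 0.3 x 0.3 plate near the top of the cube in y, 0.125 thick; small
    # enough not to shadow the part below it from above, wide enough that
    # the grasp-ray lattice always meets it
    "P7": np.stack([_box((-0.15, 1.0 / 24.0, -0.15), (0.15, _H, 0.15))]),
    # the same plate, slightly thinner: smallest part, subset of P7
    "P8": np.stack([_box((-0.15, 1.0 / 24.0, -0.15), (0.15, _H - 0.02, 0.15))]),
}


def template_cell_set(part: str, n: int = 24) -> set[tuple[int, int, int]]:
    """Occupied cells of a P1..P8 template on an n^3 grid over the part
    bounding cube (used for distinguishability/confusability checks)."""
    boxes = PART_TEMPLATES[part]
    cells = set()
    for i, j, k in itertools.product(range(n), repeat=3):
        center = (np.array([i, j, k]) + 0.5) * (2 * _H / n) - _H
        for lo, hi in boxes:
            if np.all(center > lo) and np.all(center < hi):
                cells.add((i, j, k))
                break
    return cells


def template_volume(part: str) -> float:
    """Occupied volume of a template, by fine-grid rasterization (boxes
    may overlap, so summing box volumes would overcount)."""
    if part == "P0":
        lo, hi = PART_TEMPLATES[part][0]
        return float(np.prod(hi - lo))
    return len(template_cell_set(part, 24)) * (2 * _H / 24) ** 3


# ---------------------------------------------------------------------------
# object construction


def _normalize_code(code) -> Code:
    if isinstance(code, str):
        if len(code) != 4 or set(code) - {"0", "1"}:
            raise ValueError(f"part code string must be 4 bits, got {code!r}")
        return tuple(int(c) for c in code)  # type: ignore[return-value]
    if isinstance(code, int):
        if not 0 <= code < 16:
            raise ValueError("integer part code must be in [0, 16)")
        return tuple((code >> (3 - i)) & 1 for i in range(4))  # type: ignore[return-value]
    code = tuple(int(c) for c in code)
    if len(code) != 4 or set(code) - {0, 1}:
        raise ValueError(f"part code must be 4 bits, got {code!r}")
    return code  # type: ignore[return-value]


def code_string(code) -> str:
    return "".join(str(b) for b in _normalize_code(code))


def make_object(code, workspace_edge: float = 1.0) -> ObjectRepresentation:
    """Build the stimulus for a 4-bit list-of-parts code.

    The layout mirrors the grammar's canonical example: the root expands
    ``S -> P S S S`` holding the body P0, the first three S children sit
    at the three level-1 voxels, and L4's part hangs one level deeper
    under L3's node.
    """
    bits = _normalize_code(code)

    def part_node(part: str) -> Node:
        return Node("P", [Node(part)])

    (v1, p1s), (v2, p2s), (v3, p3s), (v4, p4s) = LOCATIONS
    s_a = Node("S", [part_node(p1s[bits[0]])], coord=v1)
    s_b = Node("S", [part_node(p2s[bits[1]])], coord=v2)
    s_d = Node("S", [part_node(p4s[bits[3]])], coord=v4)
    s_c = Node("S", [part_node(p3s[bits[2]]), s_d], coord=v3)
    root = Node("S", [part_node("P0"), s_a, s_b, s_c])
    return ObjectRepresentation(root, workspace_edge)


def all_objects(workspace_edge: float = 1.0) -> list[ObjectRepresentation]:
    """The 16 stimuli, ordered by their code read as a binary integer."""
    return [make_object(i, workspace_edge) for i in range(16)]


def all_codes() -> list[Code]:
    return [_normalize_code(i) for i in range(16)]


def part_code_of(rep: ObjectRepresentation) -> Code:
    """Inverse of :func:`make_object`; raises for non-stimulus trees."""
    key = canonical_key(rep)
    for i in range(16):
        if canonical_key(make_object(i, rep.workspace_edge)) == key:
            return _normalize_code(i)
    raise ValueError("representation is not one of the 16 stimulus objects")


def hamming(code_a, code_b) -> int:
    a, b = _normalize_code(code_a), _normalize_code(code_b)
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# synthetic similarity ratings


RATING_CONDITIONS = ("visual", "haptic", "crossmodal", "multisensory")


def synth_ratings(
    noise_sd: float = 0.5,
    n_subjects: int = 7,
    n_blocks: int = 4,
    seed: int = 0,
    conditions: tuple[str, ...] = RATING_CONDITIONS,
) -> pd.DataFrame:
    """Emulated 1-7 similarity ratings driven by the list-of-parts code.

    For every subject, block and unordered object pair (136 per block) the
    rating is ``clamp(round(7 - 1.5 * Hamming(codes) + noise), 1, 7)`` so
    the 7..1 scale spans Hamming distances 0..4, mimicking raters who
    track shared parts.  Defaults mirror the study design: 7 subjects per
    condition, 4 blocks of 136 trials.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    codes = all_codes()
    pairs = [(i, j) for i in range(16) for j in range(i, 16)]
    rows = []
    for condition in conditions:
        for subject in range(1, n_subjects + 1):
            for block in range(1, n_blocks + 1):
                for i, j in pairs:
                    base = 7.0 - 1.5 * hamming(codes[i], codes[j])
                    noisy = base + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                    rating = int(np.clip(np.round(noisy), 1, 7))
                    rows.append(
                        {
                            "subject": f"{condition[:2]}{subject:02d}",
                            "condition": condition,
                            "block": block,
                            "object_a": code_string(codes[i]),
                            "object_b": code_string(codes[j]),
                            "rating": rating,
                        }
                    )
    return pd.DataFrame(rows)
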