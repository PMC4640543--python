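"""Probabilistic shape grammar over part-based 3-D objects.

An object is a derivation of the context-free grammar

    S -> P | P S | P S S | P S S S
    P -> P0 | P1 | ... | P8

where ``S`` (spatial) nodes carve 3-D space into a multi-resolution voxel
grid and ``P`` (part) nodes attach one of nine object parts.  A *spatial
tree* augments the parse tree with one voxel coordinate per non-root S
node, drawn from the 26 offsets ``{-1,0,1}^3 \\ {(0,0,0)}``; the root S
node is pinned to the origin.  The pair (parse tree, spatial assignment)
is the modality-independent object representation that the rest of the
package renders, grasps, and infers.

The prior over representations factorizes as
``P(T, S | G) = P(T | G) P(S | T)`` where ``P(T | G)`` marginalizes the
production probabilities under a uniform Dirichlet (a Multinomial-
Dirichlet form solved with multinomial beta functions) and ``P(S | T)``
is uniform over voxel assignments, ``|V|^-|N_S|``.  Both factors shrink
with tree size, so the prior is an Occam's razor over part count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.special import gammaln

Coord = tuple[int, int, int]

#: The 26 voxel offsets available to a non-root S node.
ALL_VOXELS: tuple[Coord, ...] = tuple(
    (x, y, z)
    for x in (-1, 0, 1)
    for y in (-1, 0, 1)
    for z in (-1, 0, 1)
    if (x, y, z) != (0, 0, 0)
)

S_PRODUCTIONS: tuple[tuple[str, ...], ...] = (
    ("P",),
    ("P", "S"),
    ("P", "S", "S"),
    ("P", "S", "S", "S"),
)

DEFAULT_TERMINALS: tuple[str, ...] = tuple(f"P{i}" for i in range(9))

#: Resampling cap on the number of parts in a sampled (sub)derivation.  The
#: grammar's branching process is supercritical under uniform rule
#: probabilities (mean offspring 1.5), so unbounded sampling diverges with
#: positive probability.  Rejecting and redrawing oversized subtrees leaves
#: every Metropolis-Hastings ratio exact because the retry normalization
#: depends only on the start symbol and cancels between forward and reverse
#: proposals.
DEFAULT_MAX_PARTS = 30


class GrammarError(ValueError):
    """A tree or document violates the grammar's structural invariants."""


@dataclass(frozen=True)
class Grammar:
    """The shape grammar: symbol sets, productions, and the voxel set.

    ``voxels`` is configurable (a subset of the 26 offsets) so that test
    oracles can enumerate tiny state spaces; the prior, the proposal
    kernels and the spatial normalization all read ``|V|`` from here, so
    a restricted grammar stays internally consistent.
    """

    terminals: tuple[str, ...] = DEFAULT_TERMINALS
    voxels: tuple[Coord, ...] = ALL_VOXELS

    nonterminals: tuple[str, str] = ("S", "P")

    def __post_init__(self) -> None:
        if len(self.terminals) < 1:
            raise GrammarError("grammar needs at least one terminal part")
        if len(self.voxels) < 1:
            raise GrammarError("grammar needs at least one voxel offset")
        if (0, 0, 0) in self.voxels:
            raise GrammarError("(0, 0, 0) is not a valid voxel offset")

    def productions(self, symbol: str) -> tuple[tuple[str, ...], ...]:
        if symbol == "S":
            return S_PRODUCTIONS
        if symbol == "P":
            return tuple((t,) for t in self.terminals)
        raise GrammarError(f"{symbol!r} is not a non-terminal of this grammar")


@dataclass(frozen=True)
class RuleProbabilities:
    """Probability vectors over the productions of each non-terminal."""

    s_probs: tuple[float, ...]
    p_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, probs in (("S", self.s_probs), ("P", self.p_probs)):
            arr = np.asarray(probs, dtype=float)
            if np.any(arr < 0):
                raise GrammarError(f"negative probability in {name} rules")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise GrammarError(f"{name} rule probabilities do not sum to 1")

    @classmethod
    def uniform(cls, grammar: Grammar) -> "RuleProbabilities":
        ns, np_ = len(S_PRODUCTIONS), len(grammar.terminals)
        return cls((1.0 / ns,) * ns, (1.0 / np_,) * np_)

    def for_symbol(self, symbol: str) -> tuple[float, ...]:
        return self.s_probs if symbol == "S" else self.p_probs


@dataclass
class Node:
    """A node of a spatial tree.

    ``symbol`` is ``"S"``, ``"P"``, or a terminal part id (``"P0"``..).
    ``coord`` is the voxel offset of a non-root S node relative to its
    parent S node; ``None`` for the root S node, P nodes, and terminals.
    """

    symbol: str
    children: list["Node"] = field(default_factory=list)
    coord: Coord | None = None

    def copy(self) -> "Node":
        return Node(self.symbol, [c.copy() for c in self.children], self.coord)

    def is_terminal(self, grammar: Grammar) -> bool:
        return self.symbol in grammar.terminals


@dataclass
class SpatialModel:
    """View of the voxel assignments of a tree's non-root S nodes."""

    tree: Node
    workspace_edge: float = 1.0

    @property
    def assignments(self) -> list[Coord]:
        return [n.coord for n in iter_s_nodes(self.tree) if n.coord is not None]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class ObjectRepresentation:
    """A parse tree plus its spatial model: the modality-independent code."""

    root: Node
    workspace_edge: float = 1.0

    @property
    def tree(self) -> Node:
        return self.root

    @property
    def spatial(self) -> SpatialModel:
        return SpatialModel(self.root, self.workspace_edge)

    def copy(self) -> "ObjectRepresentation":
        return ObjectRepresentation(self.root.copy(), self.workspace_edge)


# ---------------------------------------------------------------------------
# traversal helpers


def iter_nodes(root: Node) -> Iterator[Node]:
    """Preorder traversal of every node (including terminals)."""
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def iter_s_nodes(root: Node) -> Iterator[Node]:
    return (n for n in iter_nodes(root) if n.symbol == "S")


def iter_nonterminal_nodes(root: Node) -> Iterator[Node]:
    return (n for n in iter_nodes(root) if n.symbol in ("S", "P"))


def count_parts(root: Node) -> int:
    return sum(1 for n in iter_nodes(root) if n.symbol == "P")


def part_multiset(root: Node, grammar: Grammar) -> list[str]:
    return sorted(n.symbol for n in iter_nodes(root) if n.is_terminal(grammar))


def validate(root: Node, grammar: Grammar, *, is_root: bool = True) -> None:
    """Check the grammar's structural invariants; raise GrammarError if violated."""
    if root.symbol == "S":
        if is_root:
            if root.coord is not None:
                raise GrammarError("root S node must not carry a coordinate")
        else:
            if root.coord is None:
                raise GrammarError("non-root S node lacks a coordinate")
            if tuple(root.coord) == (0, 0, 0):
                raise GrammarError("S node assigned the forbidden voxel (0, 0, 0)")
            if tuple(root.coord) not in grammar.voxels:
                raise GrammarError(f"coordinate {root.coord} outside the voxel set")
        rhs = tuple(c.symbol for c in root.children)
        if rhs not in S_PRODUCTIONS:
            raise GrammarError(f"S node expanded to {rhs!r}, not an S-production")
        for child in root.children:
            validate(child, grammar, is_root=False)
    elif root.symbol == "P":
        if root.coord is not None:
            raise GrammarError("P node must not carry a coordinate")
        if len(root.children) != 1 or not root.children[0].is_terminal(grammar):
            raise GrammarError("P node must have exactly one terminal child")
        if root.children[0].children:
            raise GrammarError("terminal node must be a leaf")
    elif root.is_terminal(grammar):
        raise GrammarError("terminal encountered outside a P node")
    else:
        raise GrammarError(f"unknown symbol {root.symbol!r}")


def validate_representation(rep: ObjectRepresentation, grammar: Grammar) -> None:
    if rep.root.symbol != "S":
        raise GrammarError("root symbol must be S")
    validate(rep.root, grammar)


# ---------------------------------------------------------------------------
# sampling


class _SizeCapExceeded(Exception):
    pass


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _cumulative(probs: tuple[float, ...]) -> list[float]:
    out, acc = [], 0.0
    for p in probs:
        acc += p
        out.append(acc)
    out[-1] = 1.0 + 1e-12
    return out


def _pick(cum: list[float], u: float) -> int:
    for i, c in enumerate(cum):
        if u < c:
            return i
    return len(cum) - 1


def _sample_once(
    symbol: str,
    grammar: Grammar,
    rng: np.random.Generator,
    budget: list[int],
    cum_s: list[float],
    cum_p: list[float],
) -> Node:
    node = Node(symbol)
    if symbol == "P":
        budget[0] -= 1
        if budget[0] < 0:
            raise _SizeCapExceeded
        node.children = [Node(grammar.terminals[_pick(cum_p, rng.random())])]
        return node
    rhs = S_PRODUCTIONS[_pick(cum_s, rng.random())]
    for child_symbol in rhs:
        node.children.append(
            _sample_once(child_symbol, grammar, rng, budget, cum_s, cum_p)
        )
    return node


def sample_derivation(
    grammar: Grammar,
    rho: RuleProbabilities,
    seed: int | np.random.Generator,
    *,
    max_parts: int = DEFAULT_MAX_PARTS,
    start_symbol: str = "S",
) -> Node:
    """Draw a complete parse tree by recursive production sampling.

    The whole draw is rejected and retried if it would exceed ``max_parts``
    parts; conditioning on the cap keeps every draw finite even though the
    uniform-``rho`` branching process is supercritical.  Deterministic for a
    given integer seed.  Coordinates are *not* assigned here; see
    :func:`assign_random_coords`.
    """
    rng = _as_rng(seed)
    cum_s, cum_p = _cumulative(rho.s_probs), _cumulative(rho.p_probs)
    while True:
        try:
            return _sample_once(start_symbol, grammar, rng, [max_parts], cum_s, cum_p)
        except _SizeCapExceeded:
            continue


def assign_random_coords(root: Node, grammar: Grammar, rng: np.random.Generator,
                         *, is_root: bool = True) -> None:
    """Assign a uniform voxel offset to every non-root S node in place."""
    if root.symbol == "S" and not is_root:
        root.coord = grammar.voxels[int(rng.integers(len(grammar.voxels)))]
    for child in root.children:
        assign_random_coords(child, grammar, rng, is_root=False)


def sample_representation(
    grammar: Grammar,
    seed: int | np.random.Generator,
    *,
    rho: RuleProbabilities | None = None,
    max_parts: int = DEFAULT_MAX_PARTS,
    workspace_edge: float = 1.0,
) -> ObjectRepresentation:
    """Draw a full representation (tree + uniform coordinates) from the prior
    shape used to initialize MCMC chains."""
    rng = _as_rng(seed)
    rho = rho or RuleProbabilities.uniform(grammar)
    root = sample_derivation(grammar, rho, rng, max_parts=max_parts)
    assign_random_coords(root, grammar, rng)
    return ObjectRepresentation(root, workspace_edge)


# ---------------------------------------------------------------------------
# priors


def production_counts(root: Node, grammar: Grammar) -> dict[str, np.ndarray]:
    """Per non-terminal, how many times each of its productions fires."""
    cs = np.zeros(len(S_PRODUCTIONS), dtype=int)
    cp = np.zeros(len(grammar.terminals), dtype=int)
    p_rules = {t: i for i, t in enumerate(grammar.terminals)}
    stack = [root]
    while stack:
        node = stack.pop()
        if node.symbol == "S":
            rhs = tuple(c.symbol for c in node.children)
            n_s = len(node.children) - 1
            if not (1 <= len(node.children) <= 4) or rhs[0] != "P" or any(
                s != "S" for s in rhs[1:]
            ):
                raise GrammarError(f"S node expanded to {rhs!r}, not an S-production")
            cs[n_s] += 1
            stack.extend(node.children)
        elif node.symbol == "P":
            term = node.children[0].symbol
            if term not in p_rules:
                raise GrammarError(f"unknown terminal {term!r}")
            cp[p_rules[term]] += 1
    return {"S": cs, "P": cp}


def log_prior_tree_given_rho(
    root: Node, grammar: Grammar, rho: RuleProbabilities
) -> float:
    """log P(T | G, rho): the product of used-rule probabilities.

    Returns ``-inf`` (not an exception) if rho assigns zero mass to a rule
    the tree uses.
    """
    counts = production_counts(root, grammar)
    total = 0.0
    for symbol in ("S", "P"):
        probs = np.asarray(rho.for_symbol(symbol), dtype=float)
        used = counts[symbol]
        if np.any((probs == 0.0) & (used > 0)):
            return -math.inf
        with np.errstate(divide="ignore"):
            logs = np.where(used > 0, np.log(np.where(probs > 0, probs, 1.0)), 0.0)
        total += float(np.dot(used, logs))
    return total


def _log_multinomial_beta(alpha: np.ndarray) -> float:
    return float(np.sum(gammaln(alpha)) - gammaln(np.sum(alpha)))


_PRIOR_CACHE: dict[tuple, float] = {}


def log_prior_tree(root: Node, grammar: Grammar) -> float:
    """log P(T | G): the Dirichlet-marginalized derivation probability,
    ``sum_s [log beta(C(T,s) + 1) - log beta(1)]`` in log-gamma arithmetic."""
    counts = production_counts(root, grammar)
    key = (tuple(counts["S"]), tuple(counts["P"]))
    hit = _PRIOR_CACHE.get(key)
    if hit is not None:
        return hit
    total = 0.0
    for symbol in ("S", "P"):
        c = counts[symbol].astype(float)
        ones = np.ones_like(c)
        total += _log_multinomial_beta(c + ones) - _log_multinomial_beta(ones)
    if len(_PRIOR_CACHE) > 100_000:
        _PRIOR_CACHE.clear()
    _PRIOR_CACHE[key] = total
    return total


def log_prior_spatial(
    spatial: SpatialModel | ObjectRepresentation,
    grammar: Grammar | None = None,
) -> float:
    """log P(S | T) = -|N_S| log |V|, with N_S the non-root S nodes."""
    n_voxels = len(grammar.voxels) if grammar is not None else len(ALL_VOXELS)
    tree = spatial.tree if isinstance(spatial, (SpatialModel, ObjectRepresentation)) else spatial
    n_assigned = sum(1 for n in iter_s_nodes(tree) if n.coord is not None)
    return -n_assigned * math.log(n_voxels)


def log_prior_joint(rep: ObjectRepresentation, grammar: Grammar) -> float:
    """log P(T, S | G) = log P(T | G) + log P(S | T)."""
    return log_prior_tree(rep.root, grammar) + log_prior_spatial(rep.spatial, grammar)


# ---------------------------------------------------------------------------
# geometry


def absolute_part_positions(
    rep: ObjectRepresentation,
) -> list[tuple[str, np.ndarray]]:
    """Place each terminal part in workspace coordinates.

    The root S node sits at the origin; a non-root S node at depth ``d``
    (root depth 0) with offset ``v`` is centered at
    ``parent_center + v * (w / 3**d)``.  A part is placed at the center of
    the S node whose P child produced it.
    """
    w = rep.workspace_edge
    out: list[tuple[str, np.ndarray]] = []

    def walk(node: Node, center: np.ndarray, depth: int) -> None:
        for child in node.children:
            if child.symbol == "S":
                offset = np.asarray(child.coord, dtype=float) * (w / 3 ** (depth + 1))
                walk(child, center + offset, depth + 1)
            elif child.symbol == "P":
                out.append((child.children[0].symbol, center.copy()))

    walk(rep.root, np.zeros(3), 0)
    return out


# ---------------------------------------------------------------------------
# canonical form and (de)serialization


def _node_to_obj(node: Node) -> dict:
    obj: dict = {"symbol": node.symbol}
    if node.coord is not None:
        obj["coordinate"] = list(node.coord)
    if node.children:
        obj["children"] = [_node_to_obj(c) for c in node.children]
    return obj


def _canonical_key(node: Node) -> str:
    coord = "" if node.coord is None else ",".join(map(str, node.coord))
    inner = "|".join(_canonical_key(c) for c in node.children)
    return f"{node.symbol}[{coord}]({inner})"


def canonicalize(rep: ObjectRepresentation) -> ObjectRepresentation:
    """Sort the S-children of every S node by their canonical subtree string.

    The grammar leaves sibling order meaningless; fixing it makes tree
    equality and the ordered tree edit distance well-defined.  Idempotent,
    and preserves the multiset of absolute part positions (only siblings
    are permuted).
    """

    def sort_node(node: Node) -> Node:
        children = [sort_node(c) for c in node.children]
        if node.symbol == "S":
            head = [c for c in children if c.symbol == "P"]
            tail = sorted(
                (c for c in children if c.symbol == "S"), key=_canonical_key
            )
            children = head + tail
        return Node(node.symbol, children, node.coord)

    return ObjectRepresentation(sort_node(rep.root), rep.workspace_edge)


def tree_key(node: Node) -> tuple:
    """Hashable structural key (symbol, coord, children keys)."""
    return (node.symbol, node.coord, tuple(tree_key(c) for c in node.children))


def canonical_key(rep: ObjectRepresentation) -> tuple:
    return tree_key(canonicalize(rep).root)


def trees_equal(a: ObjectRepresentation, b: ObjectRepresentation) -> bool:
    """Equality up to sibling order (compares canonical forms)."""
    return canonical_key(a) == canonical_key(b)


def serialize(rep: ObjectRepresentation) -> str:
    """JSON document for one object representation (UTF-8, one object/file)."""
    doc = {
        "workspace_edge": rep.workspace_edge,
        "tree": _node_to_obj(rep.root),
    }
    return json.dumps(doc, indent=2)


def _node_from_obj(obj: dict, grammar: Grammar, path: str) -> Node:
    if not isinstance(obj, dict) or "symbol" not in obj:
        raise GrammarError(f"malformed node at {path}: missing 'symbol'")
    symbol = obj["symbol"]
    coord = obj.get("coordinate")
    if coord is not None:
        coord = tuple(int(c) for c in coord)
        if len(coord) != 3:
            raise GrammarError(f"node at {path}: coordinate must have 3 entries")
    children = [
        _node_from_obj(c, grammar, f"{path}.children[{i}]")
        for i, c in enumerate(obj.get("children", []))
    ]
    return Node(symbol, children, coord)


def parse(
    text: str, grammar: Grammar | None = None
) -> ObjectRepresentation:
    """Inverse of :func:`serialize`; validates all structural invariants."""
    grammar = grammar or Grammar()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GrammarError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "tree" not in doc:
        raise GrammarError("document must be an object with a 'tree' field")
    root = _node_from_obj(doc["tree"], grammar, "tree")
    rep = ObjectRepresentation(root, float(doc.get("workspace_edge", 1.0)))
    validate_representation(rep, grammar)
    return rep


def load(path) -> ObjectRepresentation:
    with open(path, encoding="utf-8") as fh:
        return parse(fh.read())


def save(rep: ObjectRepresentation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(rep))
        fh.write("\n")


# ---------------------------------------------------------------------------
# enumeration (test oracle support)


def enumerate_trees(
    grammar: Grammar,
    max_parts: int,
    *,
    with_coords: bool = True,
    max_states: int = 500_000,
) -> list[ObjectRepresentation]:
    """Every representation with at most ``max_parts`` parts.

    Exponential in ``max_parts`` and ``|voxels|``; intended for restricted
    grammars in tests and the exact-posterior oracle.
    """
    import itertools

    shapes: dict[int, list[Node]] = {}

    def shapes_for(budget: int) -> list[Node]:
        # all S-subtree shapes using between 1 and `budget` parts
        if budget in shapes:
            return shapes[budget]
        out: list[Node] = []
        for rhs in S_PRODUCTIONS:
            n_s_children = len(rhs) - 1
            remaining = budget - 1
            if n_s_children == 0:
                out.append(Node("S", [Node("P", [Node("?")])]))
                continue
            if remaining < n_s_children:
                continue
            child_options = shapes_for(remaining)  # each uses >= 1 part
            for combo in itertools.product(child_options, repeat=n_s_children):
                if sum(count_parts(c) for c in combo) <= remaining:
                    out.append(
                        Node("S", [Node("P", [Node("?")])] + [c.copy() for c in combo])
                    )
        shapes[budget] = out
        return out

    reps: list[ObjectRepresentation] = []
    for shape in shapes_for(max_parts):
        p_nodes = [n for n in iter_nodes(shape) if n.symbol == "P"]
        s_nodes = [n for n in iter_s_nodes(shape)][1:]  # skip root
        term_space = itertools.product(grammar.terminals, repeat=len(p_nodes))
        for terms in term_space:
            coord_space = (
                itertools.product(grammar.voxels, repeat=len(s_nodes))
                if with_coords
                else [()]
            )
            for coords in coord_space:
                root = shape.copy()
                ps = [n for n in iter_nodes(root) if n.symbol == "P"]
                ss = [n for n in iter_s_nodes(root)][1:]
                for node, term in zip(ps, terms):
                    node.children = [Node(term)]
                for node, coord in zip(ss, coords):
                    node.coord = coord
                reps.append(ObjectRepresentation(root))
                if len(reps) > max_states:
                    raise GrammarError(
                        f"enumeration exceeded {max_states} states; restrict the grammar"
                    )
    return reps
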