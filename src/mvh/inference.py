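"""Bayesian inversion of the sensory forward models by Metropolis-Hastings.

The posterior over object representations is

    P(T, S | D, G)  proportional to  P(D | T, S) P(S | T) P(T | G)

with a spherical-Gaussian likelihood ``P(D | T, S) ~ exp(-||D - F(T,S)||^2
/ 2 sigma^2)`` on the modality-scaled feature vector.  Exact computation is
intractable, so a Markov chain alternates two proposal kernels:

* *subtree regeneration* (even iterations): pick a non-terminal node
  uniformly, delete its descendants and regrow them from the grammar with
  uniform rule probabilities, assigning fresh uniform voxel coordinates to
  new S nodes.  The Hastings correction is ``|N_nt|/|N_nt'|`` times the
  uniform-rho probability ratio of the replaced/new subtrees; the uniform
  coordinate proposals cancel exactly against the uniform spatial prior.

* *add/remove part* (odd iterations): with probability 1/2 insert a fresh
  ``S -> P -> part`` chain (uniform part, uniform attachable S node,
  uniform voxel, uniform insertion slot among the parent's ``s + 1``
  S-child positions), otherwise delete a uniformly chosen removable S
  node.  The add acceptance carries the counting factor
  ``|Gt| |A| (s+1) / |R'|`` and the remove acceptance the reciprocal
  ``|R| / (|Gt| |A'| (s'+1))``, so each single move has a unique reverse
  and the kernel satisfies detailed balance exactly on ordered trees --
  including states with interchangeable sibling subtrees (audited
  exhaustively in tests; the insertion-slot factor is what makes the
  audit pass where a plain append-only kernel would not).

A move whose candidate set is empty is an automatic rejection, which keeps
the per-iteration kernel well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import grammar as gr
from .forward import (
    HAPTIC,
    VISUAL,
    GraspConfig,
    RenderConfig,
    SensoryData,
    haptic_features,
)
from .grammar import (
    Grammar,
    Node,
    ObjectRepresentation,
    RuleProbabilities,
    iter_nonterminal_nodes,
    iter_s_nodes,
    log_prior_spatial,
    log_prior_tree,
    log_prior_tree_given_rho,
)

#: Default likelihood variance per stimulus condition.  The features are
#: per-modality scaled by 1/sqrt(dim), so on that scale removing a part
#: shifts ||D - F||^2 by at least ~2.7e-3 (visual), ~8e-3 (haptic), while
#: the Occam prior refunds ~7.9 nats per removed part: sigma^2 must stay
#: below (cost / 15.8) for the true five-part representation to dominate,
#: yet large enough that chains can traverse imperfect intermediate
#: states.  One value per condition, as the free parameter of the model.
DEFAULT_SIGMA2_BY_CONDITION: dict[tuple[str, ...], float] = {
    (VISUAL,): 1.2e-4,
    (HAPTIC,): 4.0e-4,
    (VISUAL, HAPTIC): 4.0e-4,
}

DEFAULT_SIGMA2 = DEFAULT_SIGMA2_BY_CONDITION[(VISUAL,)]


def default_sigma2(modalities: tuple[str, ...]) -> float:
    key = tuple(m for m in (VISUAL, HAPTIC) if m in modalities)
    return DEFAULT_SIGMA2_BY_CONDITION[key]


@dataclass(frozen=True)
class LikelihoodConfig:
    """Per-condition Gaussian likelihood settings.

    ``sigma2=None`` selects the documented default for the condition's
    modality set.
    """

    sigma2: float | None = None
    modalities: tuple[str, ...] = (VISUAL,)

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality is required")
        if self.sigma2 is None:
            object.__setattr__(self, "sigma2", default_sigma2(self.modalities))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule: 10,000 iterations with 6,000 burn-in by default."""

    iterations: int = 10_000
    burn_in: int = 6_000
    seed: int = 0
    max_parts: int = gr.DEFAULT_MAX_PARTS

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")


@dataclass
class IterationRecord:
    representation: ObjectRepresentation  # shared reference, treat as frozen
    log_posterior: float
    proposal: str  # "regen" | "add" | "remove"
    accepted: bool


@dataclass
class ChainTrace:
    records: list[IterationRecord]
    config: ChainConfig

    def __len__(self) -> int:
        return len(self.records)

    @property
    def acceptance_rate(self) -> float:
        return sum(r.accepted for r in self.records) / max(len(self.records), 1)

    def acceptance_rate_by_kind(self) -> dict[str, float]:
        out: dict[str, list[bool]] = {}
        for r in self.records:
            out.setdefault(r.proposal, []).append(r.accepted)
        return {k: sum(v) / len(v) for k, v in out.items()}


@dataclass
class ProposalContext:
    """Candidate-set sizes entering the add/remove acceptance ratios."""

    kind: str
    n_attachable: int = 0  # |A|  (current tree, add move)
    n_removable: int = 0  # |R|  (current tree, remove move)
    n_attachable_new: int = 0  # |A'| (proposed tree)
    n_removable_new: int = 0  # |R'| (proposed tree)
    #: number of insertion slots in the add direction of this move pair
    #: (s + 1 with s the parent's S-child count in the smaller tree)
    slot_choices: int = 1


# ---------------------------------------------------------------------------
# likelihood / posterior


class ForwardEvaluator:
    """Caches forward features and squared distances to a fixed dataset.

    Likelihood evaluations dominate MCMC cost; representations recur
    heavily once a chain settles, so features are memoized by structural
    tree key.  Visual features are held as the renderer's integer images
    (a squared pixel distance is an integer sum divided by the gray-level
    and pixel dimensions); the squared distance is accumulated per
    modality on the 1/sqrt(dim) scale.
    """

    def __init__(
        self,
        data: dict[str, np.ndarray],
        render_cfg: RenderConfig | None = None,
        grasp_cfg: GraspConfig | None = None,
        templates: dict[str, np.ndarray] | None = None,
        max_cache: int = 50_000,
    ) -> None:
        self.data = data
        self.render_cfg = render_cfg or RenderConfig()
        self.grasp_cfg = grasp_cfg or GraspConfig()
        self.templates = templates
        self._cache: dict[tuple, dict[str, np.ndarray]] = {}
        self._max_cache = max_cache

    @classmethod
    def for_target(
        cls,
        rep: ObjectRepresentation,
        modalities: tuple[str, ...],
        render_cfg: RenderConfig | None = None,
        grasp_cfg: GraspConfig | None = None,
        templates: dict[str, np.ndarray] | None = None,
    ) -> "ForwardEvaluator":
        """Evaluator whose dataset is the noiseless forward of ``rep``."""
        ev = cls({}, render_cfg, grasp_cfg, templates)
        ev.data = ev.features(rep, modalities)
        ev._cache.clear()
        return ev

    def features(
        self, rep: ObjectRepresentation, modalities: tuple[str, ...] | None = None
    ) -> dict[str, np.ndarray]:
        modalities = modalities or tuple(self.data)
        key = gr.tree_key(rep.root)
        cached = self._cache.get(key)
        if cached is None:
            cached = {}
            if VISUAL in modalities:
                from .forward import render_images

                cached[VISUAL] = render_images(
                    rep, self.render_cfg, self.templates
                ).reshape(-1)
            if HAPTIC in modalities:
                cached[HAPTIC] = haptic_features(
                    rep, self.grasp_cfg, self.templates
                ).vector
            if len(self._cache) >= self._max_cache:
                self._cache.clear()
            self._cache[key] = cached
        return cached

    def scaled_sq_distance(self, rep: ObjectRepresentation) -> float:
        """||D - F(T,S)||^2 on the modality-scaled feature vector."""
        feats = self.features(rep)
        total = 0.0
        for modality, target in self.data.items():
            f = feats[modality]
            if modality == VISUAL:
                diff = f.astype(np.int32) - target
                total += float(diff @ diff) / (
                    self.render_cfg.pixel_levels**2 * f.size
                )
            else:
                diff = f - target
                total += float(diff @ diff) / f.size
        return total


def log_likelihood(
    data: SensoryData,
    rep: ObjectRepresentation,
    cfg: LikelihoodConfig,
    render_cfg: RenderConfig | None = None,
    grasp_cfg: GraspConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> float:
    """Unnormalized Gaussian log likelihood -||D - F(T,S)||^2 / (2 sigma^2).

    ``data.vector`` must be on the same per-modality-scaled scale that
    :func:`mvh.forward.forward` produces; the normalizing constant is
    omitted because it cancels in every MH ratio.
    """
    from .forward import forward as forward_fn

    predicted = forward_fn(rep, cfg.modalities, render_cfg, grasp_cfg, templates)
    if predicted.vector.size != data.vector.size:
        raise ValueError(
            f"data has {data.vector.size} features but the forward model "
            f"predicts {predicted.vector.size} for modalities {cfg.modalities}"
        )
    resid = data.vector - predicted.vector
    return -float(resid @ resid) / (2.0 * cfg.sigma2)


def make_evaluator(
    data: SensoryData,
    cfg: LikelihoodConfig,
    render_cfg: RenderConfig | None = None,
    grasp_cfg: GraspConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> ForwardEvaluator:
    """Split a scaled multisensory vector back into per-modality blocks and
    wrap it in a caching evaluator."""
    render_cfg = render_cfg or RenderConfig()
    grasp_cfg = grasp_cfg or GraspConfig()
    blocks: dict[str, np.ndarray] = {}
    offset = 0
    for modality in (VISUAL, HAPTIC):
        if modality not in cfg.modalities:
            continue
        dim = render_cfg.dim if modality == VISUAL else grasp_cfg.dim
        block = np.asarray(data.vector[offset : offset + dim]) * math.sqrt(dim)
        if modality == VISUAL:
            block = np.rint(block * render_cfg.pixel_levels).astype(np.uint8)
        blocks[modality] = block
        offset += dim
    if offset != data.vector.size:
        raise ValueError("data length does not match the configured modalities")
    return ForwardEvaluator(blocks, render_cfg, grasp_cfg, templates)


def log_posterior(
    rep: ObjectRepresentation,
    data: SensoryData,
    grammar: Grammar,
    cfg: LikelihoodConfig,
    render_cfg: RenderConfig | None = None,
    grasp_cfg: GraspConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> float:
    """Unnormalized log posterior: likelihood + spatial prior + tree prior."""
    return (
        log_likelihood(data, rep, cfg, render_cfg, grasp_cfg, templates)
        + log_prior_spatial(rep.spatial, grammar)
        + log_prior_tree(rep.root, grammar)
    )


# ---------------------------------------------------------------------------
# proposal kernels


def _nodes_with_parents(root: Node) -> list[tuple[Node, Node | None]]:
    out: list[tuple[Node, Node | None]] = [(root, None)]
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            out.append((child, node))
            stack.append(child)
    return out


def attachable_nodes(root: Node) -> list[Node]:
    """A: S nodes with fewer than four children (room for one more S)."""
    return [n for n in iter_s_nodes(root) if len(n.children) < 4]


def removable_nodes(root: Node) -> list[Node]:
    """R: non-root S nodes whose sole child is a P node.

    The root is never removable, and (following the sampler's stated
    exclusion) neither is an S node that is the only child of its parent;
    under this grammar every S child has a P sibling, so that clause can
    never fire, but it is kept for fidelity.
    """
    out = []
    for node, parent in _nodes_with_parents(root):
        if (
            node.symbol == "S"
            and parent is not None
            and len(node.children) == 1
            and node.children[0].symbol == "P"
            and len(parent.children) > 1
        ):
            out.append(node)
    return out


def propose_subtree_regeneration(
    rep: ObjectRepresentation,
    grammar: Grammar,
    rng: np.random.Generator,
    *,
    rho: RuleProbabilities | None = None,
    max_parts: int = gr.DEFAULT_MAX_PARTS,
) -> tuple[ObjectRepresentation, float]:
    """Regrow the subtree under a uniformly chosen non-terminal node.

    Returns the proposal and the log Hastings correction
    ``log |N_nt| - log |N_nt'| + log P(sub | rho) - log P(sub' | rho)``
    (the tree-probability ratio restricted to the changed subtree; shared
    factors cancel).  The uniform coordinate proposals for new S nodes
    cancel against the uniform spatial prior and are deliberately absent.
    """
    rho = rho or RuleProbabilities.uniform(grammar)
    new_root = rep.root.copy()
    targets = list(iter_nonterminal_nodes(new_root))
    node = targets[int(rng.integers(len(targets)))]

    old_sub_logp = log_prior_tree_given_rho(node, grammar, rho)
    # regrow in place: keep the node's own symbol and coordinate
    fresh = gr.sample_derivation(
        grammar, rho, rng, max_parts=max_parts, start_symbol=node.symbol
    )
    gr.assign_random_coords(fresh, grammar, rng)  # its root keeps coord=None
    node.children = fresh.children
    new_sub_logp = log_prior_tree_given_rho(node, grammar, rho)

    n_nt = sum(1 for _ in iter_nonterminal_nodes(rep.root))
    n_nt_new = sum(1 for _ in iter_nonterminal_nodes(new_root))
    correction = (
        math.log(n_nt) - math.log(n_nt_new) + old_sub_logp - new_sub_logp
    )
    return ObjectRepresentation(new_root, rep.workspace_edge), correction


def propose_add_remove(
    rep: ObjectRepresentation,
    grammar: Grammar,
    rng: np.random.Generator,
) -> tuple[ObjectRepresentation | None, str, ProposalContext]:
    """One reversible add-part / remove-part move.

    Returns ``(proposal, kind, context)``; ``proposal`` is None when the
    chosen move has an empty candidate set (automatic rejection).
    """
    add = bool(rng.integers(2) == 0)
    new_root = rep.root.copy()
    if add:
        part = grammar.terminals[int(rng.integers(len(grammar.terminals)))]
        candidates = attachable_nodes(new_root)
        ctx = ProposalContext("add", n_attachable=len(candidates))
        if not candidates:
            return None, "add", ctx
        target = candidates[int(rng.integers(len(candidates)))]
        coord = grammar.voxels[int(rng.integers(len(grammar.voxels)))]
        n_slots = len(target.children)  # == s + 1 (the P child occupies one)
        slot = int(rng.integers(n_slots))
        target.children.insert(1 + slot, Node("S", [Node("P", [Node(part)])], coord=coord))
        ctx.slot_choices = n_slots
        ctx.n_removable_new = len(removable_nodes(new_root))
        ctx.n_attachable_new = len(attachable_nodes(new_root))
        return ObjectRepresentation(new_root, rep.workspace_edge), "add", ctx
    candidates = removable_nodes(new_root)
    ctx = ProposalContext("remove", n_removable=len(candidates))
    if not candidates:
        return None, "remove", ctx
    target = candidates[int(rng.integers(len(candidates)))]
    for node, parent in _nodes_with_parents(new_root):
        if node is target:
            parent.children.remove(node)
            # reverse add would choose among the parent's remaining slots
            ctx.slot_choices = len(parent.children)
            break
    ctx.n_attachable_new = len(attachable_nodes(new_root))
    ctx.n_removable_new = len(removable_nodes(new_root))
    ctx.n_attachable = len(attachable_nodes(rep.root))
    return ObjectRepresentation(new_root, rep.workspace_edge), "remove", ctx


# ---------------------------------------------------------------------------
# acceptance functions


def _clip_prob(log_ratio: float) -> float:
    return float(min(1.0, math.exp(min(log_ratio, 0.0)))) if log_ratio < 0 else 1.0


def accept_subtree(
    log_lik_ratio: float,
    log_tree_prior_ratio: float,
    log_correction: float,
) -> float:
    """Acceptance probability of a regeneration move: min(1, likelihood
    ratio x tree-prior ratio x Hastings correction).  Spatial-prior and
    coordinate-proposal factors cancel by construction and never appear."""
    return _clip_prob(log_lik_ratio + log_tree_prior_ratio + log_correction)


def accept_add(
    log_lik_ratio: float,
    log_tree_prior_ratio: float,
    ctx: ProposalContext,
    grammar: Grammar,
) -> float:
    """min(1, lik ratio x tree-prior ratio x |Gt| |A| (s+1) / |R'|).

    The uniform-coordinate proposal factor 1/|V| cancels against the
    spatial prior of the new S node and never appears.
    """
    if ctx.n_removable_new == 0:
        return 0.0
    hastings = math.log(
        len(grammar.terminals) * ctx.n_attachable * ctx.slot_choices
    ) - math.log(ctx.n_removable_new)
    return _clip_prob(log_lik_ratio + log_tree_prior_ratio + hastings)


def accept_remove(
    log_lik_ratio: float,
    log_tree_prior_ratio: float,
    ctx: ProposalContext,
    grammar: Grammar,
) -> float:
    """min(1, lik ratio x tree-prior ratio x |R| / (|Gt| |A'| (s'+1))).

    Exactly reciprocal to :func:`accept_add` for the reverse move, which
    is what the detailed-balance audit enforces.
    """
    if ctx.n_attachable_new == 0:
        return 0.0
    hastings = math.log(ctx.n_removable) - math.log(
        len(grammar.terminals) * ctx.n_attachable_new * ctx.slot_choices
    )
    return _clip_prob(log_lik_ratio + log_tree_prior_ratio + hastings)


# ---------------------------------------------------------------------------
# chain driver


def run_chain(
    evaluator: ForwardEvaluator,
    grammar: Grammar,
    chain_cfg: ChainConfig,
    lik_cfg: LikelihoodConfig,
    *,
    initial: ObjectRepresentation | None = None,
    workspace_edge: float = 1.0,
) -> ChainTrace:
    """Alternating-kernel Metropolis-Hastings over object representations.

    Even iterations use subtree regeneration, odd iterations add/remove.
    The trace records every iteration; the initial state is a fresh prior
    draw unless ``initial`` is given.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(chain_cfg.seed)
    rho = RuleProbabilities.uniform(grammar)
    state = initial or gr.sample_representation(
        grammar, rng, rho=rho, max_parts=chain_cfg.max_parts,
        workspace_edge=workspace_edge,
    )
    sigma2 = lik_cfg.sigma2

    def lik(rep: ObjectRepresentation) -> float:
        return -evaluator.scaled_sq_distance(rep) / (2.0 * sigma2)

    cur_lik = lik(state)
    cur_tree_prior = log_prior_tree(state.root, grammar)
    cur_spatial = log_prior_spatial(state.spatial, grammar)

    records: list[IterationRecord] = []
    cap = chain_cfg.max_parts
    for it in range(chain_cfg.iterations):
        if it % 2 == 0:
            proposal, correction = propose_subtree_regeneration(
                state, grammar, rng, rho=rho, max_parts=cap
            )
            kind = "regen"
            # proposals that push the whole tree over the part cap are
            # rejected outright; the cap bounds the state space, so the
            # subtree-retry normalization cancels exactly in every ratio
            if gr.count_parts(proposal.root) > cap:
                prob = 0.0
                new_lik = cur_lik
                new_tree_prior = cur_tree_prior
            else:
                new_lik = lik(proposal)
                new_tree_prior = log_prior_tree(proposal.root, grammar)
                prob = accept_subtree(
                    new_lik - cur_lik, new_tree_prior - cur_tree_prior, correction
                )
        else:
            proposal, kind, ctx = propose_add_remove(state, grammar, rng)
            if proposal is not None and gr.count_parts(proposal.root) > cap:
                proposal = None
            if proposal is None:
                records.append(
                    IterationRecord(
                        state, cur_lik + cur_tree_prior + cur_spatial, kind, False
                    )
                )
                continue
            new_lik = lik(proposal)
            new_tree_prior = log_prior_tree(proposal.root, grammar)
            accept_fn = accept_add if kind == "add" else accept_remove
            prob = accept_fn(
                new_lik - cur_lik, new_tree_prior - cur_tree_prior, ctx, grammar
            )
        accepted = bool(rng.random() < prob)
        if accepted:
            state = proposal
            cur_lik = new_lik
            cur_tree_prior = new_tree_prior
            cur_spatial = log_prior_spatial(state.spatial, grammar)
        records.append(
            IterationRecord(
                state, cur_lik + cur_tree_prior + cur_spatial, kind, accepted
            )
        )
    return ChainTrace(records, chain_cfg)


def map_estimate(trace: ChainTrace, burn_in: int | None = None) -> ObjectRepresentation:
    """Canonical form of the best representation visited after burn-in
    (ties broken toward the earliest visit)."""
    burn_in = trace.config.burn_in if burn_in is None else burn_in
    retained = trace.records[burn_in:]
    if not retained:
        raise ValueError("no samples remain after burn-in")
    best = max(retained, key=lambda r: r.log_posterior)
    return gr.canonicalize(best.representation)


def infer_map(
    evaluator: ForwardEvaluator,
    grammar: Grammar,
    lik_cfg: LikelihoodConfig,
    chain_cfg: ChainConfig,
    n_chains: int = 3,
) -> tuple[ObjectRepresentation, list[ChainTrace]]:
    """Best-of-n-chains MAP: run seeded chains and keep the highest
    posterior sample across all of them."""
    traces = []
    best_rep, best_lp = None, -math.inf
    for c in range(n_chains):
        cfg = replace(chain_cfg, seed=chain_cfg.seed + 1000 * c)
        trace = run_chain(evaluator, grammar, cfg, lik_cfg)
        traces.append(trace)
        rec = max(trace.records[cfg.burn_in :], key=lambda r: r.log_posterior)
        if rec.log_posterior > best_lp:
            best_rep, best_lp = rec.representation, rec.log_posterior
    return gr.canonicalize(best_rep), traces


# ---------------------------------------------------------------------------
# exact posterior (test oracle)


def enumerate_posterior(
    grammar: Grammar,
    evaluator: ForwardEvaluator,
    max_parts: int,
    lik_cfg: LikelihoodConfig,
    *,
    max_states: int = 200_000,
) -> dict[tuple, float]:
    """Exact normalized posterior over canonical representations with at
    most ``max_parts`` parts.  Exponential; restrict the grammar first."""
    reps = gr.enumerate_trees(grammar, max_parts, max_states=max_states)
    keys, logps = [], []
    for rep in reps:
        lp = (
            -evaluator.scaled_sq_distance(rep) / (2.0 * lik_cfg.sigma2)
            + log_prior_tree(rep.root, grammar)
            + log_prior_spatial(rep.spatial, grammar)
        )
        keys.append(gr.canonical_key(rep))
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    out: dict[tuple, float] = {}
    for key, p in zip(keys, probs):
        out[key] = out.get(key, 0.0) + float(p)
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}
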