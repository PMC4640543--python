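"""Shared helpers for auditing the MCMC kernels on enumerable spaces.

These compute proposal probabilities *analytically* from the kernel
definitions (never by calling the samplers), so they serve as independent
oracles for the acceptance functions and for chain-vs-exact-posterior
comparisons.
"""

import math

import numpy as np

from mvh.grammar import (
    Grammar,
    Node,
    ObjectRepresentation,
    enumerate_trees,
    count_parts,
    iter_nonterminal_nodes,
    iter_s_nodes,
    log_prior_spatial,
    log_prior_tree,
    log_prior_tree_given_rho,
    tree_key,
    RuleProbabilities,
)
from mvh.inference import (
    ForwardEvaluator,
    LikelihoodConfig,
    ProposalContext,
    accept_add,
    accept_remove,
    accept_subtree,
    attachable_nodes,
    removable_nodes,
)


def log_target(rep, grammar, evaluator, sigma2):
    return (
        -evaluator.scaled_sq_distance(rep) / (2 * sigma2)
        + log_prior_tree(rep.root, grammar)
        + log_prior_spatial(rep.spatial, grammar)
    )


def preorder_nonterminals(root):
    return list(iter_nonterminal_nodes(root))


def add_moves(rep: ObjectRepresentation, grammar: Grammar):
    """All (proposal, log_q, ctx) triples of the add kernel from ``rep``."""
    out = []
    n_attach = len(attachable_nodes(rep.root))
    for part in grammar.terminals:
        for coord in grammar.voxels:
            attach = attachable_nodes(rep.root)
            for t_idx in range(len(attach)):
                slots = len(attach[t_idx].children)
                for slot in range(slots):
                    new = rep.copy()
                    target = attachable_nodes(new.root)[t_idx]
                    target.children.insert(
                        1 + slot, Node("S", [Node("P", [Node(part)])], coord=coord)
                    )
                    ctx = ProposalContext(
                        "add",
                        n_attachable=n_attach,
                        n_removable_new=len(removable_nodes(new.root)),
                        n_attachable_new=len(attachable_nodes(new.root)),
                        slot_choices=slots,
                    )
                    log_q = -math.log(
                        2
                        * len(grammar.terminals)
                        * len(grammar.voxels)
                        * n_attach
                        * slots
                    )
                    out.append((new, log_q, ctx))
    return out


def remove_moves(rep: ObjectRepresentation, grammar: Grammar):
    """All (proposal, log_q, ctx) triples of the remove kernel."""
    out = []
    rem = removable_nodes(rep.root)
    for r_idx in range(len(rem)):
        new = rep.copy()
        target = removable_nodes(new.root)[r_idx]
        parent = None
        stack = [new.root]
        while stack:
            node = stack.pop()
            if target in node.children:
                parent = node
                break
            stack.extend(node.children)
        parent.children.remove(target)
        ctx = ProposalContext(
            "remove",
            n_removable=len(rem),
            n_attachable=len(attachable_nodes(rep.root)),
            n_attachable_new=len(attachable_nodes(new.root)),
            n_removable_new=len(removable_nodes(new.root)),
            slot_choices=len(parent.children),
        )
        log_q = -math.log(2 * len(rem))
        out.append((new, log_q, ctx))
    return out


def subtree_replacements(grammar: Grammar, symbol: str, max_parts: int):
    """Every subtree the regeneration kernel can grow at a node of the
    given symbol, with its unnormalized log proposal probability
    (uniform-rho derivation probability times uniform coordinates)."""
    rho = RuleProbabilities.uniform(grammar)
    out = []
    if symbol == "P":
        for t in grammar.terminals:
            out.append(([Node(t)], math.log(1 / len(grammar.terminals))))
        return out
    for tree in enumerate_trees(grammar, max_parts):
        node = Node("S", [c.copy() for c in tree.root.children])
        k = sum(1 for n in iter_s_nodes(node) if n.coord is not None)
        logq = log_prior_tree_given_rho(node, grammar, rho) - k * math.log(
            len(grammar.voxels)
        )
        out.append((node.children, logq))
    return out


def regen_moves(rep: ObjectRepresentation, grammar: Grammar, max_total: int):
    """All (node_index, proposal, log_q_unnorm, log_correction) of the
    regeneration kernel; log_q omits the shared subtree-cap normalizer,
    which cancels between the forward and reverse direction."""
    rho = RuleProbabilities.uniform(grammar)
    nodes = preorder_nonterminals(rep.root)
    n_nt = len(nodes)
    out = []
    for idx, node in enumerate(nodes):
        budget = max_total - (count_parts(rep.root) - count_parts(node))
        old_logp = log_prior_tree_given_rho(node, grammar, rho)
        if node.symbol == "S":
            k_old = sum(1 for n in iter_s_nodes(node) if n.coord is not None)
        for children, logq_sub in subtree_replacements(
            grammar, node.symbol, budget
        ):
            new = rep.copy()
            new_node = preorder_nonterminals(new.root)[idx]
            new_node.children = [c.copy() for c in children]
            new_logp = log_prior_tree_given_rho(new_node, grammar, rho)
            n_nt_new = len(preorder_nonterminals(new.root))
            correction = (
                math.log(n_nt) - math.log(n_nt_new) + old_logp - new_logp
            )
            out.append((idx, new, -math.log(n_nt) + logq_sub, correction))
    return out
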