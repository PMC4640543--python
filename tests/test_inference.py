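"""Inference: likelihood, posterior, proposal kernels, chain, oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mvh.forward import RenderConfig, VISUAL, forward
from mvh.grammar import (
    Grammar,
    Node,
    ObjectRepresentation,
    canonical_key,
    count_parts,
    enumerate_trees,
    log_prior_joint,
    log_prior_tree,
    trees_equal,
)
from mvh.inference import (
    ChainConfig,
    ForwardEvaluator,
    LikelihoodConfig,
    attachable_nodes,
    enumerate_posterior,
    infer_map,
    log_likelihood,
    log_posterior,
    make_evaluator,
    map_estimate,
    propose_add_remove,
    propose_subtree_regeneration,
    removable_nodes,
    run_chain,
)
from mvh.stimuli import all_objects, make_object

import audit_utils
from conftest import one_part_tree, random_representation

RC16 = RenderConfig(resolution=16)
RC64 = RenderConfig(resolution=64)


def tiny_evaluator(tiny_grammar, target=None):
    target = target or ObjectRepresentation(
        Node(
            "S",
            [
                Node("P", [Node("P0")]),
                Node("S", [Node("P", [Node("P1")])], coord=(0, 0, 1)),
            ],
        )
    )
    return ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC16)


class TestLikelihood:
    def test_perfect_prediction_scores_zero(self, stimuli):
        cfg = LikelihoodConfig(modalities=(VISUAL,))
        data = forward(stimuli[0], (VISUAL,), render_cfg=RC64)
        assert log_likelihood(data, stimuli[0], cfg, render_cfg=RC64) == 0.0

    def test_doubling_variance_halves_magnitude(self, stimuli):
        data = forward(stimuli[0], (VISUAL,), render_cfg=RC64)
        a = log_likelihood(
            data, stimuli[1], LikelihoodConfig(1e-4, (VISUAL,)), render_cfg=RC64
        )
        b = log_likelihood(
            data, stimuli[1], LikelihoodConfig(2e-4, (VISUAL,)), render_cfg=RC64
        )
        assert a == pytest.approx(2 * b)
        assert a < 0

    def test_smaller_residual_scores_higher(self, stimuli):
        cfg = LikelihoodConfig(modalities=(VISUAL,))
        data = forward(stimuli[0], (VISUAL,), render_cfg=RC64)
        close = log_likelihood(data, make_object("0001"), cfg, render_cfg=RC64)
        far = log_likelihood(data, make_object("1111"), cfg, render_cfg=RC64)
        assert close > far

    def test_length_mismatch_raises(self, stimuli):
        cfg = LikelihoodConfig(modalities=(VISUAL,))
        data = forward(stimuli[0], (VISUAL,), render_cfg=RC16)
        with pytest.raises(ValueError):
            log_likelihood(data, stimuli[0], cfg, render_cfg=RC64)

    def test_evaluator_round_trip_matches_direct_distance(self, stimuli):
        """make_evaluator must reconstruct per-modality blocks such that
        the cached distance equals the direct scaled distance."""
        cfg = LikelihoodConfig(modalities=(VISUAL, "haptic"))
        data = forward(stimuli[2], (VISUAL, "haptic"), render_cfg=RC64)
        ev = make_evaluator(data, cfg, render_cfg=RC64)
        for rep in (stimuli[2], stimuli[9]):
            direct = float(
                np.sum(
                    (data.vector - forward(rep, (VISUAL, "haptic"), RC64).vector)
                    ** 2
                )
            )
            assert ev.scaled_sq_distance(rep) == pytest.approx(direct, rel=1e-9)


class TestPosterior:
    def test_additive_decomposition(self, grammar, stimuli):
        cfg = LikelihoodConfig(modalities=(VISUAL,))
        data = forward(stimuli[0], (VISUAL,), render_cfg=RC64)
        lp = log_posterior(stimuli[1], data, grammar, cfg, render_cfg=RC64)
        assert lp == pytest.approx(
            log_likelihood(data, stimuli[1], cfg, render_cfg=RC64)
            + log_prior_joint(stimuli[1], grammar)
        )

    def test_huge_variance_reduces_to_prior_ranking(self, grammar, stimuli):
        cfg = LikelihoodConfig(sigma2=1e9, modalities=(VISUAL,))
        data = forward(stimuli[0], (VISUAL,), render_cfg=RC64)
        small = one_part_tree()
        lp_small = log_posterior(small, data, grammar, cfg, render_cfg=RC64)
        lp_five = log_posterior(stimuli[0], data, grammar, cfg, render_cfg=RC64)
        assert (lp_small > lp_five) == (
            log_prior_joint(small, grammar) > log_prior_joint(stimuli[0], grammar)
        )

    def test_tiny_variance_generating_rep_outranks_all_others(
        self, grammar, stimuli
    ):
        cfg = LikelihoodConfig(sigma2=1e-6, modalities=(VISUAL,))
        data = forward(stimuli[7], (VISUAL,), render_cfg=RC64)
        lp_true = log_posterior(stimuli[7], data, grammar, cfg, render_cfg=RC64)
        for i, rep in enumerate(stimuli):
            if i != 7:
                assert lp_true > log_posterior(
                    rep, data, grammar, cfg, render_cfg=RC64
                )


class TestProposals:
    def test_one_part_tree_has_no_removable_node(self):
        rep = one_part_tree()
        assert removable_nodes(rep.root) == []
        assert len(attachable_nodes(rep.root)) == 1

    def test_remove_on_one_part_tree_auto_rejects(self, grammar):
        rep = one_part_tree()
        rng = np.random.default_rng(3)
        seen_auto_reject = False
        for _ in range(20):
            proposal, kind, ctx = propose_add_remove(rep, grammar, rng)
            if kind == "remove":
                assert proposal is None
                seen_auto_reject = True
        assert seen_auto_reject

    def test_add_grows_tree_by_one_part_and_one_coordinate(self, grammar):
        rep = one_part_tree()
        rng = np.random.default_rng(0)
        while True:
            proposal, kind, ctx = propose_add_remove(rep, grammar, rng)
            if kind == "add":
                break
        assert count_parts(proposal.root) == 2
        assert len(proposal.spatial) == 1
        assert ctx.n_attachable == 1 and ctx.slot_choices == 1

    def test_stimulus_reachable_by_single_add_from_reduced_tree(self, grammar):
        """A partially correct tree one part short of a stimulus must be
        one add-move away from it (the motivation for the kernel)."""
        full = make_object("0000")
        reduced = full.copy()
        reduced.root.children[1:2] = []  # drop the L1 subtree
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20_000):
            proposal, kind, _ = propose_add_remove(reduced, grammar, rng)
            if kind == "add" and proposal is not None and trees_equal(proposal, full):
                hits += 1
        assert hits > 0

    def test_regeneration_at_p_node_only_relabels(self, grammar, uniform_rho):
        rep = one_part_tree()
        rng = np.random.default_rng(2)
        for _ in range(50):
            proposal, correction = propose_subtree_regeneration(
                rep, grammar, rng, rho=uniform_rho
            )
            # picking the P node relabels; picking the S root regrows; in
            # both cases a same-shape proposal has |N_nt| unchanged and a
            # pure relabel has correction exactly 0
            if (
                count_parts(proposal.root) == 1
                and len(proposal.root.children) == 1
            ):
                assert correction == pytest.approx(0.0)

    def test_identical_regeneration_accepts_with_probability_one(
        self, grammar, uniform_rho
    ):
        from mvh.inference import accept_subtree

        rep = one_part_tree()
        rng = np.random.default_rng(4)
        for _ in range(50):
            proposal, correction = propose_subtree_regeneration(
                rep, grammar, rng, rho=uniform_rho
            )
            if trees_equal(proposal, rep):
                assert accept_subtree(0.0, 0.0, correction) == pytest.approx(1.0)
                break
        else:
            pytest.fail("identical proposal never drawn")

    def test_empirical_regeneration_frequencies_match_analytic_q(
        self, tiny_grammar
    ):
        """Monte-Carlo draw frequencies of the regeneration kernel must
        match the analytic proposal distribution on a tiny space."""
        rep = ObjectRepresentation(
            Node(
                "S",
                [
                    Node("P", [Node("P0")]),
                    Node("S", [Node("P", [Node("P1")])], coord=(0, 0, 1)),
                ],
            )
        )
        cap = 3
        moves = audit_utils.regen_moves(rep, tiny_grammar, max_total=cap)
        # analytic: normalize within each node's replacement family
        by_node: dict[int, float] = {}
        for idx, new, logq, _ in moves:
            by_node[idx] = by_node.get(idx, 0.0) + math.exp(logq)
        analytic: dict[tuple, float] = {}
        for idx, new, logq, _ in moves:
            p = math.exp(logq) / by_node[idx] / len(by_node)
            key = canonical_key(new)
            analytic[key] = analytic.get(key, 0.0) + p

        rng = np.random.default_rng(9)
        n = 20_000
        counts: dict[tuple, int] = {}
        for _ in range(n):
            proposal, _ = propose_subtree_regeneration(
                rep, tiny_grammar, rng, max_parts=cap
            )
            if count_parts(proposal.root) > cap:
                continue  # the chain would auto-reject these
            key = canonical_key(proposal)
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        scale = total / n  # mass inside the cap
        for key, p in analytic.items():
            p_scaled = p / sum(analytic.values())
            obs = counts.get(key, 0) / total
            se = math.sqrt(p_scaled * (1 - p_scaled) / total)
            assert abs(obs - p_scaled) < 3 * se + 1e-3, key


class TestDetailedBalance:
    def test_add_remove_flows_balance_exactly(self, tiny_grammar):
        """pi(x) q(x->x') A(x';x) must equal pi(x') q(x'->x) A(x;x') for
        every reachable ordered-tree pair, including symmetric-sibling
        states; aggregated per state pair."""
        from mvh.inference import accept_add, accept_remove

        sigma2 = 0.01
        ev = tiny_evaluator(tiny_grammar)
        states = enumerate_trees(tiny_grammar, 3)
        flows_add: dict[tuple, float] = {}
        flows_rem: dict[tuple, float] = {}
        for x in states:
            lp_x = audit_utils.log_target(x, tiny_grammar, ev, sigma2)
            for new, logq, ctx in audit_utils.add_moves(x, tiny_grammar):
                if count_parts(new.root) > 3:
                    continue
                lp_n = audit_utils.log_target(new, tiny_grammar, ev, sigma2)
                lik_ratio = (
                    -ev.scaled_sq_distance(new) + ev.scaled_sq_distance(x)
                ) / (2 * sigma2)
                prior_ratio = log_prior_tree(new.root, tiny_grammar) - log_prior_tree(
                    x.root, tiny_grammar
                )
                a = accept_add(lik_ratio, prior_ratio, ctx, tiny_grammar)
                pair = (audit_utils.tree_key(x.root), audit_utils.tree_key(new.root))
                flows_add[pair] = flows_add.get(pair, 0.0) + math.exp(
                    lp_x + logq
                ) * a
            for new, logq, ctx in audit_utils.remove_moves(x, tiny_grammar):
                lik_ratio = (
                    -ev.scaled_sq_distance(new) + ev.scaled_sq_distance(x)
                ) / (2 * sigma2)
                prior_ratio = log_prior_tree(new.root, tiny_grammar) - log_prior_tree(
                    x.root, tiny_grammar
                )
                a = accept_remove(lik_ratio, prior_ratio, ctx, tiny_grammar)
                pair = (audit_utils.tree_key(x.root), audit_utils.tree_key(new.root))
                flows_rem[pair] = flows_rem.get(pair, 0.0) + math.exp(
                    lp_x + logq
                ) * a
        assert flows_add, "no add moves audited"
        for (a, b), flow in flows_add.items():
            back = flows_rem.get((b, a), 0.0)
            assert flow == pytest.approx(back, rel=1e-9), (a, b)

    def test_regeneration_flows_balance_exactly(self, tiny_grammar):
        from mvh.inference import accept_subtree

        sigma2 = 0.01
        ev = tiny_evaluator(tiny_grammar)
        states = enumerate_trees(tiny_grammar, 2)
        flows: dict[tuple, float] = {}
        for x in states:
            lp_x = audit_utils.log_target(x, tiny_grammar, ev, sigma2)
            for idx, new, logq, corr in audit_utils.regen_moves(
                x, tiny_grammar, max_total=2
            ):
                lik_ratio = (
                    -ev.scaled_sq_distance(new) + ev.scaled_sq_distance(x)
                ) / (2 * sigma2)
                prior_ratio = log_prior_tree(new.root, tiny_grammar) - log_prior_tree(
                    x.root, tiny_grammar
                )
                a = accept_subtree(lik_ratio, prior_ratio, corr)
                key = (
                    idx,
                    audit_utils.tree_key(x.root),
                    audit_utils.tree_key(new.root),
                )
                flows[key] = flows.get(key, 0.0) + math.exp(lp_x + logq) * a
        for (idx, a, b), flow in flows.items():
            if a == b:
                continue
            back = flows.get((idx, b, a), 0.0)
            assert flow == pytest.approx(back, rel=1e-9), (idx, a, b)


class TestChain:
    def test_trace_length_and_determinism(self, grammar):
        target = make_object("0000")
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC16)
        cfg = ChainConfig(iterations=200, burn_in=50, seed=5)
        lik = LikelihoodConfig(modalities=(VISUAL,))
        a = run_chain(ev, grammar, cfg, lik)
        b = run_chain(ev, grammar, cfg, lik)
        assert len(a) == 200
        assert [r.log_posterior for r in a.records] == [
            r.log_posterior for r in b.records
        ]
        kinds = [r.proposal for r in a.records]
        assert all(k == "regen" for k in kinds[0::2])
        assert all(k in ("add", "remove") for k in kinds[1::2])

    def test_acceptance_rate_strictly_between_zero_and_one(self, grammar):
        target = make_object("0101")
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC16)
        trace = run_chain(
            ev,
            grammar,
            ChainConfig(iterations=2000, burn_in=100, seed=8),
            LikelihoodConfig(modalities=(VISUAL,)),
        )
        assert 0.0 < trace.acceptance_rate < 1.0

    def test_map_estimate_of_singleton_trace_is_that_sample(self, grammar):
        target = one_part_tree()
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC16)
        trace = run_chain(
            ev,
            grammar,
            ChainConfig(iterations=1, burn_in=0, seed=0),
            LikelihoodConfig(modalities=(VISUAL,)),
        )
        est = map_estimate(trace, burn_in=0)
        assert trees_equal(est, trace.records[0].representation)

    def test_map_log_posterior_dominates_retained_samples(self, grammar):
        target = make_object("0010")
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC16)
        cfg = ChainConfig(iterations=1500, burn_in=500, seed=3)
        trace = run_chain(ev, grammar, cfg, LikelihoodConfig(modalities=(VISUAL,)))
        best = max(r.log_posterior for r in trace.records[500:])
        est = map_estimate(trace)
        lp_est = audit_utils.log_target(
            est, grammar, ev, LikelihoodConfig().sigma2
        )
        assert lp_est == pytest.approx(best, abs=1e-9)

    def test_empty_post_burn_in_raises(self, grammar):
        with pytest.raises(ValueError):
            ChainConfig(iterations=10, burn_in=10)


class TestEnumeratedPosterior:
    def test_probabilities_sum_to_one(self, tiny_grammar):
        ev = tiny_evaluator(tiny_grammar)
        post = enumerate_posterior(
            tiny_grammar, ev, 3, LikelihoodConfig(0.01, (VISUAL,))
        )
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-10)

    def test_argmax_recovers_generating_representation(self, tiny_grammar):
        target = ObjectRepresentation(
            Node(
                "S",
                [
                    Node("P", [Node("P0")]),
                    Node("S", [Node("P", [Node("P1")])], coord=(0, 1, 0)),
                ],
            )
        )
        ev = tiny_evaluator(tiny_grammar, target)
        post = enumerate_posterior(
            tiny_grammar, ev, 3, LikelihoodConfig(1e-4, (VISUAL,))
        )
        best = max(post, key=post.get)
        assert best == canonical_key(target)

    def test_infinite_variance_marginal_matches_prior(self, tiny_grammar):
        ev = tiny_evaluator(tiny_grammar)
        post = enumerate_posterior(
            tiny_grammar, ev, 2, LikelihoodConfig(1e12, (VISUAL,))
        )
        states = enumerate_trees(tiny_grammar, 2)
        logps = {}
        for rep in states:
            k = canonical_key(rep)
            logps[k] = logps.get(k, 0.0) + math.exp(
                log_prior_joint(rep, tiny_grammar)
            )
        z = sum(logps.values())
        for k, p in post.items():
            assert p == pytest.approx(logps[k] / z, rel=1e-6)

    def test_chain_matches_enumerated_posterior_in_total_variation(
        self, tiny_grammar
    ):
        """Alternating-kernel chain vs exact enumeration on a restricted
        space: total variation below 0.05."""
        target = one_part_tree("P0")
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC16)
        lik = LikelihoodConfig(0.02, (VISUAL,))
        cap = 4
        post = enumerate_posterior(tiny_grammar, ev, cap, lik)
        cfg = ChainConfig(iterations=60_000, burn_in=5_000, seed=17, max_parts=cap)
        trace = run_chain(ev, tiny_grammar, cfg, lik)
        counts: dict[tuple, int] = {}
        for rec in trace.records[cfg.burn_in :]:
            k = canonical_key(rec.representation)
            counts[k] = counts.get(k, 0) + 1
        n = sum(counts.values())
        tv = 0.5 * sum(
            abs(counts.get(k, 0) / n - p) for k, p in post.items()
        ) + 0.5 * sum(
            counts[k] / n for k in counts if k not in post
        )
        assert tv < 0.05, tv


class TestRecoveryAndNearMisses:
    def test_visual_map_recovery_single_stimulus(self, grammar):
        """End-to-end check on one object at reduced settings (the full
        16-object sweep lives in the acceptance suite)."""
        target = make_object("0110")
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC64)
        est, _ = infer_map(
            ev,
            grammar,
            LikelihoodConfig(modalities=(VISUAL,)),
            ChainConfig(seed=42),
            n_chains=3,
        )
        assert trees_equal(est, target)

    def test_near_miss_structure_prefers_p8_and_p7(self, grammar):
        """For a stimulus containing P8, the best single-part corruption
        is the P7-for-P8 substitution, and dropping the small part P8 is
        among the cheapest deletions -- the characteristic near-miss
        pattern of the posterior (a missing part is *often* P8; a
        mismatched part is typically P7 standing in for P8)."""
        target = make_object("0001")  # contains P8 at the nested slot
        ev = ForwardEvaluator.for_target(target, (VISUAL,), render_cfg=RC64)
        sigma2 = LikelihoodConfig().sigma2

        def lp(rep):
            return audit_utils.log_target(rep, grammar, ev, sigma2)

        # all single-location part swaps
        swaps = {}
        for loc in range(4):
            code = [0, 0, 0, 1]
            code[loc] ^= 1
            swaps[loc] = lp(make_object(code))
        assert max(swaps, key=swaps.get) == 3  # the P8 -> P7 substitution

        # all single-part drops (remove each removable S node)
        drops = {}
        for i, node in enumerate(removable_nodes(target.root)):
            reduced = target.copy()
            victims = removable_nodes(reduced.root)
            victim = victims[i]
            stack = [reduced.root]
            while stack:
                n = stack.pop()
                if victim in n.children:
                    n.children.remove(victim)
                    break
                stack.extend(n.children)
            part = node.children[0].children[0].symbol
            drops[part] = lp(reduced)
        assert max(drops, key=drops.get) == "P8"
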