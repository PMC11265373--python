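"""Pathway grouping rules and Mk ancestral-state reconstruction."""

import itertools
import warnings

import numpy as np
import pytest

from symbiomet.gcf import build_presence_absence, cluster_gcfs
from symbiomet.pathways import (
    MkModel,
    PathwayRules,
    _p_matrix,
    call_events,
    event_recovery_report,
    fit_mk1,
    group_pathways,
    mk_loglik,
    reconstruct_marginals,
)
from symbiomet.simulate import SimConfig, evolve_binary_traits, simulate_tree
from symbiomet.tree import Node, Phylogeny
from tests.conftest import make_bgc

# distinct real protein fragments for similarity-rule fixtures
PROT_A = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
PROT_B = "MSTNPKPQRKTKRNTNRRPQDVKFPGGGQIVGGVYLLPRRGPRLGVRATRKTSERSQPRGRRQPIP"
PROT_C = "MALWMRLLPLLALLALWGPDPAAAFVNQHLCGSHLVEALYLVCGERGFFYTPKTRREAEDLQVGQV"
PROT_D = "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGPDEAPRM"


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the pruning implementation)
# ---------------------------------------------------------------------------

def enum_loglik(tree, states, mu, prior=(0.5, 0.5)):
    internal = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        amap = dict(zip([n.node_id for n in internal], assign))

        def st(n):
            return amap[n.node_id] if not n.is_leaf else states[n.label]

        p = prior[st(tree.root)]
        for n in tree.postorder():
            if n.parent is not None:
                p *= _p_matrix(mu, n.length)[st(n.parent), st(n)]
        total += p
    return np.log(total)


def enum_marginals(tree, states, mu, prior=(0.5, 0.5)):
    internal = [n for n in tree.postorder() if not n.is_leaf]
    post = {n.node_id: np.zeros(2) for n in tree.postorder()}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        amap = dict(zip([n.node_id for n in internal], assign))

        def st(n):
            return amap[n.node_id] if not n.is_leaf else states[n.label]

        p = prior[st(tree.root)]
        for n in tree.postorder():
            if n.parent is not None:
                p *= _p_matrix(mu, n.length)[st(n.parent), st(n)]
        for n in tree.postorder():
            post[n.node_id][st(n)] += p
    return {k: v / v.sum() for k, v in post.items()}


class TestMkLikelihood:
    def test_pruning_equals_enumeration_on_quartet(self, quartet_tree):
        states = {"A": 1, "B": 0, "C": 1, "D": 1}
        ll = mk_loglik(quartet_tree, states, 0.3)
        assert ll == pytest.approx(enum_loglik(quartet_tree, states, 0.3), abs=1e-10)

    def test_pruning_equals_enumeration_randomised(self):
        """Property: pruning == brute force on random trees of 2..6 tips."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            t = simulate_tree(SimConfig(seed=int(rng.integers(2**31)), n_strains=n))
            states = {lab: int(rng.integers(0, 2)) for lab in t.tip_labels}
            mu = float(rng.uniform(0.01, 3.0))
            assert mk_loglik(t, states, mu) == pytest.approx(
                enum_loglik(t, states, mu), abs=1e-10
            )

    def test_constant_character_low_rate_limit(self, quartet_tree):
        """All tips present, mu -> 0: likelihood tends to the root prior pi1."""
        states = dict.fromkeys("ABCD", 1)
        ll = mk_loglik(quartet_tree, states, 1e-9)
        assert np.exp(ll) == pytest.approx(0.5, abs=1e-6)

    def test_saturated_cherry_factorises(self):
        """At mu*t >> 1 a (1,0) cherry is two independent coin flips: L = 1/4."""
        t = Phylogeny.from_newick("(A:500,B:500);")
        ll = mk_loglik(t, {"A": 1, "B": 0}, 1.0)
        assert np.exp(ll) == pytest.approx(0.25, abs=1e-9)

    def test_fit_recovers_interior_optimum(self):
        t = simulate_tree(SimConfig(seed=77, n_strains=8))
        states = {lab: i % 2 for i, lab in enumerate(t.tip_labels)}
        model = fit_mk1(t, states)
        # the fitted rate is a local maximum: perturbing mu lowers likelihood
        for factor in (0.5, 2.0):
            assert mk_loglik(t, states, model.mu * factor) <= model.log_likelihood + 1e-9

    def test_constant_character_warns_boundary(self, quartet_tree):
        with pytest.warns(UserWarning, match="constant"):
            model = fit_mk1(quartet_tree, dict.fromkeys("ABCD", 1))
        assert model.boundary


class TestMarginals:
    def test_marginals_equal_enumeration_randomised(self):
        rng = np.random.default_rng(321)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            t = simulate_tree(SimConfig(seed=int(rng.integers(2**31)), n_strains=n))
            states = {lab: int(rng.integers(0, 2)) for lab in t.tip_labels}
            mu = float(rng.uniform(0.05, 2.0))
            marg = reconstruct_marginals(t, states, MkModel(mu=mu, log_likelihood=0.0))
            oracle = enum_marginals(t, states, mu)
            for nid, want in oracle.items():
                assert marg.probabilities.loc[nid, "present"] == pytest.approx(
                    want[1], abs=1e-10
                )

    def test_tip_marginals_match_observations(self, quartet_tree):
        states = {"A": 1, "B": 0, "C": 1, "D": 0}
        marg = reconstruct_marginals(quartet_tree, states, MkModel(mu=0.4, log_likelihood=0.0))
        for tip, s in states.items():
            assert marg.probabilities.loc[tip, "present"] == pytest.approx(float(s))

    def test_marginals_sum_to_one(self, quartet_tree):
        marg = reconstruct_marginals(
            quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 1}, MkModel(mu=0.7, log_likelihood=0.0)
        )
        total = marg.probabilities["present"] + marg.probabilities["absent"]
        assert np.allclose(total, 1.0)

    def test_all_present_tips_pull_every_node_present(self, quartet_tree):
        marg = reconstruct_marginals(
            quartet_tree, dict.fromkeys("ABCD", 1), MkModel(mu=0.3, log_likelihood=0.0)
        )
        assert (marg.probabilities["present"] > 0.5).all()


class TestEvents:
    def test_root_acquisition_when_everywhere(self, quartet_tree):
        marg = reconstruct_marginals(
            quartet_tree, dict.fromkeys("ABCD", 1), MkModel(mu=0.2, log_likelihood=0.0)
        )
        em = call_events(marg, quartet_tree)
        assert em.acquisition_nodes == [quartet_tree.root.node_id]
        assert em.loss_nodes == [] and not em.hgt_flag

    def test_single_tip_presence_called_on_terminal_edge(self):
        t = Phylogeny.from_newick("((A:0.05,B:0.05):0.5,(C:0.5,D:0.5):0.05);")
        states = {"A": 1, "B": 0, "C": 0, "D": 0}
        model = fit_mk1(t, states)
        em = call_events(reconstruct_marginals(t, states, model), t)
        assert em.acquisition_nodes == ["A"]

    def test_two_clade_gains_flag_hgt(self):
        t = Phylogeny.from_newick(
            "(((A:0.1,B:0.1):1.0,(C:0.1,D:0.1):1.0):0.5,((E:0.1,F:0.1):1.0,(G:0.1,H:0.1):1.0):0.5);"
        )
        states = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0, "F": 0, "G": 1, "H": 1}
        model = fit_mk1(t, states)
        em = call_events(reconstruct_marginals(t, states, model), t)
        assert em.hgt_flag and len(em.acquisition_nodes) == 2

    def test_alternation_along_root_to_tip_paths(self):
        """Acquisitions and losses must alternate on any root-to-tip path."""
        cfg = SimConfig(seed=33, n_strains=12, n_pathways=30)
        t = simulate_tree(cfg)
        m, _ = evolve_binary_traits(t, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for pid in m.columns:
                model = fit_mk1(t, m[pid])
                em = call_events(reconstruct_marginals(t, m[pid], model), t)
                events = {n: "A" for n in em.acquisition_nodes}
                events.update({n: "L" for n in em.loss_nodes})
                for tip in t.tips():
                    path, node = [], tip
                    while node is not None:
                        if node.node_id in events:
                            path.append(events[node.node_id])
                        node = node.parent
                    for x, y in zip(path, path[1:]):
                        assert x != y

    def test_noiseless_deep_gain_recovered(self):
        t = Phylogeny.from_newick("((A:0.1,B:0.1):0.1,((C:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1):0.1);")
        # present in the whole CDEF clade only
        states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 1}
        model = fit_mk1(t, states)
        em = call_events(reconstruct_marginals(t, states, model), t)
        cdef = {n.node_id for n in t.postorder() if t.tip_set(n) == frozenset("CDEF")}
        assert set(em.acquisition_nodes) == cdef

    def test_recovery_report_counts(self):
        from symbiomet.pathways import EventMap

        ems = {"P1": EventMap("P1", ["n1", "n2"], ["n3"], True)}
        rep = event_recovery_report(ems, {"P1": ["n1"]}, {"P1": ["n3", "n4"]})
        assert rep.loc["gain", "tp"] == 1 and rep.loc["gain", "fp"] == 1
        assert rep.loc["loss", "recall"] == pytest.approx(0.5)


class TestGroupPathways:
    def _families(self, bgcs):
        fams = cluster_gcfs(bgcs)
        pa = build_presence_absence(fams, bgcs)
        return fams, pa

    def test_identical_representatives_grouped(self):
        prots = [PROT_A, PROT_B, PROT_C]
        a = make_bgc("a", ["bb", "ox", "tr"], genome_id="s1", proteins=prots)
        b = make_bgc("b", ["bb", "ox", "tr2"], genome_id="s2",
                     proteins=[PROT_A, PROT_B, PROT_D])
        fams, pa = self._families([a, b])
        assert len(fams) == 2  # label sets differ enough to be two families?
        pws = group_pathways(fams, [a, b], pa)
        assert len(pws) == 1  # ... but one pathway: majority of genes align

    def test_disjoint_labels_stay_separate(self):
        a = make_bgc("a", ["x1", "x2", "x3"], genome_id="s1",
                     proteins=[PROT_A, PROT_B, PROT_C])
        b = make_bgc("b", ["y1", "y2", "y3"], genome_id="s2",
                     proteins=[PROT_D, PROT_D, PROT_D])
        fams, pa = self._families([a, b])
        pws = group_pathways(fams, [a, b], pa)
        assert len(pws) == 2

    def test_exactly_half_matching_not_grouped(self):
        """A strict majority is required: 2 of 4 shared labels is not enough."""
        a = make_bgc("a", ["bb", "u1", "u2", "u3"], genome_id="s1",
                     proteins=[PROT_A, PROT_B, PROT_C, PROT_D])
        b = make_bgc("b", ["bb", "u1", "v2", "v3"], genome_id="s2",
                     proteins=[PROT_A, PROT_B, PROT_D, PROT_C])
        fams, pa = self._families([a, b])
        # shared labels bb,u1 = 2/4 = exactly half
        pws = group_pathways(fams, [a, b], pa, PathwayRules(architecture_min=0.0))
        assert len(pws) == 2

    def test_different_backbone_class_blocks_grouping(self):
        a = make_bgc("a", ["bb", "ox", "tr"], genome_id="s1", bgc_class="PKS",
                     proteins=[PROT_A, PROT_B, PROT_C])
        b = make_bgc("b", ["bb", "ox", "tr2"], genome_id="s2", bgc_class="NRPS",
                     proteins=[PROT_A, PROT_B, PROT_D])
        fams, pa = self._families([a, b])
        pws = group_pathways(fams, [a, b], pa)
        assert len(pws) == 2

    def test_missing_proteins_raise_when_rule_iii_needed(self):
        from symbiomet.io import BgcGene, BgcRecord

        def naked(bid, genome, labels):
            return BgcRecord(bid, genome, "c1", 0, 1000, "PKS",
                             [BgcGene(f"{bid}{i}", l, i == 0, "") for i, l in enumerate(labels)])

        a, b = naked("a", "s1", ["bb", "ox"]), naked("b", "s2", ["bb", "ox2"])
        fams, pa = self._families([a, b])
        with pytest.raises(ValueError, match="protein sequences required"):
            group_pathways(fams, [a, b], pa)

    def test_presence_is_union_of_member_gcfs(self):
        prots = [PROT_A, PROT_B, PROT_C]
        a = make_bgc("a", ["bb", "ox", "tr"], genome_id="s1", proteins=prots)
        b = make_bgc("b", ["bb", "ox", "tr2"], genome_id="s2",
                     proteins=[PROT_A, PROT_B, PROT_D])
        fams, pa = self._families([a, b])
        pws = group_pathways(fams, [a, b], pa)
        assert pws[0].presence.tolist() == [1, 1]

    def test_grouping_input_order_invariant(self):
        prots = [PROT_A, PROT_B, PROT_C]
        bgcs = [
            make_bgc("a", ["bb", "ox", "tr"], genome_id="s1", proteins=prots),
            make_bgc("b", ["bb", "ox", "tr2"], genome_id="s2",
                     proteins=[PROT_A, PROT_B, PROT_D]),
            make_bgc("c", ["z1", "z2"], genome_id="s3", proteins=[PROT_D, PROT_C]),
        ]
        fams, pa = self._families(bgcs)
        ref = sorted(tuple(p.member_gcf_ids) for p in group_pathways(fams, bgcs, pa))
        for perm in itertools.permutations(fams):
            got = sorted(
                tuple(p.member_gcf_ids) for p in group_pathways(list(perm), bgcs, pa)
            )
            assert got == ref
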