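"""BGC curation, family clustering, presence/absence, rarefaction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from symbiomet.gcf import (
    CurationDirectives,
    GcfConfig,
    bgc_distance,
    build_presence_absence,
    cluster_gcfs,
    curate_fragments,
    occurrence_spectrum,
    rank_abundance,
    rarefaction,
)
from symbiomet.io import Assembly
from symbiomet.simulate import SimConfig, emit_bgcs_from_traits, evolve_binary_traits, simulate_tree
from tests.conftest import make_bgc


class TestBgcDistance:
    def test_identical_is_zero(self):
        a = make_bgc("a", ["x", "y", "z"])
        b = make_bgc("b", ["x", "y", "z"])
        assert bgc_distance(a, b) == 0.0

    def test_disjoint_is_one(self):
        a = make_bgc("a", ["x", "y"])
        b = make_bgc("b", ["u", "v"])
        assert bgc_distance(a, b) == 1.0

    def test_hand_computed_mixed_case(self):
        """Labels {x,y,z} vs {x,y,w}: J=2/4, adjacency {xy,yz} vs {xy,yw}: 1/3."""
        a = make_bgc("a", ["x", "y", "z"])
        b = make_bgc("b", ["x", "y", "w"])
        expected = 1 - (0.5 * 0.5 + 0.5 * (1 / 3))
        assert bgc_distance(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        a = make_bgc("a", ["x", "y", "z"])
        b = make_bgc("b", ["x", "w"])
        assert bgc_distance(a, b) == bgc_distance(b, a)

    def test_orientation_insensitive_adjacency(self):
        a = make_bgc("a", ["x", "y", "z"])
        b = make_bgc("b", ["z", "y", "x"])  # reversed gene order
        assert bgc_distance(a, b) == 0.0


class TestClusterGcfs:
    def test_three_identical_form_one_family(self):
        bgcs = [make_bgc(f"b{i}", ["x", "y"], genome_id=f"G{i}") for i in range(3)]
        fams = cluster_gcfs(bgcs)
        assert len(fams) == 1 and len(fams[0].member_bgc_ids) == 3

    def test_pair_beyond_cutoff_stays_separate(self):
        a = make_bgc("a", ["x", "y", "z", "w"])
        b = make_bgc("b", ["x", "q", "r", "s"])
        assert bgc_distance(a, b) > 0.5
        assert len(cluster_gcfs([a, b])) == 2

    def test_single_linkage_chain(self):
        """d(A,B), d(B,C) <= cutoff but d(A,C) > cutoff: one family."""
        a = make_bgc("a", ["p", "q", "r", "s", "t"])
        b = make_bgc("b", ["p", "q", "r", "s", "u"])
        c = make_bgc("c", ["p", "q", "r", "u", "v"])
        assert bgc_distance(a, b) <= 0.5
        assert bgc_distance(b, c) <= 0.5
        assert bgc_distance(a, c) > 0.5
        fams = cluster_gcfs([a, b, c])
        assert len(fams) == 1

    def test_input_order_invariance(self):
        bgcs = [
            make_bgc("a", ["x", "y", "z"]),
            make_bgc("b", ["x", "y", "w"]),
            make_bgc("c", ["p", "q"]),
            make_bgc("d", ["p", "q", "r"]),
        ]
        reference = [f.member_bgc_ids for f in cluster_gcfs(bgcs)]
        for perm in itertools.permutations(bgcs):
            assert [f.member_bgc_ids for f in cluster_gcfs(list(perm))] == reference

    def test_family_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        pool = ["a", "b", "c", "d", "e", "f"]
        bgcs = [
            make_bgc(f"b{i}", list(rng.choice(pool, size=3, replace=False)))
            for i in range(12)
        ]
        counts = [
            len(cluster_gcfs(bgcs, GcfConfig(distance_cutoff=c)))
            for c in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_external_distance_matrix(self):
        a, b = make_bgc("a", ["x"]), make_bgc("b", ["y"])
        d = pd.DataFrame([[0.0, 0.2], [0.2, 0.0]], index=["a", "b"], columns=["a", "b"])
        assert len(cluster_gcfs([a, b], distances=d)) == 1


class TestCuration:
    def test_explicit_merge(self):
        a = make_bgc("a", ["x", "y", "z"])
        b = make_bgc("b", ["u", "v", "w"])
        curated, log = curate_fragments([a, b], directives=CurationDirectives(merges=[("a", "b")]))
        assert len(curated) == 1 and len(curated[0].genes) == 6
        assert log[0]["action"] == "merge"

    def test_split_at_gene_index(self):
        a = make_bgc("a", list("abcdefgh"))
        curated, _ = curate_fragments([a], directives=CurationDirectives(splits=[("a", 4)]))
        assert sorted(len(c.genes) for c in curated) == [4, 4]

    def test_overlapping_merge_rejected(self):
        a = make_bgc("a", ["x", "y"])
        b = make_bgc("b", ["y", "z"])
        with pytest.raises(ValueError, match="overlap"):
            curate_fragments([a, b], directives=CurationDirectives(merges=[("a", "b")]))

    def test_directive_on_consumed_bgc_rejected(self):
        a, b = make_bgc("a", ["x"]), make_bgc("b", ["y"])
        with pytest.raises(ValueError, match="consumed"):
            curate_fragments(
                [a, b],
                directives=CurationDirectives(merges=[("a", "b")], splits=[("a", 1)]),
            )

    def test_auto_suggest_proposes_planted_merge(self):
        """Edge fragments {g1..g6} and {g7..g10} jointly cover a 10-gene reference."""
        ref = make_bgc("ref", [f"g{i}" for i in range(1, 11)], genome_id="G2")
        frag1 = make_bgc("f1", [f"g{i}" for i in range(1, 7)], genome_id="G1",
                         contig_id="c1", start=0, end=6000)
        frag2 = make_bgc("f2", [f"g{i}" for i in range(7, 11)], genome_id="G1",
                         contig_id="c2", start=44_500, end=49_900)
        assemblies = {
            "G1": Assembly("G1", {"c1": "A" * 50_000, "c2": "A" * 50_000}),
            "G2": Assembly("G2", {"c1": "A" * 50_000}),
        }
        _, log = curate_fragments(
            [ref, frag1, frag2], assemblies,
            CurationDirectives(auto_suggest=True),
        )
        suggestions = [e for e in log if e["action"] == "suggest_merge"]
        assert len(suggestions) == 1
        assert set(suggestions[0]["inputs"]) == {"f1", "f2"}
        # suggestion-only: nothing merged without the confirmation flag
        curated, _ = curate_fragments(
            [ref, frag1, frag2], assemblies, CurationDirectives(auto_suggest=True)
        )
        assert len(curated) == 3


class TestPresenceAbsence:
    def test_shared_family_column_of_ones(self):
        bgcs = [make_bgc("a", ["x", "y"], genome_id="s1"),
                make_bgc("b", ["x", "y"], genome_id="s2")]
        fams = cluster_gcfs(bgcs)
        m = build_presence_absence(fams, bgcs)
        assert m.to_numpy().tolist() == [[1], [1]]

    def test_two_bgcs_same_family_still_binary(self):
        bgcs = [make_bgc("a", ["x", "y"], genome_id="s1"),
                make_bgc("b", ["x", "y"], genome_id="s1")]
        fams = cluster_gcfs(bgcs)
        m = build_presence_absence(fams, bgcs, strains=["s1", "s2"])
        assert m.loc["s1"].tolist() == [1] and m.loc["s2"].tolist() == [0]

    def test_round_trip_recovers_simulated_traits(self):
        """Clustering emitted BGCs reproduces the simulated trait matrix exactly."""
        cfg = SimConfig(seed=21, n_strains=8, n_pathways=25)
        tree = simulate_tree(cfg)
        truth_matrix, _ = evolve_binary_traits(tree, cfg)
        bgcs = emit_bgcs_from_traits(truth_matrix, cfg)
        fams = cluster_gcfs(bgcs)
        got = build_presence_absence(fams, bgcs, strains=list(truth_matrix.index))
        # columns may be renamed; compare as multisets of column vectors
        want = truth_matrix.loc[:, truth_matrix.sum() > 0]
        assert sorted(map(tuple, got.T.values.tolist())) == sorted(
            map(tuple, want.T.values.tolist())
        )


class TestSummaries:
    def test_rank_abundance_spectrum(self):
        m = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 1, 1], [0, 0, 0, 1]],
            index=list("abc"), columns=list("wxyz"),
        )
        assert occurrence_spectrum(m) == {1: 1, 2: 2, 3: 1}
        ra = rank_abundance(m)
        assert ra["occurrence"].tolist() == [3, 2, 2, 1]

    def test_all_ones_and_identity(self):
        ones = pd.DataFrame(1, index=list("abcde"), columns=list("vwxyz"))
        assert occurrence_spectrum(ones) == {5: 5}
        eye = pd.DataFrame(np.eye(4, dtype=int), index=list("abcd"), columns=list("wxyz"))
        assert occurrence_spectrum(eye) == {1: 4}

    def test_rarefaction_hand_case(self):
        """Strains a={f1,f2}, b={f2,f3}: E[S(1)]=2, E[S(2)]=3."""
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=list("ab"), columns=["f1", "f2", "f3"])
        df = rarefaction(m)
        assert df["expected_richness"].tolist() == pytest.approx([2.0, 3.0])

    def test_identical_strains_flat_curve(self):
        m = pd.DataFrame([[1, 0, 1]] * 4, index=list("abcd"), columns=list("xyz"))
        df = rarefaction(m)
        assert df["expected_richness"].tolist() == pytest.approx([2.0] * 4)

    def test_endpoint_equals_observed_richness(self, binary_matrix):
        df = rarefaction(binary_matrix)
        observed = int((binary_matrix.sum() > 0).sum())
        assert df["expected_richness"].iloc[-1] == pytest.approx(observed)

    def test_curve_concave_and_non_decreasing(self, binary_matrix):
        y = rarefaction(binary_matrix)["expected_richness"].to_numpy()
        diffs = np.diff(y)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-12).all()

    def test_exact_formula_matches_monte_carlo(self, binary_matrix):
        """Exact hypergeometric curve vs 10^4 random subsamples, 3 SE."""
        rng = np.random.default_rng(5)
        n_draws = 10_000
        df = rarefaction(binary_matrix)
        strains = list(binary_matrix.index)
        for n in (3, 6):
            vals = np.empty(n_draws)
            for i in range(n_draws):
                pick = rng.choice(strains, size=n, replace=False)
                vals[i] = int((binary_matrix.loc[pick].sum() > 0).sum())
            exact = df.loc[df["n_strains"] == n, "expected_richness"].iloc[0]
            var_exact = df.loc[df["n_strains"] == n, "variance"].iloc[0]
            se = np.sqrt(var_exact / n_draws)
            assert abs(vals.mean() - exact) < 3 * se
            # the exact variance itself agrees with the Monte-Carlo variance
            assert vals.var() == pytest.approx(var_exact, rel=0.1)

    def test_grouped_curves(self, binary_matrix):
        groups = {"g1": list(binary_matrix.index[:5]), "g2": list(binary_matrix.index[5:])}
        df = rarefaction(binary_matrix, groups)
        assert set(df["group"]) == {"g1", "g2"}
        assert (df.groupby("group")["n_strains"].max() == 5).all()
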