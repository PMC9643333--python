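"""Hypergeometric testing, cofactor assignment, ranking and recovery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cofactorscope.inference import (
    CofactorAssignment,
    anchor_cofactors,
    assign_cofactors,
    pair_enrichment,
    phyper,
    predicted_tf_pairs,
    rank_cofactors,
    recovery,
    split_direct_indirect,
)
from cofactorscope.io_formats import PWM, MotifModule, PPIEdgeList


class TestPhyper:
    def test_enumeration_oracle_small_cases(self):
        """Spot-check the tail against exhaustive draw enumeration."""
        for x1, y1, x2, y2 in [(1, 2, 2, 4), (2, 3, 3, 6), (0, 4, 2, 7), (3, 5, 4, 9)]:
            hits = 0
            total = 0
            for draw in itertools.combinations(range(y2), x2):
                total += 1
                if sum(1 for item in draw if item < y1) >= x1:
                    hits += 1
            assert phyper(x1, y1, x2, y2) == pytest.approx(hits / total, abs=1e-12)

    def test_known_small_case(self):
        assert phyper(1, 2, 2, 4) == pytest.approx(5 / 6, abs=1e-12)

    def test_tail_from_zero_is_one(self):
        assert phyper(0, 5, 3, 10) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_x1(self):
        vals = [phyper(x1, 8, 6, 20) for x1 in range(0, 7)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "args", [(-1, 2, 2, 4), (1, 5, 2, 4), (1, 2, 5, 4), (0.5, 2, 2, 4)]
    )
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            phyper(*args)


class TestDirectIndirect:
    def test_direct_edge(self):
        ppi = PPIEdgeList({frozenset({"A", "B"})}, {"A": True, "B": True})
        direct, indirect = split_direct_indirect(ppi)
        assert direct == {frozenset({"A", "B"})} and indirect == set()

    def test_bridge_through_non_tf(self):
        ppi = PPIEdgeList(
            {frozenset({"A", "C"}), frozenset({"B", "C"})},
            {"A": True, "B": True, "C": False},
        )
        direct, indirect = split_direct_indirect(ppi)
        assert direct == set() and indirect == {frozenset({"A", "B"})}

    def test_triangle_excludes_indirect(self):
        edges = {frozenset(p) for p in itertools.combinations("ABC", 2)}
        ppi = PPIEdgeList(edges, {c: True for c in "ABC"})
        direct, indirect = split_direct_indirect(ppi)
        assert direct == edges and indirect == set()

    def test_matches_brute_force_on_random_graphs(self, rng):
        """Oracle: scan all TF pairs for an edge / a common neighbour."""
        for _ in range(20):
            n = 8
            names = [f"P{i}" for i in range(n)]
            flags = {p: bool(rng.random() < 0.6) for p in names}
            edges = {
                frozenset(pair)
                for pair in itertools.combinations(names, 2)
                if rng.random() < 0.3
            }
            ppi = PPIEdgeList(edges, flags)
            adj = {p: set() for p in names}
            for e in edges:
                a, b = tuple(e)
                adj[a].add(b)
                adj[b].add(a)
            tfs = [p for p in names if flags[p]]
            exp_direct, exp_indirect = set(), set()
            for a, b in itertools.combinations(tfs, 2):
                pair = frozenset({a, b})
                if pair in edges:
                    exp_direct.add(pair)
                elif adj[a] & adj[b]:
                    exp_indirect.add(pair)
            assert split_direct_indirect(ppi) == (exp_direct, exp_indirect)


class TestPairEnrichment:
    def test_single_known_pair(self):
        res = pair_enrichment({frozenset({"A", "B"})}, {frozenset({"A", "B"})}, 3)
        assert (res.n, res.m, res.M) == (2, 1, 1)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_no_overlap_gives_one(self):
        res = pair_enrichment(
            {frozenset({"A", "B"})}, {frozenset({"C", "D"})}, 6
        )
        assert res.m == 0 and res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_two_tfs_warns(self, caplog):
        with caplog.at_level("WARNING"):
            res = pair_enrichment(set(), {frozenset({"A", "B"})}, 5)
        assert res.p_value == 1.0 and "fewer than 2" in caplog.text

    def test_super_uniform_under_random_known_pairs(self, rng):
        """p-values are (super-)uniform when known pairs carry no signal."""
        tfs = [f"T{i}" for i in range(30)]
        all_pairs = [frozenset(p) for p in itertools.combinations(tfs, 2)]
        predicted = {
            all_pairs[i] for i in rng.choice(len(all_pairs), size=80, replace=False)
        }
        ps = []
        for _ in range(300):
            known = {
                all_pairs[i]
                for i in rng.choice(len(all_pairs), size=60, replace=False)
            }
            ps.append(pair_enrichment(predicted, known, 30).p_value)
        assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01


def _assign(motif, line, tfs, mode="top5"):
    return CofactorAssignment(motif, line, tuple(tfs), mode)


class TestRanking:
    def test_cutoff_boundary_is_strict(self):
        """Mean E-value 1e-5 in 3 lines scores exactly 15 and does not pass."""
        assignments = [
            _assign("m1", line, [("TFX", 1e-5)]) for line in ("A", "B", "C")
        ]
        (r,) = rank_cofactors(assignments, tau=15.0)
        assert r.score == pytest.approx(15.0, abs=1e-12)
        assert not r.passes_cutoff

    def test_single_line_score(self):
        (r,) = rank_cofactors([_assign("m1", "A", [("TFX", 1e-8)])])
        assert r.score == pytest.approx(8.0, abs=1e-12)

    def test_mean_of_neglog10(self):
        assignments = [
            _assign("m1", "A", [("TFX", 1e-4)]),
            _assign("m2", "B", [("TFX", 1e-6)]),
        ]
        (r,) = rank_cofactors(assignments)
        assert r.mean_neglog10_evalue == pytest.approx(5.0, abs=1e-12)
        assert r.score == pytest.approx(10.0, abs=1e-12)

    def test_best_evalue_per_line(self):
        assignments = [
            _assign("m1", "A", [("TFX", 1e-3)]),
            _assign("m2", "A", [("TFX", 1e-9)]),
        ]
        (r,) = rank_cofactors(assignments)
        assert r.score == pytest.approx(9.0, abs=1e-12)

    def test_invariant_to_line_order(self):
        fwd = [
            _assign("m1", "A", [("TFX", 1e-4)]),
            _assign("m2", "B", [("TFX", 1e-6)]),
            _assign("m3", "C", [("TFY", 1e-7)]),
        ]
        assert rank_cofactors(fwd) == rank_cofactors(list(reversed(fwd)))

    def test_monotone_in_lines_and_evalue(self):
        two = rank_cofactors(
            [_assign("m", ln, [("T", 1e-5)]) for ln in ("A", "B")]
        )[0]
        three = rank_cofactors(
            [_assign("m", ln, [("T", 1e-5)]) for ln in ("A", "B", "C")]
        )[0]
        stronger = rank_cofactors(
            [_assign("m", ln, [("T", 1e-7)]) for ln in ("A", "B")]
        )[0]
        assert three.score > two.score and stronger.score > two.score


class TestRecovery:
    def test_curated_29(self):
        curated = [f"C{i}" for i in range(29)]
        predicted = set(curated[:21]) | {"X1", "X2"}
        res = recovery(predicted, curated)
        assert (res.hits, res.total, res.percent) == (21, 29, 72.4)

    def test_curated_20(self):
        curated = [f"C{i}" for i in range(20)]
        res = recovery(set(curated[:15]), curated)
        assert res.percent == 75.0

    def test_empty_prediction(self):
        res = recovery(set(), ["A", "B"])
        assert res.percent == 0.0 and res.missed == ["A", "B"]

    def test_empty_curated_rejected(self):
        with pytest.raises(ValueError):
            recovery({"A"}, [])


class TestAssignment:
    def test_exact_copy_assigned_its_source_tf(self, library60, calib60):
        target = library60[5]
        per_line = {"X": [PWM("q", target.matrix)]}
        (a,) = assign_cofactors(per_line, library60, calib60, mode="top1")
        assert a.tfs[0][0] == target.tf_names[0]

    def test_top5_superset_of_top1(self, library60, calib60, rng):
        from cofactorscope.synthetic import perturb_pwm

        per_line = {
            "X": [perturb_pwm(library60[i], 50.0, rng, f"q{i}") for i in range(6)]
        }
        top1 = assign_cofactors(per_line, library60, calib60, mode="top1")
        top5 = assign_cofactors(per_line, library60, calib60, mode="top5")
        tfs1 = {(a.motif_id, t) for a in top1 for t in a.tf_names()}
        tfs5 = {(a.motif_id, t) for a in top5 for t in a.tf_names()}
        assert tfs1 <= tfs5

    def test_unmatched_motifs_absent(self, library60, calib60):
        per_line = {"X": [PWM("blank", np.full((4, 6), 0.25))]}
        assert assign_cofactors(per_line, library60, calib60) == []


class TestAnchorCofactors:
    def test_module_with_anchor_yields_partner_tfs(self):
        modules = {"X": [MotifModule("M1", "X", frozenset({"anchor", "m1"}), 3)]}
        assignments = [_assign("m1", "X", [("TFX", 1e-7)])]
        out = anchor_cofactors(modules, assignments, {"X": {"anchor"}})
        assert out == {"TFX"}

    def test_tf_only_in_anchor_free_modules_excluded(self):
        modules = {
            "X": [
                MotifModule("M1", "X", frozenset({"anchor", "m1"}), 3),
                MotifModule("M2", "X", frozenset({"m2", "m3"}), 3),
            ]
        }
        assignments = [
            _assign("m1", "X", [("TFX", 1e-7)]),
            _assign("m2", "X", [("TFY", 1e-7)]),
        ]
        out = anchor_cofactors(modules, assignments, {"X": {"anchor"}})
        assert out == {"TFX"}

    def test_no_anchor_warns_empty(self, caplog):
        modules = {"X": [MotifModule("M1", "X", frozenset({"m1", "m2"}), 3)]}
        with caplog.at_level("WARNING"):
            out = anchor_cofactors(modules, [], {"X": set()})
        assert out == set() and "no anchor motif" in caplog.text

    def test_universal_anchor_inclusion_covers_all_assigned(self):
        """With the anchor in every module, anchor cofactors = all partner TFs."""
        from cofactorscope.similarity import calibrate_null
        from cofactorscope.synthetic import SyntheticConfig, simulate_study

        bundle = simulate_study(
            SyntheticConfig(
                n_cell_lines=3, library_size=20, motifs_per_line=8,
                n_true_cofactors=4, n_modules_per_line=10,
                module_size_range=(2, 4), anchor_inclusion=1.0,
                n_genes=120, n_go_terms=12, n_decoy_proteins=10, seed=9,
            )
        )
        calib = calibrate_null(bundle.known_library, n_null=1000, seed=9)
        assignments = assign_cofactors(
            bundle.per_line_motifs, bundle.known_library, calib
        )
        anchor_set = anchor_cofactors(
            bundle.modules, assignments, bundle.anchor_motif_ids
        )
        non_anchor_tfs = set()
        anchor_mids = {m for ids in bundle.anchor_motif_ids.values() for m in ids}
        for a in assignments:
            if a.motif_id not in anchor_mids:
                non_anchor_tfs |= a.tf_names()
        assert anchor_set == non_anchor_tfs


class TestPredictedPairs:
    def test_cross_product_of_multi_tf_motifs(self):
        modules = {"X": [MotifModule("M1", "X", frozenset({"m1", "m2"}), 3)]}
        assignments = [
            _assign("m1", "X", [("A", 1e-7), ("B", 1e-6)]),
            _assign("m2", "X", [("C", 1e-7)]),
        ]
        pairs = predicted_tf_pairs(modules, assignments)
        assert pairs["X"] == {frozenset({"A", "C"}), frozenset({"B", "C"})}
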