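"""Motif-pair extraction, conservation statistics and the resampling null."""

import math

import numpy as np
import pytest
from scipy import stats

from cofactorscope.io_formats import PWM, MotifModule
from cofactorscope.module_analysis import (
    SimilarityRelation,
    build_similarity,
    cooccurrence_pvalue,
    module_pairs,
    motif_conservation,
    pair_conservation,
    random_pair_null,
)
from cofactorscope.similarity import calibrate_null
from cofactorscope.synthetic import simulate_occurrence_matrix


def _mod(module_id, members, line="X"):
    return MotifModule(module_id, line, frozenset(members), 5)


class TestModulePairs:
    def test_triple_gives_three_pairs(self):
        pairs = module_pairs([_mod("M1", {"a", "b", "c"})])
        assert pairs == {
            frozenset({"a", "b"}),
            frozenset({"a", "c"}),
            frozenset({"b", "c"}),
        }

    def test_duplicate_modules_deduplicated(self):
        pairs = module_pairs([_mod("M1", {"a", "b"}), _mod("M2", {"a", "b"})])
        assert len(pairs) == 1

    def test_empty(self):
        assert module_pairs([]) == set()


def _relation(pairs, lines):
    """Hand-built similarity relation: ``pairs`` is {(idA, idB), ...}."""
    rel = SimilarityRelation(1e-8)
    rel.line_of = dict(lines)
    for mid in rel.line_of:
        rel.similar[mid] = {}
    for a, b in pairs:
        rel.similar[a].setdefault(rel.line_of[b], set()).add(b)
        rel.similar[b].setdefault(rel.line_of[a], set()).add(a)
    return rel


class TestMotifConservation:
    def test_identical_motif_lists_fully_conserved(self, library60, calib60):
        per_line = {
            "X": [PWM(f"x{i}", library60[i].matrix) for i in range(5)],
            "Y": [PWM(f"y{i}", library60[i].matrix) for i in range(5)],
        }
        fracs = motif_conservation(per_line, 1e-8, calib=calib60)
        assert fracs == {"X": 1.0, "Y": 1.0}

    def test_uninformative_motifs_conserve_nothing(self, calib60):
        per_line = {
            "X": [PWM("x0", np.full((4, 6), 0.25))],
            "Y": [PWM("y0", np.full((4, 8), 0.25))],
        }
        fracs = motif_conservation(per_line, 1e-8, calib=calib60)
        assert fracs == {"X": 0.0, "Y": 0.0}

    def test_needs_two_lines(self, calib60):
        with pytest.raises(ValueError):
            motif_conservation({"X": []}, calib=calib60)

    def test_monotone_in_threshold(self, small_bundle, small_calib):
        loose = build_similarity(small_bundle.per_line_motifs, 1e-3, small_calib)
        strict = build_similarity(small_bundle.per_line_motifs, 1e-8, small_calib)
        f_loose = motif_conservation(small_bundle.per_line_motifs, relation=loose)
        f_strict = motif_conservation(small_bundle.per_line_motifs, relation=strict)
        for line in f_loose:
            assert f_loose[line] >= f_strict[line]

    def test_invariant_under_relabeling(self, small_bundle, small_calib):
        renamed = {
            line: [PWM(f"R_{p.motif_id}", p.matrix) for p in motifs]
            for line, motifs in small_bundle.per_line_motifs.items()
        }
        orig = motif_conservation(
            small_bundle.per_line_motifs, 1e-8, calib=small_calib
        )
        new = motif_conservation(renamed, 1e-8, calib=small_calib)
        assert orig == new


class TestPairConservation:
    def test_identical_pair_sets_fully_conserved(self):
        rel = _relation(
            [("a", "c"), ("b", "d")],
            {"a": "X", "b": "X", "c": "Y", "d": "Y"},
        )
        per_line = {
            "X": {frozenset({"a", "b"})},
            "Y": {frozenset({"c", "d"})},
        }
        per, overall = pair_conservation(per_line, rel)
        assert overall == 1.0 and per == {"X": 1.0, "Y": 1.0}

    def test_cross_orientation_matching(self):
        """(a,b) matches (d,c) when a~d and b~c."""
        rel = _relation(
            [("a", "d"), ("b", "c")],
            {"a": "X", "b": "X", "c": "Y", "d": "Y"},
        )
        per_line = {
            "X": {frozenset({"a", "b"})},
            "Y": {frozenset({"c", "d"})},
        }
        _, overall = pair_conservation(per_line, rel)
        assert overall == 1.0

    def test_single_line_is_zero_with_warning(self, caplog):
        rel = _relation([], {"a": "X", "b": "X"})
        with caplog.at_level("WARNING"):
            per, overall = pair_conservation({"X": {frozenset({"a", "b"})}}, rel)
        assert overall == 0.0 and "single cell line" in caplog.text

    def test_pair_needs_both_components_similar(self):
        rel = _relation([("a", "c")], {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        per_line = {
            "X": {frozenset({"a", "b"})},
            "Y": {frozenset({"c", "d"})},
        }
        _, overall = pair_conservation(per_line, rel)
        assert overall == 0.0


class TestRandomPairNull:
    def test_seed_determinism(self, small_bundle, small_calib):
        rel = build_similarity(small_bundle.per_line_motifs, 1e-8, small_calib)
        kw = dict(R=49, seed=11, relation=rel)
        r1 = random_pair_null(small_bundle.modules, small_bundle.per_line_motifs, **kw)
        r2 = random_pair_null(small_bundle.modules, small_bundle.per_line_motifs, **kw)
        assert r1.null_fractions == r2.null_fractions
        assert r1.p_empirical == r2.p_empirical

    def test_observed_matches_pair_conservation(self, small_bundle, small_calib):
        rel = build_similarity(small_bundle.per_line_motifs, 1e-8, small_calib)
        pairs = {ln: module_pairs(m) for ln, m in small_bundle.modules.items()}
        _, overall = pair_conservation(pairs, rel)
        res = random_pair_null(
            small_bundle.modules, small_bundle.per_line_motifs, R=9,
            seed=1, relation=rel,
        )
        assert res.observed_fraction == overall

    def test_planted_conservation_exceeds_null_mean(self, small_bundle, small_calib):
        """Planted modules conserve more pairs than random ones on average
        (full significance is asserted on the default eight-line study)."""
        rel = build_similarity(small_bundle.per_line_motifs, 1e-8, small_calib)
        res = random_pair_null(
            small_bundle.modules, small_bundle.per_line_motifs, R=99,
            seed=3, relation=rel,
        )
        assert res.observed_fraction > float(np.mean(res.null_fractions))

    def test_oversized_module_rejected(self, small_bundle, small_calib):
        rel = build_similarity(small_bundle.per_line_motifs, 1e-8, small_calib)
        line = small_bundle.cell_lines[0]
        ids = [p.motif_id for p in small_bundle.per_line_motifs[line]]
        big = {line: [MotifModule("BIG", line, frozenset(ids), 5)]}
        tiny_motifs = {line: small_bundle.per_line_motifs[line][:2]}
        with pytest.raises(ValueError, match="module size"):
            random_pair_null(big, tiny_motifs, R=9, seed=1, relation=rel)


class TestCooccurrence:
    def test_exact_binomial_tail(self):
        """10/100 joint occurrences at marginals 0.1 each: exact tail oracle."""
        n = 100
        mat = np.zeros((n, 2), dtype=bool)
        mat[:10] = True  # a and b co-occur in exactly 10 sequences
        import pandas as pd

        df = pd.DataFrame(mat, columns=["a", "b"])
        p = cooccurrence_pvalue(df, {"a", "b"})
        p0 = 0.1 * 0.1
        oracle = sum(
            math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(10, n + 1)
        )
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_zero_joint_count_gives_one(self):
        import pandas as pd

        df = pd.DataFrame(
            {"a": [True, False, False, False], "b": [False, True, False, False]}
        )
        assert cooccurrence_pvalue(df, {"a", "b"}) == 1.0

    def test_zero_marginal_warns_and_returns_one(self, caplog):
        import pandas as pd

        df = pd.DataFrame({"a": [True, True], "b": [False, False]})
        with caplog.at_level("WARNING"):
            assert cooccurrence_pvalue(df, {"a", "b"}) == 1.0
        assert "zero marginal" in caplog.text

    def test_conservative_under_independence(self):
        """Rejection rates never exceed nominal under independent matrices.

        Because the independence null is built from marginals estimated on
        the same matrix, the statistic is conservative (the joint count and
        the estimated joint rate are positively correlated), so the honest
        calibration property is a super-uniform rejection tail.
        """
        ps = np.asarray(
            [
                cooccurrence_pvalue(
                    simulate_occurrence_matrix(500, {"a": 0.2, "b": 0.2}, seed=s),
                    {"a", "b"},
                )
                for s in range(500)
            ]
        )
        n = len(ps)
        for t in (0.01, 0.05, 0.1):
            se = math.sqrt(t * (1 - t) / n)
            assert float(np.mean(ps < t)) <= t + 3 * se
        assert 0.3 < float(np.mean(ps)) < 0.7

    def test_planted_cooccurrence_detected(self):
        """A strongly co-occurring pair is flagged as significant."""
        df = simulate_occurrence_matrix(
            200, {"a": 0.2, "b": 0.2}, seed=3, planted=[(("a", "b"), 0.3)]
        )
        assert cooccurrence_pvalue(df, {"a", "b"}) < 1e-4
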