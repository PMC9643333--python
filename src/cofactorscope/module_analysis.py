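"""Cross-cell-line conservation of motifs and motif pairs.

Motif pairs are all size-2 subsets of each motif module.  A motif (or
motif pair) in one cell line is "conserved" when a similar motif (or
pair, componentwise, in either order) exists in at least one other cell
line, similarity meaning a pairwise E-value below ``theta_cross``
(default 1e-8).  Significance of the observed pair-conservation fraction
is assessed against random motif modules: each module is rebuilt by
sampling the same number of motifs uniformly from that line's predicted
motifs, exactly preserving module counts and sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .io_formats import PWM, MotifModule
from .similarity import NullCalibration, align_score, evalue

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationReport",
    "PairNullResult",
    "SimilarityRelation",
    "build_similarity",
    "module_pairs",
    "motif_conservation",
    "pair_conservation",
    "random_pair_null",
    "cooccurrence_pvalue",
]


@dataclass
class ConservationReport:
    per_line_motif_fraction: dict[str, float]
    per_line_pair_fraction: dict[str, float]
    overall_pair_fraction: float
    theta_cross: float = 1e-8


@dataclass
class PairNullResult:
    observed_fraction: float
    null_fractions: list[float]
    p_empirical: float
    p_normal: float
    seed: int


class SimilarityRelation:
    """Symmetric cross-cell-line motif similarity, cached by motif id.

    ``similar[motif_id][other_line]`` is the set of motif ids in
    ``other_line`` whose pairwise E-value with ``motif_id`` is below the
    threshold.  Only cross-line pairs are stored; within-line similarity is
    never consulted by the conservation statistics.
    """

    def __init__(self, theta_cross: float) -> None:
        self.theta_cross = theta_cross
        self.similar: dict[str, dict[str, set[str]]] = {}
        self.line_of: dict[str, str] = {}

    def similar_in(self, motif_id: str, line: str) -> set[str]:
        return self.similar.get(motif_id, {}).get(line, set())

    def has_cross_line_match(self, motif_id: str) -> bool:
        return any(ids for ids in self.similar.get(motif_id, {}).values())


def build_similarity(
    per_line_motifs: Mapping[str, Sequence[PWM]],
    theta_cross: float,
    calib: NullCalibration,
    extreme_tail: bool = True,
) -> SimilarityRelation:
    """Score every cross-line motif pair once and threshold at ``theta_cross``."""
    rel = SimilarityRelation(theta_cross)
    lines = sorted(per_line_motifs)
    for line in lines:
        for pwm in per_line_motifs[line]:
            rel.line_of[pwm.motif_id] = line
            rel.similar[pwm.motif_id] = {}
    for la, lb in combinations(lines, 2):
        for pa in per_line_motifs[la]:
            for pb in per_line_motifs[lb]:
                score = align_score(pa, pb).score
                if evalue(score, calib, extreme_tail=extreme_tail) < theta_cross:
                    rel.similar[pa.motif_id].setdefault(lb, set()).add(pb.motif_id)
                    rel.similar[pb.motif_id].setdefault(la, set()).add(pa.motif_id)
    return rel


def module_pairs(modules: Sequence[MotifModule]) -> set[frozenset[str]]:
    """All unordered motif pairs occurring in any module (deduplicated)."""
    pairs: set[frozenset[str]] = set()
    for mod in modules:
        for a, b in combinations(sorted(mod.motif_ids), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def motif_conservation(
    per_line_motifs: Mapping[str, Sequence[PWM]],
    theta_cross: float = 1e-8,
    calib: NullCalibration | None = None,
    relation: SimilarityRelation | None = None,
) -> dict[str, float]:
    """Per line, the fraction of motifs with a similar motif in another line.

    Pass a prebuilt ``relation`` to reuse pairwise scores across the motif-
    and pair-level statistics (they share one similarity relation).
    """
    if len(per_line_motifs) < 2:
        raise ValueError("need >= 2 cell lines")
    if relation is None:
        if calib is None:
            raise ValueError("either calib or relation is required")
        relation = build_similarity(per_line_motifs, theta_cross, calib)
    out: dict[str, float] = {}
    for line, motifs in per_line_motifs.items():
        if not motifs:
            out[line] = 0.0
            continue
        hits = sum(relation.has_cross_line_match(p.motif_id) for p in motifs)
        out[line] = hits / len(motifs)
    return out


def _pair_conserved(
    pair: frozenset[str],
    line: str,
    relation: SimilarityRelation,
    pair_sets: Mapping[str, set[frozenset[str]]],
) -> bool:
    a, b = tuple(pair)
    for other, pset in pair_sets.items():
        if other == line or not pset:
            continue
        for c in relation.similar_in(a, other):
            for d in relation.similar_in(b, other):
                if c != d and frozenset((c, d)) in pset:
                    return True
    return False


def pair_conservation(
    per_line_pairs: Mapping[str, set[frozenset[str]]],
    relation: SimilarityRelation,
) -> tuple[dict[str, float], float]:
    """Per-line and overall fractions of motif pairs conserved elsewhere.

    A pair (a, b) in line X is conserved iff another line has a pair (c, d)
    with a~c and b~d, or a~d and b~c (unordered matching).
    """
    if len(per_line_pairs) < 2:
        logger.warning("pair conservation with a single cell line is 0 by definition")
    per_line: dict[str, float] = {}
    total = conserved_total = 0
    for line, pairs in per_line_pairs.items():
        if not pairs:
            per_line[line] = 0.0
            continue
        conserved = sum(
            _pair_conserved(p, line, relation, per_line_pairs) for p in pairs
        )
        per_line[line] = conserved / len(pairs)
        total += len(pairs)
        conserved_total += conserved
    overall = conserved_total / total if total else 0.0
    return per_line, overall


def random_pair_null(
    per_line_modules: Mapping[str, Sequence[MotifModule]],
    per_line_motifs: Mapping[str, Sequence[PWM]],
    R: int = 199,
    theta_cross: float = 1e-8,
    seed: int = 0,
    calib: NullCalibration | None = None,
    relation: SimilarityRelation | None = None,
) -> PairNullResult:
    """Resampling null for the overall pair-conservation fraction.

    Each replicate rebuilds every module of every line by drawing, without
    replacement within the module, a uniform random motif set of the same
    size from that line's predicted motifs, then recomputes the overall
    pair-conservation fraction.  ``p_empirical = (1 + #{null >= obs}) /
    (R + 1)``; ``p_normal`` is the upper tail of a Gaussian fitted to the
    null fractions.
    """
    if R < 1:
        raise ValueError("R must be >= 1 (>= 99 recommended)")
    if relation is None:
        if calib is None:
            raise ValueError("either calib or relation is required")
        relation = build_similarity(per_line_motifs, theta_cross, calib)
    line_ids = {
        line: np.array([p.motif_id for p in motifs])
        for line, motifs in per_line_motifs.items()
    }
    for line, mods in per_line_modules.items():
        max_size = max((m.size for m in mods), default=0)
        if max_size > len(line_ids.get(line, ())):
            raise ValueError(
                f"line {line!r}: module size {max_size} exceeds motif count"
            )

    observed_pairs = {
        line: module_pairs(mods) for line, mods in per_line_modules.items()
    }
    _, observed = pair_conservation(observed_pairs, relation)

    rng = np.random.default_rng(seed)
    null_fractions: list[float] = []
    sizes = {
        line: [m.size for m in mods] for line, mods in per_line_modules.items()
    }
    for _ in range(R):
        rand_pairs: dict[str, set[frozenset[str]]] = {}
        for line, line_sizes in sizes.items():
            ids = line_ids[line]
            pairs: set[frozenset[str]] = set()
            for size in line_sizes:
                members = rng.choice(ids, size=size, replace=False)
                for a, b in combinations(members.tolist(), 2):
                    pairs.add(frozenset((a, b)))
            rand_pairs[line] = pairs
        _, frac = pair_conservation(rand_pairs, relation)
        null_fractions.append(frac)

    arr = np.asarray(null_fractions)
    p_emp = (1 + int(np.sum(arr >= observed - 1e-12))) / (R + 1)
    mu, sd = float(arr.mean()), float(arr.std(ddof=1)) if R > 1 else 0.0
    if sd > 0:
        p_norm = float(norm.sf(observed, loc=mu, scale=sd))
    else:
        p_norm = 1.0 if observed <= mu else 0.0
    p_norm = max(p_norm, 1e-300)
    return PairNullResult(observed, null_fractions, p_emp, p_norm, seed)


def cooccurrence_pvalue(occurrence, motif_set) -> float:
    """One-sided co-occurrence significance of a motif set.

    ``occurrence`` is a sequences x motifs boolean matrix (a pandas
    DataFrame with motif-id columns).  Under the independence null the
    probability a sequence contains all members is the product of the
    per-motif marginal frequencies; the p-value is the binomial upper tail
    P(X >= x) with x the observed joint count.
    """
    motif_set = sorted(set(motif_set))
    if len(motif_set) < 2:
        raise ValueError("motif set must have >= 2 members")
    if not isinstance(occurrence, pd.DataFrame):
        raise TypeError("occurrence must be a pandas DataFrame")
    missing = [m for m in motif_set if m not in occurrence.columns]
    if missing:
        raise ValueError(f"motifs absent from occurrence matrix: {missing}")
    sub = occurrence[motif_set].to_numpy(dtype=bool)
    n = sub.shape[0]
    marginals = sub.mean(axis=0)
    if np.any(marginals == 0):
        logger.warning("zero marginal frequency in motif set; p-value set to 1")
        return 1.0
    p0 = float(np.prod(marginals))
    x = int(np.all(sub, axis=1).sum())
    return float(binom.sf(x - 1, n, p0))
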