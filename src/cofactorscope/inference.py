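"""Cofactor assignment, PPI pair enrichment, ranking and recovery.

Predicted motifs are mapped to known TFs (best match only, or up to the
top five), restricted to modules containing an anchor motif where the
anchor analysis requires it, and the resulting TF pairs are tested for
enrichment of known interacting pairs with the hypergeometric upper tail

    p = phyper(m, n(n-1)/2, M, N(N-1)/2)

where N is the number of TFs in the interaction database, M the number of
known interacting TF pairs (direct: a physical edge; indirect: a shared
interactor), n the number of distinct predicted TFs and m the number of
predicted pairs that are known.  Cofactors are ranked by the product of
the mean -log10 E-value of their motifs and the number of cell lines in
which a motif was assigned to them; a score cutoff of 15 corresponds to a
mean E-value of 1e-5 in three cell lines, and passing requires a strictly
greater score.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import PWM, MotifModule, PPIEdgeList
from .similarity import THETA_KNOWN, MotifMatch, NullCalibration, match_known
from ._rounding import round1

logger = logging.getLogger(__name__)

__all__ = [
    "CofactorAssignment",
    "EnrichmentResult",
    "RankedCofactor",
    "RecoveryResult",
    "assign_cofactors",
    "identify_anchor_motifs",
    "anchor_cofactors",
    "predicted_tf_pairs",
    "split_direct_indirect",
    "phyper",
    "pair_enrichment",
    "rank_cofactors",
    "recovery",
]

#: Ranking-score cutoff: mean E-value 1e-5 over three cell lines.
TAU_DEFAULT = 15.0

_EVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class CofactorAssignment:
    """TFs assigned to one predicted motif in one cell line."""

    motif_id: str
    cell_line: str
    tfs: tuple[tuple[str, float], ...]  # (tf_name, evalue), ascending evalue
    mode: str  # {"top1", "top5"}

    def __post_init__(self) -> None:
        if self.mode not in ("top1", "top5"):
            raise ValueError(f"bad mode {self.mode!r}")
        evs = [e for _, e in self.tfs]
        if evs != sorted(evs):
            raise ValueError("tfs must be sorted by ascending evalue")
        if self.mode == "top1" and len(self.tfs) != 1:
            raise ValueError("top1 assignment must carry exactly one TF")
        if len(self.tfs) > 5:
            raise ValueError("at most five TFs per assignment")

    def tf_names(self) -> set[str]:
        return {t for t, _ in self.tfs}


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of known interacting TF pairs."""

    n: int  # distinct predicted TFs
    m: int  # predicted pairs that are known
    N: int  # TFs in the database
    M: int  # known interacting pairs
    p_value: float
    interaction_class: str = "direct"


@dataclass(frozen=True)
class RankedCofactor:
    tf_name: str
    n_cell_lines: int
    mean_neglog10_evalue: float
    score: float
    passes_cutoff: bool


@dataclass
class RecoveryResult:
    hits: int
    total: int
    percent: float
    missed: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def assignments_from_matches(
    matches_by_motif: Mapping[tuple[str, str], Sequence[MotifMatch]],
    mode: str = "top5",
    cutoff: float = THETA_KNOWN,
) -> list[CofactorAssignment]:
    """Turn per-motif match lists into cofactor assignments.

    ``matches_by_motif`` maps (cell_line, motif_id) to matches sorted by
    ascending E-value (as produced by :func:`~.similarity.match_known`).
    Motifs without a passing match are absent from the output.  In top5
    mode a TF named by several matches keeps its best E-value.
    """
    out: list[CofactorAssignment] = []
    keep = 1 if mode == "top1" else 5
    for (line, motif_id), matches in sorted(matches_by_motif.items()):
        passing = [m for m in matches if m.evalue < cutoff][:keep]
        if not passing:
            continue
        best: dict[str, float] = {}
        for m in passing:
            for tf in m.tf_names:
                if tf not in best or m.evalue < best[tf]:
                    best[tf] = m.evalue
        tfs = tuple(sorted(best.items(), key=lambda kv: (kv[1], kv[0])))
        if mode == "top1":
            tfs = tfs[:1]
        out.append(CofactorAssignment(motif_id, line, tfs, mode))
    return out


def assign_cofactors(
    per_line_motifs: Mapping[str, Sequence[PWM]],
    library: Sequence[PWM],
    calib: NullCalibration,
    mode: str = "top5",
    cutoff: float = THETA_KNOWN,
) -> list[CofactorAssignment]:
    """Assign each predicted motif the known TF(s) it matches below ``cutoff``."""
    matches: dict[tuple[str, str], list[MotifMatch]] = {}
    k = 1 if mode == "top1" else 5
    for line, motifs in per_line_motifs.items():
        for pwm in motifs:
            matches[(line, pwm.motif_id)] = match_known(
                pwm, library, calib, max_k=k, cutoff=cutoff
            )
    return assignments_from_matches(matches, mode=mode, cutoff=cutoff)


def identify_anchor_motifs(
    per_line_motifs: Mapping[str, Sequence[PWM]],
    library: Sequence[PWM],
    calib: NullCalibration,
    anchor_tf: str,
    cutoff: float = THETA_KNOWN,
) -> dict[str, set[str]]:
    """Per line, the predicted motifs whose best match is the anchor TF."""
    out: dict[str, set[str]] = {}
    for line, motifs in per_line_motifs.items():
        ids: set[str] = set()
        for pwm in motifs:
            top = match_known(pwm, library, calib, max_k=1, cutoff=cutoff)
            if top and anchor_tf in top[0].tf_names:
                ids.add(pwm.motif_id)
        out[line] = ids
    return out


def anchor_cofactors(
    per_line_modules: Mapping[str, Sequence[MotifModule]],
    assignments: Sequence[CofactorAssignment],
    anchor_ids: Mapping[str, set[str]],
) -> set[str]:
    """TFs whose motifs share >=1 module with an anchor motif in >=1 line."""
    if not any(anchor_ids.values()):
        logger.warning("no anchor motif found in any cell line")
        return set()
    tfs_of: dict[tuple[str, str], set[str]] = defaultdict(set)
    for a in assignments:
        tfs_of[(a.cell_line, a.motif_id)] |= a.tf_names()
    out: set[str] = set()
    for line, modules in per_line_modules.items():
        anchors = anchor_ids.get(line, set())
        if not anchors:
            continue
        for mod in modules:
            if not (mod.motif_ids & anchors):
                continue
            for motif_id in mod.motif_ids - anchors:
                out |= tfs_of.get((line, motif_id), set())
    return out


def predicted_tf_pairs(
    per_line_modules: Mapping[str, Sequence[MotifModule]],
    assignments: Sequence[CofactorAssignment],
) -> dict[str, set[frozenset[str]]]:
    """Per line, the predicted cofactor TF pairs from module motif pairs.

    Every motif pair in every module contributes the cross product of the
    TFs assigned to its two motifs (a motif may map to several TFs).
    """
    tfs_of: dict[tuple[str, str], set[str]] = defaultdict(set)
    for a in assignments:
        tfs_of[(a.cell_line, a.motif_id)] |= a.tf_names()
    out: dict[str, set[frozenset[str]]] = {}
    for line, modules in per_line_modules.items():
        pairs: set[frozenset[str]] = set()
        for mod in modules:
            members = sorted(mod.motif_ids)
            for ma, mb in combinations(members, 2):
                for ta in tfs_of.get((line, ma), ()):
                    for tb in tfs_of.get((line, mb), ()):
                        if ta != tb:
                            pairs.add(frozenset((ta, tb)))
        out[line] = pairs
    return out


# ---------------------------------------------------------------------------
# Known interacting pairs and enrichment
# ---------------------------------------------------------------------------


def split_direct_indirect(
    ppi: PPIEdgeList,
) -> tuple[set[frozenset[str]], set[frozenset[str]]]:
    """Direct TF pairs (a physical edge) and indirect ones (shared interactor).

    Indirect pairs are unordered TF pairs with a common neighbour (any
    protein), excluding pairs that are already direct.
    """
    tfs = ppi.tfs()
    direct = {e for e in ppi.edges if e <= tfs}
    adjacency: dict[str, set[str]] = defaultdict(set)
    for e in ppi.edges:
        a, b = tuple(e)
        adjacency[a].add(b)
        adjacency[b].add(a)
    indirect: set[frozenset[str]] = set()
    for nbrs in adjacency.values():
        tf_nbrs = sorted(nbrs & tfs)
        for u, v in combinations(tf_nbrs, 2):
            pair = frozenset((u, v))
            if pair not in direct:
                indirect.add(pair)
    return direct, indirect


def _log_choose(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def phyper(x1: int, y1: int, x2: int, y2: int) -> float:
    """Hypergeometric upper tail P(X >= x1).

    ``sum_{k=x1}^{min(y1, x2)} C(y1, k) C(y2-y1, x2-k) / C(y2, x2)`` —
    the probability of at least ``x1`` successes when drawing ``x2`` items
    without replacement from ``y2`` of which ``y1`` are successes.
    Computed in log space; infeasible terms contribute zero.
    """
    for name, v in (("x1", x1), ("y1", y1), ("x2", x2), ("y2", y2)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if x2 > y2 or y1 > y2:
        raise ValueError(f"invalid arguments: need x2 <= y2 and y1 <= y2")
    kmax = min(y1, x2)
    if x1 > kmax:
        return 0.0
    kmin = max(x1, x2 - (y2 - y1))
    ks = np.arange(kmin, kmax + 1)
    log_terms = (
        _log_choose(y1, ks) + _log_choose(y2 - y1, x2 - ks) - _log_choose(y2, x2)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def pair_enrichment(
    predicted_pairs: set[frozenset[str]],
    known_pairs: set[frozenset[str]],
    n_tfs_total: int,
    interaction_class: str = "direct",
) -> EnrichmentResult:
    """Enrichment of known interacting TF pairs among predicted cofactor pairs.

    ``n`` is the number of distinct TFs appearing in the predicted pairs,
    ``m`` the number of predicted pairs that are known, ``N`` the TF count
    of the database, ``M`` the number of known pairs;
    ``p = phyper(m, n(n-1)/2, M, N(N-1)/2)``.
    """
    tfs_in_pred = {t for p in predicted_pairs for t in p}
    n = len(tfs_in_pred)
    M = len(known_pairs)
    N = int(n_tfs_total)
    if n < 2:
        logger.warning("fewer than 2 predicted TFs; enrichment p-value set to 1")
        return EnrichmentResult(n, 0, N, M, 1.0, interaction_class)
    m = len(predicted_pairs & known_pairs)
    p = phyper(m, n * (n - 1) // 2, M, N * (N - 1) // 2)
    return EnrichmentResult(n, m, N, M, p, interaction_class)


# ---------------------------------------------------------------------------
# Ranking and recovery
# ---------------------------------------------------------------------------


def rank_cofactors(
    assignments: Sequence[CofactorAssignment], tau: float = TAU_DEFAULT
) -> list[RankedCofactor]:
    """Rank TFs by (mean -log10 best E-value per line) x (number of lines).

    Within a line, a TF's E-value is the best (smallest) across its motifs;
    across lines, -log10 values are averaged (a geometric-mean E-value).
    Passing the cutoff requires a strictly greater score.
    """
    best: dict[str, dict[str, float]] = defaultdict(dict)  # tf -> line -> evalue
    for a in assignments:
        for tf, e in a.tfs:
            cur = best[tf].get(a.cell_line)
            if cur is None or e < cur:
                best[tf][a.cell_line] = e
    ranked: list[RankedCofactor] = []
    for tf, per_line in best.items():
        L = len(per_line)
        mean_nl = float(
            np.mean([-np.log10(max(e, _EVALUE_FLOOR)) for e in per_line.values()])
        )
        s = mean_nl * L
        ranked.append(RankedCofactor(tf, L, mean_nl, s, s > tau))
    ranked.sort(key=lambda r: (-r.score, r.tf_name))
    return ranked


def recovery(
    predicted_tfs: set[str], curated: Sequence[str]
) -> RecoveryResult:
    """How many curated cofactors the predicted set recovers.

    Returns hits, the curated total, the percentage rounded to one decimal,
    and the miss list (for paralog diagnostics).
    """
    curated_set = set(curated)
    if not curated_set:
        raise ValueError("curated cofactor list is empty")
    hits = len(curated_set & predicted_tfs)
    missed = sorted(curated_set - predicted_tfs)
    percent = round1(100.0 * hits / len(curated_set))
    return RecoveryResult(hits, len(curated_set), percent, missed)
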