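"""GO over-representation of target genes and the divergence regression.

For each cell line the target genes of its (extended) peaks are tested
for GO-term over-representation with the hypergeometric upper tail and
Benjamini-Hochberg correction.  The divergence analysis then asks
whether cell-line pairs with more different cofactor repertoires also
have more different enriched GO-term sets: for every line, the Jaccard
distances of GO-term sets are regressed on the Jaccard distances of
cofactor sets over its pairings with the other lines, giving a per-line
R-squared and their mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .inference import phyper

logger = logging.getLogger(__name__)

__all__ = [
    "GOEnrichment",
    "DivergencePoint",
    "DivergenceResult",
    "go_enrichment",
    "set_difference",
    "divergence_regression",
]


@dataclass(frozen=True)
class GOEnrichment:
    term_id: str
    k: int  # study hits
    n_study: int
    K: int  # term genes in universe
    n_universe: int
    p: float
    q: float
    enriched: bool


@dataclass(frozen=True)
class DivergencePoint:
    line_pair: tuple[str, str]
    cofactor_diff: float
    go_diff: float


@dataclass
class DivergenceResult:
    per_line_r2: dict[str, float | None]
    mean_r2: float
    points: list[DivergencePoint]


def go_enrichment(
    study_genes: set[str],
    gene2go: Mapping[str, set[str]],
    universe_genes: set[str],
    alpha: float = 0.05,
) -> list[GOEnrichment]:
    """Hypergeometric GO over-representation with BH correction.

    Only terms with at least one study hit are tested;
    ``p = phyper(k, n_study, K, n_universe)`` and q is the BH-adjusted
    value across tested terms.  A term is enriched when ``q < alpha``.
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    if not study_genes <= universe_genes:
        raise ValueError("study genes must be a subset of the universe")
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe_genes:
        for term in gene2go.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in study_genes:
                term_study[term] = term_study.get(term, 0) + 1
    tested = sorted(term_study)
    if not tested:
        return []
    n_study, n_universe = len(study_genes), len(universe_genes)
    ps = [
        phyper(term_study[t], n_study, term_universe[t], n_universe) for t in tested
    ]
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    results = [
        GOEnrichment(
            t,
            term_study[t],
            n_study,
            term_universe[t],
            n_universe,
            p,
            float(q),
            bool(q < alpha),
        )
        for t, p, q in zip(tested, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def set_difference(a: set, b: set, metric: str = "jaccard") -> float:
    """Dissimilarity of two sets in [0, 1]; two empty sets differ by 0.

    ``jaccard``: 1 - |a&b| / |a|b|; ``normalized``: |a^b| / (|a| + |b|).
    """
    if not a and not b:
        return 0.0
    if metric == "jaccard":
        return 1.0 - len(a & b) / len(a | b)
    if metric == "normalized":
        return len(a ^ b) / (len(a) + len(b))
    raise ValueError(f"unknown metric {metric!r}")


def _r_squared(xs: np.ndarray, ys: np.ndarray) -> float | None:
    if np.ptp(xs) == 0:
        return None
    syy = float(np.sum((ys - ys.mean()) ** 2))
    if syy == 0:
        return 1.0  # constant response is fit exactly by a flat line
    sxx = float(np.sum((xs - xs.mean()) ** 2))
    sxy = float(np.sum((xs - xs.mean()) * (ys - ys.mean())))
    return sxy * sxy / (sxx * syy)


def divergence_regression(
    per_line_cofactors: Mapping[str, set[str]],
    per_line_terms: Mapping[str, set[str]],
    metric: str = "jaccard",
) -> DivergenceResult:
    """Regress GO-term difference on cofactor difference per cell line.

    For each line c, ordinary least squares of go_diff on cofactor_diff
    over the pairs {(c, other)}.  Lines whose cofactor differences have
    zero variance are reported as missing and excluded from the mean.
    """
    lines = sorted(per_line_cofactors)
    if sorted(per_line_terms) != lines:
        raise ValueError("cofactor and GO-term maps must cover the same lines")
    if len(lines) < 3:
        raise ValueError("need >= 3 cell lines (>= 2 pairs per regression)")
    points: list[DivergencePoint] = []
    diff: dict[frozenset[str], tuple[float, float]] = {}
    for a, b in combinations(lines, 2):
        cd = set_difference(per_line_cofactors[a], per_line_cofactors[b], metric)
        gd = set_difference(per_line_terms[a], per_line_terms[b], metric)
        points.append(DivergencePoint((a, b), cd, gd))
        diff[frozenset((a, b))] = (cd, gd)
    per_line_r2: dict[str, float | None] = {}
    for line in lines:
        xs, ys = [], []
        for other in lines:
            if other == line:
                continue
            cd, gd = diff[frozenset((line, other))]
            xs.append(cd)
            ys.append(gd)
        r2 = _r_squared(np.asarray(xs), np.asarray(ys))
        if r2 is None:
            logger.warning(
                "line %s: zero variance in cofactor differences; R^2 undefined", line
            )
        per_line_r2[line] = r2
    defined = [v for v in per_line_r2.values() if v is not None]
    if not defined:
        raise ValueError("R^2 undefined for every line")
    return DivergenceResult(per_line_r2, float(np.mean(defined)), points)
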