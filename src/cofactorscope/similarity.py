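"""PWM-PWM alignment, similarity scoring and empirical E-value calibration.

The scorer performs ungapped alignment of two probability matrices over all
offsets and both orientations.  The per-offset score is the sum of
per-column Pearson correlations over the overlapping columns, divided by
the larger motif width, so partial overlaps are penalised and uniform
(uninformative) columns contribute nothing.

E-values are calibrated empirically against a null of column-resampled
library motifs.  Because an empirical tail bottoms out at
``library_size/(n_null+1)``, an optional Gaussian tail extension
(``extreme_tail=True``) lets match E-values reach the very small
thresholds (1e-5, 1e-8) used for cofactor assignment and cross-cell-line
motif comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import PWM

__all__ = [
    "MotifMatch",
    "NullCalibration",
    "AlignmentResult",
    "reverse_complement_pwm",
    "align_score",
    "calibrate_null",
    "evalue",
    "match_known",
]

#: Default E-value threshold for calling a predicted motif "known".
THETA_KNOWN = 1e-5
#: Relaxed variant of the known-motif threshold.
THETA_RELAXED = 1e-4
#: More stringent threshold for cross-cell-line motif comparison.
THETA_CROSS = 1e-8

_SCORE_EPS = 1e-12
_MIN_EVALUE_FLOOR = 1e-300


class AlignmentResult(NamedTuple):
    score: float
    offset: int
    orientation: str


@dataclass(frozen=True)
class MotifMatch:
    """A scored, E-valued alignment of a query motif to a known motif."""

    query_id: str
    target_id: str
    tf_names: tuple[str, ...]
    offset: int
    orientation: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class NullCalibration:
    """Sorted null alignment scores plus the Gaussian fitted to them."""

    null_scores: np.ndarray
    library_size: int
    seed: int
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_scores = np.sort(np.asarray(self.null_scores, dtype=float))
        if self.n_null < 1:
            raise ValueError("empty null")
        self.mu = float(self.null_scores.mean())
        self.sigma = float(self.null_scores.std(ddof=1)) if self.n_null > 1 else 0.0

    @property
    def n_null(self) -> int:
        return int(self.null_scores.size)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "null_scores": self.null_scores.tolist(),
            "library_size": self.library_size,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullCalibration":
        obj = json.loads(Path(path).read_text())
        return cls(np.asarray(obj["null_scores"]), obj["library_size"], obj["seed"])


def reverse_complement_pwm(pwm: PWM) -> PWM:
    """Reverse-complement a PWM: columns reversed, A<->T and C<->G swapped."""
    return PWM(pwm.motif_id, pwm.matrix[::-1, ::-1], list(pwm.tf_names), pwm.source)


def _centered(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = mat - mat.mean(axis=0, keepdims=True)
    return c, np.sqrt(np.einsum("ij,ij->j", c, c))


def align_score(a: PWM, b: PWM, min_overlap: int = 4) -> AlignmentResult:
    """Best ungapped alignment score between two PWMs.

    Scans all offsets with overlap >= ``min(min_overlap, min widths)`` and
    both orientations of ``b``.  The score is
    ``sum(per-column Pearson r over the overlap) / max(width_a, width_b)``;
    a zero-variance (uniform) column contributes correlation 0.  Ties are
    broken by smaller ``|offset|``, then '+' orientation.
    """
    ma, wa = a.matrix, a.width
    wb = b.width
    mo = min(min_overlap, wa, wb)
    denom = max(wa, wb)
    ca, na = _centered(ma)

    candidates: list[tuple[int, int, int, str, np.ndarray, np.ndarray]] = []
    for oi, (orient, mb) in enumerate((("+", b.matrix), ("-", b.matrix[::-1, ::-1]))):
        cb, nb = _centered(mb)
        for s in range(-(wb - mo), wa - mo + 1):
            candidates.append((abs(s), oi, s, orient, cb, nb))
    candidates.sort(key=lambda t: (t[0], t[1]))

    best_score = -math.inf
    best_offset = 0
    best_orient = "+"
    for _, _, s, orient, cb, nb in candidates:
        i0, j0 = max(0, s), max(0, -s)
        length = min(wa - i0, wb - j0)
        num = np.einsum("ij,ij->j", ca[:, i0 : i0 + length], cb[:, j0 : j0 + length])
        den = na[i0 : i0 + length] * nb[j0 : j0 + length]
        ok = den > 0
        r = np.zeros(length)
        r[ok] = num[ok] / den[ok]
        score = float(r.sum()) / denom
        if score > best_score + _SCORE_EPS:
            best_score, best_offset, best_orient = score, s, orient
    return AlignmentResult(best_score, best_offset, best_orient)


def calibrate_null(
    library: Sequence[PWM], n_null: int = 2000, seed: int = 0
) -> NullCalibration:
    """Empirical null of alignment scores between column-resampled motifs.

    Each null motif keeps the width of a randomly chosen library motif but
    has its columns shuffled and resampled (with replacement) from the
    pooled columns of the whole library, destroying motif identity while
    preserving per-column information content.
    """
    if len(library) < 2:
        raise ValueError("need >= 2 library motifs to calibrate")
    rng = np.random.default_rng(seed)
    pool = np.concatenate([p.matrix for p in library], axis=1)
    n_cols = pool.shape[1]
    widths = np.array([p.width for p in library])
    scores = np.empty(n_null)
    for i in range(n_null):
        wa, wb = rng.choice(widths, size=2, replace=True)
        x = PWM("nullA", pool[:, rng.integers(0, n_cols, size=wa)])
        y = PWM("nullB", pool[:, rng.integers(0, n_cols, size=wb)])
        scores[i] = align_score(x, y).score
    return NullCalibration(scores, library_size=len(library), seed=seed)


def evalue(score: float, calib: NullCalibration, extreme_tail: bool = False) -> float:
    """Empirical E-value of an alignment score.

    ``E = library_size * (#null >= score + 1) / (n_null + 1)``, monotone
    non-increasing in the score.  With ``extreme_tail=True``, scores beyond
    every null observation use the upper tail of a Gaussian fitted to the
    null (capped at the empirical minimum ``1/(n_null+1)``) so that E-values
    far below the empirical resolution remain defined and monotone.
    """
    n = calib.n_null
    count = n - int(np.searchsorted(calib.null_scores, score, side="left"))
    e_emp = calib.library_size * (count + 1) / (n + 1)
    if count > 0 or not extreme_tail:
        return float(e_emp)
    if calib.sigma > 0:
        sf = float(norm.sf((score - calib.mu) / calib.sigma))
    else:
        sf = 0.0
    tail = min(1.0 / (n + 1), max(sf, _MIN_EVALUE_FLOOR))
    return float(calib.library_size * tail)


def match_known(
    query: PWM,
    library: Sequence[PWM],
    calib: NullCalibration,
    max_k: int = 5,
    cutoff: float | None = THETA_KNOWN,
    extreme_tail: bool = True,
) -> list[MotifMatch]:
    """Top-k matches of a query motif against a known library.

    Matches are sorted by ascending E-value (ties: higher score, then
    target id), truncated to ``max_k``, and filtered to ``evalue < cutoff``.
    Pass ``cutoff=None`` for the unfiltered top-k (used for paralog
    diagnostics).
    """
    if not library:
        raise ValueError("empty motif library")
    matches = []
    for target in library:
        res = align_score(query, target)
        e = evalue(res.score, calib, extreme_tail=extreme_tail)
        matches.append(
            MotifMatch(
                query.motif_id,
                target.motif_id,
                tuple(target.tf_names),
                res.offset,
                res.orientation,
                res.score,
                e,
            )
        )
    matches.sort(key=lambda m: (m.evalue, -m.score, m.target_id))
    matches = matches[:max_k]
    if cutoff is not None and math.isfinite(cutoff):
        matches = [m for m in matches if m.evalue < cutoff]
    return matches
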