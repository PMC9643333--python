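"""Model/Results interface for a whole cofactor study.

:class:`CofactorStudy` is built from a :class:`~.synthetic.StudyBundle`
(simulated or loaded from disk) plus the analysis thresholds;
:meth:`CofactorStudy.fit` runs the full pipeline — E-value calibration,
motif-to-TF matching, cross-cell-line conservation with its resampling
null, PPI pair enrichment, cofactor ranking and recovery, peak
annotation, GO enrichment and the divergence regression — and returns a
:class:`CofactorStudyResults` carrying every estimate, its diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


import pandas as pd
import yaml

from . import __version__
from ._rounding import mean1, round1
from .inference import (
    CofactorAssignment,
    EnrichmentResult,
    RankedCofactor,
    RecoveryResult,
    anchor_cofactors,
    assignments_from_matches,
    pair_enrichment,
    predicted_tf_pairs,
    rank_cofactors,
    recovery,
    split_direct_indirect,
)
from .module_analysis import (
    ConservationReport,
    PairNullResult,
    build_similarity,
    module_pairs,
    motif_conservation,
    pair_conservation,
    random_pair_null,
)
from .pathway_divergence import DivergenceResult, divergence_regression, go_enrichment
from .peak_annotation import TargetAssignment, extend_peaks, nearest_tss, overlap_fraction
from .similarity import (
    THETA_CROSS,
    THETA_KNOWN,
    THETA_RELAXED,
    calibrate_null,
    match_known,
)
from .synthetic import ANCHOR_TF, StudyBundle, SyntheticConfig, read_bundle, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "StudySummaryRow",
    "summarize_study",
    "CofactorStudy",
    "CofactorStudyResults",
    "PipelineError",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class StudySummaryRow:
    """One study-summary row: per-cell-line motif and peak statistics."""

    cell_line: str
    n_peaks: int
    n_motifs: int
    pct_known_strict: float
    pct_known_relaxed: float
    pct_conserved: float
    pct_peak_overlap: float


_PCT_COLUMNS = (
    "pct_known_strict",
    "pct_known_relaxed",
    "pct_conserved",
    "pct_peak_overlap",
)


def summarize_study(
    rows: Sequence[StudySummaryRow],
) -> tuple[list[StudySummaryRow], dict[str, float]]:
    """Column means (one decimal, exact decimal arithmetic) of summary rows."""
    if not rows:
        raise ValueError("no summary rows")
    means = {
        col: mean1([getattr(r, col) for r in rows]) for col in _PCT_COLUMNS
    }
    return list(rows), means


@dataclass
class CofactorStudyResults:
    """Fitted estimates, diagnostics and tables of one cofactor study."""

    model: "CofactorStudy"
    assignments: list[CofactorAssignment]
    anchor_motif_ids: dict[str, set[str]]
    best_evalues: dict[str, dict[str, float]]  # line -> motif_id -> best E
    conservation: ConservationReport
    pair_null: PairNullResult
    enrichment_per_line: dict[str, EnrichmentResult]
    enrichment_pooled: EnrichmentResult
    enrichment_pooled_indirect: EnrichmentResult
    ranked: list[RankedCofactor]
    anchor_cofactor_set: set[str]
    predicted_tfs: set[str]
    recovery: RecoveryResult | None
    targets: dict[str, list[TargetAssignment]]
    go_terms: dict[str, set[str]]  # enriched terms per line
    divergence: DivergenceResult | None
    summary_rows: list[StudySummaryRow]
    column_means: dict[str, float]

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text study summary in the style of a per-cell-line table."""
        lines = ["Cofactor study summary", "======================", ""]
        hdr = (
            f"{'cell line':<10}{'#peaks':>8}{'#motifs':>9}{'%known(strict)':>15}"
            f"{'%known(relaxed)':>16}{'%conserved':>12}{'%peak overlap':>14}"
        )
        lines.append(hdr)
        for r in self.summary_rows:
            lines.append(
                f"{r.cell_line:<10}{r.n_peaks:>8}{r.n_motifs:>9}"
                f"{round1(r.pct_known_strict):>15.1f}{round1(r.pct_known_relaxed):>16.1f}"
                f"{round1(r.pct_conserved):>12.1f}{round1(r.pct_peak_overlap):>14.1f}"
            )
        m = self.column_means
        lines.append(
            f"{'mean':<10}{'':>8}{'':>9}{m['pct_known_strict']:>15.1f}"
            f"{m['pct_known_relaxed']:>16.1f}{m['pct_conserved']:>12.1f}"
            f"{m['pct_peak_overlap']:>14.1f}"
        )
        lines.append("")
        lines.append(
            f"pair conservation: {self.conservation.overall_pair_fraction:.3f} observed; "
            f"random-module null p_empirical={self.pair_null.p_empirical:.4g}, "
            f"p_normal={self.pair_null.p_normal:.3g}"
        )
        per_line_ps = [e.p_value for e in self.enrichment_per_line.values()]
        sig = sum(p < 0.05 for p in per_line_ps)
        lines.append(
            f"known-pair enrichment (direct): p<0.05 in {sig}/{len(per_line_ps)} "
            f"cell lines (min p={min(per_line_ps):.3g})"
        )
        n_pass = sum(r.passes_cutoff for r in self.ranked)
        lines.append(f"ranked cofactors: {len(self.ranked)} total, {n_pass} above cutoff")
        if self.recovery is not None:
            rec = self.recovery
            lines.append(
                f"recovery of curated cofactors: {rec.hits}/{rec.total} ({rec.percent}%)"
            )
        if self.divergence is not None:
            lines.append(
                f"divergence regression mean R^2 = {self.divergence.mean_r2:.3f}"
            )
        return "\n".join(lines)

    def summary_json_obj(self) -> dict:
        """Deterministic JSON-serialisable summary (full precision)."""
        obj: dict = {
            "rows": [
                {
                    "cell_line": r.cell_line,
                    "n_peaks": r.n_peaks,
                    "n_motifs": r.n_motifs,
                    "pct_known_strict": r.pct_known_strict,
                    "pct_known_relaxed": r.pct_known_relaxed,
                    "pct_conserved": r.pct_conserved,
                    "pct_peak_overlap": r.pct_peak_overlap,
                }
                for r in self.summary_rows
            ],
            "column_means": self.column_means,
            "pair_conservation": {
                "overall": self.conservation.overall_pair_fraction,
                "per_line": self.conservation.per_line_pair_fraction,
                "p_empirical": self.pair_null.p_empirical,
                "p_normal": self.pair_null.p_normal,
            },
            "enrichment": {
                line: {"n": e.n, "m": e.m, "M": e.M, "N": e.N, "p": e.p_value}
                for line, e in self.enrichment_per_line.items()
            },
            "enrichment_pooled": {
                "direct": self.enrichment_pooled.p_value,
                "indirect": self.enrichment_pooled_indirect.p_value,
            },
            "n_ranked": len(self.ranked),
            "n_passing": sum(r.passes_cutoff for r in self.ranked),
            "predicted_tfs": sorted(self.predicted_tfs),
            "anchor_cofactors": sorted(self.anchor_cofactor_set),
        }
        if self.recovery is not None:
            obj["recovery"] = {
                "hits": self.recovery.hits,
                "total": self.recovery.total,
                "percent": self.recovery.percent,
                "missed": self.recovery.missed,
            }
        if self.divergence is not None:
            obj["divergence"] = {
                "mean_r2": self.divergence.mean_r2,
                "per_line_r2": self.divergence.per_line_r2,
            }
        return obj

    def ranked_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tf_name": [r.tf_name for r in self.ranked],
                "n_cell_lines": [r.n_cell_lines for r in self.ranked],
                "mean_neglog10_evalue": [r.mean_neglog10_evalue for r in self.ranked],
                "score": [r.score for r in self.ranked],
                "passes_cutoff": [r.passes_cutoff for r in self.ranked],
            }
        )

    def save(self, out_dir: str | Path) -> None:
        """Write summary.tsv/json, ranked cofactors, enrichment, conservation,
        target assignments, divergence points and a run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = pd.DataFrame([vars(r) for r in self.summary_rows])
        rows.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary_json_obj(), sort_keys=True, indent=1)
        )
        self.ranked_frame().to_csv(out / "ranked_cofactors.tsv", sep="\t", index=False)
        (out / "enrichment.json").write_text(
            json.dumps(
                {
                    "per_line": {
                        line: vars(e) for line, e in self.enrichment_per_line.items()
                    },
                    "pooled_direct": vars(self.enrichment_pooled),
                    "pooled_indirect": vars(self.enrichment_pooled_indirect),
                },
                sort_keys=True,
                indent=1,
            )
        )
        (out / "conservation.json").write_text(
            json.dumps(
                {
                    "per_line_motif_fraction": self.conservation.per_line_motif_fraction,
                    "per_line_pair_fraction": self.conservation.per_line_pair_fraction,
                    "overall_pair_fraction": self.conservation.overall_pair_fraction,
                    "theta_cross": self.conservation.theta_cross,
                    "null": {
                        "p_empirical": self.pair_null.p_empirical,
                        "p_normal": self.pair_null.p_normal,
                        "n_replicates": len(self.pair_null.null_fractions),
                    },
                },
                sort_keys=True,
                indent=1,
            )
        )
        target_rows = [
            {"cell_line": line, "peak_id": t.peak_id, "gene_id": t.gene_id,
             "signed_distance": t.signed_distance}
            for line in sorted(self.targets)
            for t in self.targets[line]
        ]
        pd.DataFrame(target_rows).to_csv(out / "targets.tsv", sep="\t", index=False)
        if self.divergence is not None:
            (out / "divergence.json").write_text(
                json.dumps(
                    {
                        "mean_r2": self.divergence.mean_r2,
                        "per_line_r2": self.divergence.per_line_r2,
                        "points": [
                            {
                                "line_a": p.line_pair[0],
                                "line_b": p.line_pair[1],
                                "cofactor_diff": p.cofactor_diff,
                                "go_diff": p.go_diff,
                            }
                            for p in self.divergence.points
                        ],
                    },
                    sort_keys=True,
                    indent=1,
                )
            )
        m = self.model
        log_lines = [
            f"cofactorscope {__version__}",
            f"seed={m.seed}",
            f"anchor_tf={m.anchor_tf}",
            f"mode={m.mode} theta_known={m.theta_known} theta_relaxed={m.theta_relaxed} "
            f"theta_cross={m.theta_cross} tau={m.tau}",
            f"null_reps={m.null_reps} n_null={m.n_null} alpha={m.alpha}",
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")


class CofactorStudy:
    """A cofactor-discovery analysis bound to one study bundle.

    Parameters mirror the analysis thresholds: ``theta_known`` (motif is
    "known" when matched below it), ``theta_relaxed`` (reporting-only
    relaxed variant), ``theta_cross`` (cross-cell-line motif similarity),
    ``tau`` (ranking-score cutoff), ``mode`` ("top1"/"top5" TF
    assignment), ``null_reps`` (random-module replicates) and ``n_null``
    (E-value calibration size).
    """

    def __init__(
        self,
        bundle: StudyBundle,
        anchor_tf: str | None = None,
        mode: str = "top5",
        theta_known: float = THETA_KNOWN,
        theta_relaxed: float = THETA_RELAXED,
        theta_cross: float = THETA_CROSS,
        tau: float = 15.0,
        null_reps: int = 199,
        n_null: int = 2000,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> None:
        self.bundle = bundle
        self.anchor_tf = anchor_tf or (
            bundle.truth.anchor_tf if bundle.truth is not None else ANCHOR_TF
        )
        self.mode = mode
        self.theta_known = theta_known
        self.theta_relaxed = theta_relaxed
        self.theta_cross = theta_cross
        self.tau = tau
        self.null_reps = null_reps
        self.n_null = n_null
        self.alpha = alpha
        self.seed = seed

    # -- constructors ------------------------------------------------------

    @classmethod
    def simulate(
        cls, config: SyntheticConfig | None = None, fit_seed: int | None = None, **kw
    ) -> "CofactorStudy":
        """Simulate a bundle and bind a study to it.

        Keyword arguments whose names match :class:`SyntheticConfig` fields
        go to the simulator; the rest configure the study.
        """
        cfg_fields = set(SyntheticConfig.__dataclass_fields__)
        cfg_kw = {k: v for k, v in kw.items() if k in cfg_fields}
        study_kw = {k: v for k, v in kw.items() if k not in cfg_fields}
        bundle = simulate_study(config, **cfg_kw) if config is None else simulate_study(config)
        seed = fit_seed if fit_seed is not None else bundle.config.seed
        return cls(bundle, seed=seed, **study_kw)

    @classmethod
    def from_directory(cls, path: str | Path, **kw) -> "CofactorStudy":
        return cls(read_bundle(path), **kw)

    # -- fitting -----------------------------------------------------------

    def fit(self, curated: Sequence[str] | None = None) -> CofactorStudyResults:
        """Run every pipeline stage and return the results object."""
        b = self.bundle
        stage = "calibrate"
        try:
            calib = calibrate_null(b.known_library, n_null=self.n_null, seed=self.seed)

            stage = "match"
            raw: dict[tuple[str, str], list] = {}
            for line, motifs in b.per_line_motifs.items():
                for pwm in motifs:
                    raw[(line, pwm.motif_id)] = match_known(
                        pwm, b.known_library, calib, max_k=5, cutoff=None
                    )
            best_evalues: dict[str, dict[str, float]] = {}
            for (line, mid), matches in raw.items():
                best_evalues.setdefault(line, {})[mid] = matches[0].evalue
            assignments = assignments_from_matches(
                raw, mode=self.mode, cutoff=self.theta_known
            )
            anchor_ids: dict[str, set[str]] = {line: set() for line in b.cell_lines}
            for (line, mid), matches in raw.items():
                top = matches[0]
                if self.anchor_tf in top.tf_names and top.evalue < self.theta_known:
                    anchor_ids[line].add(mid)

            stage = "conserve"
            relation = build_similarity(b.per_line_motifs, self.theta_cross, calib)
            motif_fracs = motif_conservation(
                b.per_line_motifs, self.theta_cross, relation=relation
            )
            per_line_pairs = {
                line: module_pairs(mods) for line, mods in b.modules.items()
            }
            pair_fracs, overall = pair_conservation(per_line_pairs, relation)
            conservation = ConservationReport(
                motif_fracs, pair_fracs, overall, self.theta_cross
            )
            pair_null = random_pair_null(
                b.modules,
                b.per_line_motifs,
                R=self.null_reps,
                theta_cross=self.theta_cross,
                seed=self.seed + 1,
                relation=relation,
            )

            stage = "infer"
            direct, indirect = split_direct_indirect(b.ppi)
            n_tfs = b.ppi.n_tfs
            pred_pairs = predicted_tf_pairs(b.modules, assignments)
            enrichment_per_line = {
                line: pair_enrichment(pairs, direct, n_tfs, "direct")
                for line, pairs in pred_pairs.items()
            }
            pooled_pairs = set().union(*pred_pairs.values()) if pred_pairs else set()
            enrichment_pooled = pair_enrichment(pooled_pairs, direct, n_tfs, "direct")
            enrichment_indirect = pair_enrichment(
                pooled_pairs, indirect, n_tfs, "indirect"
            )
            ranked = rank_cofactors(assignments, tau=self.tau)
            anchor_set = anchor_cofactors(b.modules, assignments, anchor_ids)
            predicted_tfs = set()
            for a in assignments:
                predicted_tfs |= a.tf_names()
            curated_list = curated
            if curated_list is None and b.truth is not None:
                curated_list = sorted(b.truth.cofactors)
            recov = (
                recovery(predicted_tfs, curated_list) if curated_list else None
            )

            stage = "annotate"
            targets: dict[str, list[TargetAssignment]] = {}
            study_genes: dict[str, set[str]] = {}
            for line in b.cell_lines:
                extended = extend_peaks(b.peaks[line], chrom_sizes=b.chrom_sizes)
                t = nearest_tss(extended, b.annotation)
                targets[line] = t
                study_genes[line] = {x.gene_id for x in t}

            stage = "diverge"
            universe = {g.gene_id for g in b.annotation}
            go_terms: dict[str, set[str]] = {}
            for line in b.cell_lines:
                enr = go_enrichment(
                    study_genes[line], b.gene2go, universe, alpha=self.alpha
                )
                go_terms[line] = {e.term_id for e in enr if e.enriched}
            per_line_cofactors = {line: set() for line in b.cell_lines}
            for a in assignments:
                per_line_cofactors[a.cell_line] |= a.tf_names()
            divergence = None
            if len(b.cell_lines) >= 3:
                divergence = divergence_regression(per_line_cofactors, go_terms)
            else:
                logger.warning("fewer than 3 cell lines; divergence regression skipped")

            stage = "summarize"
            rows = []
            for line in b.cell_lines:
                evs = best_evalues.get(line, {})
                n_motifs = len(b.per_line_motifs[line])
                strict = 100.0 * sum(e < self.theta_known for e in evs.values()) / n_motifs
                relaxed = 100.0 * sum(e < self.theta_relaxed for e in evs.values()) / n_motifs
                others = [
                    p for ol in b.cell_lines if ol != line for p in b.peaks[ol]
                ]
                rows.append(
                    StudySummaryRow(
                        line,
                        len(b.peaks[line]),
                        n_motifs,
                        strict,
                        relaxed,
                        100.0 * motif_fracs[line],
                        overlap_fraction(b.peaks[line], others),
                    )
                )
            rows, means = summarize_study(rows)
        except Exception as exc:  # annotate failures with the stage name
            raise PipelineError(stage, exc) from exc

        return CofactorStudyResults(
            model=self,
            assignments=assignments,
            anchor_motif_ids=anchor_ids,
            best_evalues=best_evalues,
            conservation=conservation,
            pair_null=pair_null,
            enrichment_per_line=enrichment_per_line,
            enrichment_pooled=enrichment_pooled,
            enrichment_pooled_indirect=enrichment_indirect,
            ranked=ranked,
            anchor_cofactor_set=anchor_set,
            predicted_tfs=predicted_tfs,
            recovery=recov,
            targets=targets,
            go_terms=go_terms,
            divergence=divergence,
            summary_rows=rows,
            column_means=means,
        )


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> CofactorStudyResults:
    """Run the full pipeline from a YAML config and write all artifacts.

    The config names either a ``synthetic`` block (SyntheticConfig fields)
    or an ``inputs: {dir: ...}`` bundle directory, plus optional ``fit``
    parameters (CofactorStudy keyword arguments) and a ``seed``.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"config file not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text()) or {}
    fit_kw = dict(cfg.get("fit") or {})
    seed = int(cfg.get("seed", 0))
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"] or {})
        syn.setdefault("seed", seed)
        for key in ("module_size_range", "width_range"):
            if key in syn:
                syn[key] = tuple(syn[key])
        bundle = simulate_study(SyntheticConfig(**syn))
    elif "inputs" in cfg:
        in_dir = Path(cfg["inputs"]["dir"])
        if not in_dir.exists():
            raise FileNotFoundError(f"input bundle directory not found: {in_dir}")
        bundle = read_bundle(in_dir)
    else:
        raise ValueError("config must contain a 'synthetic' or 'inputs' section")
    study = CofactorStudy(bundle, seed=seed, **fit_kw)
    results = study.fit()
    results.save(out_dir)
    return results
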