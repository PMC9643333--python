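"""Synthetic multi-cell-line studies with planted ground truth.

A simulated study emulates the inputs of an anchor-TF cofactor screen:
per-cell-line predicted motifs (noisy copies of known library motifs),
motif modules containing an anchor motif, ChIP-seq-like peaks on a toy
two-chromosome genome, a PPI edge list with planted cofactor edges, a
gene annotation with TSSs, and a gene-to-GO map constructed so that cell
lines sharing more cofactors share more target-gene GO terms.  The
``truth`` record carries every plant, so downstream recovery, conservation
and enrichment statistics can be scored against it.

Construction outline (one global seed fans out to fixed per-component
streams, so adding a component never shifts the others):

* A known library of ``library_size`` informative PWMs; the first motif
  is the anchor TF ("HIF1A").
* A conserved core pool of ``motifs_per_line - 1`` library TFs; each line
  draws a ``conservation_rate`` fraction of its motifs from the pool and
  fills the rest with line-private TFs dealt from the remaining library
  (recycled across lines only when the library is exhausted).
* Each line's predicted motifs are Dirichlet perturbations
  (concentration ``pwm_noise``) of its TFs' library motifs.
* Modules sample members from the line's motifs with a coverage-first
  queue (every motif appears in >=1 module) and a weight bias toward
  planted cofactor motifs; the anchor motif joins with probability
  ``anchor_inclusion``.
* The PPI contains every planted cofactor-anchor edge, a configurable
  fraction of cofactor-cofactor edges (only among pairs co-resident in a
  cell line), plus background edges among all proteins.
* Each library TF with a GO term owns a small disjoint "club" of genes;
  a line's peaks are placed near the TSSs of the club genes of its TFs,
  planting the cofactor-difference vs GO-difference trend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    PWM,
    GeneAnnotation,
    MotifModule,
    Peak,
    PPIEdgeList,
    parse_annotation,
    parse_bed,
    parse_edge_list,
    parse_gene2go,
    parse_modules,
    parse_pwm_file,
    write_annotation,
    write_bed,
    write_edge_list,
    write_gene2go,
    write_modules,
    write_pwm_file,
)

__all__ = [
    "SyntheticConfig",
    "StudyTruth",
    "StudyBundle",
    "generate_pwm_library",
    "perturb_pwm",
    "simulate_study",
    "simulate_occurrence_matrix",
    "write_bundle",
    "read_bundle",
]

ANCHOR_TF = "HIF1A"

# fixed component indices for the seed fan-out
_C_LIBRARY, _C_LINES, _C_TRUTH, _C_MODULES, _C_PPI, _C_GENES, _C_GO, _C_PEAKS = range(8)


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


@dataclass
class SyntheticConfig:
    """Study-design parameters of a simulated cofactor screen."""

    n_cell_lines: int = 8
    library_size: int = 60
    motifs_per_line: int = 25
    conservation_rate: float = 0.7
    n_modules_per_line: int = 30
    module_size_range: tuple[int, int] = (2, 5)
    anchor_inclusion: float = 0.8
    pwm_noise: float = 50.0  # Dirichlet concentration multiplier
    n_true_cofactors: int = 15
    ppi_background_density: float = 0.02
    n_genes: int = 500
    n_go_terms: int = 40
    seed: int = 0
    # secondary knobs (see docs/methods.md)
    width_range: tuple[int, int] = (6, 12)
    cofactor_edge_rate: float = 0.6
    module_cofactor_bias: float = 3.0
    module_pair_seed: float = 0.8  # P(module seeded with an interacting pair)
    n_decoy_proteins: int = 40
    go_club_size: int = 6
    go_background_rate: float = 0.05
    n_background_peaks: int = 25
    gene_spacing: int = 4000

    def validate(self) -> None:
        for name in ("conservation_rate", "anchor_inclusion",
                     "ppi_background_density", "cofactor_edge_rate",
                     "go_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.motifs_per_line > self.library_size:
            raise ValueError("motifs_per_line must not exceed library_size")
        if self.motifs_per_line < 2:
            raise ValueError("need >= 2 motifs per line")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("module sizes must be >= 2 and ordered")
        if hi > self.motifs_per_line:
            raise ValueError("module sizes cannot exceed motifs_per_line")
        if self.width_range[0] < 4:
            raise ValueError("motif widths must be >= 4")
        if self.pwm_noise <= 0:
            raise ValueError("pwm_noise must be positive")
        if self.n_true_cofactors < 1:
            raise ValueError("need >= 1 true cofactor")
        if self.n_true_cofactors > self.library_size - 1:
            raise ValueError("more true cofactors than non-anchor TFs")


@dataclass
class StudyTruth:
    """Everything planted during simulation."""

    anchor_tf: str
    cofactors: set[str]
    interacting_pairs: set[frozenset[str]]
    motif_sources: dict[str, tuple[str, str]]  # motif_id -> (cell_line, tf)
    conserved_pairs: set[frozenset[str]]  # cross-line motif-id correspondences

    def conserved_motif_ids(self) -> set[str]:
        return {m for pair in self.conserved_pairs for m in pair}

    def planted_conserved_fraction(self, per_line_ids: dict[str, list[str]]) -> dict[str, float]:
        conserved = self.conserved_motif_ids()
        return {
            line: (sum(m in conserved for m in ids) / len(ids) if ids else 0.0)
            for line, ids in per_line_ids.items()
        }


@dataclass
class StudyBundle:
    """One synthetic study: all pipeline inputs plus the planted truth."""

    config: SyntheticConfig
    known_library: list[PWM]
    per_line_motifs: dict[str, list[PWM]]
    modules: dict[str, list[MotifModule]]
    anchor_motif_ids: dict[str, set[str]]
    peaks: dict[str, list[Peak]]
    ppi: PPIEdgeList
    annotation: list[GeneAnnotation]
    gene2go: dict[str, set[str]]
    chrom_sizes: dict[str, int]
    truth: StudyTruth | None = None

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.per_line_motifs)

    def per_line_motif_ids(self) -> dict[str, list[str]]:
        return {
            line: [p.motif_id for p in motifs]
            for line, motifs in self.per_line_motifs.items()
        }


def generate_pwm_library(
    n: int,
    width_range: tuple[int, int] = (6, 12),
    seed: int = 0,
    id_prefix: str = "KM",
    alpha: float = 0.3,
) -> list[PWM]:
    """Draw ``n`` informative known motifs with sparse-Dirichlet columns.

    With ``alpha=0.3`` the mean per-column information content is about
    1 bit, comfortably above the 0.5-bit floor that keeps chance
    alignments uninformative.  Ids and TF names are deterministic in the
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = width_range
    if lo < 4:
        raise ValueError("motif widths must be >= 4")
    if hi < lo:
        raise ValueError("width_range must be ordered")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        w = int(rng.integers(lo, hi + 1))
        mat = rng.dirichlet([alpha] * 4, size=w).T
        out.append(
            PWM(f"{id_prefix}{i + 1:03d}", mat, [f"TF{i + 1:03d}"], source="known")
        )
    return out


def perturb_pwm(
    pwm: PWM,
    kappa: float,
    seed: int | np.random.Generator = 0,
    motif_id: str | None = None,
) -> PWM:
    """Resample each column from Dirichlet(kappa * column + 0.01).

    Large ``kappa`` concentrates the perturbation around the source motif;
    the width is preserved and the result is tagged as predicted (de novo)
    with no TF names.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = [rng.dirichlet(kappa * col + 0.01) for col in pwm.matrix.T]
    return PWM(
        motif_id or f"{pwm.motif_id}_p",
        np.column_stack(cols),
        [],
        source="predicted",
    )


def _deal_privates(
    rng: np.random.Generator,
    candidates: list[int],
    n_lines: int,
    n_per_line: int,
) -> list[list[int]]:
    """Deal private TF indices to lines, disjoint until the pool runs out."""
    deck: list[int] = []
    out: list[list[int]] = []
    for _ in range(n_lines):
        mine: list[int] = []
        while len(mine) < n_per_line:
            if not deck:
                deck = list(rng.permutation(candidates))
            nxt = deck.pop()
            if nxt not in mine:
                mine.append(nxt)
        out.append(mine)
    return out


def simulate_study(config: SyntheticConfig | None = None, **overrides) -> StudyBundle:
    """Generate one complete synthetic study from a config."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    config.validate()
    cfg = config
    seed = cfg.seed

    # --- known library; motif 0 is the anchor TF -------------------------
    library = generate_pwm_library(
        cfg.library_size, cfg.width_range, seed=int(_rng(seed, _C_LIBRARY).integers(2**31))
    )
    library[0] = PWM(library[0].motif_id, library[0].matrix, [ANCHOR_TF], "known")
    tf_name = {i: library[i].tf_names[0] for i in range(cfg.library_size)}

    # --- per-line TF composition ----------------------------------------
    rng_lines = _rng(seed, _C_LINES)
    lines = [f"CL{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    n_slots = cfg.motifs_per_line - 1
    n_core = round(cfg.conservation_rate * n_slots)
    non_anchor = list(range(1, cfg.library_size))
    if n_core > 0:
        pool = sorted(rng_lines.choice(non_anchor, size=n_slots, replace=False).tolist())
    else:
        pool = []
    rest = [i for i in non_anchor if i not in pool]
    n_priv = n_slots - n_core
    if n_priv > 0:
        candidates = rest if len(rest) >= n_priv else list(non_anchor)
        privates = _deal_privates(rng_lines, candidates, cfg.n_cell_lines, n_priv)
    else:
        privates = [[] for _ in lines]
    line_tf_idx: dict[str, list[int]] = {}
    for li, line in enumerate(lines):
        core = (
            sorted(rng_lines.choice(pool, size=n_core, replace=False).tolist())
            if n_core
            else []
        )
        line_tf_idx[line] = [0] + core + sorted(privates[li])

    # --- predicted motifs: perturbed copies ------------------------------
    rng_perturb = _rng(seed, _C_LINES + 100)  # separate stream, fixed key
    per_line_motifs: dict[str, list[PWM]] = {}
    anchor_motif_ids: dict[str, set[str]] = {}
    motif_sources: dict[str, tuple[str, str]] = {}
    for line in lines:
        motifs = []
        for j, idx in enumerate(line_tf_idx[line]):
            mid = f"{line}_m{j:02d}"
            motifs.append(perturb_pwm(library[idx], cfg.pwm_noise, rng_perturb, mid))
            motif_sources[mid] = (line, tf_name[idx])
        per_line_motifs[line] = motifs
        anchor_motif_ids[line] = {f"{line}_m00"}

    # cross-line correspondences: same source TF in different lines
    by_tf: dict[str, list[str]] = {}
    for mid, (line, tf) in motif_sources.items():
        by_tf.setdefault(tf, []).append(mid)
    conserved_pairs: set[frozenset[str]] = set()
    for tf, mids in by_tf.items():
        for a, b in combinations(sorted(mids), 2):
            if motif_sources[a][0] != motif_sources[b][0]:
                conserved_pairs.add(frozenset((a, b)))

    # --- planted cofactors and interacting pairs -------------------------
    rng_truth = _rng(seed, _C_TRUTH)
    cof_candidates = pool if len(pool) >= cfg.n_true_cofactors else sorted(
        {i for idxs in line_tf_idx.values() for i in idxs if i != 0}
    )
    if len(cof_candidates) < cfg.n_true_cofactors:
        raise ValueError("not enough distinct TFs to plant the requested cofactors")
    cof_idx = sorted(
        rng_truth.choice(cof_candidates, size=cfg.n_true_cofactors, replace=False).tolist()
    )
    cofactors = {tf_name[i] for i in cof_idx}
    line_tf_sets = {
        line: {tf_name[i] for i in idxs} for line, idxs in line_tf_idx.items()
    }
    coresident = [
        (a, b)
        for a, b in combinations(sorted(cofactors), 2)
        if any(a in s and b in s for s in line_tf_sets.values())
    ]
    interacting: set[frozenset[str]] = {
        frozenset((ANCHOR_TF, c)) for c in cofactors
    }
    for a, b in coresident:
        if rng_truth.random() < cfg.cofactor_edge_rate:
            interacting.add(frozenset((a, b)))

    # --- motif modules ----------------------------------------------------
    rng_mod = _rng(seed, _C_MODULES)
    lo, hi = cfg.module_size_range
    modules: dict[str, list[MotifModule]] = {}
    cof_pairs_named = sorted(
        tuple(sorted(p)) for p in interacting if ANCHOR_TF not in p
    )
    for line in lines:
        ids = [p.motif_id for p in per_line_motifs[line]]
        anchor_id = next(iter(anchor_motif_ids[line]))
        motif_of_tf = {
            motif_sources[m][1]: m for m in ids
        }  # last motif wins on duplicate source TFs; adequate for seeding
        line_pairs = [
            (motif_of_tf[a], motif_of_tf[b])
            for a, b in cof_pairs_named
            if a in motif_of_tf and b in motif_of_tf
        ]
        weights = np.array(
            [
                cfg.module_cofactor_bias
                if motif_sources[m][1] in cofactors or m == anchor_id
                else 1.0
                for m in ids
            ]
        )
        queue = list(rng_mod.permutation(ids))  # coverage-first
        mods = []
        for k in range(cfg.n_modules_per_line):
            size = int(rng_mod.integers(lo, hi + 1))
            members: list[str] = []
            if rng_mod.random() < cfg.anchor_inclusion:
                members.append(anchor_id)
            # modules mimic TF complexes: seed some with a planted
            # interacting cofactor pair so PPI structure is expressed
            if (
                line_pairs
                and size - len(members) >= 2
                and rng_mod.random() < cfg.module_pair_seed
            ):
                pa, pb = line_pairs[int(rng_mod.integers(len(line_pairs)))]
                members.extend([pa, pb])
            while queue and len(members) < size:
                nxt = queue.pop()
                if nxt not in members:
                    members.append(nxt)
            while len(members) < size:
                w = np.array(
                    [wt if m not in members else 0.0 for m, wt in zip(ids, weights)]
                )
                m = rng_mod.choice(ids, p=w / w.sum())
                members.append(str(m))
            support = int(rng_mod.integers(5, 60))
            mods.append(
                MotifModule(f"{line}_M{k:02d}", line, frozenset(members), support)
            )
        modules[line] = mods

    # --- PPI --------------------------------------------------------------
    rng_ppi = _rng(seed, _C_PPI)
    tf_names_all = [tf_name[i] for i in range(cfg.library_size)]
    decoys = [f"P{i + 1:03d}" for i in range(cfg.n_decoy_proteins)]
    proteins = tf_names_all + decoys
    tf_flags = {p: p in set(tf_names_all) for p in proteins}
    edges: set[frozenset[str]] = set(interacting)
    for a, b in combinations(proteins, 2):
        if rng_ppi.random() < cfg.ppi_background_density:
            edges.add(frozenset((a, b)))
    ppi = PPIEdgeList(edges, tf_flags)

    # --- genes on a toy two-chromosome genome -----------------------------
    rng_genes = _rng(seed, _C_GENES)
    chroms = ["chr1", "chr2"]
    per_chrom = [cfg.n_genes - cfg.n_genes // 2, cfg.n_genes // 2]
    annotation: list[GeneAnnotation] = []
    chrom_sizes: dict[str, int] = {}
    gidx = 0
    for chrom, count in zip(chroms, per_chrom):
        for i in range(count):
            tss = i * cfg.gene_spacing + int(
                rng_genes.integers(500, cfg.gene_spacing - 500)
            )
            strand = "+" if rng_genes.random() < 0.5 else "-"
            annotation.append(GeneAnnotation(f"G{gidx:04d}", chrom, tss, strand))
            gidx += 1
        chrom_sizes[chrom] = (count + 1) * cfg.gene_spacing

    # --- GO terms and gene clubs ------------------------------------------
    rng_go = _rng(seed, _C_GO)
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    termed_order = [0] + [i for i in pool] + [
        i for i in range(1, cfg.library_size) if i not in pool
    ]
    tf2term = {
        tf_name[idx]: terms[t] for t, idx in enumerate(termed_order[: cfg.n_go_terms])
    }
    club_size = min(cfg.go_club_size, max(1, cfg.n_genes // max(1, len(tf2term))))
    gene_ids = [g.gene_id for g in annotation]
    shuffled = list(rng_go.permutation(gene_ids))
    clubs: dict[str, list[str]] = {}
    pos = 0
    for idx in termed_order[: cfg.n_go_terms]:
        clubs[tf_name[idx]] = shuffled[pos : pos + club_size]
        pos += club_size
    gene2go: dict[str, set[str]] = {}
    for tf, club in clubs.items():
        for g in club:
            gene2go.setdefault(g, set()).add(tf2term[tf])
    for g in gene_ids:
        if rng_go.random() < cfg.go_background_rate:
            gene2go.setdefault(g, set()).add(str(rng_go.choice(terms)))

    # --- peaks near club-gene TSSs ----------------------------------------
    rng_peaks = _rng(seed, _C_PEAKS)
    gene_by_id = {g.gene_id: g for g in annotation}
    peaks: dict[str, list[Peak]] = {}
    for line in lines:
        raw: list[tuple[str, int, int]] = []
        targets: list[str] = []
        for idx in line_tf_idx[line]:
            targets.extend(clubs.get(tf_name[idx], []))
        for _ in range(cfg.n_background_peaks):
            targets.append(str(rng_peaks.choice(gene_ids)))
        for gid in targets:
            g = gene_by_id[gid]
            center = g.tss + int(rng_peaks.integers(-250, 251))
            half = int(rng_peaks.integers(150, 301))
            start = max(0, center - half)
            end = min(chrom_sizes[g.chrom], center + half)
            if end - start >= 50:
                raw.append((g.chrom, start, end))
        raw.sort()
        kept: list[Peak] = []
        last_end: dict[str, int] = {}
        n_kept = 0
        for chrom, start, end in raw:
            if start < last_end.get(chrom, 0):
                continue
            kept.append(Peak(chrom, start, end, line, f"{line}_p{n_kept:04d}"))
            last_end[chrom] = end
            n_kept += 1
        peaks[line] = kept

    truth = StudyTruth(ANCHOR_TF, cofactors, interacting, motif_sources, conserved_pairs)
    return StudyBundle(
        cfg,
        library,
        per_line_motifs,
        modules,
        anchor_motif_ids,
        peaks,
        ppi,
        annotation,
        gene2go,
        chrom_sizes,
        truth,
    )


def simulate_occurrence_matrix(
    n_sequences: int,
    marginals: dict[str, float],
    seed: int = 0,
    planted: Sequence[tuple[Sequence[str], float]] = (),
) -> pd.DataFrame:
    """Boolean sequences x motifs matrix for co-occurrence testing.

    Columns are independent Bernoulli draws at the given marginal
    frequencies; each ``(motif_set, joint_prob)`` plant additionally
    forces the whole set to co-occur in a ``joint_prob`` fraction of
    sequences.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(marginals)
    mat = rng.random((n_sequences, len(ids))) < np.array([marginals[m] for m in ids])
    df = pd.DataFrame(mat, columns=ids)
    for motif_set, joint in planted:
        force = rng.random(n_sequences) < joint
        df.loc[force, list(motif_set)] = True
    return df


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write every pipeline input file plus truth.json and config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pwm_file(bundle.known_library, out / "known_library.jaspar")
    for line in bundle.cell_lines:
        write_pwm_file(bundle.per_line_motifs[line], out / f"{line}.motifs.jaspar")
        write_modules(bundle.modules[line], out / f"{line}.modules.tsv")
        write_bed(bundle.peaks[line], out / f"{line}.peaks.bed")
    write_edge_list(bundle.ppi, out / "ppi.tsv")
    write_annotation(bundle.annotation, out / "genes.tsv")
    write_gene2go(bundle.gene2go, out / "gene2go.tsv")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(bundle.chrom_sizes):
            fh.write(f"{chrom}\t{bundle.chrom_sizes[chrom]}\n")
    anchors = {line: sorted(ids) for line, ids in bundle.anchor_motif_ids.items()}
    (out / "anchors.json").write_text(json.dumps(anchors, sort_keys=True, indent=1))
    if bundle.truth is not None:
        t = bundle.truth
        obj = {
            "anchor_tf": t.anchor_tf,
            "cofactors": sorted(t.cofactors),
            "interacting_pairs": sorted(sorted(p) for p in t.interacting_pairs),
            "motif_sources": {k: list(v) for k, v in sorted(t.motif_sources.items())},
            "conserved_pairs": sorted(sorted(p) for p in t.conserved_pairs),
        }
        (out / "truth.json").write_text(json.dumps(obj, sort_keys=True, indent=1))
    cfg = asdict(bundle.config)
    cfg["module_size_range"] = list(bundle.config.module_size_range)
    cfg["width_range"] = list(bundle.config.width_range)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_bundle(in_dir: str | Path) -> StudyBundle:
    """Reconstruct a bundle written by :func:`write_bundle`."""
    d = Path(in_dir)
    cfg_obj = yaml.safe_load((d / "config.yaml").read_text())
    cfg_obj["module_size_range"] = tuple(cfg_obj["module_size_range"])
    cfg_obj["width_range"] = tuple(cfg_obj["width_range"])
    config = SyntheticConfig(**cfg_obj)
    library = parse_pwm_file(d / "known_library.jaspar", source="known")
    per_line_motifs: dict[str, list[PWM]] = {}
    modules: dict[str, list[MotifModule]] = {}
    peaks: dict[str, list[Peak]] = {}
    for motif_file in sorted(d.glob("*.motifs.jaspar")):
        line = motif_file.name.removesuffix(".motifs.jaspar")
        per_line_motifs[line] = parse_pwm_file(motif_file, source="predicted")
        modules[line] = parse_modules(d / f"{line}.modules.tsv")
        peaks[line] = parse_bed(d / f"{line}.peaks.bed", cell_line=line)
    ppi = parse_edge_list(d / "ppi.tsv")
    annotation = parse_annotation(d / "genes.tsv")
    gene2go = parse_gene2go(d / "gene2go.tsv")
    chrom_sizes = {}
    for ln in (d / "chrom_sizes.tsv").read_text().splitlines():
        if ln.strip():
            chrom, size = ln.split("\t")
            chrom_sizes[chrom] = int(size)
    anchors = {
        line: set(ids)
        for line, ids in json.loads((d / "anchors.json").read_text()).items()
    }
    truth = None
    if (d / "truth.json").exists():
        obj = json.loads((d / "truth.json").read_text())
        truth = StudyTruth(
            obj["anchor_tf"],
            set(obj["cofactors"]),
            {frozenset(p) for p in obj["interacting_pairs"]},
            {k: tuple(v) for k, v in obj["motif_sources"].items()},
            {frozenset(p) for p in obj["conserved_pairs"]},
        )
    return StudyBundle(
        config,
        library,
        per_line_motifs,
        modules,
        anchors,
        peaks,
        ppi,
        annotation,
        gene2go,
        chrom_sizes,
        truth,
    )
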