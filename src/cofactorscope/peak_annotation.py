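"""Peak extension, cross-cell-line peak overlap and nearest-TSS assignment.

Peaks shorter than a minimum length (default 800 bp, roughly the median
length of a cis-regulatory region) are grown symmetrically about their
midpoint, with the extra base going to the right when the deficit is odd,
and shifted inward when the chromosome boundary would be crossed.  Target
genes are assigned by minimal |peak midpoint - TSS| distance on the
peak's chromosome, with the signed distance reported relative to the
gene's strand (negative = upstream).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneAnnotation, Peak

__all__ = ["TargetAssignment", "extend_peaks", "overlap_fraction", "nearest_tss"]

MIN_PEAK_LEN = 800


@dataclass(frozen=True)
class TargetAssignment:
    peak_id: str
    gene_id: str
    signed_distance: int  # midpoint - TSS, sign flipped on '-' strand


def extend_peaks(
    peaks: Sequence[Peak],
    min_len: int = MIN_PEAK_LEN,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Grow every peak to at least ``min_len`` bp, symmetrically.

    Longer peaks pass through unchanged.  With ``chrom_sizes`` supplied the
    extension is clamped to the chromosome, preserving the total length by
    shifting inward when possible; a peak on an unknown chromosome is an
    error.
    """
    out: list[Peak] = []
    for p in peaks:
        clen = None
        if chrom_sizes is not None:
            if p.chrom not in chrom_sizes:
                raise ValueError(f"chromosome {p.chrom!r} absent from chrom_sizes")
            clen = chrom_sizes[p.chrom]
        if p.length >= min_len:
            out.append(p)
            continue
        deficit = min_len - p.length
        start = p.start - deficit // 2
        end = p.end + (deficit - deficit // 2)
        if start < 0:
            end += -start
            start = 0
        if clen is not None and end > clen:
            shift = end - clen
            start = max(0, start - shift)
            end = clen
        out.append(Peak(p.chrom, start, end, p.cell_line, p.peak_id))
    return out


def _merge_intervals(peaks: Sequence[Peak]) -> dict[str, tuple[list[int], list[int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivls in by_chrom.items():
        ivls.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivls:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)
    return merged


def overlap_fraction(peaks_a: Sequence[Peak], peaks_other: Sequence[Peak]) -> float:
    """Percent of peaks in ``peaks_a`` overlapping (>= 1 bp) ``peaks_other``."""
    if not peaks_a:
        return 0.0
    merged = _merge_intervals(peaks_other)
    hits = 0
    for p in peaks_a:
        if p.chrom not in merged:
            continue
        starts, ends = merged[p.chrom]
        i = bisect_right(starts, p.end - 1) - 1  # last interval starting before p.end
        if i >= 0 and ends[i] > p.start:
            hits += 1
    return 100.0 * hits / len(peaks_a)


def nearest_tss(
    peaks: Sequence[Peak], annotation: Sequence[GeneAnnotation]
) -> list[TargetAssignment]:
    """Assign every peak the gene with the nearest TSS on its chromosome.

    The peak position is ``floor((start + end) / 2)``.  Equidistant genes
    are broken by the lexicographically smaller gene id.  The signed
    distance is midpoint - TSS, flipped on '-' strand so that negative
    always means upstream of the gene.
    """
    if not annotation:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, dict[int, GeneAnnotation]] = {}
    for g in annotation:
        reps = by_chrom.setdefault(g.chrom, {})
        if g.tss not in reps or g.gene_id < reps[g.tss].gene_id:
            reps[g.tss] = g
    index: dict[str, tuple[np.ndarray, list[GeneAnnotation]]] = {}
    for chrom, reps in by_chrom.items():
        tss_sorted = sorted(reps)
        index[chrom] = (np.asarray(tss_sorted), [reps[t] for t in tss_sorted])

    out: list[TargetAssignment] = []
    for p in peaks:
        if p.chrom not in index:
            raise ValueError(f"no annotated gene on chromosome {p.chrom!r}")
        tss_arr, genes = index[p.chrom]
        mid = p.midpoint
        i = int(np.searchsorted(tss_arr, mid))
        cands = [j for j in (i - 1, i) if 0 <= j < len(genes)]
        dmin = min(abs(mid - int(tss_arr[j])) for j in cands)
        best = min(
            (genes[j] for j in cands if abs(mid - int(tss_arr[j])) == dmin),
            key=lambda g: g.gene_id,
        )
        signed = mid - best.tss
        if best.strand == "-":
            signed = -signed
        out.append(TargetAssignment(p.peak_id, best.gene_id, signed))
    return out
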