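"""Runs of homozygosity: PLINK-style sliding-window calling.

A window of ``window_snp`` consecutive SNPs slides one SNP at a time
over each individual's genotypes; a window is homozygous if it holds at
most ``window_het`` heterozygous and ``window_missing`` missing calls.
A SNP qualifies when the fraction of overlapping homozygous windows is
at least ``window_threshold`` (windows truncated at chromosome ends
still count with their reduced overlap).  Maximal runs of qualifying
SNPs are emitted as segments when they satisfy the minimum SNP count,
minimum physical length and marker-density requirements and contain no
adjacent-SNP gap larger than ``max_gap_kb`` (runs are split at larger
gaps).

Defaults follow array-data practice: 50-SNP windows with no
heterozygote allowed, >= 1 Mb and >= 50 SNPs per segment, 1 Mb gap
split, one SNP per 50 kb density.  WGS-like calling uses
``window_het=3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["ROHParams", "ROHSegment", "call_roh", "call_roh_panel", "summarize_roh"]

MISSING = -1


@dataclass(frozen=True)
class ROHParams:
    window_snp: int = 50
    window_het: int = 0
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    density_kb: float = 50.0  # max average kb per SNP inside a segment

    def __post_init__(self):
        if min(self.window_snp, self.window_het, self.window_missing,
               self.min_snp) < 0 or self.min_kb < 0 or self.max_gap_kb < 0:
            raise ValueError("ROH parameters must be non-negative")
        if not (0.0 < self.window_threshold <= 1.0):
            raise ValueError("window_threshold must be in (0, 1]")


@dataclass
class ROHSegment:
    individual_id: str
    start_bp: int
    end_bp: int
    n_snp: int
    length_kb: float


def _qualifying_snps(gt: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean mask of SNPs covered by a sufficient fraction of homozygous windows."""
    m = gt.size
    w = min(params.window_snp, m)
    het = (gt == 1).astype(np.int64)
    mis = (gt == MISSING).astype(np.int64)
    # window w starting at s covers SNPs [s, s+w)
    n_windows = m - w + 1
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    win_het = chet[w:] - chet[:-w]
    win_mis = cmis[w:] - cmis[:-w]
    win_ok = (win_het <= params.window_het) & (win_mis <= params.window_missing)
    # SNP t is covered by window starts in [t-w+1, t] clipped to [0, n_windows)
    cok = np.concatenate([[0], np.cumsum(win_ok.astype(np.int64))])
    t = np.arange(m)
    lo = np.clip(t - w + 1, 0, n_windows)
    hi = np.clip(t + 1, 0, n_windows)
    n_ok = cok[hi] - cok[lo]
    n_cover = hi - lo
    frac = np.where(n_cover > 0, n_ok / np.maximum(n_cover, 1), 0.0)
    return frac >= params.window_threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def call_roh(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: ROHParams = ROHParams(),
    individual_ids: Optional[Sequence[str]] = None,
) -> list[ROHSegment]:
    """Call ROH segments for one or more individuals.

    ``genotypes`` is (n individuals x m markers) of derived-allele dosage
    0/1/2, with -1 for missing; ``positions`` are ascending bp.
    """
    genotypes = np.atleast_2d(np.asarray(genotypes))
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly ascending")
    if genotypes.shape[1] != positions.size:
        raise ValueError("genotype/position length mismatch")
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(genotypes.shape[0])]
    segments: list[ROHSegment] = []
    for ind, gt in zip(individual_ids, genotypes):
        qual = _qualifying_snps(gt, params)
        for start, end in _runs(qual):
            # split runs at gaps larger than max_gap_kb
            sub_start = start
            gap_bp = params.max_gap_kb * 1e3
            cuts = [
                k
                for k in range(start, end)
                if positions[k + 1] - positions[k] > gap_bp
            ]
            for cut in cuts + [end]:
                segments.extend(
                    _emit(ind, sub_start, cut, positions, params)
                )
                sub_start = cut + 1
    segments.sort(key=lambda s: (s.individual_id, s.start_bp))
    return segments


def _emit(ind: str, start: int, end: int, positions: np.ndarray,
          params: ROHParams) -> list[ROHSegment]:
    n_snp = end - start + 1
    if n_snp < params.min_snp:
        return []
    length_kb = (positions[end] - positions[start]) / 1e3
    if length_kb < params.min_kb:
        return []
    if params.density_kb > 0 and length_kb / n_snp > params.density_kb:
        return []
    return [
        ROHSegment(
            individual_id=str(ind),
            start_bp=int(positions[start]),
            end_bp=int(positions[end]),
            n_snp=n_snp,
            length_kb=float(length_kb),
        )
    ]


def call_roh_panel(panel, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Call ROH on a HaplotypePanel by pairing each individual's haplotypes."""
    return call_roh(
        panel.genotypes(), panel.positions, params, panel.individual_ids
    )


def summarize_roh(
    segments: Sequence[ROHSegment], individuals: Sequence[str]
) -> tuple[dict[str, tuple[int, float]], float]:
    """Per-individual (count, total kb) and the population median segment length (kb).

    Individuals without segments are reported as (0, 0.0); the median is
    nan when there are no segments at all.
    """
    per = {str(i): [0, 0.0] for i in individuals}
    lengths = []
    for s in segments:
        per.setdefault(s.individual_id, [0, 0.0])
        per[s.individual_id][0] += 1
        per[s.individual_id][1] += s.length_kb
        lengths.append(s.length_kb)
    median = float(np.median(lengths)) if lengths else float("nan")
    return {k: (v[0], v[1]) for k, v in per.items()}, median
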