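"""Core haplotype statistics: EHH, iHS, LD decay, diversity.

EHH (extended haplotype homozygosity) at distance x from a core allele
is the probability that two randomly chosen carrier chromosomes are
identical over the whole interval from the core to x.  The
unstandardized iHS is ln(iHH_A / iHH_D), the log ratio of the areas
under the ancestral- and derived-allele EHH curves integrated with
respect to genetic distance (linear interpolation between markers, out
to the interpolated crossing of EHH = 0.05 on each side).  Scores are
standardized to mean 0, variance 1 within derived-allele-frequency
bins, so extreme values flag unusually long haplotypes for their
frequency — the signature of an incomplete sweep.

LD decay is the mean squared Pearson correlation of genotype dosages
in 1 kb distance bins out to 100 kb.  Diversity statistics are Nei's
haplotype diversity over 10-marker windows and per-site expected
heterozygosity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .io_formats import GeneticMap, HaplotypePanel

logger = logging.getLogger("hapfeatures")

__all__ = [
    "EHHCurve",
    "IHSRecord",
    "LDBin",
    "DiversityResult",
    "compute_ehh",
    "compute_ihs_unstd",
    "ihs_scan",
    "standardize_ihs",
    "ld_decay",
    "haplotype_diversity",
    "expected_heterozygosity",
    "pairwise_diversity",
]

ANCESTRAL, DERIVED = 0, 1
_GAP_WARN_BP = 200_000


@dataclass
class EHHCurve:
    """EHH values for one core allele, marker-stepped on each side.

    ``left``/``right`` are (distance_cM, EHH) arrays starting at the core
    (0, 1.0); ``crossed_left``/``crossed_right`` say whether the curve
    reached the stop threshold before the chromosome end.
    """

    core_index: int
    allele: int
    left: np.ndarray
    right: np.ndarray
    crossed_left: bool
    crossed_right: bool
    n_carriers: int


@dataclass
class IHSRecord:
    marker_id: str
    position: int
    daf: float
    ihh_a: float
    ihh_d: float
    uihs: float
    sihs: float
    skipped: bool = False
    reason: str = ""


@dataclass
class LDBin:
    lo_kb: float
    hi_kb: float
    mean_r2: float
    n_pairs: int


@dataclass
class DiversityResult:
    window_hap_div: list = field(default_factory=list)
    mean_hap_div: float = float("nan")
    mean_exp_het: float = float("nan")


# ---------------------------------------------------------------------------
# EHH / iHS


@njit(cache=False)
def _ehh_side(alleles, carriers, core, step, cm, stop):  # pragma: no cover
    """March outward from the core, splitting haplotype classes marker by marker.

    Returns (distances_cM, ehh_values, crossed) including the core point
    (0, 1).  EHH_k = sum_h C(c_h, 2) / C(n_c, 2) over the counts c_h of
    distinct extended haplotypes among the n_c carriers; classes only
    ever split, so the curve is non-increasing.  The scan stops at the
    first point with EHH <= ``stop`` (crossed=True) or at the chromosome
    end (crossed=False).
    """
    n_c = carriers.shape[0]
    m = alleles.shape[1]
    max_pts = (m - core) if step > 0 else core + 1
    dist = np.empty(max_pts + 1, dtype=np.float64)
    ehh = np.empty(max_pts + 1, dtype=np.float64)
    dist[0] = 0.0
    ehh[0] = 1.0
    npts = 1
    # active set: carriers whose extended haplotype is still shared with
    # another carrier; singletons never rejoin a class and contribute 0
    active = carriers.copy()
    labels = np.zeros(n_c, dtype=np.int64)
    denom = n_c * (n_c - 1) / 2.0
    j = core
    crossed = False
    if stop >= 1.0:
        return dist[:1], ehh[:1], True
    while True:
        j += step
        if j < 0 or j >= m:
            break
        n_a = active.shape[0]
        num = 0.0
        if n_a >= 2:
            keys = np.empty(n_a, dtype=np.int64)
            for i in range(n_a):
                keys[i] = labels[i] * 2 + alleles[active[i], j]
            order = np.argsort(keys, kind="mergesort")
            # rank-compress keys into labels and accumulate pair counts
            rank = 0
            run = 1
            labels[order[0]] = 0
            for t in range(1, n_a):
                if keys[order[t]] == keys[order[t - 1]]:
                    run += 1
                else:
                    num += run * (run - 1) / 2.0
                    rank += 1
                    run = 1
                labels[order[t]] = rank
            num += run * (run - 1) / 2.0
            # drop carriers that have become singletons
            run_len = np.zeros(rank + 1, dtype=np.int64)
            for t in range(n_a):
                run_len[labels[t]] += 1
            n_keep = 0
            for t in range(n_a):
                if run_len[labels[t]] >= 2:
                    active[n_keep] = active[t]
                    labels[n_keep] = labels[t]
                    n_keep += 1
            active = active[:n_keep]
            labels = labels[:n_keep]
        e = num / denom
        dist[npts] = abs(cm[j] - cm[core])
        ehh[npts] = e
        npts += 1
        if e <= stop:
            crossed = True
            break
        if e == 0.0:
            break
    return dist[:npts], ehh[:npts], crossed


def _carriers(panel: HaplotypePanel, core_index: int, allele: int) -> np.ndarray:
    return np.flatnonzero(panel.alleles[:, core_index] == allele).astype(np.int64)


def compute_ehh(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    core_index: int,
    allele: int,
    stop_ehh: float = 0.0,
    _cm: Optional[np.ndarray] = None,
) -> EHHCurve:
    """EHH curve for one core allele, computed independently left and right.

    With fewer than 2 carriers the curve is empty (``n_carriers`` < 2);
    callers record this as a skip rather than an error.
    """
    carriers = _carriers(panel, core_index, allele)
    cm = _cm if _cm is not None else np.asarray(
        gmap.cm_at(panel.positions), dtype=np.float64
    )
    if carriers.size < 2:
        empty = np.zeros(0)
        return EHHCurve(core_index, allele, empty, empty, False, False, carriers.size)
    dl, el, cl = _ehh_side(panel.alleles, carriers, core_index, -1, cm, stop_ehh)
    dr, er, cr = _ehh_side(panel.alleles, carriers, core_index, 1, cm, stop_ehh)
    return EHHCurve(
        core_index,
        allele,
        np.column_stack([dl, el]),
        np.column_stack([dr, er]),
        cl,
        cr,
        int(carriers.size),
    )


def _ihh_side(dist: np.ndarray, ehh: np.ndarray, cutoff: float) -> float:
    """Trapezoid integral of one EHH side out to the interpolated cutoff crossing.

    The last point is guaranteed to satisfy ehh <= cutoff (the caller
    checks ``crossed``); an extra point is interpolated at the exact
    crossing so integration ends at EHH = cutoff.
    """
    k = int(np.argmax(ehh <= cutoff))
    if k == 0:
        return 0.0
    d0, e0 = dist[k - 1], ehh[k - 1]
    d1, e1 = dist[k], ehh[k]
    d_cross = d0 if e1 == e0 else d0 + (e0 - cutoff) * (d1 - d0) / (e0 - e1)
    d_trunc = np.concatenate([dist[:k], [d_cross]])
    e_trunc = np.concatenate([ehh[:k], [cutoff]])
    return float(np.trapezoid(e_trunc, d_trunc))


def compute_ihs_unstd(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    core_index: int,
    cutoff: float = 0.05,
    _cm: Optional[np.ndarray] = None,
) -> IHSRecord:
    """Unstandardized iHS at one core marker.

    iHH for each core allele is the EHH area (cM units) integrated to the
    interpolated crossing of EHH = ``cutoff`` on both sides; if either
    curve fails to reach the cutoff before the chromosome end the marker
    is skipped.  uiHS = ln(iHH_ancestral / iHH_derived).
    """
    daf = float(panel.alleles[:, core_index].mean())
    rec = IHSRecord(
        marker_id=panel.marker_ids[core_index],
        position=int(panel.positions[core_index]),
        daf=daf,
        ihh_a=float("nan"),
        ihh_d=float("nan"),
        uihs=float("nan"),
        sihs=float("nan"),
    )
    if not (0.05 <= daf <= 0.95):
        rec.skipped, rec.reason = True, "maf"
        return rec
    ihh = {}
    for allele in (ANCESTRAL, DERIVED):
        curve = compute_ehh(panel, gmap, core_index, allele, stop_ehh=cutoff, _cm=_cm)
        if curve.n_carriers < 2:
            rec.skipped, rec.reason = True, "too_few_carriers"
            return rec
        if not (curve.crossed_left and curve.crossed_right):
            rec.skipped, rec.reason = True, "no_cutoff_crossing"
            return rec
        ihh[allele] = _ihh_side(
            curve.left[:, 0], curve.left[:, 1], cutoff
        ) + _ihh_side(curve.right[:, 0], curve.right[:, 1], cutoff)
    rec.ihh_a, rec.ihh_d = ihh[ANCESTRAL], ihh[DERIVED]
    if rec.ihh_a <= 0.0 or rec.ihh_d <= 0.0:
        rec.skipped, rec.reason = True, "zero_ihh"
        return rec
    rec.uihs = math.log(rec.ihh_a / rec.ihh_d)
    return rec


def _extension_classes(alleles: np.ndarray, direction: int) -> np.ndarray:
    """Haplotype equivalence classes under maximal one-sided extension.

    For direction +1, ``labels[j]`` groups haplotypes identical over
    markers [j, m); for -1, over [0, j].  Because EHH is non-increasing,
    the EHH of these classes is the curve's floor: if it exceeds the
    cutoff, the curve can never cross before the chromosome end.
    """
    n, m = alleles.shape
    labels = np.zeros((m, n), dtype=np.int32)
    cur = alleles[:, m - 1 if direction > 0 else 0].astype(np.int64)
    rng_j = range(m - 1, -1, -1) if direction > 0 else range(m)
    first = True
    for j in rng_j:
        if not first:
            cur = cur * 2 + alleles[:, j]
            _, cur = np.unique(cur, return_inverse=True)
            cur = cur.astype(np.int64)
        labels[j] = cur
        first = False
    return labels


def _class_ehh(labels: np.ndarray, carriers: np.ndarray) -> float:
    counts = np.bincount(labels[carriers])
    n_c = carriers.size
    return float((counts * (counts - 1)).sum() / (n_c * (n_c - 1)))


def ihs_scan(
    panel: HaplotypePanel, gmap: GeneticMap, cutoff: float = 0.05
) -> list[IHSRecord]:
    """Unstandardized iHS at every marker of the panel.

    Identical to calling :func:`compute_ihs_unstd` per marker, but
    markers whose EHH floor (the fully-extended haplotype classes) never
    reaches the cutoff on a side are skipped without a full outward scan.
    """
    gaps = np.diff(panel.positions)
    if gaps.size and gaps.max() > _GAP_WARN_BP:
        logger.warning(
            "largest inter-marker gap is %.0f kb (> %.0f kb); EHH integration "
            "spans it without penalty",
            gaps.max() / 1e3,
            _GAP_WARN_BP / 1e3,
        )
    cm = np.asarray(gmap.cm_at(panel.positions), dtype=np.float64)
    m = panel.n_markers
    suffix = _extension_classes(panel.alleles, +1)
    prefix = _extension_classes(panel.alleles, -1)
    p = panel.derived_freq()
    out: list[IHSRecord] = []
    for j in range(m):
        if not (0.05 <= p[j] <= 0.95):
            out.append(compute_ihs_unstd(panel, gmap, j, cutoff, _cm=cm))
            continue
        crosses = True
        if j == 0 or j == m - 1:
            crosses = False  # no markers on one side: EHH stays at 1
        else:
            for allele in (ANCESTRAL, DERIVED):
                carriers = _carriers(panel, j, allele)
                if carriers.size < 2:
                    continue  # handled (and recorded) by compute_ihs_unstd
                if (
                    _class_ehh(suffix[j + 1], carriers) > cutoff
                    or _class_ehh(prefix[j - 1], carriers) > cutoff
                ):
                    crosses = False
                    break
        if crosses:
            out.append(compute_ihs_unstd(panel, gmap, j, cutoff, _cm=cm))
        else:
            rec = IHSRecord(
                marker_id=panel.marker_ids[j],
                position=int(panel.positions[j]),
                daf=float(p[j]),
                ihh_a=float("nan"),
                ihh_d=float("nan"),
                uihs=float("nan"),
                sihs=float("nan"),
                skipped=True,
                reason="no_cutoff_crossing",
            )
            out.append(rec)
    return out


def standardize_ihs(
    records: Sequence[IHSRecord], bin_width: float = 0.02
) -> list[IHSRecord]:
    """Standardize uiHS within derived-allele-frequency bins.

    Within each DAF bin of width ``bin_width``: sihs = (uihs - bin mean)
    / bin SD (denominator n).  Bins with fewer than 2 usable records
    leave sihs undefined with a warning.  Records are returned in input
    order with sihs filled in; skipped records pass through unchanged.
    """
    records = list(records)
    if not records:
        raise ValueError("no iHS records to standardize")
    usable = [r for r in records if not r.skipped and np.isfinite(r.uihs)]
    n_bins = int(round(1.0 / bin_width))
    by_bin: dict[int, list[IHSRecord]] = {}
    for r in usable:
        b = min(int(r.daf / bin_width), n_bins - 1)
        by_bin.setdefault(b, []).append(r)
    for b, recs in sorted(by_bin.items()):
        if len(recs) < 2:
            logger.warning(
                "DAF bin %d has %d record(s); sihs left undefined", b, len(recs)
            )
            continue
        u = np.array([r.uihs for r in recs])
        mean = u.mean()
        sd = u.std()  # denominator n
        if sd == 0.0:
            logger.warning("DAF bin %d has zero variance; sihs left undefined", b)
            continue
        for r in recs:
            r.sihs = (r.uihs - mean) / sd
    return records


# ---------------------------------------------------------------------------
# LD decay


def ld_decay(
    genotypes: np.ndarray,
    positions: np.ndarray,
    window_kb: float = 100.0,
    bin_kb: float = 1.0,
) -> list[LDBin]:
    """Mean pairwise r-squared in distance bins.

    r2 is the squared Pearson correlation of per-individual derived-
    allele dosage vectors (0/1/2) for every marker pair within
    ``window_kb``; pairs where either marker has zero variance are
    excluded.  Bins partition (0, window_kb] in ``bin_kb`` steps.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    if G.ndim != 2 or G.shape[1] != positions.size:
        raise ValueError("genotypes must be (individuals x markers)")
    n, m = G.shape
    if m < 2:
        raise ValueError("need at least 2 markers")
    window_bp = window_kb * 1e3
    bin_bp = bin_kb * 1e3
    n_bins = int(round(window_kb / bin_kb))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    sd = G.std(axis=0)
    valid = sd > 0
    Z = np.zeros_like(G)
    Z[:, valid] = (G[:, valid] - G[:, valid].mean(axis=0)) / sd[valid]
    for d in range(1, m):
        dist = positions[d:] - positions[:-d]
        in_win = dist <= window_bp
        if not in_win.any():
            break
        r = (Z[:, :-d] * Z[:, d:]).sum(axis=0) / n
        ok = in_win & valid[:-d] & valid[d:] & (dist > 0)
        if not ok.any():
            continue
        idx = np.ceil(dist[ok] / bin_bp).astype(np.int64) - 1
        np.add.at(sums, idx, r[ok] ** 2)
        np.add.at(counts, idx, 1)
    out = []
    for b in range(n_bins):
        mean_r2 = float(sums[b] / counts[b]) if counts[b] else float("nan")
        out.append(LDBin(b * bin_kb, (b + 1) * bin_kb, mean_r2, int(counts[b])))
    return out


def mean_r2_between(bins: Sequence[LDBin], lo_kb: float, hi_kb: float) -> float:
    """Pair-weighted mean r2 over bins whose span lies within [lo_kb, hi_kb]."""
    tot = 0.0
    n = 0
    for b in bins:
        if b.lo_kb >= lo_kb and b.hi_kb <= hi_kb and b.n_pairs:
            tot += b.mean_r2 * b.n_pairs
            n += b.n_pairs
    return tot / n if n else float("nan")


# ---------------------------------------------------------------------------
# Diversity


def _window_hap_div(window: np.ndarray) -> float:
    """Nei haplotype diversity H = n/(n-1) (1 - sum p_i^2) for one window."""
    n = window.shape[0]
    _, counts = np.unique(window, axis=0, return_counts=True)
    p = counts / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


def haplotype_diversity(
    panel: HaplotypePanel, window_markers: int = 10
) -> DiversityResult:
    """Nei haplotype diversity over non-overlapping marker windows."""
    if panel.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if panel.n_markers < window_markers:
        raise ValueError("fewer markers than one window")
    divs = []
    for start in range(0, panel.n_markers - window_markers + 1, window_markers):
        divs.append(_window_hap_div(panel.alleles[:, start:start + window_markers]))
    return DiversityResult(window_hap_div=divs, mean_hap_div=float(np.mean(divs)))


def expected_heterozygosity(panel: HaplotypePanel) -> DiversityResult:
    """Mean per-site expected heterozygosity He = 2p(1-p)."""
    if panel.n_markers < 1:
        raise ValueError("need at least 1 marker")
    p = panel.derived_freq()
    return DiversityResult(mean_exp_het=float(np.mean(2.0 * p * (1.0 - p))))


def pairwise_diversity(
    panel: HaplotypePanel, length_bp: float, n_blocks: int = 10
) -> tuple[float, float]:
    """Mean pairwise diversity per bp with a block-jackknife standard error.

    pi per site is the unbiased 2p(1-p) * 2n/(2n-1); the total over sites
    is divided by ``length_bp``.  The SE comes from a delete-one jackknife
    over ``n_blocks`` equal-length physical windows.
    """
    n = panel.n_haplotypes
    p = panel.derived_freq()
    site_pi = 2.0 * p * (1.0 - p) * n / (n - 1)
    edges = np.linspace(0, length_bp, n_blocks + 1)
    block_of = np.clip(
        np.searchsorted(edges, panel.positions, side="right") - 1, 0, n_blocks - 1
    )
    block_sums = np.bincount(block_of, weights=site_pi, minlength=n_blocks)
    block_len = np.diff(edges)
    total = site_pi.sum()
    pi = total / length_bp
    loo = np.array(
        [(total - block_sums[b]) / (length_bp - block_len[b]) for b in range(n_blocks)]
    )
    se = math.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2))
    return float(pi), float(se)
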