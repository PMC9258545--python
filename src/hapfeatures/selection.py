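"""Simulation-calibrated selection-scan thresholds and allele-age dating.

Standardized iHS values from neutral demographic simulations provide
empirical significance cutoffs matched to the number of tests run in a
real population: the lower/upper cutoff is the expected minimum/maximum
of a without-replacement draw of that many scores from the pooled
neutral distribution (B resamples).  Markers beyond the cutoffs are
selection candidates; candidates shared across populations are tallied
on marker identity.

Candidate alleles are dated by haplotype decay: under a star phylogeny
with recombination clock Pr[two chromosomes still homozygous at genetic
distance r Morgans] = exp(-2 r T), the TMRCA in generations is
T = ln(4) / (2 r) at the distance where the favored allele's EHH decays
to 0.25.  r is taken as half the genetic span between the two EHH=0.25
crossings; spans over 1.1 cM imply implausibly recent, strongly
selected alleles and are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hapstats import ANCESTRAL, DERIVED, IHSRecord, compute_ehh
from .io_formats import GeneticMap, HaplotypePanel

__all__ = [
    "CutoffPair",
    "SelectionCandidate",
    "TMRCAResult",
    "derive_cutoffs",
    "filter_candidates",
    "tally_shared",
    "estimate_tmrca",
]

HOMOZ_TARGET = 0.25
MAX_SPAN_CM = 1.1


@dataclass(frozen=True)
class CutoffPair:
    lo: float
    hi: float
    n_tests: int
    n_resamples: int
    seed: int
    method: str = "expected_extremes"

    def __post_init__(self):
        # standardized null scores give lo < 0 < hi except in degenerate
        # draws (n_tests = 1), where lo = hi = pool mean
        if self.lo > self.hi:
            raise ValueError("cutoff lo must not exceed hi")


@dataclass
class SelectionCandidate:
    marker_id: str
    population: str
    sihs: float
    lo: float
    hi: float
    shared_by: int = 1
    tmrca_years: Optional[float] = None


@dataclass
class TMRCAResult:
    marker_id: str
    r_morgans: float
    t_generations: float
    years: float
    span_cm: float
    skipped: bool = False
    unresolved: bool = False
    reason: str = ""


def derive_cutoffs(
    simulated_scores: Sequence[float],
    n_tests: int,
    B: int = 1000,
    seed: int = 0,
    method: str = "expected_extremes",
) -> CutoffPair:
    """Empirical iHS cutoffs matched to the number of tests.

    ``expected_extremes``: lo/hi are the means over B without-replacement
    draws of size ``n_tests`` of the draw minimum/maximum.  The
    ``tail_quantile`` alternative uses the alpha = 1/n_tests per-tail
    quantiles of the pool.  Deterministic given ``seed``.
    """
    pool = np.asarray(simulated_scores, dtype=np.float64)
    pool = pool[np.isfinite(pool)]
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if n_tests > pool.size:
        raise ValueError(f"n_tests={n_tests} exceeds pooled score count {pool.size}")
    if method == "tail_quantile":
        alpha = 1.0 / n_tests
        lo = float(np.quantile(pool, alpha))
        hi = float(np.quantile(pool, 1.0 - alpha))
    elif method == "expected_extremes":
        rng = np.random.default_rng(seed)
        if n_tests == pool.size:
            lo, hi = float(pool.min()), float(pool.max())
        else:
            mins = np.empty(B)
            maxs = np.empty(B)
            for b in range(B):
                draw = rng.choice(pool, size=n_tests, replace=False)
                mins[b] = draw.min()
                maxs[b] = draw.max()
            lo, hi = float(mins.mean()), float(maxs.mean())
    else:
        raise ValueError(f"unknown cutoff method: {method!r}")
    return CutoffPair(lo=lo, hi=hi, n_tests=n_tests, n_resamples=B, seed=seed,
                      method=method)


def filter_candidates(
    records: Sequence[IHSRecord], cutoffs: CutoffPair, population: str
) -> list[SelectionCandidate]:
    """Markers whose standardized iHS lies strictly beyond the cutoffs.

    sihs > 0 flags selection on the derived allele, sihs < 0 on the
    ancestral allele; values exactly at a cutoff are excluded (strict
    inequality).
    """
    out = []
    for r in records:
        if r.skipped or not np.isfinite(r.sihs):
            continue
        if r.sihs < cutoffs.lo or r.sihs > cutoffs.hi:
            out.append(
                SelectionCandidate(
                    marker_id=r.marker_id,
                    population=population,
                    sihs=r.sihs,
                    lo=cutoffs.lo,
                    hi=cutoffs.hi,
                )
            )
    return out


def tally_shared(
    candidates_by_pop: dict[str, Sequence[SelectionCandidate]]
) -> tuple[int, int, int]:
    """(unique markers, markers shared by >= 2 populations, total signals).

    Also fills each candidate's ``shared_by`` with the number of
    populations flagging its marker.
    """
    marker_sets = {
        pop: {c.marker_id for c in cands} for pop, cands in candidates_by_pop.items()
    }
    union: set[str] = set()
    for s in marker_sets.values():
        union |= s
    n_pops = {mk: sum(mk in s for s in marker_sets.values()) for mk in union}
    for cands in candidates_by_pop.values():
        for c in cands:
            c.shared_by = n_pops[c.marker_id]
    shared = sum(1 for mk in union if n_pops[mk] >= 2)
    total = sum(len(s) for s in marker_sets.values())
    return len(union), shared, total


def tmrca_from_r(r_morgans: float, gen_years: float = 30.0,
                 homoz_target: float = HOMOZ_TARGET) -> tuple[float, float]:
    """(generations, years) from the one-sided breakpoint distance r (Morgans)."""
    if r_morgans <= 0:
        raise ValueError("r must be positive")
    t_gen = -math.log(homoz_target) / (2.0 * r_morgans)
    return t_gen, t_gen * gen_years


def estimate_tmrca(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    candidate: SelectionCandidate,
    gen_years: float = 30.0,
    max_span_cm: float = MAX_SPAN_CM,
) -> TMRCAResult:
    """Date a candidate allele by the decay of its extended haplotype.

    The favored allele (derived if sihs > 0, else ancestral) defines the
    core; the interpolated EHH = 0.25 crossings left and right give the
    haplotype breakpoints.  If the genetic span between breakpoints
    exceeds ``max_span_cm`` the estimate is skipped (such an allele would
    need an implausibly large selection coefficient); if EHH never
    reaches 0.25 inside the panel the result is unresolved.
    """
    try:
        core = panel.marker_ids.index(candidate.marker_id)
    except ValueError:
        raise ValueError(f"marker {candidate.marker_id!r} not in panel") from None
    allele = DERIVED if candidate.sihs > 0 else ANCESTRAL
    curve = compute_ehh(panel, gmap, core, allele, stop_ehh=HOMOZ_TARGET)
    base = TMRCAResult(
        marker_id=candidate.marker_id,
        r_morgans=float("nan"),
        t_generations=float("nan"),
        years=float("nan"),
        span_cm=float("nan"),
    )
    if curve.n_carriers < 2:
        base.unresolved, base.reason = True, "too_few_carriers"
        return base
    if not (curve.crossed_left and curve.crossed_right):
        base.unresolved, base.reason = True, "no_homoz_crossing"
        return base
    span = _crossing_distance(curve.left) + _crossing_distance(curve.right)
    base.span_cm = span
    if span > max_span_cm:
        base.skipped, base.reason = True, "span_exceeds_limit"
        return base
    r = span / 2.0 / 100.0  # cM -> Morgans, symmetric decay
    t_gen, years = tmrca_from_r(r, gen_years)
    base.r_morgans = r
    base.t_generations = t_gen
    base.years = years
    return base


def null_calibration(
    model,
    pool_seeds: Sequence[int],
    test_seeds: Sequence[int],
    n_individuals: int = 320,
    group_size: int = 80,
    n_groups: int = 4,
    B: int = 1000,
    seed: int = 0,
    naive_threshold: float = 2.0,
) -> dict:
    """End-to-end null calibration of the selection scan.

    Simulates independent neutral replicates of the demographic model,
    splits each into groups, computes standardized iHS per group, pools
    the scores of the ``pool_seeds`` replicates, derives cutoffs matched
    to the number of usable tests in the ``test_seeds`` replicates, and
    filters those independent scores.  Because the cutoffs are the
    expected extremes at the matched test count, only excursions beyond
    what neutrality produces at that many tests survive: the surviving
    fraction falls far below the naive |iHS| > ``naive_threshold`` rate.

    Returns a dict with the naive exceedance rate, surviving fraction,
    cutoff pair and counts.
    """
    from .hapstats import ihs_scan, standardize_ihs
    from .simdata import partition_groups, simulate

    gmap = model.genetic_map()

    def replicate_scores(rep_seed: int) -> np.ndarray:
        sample = simulate(model, n_individuals, rep_seed)
        groups = partition_groups([sample], group_size, n_groups, seed=rep_seed + 7)
        vals = []
        for g in groups:
            recs = standardize_ihs(ihs_scan(g, gmap))
            vals.extend(r.sihs for r in recs if np.isfinite(r.sihs))
        return np.asarray(vals)

    pool = np.concatenate([replicate_scores(s) for s in pool_seeds])
    test = np.concatenate([replicate_scores(s) for s in test_seeds])
    # a without-replacement draw cannot exceed the pool; if the usable
    # pool is smaller than the test count the match saturates at the
    # full pool (cutoffs = pool extremes)
    n_match = min(test.size, pool.size)
    cutoffs = derive_cutoffs(pool, n_tests=n_match, B=B, seed=seed)
    n_naive = int((np.abs(test) > naive_threshold).sum())
    n_surviving = int(((test < cutoffs.lo) | (test > cutoffs.hi)).sum())
    return {
        "pool_size": int(pool.size),
        "n_tests": int(test.size),
        "cutoff_lo": cutoffs.lo,
        "cutoff_hi": cutoffs.hi,
        "n_naive": n_naive,
        "naive_rate": n_naive / test.size,
        "n_surviving": n_surviving,
        "surviving_fraction": n_surviving / test.size,
    }


def _crossing_distance(side: np.ndarray, target: float = HOMOZ_TARGET) -> float:
    """Interpolated distance (cM) at which one EHH side decays to ``target``."""
    dist, ehh = side[:, 0], side[:, 1]
    k = int(np.argmax(ehh <= target))
    if k == 0:
        return 0.0
    d0, e0 = dist[k - 1], ehh[k - 1]
    d1, e1 = dist[k], ehh[k]
    if e1 == e0:
        return float(d0)
    return float(d0 + (e0 - target) * (d1 - d0) / (e0 - e1))
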