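"""Forward Wright-Fisher simulation of admixture and colonization bottlenecks.

The demographic model is a single 10 Mb chromosome evolving neutrally
through a piecewise-constant population-size history: an ancestral
population of Ne 10,000, an out-of-Africa reduction to 2,000 at 50 kya,
recovery to 10,000 at 5 kya, then a colonization bottleneck to 100
individuals lasting from 500 to 90 years ago, opened by a 70% admixture
pulse from a European-like lineage and accompanied by a 70% selfing
(inbreeding) probability, with recovery to 10,000 afterwards.
Generations are 30 years.

Two lineages are maintained after the out-of-Africa event: the focal
("colonized") lineage, which experiences the bottleneck, pulse and
inbreeding, and a European-like source lineage that follows the same
size trajectory but skips the colonization bottleneck.  This is the
minimal structure that makes a single-pulse admixture event executable
inside one forward simulation.

A rescaling factor q shrinks all population sizes and times by q while
inflating the per-generation mutation and recombination rates by q, so
the population-scaled parameters theta = 4*Ne*mu and rho = 4*Ne*rec —
and hence sample statistics — are preserved at a fraction of the
compute cost.

Burn-in to mutation-drift equilibrium is obtained by default from a
coalescent (msprime) sample of the ancestral population, which has the
identical stationary distribution to a long forward burn-in; a forward
burn-in of 10*Ne generations is available via ``burn_in="forward"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io_formats import GeneticMap, HaplotypePanel

__all__ = [
    "Admixture",
    "Inbreeding",
    "DemographyModel",
    "SimSample",
    "build_colonization_model",
    "build_constant_model",
    "rescale",
    "simulate",
    "partition_groups",
]


@dataclass(frozen=True)
class Admixture:
    years_ago: float = 500.0
    fraction: float = 0.70
    source: str = "European-like lineage"


@dataclass(frozen=True)
class Inbreeding:
    prob: float = 0.70
    start_years_ago: float = 500.0
    end_years_ago: float = 90.0


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant demography plus admixture/inbreeding parameters.

    ``epochs`` is ordered oldest to youngest as (start_years_ago, Ne)
    pairs; each epoch's size applies from its start until the next
    epoch's start.  All times are in (possibly rescaled) years; divide
    by ``gen_years`` for generations.
    """

    epochs: tuple = (
        (2_150_000.0, 10_000),
        (50_000.0, 2_000),
        (5_000.0, 10_000),
        (500.0, 100),
        (90.0, 10_000),
    )
    admixture: Optional[Admixture] = Admixture()
    inbreeding: Optional[Inbreeding] = Inbreeding()
    mu: float = 1.5e-8
    rec: float = 1e-8
    chrom_len_bp: int = 10_000_000
    gen_years: float = 30.0
    scale_q: float = 1.0

    def __post_init__(self):
        starts = [e[0] for e in self.epochs]
        if any(starts[i] <= starts[i + 1] for i in range(len(starts) - 1)):
            raise ValueError(
                "epochs must be ordered oldest to youngest (decreasing start)"
            )
        if any(e[1] < 2 for e in self.epochs):
            raise ValueError("all Ne must be >= 2")
        if self.admixture is not None and not (0.0 <= self.admixture.fraction <= 1.0):
            raise ValueError("admixture fraction must be in [0, 1]")
        if self.scale_q < 1.0:
            raise ValueError("scale_q must be >= 1")

    def theta(self) -> float:
        """Population-scaled mutation rate 4*Ne*mu of the ancestral epoch (per bp)."""
        return 4.0 * self.epochs[0][1] * self.mu

    def rho(self) -> float:
        """Population-scaled recombination rate 4*Ne*rec of the ancestral epoch (per bp)."""
        return 4.0 * self.epochs[0][1] * self.rec

    def genetic_map(self) -> GeneticMap:
        """Uniform map at the model's recombination rate (cM/Mb = rec * 1e8)."""
        return GeneticMap.uniform(self.rec * 1e8, self.chrom_len_bp)

    @property
    def final_ne(self) -> int:
        return int(self.epochs[-1][1])


@dataclass
class SimSample:
    """A sample of diploid individuals drawn from the focal lineage at present."""

    panel: HaplotypePanel
    seed: int
    run_index: int
    model: DemographyModel
    source_panel: Optional[HaplotypePanel] = None
    prepulse_freqs: Optional[dict] = None  # position -> (focal_freq, source_freq)


def build_colonization_model() -> DemographyModel:
    """The admixed colonization-bottleneck demography (unscaled).

    Burn-in from 2.15 Mya at Ne 10,000; reduction to 2,000 at 50 kya;
    recovery to 10,000 at 5 kya; bottleneck to 100 from 500 to 90 years
    ago with a 70% European-like admixture pulse at 500 ya and 70%
    inbreeding probability during the window; recovery to 10,000 at
    90 ya.  mu = 1.5e-8, rec = 1e-8 per bp per generation; 10 Mb
    chromosome; 30-year generations.
    """
    return DemographyModel()


def build_constant_model(ne: int = 10_000, duration_years: float = 12_000.0,
                         **kwargs) -> DemographyModel:
    """A constant-size neutral control with no admixture or inbreeding."""
    return DemographyModel(
        epochs=((float(duration_years), int(ne)),),
        admixture=None,
        inbreeding=None,
        **kwargs,
    )


def rescale(model: DemographyModel, q: float) -> DemographyModel:
    """Rescale a model by q >= 1: Ne / q (floor, min 2), times / q, rates * q.

    theta = 4*Ne*mu and rho = 4*Ne*rec are preserved up to the integer
    floor on Ne.
    """
    if q < 1:
        raise ValueError("rescaling factor q must be >= 1")
    if q == 1:
        return model
    epochs = tuple(
        (start / q, max(2, int(math.floor(ne / q)))) for start, ne in model.epochs
    )
    admix = (
        replace(model.admixture, years_ago=model.admixture.years_ago / q)
        if model.admixture
        else None
    )
    inb = (
        replace(
            model.inbreeding,
            start_years_ago=model.inbreeding.start_years_ago / q,
            end_years_ago=model.inbreeding.end_years_ago / q,
        )
        if model.inbreeding
        else None
    )
    return replace(
        model,
        epochs=epochs,
        admixture=admix,
        inbreeding=inb,
        mu=model.mu * q,
        rec=model.rec * q,
        scale_q=model.scale_q * q,
    )


# ---------------------------------------------------------------------------
# Forward machinery


def _ages_in_generations(model: DemographyModel) -> list[tuple[int, int]]:
    """Scaled epoch boundaries as (age_in_generations, Ne), oldest first.

    The burn-in epoch (index 0) is excluded; collisions from rounding are
    resolved by pushing younger boundaries one generation apart.
    """
    g = model.gen_years
    ages = [int(round(start / g)) for start, _ in model.epochs[1:]]
    nes = [ne for _, ne in model.epochs[1:]]
    if not ages:  # constant model: single epoch spans its whole duration
        return [(int(round(model.epochs[0][0] / g)), model.epochs[0][1])]
    for i in range(1, len(ages)):
        ages[i] = min(ages[i], ages[i - 1] - 1)
    ages = [max(a, 0) for a in ages]
    return list(zip(ages, nes))


def _size_at(age: int, bounds: list[tuple[int, int]]) -> int:
    """Ne applying to the generation living ``age`` generations before present.

    Epoch i (boundaries oldest first) covers ages in (b_{i+1}, b_i]; the
    youngest epoch covers everything from its start down to the present.
    """
    if age >= bounds[0][0]:
        return bounds[0][1]
    for (b_age, ne), (nxt_age, _) in zip(bounds, bounds[1:]):
        if nxt_age < age <= b_age:
            return ne
    return bounds[-1][1]


def _msprime_panel(n_diploids: int, ne: int, model: DemographyModel, seed: int):
    """Equilibrium standing variation from the coalescent: (haplotypes, float positions)."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_diploids,
        population_size=ne,
        sequence_length=model.chrom_len_bp,
        recombination_rate=model.rec,
        discrete_genome=False,
        random_seed=max(1, seed % (2**31 - 2)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=model.mu,
        model="binary",
        discrete_genome=False,
        random_seed=max(1, (seed + 1) % (2**31 - 2)),
    )
    if ts.num_sites == 0:
        return (
            np.zeros((2 * n_diploids, 0), dtype=np.uint8),
            np.zeros(0, dtype=np.float64),
        )
    geno = ts.genotype_matrix().astype(np.uint8).T  # haplotypes x sites
    positions = np.array([s.position for s in ts.sites()], dtype=np.float64)
    return np.ascontiguousarray(geno), positions


class _Registry:
    """Two-tier shared site registry for all lineages of one simulation.

    ``pos_main`` is the large, sorted registry backing slice-copy gamete
    assembly; ``pos_buf`` is a small unsorted buffer of recent mutations,
    pruned every generation and merged into the main registry every few
    generations.  Both tiers are shared across lineages so admixture can
    move haplotypes between them.
    """

    def __init__(self, pos_main: np.ndarray):
        self.pos_main = pos_main
        self.pos_buf = np.zeros(0, dtype=np.float64)

    def prune_buffer(self, lineages: list["_Lineage"]) -> None:
        if self.pos_buf.size == 0:
            return
        total = sum(l.buf.sum(axis=0, dtype=np.int64) for l in lineages)
        n_haps = sum(l.buf.shape[0] for l in lineages)
        keep = (total > 0) & (total < n_haps)
        if keep.all():
            return
        self.pos_buf = self.pos_buf[keep]
        for l in lineages:
            l.buf = np.ascontiguousarray(l.buf[:, keep])

    def prune_main(self, lineages: list["_Lineage"]) -> None:
        if self.pos_main.size == 0:
            return
        total = sum(l.main.sum(axis=0, dtype=np.int64) for l in lineages)
        n_haps = sum(l.main.shape[0] for l in lineages)
        keep = (total > 0) & (total < n_haps)
        if keep.all():
            return
        self.pos_main = self.pos_main[keep]
        for l in lineages:
            l.main = np.ascontiguousarray(l.main[:, keep])

    def merge(self, lineages: list["_Lineage"]) -> None:
        """Fold the buffer into the sorted main registry."""
        self.prune_buffer(lineages)
        self.prune_main(lineages)
        if self.pos_buf.size == 0:
            return
        combined = np.concatenate([self.pos_main, self.pos_buf])
        order = np.argsort(combined, kind="stable")
        self.pos_main = combined[order]
        for l in lineages:
            wide = np.concatenate([l.main, l.buf], axis=1)
            l.main = np.take(wide, order, axis=1)
            l.buf = np.zeros((l.main.shape[0], 0), dtype=np.uint8)
        self.pos_buf = np.zeros(0, dtype=np.float64)


class _Lineage:
    """Haplotypes of one lineage: main (sorted registry) + buffer columns."""

    def __init__(self, main: np.ndarray, buf: Optional[np.ndarray] = None):
        self.main = np.ascontiguousarray(main, dtype=np.uint8)
        self.buf = (
            buf
            if buf is not None
            else np.zeros((self.main.shape[0], 0), dtype=np.uint8)
        )

    @property
    def n_ind(self) -> int:
        return self.main.shape[0] // 2


def _reproduce(pools: list[_Lineage], pool_probs, n_children: int, p_self: float,
               reg: _Registry, model: DemographyModel,
               rng: np.random.Generator) -> tuple[_Lineage, list[tuple[int, float]]]:
    """Produce ``n_children`` diploids from parent ``pools``.

    Each gamete is a crossover mosaic of one parent's two chromosomes:
    crossover count Poisson(rec * L), breakpoints uniform; new mutations
    Poisson(mu * L) per gamete at fresh uniform positions.  With
    probability ``p_self`` the two gametes of an offspring come from the
    same parent (selfing); ``pool_probs[1]`` is the per-draw probability
    of taking the parent from the second (source) pool.
    """
    L = float(model.chrom_len_bp)
    rec_mean = model.rec * L
    mu_mean = model.mu * L
    pos_main, pos_buf = reg.pos_main, reg.pos_buf
    s_main, s_buf = pos_main.size, pos_buf.size
    child_main = np.empty((2 * n_children, s_main), dtype=np.uint8)
    child_buf = np.empty((2 * n_children, s_buf), dtype=np.uint8)
    new_muts: list[tuple[int, float]] = []
    p_other = pool_probs[1] if len(pools) > 1 else 0.0

    def draw_parent():
        pool = pools[1] if (p_other > 0.0 and rng.random() < p_other) else pools[0]
        return pool, int(rng.integers(pool.n_ind))

    for c in range(n_children):
        if p_self > 0.0 and rng.random() < p_self:
            pool, p = draw_parent()
            parents = ((pool, p), (pool, p))
        else:
            parents = (draw_parent(), draw_parent())
        for side, (pool, p) in enumerate(parents):
            row = 2 * c + side
            start = int(rng.integers(2))
            k = rng.poisson(rec_mean)
            if k == 0:
                child_main[row] = pool.main[2 * p + start]
                if s_buf:
                    child_buf[row] = pool.buf[2 * p + start]
            else:
                bks = np.sort(rng.random(k) * L)
                cuts = np.searchsorted(pos_main, bks)
                lo, phase = 0, start
                for cut in cuts:
                    if cut > lo:
                        child_main[row, lo:cut] = pool.main[2 * p + phase, lo:cut]
                    lo = cut
                    phase ^= 1
                child_main[row, lo:] = pool.main[2 * p + phase, lo:]
                if s_buf:
                    bphase = (np.searchsorted(bks, pos_buf) + start) & 1
                    child_buf[row] = np.where(
                        bphase == 0, pool.buf[2 * p], pool.buf[2 * p + 1]
                    )
            nm = rng.poisson(mu_mean)
            for _ in range(nm):
                new_muts.append((row, rng.random() * L))
    return _Lineage(child_main, child_buf), new_muts


def _add_mutation_columns(reg: _Registry, lineages: list[_Lineage],
                          per_lineage_muts: list[list[tuple[int, float]]]) -> None:
    """Append this generation's new mutations as buffer columns."""
    total_new = sum(len(m) for m in per_lineage_muts)
    if total_new == 0:
        return
    new_pos = np.empty(total_new, dtype=np.float64)
    col = 0
    starts = []
    for muts in per_lineage_muts:
        starts.append(col)
        for _, pos in muts:
            new_pos[col] = pos
            col += 1
    reg.pos_buf = np.concatenate([reg.pos_buf, new_pos])
    for li, (lin, muts) in enumerate(zip(lineages, per_lineage_muts)):
        block = np.zeros((lin.buf.shape[0], total_new), dtype=np.uint8)
        for j, (row, _) in enumerate(muts):
            block[row, starts[li] + j] = 1
        lin.buf = np.concatenate([lin.buf, block], axis=1)


def _float_positions_to_bp(pos: np.ndarray) -> np.ndarray:
    """Map sorted float positions to unique, strictly increasing 1-based int bp."""
    ip = np.floor(pos).astype(np.int64) + 1
    for i in range(1, ip.size):
        if ip[i] <= ip[i - 1]:
            ip[i] = ip[i - 1] + 1
    return ip


def _export_panel(mat: np.ndarray, positions: np.ndarray, maf: float,
                  chrom: str, id_prefix: str,
                  marker_keep: Optional[np.ndarray] = None):
    """Sort sites, apply the derived-frequency filter, and build a panel.

    Returns (panel, kept float positions).  ``marker_keep``, when given,
    overrides the frequency filter with a precomputed site selection so
    two panels can share one marker registry.  ``positions`` must be
    sorted (the registry invariant).
    """
    if marker_keep is None:
        p = mat.mean(axis=0)
        keep = (p > maf) & (p < 1.0)
    else:
        keep = marker_keep
    positions = positions[keep]
    mat = mat[:, keep]
    bp = _float_positions_to_bp(positions)
    panel = HaplotypePanel(
        mat,
        bp,
        [f"{chrom}:{b}" for b in bp],
        [f"{id_prefix}{i}" for i in range(mat.shape[0] // 2)],
        chrom,
    )
    return panel, positions, keep


def simulate(
    model: DemographyModel,
    n_sample_individuals: int,
    seed: int,
    *,
    maf: float = 0.05,
    burn_in: str = "coalescent",
    n_sample_source: int = 0,
    record_prepulse: bool = False,
    run_index: int = 0,
) -> SimSample:
    """Run the forward Wright-Fisher model and sample diploids at present.

    Offspring chromosomes are recombinants of one parent's two
    chromosomes, with Poisson crossover counts (mean rec * L, uniform
    breakpoints) and Poisson new mutations (mean mu * L per chromosome
    per generation) at unique infinite-sites positions.  During the
    inbreeding window, with probability ``inbreeding.prob`` the two
    parents of an offspring are the same individual (selfing); at the
    admixture pulse, each parent draw of the focal lineage comes from
    the European-like source lineage with probability
    ``admixture.fraction``.

    The output panel retains sites with sampled derived frequency in
    (``maf``, 1.0); fixed sites are dropped.  Identical (model, n, seed)
    yields a byte-for-byte identical panel.
    """
    rng = np.random.default_rng(seed)
    bounds = _ages_in_generations(model)
    t_start = bounds[0][0]
    if _size_at(0, bounds) < n_sample_individuals:
        raise ValueError(
            f"sample of {n_sample_individuals} exceeds final population size "
            f"{_size_at(0, bounds)}"
        )

    two_lineages = model.admixture is not None
    pulse_age = None
    eu_bounds = bounds
    if two_lineages:
        g = model.gen_years
        pulse_age = int(round(model.admixture.years_ago / g))
        # snap the pulse to the (possibly collision-shifted) epoch boundary
        for (b_age, _), (start, _) in zip(bounds, model.epochs[1:]):
            if abs(start - model.admixture.years_ago) < 1e-9:
                pulse_age = b_age
        pulse_age = min(pulse_age, t_start - 1)
        eu_bounds = [
            (b_age, ne)
            for (b_age, ne), (start, _) in zip(bounds, model.epochs[1:])
            if model.admixture is None
            or abs(start - model.admixture.years_ago) > 1e-9
        ]
        if not eu_bounds:
            eu_bounds = bounds

    inb_lo = inb_hi = None
    if model.inbreeding is not None:
        g = model.gen_years
        inb_hi = int(round(model.inbreeding.start_years_ago / g))
        inb_lo = int(round(model.inbreeding.end_years_ago / g))
        if two_lineages:
            inb_hi = max(inb_hi, pulse_age)

    n_focal0 = _size_at(t_start, bounds)
    n_eu0 = _size_at(t_start, eu_bounds) if two_lineages else 0

    # --- standing variation at the start of the forward phase
    if burn_in == "coalescent":
        ms_seed = int(rng.integers(1, 2**31 - 3))
        founders, positions = _msprime_panel(
            n_focal0 + n_eu0, model.epochs[0][1], model, ms_seed
        )
    elif burn_in == "forward":
        ne0 = model.epochs[0][1]
        reg0 = _Registry(np.zeros(0, dtype=np.float64))
        pop = _Lineage(np.zeros((2 * ne0, 0), dtype=np.uint8))
        for gen in range(10 * ne0):
            pop, muts = _reproduce([pop], [1.0], ne0, 0.0, reg0, model, rng)
            _add_mutation_columns(reg0, [pop], [muts])
            reg0.prune_buffer([pop])
            if gen % 8 == 7:
                reg0.merge([pop])
        reg0.merge([pop])
        rows = rng.choice(ne0, size=n_focal0 + n_eu0, replace=False)
        idx = np.empty(2 * rows.size, dtype=np.int64)
        idx[0::2], idx[1::2] = 2 * rows, 2 * rows + 1
        founders = pop.main[idx]
        positions = reg0.pos_main
    else:
        raise ValueError("burn_in must be 'coalescent' or 'forward'")

    reg = _Registry(positions)
    focal = _Lineage(founders[: 2 * n_focal0])
    eu = _Lineage(founders[2 * n_focal0:]) if two_lineages else None
    eu_active = two_lineages
    prepulse = None

    for g_ago in range(t_start, 0, -1):
        child_age = g_ago - 1
        pulse = two_lineages and child_age == pulse_age
        if pulse and record_prepulse:
            reg.merge([focal, eu])
            prepulse = (
                reg.pos_main.copy(),
                focal.main.mean(axis=0),
                eu.main.mean(axis=0),
            )
        p_self = 0.0
        if inb_lo is not None and inb_lo < child_age <= inb_hi:
            p_self = model.inbreeding.prob

        n_focal_child = _size_at(child_age, bounds)
        probs = [1.0, model.admixture.fraction] if pulse else [1.0, 0.0]
        pools = [focal, eu] if pulse else [focal]
        new_focal, muts_f = _reproduce(
            pools, probs, n_focal_child, p_self, reg, model, rng
        )

        children = [new_focal]
        per_muts = [muts_f]
        if eu_active:
            keep_eu = n_sample_source > 0 or child_age >= pulse_age
            if keep_eu:
                n_eu_child = _size_at(child_age, eu_bounds)
                new_eu, muts_e = _reproduce(
                    [eu], [1.0], n_eu_child, 0.0, reg, model, rng
                )
                children.append(new_eu)
                per_muts.append(muts_e)
            else:
                eu_active = False
                eu = None
        _add_mutation_columns(reg, children, per_muts)
        reg.prune_buffer(children)
        if g_ago % 8 == 1 or reg.pos_buf.size > 8192:
            reg.merge(children)
        focal = children[0]
        if eu_active:
            eu = children[1]

    # --- sample and export
    lineages = [focal] + ([eu] if eu_active else [])
    reg.merge(lineages)
    positions = reg.pos_main
    n_final = focal.n_ind
    rows = np.sort(rng.choice(n_final, size=n_sample_individuals, replace=False))
    idx = np.empty(2 * rows.size, dtype=np.int64)
    idx[0::2], idx[1::2] = 2 * rows, 2 * rows + 1
    sample = focal.main[idx]
    panel, kept_pos, keep_mask = _export_panel(sample, positions, maf, "1", "sim")

    source_panel = None
    if n_sample_source:
        if eu is None:
            raise ValueError("source sampling requires a model with admixture")
        erows = np.sort(rng.choice(eu.n_ind, size=n_sample_source, replace=False))
        eidx = np.empty(2 * erows.size, dtype=np.int64)
        eidx[0::2], eidx[1::2] = 2 * erows, 2 * erows + 1
        eu_sample = eu.main[eidx]
        source_panel = HaplotypePanel(
            eu_sample[:, keep_mask],
            panel.positions.copy(),
            list(panel.marker_ids),
            [f"src{i}" for i in range(erows.size)],
            panel.chrom,
        )

    prepulse_freqs = None
    if prepulse is not None:
        snap_pos, f_focal, f_eu = prepulse
        snap_order = np.argsort(snap_pos)
        snap_pos = snap_pos[snap_order]
        f_focal, f_eu = f_focal[snap_order], f_eu[snap_order]
        loc = np.searchsorted(snap_pos, kept_pos)
        prepulse_freqs = {}
        for j, (pos, bp) in enumerate(zip(kept_pos, panel.positions)):
            i = loc[j]
            if i < snap_pos.size and snap_pos[i] == pos:
                prepulse_freqs[int(bp)] = (float(f_focal[i]), float(f_eu[i]))
            else:
                prepulse_freqs[int(bp)] = (0.0, 0.0)

    return SimSample(
        panel=panel,
        seed=seed,
        run_index=run_index,
        model=model,
        source_panel=source_panel,
        prepulse_freqs=prepulse_freqs,
    )


def partition_groups(
    samples: Sequence[SimSample] | Sequence[HaplotypePanel],
    group_size: int,
    n_groups: int,
    seed: int,
    min_maf: float = 0.05,
) -> list[HaplotypePanel]:
    """Divide sampled individuals into disjoint random groups.

    All inputs must share one marker registry (i.e. come from the same
    simulation run); individuals are pooled, shuffled, and cut into
    ``n_groups`` disjoint groups of exactly ``group_size``.  Each group
    panel is re-filtered to minor allele frequency >= ``min_maf`` within
    the group.
    """
    panels = [s.panel if isinstance(s, SimSample) else s for s in samples]
    if not panels:
        raise ValueError("no samples given")
    base = panels[0]
    for p in panels[1:]:
        if p.n_markers != base.n_markers or not np.array_equal(p.positions, base.positions):
            raise ValueError(
                "all samples must share one marker registry; partition runs separately"
            )
    alleles = np.concatenate([p.alleles for p in panels], axis=0)
    ids = [f"{k}:{i}" for k, p in enumerate(panels) for i in p.individual_ids]
    total = alleles.shape[0] // 2
    if total < group_size * n_groups:
        raise ValueError(
            f"insufficient individuals: {total} < {group_size} x {n_groups}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    out = []
    pooled = HaplotypePanel(alleles, base.positions.copy(), list(base.marker_ids), ids, base.chrom)
    for k in range(n_groups):
        members = np.sort(perm[k * group_size: (k + 1) * group_size])
        out.append(pooled.take_individuals(members).filter_maf(min_maf))
    return out
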