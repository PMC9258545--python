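"""Core containers and file formats.

The two containers everything else consumes are :class:`HaplotypePanel`
(a phased, ancestral/derived-polarized 0/1 haplotype matrix) and
:class:`GeneticMap` (a monotone bp -> cM interpolator).  Readers exist
for phased VCF (via cyvcf2) and for PLINK ``.map`` / two-column
recombination maps; results are written as plain TSV.

Coordinate conventions: physical positions are 1-based inclusive bp
(VCF convention); genetic positions are centimorgans at the API surface
and Morgans only inside closed-form clocks, stated per function.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("hapfeatures")

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "read_phased_vcf",
    "read_genetic_map",
    "write_results_table",
    "read_results_table",
    "write_phased_vcf",
    "write_genetic_map",
]


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one chromosome.

    ``alleles`` has shape (2n haplotypes, m markers) with 0 = ancestral and
    1 = derived; haplotypes ``2i`` and ``2i+1`` belong to individual ``i``.
    Positions are 1-based bp, strictly increasing and unique.
    """

    alleles: np.ndarray
    positions: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x marker matrix")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (diploid individuals)")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length does not match marker count")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        if not self.marker_ids:
            self.marker_ids = [f"m{p}" for p in self.positions]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.n_individuals)]
        if len(self.marker_ids) != self.n_markers:
            raise ValueError("marker_ids length mismatch")
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Per-marker derived allele frequency."""
        return self.alleles.mean(axis=0)

    def genotypes(self) -> np.ndarray:
        """Per-individual derived-allele dosage matrix, shape (n, m), values 0/1/2."""
        a = self.alleles.astype(np.int8)
        return a[0::2] + a[1::2]

    def take_markers(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            self.alleles[:, idx],
            self.positions[idx],
            [self.marker_ids[i] for i in np.atleast_1d(idx)],
            list(self.individual_ids),
            self.chrom,
        )

    def take_individuals(self, idx: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(idx, dtype=np.int64)
        rows = np.empty(2 * idx.size, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypePanel(
            self.alleles[rows],
            self.positions.copy(),
            list(self.marker_ids),
            [self.individual_ids[i] for i in idx],
            self.chrom,
        )

    def filter_maf(self, min_maf: float = 0.05) -> "HaplotypePanel":
        """Keep markers whose minor allele frequency is >= ``min_maf``."""
        p = self.derived_freq()
        maf = np.minimum(p, 1.0 - p)
        return self.take_markers(np.flatnonzero(maf >= min_maf))

    def thin_to_spacing(self, spacing_bp: int) -> "HaplotypePanel":
        """Greedily keep markers at least ``spacing_bp`` apart (array-density emulation)."""
        keep = []
        last = -np.inf
        for i, pos in enumerate(self.positions):
            if pos - last >= spacing_bp:
                keep.append(i)
                last = pos
        return self.take_markers(np.asarray(keep, dtype=np.int64))


@dataclass
class GeneticMap:
    """Monotone bp -> cM map, linear between anchors, constant beyond the ends."""

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.bp.ndim != 1 or self.bp.shape != self.cm.shape or self.bp.size < 1:
            raise ValueError("map needs matching 1-D bp and cM arrays")
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("bp anchors must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            i = int(np.flatnonzero(np.diff(self.cm) < 0)[0]) + 1
            raise ValueError(
                f"cM values must be non-decreasing in bp; first offending anchor "
                f"#{i} (bp={self.bp[i]:.0f}, cM={self.cm[i]})"
            )

    @classmethod
    def uniform(cls, rate_cm_per_mb: float, length_bp: float) -> "GeneticMap":
        return cls(
            np.array([1.0, float(length_bp)]),
            np.array([0.0, rate_cm_per_mb * (length_bp - 1.0) / 1e6]),
        )

    def cm_at(self, bp) -> np.ndarray | float:
        """Interpolated genetic position (cM) at physical position(s) bp."""
        out = np.interp(np.asarray(bp, dtype=np.float64), self.bp, self.cm)
        return float(out) if np.ndim(bp) == 0 else out

    def cm_between(self, bp_a, bp_b) -> float:
        return abs(self.cm_at(bp_b) - self.cm_at(bp_a))


# ---------------------------------------------------------------------------
# Readers


def read_phased_vcf(path: str, ancestral_tag: str = "AA") -> HaplotypePanel:
    """Read a phased, biallelic-SNP VCF into a HaplotypePanel.

    Alleles are polarized so 1 = derived using the INFO field named by
    ``ancestral_tag``.  Sites whose annotated ancestral allele matches
    neither REF nor ALT (or is missing) are dropped with a logged count;
    non-biallelic sites are skipped with a warning.  Any unphased GT is a
    hard error naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    positions: list[int] = []
    marker_ids: list[str] = []
    chrom = None
    n_dropped_polarity = 0
    n_skipped_multiallelic = 0
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        if len(var.ALT) != 1:
            n_skipped_multiallelic += 1
            continue
        gt = np.asarray(var.genotype.array())
        if not np.all(gt[:, 2] == 1):
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} ({var.ID or '.'}); "
                "all GT fields must use '|'"
            )
        aa = var.INFO.get(ancestral_tag)
        if aa is not None:
            aa = str(aa).strip().upper().rstrip("|").split("|")[0]
        if aa == var.REF.upper():
            flip = False
        elif aa == var.ALT[0].upper():
            flip = True
        else:
            n_dropped_polarity += 1
            continue
        hap = gt[:, :2].reshape(-1).astype(np.uint8)
        if flip:
            hap = (1 - hap).astype(np.uint8)
        cols.append(hap)
        positions.append(var.POS)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if n_skipped_multiallelic:
        logger.warning("skipped %d non-biallelic sites", n_skipped_multiallelic)
    if n_dropped_polarity:
        logger.warning(
            "dropped %d sites lacking usable %s polarity annotation",
            n_dropped_polarity,
            ancestral_tag,
        )
    alleles = (
        np.column_stack(cols)
        if cols
        else np.zeros((2 * len(individual_ids), 0), dtype=np.uint8)
    )
    return HaplotypePanel(
        alleles,
        np.asarray(positions, dtype=np.int64),
        marker_ids,
        individual_ids,
        chrom or "1",
    )


def read_genetic_map(path: str, dialect: str = "two_column") -> GeneticMap:
    """Read a genetic map.

    ``two_column`` files hold whitespace-separated ``bp cM`` rows; the
    ``plink_map`` dialect reads PLINK .map columns (chrom, id, cM, bp).
    """
    bps: list[float] = []
    cms: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if dialect == "plink_map":
                if len(parts) < 4:
                    raise ValueError(f"line {lineno}: expected 4 PLINK .map columns")
                cm, bp = float(parts[2]), float(parts[3])
            elif dialect == "two_column":
                if len(parts) < 2:
                    raise ValueError(f"line {lineno}: expected 'bp cM'")
                bp, cm = float(parts[0]), float(parts[1])
            else:
                raise ValueError(f"unknown map dialect: {dialect!r}")
            if bps and cm < cms[-1]:
                raise ValueError(
                    f"line {lineno}: cM column decreases ({cms[-1]} -> {cm}); "
                    "genetic map must be monotone"
                )
            bps.append(bp)
            cms.append(cm)
    return GeneticMap(np.asarray(bps), np.asarray(cms))


# ---------------------------------------------------------------------------
# Writers


def _fmt(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        if value != value:  # NaN
            return "nan"
        return f"{value:.6g}"
    if value is None:
        return "NA"
    return str(value)


def write_results_table(records: Iterable, path: str) -> None:
    """Write a homogeneous collection of result dataclasses as TSV.

    Column order follows the dataclass field order; floats are rendered at
    6 significant digits.  Mixed record types are rejected.
    """
    records = list(records)
    with open(path, "w") as fh:
        if not records:
            fh.write("\n")
            return
        cls = type(records[0])
        if not dataclasses.is_dataclass(cls):
            raise TypeError("records must be dataclasses")
        if any(type(r) is not cls for r in records):
            raise TypeError("mixed record types in one table")
        names = [f.name for f in dataclasses.fields(cls)]
        fh.write("\t".join(names) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, n)) for n in names) + "\n")


def read_results_table(path: str):
    """Read a TSV written by :func:`write_results_table` into a DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def write_phased_vcf(panel: HaplotypePanel, path: str, ancestral_tag: str = "AA") -> None:
    """Emit a panel as a minimal phased VCF (REF=A ancestral, ALT=G derived)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={ancestral_tag},Number=1,Type=String,'
            'Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        a = panel.alleles
        for j in range(panel.n_markers):
            gts = "\t".join(
                f"{a[2 * i, j]}|{a[2 * i + 1, j]}" for i in range(panel.n_individuals)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{panel.marker_ids[j]}\t"
                f"A\tG\t.\tPASS\t{ancestral_tag}=A\tGT\t{gts}\n"
            )


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    """Write a two-column ``bp cM`` map."""
    with open(path, "w") as fh:
        for bp, cm in zip(gmap.bp, gmap.cm):
            fh.write(f"{bp:.0f}\t{cm:.8g}\n")
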