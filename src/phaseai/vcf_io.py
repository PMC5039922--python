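"""Input/output: sample VCF with allelic depths, phased haplotypes, reports.

Coordinate conventions: VCF positions are 1-based; BED output is 0-based
half-open.  Only biallelic SNVs with heterozygous genotypes are retained;
multi-allelic records and indels are excluded because the RAF model is
defined on a single ref/alt depth pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "HetSite",
    "PhasedPair",
    "MarkerTable",
    "read_sample_vcf",
    "read_phased_haplotypes",
    "write_site_report",
    "read_site_report",
    "write_events_bed",
]


@dataclass(frozen=True)
class HetSite:
    """One heterozygous marker with its reference/alternate read depths."""

    chrom: str
    pos: int  # 1-based
    ref_depth: int
    alt_depth: int

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def raf(self) -> float:
        """Reference-allele frequency; only defined for depth > 0."""
        total = self.depth
        if total == 0:
            return float("nan")
        return self.ref_depth / total


@dataclass(frozen=True)
class PhasedPair:
    """Germline haplotype alleles at a het site: 0 = REF, 1 = ALT."""

    hap1_allele: int
    hap2_allele: int

    def __post_init__(self) -> None:
        if {self.hap1_allele, self.hap2_allele} != {0, 1}:
            raise ValueError(
                "a heterozygous phased pair must carry one REF and one ALT allele"
            )


class MarkerTable:
    """Ordered per-chromosome collection of het sites joined with phased pairs.

    Columns are parallel numpy arrays; positions are strictly increasing
    within each chromosome and chromosomes appear in a single contiguous
    block each.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref_depth: np.ndarray,
        alt_depth: np.ndarray,
        hap1: np.ndarray,
        hap2: np.ndarray,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref_depth = np.asarray(ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(alt_depth, dtype=np.int64)
        self.hap1 = np.asarray(hap1, dtype=np.int8)
        self.hap2 = np.asarray(hap2, dtype=np.int8)
        n = len(self.pos)
        for arr in (self.chrom, self.ref_depth, self.alt_depth, self.hap1, self.hap2):
            if len(arr) != n:
                raise ValueError("MarkerTable columns must have equal length")
        if np.any(self.hap1 == self.hap2):
            raise ValueError("het sites require hap1_allele != hap2_allele")
        self._check_sorted()

    def _check_sorted(self) -> None:
        codes = self.chrom_codes
        if len(codes) > 1:
            same = codes[1:] == codes[:-1]
            if np.any(same & (self.pos[1:] <= self.pos[:-1])):
                raise ValueError("positions must be strictly increasing per chromosome")
            # chromosomes must form contiguous blocks
            seen: set = set()
            prev = None
            for c in self.chrom:
                if c != prev:
                    if c in seen:
                        raise ValueError(f"chromosome {c} appears in two blocks")
                    seen.add(c)
                    prev = c

    @property
    def depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    @property
    def raf(self) -> np.ndarray:
        total = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.ref_depth / total, np.nan)

    @property
    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome labels in order of first appearance."""
        codes = np.empty(len(self.chrom), dtype=np.int64)
        mapping: dict = {}
        for i, c in enumerate(self.chrom):
            codes[i] = mapping.setdefault(c, len(mapping))
        return codes

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_blocks(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) blocks in table order."""
        blocks: list[tuple[str, slice]] = []
        if len(self) == 0:
            return blocks
        start = 0
        for i in range(1, len(self)):
            if self.chrom[i] != self.chrom[start]:
                blocks.append((self.chrom[start], slice(start, i)))
                start = i
        blocks.append((self.chrom[start], slice(start, len(self))))
        return blocks

    def subset(self, mask: np.ndarray) -> "MarkerTable":
        mask = np.asarray(mask)
        return MarkerTable(
            self.chrom[mask],
            self.pos[mask],
            self.ref_depth[mask],
            self.alt_depth[mask],
            self.hap1[mask],
            self.hap2[mask],
        )

    def __len__(self) -> int:
        return len(self.pos)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerTable):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.ref_depth == other.ref_depth))
            and bool(np.all(self.alt_depth == other.alt_depth))
            and bool(np.all(self.hap1 == other.hap1))
            and bool(np.all(self.hap2 == other.hap2))
        )


def _natural_key(chrom: str) -> tuple:
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _header_has_format(vcf: VCF, field: str) -> bool:
    for h in vcf.header_iter():
        try:
            info = h.info()
        except Exception:  # pragma: no cover - defensive
            continue
        if info.get("HeaderType") == "FORMAT" and info.get("ID") == field:
            return True
    return False


def _sample_index(vcf: VCF, path: str, sample_name: str | None) -> int:
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF carries no sample columns")
    if sample_name is None:
        if len(samples) > 1:
            raise ValueError(
                f"{path}: multi-sample VCF ({len(samples)} samples); "
                "sample_name must be given"
            )
        return 0
    if sample_name not in samples:
        raise ValueError(f"{path}: unknown sample {sample_name!r}")
    return samples.index(sample_name)


def read_sample_vcf(
    path: str | Path,
    min_depth: int = 10,
    sample_name: str | None = None,
) -> list[HetSite]:
    """Read heterozygous biallelic SNVs with AD depths from a VCF.

    Returns sites sorted by (chromosome, position) with total AD depth of at
    least ``min_depth``.  Chromosome order follows the VCF header contigs
    when present, else a numeric-aware lexicographic sort.  Duplicate
    positions keep the first record; malformed AD entries (fewer than two
    values) are skipped and tallied in a log line.
    """
    path = str(path)
    vcf = VCF(path)
    if not _header_has_format(vcf, "AD"):
        raise ValueError(f"{path}: required FORMAT field 'AD' is missing")
    si = _sample_index(vcf, path, sample_name)

    contig_rank = {name: i for i, name in enumerate(vcf.seqnames)}
    sites: list[HetSite] = []
    seen: set[tuple[str, int]] = set()
    n_dup = 0
    n_malformed = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        alleles = v.genotypes[si][:-1]
        if sorted(alleles) != [0, 1]:
            continue
        ad = v.format("AD")
        if ad is None:
            n_malformed += 1
            continue
        row = ad[si]
        if len(row) < 2 or row[0] < 0 or row[1] < 0:
            n_malformed += 1
            continue
        ref_d, alt_d = int(row[0]), int(row[1])
        if ref_d + alt_d < min_depth:
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        sites.append(HetSite(v.CHROM, v.POS, ref_d, alt_d))
    vcf.close()

    if contig_rank:
        sites.sort(key=lambda s: (contig_rank.get(s.chrom, len(contig_rank)), s.pos))
    else:
        sites.sort(key=lambda s: (_natural_key(s.chrom), s.pos))
    if n_dup:
        logger.warning("read_sample_vcf: dropped %d duplicate positions", n_dup)
    if n_malformed:
        logger.warning("read_sample_vcf: skipped %d sites with malformed AD", n_malformed)
    logger.info("read_sample_vcf: %d het sites retained from %s", len(sites), path)
    return sites


def read_phased_haplotypes(
    path: str | Path,
    sites: Sequence[HetSite],
    sample_name: str | None = None,
) -> MarkerTable:
    """Inner-join het sites with phased genotypes from a phased VCF.

    Only phased ('|') heterozygous genotypes are used; sites without a
    phased record are dropped with a logged count.  Raises if no site
    overlaps.
    """
    path = str(path)
    vcf = VCF(path)
    si = _sample_index(vcf, path, sample_name)
    phase: dict[tuple[str, int], tuple[int, int]] = {}
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        g = v.genotypes[si]
        a, b, phased = g[0], g[1], g[-1]
        if not phased or sorted((a, b)) != [0, 1]:
            continue
        phase.setdefault((v.CHROM, v.POS), (a, b))
    vcf.close()

    chrom, pos, rd, ad_, h1, h2 = [], [], [], [], [], []
    n_dropped = 0
    for s in sites:
        pair = phase.get((s.chrom, s.pos))
        if pair is None:
            n_dropped += 1
            continue
        chrom.append(s.chrom)
        pos.append(s.pos)
        rd.append(s.ref_depth)
        ad_.append(s.alt_depth)
        h1.append(pair[0])
        h2.append(pair[1])
    if not pos:
        raise ValueError(
            f"{path}: no overlap between sample het sites and phased haplotypes"
        )
    if n_dropped:
        logger.info("read_phased_haplotypes: dropped %d sites without phase", n_dropped)
    logger.info("read_phased_haplotypes: %d markers joined", len(pos))
    return MarkerTable(
        np.array(chrom, dtype=object),
        np.array(pos),
        np.array(rd),
        np.array(ad_),
        np.array(h1),
        np.array(h2),
    )


def write_site_report(
    table: MarkerTable,
    z: np.ndarray,
    posteriors: np.ndarray,
    path: str | Path,
    threshold: float | None = None,
) -> None:
    """Write the per-marker TSV report (one row per marker, header included).

    ``z`` is the concordance-indicator track (1.0 / 0.0 / NaN) and
    ``posteriors`` the per-marker AI posterior.  ``threshold`` is only used
    to label the excess allele; when omitted the label is derived from z.
    """
    z = np.asarray(z, dtype=float)
    posteriors = np.asarray(posteriors, dtype=float)
    if len(table) != len(z) or len(table) != len(posteriors):
        raise ValueError(
            f"length mismatch: {len(table)} markers, {len(z)} indicators, "
            f"{len(posteriors)} posteriors"
        )
    raf = table.raf
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref_depth\talt_depth\traf\texcess_allele\t"
            "concordance_indicator\tposterior_AI\n"
        )
        for i in range(len(table)):
            if np.isnan(z[i]):
                excess = "NA"
                zi = "NA"
            else:
                zi = str(int(z[i]))
                if threshold is not None:
                    excess = "REF" if raf[i] > threshold else "ALT"
                else:
                    hap = table.hap1[i] if z[i] == 1 else table.hap2[i]
                    excess = "REF" if hap == 0 else "ALT"
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref_depth[i]}\t"
                f"{table.alt_depth[i]}\t{raf[i]:.6f}\t{excess}\t{zi}\t"
                f"{posteriors[i]:.8f}\n"
            )


def read_site_report(path: str | Path):
    """Read a site report written by :func:`write_site_report` (round-trip)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_events_bed(events: Iterable, path: str | Path) -> None:
    """Write called events as BED5+2 (0-based half-open intervals).

    Columns: chrom, start, end, name, score (1000 * mean posterior,
    rounded), n_markers, mean |RAF - 0.5|.  An empty event list yields an
    empty file.
    """
    with open(path, "w") as fh:
        for i, ev in enumerate(events):
            score = int(round(1000 * ev.mean_posterior))
            fh.write(
                f"{ev.chrom}\t{ev.start_pos - 1}\t{ev.end_pos}\tAI_{i + 1}\t"
                f"{score}\t{ev.n_markers}\t{ev.mean_raf_dev:.6f}\n"
            )
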