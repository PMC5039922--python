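"""RAF threshold, frequency-based phasing and phase concordance.

The over-represented ("excess") allele at each marker is the one whose read
frequency exceeds a genome-wide threshold (default: median RAF).  The
concordance indicator z marks whether that excess allele sits on haplotype
1 of the statistical phase estimate; under no imbalance z is a fair coin,
under imbalance z tracks one haplotype, up to switch errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from phaseai.vcf_io import HetSite, MarkerTable

__all__ = [
    "compute_threshold",
    "frequency_based_phase",
    "phase_concordance",
    "windowed_concordance_scan",
    "WindowStat",
]

MISSING = np.nan


def _raf_array(sites) -> np.ndarray:
    if isinstance(sites, MarkerTable):
        return sites.raf
    return np.array([s.raf for s in sites], dtype=float)


def compute_threshold(
    sites: MarkerTable | Sequence[HetSite],
    override: float | None = None,
) -> float:
    """Genome-wide RAF cut point: the median RAF unless overridden.

    The median of an even count is the mean of the two central values
    (numpy convention).  Raises on empty input.
    """
    if override is not None:
        return float(override)
    raf = _raf_array(sites)
    raf = raf[~np.isnan(raf)]
    if raf.size == 0:
        raise ValueError("cannot compute a RAF threshold from zero sites")
    return float(np.median(raf))


def frequency_based_phase(table: MarkerTable, threshold: float) -> np.ndarray:
    """Per-marker indicator that the excess allele lies on haplotype 1.

    Excess allele is REF when raf > threshold, ALT otherwise; z = 1 iff the
    excess allele equals hap1_allele.  A marker with raf == threshold
    exactly, or zero depth, is missing (NaN) — a deterministic tie rule.
    """
    raf = table.raf
    z = np.full(len(table), MISSING, dtype=float)
    defined = ~np.isnan(raf) & (raf != threshold)
    excess_allele = np.where(raf > threshold, 0, 1)  # 0=REF, 1=ALT
    z[defined] = (excess_allele[defined] == table.hap1[defined]).astype(float)
    return z


def phase_concordance(
    z: np.ndarray,
    window: tuple[int, int] | None = None,
) -> float:
    """Fraction of adjacent non-missing indicator pairs that agree.

    ``window`` is an inclusive (start, stop) marker index range; missing
    markers are skipped, joining their neighbours into a pair.  Adjacent
    pairs (rather than all pairs) make the statistic robust to a single
    long-range switch error, which corrupts only one pair.  Returns NaN
    when fewer than two non-missing markers are available (undefined,
    distinct from 0).
    """
    z = np.asarray(z, dtype=float)
    if window is not None:
        lo, hi = window
        z = z[lo : hi + 1]
    obs = z[~np.isnan(z)]
    if obs.size < 2:
        return float("nan")
    agree = obs[1:] == obs[:-1]
    return float(np.mean(agree))


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int
    concordance: float  # NaN when < 2 non-missing markers


def windowed_concordance_scan(
    table: MarkerTable,
    z: np.ndarray,
    window_size: int,
    step: int | None = None,
) -> list[WindowStat]:
    """Sliding-window phase concordance per chromosome.

    Windows are ``window_size`` markers wide and advance by ``step``
    (default: window_size).  A chromosome shorter than the window yields a
    single truncated window; pairing never crosses chromosome boundaries.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if step is None:
        step = window_size
    if step < 1:
        raise ValueError("step must be >= 1")
    z = np.asarray(z, dtype=float)
    out: list[WindowStat] = []
    for chrom, block in table.chrom_blocks():
        pos = table.pos[block]
        zb = z[block]
        n = len(pos)
        starts = range(0, max(n - window_size, 0) + 1, step) if n > window_size else [0]
        for lo in starts:
            hi = min(lo + window_size, n)
            conc = phase_concordance(zb[lo:hi])
            out.append(
                WindowStat(
                    chrom=chrom,
                    start_pos=int(pos[lo]),
                    end_pos=int(pos[hi - 1]),
                    n_markers=hi - lo,
                    concordance=conc,
                )
            )
    return out


def write_scan_tsv(stats: list[WindowStat], path) -> None:
    """Dump a windowed scan as TSV (chrom, span, n_markers, concordance)."""
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start\twindow_end\tn_markers\tconcordance\n")
        for w in stats:
            conc = "NA" if np.isnan(w.concordance) else f"{w.concordance:.6f}"
            fh.write(f"{w.chrom}\t{w.start_pos}\t{w.end_pos}\t{w.n_markers}\t{conc}\n")
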