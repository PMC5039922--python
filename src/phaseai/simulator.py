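"""Synthetic allele-depth data with configurable imbalance events.

Generates marker positions (exome-like clustered islands or genome-like
uniform), germline haplotypes, read depths, allele counts drawn around the
mixture-model expected RAF for each event type, and statistically-phased
haplotype estimates corrupted by a persistent switch process.  Emits plain
VCF v4.2 text so the full detection pipeline can be exercised end to end.

Aberrant-fraction mixing is analytic (expected allele frequency), not
read-level: the allele-count distribution is identical and no alignment
machinery is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from phaseai.ai_hmm import HMMParams, detect_track
from phaseai.vcf_io import MarkerTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimEvent",
    "SimConfig",
    "SimTruth",
    "SimData",
    "expected_raf",
    "simulate_dataset",
    "purity_grid_experiment",
    "PowerResult",
]

EVENT_KINDS = ("cnloh", "deletion", "amplification")


@dataclass(frozen=True)
class SimEvent:
    """A ground-truth imbalance event on the simulated chromosome."""

    start: int  # 1-based inclusive bp
    end: int
    kind: str = "cnloh"
    fraction: float = 0.2  # aberrant-cell fraction f

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0,1], got {self.fraction}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid event span")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimConfig:
    """Simulation design. Use :meth:`wes` / :meth:`wgs` for the presets."""

    region_length: int = 100_000_000
    chrom: str = "1"
    marker_layout: str = "clustered"  # "clustered" (exome-like) or "uniform"
    het_spacing: float = 3000.0  # mean bp per het site
    island_width: int = 150  # exon-like island width for clustered layout
    mean_depth: float = 80.0
    depth_model: str = "poisson"  # "poisson" or "nbinom"
    depth_dispersion: float = 10.0  # nbinom size parameter
    rho: float = 0.0  # beta-binomial overdispersion; 0 = binomial
    switch_error_rate: float = 0.02  # per adjacent marker pair
    events: tuple[SimEvent, ...] = ()
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self) -> None:
        if self.marker_layout not in ("clustered", "uniform"):
            raise ValueError(f"unknown marker_layout {self.marker_layout!r}")
        if self.depth_model not in ("poisson", "nbinom"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0,1)")
        if not 0.0 <= self.switch_error_rate <= 1.0:
            raise ValueError("switch_error_rate must be in [0,1]")
        spans = sorted((e.start, e.end) for e in self.events)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("events must be non-overlapping")
        for e in self.events:
            if e.end > self.region_length:
                raise ValueError(
                    f"event [{e.start},{e.end}] exceeds region of {self.region_length} bp"
                )
        object.__setattr__(self, "events", tuple(self.events))

    @classmethod
    def wes(cls, **kw) -> "SimConfig":
        """Exome-like: sparse clustered hets (~1/3 kb), deep coverage (80x)."""
        base = dict(
            marker_layout="clustered", het_spacing=3000.0, mean_depth=80.0
        )
        base.update(kw)
        return cls(**base)

    @classmethod
    def wgs(cls, **kw) -> "SimConfig":
        """Genome-like: dense uniform hets (~1/1.5 kb), 30x coverage."""
        base = dict(
            marker_layout="uniform", het_spacing=1500.0, mean_depth=30.0
        )
        base.update(kw)
        return cls(**base)


def expected_raf(state_type: str | None, f: float, ref_on_favored_hap: bool) -> float:
    """Expected REF-allele frequency under the mixture model.

    The favored-haplotype allele frequency is (1+f)/2 for cn-LOH,
    1/(2-f) for deletion (the retained haplotype is favored) and
    (1+f)/(2+f) for amplification; the balanced state gives 0.5.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0,1]")
    if state_type is None or state_type == "normal":
        p_fav = 0.5
    elif state_type == "cnloh":
        p_fav = (1.0 + f) / 2.0
    elif state_type == "deletion":
        p_fav = 1.0 / (2.0 - f)
    elif state_type == "amplification":
        p_fav = (1.0 + f) / (2.0 + f)
    else:
        raise ValueError(f"unknown state_type {state_type!r}")
    return p_fav if ref_on_favored_hap else 1.0 - p_fav


@dataclass
class SimTruth:
    """Ground truth aligned with the simulated marker table."""

    state_idx: np.ndarray  # event index per marker, -1 for balanced
    expected_raf: np.ndarray  # per marker
    true_hap1: np.ndarray  # germline hap1 allele (0/1) per marker
    events: tuple[SimEvent, ...]
    favored_hap: np.ndarray  # per event: 1 or 2

    def subset(self, mask: np.ndarray) -> "SimTruth":
        return SimTruth(
            state_idx=self.state_idx[mask],
            expected_raf=self.expected_raf[mask],
            true_hap1=self.true_hap1[mask],
            events=self.events,
            favored_hap=self.favored_hap,
        )


@dataclass
class SimData:
    """A simulated dataset: observable marker table plus hidden truth."""

    config: SimConfig
    table: MarkerTable  # carries the *estimated* (switch-corrupted) haplotypes
    truth: SimTruth

    def subset(self, mask: np.ndarray) -> "SimData":
        return SimData(self.config, self.table.subset(mask), self.truth.subset(mask))

    def filter_depth(self, min_depth: int) -> "SimData":
        return self.subset(self.table.depth >= min_depth)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write sample.vcf (GT+AD), phased.vcf and truth.tsv; returns paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sample_vcf": out_dir / "sample.vcf",
            "phased_vcf": out_dir / "phased.vcf",
            "truth_tsv": out_dir / "truth.tsv",
        }
        t = self.table
        _write_vcf(
            paths["sample_vcf"],
            self.config,
            t,
            phased=False,
        )
        _write_vcf(
            paths["phased_vcf"],
            self.config,
            t,
            phased=True,
        )
        tr = self.truth
        with open(paths["truth_tsv"], "w") as fh:
            fh.write("chrom\tpos\tstate_idx\texpected_raf\ttrue_hap1\n")
            for i in range(len(t)):
                fh.write(
                    f"{t.chrom[i]}\t{t.pos[i]}\t{tr.state_idx[i]}\t"
                    f"{tr.expected_raf[i]:.6f}\t{tr.true_hap1[i]}\n"
                )
        return paths


def _draw_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    L = config.region_length
    if config.marker_layout == "uniform":
        n = rng.poisson(L / config.het_spacing)
        pos = np.unique(rng.integers(1, L + 1, size=n))
    else:
        # exon-like islands: one island per het_spacing stride, each carrying
        # a Poisson(1) number of markers within island_width bp
        stride = int(config.het_spacing)
        starts = np.arange(1, L - config.island_width, stride)
        counts = rng.poisson(1.0, size=len(starts))
        offsets = [
            s + rng.integers(0, config.island_width, size=c)
            for s, c in zip(starts, counts)
            if c > 0
        ]
        pos = (
            np.unique(np.concatenate(offsets))
            if offsets
            else np.empty(0, dtype=np.int64)
        )
    return pos.astype(np.int64)


def _draw_depths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.depth_model == "poisson":
        depth = rng.poisson(config.mean_depth, size=n)
    else:
        k = config.depth_dispersion
        m = config.mean_depth
        depth = rng.negative_binomial(k, k / (k + m), size=n)
    return np.maximum(depth, 1)


def _draw_ref_counts(
    p: np.ndarray, depth: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    if rho == 0.0:
        return rng.binomial(depth, p)
    # beta-binomial: p_i ~ Beta(a,b) with mean p and overdispersion rho
    scale = (1.0 - rho) / rho
    interior = (p > 0.0) & (p < 1.0)
    pi = p.astype(float).copy()
    if interior.any():
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        pi[interior] = rng.beta(a, b)
    return rng.binomial(depth, pi)


def simulate_dataset(config: SimConfig) -> SimData:
    """Generate one dataset; fully deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pos = _draw_positions(config, rng)
    n = len(pos)
    if n == 0:
        raise ValueError("simulation produced zero markers; enlarge the region")

    hap1 = rng.integers(0, 2, size=n).astype(np.int8)  # fair coin per site
    hap2 = (1 - hap1).astype(np.int8)

    state_idx = np.full(n, -1, dtype=np.int64)
    favored = np.empty(len(config.events), dtype=np.int64)
    exp_raf = np.full(n, 0.5)
    for ei, ev in enumerate(config.events):
        favored[ei] = rng.integers(1, 3)
        in_ev = (pos >= ev.start) & (pos <= ev.end)
        state_idx[in_ev] = ei
        fav_allele = hap1[in_ev] if favored[ei] == 1 else hap2[in_ev]
        p_fav = expected_raf(ev.kind, ev.fraction, True)
        exp_raf[in_ev] = np.where(fav_allele == 0, p_fav, 1.0 - p_fav)

    depth = _draw_depths(config, n, rng)
    ref = _draw_ref_counts(exp_raf, depth, config.rho, rng)
    alt = depth - ref

    # persistent switch process corrupting the estimated haplotypes
    if n > 1:
        flips = rng.random(n - 1) < config.switch_error_rate
        orient = np.concatenate([[0], np.cumsum(flips) % 2])
    else:
        orient = np.zeros(n, dtype=np.int64)
    est_hap1 = np.where(orient == 0, hap1, hap2).astype(np.int8)
    est_hap2 = (1 - est_hap1).astype(np.int8)

    table = MarkerTable(
        np.full(n, config.chrom, dtype=object), pos, ref, alt, est_hap1, est_hap2
    )
    truth = SimTruth(
        state_idx=state_idx,
        expected_raf=exp_raf,
        true_hap1=hap1,
        events=config.events,
        favored_hap=favored,
    )
    return SimData(config=config, table=table, truth=truth)


def _write_vcf(path: Path, config: SimConfig, t: MarkerTable, phased: bool) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={config.chrom},length={config.region_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not phased:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref,alt)">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSIM\n")
        for i in range(len(t)):
            if phased:
                gt = f"{t.hap1[i]}|{t.hap2[i]}"
                fh.write(
                    f"{t.chrom[i]}\t{t.pos[i]}\t.\tA\tC\t.\tPASS\t.\tGT\t{gt}\n"
                )
            else:
                fh.write(
                    f"{t.chrom[i]}\t{t.pos[i]}\t.\tA\tC\t.\tPASS\t.\tGT:AD\t"
                    f"0/1:{t.ref_depth[i]},{t.alt_depth[i]}\n"
                )


# ---------------------------------------------------------------------------
# power / sensitivity grid


@dataclass
class PowerResult:
    """Per-replicate detection outcomes over a fraction grid."""

    table: pd.DataFrame  # fraction, replicate, detected, n_false_events, ...

    def detection_rates(self) -> pd.DataFrame:
        g = self.table.groupby("fraction", sort=True)
        return pd.DataFrame(
            {
                "detection_rate": g["detected"].mean(),
                "mean_false_events": g["n_false_events"].mean(),
                "n_replicates": g["detected"].size(),
            }
        ).reset_index()

    def smallest_fraction(self, min_rate: float) -> float | None:
        """Smallest grid fraction whose detection rate reaches ``min_rate``."""
        rates = self.detection_rates()
        hit = rates[rates["detection_rate"] >= min_rate]
        if hit.empty:
            return None
        return float(hit["fraction"].iloc[0])


# grid of aberrant-cell fractions used by the sensitivity experiments
DEFAULT_FRACTION_GRID = (0.04, 0.08, 0.12, 0.16, 0.20, 0.28, 0.40, 0.56, 0.80)


def detection_limit_experiment(
    preset: str = "wes",
    replicates: int = 20,
    base_seed: int = 0,
    fractions: Sequence[float] = DEFAULT_FRACTION_GRID,
    region_length: int = 100_000_000,
    event_span: tuple[int, int] = (45_000_001, 55_000_000),
    **grid_kwargs,
) -> "PowerResult":
    """Sensitivity grid for one 10 Mb cn-LOH event on a 100 Mb chromosome.

    ``preset`` selects the exome-like ("wes", 80x, ~1 het/3 kb, event prior
    length 200 markers) or genome-like ("wgs", 30x, ~1 het/1.5 kb, 2000
    markers) design; everything else is pipeline defaults.
    """
    if preset == "wes":
        cfg = SimConfig.wes
        mean_event_markers = 200.0
    elif preset == "wgs":
        cfg = SimConfig.wgs
        mean_event_markers = 2000.0
    else:
        raise ValueError(f"unknown preset {preset!r}")
    base = cfg(
        region_length=region_length,
        events=(SimEvent(event_span[0], event_span[1], "cnloh", 0.2),),
    )
    params = HMMParams(mean_event_markers=mean_event_markers)
    return purity_grid_experiment(
        base,
        list(fractions),
        replicates,
        hmm_params=params,
        base_seed=base_seed,
        **grid_kwargs,
    )


def _event_detected(
    true_event: SimEvent,
    called,
    posterior_cut: float,
    overlap_frac: float,
) -> bool:
    span = true_event.length
    for ev in called:
        ov = min(ev.end_pos, true_event.end) - max(ev.start_pos, true_event.start) + 1
        if ov >= overlap_frac * span and ev.mean_posterior >= posterior_cut:
            return True
    return False


def purity_grid_experiment(
    base_config: SimConfig,
    fractions: Sequence[float],
    replicates: int,
    hmm_params: HMMParams | None = None,
    min_depth: int = 10,
    posterior_cut: float = 0.90,
    min_event_markers: int = 10,
    overlap_frac: float = 0.5,
    em: bool = True,
    base_seed: int = 0,
) -> PowerResult:
    """Detection power across a grid of aberrant-cell fractions.

    Each (fraction, replicate) pair re-simulates the ``base_config`` design
    with all events set to that fraction, runs the full detection pipeline
    with default parameters, and records whether each true event is
    recovered (a called segment covering >= ``overlap_frac`` of the true
    span with mean posterior >= ``posterior_cut``).  Called events touching
    no true event are counted as false events.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if not base_config.events:
        raise ValueError("base_config must define at least one event template")
    rows = []
    for fi, f in enumerate(fractions):
        events = tuple(replace(ev, fraction=f) for ev in base_config.events)
        for rep in range(replicates):
            seed = np.random.SeedSequence([base_seed, fi, rep])
            cfg = replace(base_config, events=events, seed=seed)
            sim = simulate_dataset(cfg).filter_depth(min_depth)
            res = detect_track(
                sim.table,
                params=hmm_params,
                em=em,
                posterior_cut=posterior_cut,
                min_event_markers=min_event_markers,
            )
            n_false = sum(
                1
                for ce in res.events
                if not any(
                    min(ce.end_pos, te.end) >= max(ce.start_pos, te.start)
                    for te in events
                )
            )
            for ei, te in enumerate(events):
                detected = _event_detected(te, res.events, posterior_cut, overlap_frac)
                rows.append(
                    dict(
                        fraction=f,
                        replicate=rep,
                        event=ei,
                        detected=bool(detected),
                        n_false_events=n_false,
                        n_markers=len(sim.table),
                        gamma=res.gamma,
                        n_called=len(res.events),
                    )
                )
        logger.info(
            "purity_grid: fraction=%.3f detection=%.2f",
            f,
            np.mean([r["detected"] for r in rows if r["fraction"] == f]),
        )
    return PowerResult(table=pd.DataFrame(rows))
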