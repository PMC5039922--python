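"""Three-state HMM over concordance indicators: AI posteriors and events.

States: N (balanced) and two imbalance orientations A1/A2, one per favored
haplotype.  The two orientations absorb switch errors in the statistical
phase estimate: a switch flips which haplotype the excess allele tracks,
moving the chain between A1 and A2 without leaving the imbalanced regime.

Transitions are homogeneous per marker index (not genomic distance); the
N->AI entry rate is solved so the stationary AI occupancy equals the
``prevalence`` prior, and the AI->N exit rate is the reciprocal of the mean
event length in markers.  Emissions are Bernoulli on the indicator with a
single genome-wide parameter gamma, optionally re-estimated by EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from phaseai import raf_model
from phaseai.vcf_io import MarkerTable

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "Posteriors",
    "AIEvent",
    "build_transition_matrix",
    "stationary_distribution",
    "emission_prob",
    "emission_matrix",
    "forward_backward",
    "viterbi_segments",
    "call_events",
    "estimate_gamma_em",
    "estimate_fraction",
    "simulate_hmm_track",
    "detect_track",
    "DetectResult",
]

STATE_N, STATE_A1, STATE_A2 = 0, 1, 2
_CODE_MISSING = 2  # observation codes: 0, 1, missing


@dataclass(frozen=True)
class HMMParams:
    """Chain and emission parameters.

    prevalence: prior stationary fraction of markers inside AI.
    mean_event_markers: expected AI event length, in markers.
    gamma: P(indicator matches the favored haplotype | AI state).
    switch_rate: per-step A1<->A2 probability inside AI, absorbing
        statistical-phasing switch errors.
    """

    prevalence: float = 0.05
    mean_event_markers: float = 200.0
    gamma: float = 0.65
    switch_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.mean_event_markers <= 1.0:
            raise ValueError("mean_event_markers must exceed 1")
        if not 0.5 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0.5,1), got {self.gamma}")
        if not 0.0 <= self.switch_rate < 0.5:
            raise ValueError(f"switch_rate must be in [0,0.5), got {self.switch_rate}")


def build_transition_matrix(params: HMMParams) -> np.ndarray:
    """3x3 stochastic matrix over (N, A1, A2).

    Exit mass from each AI state is q = 1/mean_event_markers; the entry rate
    r = q * prevalence / (1 - prevalence) makes the stationary distribution
    (1-prevalence, prevalence/2, prevalence/2) exact.
    """
    q = 1.0 / params.mean_event_markers
    r = q * params.prevalence / (1.0 - params.prevalence)
    if r > 1.0:
        raise ValueError(
            "no valid N->AI entry rate: prevalence "
            f"{params.prevalence} with mean_event_markers "
            f"{params.mean_event_markers} requires rate {r:.3g} > 1"
        )
    s = params.switch_rate * (1.0 - q)
    stay = (1.0 - q) * (1.0 - params.switch_rate)
    T = np.array(
        [
            [1.0 - r, r / 2.0, r / 2.0],
            [q, stay, s],
            [q, s, stay],
        ]
    )
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
    return T


def stationary_distribution(params: HMMParams) -> np.ndarray:
    p = params.prevalence
    return np.array([1.0 - p, p / 2.0, p / 2.0])


def emission_prob(state: int, z: float | None, gamma: float) -> float:
    """P(indicator | state). Missing indicators are uninformative (1.0)."""
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return 1.0
    z = int(z)
    if state == STATE_N:
        return 0.5
    if state == STATE_A1:
        return gamma if z == 1 else 1.0 - gamma
    if state == STATE_A2:
        return gamma if z == 0 else 1.0 - gamma
    raise ValueError(f"unknown state {state}")


def emission_matrix(gamma: float) -> np.ndarray:
    """Rows: states (N, A1, A2); columns: observation codes (0, 1, missing)."""
    g = gamma
    return np.array(
        [
            [0.5, 0.5, 1.0],
            [1.0 - g, g, 1.0],
            [g, 1.0 - g, 1.0],
        ]
    )


def encode_track(z: np.ndarray) -> np.ndarray:
    """Map an indicator track (0.0/1.0/NaN) to int8 codes (0/1/2)."""
    z = np.asarray(z, dtype=float)
    codes = np.full(len(z), _CODE_MISSING, dtype=np.int8)
    codes[z == 0.0] = 0
    codes[z == 1.0] = 1
    return codes


@njit(cache=True)
def _forward_backward_core(codes, T, pi, E):  # pragma: no cover - jitted
    n = codes.shape[0]
    ns = 3
    alpha = np.empty((n, ns))
    scale = np.empty(n)
    tot = 0.0
    for s in range(ns):
        alpha[0, s] = pi[s] * E[s, codes[0]]
        tot += alpha[0, s]
    scale[0] = tot
    for s in range(ns):
        alpha[0, s] /= tot
    for t in range(1, n):
        tot = 0.0
        for s in range(ns):
            a = 0.0
            for u in range(ns):
                a += alpha[t - 1, u] * T[u, s]
            a *= E[s, codes[t]]
            alpha[t, s] = a
            tot += a
        scale[t] = tot
        for s in range(ns):
            alpha[t, s] /= tot
    beta = np.empty((n, ns))
    for s in range(ns):
        beta[n - 1, s] = 1.0
    for t in range(n - 2, -1, -1):
        for s in range(ns):
            b = 0.0
            for u in range(ns):
                b += T[s, u] * E[u, codes[t + 1]] * beta[t + 1, u]
            beta[t, s] = b / scale[t + 1]
    post = np.empty((n, ns))
    for t in range(n):
        tot = 0.0
        for s in range(ns):
            post[t, s] = alpha[t, s] * beta[t, s]
            tot += post[t, s]
        for s in range(ns):
            post[t, s] /= tot
    ll = 0.0
    for t in range(n):
        ll += np.log(scale[t])
    return post, ll


@njit(cache=True)
def _viterbi_core(codes, logT, logpi, logE):  # pragma: no cover - jitted
    n = codes.shape[0]
    ns = 3
    delta = np.empty((n, ns))
    psi = np.empty((n, ns), dtype=np.int8)
    for s in range(ns):
        delta[0, s] = logpi[s] + logE[s, codes[0]]
        psi[0, s] = 0
    for t in range(1, n):
        for s in range(ns):
            best = delta[t - 1, 0] + logT[0, s]
            barg = 0
            for u in range(1, ns):
                v = delta[t - 1, u] + logT[u, s]
                if v > best:  # strict: ties resolve to the lowest index (N)
                    best = v
                    barg = u
            delta[t, s] = best + logE[s, codes[t]]
            psi[t, s] = barg
    path = np.empty(n, dtype=np.int8)
    best = delta[n - 1, 0]
    barg = 0
    for s in range(1, ns):
        if delta[n - 1, s] > best:
            best = delta[n - 1, s]
            barg = s
    path[n - 1] = barg
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _chrom_blocks(n: int, chrom_ids: np.ndarray | None) -> list[slice]:
    if chrom_ids is None:
        return [slice(0, n)]
    chrom_ids = np.asarray(chrom_ids)
    if len(chrom_ids) != n:
        raise ValueError("chrom_ids length mismatch")
    blocks = []
    start = 0
    for i in range(1, n):
        if chrom_ids[i] != chrom_ids[start]:
            blocks.append(slice(start, i))
            start = i
    blocks.append(slice(start, n))
    return blocks


@dataclass
class Posteriors:
    """Exact marginal state posteriors from forward-backward."""

    state_probs: np.ndarray  # (n, 3) over (N, A1, A2)
    loglik: float

    @property
    def p_ai(self) -> np.ndarray:
        return self.state_probs[:, STATE_A1] + self.state_probs[:, STATE_A2]


def forward_backward(
    z: np.ndarray,
    params: HMMParams,
    chrom_ids: np.ndarray | None = None,
) -> Posteriors:
    """Scaled forward-backward; chromosomes are independent chains, each
    initialized at the stationary distribution."""
    codes = encode_track(z)
    n = len(codes)
    if n == 0:
        raise ValueError("empty track")
    T = build_transition_matrix(params)
    pi = stationary_distribution(params)
    E = emission_matrix(params.gamma)
    post = np.empty((n, 3))
    ll = 0.0
    for block in _chrom_blocks(n, chrom_ids):
        p, l = _forward_backward_core(codes[block], T, pi, E)
        post[block] = p
        ll += l
    return Posteriors(state_probs=post, loglik=ll)


def viterbi_segments(
    z: np.ndarray,
    params: HMMParams,
    chrom_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Most probable state path (int8 over N=0, A1=1, A2=2); ties -> N."""
    codes = encode_track(z)
    n = len(codes)
    if n == 0:
        raise ValueError("empty track")
    T = build_transition_matrix(params)
    pi = stationary_distribution(params)
    E = emission_matrix(params.gamma)
    with np.errstate(divide="ignore"):
        logT, logpi, logE = np.log(T), np.log(pi), np.log(E)
    path = np.empty(n, dtype=np.int8)
    for block in _chrom_blocks(n, chrom_ids):
        path[block] = _viterbi_core(codes[block], logT, logpi, logE)
    return path


@dataclass(frozen=True)
class AIEvent:
    """A called genomic segment of allelic imbalance."""

    chrom: str
    start_pos: int  # 1-based inclusive, first marker
    end_pos: int  # 1-based inclusive, last marker
    n_markers: int
    mean_posterior: float
    mean_raf_dev: float  # mean |RAF - 0.5| over event markers
    est_fraction_cnloh: float

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must not exceed end_pos")


def estimate_fraction(mean_raf_dev: float, model: str = "cnloh") -> float:
    """Aberrant-cell fraction implied by a mean RAF deviation d = |RAF-0.5|.

    Inverts the mixture algebra of each event model: cn-LOH f = 2d,
    deletion f = 4d/(1+2d), amplification f = 4d/(1-2d) capped at 1.
    """
    d = float(mean_raf_dev)
    if d < 0:
        raise ValueError("mean_raf_dev must be non-negative")
    if model == "cnloh":
        f = 2.0 * d
    elif model == "deletion":
        f = 4.0 * d / (1.0 + 2.0 * d)
    elif model == "amplification":
        if d >= 0.5:
            logger.warning("amplification model undefined for d >= 0.5; capping at 1")
            return 1.0
        f = 4.0 * d / (1.0 - 2.0 * d)
        if f > 1.0:
            logger.warning("amplification fraction %.3f capped at 1", f)
            f = 1.0
    else:
        raise ValueError(f"unknown model {model!r}")
    return min(f, 1.0)


def call_events(
    posteriors: Posteriors | np.ndarray,
    table: MarkerTable,
    z: np.ndarray,
    posterior_cut: float = 0.90,
    min_event_markers: int = 10,
) -> list[AIEvent]:
    """Maximal runs of markers with p_ai >= posterior_cut.

    Runs are trimmed of missing-indicator flanks, then retained when at
    least ``min_event_markers`` long.  Runs separated by any sub-cut marker
    are never merged.
    """
    if not 0.0 < posterior_cut < 1.0:
        raise ValueError("posterior_cut must be in (0,1)")
    p_ai = posteriors.p_ai if isinstance(posteriors, Posteriors) else np.asarray(posteriors)
    if len(p_ai) != len(table):
        raise ValueError("posterior/table length mismatch")
    z = np.asarray(z, dtype=float)
    raf = table.raf
    events: list[AIEvent] = []
    for chrom, block in table.chrom_blocks():
        lo0 = block.start
        above = p_ai[block] >= posterior_cut
        n = len(above)
        i = 0
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            # trim missing-z flanks
            a, b = i + lo0, j + lo0
            while a <= b and np.isnan(z[a]):
                a += 1
            while b >= a and np.isnan(z[b]):
                b -= 1
            n_markers = b - a + 1
            if n_markers >= min_event_markers:
                mrd = float(np.nanmean(np.abs(raf[a : b + 1] - 0.5)))
                events.append(
                    AIEvent(
                        chrom=chrom,
                        start_pos=int(table.pos[a]),
                        end_pos=int(table.pos[b]),
                        n_markers=n_markers,
                        mean_posterior=float(np.mean(p_ai[a : b + 1])),
                        mean_raf_dev=mrd,
                        est_fraction_cnloh=estimate_fraction(mrd, "cnloh"),
                    )
                )
            i = j + 1
    return events


@dataclass
class EMResult:
    gamma: float
    loglik_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


_GAMMA_LO = 0.5 + 1e-6
_GAMMA_HI = 1.0 - 1e-6


def estimate_gamma_em(
    z: np.ndarray,
    params: HMMParams,
    chrom_ids: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> EMResult:
    """Baum-Welch re-estimation of gamma only (transitions held fixed).

    Stops when |change in gamma| < tol or max_iter is reached.  The
    observed-data log-likelihood is recorded each iteration and is
    guaranteed non-decreasing by the EM construction.  A fully missing
    track returns the input gamma with a warning.
    """
    z = np.asarray(z, dtype=float)
    obs = ~np.isnan(z)
    if not obs.any():
        logger.warning("estimate_gamma_em: all indicators missing; gamma unchanged")
        return EMResult(gamma=params.gamma)
    gamma = params.gamma
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = forward_backward(z, replace(params, gamma=gamma), chrom_ids)
        history.append(post.loglik)
        p_a1 = post.state_probs[obs, STATE_A1]
        p_a2 = post.state_probs[obs, STATE_A2]
        zo = z[obs]
        num = float(np.sum(p_a1 * (zo == 1.0)) + np.sum(p_a2 * (zo == 0.0)))
        den = float(np.sum(p_a1) + np.sum(p_a2))
        if den == 0.0:
            break
        new_gamma = min(max(num / den, _GAMMA_LO), _GAMMA_HI)
        delta = abs(new_gamma - gamma)
        gamma = new_gamma
        if delta < tol:
            converged = True
            break
    return EMResult(gamma=gamma, loglik_history=history, n_iter=it, converged=converged)


def simulate_hmm_track(
    params: HMMParams,
    n_markers: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (states, indicator track) from the model itself.

    Used for parameter-recovery checks; the chain starts at its stationary
    distribution.
    """
    T = build_transition_matrix(params)
    pi = stationary_distribution(params)
    E = emission_matrix(params.gamma)
    states = np.empty(n_markers, dtype=np.int8)
    states[0] = rng.choice(3, p=pi)
    u = rng.random(n_markers)
    for t in range(1, n_markers):
        states[t] = np.searchsorted(np.cumsum(T[states[t - 1]]), u[t])
    z = (rng.random(n_markers) < E[states, 1]).astype(float)
    if missing_rate > 0:
        z[rng.random(n_markers) < missing_rate] = np.nan
    return states, z


@dataclass
class DetectResult:
    threshold: float
    z: np.ndarray
    params: HMMParams
    gamma: float
    posteriors: Posteriors
    events: list[AIEvent]
    em: EMResult | None = None


def detect_track(
    table: MarkerTable,
    params: HMMParams | None = None,
    threshold_override: float | None = None,
    em: bool = True,
    em_max_iter: int = 50,
    em_tol: float = 1e-4,
    posterior_cut: float = 0.90,
    min_event_markers: int = 10,
) -> DetectResult:
    """Full statistical pipeline on a joined marker table.

    threshold -> frequency-based phasing -> (optional EM on gamma) ->
    forward-backward posteriors -> event calling.
    """
    if params is None:
        params = HMMParams()
    threshold = raf_model.compute_threshold(table, threshold_override)
    z = raf_model.frequency_based_phase(table, threshold)
    chrom_ids = table.chrom_codes
    em_result = None
    if em:
        em_result = estimate_gamma_em(
            z, params, chrom_ids, max_iter=em_max_iter, tol=em_tol
        )
        params = replace(params, gamma=em_result.gamma)
    post = forward_backward(z, params, chrom_ids)
    events = call_events(post, table, z, posterior_cut, min_event_markers)
    return DetectResult(
        threshold=threshold,
        z=z,
        params=params,
        gamma=params.gamma,
        posteriors=post,
        events=events,
        em=em_result,
    )
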