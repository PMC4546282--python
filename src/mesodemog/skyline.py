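"""Skyline reconstruction of Nef(t) from genealogies.

The estimator is the piecewise-constant coalescent skyline: conditional on a
genealogy (either the simulator's true tree or a UPGMA estimate from
HKY-corrected distances under a strict clock), the (k lineages, duration)
interval decomposition is the sufficient statistic. With k lineages in an
epoch of size N the log-likelihood contribution is -k(k-1)Δt/(2N), minus
ln N at each coalescence. A Metropolis-Hastings sampler with multiplicative
moves on Nef and integer moves on group boundaries yields the posterior; a
scale-invariant (log-uniform) prior applies to the first group's Nef and
each later group is exponentially smoothed around its predecessor. Classic
(deterministic, per-interval) skylines are provided as a cross-check.

Joint tree+parameter inference over tree space is deliberately out of scope;
the conditional-likelihood core is the defining computation and is validated
by parameter recovery against the simulator.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.spatial.distance import squareform

from ._util import derive_rng, hpd_interval
from .simulate import DEFAULT_GENERATION_YEARS, DEFAULT_MU, Genealogy

logger = logging.getLogger(__name__)


class SkylineError(ValueError):
    pass


@dataclass(frozen=True)
class ClockConfig:
    """Strict molecular clock: substitutions/site/year and years/generation."""

    mu: float = DEFAULT_MU
    generation_years: float = DEFAULT_GENERATION_YEARS

    def __post_init__(self):
        if self.mu <= 0 or self.generation_years <= 0:
            raise SkylineError("mu and generation_years must be positive")

    @property
    def subs_per_generation(self) -> float:
        return self.mu * self.generation_years


@dataclass(frozen=True)
class CoalescentIntervals:
    """(k, Δt) decomposition of an ultrametric genealogy, times in generations.

    k starts at n and drops by one at each of the n-1 coalescences; zero
    durations encode simultaneous coalescent heights.
    """

    n_tips: int
    ks: np.ndarray  # lineage count during each interval, n..2
    durations: np.ndarray  # interval lengths, >= 0

    def __post_init__(self):
        ks = np.asarray(self.ks, dtype=int)
        dts = np.asarray(self.durations, dtype=float)
        if ks.size != self.n_tips - 1 or dts.size != ks.size:
            raise SkylineError("expected n-1 coalescent intervals")
        if not np.array_equal(ks, np.arange(self.n_tips, 1, -1)):
            raise SkylineError("lineage counts must run n, n-1, ..., 2")
        if np.any(dts < 0):
            raise SkylineError("durations must be nonnegative")
        object.__setattr__(self, "ks", ks)
        object.__setattr__(self, "durations", dts)

    @property
    def n_events(self) -> int:
        return self.n_tips - 1

    @property
    def event_times(self) -> np.ndarray:
        """Coalescent heights, ascending (generations before present)."""
        return np.cumsum(self.durations)

    @property
    def weights(self) -> np.ndarray:
        """k(k-1)Δt/2 per interval: the hazard integral ending at each event."""
        return self.ks * (self.ks - 1) / 2.0 * self.durations

    @property
    def tmrca(self) -> float:
        return float(self.durations.sum())


def coalescent_intervals(tree: Genealogy, tol: float = 1e-6) -> CoalescentIntervals:
    """Interval decomposition of an ultrametric genealogy."""
    n = tree.n_tips
    if n < 2:
        raise SkylineError("need at least 2 tips")
    # ultrametricity (contemporaneous tips) is enforced by the Genealogy
    # representation itself: tip heights are zero within tolerance, so every
    # root-to-tip path equals the root height. Monotone parent heights are
    # the remaining structural requirement.
    bl = tree.branch_lengths()
    if np.any(bl < -tol):
        raise SkylineError("negative branch length: tree not ultrametric within tolerance")
    heights = np.sort(tree.heights[n:])
    dts = np.diff(np.concatenate([[0.0], heights]))
    return CoalescentIntervals(n_tips=n, ks=np.arange(n, 1, -1), durations=dts)


# ---------------------------------------------------------------------------
# Genealogy estimation: corrected distances + UPGMA
# ---------------------------------------------------------------------------


def hky_corrected_distance(seq_a: str, seq_b: str, base_freqs=None) -> float:
    """Substitutions/site between two sequences corrected for multiple hits
    under the HKY/TN93 family (closed-form TN93 estimator with empirical
    base frequencies).

    Raises on saturation (logarithm of a non-positive quantity).
    """
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    if a.size != b.size:
        raise SkylineError("sequences must be aligned (equal length)")
    valid = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) & np.isin(
        b, np.frombuffer(b"ACGT", dtype=np.uint8)
    )
    a, b = a[valid], b[valid]
    L = a.size
    if L == 0:
        raise SkylineError("no jointly-called sites")
    if base_freqs is None:
        both = np.concatenate([a, b])
        pi = np.array([(both == ord(c)).mean() for c in "ACGT"])
    else:
        pi = np.asarray(base_freqs, dtype=float)
    pi = np.clip(pi, 1e-9, None)
    pi /= pi.sum()
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT

    diff = a != b
    is_a = {c: (lambda x, o=ord(c): x == o) for c in "ACGT"}
    p1 = float((diff & ((a == ord("A")) & (b == ord("G")) | (a == ord("G")) & (b == ord("A")))).mean())
    p2 = float((diff & ((a == ord("C")) & (b == ord("T")) | (a == ord("T")) & (b == ord("C")))).mean())
    purine = np.isin(a, np.frombuffer(b"AG", dtype=np.uint8))
    purine_b = np.isin(b, np.frombuffer(b"AG", dtype=np.uint8))
    q = float((diff & (purine != purine_b)).mean())
    del is_a

    k1 = 2.0 * piA * piG / piR
    k2 = 2.0 * piT * piC / piY
    k3 = 2.0 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY)
    w1 = 1.0 - p1 / k1 - q / (2.0 * piR)
    w2 = 1.0 - p2 / k2 - q / (2.0 * piY)
    w3 = 1.0 - q / (2.0 * piR * piY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SkylineError("saturated distance: TN93 correction undefined")
    return float(-k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3))


def estimate_genealogy(
    sequences: dict[str, str], clock: ClockConfig = ClockConfig()
) -> Genealogy:
    """UPGMA genealogy from HKY-corrected distances, heights in generations.

    Distances (expected substitutions/site) are halved at each merge height
    and converted to generations via mu * generation_years. Ultrametric by
    construction. An all-identical alignment yields a zero-height tree,
    flagged degenerate via a log warning.
    """
    labels = list(sequences)
    n = len(labels)
    if n < 3:
        raise SkylineError("need at least 3 sequences")
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dmat[i, j] = dmat[j, i] = hky_corrected_distance(
                    sequences[labels[i]], sequences[labels[j]]
                )
            except SkylineError as exc:
                raise SkylineError(
                    f"distance undefined for pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
    z = upgma_linkage(squareform(dmat, checks=False))
    parent = np.full(2 * n - 1, -1, dtype=int)
    heights = np.zeros(2 * n - 1)
    for m in range(n - 1):
        left, right, h, _ = z[m]
        node = n + m
        parent[int(left)] = node
        parent[int(right)] = node
        # UPGMA merge height is the average pairwise distance; the ultrametric
        # node height is half of it (subs/site), then converted to generations
        heights[node] = max((h / 2.0) / clock.subs_per_generation, 0.0)
    # enforce monotone heights against floating-point jitter
    for node in range(n, 2 * n - 1):
        p = parent[node]
        if p >= 0:
            heights[p] = max(heights[p], heights[node])
    if heights[2 * n - 2] == 0:
        logger.warning("estimate_genealogy: all sequences identical, degenerate star tree")
    return Genealogy(parent, heights, labels)


# ---------------------------------------------------------------------------
# Classic (deterministic) skyline
# ---------------------------------------------------------------------------


def classic_skyline(intervals: CoalescentIntervals) -> np.ndarray:
    """Per-interval N̂_i = k_i(k_i-1)Δt_i/2 (the Pybus-Rambaut construction)."""
    w = intervals.weights
    if np.any(intervals.durations == 0):
        warnings.warn("zero-length coalescent interval: N̂=0 for that interval")
    return w


def pooled_constant_mle(intervals_list: list[CoalescentIntervals]) -> float:
    """Analytic MLE of a single constant Nef: Σ k(k-1)Δt/2 / (#events)."""
    total_w = sum(float(iv.weights.sum()) for iv in intervals_list)
    events = sum(iv.n_events for iv in intervals_list)
    return total_w / events


# ---------------------------------------------------------------------------
# Bayesian skyline: likelihood and MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkylineModel:
    """m-group piecewise-constant Nef on the pooled coalescent events."""

    group_sizes: tuple[int, ...]
    nefs: tuple[float, ...]

    def __post_init__(self):
        if len(self.group_sizes) != len(self.nefs) or not self.group_sizes:
            raise SkylineError("need one Nef per group, m >= 1")
        if any(s < 1 for s in self.group_sizes):
            raise SkylineError("group sizes must be positive integers")
        if any(x <= 0 for x in self.nefs):
            raise SkylineError("Nef must be positive")


def _pooled_events(intervals_list: list[CoalescentIntervals]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled sorted event times and per-event hazard weights.

    Weight j is Σ_g ∫ k_g(k_g-1)/2 dt over the span between pooled events
    j-1 and j, computed from each genealogy's piecewise-linear cumulative
    hazard integral.
    """
    all_times = np.sort(np.concatenate([iv.event_times for iv in intervals_list]))
    edges = np.concatenate([[0.0], all_times])
    cum = np.zeros(all_times.size + 1)
    for iv in intervals_list:
        t_ev = np.concatenate([[0.0], iv.event_times])
        c_ev = np.concatenate([[0.0], np.cumsum(iv.weights)])
        # piecewise-linear interpolation of the cumulative hazard; flat beyond root
        cum += np.interp(edges, t_ev, c_ev)
    w = np.diff(cum)
    return all_times, w


def skyline_log_likelihood(
    intervals: CoalescentIntervals | list[CoalescentIntervals], model: SkylineModel
) -> float:
    """Coalescent log-likelihood of an m-group skyline.

    Each epoch of size N contributes -W/N - c ln N where W is the pooled
    hazard integral over the epoch and c its number of coalescences.
    """
    ivs = intervals if isinstance(intervals, list) else [intervals]
    times, w = _pooled_events(ivs)
    if sum(model.group_sizes) != times.size:
        raise SkylineError(
            f"group sizes sum to {sum(model.group_sizes)}, but there are {times.size} events"
        )
    ll = 0.0
    start = 0
    for size, nef in zip(model.group_sizes, model.nefs):
        w_g = float(w[start : start + size].sum())
        ll += -w_g / nef - size * math.log(nef)
        start += size
    return ll


@dataclass
class SkylinePosterior:
    """Thinned post-burn-in MCMC draws of the skyline model."""

    event_times: np.ndarray  # pooled coalescent heights (generations)
    group_sizes: np.ndarray  # (draws, m)
    nefs: np.ndarray  # (draws, m)
    log_likelihoods: np.ndarray
    acceptance: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.nefs.shape[0]

    def boundary_times(self) -> np.ndarray:
        """(draws, m) time of each group's last (oldest) event."""
        cum = np.cumsum(self.group_sizes, axis=1) - 1
        return self.event_times[cum]

    def nef_at(self, t_gen: np.ndarray) -> np.ndarray:
        """(draws, len(t)) Nef evaluated at times in generations."""
        t = np.asarray(t_gen, dtype=float)
        out = np.empty((self.n_draws, t.size))
        bounds = self.boundary_times()
        m = self.nefs.shape[1]
        for i in range(self.n_draws):
            idx = np.searchsorted(bounds[i], t, side="left").clip(max=m - 1)
            out[i] = self.nefs[i, idx]
        return out


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def mcmc_skyline(
    intervals: CoalescentIntervals | list[CoalescentIntervals],
    m: int = 5,
    iterations: int = 200_000,
    thin: int = 100,
    burn_in: float = 0.1,
    seed: int = 0,
    proposal_scale: float = 0.7,
    prior_log_bounds: tuple[float, float] = (-5.0, 30.0),
    flat_likelihood: bool = False,
    ess_threshold: float = 100.0,
) -> SkylinePosterior:
    """Metropolis-Hastings sampler for the m-group Bayesian skyline.

    Priors: scale-invariant (log-uniform within ``prior_log_bounds``, natural
    log of Nef) on the first group's Nef; each subsequent group's Nef ~
    Exponential(mean = previous group's Nef), the standard smoothing prior.
    Moves: multiplicative scale moves on a random group's Nef and swaps of
    one coalescent event between adjacent groups. ``flat_likelihood=True``
    samples the prior alone (detailed-balance check).
    """
    if proposal_scale <= 0:
        raise SkylineError("proposal scale must be positive")
    if iterations < thin:
        raise SkylineError("iterations must be >= thin")
    ivs = intervals if isinstance(intervals, list) else [intervals]
    times, w = _pooled_events(ivs)
    E = times.size
    if m > E:
        raise SkylineError(f"m={m} groups exceed {E} coalescent events")
    rng = derive_rng(seed, "mcmc")
    lo, hi = prior_log_bounds

    # initial state: equal group sizes, Nef at the pooled constant MLE
    sizes = np.full(m, E // m, dtype=int)
    sizes[: E % m] += 1
    nef0 = max(float(w.sum()) / E, math.exp(lo + 1e-3))
    log_nef = np.full(m, math.log(nef0))
    bounds_idx = np.cumsum(sizes)

    def group_stats():
        a = np.zeros(m)
        c = np.zeros(m)
        start = 0
        for g in range(m):
            a[g] = w[start : start + sizes[g]].sum()
            c[g] = sizes[g]
            start += sizes[g]
        return a, c

    a_g, c_g = group_stats()

    def loglik_terms(g: int, lognef_g: float) -> float:
        if flat_likelihood:
            return 0.0
        return -a_g[g] * math.exp(-lognef_g) - c_g[g] * lognef_g

    def logprior_term(g: int, log_nefs: np.ndarray) -> float:
        # terms of the joint prior that involve group g
        lp = 0.0
        if g == 0:
            if not lo <= log_nefs[0] <= hi:
                return -math.inf
            lp += 0.0  # log-uniform: constant within bounds (in log space)
        else:
            # N_g ~ Exp(mean N_{g-1}); density in N, expressed with log-N jacobian
            lp += -log_nefs[g - 1] - math.exp(log_nefs[g] - log_nefs[g - 1]) + log_nefs[g]
        if g + 1 < m:
            lp += -log_nefs[g] - math.exp(log_nefs[g + 1] - log_nefs[g]) + log_nefs[g + 1]
        return lp

    total_ll = sum(loglik_terms(g, log_nef[g]) for g in range(m))
    n_keep = iterations // thin
    burn_draws = int(burn_in * n_keep)
    kept_sizes = np.empty((n_keep, m), dtype=int)
    kept_nefs = np.empty((n_keep, m))
    kept_ll = np.empty(n_keep)
    acc = {"scale": 0, "scale_tries": 0, "boundary": 0, "boundary_tries": 0}

    for it in range(iterations):
        if rng.random() < 0.7 or m == 1:
            # multiplicative scale move on one group's Nef (symmetric in log space)
            g = int(rng.integers(m))
            acc["scale_tries"] += 1
            proposal = log_nef[g] + proposal_scale * (rng.random() * 2.0 - 1.0)
            old_ll = loglik_terms(g, log_nef[g])
            old_lp = logprior_term(g, log_nef)
            new_lognef = log_nef.copy()
            new_lognef[g] = proposal
            new_lp = logprior_term(g, new_lognef)
            new_ll = loglik_terms(g, proposal)
            if math.log(rng.random() + 1e-300) < (new_ll + new_lp) - (old_ll + old_lp):
                log_nef[g] = proposal
                total_ll += new_ll - old_ll
                acc["scale"] += 1
        else:
            # move one coalescent event between adjacent groups
            g = int(rng.integers(m - 1))
            acc["boundary_tries"] += 1
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1 and sizes[g] > 1:
                # last event of group g moves to group g+1
                ev = bounds_idx[g] - 1
                delta = w[ev]
                old = -a_g[g] * math.exp(-log_nef[g]) - c_g[g] * log_nef[g] \
                      - a_g[g + 1] * math.exp(-log_nef[g + 1]) - c_g[g + 1] * log_nef[g + 1]
                a_new_g, a_new_h = a_g[g] - delta, a_g[g + 1] + delta
                c_new_g, c_new_h = c_g[g] - 1, c_g[g + 1] + 1
                new = -a_new_g * math.exp(-log_nef[g]) - c_new_g * log_nef[g] \
                      - a_new_h * math.exp(-log_nef[g + 1]) - c_new_h * log_nef[g + 1]
                if flat_likelihood:
                    old = new = 0.0
                if math.log(rng.random() + 1e-300) < new - old:
                    sizes[g] -= 1
                    sizes[g + 1] += 1
                    bounds_idx = np.cumsum(sizes)
                    a_g[g], a_g[g + 1] = a_new_g, a_new_h
                    c_g[g], c_g[g + 1] = c_new_g, c_new_h
                    total_ll += new - old
                    acc["boundary"] += 1
            elif direction == -1 and sizes[g + 1] > 1:
                # first event of group g+1 moves to group g
                ev = bounds_idx[g]
                delta = w[ev]
                old = -a_g[g] * math.exp(-log_nef[g]) - c_g[g] * log_nef[g] \
                      - a_g[g + 1] * math.exp(-log_nef[g + 1]) - c_g[g + 1] * log_nef[g + 1]
                a_new_g, a_new_h = a_g[g] + delta, a_g[g + 1] - delta
                c_new_g, c_new_h = c_g[g] + 1, c_g[g + 1] - 1
                new = -a_new_g * math.exp(-log_nef[g]) - c_new_g * log_nef[g] \
                      - a_new_h * math.exp(-log_nef[g + 1]) - c_new_h * log_nef[g + 1]
                if flat_likelihood:
                    old = new = 0.0
                if math.log(rng.random() + 1e-300) < new - old:
                    sizes[g] += 1
                    sizes[g + 1] -= 1
                    bounds_idx = np.cumsum(sizes)
                    a_g[g], a_g[g + 1] = a_new_g, a_new_h
                    c_g[g], c_g[g + 1] = c_new_g, c_new_h
                    total_ll += new - old
                    acc["boundary"] += 1
        if (it + 1) % thin == 0:
            j = (it + 1) // thin - 1
            kept_sizes[j] = sizes
            kept_nefs[j] = np.exp(log_nef)
            kept_ll[j] = total_ll

    kept_sizes = kept_sizes[burn_draws:]
    kept_nefs = kept_nefs[burn_draws:]
    kept_ll = kept_ll[burn_draws:]
    diagnostics = {
        "ess_loglik": _ess(kept_ll),
        "ess_nef_recent": _ess(np.log(kept_nefs[:, 0])),
        "n_events": int(E),
        "m": m,
    }
    if min(diagnostics["ess_loglik"], diagnostics["ess_nef_recent"]) < ess_threshold:
        warnings.warn(
            f"low effective sample size: {diagnostics['ess_loglik']:.0f} (loglik), "
            f"{diagnostics['ess_nef_recent']:.0f} (recent Nef)"
        )
    rates = {
        "scale": acc["scale"] / max(acc["scale_tries"], 1),
        "boundary": acc["boundary"] / max(acc["boundary_tries"], 1),
    }
    return SkylinePosterior(
        event_times=times, group_sizes=kept_sizes, nefs=kept_nefs,
        log_likelihoods=kept_ll, acceptance=rates, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Trajectories and robustness
# ---------------------------------------------------------------------------


@dataclass
class SkylineTrajectory:
    """Time grid with posterior median and 95% HPD of Nef.

    Times ascend from 0 (present); ybp = generations * generation_years.
    """

    times_gen: np.ndarray
    times_ybp: np.ndarray
    median: np.ndarray
    hpd_low: np.ndarray
    hpd_high: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.times_gen) <= 0):
            raise SkylineError("time grid must be strictly increasing")
        if np.any(self.hpd_low > self.median + 1e-9) or np.any(self.median > self.hpd_high + 1e-9):
            raise SkylineError("HPD bounds must bracket the median")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ybp": self.times_ybp, "median_Nef": self.median,
             "hpd_low": self.hpd_low, "hpd_high": self.hpd_high}
        )


def skyline_trajectory(
    posterior: SkylinePosterior,
    clock: ClockConfig = ClockConfig(),
    grid: np.ndarray | int = 100,
    prob: float = 0.95,
) -> SkylineTrajectory:
    """Evaluate each posterior draw on a time grid; per-gridpoint median and HPD.

    ``grid`` is either explicit times in generations or a number of evenly
    spaced gridpoints between 0 and the root height. Gridpoints beyond the
    root are truncated with a warning.
    """
    if posterior.n_draws == 0:
        raise SkylineError("empty posterior chain")
    root = float(posterior.event_times[-1])
    if isinstance(grid, (int, np.integer)):
        t = np.linspace(0.0, root, int(grid))
    else:
        t = np.asarray(grid, dtype=float)
        if t.size and t.max() > root:
            warnings.warn("grid extends beyond the root height; truncating")
            t = t[t <= root]
    draws = posterior.nef_at(t)
    med = np.median(draws, axis=0)
    low = np.empty_like(med)
    high = np.empty_like(med)
    for j in range(t.size):
        low[j], high[j] = hpd_interval(draws[:, j], prob)
    low = np.minimum(low, med)
    high = np.maximum(high, med)
    return SkylineTrajectory(
        times_gen=t, times_ybp=t * clock.generation_years,
        median=med, hpd_low=low, hpd_high=high,
        diagnostics=dict(posterior.diagnostics),
    )


def subsample_robustness(
    sequences: dict[str, str],
    sizes: list[int],
    seed: int = 0,
    clock: ClockConfig = ClockConfig(),
    m: int = 5,
    iterations: int = 100_000,
    thin: int = 100,
) -> dict[int, SkylineTrajectory]:
    """Skyline per random subsample size (without replacement).

    Sizes below 3 are skipped with a warning; size n reuses the full data.
    """
    labels = sorted(sequences)
    n = len(labels)
    out: dict[int, SkylineTrajectory] = {}
    for size in sizes:
        if size < 3:
            warnings.warn(f"subsample size {size} < 3: skipped")
            continue
        if size > n:
            raise SkylineError(f"subsample size {size} exceeds n={n}")
        rng = derive_rng(seed, "subsample", size)
        chosen = labels if size == n else [labels[i] for i in rng.choice(n, size, replace=False)]
        sub = {lab: sequences[lab] for lab in chosen}
        tree = estimate_genealogy(sub, clock)
        ivs = coalescent_intervals(tree)
        post = mcmc_skyline(ivs, m=min(m, ivs.n_events), iterations=iterations,
                            thin=thin, seed=derive_rng(seed, "mcmc", size).integers(2**31))
        out[size] = skyline_trajectory(post, clock)
    return out
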