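"""Within-population diversity estimators and neutrality tests.

Conventions follow the Arlequin/DnaSP school for haploid sequence data:

* θ is the mean number of pairwise differences between sequences (NOT
  Watterson's estimator, which appears only inside Tajima's D as S/a1);
* missing data (non-ACGT characters) are excluded pairwise, so each pair is
  compared over its jointly-called sites only;
* haplotype diversity Ĥ = n/(n-1) (1 - Σ p_i²) with Nei's sampling variance;
* nucleotide diversity π = θ/L with Tajima's (1983) sampling variance
  (the estimator choice is documented, not reverse-engineered);
* Fu's FS uses θ (mean pairwise differences) as the plug-in for the Ewens
  sampling distribution, computed with log-space unsigned Stirling numbers
  of the first kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    k: int
    S: int
    H: float
    H_sd: float
    pi: float
    pi_sd: float
    theta: float
    tajima_d: float | None
    fu_fs: float | None
    notes: tuple[str, ...] = ()


def _encode(sequences: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype=np.uint8)
    return arr.reshape(len(sequences), -1)


def _called_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, VALID)


def pairwise_difference_matrix(sequences: list[str]) -> np.ndarray:
    """d_ij = number of differing, jointly-called sites (pairwise deletion)."""
    arr = _encode(sequences)
    called = _called_mask(arr)
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & both
        d[i, i + 1 :] = diff.sum(axis=1)
    return d + d.T


def segregating_sites(sequences: list[str]) -> int:
    """Sites with >= 2 observed states among called bases."""
    arr = _encode(sequences)
    called = _called_mask(arr)
    S = 0
    for j in range(arr.shape[1]):
        states = set(arr[called[:, j], j].tolist())
        if len(states) >= 2:
            S += 1
    return S


def mean_pairwise_differences(sequences: list[str]) -> float:
    n = len(sequences)
    if n < 2:
        raise DiversityError("need at least 2 sequences")
    d = pairwise_difference_matrix(sequences)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def haplotype_counts(sequences: list[str]) -> list[int]:
    """Multiplicities of distinct sequences (exact string identity)."""
    seen: dict[str, int] = {}
    for s in sequences:
        seen[s] = seen.get(s, 0) + 1
    return sorted(seen.values(), reverse=True)


def summary_stats(sequences: list[str]) -> tuple[int, int, int, float]:
    """(n, k, S, θ) for one population's alignment."""
    n = len(sequences)
    if n < 2:
        raise DiversityError("need at least 2 sequences")
    k = len(haplotype_counts(sequences))
    S = segregating_sites(sequences)
    theta = mean_pairwise_differences(sequences)
    return n, k, S, theta


def haplotype_diversity(counts: list[int], n: int | None = None) -> tuple[float, float]:
    """Ĥ = n/(n-1) (1 - Σ p_i²) and Nei's (1987) sampling s.d."""
    counts = [int(c) for c in counts if c > 0]
    total = sum(counts)
    if n is None:
        n = total
    if n != total:
        raise DiversityError(f"counts sum to {total}, but n={n}")
    if n < 2:
        raise DiversityError("need n >= 2")
    p = np.array(counts, dtype=float) / n
    sum_p2 = float(np.sum(p**2))
    sum_p3 = float(np.sum(p**3))
    h = n / (n - 1) * (1.0 - sum_p2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2
    )
    return float(h), math.sqrt(max(var, 0.0))


def nucleotide_diversity(sequences: list[str]) -> tuple[float, float]:
    """π = θ/L and Tajima's (1983) sampling s.d.

    L is the alignment length; pairwise deletion applies inside θ.
    """
    n = len(sequences)
    if n < 2:
        raise DiversityError("need at least 2 sequences")
    L = len(sequences[0])
    if L == 0:
        raise DiversityError("zero-length alignment")
    arr = _encode(sequences)
    if not _called_mask(arr).any():
        raise DiversityError("no usable sites")
    theta = mean_pairwise_differences(sequences)
    pi = theta / L
    var = (n + 1) / (3.0 * (n - 1)) * pi / L + 2.0 * (n**2 + n + 3) / (
        9.0 * n * (n - 1)
    ) * pi**2
    return float(pi), math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1..e2 constants of Tajima's (1989) test."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, theta: float, n: int) -> float | None:
    """D = (θ - S/a1) / sqrt(e1 S + e2 S (S-1)); None (undefined) when S=0."""
    if n < 4:
        raise DiversityError("Tajima's D needs n >= 4")
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return float((theta - S / c["a1"]) / math.sqrt(var))


# ---------------------------------------------------------------------------
# Fu's FS
# ---------------------------------------------------------------------------


def log_stirling_first_kind(n: int) -> np.ndarray:
    """log |s(n, k)| for k=0..n via the recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|."""
    log_s = np.full(n + 1, -np.inf)
    log_s[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # k ranges 1..m
        new[1 : m + 1] = np.logaddexp(
            math.log(m - 1) + log_s[1 : m + 1] if m > 1 else -np.inf,
            log_s[0:m],
        )
        log_s = new
    return log_s


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | θ, n) for k=1..n under the Ewens sampling distribution."""
    if theta <= 0:
        raise DiversityError("Fu's FS needs θ > 0")
    log_s = log_stirling_first_kind(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_p = log_s[1 : n + 1] + np.arange(1, n + 1) * math.log(theta) - log_rising
    p = np.exp(log_p)
    return p / p.sum()  # guard tiny numerical drift; sums to 1 analytically


def fus_fs(n: int, k: int, theta: float) -> float:
    """FS = ln(S'/(1-S')) with S' = P(K >= k | θ, n) under Ewens sampling.

    Returns signed infinity when S' is numerically 0 or 1 (e.g. k = 1).
    """
    if n < 2:
        raise DiversityError("need n >= 2")
    if not 1 <= k <= n:
        raise DiversityError("k must lie in 1..n")
    p = ewens_k_distribution(n, theta)
    s_prime = float(p[k - 1 :].sum())
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


# ---------------------------------------------------------------------------
# One-call summary
# ---------------------------------------------------------------------------


def diversity_summary(sequences: list[str]) -> DiversitySummary:
    """All Table-3-style statistics for one population."""
    n, k, S, theta = summary_stats(sequences)
    counts = haplotype_counts(sequences)
    h, h_sd = haplotype_diversity(counts, n)
    pi, pi_sd = nucleotide_diversity(sequences)
    notes = []
    d = tajimas_d(S, theta, n) if n >= 4 else None
    if d is None:
        notes.append("Tajima's D undefined (S=0 or n<4)")
    fs = fus_fs(n, k, theta) if theta > 0 else None
    if fs is None:
        notes.append("Fu's FS undefined (θ=0)")
    elif not math.isfinite(fs):
        notes.append("Fu's FS at boundary (S' numerically 0 or 1)")
    return DiversitySummary(
        n=n, k=k, S=S, H=h, H_sd=h_sd, pi=pi, pi_sd=pi_sd, theta=theta,
        tajima_d=d, fu_fs=fs, notes=tuple(notes),
    )


def diversity_table(populations: dict[str, list[str]]):
    """Table-3-shaped DataFrame: one row per population."""
    import pandas as pd

    rows = []
    for pop, seqs in populations.items():
        s = diversity_summary(seqs)
        rows.append(
            {"population": pop, "n": s.n, "k": s.k, "S": s.S,
             "H": s.H, "H_sd": s.H_sd, "pi": s.pi, "pi_sd": s.pi_sd,
             "theta": s.theta, "tajimas_D": s.tajima_d, "fus_FS": s.fu_fs}
        )
    return pd.DataFrame(rows)
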