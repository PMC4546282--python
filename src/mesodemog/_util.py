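"""Shared numerical helpers: seeding, HPD intervals, great-circle distances."""

from __future__ import annotations

import zlib

import numpy as np

# Seeds handed to external libraries must stay in [1, 2**31).
MAX_SEED = 2**31 - 1


def derive_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Child generator derived from a master seed and a stable key path.

    String keys are hashed with CRC32 so the same population name always
    yields the same stream regardless of iteration order.
    """
    entropy = [int(master_seed) & MAX_SEED]
    for key in keys:
        if isinstance(key, str):
            entropy.append(zlib.crc32(key.encode("utf-8")))
        else:
            entropy.append(int(key) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def draw_seed(rng: np.random.Generator) -> int:
    """A positive integer seed usable by msprime and friends."""
    return int(rng.integers(1, MAX_SEED))


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `prob` posterior mass (empirical HPD)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres (mean Earth radius 6371.0088 km)."""
    r = 6371.0088
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * r * np.arcsin(np.sqrt(a)))
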