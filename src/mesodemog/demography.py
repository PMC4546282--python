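"""Inter-generational growth rates (IGR) and Mesoamerican period mapping.

The downstream demographic statistic: a skyline trajectory is resampled to a
25-year generation grid, per-generation percent growth rates

    IGR_n = 100 * (Nef_n - Nef_{n-1}) / Nef_{n-1}

are computed with n-1 the older generation, extrema (Nef max/min, IGRmax,
IGRmin) are located and mapped onto the Mesoamerican chronology, and trend
inversions (the time at which growth turns to decline or vice versa) are
detected on a smoothed IGR series, since raw per-generation rates fluctuate
intensely. Calendar anchor: present = 1950 CE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

PRE_CHRONOLOGY = "pre-chronology"


class DemographyError(ValueError):
    pass


@dataclass(frozen=True)
class Period:
    name: str
    start_ybp: float  # older boundary
    end_ybp: float  # younger boundary

    def __post_init__(self):
        if self.start_ybp <= self.end_ybp:
            raise DemographyError(f"period {self.name!r}: start must exceed end (ybp)")


@dataclass(frozen=True)
class PeriodTable:
    """Contiguous, non-overlapping chronological periods in decreasing ybp."""

    periods: tuple[Period, ...]

    def __post_init__(self):
        ps = tuple(self.periods)
        if not ps:
            raise DemographyError("empty period table")
        for a, b in zip(ps, ps[1:]):
            if abs(a.end_ybp - b.start_ybp) > 1e-9:
                raise DemographyError(
                    f"periods {a.name!r} and {b.name!r} are not contiguous"
                )
        object.__setattr__(self, "periods", ps)

    @classmethod
    def default(cls) -> "PeriodTable":
        with resources.files("mesodemog.data").joinpath("default_periods.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls.from_records(raw)

    @classmethod
    def from_records(cls, records: list[dict]) -> "PeriodTable":
        return cls(tuple(Period(r["name"], float(r["start_ybp"]), float(r["end_ybp"]))
                         for r in records))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeriodTable":
        return cls.from_records(yaml.safe_load(Path(path).read_text()))

    @property
    def oldest_ybp(self) -> float:
        return self.periods[0].start_ybp

    def period_of(self, t_ybp: float) -> str:
        """Period containing time t: end_ybp <= t < start_ybp, with the oldest
        period's start inclusive; older times map to 'pre-chronology'."""
        if t_ybp > self.oldest_ybp:
            return PRE_CHRONOLOGY
        for i, p in enumerate(self.periods):
            upper_ok = t_ybp <= p.start_ybp if i == 0 else t_ybp < p.start_ybp
            if upper_ok and t_ybp >= p.end_ybp:
                return p.name
        return PRE_CHRONOLOGY


@dataclass
class IGRSeries:
    """Per-generation Nef and percent growth rates, oldest generation first.

    ``igr[0]`` is NaN (no older generation); IGR is 0 wherever consecutive
    Nef values are equal. ``periods`` labels each generation's time.
    """

    times_ybp: np.ndarray  # strictly decreasing: oldest -> present
    nef: np.ndarray
    igr: np.ndarray
    periods: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.times_ybp) >= 0):
            raise DemographyError("times must strictly decrease (oldest first)")
        if self.nef.size != self.times_ybp.size or self.igr.size != self.nef.size:
            raise DemographyError("times, nef and igr must align")


@dataclass
class ExtremaReport:
    population: str
    nef_max: float
    nef_max_time_ybp: float
    nef_max_period: str
    nef_min: float
    nef_min_time_ybp: float
    nef_min_period: str
    igr_max: float
    igr_max_time_ybp: float
    igr_max_period: str
    igr_min: float
    igr_min_time_ybp: float
    igr_min_period: str


@dataclass
class InversionReport:
    population: str
    time_ybp: float | None
    period: str | None
    direction: str | None  # 'positive->negative' or 'negative->positive'
    window: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def resample_to_generations(
    times_ybp: np.ndarray,
    values: np.ndarray,
    generation_years: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a step trajectory on the generation grid, oldest first.

    The input is a right-continuous step function: ``values[i]`` applies on
    [times[i], times[i+1]) with times ascending in ybp. The output grid runs
    at ``generation_years`` steps from the oldest covered generation down to
    0 ybp; evaluation is step-function lookup, no interpolation.
    """
    t = np.asarray(times_ybp, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise DemographyError("empty trajectory")
    if np.any(np.diff(t) < 0):
        raise DemographyError("trajectory times must ascend in ybp")
    n_gen = int(np.floor(t[-1] / generation_years))
    grid = np.arange(n_gen, -1, -1, dtype=float) * generation_years
    idx = np.searchsorted(t, grid, side="right") - 1
    idx = idx.clip(min=0)
    return grid, v[idx]


def trajectory_to_generations(trajectory, generation_years: float = 25.0):
    """Convenience wrapper: skyline trajectory median -> generation grid."""
    return resample_to_generations(
        trajectory.times_ybp, trajectory.median, generation_years
    )


def igr_series(
    times_ybp: np.ndarray,
    nef: np.ndarray,
    periods: PeriodTable | None = None,
) -> IGRSeries:
    """Per-generation percent growth rates, n-1 being the older generation."""
    t = np.asarray(times_ybp, dtype=float)
    x = np.asarray(nef, dtype=float)
    if t.size < 2:
        raise DemographyError("need at least 2 gridpoints")
    if np.any(x <= 0):
        raise DemographyError("Nef must be positive everywhere (rate undefined at 0)")
    igr = np.full(t.size, np.nan)
    igr[1:] = 100.0 * (x[1:] - x[:-1]) / x[:-1]
    table = periods or PeriodTable.default()
    labels = [table.period_of(ti) for ti in t]
    return IGRSeries(times_ybp=t, nef=x, igr=igr, periods=labels)


def _argbest(values: np.ndarray, times: np.ndarray, maximum: bool) -> int:
    """Index of the extreme value; ties broken toward the most recent time."""
    target = np.nanmax(values) if maximum else np.nanmin(values)
    candidates = np.flatnonzero(np.isclose(values, target, rtol=0.0, atol=0.0) | (values == target))
    # times decrease with index, so the most recent tie is the largest index
    return int(candidates[-1])


def locate_extrema(
    series: IGRSeries, periods: PeriodTable | None = None, population: str = ""
) -> ExtremaReport:
    """Nef and IGR extrema with their times and period labels."""
    table = periods or PeriodTable.default()
    t = series.times_ybp
    i_nmax = _argbest(series.nef, t, maximum=True)
    i_nmin = _argbest(series.nef, t, maximum=False)
    igr = series.igr.copy()
    defined = ~np.isnan(igr)
    if not defined.any():
        raise DemographyError("IGR undefined everywhere")
    igr_masked = np.where(defined, igr, -np.inf)
    i_gmax = _argbest(igr_masked, t, maximum=True)
    igr_masked = np.where(defined, igr, np.inf)
    i_gmin = _argbest(igr_masked, t, maximum=False)
    return ExtremaReport(
        population=population,
        nef_max=float(series.nef[i_nmax]), nef_max_time_ybp=float(t[i_nmax]),
        nef_max_period=table.period_of(t[i_nmax]),
        nef_min=float(series.nef[i_nmin]), nef_min_time_ybp=float(t[i_nmin]),
        nef_min_period=table.period_of(t[i_nmin]),
        igr_max=float(igr[i_gmax]), igr_max_time_ybp=float(t[i_gmax]),
        igr_max_period=table.period_of(t[i_gmax]),
        igr_min=float(igr[i_gmin]), igr_min_time_ybp=float(t[i_gmin]),
        igr_min_period=table.period_of(t[i_gmin]),
    )


def smooth_igr(igr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over `window` generations (NaN-aware edges)."""
    if window < 1:
        raise DemographyError("window must be >= 1")
    x = np.asarray(igr, dtype=float)
    out = np.full(x.size, np.nan)
    half = window // 2
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        vals = x[lo:hi]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[i] = vals.mean()
    return out


def detect_inversion(
    series: IGRSeries,
    window: int = 5,
    periods: PeriodTable | None = None,
    population: str = "",
    mode: str = "smoothed",
    peak_tolerance: float = 0.15,
) -> InversionReport:
    """Dominant trend inversion of the (smoothed) IGR series.

    The IGR is smoothed by a centered moving average over ``window``
    generations (``mode='raw'`` skips smoothing). The inversion of record is
    the sign reversal between the global smoothed IGR maximum and minimum;
    its onset is located where the trajectory leaves the neighbourhood of
    its extreme (within ``peak_tolerance`` of the span's dynamic range) and
    the opposite trend takes over. Returns time None when the series never
    carries both signs.
    """
    table = periods or PeriodTable.default()
    if series.igr.size < window:
        raise DemographyError(f"series of {series.igr.size} generations shorter than window {window}")
    if mode == "smoothed":
        s = smooth_igr(series.igr, window)
    elif mode == "raw":
        s = series.igr.copy()
    else:
        raise DemographyError(f"unknown mode {mode!r}")
    t = series.times_ybp
    flank = max(1, window // 2)
    s = np.where(np.isnan(s), 0.0, s)

    # dominant trend reversal: the sign change between the global (smoothed)
    # IGR maximum and minimum. Raw per-generation rates fluctuate intensely,
    # so minor wiggles must not masquerade as the inversion; the reversal of
    # record runs from the strongest growth to the strongest decline (or the
    # converse), and the inversion is its onset: the first time, moving
    # forward from the dominant extreme, where the smoothed rate takes the
    # opposite sign and keeps it for at least window//2 generations.
    i_max = int(np.flatnonzero(s == s.max())[-1])  # ties -> most recent
    i_min = int(np.flatnonzero(s == s.min())[-1])
    if not (s[i_max] > 0.0 > s[i_min]):
        return InversionReport(population=population, time_ybp=None, period=None,
                               direction=None, window=window)
    if i_max < i_min:
        lo, hi, direction = i_max, i_min, "positive->negative"
    else:
        lo, hi, direction = i_min, i_max, "negative->positive"
    # Onset within the reversal span: the most recent gridpoint at which the
    # trajectory still sits within `peak_tolerance` of its extreme over the
    # span — the last moment before the opposite trend unambiguously takes
    # over. A pure sign rule is fragile here: an estimated plateau always
    # carries small persistent tilts, so the rates "have equal values"
    # (fluctuate around zero) throughout it, and the inversion belongs at the
    # plateau's recent edge, where the dominant opposite-signed rates begin.
    span = slice(lo, hi + 1)
    nef_span = series.nef[span]
    margin = peak_tolerance * (nef_span.max() - nef_span.min())
    if direction == "positive->negative":
        near = np.flatnonzero(nef_span >= nef_span.max() - margin)
    else:
        near = np.flatnonzero(nef_span <= nef_span.min() + margin)
    onset = lo + int(near[-1])
    if onset < hi:
        onset += 1  # first gridpoint of the opposing trend
    time_ybp = float(t[onset])
    return InversionReport(
        population=population, time_ybp=time_ybp, period=table.period_of(time_ybp),
        direction=direction, window=window,
    )


def report_tables(
    extrema: list[ExtremaReport],
    inversions: list[InversionReport],
    regions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population summary table and long-format scatter data.

    The summary has one row per population (Nef and IGR extrema with times,
    periods and the inversion period); the scatter frame is long format
    (population, region, metric, time_ybp, period) for period-distribution
    plots by cultural area.
    """
    if not extrema:
        raise DemographyError("no populations")
    regions = regions or {}
    inv_by_pop = {r.population: r for r in inversions}
    rows = []
    scatter = []
    for e in extrema:
        inv = inv_by_pop.get(e.population)
        rows.append({
            "population": e.population,
            "region": regions.get(e.population, ""),
            "nef_max": e.nef_max, "nef_max_time_ybp": e.nef_max_time_ybp,
            "nef_max_period": e.nef_max_period,
            "nef_min": e.nef_min, "nef_min_time_ybp": e.nef_min_time_ybp,
            "nef_min_period": e.nef_min_period,
            "igr_max": e.igr_max, "igr_max_time_ybp": e.igr_max_time_ybp,
            "igr_max_period": e.igr_max_period,
            "igr_min": e.igr_min, "igr_min_time_ybp": e.igr_min_time_ybp,
            "igr_min_period": e.igr_min_period,
            "inversion_time_ybp": inv.time_ybp if inv else None,
            "inversion_period": inv.period if inv else None,
            "inversion_direction": inv.direction if inv else None,
        })
        for metric, time, period in (
            ("nef_max", e.nef_max_time_ybp, e.nef_max_period),
            ("nef_min", e.nef_min_time_ybp, e.nef_min_period),
            ("igr_max", e.igr_max_time_ybp, e.igr_max_period),
            ("igr_min", e.igr_min_time_ybp, e.igr_min_period),
        ):
            scatter.append({"population": e.population,
                            "region": regions.get(e.population, ""),
                            "metric": metric, "time_ybp": time, "period": period})
    return pd.DataFrame(rows), pd.DataFrame(scatter)
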