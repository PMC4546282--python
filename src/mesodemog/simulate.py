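"""Synthetic mtDNA-like data: coalescent genealogies, HKY+G sequence
evolution, and multi-population study fixtures.

The coalescent machinery (single-deme with piecewise-constant Nef, and the
structured coalescent with migration) runs on msprime with haploid lineages,
so a population of effective size Nef (number of breeding females) coalesces
a pair of lineages at rate 1/Nef per generation — the mtDNA convention.
Sequence evolution is implemented here directly: exact HKY transition
matrices per branch and per discrete-gamma rate category, with optional
diagnostic-motif planting at the root so haplogroup structure is known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from ._util import derive_rng, draw_seed
from .coords import DEFAULT_MAP, ControlRegionMap

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Defaults emulating a human mtDNA control-region study: 1122 concatenated
# control-region sites, pedigree-calibrated non-coding substitution rate of
# 3.02e-7 per site per year, 25-year generations.
DEFAULT_MU = 3.02e-7
DEFAULT_GENERATION_YEARS = 25.0
DEFAULT_SEQ_LENGTH = 1122
DEFAULT_KAPPA = 22.0
DEFAULT_GAMMA_SHAPE = 0.40
# Illustrative control-region base composition (A, C, G, T)
DEFAULT_BASE_FREQS = (0.31, 0.33, 0.13, 0.23)


class SimulationError(ValueError):
    """Invalid simulation input or model."""


class NonCoalescenceError(SimulationError):
    """Structured coalescent cannot reach a common ancestor."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant Nef(t) trajectory, time in generations before present.

    ``sizes[0]`` applies on [0, change_times[0]), ``sizes[i]`` on
    [change_times[i-1], change_times[i]); Nef(t) is right-continuous in
    time-before-present.
    """

    sizes: tuple[float, ...]
    change_times: tuple[float, ...] = ()
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sizes", tuple(float(s) for s in self.sizes))
        object.__setattr__(self, "change_times", tuple(float(t) for t in self.change_times))
        if len(self.sizes) != len(self.change_times) + 1:
            raise SimulationError(
                f"need len(sizes) == len(change_times)+1, got "
                f"{len(self.sizes)} sizes and {len(self.change_times)} change times"
            )
        if any(s <= 0 for s in self.sizes):
            raise SimulationError("all Nef sizes must be positive")
        if any(t2 <= t1 for t1, t2 in zip(self.change_times, self.change_times[1:])):
            raise SimulationError("change_times must be strictly increasing")
        if self.change_times and self.change_times[0] <= 0:
            raise SimulationError("change_times must be positive")

    def nef_at(self, t: float) -> float:
        """Nef at time t generations before present (right-continuous)."""
        i = int(np.searchsorted(np.asarray(self.change_times), t, side="right"))
        return self.sizes[i]


@dataclass(frozen=True)
class SimulationConfig:
    """Mutation-process settings for sequence evolution (HKY + discrete gamma)."""

    seq_length: int = DEFAULT_SEQ_LENGTH
    mu: float = DEFAULT_MU  # substitutions / site / year
    generation_years: float = DEFAULT_GENERATION_YEARS
    kappa: float = DEFAULT_KAPPA
    gamma_shape: float = DEFAULT_GAMMA_SHAPE
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    # optional relaxed clock: per-branch lognormal rate multipliers with
    # E[multiplier]=1; 0 disables (strict clock)
    lognormal_clock_sigma: float = 0.0

    def __post_init__(self):
        if self.mu < 0:
            raise SimulationError("mu must be >= 0")
        if self.generation_years <= 0:
            raise SimulationError("generation_years must be positive")
        if self.kappa <= 0:
            raise SimulationError("kappa must be positive")
        if self.gamma_shape <= 0:
            raise SimulationError("gamma_shape must be positive")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-12:
            raise SimulationError("base_freqs must be 4 nonnegative values summing to 1")


@dataclass(frozen=True)
class MigrationMatrix:
    """Backward per-generation migration rates between demes; diagonal ignored."""

    rates: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.rates, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise SimulationError("migration matrix must be square")
        off = m - np.diag(np.diag(m))
        if np.any(off < 0):
            raise SimulationError("off-diagonal migration rates must be >= 0")
        object.__setattr__(self, "rates", m)

    @property
    def n_demes(self) -> int:
        return self.rates.shape[0]

    def is_connected(self) -> bool:
        """Every deme reachable from every other treating positive rates as edges."""
        n = self.n_demes
        adj = (self.rates > 0) | (self.rates.T > 0)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in range(n):
                if v not in seen and adj[u, v]:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == n


class Genealogy:
    """Rooted binary ultrametric tree with node heights in generations.

    Nodes 0..n-1 are tips (height 0); internal nodes follow. ``parent[i]`` is
    -1 at the root. ``demes`` optionally records each tip's deme label.
    """

    ULTRAMETRIC_TOL = 1e-9

    def __init__(
        self,
        parent: np.ndarray,
        heights: np.ndarray,
        tip_labels: list[str],
        demes: dict[str, str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.heights = np.asarray(heights, dtype=float)
        self.tip_labels = list(tip_labels)
        self.demes = demes
        n = len(self.tip_labels)
        if n < 1:
            raise SimulationError("genealogy needs at least one tip")
        if self.parent.shape != self.heights.shape or self.parent.size != 2 * n - 1:
            raise SimulationError("a binary tree on n tips has 2n-1 nodes")
        if np.any(np.abs(self.heights[:n]) > self.ULTRAMETRIC_TOL):
            raise SimulationError("tip heights must be 0 (contemporaneous sampling)")
        if n > 1 and np.any(self.heights[n:] < 0):
            raise SimulationError("internal node heights must be nonnegative")
        # zero internal heights mark a degenerate (star-like) estimate
        self.degenerate = bool(n > 1 and float(self.heights[n:].max()) == 0.0)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.heights[self.root])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(u)
        return kids

    def branch_lengths(self) -> np.ndarray:
        """Parent height minus own height, 0 for the root."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.heights[self.parent[has_parent]] - self.heights[has_parent]
        return bl

    def coalescent_heights(self) -> np.ndarray:
        return np.sort(self.heights[self.n_tips :])

    def to_newick(self, precision: int = 10) -> str:
        kids = self.children()

        def rec(u: int) -> str:
            if u < self.n_tips:
                core = self.tip_labels[u]
            else:
                core = "(" + ",".join(rec(c) for c in kids[u]) + ")"
            p = self.parent[u]
            if p < 0:
                return core
            bl = self.heights[p] - self.heights[u]
            return f"{core}:{bl:.{precision}f}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, demes: dict[str, str] | None = None) -> "Genealogy":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.suppress_unifurcations()
        nodes = list(tree.preorder_node_iter())
        # depth from root, then height = max_depth - depth
        depth: dict = {tree.seed_node: 0.0}
        for nd in nodes:
            if nd is not tree.seed_node:
                depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
        tips = [nd for nd in tree.leaf_node_iter()]
        max_depth = max(depth[t] for t in tips)
        labels = [t.taxon.label for t in tips]
        n = len(tips)
        index: dict = {t: i for i, t in enumerate(tips)}
        internal = [nd for nd in nodes if nd not in index]
        internal.sort(key=lambda nd: max_depth - depth[nd])  # increasing height
        for j, nd in enumerate(internal):
            index[nd] = n + j
        parent = np.full(2 * n - 1, -1, dtype=int)
        heights = np.zeros(2 * n - 1)
        for nd, i in index.items():
            h = max_depth - depth[nd]
            heights[i] = 0.0 if abs(h) < cls.ULTRAMETRIC_TOL else h
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
        return cls(parent, heights, labels, demes=demes)


# ---------------------------------------------------------------------------
# Coalescent genealogies (msprime backend, haploid lineages)
# ---------------------------------------------------------------------------


def _demography_events(dem: msprime.Demography, model: DemographicModel, population: str):
    for t, size in zip(model.change_times, model.sizes[1:]):
        dem.add_population_parameters_change(time=t, initial_size=size, population=population)


def _tskit_to_genealogy(ts, tip_labels: list[str], demes: dict[str, str] | None = None) -> Genealogy:
    tree = ts.first()
    n = ts.num_samples
    order = sorted(
        (u for u in tree.nodes() if u >= n), key=lambda u: tree.time(u)
    )
    remap = {u: i for i, u in enumerate(range(n))}
    for j, u in enumerate(order):
        remap[u] = n + j
    parent = np.full(2 * n - 1, -1, dtype=int)
    heights = np.zeros(2 * n - 1)
    for u in tree.nodes():
        i = remap[u]
        heights[i] = tree.time(u)
        p = tree.parent(u)
        if p != -1:
            parent[i] = remap[p]
    return Genealogy(parent, heights, tip_labels, demes=demes)


def simulate_genealogy(
    model: DemographicModel, n: int, seed: int, tip_prefix: str = "s"
) -> Genealogy:
    """Coalescent genealogy of n haploid tips under a piecewise-constant Nef.

    While k lineages remain, the coalescence hazard is k(k-1)/(2 Nef(t)) per
    generation; waiting times follow by time-rescaling across epochs.
    Deterministic given ``seed``.
    """
    if n < 2:
        raise SimulationError("need at least 2 tips to coalesce")
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=model.sizes[0])
    _demography_events(dem, model, "pop0")
    ts = msprime.sim_ancestry(
        samples={"pop0": n}, demography=dem, ploidy=1, random_seed=int(seed)
    )
    labels = [f"{tip_prefix}{i:03d}" for i in range(n)]
    return _tskit_to_genealogy(ts, labels)


def simulate_structured_genealogy(
    models: list[DemographicModel],
    mig: MigrationMatrix,
    n_per_deme: list[int],
    seed: int,
    deme_names: list[str] | None = None,
) -> Genealogy:
    """Structured coalescent: lineages migrate between demes at the given
    backward rates and coalesce only within demes. Tip demes are recorded on
    the returned genealogy.
    """
    d = len(models)
    if d < 2:
        raise SimulationError("need at least 2 demes")
    if mig.n_demes != d or len(n_per_deme) != d:
        raise SimulationError("models, migration matrix and sample sizes disagree on deme count")
    if not mig.is_connected():
        raise NonCoalescenceError(
            "migration graph is disconnected: lineages in separate demes can never coalesce"
        )
    names = deme_names or [f"deme{i}" for i in range(d)]
    dem = msprime.Demography()
    for name, model in zip(names, models):
        dem.add_population(name=name, initial_size=model.sizes[0])
    for name, model in zip(names, models):
        _demography_events(dem, model, name)
    for i in range(d):
        for j in range(d):
            if i != j and mig.rates[i, j] > 0:
                dem.set_migration_rate(source=names[i], dest=names[j], rate=mig.rates[i, j])
    dem.sort_events()
    try:
        ts = msprime.sim_ancestry(
            samples={name: k for name, k in zip(names, n_per_deme)},
            demography=dem,
            ploidy=1,
            random_seed=int(seed),
        )
    except Exception as exc:  # msprime raises LibraryError on infinite waiting time
        if "nfinite" in str(exc):
            raise NonCoalescenceError(str(exc)) from exc
        raise
    labels = []
    demes = {}
    for name, k in zip(names, n_per_deme):
        for i in range(k):
            lab = f"{name}_{i:03d}"
            labels.append(lab)
            demes[lab] = name
    return _tskit_to_genealogy(ts, labels, demes=demes)


# ---------------------------------------------------------------------------
# Sequence evolution: HKY + discrete gamma
# ---------------------------------------------------------------------------


def discrete_gamma_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Median-of-category discrete gamma rates, normalised to mean 1."""
    q = (np.arange(ncat) + 0.5) / ncat
    rates = gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY85 generator scaled to one expected substitution per unit time."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.dot(pi, np.diag(q))
    if mean_rate > 0:
        q /= mean_rate
    return q


def _sample_children_states(parent_states, cum_p, rng):
    """Vectorised categorical draw: cum_p is (4,4) row-cumulative P matrix."""
    u = rng.random(parent_states.size)
    rows = cum_p[parent_states]
    return (u[:, None] > rows).sum(axis=1)


def evolve_sequences(
    tree: Genealogy,
    cfg: SimulationConfig,
    root_seq: str | None = None,
    motif: list[tuple[int, str]] | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Evolve sequences down a genealogy under HKY + 4-category discrete gamma.

    ``motif`` lists (1-based concatenated position, allele) variants applied
    to the root before evolution (haplogroup planting). Branch lengths in
    generations are converted to expected substitutions per site via
    mu * generation_years. Returns {tip label: sequence}.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = cfg.seq_length
    if root_seq is not None:
        if len(root_seq) != L:
            raise SimulationError(f"root_seq length {len(root_seq)} != seq_length {L}")
        root_states = np.array([BASE_INDEX[b] for b in root_seq.upper()], dtype=int)
    else:
        root_states = rng.choice(4, size=L, p=np.asarray(cfg.base_freqs))
    if motif:
        root_states = root_states.copy()
        for pos, allele in motif:
            if not 1 <= pos <= L:
                raise SimulationError(f"motif position {pos} outside 1..{L}")
            root_states[pos - 1] = BASE_INDEX[allele.upper()]

    rates = discrete_gamma_rates(cfg.gamma_shape)
    categories = rng.integers(0, rates.size, size=L)
    q = hky_rate_matrix(cfg.kappa, cfg.base_freqs)
    subs_per_gen = cfg.mu * cfg.generation_years

    states = np.empty((tree.n_nodes, L), dtype=int)
    states[tree.root] = root_states
    order = sorted(range(tree.n_nodes), key=lambda u: -tree.heights[u])
    bl = tree.branch_lengths()
    sigma = cfg.lognormal_clock_sigma
    for u in order:
        p = tree.parent[u]
        if p < 0:
            continue
        b = bl[u] * subs_per_gen
        if sigma > 0:
            b *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
        if b <= 0:
            states[u] = states[p]
            continue
        child = states[p].copy()
        for c, rate in enumerate(rates):
            sites = np.flatnonzero(categories == c)
            if sites.size == 0:
                continue
            pmat = expm(q * (b * rate))
            np.clip(pmat, 0.0, None, out=pmat)
            pmat /= pmat.sum(axis=1, keepdims=True)
            cum = np.cumsum(pmat, axis=1)
            child[sites] = _sample_children_states(states[p][sites], cum, rng)
        states[u] = child

    out = {}
    for i, label in enumerate(tree.tip_labels):
        out[label] = "".join(BASES[s] for s in states[i])
    return out


# ---------------------------------------------------------------------------
# Study fixtures
# ---------------------------------------------------------------------------

def model_from_anchors(
    anchors: list[tuple[float, float]], step: float = 25.0, label: str = ""
) -> DemographicModel:
    """Piecewise-constant DemographicModel through (time, Nef) anchor points.

    Anchors ascend in generations before present; Nef is geometrically
    interpolated between anchors and discretised into ``step``-generation
    epochs (one generation = one epoch at the default 25-year resolution).
    """
    if len(anchors) < 2:
        raise SimulationError("need at least 2 anchors")
    times: list[float] = []
    sizes: list[float] = [float(anchors[0][1])]
    t = step
    while t <= anchors[-1][0] + 1e-9:
        for (t0, n0), (t1, n1) in zip(anchors, anchors[1:]):
            if t0 < t <= t1:
                f = (t - t0) / (t1 - t0)
                sizes.append(n0 * (n1 / n0) ** f)
                break
        else:
            raise SimulationError("anchors must ascend in time")
        times.append(t)
        t += step
    # close the final epoch exactly at the last anchor if it is off-grid
    last_t, last_n = anchors[-1]
    if not times or times[-1] < last_t - 1e-9:
        times.append(float(last_t))
        sizes.append(float(last_n))
    return DemographicModel(sizes=tuple(sizes), change_times=tuple(times), label=label)


def mesoamerican_growth_decline_model(
    n_ancient: float = 1_000.0,
    n_peak: float = 20_000.0,
    n_present: float = 2_000.0,
    growth_start_gen: float = 520.0,  # ~13,000 ybp
    fast_growth_start_gen: float = 280.0,  # ~7,000 ybp
    fast_growth_end_gen: float = 120.0,  # ~3,000 ybp
    decline_start_gen: float = 100.0,  # ~2,500 ybp
) -> DemographicModel:
    """The canonical qualitative Mesoamerican Nef history for recovery tests.

    A stable ancient phase, growth beginning ~13,000 ybp with the fastest
    growth between ~7,000 and ~3,000 ybp, a peak around 2,500 ybp and a
    roughly ten-fold decline to the present (the post-contact collapse).
    """
    return model_from_anchors(
        [
            (0.0, n_present),
            (decline_start_gen, n_peak),
            (fast_growth_end_gen, n_peak * 0.9),
            (fast_growth_start_gen, n_ancient * 3.0),
            (growth_start_gen, n_ancient),
        ],
        label="growth-then-decline",
    )


_PSEUDO_RCRS_SEED = 777001  # fixed: the synthetic stand-in reference is a constant


def pseudo_rcrs(length: int = DEFAULT_SEQ_LENGTH, base_freqs=DEFAULT_BASE_FREQS) -> str:
    """A fixed synthetic reference sequence (pseudo-rCRS stand-in).

    Deterministic regardless of caller seeds; it plays the role a real
    revised Cambridge Reference Sequence would play but carries no
    real-world information.
    """
    rng = np.random.default_rng(_PSEUDO_RCRS_SEED)
    states = rng.choice(4, size=length, p=np.asarray(base_freqs))
    return "".join(BASES[s] for s in states)


def motif_compatible_reference(
    reference: str,
    motifs: dict[str, list[str]],
    coord_map: ControlRegionMap = DEFAULT_MAP,
) -> str:
    """Adjust a reference so every diagnostic motif allele is derived.

    At each diagnostic position the reference base is forced to differ from
    all motif alleles used there (as the real rCRS does for derived
    haplogroup variants); otherwise planting a motif would be unobservable
    in difference coding.
    """
    seq = list(reference)
    alleles_at: dict[int, set[str]] = {}
    for tokens in motifs.values():
        for token in tokens:
            pos, allele = parse_variant(token)
            alleles_at.setdefault(coord_map.ref_to_sim(pos), set()).add(allele)
    for sim_pos, used in alleles_at.items():
        if seq[sim_pos - 1] in used:
            seq[sim_pos - 1] = next(b for b in BASES if b not in used)
    return "".join(seq)


def parse_variant(token: str) -> tuple[int, str]:
    """'16223T' -> (16223, 'T') in reference coordinates."""
    pos, allele = token[:-1], token[-1].upper()
    if allele not in BASE_INDEX:
        raise SimulationError(f"bad allele in variant token {token!r}")
    return int(pos), allele


@dataclass
class PopulationScenario:
    name: str
    n: int
    mixture: dict[str, float]
    model: DemographicModel
    region: str = "Unknown"
    language: str = "Unknown"
    lat: float = 0.0
    lon: float = 0.0


@dataclass
class StudyFixture:
    """Everything make_study_fixture knows: alignment, metadata and ground truth."""

    sequences: dict[str, str]
    metadata: "object"  # pandas.DataFrame
    truth: dict
    reference: str
    coord_map: ControlRegionMap = field(default_factory=lambda: DEFAULT_MAP)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        import pandas as pd  # noqa: F401 (metadata is a DataFrame)
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        fasta = outdir / "alignment.fasta"
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(fasta), "fasta")
        paths["fasta"] = fasta
        ref = outdir / "reference.fasta"
        SeqIO.write(
            [SeqRecord(Seq(self.reference), id="reference", description="synthetic pseudo-rCRS")],
            str(ref),
            "fasta",
        )
        paths["reference"] = ref
        meta = outdir / "metadata.tsv"
        self.metadata.to_csv(meta, sep="\t", index=False)
        paths["metadata"] = meta
        sidecar = outdir / "truth.json"
        sidecar.write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        paths["truth"] = sidecar
        trees = self.truth.get("trees", {})
        if trees:
            nwk = outdir / "true_genealogies.nwk"
            with nwk.open("w") as fh:
                for key in sorted(trees):
                    fh.write(trees[key] + "\n")
            paths["trees"] = nwk
        return paths


def make_study_fixture(
    populations: list[PopulationScenario],
    seed: int,
    cfg: SimulationConfig | None = None,
    motifs: dict[str, list[str]] | None = None,
    coord_map: ControlRegionMap = DEFAULT_MAP,
) -> StudyFixture:
    """Simulate a multi-population control-region study.

    Each population draws haplogroup membership from its mixture, simulates
    one genealogy per haplogroup cluster under the population's demographic
    model, plants the haplogroup's diagnostic motif at the cluster root, and
    evolves sequences. The truth sidecar records requested mixtures, realised
    counts, true Nef trajectories and true genealogies (Newick, branch
    lengths in generations) for parameter-recovery tests.
    """
    import pandas as pd

    from .seqdata import default_motif_table

    cfg = cfg or SimulationConfig()
    if motifs is None:
        motifs = {hg: [f"{p}{a}" for p, a in sorted(vs)] for hg, vs in default_motif_table().items()}
    reference = motif_compatible_reference(
        pseudo_rcrs(cfg.seq_length, cfg.base_freqs), motifs, coord_map
    )

    sequences: dict[str, str] = {}
    meta_rows = []
    truth: dict = {"populations": {}, "trees": {}, "clock": {
        "mu": cfg.mu, "generation_years": cfg.generation_years,
        "kappa": cfg.kappa, "gamma_shape": cfg.gamma_shape,
    }}
    true_labels: dict[str, str] = {}

    for pop in populations:
        probs = np.array(list(pop.mixture.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise SimulationError(
                f"haplogroup mixture for {pop.name} sums to {probs.sum():.6f}, not 1"
            )
        hgs = list(pop.mixture.keys())
        rng = derive_rng(seed, pop.name)
        counts = rng.multinomial(pop.n, probs)
        sample_idx = 0
        pop_truth = {
            "n": pop.n,
            "mixture_requested": dict(pop.mixture),
            "haplogroup_counts": {hg: int(c) for hg, c in zip(hgs, counts)},
            "model": {
                "sizes": list(pop.model.sizes),
                "change_times": list(pop.model.change_times),
            },
        }
        for hg, count in zip(hgs, counts):
            if count == 0:
                continue
            motif_sim = []
            for token in motifs.get(hg, []):
                ref_pos, allele = parse_variant(token)
                motif_sim.append((coord_map.ref_to_sim(ref_pos), allele))
            labels = [f"{pop.name}_{sample_idx + i:03d}" for i in range(count)]
            sample_idx += count
            hg_rng = derive_rng(seed, pop.name, hg)
            if count >= 2:
                tree = simulate_genealogy(pop.model, count, draw_seed(hg_rng))
                tree.tip_labels = labels
                seqs = evolve_sequences(tree, cfg, root_seq=reference, motif=motif_sim, rng=hg_rng)
                truth["trees"][f"{pop.name}/{hg}"] = tree.to_newick()
            else:
                # single lineage: evolve the planted root along one branch of
                # Nef(0) generations (a coalescent timescale's worth of drift)
                single = _single_lineage_sequence(
                    reference, motif_sim, pop.model.sizes[0], cfg, hg_rng
                )
                seqs = {labels[0]: single}
            for lab in labels:
                sequences[lab] = seqs[lab]
                true_labels[lab] = hg
                meta_rows.append(
                    {"sample": lab, "population": pop.name, "region": pop.region,
                     "language": pop.language, "lat": pop.lat, "lon": pop.lon}
                )
        truth["populations"][pop.name] = pop_truth

    truth["haplogroup_labels"] = true_labels
    metadata = pd.DataFrame(meta_rows, columns=["sample", "population", "region", "language", "lat", "lon"])
    return StudyFixture(sequences=sequences, metadata=metadata, truth=truth,
                        reference=reference, coord_map=coord_map)


def _single_lineage_sequence(reference, motif_sim, nef0, cfg, rng):
    L = cfg.seq_length
    states = np.array([BASE_INDEX[b] for b in reference], dtype=int)
    for pos, allele in motif_sim:
        states[pos - 1] = BASE_INDEX[allele]
    b = nef0 * cfg.mu * cfg.generation_years
    if b > 0:
        rates = discrete_gamma_rates(cfg.gamma_shape)
        categories = rng.integers(0, rates.size, size=L)
        q = hky_rate_matrix(cfg.kappa, cfg.base_freqs)
        for c, rate in enumerate(rates):
            sites = np.flatnonzero(categories == c)
            if sites.size == 0:
                continue
            pmat = expm(q * (b * rate))
            np.clip(pmat, 0.0, None, out=pmat)
            pmat /= pmat.sum(axis=1, keepdims=True)
            cum = np.cumsum(pmat, axis=1)
            states[sites] = _sample_children_states(states[sites], cum, rng)
    return "".join(BASES[s] for s in states)
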