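"""Between-population analyses: Φst, corrected pairwise differences,
hierarchical AMOVA with permutation tests, Mantel test, classical MDS,
shared-haplotype counts, and the MDS-centroid vs diversity correlation.

'Fst' throughout this package is the haplotype-distance-based Φst of the
AMOVA framework (Excoffier, Smouse & Quattro), the convention of Arlequin,
not allele-frequency Fst. Pairwise difference counts play the role of
squared Euclidean distances in the variance decomposition. Permutation
p-values use the (b+1)/(m+1) estimator and are seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import derive_rng, haversine_km
from .diversity import pairwise_difference_matrix


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric nonnegative distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "pairwise-difference"  # or Fst, geographic-km, euclidean

    def __post_init__(self):
        m = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise StructureError("matrix shape does not match labels")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise StructureError("diagonal must be zero")
        if np.any(np.abs(m - m.T) > 1e-12):
            raise StructureError("matrix must be symmetric")
        object.__setattr__(self, "values", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None
    grouping: str = ""


@dataclass
class MdsSolution:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n, dims), column means zero
    eigenvalues: np.ndarray  # all eigenvalues of the centered Gram matrix
    goodness_of_fit: float  # positive-eigenvalue mass captured by the kept axes
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Variance components from squared distances
# ---------------------------------------------------------------------------


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    """(1/n) Σ_{i<j in set} δ²_ij."""
    sub = d2[np.ix_(idx, idx)]
    return float(np.triu(sub, k=1).sum() / idx.size)


def two_level_components(d2: np.ndarray, pop_of: np.ndarray) -> tuple[float, float]:
    """(σ²_among, σ²_within) from squared distances and population codes."""
    n = d2.shape[0]
    pops, counts = np.unique(pop_of, return_counts=True)
    P = pops.size
    if P < 2:
        raise StructureError("need at least 2 populations")
    ss_total = float(np.triu(d2, k=1).sum() / n)
    ss_wp = sum(_ss_within(d2, np.flatnonzero(pop_of == p)) for p in pops)
    ss_ap = ss_total - ss_wp
    df_wp = n - P
    df_ap = P - 1
    sigma_w = ss_wp / df_wp if df_wp > 0 else 0.0
    n_c = (n - (counts**2).sum() / n) / df_ap
    sigma_a = (ss_ap / df_ap - sigma_w) / n_c
    return sigma_a, sigma_w


def pairwise_phist(
    seqs_a: list[str],
    seqs_b: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Φst between two populations with a permutation p-value.

    Returns (Φst, p, negative_flag). Negative estimates are reported as
    computed (flagged), not truncated. p = (b+1)/(m+1) over label
    permutations with Φst >= observed.
    """
    if n_perm < 1:
        raise StructureError("n_perm must be >= 1")
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise StructureError("both populations need n >= 2")
    seqs = list(seqs_a) + list(seqs_b)
    d2 = pairwise_difference_matrix(seqs)
    labels = np.array([0] * len(seqs_a) + [1] * len(seqs_b))
    obs = phist_from_distances(d2, labels)
    rng = derive_rng(seed, "phist")
    b = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if phist_from_distances(d2, perm) >= obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return float(obs), float(p), obs < 0


def phist_from_distances(d2: np.ndarray, pop_of: np.ndarray) -> float:
    sigma_a, sigma_w = two_level_components(d2, pop_of)
    total = sigma_a + sigma_w
    if total == 0:
        return 0.0
    return sigma_a / total


def phist_matrix(
    populations: dict[str, list[str]], n_perm: int = 10_000, seed: int = 0
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise Φst matrix (distance kind 'Fst') and a table with p-values.

    Negative Φst estimates are kept in the table but clipped to 0 in the
    distance matrix so downstream MDS sees a valid dissimilarity.
    """
    names = sorted(populations)
    n = len(names)
    mat = np.zeros((n, n))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            phist, p, neg = pairwise_phist(
                populations[names[i]], populations[names[j]], n_perm=n_perm,
                seed=derive_rng(seed, names[i], names[j]).integers(2**31),
            )
            mat[i, j] = mat[j, i] = max(phist, 0.0)
            rows.append({"pop_a": names[i], "pop_b": names[j], "phist": phist,
                         "p": p, "negative": neg})
    return DistanceMatrix(tuple(names), mat, kind="Fst"), pd.DataFrame(rows)


def corrected_pairwise_diff(seqs_a: list[str], seqs_b: list[str]) -> float:
    """d_xy - (d_x + d_y)/2: between-population mean difference corrected for
    within-population diversity."""
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise StructureError("both populations need n >= 2")
    na, nb = len(seqs_a), len(seqs_b)
    d = pairwise_difference_matrix(list(seqs_a) + list(seqs_b))
    between = d[:na, na:].mean()
    within_a = np.triu(d[:na, :na], k=1).sum() / (na * (na - 1) / 2)
    within_b = np.triu(d[na:, na:], k=1).sum() / (nb * (nb - 1) / 2)
    return float(between - (within_a + within_b) / 2.0)


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------


def _amova_components(
    d2: np.ndarray, pop_of: np.ndarray, group_of_pop: dict
) -> tuple[float, float, float]:
    """Excoffier-Smouse-Quattro three-level variance components.

    pop_of: per-individual population code; group_of_pop maps population code
    to group code.
    """
    n = d2.shape[0]
    pops, pop_counts = np.unique(pop_of, return_counts=True)
    P = pops.size
    group_of = np.array([group_of_pop[p] for p in pop_of])
    groups = np.unique(group_of)
    G = groups.size
    if G < 2:
        raise StructureError("need at least 2 groups")
    ss_total = float(np.triu(d2, k=1).sum() / n)
    ss_wp = sum(_ss_within(d2, np.flatnonzero(pop_of == p)) for p in pops)
    ss_groups = sum(_ss_within(d2, np.flatnonzero(group_of == g)) for g in groups)
    ss_ap_wg = ss_groups - ss_wp
    ss_ag = ss_total - ss_groups

    df_wp = n - P
    df_ap = P - G
    df_ag = G - 1

    count_of_pop = dict(zip(pops, pop_counts))
    group_sizes = {g: int((group_of == g).sum()) for g in groups}
    sum_n2_by_group = {
        g: sum(count_of_pop[p] ** 2 for p in pops if group_of_pop[p] == g) for g in groups
    }

    sigma_w = ss_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0:
        n_prime = (n - sum(sum_n2_by_group[g] / group_sizes[g] for g in groups)) / df_ap
        sigma_b = (ss_ap_wg / df_ap - sigma_w) / n_prime
    else:
        sigma_b = 0.0
    n_dprime = (
        sum(sum_n2_by_group[g] / group_sizes[g] for g in groups)
        - sum(count_of_pop[p] ** 2 for p in pops) / n
    ) / df_ag
    n_tprime = (n - sum(s**2 for s in group_sizes.values()) / n) / df_ag
    sigma_a = (ss_ag / df_ag - sigma_w - n_dprime * sigma_b) / n_tprime
    return sigma_a, sigma_b, sigma_w


def amova(
    populations: dict[str, list[str]],
    grouping: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    grouping_label: str = "",
) -> AmovaResult:
    """Three-level AMOVA on pairwise difference counts.

    ``grouping`` maps population name -> group name. Permutation tests:
    F_CT permutes whole populations among groups, F_SC permutes individuals
    among populations within groups, F_ST permutes individuals among all
    populations.
    """
    names = sorted(populations)
    missing = [p for p in names if p not in grouping]
    if missing:
        raise StructureError(f"populations without a group: {missing}")
    groups = {grouping[p] for p in names}
    if len(groups) < 2:
        raise StructureError("need at least 2 groups")
    if any(sum(1 for p in names if grouping[p] == g) == len(names) for g in groups):
        raise StructureError("degenerate design: one group contains all populations")

    seqs: list[str] = []
    pop_of_list: list[int] = []
    for i, name in enumerate(names):
        seqs.extend(populations[name])
        pop_of_list.extend([i] * len(populations[name]))
    pop_of = np.array(pop_of_list)
    d2 = pairwise_difference_matrix(seqs)
    group_names = sorted(groups)
    gcode = {g: i for i, g in enumerate(group_names)}
    group_of_pop = {i: gcode[grouping[name]] for i, name in enumerate(names)}

    sigma_a, sigma_b, sigma_w = _amova_components(d2, pop_of, group_of_pop)
    total = sigma_a + sigma_b + sigma_w
    f_ct = sigma_a / total if total else 0.0
    f_sc = sigma_b / (sigma_b + sigma_w) if (sigma_b + sigma_w) else 0.0
    f_st = (sigma_a + sigma_b) / total if total else 0.0

    rng = derive_rng(seed, "amova", grouping_label)

    # F_CT: permute whole populations among groups (keep group sizes in pops)
    pop_groups = np.array([group_of_pop[i] for i in range(len(names))])
    b_ct = 0
    for _ in range(n_perm):
        perm = rng.permutation(pop_groups)
        gp = {i: perm[i] for i in range(len(names))}
        sa, sb, sw = _amova_components(d2, pop_of, gp)
        tot = sa + sb + sw
        if (sa / tot if tot else 0.0) >= f_ct - 1e-12:
            b_ct += 1
    p_ct = (b_ct + 1) / (n_perm + 1)

    # F_SC: permute individuals among populations within their group
    b_sc = 0
    group_of_ind = np.array([group_of_pop[p] for p in pop_of])
    for _ in range(n_perm):
        perm_pop = pop_of.copy()
        for g in set(group_of_pop.values()):
            idx = np.flatnonzero(group_of_ind == g)
            perm_pop[idx] = perm_pop[idx][rng.permutation(idx.size)]
        sa, sb, sw = _amova_components(d2, perm_pop, group_of_pop)
        if (sb / (sb + sw) if (sb + sw) else 0.0) >= f_sc - 1e-12:
            b_sc += 1
    p_sc = (b_sc + 1) / (n_perm + 1)

    # F_ST: permute individuals among populations
    b_st = 0
    for _ in range(n_perm):
        perm_pop = pop_of[rng.permutation(pop_of.size)]
        sa, sb, sw = _amova_components(d2, perm_pop, group_of_pop)
        tot = sa + sb + sw
        if ((sa + sb) / tot if tot else 0.0) >= f_st - 1e-12:
            b_st += 1
    p_st = (b_st + 1) / (n_perm + 1)

    return AmovaResult(
        sigma_among_groups=sigma_a, sigma_among_pops=sigma_b, sigma_within=sigma_w,
        f_ct=f_ct, f_sc=f_sc, f_st=f_st, p_ct=p_ct, p_sc=p_sc, p_st=p_st,
        grouping=grouping_label,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel(
    dA: DistanceMatrix, dB: DistanceMatrix, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Pearson correlation between distance matrices with a permutation p.

    One matrix's rows and columns are permuted jointly; p = (b+1)/(m+1) for a
    two-sided test on |r|.
    """
    if dA.labels != dB.labels:
        raise StructureError("matrices must share labels and order")
    n = dA.n
    if n < 3:
        raise StructureError("Mantel needs at least 3 labels")
    a = dA.upper_triangle()
    if np.std(a) == 0 or np.std(dB.upper_triangle()) == 0:
        raise StructureError("constant distance matrix: correlation undefined")

    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        b = dB.values[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(a, b)[0, 1])

    obs = corr(np.arange(n))
    rng = derive_rng(seed, "mantel")
    b_count = 0
    for _ in range(n_perm):
        if abs(corr(rng.permutation(n))) >= abs(obs) - 1e-12:
            b_count += 1
    p = (b_count + 1) / (n_perm + 1)
    return obs, p


def geographic_distance_matrix(meta: pd.DataFrame) -> DistanceMatrix:
    """Great-circle kilometres between population centroids from metadata lat/lon."""
    pops = meta.groupby("population")[["lat", "lon"]].mean().sort_index()
    names = tuple(pops.index)
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = haversine_km(
                pops.iloc[i]["lat"], pops.iloc[i]["lon"],
                pops.iloc[j]["lat"], pops.iloc[j]["lon"],
            )
    return DistanceMatrix(names, mat, kind="geographic-km")


# ---------------------------------------------------------------------------
# Classical MDS (principal coordinates)
# ---------------------------------------------------------------------------


def mds(d: DistanceMatrix, dims: int = 2) -> MdsSolution:
    """Classical (metric) multidimensional scaling.

    Double-centers the squared distance matrix, takes the top eigenpairs;
    negative eigenvalues are dropped and their mass reported through the
    goodness-of-fit (positive-eigenvalue mass captured by the kept axes).
    """
    n = d.n
    if n < 3:
        raise StructureError("MDS needs at least 3 labels")
    if dims > n - 1:
        raise StructureError(f"dims={dims} exceeds n-1={n - 1}")
    sq = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ sq @ j
    gram = (gram + gram.T) / 2.0
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    kept = eigval[:dims].clip(min=0.0)
    coords = eigvec[:, :dims] * np.sqrt(kept)
    coords = coords - coords.mean(axis=0, keepdims=True)
    pos_mass = eigval[eigval > 0].sum()
    gof = float(kept.sum() / pos_mass) if pos_mass > 0 else 1.0
    return MdsSolution(
        labels=d.labels, coordinates=coords, eigenvalues=eigval,
        goodness_of_fit=gof,
        metadata={"method": "classical-metric-scaling", "input_kind": d.kind},
    )


def centroid_diversity_correlation(
    solution: MdsSolution, diversity: dict[str, float]
) -> tuple[float, float]:
    """Pearson r (and p) between distance-from-centroid in MDS space and Ĥ."""
    from scipy.stats import pearsonr

    labels = solution.labels
    if set(labels) != set(diversity):
        raise StructureError("MDS labels and diversity keys differ")
    if len(labels) < 3:
        raise StructureError("need at least 3 populations")
    centroid = solution.coordinates.mean(axis=0)
    dist = np.linalg.norm(solution.coordinates - centroid, axis=1)
    h = np.array([diversity[lab] for lab in labels])
    if np.std(h) == 0 or np.std(dist) == 0:
        raise StructureError("constant input: correlation undefined")
    r, p = pearsonr(dist, h)
    return float(r), float(p)


def shared_haplotype_matrix(hap_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Entry (i, j): number of distinct haplotypes present in both populations."""
    names = sorted(hap_sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i:]:
            shared = len(hap_sets[a] & hap_sets[b]) if a != b else len(hap_sets[a])
            mat.loc[a, b] = mat.loc[b, a] = shared
    return mat
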