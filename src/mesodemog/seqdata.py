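"""Alignment and metadata I/O, EMPOP-style variant profiles, haplogroup
assignment from diagnostic motifs, and haplogroup frequency tables.

Sequences are expressed as differences from a reference (position + allele,
1-based reference coordinates); haplogroup calling scores each candidate by
the fraction of its diagnostic variants present in the profile. Indels and
ambiguity codes are excluded from profiles and haplotype identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .coords import DEFAULT_MAP, ControlRegionMap, region_of

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

METADATA_COLUMNS = ["sample", "population", "region", "language", "lat", "lon"]


class FormatError(ValueError):
    """Malformed alignment or metadata file."""


class ReconciliationError(ValueError):
    """FASTA and metadata disagree on sample membership."""


class ConfigError(ValueError):
    """Invalid motif table or option."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantProfile:
    """A sequence as a set of substitutions relative to the reference.

    ``variants`` holds (1-based reference position, allele) pairs; every
    allele differs from the reference base at that position. ``n_skipped``
    counts mismatching sites dropped for ambiguity (N etc.).
    """

    sample: str
    variants: frozenset[tuple[int, str]]
    n_skipped: int = 0

    def __post_init__(self):
        positions = [p for p, _ in self.variants]
        if len(positions) != len(set(positions)):
            raise ConfigError(f"duplicate positions in profile for {self.sample}")

    def in_region(self, region: str) -> frozenset[tuple[int, str]]:
        """Variants restricted to 'HVRI', 'HVRII' or 'full'."""
        if region == "full":
            return self.variants
        if region not in ("HVRI", "HVRII"):
            raise ConfigError(f"unknown region filter {region!r}")
        return frozenset((p, a) for p, a in self.variants if region_of(p) == region)

    def regions(self) -> dict[tuple[int, str], str]:
        return {(p, a): region_of(p) for p, a in self.variants}


class MotifTable(dict):
    """Mapping haplogroup label -> frozenset of diagnostic (position, allele)."""

    def __init__(self, data: dict):
        super().__init__()
        for label, variants in data.items():
            vs = frozenset(variants)
            if not vs:
                raise ConfigError(f"haplogroup {label!r} has no diagnostic variants")
            self[str(label)] = vs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotifTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_tokens(raw)

    @classmethod
    def from_tokens(cls, raw: dict[str, list[str]]) -> "MotifTable":
        data = {}
        for label, tokens in raw.items():
            variants = []
            for token in tokens:
                token = str(token)
                pos, allele = token[:-1], token[-1].upper()
                if allele not in VALID_BASES:
                    raise ConfigError(f"bad allele in motif token {token!r} for {label}")
                variants.append((int(pos), allele))
            data[label] = variants
        return cls(data)


def default_motif_table() -> MotifTable:
    """The packaged illustrative motif table (see data/default_motifs.yaml)."""
    with resources.files("mesodemog.data").joinpath("default_motifs.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return MotifTable.from_tokens(raw)


@dataclass(frozen=True)
class HaplogroupCall:
    sample: str
    label: str
    score: float
    runner_up: str | None = None
    runner_up_score: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ConfigError("score must lie in [0, 1]")
        if self.score < self.runner_up_score - 1e-12:
            raise ConfigError("best score must be >= runner-up score")


UNASSIGNED = "unassigned"


@dataclass
class FrequencyTable:
    """Haplogroup counts and percentages per population plus a pooled Total.

    Rows are haplogroups (plus an 'unassigned' row when present), columns are
    populations plus 'Total'; column count sums equal each population's n and
    percentages are 100*count/n rounded to one decimal.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_alignment(fasta_path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA; all sequences must have equal length."""
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    length = None
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise FormatError(
                f"ragged alignment: record {record.id!r} has length {len(seq)}, expected {length}"
            )
        if record.id in sequences:
            raise FormatError(f"duplicate record id {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no sequences in {fasta_path}")
    return sequences


def read_metadata(tsv_path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (sample, population, region, language, lat, lon)."""
    meta = pd.read_csv(tsv_path, sep="\t", dtype={"sample": str, "population": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    return meta


def load_dataset(fasta_path: str | Path, tsv_path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Join alignment and metadata; every FASTA sample must appear in the metadata."""
    sequences = read_alignment(fasta_path)
    meta = read_metadata(tsv_path)
    known = set(meta["sample"])
    orphans = sorted(s for s in sequences if s not in known)
    if orphans:
        raise ReconciliationError(f"samples in FASTA but not metadata: {orphans}")
    meta = meta[meta["sample"].isin(sequences)].reset_index(drop=True)
    return sequences, meta


# ---------------------------------------------------------------------------
# Variant profiles and haplogroup calling
# ---------------------------------------------------------------------------


def call_variants(
    sample: str,
    sequence: str,
    reference: str,
    coord_map: ControlRegionMap = DEFAULT_MAP,
) -> VariantProfile:
    """Differences between an aligned sequence and the reference.

    One variant per mismatching unambiguous site; sites where either base is
    not A/C/G/T are skipped (counted in ``n_skipped``). Positions reported in
    1-based reference coordinates via the control-region offset map.
    """
    if len(sequence) != len(reference):
        raise FormatError(
            f"sequence {sample!r} length {len(sequence)} != reference length {len(reference)}"
        )
    variants = []
    skipped = 0
    for i, (s, r) in enumerate(zip(sequence.upper(), reference.upper())):
        if s == r:
            continue
        if s not in VALID_BASES or r not in VALID_BASES:
            skipped += 1
            continue
        variants.append((coord_map.sim_to_ref(i + 1), s))
    if skipped:
        logger.info("call_variants(%s): skipped %d ambiguous mismatching sites", sample, skipped)
    return VariantProfile(sample=sample, variants=frozenset(variants), n_skipped=skipped)


def assign_haplogroup(
    profile: VariantProfile, motifs: MotifTable, min_score: float = 0.8
) -> HaplogroupCall:
    """Best-matching haplogroup by diagnostic-variant fraction.

    Score per label = |profile ∩ diagnostics| / |diagnostics|; the best label
    is returned if its score reaches ``min_score``, otherwise 'unassigned'.
    Ties go to the larger diagnostic set, then lexicographically smaller label.
    """
    if not motifs:
        raise ConfigError("empty motif table")
    scored = []
    for label, diag in motifs.items():
        score = len(profile.variants & diag) / len(diag)
        scored.append((-score, -len(diag), label))
    scored.sort()
    best_score = -scored[0][0]
    best_label = scored[0][2]
    runner_up, runner_up_score = (scored[1][2], -scored[1][0]) if len(scored) > 1 else (None, 0.0)
    if best_score < min_score:
        return HaplogroupCall(profile.sample, UNASSIGNED, best_score, best_label, best_score)
    return HaplogroupCall(profile.sample, best_label, best_score, runner_up, runner_up_score)


def frequency_table(
    calls: list[HaplogroupCall], populations: dict[str, str]
) -> FrequencyTable:
    """Gene-counting haplogroup frequencies per population plus pooled Total."""
    warnings: list[str] = []
    by_sample = {c.sample: c.label for c in calls}
    missing = [s for s in populations if s not in by_sample]
    if missing:
        raise ConfigError(f"samples without haplogroup calls: {sorted(missing)[:5]}")
    pops = sorted(set(populations.values()))
    labels = sorted({c.label for c in calls if c.label != UNASSIGNED})
    rows = labels + ([UNASSIGNED] if any(c.label == UNASSIGNED for c in calls) else [])
    counts = pd.DataFrame(0, index=rows, columns=pops + ["Total"], dtype=int)
    for sample, pop in populations.items():
        label = by_sample[sample]
        counts.loc[label, pop] += 1
        counts.loc[label, "Total"] += 1
    empty = [p for p in pops if counts[p].sum() == 0]
    for p in empty:
        warnings.append(f"population {p!r} has no samples; excluded")
        counts = counts.drop(columns=p)
    n_per_col = counts.sum(axis=0)
    percent = (100.0 * counts / n_per_col).round(1)
    return FrequencyTable(counts=counts, percent=percent, warnings=warnings)


def haplogroup_heterogeneity(table: FrequencyTable) -> tuple[float, int, float, bool]:
    """Pearson chi-square test of haplogroup-frequency homogeneity.

    Unassigned calls and the pooled Total column are excluded; zero rows and
    columns are dropped with a warning before testing. Returns
    (statistic, df, p, low_expected_flag) where the flag marks any expected
    cell count below 1.
    """
    from scipy.stats import chi2_contingency

    counts = table.counts.drop(columns=["Total"], errors="ignore")
    counts = counts.drop(index=[UNASSIGNED], errors="ignore")
    zero_rows = counts.index[(counts.sum(axis=1) == 0)]
    zero_cols = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        logger.warning(
            "dropping zero rows %s / columns %s before chi-square",
            list(zero_rows), list(zero_cols),
        )
        counts = counts.drop(index=zero_rows, columns=zero_cols)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigError("chi-square needs at least 2 haplogroups and 2 populations")
    obs = counts.to_numpy(dtype=float)
    stat, p, df, expected = chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p), bool((expected < 1).any())


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------


def haplotype_id(variants: frozenset[tuple[int, str]]) -> str:
    """Canonical stable id: sorted 'posALLELE' tokens joined by '|'; 'ref' if empty."""
    if not variants:
        return "ref"
    return "|".join(f"{p}{a}" for p, a in sorted(variants))


def collapse_haplotypes(
    profiles: list[VariantProfile], region: str = "full"
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Haplotype identity by exact variant-set equality within a region.

    Returns (sample -> haplotype id, haplotype id -> set of samples).
    """
    per_sample: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for prof in profiles:
        hid = haplotype_id(prof.in_region(region))
        per_sample[prof.sample] = hid
        members.setdefault(hid, set()).add(prof.sample)
    return per_sample, members


def population_haplotype_sets(
    per_sample: dict[str, str], populations: dict[str, str]
) -> dict[str, set[str]]:
    """Distinct haplotype ids present in each population."""
    sets: dict[str, set[str]] = {}
    for sample, hid in per_sample.items():
        pop = populations[sample]
        sets.setdefault(pop, set()).add(hid)
    return sets
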