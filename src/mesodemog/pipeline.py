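"""Pipeline orchestration: simulate -> haplogroups -> diversity -> structure
-> skyline -> demography from one YAML config, with fail-fast validation,
stage-tagged logging and a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import demography, diversity, seqdata, skyline, structure
from ._util import derive_rng
from .simulate import (
    DemographicModel,
    PopulationScenario,
    SimulationConfig,
    make_study_fixture,
)

logger = logging.getLogger("mesodemog.pipeline")

ALL_STAGES = ("simulate", "haplogroups", "diversity", "structure", "skyline", "demography")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One run: either a simulation scenario or input paths, stage toggles,
    seeds and clock/period settings."""

    outdir: Path
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    scenario: dict | None = None  # simulate stage input
    fasta: Path | None = None  # pre-existing inputs (skip simulate)
    metadata: Path | None = None
    reference: Path | None = None
    motifs: Path | None = None
    periods: Path | None = None
    mu: float = 3.02e-7
    generation_years: float = 25.0
    skyline_groups: int = 5
    skyline_iterations: int = 100_000
    skyline_thin: int = 100
    n_perm: int = 1000
    use_true_trees: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["outdir"] = Path(raw["outdir"])
        for key in ("fasta", "metadata", "reference", "motifs", "periods"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        if "simulate" in self.stages:
            if not self.scenario:
                raise PipelineError("simulate stage enabled but no scenario given")
        else:
            for name in ("fasta", "metadata", "reference"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"required input {name!r} missing: {p}")
        for name in ("motifs", "periods"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"configured {name} file does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scenario_populations(scenario: dict) -> list[PopulationScenario]:
    pops = []
    for p in scenario["populations"]:
        model = DemographicModel(
            sizes=tuple(p["model"]["sizes"]),
            change_times=tuple(p["model"].get("change_times", ())),
            label=p["name"],
        )
        pops.append(PopulationScenario(
            name=p["name"], n=int(p["n"]), mixture=dict(p["mixture"]), model=model,
            region=p.get("region", "Unknown"), language=p.get("language", "Unknown"),
            lat=float(p.get("lat", 0.0)), lon=float(p.get("lon", 0.0)),
        ))
    return pops


def run(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the run manifest.

    Any stage failure aborts with the stage name; partial outputs are moved
    under ``failed/``. Output directories are write-once per stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    filehandler = logging.FileHandler(outdir / "run.log")
    root = logging.getLogger("mesodemog")
    root.addHandler(handler)
    root.addHandler(filehandler)
    root.setLevel(logging.INFO)

    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            logger.info("[%s] starting", stage)
            stage_dir = outdir / stage
            if stage_dir.exists() and any(stage_dir.iterdir()):
                raise PipelineError(f"stage directory {stage_dir} already has outputs (write-once)")
            stage_dir.mkdir(exist_ok=True)
            _STAGE_FUNCS[stage](config, state, stage_dir)
            manifest["stages"][stage] = {
                "outputs": sorted(p.name for p in stage_dir.iterdir())
            }
            manifest["outputs"].update(
                {f"{stage}/{p.name}": _sha256(p) for p in stage_dir.iterdir() if p.is_file()}
            )
            logger.info("[%s] done", stage)
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.txt").write_text(f"stage failure: {exc}\n")
        raise PipelineError(f"pipeline aborted: {exc}") from exc
    finally:
        root.removeHandler(handler)
        root.removeHandler(filehandler)
        filehandler.close()

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict, stage_dir: Path) -> None:
    pops = _scenario_populations(config.scenario)
    cfg_kwargs = config.scenario.get("simulation", {})
    cfg = SimulationConfig(mu=config.mu, generation_years=config.generation_years, **cfg_kwargs)
    fixture = make_study_fixture(pops, seed=config.seed, cfg=cfg)
    paths = fixture.write(stage_dir)
    state["fixture"] = fixture
    state["sequences"] = fixture.sequences
    state["metadata"] = fixture.metadata
    state["reference"] = fixture.reference
    state["truth"] = fixture.truth
    logger.info("[simulate] wrote %d samples to %s", len(fixture.sequences), paths["fasta"])


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "sequences" in state:
        return
    sequences, meta = seqdata.load_dataset(config.fasta, config.metadata)
    ref = seqdata.read_alignment(config.reference)
    state["sequences"] = sequences
    state["metadata"] = meta
    state["reference"] = next(iter(ref.values()))


def _profiles(config: RunConfig, state: dict) -> list[seqdata.VariantProfile]:
    if "profiles" not in state:
        _load_inputs(config, state)
        state["profiles"] = [
            seqdata.call_variants(name, seq, state["reference"])
            for name, seq in state["sequences"].items()
        ]
    return state["profiles"]


def _populations_of(state: dict) -> dict[str, str]:
    meta = state["metadata"]
    return dict(zip(meta["sample"], meta["population"]))


def _seqs_by_pop(state: dict) -> dict[str, list[str]]:
    pops: dict[str, list[str]] = {}
    for sample, pop in _populations_of(state).items():
        pops.setdefault(pop, []).append(state["sequences"][sample])
    return pops


def _stage_haplogroups(config: RunConfig, state: dict, stage_dir: Path) -> None:
    profiles = _profiles(config, state)
    motifs = (seqdata.MotifTable.from_yaml(config.motifs) if config.motifs
              else seqdata.default_motif_table())
    calls = [seqdata.assign_haplogroup(p, motifs) for p in profiles]
    state["calls"] = calls
    table = seqdata.frequency_table(calls, _populations_of(state))
    table.counts.to_csv(stage_dir / "haplogroup_counts.tsv", sep="\t")
    table.percent.to_csv(stage_dir / "haplogroup_percent.tsv", sep="\t")
    per_sample, _ = seqdata.collapse_haplotypes(profiles, region="HVRI")
    pd.DataFrame(
        {"sample": list(per_sample), "hvri_haplotype": list(per_sample.values())}
    ).to_csv(stage_dir / "haplotypes_hvri.tsv", sep="\t", index=False)
    state["frequency_table"] = table


def _stage_diversity(config: RunConfig, state: dict, stage_dir: Path) -> None:
    _load_inputs(config, state)
    table = diversity.diversity_table(_seqs_by_pop(state))
    table.to_csv(stage_dir / "diversity.tsv", sep="\t", index=False)
    state["diversity"] = table


def _stage_structure(config: RunConfig, state: dict, stage_dir: Path) -> None:
    _load_inputs(config, state)
    pops = _seqs_by_pop(state)
    rng = derive_rng(config.seed, "structure")
    dmat, ptable = structure.phist_matrix(pops, n_perm=config.n_perm,
                                          seed=int(rng.integers(2**31)))
    ptable.to_csv(stage_dir / "phist.tsv", sep="\t", index=False)
    if dmat.n >= 3:
        sol = structure.mds(dmat)
        pd.DataFrame(sol.coordinates, index=list(sol.labels),
                     columns=["mds1", "mds2"]).to_csv(stage_dir / "mds.tsv", sep="\t")
        state["mds"] = sol
        meta = state["metadata"]
        if meta[["lat", "lon"]].abs().to_numpy().sum() > 0:
            geo = structure.geographic_distance_matrix(meta)
            if geo.labels == dmat.labels:
                try:
                    r, p = structure.mantel(dmat, geo, n_perm=config.n_perm,
                                            seed=int(rng.integers(2**31)))
                    (stage_dir / "mantel.json").write_text(
                        json.dumps({"r": r, "p": p}))
                except structure.StructureError as exc:
                    logger.warning("[structure] mantel skipped: %s", exc)
    # AMOVA grouped by metadata region when >= 2 regions
    meta = state["metadata"]
    grouping = dict(meta.drop_duplicates("population")[["population", "region"]].values)
    if len(set(grouping.values())) >= 2:
        res = structure.amova(pops, grouping, n_perm=config.n_perm,
                              seed=int(rng.integers(2**31)), grouping_label="region")
        (stage_dir / "amova_region.json").write_text(json.dumps({
            "f_ct": res.f_ct, "f_sc": res.f_sc, "f_st": res.f_st,
            "p_ct": res.p_ct, "p_sc": res.p_sc, "p_st": res.p_st,
        }, indent=2))
    profiles = _profiles(config, state)
    per_sample, _ = seqdata.collapse_haplotypes(profiles, region="HVRI")
    hap_sets = seqdata.population_haplotype_sets(per_sample, _populations_of(state))
    structure.shared_haplotype_matrix(hap_sets).to_csv(
        stage_dir / "shared_haplotypes_hvri.tsv", sep="\t")


def _stage_skyline(config: RunConfig, state: dict, stage_dir: Path) -> None:
    _load_inputs(config, state)
    clock = skyline.ClockConfig(mu=config.mu, generation_years=config.generation_years)
    trajectories: dict[str, skyline.SkylineTrajectory] = {}
    meta = state["metadata"]
    truth = state.get("truth", {})
    for pop in sorted(meta["population"].unique()):
        samples = meta.loc[meta["population"] == pop, "sample"]
        if len(samples) < 3:
            logger.warning("[skyline] population %s has <3 samples; skipped", pop)
            continue
        ivs_list = []
        if config.use_true_trees and truth.get("trees"):
            from .simulate import Genealogy

            for key, nwk in truth["trees"].items():
                if key.startswith(f"{pop}/"):
                    tree = Genealogy.from_newick(nwk)
                    if tree.n_tips >= 2:
                        ivs_list.append(skyline.coalescent_intervals(tree))
        if not ivs_list:
            seqs = {s: state["sequences"][s] for s in samples}
            tree = skyline.estimate_genealogy(seqs, clock)
            if tree.tmrca == 0:
                logger.warning("[skyline] population %s degenerate (no variation); skipped", pop)
                continue
            ivs_list = [skyline.coalescent_intervals(tree)]
        n_events = sum(iv.n_events for iv in ivs_list)
        post = skyline.mcmc_skyline(
            ivs_list, m=min(config.skyline_groups, n_events),
            iterations=config.skyline_iterations, thin=config.skyline_thin,
            seed=int(derive_rng(config.seed, "skyline", pop).integers(2**31)),
        )
        traj = skyline.skyline_trajectory(post, clock)
        traj.to_frame().to_csv(stage_dir / f"trajectory_{pop}.tsv", sep="\t", index=False)
        trajectories[pop] = traj
    state["trajectories"] = trajectories


def _stage_demography(config: RunConfig, state: dict, stage_dir: Path) -> None:
    if "trajectories" not in state:
        raise PipelineError("demography stage needs skyline trajectories")
    periods = (demography.PeriodTable.from_yaml(config.periods) if config.periods
               else demography.PeriodTable.default())
    extrema, inversions, series_rows = [], [], []
    for pop, traj in state["trajectories"].items():
        grid_t, grid_n = demography.trajectory_to_generations(
            traj, config.generation_years)
        series = demography.igr_series(grid_t, grid_n, periods)
        for t, nef, igr, per in zip(series.times_ybp, series.nef, series.igr, series.periods):
            series_rows.append({"population": pop, "time_ybp": t, "nef": nef,
                                "igr_percent": igr, "period": per})
        extrema.append(demography.locate_extrema(series, periods, population=pop))
        if series.igr.size >= 5:
            inversions.append(demography.detect_inversion(series, window=5,
                                                          periods=periods, population=pop))
    meta = state["metadata"]
    regions = dict(meta.drop_duplicates("population")[["population", "region"]].values)
    summary, scatter = demography.report_tables(extrema, inversions, regions)
    summary.to_csv(stage_dir / "extrema.tsv", sep="\t", index=False)
    scatter.to_csv(stage_dir / "period_scatter.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"population": r.population, "time_ybp": r.time_ybp, "period": r.period,
          "direction": r.direction, "window": r.window} for r in inversions]
    ).to_csv(stage_dir / "inversions.tsv", sep="\t", index=False)
    pd.DataFrame(series_rows).to_csv(stage_dir / "igr_series.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "haplogroups": _stage_haplogroups,
    "diversity": _stage_diversity,
    "structure": _stage_structure,
    "skyline": _stage_skyline,
    "demography": _stage_demography,
}
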