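# mesodemog

Demographic history from mtDNA control-region sequences, end to end: the
analysis pipeline used for questions like *"when did Mesoamerican
populations grow, and when did they begin to decline?"* applied to
hypervariable-region alignments (HVRI/HVRII) from multiple populations.

The package is aimed at population geneticists and molecular anthropologists
who work with haploid control-region data and want a reproducible, testable
version of the classic toolchain:

* **haplogroup frequencies** by gene counting from diagnostic-motif calls
  on EMPOP-style variant profiles (A2, B2, B4b1, C1, D1, D4h3a, X2a, ...);
* **within-population diversity**: haplotype count *k*, segregating sites
  *S*, haplotype diversity *Ĥ*, nucleotide diversity *π*, mean pairwise
  differences *θ*, Tajima's *D* and Fu's *F*<sub>S</sub>;
* **structure**: pairwise Φ<sub>ST</sub> (AMOVA-based, the Arlequin
  convention), corrected pairwise differences, hierarchical AMOVA
  (F<sub>CT</sub>/F<sub>SC</sub>/F<sub>ST</sub> with the three permutation
  schemes), Mantel test against great-circle distances, classical MDS and
  shared HVRI haplotypes;
* **Bayesian skyline**: the effective number of breeding females Nef(t)
  reconstructed from coalescent intervals of a genealogy by MCMC over an
  m-group piecewise-constant model, with the classic (deterministic)
  skyline as a cross-check;
* **inter-generational growth rates (IGR)**: per 25-year generation,
  IGR<sub>n</sub> = 100·(Nef<sub>n</sub> − Nef<sub>n−1</sub>)/Nef<sub>n−1</sub>,
  with extrema and trend inversions mapped onto the Mesoamerican chronology
  (Lithic, Preclassic, Classic, Postclassic, Colonial).

A coalescent simulator (msprime-backed genealogies, exact HKY+Γ sequence
evolution with planted haplogroup motifs) provides synthetic datasets with
fully known truth, so every stage is validated by parameter recovery.

## The core model

Conditional on an ultrametric genealogy, the time spans during which exactly
*k* lineages persist are the sufficient statistic for Nef. With *k* lineages
in an epoch of size *N* the coalescent log-likelihood contributes
−*k*(*k*−1)Δ*t*/(2*N*), minus ln *N* at each coalescence. The skyline
sampler places the *n*−1 coalescent events of one or more genealogies into
*m* contiguous groups, assigns each group a constant Nef, and explores both
group boundaries and sizes by Metropolis–Hastings under a scale-invariant
prior on the first group and exponential smoothing between neighbours.
Generations convert to calendar years via a strict clock
(μ = 3.02×10⁻⁷ substitutions/site/year, 25-year generations).

## Worked example

```python
import numpy as np
from mesodemog import (
    DemographicModel, simulate_genealogy, coalescent_intervals,
    mcmc_skyline, skyline_trajectory,
)
from mesodemog import demography as dg
from mesodemog.simulate import mesoamerican_growth_decline_model

# growth from ~13,000 ybp, peak ~2,500 ybp, ten-fold decline to the present
model = mesoamerican_growth_decline_model()
intervals = [
    coalescent_intervals(simulate_genealogy(model, 80, seed=2000 + j))
    for j in range(6)
]
post = mcmc_skyline(intervals, m=20, iterations=150_000, thin=100, seed=0)
traj = skyline_trajectory(post)
grid_t, grid_n = dg.trajectory_to_generations(traj)
series = dg.igr_series(grid_t, grid_n)
inv = dg.detect_inversion(series, window=21)
print(f"Nef at present (median): {traj.median[0]:.0f}")
print(f"detected inversion: {inv.time_ybp:.0f} ybp "
      f"({inv.period}, {inv.direction})")
```

Output:

```
Nef at present (median): 2160
detected inversion: 2425 ybp (Preclassic, positive->negative)
```

The skyline recovers the simulated present-day size (truth 2,000) and the
IGR inversion lands next to the true decline onset (truth 2,500 ybp, the
Lithic/Preclassic boundary). Replicate-to-replicate the detected onset
scatters by a few hundred years around the truth — the resolution limit of
coalescent data in a high-Nef epoch.

The full pipeline runs from one YAML config:

```bash
mesodemog run --config run.yaml          # simulate → ... → demography
mesodemog skyline --fasta aln.fasta --groups 10 --seed 1 --out traj.tsv
mesodemog igr --trajectory traj.tsv --out igr_out/
```

## Layout

```
src/mesodemog/
  simulate.py    coalescent genealogies, HKY+Γ evolution, study fixtures
  coords.py      control-region coordinate map (16024-16569 + 1-576)
  seqdata.py     alignments, variant profiles, haplogroup calling, tables
  diversity.py   k, S, Ĥ, π, θ, Tajima's D, Fu's FS
  structure.py   Φst, AMOVA, Mantel, MDS, shared haplotypes
  skyline.py     UPGMA genealogy, coalescent intervals, MCMC skyline
  demography.py  IGR series, extrema, period mapping, inversion detection
  pipeline.py    orchestration, manifest, logging
  cli.py         `mesodemog` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
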