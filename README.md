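# reefconn

Biophysical modelling of coral-reef connectivity: where do the larvae a
reef produces actually end up, and which groups of reefs consistently
retain larvae despite the stochasticity of ocean currents?

Broadcast-spawning corals release larvae that drift with surface currents
for days to months before they can settle.  Managers deciding where to
concentrate restoration effort need the *potential connectivity* between
reefs — the probability that a larva spawned at source reef *i* settles at
destination reef *j* in one spawning event — and need to know which
apparent dispersal barriers are persistent features of the circulation
rather than accidents of a particular spawning date.  `reefconn`
implements that analysis end to end on fully synthetic, seed-controlled
inputs: analytic current fields, planted reef grids, spawning calendars
and planted-structure gene-flow matrices, so every stage can be checked
against closed-form oracles.

## The model

Virtual larvae are passive surface drifters, advected through a gridded
velocity field by fixed-step RK4 with bilinear/linear interpolation.  Each
particle carries a larval cohort split into a pre-competent fraction L₁
and a competent fraction L₂:

    dL₁/dt = −(α + μ_m(t)) L₁
    dL₂/dt = α L₁ − (β + μ_m(t) + μ_s F_r(t)) L₂

where α is the competency acquisition rate (zero before the minimum
competency period t_c), β the competency loss rate, μ_m(t) the mortality
rate (constant or Weibull), μ_s the settling rate and F_r(t) the reef
fraction of the occupied grid cell.  A *settling event* j is a contiguous
stay over one reef cell (F_r > 0, t ≥ t_c); the larvae settling during it
are

    S_j = (ρ A_i μ_s F_r^j / N) ∫ L₂(t) dt,

with ρ the fecundity, A_i the source-cell area and N the particles per
cell.  Summing S_j over particles and normalising by the larvae released
gives a potential-connectivity matrix C[source, destination] per spawning
date.  The solver uses exact 2×2 linear propagators per trajectory step,
so mass balance (settled + dead + competency-lost + still-drifting =
released) closes to machine precision.

Downstream, dated matrices are restricted to the October–March spawning
season and resampled into a bootstrap ensemble of short-term connectivity
matrices (1000 replicates, each the mean of 10 random spawning events, at
full scale).  Every replicate is partitioned into modules by minimising
the two-level map equation (1% uniform teleportation) with a seeded greedy
search; module labels are canonicalised by flow and the groups ×
replicates membership matrix is summarised by a centred PCA — separation
along PC1 is the proxy for how *consistently* two reefs share a module,
i.e. for persistent dispersal barriers.  Finally, modelled larval flow
between site pairs is compared against an observed (BayesAss-style)
migration-rate matrix across the whole ensemble, reporting each pair's
feasible range and flagging observations that exceed it.

## Worked example

The demonstration configuration builds a double-gyre ocean (2000 × 1000 m,
40 × 20 cells) with four planted reef clusters — two per gyre, sitting on
a shared orbit near the separatrix — simulates ~20 spawning dates with a
30-day drift cap, and runs the full pipeline:

```python
import reefconn as rc

cfg = rc.demo_config(seed=1)          # impermeable separatrix (perturbation 0)
manifest = rc.run_pipeline(cfg, "artifacts")

ens = rc.BootstrapEnsemble.from_netcdf("artifacts/ensemble.nc")
print(ens.mean())
```

```
[[0.034  0.0459 0.     0.    ]
 [0.0359 0.0457 0.     0.    ]
 [0.     0.     0.053  0.0262]
 [0.     0.     0.0546 0.0263]]
```

The ensemble-mean connectivity is block-diagonal: 3–5% of larvae released
in a cluster settle within its own gyre per spawning event, and none cross
the unperturbed separatrix.  Clustering each of the 100 bootstrap
replicates recovers the planted two-gyre partition every time
(`artifacts/partitions.csv`: groups 0,1 → module 1, groups 2,3 → module
2 in every replicate), and the membership PCA
(`artifacts/pca_summary.json`) reports

```
explained_variance_ratio: [1.0, 0.0, 0.0, 0.0]
```

with PC1 scores −5, −5, +5, +5: the first component alone captures the
(perfectly consistent) barrier, and its score gap separates the two
gyres.  The closed-loop gene-flow comparison
(`artifacts/compare_summary.json`) finds all 12 ordered site pairs inside
the model's feasible range (`outside_95_rate: 0.0`).  Setting the gyre
perturbation to 0.05 (`cfg.ocean.perturbation`) opens a weak leak across
the separatrix — cross-gyre connectivity roughly an order of magnitude
below within-gyre values — and the recovered clustering stays essentially
identical (mean adjusted Rand index ≥ 0.9 against the planted truth).

The same pipeline is available from the shell:

```bash
reefconn pipeline --seed 1 --out artifacts
reefconn make-fixtures --config my.yaml --out fx   # inputs only
```

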