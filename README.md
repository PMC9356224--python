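# ionperm

Ion-permeation energetics of a membrane-protein groove, as a tested,
reusable pipeline run end-to-end on synthetic Brownian-dynamics data
whose free-energy surface is known exactly:

* **`ionperm.core`** — shared types (beads, frames, reaction coordinate),
  unit conventions (A, kcal/mol, ps, e), frozen physical constants.
* **`ionperm.synth`** — everything the pipeline consumes, generated from
  a seed: overdamped-Langevin trajectories on designed groove potentials
  (barrier presets of ~2, ~7, and ~8 kcal/mol), steered initialization,
  partner-bead frame streams with controllable contact probabilities,
  channel-lining bead geometries, and an exact Boltzmann window sampler
  used as the estimator oracle.
* **`ionperm.umbrella`** — harmonic-window grids, per-window sample
  bookkeeping with equilibration discard, shared-grid histograms, and
  neighbor-overlap QC.
* **`ionperm.wham`** — self-consistent WHAM with gap-aware profiles,
  Monte-Carlo bootstrap error bars at a stated correlation time, and
  barrier measurement.
* **`ionperm.contacts`** — per-window contact counting at a 3 A cutoff,
  the strict >50% critical-interaction rule, contiguous critical
  Z-ranges, and permeation-event detection on unbiased runs.
* **`ionperm.geometry`** — average XY permeation path per Z bin, a
  maximal-inscribed-sphere pore-radius profile with its geometric axis,
  and the path-vs-axis comparison.
* **`ionperm.electrostatics`** — finite-difference linearized
  Poisson-Boltzmann on a membrane-slab dielectric model (eps 2 core /
  30 headgroups / 80 water, 18 A ion-accessible cylindrical hole,
  150 mM monovalent screening), with potential sampling along the
  average path.
* **`ionperm.pipeline` / `ionperm.cli`** — YAML-configured scenario runs
  writing CSV/JSON bundles, with a `ci` and a `full` profile.

## CLI

```sh
# print the standard wild-type window grid (84 centers)
ionperm windows --z-min=-10.25 --z-max=10.5 --spacing=0.25

# run a full scenario from a config
cat > scenario.yaml <<EOF
preset: open_pg        # or open_pc, l302a
profile: ci            # ci = reduced; full = experiment-scale grids
seed: 1
outdir: scenario_out
EOF
ionperm run-all --config scenario.yaml
ionperm report --outdir scenario_out
```

Exit codes: 0 success, 2 config error, 3 stage failure. Every output
file carries the config hash; reruns with the same config are
byte-identical apart from that hash.

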