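# helixfriction

Analysis pipeline for local and global internal friction in α-helical
peptide folding: from per-frame hydrogen-bond (HB) states and end-to-end
distances to friction coefficients and their extrapolation to zero
solvent viscosity.  A synthetic trajectory generator stands in for MD
output so every estimator can be validated against known ground truth.

## What it computes

- **structure** — helical (i, i+4) HB detection by a strict 0.36 nm
  O···N distance criterion, helix fraction `f = ⟨h⟩/h_max`, end-to-end
  distances, and RMSD from an ideal-helix reference after optimal
  rigid-body superposition (RMSDH), plus state-density histograms.
- **kinetics** — autocorrelation of the HB-count series, mono-exponential
  relaxation fits (optional constant chosen by AICc), the two-state
  closure `k_fold = f/τ_f`, `k_unfold = (1−f)/τ_f`, `K = f/(1−f)`, and
  the complete-differential error rule for K.
- **dwell** — censoring-aware dwell-time extraction from the bond state
  signals (or from constancy of the total HB count), log-binned
  histograms, one/two-component exponential-mixture fits of the
  log-domain generating function, and the ensemble dwell time τ.
- **friction** — local friction via the Einstein relation
  `γ = kB·T/(δ²/2τ)` with δ = 0.15 nm (helix rise per residue; the
  alternative 0.34 nm convention differs by the factor (0.34/0.15)² =
  5.14), and global friction `γ_G = kB·T/(k_fold·ΣΔx_i²)`.
- **landscape** — free-energy surfaces `G = −RT ln Ω` over
  (HB count × end-to-end distance), per-level histogram centers of mass
  `x_i` and the squared-increment total `ΣΔx_i²` feeding global friction.
- **viscosity** — water diffusion from ensemble/time-origin-averaged MSD
  (`D = slope/6`, chunk-averaged), relative viscosity `η/η₀ = D_w0/D_w`,
  and linear (`γ = a·η + γ₀`, γ₀ = internal friction) or power-law
  (`γ = γ_w·η^β`) extrapolation, with normalization at η/η₀ = 1.
- **synthgen** — exact-discretization two-state HB kinetics (with
  optional nearest-neighbour cooperativity), helix-geometry end-to-end
  distances, 3-D Brownian particle paths and ideal-helix coordinates.
- **pipeline** — per-peptide/condition orchestration with paired e/h
  trajectory averaging (error = half the absolute difference) and CSV
  result tables plus a JSON manifest.

## CLI

```sh
helixfriction run --config config.yaml --out results/

helixfriction simulate hb --n-bonds 4 --k-form 2000 --k-break 6000 \
    --n-frames 200000 --seed 1 --output hb.tsv
helixfriction kinetics --hb-series hb.tsv --output rates.csv
helixfriction dwell --hb-states hb.tsv --mode per_bond_formed \
    --components 2 --output fit.json
helixfriction friction local --tau 12.8            # -> 4.71 ng/s
helixfriction friction global --kfold 10 --dxsq 0.1  # -> 4.14 ug/s
helixfriction viscosity msd --paths paths.xyz --chunk-ps 2000
helixfriction viscosity fit --points points.tsv --model power
```

A pipeline config is one YAML file: global defaults (seed, temperature
300 K, dt 2 ps, δ 0.15 nm, HB cutoff 0.36 nm) plus a list of peptides,
each with conditions (per-bond rates, cooperativity, frame count,
relative viscosity, geometry) and trajectory tags (`e`/`h`).  See
`tests/test_pipeline.py::small_config` for a worked example.

## File formats

All I/O is plain text: HB state matrices and scalar series as delimited
tables with `# key = value` headers, particle paths and coordinate
frames as per-frame XYZ blocks (nm), a minimal fixed-column PDB ATOM
subset (Å, converted to nm on read), flat `key: value` configs, and CSV
result tables.
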