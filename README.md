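# sproutfield

Phase-field simulation of chemotactic sprouting endothelial cells migrating
through a porous extracellular-matrix (ECM) landscape.

The order parameter `phi` (+1 cells, -1 medium) evolves under a conserved
Cahn-Hilliard flow coupled to a single composite environment map
`C0 = max(nu_c - gamma * h, floor)`, where `nu_c` is the chemoattractant
distribution and `h` the hydrogel density. The coupling acts through the
interface-localized term `B = eps * C0 * (phi**2 - 1)`, so cells advance
where `C0` is positive and stall where it is (near) zero. An extended model
lets the leading tip cell sense the matrix a couple of cell diameters ahead
and erode it with a Gaussian MMP footprint, steering toward the path of
least matrix density along the chemoattractant ascent.

## Layout

| module                     | contents                                                        |
| -------------------------- | --------------------------------------------------------------- |
| `sproutfield.grid_env`     | grid spec, chemoattractant profiles, hydrogel image loading, synthetic porous-ECM generator, corridor carving, `C0` composition and band classification |
| `sproutfield.solver`       | five-point-stencil Laplacian, governing-equation RHS, explicit Euler stepping (numpy reference + numba fast kernel), Dirichlet cell reservoirs, free energy, simulation driver |
| `sproutfield.degradation`  | tip detection, look-ahead sensing, MMP deposition, degradation events |
| `sproutfield.metrics`      | tip tracking, mean tip velocity, migration distance, phase volume flux, local-thickness pore-size morphometrics |
| `sproutfield.scenarios`    | reproducible builders for the canonical experiments (pore pocket contact/distant, carved open path, spherical reservoir with/without degradation, static-tip demo, no-gradient control) |
| `sproutfield.config` / `runio` / `render` / `cli` | YAML config schema, run persistence (npz + CSV + JSON manifest), raster rendering, command-line interface |

## CLI

```bash
# emit a reproducible scenario config
sproutfield scenario --name sphere_degradation --seed 3 --out cfg.yaml

# run it (snapshots + series + manifest written to the run directory)
sproutfield simulate --config cfg.yaml --out run_dir --until-hours 48 \
    --snapshot-every-hours 12

# summary metrics (tip velocity, migration distance, volume flux, pore size)
sproutfield measure --run run_dir --out metrics.csv

# synthetic porous hydrogel (calibrated to a 40 um mean pore size)
sproutfield generate-ecm --out ecm.npz --seed 2

# render snapshots to PNG
sproutfield render --run run_dir --out pngs --style perimeter
```

Scenario names: `pocket_contact`, `pocket_distant`, `open_path`,
`sphere_path`, `sphere_degradation`, `static_tip`, `no_gradient`.

## Notes on defaults

Grid and model defaults follow the published calibration: 200x200 points at
3.85 um/px, one in-silico time unit = 2.75e-3 h, `eps = M = 1`, linear
chemoattractant gradient spanning [0.3, 0.5] across the domain, `gamma =
0.5`, environment bands at 0.1/0.2/0.5. The synthetic ECM defaults to
porosity 0.25 (below the level-set percolation threshold, so pore clusters
are finite and matrix traversal genuinely requires degradation) with the
smoothing scale calibrated so the measured mean pore diameter is 40 um.
Long runs use a larger Euler step (`dt = 0.02`, still inside the explicit
stability bound `0.8 * dx^4 / (32 M eps^2) = 0.025`) than the tabulated
`1e-3`; the dynamics are insensitive to this choice.
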