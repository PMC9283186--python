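# scaffoldrom

Parametric steady advection–diffusion transport of released ions (Ca²⁺)
through the interstitial-fluid domain of bone-scaffold geometries, with
POD-based reduced-order solvers.

The model has six parameters: inflow speed `v` (μm/s) and direction
angles `γ, β` (degrees), a concentration–diffusivity coupling exponent
`α`, fluid viscosity `η` (Pa·s, entering through the Stokes–Einstein
diffusivity) and a wall release rate `r` (Robin boundary coefficient).
The quantity of interest is the percentage of fluid volume where the
saturation-normalized concentration exceeds 0.9.

## What is inside

| module | role |
| --- | --- |
| `scaffoldrom.scaffold_geometry` | voxel-based synthetic scaffold generators (strand-grid "printed" and overlapping-sphere "foamed" pore domains), conforming 6-tet meshing, inlet/outlet/solid boundary tagging |
| `scaffoldrom.mesh_io` | tagged tet-mesh I/O: ASCII VTU, Gmsh MSH 4.1, XDMF+HDF5 |
| `scaffoldrom.potential_flow` | normalized potential-flow velocity basis `v_x, v_y, v_z` and the parametrized advection field `v(sinγcosβ v_x + sinγsinβ v_y + cosγ v_z)` |
| `scaffoldrom.transport_fe` | P1 Galerkin assembly (optional SUPG), Stokes–Einstein / concentration-dependent diffusivity, Picard iteration (tol 1e-8) |
| `scaffoldrom.rom_pod` | corner/grid sampling, snapshot building with caching, SVD reduction with cumulative-σ truncation, global / local / quadratic / local-quadratic variants, online reduced Picard solves |
| `scaffoldrom.qoi_analysis` | exact linear-interpolant sub-volume QoI, element masks, parameter sweeps with ROM comparison |
| `scaffoldrom.workspace_cli` | YAML config, workspace with hash-keyed artifacts, `scaffoldrom` CLI |

## CLI

```bash
scaffoldrom gen-mesh   --config config.yaml
scaffoldrom flow-basis --config config.yaml
scaffoldrom solve      --config config.yaml --mu 30,45,45,0.5,1e-3,1.25
scaffoldrom offline    --config config.yaml                 # snapshots + basis
scaffoldrom online     --config config.yaml --mu 20,30,20,0.7,1.25e-3,1.5 --variant quadratic
scaffoldrom sweep      --config config.yaml --param v --values 1,20,40,60 --variant global
```

A minimal configuration:

```yaml
workspace: ws
seed: 0
geometry:
  kind: structured        # structured | foamed | box | external
  lengths: [240, 240, 240]
  h: 20
rom:
  sampling: corner        # corner (2^6 = 64) | grid (levels^6)
  eps: 1.0e-2
  variant: global
  n_neighbors: 10
```

All defaults (parameter ranges, ε = 1e-2, Picard tolerance 1e-8, QoI
threshold 0.9, physical constants) are in `RunConfig` /
`PhysicalConstants`.

## Notes

- Coordinates are in μm, speeds in μm/s, diffusivities internally in
  μm²/s; the printed release rate is scaled by the configurable
  `r_scale` (default 10 μm/s per unit).
- Generators are deterministic functions of (spec, seed); meshes,
  velocity bases, snapshots and reduced bases are cached in the
  workspace keyed by content hashes.
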