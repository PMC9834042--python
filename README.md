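# critnat

Critical natural asset mapping on synthetic landscapes: generate a seeded
gridded world, compute 14 simplified nature's-contributions-to-people (NCP)
surfaces, attribute their value to natural-asset cells, solve minimum-area
prioritizations that meet proportional targets for every NCP per region, and
derive accumulation curves, beneficiary counts, drop-one sensitivity and
overlap statistics — all runnable offline, with no data downloads.

## Layout

| module | role |
|---|---|
| `critnat.synthkit` | seeded synthetic landscapes (land cover, DEM with coherent drainage, population centres, friction, crop/carbon/ET surfaces, regions, realms) and species/language overlays |
| `critnat.terrain_flow` | pit filling, D8 flow directions, downstream-population accounting, flow accumulation, floodplain proxy, basin labels |
| `critnat.travelgraph` | least-cost travel-time fields over a friction surface; population-within-time accounting |
| `critnat.ncp_layers` | the 14 NCP surfaces (12 country-scale, 2 global), each masked to its natural-asset classes |
| `critnat.prioritizer` | minimum-area set multicover: exact binary integer program (HiGHS) and audited greedy surrogate; accumulation curves; drop-one sensitivity; solution overlap |
| `critnat.beneficiaries` | benefitting-area delineation (downstream / travel / gathering / protective distance) and unique-beneficiary counts |
| `critnat.overlaps` | local-vs-global partition, protected-area share, species representation targets (log-linear and minimum-area rules), language intersection |
| `critnat.workbench` | YAML configuration, raster/vector/table I/O, pipeline orchestration, CLI |

Rasters are written as single-band TIFF with a JSON sidecar carrying the
synthetic equal-area registration (2 km pixels by default); regions go to
GeoJSON, tables to CSV, reports and the run manifest to JSON.

## CLI

```sh
critnat run --seed 1 --out my_run                 # full pipeline
critnat simulate --seed 1 --out my_run            # landscape only
critnat ncp --seed 1 --out my_run --max-hours 1   # 14 NCP surfaces
critnat prioritize --seed 1 --targets 0.9 --scale country --solver greedy --out my_run
critnat curve --seed 1 --out my_run               # accumulation curve CSV
critnat beneficiaries --seed 1 --solution my_run/solution_country_0.9.tif --out my_run
critnat overlap --seed 1 --solution local.tif --solution-global global.tif --out my_run
```

All subcommands accept `--config config.yaml` (see
`critnat.workbench.RunConfig` for every knob: generator shares, retention
efficiencies, the 1 h / 6 h access budget, the 6 h / 50,000-person / <70 %
slope commercial-timber rule, 10 km radii, the <10 m coastal strip, target
grid, solver policy). A full run writes landscape rasters, the 14 NCP
layers, solution masks, the accumulation curve (CSV + PNG), the drop-one
sensitivity table, beneficiary and overlap reports, and a manifest with a
sha256 per artifact; runs are byte-identical for a fixed config and seed.

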