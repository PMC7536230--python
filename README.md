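# circuitflux

Genetic-circuit characterization from sequencing-derived profiles.
`circuitflux` infers per-nucleotide RNA-polymerase flux and ribosome
occupancy from strand-specific short-fragment alignments, extracts
quantitative parameters for every genetic part of a layered NOT/NOR logic
circuit (promoters, terminators, ribozyme insulators, RBSs), fits gate
response functions, and drives a fully parameterized kinetic ODE model of
a 7-gate, 3-input circuit with circuit-score and sensitivity analysis.
A first-class synthetic-data generator produces profiles and raw fragments
with known ground truth so the entire pipeline is testable offline.

## Modules

| module | contents |
| --- | --- |
| `circuitflux.profiles` | `StrandedProfile`, fragment-to-profile construction, FPKM, flux conversion (`J = gamma*M`), absolute-unit power-law calibration, center-weighted P-site mapping, absolute ribosome normalization |
| `circuitflux.part_calling` | TSS calling (neighboring-position ratios), TTS calling (averaged-window ratio), promoter strength (window-mean difference), terminator fold, ribozyme cleavage efficiency from cut/uncut fragments |
| `circuitflux.metrics` | ribosome density (trimming, metagene decay correction, 90% winsorization), steady-state mRNA counts, translation efficiency, ribosome usage, proteome fractions, repressor off-target screen |
| `circuitflux.gates` | RPU conversions, repression Hill function, Poisson-regression (K, n) fitting, flux-space to protein-space binding-constant conversion |
| `circuitflux.model` | kinetic ODE model of the circuit (forward Euler and analytic steady states), Boolean propagation, circuit score, one-at-a-time sensitivity scans; ships a nominal parameter set in `circuitflux/data/nominal_circuit.yaml` |
| `circuitflux.synth` | transcript-class forward model, Poisson fragment/footprint samplers, genome background generator, full ground-truth bundles |
| `circuitflux.io` / `circuitflux.cli` | BedGraph / BED6 / GFF3 / TSV / YAML formats, run-config validation, pipeline orchestration, CLI |

## CLI

```sh
circuitflux model score                 # circuit score from the nominal tables
circuitflux model truth-table           # designed Boolean truth table
circuitflux model simulate --initial 1,1,0 --final 1,0,1 --out traj.tsv
circuitflux model scan --parameter rbs.H1 --out scan.tsv
circuitflux synth generate --state 1,0,0 --depth 1e6 --seed 1 --out bundle/
circuitflux profiles build --fragments bundle/fragments_circuit.bed \
    --reference-length 5680 --flux --out profiles/
circuitflux parts call --profile profiles/profile_plus.bedgraph --out parts/
circuitflux run --config run.yaml --out results/   # full pipeline
```

Parameters are addressed as `section.key[.field]`, e.g.
`promoters.P_Tac.y_max`, `ribozymes.riboJ53`, `repressors.P_PhlF.k`.

## Conventions

All coordinates are 0-based, half-open; GFF3 I/O converts explicitly.
Antisense signal is stored as a separate array in genome coordinates.
Profiles carry a units tag (`arb_mrna`, `arb_flux`, `rnap_per_s_*`,
`ribosomes`, `ribosomes_per_mrna`) and conversions check it.
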