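# confswitch

An integrative, fully synthetic-testable pipeline for characterizing a
two-domain protein conformational switch and its oligomeric assembly. The
package combines the structural-biophysics stages typically used for this
problem into one tested toolkit:

- **struct_io** — PDB/mmCIF reading (via biotite), Cα extraction with domain
  labels, Kabsch superposition, inter-domain geometry, per-residue scalar
  maps written to the PDB temperature-factor column.
- **enm** — Cα anisotropic elastic-network normal modes and an iterative
  eigenvector-tracking procedure that closes one domain onto the other
  (displace along the tracked low-frequency mode, relax chain geometry,
  repeat until contact).
- **xlms** — chemical crosslink restraints (DMTMM 30 Å, DSS/BS3 35 Å Cα–Cα
  bounds), chemistry validation, minimal-distance mapping over monomer or
  multi-protomer assemblies, intersubunit classification, satisfaction
  scoring.
- **hdx** — peptide-level HDX-MS tables to per-residue deuteration profiles
  (N-terminal prefix exclusion, replicate-first averaging) and differential
  (state A − state B) maps.
- **saxs** — Guinier fitting, regularized indirect Fourier transform P(r)
  with Dmax estimation, Debye model scattering, χ fitting, and C4-symmetric
  restrained rigid-body tetramer modeling (seeded simulated annealing +
  harmonic refinement).
- **nativems** — native ESI charge-envelope simulation and consensus
  charge-state mass deconvolution with stoichiometry reporting.
- **binding** — thermal-shift melt-curve Tm extraction (derivative maximum,
  sigmoid-fit alternative) and single-site ΔTm-titration Kd fitting.
- **auc** — sedimentation-velocity simulation (conservative exponential-
  fitting Lamm solver in sector geometry) and Tikhonov-regularized
  non-negative c(s) distribution fitting with s20,w standardization.
- **synth** — seeded generators for every input the pipeline consumes (toy
  two-domain structures, crosslink sets with controlled violation rates,
  overlapping-peptide HDX tilings, Debye SAXS curves, ESI envelopes,
  titrations, Lamm scan series), each with a ground-truth sidecar.
- **cli** — a typer subcommand CLI plus a YAML-configured staged runner.

## Tests

```bash
python -m pytest -q tests/
```

The suite is fully synthetic and self-contained, except
`tests/test_acceptance.py::TestCriterion4StructuralCheck`, which compares
two deposited crystal structures and therefore needs network access to
fetch PDB entries 6BWK and 4MWI; it fails with a clear message offline.

## CLI

```bash
confswitch --help
confswitch simulate tetramer-recovery out/scenario --seed 7
confswitch saxs-guinier curve.dat --out guinier.json
confswitch saxs-pofr curve.dat --dmax 170 --out pofr.json
confswitch saxs-fit-tetramer protomer.pdb target.dat --seed 1 --out fit.json
confswitch xlink-validate links.csv model.pdb --out report.json
confswitch hdx-map peptides.csv 300 plusATP --state-b minusATP \
    --structure model.pdb --map-out hdx_map.pdb
confswitch track-closure model.pdb --domain-map '{2-154: 4HB, 155-189: brace, 190-471: PsKD}'
confswitch nativems-deconv peaks.txt --z-min 10 --z-max 40 --monomer-mass 55350
confswitch tsa-kd titration.csv
confswitch auc-cs scans.tsv --rpm 50000
```

A staged pipeline runs from a YAML config (unknown keys are rejected; a
resolved-config snapshot is written next to the reports):

```yaml
seed: 1
output_dir: out/run1
stages:
  - name: saxs-guinier
    params: {curve: data/curve.dat}
  - name: saxs-fit-tetramer
    params: {protomer: data/protomer.pdb, curve: data/curve.dat}
```

```bash
confswitch run config.yaml
```

## File formats

All interfaces are plain text: SAXS curves as 3-column `q I sigma`;
crosslink tables as CSV (`residueA,residueB,linker[,score,count]`); HDX
peptide tables as CSV (`sequence,start,end,time_s,replicate,state,
percent_D`); native-MS peak lists as 2-column `mz intensity`; AUC scan
matrices as TSV (first column radius, one column per scan); structures as
PDB; ground-truth sidecars as key-value TSV.
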