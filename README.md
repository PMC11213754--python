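# biodeg

Analytics for closed-bottle plastic biodegradation assays:

- **`biodeg.stoichiometry`** — parse polymer repeat-unit formulas
  (CxHyOzNdSe), compute Buswell stoichiometric coefficients, the theoretical
  biochemical methane potential (BMP, L CH4 at STP per g) and the
  theoretical oxygen demand (ThOD, g O2 per g).
- **`biodeg.gas`** — convert periodic headspace mole-fraction readings into
  blank-corrected cumulative methane production or oxygen consumption at
  STP, with air-reflush handling and triplicate aggregation.
- **`biodeg.pipeline`** — percent biodegradation per assay group
  (BMP basis anaerobic, ThOD basis aerobic), cellulose-control inoculum
  validation (anaerobic band 82–95 %, inclusive), and a config-driven
  end-to-end run producing JSON/CSV reports.
- **`biodeg.community`** — taxon count-table summaries: relative abundance
  at any rank, the strict “> 1 %” display filter with a pooled residual
  bucket, and kingdom-level proportions.
- **`biodeg.synthetic`** — seeded generators with known ground truth:
  modified-Gompertz gas curves (lag, rate, asymptote) with shared blank
  components and flush schedules, plus Dirichlet-multinomial taxon tables.

## CLI

```sh
# theoretical potentials for the built-in registry (PE, PET, PCL, cellulose)
biodeg potentials
biodeg potentials --formula C6H10O2

# generate a full synthetic study, then analyse it
biodeg synth gas --seed 42 --out fixtures/
biodeg run --config fixtures/study.yaml --out results/
biodeg validate --config fixtures/study.yaml   # cellulose controls only

# community profiles
biodeg synth community --seed 42 --depth 100000 --out fixtures/
biodeg community --table fixtures/taxa.tsv --rank genus --threshold 1
```

`biodeg run` reads a YAML/JSON config naming bottle specs, a gas-readings
CSV (`bottle_id,time_days,gas,mole_fraction[,pressure_pa]`), an optional
flush-events CSV (`bottle_id,time_days,post_flush_fraction,
post_flush_pressure_pa`) and group definitions; it writes `results.json`,
`results.csv` and `warnings.log`.

## Conventions

Atomic masses are the integers 12/1/16/14/32 (O2 = 31.9988 in the ThOD
formula) and the STP molar volume is exactly 22.4 L/mol, so that rounded
potentials match the standard tabulated values. Headspace accounting
assumes constant pressure (the configured initial pressure) unless
per-reading pressures are supplied; dissolved gas and sampling withdrawal
are neglected.
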