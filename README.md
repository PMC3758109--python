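# isletpk

Compartmental pharmacokinetics for beta-cell-targeted PET tracers.

The package implements the analysis chain used to evaluate a fast-clearing
GLP-1-receptor imaging agent and to project its behavior from mouse to
human:

- **`radiometrics`** — radioactivity bookkeeping: decay correction,
  decay-corrected radiochemical yield, logP from phase gamma counts,
  %ID/g conversion.
- **`blood_kinetics`** — biexponential blood-clearance model: prediction,
  least-squares fitting of serial bleed data (log/logit parameterization
  with curve-peeling initialization), and the fraction-weighted half-life
  summary.
- **`plasma_model`** — two-compartment plasma disposition: micro ↔ macro
  parameter conversion, closed-form bolus and constant-infusion solutions,
  and fitting of infusion-phase concentration data.
- **`tissue_model`** — mechanistic pancreas uptake: endocrine (islet) and
  exocrine compartments exchanging with plasma at a permeability × (S/V)
  rate, with saturable receptor binding, dissociation, internalization, and
  washout; stiff-aware simulation and exchange-rate fitting.
- **`extrapolation`** — mouse → human translation: mechanistic rates held
  fixed, human plasma disposition swapped in, %ID/kg normalization, and an
  imaging-window report (contrast ratio, decay-weighted signal, clearance
  compatibility with the isotope half-life).
- **`synthetic_data`** — seeded generators for every input (serial bleeds,
  infusion plasma samples, pancreas uptake curves), so all stages are
  testable fully offline.
- **`cli_io`** — time–activity table I/O, schema-validated configuration,
  and the end-to-end pipeline driver.

## CLI

All stages are exposed as subcommands of `isletpk` (every generator takes a
mandatory `--seed`):

```sh
isletpk simulate-blood --seed 1 --out blood.csv
isletpk fit-blood blood.csv
isletpk simulate-infusion --seed 1 --out infusion.csv
isletpk fit-infusion infusion.csv
isletpk simulate-pancreas --seed 1 --out-dir pancreas/
isletpk fit-exchange pancreas/mouse_exocrine.csv
isletpk extrapolate-human --out-dir human/
isletpk run-all --seed 1 --out-dir pipeline_out/
```

`run-all` executes the full chain — generate and fit mouse blood clearance,
generate and fit human infusion plasma data, simulate mouse pancreas uptake
and refit the exocrine exchange rate, extrapolate to human — and writes TAC
tables plus `summary.json` / `imaging_window.json`. A YAML configuration
(schema-validated, unknown keys rejected, seed mandatory) can replace the
built-in demo defaults via `--config`.

With the demo configuration the pipeline reports a mouse weighted blood
half-life of ≈6.88 min and a human weighted plasma half-life of ≈17.74 min.

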