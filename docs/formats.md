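# File formats

All files are UTF-8 with LF endings; floats are written with 12 significant
digits so write → read → write cycles are byte-identical.

## Scan CSV (equilibrium and velocity)

`#`-prefixed header lines carry metadata, then `radius_cm,absorbance` rows:

```
# rotor_rpm: 25000
# wavelength_nm: 230
# channel: ch0
# meniscus_cm: 6
# bottom_cm: 6.3
radius_cm,absorbance
6.006,0.123456789012
...
```

Required keys: `rotor_rpm`, `wavelength_nm`, `channel`, `meniscus_cm`,
`bottom_cm`. Velocity scans add `# time_s:`. Radii must be strictly
increasing (cm, ≥ 2 decimals); absorbance in AU. A missing required key or
non-monotone radii raise a parse error naming the problem.

## pH series CSV

```
pH,L_obs,SE,upper_limit
6.4,2.67e5,0.04e5,0
...
9.0,500,,1
```

`SE` (standard error of L_obs, M⁻¹) and `upper_limit` (0/1) are optional
columns; rows flagged as upper limits are excluded from linkage fits.

## Fixture YAML

```yaml
kind: SE | SV | ITC
noise_sd: 0.005
seed: 0            # optional; the CLI --seed overrides
truth:             # generator ground truth (model constants)
  L_obs: 2.16e+5
design:            # experimental design (concentrations, speeds, schedule)
  loadings_uM_monomer: [4.0, 8.0, 12.0]
```

Note YAML 1.1 floats need a signed exponent (`2.16e+5`); unsigned forms are
coerced by the loader. Shipped fixtures live in
`assemblink/fixtures/paper/` and are addressed by bare name
(`recr_ph8_se`, `scheme1_noP15`, `scheme1_plusP15`, `itc_p15_reco`).

## Network YAML (velocity fixtures)

The `truth` block of an SV fixture mirrors the reaction-scheme names:
`L_obs`, `K2`, `K3`, `K4` (M⁻¹), optional `variant` (`no_p15` | `plus_p15`)
selecting the default constant set, and `k_off` (s⁻¹).

## Result JSON

Fit results serialize as schema-versioned JSON (`schema_version: "1.0"`)
with parameters, standard errors, and per-scan RMSDs. Every CLI run appends
a JSON-lines entry to `run_log.jsonl` in the output directory recording the
command, package version, and a hash of the configuration.

## Titration JSON

`gen`/`simulate-itc` write `titration.json` with `injection_volumes_ul`,
`heats_ucal`, `blank_heats_ucal`, `syringe_M`, `cell_M`, `V0_ml`; `fit-itc`
consumes the same structure.
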