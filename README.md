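# radplan

Preclinical radiopharmaceutical dosimetry and dose planning for a
β-emitting radioimmunoconjugate: from raw γ-counter and planar γ-camera
counts, through noncompartmental pharmacokinetics and humanized
time-integrated activity coefficients (TIACs), to absorbed-dose tables,
dose-limiting-organ identification, maximum administrable activity, and
interspecies antibody/activity dose conversion.

## Modules

| Module | Purpose |
| --- | --- |
| `radplan.quantify` | Counting-standard arithmetic (%ID/mL, %ID/g), pooled background counts-per-pixel, conjugate-view planar %ID quantification, blood-volume scaling |
| `radplan.nca` | Noncompartmental analysis (Cmax, AUC, λz, T½, CL, Vss, MRT), ⁹⁰Y decay imposition, monkey→man humanization, blood-based red-marrow TIAC, remainder-of-body TIAC |
| `radplan.dose` | Simplified pure-β absorbed-dose engine (local-deposition self S-values + uniform remainder) on a reference adult male phantom |
| `radplan.planning` | Dose-limiting organ and maximum activity under organ dose limits; km-factor (BSA) interspecies conversions; safety margins |
| `radplan.assays` | Saturation-binding Kd/Bmax fitting, Scatchard transform, serum-stability normalization, tumor volume and humane-endpoint rules |
| `radplan.synth` | Synthetic-data generators with analytic ground truth (biexponential blood, uptake–washout organs, two-view planar projection, Poisson counting noise, serial-dilution binding assays, xenograft growth) |
| `radplan.pipeline` / `radplan.cli` | End-to-end orchestration with provenance logging, and the `radplan` command-line interface |

Constants (nuclide, phantom masses, km factors, dose limits) ship as
editable YAML under `src/radplan/data/`; printed summary tables used as
planning inputs ship as CSV fixtures under `src/radplan/data/fixtures/`.

The dose engine intentionally replaces full phantom Monte Carlo
software: for a pure β-emitter the self-absorbed fraction is taken as 1
and photon/bremsstrahlung cross-dose is neglected, so published
absorbed-dose tables are treated as planning *inputs*, not as a
reproduction target.

## CLI

```sh
# generate a fully synthetic monkey study (CSV inputs + truth.json)
radplan simulate --seed 1 --out scratch/sim

# full chain: quantify -> nca -> tiac -> dose -> plan
radplan run-all \
  --planar-rois scratch/sim/planar_rois.csv \
  --gamma-counts scratch/sim/gamma_counts.csv \
  --counting-standard scratch/sim/counting_standard.csv \
  --calibration-ratio 0.001 --body-weight-kg 3.2 \
  --therapeutic-mbq 1678 --out scratch/run

# plan directly from a dose table (mGy/MBq per organ)
radplan plan --dose-table dose_table.csv --therapeutic-mbq 1678 --out report.csv
```

Individual stages are also exposed (`quantify`, `nca`, `tiac`, `dose`).
All tabular I/O is CSV with documented headers; each run writes a
`provenance.json` with input hashes and the constants in effect.

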