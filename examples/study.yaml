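# Example study config for `fibrilscatter run`.
#
# Generate the synthetic inputs referenced below with:
#
#   fibrilscatter synth saxs --preset A8K-water  --seed 7 --out examples/data --concentration 1.0
#   fibrilscatter synth saxs --preset A10K-MeOH  --seed 7 --out examples/data --concentration 0.125
#   fibrilscatter synth saxs --preset A10K-MeOH  --seed 8 --out examples/data --concentration 1.0
#   fibrilscatter synth saxs --preset A10K-DMF   --seed 7 --out examples/data --concentration 0.125
#   fibrilscatter synth dls  --preset A10K-MeOH  --seed 7 --out examples/data
#   fibrilscatter synth dilution --c-s 0.001 --seed 7 --out examples/data
#
# Each sample names either a `preset` (peptide-solvent pair with the built-in
# physical parameters) or an inline `sample_spec` mapping with the SampleSpec
# fields; file paths are relative to this config file.

samples:
  - name: A8K-water
    preset: A8K-water
    concentration_wt_percent: 1.0
    saxs_dilute:
      path: data/saxs-A8K-water-1.0wt-seed7.dat
      concentration_wt_percent: 1.0

  - name: A10K-MeOH
    preset: A10K-MeOH
    concentration_wt_percent: 1.0
    saxs_dilute:
      path: data/saxs-A10K-MeOH-0.125wt-seed7.dat
      concentration_wt_percent: 0.125
    saxs_concentrated:
      - path: data/saxs-A10K-MeOH-1.0wt-seed8.dat
        concentration_wt_percent: 1.0
    dls:
      path: data/dls-A10K-MeOH-seed7.dat
      beta: 0.98
    dilution:
      path: data/dilution-cs0.001-seed7.csv
      baseline: 10.0

  - name: A10K-DMF
    preset: A10K-DMF
    concentration_wt_percent: 0.125
    saxs_dilute:
      path: data/saxs-A10K-DMF-0.125wt-seed7.dat
      concentration_wt_percent: 0.125

options:
  freeze_length: true
  dmax: 12.0
  peak_search_q_max: 0.635
  dls_diameter: 6.0
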