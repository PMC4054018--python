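# Demo configuration: a small synthetic study that runs end to end in well
# under a minute on one CPU.  `crfdrivers all --config examples/demo.yaml`
outdir: results/demo
seed: 7

simulate:
  n_samples: 100
  n_genes: 150
  mutations_per_sample: 10.0
  n_fis_drivers: 6
  n_hotspot_drivers: 6
  n_modules: 10
  module_size: 15

drivers:
  min_pams: 3
  n_samplings: 2000

slea:
  n_random: 2000
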