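# Demo configuration: 20 studies x 20 sites, 24 monthly reflectance steps.
n_studies: 20
sites_per_study: [20, 20]
n_methodology_groups: 6
species_pool_per_study: 40
months: 24
gap_rate: 0.03
slope_sd: 0.5
seed: 0
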