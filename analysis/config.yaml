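# Study conditions for the synthetic multi-city analysis
n_cities: 12
fit_start: 1987
fit_end: 2000
horizon_end: 2100
reference_decade: [2011, 2020]
seed: 1
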