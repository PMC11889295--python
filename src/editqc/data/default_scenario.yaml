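# Default synthetic screening scenario: a 1-Mb host standing in for a cereal
# genome, the 19,074-bp construct with T-DNA 1-12,584, ~30x 150-bp reads with
# 0.5% substitution error.
seed: 0
host_length: 1000000
gc: 0.44
construct_length: 19074
tdna_end: 12584
homology_length: 2000
homology_start: 3001
decoy_start: 2069
decoy_host_copies: 25
event: full_insertion
fragment_lengths: [20, 21]
depth: 30.0
read_length: 150
error_rate: 0.005
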