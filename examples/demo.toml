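# Seeded demo: simulate a small spike-in dilution library and run the full
# pipeline. Outputs land in demo_out/ next to where you invoke the command.
seed = 7
out_dir = "demo_out"

[simulate]
n_transcripts = 12
orders_of_magnitude = 3.0
total_molecules = 20000
n_reads = 3000
pcr_cycles = 2
pcr_efficiency = 0.9

[dedup]
mode = "corrected"
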