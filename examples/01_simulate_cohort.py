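"""Simulate the default camel-like cohort and write it to standard files.

Builds the eight-population scenario (dromedary outgroup, wild Bactrian,
six domestic Bactrian populations with Iran as the earliest split, and 1-10%
dromedary admixture pulses into the Central Asian domestics confined to 20%
of 100 kb windows), draws genotypes for 128 diploids at ~1e5 SNPs, and
writes VCF + population map + truth BED.
"""

from camelscan import make_camel_scenario, simulate, write_outputs

cfg = make_camel_scenario(seed=1)
matrix, popmap, truth, freqs = simulate(cfg)
paths = write_outputs(matrix, popmap, truth, "scratch_example_sim",
                      contig_lengths=cfg.chromosome_lengths)

print(f"simulated {matrix.n_sites} SNPs x {matrix.n_samples} diploids")
print(f"populations: {popmap.populations}")
print(f"truly introgressed 100 kb windows: {len(truth.introgressed_windows)}")
print(f"files: {paths}")
# The truth BED marks exactly the windows where dromedary ancestry was mixed
# into IRAN/KAZA/RUS; downstream scans are judged against it.
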