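"""Genome-wide F3 and F4 admixture tests with SNP-block jackknife.

F3(Z; X, Y): a strongly negative Z-score marks Z as a mixture of X-like and
Y-like sources.  F4(Y, Z; W, X): a significantly positive Z-score means the
second ingroup Z shares more ancestry with X than Y does.
"""

from camelscan import allele_frequencies, f3_test, f4_test, make_camel_scenario, simulate

cfg = make_camel_scenario(seed=5)
matrix, popmap, _, _ = simulate(cfg)
freqs = allele_frequencies(
    matrix, popmap,
    ["east_asian", "central_asian", "wild_bactrian", "dromedary", "IRAN", "MG", "drom"],
)

res = f4_test(freqs, "east_asian", "central_asian", "wild_bactrian", "dromedary")
print(f"F4(east, central; wild, drom) = {res.statistic:+.5f}, Z = {res.z_score:+.1f}")
# Positive and significant: the Central Asian domestics share more ancestry
# with the dromedary donor than the East Asian domestics do, the genome-wide
# signature of the 1-10% admixture pulses.

res = f3_test(freqs, "IRAN", "drom", "MG")
print(f"F3(IRAN; drom, MG) = {res.statistic:+.4f}, Z = {res.z_score:+.1f}")
# With pulses this small, IRAN's own drift dominates and F3 stays positive —
# the known insensitivity of F3 for weakly admixed, drifted targets.

strong = make_camel_scenario(seed=5, pulse_proportions={"IRAN": 0.5}, pulse_window_fraction=1.0)
smatrix, spopmap, _, _ = simulate(strong)
sfreqs = allele_frequencies(smatrix, spopmap, ["IRAN", "MG", "drom"])
res = f3_test(sfreqs, "IRAN", "drom", "MG")
print(f"F3(IRAN; drom, MG) under a 50% genome-wide mixture = "
      f"{res.statistic:+.4f}, Z = {res.z_score:+.1f}")
# A genuinely mixed target flips F3 strongly negative — the classic admixture
# signal.
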