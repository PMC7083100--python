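"""How large must a population be before heterozygote excess is detectable?

With zero homozygotes, every minor allele sits in a carrier; the smallest
carrier count whose excess reaches mid-P <= alpha fixes a minimum allele
frequency below which the screen is blind.  The thresholds below show how
that floor falls as cohorts grow.
"""

from hetexc import min_detectable_het_af

print("n_individuals  alpha   min_het_count  min_AF")
for n, alpha in [(5_185, 0.05), (12_487, 0.05), (64_603, 0.05),
                 (1_000_000, 0.05), (5_000_000, 0.05), (104, 0.001)]:
    d = min_detectable_het_af(n, alpha=alpha)
    print(f"{n:>13,}  {alpha:<6g} {d.min_het_count:>13,}  {d.min_af:.4f}")

# At today's largest single-population cohort (~64,603 individuals) only
# variants with AF >= ~0.0072 can show significant excess; a 5-million
# cohort would push that down to ~0.0008, covering most alleles in the
# 0.001-0.05 band where recessive disease variants live.
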