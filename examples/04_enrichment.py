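"""Group comparisons: is one class of variants enriched for a property?

A 2x2 table (group x outcome) is summarised as Fold Enrichment — the
ratio of the two group proportions — with a two-sided Fisher exact P.
Here: a toy comparison of how often variants in segmental duplications
versus ordinary regions show heterozygote excess.
"""

from hetexc import ContingencyTable2x2, fold_enrichment

# rows: segdup variants / reference-region variants
# columns: heterozygote-excess / not
table = ContingencyTable2x2(a=67, b=2_609, c=408, d=40_393)
result = fold_enrichment(table)

print(f"proportion in segdup group:  {result.proportions[0]:.4f}")
print(f"proportion in Ref group:     {result.proportions[1]:.4f}")
print(f"fold enrichment:             {result.fold_enrichment:.2f}")
print(f"two-sided Fisher P:          {result.p_value:.2e}")

# Fold enrichment well above 1 with a small P means excess calls pile up
# in duplicated sequence — a genotyping-artefact signature, which is why
# the candidate pipeline excludes those regions outright.
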