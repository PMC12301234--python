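"""Rank clonotypes by round-3-to-4 enrichment and pick candidates.

Groups campaign variants into CDR3 clonotypes, scores each by the log2
ratio of round-4 to round-3 frequency (with pseudocount), and selects the
top clonotypes' three most abundant variants - the enrichment workflow's
candidate list.
"""

from panscreen import PanningConfig, simulate_campaign
from panscreen.enrichment import (assign_clonotypes, build_enrichment_table,
                                  campaign_variants,
                                  select_enrichment_candidates)

campaign = simulate_campaign(n_clones=1000, seed=5,
                             config=PanningConfig(reads_per_round=20_000,
                                                  seed=5))
variants = campaign_variants(campaign, rounds=(3, 4))
clonotypes, _ = assign_clonotypes(variants)
table = build_enrichment_table(clonotypes, round_a=3, round_b=4)

top = table[table["count_r3"] >= 10].nlargest(5, "enrichment_score")
print("top clonotypes by log2 enrichment (round 3 -> 4):")
print(top[["clonotype_id", "freq_r3", "freq_r4", "enrichment_score"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

binder_keys = campaign.design.binder_cdr3_aa
hits = sum(t in binder_keys for t in top["key"])
print(f"\n{hits}/5 of the top clonotypes carry a true binder CDR3.")

candidates = select_enrichment_candidates(table, clonotypes,
                                          n_top_clonotypes=5)
print(f"candidate list: {len(candidates)} variants "
      "(up to 3 most-abundant per clonotype).")
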