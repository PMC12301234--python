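"""Simulate a 4-round panning campaign and watch binders take over.

Builds a 500-clone fixed-framework VHH library (~10% true binders with
K_D 0.1-10 nM against a micromolar background), pans it over four rounds of
decreasing antigen concentration, and prints the binder population share per
round. Rising share = affinity-driven selection working as designed.
"""

from panscreen import PanningConfig, simulate_campaign

campaign = simulate_campaign(
    n_clones=500, seed=42,
    config=PanningConfig(reads_per_round=10_000, seed=42))

binders = {c.clone_id for c in campaign.clones if c.is_binder}
print(f"library: {len(campaign.clones)} clones, {len(binders)} true binders")
print("round  antigen(nM)  binder share")
conc = ["input"] + [f"{c * 1e9:.0f}" for c in (100e-9, 50e-9, 25e-9, 10e-9)]
for r, counts in enumerate(campaign.round_counts):
    share = sum(counts[b] for b in binders) / sum(counts.values())
    print(f"{r:>5}  {conc[r]:>11}  {share:12.4f}")
print("\nThe binder share climbs toward 1.0 as antigen is reduced and")
print("non-specific carryover is washed out round over round.")
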