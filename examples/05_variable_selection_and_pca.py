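"""Reduce the trait list before gradient estimation; map trait structure.

Variable reduction (two-stage random-forest screening) picks the traits
that actually predict relative fitness, so only those enter the gradient
regressions.  The PCA of combined behaviour + CHC strain means shows which
traits covary across the panel.
"""

from courtship_select import default_config, simulate_panel, summarize_panel
from courtship_select.io import chc_profiles_to_frame
from courtship_select.selection import build_trait_table, pca_traits, variable_select

panel = simulate_panel(default_config(seed=3, n_strains=20, trials_per_pair=5))
summaries = summarize_panel(panel.trials)
chc = chc_profiles_to_frame(panel.chc_profiles)
chc_means = chc.drop(columns=["individual", "sex", "treatment"]).groupby("strain").mean()

chosen = set()
for female in ("Zlike", "Mlike"):
    table = build_trait_table(summaries, female, chc_means)
    traits = [c[2:] for c in table.columns if c.startswith("z_")]
    X = table[[f"z_{t}" for t in traits]].rename(columns=lambda c: c[2:])
    picked = variable_select(X, table["w"].to_numpy(), seed=11)
    print(f"{female}: selected {picked}")
    chosen.update(picked)
print(f"union analysed for gradients: {sorted(chosen)}")
# cVA drives latency in both contexts, so it should survive screening;
# neutral CHCs should mostly be discarded.

table = build_trait_table(summaries, "Zlike", chc_means)
X = table[[c for c in table.columns if c.startswith("z_")]].rename(columns=lambda c: c[2:])
pca = pca_traits(X)
print("\nvariance explained:", pca["explained"].round(3).head(3).to_dict())
print("PC1 loadings:\n", pca["loadings"]["PC1"].round(2).to_string())
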