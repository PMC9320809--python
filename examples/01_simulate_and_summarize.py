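"""Simulate a courtship panel and summarize each trial.

Builds a 12-strain × 2-female-context panel (5 bouts per pair, 10-s
ethogram grid), then computes per-trial courtship initiation, copulation
latency and time budgets, plus the diagnostic comparing the two initiation
rules.
"""

from courtship_select import default_config, simulate_panel, summarize_panel
from courtship_select.behavior import compare_initiation_methods

cfg = default_config(seed=1)
panel = simulate_panel(cfg)
print(f"{len(panel.trials)} trials; {sum(t.copulated for t in panel.trials)} ended in copulation")

summaries = summarize_panel(panel.trials, initiation_method="consecutive3")
cols = ["trial_id", "initiation_time_s", "copulation_latency_s", "censored", "singing"]
print(summaries[cols].head(8).to_string(index=False))

diag = compare_initiation_methods(panel.trials)
print(
    f"\ninitiation-rule discrepancy over {diag['n']} trials: "
    f"mean {diag['mean_abs_s']:.1f} s, max {diag['max_abs_s']:.1f} s"
)
# The mean tells you the two initiation definitions (first non-separate
# state vs. first run of three) usually agree to within one or two grid
# steps; the max flags bouts where a single isolated "engaging" score would
# have started the courtship clock far too early.
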