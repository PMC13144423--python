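"""Score individual 7-bp windows with the T-score and AT-score.

The score counts matching bases (T, or A/T), adds a bonus for each run of
consecutive matches, subtracts the longest run of non-matches and clamps at
zero; 28 is the maximum for a 7-bp window, 0 means no local richness.
"""

from polvterm import score_window, t_score_config, at_score_config

for window in ["TTTTTTT", "TTCCTTT", "CTTTCCT", "CCTCCCC"]:
    score, comp = score_window(window, t_score_config())
    print(f"T-score({window}) = {score:2d}   (t={comp.t}, runs={comp.run_lengths}, g={comp.g})")

for window in ["ATATATA", "TACCTAA", "CTAACCT", "CCTCCCC"]:
    score, comp = score_window(window, at_score_config())
    print(f"AT-score({window}) = {score:2d}   (t={comp.t}, runs={comp.run_lengths}, g={comp.g})")
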