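"""Urease pre-treatment: does removing urea pay off?

Simulates the five treatment arms (urease/non-treated/water x heating or
sonication), quantifies the urea reduction as a between-group mean-signal
ratio, and ranks the arms on the same three criteria as the extraction
methods.  Urease arms crush the urea signal but lose overall signal,
repeatability and recovery, so they rank last.
"""

import urimex as ux

sim = ux.simulate_study(ux.urease_config(seed=2))

ratio = ux.group_mean_ratio(sim.table, list(sim.meta), "Urea", "UT-H", "NT-H")
print(f"urea signal, urease-treated / non-treated (heating): "
      f"{ratio.value:.2f}  (configured attenuation 0.10)")

report = ux.evaluate_design(sim.table, sim.meta, ux.default_spike_mixture())
table = report.ranking.ranks.copy()
table["cumulative"] = [report.ranking.cumulative[a] for a in table.index]
print("\nrank-sum comparison of the treatment arms (1 = best):")
print(table.loc[list(report.ranking.ordering)])
print(f"\nbest arm: {report.best} — urea removal is not worth the "
      "collateral signal loss for non-targeted profiling.")
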