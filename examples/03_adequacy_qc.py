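"""Sample-adequacy QC and the study-level exclusion cascade.

A sample passes QC only with >= 1.5e6 pre-stain cells, >= 1000 CD45+
events, >= 0.05% combined macrophages (five per 10,000 live single cells)
and at least one alveolar macrophage.  The cascade tallies how a cohort
shrinks from intake to the finally analyzed set.
"""

import sputumflow as sf

# rule-level checks on explicit inputs
cases = [
    ("healthy sample", (8e6, 5000, 0.8, True)),
    ("exactly at the 0.05% cutoff", (8e6, 5000, 0.05, True)),
    ("interstitial only", (8e6, 5000, 0.2, False)),
    ("tiny specimen", (1.2e6, 600, 0.8, True)),
]
for label, args in cases:
    reasons = sf.evaluate_adequacy(*args)
    verdict = "adequate" if not reasons else f"inadequate {reasons}"
    print(f"{label:30s} -> {verdict}")

# the background-derived alternative threshold
stats = sf.fmo_background_stats([0.0023 - 0.0021 / 2**0.5, 0.0023 + 0.0021 / 2**0.5])
print(f"\nFMO background mean + 2 SD: {stats['mean_plus_2sd']:.4f} % "
      f"(~{sf.macrophages_per(stats['mean_plus_2sd'], 100_000):.0f} macrophages "
      f"per 100,000 cells)")
print(f"adequacy cutoff 0.05% = {sf.macrophages_per(0.05, 10_000):.0f} per 10,000 cells")

# study-scale exclusion cascade
ledger = sf.ExclusionLedger.from_counts(
    ineligible=7, status_unconfirmed=8, technical_failure=16,
    too_few_cells=6, too_few_macrophages=9,
    analyzed_groups={"high_risk": 132, "cancer": 32},
)
s = sf.exclusion_cascade(ledger)
print(f"\nintake {s.n_intake} -> flow-analyzed {s.n_flow_analyzed} "
      f"-> final {s.n_final} {s.group_counts}")
print(f"too few CD45+ events: {s.pct_too_few_cells_of_flow} % of flow-analyzed; "
      f"macrophage criterion: {s.pct_too_few_macrophages_of_flow} %")
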