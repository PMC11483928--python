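"""Derive treatment episodes and lines of therapy for one synthetic cohort.

Shows the regimen timeline machinery end to end: dispensings → gap-merged
episodes → numbered lines with general/specific regimen labels, plus the
Sankey flow counts between the first three lines.
"""

from gpp_journey import generate_cohort, preset_scenarios, run_pipeline
from gpp_journey.patterns import sankey_flows

bundle, truth = generate_cohort(preset_scenarios("combinations", n_patients=200, seed=2))
res = run_pipeline(bundle)

print(f"episodes: {len(res.episodes)} over "
      f"{res.episodes['patient_id'].nunique()} patients")
print(f"lines of therapy: {len(res.lots)}")

# distribution of general regimens at first line
first = res.lots[res.lots["lot_number"] == 1]
print("\nfirst-line general regimens (%):")
print((first["general_regimen"].value_counts(normalize=True) * 100).round(1).to_string())

print("\ntop line-1 -> line-2 flows (n patients):")
flows = sankey_flows(res.lots, depth=3)
print(flows[flows["line"] == 1].sort_values("n", ascending=False).head(8).to_string(index=False))

# Each flow row counts patients moving from one general regimen to the
# next; "No further therapy" is the explicit terminal sink, so outflows
# always sum to the regimen's patient count at that line.
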