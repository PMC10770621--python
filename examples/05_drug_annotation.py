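"""Annotate prioritized targets with late-stage cardiovascular drugs.

The packaged fixture joins the three druggable prioritized heart proteins
(ADRA1A, PPARG, ROCK2) to 15 phase III/IV drugs spanning 5 mechanisms of
action and 13 cardiovascular indications.
"""

from heartomics import annotate_targets, packaged_drug_table
from heartomics.drugs import sankey_table

mapping = annotate_targets({"ADRA1A", "PPARG", "ROCK2"}, packaged_drug_table())
print(mapping.records[["target", "drug", "mechanism", "max_phase"]].to_string(index=False))
print("\nsummary:", mapping.summary)

rock2 = mapping.drugs_for("ROCK2")
print(f"\nROCK2 is targeted by {rock2['drug'].tolist()} "
      f"({rock2['mechanism'].iloc[0]})")
print("\nSankey rows (indication -> target -> drug):")
print(sankey_table(mapping).head(6).to_string(index=False))
# 15 distinct drugs, 5 mechanisms, 13 indications; fasudil is the single
# Rho-associated kinase inhibitor against ROCK2.
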