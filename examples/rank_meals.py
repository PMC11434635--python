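"""Rank meal options for a client: refined weights times qualitative scores.

Qualitative levels (high/moderate/low) map to 3/2/1, are column-normalized
into the option score matrix P, and the ranking vector is v = P w.  The
larger v, the better the meal fits the client's weighted criteria; for the
diabetic client the low-glycemic salad should beat the refined-carb pasta.
"""

from ahp_refine import QualitativeScale, recommend, SwarmConfig
from ahp_refine.datasets import client1_criteria, client1_meals

criteria = client1_criteria()
meals = client1_meals()
ranked = recommend(criteria, meals, scale=QualitativeScale(),
                   swarm_cfg=SwarmConfig(seed=1))

print("ranking for client 1 (type 2 diabetes):")
for pos, idx in enumerate(ranked.order, start=1):
    print(f"  {pos}. {ranked.option_labels[idx]:24s} v={ranked.values[idx]:.4f}")
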