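"""Score deletions for breakpoint microhomology and compare burdens.

Generates an indel cohort in which signature-positive samples carry a
4-fold excess of microhomology deletions, classifies every indel against
the reference, and runs the Mann-Whitney comparison between groups.
"""

import numpy as np

from sigscar import (
    SimulationConfig,
    burden_table,
    classify_indels,
    mann_whitney_u,
    microhomology_length,
    simulate_indel_cohort,
)

print("microhomology_length('ACGT', up='GGGGG', down='ACTTG') =",
      microhomology_length("ACGT", "GGGGG", "ACTTG"), "(prefix 'AC' recurs)")

rng = np.random.default_rng(60)
reference = {"chrSim": "".join(rng.choice(list("ACGT"), size=100_000))}
config = SimulationConfig(mh_base_rate=170.0, mh_enrichment=4.0, filler_indel_rate=100.0)
calls = {f"S{i:03d}": i < 12 for i in range(100)}

records, truth = simulate_indel_cohort(config, reference, calls, seed=61)
annotated, counts = classify_indels(records, reference, min_size=3, min_mh=1)
for s in calls:
    counts.setdefault(s, 0)

burdens = burden_table(counts, None, calls)
positive = [b.n_mh_indels for b in burdens if b.sig3_present]
negative = [b.n_mh_indels for b in burdens if not b.sig3_present]
u, p = mann_whitney_u(positive, negative)
print(f"indels classified        : {len(annotated)}")
print(f"planted MH deletions     : {sum(truth.true_indel_labels)}"
      f" (counted: {sum(counts.values())})")
print(f"median MH burden         : positive {np.median(positive):.0f}"
      f" vs negative {np.median(negative):.0f}")
print(f"Mann-Whitney two-sided p : {p:.2e}")
# The ~4:1 median contrast and tiny p echo the scar pattern expected when
# double-strand breaks are repaired by microhomology-mediated end joining.
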