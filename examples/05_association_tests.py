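"""Fisher exact tests of histology against signature status.

First reproduces p-values from published 2x2 gastric-histology tables,
then builds a table from a simulated annotated cohort with a planted
association.
"""

from sigscar import (
    ContingencyTable2x2,
    build_contingency,
    fisher_exact_two_tailed,
    simulate_annotations,
)
from sigscar.stats import format_p

published = {
    "compact discohesive growth": (6, 5, 6, 83),
    "intestinal vs diffuse+mixed": (32, 239, 5, 133),
    "diffuse vs intestinal+mixed": (2, 103, 35, 269),
}
for name, cells in published.items():
    p = fisher_exact_two_tailed(ContingencyTable2x2(*cells))
    print(f"{name:28s} p = {format_p(p)}")

calls = {f"S{i:03d}": i < 12 for i in range(100)}
annotations = simulate_annotations(100, base_rate=0.07, association_odds=15.0,
                                   calls=calls, seed=8)
table = build_contingency(annotations, calls, "discohesive_growth", (True,))
p = fisher_exact_two_tailed(table)
print(f"simulated cohort table ({table.a},{table.b},{table.c},{table.d})"
      f" p = {format_p(p)}")
# Rows are annotation present/absent, columns signature present/absent; a
# small p says the growth pattern tracks signature status.
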