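"""De novo signature extraction from a synthetic cohort.

Plants 3 well-separated signatures in a 60-sample cohort, then runs the
bootstrap-NMF-consensus extraction over candidate ranks 1-4 and reports
the selected rank, per-rank stability, and how well each planted
signature was recovered.
"""

import numpy as np

from sigscar import (
    SimulationConfig,
    extract_signatures,
    simulate_cohort,
    simulate_signatures,
)

signatures = simulate_signatures(3, min_pairwise_cosine_distance=0.7, seed=11)
config = SimulationConfig(
    n_samples=60, burden_mu=np.log(5_000), burden_sigma=0.3,
    signature_of_interest=None, sparsity=0.0, seed=12,
)
matrix, _ = simulate_cohort(config, signatures)

result = extract_signatures(matrix.to_numpy(), range(1, 5), n_bootstraps=10, seed=13)
print("rank  stability  reconstruction_error")
for k in sorted(result.per_k_stability):
    print(f"{k:4d}  {result.per_k_stability[k]:9.3f}  {result.per_k_error[k]:.4f}")
print(f"chosen k = {result.chosen_k}")
for s in signatures:
    best = max(s.cosine(c) for c in result.consensus_signatures)
    print(f"planted {s.name}: best consensus cosine {best:.4f}")
# Stability collapses above the true rank while the error barely improves;
# cosine ~1 means the consensus spectra are the planted ones.
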