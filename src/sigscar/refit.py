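"""Constrained refitting of known signatures onto sample catalogues.

Given a sample's 96-channel catalogue m and a candidate set Q of signature
densities s_1..s_q, the exposure vector E minimizes

    || m - sum_i E_i * s_i ||_2

subject to E_i >= 0, E_i <= N and sum_i E_i = N, where N is the sample's
total mutation count: exposures are numbers of mutations, they cannot be
negative, no signature can contribute more mutations than the sample has,
and together the signatures must account for every mutation.

The candidate set Q is selected per sample from the cancer-type registry,
then pruned by biological features: a signature tagged with an indel class,
strand bias, dinucleotide mutations or hypermutation is retained only when
the sample itself exhibits that feature above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .catalogue import MutationalCatalogue
from .signature import Signature, SignatureSet


@dataclass
class SampleFeatures:
    """Per-sample biological features that gate signature inclusion."""

    cancer_type: str
    n_indels_at_repeats: int = 0
    n_indels_microhomology: int = 0
    has_strand_bias: bool = False
    n_dinucleotides: int = 0
    hypermutator: bool = False

    def __post_init__(self) -> None:
        for name in ("n_indels_at_repeats", "n_indels_microhomology", "n_dinucleotides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FeatureThresholds:
    """Minimum evidence a sample must show for a flagged signature to stay in Q."""

    min_indels_at_repeats: int = 10
    min_indels_microhomology: int = 10
    min_dinucleotides: int = 5


@dataclass
class ExposureVector:
    """Per-signature mutation counts for one sample."""

    sample_id: str
    exposures: dict[str, float]
    total: int
    residual_norm: float

    def __post_init__(self) -> None:
        for name, value in self.exposures.items():
            if value < -1e-9:
                raise ValueError(f"negative exposure for {name}")
            if value > self.total * (1 + 1e-9) + 1e-9:
                raise ValueError(f"exposure for {name} exceeds total")
        if self.total > 0:
            assigned = sum(self.exposures.values())
            if abs(assigned - self.total) > 1e-6 * max(self.total, 1):
                raise ValueError(
                    f"exposures sum to {assigned}, expected {self.total}"
                )

    def __getitem__(self, name: str) -> float:
        return self.exposures[name]

    def fraction(self, name: str) -> float:
        return self.exposures[name] / self.total if self.total else 0.0


def select_subset(
    features: SampleFeatures,
    registry: SignatureSet,
    thresholds: FeatureThresholds | None = None,
) -> SignatureSet:
    """Build the candidate set Q for one sample.

    Q starts from the registry entry for the sample's cancer type; any
    signature carrying a feature flag is dropped unless the sample shows the
    corresponding feature at or above threshold.
    """
    thresholds = thresholds or FeatureThresholds()
    if features.cancer_type not in registry.registry:
        known = ", ".join(sorted(registry.registry)) or "(none)"
        raise KeyError(
            f"unknown cancer type {features.cancer_type!r}; known types: {known}"
        )
    names = registry.registry[features.cancer_type]
    kept: list[str] = []
    for name in names:
        flags = registry[name].feature_flags
        if "indels_at_repeats" in flags and features.n_indels_at_repeats < thresholds.min_indels_at_repeats:
            continue
        if "indels_with_microhomology" in flags and features.n_indels_microhomology < thresholds.min_indels_microhomology:
            continue
        if "dinucleotides" in flags and features.n_dinucleotides < thresholds.min_dinucleotides:
            continue
        if "strand_bias" in flags and not features.has_strand_bias:
            continue
        if "hypermutator" in flags and not features.hypermutator:
            continue
        kept.append(name)
    return registry.subset(kept)


#: Weight of the equality-constraint row relative to the data rows. The sum
#: constraint is then enforced exactly by rescaling, so this only needs to be
#: large enough to keep the solution near the constraint surface.
_PENALTY = 1e4


def fit_exposures(catalogue: MutationalCatalogue, Q: SignatureSet) -> ExposureVector:
    """Solve the constrained least-squares refit for one sample.

    The convex program min ||m - S E|| s.t. E >= 0, sum(E) = N is solved as
    non-negative least squares on the system augmented with a heavily
    weighted row encoding the sum constraint, after which the solution is
    rescaled exactly onto the constraint surface (rescaling preserves
    non-negativity and perturbs the objective negligibly). The per-signature
    cap E_i <= N is implied by non-negativity and the sum constraint.
    """
    if len(Q) == 0:
        raise ValueError("candidate signature set Q is empty")
    total = catalogue.n_mutations
    names = Q.names
    if total == 0:
        return ExposureVector(
            sample_id=catalogue.sample_id,
            exposures={n: 0.0 for n in names},
            total=0,
            residual_norm=0.0,
        )
    S = Q.matrix()
    m = catalogue.counts.astype(float)
    scale = max(np.abs(m).max(), 1.0)
    A = np.vstack([S / scale, np.full((1, S.shape[1]), _PENALTY)])
    b = np.concatenate([m / scale, [_PENALTY * total]])
    solution, _ = nnls(A, b)
    if solution.sum() <= 0:
        solution = np.full(len(names), 1.0)
    solution = solution * (total / solution.sum())
    residual = float(np.linalg.norm(m - S @ solution))
    return ExposureVector(
        sample_id=catalogue.sample_id,
        exposures=dict(zip(names, solution.tolist())),
        total=total,
        residual_norm=residual,
    )


def call_signature_present(
    exposure: ExposureVector,
    signature_name: str,
    min_mutations: float = 10.0,
    min_fraction: float = 0.05,
) -> bool:
    """Binary presence call for a signature in one sample.

    True iff the fitted exposure reaches both an absolute mutation count and
    a fraction of the sample's total. The default thresholds (10 mutations,
    5%) are this package's convention; tune them to the cohort.
    """
    if signature_name not in exposure.exposures:
        raise KeyError(f"unknown signature {signature_name!r}")
    e = exposure.exposures[signature_name]
    return e >= min_mutations and (exposure.total > 0 and e / exposure.total >= min_fraction)


def fit_cohort(
    matrix,
    features: Mapping[str, SampleFeatures] | None,
    registry: SignatureSet,
    thresholds: FeatureThresholds | None = None,
) -> list[ExposureVector]:
    """Refit every sample of a catalogue matrix independently.

    ``matrix`` is a 96 x samples DataFrame (or array with sample order taken
    from ``features``). When ``features`` is None every sample uses the full
    signature set, which keeps the signature definitions identical across
    samples and cancer types so exposures are directly comparable.
    """
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        samples = list(matrix.columns)
        columns = {s: matrix[s].to_numpy() for s in samples}
    else:
        matrix = np.asarray(matrix)
        samples = list(features.keys()) if features else [
            f"sample_{i}" for i in range(matrix.shape[1])
        ]
        columns = {s: matrix[:, i] for i, s in enumerate(samples)}
    out = []
    for sample in samples:
        catalogue = MutationalCatalogue(sample_id=sample, counts=columns[sample])
        if features is None:
            Q = registry
        else:
            Q = select_subset(features[sample], registry, thresholds)
        out.append(fit_exposures(catalogue, Q))
    return out


def exposures_frame(exposures: Sequence[ExposureVector]):
    """Tabulate a cohort's exposures: samples x signatures, plus total and residual."""
    import pandas as pd

    names: list[str] = []
    for e in exposures:
        for n in e.exposures:
            if n not in names:
                names.append(n)
    rows = {}
    for e in exposures:
        row = {n: e.exposures.get(n, 0.0) for n in names}
        row["total"] = e.total
        row["residual_norm"] = e.residual_norm
        rows[e.sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample"
    return frame
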