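"""Mutational signatures and the per-cancer-type signature registry."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import json

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS

#: Feature tags that gate a signature's inclusion in a refit (the subset Q).
FEATURE_FLAGS = frozenset(
    {"indels_at_repeats", "indels_with_microhomology", "strand_bias",
     "dinucleotides", "hypermutator"}
)


@dataclass
class Signature:
    """A discrete probability density over the 96 mutation channels.

    ``feature_flags`` mark biological features (indel classes, strand bias,
    dinucleotide mutations, hypermutation) whose absence from a sample
    excludes the signature from that sample's candidate set.
    """

    name: str
    values: np.ndarray
    feature_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (96,):
            raise ValueError(f"signature {self.name!r} must have 96 channels")
        if (self.values < 0).any():
            raise ValueError(f"signature {self.name!r} has negative components")
        total = self.values.sum()
        if total <= 0:
            raise ValueError(f"signature {self.name!r} has no mass")
        self.values = self.values / total
        unknown = set(self.feature_flags) - FEATURE_FLAGS
        if unknown:
            raise ValueError(f"unknown feature flags {sorted(unknown)}")
        self.feature_flags = frozenset(self.feature_flags)

    def cosine(self, other: "Signature | np.ndarray") -> float:
        v = other.values if isinstance(other, Signature) else np.asarray(other, float)
        return float(
            self.values @ v / (np.linalg.norm(self.values) * np.linalg.norm(v))
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(CHANNEL_LABELS), name=self.name)


@dataclass
class SignatureSet:
    """An ordered collection of signatures plus a cancer-type registry.

    The registry maps each cancer type to the names of the signatures known
    to be operative in it; a sample's candidate set starts from its cancer
    type's registry entry.
    """

    signatures: list[Signature]
    registry: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            raise ValueError("signature names must be unique")
        for cancer_type, entry in self.registry.items():
            unknown = set(entry) - set(names)
            if unknown:
                raise ValueError(
                    f"registry for {cancer_type!r} names unknown signatures {sorted(unknown)}"
                )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def __getitem__(self, name: str) -> Signature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        return SignatureSet(signatures=[self[n] for n in names])

    def matrix(self) -> np.ndarray:
        """Channels x signatures matrix, columns in set order."""
        return np.column_stack([s.values for s in self.signatures])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {s.name: s.values for s in self.signatures}, index=list(CHANNEL_LABELS)
        )
        frame.index.name = "channel"
        return frame

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        feature_flags: dict[str, Iterable[str]] | None = None,
        registry: dict[str, list[str]] | None = None,
    ) -> "SignatureSet":
        feature_flags = feature_flags or {}
        signatures = [
            Signature(
                name=str(col),
                values=frame[col].to_numpy(dtype=float),
                feature_flags=frozenset(feature_flags.get(str(col), ())),
            )
            for col in frame.columns
        ]
        return cls(signatures=signatures, registry=registry or {})

    @classmethod
    def load(
        cls, matrix_path: str | Path, sidecar_path: str | Path | None = None
    ) -> "SignatureSet":
        """Load a 96 x k signature TSV plus an optional JSON sidecar.

        The sidecar carries ``feature_flags`` (signature name -> list of
        tags) and ``registry`` (cancer type -> list of signature names).
        """
        from .io import read_signature_matrix

        frame = read_signature_matrix(matrix_path)
        flags: dict[str, list[str]] = {}
        registry: dict[str, list[str]] = {}
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                sidecar = json.load(fh)
            flags = sidecar.get("feature_flags", {})
            registry = sidecar.get("registry", {})
        return cls.from_frame(frame, feature_flags=flags, registry=registry)

    def save(self, matrix_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        from .io import write_signature_matrix

        write_signature_matrix(self.to_frame(), matrix_path)
        if sidecar_path is not None:
            sidecar = {
                "feature_flags": {s.name: sorted(s.feature_flags) for s in self.signatures},
                "registry": self.registry,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(sidecar, fh, indent=2, sort_keys=True)
                fh.write("\n")
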