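"""Somatic-variant filtering and 96-channel mutational catalogues.

A sample's mutational catalogue is the vector of counts over the 96
substitution-in-context channels. Variants are filtered against a germline
site list and a panel-of-normals evidence table before counting; the local
sequence context is read from an indexed reference (1-based, fully closed
coordinates, as in VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    CHANNEL_INDEX,
    CHANNEL_LABELS,
    CHANNELS,
    PYRIMIDINE_TRINUCLEOTIDES,
    ParseError,
    classify_substitution,
    collapse_trinucleotide,
)


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant call (SNV or indel) in 1-based coordinates."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ParseError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("ref", "alt"):
            seq = getattr(self, name)
            if not seq or any(b not in BASES for b in seq):
                raise ParseError(
                    f"{name} must be non-empty A/C/G/T, got {seq!r} at {self.chrom}:{self.pos}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class MutationalCatalogue:
    """Per-sample counts over the 96 channels, in canonical order."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"catalogue must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalogue counts must be non-negative")

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNEL_LABELS), name=self.sample_id)


@dataclass(frozen=True)
class SiteEvidence:
    """Alt-supporting read counts at one site across a panel of normals."""

    chrom: str
    pos: int
    ref: str
    alt: str
    panel_read_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.panel_read_counts):
            raise ValueError("panel read counts must be non-negative")

    def is_artifact(self, min_reads: int = 2, min_samples: int = 2) -> bool:
        """Recurrent-artifact rule: alt seen in >= min_reads reads in >= min_samples normals."""
        return sum(c >= min_reads for c in self.panel_read_counts) >= min_samples


@dataclass
class TrinucleotideFrequencies:
    """Abundance of each pyrimidine-centric trinucleotide in a territory."""

    freq: dict[str, float]
    territory_bp: int = 0

    def __post_init__(self) -> None:
        collapsed: dict[str, float] = {}
        for trinuc, value in self.freq.items():
            if value < 0:
                raise ValueError(f"negative abundance for {trinuc!r}")
            collapsed[collapse_trinucleotide(trinuc)] = (
                collapsed.get(collapse_trinucleotide(trinuc), 0.0) + float(value)
            )
        self.freq = collapsed

    @classmethod
    def from_sequence(cls, seq: str) -> "TrinucleotideFrequencies":
        """Count trinucleotides in a sequence (windows containing N are skipped)."""
        counts: dict[str, float] = {t: 0.0 for t in PYRIMIDINE_TRINUCLEOTIDES}
        seq = seq.upper()
        for i in range(len(seq) - 2):
            window = seq[i : i + 3]
            if any(b not in BASES for b in window):
                continue
            counts[collapse_trinucleotide(window)] += 1.0
        return cls(freq=counts, territory_bp=len(seq))

    def __getitem__(self, trinuc: str) -> float:
        return self.freq.get(collapse_trinucleotide(trinuc), 0.0)


class ContextUnavailable(Exception):
    """The +/-1 bp context cannot be read (contig edge, N, missing contig)."""


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Read reference[start0:end0) (0-based) from a dict of strings or a FASTA."""
    try:
        contig = reference[chrom]
    except KeyError:
        raise ContextUnavailable(f"contig {chrom!r} not in reference") from None
    piece = contig[start0:end0]
    seq = piece if isinstance(piece, str) else str(piece)
    return seq.upper()


def extract_context(reference, chrom: str, pos: int) -> tuple[str, str, str]:
    """Return (5' flank, base, 3' flank) at a 1-based position.

    Accepts any mapping from contig name to a sliceable sequence (a plain
    dict of strings or a ``pyfaidx.Fasta``). Positions at a contig edge or
    with an ambiguous base anywhere in the window raise ContextUnavailable;
    such variants are excluded from the catalogue.
    """
    if pos < 2:
        raise ContextUnavailable(f"{chrom}:{pos} has no 5' flank")
    window = _fetch(reference, chrom, pos - 2, pos + 1)
    if len(window) < 3:
        raise ContextUnavailable(f"{chrom}:{pos} has no 3' flank")
    if any(b not in BASES for b in window):
        raise ContextUnavailable(f"ambiguous base in context {window!r} at {chrom}:{pos}")
    return window[0], window[1], window[2]


@dataclass
class FilterResult:
    kept: list[SomaticVariant]
    removed: list[tuple[SomaticVariant, str]] = field(default_factory=list)


def filter_variants(
    variants: Iterable[SomaticVariant],
    germline_sites: set[tuple[str, int, str, str]] | None = None,
    panel: Mapping[tuple[str, int, str, str], SiteEvidence] | None = None,
    *,
    min_reads: int = 2,
    min_samples: int = 2,
) -> FilterResult:
    """Remove germline sites and panel-of-normals recurrent artifacts.

    A variant is removed iff its (chrom, pos, ref, alt) key is in
    ``germline_sites``, or its panel evidence shows alt support in at least
    ``min_reads`` well-mapping reads in at least ``min_samples`` normal
    samples. Variants without a panel entry are kept.
    """
    germline_sites = germline_sites or set()
    panel = panel or {}
    result = FilterResult(kept=[])
    for v in variants:
        key = (v.chrom, v.pos, v.ref, v.alt)
        if key in germline_sites:
            result.removed.append((v, "germline"))
            continue
        evidence = panel.get(key)
        if evidence is not None and evidence.is_artifact(min_reads, min_samples):
            result.removed.append((v, "panel_of_normals"))
            continue
        result.kept.append(v)
    return result


def build_catalogue(
    variants: Iterable[SomaticVariant],
    reference,
    sample_id: str | None = None,
) -> tuple[MutationalCatalogue, list[tuple[SomaticVariant, str]]]:
    """Count post-filter SNVs into a 96-channel catalogue.

    Non-SNV records are ignored (indels are handled by the indel module).
    SNVs whose context cannot be read are excluded and returned with a
    reason, so kept + excluded always equals the number of input SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    excluded: list[tuple[SomaticVariant, str]] = []
    inferred_sample = sample_id
    for v in variants:
        if inferred_sample is None:
            inferred_sample = v.sample_id
        if not v.is_snv:
            continue
        try:
            flank5, center, flank3 = extract_context(reference, v.chrom, v.pos)
        except ContextUnavailable as exc:
            excluded.append((v, str(exc)))
            continue
        if center != v.ref:
            excluded.append((v, f"reference mismatch: expected {center}, got {v.ref}"))
            continue
        channel = classify_substitution(v.ref, v.alt, flank5, flank3)
        counts[CHANNEL_INDEX[channel.label]] += 1
    return MutationalCatalogue(sample_id=inferred_sample or "", counts=counts), excluded


def build_catalogue_matrix(
    variants: Iterable[SomaticVariant], reference
) -> tuple[pd.DataFrame, list[tuple[SomaticVariant, str]]]:
    """Catalogue a multi-sample variant list into a 96 x samples DataFrame."""
    by_sample: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    columns = {}
    excluded: list[tuple[SomaticVariant, str]] = []
    for sample in sorted(by_sample):
        catalogue, dropped = build_catalogue(by_sample[sample], reference, sample)
        columns[sample] = catalogue.counts
        excluded.extend(dropped)
    frame = pd.DataFrame(columns, index=list(CHANNEL_LABELS), dtype=np.int64)
    frame.index.name = "channel"
    return frame, excluded


def normalize_exome_signature(
    values: np.ndarray | Sequence[float],
    exome_freq: TrinucleotideFrequencies,
    genome_freq: TrinucleotideFrequencies,
) -> np.ndarray:
    """Renormalize a 96-channel signature from exome to genome trinucleotide frequencies.

    Each channel is reweighted by genome/exome abundance of its trinucleotide
    context and the vector is rescaled to sum to 1. A channel with nonzero
    mass but zero exome frequency is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (96,):
        raise ValueError("signature must have 96 channels")
    out = np.empty(96, dtype=float)
    for i, channel in enumerate(CHANNELS):
        trinuc = channel.trinucleotide
        exome = exome_freq[trinuc]
        if values[i] != 0 and exome == 0:
            raise ValueError(f"zero exome frequency for {trinuc} with nonzero signature mass")
        out[i] = values[i] * (genome_freq[trinuc] / exome) if exome > 0 else 0.0
    total = out.sum()
    if total <= 0:
        raise ValueError("normalized signature has no mass")
    return out / total


def mutations_per_megabase(catalogue: MutationalCatalogue, territory_bp: int) -> float:
    """Somatic-mutation prevalence as mutations per megabase of territory."""
    if territory_bp <= 0:
        raise ValueError(f"territory_bp must be positive, got {territory_bp}")
    return catalogue.n_mutations / (territory_bp / 1e6)
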