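"""Breakpoint-microhomology classification of indels and per-sample burdens.

Deletions arising from microhomology-mediated end joining carry short
identical sequence shared between the deleted bases and a flank: repair of a
double-strand break anneals the matching stretches, deleting one copy and
the sequence between. Large deletions (>3 bp) with such overlapping
microhomology at the breakpoints, counted per sample, are a genomic scar of
failed homologous-recombination repair and accompany the corresponding base
substitution signature.

Deletions whose removed sequence is an exact copy of the adjacent sequence
over its full length are tandem-repeat (slippage) events, not microhomology
events; they are flagged ``at_repeat`` and excluded from microhomology
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .catalogue import _fetch, ContextUnavailable


@dataclass
class IndelRecord:
    """One indel; ``pos`` is the 1-based first deleted (or inserted) base."""

    sample_id: str
    chrom: str
    pos: int
    kind: str  # "deletion" | "insertion"
    seq: str
    mh_length: int | None = None
    at_repeat: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"kind must be deletion or insertion, got {self.kind!r}")
        if len(self.seq) < 1:
            raise ValueError("indel sequence must be non-empty")


@dataclass
class SampleBurden:
    """Microhomology-deletion and structural-variant burden for one sample."""

    sample_id: str
    n_mh_indels: int
    n_structural_variants: int | None
    sig3_present: bool


def microhomology_length(deleted_seq: str, upstream_flank: str, downstream_flank: str) -> int:
    """Length of breakpoint microhomology for a deletion.

    Measures the longest prefix of the deleted sequence that is also a
    prefix of the downstream flank, and the longest suffix of the deleted
    sequence that is also a suffix of the upstream flank, and returns the
    larger. A full-length match means the deletion removed one unit of a
    tandem repeat, which is a slippage event rather than microhomology, so
    the value is capped at len(deleted_seq) - 1 (use :func:`is_repeat_deletion`
    to detect the repeat case).
    """
    n = len(deleted_seq)
    if len(upstream_flank) < n or len(downstream_flank) < n:
        raise ValueError("flanks must be at least as long as the deleted sequence")
    p = 0
    while p < n and deleted_seq[p] == downstream_flank[p]:
        p += 1
    q = 0
    while q < n and deleted_seq[n - 1 - q] == upstream_flank[len(upstream_flank) - 1 - q]:
        q += 1
    return min(max(p, q), n - 1)


def is_repeat_deletion(deleted_seq: str, upstream_flank: str, downstream_flank: str) -> bool:
    """True when the deleted sequence exactly copies an adjacent flank."""
    n = len(deleted_seq)
    if len(upstream_flank) < n or len(downstream_flank) < n:
        raise ValueError("flanks must be at least as long as the deleted sequence")
    return downstream_flank[:n] == deleted_seq or upstream_flank[-n:] == deleted_seq


def annotate_indel(record: IndelRecord, reference) -> IndelRecord:
    """Fill mh_length and at_repeat from the reference flanks.

    Insertions get mh_length 0 and at_repeat False: breakpoint microhomology
    is defined for deletions only.
    """
    if record.kind == "insertion":
        record.mh_length = 0
        record.at_repeat = False
        return record
    n = len(record.seq)
    start0 = record.pos - 1
    upstream = _fetch(reference, record.chrom, max(start0 - n, 0), start0)
    downstream = _fetch(reference, record.chrom, start0 + n, start0 + 2 * n)
    if len(upstream) < n or len(downstream) < n:
        raise ContextUnavailable(
            f"flanks unavailable for {record.chrom}:{record.pos} (len {n})"
        )
    record.mh_length = microhomology_length(record.seq, upstream, downstream)
    record.at_repeat = is_repeat_deletion(record.seq, upstream, downstream)
    return record


def counts_microhomology(
    record: IndelRecord, min_size: int = 3, min_mh: int = 1
) -> bool:
    """Whether an annotated indel counts toward the microhomology-deletion burden.

    Rules: deletions only; size strictly greater than ``min_size`` bp;
    microhomology at least ``min_mh`` bp; tandem-repeat deletions excluded.
    """
    if record.mh_length is None or record.at_repeat is None:
        raise ValueError("record must be annotated first")
    return (
        record.kind == "deletion"
        and len(record.seq) > min_size
        and record.mh_length >= min_mh
        and not record.at_repeat
    )


def classify_indels(
    indels: Iterable[IndelRecord],
    reference,
    min_size: int = 3,
    min_mh: int = 1,
) -> tuple[list[IndelRecord], dict[str, int]]:
    """Annotate indels against the reference and tally per-sample MH deletions.

    Records whose locus falls outside the reference are skipped (with the
    per-sample tally unaffected). Returns the annotated records and a map
    sample -> number of qualifying microhomology deletions.
    """
    annotated: list[IndelRecord] = []
    per_sample: dict[str, int] = {}
    for record in indels:
        per_sample.setdefault(record.sample_id, 0)
        try:
            record = annotate_indel(record, reference)
        except (ContextUnavailable, KeyError):
            warnings.warn(
                f"skipping indel at {record.chrom}:{record.pos}: locus outside reference",
                stacklevel=2,
            )
            continue
        annotated.append(record)
        if counts_microhomology(record, min_size=min_size, min_mh=min_mh):
            per_sample[record.sample_id] += 1
    return annotated, per_sample


def burden_table(
    mh_counts: Mapping[str, int],
    sv_counts: Mapping[str, int] | None,
    sig3_calls: Mapping[str, bool],
) -> list[SampleBurden]:
    """Join per-sample MH-deletion counts, SV counts and signature calls.

    Every sample with indel data must have a signature call; samples absent
    from ``sv_counts`` get no SV burden (None), not zero.
    """
    sv_counts = sv_counts or {}
    missing = sorted(set(mh_counts) - set(sig3_calls))
    if missing:
        raise ValueError(f"samples without a signature call: {missing}")
    return [
        SampleBurden(
            sample_id=sample,
            n_mh_indels=mh_counts[sample],
            n_structural_variants=sv_counts.get(sample),
            sig3_present=bool(sig3_calls[sample]),
        )
        for sample in sorted(mh_counts)
    ]


def indels_from_variants(variants) -> list[IndelRecord]:
    """Convert anchored VCF-style indel variants to IndelRecords.

    A deletion is REF = anchor + deleted bases, ALT = anchor; an insertion is
    REF = anchor, ALT = anchor + inserted bases (left-aligned assumed). SNVs
    and non-anchored records are ignored.
    """
    out = []
    for v in variants:
        if len(v.ref) > 1 and len(v.alt) == 1 and v.ref[0] == v.alt:
            out.append(
                IndelRecord(
                    sample_id=v.sample_id, chrom=v.chrom, pos=v.pos + 1,
                    kind="deletion", seq=v.ref[1:],
                )
            )
        elif len(v.alt) > 1 and len(v.ref) == 1 and v.alt[0] == v.ref:
            out.append(
                IndelRecord(
                    sample_id=v.sample_id, chrom=v.chrom, pos=v.pos + 1,
                    kind="insertion", seq=v.alt[1:],
                )
            )
    return out
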