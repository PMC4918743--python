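"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 1-based and fully closed throughout, matching VCF. Variant
input is either a minimal VCF (CHROM, POS, REF, ALT; one sample per file)
read through pysam, or a 5-column TSV (sample, chrom, pos, ref, alt) with
'#' comment lines. Catalogues, signatures, exposures and annotations are
TSVs; run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .channels import BASES, CHANNEL_LABELS, ParseError
from .catalogue import SiteEvidence, SomaticVariant


def read_variants_tsv(path: str | Path) -> list[SomaticVariant]:
    """Read a 5-column TSV: sample, chrom, pos, ref, alt ('#' lines ignored)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["sample", "chrom", "pos", "ref", "alt"],
        dtype={"sample": str, "chrom": str, "ref": str, "alt": str},
    )
    variants = []
    for row in frame.itertuples(index=False):
        variants.append(
            SomaticVariant(
                sample_id=row.sample,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref.upper(),
                alt=row.alt.upper(),
            )
        )
    return variants


def read_variants_vcf(path: str | Path, sample_id: str | None = None) -> list[SomaticVariant]:
    """Read a minimal VCF; multi-allelic records are split one variant per alt.

    Records with N or other ambiguity codes in REF or ALT are rejected with a
    parse error naming the record; symbolic/breakend alts are skipped.
    """
    import pysam

    sample = sample_id or Path(path).stem.removesuffix(".vcf")
    variants: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            for alt in record.alts or ():
                if alt is None or alt.startswith("<") or "[" in alt or "]" in alt:
                    continue
                ref, alt = record.ref.upper(), alt.upper()
                if any(b not in BASES for b in ref + alt):
                    raise ParseError(
                        f"non-ACGT allele {ref}>{alt} at {record.chrom}:{record.pos}"
                    )
                variants.append(
                    SomaticVariant(
                        sample_id=sample,
                        chrom=record.chrom,
                        pos=record.pos,
                        ref=ref,
                        alt=alt,
                    )
                )
    return variants


def read_variants(path: str | Path, sample_id: str | None = None) -> list[SomaticVariant]:
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return read_variants_vcf(path, sample_id)
    return read_variants_tsv(path)


def write_variants_tsv(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\tchrom\tpos\tref\talt\n")
        for v in variants:
            fh.write(f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")


def read_germline_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a 4-column TSV of germline sites: chrom, pos, ref, alt."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "ref", "alt"], dtype={"chrom": str, "ref": str, "alt": str},
    )
    return {
        (row.chrom, int(row.pos), row.ref.upper(), row.alt.upper())
        for row in frame.itertuples(index=False)
    }


def read_site_evidence(path: str | Path) -> dict[tuple[str, int, str, str], SiteEvidence]:
    """Read a panel-of-normals table: chrom, pos, ref, alt, comma-separated counts."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "ref", "alt", "counts"],
        dtype={"chrom": str, "ref": str, "alt": str, "counts": str},
    )
    panel = {}
    for row in frame.itertuples(index=False):
        counts = tuple(int(c) for c in str(row.counts).split(",") if c != "")
        evidence = SiteEvidence(
            chrom=row.chrom, pos=int(row.pos),
            ref=row.ref.upper(), alt=row.alt.upper(),
            panel_read_counts=counts,
        )
        panel[(evidence.chrom, evidence.pos, evidence.ref, evidence.alt)] = evidence
    return panel


def read_catalogue_matrix(path: str | Path) -> pd.DataFrame:
    """Read a catalogue TSV (96 channel rows x sample columns) in canonical order."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNEL_LABELS) - set(frame.index)
    if missing:
        raise ParseError(f"catalogue missing {len(missing)} channels, e.g. {sorted(missing)[:3]}")
    frame = frame.loc[list(CHANNEL_LABELS)]
    frame.index.name = "channel"
    return frame


def write_catalogue_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a 96 x k signature TSV; columns are renormalized to sum to 1."""
    frame = read_catalogue_matrix(path).astype(float)
    sums = frame.sum(axis=0)
    if (sums <= 0).any():
        raise ParseError("signature column with no mass")
    return frame / sums


def write_signature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
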