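"""End-to-end orchestration: filter -> catalogue -> [extract] -> refit ->
indels -> associate -> report.

A run is configured by a flat INI file (sections [input], [params],
[output]) mirrored by CLI flags; unknown keys are rejected. Outputs are
deterministic for a fixed config, inputs and seed: samples are ordered
lexicographically, signatures in registry order, and the fully resolved
configuration is written into the output directory beside a JSON manifest.
"""

from __future__ import annotations

import configparser
import logging
import sys
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .catalogue import build_catalogue_matrix, filter_variants
from .extraction import extract_signatures
from .indels import burden_table, classify_indels, indels_from_variants
from .refit import call_signature_present, exposures_frame, fit_cohort
from .signature import SignatureSet
from .stats import (
    SampleAnnotation,
    build_contingency,
    fisher_exact_two_tailed,
    format_p,
    mann_whitney_u,
)

logger = logging.getLogger("sigscar")


class ConfigError(ValueError):
    """The run configuration failed validation."""


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    # [input]
    variants: str = ""
    reference: str = ""
    germline_sites: str = ""
    site_evidence: str = ""
    signatures: str = ""
    signature_sidecar: str = ""
    indels: str = ""
    sv_counts: str = ""
    annotations: str = ""
    # [params]
    seed: int = 0
    extract: bool = False
    k_min: int = 1
    k_max: int = 5
    bootstraps: int = 20
    signature_of_interest: str = ""
    min_mutations: float = 10.0
    min_fraction: float = 0.05
    min_indel_size: int = 3
    min_mh: int = 1
    # [output]
    outdir: str = "sigscar_out"
    verbosity: int = 1

    _SECTIONS = {
        "input": ("variants", "reference", "germline_sites", "site_evidence",
                  "signatures", "signature_sidecar", "indels", "sv_counts", "annotations"),
        "params": ("seed", "extract", "k_min", "k_max", "bootstraps",
                   "signature_of_interest", "min_mutations", "min_fraction",
                   "min_indel_size", "min_mh"),
        "output": ("outdir", "verbosity"),
    }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        parser.read(path)
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for section in parser.sections():
            if section not in cls._SECTIONS:
                raise ConfigError(f"unknown config section [{section}]")
            for key, value in parser.items(section):
                if key not in cls._SECTIONS[section]:
                    raise ConfigError(f"unknown config key {key!r} in [{section}]")
                if types[key] == "bool":
                    kwargs[key] = parser.getboolean(section, key)
                elif types[key] == "int":
                    kwargs[key] = int(value)
                elif types[key] == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def validate_inputs(self) -> None:
        if not self.variants or not self.reference:
            raise ConfigError("a run needs at least 'variants' and 'reference' inputs")
        for name in ("variants", "reference", "germline_sites", "site_evidence",
                     "signatures", "signature_sidecar", "indels", "sv_counts",
                     "annotations"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"input file for {name!r} not found: {value}")
        if not self.extract and not self.signatures:
            raise ConfigError("provide a signature matrix or enable extraction")

    def write(self, path: str | Path) -> None:
        parser = configparser.ConfigParser()
        data = asdict(self)
        for section, keys in self._SECTIONS.items():
            parser[section] = {k: str(data[k]) for k in keys}
        with open(path, "w") as fh:
            parser.write(fh)


def _load_reference(path: str):
    import pyfaidx

    return pyfaidx.Fasta(path, sequence_always_upper=True)


def _read_annotations(path: str) -> list[SampleAnnotation]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("unknown")
    out = []
    for row in frame.itertuples(index=False):
        disc = str(getattr(row, "discohesive", "unknown")).lower()
        out.append(
            SampleAnnotation(
                sample_id=row.sample,
                cohort=getattr(row, "cohort", ""),
                histology_lauren=str(getattr(row, "lauren", "unknown")).lower(),
                discohesive_growth=None if disc == "unknown" else disc in ("true", "1", "yes"),
            )
        )
    return out


def _read_sv_counts(path: str) -> dict[str, int]:
    if path.endswith(".bedpe"):
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 7:
                    raise ConfigError(f"BEDPE line with <7 columns in {path}")
                counts[parts[6]] = counts.get(parts[6], 0) + 1
        return counts
    frame = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["sample", "count"], dtype={"sample": str})
    return {row.sample: int(row.count) for row in frame.itertuples(index=False)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write outputs; returns the manifest."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbosity else logging.WARNING,
        format="[sigscar %(levelname)s] %(message)s",
        force=False,
    )
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    reference = _load_reference(config.reference)

    # --- filter ---------------------------------------------------------
    stage("filter")
    variants = sio.read_variants(config.variants)
    germline = sio.read_germline_sites(config.germline_sites) if config.germline_sites else set()
    panel = sio.read_site_evidence(config.site_evidence) if config.site_evidence else {}
    filtered = filter_variants(variants, germline, panel)
    manifest["n_variants_in"] = len(variants)
    manifest["n_variants_removed"] = len(filtered.removed)

    # --- catalogue ------------------------------------------------------
    stage("catalogue")
    matrix, excluded = build_catalogue_matrix(filtered.kept, reference)
    manifest["n_context_excluded"] = len(excluded)
    sio.write_catalogue_matrix(matrix, outdir / "catalogues.tsv")

    # --- extract (optional) --------------------------------------------
    if config.extract:
        stage("extract")
        result = extract_signatures(
            matrix.to_numpy(),
            range(config.k_min, config.k_max + 1),
            n_bootstraps=config.bootstraps,
            seed=config.seed,
        )
        extracted = SignatureSet(signatures=result.consensus_signatures)
        extracted.save(outdir / "extracted_signatures.tsv")
        stability = pd.DataFrame(
            {
                "k": sorted(result.per_k_stability),
                "stability": [result.per_k_stability[k] for k in sorted(result.per_k_stability)],
                "reconstruction_error": [result.per_k_error[k] for k in sorted(result.per_k_error)],
            }
        )
        stability.to_csv(outdir / "extraction_selection.tsv", sep="\t", index=False)
        manifest["chosen_k"] = result.chosen_k

    # --- refit ----------------------------------------------------------
    signature_set = None
    calls: dict[str, bool] = {}
    exposures = []
    if config.signatures:
        stage("refit")
        signature_set = SignatureSet.load(
            config.signatures, config.signature_sidecar or None
        )
        exposures = fit_cohort(matrix, None, signature_set)
        frame = exposures_frame(exposures)
        frame.to_csv(outdir / "exposures.tsv", sep="\t", float_format="%.4f")
        soi = config.signature_of_interest
        if soi:
            if soi not in signature_set.names:
                raise ConfigError(f"signature_of_interest {soi!r} not in signature matrix")
            calls = {
                e.sample_id: call_signature_present(
                    e, soi, config.min_mutations, config.min_fraction
                )
                for e in exposures
            }
            pd.Series(calls, name="present").rename_axis("sample").to_csv(
                outdir / "signature_calls.tsv", sep="\t"
            )
            manifest["n_positive_calls"] = int(sum(calls.values()))

    # --- indels ---------------------------------------------------------
    burdens = []
    if config.indels:
        stage("indels")
        indel_variants = sio.read_variants(config.indels)
        records = indels_from_variants(indel_variants)
        _, mh_counts = classify_indels(
            records, reference, min_size=config.min_indel_size, min_mh=config.min_mh
        )
        for sample in calls:
            mh_counts.setdefault(sample, 0)
        sv_counts = _read_sv_counts(config.sv_counts) if config.sv_counts else None
        if calls:
            burdens = burden_table(mh_counts, sv_counts, calls)

    # --- associate ------------------------------------------------------
    association_rows = []
    if config.annotations and calls:
        stage("associate")
        annotations = _read_annotations(config.annotations)
        comparisons = [
            ("discohesive_growth", "discohesive_growth", (True,)),
            ("lauren_intestinal_vs_rest", "histology_lauren", ("intestinal",)),
            ("lauren_diffuse_vs_rest", "histology_lauren", ("diffuse",)),
        ]
        for name, stratifier, levels in comparisons:
            try:
                table = build_contingency(annotations, calls, stratifier, levels)
            except ValueError:
                continue
            p = fisher_exact_two_tailed(table)
            association_rows.append(
                {"comparison": name, "a": table.a, "b": table.b, "c": table.c,
                 "d": table.d, "p_value": format_p(p)}
            )
    if burdens:
        positive = [b.n_mh_indels for b in burdens if b.sig3_present]
        negative = [b.n_mh_indels for b in burdens if not b.sig3_present]
        if positive and negative:
            u, p = mann_whitney_u(positive, negative)
            association_rows.append(
                {"comparison": "mh_indels_by_signature_status", "a": len(positive),
                 "b": len(negative), "c": int(np.median(positive)),
                 "d": int(np.median(negative)), "p_value": format_p(p)}
            )

    # --- report ---------------------------------------------------------
    stage("report")
    write_report(exposures, burdens, association_rows, outdir)
    config.write(outdir / "run_config.ini")
    sio.write_manifest(manifest, outdir / "manifest.json")
    return manifest


def write_report(exposures, burdens, association_rows, outdir: str | Path) -> None:
    """Write the per-sample burden table and association summary as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    burden_frame = pd.DataFrame(
        [
            {
                "sample": b.sample_id,
                "n_mh_indels": b.n_mh_indels,
                "n_structural_variants": (
                    "" if b.n_structural_variants is None else b.n_structural_variants
                ),
                "signature_present": b.sig3_present,
            }
            for b in sorted(burdens, key=lambda b: b.sample_id)
        ],
        columns=["sample", "n_mh_indels", "n_structural_variants", "signature_present"],
    )
    burden_frame.to_csv(outdir / "burdens.tsv", sep="\t", index=False)
    association_frame = pd.DataFrame(
        association_rows, columns=["comparison", "a", "b", "c", "d", "p_value"]
    )
    association_frame.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    if exposures:
        summary = exposures_frame(exposures)
        totals_ok = np.allclose(
            summary.drop(columns=["total", "residual_norm"]).sum(axis=1),
            summary["total"],
            rtol=1e-6,
        )
        if not totals_ok:
            raise AssertionError("exposure totals do not match per-signature sums")
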