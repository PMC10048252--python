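"""File formats, configuration and the pipeline driver.

Tabular outputs are TSV with a header line preceded by ``#``-prefixed
metadata lines (schema version included); nested results are JSON.  Every
pipeline run writes a machine-readable manifest (config, package version,
input checksums) alongside its outputs, and all randomness derives from a
single run seed via stage-named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .amplicon_aei import AlleleCounts
from .cohort_sim import CohortSample, SNP_ALLELES

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_sample_sheet",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_table_tsv",
    "read_table_tsv",
    "write_manifest",
    "sha256_of",
]

TSV_SCHEMA_VERSION = 1

REQUIRED_SHEET_COLUMNS = [
    "sample_id", "barcode", "material",
    "genotype_rs35349669", "genotype_rs10933431", "genotype_rs1141328",
    "niari", "ad_status", "sex", "age_years", "pmi_hours",
]


class SchemaError(ValueError):
    """A file does not match the expected schema version or layout."""


@dataclass
class RunConfig:
    """Pipeline run settings (see the CLI for the flag surface)."""

    subcommand: str = "run-all"
    inputs: dict = field(default_factory=dict)
    output_dir: str = "results"
    seed: int = 0
    kmer_spec: str = "GCCGGCCC[G/A]GCCGAGG"
    max_mismatch: int = 0
    allow_revcomp: bool = True
    min_depth: int = 100
    normalization: str = "cohort_mean"
    nmd_threshold_nt: int = 50
    genotype_coding: str = "additive"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# sample sheets

def _normalize_genotype(value: str, snp: str) -> str:
    """Canonicalize allele order ("CT" == "TC") and validate the alphabet."""
    minor, major = SNP_ALLELES[snp]
    if not isinstance(value, str) or len(value) != 2:
        raise ValueError(f"illegal genotype {value!r} for {snp}")
    alleles = sorted(value.upper(), key=lambda a: (a != minor, a != major))
    if any(a not in (minor, major) for a in alleles):
        raise ValueError(f"illegal genotype {value!r} for {snp} "
                         f"(alleles are {minor}/{major})")
    return "".join(alleles)


def read_sample_sheet(path) -> list[CohortSample]:
    """Read and validate a cohort sample sheet (CSV).

    Genotype strings are normalized allele-order-insensitively; errors name
    the offending column or 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet {path}: missing column(s) {missing}")
    samples, errors = [], []
    for i, row in df.iterrows():
        try:
            genos = {snp: _normalize_genotype(row[f"genotype_{snp}"], snp)
                     for snp in SNP_ALLELES}
            if row["niari"] not in ("low", "high"):
                raise ValueError(f"illegal niari {row['niari']!r}")
            if row["ad_status"] not in ("AD", "non-AD"):
                raise ValueError(f"illegal ad_status {row['ad_status']!r}")
            samples.append(CohortSample(
                sample_id=str(row["sample_id"]),
                genotype_rs35349669=genos["rs35349669"],
                genotype_rs10933431=genos["rs10933431"],
                genotype_rs1141328=genos["rs1141328"],
                niari=row["niari"], ad_status=row["ad_status"],
                sex=str(row["sex"]), age_years=float(row["age_years"]),
                pmi_hours=float(row["pmi_hours"])))
        except ValueError as exc:
            errors.append(f"row {i + 1}: {exc}")
    if errors:
        raise SchemaError(f"sample sheet {path}: " + "; ".join(errors))
    return samples


# --------------------------------------------------------------------------
# TSV dialect

def write_table_tsv(df: pd.DataFrame, path, kind: str):
    with open(path, "w") as fh:
        fh.write(f"# schema_version={TSV_SCHEMA_VERSION}\n")
        fh.write(f"# kind={kind}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path, kind: str) -> pd.DataFrame:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, sep="\t")
        except Exception as exc:
            raise SchemaError(f"{path}: unreadable TSV body: {exc}") from exc
    version = int(meta.get("schema_version", -1))
    if version != TSV_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {version} != {TSV_SCHEMA_VERSION}; "
            "migrate the file before reading")
    if meta.get("kind") != kind:
        raise SchemaError(f"{path}: kind {meta.get('kind')!r}, expected "
                          f"{kind!r}")
    return df


_COUNT_COLUMNS = ["sample_id", "material", "n_allele1", "n_allele2",
                  "n_ambiguous", "n_unassigned", "n_total"]


def write_counts_tsv(counts: Sequence[AlleleCounts], path):
    rows = [{**{c: getattr(x, c) for c in _COUNT_COLUMNS[:-1]},
             "n_total": x.n_total} for x in counts]
    write_table_tsv(pd.DataFrame(rows, columns=_COUNT_COLUMNS), path,
                    kind="allele_counts")


def read_counts_tsv(path) -> list[AlleleCounts]:
    df = read_table_tsv(path, kind="allele_counts")
    out = []
    for i, row in df.iterrows():
        try:
            c = AlleleCounts(sample_id=str(row["sample_id"]),
                             material=str(row["material"]),
                             n_allele1=int(row["n_allele1"]),
                             n_allele2=int(row["n_allele2"]),
                             n_ambiguous=int(row["n_ambiguous"]),
                             n_unassigned=int(row["n_unassigned"]))
            if c.n_total != int(row["n_total"]):
                raise ValueError("count conservation violated")
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}: corrupted row {i + 1}: {exc}") from exc
        out.append(c)
    return out


# --------------------------------------------------------------------------
# manifests

def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(output_dir, config: RunConfig, input_paths: dict):
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                   for name, p in input_paths.items() if Path(p).exists()},
    }
    path = Path(output_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
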