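"""Text-table IO and run manifests.

Phenotype tables are TSV (UTF-8, header row, `NA` for missing) with
columns `participant, family, condition, <feature> ...`.  Every CLI run
writes a JSON manifest (configuration, seeds, SHA-256 digests of inputs)
sufficient to reproduce its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FamilyDesign, GenotypeTable, SpectralPhenotype

__all__ = [
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_manifest",
    "sha256_file",
]


def write_phenotype_tsv(
    Y: SpectralPhenotype,
    path: str | Path,
    family_labels: list[str] | None = None,
) -> None:
    df = Y.to_frame().copy()
    df.insert(0, "condition", Y.condition if Y.condition is not None else "NA")
    df.insert(0, "family", family_labels if family_labels is not None else "NA")
    df.insert(0, "participant", Y.participants)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotype_tsv(path: str | Path) -> tuple[SpectralPhenotype, list[str] | None]:
    df = pd.read_csv(path, sep="\t", dtype={"participant": str, "family": str})
    meta = ["participant", "family", "condition"]
    feats = [c for c in df.columns if c not in meta]
    fam = df["family"].tolist() if "family" in df else None
    if fam is not None and all(f == "NA" for f in fam):
        fam = None
    cond = df["condition"].iloc[0] if "condition" in df else None
    Y = SpectralPhenotype(
        values=df[feats].to_numpy(dtype=float),
        participants=df["participant"].tolist(),
        feature_names=feats,
        condition=None if cond == "NA" else cond,
    )
    return Y, fam


def write_genotype_tsv(G: GenotypeTable, prefix: str | Path) -> None:
    """TSV fallback for genotypes: counts table + SNP metadata sidecar."""
    prefix = Path(prefix)
    df = pd.DataFrame(G.counts, columns=G.snps["snp"].tolist())
    df.insert(0, "family", G.family_ids if G.family_ids is not None else "NA")
    df.insert(0, "participant", G.samples)
    df.to_csv(prefix.with_suffix(".geno.tsv"), sep="\t", index=False, na_rep="NA")
    G.snps.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_genotype_tsv(prefix: str | Path) -> GenotypeTable:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".geno.tsv"), sep="\t",
                     dtype={"participant": str, "family": str})
    snps = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    snp_cols = [c for c in df.columns if c not in ("participant", "family")]
    fam = df["family"].tolist() if "family" in df else None
    if fam is not None and all(str(f) == "NA" for f in fam):
        fam = None
    return GenotypeTable(
        counts=df[snp_cols].to_numpy(dtype=float),
        snps=snps,
        samples=df["participant"].tolist(),
        family_ids=fam,
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(
    path: str | Path,
    stage: str,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
    seeds: dict[str, int] | None = None,
) -> None:
    manifest = {
        "stage": stage,
        "config": _jsonable(config),
        "seeds": _jsonable(seeds or {}),
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in (inputs or {}).items()
        },
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
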