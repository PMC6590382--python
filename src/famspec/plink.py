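"""PLINK 1 binary genotype IO (.bed/.bim/.fam), SNP-major.

Two-bit codes per the PLINK v1 .bed specification, with A1 treated as the
counted (minor) allele:

    00 -> two A1 alleles (count 2)     10 -> heterozygous (count 1)
    11 -> zero A1 alleles (count 0)    01 -> missing

Round trips are bit-exact for {0, 1, 2, missing}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeTable

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# two-bit code -> allele count (NaN = missing)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])
_COUNT_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

_BYTE_LUT = np.empty((256, 4))
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_COUNT[(_b >> (2 * _i)) & 0b11]


def write_plink(G: GenotypeTable, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam files for a genotype table."""
    prefix = Path(prefix)
    n, d = G.n, G.d
    nbytes = (n + 3) // 4
    bed = bytearray()
    bed += _MAGIC + bytes([_SNP_MAJOR])
    for s in range(d):
        packed = np.zeros(nbytes, dtype=np.uint8)
        col = G.counts[:, s]
        for i in range(n):
            v = col[i]
            code = 0b01 if not np.isfinite(v) else _COUNT_TO_CODE[float(v)]
            packed[i // 4] |= code << (2 * (i % 4))
        bed += packed.tobytes()
    prefix.with_suffix(".bed").write_bytes(bytes(bed))

    bim = pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "snp": G.snps["snp"],
            "cm": 0,
            "pos": G.snps["pos"],
            "a1": G.snps["a1"],
            "a2": G.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fids = G.family_ids if G.family_ids is not None else G.samples
    fam = pd.DataFrame(
        {"fid": fids, "iid": G.samples, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeTable:
    """Read a .bed/.bim/.fam trio into a genotype table (bit-exact)."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    n, d = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes; not a PLINK .bed file")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{prefix}.bed: only SNP-major mode (0x01) is supported")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != nbytes * d:
        raise ValueError(
            f"{prefix}.bed: size {body.size} bytes does not match "
            f"{n} samples x {d} SNPs from .fam/.bim"
        )
    counts = np.empty((n, d))
    per_snp = body.reshape(d, nbytes)
    decoded = _BYTE_LUT[per_snp].reshape(d, nbytes * 4)[:, :n]  # (D, N)
    counts = decoded.T.copy()
    snps = pd.DataFrame(
        {
            "snp": bim["snp"].astype(str),
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "a1": bim["a1"].astype(str),
            "a2": bim["a2"].astype(str),
        }
    )
    return GenotypeTable(
        counts=counts,
        snps=snps,
        samples=fam["iid"].tolist(),
        family_ids=fam["fid"].tolist(),
    )
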