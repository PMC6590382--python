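"""Core in-memory containers for the cohort analysis.

The pipeline moves three matrices around: the phenotype matrix Y
(participants x spatiospectral band-power features), the family design
F (participants x families, binary membership indicators), and the
genotype matrix G (participants x SNPs, minor-allele counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpectralPhenotype", "FamilyDesign", "GenotypeTable", "RawCohort"]


@dataclass
class SpectralPhenotype:
    """N x P matrix of spectral band powers (or any multivariate phenotype).

    Rows are participants, columns are (channel, band) features.  Band
    powers proper are non-negative; model-simulated phenotypes may be
    signed, so non-negativity is not enforced here.
    """

    values: np.ndarray
    participants: list[str]
    feature_names: list[str]
    condition: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.participants) != n:
            raise ValueError(f"{len(self.participants)} participant ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def centered(self) -> np.ndarray:
        """Column-centered copy of the value matrix."""
        return self.values - self.values.mean(axis=0, keepdims=True)

    def with_values(self, values: np.ndarray, condition: str | None = None) -> "SpectralPhenotype":
        return SpectralPhenotype(
            values=np.asarray(values, dtype=float),
            participants=list(self.participants),
            feature_names=list(self.feature_names),
            condition=self.condition if condition is None else condition,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.participants, columns=self.feature_names)


@dataclass
class FamilyDesign:
    """Binary family-membership design matrix F (N x M).

    Each row has exactly one 1 (every participant belongs to one family);
    every column has at least one member.
    """

    indicator: np.ndarray
    family_ids: list[str]
    participants: list[str]

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=float)
        if self.indicator.ndim != 2:
            raise ValueError("family indicator must be a 2-D matrix")
        n, m = self.indicator.shape
        if len(self.family_ids) != m:
            raise ValueError("family id count does not match indicator columns")
        if len(self.participants) != n:
            raise ValueError("participant count does not match indicator rows")
        if not np.all(np.isin(self.indicator, (0.0, 1.0))):
            raise ValueError("family indicator must be binary")
        if not np.all(self.indicator.sum(axis=1) == 1):
            raise ValueError("each participant must belong to exactly one family")
        if np.any(self.indicator.sum(axis=0) < 1):
            raise ValueError("every family must have at least one member")

    @classmethod
    def from_labels(
        cls, labels: Sequence[str], participants: Sequence[str] | None = None
    ) -> "FamilyDesign":
        labels = [str(x) for x in labels]
        fam_ids = sorted(set(labels))
        col = {f: j for j, f in enumerate(fam_ids)}
        ind = np.zeros((len(labels), len(fam_ids)))
        for i, lab in enumerate(labels):
            ind[i, col[lab]] = 1.0
        if participants is None:
            participants = [f"P{i:04d}" for i in range(len(labels))]
        return cls(indicator=ind, family_ids=fam_ids, participants=list(participants))

    @property
    def n(self) -> int:
        return self.indicator.shape[0]

    @property
    def m(self) -> int:
        return self.indicator.shape[1]

    @property
    def labels(self) -> list[str]:
        """Per-participant family label."""
        idx = np.argmax(self.indicator, axis=1)
        return [self.family_ids[j] for j in idx]

    def members(self, family_id: str) -> np.ndarray:
        j = self.family_ids.index(family_id)
        return np.flatnonzero(self.indicator[:, j] == 1)

    def subset(self, rows: np.ndarray) -> "FamilyDesign":
        """Row subset with empty family columns dropped."""
        rows = np.asarray(rows)
        ind = self.indicator[rows]
        keep = ind.sum(axis=0) >= 1
        return FamilyDesign(
            indicator=ind[:, keep],
            family_ids=[f for f, k in zip(self.family_ids, keep) if k],
            participants=[self.participants[i] for i in rows],
        )


@dataclass
class GenotypeTable:
    """Minor-allele-count genotypes (N x D) with per-SNP metadata.

    ``counts`` is a float matrix with entries in {0, 1, 2} and NaN for
    missing calls.  ``snps`` carries id/chromosome/position/alleles.
    """

    counts: np.ndarray
    snps: pd.DataFrame
    samples: list[str]
    family_ids: list[str] | None = None

    _REQUIRED = ("snp", "chrom", "pos", "a1", "a2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("genotype counts must be a 2-D matrix")
        n, d = self.counts.shape
        if d < 1:
            raise ValueError("genotype table must contain at least one SNP")
        if len(self.snps) != d:
            raise ValueError("SNP metadata length does not match genotype columns")
        for col in self._REQUIRED:
            if col not in self.snps.columns:
                raise ValueError(f"SNP metadata missing column {col!r}")
        if len(self.samples) != n:
            raise ValueError("sample id count does not match genotype rows")
        if self.family_ids is not None and len(self.family_ids) != n:
            raise ValueError("family id count does not match genotype rows")
        finite = self.counts[np.isfinite(self.counts)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValueError("genotype counts must be 0, 1, 2 or missing")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def d(self) -> int:
        return self.counts.shape[1]

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeTable":
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        cols = np.arange(self.d) if cols is None else np.asarray(cols)
        return GenotypeTable(
            counts=self.counts[np.ix_(rows, cols)],
            snps=self.snps.iloc[cols].reset_index(drop=True),
            samples=[self.samples[i] for i in rows],
            family_ids=None if self.family_ids is None else [self.family_ids[i] for i in rows],
        )


@dataclass
class RawCohort:
    """Multichannel raw recordings for a cohort: signals (N, C, T) at fs Hz."""

    signals: np.ndarray
    fs: float
    participants: list[str]
    family_labels: list[str] | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 3:
            raise ValueError("raw signals must have shape (participants, channels, samples)")
        if len(self.participants) != self.signals.shape[0]:
            raise ValueError("participant ids do not match signal rows")

    @property
    def duration_s(self) -> float:
        return self.signals.shape[2] / self.fs
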