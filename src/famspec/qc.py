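"""Genotype quality control.

Filter chain, applied in order: marker call rate, individual call rate,
minor allele frequency, Hardy-Weinberg exact test, and finally removal of
individuals whose siblings were removed (families reduced below two
members).  The HWE test is the exact conditional test on heterozygote
counts given the allele counts, evaluated on one sibling per family when
family information is available (siblings are not independent draws from
the population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .cohort import GenotypeTable

__all__ = ["QCThresholds", "hwe_exact_pvalue", "genotype_qc"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Keep markers/individuals strictly above these thresholds."""

    marker_call_min: float = 0.98
    individual_call_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 0.0001

    def __post_init__(self) -> None:
        for name in ("marker_call_min", "individual_call_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, no mid-p correction).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the
    observed table.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    het_values = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log P(h | allele counts) up to a shared constant
    hom_min = (n_minor - het_values) // 2
    hom_maj = n - het_values - hom_min
    logp = (
        het_values * np.log(2.0)
        - gammaln(het_values + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[het_values == n_het]
    if obs.size != 1:
        raise ValueError("observed heterozygote count incompatible with allele counts")
    return float(np.sum(p[p <= obs[0] * (1 + 1e-12)]))


def _call_rates(counts: np.ndarray, axis: int) -> np.ndarray:
    return np.mean(np.isfinite(counts), axis=axis)


def _one_per_family_rows(G: GenotypeTable) -> np.ndarray:
    if G.family_ids is None:
        return np.arange(G.n)
    seen: set[str] = set()
    rows = []
    for i, f in enumerate(G.family_ids):
        if f not in seen:
            seen.add(f)
            rows.append(i)
    return np.asarray(rows)


def genotype_qc(
    G: GenotypeTable,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeTable, dict]:
    """Apply the QC filter chain; returns the filtered table and a report.

    The report maps each filter, in application order, to the number of
    markers or individuals it removed.  Raises if no marker survives.
    """
    report: dict[str, int] = {}
    # 1. marker call rate
    keep_m = _call_rates(G.counts, axis=0) > thresholds.marker_call_min
    report["markers_call_rate"] = int(np.sum(~keep_m))
    if not keep_m.any():
        raise ValueError("all markers removed by call-rate filter")
    G = G.subset(cols=np.flatnonzero(keep_m))
    # 2. individual call rate
    keep_i = _call_rates(G.counts, axis=1) > thresholds.individual_call_min
    report["individuals_call_rate"] = int(np.sum(~keep_i))
    G = G.subset(rows=np.flatnonzero(keep_i))
    # 3. minor allele frequency
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G.counts, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf > thresholds.maf_min
    report["markers_maf"] = int(np.sum(~keep_maf))
    if not keep_maf.any():
        raise ValueError("all markers removed by MAF filter")
    G = G.subset(cols=np.flatnonzero(keep_maf))
    # 4. Hardy-Weinberg exact test on unrelated subset (one sibling per family)
    rows = _one_per_family_rows(G)
    sub = G.counts[rows]
    keep_hwe = np.ones(G.d, dtype=bool)
    for s in range(G.d):
        g = sub[:, s]
        g = g[np.isfinite(g)]
        n_het = int(np.sum(g == 1))
        n_hom1 = int(np.sum(g == 2))
        n_hom2 = int(np.sum(g == 0))
        keep_hwe[s] = hwe_exact_pvalue(n_het, n_hom1, n_hom2) > thresholds.hwe_p_min
    report["markers_hwe"] = int(np.sum(~keep_hwe))
    if not keep_hwe.any():
        raise ValueError("all markers removed by HWE filter")
    G = G.subset(cols=np.flatnonzero(keep_hwe))
    # 5. individuals whose siblings were removed
    if G.family_ids is not None:
        fam_counts: dict[str, int] = {}
        for f in G.family_ids:
            fam_counts[f] = fam_counts.get(f, 0) + 1
        keep_sib = np.array([fam_counts[f] >= 2 for f in G.family_ids])
        report["individuals_sibling"] = int(np.sum(~keep_sib))
        G = G.subset(rows=np.flatnonzero(keep_sib))
    else:
        report["individuals_sibling"] = 0
    return G, report
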