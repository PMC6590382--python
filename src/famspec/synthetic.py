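"""Synthetic family cohort generator.

Emulates the study design the pipeline targets: ~100 sibling families
(~200 participants), Hardy-Weinberg genotypes with Mendelian transmission
within families (so sibling allele sharing of ~1/2 is emergent, not
imposed), low-rank familial structure in a high-dimensional band-power
phenotype, and SNP effects planted at a controlled proportion of total
variance explained (PTVE).

The phenotype follows the generative direction of the reduced-rank model

    Y = F Psi Gamma + E,

with F the family design, Psi (M x K_true) per-family latent scores,
Gamma (K_true x P) latent-to-feature loadings and i.i.d. Gaussian noise E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from ._rng import substream
from .cohort import FamilyDesign, GenotypeTable, RawCohort, SpectralPhenotype

__all__ = [
    "CohortTruth",
    "simulate_genotypes",
    "simulate_phenotype",
    "plant_snp_effect",
    "simulate_raw_signals",
    "familial_band_profiles",
    "synthesize_cohort",
]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    psi_true : (M, K_true) familial latent coefficients.
    gamma_true : (K_true, P) latent-to-feature loadings.
    snp_effects : map SNP index -> (unit direction (P,), scale c) for
        effects planted on the mean-centered genotype.
    noise_sd : residual SD of E.
    seed : root seed; fully determines every draw.
    """

    psi_true: np.ndarray
    gamma_true: np.ndarray
    snp_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.psi_true = np.atleast_2d(np.asarray(self.psi_true, dtype=float))
        self.gamma_true = np.atleast_2d(np.asarray(self.gamma_true, dtype=float))
        m, k = self.psi_true.shape
        k2, p = self.gamma_true.shape
        if k != k2:
            raise ValueError("psi_true and gamma_true disagree on K_true")
        if k > min(m, p):
            raise ValueError("K_true must not exceed min(M, P)")
        if not np.all(np.isfinite(self.gamma_true)):
            raise ValueError("gamma_true must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def k_true(self) -> int:
        return self.psi_true.shape[1]


def simulate_genotypes(
    n_families: int,
    sibs_per_family: int = 2,
    n_snps: int = 100,
    maf_low: float = 0.2,
    maf_high: float = 0.5,
    seed: int = 0,
) -> GenotypeTable:
    """Biallelic SNP genotypes for sibling families by explicit Mendelian descent.

    Per family and SNP, two parental diplotypes are drawn at Hardy-Weinberg
    proportions with allele frequency ~ U(maf_low, maf_high); each sibling
    inherits one uniformly chosen haplotype from each parent.  Entries are
    minor-allele counts in {0, 1, 2}.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("minor allele frequencies must satisfy 0 < maf_low <= maf_high <= 0.5")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if sibs_per_family < 2:
        raise ValueError("sibs_per_family must be >= 2")
    rng = substream(seed, "genotypes")
    freqs = rng.uniform(maf_low, maf_high, size=n_snps)
    # parental haplotypes: (families, parent, haplotype, snp)
    hap = rng.random((n_families, 2, 2, n_snps)) < freqs
    n = n_families * sibs_per_family
    counts = np.empty((n, n_snps), dtype=float)
    samples: list[str] = []
    fam_labels: list[str] = []
    row = 0
    for f in range(n_families):
        for s in range(sibs_per_family):
            pick = rng.integers(0, 2, size=(2, n_snps))  # which haplotype from each parent
            gm = hap[f, 0][pick[0], np.arange(n_snps)]
            gp = hap[f, 1][pick[1], np.arange(n_snps)]
            counts[row] = gm.astype(float) + gp.astype(float)
            samples.append(f"F{f:03d}_S{s}")
            fam_labels.append(f"F{f:03d}")
            row += 1
    snps = pd.DataFrame(
        {
            "snp": [f"rs{j:06d}" for j in range(n_snps)],
            "chrom": np.full(n_snps, 1, dtype=int),
            "pos": np.arange(1, n_snps + 1) * 1000,
            "a1": ["A"] * n_snps,
            "a2": ["G"] * n_snps,
            "maf_true": freqs,
        }
    )
    return GenotypeTable(counts=counts, snps=snps, samples=samples, family_ids=fam_labels)


def simulate_phenotype(F: FamilyDesign, truth: CohortTruth) -> SpectralPhenotype:
    """Draw Y = F psi_true gamma_true + E with i.i.d. N(0, noise_sd^2) noise."""
    if truth.psi_true.shape[0] != F.m:
        raise ValueError(
            f"psi_true has {truth.psi_true.shape[0]} rows but design has {F.m} families"
        )
    rng = substream(truth.seed, "phenotype")
    signal = F.indicator @ truth.psi_true @ truth.gamma_true
    noise = truth.noise_sd * rng.standard_normal(signal.shape)
    p = truth.gamma_true.shape[1]
    return SpectralPhenotype(
        values=signal + noise,
        participants=list(F.participants),
        feature_names=[f"feat{j:04d}" for j in range(p)],
        condition="synthetic",
    )


def plant_snp_effect(
    Y: SpectralPhenotype,
    g: np.ndarray,
    direction: np.ndarray,
    target_ptve: float,
) -> tuple[SpectralPhenotype, float]:
    """Add a SNP effect c*(g - mean(g)) outer direction at an exact PTVE.

    The scale c solves ||c (g - gbar) direction||_F^2 / ||Y'_c||_F^2 =
    target_ptve in closed form (quadratic in c), where Y' = Y + effect and
    Y'_c is column-centered.  Returns the new phenotype and c.
    """
    if not (0 <= target_ptve < 1):
        raise ValueError("target_ptve must lie in [0, 1)")
    g = np.asarray(g, dtype=float)
    if g.shape != (Y.n,):
        raise ValueError(f"genotype vector length {g.shape} does not match N={Y.n}")
    direction = np.asarray(direction, dtype=float).ravel()
    if direction.shape != (Y.p,):
        raise ValueError("direction must have one entry per phenotype feature")
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("direction must be non-zero")
    direction = direction / nrm
    if target_ptve == 0:
        return Y.with_values(Y.values.copy()), 0.0
    gc = g - g.mean()
    if np.allclose(gc, 0):
        raise ValueError("monomorphic genotype: effect scale undefined")
    Yc = Y.centered()
    A = np.outer(gc, direction)  # column means already zero
    a2 = float(np.sum(A * A))
    cross = float(np.sum(Yc * A))
    y2 = float(np.sum(Yc * Yc))
    t = target_ptve
    # c^2 a2 (1-t) - 2 t c cross - t y2 = 0
    qa, qb, qc_ = a2 * (1 - t), -2 * t * cross, -t * y2
    disc = qb * qb - 4 * qa * qc_
    c = (-qb + np.sqrt(disc)) / (2 * qa)
    return Y.with_values(Y.values + c * A), float(c)


def achieved_snp_ptve(Y: SpectralPhenotype, g: np.ndarray, direction: np.ndarray, c: float) -> float:
    """Recompute the Frobenius variance ratio of a planted effect (oracle check)."""
    gc = np.asarray(g, float) - np.mean(g)
    d = np.asarray(direction, float).ravel()
    d = d / np.linalg.norm(d)
    eff = c * np.outer(gc, d)
    return float(np.sum(eff * eff) / np.sum(Y.centered() ** 2))


def _bandpass_fir(lo: float, hi: float, fs: float, numtaps: int = 601) -> np.ndarray:
    nyq = fs / 2
    if hi > nyq:
        raise ValueError(f"band edge {hi} Hz above Nyquist {nyq} Hz")
    if lo <= 0:
        return _signal.firwin(numtaps, hi, pass_zero="lowpass", fs=fs)
    return _signal.firwin(numtaps, [lo, hi], pass_zero="bandpass", fs=fs)


def simulate_raw_signals(
    profile: np.ndarray,
    bands: list[tuple[float, float]],
    duration_s: float,
    fs: float,
    seed: int = 0,
) -> np.ndarray:
    """Multichannel noise with prescribed per-band power.

    Each channel is a sum over bands of FIR band-pass filtered white noise,
    scaled so the expected power in each band equals ``profile[c, b]``
    (signal-units^2).  Returns an array (n_channels, n_samples).
    """
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    n_ch, n_b = profile.shape
    if n_b != len(bands):
        raise ValueError("profile columns must match number of bands")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 2 * max(hi for _, hi in bands):
        raise ValueError("sampling rate must exceed twice the highest band edge")
    if np.any(profile < 0):
        raise ValueError("band-power targets must be non-negative")
    rng = substream(seed, "raw-signals")
    n = int(round(duration_s * fs))
    out = np.zeros((n_ch, n))
    numtaps = 601
    for b, (lo, hi) in enumerate(bands):
        if not np.any(profile[:, b] > 0):
            continue
        h = _bandpass_fir(lo, hi, fs, numtaps)
        # normalize by the filter's in-band noise power so that the power
        # re-estimated inside [lo, hi) matches the target despite
        # transition-band leakage
        freqs, resp = _signal.freqz(h, worN=8192, fs=fs)
        power = np.abs(resp) ** 2
        df = freqs[1] - freqs[0]
        inband = (freqs >= lo) & (freqs < hi)
        gain = 2 * np.sum(power[inband]) * df / fs  # one-sided
        white = rng.standard_normal((n_ch, n + numtaps))
        filt = _signal.lfilter(h, [1.0], white, axis=1)[:, numtaps:]
        out += np.sqrt(profile[:, b] / gain)[:, None] * filt
    return out


def familial_band_profiles(
    F: FamilyDesign,
    n_channels: int,
    n_bands: int,
    familial_share: float = 0.5,
    base_power: float = 1.0,
    rel_sd: float = 0.3,
    seed: int = 0,
    k_true: int = 2,
) -> np.ndarray:
    """Per-participant positive band-power target profiles with familial structure.

    Profiles are base_power + a low-rank familial term + an individual
    term, scaled so the between-family share of profile variance is
    approximately ``familial_share``; clipped to stay positive.
    Returns (N, n_channels, n_bands).
    """
    rng = substream(seed, "profiles")
    p = n_channels * n_bands
    k = min(k_true, F.m, p)
    psi = rng.standard_normal((F.m, k))
    gamma = rng.standard_normal((k, p))
    gamma /= np.linalg.norm(gamma, axis=1, keepdims=True)
    fam = F.indicator @ psi @ gamma
    fam *= 1.0 / max(fam.std(), 1e-12)
    indiv = rng.standard_normal((F.n, p))
    s = np.sqrt(familial_share)
    mix = s * fam + np.sqrt(1 - familial_share) * indiv
    prof = base_power * (1 + rel_sd * mix)
    prof = np.clip(prof, 0.05 * base_power, None)
    return prof.reshape(F.n, n_channels, n_bands)


def synthesize_cohort(
    n_families: int = 100,
    sibs_per_family: int = 2,
    n_snps: int = 200,
    p_features: int = 200,
    k_true: int = 6,
    familial_share: float = 0.5,
    noise_sd: float = 0.1,
    n_causal: int = 0,
    target_ptve: float = 0.03,
    maf_low: float = 0.2,
    maf_high: float = 0.5,
    component_decay: float = 0.6,
    seed: int = 0,
) -> tuple[SpectralPhenotype, FamilyDesign, GenotypeTable, CohortTruth]:
    """One-call study cohort: genotypes, family design, phenotype, planted SNPs.

    The familial signal F Psi Gamma is rescaled so its Frobenius share of
    total phenotype variance is ``familial_share`` in expectation.
    Component variances decay geometrically (ratio ``component_decay``),
    mirroring the dominant-mode structure of spectral-power cohorts where
    the first familial component (overall power) carries far more variance
    than later ones; the first ``n_causal`` SNPs get effects of PTVE
    ``target_ptve`` planted along that leading loading direction.
    """
    if not (0 < component_decay <= 1):
        raise ValueError("component_decay must lie in (0, 1]")
    G = simulate_genotypes(n_families, sibs_per_family, n_snps, maf_low, maf_high, seed=seed)
    F = FamilyDesign.from_labels(G.family_ids, participants=G.samples)
    rng = substream(seed, "truth")
    weights = component_decay ** np.arange(k_true)
    psi = rng.standard_normal((F.m, k_true)) * np.sqrt(weights)
    gamma = rng.standard_normal((k_true, p_features))
    gamma /= np.linalg.norm(gamma, axis=1, keepdims=True)
    sig = F.indicator @ psi @ gamma
    # scale the familial term to the requested variance share
    sig_ms = np.mean((sig - sig.mean(axis=0)) ** 2)
    target_sig_var = familial_share / (1 - familial_share) * noise_sd**2
    scale = np.sqrt(target_sig_var / sig_ms)
    psi *= scale
    truth = CohortTruth(psi_true=psi, gamma_true=gamma, noise_sd=noise_sd, seed=seed)
    Y = simulate_phenotype(F, truth)
    direction = gamma[0] / np.linalg.norm(gamma[0])
    for j in range(n_causal):
        Y, c = plant_snp_effect(Y, G.counts[:, j], direction, target_ptve)
        truth.snp_effects[j] = (direction, c)
    return Y, F, G, truth
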