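# Methods

## Model

The core model regresses a column-centered phenotype matrix Y (N
participants × P band-power features) on covariates X (family indicators
F, optionally augmented with one SNP's mean-centered minor-allele
counts):

    Y = (X Ψ + Ω) Γ + E.

Ψ (M′ × K) maps covariates into a K-dimensional latent space, Γ (K × P)
maps the latent space onto the features, Ω (N × K) is latent-space
noise, and E is i.i.d. Gaussian observation noise.  β = ΨΓ is a rank-K
coefficient matrix: the model is a reduced-rank regression, which is
what makes P ≫ N tractable.  Note the factorization as written in the
summation form FΨ + ΩΓ is dimensionally inconsistent; the only reading
compatible with the stated shapes of Ψ, Γ and Ω is latent scores
XΨ + Ω mapped through Γ, which is what we implement.

Priors and fixed scales:

- ψ_:k ~ N(0, τ_k⁻¹ I), γ_k,: ~ N(0, τ_k⁻¹ I) with τ_k = ∏_{l≤k} δ_l,
  δ_1 ~ Gamma(10, 1), δ_{l>1} ~ Gamma(4.1, 1) (shape/rate).  The
  cumulative-product construction shrinks later components harder —
  E[τ_k] grows by a factor 4.1 per component — which orders components
  by importance and resolves the rotation ambiguity of the
  factorization.
- σ_e is **fixed** at 0.1 (not sampled), and Ω entries have fixed prior
  SD 10⁻⁶ τ_k⁻¹.  Fixing the noise scales is a deliberate part of the
  method (a small fixed K already controls complexity); with the scale
  10⁻⁶, Ω is effectively a ridge that keeps the latent scores
  well-defined rather than a substantive noise term.

## Inference

Gibbs sampling with conjugate full conditionals:

- Γ columns: Gaussian with shared K × K precision ZᵀZ/σ² + diag(τ),
  Z = XΨ + Ω.
- Ψ columns (one component at a time): Gaussian with precision
  (‖γ_k‖²/σ²) XᵀX + τ_k I, drawn in the eigenbasis of XᵀX (computed
  once), making each draw O(M²).
- Ω rows: Gaussian with shared K × K precision.
- δ_l: Gamma updates of the multiplicative-Gamma construction, using the
  sums of squares of Ψ and Γ.  Ω is excluded from these updates: its
  prior SD depends on τ_k⁻¹ (not τ_k^{-1/2}), which breaks conjugacy,
  so its scale is treated as a plug-in at the current τ.  Because the
  Ω scale is ~10⁻⁶, its feedback on τ would be negligible in any case.

Initialization is informed: ridge-stabilized least squares
(λ = 10⁻⁸ · tr XᵀX) followed by a rank-K SVD of the fitted values, so
components start ordered by explained variance and the chain converges
within the 250-iteration burn-in (500 iterations total; a 1500-iteration
chain changes the PTVE by < 0.005 on the synthetic cohort, and
`convergence_diagnostic` checks split-half stability and trace
dispersion of the PTVE trace).  One root seed drives every stream;
per-SNP and per-fold seeds are derived deterministically, so results are
bit-reproducible and independent of scan order or parallel partitioning.

The fit costs O(n_iter · (NPK + KM²)) after the one-off eigendecomposition:
about 0.6 s at N = 200, P = 200, K = 6 and 7 s at P = 4284 on one core.

## PTVE and its uncertainty

For a covariate subset S, each retained sample s gives

    PTVE_s = ‖X[:,S] Ψ_s[S,:] Γ_s‖²_F / ‖Y_c‖²_F,

and we report the posterior mean and SD of the trace.  Two distinct
uncertainty scales matter downstream and must not be conflated:

- the **posterior SD** of a single fit (stored as `ptve_sd`), used for
  the chain-stability diagnostic;
- the **scan spread**, the SD of PTVEs across the scanned SNPs, which
  includes genotype-draw chance variation.  A null SNP's PTVE varies
  with the genotype vector itself far more than with posterior
  uncertainty, and the null distribution is right-skewed, so scoring
  effects against the posterior SD declares 5σ chance outliers
  significant.  The LFDR stage therefore uses one common standard error,
  the SD of the non-permuted scan's PTVEs — the scale on which a real
  effect must stand out from the scan it was found in.  (A per-record
  posterior-SD mode is retained for diagnostic use.)

Two small-sample biases of PTVE are worth knowing:

- family fixed effects absorb chance noise along the K latent
  directions, inflating the family PTVE by roughly (M/N)(1 − share)(K/P);
- a real (unpermuted) SNP of siblings carries ~(1 + r)/2 = 75% of its
  variance inside span(F), and when F explains real signal the shrinkage
  prior splits that collinear variance between F and the SNP, so
  unpermuted null-SNP PTVEs sit slightly above the all-participant
  permutation null.  This is the familiar upper-tail excess in
  observed-versus-permuted Q-Q comparisons; the permutation null and the
  common-SE LFDR absorb it.  Consequently the distributional identity
  "null SNPs ≡ permuted SNPs" holds exactly only when the phenotype has
  no familial signal, which is how the property is tested.

## Association scan, permutation null, LFDR

One model per SNP with X = [F | g_s]; the SNP's PTVE uses the last
covariate row of Ψ only.  Missing genotypes are mean-imputed per SNP and
the covariate is mean-centered (effects are planted on the centered
genotype, matching the linear model).  Monomorphic SNPs are flagged with
PTVE 0.  The permutation null shuffles one genotype vector across all
participants (family covariates untouched) and refits; the mean of the
null PTVEs is the offset subtracted before LFDR estimation, since PTVE
is non-negative and its null center is a positive chance level.

LFDRs come from an empirical-Bayes two-group mixture: a point mass at
zero plus half-uniform components Uniform(0, a_j) on a geometric grid,
convolved with Gaussian noise at each effect's SE, weights fitted by EM
with a mild Dirichlet penalty (pseudo-count 10) on the null weight.
Significant/suggestive labels use LFDR < 0.05 / < 0.1.  Permuted runs
are scored under the mixture fitted to the observed scan
(`MixtureFit.lfdr_at`); on the synthetic cohort none of 200 permuted
refits reaches LFDR 0.05 while planted PTVE-0.03 effects score ~10⁻⁵.

## Fingerprinting

Families are assigned whole to cross-validation folds (seeded).  Per
fold, the model is fit to the training families and all rows are
embedded with the fold's Γ via the right pseudo-inverse Γ⁺ = Γᵀ(ΓΓᵀ)⁻¹,
centering by training column means.  Candidate sets are restricted to
the test fold: training rows carry fitted family means and are
systematically farther from any held-out query, so mixing them into the
candidate set biases even the chance level (measured mean rank ~7 on
pure noise instead of 10).  With 10 folds over ~100 sib-pair families
the candidate set is exactly 1 related + 18 unrelated.  Ties in L1
distance receive midranks; when a fold is larger than 19, the 18
unrelated are resampled (default 20 times, seeded) and ranks averaged.

A known degeneracy of the pseudo-inverse embedding: if the fitted K
exceeds the data's true latent rank, the shrinkage prior drives the
surplus Γ rows toward zero and Γ⁺ amplifies their noise coordinates by
the inverse row norm, drowning the informative coordinates in the L1
distance.  The synthetic default therefore matches the generator rank to
the reference analysis dimension (K_true = 6); on real data the fitted
components all carry signal and the issue does not arise until K is
pushed far past the informative rank.

## Band powers

`band_edges` builds 22 contiguous half-open bands starting at 1 Hz with
widths linear from 2 to 6 Hz and drops the single band containing
50 Hz (power-line interference), retaining 21.  The printed endpoints of
the original band scheme (first band 1–3 Hz, last 81.8–87.8 Hz, 21
bands) are mutually inconsistent with any single linear-width scheme, so
the constructor is parameterized and the defaults approximate those
endpoints; with 204 channels the layout gives P = 4284 features.
`band_power` integrates a Hamming-windowed full-length one-sided
periodogram over [lo, hi) on bin centers; the convention is
Parseval-consistent (white-noise band powers over a partition of
[0, Nyquist) sum to the variance), and no transform is applied to band
powers by default (log10 available as an option).

## Synthetic cohort

The generator is the study-design stand-in for the protected cohort:

- **Genotypes**: per family and SNP, two parental diplotypes at
  Hardy-Weinberg proportions with allele frequency ~ U(0.2, 0.5), one
  haplotype transmitted per parent per sibling.  Sibling genotype
  correlation ≈ ½ is emergent (measured 0.492 over 1000 SNPs), and
  founders satisfy HWE — both are tested, not assumed.
- **Phenotype**: Y = FΨΓ + E with K_true = 6 components whose variances
  decay geometrically (ratio 0.6), mirroring the dominant-total-power
  structure of spectral cohorts where the first familial component
  carries several times the variance of later ones; the familial signal
  is rescaled so its variance share is 0.5 (within-family phenotype
  correlations are not published for the reference cohort, so the share
  is a modeling choice).  noise_sd defaults to 0.1, matching the model's
  fixed σ_e so the sampler is well-specified on its own generative
  family.
- **SNP effects**: added as c·(g − ḡ)·direction with c solved in closed
  form so the realized Frobenius variance ratio equals the target
  (default 0.03) to 1e-6; the direction is the leading familial loading.
- **Raw signals**: sums of FIR band-pass filtered Gaussian noise, scaled
  by the filter's in-band noise power gain so re-estimated band powers
  hit their targets despite transition-band leakage.

What the generator does **not** emulate: sensor geometry and spatially
correlated noise, 1/f spectral shape within bands, linkage
disequilibrium between SNPs, non-Gaussian phenotype tails, and
population structure.  Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated design,
not robustness to those real-data features.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| K | 6 | latent components (association-study reference) |
| n_iter / burn_in | 500 / 250 | Gibbs iterations / discarded prefix |
| sigma_e | 0.1 | fixed observation-noise SD |
| omega_scale | 1e-6 | Ω prior SD multiplier on τ_k⁻¹ |
| δ shapes/rates | (10,1), (4.1,1) | shrinkage hyperpriors |
| n_folds / n_unrelated | 10 / 18 | fingerprint cross-validation design |
| marker/individual call | >0.98 / >0.95 | QC call-rate thresholds |
| MAF / HWE p | >0.05 / >1e-4 | QC marker filters |
| LFDR thresholds | 0.05 / 0.1 | significant / suggestive |

Degenerate inputs: requested K above the achievable initialization rank
is reduced with a warning; rank-deficient Γ falls back to a
truncated-SVD pseudo-inverse with a warning; monomorphic SNPs are
flagged rather than fit; a notch frequency outside the covered range
drops no band and logs a warning; QC raises if a filter removes every
marker.  HWE is evaluated on one sibling per family (siblings are not
independent population draws); filters apply in the order marker call
rate → individual call rate → MAF → HWE → sibling completeness and the
chain is idempotent.

Problem sizes in the test suite and acceptance script are scaled-down
replicates of the study design (N = 200 throughout; P = 100–200 for most
checks, the full P = 4284 for the chain-stability experiment whose
Monte-Carlo scale depends on P; 200 permutation refits), chosen so the
whole suite completes in minutes on one core while keeping every
qualitative regime — P ≫ N within fits, familial share 0.5, planted
effects at PTVE 0.03 — intact.

## Known limitations

- The Gibbs sampler keeps dense per-sample Ψ, Γ, Ω arrays in memory;
  at 150k SNPs the scan is embarrassingly parallel but the package
  provides only serial execution (results are partition-order
  invariant by construction).
- The LFDR mixture assumes a unimodal non-negative effect prior; other
  empirical-Bayes variants (e.g. normal mixtures) are not implemented.
- PTVE's collinearity leak between F and sibling genotypes (above)
  means the SNP PTVE is a slightly conservative-to-liberal hybrid
  depending on familial share; the permutation null is the calibrated
  reference.
- No VCF ingestion, no imputation, no LD-aware multi-SNP models, no
  source-space or sensor-geometry modeling.
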