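# famspec

Familial structure and genome-wide association for multichannel
spectral-power phenotypes, via Bayesian reduced-rank regression (BRRR).

## The problem

Oscillatory brain activity, summarized as band power per sensor over a
grid of frequency bands, is heritable — but the phenotype is very
high-dimensional (hundreds of channels × ~20 bands ≈ thousands of
correlated features) while sibling cohorts are small (a few hundred
participants). `famspec` implements the analysis chain for this setting:

1. **Band-power phenotyping** — Hamming-windowed full-length periodograms
   integrated over linearly widening bands (21 retained bands from 1 Hz,
   the band containing 50 Hz dropped), giving the phenotype matrix
   **Y** (N × P).
2. **Reduced-rank familial model** — with family membership indicators
   **F** (N × M),

   Y = (F Ψ + Ω) Γ + E,

   where Ψ (M × K) holds per-family latent scores, Γ (K × P) projects the
   K-dimensional latent space onto the features, Ω is latent-space noise,
   and E is Gaussian observation noise with fixed SD σ_e = 0.1.  The
   product β = ΨΓ is a rank-K regression coefficient matrix.  Columns of
   Ψ and rows of Γ carry multiplicative-Gamma shrinkage priors
   N(0, τ_k⁻¹ I), τ_k = ∏_{l≤k} δ_l with δ_1 ~ G(10, 1),
   δ_{l>1} ~ G(4.1, 1), so components are ordered by importance.
   Inference is Gibbs sampling (500 iterations, 250 burn-in) from an
   informed initialization in which the covariates explain maximal
   variance.
3. **Fingerprinting** — Γ is learned on 90% of the families; held-out
   participants are embedded by the right pseudo-inverse **Y**Γ⁺ and each
   sibling is ranked among 1 related + 18 unrelated candidates by L1
   distance (rank 1 = perfect, 10 = chance).  The same machinery ranks a
   participant's own data from a disjoint time segment.
4. **Association scan** — one model per SNP with covariates [F | g_s],
   scored by the proportion of total variance explained,

   PTVE = ‖g_s ψ_s Γ‖²_F / ‖Y_c‖²_F,

   calibrated against genotype-permuted refits, with empirical-Bayes
   local false discovery rates (point mass at zero + half-uniform
   mixture, EM-fitted) labeling significant (LFDR < 0.05) and suggestive
   (< 0.1) SNPs.
5. **Genotype QC and IO** — call-rate/MAF/exact-HWE filters with
   sibling-completeness, PLINK .bed/.bim/.fam and TSV round trips.

Protected cohort data cannot ship, so a first-class synthetic module
generates the full study design: sibling families with Mendelian
genotype transmission (IBD ≈ ½ emergent), low-rank familial phenotype
structure with geometrically decaying component variances, SNP effects
planted at exact PTVE, and band-limited raw signals for the
segment-length experiments.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
synthetic cohort (100 sibling-pair families, P = 200 features, familial
variance share 0.5, two SNP effects planted at PTVE 0.03):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_fingerprint.py     --seed 1
python analysis/03_association.py    --seed 1
python analysis/04_sensitivity.py    --seed 1
```

which prints (abridged):

```
realized familial variance share: 0.476 (target 0.50)
mean sibling genotype correlation: 0.492 (Mendelian expectation 0.5)

sibling mean rank (familial signal): 1.15 over 200 queries
sibling mean rank (pure noise):      8.95 (chance level 10)

scanned 60 SNPs: 2 significant (LFDR<0.05), 0 suggestive (LFDR<0.1); pi0 = 0.964
permutation null: mean PTVE 0.00068 over 200 runs; 0 permuted runs below LFDR 0.05
     snp  chr   pos     ptve  ptve_sd     lfdr       label
rs000001    1  2000 0.037760 0.002269 0.000018 significant
rs000000    1  1000 0.037646 0.002655 0.000020 significant

K sensitivity (SNP rs000000): max |PTVE_K - PTVE_6| = 0.00164 over K=1..12
chain stability: max |PTVE difference| = 0.0061 percentage points
stratification: max r^2 = 0.0296; 0 of 60 pairs below the Bonferroni limit 8.33e-04
```

Reading the numbers: siblings of held-out families are found at mean
rank 1.15 (chance would be 10), i.e. the latent components are a strong
familial fingerprint; both planted SNPs are recovered near their target
effect size and flagged significant while none of the 200 permuted
genotypes is; the SNP PTVE is insensitive to the latent dimension K; and
the latent components show no spurious correlation with ancestry axes.

A `famspec` console command exposes the same stages
(`simulate`, `bandpower`, `qc`, `fit`, `fingerprint`, `gwas`, `lfdr`,
`report`); every run writes a JSON manifest with its configuration,
seeds and input digests.

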