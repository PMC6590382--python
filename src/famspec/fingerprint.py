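"""Cross-validated familial fingerprinting in the latent space.

The question: do the latent spectral components learned from training
families place held-out siblings near each other?  Procedure: learn Gamma
on 90% of families, embed test participants via the right pseudo-inverse
(Y Gamma^+), and rank each participant's sibling among a candidate set of
1 related + 18 unrelated participants by L1 distance.  Perfect prediction
gives rank 1; chance gives (n_candidates + 1)/2 = 10.

The same machinery ranks a participant's own data from a disjoint time
segment ("self identification"), and both are traced as a function of the
segment length used for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._rng import child_seed, substream
from .bandpower import BandScheme, spectra_matrix
from .brrr import BRRRConfig, fit, latent_embed
from .cohort import FamilyDesign, RawCohort, SpectralPhenotype

__all__ = [
    "RankingSummary",
    "rank_by_l1",
    "family_crossval",
    "self_identification",
    "segment_rank_curve",
]

log = logging.getLogger(__name__)


@dataclass
class RankingSummary:
    """Aggregate of similarity ranks over queries (1 = perfect, 10 = chance)."""

    mean_rank: float
    ranks: list[float]
    n_candidates: int = 19
    segment_length_s: float | None = None
    condition: str | None = None
    K: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.mean_rank <= self.n_candidates):
            raise ValueError("mean rank outside [1, n_candidates]")


def rank_by_l1(query: np.ndarray, related_index: int, candidates: np.ndarray) -> float:
    """Rank of the related candidate by ascending L1 distance to the query.

    Exact ties receive midranks.
    """
    query = np.asarray(query, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.ndim != 2 or candidates.shape[0] < 2:
        raise ValueError("need at least two candidates")
    if not (0 <= related_index < candidates.shape[0]):
        raise ValueError("related_index out of range")
    if not (np.all(np.isfinite(query)) and np.all(np.isfinite(candidates))):
        raise ValueError("non-finite coordinates")
    dists = np.sum(np.abs(candidates - query), axis=1)
    return float(rankdata(dists, method="average")[related_index])


def _rank_queries(
    embeddings: np.ndarray,
    queries: list[tuple[int, int]],
    family_labels: list[str],
    n_unrelated: int,
    n_repeats: int,
    rng: np.random.Generator,
    query_embeddings: np.ndarray | None = None,
    pool_rows: list[int] | None = None,
) -> list[float]:
    """Average rank per (query, related) pair over resampled candidate sets.

    ``embeddings`` hold the candidate coordinates; queries are indices into
    ``query_embeddings`` (defaults to the candidate embeddings).  Unrelated
    candidates are drawn from ``pool_rows`` (defaults to all rows) minus
    the query's family.
    """
    if query_embeddings is None:
        query_embeddings = embeddings
    n = embeddings.shape[0]
    if pool_rows is None:
        pool_rows = list(range(n))
    ranks = []
    for qi, ri in queries:
        fam = family_labels[qi]
        pool = np.array(
            [j for j in pool_rows if family_labels[j] != fam],
            dtype=int,
        )
        if pool.size < n_unrelated:
            raise ValueError("not enough unrelated participants for candidate set")
        reps = []
        for _ in range(n_repeats):
            unrel = rng.choice(pool, size=n_unrelated, replace=False)
            cand = np.vstack([embeddings[ri][None, :], embeddings[unrel]])
            reps.append(rank_by_l1(query_embeddings[qi], 0, cand))
        ranks.append(float(np.mean(reps)))
    return ranks


def _fold_assignment(family_ids: list[str], n_folds: int, rng: np.random.Generator) -> dict[str, int]:
    fams = list(family_ids)
    order = rng.permutation(len(fams))
    return {fams[j]: i % n_folds for i, j in enumerate(order)}


def family_crossval(
    Y: SpectralPhenotype,
    F: FamilyDesign,
    config: BRRRConfig,
    n_folds: int = 10,
    n_unrelated: int = 18,
    n_repeats: int = 20,
    seed: int = 0,
) -> RankingSummary:
    """Sibling ranking under family-wise cross-validation.

    Families (never individuals) are assigned to folds; per fold, BRRR is
    fit on the training families, test participants are embedded with the
    fold's Gamma (centering by training means), and each test participant
    with a sibling ranks that sibling against ``n_unrelated`` test-fold
    participants sampled from outside the family (averaged over
    ``n_repeats`` seeded resamples).  Candidates are restricted to the
    test fold so every member of the candidate set is embedded under the
    same held-out conditions as the query; with 10 folds over ~100
    sib-pair families this yields exactly 1 related + 18 unrelated.
    """
    if Y.n != F.n:
        raise ValueError("phenotype and family design disagree on N")
    rng = substream(seed, "crossval")
    folds = _fold_assignment(F.family_ids, n_folds, rng)
    labels = F.labels
    all_ranks: list[float] = []
    for fold in range(n_folds):
        test_fams = {f for f, k in folds.items() if k == fold}
        if not test_fams:
            continue
        train_rows = np.array([i for i, lab in enumerate(labels) if lab not in test_fams])
        F_train = F.subset(train_rows)
        Y_train = Y.values[train_rows]
        cfg = config.with_seed(child_seed(config.seed, "fold", fold))
        post = fit(Y_train, F_train.indicator, cfg)
        emb = latent_embed(Y.values, post.gamma_mean, center=post.col_means)
        queries = []
        test_rows = []
        for i, lab in enumerate(labels):
            if lab not in test_fams:
                continue
            test_rows.append(i)
            sibs = [j for j in F.members(lab) if j != i]
            if sibs:
                queries.append((i, sibs[0]))
        all_ranks.extend(
            _rank_queries(emb, queries, labels, n_unrelated, n_repeats, rng,
                          pool_rows=test_rows)
        )
    return RankingSummary(
        mean_rank=float(np.mean(all_ranks)),
        ranks=all_ranks,
        n_candidates=n_unrelated + 1,
        condition=Y.condition,
        K=config.K,
    )


def self_identification(
    Y_segment_a: SpectralPhenotype,
    Y_segment_b: SpectralPhenotype,
    Gamma: np.ndarray,
    n_unrelated: int = 18,
    seed: int = 0,
    n_repeats: int = 20,
    family_labels: list[str] | None = None,
    center: np.ndarray | None = None,
) -> RankingSummary:
    """Rank each participant's own later-segment data among other participants.

    Queries come from segment a, candidates (the same participant plus
    ``n_unrelated`` others) from segment b; both segments are embedded with
    the same Gamma.  Unrelated candidates exclude the query's family when
    family labels are given.
    """
    if Y_segment_a.participants != Y_segment_b.participants:
        raise ValueError("segments must contain the same participants in the same order")
    rng = substream(seed, "self-id")
    emb_a = latent_embed(Y_segment_a.values, Gamma, center=center)
    emb_b = latent_embed(Y_segment_b.values, Gamma, center=center)
    n = emb_a.shape[0]
    labels = family_labels if family_labels is not None else [str(i) for i in range(n)]
    queries = [(i, i) for i in range(n)]
    ranks = _rank_queries(emb_b, queries, labels, n_unrelated, n_repeats, rng,
                          query_embeddings=emb_a)
    return RankingSummary(
        mean_rank=float(np.mean(ranks)),
        ranks=ranks,
        n_candidates=n_unrelated + 1,
        condition=Y_segment_a.condition,
        K=int(np.asarray(Gamma).shape[0]),
    )


def segment_rank_curve(
    raw: RawCohort,
    F: FamilyDesign,
    scheme: BandScheme,
    durations_s: list[float],
    config: BRRRConfig,
    seed: int = 0,
    n_folds: int = 5,
    n_unrelated: int = 18,
    n_repeats: int = 10,
) -> dict[str, list[RankingSummary]]:
    """Sibling / self / full-data-baseline ranking versus evaluation length.

    Gamma is learned per fold from full-length band powers; for each
    duration t, test band powers are recomputed from the first t seconds
    (and a disjoint t-second window for self identification), embedded,
    and ranked.  The baseline ranks on the raw band-power vectors
    themselves (identity embedding, L1), as a full-dimensional reference.
    """
    max_t = max(durations_s)
    if 2 * max_t > raw.duration_s + 1e-9:
        raise ValueError("recordings must cover twice the longest duration")
    rng = substream(seed, "segment-curve")
    Y_full = spectra_matrix(raw, scheme)
    labels = F.labels
    folds = _fold_assignment(F.family_ids, n_folds, rng)
    # one fit per fold on full-length data
    fold_models = {}
    for fold in range(n_folds):
        test_fams = {f for f, k in folds.items() if k == fold}
        train_rows = np.array([i for i, lab in enumerate(labels) if lab not in test_fams])
        F_train = F.subset(train_rows)
        cfg = config.with_seed(child_seed(config.seed, "curve-fold", fold))
        post = fit(Y_full.values[train_rows], F_train.indicator, cfg)
        fold_models[fold] = (test_fams, post)

    out: dict[str, list[RankingSummary]] = {"sibling": [], "self": [], "baseline": []}
    for t in durations_s:
        Y_a = spectra_matrix(raw, scheme, 0.0, t)
        Y_b = spectra_matrix(raw, scheme, t, 2 * t)
        sib_ranks: list[float] = []
        self_ranks: list[float] = []
        base_ranks: list[float] = []
        for fold, (test_fams, post) in fold_models.items():
            emb_a = latent_embed(Y_a.values, post.gamma_mean, center=post.col_means)
            emb_b = latent_embed(Y_b.values, post.gamma_mean, center=post.col_means)
            queries_sib = []
            test_rows = []
            for i, lab in enumerate(labels):
                if lab not in test_fams:
                    continue
                test_rows.append(i)
                sibs = [j for j in F.members(lab) if j != i]
                if sibs:
                    queries_sib.append((i, sibs[0]))
            sib_ranks.extend(
                _rank_queries(emb_a, queries_sib, labels, n_unrelated, n_repeats,
                              rng, pool_rows=test_rows)
            )
            self_ranks.extend(
                _rank_queries(emb_b, [(i, i) for i in test_rows], labels,
                              n_unrelated, n_repeats, rng, query_embeddings=emb_a,
                              pool_rows=test_rows)
            )
            base_ranks.extend(
                _rank_queries(Y_a.values, queries_sib, labels, n_unrelated,
                              n_repeats, rng, pool_rows=test_rows)
            )
        for key, ranks in (("sibling", sib_ranks), ("self", self_ranks),
                           ("baseline", base_ranks)):
            out[key].append(
                RankingSummary(
                    mean_rank=float(np.mean(ranks)),
                    ranks=ranks,
                    n_candidates=n_unrelated + 1,
                    segment_length_s=t,
                    condition=raw.condition,
                    K=config.K if key != "baseline" else None,
                )
            )
    return out
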