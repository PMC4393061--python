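"""One-class screening of topology feature vectors.

Only a handful of topologies are verified as real RNA structures, so
the classification question is not "class A or class B" but "how well
does the verified set typify the whole class?" — a data-domain-
description problem.  This module provides the toolbox:

* nearest-neighbor ranking of candidates by distance to the verified
  set, and closest-k / furthest splits;
* average-linkage hierarchical clustering and PAM k-medoids over the
  normalized feature rows;
* a leave-one-as-negative scheme: declare a single candidate negative,
  train a two-class scorer against the verified set, and see where the
  remaining candidates land;
* the iterative cognitive one-class algorithm.  Starting from the
  verified patterns ``P`` and the unclassified pool ``S``, synthetic
  "large-σ" patterns many reference standard deviations from every
  training pattern seed a negative set ``N``.  Each iteration trains a
  scorer on ``P ∪ N``, scores ``S``, derives a ROC threshold between
  the current ``P`` and ``N`` scores, promotes up to ``n`` top-scoring
  patterns above the threshold into ``P``, demotes up to ``m``
  bottom-scoring patterns below it into ``N``, returns misclassified
  members of ``N`` and ``P`` to ``S``, and drops the synthetic seeds
  after the first iteration (re-seeding only when ``N`` would
  otherwise be empty while work remains).  With a single underlying
  class ``N`` empties and ``S`` is absorbed into ``P``; with two real
  classes a two-class partition emerges, the second class accumulating
  in the final negative set ``N_f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .features import FeatureMatrix
from .multigraph import Multigraph

__all__ = [
    "Scorer",
    "NeuralScorer",
    "LogisticScorer",
    "PatternSets",
    "IterationRecord",
    "nn_rank",
    "split_by_rank",
    "cluster",
    "leave_one_negative",
    "make_large_sigma_patterns",
    "roc_threshold",
    "cognitive_one_class",
    "persistence_ranking",
    "triangle_annotation",
]


# -- scorers -------------------------------------------------------------

class Scorer(Protocol):
    """Trainable binary scorer contract: scores lie in [0, 1]."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Scorer": ...
    def score_samples(self, X: np.ndarray) -> np.ndarray: ...


class NeuralScorer:
    """Small feed-forward network with a logistic output (default scorer)."""

    def __init__(self, seed: int = 0, hidden: int = 8, alpha: float = 0.5,
                 max_iter: int = 400):
        self._model = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            solver="lbfgs",
            alpha=alpha,  # L2 penalty; keeps the learned boundary smooth
            max_iter=max_iter,
            random_state=seed,
        )

    def fit(self, X, y):
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._model.fit(X, y)
        return self

    def score_samples(self, X):
        return self._model.predict_proba(X)[:, list(self._model.classes_).index(1)]


class LogisticScorer:
    """Logistic regression satisfying the same contract."""

    def __init__(self, seed: int = 0, C: float = 1.0):
        self._model = LogisticRegression(C=C, max_iter=1000, random_state=seed)

    def fit(self, X, y):
        self._model.fit(X, y)
        return self

    def score_samples(self, X):
        return self._model.predict_proba(X)[:, list(self._model.classes_).index(1)]


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < -1e-9 or scores.max() > 1 + 1e-9):
        raise ValueError("scorer violated the [0, 1] score contract")
    return np.clip(scores, 0.0, 1.0)


# -- nearest-neighbor ranking and clustering -----------------------------

def nn_rank(fm: FeatureMatrix, verified_ids: Sequence[str]) -> pd.Series:
    """Distance from each non-verified row to its nearest verified row.

    Euclidean distance on the (normalized) feature rows; returned as a
    Series indexed by graph id, ascending, ties broken by id.
    """
    verified = list(verified_ids)
    if not verified:
        raise ValueError("verified set is empty")
    others = [g for g in fm.values.index if g not in set(verified)]
    vx = fm.values.loc[verified].to_numpy()
    ox = fm.values.loc[others].to_numpy()
    d = cdist(ox, vx).min(axis=1)
    series = pd.Series(d, index=others, name="distance_to_verified")
    # stable sort after an id sort -> ascending distance, ties by id
    return series.sort_index(kind="stable").sort_values(kind="stable")


def split_by_rank(ranking: pd.Series, k: int) -> tuple[list[str], list[str]]:
    """Stable split of a ranking into the closest ``k`` and the rest."""
    if not 0 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range for ranking of length {len(ranking)}")
    ids = list(ranking.index)
    return ids[:k], ids[k:]


def _pam_kmedoids(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic PAM (BUILD + swap) k-medoids on Euclidean distances."""
    n = X.shape[0]
    D = cdist(X, X)
    # BUILD: greedy medoid selection minimizing total assignment cost
    medoids: list[int] = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = None, None
        current = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0).sum()
            if best_gain is None or gain > best_gain or (gain == best_gain and j < best_j):
                best_gain, best_j = gain, j
        medoids.append(best_j)
    # SWAP until no improvement
    improved = True
    while improved:
        improved = False
        cost = D[:, medoids].min(axis=1).sum()
        for mi, m in enumerate(list(medoids)):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = j
                tc = D[:, trial].min(axis=1).sum()
                if tc < cost - 1e-12:
                    medoids = trial
                    cost = tc
                    improved = True
    return D[:, medoids].argmin(axis=1)


def cluster(fm: FeatureMatrix, k: int, method: str = "hierarchical", seed: int = 0) -> pd.Series:
    """Cluster feature rows into ``k`` groups.

    ``method`` is ``"hierarchical"`` (average linkage on Euclidean
    distances, cut at ``k`` clusters) or ``"kmedoids"`` (PAM).  Both
    are deterministic; ``seed`` is accepted for interface uniformity.
    Labels are renumbered 0..k-1 by first appearance for stability.
    """
    X = fm.values.to_numpy()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    if method == "hierarchical":
        if k == 1 or X.shape[0] == 1:
            labels = np.zeros(X.shape[0], dtype=int)
        else:
            Z = linkage(pdist(X), method="average")
            labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif method == "kmedoids":
        labels = _pam_kmedoids(X, k)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        remap.setdefault(int(lab), len(remap))
        out.append(remap[int(lab)])
    return pd.Series(out, index=fm.values.index, name="cluster")


# -- leave-one-as-negative -----------------------------------------------

def leave_one_negative(
    fm: FeatureMatrix,
    verified_ids: Sequence[str],
    scorer_factory=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Declare each candidate negative in turn and see who follows it.

    For each unverified candidate ``c``, a scorer is trained on the
    verified rows (label 1) plus ``c`` alone (label 0) and applied to
    the remaining unverified rows; the report records the fraction
    scored above 0.5, i.e. classed with the verified side.  A fraction
    near 1 for every choice of ``c`` says the candidates are
    indistinguishable from the verified class no matter which single
    graph is presumed non-RNA.
    """
    scorer_factory = scorer_factory or (lambda s: NeuralScorer(seed=s))
    verified = list(verified_ids)
    others = [g for g in fm.values.index if g not in set(verified)]
    if len(others) < 2:
        raise ValueError("need at least two unverified candidates")
    vx = fm.values.loc[verified].to_numpy()
    rows = []
    for c in others:
        rest = [g for g in others if g != c]
        X = np.vstack([vx, fm.values.loc[[c]].to_numpy()])
        y = np.array([1] * len(verified) + [0])
        try:
            scorer = scorer_factory(seed).fit(X, y)
            scores = _check_scores(scorer.score_samples(fm.values.loc[rest].to_numpy()))
        except Exception as exc:  # noqa: BLE001 - annotate failing candidate
            raise RuntimeError(f"scorer failed with candidate {c!r}: {exc}") from exc
        rows.append({
            "candidate": c,
            "n_scored": len(rest),
            "fraction_with_verified": float(np.mean(scores > 0.5)),
        })
    return pd.DataFrame(rows).set_index("candidate")


# -- large-sigma negatives and thresholds --------------------------------

def make_large_sigma_patterns(
    P_vectors: np.ndarray,
    count: int,
    sigma_min: float,
    seed: int,
    sigma: np.ndarray | None = None,
) -> np.ndarray:
    """Synthetic negatives far from every training pattern.

    Each output vector differs from every row of ``P_vectors`` by at
    least ``sigma_min`` reference standard deviations *in every
    descriptor*: per coordinate a random side of the training range is
    chosen and a random nonnegative overshoot added beyond the
    ``sigma_min`` clearance.  Distances are therefore "many standard
    deviations" on the same per-descriptor scale used to standardize
    the features.  ``sigma`` defaults to 1 per coordinate (features
    already standardized).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if sigma_min <= 0:
        raise ValueError("sigma_min must be > 0")
    P = np.atleast_2d(np.asarray(P_vectors, dtype=float))
    dim = P.shape[1]
    sig = np.ones(dim) if sigma is None else np.asarray(sigma, dtype=float)
    rng = np.random.default_rng(seed)
    lo = P.min(axis=0)
    hi = P.max(axis=0)
    signs = rng.integers(0, 2, size=(count, dim)) * 2 - 1
    overshoot = rng.exponential(scale=0.5, size=(count, dim)) * sig
    above = hi + sigma_min * sig + overshoot
    below = lo - sigma_min * sig - overshoot
    return np.where(signs > 0, above, below)


def _youden_band(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """The [low, high] interval of thresholds maximizing Youden's J.

    Candidates are the observed scores plus midpoints between adjacent
    distinct scores, so with perfectly separated classes the band spans
    from the midpoint of the separating gap up to the smallest positive
    score.  Scores inside the band are ambiguous: a pattern must score
    above the band to be confidently positive and below it to be
    confidently negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    distinct = np.unique(scores)
    cands = np.concatenate([distinct, (distinct[:-1] + distinct[1:]) / 2.0]) \
        if distinct.size > 1 else distinct
    best_j, lo, hi = None, None, None
    for t in np.sort(cands):
        j = float(np.mean(pos >= t)) + float(np.mean(neg < t)) - 1.0
        if best_j is None or j > best_j + 1e-12:
            best_j, lo, hi = j, t, t
        elif abs(j - best_j) <= 1e-12:
            hi = t
    return float(lo), float(hi)


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1.

    A score >= threshold is classed positive.  Candidate thresholds are
    the observed scores; ties in J resolve toward the larger threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both labels required to place a threshold")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t, best_j = None, None
    for t in sorted(set(scores.tolist())):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        if best_j is None or j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


# -- the cognitive one-class algorithm -----------------------------------

@dataclass
class IterationRecord:
    iteration: int
    threshold: float
    lower_threshold: float
    scores: dict[str, float]          # scores of S members this iteration
    moved_to_P: list[str]
    moved_to_N: list[str]
    returned_to_S: list[str]
    synthetic_count: int
    P: list[str]
    N: list[str]
    S: list[str]


@dataclass
class PatternSets:
    """The evolving P / N / S partition with full iteration history."""

    P: list[str]
    N: list[str]
    S: list[str]
    history: list[IterationRecord] = field(default_factory=list)

    def check_disjoint(self) -> None:
        p, n, s = set(self.P), set(self.N), set(self.S)
        if p & n or p & s or n & s:
            raise AssertionError("P, N, S must be pairwise disjoint")

    @property
    def N_f(self) -> list[str]:
        """Final negative set (real patterns only; synthetics never enter)."""
        return list(self.N)


def cognitive_one_class(
    fm: FeatureMatrix,
    P0_ids: Sequence[str],
    scorer_factory=None,
    *,
    n: int | None = None,
    m: int | None = None,
    sigma_min: float = 5.0,
    n_synthetic: int | None = None,
    max_iter: int = 20,
    seed: int = 0,
) -> PatternSets:
    """Iterative data-domain description around the verified class.

    ``n`` / ``m`` cap how many patterns may be promoted to ``P`` /
    demoted to ``N`` per iteration (default: 10% of the initial ``S``,
    at least 1); promotions must score above the iteration's ROC
    threshold and demotions below it, so fewer than the cap may move.
    ``n_synthetic`` defaults to ``max(2 |P0|, 40)`` — enough scaffolding
    negatives to balance and surround the positive class.
    ``q`` and ``r`` — the members of ``N`` and ``P`` returned to ``S``
    — are determined by misclassification against the threshold, not
    free parameters.  Synthetic large-σ negatives (``n_synthetic``,
    default ``max(2 |P0|, 40)``) seed ``N`` and are discarded after
    the first iteration; they are re-seeded in a later iteration only
    if ``N`` has no real members, since the scorer needs both classes.

    Runs until ``S`` is empty or ``max_iter`` iterations; fully
    reproducible given ``seed``.
    """
    scorer_factory = scorer_factory or (lambda s: NeuralScorer(seed=s))
    P = sorted(P0_ids)
    if not P:
        raise ValueError("initial P must be non-empty")
    S = sorted(g for g in fm.values.index if g not in set(P))
    sets = PatternSets(P=P, N=[], S=S)
    if max_iter == 0:
        return sets
    n = n if n is not None else max(1, len(S) // 10)
    m = m if m is not None else max(1, len(S) // 10)
    if n == 0 and m == 0:
        raise ValueError("n and m both zero: no progress is possible")
    n_synthetic = n_synthetic if n_synthetic is not None else max(2 * len(P), 40)

    X = fm.values
    seed_P = set(P)
    rng_seed = np.random.default_rng(seed)

    for it in range(1, max_iter + 1):
        if not sets.S and not sets.N:
            break
        P_vec = X.loc[sets.P].to_numpy()
        use_synth = (it == 1) or not sets.N
        synth = (
            make_large_sigma_patterns(
                P_vec, n_synthetic, sigma_min,
                seed=int(rng_seed.integers(0, 2**31 - 1)),
            )
            if use_synth else np.empty((0, X.shape[1]))
        )
        N_vec = X.loc[sets.N].to_numpy() if sets.N else np.empty((0, X.shape[1]))
        train_X = np.vstack([P_vec, N_vec, synth])
        train_y = np.array([1] * len(sets.P) + [0] * (len(sets.N) + len(synth)))
        scorer = scorer_factory(seed + it).fit(train_X, train_y)

        train_scores = _check_scores(scorer.score_samples(train_X))
        # the Youden-optimal thresholds form a band: to be promoted a
        # pattern must score above the whole band ("stay above the
        # threshold"), to be demoted below it ("stay below")
        lower_threshold, threshold = _youden_band(train_scores, train_y)

        s_scores = _check_scores(scorer.score_samples(X.loc[sets.S].to_numpy())) \
            if sets.S else np.empty(0)
        score_map = dict(zip(sets.S, s_scores.tolist()))
        by_score_desc = sorted(sets.S, key=lambda g: (-score_map[g], g))
        to_P = [g for g in by_score_desc if score_map[g] >= threshold][:n]
        by_score_asc = sorted(sets.S, key=lambda g: (score_map[g], g))
        to_N = [g for g in by_score_asc
                if score_map[g] < lower_threshold and g not in set(to_P)][:m]

        # q, r: a trained network classifies its own training patterns
        # correctly almost by construction, so membership consistency
        # is judged against the algorithm's founding assumption
        # instead: only patterns many standard deviations from the
        # positive class can be asserted negative.  Distances are
        # compared to the positive cloud's own nearest-neighbor scale
        # rho, so the criteria track the data's dimensionality.
        # An N member is returned to S when it is as close to P as P
        # members are to each other, or when it is near P and isolated
        # among the negatives (a pattern backed by other nearby
        # negatives is negative on the data's evidence, not just its
        # own label).  A non-seed P member farther from every seed
        # pattern than the seed scale allows is returned to S.  Seeds
        # are ground truth and never move.
        q_back: list[str] = []
        r_back: list[str] = []
        grown = [g for g in sets.P if g not in seed_P]
        if len(sets.P) > 1:
            d_PP = cdist(P_vec, P_vec)
            np.fill_diagonal(d_PP, np.inf)
            rho = float(np.median(d_PP.min(axis=1)))
        else:
            rho = 0.0
        if sets.N:
            N_mat = X.loc[sets.N].to_numpy()
            d_NP = cdist(N_mat, P_vec).min(axis=1)
            if len(sets.N) > 1:
                d_NN = cdist(N_mat, N_mat)
                np.fill_diagonal(d_NN, np.inf)
                d_mate = d_NN.min(axis=1)
            else:
                d_mate = np.full(1, np.inf)
            q_back = [
                g for g, dp, dn in zip(sets.N, d_NP, d_mate)
                if dp <= 1.25 * rho
                or (dp < dn and dp < max(sigma_min, 1.25 * rho))
            ]
        if grown:
            seed_mat = X.loc[sorted(seed_P)].to_numpy()
            if len(seed_P) > 1:
                d_00 = cdist(seed_mat, seed_mat)
                np.fill_diagonal(d_00, np.inf)
                seed_scale = float(np.median(d_00.min(axis=1)))
            else:
                seed_scale = 0.0
            evict_at = max(sigma_min, 1.5 * seed_scale)
            d_P0 = cdist(X.loc[grown].to_numpy(), seed_mat).min(axis=1)
            r_back = [g for g, d in zip(grown, d_P0) if d >= evict_at]

        new_P = sorted((set(sets.P) - set(r_back)) | set(to_P))
        new_N = sorted((set(sets.N) - set(q_back)) | set(to_N))
        new_S = sorted((set(sets.S) - set(to_P) - set(to_N)) | set(r_back) | set(q_back))
        sets.P, sets.N, sets.S = new_P, new_N, new_S
        sets.check_disjoint()
        sets.history.append(IterationRecord(
            iteration=it,
            threshold=threshold,
            lower_threshold=lower_threshold,
            scores={g: round(v, 12) for g, v in score_map.items()},
            moved_to_P=to_P,
            moved_to_N=to_N,
            returned_to_S=sorted(set(r_back) | set(q_back)),
            synthetic_count=int(len(synth)),
            P=list(sets.P),
            N=list(sets.N),
            S=list(sets.S),
        ))
        if not to_P and not to_N and not r_back and not q_back:
            break  # fixed point
    return sets


def persistence_ranking(history: Sequence[IterationRecord]) -> pd.Series:
    """Iterations each pattern spent in N, descending (ties by id)."""
    if not history:
        raise ValueError("history is empty")
    counts: dict[str, int] = {}
    for rec in history:
        for g in rec.N:
            counts[g] = counts.get(g, 0) + 1
    series = pd.Series(counts, dtype=int)
    return series.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


def triangle_annotation(g: Multigraph) -> dict[str, object]:
    """Structural note: does the graph contain a triangle, and with what degrees?

    Patterns persisting in the negative set were observed to contain
    triangles with a high-degree corner; this report annotation
    surfaces that structure without making it a classification rule.
    """
    import networkx as nx

    support = g.simple_support()
    triangles = [c for c in nx.enumerate_all_cliques(support) if len(c) == 3]
    has_high_degree_corner = any(
        any(g.degree(v) >= 3 for v in tri) for tri in triangles
    )
    return {
        "has_triangle": bool(triangles),
        "triangle_with_degree_3_or_4": bool(has_high_degree_corner),
        "max_degree": max((g.degree(v) for v in g.vertices), default=0),
    }
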