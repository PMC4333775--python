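"""Gaussian Bayesian-network learning over node time series.

The directed network among nodes is learned in three stages:

1. *Candidate-parent screening.*  For every target node, the lasso
   regularization path of the target regressed on all other nodes is scanned
   over a descending penalty grid; each support on the path is refit by
   ordinary least squares and scored with a per-node Gaussian BIC.  The
   support at the BIC-optimal penalty becomes the target's candidate-parent
   set.  This prunes the search space the way sparse-regression DAG learners
   do, while the final score below — not the lasso — decides the structure.

2. *BIC hill-climbing.*  Greedy search over DAGs with add/delete/reverse
   moves restricted to the candidate skeleton, maximizing the decomposable
   Gaussian BIC; seeded random restarts guard against local optima.

3. *Maximum-likelihood weights.*  Given the structure, each node is
   regressed on its parents by least squares (no intercept, the data is
   standardized); residual variances use the ML denominator N.

The per-family score for node j with parent set P on N standardized samples:

    score_j = -(N/2) * (1 + log(2 pi sigma2_j)) - (d_j / 2) * log N

with ``sigma2_j`` the ML residual variance and ``d_j = |P| + 1`` (the
variance parameter counts).  The total BIC is the sum over families; higher
is better.

Group-level networks are learned on the row-concatenation of per-recording
standardized series; per-recording networks supply the 81 directed-edge
features (9 x 9 node pairs, diagonal fixed at zero) used for state
classification; cross-subject one-sample t-tests give per-edge significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .datatypes import DAGModel, CohortDataset, TimeSeriesMatrix

__all__ = [
    "StandardizedData",
    "BNLearnConfig",
    "EdgeStat",
    "FeatureTable",
    "standardize",
    "FamilyScorer",
    "lasso_parent_candidates",
    "gaussian_bic",
    "hill_climb_dag",
    "fit_weights_ml",
    "learn_bn",
    "group_bn",
    "subject_feature_table",
    "edge_group_stats",
]

Structure = dict[int, frozenset[int]]


@dataclass
class StandardizedData:
    """An N x K matrix with each column z-scored (population denominator)."""

    data: np.ndarray
    node_names: list[str]
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n, k = self.data.shape
        if n <= k:
            raise ValueError(f"need more samples than nodes (N={n}, K={k})")
        if len(self.node_names) != k:
            raise ValueError("node_names length does not match data columns")
        means = self.data.mean(axis=0)
        sds = self.data.std(axis=0)
        if np.any(np.abs(means) > 1e-8) or np.any(np.abs(sds - 1) > 1e-8):
            raise ValueError("columns are not standardized (mean 0, sd 1)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def standardize(
    ts: TimeSeriesMatrix | np.ndarray,
    node_names: list[str] | None = None,
    source: str | None = None,
) -> StandardizedData:
    """Z-score each column to mean 0, standard deviation 1 (denominator N).

    Raises
    ------
    ValueError
        If any column has zero variance (the offending node is named).
    """
    if isinstance(ts, TimeSeriesMatrix):
        data = ts.data
        node_names = ts.node_names
        source = source or f"{ts.subject_id}/{ts.condition}"
    else:
        data = np.asarray(ts, dtype=float)
        if node_names is None:
            node_names = [f"x{i}" for i in range(data.shape[1])]
        source = source or "array"
    sds = data.std(axis=0)
    dead = np.nonzero(sds == 0)[0]
    if dead.size:
        names = ", ".join(node_names[i] for i in dead)
        raise ValueError(f"zero-variance column(s), cannot standardize: {names}")
    z = (data - data.mean(axis=0)) / sds
    return StandardizedData(data=z, node_names=list(node_names), source=source)


class FamilyScorer:
    """Cached per-family Gaussian BIC scores over one dataset.

    Works from the Gram matrix, so a family with p parents costs O(p^3)
    independent of N.  Scores are cached by (node, parent set) — the hill
    climber revisits the same families constantly.
    """

    def __init__(self, data: StandardizedData):
        self.n = data.n_samples
        self.k = data.n_nodes
        self.gram = data.data.T @ data.data
        self._cache: dict[tuple[int, frozenset[int]], float] = {}
        self.subset_cache: dict = {}

    def residual_variance(self, node: int, parents: frozenset[int]) -> float:
        """ML residual variance of ``node`` regressed on ``parents`` (no
        intercept; the data is standardized)."""
        gy = self.gram[node, node]
        if not parents:
            return gy / self.n
        p = sorted(parents)
        gxx = self.gram[np.ix_(p, p)]
        gxy = self.gram[p, node]
        beta, _, rank, _ = np.linalg.lstsq(gxx, gxy, rcond=None)
        if rank < len(p):
            raise ValueError(
                f"singular parent design for node {node} with parents {p}"
            )
        return max(float(gy - gxy @ beta) / self.n, 0.0)

    def family_score(self, node: int, parents: frozenset[int]) -> float:
        """Per-family BIC; a numerically singular parent design scores -inf
        (such a family is unidentifiable and must never win a search)."""
        key = (node, parents)
        if key not in self._cache:
            try:
                sigma2 = max(self.residual_variance(node, parents), 1e-300)
            except ValueError:
                self._cache[key] = -np.inf
                return self._cache[key]
            d = len(parents) + 1
            self._cache[key] = (
                -(self.n / 2.0) * (1.0 + np.log(2.0 * np.pi * sigma2))
                - (d / 2.0) * np.log(self.n)
            )
        return self._cache[key]

    def total_score(self, structure: Structure) -> float:
        return sum(self.family_score(j, structure[j]) for j in range(self.k))


def _as_structure(structure, k: int) -> Structure:
    out: Structure = {}
    for j in range(k):
        parents = frozenset(int(i) for i in structure.get(j, ()))
        if j in parents:
            raise ValueError(f"node {j} cannot be its own parent")
        out[j] = parents
    return out


def _is_acyclic(structure: Structure) -> bool:
    color = {j: 0 for j in structure}  # 0 unvisited, 1 in stack, 2 done

    def visit(j: int) -> bool:
        color[j] = 1
        for p in structure[j]:  # walk parent-ward; direction is irrelevant
            if color[p] == 1 or (color[p] == 0 and not visit(p)):
                return False
        color[j] = 2
        return True

    return all(color[j] != 0 or visit(j) for j in structure)


def gaussian_bic(structure, data: StandardizedData) -> float:
    """Decomposable Gaussian BIC of a DAG structure on standardized data.

    ``structure`` maps node index -> iterable of parent indices.  Higher is
    better.  Raises on cyclic structures and singular parent designs.
    """
    struct = _as_structure(structure, data.n_nodes)
    if not _is_acyclic(struct):
        raise ValueError("structure contains a directed cycle")
    score = FamilyScorer(data).total_score(struct)
    if not np.isfinite(score):
        raise ValueError("singular parent design in structure")
    return score


def lasso_parent_candidates(
    data: StandardizedData,
    target: int | str,
    lambda_grid: np.ndarray | None = None,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
) -> frozenset[int]:
    """Candidate parents of one node via its lasso regularization path.

    The target column is regressed on all other columns with an L1 penalty
    along a strictly descending grid.  Each support on the path is refit by
    least squares and scored with the per-node Gaussian BIC; the support at
    the best-scoring penalty is returned.  The default grid runs from the
    critical penalty (smallest that zeroes every coefficient) down to
    ``lambda_min_ratio`` times it, log-spaced.
    """
    j = data.node_names.index(target) if isinstance(target, str) else int(target)
    others = [i for i in range(data.n_nodes) if i != j]
    x = data.data[:, others]
    y = data.data[:, j]
    n = data.n_samples
    if lambda_grid is None:
        lam_max = max(float(np.max(np.abs(x.T @ y))) / n, 1e-12)
        lambda_grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)
    else:
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        if lambda_grid.size == 0 or np.any(np.diff(lambda_grid) >= 0) or np.any(
            lambda_grid <= 0
        ):
            raise ValueError("lambda_grid must be nonempty, positive, strictly descending")
    _, coefs, _ = lasso_path(x, y, alphas=lambda_grid)
    scorer = FamilyScorer(data)
    best_support: frozenset[int] = frozenset()
    best_score = -np.inf
    for col in range(coefs.shape[1]):  # lasso_path returns the grid order
        support = frozenset(others[i] for i in np.nonzero(coefs[:, col])[0])
        score = scorer.family_score(j, support)
        if score > best_score + 1e-12:
            best_score, best_support = score, support
    return best_support


def _best_parent_subset(
    scorer: FamilyScorer, j: int, allowed: list[int], max_exhaustive: int = 12
) -> tuple[frozenset[int], float]:
    """Highest-scoring parent subset of ``allowed`` for node ``j``.

    Exhaustive over 2^|allowed| subsets while that is small (it always is
    after lasso screening); greedy forward selection beyond
    ``max_exhaustive`` candidates.
    """
    key = (j, tuple(allowed))
    cached = scorer.subset_cache.get(key)
    if cached is not None:
        return cached
    best: frozenset[int] = frozenset()
    best_s = scorer.family_score(j, best)
    if len(allowed) <= max_exhaustive:
        import itertools

        for r in range(1, len(allowed) + 1):
            for sub in itertools.combinations(allowed, r):
                s = scorer.family_score(j, frozenset(sub))
                if s > best_s:
                    best, best_s = frozenset(sub), s
    else:
        current: frozenset[int] = frozenset()
        improved = True
        while improved:
            improved = False
            for i in allowed:
                if i in current:
                    continue
                s = scorer.family_score(j, current | {i})
                if s > best_s:
                    best, best_s = current | {i}, s
                    improved = True
            current = best
    scorer.subset_cache[key] = (best, best_s)
    return best, best_s


def _order_optimal(
    scorer: FamilyScorer, sym: dict[int, frozenset[int]], order: list[int]
) -> tuple[Structure, float]:
    """Best structure whose edges respect ``order``, parents within the
    symmetrized candidate sets: per-node best predecessor subset."""
    pos = {n: i for i, n in enumerate(order)}
    struct: Structure = {}
    total = 0.0
    for j in sym:
        allowed = sorted(i for i in sym[j] if pos[i] < pos[j])
        struct[j], s = _best_parent_subset(scorer, j, allowed)
        total += s
    return struct, total


def _order_search_start(
    scorer: FamilyScorer,
    sym: dict[int, frozenset[int]],
    k: int,
    rng: np.random.Generator,
) -> Structure:
    """A strong random start: draw a random node order, locally optimize it
    with single-node insertion moves (each order scored by its per-node best
    candidate-parent subsets), and return the order-optimal structure — a
    random acyclic subgraph of the candidate skeleton."""
    order = list(rng.permutation(k))
    _, cur = _order_optimal(scorer, sym, order)
    while True:
        best_delta, best_order = 1e-9, None
        for p in range(k):
            for q in range(k):
                if q == p:
                    continue
                cand = order.copy()
                cand.insert(q, cand.pop(p))
                _, s = _order_optimal(scorer, sym, cand)
                if s - cur > best_delta:
                    best_delta, best_order = s - cur, cand
        if best_order is None:
            return _order_optimal(scorer, sym, order)[0]
        order, cur = best_order, cur + best_delta


def _creates_cycle(structure: Structure, src: int, tgt: int) -> bool:
    """Would adding src->tgt close a directed cycle (path tgt ~> src)?"""
    children: dict[int, list[int]] = {j: [] for j in structure}
    for j, parents in structure.items():
        for p in parents:
            children[p].append(j)
    stack, seen = [tgt], {tgt}
    while stack:
        u = stack.pop()
        if u == src:
            return True
        for v in children[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _climb(
    scorer: FamilyScorer,
    start: Structure,
    skeleton: list[tuple[int, int]],
    tol: float = 1e-9,
) -> tuple[Structure, float]:
    """Greedy best-first ascent from ``start`` over add/delete/reverse moves.

    Moves are enumerated in a fixed (kind, source, target) order and the
    single best strictly-improving move is applied per step, so ties resolve
    to the lexicographically first move.
    """
    struct = dict(start)
    score = scorer.total_score(struct)
    while True:
        best_delta, best_apply = tol, None
        for src, tgt in skeleton:
            fam_t = scorer.family_score(tgt, struct[tgt])
            if src not in struct[tgt]:
                if not _creates_cycle(struct, src, tgt):
                    delta = scorer.family_score(tgt, struct[tgt] | {src}) - fam_t
                    if delta > best_delta:
                        best_delta = delta
                        best_apply = ("add", src, tgt)
            else:
                delta = scorer.family_score(tgt, struct[tgt] - {src}) - fam_t
                if delta > best_delta:
                    best_delta = delta
                    best_apply = ("delete", src, tgt)
                # reverse src->tgt: legal unless another tgt ~> src path exists
                removed = dict(struct)
                removed[tgt] = struct[tgt] - {src}
                if not _creates_cycle(removed, tgt, src):
                    delta = (
                        scorer.family_score(tgt, removed[tgt])
                        - fam_t
                        + scorer.family_score(src, struct[src] | {tgt})
                        - scorer.family_score(src, struct[src])
                    )
                    if delta > best_delta:
                        best_delta = delta
                        best_apply = ("reverse", src, tgt)
        if best_apply is None:
            return struct, score
        kind, src, tgt = best_apply
        if kind == "add":
            struct[tgt] = struct[tgt] | {src}
        elif kind == "delete":
            struct[tgt] = struct[tgt] - {src}
        else:
            struct[tgt] = struct[tgt] - {src}
            struct[src] = struct[src] | {tgt}
        score += best_delta


def hill_climb_dag(
    data: StandardizedData,
    candidates: dict[int, frozenset[int]] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> Structure:
    """BIC-maximizing DAG search restricted to a candidate skeleton.

    Greedy best-first ascent over add/delete/reverse moves, starting from
    the empty graph.  After each local optimum, the search restarts from a
    seeded random acyclic subgraph of the candidate skeleton — drawn by
    optimizing a random node order with insertion moves and taking the
    per-node best candidate-parent subsets consistent with it, which lands
    restarts in far better basins than uniform subgraphs would — and the
    best-scoring structure over all climbs is returned.  An edge i->j is
    searchable when ``i`` is a candidate parent of ``j`` or ``j`` one of
    ``i`` (the skeleton is symmetrized so reversals stay inside the move
    set).  Deterministic given ``seed``.
    """
    k = data.n_nodes
    if candidates is None:
        candidates = {j: frozenset(i for i in range(k) if i != j) for j in range(k)}
    candidates = _as_structure(candidates, k)
    skeleton = sorted(
        (i, j)
        for i in range(k)
        for j in range(k)
        if i != j and (i in candidates[j] or j in candidates[i])
    )
    sym = {
        j: frozenset(i for i, t in skeleton if t == j) for j in range(k)
    }
    scorer = FamilyScorer(data)
    empty: Structure = {j: frozenset() for j in range(k)}
    best_struct, best_score = _climb(scorer, empty, skeleton)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        start = _order_search_start(scorer, sym, k, rng)
        struct, score = _climb(scorer, start, skeleton)
        if score > best_score + 1e-9:
            best_struct, best_score = struct, score
    return best_struct


def fit_weights_ml(structure, data: StandardizedData) -> DAGModel:
    """Maximum-likelihood edge weights and noise scales for a fixed structure.

    Each node is regressed on its parents by least squares without intercept;
    non-edges get weight zero; ``noise_sd`` is the square root of the ML
    (denominator N) residual variance, floored at the smallest positive float
    so that exactly-deterministic families remain representable.
    """
    struct = _as_structure(structure, data.n_nodes)
    if not _is_acyclic(struct):
        raise ValueError("structure contains a directed cycle")
    k = data.n_nodes
    n = data.n_samples
    weights = np.zeros((k, k))
    noise_sd = np.empty(k)
    x = data.data
    for j in range(k):
        parents = sorted(struct[j])
        if parents:
            xp = x[:, parents]
            if np.linalg.matrix_rank(xp) < len(parents):
                raise ValueError(
                    f"rank-deficient parent design for node {data.node_names[j]}"
                )
            beta, *_ = np.linalg.lstsq(xp, x[:, j], rcond=None)
            weights[parents, j] = beta
            resid = x[:, j] - xp @ beta
        else:
            resid = x[:, j]
        noise_sd[j] = max(np.sqrt((resid**2).sum() / n), np.finfo(float).tiny)
    return DAGModel(node_names=list(data.node_names), weights=weights, noise_sd=noise_sd)


@dataclass
class BNLearnConfig:
    """Tunables of the structure learner.

    ``n_lambdas`` and ``lambda_min_ratio`` shape the per-node lasso grid
    (50 log-spaced penalties down to 1% of the critical penalty);
    ``n_restarts`` seeded random restarts follow the empty-graph climb.
    """

    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    n_restarts: int = 10
    seed: int = 0
    alpha: float = 0.05


def learn_bn(data: StandardizedData, config: BNLearnConfig | None = None) -> DAGModel:
    """Full structure-and-weights learning on one standardized dataset.

    Candidate parents per node (lasso path + per-node BIC) -> restricted
    hill-climb -> ML weight fit; the final BIC is recorded on the model.
    """
    if config is None:
        config = BNLearnConfig()
    candidates = {
        j: lasso_parent_candidates(
            data, j, n_lambdas=config.n_lambdas, lambda_min_ratio=config.lambda_min_ratio
        )
        for j in range(data.n_nodes)
    }
    structure = hill_climb_dag(
        data, candidates, n_restarts=config.n_restarts, seed=config.seed
    )
    model = fit_weights_ml(structure, data)
    model.bic = gaussian_bic(structure, data)
    return model


def group_bn(
    cohort: CohortDataset, condition: str, config: BNLearnConfig | None = None
) -> DAGModel:
    """Group-level network for one condition.

    Each recording is standardized individually (removing between-subject
    scale differences), the rows are concatenated across subjects, and a
    single network is learned on the pooled samples.
    """
    recs = cohort.by_condition(condition)
    blocks = [standardize(r).data for r in recs]
    pooled = StandardizedData(
        data=np.vstack(blocks),
        node_names=list(cohort.node_names),
        source=f"group-concatenated/{condition}",
    )
    return learn_bn(pooled, config)


@dataclass
class FeatureTable:
    """Per-recording directed-edge weights as a samples x K^2 feature matrix.

    Column ``9*i + j`` holds the weight of edge ``node i -> node j`` (row-major
    over the full K x K grid, diagonal included and identically zero).
    """

    matrix: np.ndarray
    node_names: list[str]
    labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.node_names)
        if self.matrix.shape[1] != k * k:
            raise ValueError(f"expected {k * k} feature columns")
        if not (len(self.labels) == len(self.subject_ids) == self.matrix.shape[0]):
            raise ValueError("labels/subject_ids must match the number of rows")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def column_pairs(self) -> list[tuple[str, str]]:
        """(source, target) node pair of every feature column, in order."""
        return [(s, t) for s in self.node_names for t in self.node_names]

    def column_names(self) -> list[str]:
        return [f"{s}->{t}" for s, t in self.column_pairs()]

    def column_index(self, source: str, target: str) -> int:
        k = len(self.node_names)
        return k * self.node_names.index(source) + self.node_names.index(target)

    def rows_for(self, condition: str) -> np.ndarray:
        return np.asarray([lab == condition for lab in self.labels])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.column_names())
        df.insert(0, "condition", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def subject_feature_table(
    cohort: CohortDataset, config: BNLearnConfig | None = None
) -> FeatureTable:
    """Learn one network per recording and flatten its weights into features.

    Every recording (subject x condition) yields a full K x K weight matrix
    from its own standardized series; absent edges contribute zeros, so all
    rows share the same K^2-column layout.
    """
    rows = []
    labels = []
    subject_ids = []
    for rec in cohort.recordings:
        model = learn_bn(standardize(rec), config)
        rows.append(model.weights.reshape(-1))
        labels.append(rec.condition)
        subject_ids.append(rec.subject_id)
    return FeatureTable(
        matrix=np.vstack(rows),
        node_names=list(cohort.node_names),
        labels=labels,
        subject_ids=subject_ids,
    )


@dataclass(frozen=True)
class EdgeStat:
    """Cross-subject significance of one directed edge's weights."""

    source: str
    target: str
    mean_weight: float
    t_stat: float
    p_value: float
    significant: bool


def edge_group_stats(
    features: FeatureTable, condition: str, alpha: float = 0.05
) -> list[EdgeStat]:
    """One-sample t-tests of each directed edge's weight against zero.

    Tests are two-sided over the condition's rows, uncorrected; an edge is
    significant when ``p < alpha``.  A column with zero variance has no
    defined t statistic: an identically-zero column reports ``p = 1`` (no
    edge anywhere), a nonzero constant column reports ``p = 0``.
    """
    mask = features.rows_for(condition)
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 recordings in condition {condition!r} for the t-test"
        )
    sub = features.matrix[mask]
    out = []
    for col, (src, tgt) in enumerate(features.column_pairs()):
        if src == tgt:
            continue
        vals = sub[:, col]
        mean = float(vals.mean())
        if vals.std() == 0:
            t_stat, p = (0.0, 1.0) if mean == 0 else (np.inf, 0.0)
        else:
            t_stat, p = stats.ttest_1samp(vals, 0.0)
        out.append(
            EdgeStat(
                source=src,
                target=tgt,
                mean_weight=mean,
                t_stat=float(t_stat),
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    return out
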