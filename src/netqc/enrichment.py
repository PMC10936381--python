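"""Neighborhood enrichment z-scores under two permutation nulls.

The enrichment score for an ordered pair of cell types (A focal, B query) is

    z = (observed - mu) / sigma

where *observed* is the average number of B cells within radius d of each A
cell, and mu, sigma are the mean and standard deviation of that same average
over R randomizations of B.

Two nulls are provided:

* **conditional** — the tissue-structure-compensating null: the A cells stay
  at their original positions and, in every replicate, n_B positions are drawn
  uniformly without replacement from the fixed set of *all non-A* cell
  positions (the original B positions belong to that pool). Because the
  candidate positions are real cell positions, the null inherits the tissue's
  own architecture, so regional density structure alone does not register as
  attraction or repulsion. The resulting matrix is directional: z[A][B] and
  z[B][A] answer different questions and need not agree.

* **full_shuffle** — the baseline used by common spatial-omics tools: every
  replicate permutes *all* class labels over *all* cell positions at once, and
  the same permutation serves every ordered pair of that replicate. Since the
  close-pair count between two types is symmetric and the 1/n_A scaling
  cancels in the z-score, this null yields an exactly symmetric matrix — it
  cannot express directional structure.

A positive score means attraction, a negative score repulsion, and a score
near zero mutual randomness. With R replicates sigma uses the sample (R - 1)
divisor by default. A degenerate null (sigma = 0) leaves the score undefined
(NaN with a recorded reason), never +/-infinity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_tables import CellTable, EnrichmentMatrix
from .neighborhood import NeighborhoodConfig, mean_neighbor_count, neighbor_counts

DEFAULT_PERMUTATIONS = 1000


@dataclass(frozen=True)
class NullSummary:
    """Replicate statistics of one permutation null."""

    replicate_values: np.ndarray
    mu: float
    sigma: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.replicate_values, dtype=float)
        object.__setattr__(self, "replicate_values", vals)
        if len(vals) != self.n_permutations:
            raise ValidationError("replicate_values length must equal n_permutations")


@dataclass(frozen=True)
class NetResult:
    """Score plus its ingredients for one ordered pair (NaN score = undefined)."""

    score: float
    observed: float
    null: NullSummary
    reason: str | None = None


def _pair_rng(seed: int, focal: str, query: str) -> np.random.Generator:
    """Deterministic sub-stream for one ordered class pair of a matrix run.

    Keyed by the class *names* (hashed), not their matrix indices, so a pair's
    results survive row reordering of the input table and the addition or
    removal of unrelated classes.
    """
    digest = hashlib.sha256(f"{focal}\x1f{query}".encode()).digest()
    key = tuple(int.from_bytes(digest[k : k + 4], "little") for k in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _canonical_order(xy: np.ndarray) -> np.ndarray:
    """Row-order-independent ordering of positions (lexicographic by x, then y)."""
    return np.lexsort((xy[:, 1], xy[:, 0]))


def _summarize(values: np.ndarray, n_permutations: int, seed: int, sigma_ddof: int) -> NullSummary:
    # identical replicates mean an exactly degenerate null; don't let summation
    # round-off masquerade as a tiny positive sigma
    sigma = 0.0 if np.all(values == values[0]) else float(np.std(values, ddof=sigma_ddof))
    return NullSummary(
        replicate_values=values,
        mu=float(np.mean(values)),
        sigma=sigma,
        n_permutations=n_permutations,
        seed=seed,
    )


def net_score_pair(
    cells: CellTable,
    focal: str,
    query: str,
    cfg: NeighborhoodConfig,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    sigma_ddof: int = 1,
    rng: np.random.Generator | None = None,
) -> NetResult:
    """Conditional-null enrichment score for one ordered pair (focal, query).

    The focal cells are fixed; each replicate relocates the query type onto a
    uniformly drawn subset of the non-focal cell positions.
    """
    if focal == query:
        raise ValidationError("focal and query type must differ under the conditional null")
    for label in (focal, query):
        if label not in cells.class_set:
            raise ValidationError(f"unknown class label: {label!r}")
    if n_permutations < 2:
        raise ValidationError("at least 2 permutations are required to estimate sigma")

    pos_a = cells.positions_of(focal)
    n_b = cells.n_of(query)
    pool = cells.xy[cells.labels != focal]
    pool = pool[_canonical_order(pool)]  # draws must not depend on record order
    if len(pool) < n_b:
        raise ValidationError(
            f"non-{focal} position pool ({len(pool)}) is smaller than n_{query} ({n_b})"
        )

    observed = mean_neighbor_count(cells, focal, query, cfg)

    # Per pool position: number of focal cells within d. A replicate's mean
    # neighbor count is then sum(counts over the drawn subset) / n_A, exactly
    # the double-loop statistic, so replicates cost O(n_B) each.
    counts = neighbor_counts(pool, pos_a, cfg)
    gen = rng if rng is not None else np.random.default_rng(seed)
    n_a = len(pos_a)
    values = np.empty(n_permutations, dtype=float)
    for r in range(n_permutations):
        idx = gen.choice(len(pool), size=n_b, replace=False)
        values[r] = counts[idx].sum() / n_a

    null = _summarize(values, n_permutations, seed, sigma_ddof)
    if null.sigma == 0.0:
        return NetResult(np.nan, observed, null, reason="degenerate null: sigma = 0")
    return NetResult((observed - null.mu) / null.sigma, observed, null)


def net_score_matrix(
    cells: CellTable,
    cfg: NeighborhoodConfig,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    diagonal_policy: str = "undefined",
    sigma_ddof: int = 1,
) -> EnrichmentMatrix:
    """Conditional-null enrichment matrix over all ordered class pairs.

    Each ordered pair gets its own deterministic sub-seed derived from
    (seed, row index, column index), so results per pair are reproducible in
    isolation. Per-pair degeneracies become NaN entries with a reason in
    ``notes`` rather than aborting the whole matrix. ``diagonal_policy`` is
    ``"undefined"`` (default: the conditional randomization is not defined for
    A = A) or ``"full_shuffle"`` (fill the diagonal from a full-shuffle run,
    flagged in the notes).
    """
    names = cells.class_set
    k = len(names)
    if k < 2:
        raise ValidationError("an enrichment matrix needs at least 2 classes")
    if diagonal_policy not in ("undefined", "full_shuffle"):
        raise ValidationError(f"unknown diagonal policy: {diagonal_policy!r}")

    scores = np.full((k, k), np.nan)
    observed = np.full((k, k), np.nan)
    null_mean = np.full((k, k), np.nan)
    null_std = np.full((k, k), np.nan)
    notes: dict = {}
    for i, focal in enumerate(names):
        for j, query in enumerate(names):
            if i == j:
                continue
            try:
                res = net_score_pair(
                    cells, focal, query, cfg, n_permutations,
                    seed=seed, sigma_ddof=sigma_ddof, rng=_pair_rng(seed, focal, query),
                )
            except ValidationError as exc:
                notes[(focal, query)] = str(exc)
                continue
            scores[i, j] = res.score
            observed[i, j] = res.observed
            null_mean[i, j] = res.null.mu
            null_std[i, j] = res.null.sigma
            if res.reason:
                notes[(focal, query)] = res.reason

    if diagonal_policy == "full_shuffle":
        fs = full_shuffle_score_matrix(
            cells, cfg, n_permutations, seed=seed, diagonal_policy="include",
            sigma_ddof=sigma_ddof,
        )
        for i in range(k):
            scores[i, i] = fs.scores[i, i]
            observed[i, i] = fs.observed[i, i]
            null_mean[i, i] = fs.null_mean[i, i]
            null_std[i, i] = fs.null_std[i, i]
            notes[(names[i], names[i])] = "diagonal computed under the full-shuffle null"

    return EnrichmentMatrix(
        class_names=names, scores=scores, radius=cfg.radius,
        n_permutations=n_permutations, seed=seed, method="conditional",
        observed=observed, null_mean=null_mean, null_std=null_std, notes=notes,
    )


def _ordered_pair_counts(pairs: np.ndarray, labels_int: np.ndarray, k: int, n: int) -> np.ndarray:
    """K x K ordered close-pair counts from an i<j unordered pair list."""
    counts = np.zeros(k * k, dtype=np.int64)
    if len(pairs):
        li = labels_int[pairs[:, 0]]
        lj = labels_int[pairs[:, 1]]
        np.add.at(counts, li * k + lj, 1)
        np.add.at(counts, lj * k + li, 1)
    return counts.reshape(k, k)


def full_shuffle_score_matrix(
    cells: CellTable,
    cfg: NeighborhoodConfig,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    diagonal_policy: str = "undefined",
    sigma_ddof: int = 1,
) -> EnrichmentMatrix:
    """Full-shuffle (label permutation) enrichment matrix.

    Every replicate applies one uniform permutation of all class labels over
    all positions and reuses it for every ordered pair; positions never move,
    so the close-pair geometry is computed once.
    """
    from scipy.spatial import cKDTree

    names = cells.class_set
    k = len(names)
    if k < 2:
        raise ValidationError("an enrichment matrix needs at least 2 classes")
    if diagonal_policy not in ("undefined", "include"):
        raise ValidationError(f"unknown diagonal policy: {diagonal_policy!r}")
    if n_permutations < 2:
        raise ValidationError("at least 2 permutations are required to estimate sigma")

    n = len(cells)
    # internal codes in sorted-name order over canonically ordered positions,
    # so the permutation stream is independent of record and class order
    sorted_names = sorted(names)
    code_of = {name: idx for idx, name in enumerate(sorted_names)}
    order = _canonical_order(cells.xy)
    xy = cells.xy[order]
    labels_int = np.asarray([code_of[l] for l in cells.labels[order]], dtype=np.int64)
    n_per = np.bincount(labels_int, minlength=k).astype(float)

    tree = cKDTree(xy)
    pairs = tree.query_pairs(cfg.radius, output_type="ndarray")

    obs_counts = _ordered_pair_counts(pairs, labels_int, k, n)
    observed = obs_counts / n_per[:, None]

    gen = np.random.default_rng(seed)
    reps = np.empty((n_permutations, k, k), dtype=float)
    for r in range(n_permutations):
        perm = gen.permutation(labels_int)
        reps[r] = _ordered_pair_counts(pairs, perm, k, n) / n_per[:, None]

    null_mean = reps.mean(axis=0)
    null_std = reps.std(axis=0, ddof=sigma_ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(null_std > 0, (observed - null_mean) / null_std, np.nan)

    # back to first-appearance class order for presentation
    perm = np.asarray([sorted_names.index(name) for name in names])
    observed = observed[np.ix_(perm, perm)]
    null_mean = null_mean[np.ix_(perm, perm)]
    null_std = null_std[np.ix_(perm, perm)]
    scores = scores[np.ix_(perm, perm)]

    notes: dict = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if null_std[i, j] == 0:
                notes[(a, b)] = "degenerate null: sigma = 0"
    if diagonal_policy == "undefined":
        np.fill_diagonal(scores, np.nan)

    return EnrichmentMatrix(
        class_names=names, scores=scores, radius=cfg.radius,
        n_permutations=n_permutations, seed=seed, method="full_shuffle",
        observed=observed, null_mean=null_mean, null_std=null_std, notes=notes,
    )
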