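"""Reference quality scores and ranking-evaluation metrics.

GDT-TS is estimated with an LGA-like heuristic: rigid superpositions are
seeded from every sliding window of lengths 3/5/7 along the shared
residues, then iteratively refined by re-superposing on the residues that
currently fit under each distance threshold (1/2/4/8 Å). The score is the
mean over thresholds of the largest fitting fraction found; the
denominator is the full target length, so missing residues in partial
models count as failures. lDDT is the Cα variant: preserved inter-residue
distances within a 15 Å inclusion radius at thresholds 0.5/1/2/4 Å.

Evaluation follows the CASP EMA convention: per-target ranking loss (true
quality of the best pool model minus true quality of the model ranked
first by the predictor) and per-target Pearson correlation, averaged
overall and per difficulty category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .structio import DataError, ProteinModel

logger = logging.getLogger(__name__)

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_INCLUSION_RADIUS = 15.0
GDT_SEED_WINDOWS = (3, 5, 7)
GDT_MAX_ITER = 10
CONSENSUS_MAX_REFS = 30
CONSENSUS_SEED = 1729

CATEGORIES = ("TBM-easy", "TBM-hard", "FM/TBM", "FM")


@dataclass
class RankingEvaluation:
    """Per-target ranking loss / correlation with category breakdowns."""

    per_target: pd.DataFrame  # columns: target_id, category, loss, pearson
    overall_loss: float
    overall_pearson: float
    category_loss: dict[str, float]
    category_pearson: dict[str, float]


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition of A onto B.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``coords_a @ rotation.T + translation ≈ coords_b``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise DataError("coordinate sets must both be (n, 3)")
    if len(A) < 3:
        raise DataError("at least 3 point pairs are required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A @ R.T + t - B
    rmsd = float(np.sqrt((diff * diff).sum() / len(A)))
    return R, t, rmsd


def _batched_superpose(A: np.ndarray, B: np.ndarray, w: np.ndarray):
    """Weighted Kabsch for a stack of selections.

    ``A``/``B`` are (n, 3) coordinate sets shared across the stack; ``w`` is
    (m, n) of {0,1} selection weights with row sums >= 3. Returns rotations
    (m, 3, 3) and translations (m, 3) mapping A onto B.
    """
    wsum = w.sum(axis=1, keepdims=True)  # (m, 1)
    ca = (w[:, :, None] * A[None]).sum(axis=1) / wsum  # (m, 3)
    cb = (w[:, :, None] * B[None]).sum(axis=1) / wsum
    Ac = A[None] - ca[:, None, :]
    Bc = B[None] - cb[:, None, :]
    H = np.einsum("mn,mni,mnj->mij", w, Ac, Bc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("mij,mkj->mik", Vt.transpose(0, 2, 1), U)))
    D = np.zeros((len(w), 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("mji,mjk,mlk->mil", Vt, D, U)
    t = cb - np.einsum("mij,mj->mi", R, ca)
    return R, t


def _common_coords(model: ProteinModel, native: ProteinModel):
    common = model.present_mask & native.present_mask
    idx = np.nonzero(common)[0] + 1
    mpos = np.searchsorted(model.residue_ids, idx)
    npos = np.searchsorted(native.residue_ids, idx)
    return model.ca_coords[mpos], native.ca_coords[npos]


def gdt_ts(model: ProteinModel, native: ProteinModel) -> float:
    """Heuristic GDT-TS of a model against a reference structure, in [0, 1]."""
    if model.target_id != native.target_id:
        raise DataError("model and native belong to different targets")
    A, B = _common_coords(model, native)
    n = len(A)
    if n < 3:
        raise DataError("fewer than 3 residues shared with the reference")
    L = native.length

    # seed selections: sliding windows over the shared residues; for very
    # short chains every residue triple is cheap and seeds the refinement
    # much closer to the optimal (possibly non-contiguous) subset
    seeds = []
    for wlen in GDT_SEED_WINDOWS:
        if n < wlen:
            continue
        for start in range(n - wlen + 1):
            sel = np.zeros(n)
            sel[start:start + wlen] = 1.0
            seeds.append(sel)
    if n <= 12:
        from itertools import combinations

        small_sizes = (3, 4) if n <= 9 else (3,)
        for size in small_sizes:
            for subset in combinations(range(n), size):
                sel = np.zeros(n)
                sel[list(subset)] = 1.0
                seeds.append(sel)
    if not seeds:
        seeds = [np.ones(n)]
    seeds = np.array(seeds)

    thresholds = np.asarray(GDT_THRESHOLDS)
    # one stacked problem per (seed, threshold)
    w = np.tile(seeds, (len(thresholds), 1))
    thr = np.repeat(thresholds, len(seeds))[:, None]
    best = np.zeros(len(thresholds))
    active = np.ones(len(w), dtype=bool)
    for _ in range(GDT_MAX_ITER):
        if not active.any():
            break
        R, t = _batched_superpose(A, B, w[active])
        moved = np.einsum("mij,nj->mni", R, A) + t[:, None, :]
        dist = np.linalg.norm(moved - B[None], axis=2)  # (m_active, n)
        fit = (dist <= thr[active]).astype(float)
        counts = fit.sum(axis=1)
        # track the best fitting set per threshold
        tidx = np.repeat(np.arange(len(thresholds)), len(seeds))[active]
        np.maximum.at(best, tidx, counts)
        same = (fit == w[active]).all(axis=1)
        degenerate = counts < 3
        still = ~(same | degenerate)
        w[active] = np.where(degenerate[:, None], w[active], fit)
        nxt = active.copy()
        nxt[active] = still
        active = nxt
    return float(best.sum() / (len(thresholds) * L))


def gdt_ts_exhaustive(model: ProteinModel, native: ProteinModel) -> float:
    """Exhaustive GDT-TS upper-bound oracle (tiny structures only).

    Superposes on every subset of >= 3 shared residues and keeps, per
    threshold, the largest count of residues fitting under it.
    """
    from itertools import combinations

    A, B = _common_coords(model, native)
    n = len(A)
    if n < 3:
        raise DataError("fewer than 3 residues shared with the reference")
    if n > 12:
        raise ValueError("exhaustive oracle is for n <= 12")
    best = np.zeros(len(GDT_THRESHOLDS))
    for k in range(3, n + 1):
        for subset in combinations(range(n), k):
            sel = list(subset)
            R, t, _ = kabsch_superpose(A[sel], B[sel])
            dist = np.linalg.norm(A @ R.T + t - B, axis=1)
            for ti, thr in enumerate(GDT_THRESHOLDS):
                best[ti] = max(best[ti], np.count_nonzero(dist <= thr))
    return float(best.sum() / (len(GDT_THRESHOLDS) * native.length))


def lddt(model: ProteinModel, native: ProteinModel) -> float:
    """Cα lDDT of a model against a reference structure, in [0, 1].

    Reference pairs are native Cα pairs closer than 15 Å with |i-j| >= 1;
    pairs involving a residue missing from the model count as unpreserved.
    """
    if model.target_id != native.target_id:
        raise DataError("model and native belong to different targets")
    nat_d = squareform(pdist(native.ca_coords))
    iu, ju = np.triu_indices(native.n_present, k=1)
    ref = nat_d[iu, ju] < LDDT_INCLUSION_RADIUS
    iu, ju = iu[ref], ju[ref]
    if len(iu) == 0:
        raise DataError("no reference pairs within the inclusion radius")
    nat_pairs = nat_d[iu, ju]

    # map native residue ids to model rows where present
    rid_i = native.residue_ids[iu]
    rid_j = native.residue_ids[ju]
    present = model.present_mask
    both = present[rid_i - 1] & present[rid_j - 1]
    mi = np.searchsorted(model.residue_ids, rid_i[both])
    mj = np.searchsorted(model.residue_ids, rid_j[both])
    mod_pairs = np.linalg.norm(model.ca_coords[mi] - model.ca_coords[mj], axis=1)
    diff = np.abs(mod_pairs - nat_pairs[both])

    fractions = []
    for thr in LDDT_THRESHOLDS:
        preserved = np.count_nonzero(diff < thr)
        fractions.append(preserved / len(iu))
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# consensus and score bookkeeping


def pairwise_consensus(pool: list[ProteinModel], max_refs: int = CONSENSUS_MAX_REFS,
                       seed: int = CONSENSUS_SEED) -> np.ndarray:
    """Pairwise-GDT consensus score per model.

    A model's score is the mean symmetrised GDT-TS against the other models
    of the pool (both directions averaged). For pools larger than
    ``max_refs`` a fixed-seed random reference subset keeps the cost
    quadratic in ``max_refs`` rather than the pool size.
    """
    n = len(pool)
    if n < 2:
        raise DataError("consensus requires at least 2 models")
    if n > max_refs:
        rng = np.random.default_rng(seed)
        refs = np.sort(rng.choice(n, size=max_refs, replace=False))
    else:
        refs = np.arange(n)
    cache: dict[tuple[int, int], float] = {}

    def sym_gdt(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in cache:
            cache[key] = 0.5 * (gdt_ts(pool[a], pool[b]) + gdt_ts(pool[b], pool[a]))
        return cache[key]

    scores = np.empty(n)
    for m in range(n):
        others = [r for r in refs if r != m]
        if not others:  # model outside the reference subset pool
            others = [r for r in refs]
        scores[m] = np.mean([sym_gdt(m, r) for r in others])
    return scores


def normalize_partial(score: float, n_present: int, L: int) -> float:
    """Scale a predicted score by the fraction of residues actually modelled."""
    if L <= 0 or not (0 <= n_present <= L):
        raise DataError("need 0 <= n_present <= L and L > 0")
    return score * n_present / L


def domain_average(domain_scores) -> float:
    """Mean of per-domain scores = the full-length model's quality."""
    scores = list(domain_scores)
    if not scores:
        raise DataError("no domain scores to average")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# evaluation metrics


def _as_series(scores) -> pd.Series:
    s = pd.Series(dict(scores)) if isinstance(scores, dict) else pd.Series(scores)
    return s.astype(float)


def ranking_loss(true_scores, predicted_scores) -> float:
    """True quality of the best model minus that of the model ranked first.

    Ties in the predicted ranking break lexicographically on model id for
    reproducibility.
    """
    t = _as_series(true_scores)
    p = _as_series(predicted_scores)
    if len(t) == 0:
        raise DataError("empty score table")
    if set(t.index) != set(p.index):
        raise DataError("true and predicted model sets differ")
    p = p.reindex(sorted(p.index))  # lexicographic tie-break under stable idxmax
    chosen = p.idxmax()
    return float(abs(t.max() - t[chosen]))


def per_target_pearson(true_scores, predicted_scores) -> float:
    """Pearson correlation between true and predicted scores of one pool."""
    t = _as_series(true_scores)
    p = _as_series(predicted_scores)
    if len(t) < 3:
        raise DataError("per-target correlation requires at least 3 models")
    p = p.reindex(t.index)
    if t.std(ddof=0) == 0.0 or p.std(ddof=0) == 0.0:
        logger.warning("per_target_pearson: constant scores; returning 0")
        return 0.0
    return float(np.corrcoef(t.to_numpy(), p.to_numpy())[0, 1])


def evaluate_predictor(per_target_tables: dict[str, tuple], categories: dict[str, str]) -> RankingEvaluation:
    """Per-target and aggregate ranking evaluation.

    ``per_target_tables`` maps target_id to ``(true_scores, predicted_scores)``
    (model_id-keyed mappings); ``categories`` maps target_id to one of the
    four difficulty categories.
    """
    if not per_target_tables:
        raise DataError("no targets to evaluate")
    rows = []
    for target_id, (true_scores, predicted_scores) in per_target_tables.items():
        cat = categories[target_id]
        if cat not in CATEGORIES:
            raise DataError(
                f"unknown category {cat!r} for target {target_id}; "
                f"expected one of {', '.join(CATEGORIES)}"
            )
        rows.append({
            "target_id": target_id,
            "category": cat,
            "loss": ranking_loss(true_scores, predicted_scores),
            "pearson": per_target_pearson(true_scores, predicted_scores),
        })
    table = pd.DataFrame(rows)
    cat_loss = table.groupby("category")["loss"].mean().to_dict()
    cat_pearson = table.groupby("category")["pearson"].mean().to_dict()
    return RankingEvaluation(
        per_target=table,
        overall_loss=float(table["loss"].mean()),
        overall_pearson=float(table["pearson"].mean()),
        category_loss=cat_loss,
        category_pearson=cat_pearson,
    )
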