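"""Classification, clustering and disentanglement evaluation.

Covers macro-F1 and ARI for label recovery, and a disentanglement suite:
a Spearman correlation matrix between latent dimensions and generative
factors, the Mutual Information Gap (MIG), the Attribute Predictability
Score (SAP), the DCI triplet (disentanglement / completeness /
informativeness) and Hungarian matching of factor-owned latent blocks to
factors.

Estimator choices (documented, since the literature leaves them open):
mutual information uses 20 quantile bins per continuous dimension; the SAP
probe is a single-dimension threshold stump scored by balanced accuracy
(one-vs-rest averaged for multi-class factors); the DCI probe is a
100-tree random forest with a 50/50 train/held-out split and fixed seed;
Hungarian matching operates on factor-level block scores (max |rho| of the
one-vs-rest Spearman within each block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (adjusted_rand_score, balanced_accuracy_score,
                             f1_score, mutual_info_score)

from .data import LabelTable

__all__ = [
    "DisentanglementReport",
    "macro_f1",
    "ari",
    "SpearmanResult",
    "spearman_matrix",
    "mig",
    "sap",
    "dci",
    "dci_from_importance",
    "hungarian_alignment",
    "block_score_matrix",
    "evaluate_disentanglement",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Label-recovery metrics
# ---------------------------------------------------------------------------


def macro_f1(true, pred) -> float:
    """Unweighted mean per-category F1; categories absent from both sides excluded."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.size == 0:
        raise ValueError("empty input")
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    labels = sorted(set(true.tolist()) | set(pred.tolist()))
    return float(f1_score(true, pred, labels=labels, average="macro",
                          zero_division=0))


def ari(a, b) -> float:
    """Adjusted Rand index; 1 for identical partitions (incl. the
    degenerate single-cluster case, where chance correction is undefined)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0:
        raise ValueError("empty input")
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        return 1.0
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# Spearman correlation structure
# ---------------------------------------------------------------------------


@dataclass
class SpearmanResult:
    """Correlations of latent dims with factors.

    ``integer_coded``: rho against the raw 0..K-1 integer coding (order-
    dependent for multi-class factors, reported for comparability).
    ``one_vs_rest``: max |rho| over per-category one-vs-rest indicators —
    the recommended, order-free statistic.
    """

    integer_coded: np.ndarray  # (D, k), signed
    one_vs_rest: np.ndarray  # (D, k), absolute


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.info("constant input to Spearman; defining rho = 0")
        return 0.0
    rho = spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def spearman_matrix(latent: np.ndarray, factors: LabelTable) -> SpearmanResult:
    """Spearman rho between every latent dimension and every factor."""
    if not factors.fully_observed():
        raise ValueError("spearman_matrix requires fully observed labels")
    Z = np.asarray(latent, dtype=np.float64)
    labs = factors.labels
    D, k = Z.shape[1], labs.shape[1]
    integer = np.zeros((D, k))
    ovr = np.zeros((D, k))
    for j in range(k):
        col = labs[:, j]
        cats = np.unique(col)
        for d in range(D):
            integer[d, j] = _safe_spearman(Z[:, d], col.astype(np.float64))
            if len(cats) <= 2:
                ovr[d, j] = abs(integer[d, j])
            else:
                ovr[d, j] = max(
                    abs(_safe_spearman(Z[:, d], (col == c).astype(np.float64)))
                    for c in cats
                )
    return SpearmanResult(integer_coded=integer, one_vs_rest=ovr)


# ---------------------------------------------------------------------------
# Mutual information gap
# ---------------------------------------------------------------------------


def _quantile_discretize(z: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(z, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, z, side="right")


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mig(latent: np.ndarray, factors: LabelTable, n_bins: int = 20) -> float:
    """Mutual Information Gap, clamped to [0, 1].

    Each latent dimension is discretized into ``n_bins`` quantile bins;
    per factor the gap between the two most informative dimensions is
    normalized by the factor's entropy, then averaged over factors.
    """
    Z = np.asarray(latent, dtype=np.float64)
    if Z.shape[1] < 2:
        raise ValueError("MIG needs at least 2 latent dimensions")
    if not factors.fully_observed():
        raise ValueError("mig requires fully observed labels")
    disc = [_quantile_discretize(Z[:, d], n_bins) for d in range(Z.shape[1])]
    gaps = []
    for j in range(factors.k):
        v = factors.labels[:, j]
        hv = _entropy(v)
        if hv == 0.0:
            log.warning("factor %d has a single category; excluded from MIG", j)
            continue
        mis = sorted((mutual_info_score(zd, v) for zd in disc), reverse=True)
        gaps.append((mis[0] - mis[1]) / hv)
    if not gaps:
        raise ValueError("no multi-category factor available for MIG")
    return float(np.clip(np.mean(gaps), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Attribute predictability score
# ---------------------------------------------------------------------------


def _stump_balanced_accuracy(z: np.ndarray, y: np.ndarray) -> float:
    """Balanced accuracy of the best single-threshold rule on one dimension."""
    order = np.argsort(z, kind="mergesort")
    ys = y[order].astype(np.float64)
    zs = z[order]
    P = ys.sum()
    N = len(ys) - P
    if P == 0 or N == 0:
        return 0.5
    cum_pos = np.cumsum(ys)
    cum_neg = np.cumsum(1.0 - ys)
    # candidate cuts between distinct consecutive values; rule: positive if z > t
    valid = zs[:-1] < zs[1:]
    tpr = (P - cum_pos[:-1][valid]) / P
    tnr = cum_neg[:-1][valid] / N
    if tpr.size == 0:
        return 0.5
    bal = (tpr + tnr) / 2.0
    # both orientations; constant rules score exactly 0.5
    return float(max(bal.max(), (1.0 - bal).max(), 0.5))


def sap(latent: np.ndarray, factors: LabelTable) -> float:
    """Attribute Predictability Score in [0, 1].

    The probe score S[d, j] is the balanced accuracy of the best threshold
    stump predicting factor j from dimension d alone (one-vs-rest averaged
    for multi-class factors); SAP is the mean over factors of the gap
    between the two best dimensions.
    """
    Z = np.asarray(latent, dtype=np.float64)
    if Z.shape[1] < 2:
        raise ValueError("SAP needs at least 2 latent dimensions")
    if not factors.fully_observed():
        raise ValueError("sap requires fully observed labels")
    gaps = []
    for j in range(factors.k):
        v = factors.labels[:, j]
        cats = np.unique(v)
        col = np.empty(Z.shape[1])
        for d in range(Z.shape[1]):
            if len(cats) == 2:
                col[d] = _stump_balanced_accuracy(Z[:, d], (v == cats[1]).astype(float))
            else:
                col[d] = np.mean([
                    _stump_balanced_accuracy(Z[:, d], (v == c).astype(float))
                    for c in cats
                ])
        top = np.sort(col)[::-1]
        gaps.append(top[0] - top[1])
    return float(np.clip(np.mean(gaps), 0.0, 1.0))


# ---------------------------------------------------------------------------
# DCI
# ---------------------------------------------------------------------------


def _norm_entropy(p: np.ndarray, base_count: int) -> float:
    p = p / p.sum() if p.sum() > 0 else np.full_like(p, 1.0 / len(p))
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    if base_count <= 1:
        return 0.0
    return float(h / np.log(base_count))


def dci_from_importance(R: np.ndarray) -> tuple[float, float]:
    """Disentanglement and completeness from a (dims x factors) importance matrix."""
    R = np.asarray(R, dtype=np.float64)
    D, k = R.shape
    col_sums = R.sum(axis=0)
    Rn = R / np.where(col_sums > 0, col_sums, 1.0)
    # disentanglement: importance-weighted mean over dims of 1 - H_norm(row)
    row_sums = Rn.sum(axis=1)
    weights = row_sums / row_sums.sum() if row_sums.sum() > 0 else np.full(D, 1.0 / D)
    if k <= 1 or D == 1:
        dis = 1.0
    else:
        per_dim = np.array([1.0 - _norm_entropy(Rn[i], k) if row_sums[i] > 0 else 0.0
                            for i in range(D)])
        dis = float((weights * per_dim).sum())
    comp = float(np.mean([1.0 - _norm_entropy(Rn[:, j], D) for j in range(k)])) \
        if D > 1 else 1.0
    return dis, comp


def dci(latent: np.ndarray, factors: LabelTable, n_trees: int = 100,
        seed: int = 0) -> tuple[float, float, float]:
    """DCI triplet (informativeness, disentanglement, completeness).

    Per factor a random-forest classifier is fit on a 50/50 split; its
    feature importances form the importance matrix, and informativeness is
    the mean held-out balanced accuracy.
    """
    Z = np.asarray(latent, dtype=np.float64)
    if not factors.fully_observed():
        raise ValueError("dci requires fully observed labels")
    n, D = Z.shape
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    tr, te = perm[:half], perm[half:]
    R = np.zeros((D, factors.k))
    accs = []
    for j in range(factors.k):
        y = factors.labels[:, j]
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                     n_jobs=1)
        clf.fit(Z[tr], y[tr])
        R[:, j] = clf.feature_importances_
        accs.append(balanced_accuracy_score(y[te], clf.predict(Z[te])))
    dis, comp = dci_from_importance(R)
    return float(np.mean(accs)), dis, comp


# ---------------------------------------------------------------------------
# Hungarian block alignment
# ---------------------------------------------------------------------------


def hungarian_alignment(score: np.ndarray) -> float:
    """Mean matched score of the optimal one-to-one (block, factor) assignment."""
    S = np.asarray(score, dtype=np.float64)
    if S.ndim != 2:
        raise ValueError("score must be a 2-D matrix")
    if S.shape[1] > S.shape[0]:
        raise ValueError("more factors than latent blocks; assignment ill-posed")
    if S.min() < 0 or S.max() > 1:
        raise ValueError("score entries must lie in [0, 1]")
    rows, cols = linear_sum_assignment(-S)
    return float(S[rows, cols].mean())


def block_score_matrix(latent: np.ndarray, column_map: dict[str, tuple[int, int]],
                       factors: LabelTable, factor_names: list[str]) -> np.ndarray:
    """(blocks x factors) score matrix: max one-vs-rest |rho| inside each block."""
    sp = spearman_matrix(latent, factors)
    block_names = list(column_map.keys())
    S = np.zeros((len(block_names), len(factor_names)))
    for b, name in enumerate(block_names):
        lo, hi = column_map[name]
        S[b] = sp.one_vs_rest[lo:hi].max(axis=0)
    return np.clip(S, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------


@dataclass
class DisentanglementReport:
    """Everything the evaluation suite computes for one latent + truth pair."""

    spearman: np.ndarray
    spearman_one_vs_rest: np.ndarray
    mig: float
    sap: float
    hungarian: float
    dci_informativeness: float
    dci_disentanglement: float
    dci_completeness: float
    per_factor_f1: dict[str, float] = field(default_factory=dict)
    ari: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "spearman": self.spearman.tolist(),
            "spearman_one_vs_rest": self.spearman_one_vs_rest.tolist(),
            "mig": self.mig,
            "sap": self.sap,
            "hungarian": self.hungarian,
            "dci_informativeness": self.dci_informativeness,
            "dci_disentanglement": self.dci_disentanglement,
            "dci_completeness": self.dci_completeness,
            "per_factor_f1": self.per_factor_f1,
            "ari": self.ari,
        }


def evaluate_disentanglement(latent: np.ndarray,
                             column_map: dict[str, tuple[int, int]],
                             truth: LabelTable,
                             factor_names: list[str],
                             predictions: LabelTable | None = None,
                             cell_type_factor: str | None = None,
                             n_bins: int = 20,
                             seed: int = 0) -> DisentanglementReport:
    """Run the full metric suite on a latent matrix against ground truth."""
    sp = spearman_matrix(latent, truth)
    S = block_score_matrix(latent, column_map, truth, factor_names)
    per_f1: dict[str, float] = {}
    ari_val = float("nan")
    if predictions is not None:
        for j, name in enumerate(factor_names):
            per_f1[name] = macro_f1(truth.labels[:, j], predictions.labels[:, j])
        ct = cell_type_factor or factor_names[-1]
        jc = factor_names.index(ct)
        ari_val = ari(truth.labels[:, jc], predictions.labels[:, jc])
    info, dis, comp = dci(latent, truth, seed=seed)
    return DisentanglementReport(
        spearman=sp.integer_coded,
        spearman_one_vs_rest=sp.one_vs_rest,
        mig=mig(latent, truth, n_bins=n_bins),
        sap=sap(latent, truth),
        hungarian=hungarian_alignment(S),
        dci_informativeness=info,
        dci_disentanglement=dis,
        dci_completeness=comp,
        per_factor_f1=per_f1,
        ari=ari_val,
    )
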