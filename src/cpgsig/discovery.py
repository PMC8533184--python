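"""KNN diagnostic-signature discovery with nested cross-validation.

The procedure mirrors class-prediction tools of the Tnasas family:

1. rank all probes by the one-way ANOVA F-ratio of their β values across
   classes;
2. build k-nearest-neighbour predictors (Euclidean distance, majority
   vote) from the top-ranked probes at several candidate sizes and k;
3. choose (size, k) by an inner cross-validation — smallest error, ties
   to the smaller predictor;
4. estimate the generalisation error by an outer stratified 10-fold
   loop whose held-out ("out-of-bag") samples never participate in
   ranking or selection;
5. refit on the complete series to produce the final signature with
   per-probe Δβ (mean β in the positive class minus the reference class).

:class:`SignatureModel` packages the procedure statsmodels-style: build
the model from a :class:`~cpgsig.matrix.BetaMatrix` plus sample sheet,
call :meth:`~SignatureModel.fit`, and read the estimates and diagnostics
off the returned :class:`SignatureResults`.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, SampleSheet, Signature, align_labels

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "ProbeRanking",
    "PredictorModel",
    "CVResult",
    "InnerSelection",
    "anova_f_ratio",
    "rank_probes",
    "knn_predict",
    "inner_select",
    "outer_cv_error",
    "fit_final_signature",
    "stratified_folds",
    "SignatureModel",
    "SignatureResults",
]

DEFAULT_SIZE_GRID = (1, 2, 3, 5, 10, 20, 35, 50, 100, 200)
DEFAULT_K_GRID = (1, 3, 5)


@dataclass
class CVConfig:
    """Cross-validation design for signature discovery.

    ``size_grid`` holds the candidate numbers of top-ranked probes; it
    includes 35 by default so array-scale signatures of that size are
    reachable.  ``k_grid`` holds odd neighbour counts to avoid most
    two-class voting ties.
    """

    outer_folds: int = 10
    inner_folds: int = 10
    size_grid: Sequence[int] = DEFAULT_SIZE_GRID
    k_grid: Sequence[int] = DEFAULT_K_GRID
    seed: int = 0

    def validate(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not self.size_grid or any(s < 1 for s in self.size_grid):
            raise ValueError("size_grid entries must be >= 1")
        if list(self.size_grid) != sorted(set(self.size_grid)):
            raise ValueError("size_grid must be strictly increasing")
        if not self.k_grid or any(k < 1 for k in self.k_grid):
            raise ValueError("k_grid entries must be >= 1")


@dataclass
class ProbeRanking:
    """Probes ordered best-first by ANOVA F-ratio."""

    probe_ids: list[str]
    f_scores: np.ndarray  # aligned with probe_ids, non-increasing

    def top(self, n: int) -> list[str]:
        return self.probe_ids[:n]

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class PredictorModel:
    """A fitted KNN classifier: probe subset, k, and reference samples."""

    probes: list[str]
    k: int
    reference_matrix: BetaMatrix
    reference_labels: pd.Series  # sample id -> class

    def __post_init__(self) -> None:
        if self.k > len(self.reference_labels):
            raise ValueError("k exceeds the number of reference samples")
        absent = [p for p in self.probes if p not in self.reference_matrix.data.index]
        if absent:
            raise ValueError(f"probes absent from reference matrix: {absent[:5]}")


@dataclass
class InnerSelection:
    """Outcome of the inner CV grid search."""

    size: int
    k: int
    cv_error: float
    error_grid: pd.DataFrame  # size x k mean inner-CV error


@dataclass
class CVResult:
    """Out-of-bag predictions and error from the outer CV loop."""

    oob_predictions: dict[str, str]
    true_labels: dict[str, str]
    per_fold_size: list[int]
    per_fold_k: list[int]
    error_rate: float
    n_outer_folds: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "oob_predictions": self.oob_predictions,
            "true_labels": self.true_labels,
            "per_fold_size": self.per_fold_size,
            "per_fold_k": self.per_fold_k,
            "error_rate": self.error_rate,
            "error_rate_rounded": round(self.error_rate, 3),
            "n_outer_folds": self.n_outer_folds,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


# ---------------------------------------------------------------------------
# ANOVA F-ratio ranking


def _f_statistics(
    x: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA F for every row of ``x`` (probes x samples).

    Returns (F, tie_key) where F uses +inf as the zero-within-variance
    sentinel and tie_key orders sentinel probes by the spread of their
    group means (largest first).
    """
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("ANOVA needs >= 2 classes")
    n = x.shape[1]
    grand = x.mean(axis=1)
    between = np.zeros(x.shape[0])
    within = np.zeros(x.shape[0])
    mean_lo = np.full(x.shape[0], np.inf)
    mean_hi = np.full(x.shape[0], -np.inf)
    for cls in classes:
        cols = labels == cls
        ng = int(cols.sum())
        mg = x[:, cols].mean(axis=1)
        between += ng * (mg - grand) ** 2
        within += ((x[:, cols] - mg[:, None]) ** 2).sum(axis=1)
        mean_lo = np.minimum(mean_lo, mg)
        mean_hi = np.maximum(mean_hi, mg)
    df_between = classes.size - 1
    df_within = n - classes.size
    total = between + within
    tol = 1e-12 * np.maximum(total, 1e-30)
    f = np.empty(x.shape[0])
    zero_between = between <= tol
    zero_within = within <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        if df_within > 0:
            f = (between / df_between) / (within / df_within)
    if df_within <= 0:
        f = np.full(x.shape[0], np.inf)
    f[zero_within & ~zero_between] = np.inf
    f[zero_between] = 0.0
    return f, mean_hi - mean_lo


def anova_f_ratio(values: Sequence[float], labels: Sequence[str]) -> float:
    """One-way ANOVA F statistic for a single probe.

    F = between-group mean square / within-group mean square.  With two
    classes this equals the squared pooled-variance t statistic.  Zero
    within-group variance with distinct group means returns the ``+inf``
    sentinel (near-constant probes are common on 450K-like arrays); equal
    group means return 0.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.ndim != 1 or v.shape != lab.shape:
        raise ValueError("values and labels must be 1-D and aligned")
    if np.isnan(v).any():
        raise ValueError("missing values: apply drop_incomplete_probes first")
    for cls in np.unique(lab):
        if (lab == cls).sum() < 1:  # pragma: no cover - unreachable
            raise ValueError(f"class {cls!r} has no samples")
    f, _ = _f_statistics(v[None, :], lab)
    return float(f[0])


def rank_probes(m: BetaMatrix, labels: SampleSheet | pd.Series) -> ProbeRanking:
    """Rank every probe by ANOVA F-ratio, best first.

    Ties among finite F are broken by probe id; the +inf sentinels sort
    above all finite scores, ordered among themselves by the spread of
    their group means and then probe id.
    """
    lab = _as_labels(m, labels)
    if not m.is_complete():
        raise ValueError(
            "matrix has missing values: apply drop_incomplete_probes first"
        )
    f, spread = _f_statistics(m.values, lab.to_numpy())
    probes = m.probe_ids
    is_inf = np.isinf(f)
    # sort key: F desc, sentinel spread desc (only sentinels), probe id asc
    order = sorted(
        range(len(probes)),
        key=lambda i: (
            -f[i] if not is_inf[i] else -math.inf,
            -(spread[i] if is_inf[i] else 0.0),
            probes[i],
        ),
    )
    return ProbeRanking(
        probe_ids=[probes[i] for i in order], f_scores=f[np.array(order)]
    )


def _as_labels(m: BetaMatrix, labels: SampleSheet | pd.Series) -> pd.Series:
    if isinstance(labels, SampleSheet):
        return align_labels(m, labels)
    lab = pd.Series(labels)
    missing = [s for s in m.sample_ids if s not in lab.index]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    return lab.loc[m.sample_ids]


# ---------------------------------------------------------------------------
# KNN prediction


def _vote(
    d2: np.ndarray, ref_labels: np.ndarray, ref_ids: Sequence[str], k: int
) -> str:
    """Majority vote among the k nearest references.

    Exact distance ties at the k-th position include every tied
    neighbour.  A voting tie falls back to the nearest-neighbour rule;
    a residual tie at zero distance spread is resolved by the smallest
    reference sample id, for determinism.
    """
    order = np.lexsort((np.asarray(ref_ids), d2))
    kth = d2[order[k - 1]]
    included = order[d2[order] <= kth]
    counts = Counter(ref_labels[i] for i in included)
    top = counts.most_common()
    if len(top) == 1 or top[0][1] > top[1][1]:
        return top[0][0]
    # vote tie: class of the single nearest neighbour
    d0 = d2[order[0]]
    nearest = [i for i in order if d2[i] == d0]
    near_counts = Counter(ref_labels[i] for i in nearest)
    ntop = near_counts.most_common()
    if len(ntop) == 1 or ntop[0][1] > ntop[1][1]:
        return ntop[0][0]
    best = min(nearest, key=lambda i: ref_ids[i])
    return ref_labels[best]


def knn_predict(model: PredictorModel, query: pd.Series | Mapping[str, float]) -> str:
    """Predict the class of one sample by majority vote of its k nearest
    reference samples under Euclidean distance over the model's probes."""
    q = pd.Series(query, dtype=float)
    missing = [p for p in model.probes if p not in q.index]
    if missing:
        raise ValueError(f"query lacks probes: {missing[:5]}")
    qv = q.loc[model.probes].to_numpy()
    if np.isnan(qv).any():
        raise ValueError("query has missing values over the model's probes")
    ref = model.reference_matrix.data.loc[model.probes]
    d2 = ((ref.to_numpy() - qv[:, None]) ** 2).sum(axis=0)
    ref_ids = list(ref.columns)
    labels = model.reference_labels.loc[ref_ids].to_numpy()
    return _vote(d2, labels, ref_ids, model.k)


# ---------------------------------------------------------------------------
# folds


def stratified_folds(
    labels: pd.Series, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment (positions into ``labels``).

    Each class is shuffled and dealt round-robin, so fold sizes differ by
    at most one per class.  When the smallest class has fewer members
    than ``n_folds`` the effective fold count shrinks to that size (with
    a logged warning) — otherwise some folds would lack a class entirely.
    """
    counts = labels.value_counts()
    smallest = int(counts.min())
    eff = min(n_folds, smallest)
    if eff < 2:
        raise ValueError(
            f"smallest class has {smallest} sample(s); cannot stratify"
        )
    if eff < n_folds:
        logger.warning(
            "reducing folds from %d to %d (smallest class has %d samples)",
            n_folds,
            eff,
            smallest,
        )
    folds: list[list[int]] = [[] for _ in range(eff)]
    lab_arr = labels.to_numpy()
    for cls in sorted(counts.index):
        pos = np.flatnonzero(lab_arr == cls)
        pos = pos[rng.permutation(len(pos))]
        for i, p in enumerate(pos):
            folds[i % eff].append(int(p))
    return [np.array(sorted(f), dtype=int) for f in folds]


# ---------------------------------------------------------------------------
# inner selection


def inner_select(
    m_train: BetaMatrix,
    labels_train: SampleSheet | pd.Series,
    cfg: CVConfig,
    rng: np.random.Generator | None = None,
) -> InnerSelection:
    """Choose (predictor size, k) by inner cross-validation.

    For every inner fold the probes are re-ranked on the in-fold portion
    only (leakage-safe), predictors are built at each candidate size and
    k, and the held-out portion is predicted.  The pair minimising the
    pooled inner-CV error wins; ties go to the smaller size, then the
    smaller k.
    """
    cfg.validate()
    lab = _as_labels(m_train, labels_train)
    if lab.nunique() < 2:
        raise ValueError("training set must contain >= 2 classes")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_probes = m_train.shape[0]
    sizes = [s for s in cfg.size_grid if s <= n_probes]
    skipped = [s for s in cfg.size_grid if s > n_probes]
    if skipped:
        logger.warning("size_grid entries exceeding %d probes skipped: %s",
                       n_probes, skipped)
    folds = stratified_folds(lab, cfg.inner_folds, rng)
    min_train = min(len(lab) - len(f) for f in folds)
    ks = [k for k in cfg.k_grid if k <= min_train]
    if not sizes or not ks:
        raise ValueError("empty effective (size, k) grid")

    errors = np.zeros((len(sizes), len(ks)))
    total = 0
    x = m_train.data
    sample_ids = np.array(m_train.sample_ids)
    lab_arr = lab.to_numpy()
    max_size = max(sizes)
    for fold in folds:
        mask = np.zeros(len(sample_ids), dtype=bool)
        mask[fold] = True
        train_idx = np.flatnonzero(~mask)
        test_idx = fold
        sub = BetaMatrix(x.iloc[:, train_idx], copy=False)
        ranking = rank_probes(sub, pd.Series(lab_arr[train_idx],
                                             index=sample_ids[train_idx]))
        top = ranking.top(max_size)
        ref = x.loc[top].iloc[:, train_idx].to_numpy()  # probes x train
        qry = x.loc[top].iloc[:, test_idx].to_numpy()  # probes x test
        # cumulative squared distance over the ranked probe prefix:
        # axis order (test, train, probe)
        diff2 = (qry.T[:, None, :] - ref.T[None, :, :]) ** 2
        d2cum = np.cumsum(diff2, axis=2)
        ref_ids = list(sample_ids[train_idx])
        ref_lab = lab_arr[train_idx]
        true = lab_arr[test_idx]
        for si, s in enumerate(sizes):
            d2 = d2cum[:, :, s - 1]
            for ki, k in enumerate(ks):
                preds = [
                    _vote(d2[t], ref_lab, ref_ids, k) for t in range(len(test_idx))
                ]
                errors[si, ki] += sum(p != t for p, t in zip(preds, true))
        total += len(test_idx)
    mean_err = errors / total
    best = min(
        ((si, ki) for si in range(len(sizes)) for ki in range(len(ks))),
        key=lambda t: (mean_err[t[0], t[1]], sizes[t[0]], ks[t[1]]),
    )
    grid = pd.DataFrame(mean_err, index=sizes, columns=ks)
    return InnerSelection(
        size=sizes[best[0]],
        k=ks[best[1]],
        cv_error=float(mean_err[best[0], best[1]]),
        error_grid=grid,
    )


# ---------------------------------------------------------------------------
# outer CV


def outer_cv_error(
    m: BetaMatrix,
    labels: SampleSheet | pd.Series,
    cfg: CVConfig,
    fold_callback: Callable[[int, list[str], list[str], ProbeRanking], None]
    | None = None,
) -> CVResult:
    """Out-of-bag error of the whole discovery procedure.

    Samples are split into stratified outer folds; for each fold the
    inner selection *and* the probe ranking are run on the in-bag samples
    only, a predictor is fitted, and the out-of-bag samples are
    predicted.  Every sample is out-of-bag exactly once, and the pooled
    out-of-bag misclassification rate is the reported error.

    ``fold_callback(fold_index, in_bag_ids, oob_ids, in_bag_ranking)`` is
    an instrumentation hook for leakage audits.
    """
    cfg.validate()
    lab = _as_labels(m, labels)
    if not m.is_complete():
        raise ValueError("matrix has missing values: apply drop_incomplete_probes")
    counts = lab.value_counts()
    if int(counts.min()) < 2:
        raise ValueError("every class needs >= 2 samples for stratified CV")
    ss = np.random.SeedSequence(cfg.seed)
    fold_seed, *inner_seeds = ss.spawn(cfg.outer_folds + 1)
    folds = stratified_folds(lab, cfg.outer_folds, np.random.default_rng(fold_seed))

    sample_ids = np.array(m.sample_ids)
    lab_arr = lab.to_numpy()
    oob_pred: dict[str, str] = {}
    per_fold_size: list[int] = []
    per_fold_k: list[int] = []
    for i, fold in enumerate(folds):
        mask = np.zeros(len(sample_ids), dtype=bool)
        mask[fold] = True
        inbag_idx = np.flatnonzero(~mask)
        inbag = BetaMatrix(m.data.iloc[:, inbag_idx], copy=False)
        inbag_lab = pd.Series(lab_arr[inbag_idx], index=sample_ids[inbag_idx])
        sel = inner_select(
            inbag, inbag_lab, cfg, rng=np.random.default_rng(inner_seeds[i])
        )
        ranking = rank_probes(inbag, inbag_lab)
        probes = ranking.top(sel.size)
        model = PredictorModel(
            probes=probes,
            k=sel.k,
            reference_matrix=inbag.subset_probes(probes),
            reference_labels=inbag_lab,
        )
        if fold_callback is not None:
            fold_callback(
                i, list(sample_ids[inbag_idx]), list(sample_ids[fold]), ranking
            )
        for j in fold:
            sid = sample_ids[j]
            oob_pred[sid] = knn_predict(model, m.data[sid])
        per_fold_size.append(sel.size)
        per_fold_k.append(sel.k)
    true = {s: c for s, c in zip(sample_ids, lab_arr)}
    n_err = sum(oob_pred[s] != true[s] for s in sample_ids)
    return CVResult(
        oob_predictions=oob_pred,
        true_labels=true,
        per_fold_size=per_fold_size,
        per_fold_k=per_fold_k,
        error_rate=n_err / len(sample_ids),
        n_outer_folds=len(folds),
    )


# ---------------------------------------------------------------------------
# final fit


def fit_final_signature(
    m: BetaMatrix,
    labels: SampleSheet | pd.Series,
    cfg: CVConfig,
    *,
    positive_class: str = "TNBC",
    reference_class: str | None = None,
) -> tuple[Signature, PredictorModel]:
    """Fit the signature on the complete series.

    Runs the inner selection on all samples to fix (size, k), ranks the
    probes on all samples, and returns the top-``size`` probes with their
    Δβ together with the final KNN predictor.
    """
    cfg.validate()
    lab = _as_labels(m, labels)
    classes = sorted(lab.unique())
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {classes}")
    if reference_class is None:
        others = [c for c in classes if c != positive_class]
        if len(others) != 1:
            raise ValueError(
                "reference_class must be given explicitly with > 2 classes"
            )
        reference_class = others[0]
    ss = np.random.SeedSequence(cfg.seed)
    (final_seed,) = ss.spawn(1)
    sel = inner_select(m, lab, cfg, rng=np.random.default_rng(final_seed))
    ranking = rank_probes(m, lab)
    probes = ranking.top(sel.size)
    sub = m.data.loc[probes]
    pos_mean = sub.loc[:, (lab == positive_class).to_numpy()].mean(axis=1)
    ref_mean = sub.loc[:, (lab == reference_class).to_numpy()].mean(axis=1)
    dbeta = pos_mean - ref_mean
    signature = Signature(
        probes=probes,
        delta_beta=dbeta,
        metadata={
            "seed": cfg.seed,
            "outer_folds": cfg.outer_folds,
            "inner_folds": cfg.inner_folds,
            "size_grid": list(cfg.size_grid),
            "k_grid": list(cfg.k_grid),
            "chosen_size": sel.size,
            "chosen_k": sel.k,
            "inner_cv_error": sel.cv_error,
            "positive_class": positive_class,
            "reference_class": reference_class,
        },
    )
    predictor = PredictorModel(
        probes=probes,
        k=sel.k,
        reference_matrix=m.subset_probes(probes),
        reference_labels=lab,
    )
    return signature, predictor


# ---------------------------------------------------------------------------
# model / results facade


class SignatureModel:
    """Diagnostic-signature discovery model over a β matrix.

    Parameters
    ----------
    beta : BetaMatrix
        Complete (no missing values) probe-by-sample β matrix.
    samples : SampleSheet or pandas.Series
        Class labels; must cover the matrix's samples exactly.
    positive_class : str
        The class sensitivity refers to (default ``"TNBC"``).
    reference_class : str, optional
        Required when more than two classes are present.

    Examples
    --------
    >>> model = SignatureModel(beta, sheet, positive_class="TNBC")
    >>> res = model.fit(CVConfig(seed=7))
    >>> print(res.summary())
    """

    def __init__(
        self,
        beta: BetaMatrix,
        samples: SampleSheet | pd.Series,
        *,
        positive_class: str = "TNBC",
        reference_class: str | None = None,
    ):
        self.beta = beta
        self.labels = _as_labels(beta, samples)
        if not beta.is_complete():
            raise ValueError(
                "matrix has missing values: apply drop_incomplete_probes first"
            )
        classes = sorted(self.labels.unique())
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        if positive_class not in classes:
            raise ValueError(f"positive class {positive_class!r} not among {classes}")
        self.positive_class = positive_class
        if reference_class is None and len(classes) == 2:
            reference_class = next(c for c in classes if c != positive_class)
        self.reference_class = reference_class

    @classmethod
    def from_files(
        cls,
        beta_path: str | Path,
        sheet_path: str | Path,
        **kwargs,
    ) -> "SignatureModel":
        from .matrix import read_beta_matrix, read_sample_sheet

        return cls(read_beta_matrix(beta_path), read_sample_sheet(sheet_path),
                   **kwargs)

    def fit(self, config: CVConfig | None = None) -> "SignatureResults":
        """Run outer CV (diagnostics) and the final signature fit."""
        cfg = config or CVConfig()
        cv = outer_cv_error(self.beta, self.labels, cfg)
        signature, predictor = fit_final_signature(
            self.beta,
            self.labels,
            cfg,
            positive_class=self.positive_class,
            reference_class=self.reference_class,
        )
        return SignatureResults(self, cfg, signature, predictor, cv)


class SignatureResults:
    """Fitted signature, final predictor and cross-validation diagnostics."""

    def __init__(
        self,
        model: SignatureModel,
        config: CVConfig,
        signature: Signature,
        predictor: PredictorModel,
        cv_result: CVResult,
    ):
        self.model = model
        self.config = config
        self.signature = signature
        self.predictor = predictor
        self.cv_result = cv_result

    def predict(self, beta: BetaMatrix) -> pd.Series:
        """Classify new samples with the final KNN predictor."""
        preds = {
            s: knn_predict(self.predictor, beta.data[s]) for s in beta.sample_ids
        }
        return pd.Series(preds, name="predicted_class")

    def per_class_rates(self) -> pd.Series:
        """Fraction of out-of-bag samples correctly predicted, per class."""
        cv = self.cv_result
        out = {}
        for cls in sorted(set(cv.true_labels.values())):
            ids = [s for s, c in cv.true_labels.items() if c == cls]
            ok = sum(cv.oob_predictions[s] == cls for s in ids)
            out[cls] = ok / len(ids)
        return pd.Series(out, name="oob_correct_rate")

    def summary(self) -> str:
        cv = self.cv_result
        lab = self.model.labels
        lines = [
            "KNN Methylation Signature Discovery",
            "=" * 51,
            f"Samples: {len(lab)} "
            + ", ".join(f"{c}={int((lab == c).sum())}" for c in sorted(lab.unique())),
            f"Probes ranked: {self.model.beta.shape[0]}",
            f"Positive class: {self.model.positive_class}"
            + (f" (reference: {self.model.reference_class})"
               if self.model.reference_class else ""),
            f"Outer folds: {cv.n_outer_folds} (requested {self.config.outer_folds})",
            f"Out-of-bag error rate: {cv.error_rate:.3f}",
            "Per-class correct rate: "
            + ", ".join(f"{c}={r:.1%}" for c, r in self.per_class_rates().items()),
            f"Per-fold (size, k): "
            + " ".join(f"({s},{k})" for s, k in
                       zip(cv.per_fold_size, cv.per_fold_k)),
            "-" * 51,
            f"Final signature: {len(self.signature)} probes "
            f"(k={self.signature.metadata.get('chosen_k')})",
            f"{'probe_id':<16}{'delta_beta':>12}",
        ]
        for p in self.signature.probes[:20]:
            lines.append(f"{p:<16}{self.signature.delta_beta[p]:>12.4f}")
        if len(self.signature) > 20:
            lines.append(f"... ({len(self.signature) - 20} more probes)")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "signature_tsv": self.signature.to_tsv(outdir / "signature.tsv"),
            "signature_json": self.signature.to_json(outdir / "signature.json"),
            "cv_result_json": self.cv_result.to_json(outdir / "cv_result.json"),
        }
        return paths

    def plot_delta_beta(self, ax=None):
        """Bar plot of per-probe Δβ, hypomethylated probes below zero."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, len(self.signature) * 0.3), 3))
        dbeta = self.signature.delta_beta
        ax.bar(range(len(dbeta)), dbeta.to_numpy(), color="steelblue")
        ax.axhline(0, color="black", lw=0.8)
        ax.set_xticks(range(len(dbeta)))
        ax.set_xticklabels(dbeta.index, rotation=90, fontsize=6)
        ax.set_ylabel(r"$\Delta\beta$")
        ax.set_title("Signature probes")
        return ax
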