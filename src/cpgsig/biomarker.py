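"""Biomarker-level evaluation of methylation differences.

Works on two scales kept deliberately distinct: array β fractions in
[0, 1] and pyrosequencing methylation percentages in [0, 100].  Provides
Δβ shortlisting of signature probes, Mann–Whitney U group comparisons
(exact for small tie-free samples, normal approximation with tie and
continuity corrections otherwise), ROC cut-off selection by the largest
positive likelihood ratio LR+ = sensitivity / (1 − specificity), the
simultaneous-hypomethylation multi-probe diagnostic rule, and stage-wise
comparisons against a reference group.  No multiple-testing adjustment
is applied anywhere; outputs carry ``multiplicity_adjustment: none`` so
downstream users see it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .matrix import BetaMatrix, SampleSheet, Signature
from .discovery import _as_labels

__all__ = [
    "MWTestResult",
    "RocResult",
    "StagewiseResult",
    "delta_beta",
    "top_abs_delta_beta",
    "mann_whitney_u",
    "roc_cutoff_max_lr_plus",
    "simultaneous_hypomethylation_rule",
    "stagewise_compare",
    "beta_to_percent",
]

#: exact Mann-Whitney enumeration is used up to this combined sample size
EXACT_MW_LIMIT = 12

STAGE_ORDER = ("I", "IIA", "IIB", "IIIA", "IIIC")


def beta_to_percent(beta: float | np.ndarray) -> float | np.ndarray:
    """Explicit β-fraction → methylation-percent conversion (×100)."""
    return np.asarray(beta, dtype=float) * 100.0 if isinstance(
        beta, (list, tuple, np.ndarray)
    ) else float(beta) * 100.0


# ---------------------------------------------------------------------------
# delta beta


def delta_beta(
    m: BetaMatrix,
    labels: SampleSheet | pd.Series,
    positive_class: str,
    reference_class: str,
) -> pd.Series:
    """Per-probe Δβ: mean β in the positive class minus the reference class."""
    lab = _as_labels(m, labels)
    pos = (lab == positive_class).to_numpy()
    ref = (lab == reference_class).to_numpy()
    if not pos.any():
        raise ValueError(f"no samples in positive class {positive_class!r}")
    if not ref.any():
        raise ValueError(f"no samples in reference class {reference_class!r}")
    x = m.data
    if x.iloc[:, pos | ref].isna().any().any():
        raise ValueError("missing values among the compared samples")
    return x.iloc[:, pos].mean(axis=1) - x.iloc[:, ref].mean(axis=1)


def top_abs_delta_beta(sig: Signature, n: int) -> list[str]:
    """The ``n`` signature probes with the largest |Δβ| (ties by probe id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(sig):
        raise ValueError(f"n={n} exceeds signature size {len(sig)}")
    order = sorted(sig.probes, key=lambda p: (-abs(sig.delta_beta[p]), p))
    return order[:n]


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class MWTestResult:
    """Mann–Whitney U comparison of two value lists."""

    u: float  # U statistic of the first sample
    p_value: float
    median_a: float
    median_b: float
    method: str  # "exact" or "normal"

    def as_dict(self) -> dict:
        return {
            "U": self.u,
            "p_value": self.p_value,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "method": self.method,
        }


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample ``a`` via midrank rank sums."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> MWTestResult:
    """Two-sided Mann–Whitney U test.

    U is computed from midranks.  When n₁+n₂ ≤ 12 and the pooled values
    are tie-free, the two-sided p is exact, by enumerating every
    assignment of the pooled values to the two groups; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction is used.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = av.size, bv.size
    u = _u_statistic(av, bv)
    pooled = np.concatenate([av, bv])
    has_ties = np.unique(pooled).size < pooled.size
    mean_u = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MW_LIMIT and not has_ties:
        # exact two-sided p: share of group assignments at least as far
        # from the null mean as the observed U
        dev = abs(u - mean_u)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for combo in combinations(idx, n1):
            ua = _u_statistic(pooled[list(combo)],
                              np.delete(pooled, list(combo)))
            total += 1
            if abs(ua - mean_u) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
            z = max(z, 0.0)
            p = 2.0 * float(norm.sf(z))
        p = min(p, 1.0)
        method = "normal"
    return MWTestResult(
        u=u,
        p_value=p,
        median_a=float(np.median(av)),
        median_b=float(np.median(bv)),
        method=method,
    )


# ---------------------------------------------------------------------------
# ROC cut-off by largest LR+


@dataclass
class RocResult:
    """Optimal dichotomising cut-off on the methylation-percent scale."""

    cutoff: float
    sensitivity: float
    specificity: float
    lr_plus: float  # +inf sentinel at perfect specificity
    direction: str  # "below" or "above"

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "lr_plus": self.lr_plus if math.isfinite(self.lr_plus) else "inf",
            "direction": self.direction,
        }


def _roc_candidates(values: np.ndarray) -> list[float]:
    distinct = np.unique(values)
    mids = [(distinct[i] + distinct[i + 1]) / 2.0 for i in range(len(distinct) - 1)]
    return [-math.inf, *mids, math.inf]


def roc_cutoff_max_lr_plus(
    values: Sequence[float],
    labels: Sequence[bool],
    positive_direction: str = "below",
) -> RocResult:
    """Choose the cut-off maximising the positive likelihood ratio.

    Candidate cut-offs are the midpoints between consecutive distinct
    values plus ±∞ sentinels.  With ``positive_direction="below"`` a
    sample is called positive when its value is strictly below the
    cut-off (the hypomethylation convention); ``"above"`` is the mirror.
    If any candidate reaches specificity 1 with non-zero sensitivity the
    LR+ is the +∞ sentinel and the candidate with the largest sensitivity
    wins; otherwise the finite LR+ maximiser wins.  Remaining ties go to
    the lower cut-off.
    """
    if positive_direction not in ("below", "above"):
        raise ValueError("positive_direction must be 'below' or 'above'")
    v = np.asarray(list(values), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must be aligned")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if np.unique(v).size < 2:
        raise ValueError("all values identical: no informative cut-off")

    best: RocResult | None = None
    for c in _roc_candidates(v):
        called = v < c if positive_direction == "below" else v > c
        sens = float((called & y).sum()) / n_pos
        spec = float((~called & ~y).sum()) / n_neg
        if spec == 1.0:
            if sens == 0.0:
                continue
            lr = math.inf
        else:
            lr = sens / (1.0 - spec)
        cand = RocResult(c, sens, spec, lr, positive_direction)
        if best is None:
            best = cand
            continue
        if _roc_better(cand, best):
            best = cand
    assert best is not None
    return best


def _roc_better(a: RocResult, b: RocResult) -> bool:
    """Is candidate ``a`` preferable to incumbent ``b``?"""
    a_inf = math.isinf(a.lr_plus)
    b_inf = math.isinf(b.lr_plus)
    if a_inf != b_inf:
        return a_inf
    if a_inf:  # both perfect specificity: max sensitivity, then lower cutoff
        if a.sensitivity != b.sensitivity:
            return a.sensitivity > b.sensitivity
        return a.cutoff < b.cutoff
    if a.lr_plus != b.lr_plus:
        return a.lr_plus > b.lr_plus
    return a.cutoff < b.cutoff


# ---------------------------------------------------------------------------
# simultaneous hypomethylation rule


def simultaneous_hypomethylation_rule(
    sample_values: Mapping[str, float], cutoffs: Mapping[str, float]
) -> bool:
    """Positive (tumour-like) call iff every probe's methylation percent is
    strictly below its cut-off; equality at a cut-off is negative."""
    if set(sample_values) != set(cutoffs):
        raise ValueError("sample values and cut-offs must share probe keys")
    if not sample_values:
        raise ValueError("no probes supplied")
    return all(sample_values[p] < cutoffs[p] for p in cutoffs)


# ---------------------------------------------------------------------------
# stage-wise comparison


@dataclass
class StagewiseResult:
    """Group medians plus stage-vs-reference and consecutive-stage tests."""

    medians: pd.Series
    vs_reference: dict[str, MWTestResult]
    consecutive: dict[str, MWTestResult]
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "medians": {g: float(v) for g, v in self.medians.items()},
            "vs_reference": {g: t.as_dict() for g, t in self.vs_reference.items()},
            "consecutive": {g: t.as_dict() for g, t in self.consecutive.items()},
            "metadata": self.metadata,
        }


def stagewise_compare(
    table: pd.DataFrame,
    reference_group: str,
    *,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> StagewiseResult:
    """Compare each stage group's methylation percents to a reference.

    ``table`` needs ``group`` and ``percent`` columns; groups other than
    the reference are treated as stages and ordered by ``stage_order``
    (unknown groups keep their input order, after the known stages).
    Reports per-group medians, a Mann–Whitney test of each stage against
    the reference, and tests between consecutive stages.  Stages with no
    samples are skipped with a warning; no multiplicity adjustment is
    applied (flagged in the metadata).
    """
    if "group" not in table.columns or "percent" not in table.columns:
        raise ValueError("table needs 'group' and 'percent' columns")
    groups = list(dict.fromkeys(table["group"]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} absent")
    stages = [g for g in groups if g != reference_group]
    known = [s for s in stage_order if s in stages]
    unknown = [s for s in stages if s not in stage_order]
    stages = known + unknown

    ref_vals = table.loc[table["group"] == reference_group, "percent"].to_numpy()
    medians = {reference_group: float(np.median(ref_vals))}
    vs_ref: dict[str, MWTestResult] = {}
    present: list[str] = []
    for s in stages:
        vals = table.loc[table["group"] == s, "percent"].to_numpy()
        if vals.size == 0:
            import warnings

            warnings.warn(f"stage {s!r} has no samples; skipped", stacklevel=2)
            continue
        present.append(s)
        medians[s] = float(np.median(vals))
        vs_ref[s] = mann_whitney_u(vals, ref_vals)
    consecutive: dict[str, MWTestResult] = {}
    for s1, s2 in zip(present, present[1:]):
        v1 = table.loc[table["group"] == s1, "percent"].to_numpy()
        v2 = table.loc[table["group"] == s2, "percent"].to_numpy()
        consecutive[f"{s1} vs {s2}"] = mann_whitney_u(v1, v2)
    return StagewiseResult(
        medians=pd.Series(medians),
        vs_reference=vs_ref,
        consecutive=consecutive,
        metadata={
            "multiplicity_adjustment": "none",
            "reference_group": reference_group,
        },
    )
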