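"""Seeded generators for synthetic methylation-array and pyrosequencing data.

The β-value generator emulates the structure of Illumina 450K cohorts:
per-probe background means drawn from the tri-modal β landscape of real
arrays (mostly-unmethylated, intermediate, mostly-methylated probes), a
small planted subset of differentially methylated probes (DMPs) whose
mean is shifted by a configured Δβ in the positive class, Beta-distributed
within-class noise, samples organised into "dataset" batches, and
per-(probe, dataset) dropout that blanks a probe for every sample of a
dataset — the way a whole platform export can lack a probe.

A second generator emits per-sample methylation-percentage tables on the
0–100 pyrosequencing scale for group-comparison and ROC work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, SampleSheet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_beta_matrix",
    "simulate_methylation_percent_table",
]

#: background β-mean mixture: (component mean, weight).  Real 450K arrays
#: are strongly bimodal with a minor intermediate mode.
BACKGROUND_MODES: tuple[tuple[float, float], ...] = (
    (0.1, 0.4),
    (0.5, 0.2),
    (0.9, 0.4),
)

# class means must stay inside this band so Beta(mean, concentration)
# stays well-conditioned and values cannot pile up on 0/1
_MEAN_LO, _MEAN_HI = 0.02, 0.98


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic methylation cohort.

    Defaults mirror the discovery design this package targets: a 450K-like
    probe count scaled to 10,000, 35 planted DMPs hypomethylated by
    Δβ = −0.35 in the positive class, 5 non-neoplastic vs 7 tumour
    samples, and a Beta-noise concentration of 50.
    """

    n_probes: int = 10_000
    n_planted_dmps: int = 35
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"N": 5, "TNBC": 7}
    )
    positive_class: str = "TNBC"
    dmp_effect: float = -0.35
    dispersion: float = 50.0
    dataset_assignment: Mapping[str, str] | None = None
    probe_dropout_per_dataset: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not 0 <= self.n_planted_dmps <= self.n_probes:
            raise ValueError("n_planted_dmps must lie in [0, n_probes]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.probe_dropout_per_dataset < 1.0:
            raise ValueError("probe_dropout_per_dataset must lie in [0, 1)")
        if self.positive_class not in self.class_sizes:
            raise ValueError(
                f"positive_class {self.positive_class!r} not in class_sizes"
            )
        if any(n < 1 for n in self.class_sizes.values()):
            raise ValueError("every class needs >= 1 sample")
        if abs(self.dmp_effect) > 1:
            raise ValueError("dmp_effect must lie in [-1, 1]")
        if self.n_planted_dmps and not self._eligible_planted_means():
            raise ValueError(
                f"dmp_effect {self.dmp_effect} leaves no background mode with "
                f"both class means inside [{_MEAN_LO}, {_MEAN_HI}]"
            )

    def _eligible_planted_means(self) -> list[float]:
        out = []
        for mean, _w in BACKGROUND_MODES:
            if (
                _MEAN_LO <= mean <= _MEAN_HI
                and _MEAN_LO <= mean + self.dmp_effect <= _MEAN_HI
            ):
                out.append(mean)
        return out


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort: what a perfect analysis recovers."""

    planted_probe_ids: list[str]
    class_means: pd.DataFrame  # probe x class, the true Beta means
    labels: pd.Series  # sample id -> class

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_probe_ids": self.planted_probe_ids,
            "labels": {s: c for s, c in self.labels.items()},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _sample_ids(class_sizes: Mapping[str, int]) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for cls in class_sizes:
        for i in range(class_sizes[cls]):
            ids.append(f"{cls}_{i + 1:03d}")
            labels.append(cls)
    return ids, labels


def simulate_beta_matrix(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, SimulationTruth]:
    """Draw a seeded synthetic β matrix with planted DMPs.

    Every value is Beta-distributed with mean equal to the probe's
    class-specific true mean and concentration ``cfg.dispersion``
    (α = mean·c, β = (1−mean)·c).  Planted probes shift the positive
    class's mean by ``cfg.dmp_effect``; all other probes share one mean
    across classes.  Identical seeds give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    sample_ids, labels = _sample_ids(cfg.class_sizes)
    classes = list(cfg.class_sizes)
    n_samples = len(sample_ids)
    probe_ids = [f"cg{i:08d}" for i in range(1, cfg.n_probes + 1)]

    # background mean per probe from the tri-modal mixture
    modes = np.array([m for m, _ in BACKGROUND_MODES])
    weights = np.array([w for _, w in BACKGROUND_MODES])
    weights = weights / weights.sum()
    background = modes[rng.choice(len(modes), size=cfg.n_probes, p=weights)]

    # planted probes: uniformly among probes whose shifted mean stays legal
    eligible_means = set(cfg._eligible_planted_means())
    eligible_idx = np.flatnonzero(np.isin(background, sorted(eligible_means)))
    if cfg.n_planted_dmps > len(eligible_idx):
        raise ValueError(
            f"only {len(eligible_idx)} probes eligible for planting "
            f"{cfg.n_planted_dmps} DMPs"
        )
    planted_idx = np.sort(
        rng.choice(eligible_idx, size=cfg.n_planted_dmps, replace=False)
    )
    planted = [probe_ids[i] for i in planted_idx]

    means = pd.DataFrame(
        np.repeat(background[:, None], len(classes), axis=1),
        index=probe_ids,
        columns=classes,
    )
    means.loc[planted, cfg.positive_class] = (
        means.loc[planted, cfg.positive_class] + cfg.dmp_effect
    )

    label_arr = np.array(labels)
    grid = np.empty((cfg.n_probes, n_samples))
    c = cfg.dispersion
    for cls in classes:
        cols = np.flatnonzero(label_arr == cls)
        mu = means[cls].to_numpy()[:, None]
        grid[:, cols] = rng.beta(mu * c, (1.0 - mu) * c, size=(cfg.n_probes, len(cols)))
    # Beta draws are in (0,1) open interval; clip defensively for float edge
    np.clip(grid, 0.0, 1.0, out=grid)

    # dataset structure + per-(probe, dataset) dropout
    if cfg.dataset_assignment is None:
        dataset_of = {s: "d1" for s in sample_ids}
    else:
        missing = [s for s in sample_ids if s not in cfg.dataset_assignment]
        if missing:
            raise ValueError(f"dataset_assignment lacks samples: {missing[:5]}")
        dataset_of = {s: cfg.dataset_assignment[s] for s in sample_ids}
    if cfg.probe_dropout_per_dataset > 0:
        for ds in sorted(set(dataset_of.values())):
            cols = [j for j, s in enumerate(sample_ids) if dataset_of[s] == ds]
            n_drop = int(round(cfg.probe_dropout_per_dataset * cfg.n_probes))
            drop = rng.choice(cfg.n_probes, size=n_drop, replace=False)
            grid[np.ix_(drop, cols)] = np.nan

    matrix = BetaMatrix(
        pd.DataFrame(grid, index=probe_ids, columns=sample_ids), copy=False
    )
    sheet = SampleSheet.from_records(
        [(s, lab, dataset_of[s]) for s, lab in zip(sample_ids, labels)]
    )
    truth = SimulationTruth(
        planted_probe_ids=planted,
        class_means=means,
        labels=pd.Series(labels, index=sample_ids, name="class_label"),
    )
    return matrix, sheet, truth


def simulate_methylation_percent_table(
    group_means: Mapping[str, float],
    group_sizes: Mapping[str, int],
    sd: float,
    seed: int,
    *,
    sample_ids: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-sample methylation percentages (0–100 pyrosequencing scale).

    Draws are normal with the group's mean and common ``sd``, truncated by
    clipping to [0, 100].  ``sd == 0`` returns every group's mean exactly.
    Optionally reuse caller-supplied sample ids per group (so several
    probes can be simulated for the same patients).

    Returns a DataFrame with columns ``sample_id``, ``group``, ``percent``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    for g, mu in group_means.items():
        if not 0.0 <= mu <= 100.0:
            raise ValueError(f"group {g!r} mean {mu} outside [0, 100]")
    if set(group_means) != set(group_sizes):
        raise ValueError("group_means and group_sizes must share keys")
    rng = np.random.default_rng(seed)
    rows = []
    for g in group_means:
        n = group_sizes[g]
        if n < 1:
            raise ValueError(f"group {g!r} has size {n}")
        draws = np.full(n, group_means[g]) if sd == 0 else rng.normal(
            group_means[g], sd, size=n
        )
        np.clip(draws, 0.0, 100.0, out=draws)
        if sample_ids is not None:
            ids = list(sample_ids[g])
            if len(ids) != n:
                raise ValueError(f"sample_ids for group {g!r} has wrong length")
        else:
            ids = [f"{g}_{i + 1:03d}" for i in range(n)]
        rows.extend(
            {"sample_id": s, "group": g, "percent": float(v)}
            for s, v in zip(ids, draws)
        )
    return pd.DataFrame(rows, columns=["sample_id", "group", "percent"])
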