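"""One-command synthetic end-to-end reenactment of the analysis.

The demo walks the full workflow on seeded synthetic data: a small
discovery cohort (5 non-neoplastic vs 7 tumour samples, 10,000 probes,
35 planted DMPs at Δβ = −0.35), KNN signature discovery with nested CV,
extension cohorts (58 additional non-neoplastic, 93 tumour samples drawn
from the same planted truth, split over "GEO-like" dataset batches) with
one signature probe unavailable — emulating a probe that cannot be
retrieved from a platform export — UPGMA two-cluster validation, and
pyrosequencing-scale evaluation of the top-|Δβ| probes with LR+ cut-offs,
the simultaneous-hypomethylation rule, stage-wise comparisons and a
small cfDNA contrast.  Identical seeds give identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import Signature, intersect_probes, write_beta_matrix
from .simulate import SimulationConfig, simulate_methylation_percent_table
from .simulate import simulate_beta_matrix
from .discovery import CVConfig, SignatureModel
from .cluster import (
    classification_metrics,
    euclidean_distances,
    two_cluster_classes,
    upgma,
)
from .biomarker import (
    mann_whitney_u,
    roc_cutoff_max_lr_plus,
    simultaneous_hypomethylation_rule,
    stagewise_compare,
    top_abs_delta_beta,
)

logger = logging.getLogger(__name__)

#: discovery cohort shape: 5 non-neoplastic vs 7 tumour samples
DISCOVERY_SIZES = {"N": 5, "TNBC": 7}
#: extension cohorts added on top of discovery
EXTENSION_SIZES = {"N": 58, "TNBC": 93}
#: tumour stage group sizes of the tissue validation series
STAGE_SIZES = {"I": 8, "IIA": 21, "IIB": 6, "IIIA": 8, "IIIC": 3}
#: pyrosequencing series sizes
PYRO_N = 16
PYRO_BC = 57
CFDNA_SIZES = {"healthy": 15, "TNBC": 6}
#: scatter of simulated pyrosequencing percentages, in percent points
PYRO_SD = 8.0
#: fraction of the tumour methylation shift visible in plasma cfDNA
CFDNA_ATTENUATION = 0.5


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_demo(
    seed: int,
    outdir: str | Path,
    *,
    dmp_effect: float = -0.35,
    dispersion: float = 50.0,
    n_probes: int = 10_000,
    n_planted: int = 35,
    write_matrices: bool = True,
) -> dict:
    """Run the full synthetic pipeline; returns the summary dict.

    Writes signature, tree, predictions, metrics, cut-offs, calls, test
    and summary artifacts under ``outdir`` (β matrices too unless
    ``write_matrices=False``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed, 8)
    t0 = time.perf_counter()

    # ------------------------------------------------------------------ 1
    # simulate discovery + extension in one cohort sharing the planted truth
    class_sizes = {
        c: DISCOVERY_SIZES[c] + EXTENSION_SIZES[c] for c in DISCOVERY_SIZES
    }
    assignment: dict[str, str] = {}
    for cls, n_disc in DISCOVERY_SIZES.items():
        total = class_sizes[cls]
        ext_ids = [f"{cls}_{i + 1:03d}" for i in range(n_disc, total)]
        for i in range(n_disc):
            assignment[f"{cls}_{i + 1:03d}"] = "GSE-DISC"
        half = len(ext_ids) // 2
        for s in ext_ids[:half]:
            assignment[s] = f"EXT-{cls}1"
        for s in ext_ids[half:]:
            assignment[s] = f"EXT-{cls}2"
    cfg = SimulationConfig(
        n_probes=n_probes,
        n_planted_dmps=n_planted,
        class_sizes=class_sizes,
        positive_class="TNBC",
        dmp_effect=dmp_effect,
        dispersion=dispersion,
        dataset_assignment=assignment,
        seed=seeds[0],
    )
    matrix, sheet, truth = simulate_beta_matrix(cfg)
    disc_samples = [s for s, d in assignment.items() if d == "GSE-DISC"]
    ext_samples = [s for s in matrix.sample_ids if s not in set(disc_samples)]
    disc = matrix.subset_samples(disc_samples)
    ext = matrix.subset_samples(ext_samples)
    logger.info("simulated %s in %.1fs", matrix, time.perf_counter() - t0)
    if write_matrices:
        write_beta_matrix(disc, outdir / "discovery_beta.tsv")
        write_beta_matrix(ext, outdir / "extension_beta.tsv")
        sheet.to_csv(outdir / "samples.csv")
        truth.to_json(outdir / "truth.json")

    # ------------------------------------------------------------------ 2
    # discover the signature on the discovery cohort only.  The demo fixes
    # the candidate signature size at the planted DMP count: on clean
    # synthetic data the smallest-error/smallest-size selection rule would
    # otherwise settle on one or two probes, and the probe-loss and
    # multi-probe-rule stages downstream need an array-scale signature.
    t1 = time.perf_counter()
    model = SignatureModel(
        disc, truth.labels.loc[disc.sample_ids], positive_class="TNBC"
    )
    res = model.fit(CVConfig(seed=seeds[1], size_grid=(n_planted,)))
    res.save(outdir)
    sig = res.signature
    planted = set(truth.planted_probe_ids)
    found = set(sig.probes)
    jaccard = len(planted & found) / len(planted | found)
    logger.info(
        "discovery: %d probes, oob error %.3f (%.1fs)",
        len(sig),
        res.cv_result.error_rate,
        time.perf_counter() - t1,
    )

    # ------------------------------------------------------------------ 3
    # extension cohorts lack one signature probe (platform export loss)
    if len(sig) > 1:
        lost_probe = min(sig.probes, key=lambda p: (abs(sig.delta_beta[p]), p))
        available = [p for p in sig.probes if p != lost_probe]
    else:
        lost_probe = None
        available = list(sig.probes)
    merged, dropped = intersect_probes(
        [disc.subset_probes(sig.probes), ext.subset_probes(available)]
    )
    retained_sig = Signature(
        probes=[p for p in sig.probes if p in set(merged.probe_ids)],
        delta_beta=sig.delta_beta,
        metadata={"derived_from": "discovery signature", "dropped": dropped},
    )

    # ------------------------------------------------------------------ 4
    # UPGMA two-cluster validation on discovery + extension samples
    t2 = time.perf_counter()
    tree = upgma(euclidean_distances(merged))
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    true_labels = {s: truth.labels[s] for s in merged.sample_ids}
    metrics_all = metrics_ext = None
    segregation_failure: str | None = None
    try:
        predicted = two_cluster_classes(tree, true_labels)
    except ValueError as exc:
        if "non-segregation" not in str(exc):
            raise
        # a null signature cannot segregate the classes; record and move on
        segregation_failure = str(exc)
        logger.warning("clustering: %s", exc)
    else:
        pd.DataFrame(
            {
                "sample_id": list(predicted),
                "predicted_class": [predicted[s] for s in predicted],
                "true_class": [true_labels[s] for s in predicted],
            }
        ).to_csv(outdir / "predictions.csv", index=False)
        metrics_all = classification_metrics(true_labels, predicted, "TNBC")
        ext_true = {s: true_labels[s] for s in ext_samples}
        ext_pred = {s: predicted[s] for s in ext_samples}
        metrics_ext = classification_metrics(ext_true, ext_pred, "TNBC")
        metrics_all.to_json(outdir / "metrics.json")
        logger.info(
            "clustering: error %.3f overall, %.3f extension (%.1fs)",
            metrics_all.error_rate,
            metrics_ext.error_rate,
            time.perf_counter() - t2,
        )

    # ------------------------------------------------------------------ 5
    # pyrosequencing-scale evaluation of the top |Δβ| probes
    n_top = min(3, len(retained_sig))
    top_probes = top_abs_delta_beta(retained_sig, n_top)
    group_sizes = {"N": PYRO_N, **STAGE_SIZES, "BC": PYRO_BC}
    sample_ids = {
        g: [f"pyro_{g}_{i + 1:03d}" for i in range(n)]
        for g, n in group_sizes.items()
    }
    tables: dict[str, pd.DataFrame] = {}
    for pi, probe in enumerate(top_probes):
        mean_n = float(truth.class_means.loc[probe, "N"]) * 100.0
        mean_t = float(truth.class_means.loc[probe, "TNBC"]) * 100.0
        group_means = {"N": mean_n, "BC": mean_n}
        group_means.update({st: mean_t for st in STAGE_SIZES})
        tables[probe] = simulate_methylation_percent_table(
            group_means,
            group_sizes,
            PYRO_SD,
            seeds[2] + pi,
            sample_ids=sample_ids,
        )

    stage_groups = list(STAGE_SIZES)
    cutoffs: dict[str, float] = {}
    roc_details: dict[str, dict] = {}
    tissue_tests: dict[str, dict] = {}
    stage_results: dict[str, dict] = {}
    for probe, tab in tables.items():
        tn = tab[tab["group"].isin(stage_groups)]["percent"].to_numpy()
        nn = tab[tab["group"] == "N"]["percent"].to_numpy()
        bc = tab[tab["group"] == "BC"]["percent"].to_numpy()
        roc = roc_cutoff_max_lr_plus(
            np.concatenate([tn, nn]),
            [True] * len(tn) + [False] * len(nn),
            positive_direction="below",
        )
        cutoffs[probe] = roc.cutoff
        roc_details[probe] = roc.as_dict()
        tissue_tests[probe] = {
            "TNBC_vs_N": mann_whitney_u(tn, nn).as_dict(),
            "TNBC_vs_BC": mann_whitney_u(tn, bc).as_dict(),
        }
        stage_tab = tab[tab["group"].isin(["N", *stage_groups])]
        stage_results[probe] = stagewise_compare(stage_tab, "N").as_dict()

    # simultaneous-hypomethylation rule over N + TNBC samples
    rule_true: dict[str, str] = {}
    rule_pred: dict[str, str] = {}
    call_rows = []
    rule_samples = [(s, "N") for s in sample_ids["N"]] + [
        (s, "TNBC") for g in stage_groups for s in sample_ids[g]
    ]
    wide = {
        probe: tab.set_index("sample_id")["percent"] for probe, tab in tables.items()
    }
    for s, cls in rule_samples:
        values = {probe: float(wide[probe][s]) for probe in top_probes}
        positive = simultaneous_hypomethylation_rule(values, cutoffs)
        rule_true[s] = cls
        rule_pred[s] = "TNBC" if positive else "N"
        call_rows.append({"sample_id": s, "true_class": cls,
                          "call": rule_pred[s], **values})
    rule_metrics = classification_metrics(rule_true, rule_pred, "TNBC")
    pd.DataFrame(call_rows).to_csv(outdir / "calls.csv", index=False)

    # cfDNA contrast: plasma dilutes the tumour methylation shift
    cf_tests: dict[str, dict] = {}
    for pi, probe in enumerate(top_probes):
        mean_n = float(truth.class_means.loc[probe, "N"]) * 100.0
        mean_t = float(truth.class_means.loc[probe, "TNBC"]) * 100.0
        cf_mean_t = mean_n + CFDNA_ATTENUATION * (mean_t - mean_n)
        cf = simulate_methylation_percent_table(
            {"healthy": mean_n, "TNBC": cf_mean_t},
            CFDNA_SIZES,
            PYRO_SD,
            seeds[3] + pi,
        )
        h = cf[cf["group"] == "healthy"]["percent"].to_numpy()
        t = cf[cf["group"] == "TNBC"]["percent"].to_numpy()
        cf_tests[probe] = mann_whitney_u(t, h).as_dict()

    (outdir / "cutoffs.json").write_text(
        json.dumps(roc_details, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "tests.json").write_text(
        json.dumps(
            {
                "tissue": tissue_tests,
                "stagewise": stage_results,
                "cfdna": cf_tests,
                "multiplicity_adjustment": "none",
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    # ------------------------------------------------------------------ 6
    summary = {
        "seed": seed,
        "config": {
            "n_probes": n_probes,
            "n_planted_dmps": n_planted,
            "dmp_effect": dmp_effect,
            "dispersion": dispersion,
            "discovery_sizes": DISCOVERY_SIZES,
            "extension_sizes": EXTENSION_SIZES,
            "size_grid": list(res.config.size_grid),
            "k_grid": list(res.config.k_grid),
        },
        "discovery": {
            "signature_size": len(sig),
            "chosen_k": sig.metadata["chosen_k"],
            "oob_error_rate": res.cv_result.error_rate,
            "per_fold_size": res.cv_result.per_fold_size,
            "per_fold_k": res.cv_result.per_fold_k,
            "planted_jaccard": jaccard,
            "planted_recovered": len(planted & found),
        },
        "extension": {
            "lost_probe": lost_probe,
            "retained_probes": len(retained_sig),
            "segregation_failure": segregation_failure,
            "cluster_error_rate_overall": (
                metrics_all.error_rate if metrics_all else None
            ),
            "cluster_error_rate_extension": (
                metrics_ext.error_rate if metrics_ext else None
            ),
            "metrics_overall": metrics_all.as_dict() if metrics_all else None,
            "metrics_extension": metrics_ext.as_dict() if metrics_ext else None,
        },
        "biomarker": {
            "top_probes": top_probes,
            "cutoffs_percent": cutoffs,
            "rule_error_rate": rule_metrics.error_rate,
            "rule_metrics": rule_metrics.as_dict(),
            "cfdna_p_values": {p: cf_tests[p]["p_value"] for p in top_probes},
        },
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("demo complete in %.1fs", time.perf_counter() - t0)
    return summary
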