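"""End-to-end study pipelines: simulate, analyze, report.

Two entry points mirror the two halves of the experimental design:

- :func:`run_behavior_study`: simulate stimulation sessions, fit the
  psychometric variants with bootstrap tests, fit per-choice
  chronometric lines, and (optionally) run the eight-variant DDM
  comparison per session.
- :func:`run_recording_study`: generate a labeled neural population,
  run the window-wise regressions and fraction-significant curves, build
  activity vectors, cluster with model seeds, and quantify stability and
  spatial mixing.

Reports are JSON-serializable dicts; identical config + seed reproduce
identical numeric content.
"""

from __future__ import annotations

import logging

import numpy as np

from stndecide import behavior as bhv
from stndecide import neural
from stndecide.cluster import (
    build_activity_vectors,
    kmeans_fit,
    make_model_seeds,
    rand_index,
    silhouette,
    spatial_silhouette,
    stability_grid,
)
from stndecide.cluster.vectors import vector_matrix
from stndecide.config import config_hash, merge_config
from stndecide.ddm.fit import compare_models
from stndecide.ddm.params import DDMEffect, DDMParams
from stndecide.synth import (
    generate_recording_dataset,
    sample_spike_counts,
    simulate_ddm_trials,
)
from stndecide.synth.neurons import CANONICAL_WINDOWS

__all__ = ["run_behavior_study", "run_recording_study"]

logger = logging.getLogger(__name__)


def _provenance(cfg: dict) -> dict:
    from stndecide import __version__

    return {"config_hash": config_hash(cfg), "seed": cfg["seed"], "version": __version__}


def run_behavior_study(config: dict | None = None) -> dict:
    """Simulate and analyze stimulation sessions per the config."""
    cfg = merge_config(config) if not _is_merged(config) else config
    bc = cfg["behavior_study"]
    params = DDMParams(**bc["params"])
    effect = DDMEffect(**bc["effect"])
    rng = np.random.default_rng(cfg["seed"])

    sessions = []
    for s in range(bc["n_sessions"]):
        sid = f"session_{s:02d}"
        logger.info("behavior study: simulating %s", sid)
        trials = simulate_ddm_trials(
            params,
            effect,
            coherences=bc["coherences"],
            n_per_cond=bc["n_per_cond"],
            seed=int(rng.integers(2**31 - 1)),
            session_id=sid,
        )
        psych = {v: bhv.fit_logistic(trials, v) for v in bc["psychometric_variants"]}
        selected = min(
            psych.values(), key=lambda f: (round(f.aic, 9), len(f.params))
        )
        boot = bhv.bootstrap_estim_test(
            trials,
            selected.variant,
            n_shuffles=bc["n_shuffles"],
            seed=int(rng.integers(2**31 - 1)),
        )
        chrono = {
            ch: bhv.fit_rt_linear(trials, ch).to_dict() for ch in ("contra", "ipsi")
        }
        entry = {
            "session_id": sid,
            "n_trials": len(trials),
            "psychometric": {v: f.to_dict() for v, f in psych.items()},
            "selected_variant": selected.variant,
            "bootstrap": boot.to_dict(),
            "chronometric": chrono,
        }
        if bc["run_ddm_compare"]:
            logger.info("behavior study: DDM comparison for %s", sid)
            cm = compare_models(trials, seed=int(rng.integers(2**31 - 1)))
            entry["ddm_comparison"] = {
                "table": cm["table"].to_dict(orient="records"),
                "session_effect": cm["session_effect"],
                "group_flags": cm["group_flags"],
                "fits": {n: f.to_dict() for n, f in cm["fits"].items()},
            }
        sessions.append(entry)
    return {"kind": "behavior_study", "provenance": _provenance(cfg), "sessions": sessions}


def run_recording_study(config: dict | None = None) -> dict:
    """Generate and analyze a labeled synthetic population."""
    cfg = merge_config(config) if not _is_merged(config) else config
    rc = cfg["recording_study"]
    cl = rc["clustering"]
    rng = np.random.default_rng(cfg["seed"] + 1)

    logger.info("recording study: generating population")
    spikes, trials, templates = generate_recording_dataset(
        rc["n_per_cluster"],
        trials_per_cond=rc["trials_per_cond"],
        seed=int(rng.integers(2**31 - 1)),
        separation=rc["separation"],
    )
    truth = {t.neuron_id: t.true_cluster for t in templates}

    # running-window regressions on a motion-aligned grid
    step, width = rc["step_ms"], rc["window_ms"]
    starts = list(range(-step * 2, 600 + step, step))
    run_windows = [("motion", s, width) for s in starts]
    logger.info("recording study: sampling running windows")
    spikes_run = sample_spike_counts(
        templates, trials, windows=run_windows, seed=int(rng.integers(2**31 - 1))
    )
    rates = neural.compute_running_rates(
        spikes_run, trials, "motion", window_ms=width, correct_only=True
    )
    reg_coh = neural.regress_coherence(rates, trials)
    reg_rt = neural.regress_rt(rates, trials)
    fractions = {
        name: neural.fraction_significant(res, coef).to_dict(orient="records")
        for name, res, coef in (
            ("choice", reg_coh, "bChoice"),
            ("coh_contra", reg_coh, "bCohContra"),
            ("coh_ipsi", reg_coh, "bCohIpsi"),
            ("rt_contra", reg_rt, "bRTContra"),
            ("rt_ipsi", reg_rt, "bRTIpsi"),
        )
    }

    logger.info("recording study: clustering")
    vectors = build_activity_vectors(spikes, trials)
    X = vector_matrix(vectors)
    seeded = kmeans_fit(
        X, cl["k"], distance=cl["distance"], init=make_model_seeds(),
        seed=int(rng.integers(2**31 - 1)),
    )
    random_seeded = kmeans_fit(
        X, cl["k"], distance=cl["distance"], init="random", n_reps=cl["n_reps"],
        seed=int(rng.integers(2**31 - 1)),
    )
    truth_labels = np.array([truth[nid] for nid in vectors.index])
    sil = silhouette(X, seeded.assignments, distance=cl["distance"])
    locations = np.array(
        [t.location for t in templates if t.neuron_id in set(vectors.index)]
    )
    report = {
        "kind": "recording_study",
        "provenance": _provenance(cfg),
        "population": {
            "n_neurons": len(templates),
            "n_per_cluster": rc["n_per_cluster"],
            "n_vectors": len(vectors),
        },
        "fractions": fractions,
        "chance_level": neural.CHANCE_LEVEL,
        "clustering": {
            "k": cl["k"],
            "distance": cl["distance"],
            "seeded_assignments": seeded.assignments.tolist(),
            "rand_vs_truth": rand_index(seeded.assignments, truth_labels),
            "rand_seeded_vs_random": rand_index(
                seeded.assignments, random_seeded.assignments
            ),
            "mean_silhouette": float(np.mean(sil)),
            "n_negative_silhouette": int(np.sum(sil < 0)),
            "spatial_silhouette": spatial_silhouette(
                locations, seeded.assignments
            ),
        },
        "neuron_ids": list(vectors.index),
        "true_clusters": truth_labels.tolist(),
    }
    if cl["run_stability_grid"]:
        logger.info("recording study: stability grid")
        rep = stability_grid(
            X, n_runs=cl["n_runs"], n_reps=cl["n_reps"],
            seed=int(rng.integers(2**31 - 1)),
        )
        report["stability"] = rep.to_dict()
    return report


def _is_merged(config) -> bool:
    return isinstance(config, dict) and set(config) == {
        "seed",
        "behavior_study",
        "recording_study",
    }
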