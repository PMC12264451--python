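"""End-to-end study pipeline on a synthetic cohort.

Generates a normal-control reference and a two-group patient cohort,
propensity-matches the groups, builds each patient's individual metabolic
network and its 9 graph features, simulates and analyzes each patient's EEG
for the 13 RQA features, assembles the feature matrix, runs the paired
feature comparison on the matched pairs, and evaluates the classifier bench.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    MODEL_NAMES, ClassifierReport, FeatureMatrix, assemble_feature_matrix,
    crossval_evaluate, delong_compare,
)
from .graphs import DEFAULT_SPARSITY_GRID, graph_feature_profile
from .matching import MatchResult, balance_report, match_pairs, propensity_scores
from .metabolic import NCReference, build_individual_network, build_nc_reference
from .rqa import rqa_protocol
from .stats import paired_group_compare
from .synthetic import (
    CovariateImbalance, EffectSpec, PatientCohort, default_effect_specs,
    gen_eeg_recording, gen_nc_uptake, gen_patient_cohort,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "compute_feature_matrix"]


@dataclass
class StudyConfig:
    """Study conditions; defaults mirror the modeled clinical protocol."""

    n_nc: int = 52
    n_per_group: dict[str, int] | int = 25
    effect_specs: dict[str, EffectSpec] | None = None
    imbalance: CovariateImbalance | None = None
    # graph analysis
    sparsity_grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID
    n_rand: int = 100
    # EEG / RQA
    eeg_channels: int = 19
    eeg_fs: float = 500.0
    eeg_duration: float = 60.0
    eeg_determinism: dict[str, float] = field(
        default_factory=lambda: {"TLE": 0.55, "TPE": 0.45}
    )
    eeg_determinism_sd: float = 0.1  # between-subject spread
    rqa_n_iter: int = 1000
    rqa_embed_mode: str = "per_window"
    rr_target: float = 0.05
    # matching / CV
    caliper: float = 0.1
    cv_folds: int = 10

    @classmethod
    def desk_scale(cls, **overrides) -> "StudyConfig":
        """Reduced problem sizes for interactive and test runs."""
        defaults = dict(
            n_rand=10, eeg_channels=2, eeg_fs=128.0, eeg_duration=40.0,
            rqa_n_iter=20, rqa_embed_mode="per_channel",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class StudyResult:
    nc_ref: NCReference
    cohort: PatientCohort
    match: MatchResult
    balance: pd.DataFrame
    features: FeatureMatrix
    comparisons: pd.DataFrame
    reports: dict[str, ClassifierReport]
    delong: pd.DataFrame


def compute_feature_matrix(
    cohort: PatientCohort, nc_ref: NCReference, cfg: StudyConfig, seed: int
) -> FeatureMatrix:
    """9 graph + 13 RQA features for every patient in the cohort."""
    rng = np.random.default_rng(seed)
    graph_sets, rqa_sets = {}, {}
    for i, sid in enumerate(cohort.uptake.subject_ids):
        net = build_individual_network(cohort.uptake.values[i], nc_ref, subject_id=sid)
        graph_sets[sid] = graph_feature_profile(
            net, grid=cfg.sparsity_grid, n_rand=cfg.n_rand,
            seed=int(rng.integers(2**31)),
        )
        group = cohort.covariates.loc[sid, "group"]
        det = float(np.clip(
            rng.normal(cfg.eeg_determinism[group], cfg.eeg_determinism_sd), 0.0, 1.0
        ))
        rec = gen_eeg_recording(
            det, n_channels=cfg.eeg_channels,
            duration=cfg.eeg_duration, fs=cfg.eeg_fs,
            seed=int(rng.integers(2**31)),
        )
        rqa_sets[sid] = rqa_protocol(
            rec, n_iter=cfg.rqa_n_iter, seed=int(rng.integers(2**31)),
            rr_target=cfg.rr_target, embed_mode=cfg.rqa_embed_mode,
        )
    return assemble_feature_matrix(graph_sets, rqa_sets, cohort.covariates["group"])


def run_study(cfg: StudyConfig | None = None, seed: int = 0) -> StudyResult:
    cfg = cfg if cfg is not None else StudyConfig()
    rng = np.random.default_rng(seed)
    nc = gen_nc_uptake(cfg.n_nc, seed=int(rng.integers(2**31)))
    nc_ref = build_nc_reference(nc)
    specs = cfg.effect_specs if cfg.effect_specs is not None else default_effect_specs()
    cohort = gen_patient_cohort(
        cfg.n_per_group, specs=specs, seed=int(rng.integers(2**31)),
        imbalance=cfg.imbalance,
    )
    scores = propensity_scores(cohort.covariates)
    match = match_pairs(
        scores, cohort.covariates["group"], caliper=cfg.caliper,
        seed=int(rng.integers(2**31)),
    )
    balance = balance_report(cohort.covariates, match)
    features = compute_feature_matrix(cohort, nc_ref, cfg, int(rng.integers(2**31)))

    case_ids = [p[0] for p in match.pairs]
    ctrl_ids = [p[1] for p in match.pairs]
    comparisons = paired_group_compare(
        features.X.loc[case_ids], features.X.loc[ctrl_ids],
        seed=int(rng.integers(2**31)),
    )

    cv_seed = int(rng.integers(2**31))
    reports = {
        m: crossval_evaluate(features, m, k=cfg.cv_folds, seed=cv_seed)
        for m in MODEL_NAMES
    }
    rows = []
    y = features.y.to_numpy()
    for m in MODEL_NAMES:
        if m == "xgboost":
            continue
        auc_a, auc_b, z, p = delong_compare(
            reports["xgboost"].scores, reports[m].scores, y
        )
        rows.append({"model": m, "auc_xgboost": auc_a, "auc_other": auc_b,
                     "z": z, "p": p})
    delong = pd.DataFrame(rows).set_index("model") if rows else pd.DataFrame()
    return StudyResult(
        nc_ref=nc_ref, cohort=cohort, match=match, balance=balance,
        features=features, comparisons=comparisons, reports=reports,
        delong=delong,
    )
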