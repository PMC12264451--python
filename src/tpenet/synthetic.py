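"""Synthetic cohorts: normal-control PET uptake, patient groups with implanted
network effects, scalp-EEG-like signals and clinical covariates.

The generator encodes the study conditions the downstream pipeline is built
for: a normal-control (NC) cohort with modular interregional uptake
covariance, two patient groups (temporal lobe epilepsy, TLE, and
temporal-plus epilepsy, TPE) sharing focal hypometabolism but differing in
how strongly insular connectivity is attenuated, EEG as a mixture of a
chaotic deterministic source and filtered noise, and covariates with
controllable group imbalance so propensity matching has work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import butter, sosfiltfilt

from . import atlas

__all__ = [
    "UptakeMatrix",
    "EffectSpec",
    "EEGRecording",
    "CorrelationSpec",
    "PatientCohort",
    "default_corr_spec",
    "default_effect_specs",
    "strong_effect_specs",
    "null_effect_specs",
    "gen_nc_uptake",
    "gen_patient_cohort",
    "gen_eeg_recording",
]


@dataclass
class UptakeMatrix:
    """Subjects x 56 regional uptake intensities."""

    values: np.ndarray
    region_labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != atlas.N_REGIONS:
            raise ValueError(
                f"uptake matrix must be subjects x {atlas.N_REGIONS}, "
                f"got {self.values.shape}"
            )
        if len(self.region_labels) != atlas.N_REGIONS:
            raise ValueError("need exactly 56 region labels")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("uptake values must be finite and positive")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.region_labels
        )


@dataclass
class EffectSpec:
    """Implanted group effect: focal uptake shift plus connectivity attenuation.

    ``uptake_shift`` is in NC z-units (negative = hypometabolism) applied to
    ``affected_regions``; ``decorrelation_strength`` s in [0, 1] replaces a
    fraction of each decorrelated region's shared variance by an independent
    focal-disease component of scale ``disease_scale`` (in NC z-units),
    attenuating the region's correlations with the rest of the brain and --
    when the scale exceeds 1 -- adding patient-to-patient heterogeneity in
    how deeply the region is involved.
    """

    group_label: str
    affected_regions: list[int] = field(default_factory=list)
    uptake_shift: float = 0.0
    decorrelated_regions: list[int] | None = None
    decorrelation_strength: float = 0.0
    disease_scale: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decorrelation_strength <= 1.0:
            raise ValueError("decorrelation_strength must lie in [0, 1]")
        if self.decorrelated_regions is None:
            self.decorrelated_regions = list(self.affected_regions)
        for idx in list(self.affected_regions) + list(self.decorrelated_regions):
            if not 0 <= idx < atlas.N_REGIONS:
                raise ValueError(f"region index {idx} outside 0..{atlas.N_REGIONS - 1}")


@dataclass
class EEGRecording:
    """Channels x samples scalp signal in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] < 1:
            raise ValueError("at least one channel required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class CorrelationSpec:
    """Block-diagonal-plus-baseline NC correlation prior.

    R = baseline * J + sum_k (r_k - baseline) * J_block_k + (1 - r_k) * I on
    the block diagonal; positive semi-definite by construction whenever
    0 <= baseline <= r_k <= 1 and blocks are disjoint.
    """

    baseline: float = 0.15
    blocks: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        n = atlas.N_REGIONS
        R = np.full((n, n), self.baseline)
        seen = np.zeros(n, dtype=bool)
        for idx, (members, r) in enumerate(self.blocks):
            members = np.asarray(members, dtype=int)
            if seen[members].any():
                raise ValueError(f"block {idx} overlaps a previous block")
            seen[members] = True
            R[np.ix_(members, members)] = r
        np.fill_diagonal(R, 1.0)
        self._check_psd(R)
        return R

    def _check_psd(self, R: np.ndarray) -> None:
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            # locate the offending block for the diagnostic
            for idx, (members, r) in enumerate(self.blocks):
                members = np.asarray(members, dtype=int)
                sub = R[np.ix_(members, members)]
                if np.linalg.eigvalsh(sub).min() < -1e-10 or r < self.baseline:
                    raise ValueError(
                        f"correlation spec is not positive semi-definite; "
                        f"offending block: {idx} (r={r}, baseline={self.baseline})"
                    )
            raise ValueError(
                "correlation spec is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )


def default_corr_spec() -> CorrelationSpec:
    """Lobe-block NC prior: within-lobe r=0.5 over a 0.15 baseline."""
    blocks = [(idx, 0.5) for idx in atlas.LOBE_SLICES.values()]
    return CorrelationSpec(baseline=0.15, blocks=blocks)


def default_effect_specs(
    shift: float = -1.5,
    tle_decorrelation: float = 0.25,
    tpe_decorrelation: float = 0.6,
    disease_scale: float = 2.0,
) -> dict[str, EffectSpec]:
    """Group effects: shared focal hypometabolism, group-graded insular
    decorrelation (TPE stronger, recruiting opercular neighbors)."""
    return {
        "TLE": EffectSpec(
            group_label="TLE",
            affected_regions=list(atlas.HYPOMETABOLIC_REGIONS),
            uptake_shift=shift,
            decorrelated_regions=list(atlas.TLE_DECORRELATED),
            decorrelation_strength=tle_decorrelation,
            disease_scale=disease_scale,
        ),
        "TPE": EffectSpec(
            group_label="TPE",
            affected_regions=list(atlas.HYPOMETABOLIC_REGIONS),
            uptake_shift=shift,
            decorrelated_regions=list(atlas.TPE_DECORRELATED),
            decorrelation_strength=tpe_decorrelation,
            disease_scale=disease_scale,
        ),
    }


def strong_effect_specs() -> dict[str, EffectSpec]:
    """Fully expressed insular phenotype for sensitivity analyses: the TPE
    group's insular/opercular variance is entirely replaced by a focal
    disease component of 6 NC-SD scale, the TLE group's is untouched."""
    return default_effect_specs(
        tle_decorrelation=0.0, tpe_decorrelation=1.0, disease_scale=6.0
    )


def null_effect_specs() -> dict[str, EffectSpec]:
    """All effects zeroed: both groups are NC-like draws."""
    return default_effect_specs(
        shift=0.0, tle_decorrelation=0.0, tpe_decorrelation=0.0
    )


def _draw_uptake(
    n: int,
    R: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
    spec: EffectSpec | None = None,
) -> np.ndarray:
    L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
    Z = rng.standard_normal((n, R.shape[0])) @ L.T
    if spec is not None and spec.decorrelation_strength > 0:
        d = np.asarray(spec.decorrelated_regions, dtype=int)
        s = spec.decorrelation_strength
        eta = spec.disease_scale * rng.standard_normal((n, d.size))
        Z[:, d] = np.sqrt(1.0 - s) * Z[:, d] + np.sqrt(s) * eta
    if spec is not None and spec.affected_regions:
        Z[:, np.asarray(spec.affected_regions, dtype=int)] += spec.uptake_shift
    X = mu + sigma * Z
    return np.maximum(X, 0.02)  # uptake intensities floored at positivity


def gen_nc_uptake(
    n_subjects: int,
    corr_spec: CorrelationSpec | None = None,
    seed: int = 0,
) -> UptakeMatrix:
    """Draw a normal-control uptake cohort from the block-structured prior."""
    if n_subjects < 10:
        raise ValueError("need at least 10 NC subjects")
    corr_spec = corr_spec if corr_spec is not None else default_corr_spec()
    R = corr_spec.matrix()
    mu, sigma = atlas.reference_means_sds()
    rng = np.random.default_rng(seed)
    X = _draw_uptake(n_subjects, R, mu, sigma, rng)
    ids = [f"NC{i:03d}" for i in range(n_subjects)]
    return UptakeMatrix(X, list(atlas.REGION_LABELS), ids)


@dataclass
class PatientCohort:
    uptake: UptakeMatrix
    covariates: pd.DataFrame  # gender, soz_side, age_onset, duration, group


@dataclass
class CovariateImbalance:
    """Additive shifts applied to the TLE group's covariate distribution."""

    age_onset_shift: float = 0.0
    duration_shift: float = 0.0
    gender_p_shift: float = 0.0


def _draw_covariates(
    n: int, group: str, rng: np.random.Generator, imbalance: CovariateImbalance
) -> pd.DataFrame:
    shift_age = imbalance.age_onset_shift if group == "TLE" else 0.0
    shift_dur = imbalance.duration_shift if group == "TLE" else 0.0
    shift_p = imbalance.gender_p_shift if group == "TLE" else 0.0
    gender = rng.binomial(1, min(max(0.5 + shift_p, 0.05), 0.95), size=n)
    soz_side = rng.binomial(1, 0.7, size=n)  # right-lateralized majority
    age_onset = np.clip(rng.normal(10.0 + shift_age, 7.5, size=n), 0.5, None)
    duration = np.clip(rng.normal(11.0 + shift_dur, 7.0, size=n), 0.5, None)
    return pd.DataFrame(
        {
            "gender": gender,
            "soz_side": soz_side,
            "age_onset": age_onset,
            "duration": duration,
            "group": group,
        }
    )


def gen_patient_cohort(
    n_per_group: dict[str, int] | int,
    specs: dict[str, EffectSpec] | None = None,
    corr_spec: CorrelationSpec | None = None,
    seed: int = 0,
    imbalance: CovariateImbalance | None = None,
) -> PatientCohort:
    """Generate patient uptake + covariates with implanted group effects.

    ``n_per_group`` may be a single count (both groups) or a mapping
    {"TLE": n1, "TPE": n2}; unequal sizes emulate the pre-matching cohort.
    """
    specs = specs if specs is not None else default_effect_specs()
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in specs}
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"group {g}: need >= 2 subjects for matching and CV")
        if g not in specs:
            raise ValueError(f"no effect spec for group {g}")
    corr_spec = corr_spec if corr_spec is not None else default_corr_spec()
    imbalance = imbalance if imbalance is not None else CovariateImbalance()
    R = corr_spec.matrix()
    mu, sigma = atlas.reference_means_sds()
    rng = np.random.default_rng(seed)
    values, ids, cov_frames = [], [], []
    for g in sorted(n_per_group):
        n = n_per_group[g]
        grp_rng = np.random.default_rng(rng.integers(2**31))
        values.append(_draw_uptake(n, R, mu, sigma, grp_rng, specs[g]))
        ids.extend(f"{g}{i:03d}" for i in range(n))
        cov_frames.append(_draw_covariates(n, g, grp_rng, imbalance))
    X = np.vstack(values)
    cov = pd.concat(cov_frames, ignore_index=True)
    cov.index = pd.Index(ids, name="subject_id")
    return PatientCohort(UptakeMatrix(X, list(atlas.REGION_LABELS), ids), cov)


def _lorenz_source(n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Integrate a time-rescaled Lorenz system; returns 3 x n_samples.

    The attractor's lobe oscillation (~1.3 Hz in natural time at the classic
    sigma=10, rho=28, beta=8/3 parameters) is sped up to sit near 8 Hz, inside
    the EEG alpha band.
    """
    speed = 6.0
    t_end = n_samples / fs * speed
    x0 = rng.normal([1.0, 1.0, 25.0], 0.5)

    def f(_t, s):
        x, y, z = s
        return [10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z]

    # settle onto the attractor first; tolerances loose enough for speed --
    # only the statistical character of the trajectory matters here
    warm = solve_ivp(f, (0, 20.0), x0, rtol=1e-6, atol=1e-6)
    t_eval = np.arange(n_samples) / fs * speed
    sol = solve_ivp(f, (0, t_end), warm.y[:, -1], t_eval=t_eval,
                    rtol=1e-6, atol=1e-6)
    return sol.y


def gen_eeg_recording(
    determinism_level: float,
    n_channels: int = 19,
    duration: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
) -> EEGRecording:
    """EEG-like mixture of a shared chaotic source and filtered noise.

    Each channel is ``d * source + (1 - d) * noise`` with both parts scaled to
    unit variance; channels see the 3-dimensional source through a random
    mixing matrix, so the deterministic component is shared but not identical
    across the montage.
    """
    if not 0.0 <= determinism_level <= 1.0:
        raise ValueError("determinism_level must lie in [0, 1]")
    if fs < 60.0:
        raise ValueError("sampling rate too low to represent the source band")
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    d = determinism_level

    channels = np.zeros((n_channels, n_samples))
    if d > 0:
        src = _lorenz_source(n_samples, fs, rng)
        src = (src - src.mean(axis=1, keepdims=True)) / src.std(axis=1, keepdims=True)
        mix = rng.normal(size=(n_channels, 3))
        mix /= np.linalg.norm(mix, axis=1, keepdims=True)
        det_part = mix @ src
        det_part /= det_part.std(axis=1, keepdims=True)
        channels += d * det_part
    if d < 1:
        sos = butter(4, [1.0, min(30.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
        noise = sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples)), axis=1)
        noise /= noise.std(axis=1, keepdims=True)
        channels += (1 - d) * noise
    channels *= 20.0  # microvolt scale
    labels = [f"CH{i:02d}" for i in range(n_channels)]
    return EEGRecording(channels, fs, labels)
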