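"""Individual metabolic brain networks from regional FDG-PET uptake.

A subject's network is the normal-control (NC) Pearson correlation matrix,
edge-wise attenuated by how discordantly the two endpoint regions deviate
from the NC mean: W_ij = w(|e_i - e_j|) * R_ij, where e is the subject's
regional z-score vector against the NC cohort and the default kernel is
w(d) = exp(-d). A subject sitting exactly at the NC mean reproduces R; the
more two regions' deviations disagree, the weaker their retained edge. The
kernel is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import atlas
from .synthetic import UptakeMatrix

__all__ = [
    "NCReference",
    "IndividualNetwork",
    "build_nc_reference",
    "subject_effect_sizes",
    "build_individual_network",
]


@dataclass
class NCReference:
    """NC region means, SDs and Pearson correlation matrix."""

    mu: np.ndarray
    sigma: np.ndarray
    R: np.ndarray
    n_nc: int
    region_labels: list[str]

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("all region SDs must be positive")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")


@dataclass
class IndividualNetwork:
    """Weighted symmetric 56x56 network, zero diagonal."""

    W: np.ndarray
    subject_id: str
    region_labels: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.W)):
            raise ValueError("network weights must be finite")


def build_nc_reference(nc: UptakeMatrix) -> NCReference:
    """Columnwise mean/SD and full pairwise Pearson matrix of the NC cohort."""
    if nc.n_subjects < 10:
        raise ValueError("need at least 10 NC subjects")
    X = nc.values
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance region(s): {[nc.region_labels[i] for i in dead]}"
        )
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0  # BLAS reductions are not bitwise symmetric
    np.fill_diagonal(R, 1.0)
    return NCReference(
        mu=X.mean(axis=0), sigma=sd, R=R, n_nc=nc.n_subjects,
        region_labels=list(nc.region_labels),
    )


def subject_effect_sizes(x: np.ndarray, ref: NCReference) -> np.ndarray:
    """Regional deviation e_i = (x_i - mu_i) / sigma_i in NC z-units."""
    x = np.asarray(x, dtype=float)
    if x.shape != ref.mu.shape:
        raise ValueError(f"expected {ref.mu.shape[0]} regional values, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("uptake values must be finite")
    return (x - ref.mu) / ref.sigma


def build_individual_network(
    x: np.ndarray,
    ref: NCReference,
    subject_id: str = "subject",
    kernel: Callable[[np.ndarray], np.ndarray] = None,
) -> IndividualNetwork:
    """W_ij = kernel(|e_i - e_j|) * R_ij, diagonal zeroed.

    The default kernel exp(-d) maps concordant deviation (d=0) to full
    preservation of the NC edge and discordant deviation to attenuation,
    so |W_ij| <= |R_ij| always.
    """
    if kernel is None:
        kernel = lambda d: np.exp(-d)  # noqa: E731
    e = subject_effect_sizes(x, ref)
    D = np.abs(e[:, None] - e[None, :])
    W = kernel(D) * ref.R
    np.fill_diagonal(W, 0.0)
    return IndividualNetwork(W=W, subject_id=subject_id, region_labels=ref.region_labels)


def cohort_networks(
    uptake: UptakeMatrix, ref: NCReference
) -> list[IndividualNetwork]:
    """Individual network for every row of an uptake cohort."""
    return [
        build_individual_network(uptake.values[i], ref, subject_id=sid)
        for i, sid in enumerate(uptake.subject_ids)
    ]
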