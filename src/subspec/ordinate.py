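"""Principal coordinates analysis (PCoA) of sample dissimilarities.

Classical metric scaling: the squared distance matrix is double-centered
(B = -1/2 J D^2 J) and eigendecomposed; coordinates are eigenvectors scaled
by the square roots of the eigenvalues.  Negative eigenvalues — which arise
because the allele-frequency Manhattan distance is not Euclidean — are
dropped and their magnitude reported rather than corrected.

New points (low-coverage samples or reference-genome allele profiles) are
projected into an existing ordination with the Gower out-of-sample formula
from their distances to the training samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["Ordination", "pcoa", "project", "genome_profile"]


@dataclass
class Ordination:
    """PCoA result; axes ordered by decreasing eigenvalue."""

    samples: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues kept, decreasing
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalue_mass: float
    eigenvectors: np.ndarray  # samples x axes, unit norm (for projection)
    mean_sq_distance: np.ndarray  # column means of squared training D


def pcoa(dm: DistanceMatrix | np.ndarray, n_axes: int | None = None) -> Ordination:
    """Classical scaling of a complete distance matrix."""
    if isinstance(dm, DistanceMatrix):
        if not dm.is_complete:
            raise ValueError("PCoA requires a complete distance matrix")
        d = dm.d
        samples = list(dm.samples)
    else:
        d = np.asarray(dm, dtype=float)
        samples = [f"s{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0)
    pos = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    eigvals_pos = eigvals[pos]
    eigvecs_pos = eigvecs[:, pos]
    if n_axes is not None and n_axes > eigvals_pos.size:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes, eigvals_pos.size,
        )
    n_keep = eigvals_pos.size if n_axes is None else min(n_axes, eigvals_pos.size)
    eigvals_kept = eigvals_pos[:n_keep]
    eigvecs_kept = eigvecs_pos[:, :n_keep]
    coords = eigvecs_kept * np.sqrt(eigvals_kept)
    return Ordination(
        samples=samples,
        coordinates=coords,
        eigenvalues=eigvals_kept,
        proportion_explained=eigvals_kept / eigvals_pos.sum(),
        negative_eigenvalue_mass=neg_mass,
        eigenvectors=eigvecs_kept,
        mean_sq_distance=d2.mean(axis=0),
    )


def project(ordination: Ordination, d_new: np.ndarray) -> np.ndarray:
    """Project a new point from its distances to all training samples.

    Gower's formula: the coordinate on axis a is
    -1/2 * v_a . (d_new^2 - mean training d^2) / sqrt(lambda_a).
    Projecting a training sample's own distance row reproduces its
    coordinates.
    """
    d_new = np.asarray(d_new, dtype=float)
    if d_new.shape != (len(ordination.samples),):
        raise ValueError("d_new must hold one distance per training sample")
    if np.isnan(d_new).any():
        raise ValueError("d_new contains missing distances")
    if (ordination.eigenvalues <= 0).any():
        raise ValueError("projection requires positive-eigenvalue axes only")
    delta = d_new**2 - ordination.mean_sq_distance
    return -0.5 * (ordination.eigenvectors.T @ delta) / np.sqrt(
        ordination.eigenvalues
    )


_STATE_TO_FREQ = {"ref": 0.0, "alt": 1.0, "uncovered": np.nan}


def genome_profile(alleles: Sequence[str] | Mapping[object, str]) -> np.ndarray:
    """Allele-frequency vector for a sequenced genome.

    A genome carrying the non-reference allele at a position has frequency
    1.0 there, 0.0 where it matches the reference, and missing where the
    position is uncovered.  The result is directly comparable to a sample's
    variation profile (usable by ``allele_distance`` and :func:`project`).
    """
    states = (
        list(alleles.values()) if isinstance(alleles, Mapping) else list(alleles)
    )
    out = np.empty(len(states))
    for i, st in enumerate(states):
        if st not in _STATE_TO_FREQ:
            raise ValueError(
                f"allele state {st!r} at index {i} matches neither ref, alt "
                "nor uncovered"
            )
        out[i] = _STATE_TO_FREQ[st]
    return out
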