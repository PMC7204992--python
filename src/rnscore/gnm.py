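"""Gaussian Network Model analysis of Cα structures.

The GNM represents a protein as an elastic network with one node per Cα:
residues closer than a cutoff distance (7.3 Å by default) are connected
by identical springs. The Kirchhoff (contact Laplacian) matrix Γ has
Γ_ij = −1 for contacting pairs and contact degrees on the diagonal. Its
eigendecomposition gives the vibrational spectrum: zero modes correspond
to connected components of the contact graph, the smallest nonzero
eigenvalues ("slow modes") describe the most collective motions, and
mean-square fluctuations are MSF_i ∝ Σ_k v_ki² / λ_k over nonzero modes.

Hinge sites — mechanically pivotal residues proposed as drug-targeting
sites — are read off a slow mode's squared shape profile: prominent
strict local minima below the profile mean, plus residues where the raw
mode component changes sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError, ValidationError
from .io import StructureModel

logger = logging.getLogger(__name__)

ZERO_TOL = 1e-8


@dataclass
class GNMResult:
    """Spectrum and shape profiles of one GNM.

    ``eigenvalues`` ascend with the zero modes first; ``modes`` holds the
    matching orthonormal eigenvectors as columns, signs fixed so each
    vector's largest-magnitude component is positive. ``msf`` is the
    unnormalized mean-square fluctuation profile.
    """

    cutoff: float
    kirchhoff: np.ndarray
    eigenvalues: np.ndarray
    modes: np.ndarray
    n_zero_modes: int
    msf: np.ndarray

    def slow_mode(self, mode_index: int = 1) -> np.ndarray:
        """Raw shape of the ``mode_index``-th nonzero mode (1 = slowest)."""
        if not 1 <= mode_index <= self.n_nonzero:
            raise ParameterError(
                f"mode_index {mode_index} outside 1..{self.n_nonzero}"
            )
        return self.modes[:, self.n_zero_modes + mode_index - 1]

    def squared_shape(self, mode_index: int = 1) -> np.ndarray:
        return np.square(self.slow_mode(mode_index))

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero_modes


@dataclass
class HingeReport:
    """Hinge residues of one slow mode: indices into the residue list."""

    mode_index: int
    hinges: list[int]
    shape_values: list[float]


def kirchhoff_matrix(structure: StructureModel, cutoff: float = 7.3) -> np.ndarray:
    """Contact Laplacian: Γ_ij = −1 iff |r_i − r_j| ≤ cutoff (i ≠ j)."""
    if len(structure) < 2:
        raise ValidationError("need at least two residues")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    dists = squareform(pdist(structure.coords))
    contact = (dists <= cutoff).astype(float)
    np.fill_diagonal(contact, 0.0)
    gamma = -contact
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return gamma


def gnm_modes(kirchhoff: np.ndarray, n_modes: int | None = None) -> GNMResult:
    """Full eigendecomposition of a Kirchhoff matrix.

    ``n_modes`` limits the *reported* slow modes (clamped with a warning
    when it exceeds the number of nonzero modes); the spectrum itself is
    always complete so the invariants (trace identity, zero-mode count)
    are exact.
    """
    gamma = np.asarray(kirchhoff, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValidationError("kirchhoff must be square")
    if not np.allclose(gamma, gamma.T):
        raise ValidationError("kirchhoff must be symmetric")
    if not np.allclose(gamma.sum(axis=1), 0.0, atol=1e-9):
        raise ValidationError("kirchhoff rows must sum to zero")
    evals, evecs = eigh(gamma)
    evals = np.where(np.abs(evals) < ZERO_TOL, 0.0, evals)
    n_zero = int(np.sum(evals == 0.0))
    # deterministic sign: largest-|component| entry positive (first on ties)
    for k in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    nonzero = evals > 0
    msf = np.einsum("ik,k->i", np.square(evecs[:, nonzero]), 1.0 / evals[nonzero])
    n_nonzero = int(nonzero.sum())
    if n_modes is not None and n_modes > n_nonzero:
        logger.warning("n_modes=%d clamped to %d nonzero modes", n_modes, n_nonzero)
    return GNMResult(
        cutoff=np.nan,
        kirchhoff=gamma,
        eigenvalues=evals,
        modes=evecs,
        n_zero_modes=n_zero,
        msf=msf,
    )


def gnm_analyze(structure: StructureModel, cutoff: float = 7.3,
                n_modes: int | None = None) -> GNMResult:
    """Convenience wrapper: Kirchhoff matrix then mode decomposition."""
    result = gnm_modes(kirchhoff_matrix(structure, cutoff), n_modes)
    result.cutoff = cutoff
    return result


def find_hinges(
    result: GNMResult, mode_index: int = 1, min_prominence: float | None = None
) -> HingeReport:
    """Hinge residues of one slow mode.

    A residue is a hinge when it is a strict local minimum of the squared
    shape profile, lies below the profile mean, and the profile maxima on
    both sides of it exceed it by at least ``min_prominence``
    (default: 10% of the profile range) — or when the raw mode component
    changes sign there (the residue nearer zero of a sign-flipping
    adjacent pair, and any residue with an exactly/numerically zero
    component). A flat profile yields no hinges.
    """
    shape = result.squared_shape(mode_index)
    raw = result.slow_mode(mode_index)
    n = len(shape)
    rng = float(shape.max() - shape.min())
    if rng <= ZERO_TOL:
        return HingeReport(mode_index=mode_index, hinges=[], shape_values=[])
    if min_prominence is None:
        min_prominence = 0.1 * rng
    mean = float(shape.mean())

    hinges: set[int] = set()
    for i in range(1, n - 1):
        if not (shape[i] < shape[i - 1] and shape[i] < shape[i + 1]):
            continue
        if shape[i] >= mean:
            continue
        left_max = max(shape[:i])
        right_max = max(shape[i + 1:])
        if left_max - shape[i] >= min_prominence and right_max - shape[i] >= min_prominence:
            hinges.add(i)
    # sign crossings of the raw mode always count as hinges
    near_zero = np.abs(raw) < ZERO_TOL * max(1.0, float(np.abs(raw).max()))
    for i in np.flatnonzero(near_zero):
        hinges.add(int(i))
    for i in range(n - 1):
        if raw[i] * raw[i + 1] < 0:
            hinges.add(i if abs(raw[i]) <= abs(raw[i + 1]) else i + 1)
    ordered = sorted(hinges)
    return HingeReport(
        mode_index=mode_index,
        hinges=ordered,
        shape_values=[float(shape[i]) for i in ordered],
    )
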