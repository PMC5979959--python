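"""Calpha elastic-network normal-mode analysis.

The protein is modeled as an anisotropic network model (ANM): one node per
Calpha, uniform-stiffness springs between all node pairs closer than a cutoff
(default 10 A).  The 3Nx3N Hessian of this harmonic system has six zero
eigenvalues (rigid-body translations/rotations of a connected network); the
lowest non-trivial eigenvectors - "mode 7" onward in the numbering used
throughout structural biology - describe the softest internal deformations
and typically localize on functionally relevant flexible regions.

The per-pair Hessian super-element is -gamma/d^2 * (dr dr^T), i.e. spring
stiffness normalized by the squared equilibrium distance, a common ANM
convention; eigenvalues therefore carry arbitrary units and only relative
magnitudes and eigenvector shapes are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .structmap import StructureModel

__all__ = [
    "ENMParameters",
    "ModeSet",
    "FluctuationProfile",
    "build_hessian",
    "solve_modes",
    "compute_modes",
    "mode_fluctuations",
    "flexible_region",
    "displaced_conformers",
    "contact_deviation",
]

RIGID_BODY_MODES = 6
_ZERO_MODE_RTOL = 1e-8


@dataclass(frozen=True)
class ENMParameters:
    """Elastic-network parameters.

    ``cutoff``: spring interaction distance in angstrom.  ``gamma``: uniform
    spring constant (arbitrary units; rescales eigenvalues only).
    ``n_modes``: number of lowest modes to keep (must reach past the six
    rigid-body modes for any flexibility analysis).  ``amplitude``: default
    Calpha displacement amplitude (angstrom) for conformer generation.
    """

    cutoff: float = 10.0
    gamma: float = 1.0
    n_modes: int = 20
    amplitude: float = 3.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_modes < RIGID_BODY_MODES + 1:
            raise ValueError("need at least 7 modes for any flexibility analysis")


@dataclass
class ModeSet:
    """Eigenvalues (ascending) and orthonormal eigenvectors of the ENM Hessian.

    ``eigenvectors`` has shape (3N, k); mode numbering is 1-based, so mode 7
    is the first internal mode (columns 0..5 are the rigid-body space).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_nodes: int

    def mode(self, number: int) -> tuple[float, np.ndarray]:
        """Eigenpair for a 1-based mode number; mode 7 = first internal."""
        if not 1 <= number <= len(self.eigenvalues):
            raise IndexError(f"mode {number} outside computed range")
        return float(self.eigenvalues[number - 1]), self.eigenvectors[:, number - 1]

    @property
    def n_near_zero(self) -> int:
        """Number of near-zero (rigid-body) eigenvalues."""
        if len(self.eigenvalues) <= RIGID_BODY_MODES:
            return int(np.sum(np.abs(self.eigenvalues) < 1e-10))
        scale = abs(self.eigenvalues[RIGID_BODY_MODES])
        if scale == 0:
            return len(self.eigenvalues)
        return int(np.sum(np.abs(self.eigenvalues) < _ZERO_MODE_RTOL * scale))


@dataclass
class FluctuationProfile:
    """Per-residue Calpha displacement magnitudes for a mode (or mode range)."""

    residue_numbers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.residue_numbers) != len(self.values):
            raise ValueError("length mismatch")


def _model_nodes(model: StructureModel) -> tuple[np.ndarray, list[int]]:
    coords = []
    numbers = []
    for cid in model.chain_ids:
        for num, (_, xyz) in model.chains[cid].items():
            coords.append(xyz)
            numbers.append(num)
    return np.asarray(coords, dtype=float), numbers


def build_hessian(model: "StructureModel | np.ndarray",
                  p: ENMParameters = ENMParameters()) -> np.ndarray:
    """Assemble the 3Nx3N ANM Hessian for a Calpha model.

    Off-diagonal super-element for a pair (i, j) within the cutoff:
    ``-gamma/d_ij^2 * dr dr^T``; diagonal blocks are the negative sums of the
    off-diagonal blocks in their row, making the matrix symmetric positive
    semidefinite with the rigid-body null space.
    """
    coords = model if isinstance(model, np.ndarray) else _model_nodes(model)[0]
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 nodes")
    diff = coords[:, None, :] - coords[None, :, :]  # (n, n, 3)
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    within = d2 <= p.cutoff**2
    H = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(within)
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        dr = diff[i, j]
        block = -(p.gamma / d2[i, j]) * np.outer(dr, dr)
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    # connectivity check: every node needs at least one spring
    degree = within.sum(axis=1)
    if np.any(degree == 0):
        warnings.warn(
            "elastic network is disconnected (isolated nodes); expect more than "
            "six near-zero modes"
        )
    return H


def solve_modes(hessian: np.ndarray, k: int) -> "ModeSet":
    """Lowest ``k`` eigenpairs of the Hessian, ascending."""
    n3 = hessian.shape[0]
    if k > n3:
        raise ValueError(f"requested {k} modes from a {n3}-dimensional operator")
    vals, vecs = scipy.linalg.eigh(hessian, subset_by_index=(0, k - 1))
    return ModeSet(vals, vecs, n_nodes=n3 // 3)


def compute_modes(model: StructureModel, p: ENMParameters = ENMParameters()) -> ModeSet:
    """Convenience: Hessian assembly plus eigendecomposition."""
    H = build_hessian(model, p)
    modes = solve_modes(H, min(p.n_modes, H.shape[0]))
    if modes.n_near_zero != RIGID_BODY_MODES:
        warnings.warn(
            f"{modes.n_near_zero} near-zero modes (expected {RIGID_BODY_MODES}); "
            "the network may be disconnected"
        )
    return modes


def _per_residue_magnitude(vec: np.ndarray) -> np.ndarray:
    return np.linalg.norm(vec.reshape(-1, 3), axis=1)


def mode_fluctuations(modes: ModeSet, mode_numbers: "int | Sequence[int]",
                      residue_numbers: Optional[Sequence[int]] = None,
                      ) -> FluctuationProfile:
    """Per-residue displacement magnitude for one internal mode or a range.

    For a range the profiles are combined as a 1/lambda-weighted mean
    (thermal amplitudes of harmonic modes scale with the inverse eigenvalue,
    so softer modes dominate).
    """
    if isinstance(mode_numbers, int):
        mode_numbers = [mode_numbers]
    if any(m <= RIGID_BODY_MODES for m in mode_numbers):
        raise ValueError("modes 1-6 are rigid-body motions, not internal fluctuations")
    weights = []
    profiles = []
    for m in mode_numbers:
        lam, vec = modes.mode(m)
        weights.append(1.0 / lam)
        profiles.append(_per_residue_magnitude(vec))
    w = np.asarray(weights)
    prof = np.average(np.vstack(profiles), axis=0, weights=w)
    if residue_numbers is None:
        residue_numbers = np.arange(1, modes.n_nodes + 1)
    return FluctuationProfile(np.asarray(residue_numbers), prof)


def flexible_region(profile: FluctuationProfile, window: int = 11,
                    ) -> tuple[tuple[int, int], list[int]]:
    """Most flexible residue interval by sliding-window mean.

    Returns ``((first_residue, last_residue), peak_residues)`` where the
    interval is the ``window``-residue stretch with the highest mean
    fluctuation (ties resolved toward lower residue numbers) and
    ``peak_residues`` are the residue(s) attaining the profile maximum inside
    it.
    """
    n = len(profile.values)
    if window > n:
        raise ValueError("window longer than profile")
    means = np.convolve(profile.values, np.ones(window) / window, mode="valid")
    start = int(np.argmax(means))  # argmax returns the first maximum: low-residue tie rule
    idx = slice(start, start + window)
    seg = profile.values[idx]
    peak_val = seg.max()
    peaks = [int(profile.residue_numbers[start + i]) for i in np.flatnonzero(seg == peak_val)]
    interval = (int(profile.residue_numbers[start]), int(profile.residue_numbers[start + window - 1]))
    return interval, peaks


def displaced_conformers(model: StructureModel, modes: ModeSet, mode_number: int,
                         amplitude: float = 3.0) -> tuple[StructureModel, StructureModel]:
    """Conformer pair displaced by +/- amplitude along one internal mode.

    ``amplitude`` scales the unit-norm eigenvector, in angstrom; the per-node
    displacement is amplitude times the node's eigenvector magnitude.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if mode_number <= RIGID_BODY_MODES:
        raise ValueError("refusing to animate a rigid-body mode")
    _, vec = modes.mode(mode_number)
    disp = amplitude * vec.reshape(-1, 3)
    coords = model.all_coords()
    if len(coords) != modes.n_nodes:
        raise ValueError("model size does not match mode set")
    # single-chain assumption for conformers keeps the bookkeeping simple
    if len(model.chain_ids) != 1:
        raise ValueError("conformer generation expects a single-chain model")
    plus = model.with_coords(coords + disp)
    minus = model.with_coords(coords - disp)
    plus.model_id = f"{model.model_id}+m{mode_number}"
    minus.model_id = f"{model.model_id}-m{mode_number}"
    return plus, minus


def contact_deviation(conf_plus: StructureModel, conf_minus: StructureModel) -> np.ndarray:
    """Absolute pairwise-distance change |d+(i,j) - d-(i,j)| between conformers.

    Large rows/columns mark residues whose contacts rearrange most along the
    mode (hinges and mobile loops).
    """
    a = conf_plus.all_coords()
    b = conf_minus.all_coords()
    if a.shape != b.shape:
        raise ValueError("conformers have different residue sets")
    da = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=-1)
    db = np.linalg.norm(b[:, None, :] - b[None, :, :], axis=-1)
    return np.abs(da - db)
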