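"""Vibrational normal-mode analysis.

The harmonic vibrational problem is set up in mass-weighted coordinates
q = M^{1/2} x.  Six orthonormal vectors spanning global translation and
rotation (Sayvetz/Eckart conditions, rotations taken about the principal
axes of inertia through the centre of mass) are completed to a full
orthonormal 3N x 3N transformation matrix D by iterative Gram-Schmidt.  The
mass-weighted Hessian is transformed into this internal basis,
H_s = D^T H_q D, and diagonalized; the six near-zero eigenvalues are the
external modes and the remaining 3N-6 are the vibrations, with frequencies
nu_i = sqrt(lambda_i) expressed in cm^-1.

Conventions for derived per-mode quantities (stated explicitly because more
than one normalization is in circulation):

* the mode shape in Cartesian space is l_a = e_{(3a:3a+3)} / sqrt(m_a) with
  e the mass-weighted eigenvector;
* the reduced mass is mu_i = 1 / sum_a |l_{i,a}|^2 (with e normalized),
  i.e. the Gaussian-style convention;
* the force constant is k_i = lambda_i * mu_i.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import constants
from .chem_io import HessianMatrix, LabeledGeometry

__all__ = [
    "TransformationMatrix",
    "NormalModeSet",
    "LinearMoleculeError",
    "SaddlePointError",
    "mass_weight_hessian",
    "external_frame_vectors",
    "complete_basis",
    "internal_hessian",
    "eigensolve",
    "frequencies",
    "vibrational_analysis",
    "vibrational_report",
]

ORTHO_TOL = 1e-8  # orthonormality threshold for the transformation matrix


class LinearMoleculeError(ValueError):
    """Raised for (near-)linear molecules, which need 5 external modes."""


class SaddlePointError(ValueError):
    """Raised when a vibrational eigenvalue is negative (imaginary mode)."""


@dataclasses.dataclass
class TransformationMatrix:
    """Orthonormal 3N x 3N basis; the first 6 columns span translation/rotation."""

    D: np.ndarray
    external_count: int = 6

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = self.D.shape[0]
        if self.D.shape != (n, n):
            raise ValueError("transformation matrix must be square")
        gram = self.D.T @ self.D
        err = np.abs(gram - np.eye(n)).max()
        if err > ORTHO_TOL:
            raise ValueError(f"columns not orthonormal: max |D^T D - I| = {err:.2e}")


@dataclasses.dataclass
class NormalModeSet:
    """The 3N-6 vibrational modes of a nonlinear molecule."""

    eigenvalues: np.ndarray       # (n_vib,) hartree/(m_e bohr^2), ascending
    eigenvectors: np.ndarray      # (3N, n_vib) mass-weighted Cartesian, orthonormal
    frequencies: np.ndarray       # (n_vib,) cm^-1
    force_constants: np.ndarray   # (n_vib,) hartree/bohr^2 (Cartesian convention)
    reduced_masses: np.ndarray    # (n_vib,) electron masses

    @property
    def n_vib(self) -> int:
        return self.eigenvalues.size


def mass_weight_hessian(hessian: HessianMatrix, masses: np.ndarray) -> np.ndarray:
    """H_q[3a+i, 3b+j] = H[3a+i, 3b+j] / sqrt(m_a m_b), masses in m_e."""
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if masses.size != hessian.atom_count:
        raise ValueError("mass count does not match Hessian")
    w = 1.0 / np.sqrt(np.repeat(masses, 3))
    return hessian.values * np.outer(w, w)


def _inertia_principal_axes(geom: LabeledGeometry):
    r = geom.coords - geom.center_of_mass()
    m = geom.masses
    inertia = np.einsum("a,aij->ij", m, (
        np.einsum("a,ij->aij", (r ** 2).sum(axis=1), np.eye(3))
        - np.einsum("ai,aj->aij", r, r)
    ))
    moments, axes = np.linalg.eigh(inertia)
    return r, moments, axes


def external_frame_vectors(geom: LabeledGeometry) -> np.ndarray:
    """Six orthonormal mass-weighted vectors of global translation/rotation.

    Returns an array (3N, 6): columns 0-2 translations, 3-5 rotations about
    the principal axes of inertia through the centre of mass.
    """
    n = geom.n_atoms
    m = geom.masses
    r, moments, axes = _inertia_principal_axes(geom)
    if moments[0] < 1e-10 * moments[-1]:
        raise LinearMoleculeError(
            "smallest principal moment of inertia vanishes; linear molecules "
            "are not supported"
        )
    sqm = np.sqrt(m)
    vecs = np.zeros((3 * n, 6))
    for alpha in range(3):
        v = np.zeros((n, 3))
        v[:, alpha] = sqm
        vecs[:, alpha] = v.ravel()
    for k in range(3):
        p = axes[:, k]
        v = sqm[:, None] * np.cross(np.broadcast_to(p, (n, 3)), r)
        vecs[:, 3 + k] = v.ravel()
    vecs /= np.linalg.norm(vecs, axis=0)
    return vecs


def complete_basis(externals: np.ndarray) -> TransformationMatrix:
    """Complete 6 orthonormal external vectors to a full orthonormal basis.

    Candidate columns are the canonical unit vectors; each is iteratively
    re-orthogonalized against the accepted columns until every pairwise
    projection is below 1e-8, then normalized.  Near-dependent candidates
    are skipped.
    """
    externals = np.asarray(externals, dtype=float)
    n3 = externals.shape[0]
    if externals.shape != (n3, 6):
        raise ValueError("expected 6 external column vectors")
    gram = externals.T @ externals
    if np.abs(gram - np.eye(6)).max() > ORTHO_TOL:
        raise ValueError("external vectors are not orthonormal")
    cols = [externals[:, i] for i in range(6)]
    for cand_idx in range(n3):
        if len(cols) == n3:
            break
        v = np.zeros(n3)
        v[cand_idx] = 1.0
        # iterated Gram-Schmidt until all projections < tolerance
        for _ in range(10):
            basis = np.column_stack(cols)
            proj = basis.T @ v
            if np.abs(proj).max() < ORTHO_TOL * max(np.linalg.norm(v), 1e-30):
                break
            v = v - basis @ proj
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            continue  # candidate (numerically) inside the current span
        cols.append(v / norm)
    if len(cols) != n3:
        raise ValueError(
            "could not complete the basis: canonical candidates exhausted"
        )
    return TransformationMatrix(np.column_stack(cols))


def internal_hessian(h_q: np.ndarray, transform: TransformationMatrix) -> np.ndarray:
    """H_s = D^T H_q D."""
    D = transform.D
    if h_q.shape != D.shape:
        raise ValueError("Hessian and transformation matrix shapes differ")
    h_s = D.T @ h_q @ D
    return 0.5 * (h_s + h_s.T)


def eigensolve(h_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of a symmetric matrix."""
    h_s = np.asarray(h_s, dtype=float)
    scale = np.abs(h_s).max() or 1.0
    if np.abs(h_s - h_s.T).max() > 1e-8 * scale:
        raise ValueError("matrix is not symmetric")
    return np.linalg.eigh(0.5 * (h_s + h_s.T))


def frequencies(eigenvalues: np.ndarray) -> np.ndarray:
    """Harmonic wavenumbers (cm^-1) from mass-weighted eigenvalues (a.u.).

    Negative eigenvalues (imaginary modes) are reported as negative
    wavenumbers of magnitude sqrt(|lambda|).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    return np.sign(lam) * np.sqrt(np.abs(lam)) * constants.WAVENUMBER_PER_SQRT_HARTREE


def vibrational_analysis(
    geom: LabeledGeometry,
    hessian: HessianMatrix,
    allow_imaginary: bool = False,
    zero_tol: float = 1e-8,
) -> NormalModeSet:
    """Full normal-mode analysis of a nonlinear molecule at a minimum.

    External modes are the eigenvalues with |lambda| < zero_tol * max|lambda|;
    there must be exactly six.  A negative vibrational eigenvalue raises
    SaddlePointError unless allow_imaginary is set.
    """
    h_q = mass_weight_hessian(hessian, geom.masses)
    transform = complete_basis(external_frame_vectors(geom))
    h_s = internal_hessian(h_q, transform)
    lam, vecs = eigensolve(h_s)
    scale = np.abs(lam).max() or 1.0
    external = np.abs(lam) < zero_tol * scale
    n_ext = int(external.sum())
    if n_ext > 6:
        raise ValueError(
            f"found {n_ext} near-zero eigenvalues (expected 6); the system "
            "is flat or linear"
        )
    if n_ext < 6:
        raise ValueError(
            f"found only {n_ext} near-zero eigenvalues (expected 6); the "
            "geometry is not a stationary point of the Hessian"
        )
    keep = ~external
    lam_vib = lam[keep]
    if np.any(lam_vib < 0) and not allow_imaginary:
        raise SaddlePointError(
            "negative vibrational eigenvalue: geometry is a saddle point"
        )
    # mass-weighted Cartesian mode vectors
    e_cart = transform.D @ vecs[:, keep]
    n = geom.n_atoms
    inv_m = 1.0 / np.repeat(geom.masses, 3)
    # Cartesian (unweighted) shapes and Gaussian-convention reduced masses
    shapes = e_cart * np.sqrt(inv_m)[:, None]
    red_mass = 1.0 / (shapes ** 2).sum(axis=0)
    force_k = lam_vib * red_mass
    return NormalModeSet(
        eigenvalues=lam_vib,
        eigenvectors=e_cart,
        frequencies=frequencies(lam_vib),
        force_constants=force_k,
        reduced_masses=red_mass,
    )


def vibrational_report(modes: NormalModeSet) -> str:
    """Plain-text table: mode, wavenumber, force constant, reduced mass."""
    lines = [
        f"{'mode':>4s} {'nu (cm^-1)':>12s} {'k (Eh/bohr^2)':>14s} {'mu (m_e)':>12s}"
    ]
    for i in range(modes.n_vib):
        lines.append(
            f"{i + 1:>4d} {modes.frequencies[i]:>12.2f} "
            f"{modes.force_constants[i]:>14.6e} {modes.reduced_masses[i]:>12.2f}"
        )
    return "\n".join(lines)
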