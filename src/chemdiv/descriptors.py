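"""Coulomb-matrix descriptors: construction, canonical sorting, featurization.

The Coulomb matrix encodes a 3D geometry as

    C_II = 0.5 * Z_I^2.4
    C_IJ = Z_I * Z_J / |R_I - R_J|    (distances in Bohr)

which is invariant to rotation and translation; simultaneous row/column
sorting by row norm removes the atom-indexing ambiguity.  Matrices are
zero-padded to a common size, flattened (upper triangle, row-major) and
either standardized on a training subset or normalized per-vector (L1 for
Laplacian kernels, L2 for RBF kernels).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_TO_BOHR
from .core import Dataset, Molecule


def coulomb_matrix(molecule: Molecule, n_max: int | None = None) -> np.ndarray:
    """Sorted-input-free Coulomb matrix, zero-padded to ``n_max``."""
    n = molecule.n_atoms
    if n_max is None:
        n_max = n
    if n > n_max:
        raise ValueError(f"molecule has {n} atoms but n_max={n_max}")
    Z = molecule.atomic_numbers.astype(float)
    R = molecule.coords * ANGSTROM_TO_BOHR
    diff = R[:, None, :] - R[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    off = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    if np.any(d <= 0.0):
        raise ValueError("coincident atoms: Coulomb matrix undefined")
    off[iu] = (Z[:, None] * Z[None, :])[iu] / d
    C = off + off.T
    np.fill_diagonal(C, 0.5 * Z**2.4)
    out = np.zeros((n_max, n_max))
    out[:n, :n] = C
    return out


def sort_cm(C: np.ndarray, atomic_numbers: np.ndarray | None = None) -> np.ndarray:
    """Permute rows/columns into non-increasing row-L2-norm order.

    Ties are broken by descending nuclear charge (when provided via the
    diagonal or explicitly) and then by original index, which keeps the
    operation deterministic and idempotent.
    """
    norms = np.linalg.norm(C, axis=1)
    if atomic_numbers is None:
        # recover Z ranking from the diagonal (monotone in Z)
        z_key = np.diag(C)
    else:
        z_key = np.asarray(atomic_numbers, dtype=float)
        z_key = np.pad(z_key, (0, len(C) - len(z_key)))
    order = np.lexsort((np.arange(len(C)), -z_key, -norms))
    return C[np.ix_(order, order)]


def flatten_cm(C: np.ndarray) -> np.ndarray:
    """Upper triangle including the diagonal, row-major."""
    iu = np.triu_indices(len(C))
    return C[iu]


def feature_length(n_max: int) -> int:
    return n_max * (n_max + 1) // 2


@dataclass
class DescriptorSet:
    """Flattened sorted-CM vectors plus the transformation statistics.

    ``mode`` is one of ``standardize`` (train-subset mean/sd per feature,
    zero-variance features mapped to 0), ``normalize_l1`` or ``normalize_l2``
    (per-vector norms, used with Laplacian/RBF kernels respectively) or
    ``none``.
    """

    X: np.ndarray
    n_max: int
    mode: str
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def transform_raw(self, X_raw: np.ndarray) -> np.ndarray:
        """Apply this set's fitted transformation to new raw vectors."""
        return _apply_mode(X_raw, self.mode, self.mean, self.sd)


def raw_features(dataset: Dataset, n_max: int | None = None) -> np.ndarray:
    """Sorted, padded, flattened Coulomb-matrix vectors (no scaling)."""
    if n_max is None:
        n_max = dataset.max_atoms()
    rows = []
    for entry in dataset:
        C = coulomb_matrix(entry.molecule, n_max)
        rows.append(flatten_cm(sort_cm(C)))
    return np.array(rows) if rows else np.empty((0, feature_length(n_max)))


def _apply_mode(X: np.ndarray, mode: str, mean, sd) -> np.ndarray:
    if mode == "none":
        return X.copy()
    if mode == "standardize":
        out = X - mean
        nonzero = sd > 0
        out[:, nonzero] /= sd[nonzero]
        out[:, ~nonzero] = 0.0
        return out
    if mode in ("normalize_l1", "normalize_l2"):
        ord_ = 1 if mode == "normalize_l1" else 2
        norms = np.linalg.norm(X, ord=ord_, axis=1)
        out = X.astype(float).copy()
        zero = norms == 0
        if np.any(zero):
            warnings.warn("all-zero descriptor vector left unnormalized", stacklevel=3)
        out[~zero] /= norms[~zero, None]
        return out
    raise ValueError(f"unknown mode {mode!r}")


def featurize(
    dataset: Dataset,
    n_max: int | None = None,
    train_index: np.ndarray | None = None,
    mode: str = "standardize",
) -> DescriptorSet:
    """Build the descriptor matrix for a dataset.

    For ``standardize`` the per-feature mean and sd are fitted on
    ``train_index`` only (all rows if omitted) so that test rows never leak
    into the scaling.
    """
    if n_max is None:
        n_max = dataset.max_atoms()
    X_raw = raw_features(dataset, n_max)
    return featurize_matrix(X_raw, n_max, train_index=train_index, mode=mode)


def featurize_matrix(
    X_raw: np.ndarray,
    n_max: int,
    train_index: np.ndarray | None = None,
    mode: str = "standardize",
) -> DescriptorSet:
    """Like :func:`featurize` but starting from precomputed raw vectors."""
    mean = sd = None
    if mode == "standardize":
        if len(X_raw) == 0:
            raise ValueError("cannot standardize an empty feature matrix")
        idx = np.arange(len(X_raw)) if train_index is None else np.asarray(train_index)
        if len(idx) == 0:
            raise ValueError("train_index must be non-empty for standardize mode")
        mean = X_raw[idx].mean(axis=0)
        sd = X_raw[idx].std(axis=0)
    X = _apply_mode(X_raw, mode, mean, sd)
    return DescriptorSet(X=X, n_max=n_max, mode=mode, mean=mean, sd=sd)
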