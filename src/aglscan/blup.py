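"""Pedigree relationship matrix, Henderson's mixed-model equations, and GLS.

Desk-scale (n up to a few thousand) exact machinery for the animal model

    y = X b + Z a + e,    a ~ N(0, sigma_a^2 A),   e ~ N(0, sigma_e^2 I),

used two ways: as the source of exact polygenic predictions (BLUP a_hat)
when pre-adjusting phenotypes, and as the independent oracle that the AGLS
shortcut must reproduce -- the GLS solution b_hat = (X'V^-1 X)^- X'V^-1 y
and the MME solution agree on every estimable function, and so does
(X'X)^- X'(y - Z a_hat) when a_hat is the BLUP from the same model.

A is built by the tabular method with unknown parents treated as unrelated
non-inbred founders.  Everything is dense; large-scale sparse solvers are
deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

__all__ = ["Pedigree", "MixedModelSpec", "build_A", "solve_mme", "gls_estimate"]

_UNKNOWN = {None, "", "0", 0, "NA", "na", "nan"}


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree: every parent precedes its offspring.

    ``sire`` and ``dam`` hold row indices into ``ids`` (-1 = unknown).
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("pedigree ids must be unique")
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            if len(parent) != n:
                raise ValueError(f"{name} array length mismatch")
            ahead = np.flatnonzero(parent >= np.arange(n))
            if ahead.size:
                raise ValueError(
                    f"animal {self.ids[ahead[0]]!r} precedes its {name}; "
                    "pedigree must list parents before offspring"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Pedigree":
        """Build from (animal, sire, dam) triples; 0/NA/None = unknown parent."""
        ids = tuple(r[0] for r in records)
        index = {a: i for i, a in enumerate(ids)}

        def parent_index(p, child) -> int:
            if p in _UNKNOWN or (isinstance(p, float) and np.isnan(p)):
                return -1
            if p not in index:
                raise ValueError(f"parent {p!r} of {child!r} not in pedigree")
            return index[p]

        sire = np.array([parent_index(r[1], r[0]) for r in records], dtype=int)
        dam = np.array([parent_index(r[2], r[0]) for r in records], dtype=int)
        return cls(ids, sire, dam)


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + F_i with inbreeding F_i = 0.5 * A(sire_i, dam_i);
    A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i)).  Unknown parents contribute
    zero relationship.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


@dataclass
class MixedModelSpec:
    """Variance components and relationship structure of the animal model."""

    sigma2_a: float
    sigma2_e: float
    A: np.ndarray
    Z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(self.A) < 1.0 - 1e-10):
            raise ValueError("A diagonal must be >= 1")

    @property
    def lam(self) -> float:
        """Variance ratio sigma_e^2 / sigma_a^2 entering the MME."""
        return self.sigma2_e / self.sigma2_a

    def incidence(self, n_records: int) -> np.ndarray:
        if self.Z is not None:
            return np.asarray(self.Z, dtype=float)
        if n_records != self.A.shape[0]:
            raise ValueError("Z omitted but records != animals")
        return np.eye(n_records)


def _inv_with_ridge(M: np.ndarray, label: str) -> np.ndarray:
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"{label} numerically singular; adding 1e-8 ridge", stacklevel=3
        )
        return np.linalg.inv(M + 1e-8 * np.eye(M.shape[0]))


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: Optional[np.ndarray],
    spec: MixedModelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve Henderson's mixed-model equations; returns (b_hat, a_hat).

    The coefficient matrix is [[X'X, X'Z], [Z'X, Z'Z + lam * A^-1]].  With a
    rank-deficient X the system is solved in the minimum-norm least-squares
    sense, which fixes one generalized-inverse solution; estimable functions
    of b_hat and the predictor a_hat are invariant to that choice.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = spec.incidence(len(y)) if Z is None else np.asarray(Z, dtype=float)
    n, p = X.shape
    q = Z.shape[1]
    if len(y) != n or Z.shape[0] != n:
        raise ValueError("dimension mismatch between y, X and Z")
    if q != spec.A.shape[0]:
        raise ValueError("Z columns must match the order of A")

    Ainv = _inv_with_ridge(spec.A, "A")
    C = np.block(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + spec.lam * Ainv],
        ]
    )
    r = np.concatenate([X.T @ y, Z.T @ y])
    if np.linalg.matrix_rank(X) == p:
        try:
            sol = scipy.linalg.solve(C, r, assume_a="sym")
        except (np.linalg.LinAlgError, ValueError):
            sol = scipy.linalg.lstsq(C, r, lapack_driver="gelsd")[0]
    else:
        sol = scipy.linalg.lstsq(C, r, lapack_driver="gelsd")[0]
    return sol[:p], sol[p:]


def gls_estimate(
    y: np.ndarray,
    X: np.ndarray,
    spec: MixedModelSpec,
    Z: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Generalized least squares b_hat = (X'V^-1 X)^- X'V^-1 y (oracle only).

    Forms V = sigma_a^2 Z A Z' + sigma_e^2 I explicitly, so this is limited
    to small n by design.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = spec.incidence(len(y)) if Z is None else np.asarray(Z, dtype=float)
    V = spec.sigma2_a * (Z @ spec.A @ Z.T) + spec.sigma2_e * np.eye(len(y))
    try:
        Vx = np.linalg.solve(V, X)
        Vy = np.linalg.solve(V, y)
    except np.linalg.LinAlgError:
        warnings.warn("V numerically singular; adding 1e-8 ridge", stacklevel=2)
        V = V + 1e-8 * np.eye(len(y))
        Vx = np.linalg.solve(V, X)
        Vy = np.linalg.solve(V, y)
    return np.linalg.pinv(X.T @ Vx) @ (X.T @ Vy)
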