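"""Cα superposition and structure-similarity metrics.

Implements least-squares rigid superposition (Kabsch, via SVD with the
proper-rotation sign correction), an iterative weighted variant that
down-weights divergent residues with Gaussian weights
``w_i = exp(-d_i^2 / <d^2>_w)``, the global distance test (GDT) over a
threshold grid (default 1..20 Å plus 2.5 Å), per-residue distance
profiles, and all-versus-all comparison matrices.

Residue correspondence is strictly positional: residue i of one trace is
paired with residue i of the other over the common prefix
(min(L_a, L_b) pairs), regardless of residue identity — the appropriate
convention when comparing a wild-type structure against truncated or
frameshifted variants whose tails differ in sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .structure_io import CaTrace

__all__ = [
    "ResidueCorrespondence",
    "SuperpositionResult",
    "GdtCurve",
    "ComparisonMatrix",
    "pair_residues",
    "kabsch_superpose",
    "iterative_weighted_superpose",
    "gdt_curve",
    "distance_profile",
    "pairwise_matrix",
    "DEFAULT_GDT_THRESHOLDS",
]

# integers 1..20 Å plus the 2.5 Å reporting threshold
DEFAULT_GDT_THRESHOLDS = tuple(sorted(set(range(1, 21)) | {2.5}))


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Identity pairing over the common prefix of two traces."""

    n_pairs: int
    unpaired_tail: int  # trailing residues of the longer trace

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.n_pairs)


def pair_residues(a: CaTrace, b: CaTrace) -> ResidueCorrespondence:
    """Pair positions 1..min(L_a, L_b) in order."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("cannot pair residues with an empty trace")
    n = min(len(a), len(b))
    return ResidueCorrespondence(n_pairs=n, unpaired_tail=max(len(a), len(b)) - n)


@dataclass
class SuperpositionResult:
    """Rigid transform mapping the mobile coordinates onto the reference.

    ``transform(x) = x @ rotation.T + translation``; ``rmsd`` is the plain
    (unweighted) RMSD over the pairs under the final transform,
    ``weighted_rmsd`` the weighted one when weights were used.
    """

    rotation: np.ndarray       # (3, 3) proper rotation
    translation: np.ndarray    # (3,)
    rmsd: float
    weighted_rmsd: float | None = None
    weights: np.ndarray | None = None
    iterations: int = 1
    converged: bool = True
    unique: bool = True

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _paired_coords(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = a.coords if isinstance(a, CaTrace) else np.asarray(a, float)
    b = b.coords if isinstance(b, CaTrace) else np.asarray(b, float)
    n = min(len(a), len(b))
    if n < 1:
        raise ValidationError("superposition requires at least one pair")
    return a[:n], b[:n]


def _rmsd(d2: np.ndarray, w: np.ndarray | None = None) -> float:
    if w is None:
        return float(np.sqrt(d2.mean()))
    return float(np.sqrt(np.average(d2, weights=w)))


def kabsch_superpose(
    a_coords, b_coords, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares (optionally weighted) rigid superposition of b onto a.

    The optimal rotation comes from the SVD of the weighted cross-covariance
    of the centered coordinate sets; a reflection (negative determinant) is
    corrected by flipping the sign of the smallest singular vector, so the
    returned matrix is always a proper rotation.  Degenerate point sets
    (< 3 points, or collinear) still return the optimal transform but are
    flagged ``unique=False``.
    """
    a, b = _paired_coords(a_coords, b_coords)
    n = len(a)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValidationError("weights must be positive, one per pair")
    wsum = w.sum()
    mu_a = (w[:, None] * a).sum(axis=0) / wsum
    mu_b = (w[:, None] * b).sum(axis=0) / wsum
    ac, bc = a - mu_a, b - mu_b

    H = (w[:, None] * bc).T @ ac  # 3x3 cross-covariance (mobile x reference)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_a - R @ mu_b

    d2 = ((b @ R.T + t - a) ** 2).sum(axis=1)
    # rotation is unique only if the covariance has rank >= 2
    unique = n >= 3 and S[1] > max(1e-9 * max(S[0], 1.0), 1e-12)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=_rmsd(d2),
        weighted_rmsd=_rmsd(d2, w) if weights is not None else None,
        weights=w if weights is not None else None,
        unique=unique,
    )


def iterative_weighted_superpose(
    a, b, tol: float = 1e-6, max_iter: int = 20
) -> SuperpositionResult:
    """Iteratively re-weighted superposition.

    Starting from unit weights, each round superposes with the current
    weights, recomputes per-pair distances ``d_i`` and sets
    ``w_i = exp(-d_i^2 / <d^2>_w)`` where ``<d^2>_w`` is the current
    weighted mean squared distance, until the weighted RMSD changes by less
    than ``tol`` Å or ``max_iter`` rounds.  Well-fitting regions thereby
    dominate the fit and divergent tails are down-weighted, which is what
    makes the superposition error robust to frameshifted tails.
    """
    a_c, b_c = _paired_coords(a, b)
    n = len(a_c)
    w = np.ones(n)
    prev = np.inf
    result = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        result = kabsch_superpose(a_c, b_c, weights=w)
        d2 = ((result.transform(b_c) - a_c) ** 2).sum(axis=1)
        wrmsd = _rmsd(d2, w)
        msd_w = wrmsd**2
        if msd_w < 1e-24 or abs(prev - wrmsd) < tol:
            converged = True
            prev = wrmsd
            break
        prev = wrmsd
        w = np.exp(-d2 / msd_w)
        w = np.maximum(w, 1e-12)  # keep weights strictly positive
    d2 = ((result.transform(b_c) - a_c) ** 2).sum(axis=1)
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=_rmsd(d2),
        weighted_rmsd=_rmsd(d2, w),
        weights=w,
        iterations=iterations,
        converged=converged,
        unique=result.unique,
    )


@dataclass
class GdtCurve:
    """Fit/difference fractions over a distance-threshold grid.

    ``fit_fraction[t]`` is the fraction of paired Cα within ``t`` Å after
    superposition; ``difference_fraction = 1 - fit_fraction`` (the
    complement is what truncation studies typically quote, e.g. "the two
    proteins differ by 90% at <= 2.5 Å").
    """

    thresholds: np.ndarray
    fit_fraction: np.ndarray
    n_pairs: int
    denominator: str = "common"  # common prefix length vs reference length

    @property
    def difference_fraction(self) -> np.ndarray:
        return 1.0 - self.fit_fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fit_fraction": self.fit_fraction,
                "difference_fraction": self.difference_fraction,
            }
        )


def _pair_distances(a: CaTrace, b: CaTrace, refit: bool = True) -> np.ndarray:
    a_c, b_c = _paired_coords(a, b)
    if refit:
        sup = iterative_weighted_superpose(a, b)
        b_c = sup.transform(b_c)
    return np.sqrt(((b_c - a_c) ** 2).sum(axis=1))


def gdt_curve(
    a: CaTrace,
    b: CaTrace,
    thresholds=DEFAULT_GDT_THRESHOLDS,
    refit_per_threshold: bool = False,
    denominator: str = "common",
) -> GdtCurve:
    """Global distance test over a threshold grid.

    By default all thresholds share one iterative weighted superposition
    (a single comparison at variable threshold, not the CASP per-segment
    search).  With ``refit_per_threshold`` the superposition is re-estimated
    per threshold on the residues currently within it (a greedy
    inlier-refit), which can only raise the fit fraction.  ``denominator``
    selects the fraction's denominator: the common prefix length
    (``"common"``, default) or the longer trace (``"reference"``).
    """
    thr = np.asarray(thresholds, float)
    if thr.size == 0:
        raise ValidationError("empty GDT threshold grid")
    if np.any(thr <= 0) or np.any(np.diff(thr) <= 0):
        raise ValidationError("thresholds must be positive and increasing")
    if denominator not in ("common", "reference"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    corr = pair_residues(a, b)
    denom = corr.n_pairs if denominator == "common" else max(len(a), len(b))

    if not refit_per_threshold:
        d = _pair_distances(a, b, refit=True)
        fit = np.array([np.count_nonzero(d <= t) / denom for t in thr])
    else:
        a_c, b_c = _paired_coords(a, b)
        fit = np.empty(thr.size)
        for k, t in enumerate(thr):
            sup = iterative_weighted_superpose(a, b)
            inliers = None
            for _ in range(10):
                d = np.sqrt(((sup.transform(b_c) - a_c) ** 2).sum(axis=1))
                new = d <= t
                if inliers is not None and np.array_equal(new, inliers):
                    break
                inliers = new
                if np.count_nonzero(inliers) < 3:
                    break
                sup = kabsch_superpose(a_c[inliers], b_c[inliers])
            d = np.sqrt(((sup.transform(b_c) - a_c) ** 2).sum(axis=1))
            fit[k] = np.count_nonzero(d <= t) / denom
    return GdtCurve(thr, fit, corr.n_pairs, denominator)


def distance_profile(a: CaTrace, b: CaTrace, refit: bool = True) -> np.ndarray:
    """Per-pair Cα distances (Å) ordered by residue index.

    With ``refit`` (default) distances are taken under the iterative
    weighted superposition; without it the coordinates are compared as
    given.  The result is the raw material for violin plots contrasting
    native prefixes with divergent tails.
    """
    return _pair_distances(a, b, refit=refit)


@dataclass
class ComparisonMatrix:
    """Symmetric all-versus-all RMSD matrices with zero diagonal."""

    labels: list[str]
    rmsd: np.ndarray           # plain RMSD under the final transform
    weighted_rmsd: np.ndarray  # weighted RMSD of the iterative scheme

    @property
    def n_pairs(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2

    def to_frame(self, weighted: bool = False) -> pd.DataFrame:
        m = self.weighted_rmsd if weighted else self.rmsd
        return pd.DataFrame(m, index=self.labels, columns=self.labels)


def pairwise_matrix(traces: list[CaTrace]) -> ComparisonMatrix:
    """Iterative weighted superposition for every unordered pair.

    Each pair is computed once with the longer trace as the reference
    (ties broken by lexicographic label order), which makes the matrix
    exactly symmetric by construction.  N traces yield N(N-1)/2 tests.
    """
    if len(traces) < 2:
        raise ValidationError("need at least two traces to compare")
    labels = [t.model_id for t in traces]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate trace labels: {labels}")
    n = len(traces)
    rmsd = np.zeros((n, n))
    wrmsd = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = traces[i], traces[j]
        if len(a) < len(b) or (len(a) == len(b) and b.model_id < a.model_id):
            a, b = b, a
        sup = iterative_weighted_superpose(a, b)
        rmsd[i, j] = rmsd[j, i] = sup.rmsd
        wrmsd[i, j] = wrmsd[j, i] = sup.weighted_rmsd
    return ComparisonMatrix(labels, rmsd, wrmsd)
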