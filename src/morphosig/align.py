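"""Procrustes superimposition of 3D landmark configurations.

Implements centroid size, least-squares pairwise superimposition (Kabsch with
optional uniform scaling), generalized Procrustes analysis (GPA), sagittal
midline-plane estimation, the reflection-augmented GPA protocol for
bilaterally symmetric structures, and landmark-level retrodeformation by
bilateral symmetrization.

Conventions: configurations are ``k x 3`` with points as rows.  Rotations are
proper (det = +1) unless reflection is explicitly requested; anatomical
chirality is only ever changed by the explicit mirroring operations.  Inside
GPA every configuration is translated to the origin and scaled to unit
centroid size (partial Procrustes with scaling); original centroid sizes are
retained separately because downstream analyses treat size and shape as
separate variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (LandmarkConfiguration, SpecimenDataset, ValidationError)


class DegenerateConfigurationError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


class RetrodeformationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# size and elementary transforms

def centroid_size(config) -> float:
    """Root summed squared distance of landmarks to their centroid.

    Accepts a ``LandmarkConfiguration`` (present landmarks only) or a plain
    ``(k, 3)`` array.  Scale-equivariant: scaling coordinates by ``c`` scales
    the result by ``c``.
    """
    if isinstance(config, LandmarkConfiguration):
        pts = config.coords[config.present]
    else:
        pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegenerateConfigurationError("need at least 2 landmarks")
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered ** 2)))
    if cs <= 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return cs


def reflect_across_plane(coords: np.ndarray, point: np.ndarray,
                         normal: np.ndarray) -> np.ndarray:
    """Householder reflection of points across the plane (point, unit normal)."""
    coords = np.asarray(coords, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = (coords - point) @ n
    return coords - 2.0 * d[:, None] * n


# ---------------------------------------------------------------------------
# pairwise superimposition

@dataclass
class PairAlignment:
    rotation: np.ndarray      # 3x3, applied on the right: x @ rotation
    translation: np.ndarray   # added after rotation/scaling
    scale: float
    residual: float           # summed squared distances after alignment

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(coords) @ self.rotation) + self.translation


def align_pair(target: np.ndarray, reference: np.ndarray,
               allow_reflection: bool = False, scale: bool = True) -> PairAlignment:
    """Least-squares orthogonal superimposition of ``target`` onto ``reference``.

    Minimizes ``sum || s * target_i @ R + t - reference_i ||^2`` over
    translations, proper rotations (improper allowed only when
    ``allow_reflection``) and, optionally, uniform scale.
    """
    X = np.asarray(target, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape:
        raise ValidationError("target and reference must have equal shapes")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0.0:
        d = 1.0
    if allow_reflection:
        signs = np.ones(3)
    else:
        signs = np.array([1.0, 1.0, d])
    R = (U * signs) @ Vt
    trace = float(np.sum(S * signs))
    nx2 = float(np.sum(Xc ** 2))
    s = trace / nx2 if scale else 1.0
    t = my - s * (mx @ R)
    resid = float(np.sum((s * (X @ R) + t - Y) ** 2))
    return PairAlignment(rotation=R, translation=t, scale=s, residual=max(resid, 0.0))


# ---------------------------------------------------------------------------
# generalized Procrustes analysis

@dataclass
class AlignedDataset:
    """Procrustes-aligned coordinates plus retained centroid sizes.

    For a plain GPA every aligned configuration is centered at the origin
    with unit centroid size.  For the reflection-augmented protocol
    (``symmetric_gpa``) the stored coordinates are the kept (original-half)
    landmarks in the frame of the augmented alignment, flagged by
    ``augmented``; per-half centroid/size invariants deliberately do not hold
    there, because re-centering each half would undo the common-midline
    registration the protocol provides.
    """

    scheme: object
    coords: np.ndarray           # (n, k, 3)
    centroid_sizes: np.ndarray   # (n,) original scale
    consensus: np.ndarray        # (k, 3), unit centroid size
    specimen_ids: list[str]
    log: dict = field(default_factory=dict)
    augmented: bool = False

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if not self.augmented:
            cent = self.coords.mean(axis=1)
            if not np.all(np.abs(cent) < atol):
                raise ValidationError("aligned configuration not centered")
            cs = np.sqrt(np.sum(self.coords ** 2, axis=(1, 2)))
            if not np.all(np.abs(cs - 1.0) < atol):
                raise ValidationError("aligned configuration not unit size")

    def flat(self) -> np.ndarray:
        """``(n, 3k)`` row-per-specimen coordinate matrix."""
        return self.coords.reshape(self.n, -1)

    def log_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic orientation: principal axes, signs by coordinate skewness.

    Makes the converged GPA frame independent of input order (the consensus
    from two runs differs only by a rotation, which principal-axis
    canonicalization removes for generic configurations).
    """
    C = consensus - consensus.mean(axis=0)
    cov = C.T @ C
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]  # descending variance
    P = C @ V
    for j in range(2):
        skew = np.sum(P[:, j] ** 3)
        if abs(skew) < 1e-12:
            i = int(np.argmax(np.abs(P[:, j])))
            skew = P[i, j]
        if skew < 0:
            V[:, j] = -V[:, j]
    V[:, 2] = np.cross(V[:, 0], V[:, 1])
    return V


def gpa(dataset: SpecimenDataset | np.ndarray, scale: bool = True,
        tol: float = 1e-10, max_iter: int = 100,
        centroid_sizes: np.ndarray | None = None,
        canonicalize: bool = True) -> AlignedDataset:
    """Generalized Procrustes alignment of complete configurations.

    Iteratively rotates every configuration to the running consensus (the
    arithmetic mean rescaled to unit centroid size) until the change in
    summed squared residuals drops below ``tol``.  Deterministic: the
    consensus is initialized from the first specimen and the converged frame
    is canonicalized to the consensus principal axes.
    """
    if isinstance(dataset, SpecimenDataset):
        X = dataset.coords_array().copy()
        ids = dataset.specimen_ids
        scheme = dataset.scheme
    else:
        X = np.asarray(dataset, dtype=float).copy()
        ids = [f"s{i}" for i in range(X.shape[0])]
        scheme = None
    n = X.shape[0]
    if centroid_sizes is None:
        sizes = np.array([centroid_size(x) for x in X])
    else:
        sizes = np.asarray(centroid_sizes, dtype=float)
    X -= X.mean(axis=1, keepdims=True)
    if scale:
        X /= np.sqrt(np.sum(X ** 2, axis=(1, 2)))[:, None, None]
    consensus = X[0] / np.sqrt(np.sum(X[0] ** 2))
    prev_ss = np.inf
    history = []
    for it in range(max_iter):
        for i in range(n):
            a = align_pair(X[i], consensus, allow_reflection=False, scale=False)
            X[i] = X[i] @ a.rotation
        mean = X.mean(axis=0)
        consensus = mean / np.sqrt(np.sum(mean ** 2))
        ss = float(np.sum((X - consensus) ** 2))
        history.append(ss)
        if abs(prev_ss - ss) < tol:
            break
        prev_ss = ss
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last change {abs(prev_ss - ss):.3e})")
    if canonicalize:
        V = _canonical_rotation(consensus)
        consensus = (consensus - consensus.mean(axis=0)) @ V
        X = X @ V
    return AlignedDataset(
        scheme=scheme, coords=X, centroid_sizes=sizes, consensus=consensus,
        specimen_ids=list(ids),
        log={"iterations": it + 1, "residual_history": history,
             "final_change": abs(prev_ss - ss), "scaled": scale})


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (size removed)."""
    A = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    B = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    A /= np.sqrt(np.sum(A ** 2))
    B /= np.sqrt(np.sum(B ** 2))
    res = align_pair(A, B, scale=True).residual
    return float(np.sqrt(max(res, 0.0)))


# ---------------------------------------------------------------------------
# midline plane, mirroring, symmetrization

def estimate_midline_plane(config: LandmarkConfiguration
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares sagittal plane through the midline landmarks.

    Returns ``(point, unit_normal)``; the normal is oriented to have a
    positive x-component (falling back to the largest-magnitude component
    when the x-component vanishes).
    """
    mid = config.scheme.midline_indices
    mid = mid[config.present[mid]]
    if mid.size < 3:
        raise DegenerateConfigurationError(
            "need at least 3 midline landmarks to estimate the sagittal plane")
    pts = config.coords[mid]
    center = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - center)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateConfigurationError("midline landmarks are collinear")
    normal = Vt[2]
    if abs(normal[0]) > 1e-12:
        if normal[0] < 0:
            normal = -normal
    else:
        i = int(np.argmax(np.abs(normal)))
        if normal[i] < 0:
            normal = -normal
    return center, normal


def mirror_incomplete_side(config: LandmarkConfiguration
                           ) -> LandmarkConfiguration:
    """Reflect a configuration across its sagittal plane, swapping pair labels.

    Converts a specimen digitized on the 'wrong' (left) side into a canonical
    right-side configuration.  An involution: applying it twice recovers the
    input; all inter-landmark distances are preserved.
    """
    point, normal = estimate_midline_plane(config)
    reflected = reflect_across_plane(config.coords, point, normal)
    perm = config.scheme.pair_permutation()
    coords = reflected[perm]
    present = config.present[perm]
    coords = np.where(present[:, None], coords, np.nan)
    return LandmarkConfiguration(config.scheme, coords, present,
                                 config.specimen_id)


def symmetric_gpa(dataset: SpecimenDataset, tol: float = 1e-10,
                  max_iter: int = 100) -> AlignedDataset:
    """GPA after augmenting each specimen with its sagittal mirror image.

    Each configuration is doubled with its reflection across its own
    estimated sagittal plane (2k landmarks), the augmented configurations are
    Procrustes-aligned, and the mirrored half is then dropped.  This keeps
    the midline registered to a common plane even when specimens differ in
    width, which plain GPA does not guarantee.  Centroid sizes are reported
    for the original (non-augmented) configurations.
    """
    X = dataset.coords_array()
    n, k, _ = X.shape
    sizes = np.array([centroid_size(x) for x in X])
    aug = np.empty((n, 2 * k, 3))
    for i, cfg in enumerate(dataset.configurations):
        point, normal = estimate_midline_plane(cfg)
        aug[i, :k] = X[i]
        aug[i, k:] = reflect_across_plane(X[i], point, normal)
    aligned = gpa(aug, scale=True, tol=tol, max_iter=max_iter)
    kept = aligned.coords[:, :k, :]
    mean = kept.mean(axis=0)
    consensus = mean / np.sqrt(np.sum((mean - mean.mean(axis=0)) ** 2))
    log = dict(aligned.log)
    log["protocol"] = "reflection-augmented"
    return AlignedDataset(
        scheme=dataset.scheme, coords=kept, centroid_sizes=sizes,
        consensus=consensus, specimen_ids=dataset.specimen_ids,
        log=log, augmented=True)


def bilateral_obliquity_deg(config: LandmarkConfiguration) -> float:
    """Angle between the midline-plane normal and the mean bilateral axis.

    Zero for an undeformed bilaterally symmetric specimen; grows with
    asymmetric (shear-like) taphonomic deformation of the sagittal plane.
    """
    point, normal = estimate_midline_plane(config)
    scheme = config.scheme
    idx = scheme.index
    diffs = []
    for a, b in scheme.pairs.items():
        ia, ib = idx[a], idx[b]
        if ia < ib and config.present[ia] and config.present[ib]:
            d = config.coords[ia] - config.coords[ib]
            if d @ normal < 0:
                d = -d
            diffs.append(d)
    if not diffs:
        raise ValidationError("bilateral pairing required to measure obliquity")
    axis = np.mean(diffs, axis=0)
    axis = axis / np.linalg.norm(axis)
    cosang = float(np.clip(abs(axis @ normal), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def symmetrize_retrodeform(config: LandmarkConfiguration,
                           max_obliquity_deg: float = 10.0
                           ) -> LandmarkConfiguration:
    """Retrodeform a mildly asymmetric specimen by bilateral symmetrization.

    Every landmark is replaced by the average of itself and its reflected,
    pair-relabelled counterpart across the estimated sagittal plane, yielding
    an exactly mirror-symmetric configuration (idempotent).  Specimens whose
    sagittal obliquity exceeds ``max_obliquity_deg`` are refused: strongly
    deformed material cannot be restored this way and should be excluded.
    """
    if not config.is_complete:
        raise ValidationError("symmetrization requires a complete configuration")
    obliq = bilateral_obliquity_deg(config)
    if obliq > max_obliquity_deg:
        raise RetrodeformationError(
            f"sagittal obliquity {obliq:.2f} deg exceeds the "
            f"{max_obliquity_deg:.1f} deg retrodeformation limit")
    point, normal = estimate_midline_plane(config)
    reflected = reflect_across_plane(config.coords, point, normal)
    perm = config.scheme.pair_permutation()
    sym = 0.5 * (config.coords + reflected[perm])
    return LandmarkConfiguration(config.scheme, sym, config.present.copy(),
                                 config.specimen_id)
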