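"""Thin-plate-spline bending energy and semilandmark sliding.

Curve and surface semilandmarks carry no information along their structure:
their spacing is an artefact of digitization.  Sliding removes it by letting
each semilandmark move within its local tangent space (curves: the 1-D
tangent from neighbouring curve points; surfaces: the 2-D tangent plane of
the local landmark neighbourhood) so as to minimize the thin-plate-spline
bending energy of the deformation from the current consensus to the
specimen.  Fixed landmarks never move.  The displacement that minimizes the
(quadratic) bending energy under the tangency constraint has a closed form.

The 3-D TPS kernel is U(r) = -r (the sign makes the bending-energy
quadratic form positive semidefinite); the bending-energy matrix is the
upper-left block of the inverted TPS system and annihilates every affine
transform of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import align_pair, gpa
from .data import (CURVE, SURFACE, LandmarkConfiguration, LandmarkScheme,
                   SpecimenDataset, ValidationError)


class SingularKernelError(ValueError):
    pass


@dataclass
class TPSModel:
    """Bending-energy structure of a 3-D thin-plate spline at a reference."""

    reference: np.ndarray          # (k, 3)
    bending_energy: np.ndarray     # (k, k), symmetric PSD

    def energy(self, target: np.ndarray) -> float:
        """Bending energy of the deformation mapping the reference onto
        ``target`` (zero for any affine image of the reference)."""
        V = np.asarray(target, dtype=float)
        return float(np.einsum("id,ij,jd->", V, self.bending_energy, V))


def bending_energy_matrix(reference: np.ndarray) -> TPSModel:
    """TPS bending-energy matrix for a 3-D reference configuration."""
    X = np.asarray(reference, dtype=float)
    k = X.shape[0]
    if X.shape != (k, 3):
        raise ValidationError("reference must be (k, 3)")
    d = np.sqrt(np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2))
    off = d[np.triu_indices(k, 1)]
    if off.size and off.min() <= 0:
        raise SingularKernelError("coincident reference landmarks")
    K = -d                                   # U(r) = -r
    P = np.column_stack([np.ones(k), X])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise SingularKernelError(f"singular TPS system: {exc}") from exc
    B = Linv[:k, :k]
    B = 0.5 * (B + B.T)
    return TPSModel(reference=X.copy(), bending_energy=B)


# ---------------------------------------------------------------------------
# tangent estimation

def _curve_tangents(coords: np.ndarray, scheme: LandmarkScheme
                    ) -> dict[int, np.ndarray]:
    """Unit tangent per curve semilandmark by central difference along the
    stated curve order (one-sided at the ends)."""
    idx = scheme.index
    out: dict[int, np.ndarray] = {}
    for curve in scheme.curves:
        ii = [idx[lid] for lid in curve]
        for pos, i in enumerate(ii):
            if scheme.types[i] != CURVE:
                continue
            a = ii[max(pos - 1, 0)]
            b = ii[min(pos + 1, len(ii) - 1)]
            t = coords[b] - coords[a]
            nt = np.linalg.norm(t)
            if nt <= 0:
                raise ValidationError(
                    f"degenerate curve tangent at {scheme.landmark_ids[i]}")
            out[i] = t / nt
    return out


def _surface_tangents(coords: np.ndarray, scheme: LandmarkScheme,
                      reference: np.ndarray, n_neighbors: int = 8
                      ) -> dict[int, np.ndarray]:
    """Two orthonormal tangent vectors per surface semilandmark from a local
    PCA of its nearest-neighbour cloud.  Neighbourhoods are fixed by
    reference-shape proximity so they are stable across specimens."""
    k = coords.shape[0]
    if k < 3:
        raise ValidationError("too few landmarks for surface tangents")
    d2 = np.sum((reference[:, None, :] - reference[None, :, :]) ** 2, axis=2)
    out: dict[int, np.ndarray] = {}
    m = min(n_neighbors, k - 1)
    for i in range(k):
        if scheme.types[i] != SURFACE:
            continue
        nbr = np.argsort(d2[i])[: m + 1]          # includes self
        cloud = coords[nbr]
        cloud = cloud - cloud.mean(axis=0)
        _, s, Vt = np.linalg.svd(cloud, full_matrices=False)
        if s.size < 2 or s[1] <= 0:
            raise ValidationError(
                f"degenerate surface neighbourhood at {scheme.landmark_ids[i]}")
        out[i] = Vt[:2]                            # (2, 3)
    return out


def _tangent_vectors(coords: np.ndarray, scheme: LandmarkScheme,
                     reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tangent directions of all sliding degrees of freedom.

    Returns ``(V, owners)``: ``V`` is ``(q, 3)`` unit tangent vectors and
    ``owners[p]`` the landmark index each belongs to (curves contribute one
    dof, surfaces two)."""
    k = coords.shape[0]
    ct = _curve_tangents(coords, scheme)
    st = _surface_tangents(coords, scheme, reference)
    vecs: list[np.ndarray] = []
    owners: list[int] = []
    for i in range(k):
        if scheme.types[i] == CURVE:
            if i not in ct:
                raise ValidationError(
                    f"curve semilandmark {scheme.landmark_ids[i]} has no curve")
            local = [ct[i]]
        elif scheme.types[i] == SURFACE:
            local = list(st[i])
        else:
            continue
        for v in local:
            vecs.append(v)
            owners.append(i)
    if not vecs:
        return np.zeros((0, 3)), np.zeros(0, dtype=int)
    return np.stack(vecs), np.asarray(owners, dtype=int)


def slide_step(coords: np.ndarray, consensus: np.ndarray,
               scheme: LandmarkScheme, tps: TPSModel | None = None
               ) -> np.ndarray:
    """One closed-form slide of a single specimen against a consensus:
    minimize the TPS bending energy of consensus -> specimen over
    displacements of the semilandmarks within their tangent spaces.

    With displacement directions supported on single landmarks, the normal
    equations reduce to ``(B[o, o'] * (v . v')) t = -(v . (B W)[o])``.
    """
    if tps is None:
        tps = bending_energy_matrix(consensus)
    V, owners = _tangent_vectors(coords, scheme, consensus)
    if V.shape[0] == 0:
        return coords.copy()
    B = tps.bending_energy
    W0 = coords - consensus
    A = B[np.ix_(owners, owners)] * (V @ V.T)
    b = np.einsum("pd,pd->p", V, (B @ W0)[owners])
    t = -np.linalg.lstsq(A, b, rcond=None)[0]
    out = coords.copy()
    np.add.at(out, owners, t[:, None] * V)
    return out


def slide_semilandmarks(dataset: SpecimenDataset, iterations: int = 3,
                        scale: bool = True) -> tuple[SpecimenDataset, dict]:
    """Slide curve/surface semilandmarks of every specimen to minimize
    bending energy against the evolving consensus.

    Each iteration aligns the dataset (GPA), slides every specimen against
    the consensus in the aligned frame, and maps the result back into the
    specimen's original frame, so the returned dataset keeps original
    positions, orientations and scales.  The log records total bending
    energy before and after each slide; within an iteration the slide never
    increases it.
    """
    scheme = dataset.scheme
    configs = [c.copy() for c in dataset.configurations]
    log = {"iterations": [], "energy_pre": [], "energy_post": []}
    for it in range(iterations):
        current = SpecimenDataset(scheme, configs)
        aligned = gpa(current, scale=scale)
        consensus = aligned.consensus
        tps = bending_energy_matrix(consensus)
        e_pre = e_post = 0.0
        new_configs = []
        for i, cfg in enumerate(configs):
            ac = aligned.coords[i]
            e_pre += tps.energy(ac - consensus)
            slid = slide_step(ac, consensus, scheme, tps)
            e_post += tps.energy(slid - consensus)
            back = align_pair(ac, cfg.coords, allow_reflection=False,
                              scale=True)
            new_configs.append(LandmarkConfiguration(
                scheme, back.apply(slid), None, cfg.specimen_id))
        configs = new_configs
        log["iterations"].append(it + 1)
        log["energy_pre"].append(e_pre)
        log["energy_post"].append(e_post)
    return SpecimenDataset(scheme, configs, set(dataset.retrodeformed)), log
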