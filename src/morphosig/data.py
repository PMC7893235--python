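"""Core landmark-data containers.

A *landmark scheme* fixes the identity, ordering and annotation of every
landmark digitized on a specimen: its type (fixed anatomical point, curve
semilandmark or surface semilandmark), the anatomical module it belongs to,
whether it lies on the sagittal midline, its bilateral partner (if any) and,
for curve semilandmarks, the ordered curve it sits on.  Configurations and
datasets always refer back to one shared scheme, so landmark order is defined
once and files are re-sorted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

FIXED = "fixed"
CURVE = "curve_semilandmark"
SURFACE = "surface_semilandmark"
LANDMARK_TYPES = (FIXED, CURVE, SURFACE)


class SchemeError(ValueError):
    """Raised when a landmark scheme violates its invariants."""


class ValidationError(ValueError):
    """Raised when a configuration or dataset violates its contract."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Ordered landmark identities plus their annotations.

    Parameters
    ----------
    landmark_ids
        Ordered unique identifiers, length ``k``.
    types
        One of ``fixed``, ``curve_semilandmark``, ``surface_semilandmark``
        per landmark.
    modules
        Module label per landmark (the module partition).
    midline
        Boolean per landmark: lies on the sagittal midline.
    pairs
        Partial map ``landmark_id -> landmark_id`` of bilateral pairs.  Must
        be an involution with no fixed points; midline landmarks are unpaired.
    curves
        Ordered landmark-id lists, one per digitized curve.  Every curve
        semilandmark belongs to exactly one curve of at least 3 members.
    """

    landmark_ids: tuple[str, ...]
    types: tuple[str, ...]
    modules: tuple[str, ...]
    midline: tuple[bool, ...]
    pairs: Mapping[str, str] = field(default_factory=dict)
    curves: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        k = len(self.landmark_ids)
        if len(set(self.landmark_ids)) != k:
            raise SchemeError("landmark ids are not unique")
        for name, attr in (("types", self.types), ("modules", self.modules),
                           ("midline", self.midline)):
            if len(attr) != k:
                raise SchemeError(f"{name} has length {len(attr)}, expected {k}")
        bad = set(self.types) - set(LANDMARK_TYPES)
        if bad:
            raise SchemeError(f"unknown landmark types: {sorted(bad)}")
        idx = self.index
        for a, b in self.pairs.items():
            if a not in idx or b not in idx:
                raise SchemeError(f"pair ({a}, {b}) references unknown landmark")
            if a == b:
                raise SchemeError(f"pair map has fixed point {a!r}")
            if self.pairs.get(b) != a:
                raise SchemeError(f"pair map is not an involution at {a!r}")
            if self.midline[idx[a]]:
                raise SchemeError(f"midline landmark {a!r} is paired")
        seen_in_curve: dict[str, int] = {}
        for ci, curve in enumerate(self.curves):
            if len(curve) < 3:
                raise SchemeError(f"curve {ci} has fewer than 3 members")
            for lid in curve:
                if lid not in idx:
                    raise SchemeError(f"curve {ci} references unknown landmark {lid!r}")
                if lid in seen_in_curve:
                    raise SchemeError(f"landmark {lid!r} belongs to two curves")
                seen_in_curve[lid] = ci
        for lid, t in zip(self.landmark_ids, self.types):
            if t == CURVE and lid not in seen_in_curve:
                raise SchemeError(f"curve semilandmark {lid!r} belongs to no curve")

    @property
    def k(self) -> int:
        return len(self.landmark_ids)

    @property
    def index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.landmark_ids)}

    @property
    def module_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in self.modules:
            if m not in seen:
                seen.append(m)
        return tuple(seen)

    def module_indices(self, module: str) -> np.ndarray:
        out = np.flatnonzero(np.asarray(self.modules, dtype=object) == module)
        if out.size == 0:
            raise KeyError(f"no landmarks in module {module!r}")
        return out

    @property
    def midline_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.midline, dtype=bool))

    def pair_permutation(self) -> np.ndarray:
        """Index permutation swapping bilateral partners (identity on the rest)."""
        idx = self.index
        perm = np.arange(self.k)
        for a, b in self.pairs.items():
            perm[idx[a]] = idx[b]
        return perm

    def partition(self) -> dict[str, np.ndarray]:
        return {m: self.module_indices(m) for m in self.module_names}


@dataclass
class LandmarkConfiguration:
    """One specimen's ``k x 3`` coordinates against a shared scheme.

    ``present`` masks landmarks that could not be digitized (partial
    specimens); coordinates at absent landmarks are NaN by convention.
    """

    scheme: LandmarkScheme
    coords: np.ndarray
    present: np.ndarray | None = None
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.scheme.k, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} != ({self.scheme.k}, 3)")
        if self.present is None:
            self.present = np.ones(self.scheme.k, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape != (self.scheme.k,):
                raise ValidationError("presence mask has wrong length")
        if not np.all(np.isfinite(self.coords[self.present])):
            raise ValidationError(
                f"non-finite coordinates at present landmarks "
                f"(specimen {self.specimen_id!r})")

    @property
    def is_complete(self) -> bool:
        return bool(np.all(self.present))

    def present_modules(self) -> tuple[str, ...]:
        """Modules all of whose landmarks are present."""
        out = []
        for m in self.scheme.module_names:
            if np.all(self.present[self.scheme.module_indices(m)]):
                out.append(m)
        return tuple(out)

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(self.scheme, self.coords.copy(),
                                     self.present.copy(), self.specimen_id)


@dataclass
class SpecimenDataset:
    """A collection of configurations sharing one landmark scheme."""

    scheme: LandmarkScheme
    configurations: list[LandmarkConfiguration]
    retrodeformed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValidationError("dataset needs at least one specimen")
        for c in self.configurations:
            if c.scheme is not self.scheme and c.scheme != self.scheme:
                raise ValidationError("all configurations must share one scheme")

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def complete_subset(self) -> "SpecimenDataset":
        sub = [c for c in self.configurations if c.is_complete]
        if not sub:
            raise ValidationError("no complete specimens")
        return SpecimenDataset(self.scheme, sub, set(self.retrodeformed))

    def module_subset(self, module: str) -> "SpecimenDataset":
        """Specimens with the module fully present, restricted to its landmarks."""
        idx = self.scheme.module_indices(module)
        sub_scheme = subset_scheme(self.scheme, idx)
        configs = []
        for c in self.configurations:
            if np.all(c.present[idx]):
                configs.append(LandmarkConfiguration(
                    sub_scheme, c.coords[idx], None, c.specimen_id))
        if not configs:
            raise ValidationError(f"module {module!r} present in no specimen")
        return SpecimenDataset(sub_scheme, configs, set(self.retrodeformed))

    def coords_array(self) -> np.ndarray:
        """``(n, k, 3)`` stack; requires complete specimens."""
        for c in self.configurations:
            if not c.is_complete:
                raise ValidationError(
                    f"specimen {c.specimen_id!r} is partial; "
                    "use complete_subset() or module_subset()")
        return np.stack([c.coords for c in self.configurations])


def subset_scheme(scheme: LandmarkScheme, indices: Sequence[int]) -> LandmarkScheme:
    """Restrict a scheme to a subset of landmarks (order preserved).

    Pairs survive only if both members survive; curves are truncated and
    dropped below 3 members, with orphaned curve semilandmarks re-typed as
    surface semilandmarks (their sliding tangent is then local-neighbourhood
    based rather than along-curve).
    """
    indices = np.asarray(indices, dtype=int)
    keep = set(scheme.landmark_ids[i] for i in indices)
    ids = tuple(scheme.landmark_ids[i] for i in indices)
    types = list(scheme.types[i] for i in indices)
    modules = tuple(scheme.modules[i] for i in indices)
    midline = tuple(scheme.midline[i] for i in indices)
    pairs = {a: b for a, b in scheme.pairs.items() if a in keep and b in keep}
    curves = []
    in_curve: set[str] = set()
    for curve in scheme.curves:
        short = tuple(lid for lid in curve if lid in keep)
        if len(short) >= 3:
            curves.append(short)
            in_curve.update(short)
    for j, lid in enumerate(ids):
        if types[j] == CURVE and lid not in in_curve:
            types[j] = SURFACE
    return LandmarkScheme(ids, tuple(types), modules, midline, pairs, tuple(curves))


def validate_partition(scheme: LandmarkScheme) -> dict:
    """Report on the module partition: module list, counts, violations."""
    violations: list[str] = []
    counts: dict[str, int] = {}
    for lid, m in zip(scheme.landmark_ids, scheme.modules):
        if m is None or str(m).strip() == "":
            violations.append(f"landmark {lid!r} has no module label")
        else:
            counts[str(m)] = counts.get(str(m), 0) + 1
    if not counts:
        violations.append("no module labels at all")
    for m, c in counts.items():
        if c == 0:  # pragma: no cover - unreachable by construction
            violations.append(f"module {m!r} is empty")
    return {
        "modules": sorted(counts),
        "counts": counts,
        "violations": violations,
        "valid": not violations,
    }
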