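"""Modularity: maximum-likelihood hypothesis comparison and covariance ratio.

Two complementary assessments of modular structure in aligned landmark data:

* :class:`CorrelationModularity` — an EMMLi-style maximum-likelihood
  comparison of alternative module partitions.  The data are the absolute
  landmark congruence coefficients (the correlation-like similarity of two
  landmarks' 3-D deviation vectors across specimens).  Each hypothesis
  assigns every landmark pair to a correlation class (one per within-module
  set, plus either a single pooled between-module class or one class per
  module pair); the class estimate is the mean absolute coefficient and the
  likelihood is normal on the Fisher-z scale with variance 1/(n-3).  Models
  are ranked by small-sample AICc and summarized with Akaike weights.
  High-density landmarking inflates support for many-module models, so the
  AICc-best partition can be post-processed with :func:`merge_modules`:
  module pairs whose between-module correlation comes within 0.1 of the
  lowest within-module correlation are merged (transitively).

* :func:`covariance_ratio` — the ratio of between-module to within-module
  covariation (CR < 1 indicates modularity), with a permutation test that
  reassigns whole landmarks to modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .align import AlignedDataset
from .data import LandmarkScheme, ValidationError

_Z_CLAMP = 0.999999


@dataclass(frozen=True)
class ModuleHypothesis:
    """A named assignment of every landmark to one of m modules."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValidationError("empty hypothesis")

    @property
    def n_modules(self) -> int:
        return len(set(self.labels))

    @classmethod
    def from_scheme(cls, scheme: LandmarkScheme, name: str = "anatomical"
                    ) -> "ModuleHypothesis":
        return cls(name, tuple(scheme.modules))


def _coords_of(aligned) -> np.ndarray:
    if isinstance(aligned, AlignedDataset):
        return aligned.coords
    return np.asarray(aligned, dtype=float)


def congruence_matrix(aligned, landmark_ids=None) -> np.ndarray:
    """Landmark congruence coefficients: entry (i, j) is the centered
    cross-product of landmarks i and j's 3-D deviation vectors across
    specimens, normalized by the product of their deviation norms.
    Symmetric, unit diagonal, entries in [-1, 1]."""
    X = _coords_of(aligned)
    n, k, _ = X.shape
    if n < 4:
        raise ValidationError("need at least 4 specimens")
    D = X - X.mean(axis=0)
    G = np.einsum("nid,njd->ij", D, D)
    norms = np.sqrt(np.diag(G))
    bad = np.flatnonzero(norms <= 0)
    if bad.size:
        name = (landmark_ids[bad[0]] if landmark_ids is not None
                else f"index {bad[0]}")
        raise ValidationError(f"zero-variance landmark: {name}")
    R = G / np.outer(norms, norms)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


# ---------------------------------------------------------------------------
# EMMLi-style maximum-likelihood fit

class CorrelationModularity:
    """ML comparison of module hypotheses on a landmark congruence matrix.

    Parameters
    ----------
    corr
        ``(k, k)`` congruence (or correlation) matrix.
    hypotheses
        Iterable of :class:`ModuleHypothesis`.  A single-module null is
        always evaluated in addition.
    n_specimens
        Sample size behind the correlations (> 3; sets the Fisher-z
        variance 1/(n-3)).
    """

    def __init__(self, corr: np.ndarray, hypotheses, n_specimens: int):
        self.corr = np.asarray(corr, dtype=float)
        k = self.corr.shape[0]
        if self.corr.shape != (k, k):
            raise ValidationError("corr must be square")
        if n_specimens <= 3:
            raise ValidationError(
                "n_specimens must exceed 3 (Fisher-z variance undefined)")
        self.n_specimens = int(n_specimens)
        self.hypotheses = list(hypotheses)
        for h in self.hypotheses:
            if len(h.labels) != k:
                raise ValidationError(
                    f"hypothesis {h.name!r} labels length {len(h.labels)} != {k}")
        if not any(h.n_modules == 1 for h in self.hypotheses):
            self.hypotheses.append(
                ModuleHypothesis("no_modules", ("all",) * k))

    def fit(self) -> "ModularityResults":
        k = self.corr.shape[0]
        iu = np.triu_indices(k, 1)
        r = np.abs(self.corr[iu])
        z = np.arctanh(np.clip(r, 0.0, _Z_CLAMP))
        var = 1.0 / (self.n_specimens - 3)
        const = -0.5 * np.log(2.0 * np.pi * var)
        n_pairs = r.size

        records = []
        rho_store: dict[str, dict[str, float]] = {}
        for hyp in self.hypotheses:
            labels = np.asarray(hyp.labels, dtype=object)
            li, lj = labels[iu[0]], labels[iu[1]]
            within = li == lj
            mods = sorted(set(hyp.labels))
            for variant in (("pooled",) if hyp.n_modules == 1
                            else ("pooled", "separate")):
                classes: dict[str, np.ndarray] = {}
                for m in mods:
                    mask = within & (li == m)
                    if mask.any():
                        classes[f"within.{m}"] = mask
                if hyp.n_modules > 1:
                    if variant == "pooled":
                        classes["between"] = ~within
                    else:
                        for a, b in combinations(mods, 2):
                            mask = ((li == a) & (lj == b)) | ((li == b) & (lj == a))
                            if mask.any():
                                classes[f"between.{a}|{b}"] = mask
                logl = 0.0
                rho: dict[str, float] = {}
                for cname, mask in classes.items():
                    rho_c = float(np.mean(r[mask]))
                    rho[cname] = rho_c
                    z_c = np.arctanh(min(rho_c, _Z_CLAMP))
                    resid = z[mask] - z_c
                    logl += float(mask.sum()) * const - float(
                        np.sum(resid ** 2)) / (2.0 * var)
                p = len(classes) + 1
                aicc = -2.0 * logl + 2.0 * p
                if n_pairs - p - 1 > 0:
                    aicc += 2.0 * p * (p + 1) / (n_pairs - p - 1)
                model_name = (hyp.name if hyp.n_modules == 1
                              else f"{hyp.name}.{variant}")
                records.append({
                    "model": model_name, "hypothesis": hyp.name,
                    "between": variant, "n_modules": hyp.n_modules,
                    "n_params": p, "logL": logl, "AICc": aicc,
                })
                rho_store[model_name] = rho
        table = pd.DataFrame(records).set_index("model")
        d = table["AICc"] - table["AICc"].min()
        w = np.exp(-0.5 * d)
        table["weight"] = w / w.sum()
        table = table.sort_values("AICc")
        return ModularityResults(model=self, table=table, rho=rho_store)


@dataclass
class ModularityResults:
    model: CorrelationModularity
    table: pd.DataFrame
    rho: dict[str, dict[str, float]]

    @property
    def best_model(self) -> str:
        return str(self.table.index[0])

    @property
    def best_hypothesis(self) -> ModuleHypothesis:
        name = self.table.iloc[0]["hypothesis"]
        for h in self.model.hypotheses:
            if h.name == name:
                return h
        raise KeyError(name)  # pragma: no cover

    def merged_partition(self, threshold: float = 0.1) -> ModuleHypothesis:
        return merge_modules(self, threshold=threshold)

    def summary(self) -> str:
        lines = ["Maximum-likelihood modularity (congruence data)",
                 "=" * 60,
                 f"pairs: {self.model.corr.shape[0] * (self.model.corr.shape[0] - 1) // 2}"
                 f"   specimens: {self.model.n_specimens}",
                 ""]
        cols = ["n_modules", "between", "n_params", "logL", "AICc", "weight"]
        lines.append(self.table[cols].to_string(
            float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def emmli_fit(corr: np.ndarray, hypotheses, n_specimens: int
              ) -> ModularityResults:
    """Functional wrapper around ``CorrelationModularity(...).fit()``."""
    return CorrelationModularity(corr, hypotheses, n_specimens).fit()


def merge_modules(result: ModularityResults, threshold: float = 0.1,
                  model: str | None = None) -> ModuleHypothesis:
    """Apply the between/within merge rule to the AICc-best partition.

    Let ``rho_min`` be the lowest within-module correlation estimate of the
    chosen model.  Every module pair whose between-module estimate is within
    ``threshold`` of ``rho_min`` (i.e. ``rho_between >= rho_min - threshold``)
    is mergeable; mergeable pairs are united transitively (connected
    components).
    """
    hyp = result.best_hypothesis
    if model is None:
        name = result.best_model
        if result.table.loc[name, "between"] != "separate":
            alt = f"{hyp.name}.separate"
            name = alt if alt in result.rho else name
    else:
        name = model
    rho = result.rho[name]
    within = {c.split(".", 1)[1]: v for c, v in rho.items()
              if c.startswith("within.")}
    between = {tuple(c.split(".", 1)[1].split("|")): v for c, v in rho.items()
               if c.startswith("between.")}
    if not within or hyp.n_modules == 1:
        return hyp
    rho_min = min(within.values())
    mods = sorted(set(hyp.labels))
    parent = {m: m for m in mods}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for (a, b), v in between.items():
        if v >= rho_min - threshold:
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for m in mods:
        groups.setdefault(find(m), []).append(m)
    renamed = {m: "+".join(sorted(groups[find(m)])) for m in mods}
    labels = tuple(renamed[m] for m in hyp.labels)
    return ModuleHypothesis(f"{hyp.name}.merged", labels)


# ---------------------------------------------------------------------------
# covariance ratio

def _landmark_cov_squares(X: np.ndarray) -> np.ndarray:
    """k x k matrix of summed squared covariances between landmark blocks.

    Same-landmark blocks are excluded entirely (set to zero): each landmark's
    own 3x3 covariance rotates with the coordinate frame, and only dropping
    the whole block keeps the covariance ratio invariant to global rotations
    of the aligned data."""
    n, k, _ = X.shape
    Y = X.reshape(n, -1)
    S = np.cov(Y, rowvar=False, ddof=1)
    W = (S ** 2).reshape(k, 3, k, 3).sum(axis=(1, 3))
    W[np.diag_indices(k)] = 0.0
    return W


def _cr_from_codes(W: np.ndarray, codes: np.ndarray, m: int) -> float:
    onehot = np.zeros((codes.size, m))
    onehot[np.arange(codes.size), codes] = 1.0
    T = onehot.T @ W @ onehot
    within = np.diag(T)
    if np.any(within <= 0):
        raise ValidationError("module with no within-module covariation")
    iu = np.triu_indices(m, 1)
    crs = np.sqrt(T[iu] / np.sqrt(within[iu[0]] * within[iu[1]]))
    return float(np.mean(crs))


def covariance_ratio(aligned, partition, n_perm: int = 999, seed: int = 0
                     ) -> tuple[float, float, pd.DataFrame]:
    """Covariance ratio of a module partition, with a landmark-permutation
    test.

    For each module pair the CR is the root ratio of summed squared
    between-module covariances to the geometric mean of the summed squared
    within-module covariances (overall variances excluded); the overall CR
    is the mean over pairs.  CR < 1 indicates modular structure.  The
    permutation null reassigns whole landmarks (keeping each landmark's
    three coordinates together) to modules, preserving module sizes;
    ``p = (1 + #{CR_perm <= CR_obs}) / (1 + n_perm)``.
    """
    X = _coords_of(aligned)
    n, k, _ = X.shape
    if n < 3:
        raise ValidationError("need at least 3 specimens")
    labels = np.asarray(partition, dtype=object)
    if labels.size != k:
        raise ValidationError("partition length != number of landmarks")
    mods = sorted(set(labels.tolist()))
    if len(mods) < 2:
        raise ValidationError("need at least 2 modules")
    for m in mods:
        if np.sum(labels == m) < 2:
            raise ValidationError(f"module {m!r} has fewer than 2 landmarks")
    W = _landmark_cov_squares(X)
    rows = []
    for a, b in combinations(mods, 2):
        ia = np.flatnonzero(labels == a)
        ib = np.flatnonzero(labels == b)
        between = float(W[np.ix_(ia, ib)].sum())
        wa = float(W[np.ix_(ia, ia)].sum())
        wb = float(W[np.ix_(ib, ib)].sum())
        rows.append({"module1": a, "module2": b,
                     "CR": float(np.sqrt(between / np.sqrt(wa * wb)))})
    pairwise = pd.DataFrame(rows)
    cr_obs = float(pairwise["CR"].mean())
    codes = np.array([mods.index(l) for l in labels])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _cr_from_codes(W, rng.permutation(codes), len(mods)) <= cr_obs:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return cr_obs, float(p), pairwise


def default_hypothesis_set(scheme: LandmarkScheme) -> list[ModuleHypothesis]:
    """A nested scan of module hypotheses built from the scheme's labels:
    the full anatomical partition plus all coarser partitions obtained by
    progressively pooling its modules, down to two modules.  Mirrors a
    2-to-m-module hypothesis scan without hard-coding anatomy."""
    base = list(scheme.module_names)
    hyps = [ModuleHypothesis.from_scheme(scheme)]
    labels = list(scheme.modules)
    pooled = list(base)
    while len(pooled) > 2:
        a, b = pooled[-2], pooled[-1]
        merged = f"{a}+{b}"
        mapping = {m: (merged if m in (a, b) else m) for m in pooled}
        labels = [mapping.get(l, l) for l in labels]
        pooled = [m for m in pooled if m not in (a, b)] + [merged]
        hyps.append(ModuleHypothesis(f"{len(pooled)}-module", tuple(labels)))
    return hyps
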