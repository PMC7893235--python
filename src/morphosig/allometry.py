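"""Shape-on-size regression and allometry analyses.

The central object is :class:`ShapeAllometry`, a multivariate regression of
Procrustes shape coordinates on (natural) log centroid size, in the style of
a statsmodels model: build it from an aligned dataset, call :meth:`fit`, and
work with the returned :class:`ShapeAllometryResults`.

The fitted coefficient vector, normalized to unit length, is the common
allometric component (CAC): the direction of shape space most closely
aligned with size.  Projecting specimens onto it gives the standardized
shape scores of the shape-size regression; the residual shape components
(RSCs) are the principal directions of the regression residuals with the
CAC score additionally partialled out, so RSC scores are exactly
uncorrelated with CAC scores.  Significance of the size-shape association
is assessed by permutation of the size labels.

Log-log module-size regressions (slope 1 = isometry), per-module CAC
slopes (slope 0 = no shape change with size), and pairwise ANCOVA slope
comparisons complete the ontogenetic toolkit.  Natural log is used for all
sizes; log-log slopes and p-values do not depend on the base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedDataset, centroid_size
from .data import SpecimenDataset, ValidationError


class ShapeAllometry:
    """Multivariate regression of aligned shape on centered log centroid size.

    Parameters
    ----------
    aligned
        A Procrustes-aligned dataset (``AlignedDataset``), or a ``(n, k, 3)``
        coordinate stack together with ``log_sizes``.
    log_sizes
        Log centroid sizes; defaults to those stored in ``aligned``.
    """

    def __init__(self, aligned, log_sizes=None):
        if isinstance(aligned, AlignedDataset):
            self.coords = aligned.coords
            self.log_sizes = (aligned.log_sizes() if log_sizes is None
                              else np.asarray(log_sizes, float))
            self.scheme = aligned.scheme
            self.specimen_ids = list(aligned.specimen_ids)
        else:
            self.coords = np.asarray(aligned, dtype=float)
            if log_sizes is None:
                raise ValidationError("log_sizes required with raw coordinates")
            self.log_sizes = np.asarray(log_sizes, dtype=float)
            self.scheme = None
            self.specimen_ids = [f"s{i}" for i in range(self.coords.shape[0])]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must be (n, k, 3)")
        if self.coords.shape[0] != self.log_sizes.size:
            raise ValidationError("size vector does not match specimen count")
        if self.coords.shape[0] < 3:
            raise ValidationError("need at least 3 specimens")
        if np.var(self.log_sizes) <= 0:
            raise ValidationError("zero size variance")

    def fit(self, n_perm: int = 999, seed: int = 0) -> "ShapeAllometryResults":
        n, k, _ = self.coords.shape
        Y = self.coords.reshape(n, -1)
        ybar = Y.mean(axis=0)
        Yc = Y - ybar
        x = self.log_sizes
        xc = x - x.mean()
        sxx = float(xc @ xc)
        coef = (xc @ Yc) / sxx                      # (3k,) slope vector
        ss_total = float(np.sum(Yc ** 2))
        ss_explained = sxx * float(coef @ coef)
        r2 = ss_explained / ss_total if ss_total > 0 else 0.0

        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            xp = rng.permutation(xc)
            ss_p = float((xp @ Yc) @ (xp @ Yc)) / sxx
            if ss_p >= ss_explained:
                exceed += 1
        p_perm = (exceed + 1.0) / (n_perm + 1.0)

        norm_b = float(np.linalg.norm(coef))
        cac = coef / norm_b if norm_b > 0 else coef
        cac_scores = Yc @ cac
        # residual shape components: principal directions of the regression
        # residual matrix (exactly orthogonal to size), with the CAC score
        # additionally partialled out so RSC scores are exactly uncorrelated
        # with CAC scores
        E = Yc - np.outer(xc, coef)
        basis = np.linalg.qr(np.column_stack([xc, cac_scores]))[0]
        E = E - basis @ (basis.T @ E)
        U, S, Vt = np.linalg.svd(E, full_matrices=False)
        nz = S > S[0] * 1e-10 if S.size and S[0] > 0 else np.zeros(0, bool)
        rsc_directions = Vt[nz]
        rsc_scores = U[:, nz] * S[nz]

        return ShapeAllometryResults(
            model=self, coef=coef, mean_shape=ybar.reshape(k, 3),
            mean_log_size=float(x.mean()), r_squared=float(r2),
            p_value=float(p_perm), n_perm=n_perm, seed=seed,
            cac=cac, cac_scores=cac_scores, cac_slope=norm_b,
            rsc_directions=rsc_directions, rsc_scores=rsc_scores)


@dataclass
class ShapeAllometryResults:
    """Fitted shape-size regression: CAC, residual components, diagnostics."""

    model: ShapeAllometry
    coef: np.ndarray
    mean_shape: np.ndarray
    mean_log_size: float
    r_squared: float
    p_value: float
    n_perm: int
    seed: int
    cac: np.ndarray
    cac_scores: np.ndarray
    cac_slope: float          # slope of CAC score on log size = |coef|
    rsc_directions: np.ndarray
    rsc_scores: np.ndarray

    @property
    def nobs(self) -> int:
        return self.model.coords.shape[0]

    def predict_shape_at_size(self, log_size: float) -> np.ndarray:
        """Projected landmark configuration at a given log centroid size:
        the consensus plus the regression displacement.  At the mean log
        size this is the consensus exactly."""
        k = self.mean_shape.shape[0]
        disp = self.coef * (float(log_size) - self.mean_log_size)
        return self.mean_shape + disp.reshape(k, 3)

    def corrected(self) -> AlignedDataset:
        """Allometry-corrected dataset: per-specimen residuals from the
        shape-size regression with the consensus added back.  Refitting
        shape-on-size on the result gives R^2 = 0."""
        m = self.model
        n, k, _ = m.coords.shape
        Y = m.coords.reshape(n, -1)
        xc = m.log_sizes - m.log_sizes.mean()
        resid = Y - np.outer(xc, self.coef)
        cons = resid.mean(axis=0).reshape(k, 3)
        cons = cons / np.sqrt(np.sum((cons - cons.mean(axis=0)) ** 2))
        return AlignedDataset(
            scheme=m.scheme, coords=resid.reshape(n, k, 3),
            centroid_sizes=np.exp(m.log_sizes), consensus=cons,
            specimen_ids=list(m.specimen_ids),
            log={"variant": "allometry-corrected"}, augmented=True)

    def residual_component_scores(self, n_components: int | None = None
                                  ) -> np.ndarray:
        """Scores on the principal shape components of the allometry-
        corrected data (the regression residuals).

        These are the components scanned for bimodality: they are exactly
        orthogonal to size but, unlike ``rsc_scores``, are not additionally
        partialled against the CAC score, so structure that a noisy CAC
        estimate happens to overlap is not removed.
        """
        m = self.model
        n = m.coords.shape[0]
        Y = m.coords.reshape(n, -1)
        xc = m.log_sizes - m.log_sizes.mean()
        E = Y - Y.mean(axis=0) - np.outer(xc, self.coef)
        E = E - E.mean(axis=0)
        U, S, _ = np.linalg.svd(E, full_matrices=False)
        keep = S > (S[0] * 1e-10 if S.size and S[0] > 0 else np.inf)
        scores = U[:, keep] * S[keep]
        if n_components is not None:
            scores = scores[:, :n_components]
        return scores

    def summary(self) -> str:
        lines = [
            "Shape ~ log(centroid size) regression",
            "=" * 46,
            f"specimens:            {self.nobs}",
            f"coordinates:          {self.coef.size} ({self.coef.size // 3} landmarks x 3)",
            f"R-squared:            {self.r_squared:.4f}",
            f"permutation p:        {self.p_value:.4f}  ({self.n_perm} perms, seed {self.seed})",
            f"CAC slope |b|:        {self.cac_slope:.4f}",
            f"residual components:  {self.rsc_directions.shape[0]}",
        ]
        return "\n".join(lines)


def fit_shape_size_regression(aligned, log_sizes=None, n_perm: int = 999,
                              seed: int = 0) -> ShapeAllometryResults:
    """Functional wrapper around ``ShapeAllometry(...).fit(...)``."""
    return ShapeAllometry(aligned, log_sizes=log_sizes).fit(n_perm=n_perm,
                                                            seed=seed)


def allometry_correct(aligned, log_sizes=None, n_perm: int = 0,
                      seed: int = 0) -> AlignedDataset:
    """Residual (allometry-corrected) coordinates; see
    :meth:`ShapeAllometryResults.corrected`."""
    res = ShapeAllometry(aligned, log_sizes=log_sizes).fit(
        n_perm=max(n_perm, 1), seed=seed)
    return res.corrected()


# ---------------------------------------------------------------------------
# module-level allometry

def module_size_allometry(dataset: SpecimenDataset) -> pd.DataFrame:
    """OLS slope of log module centroid size on log whole centroid size.

    A slope of 1 is isometry; above 1, the module grows relatively faster
    than the skull.  Uses specimens in which the module (and the whole
    configuration) is complete.  Sizes are measured on the raw (unaligned)
    coordinates.
    """
    rows = []
    complete = [c for c in dataset.configurations if c.is_complete]
    if len(complete) < 3:
        raise ValidationError("need >= 3 complete specimens")
    whole = np.log([centroid_size(c) for c in complete])
    for mod in dataset.scheme.module_names:
        idx = dataset.scheme.module_indices(mod)
        if idx.size < 2:
            raise ValidationError(f"module {mod!r} has fewer than 2 landmarks")
        mod_cs = np.log([centroid_size(c.coords[idx]) for c in complete])
        fit = stats.linregress(whole, mod_cs)
        rows.append({"module": mod, "slope": fit.slope,
                     "stderr": fit.stderr, "intercept": fit.intercept,
                     "r": fit.rvalue, "p_slope_zero": fit.pvalue,
                     "n": len(complete)})
    return pd.DataFrame(rows).set_index("module")


def cac_slope_per_module(aligned: AlignedDataset, log_sizes=None
                         ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Slope of each globally-aligned module's CAC score on log whole size.

    The module CAC is the normalized shape-size coefficient computed from
    the globally aligned coordinates restricted to the module's landmarks;
    its sign is fixed so the slope is non-negative.  A module whose shape
    does not change with size has slope 0.  Returns the slope table
    (including a ``whole`` row) and the per-specimen score vectors.
    """
    if aligned.scheme is None:
        raise ValidationError("scheme required to locate modules")
    x = aligned.log_sizes() if log_sizes is None else np.asarray(log_sizes, float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    n = aligned.n
    rows = []
    scores_out: dict[str, np.ndarray] = {}

    def one(name: str, cols: np.ndarray) -> None:
        Y = aligned.coords[:, cols, :].reshape(n, -1)
        Yc = Y - Y.mean(axis=0)
        b = (xc @ Yc) / sxx
        nb = float(np.linalg.norm(b))
        cac = b / nb if nb > 0 else b
        s = Yc @ cac
        slope = float((xc @ s) / sxx)
        if slope < 0:          # orient the CAC to correlate positively with size
            cac, s, slope = -cac, -s, -slope
        resid = s - slope * xc
        dof = max(n - 2, 1)
        se = float(np.sqrt(np.sum(resid ** 2) / dof / sxx))
        rows.append({"module": name, "slope": slope, "stderr": se, "n": n})
        scores_out[name] = s

    for mod in aligned.scheme.module_names:
        one(mod, aligned.scheme.module_indices(mod))
    one("whole", np.arange(aligned.k))
    return pd.DataFrame(rows).set_index("module"), scores_out


def compare_slopes_ancova(x, y, group) -> pd.DataFrame:
    """Pairwise slope-difference tests: for each pair of groups, fit
    ``y ~ x + group + x:group`` and F-test the interaction term."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    group = np.asarray(group)
    labels = pd.unique(group)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g1, g2 = labels[i], labels[j]
            m = (group == g1) | (group == g2)
            xs, ys = x[m], y[m]
            gs = (group[m] == g2).astype(float)
            if np.sum(gs == 0) < 3 or np.sum(gs == 1) < 3:
                raise ValidationError("need >= 3 points per group")
            X_full = np.column_stack([np.ones(xs.size), xs, gs, xs * gs])
            X_red = X_full[:, :3]
            F, p = _nested_f_test(X_red, X_full, ys)
            rows.append({"group1": g1, "group2": g2, "F": F, "p": p})
    return pd.DataFrame(rows)


def _nested_f_test(X_red: np.ndarray, X_full: np.ndarray, y: np.ndarray
                   ) -> tuple[float, float]:
    nobs = y.size
    for X in (X_red, X_full):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError("singular ANCOVA design")
    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)
    sse_r, sse_f = sse(X_red), sse(X_full)
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = nobs - X_full.shape[1]
    if df_den <= 0:
        raise ValidationError("not enough observations for the F test")
    if sse_f <= 0:
        # interaction SS zero with a perfect fit => no evidence of difference
        return 0.0, 1.0
    F = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, df_num, df_den))
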