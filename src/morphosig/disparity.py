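"""Morphological disparity: per-landmark and per-module Procrustes variance.

The Procrustes variance of a landmark is the mean squared 3-D deviation of
its aligned position from the consensus (sample divisor n-1); module
variances are the sums over their landmarks, and are additionally divided by
the landmark count so modules of different landmark density can be compared.
A small covariate test (OLS across modules) asks whether disparity tracks
growth rate or within-module integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedDataset
from .data import ValidationError


@dataclass
class DisparityTable:
    per_landmark: pd.Series       # variance per landmark id/index
    per_module: pd.DataFrame      # summed + normalized variance per module
    total: float
    variant: str = "raw"

    def __post_init__(self) -> None:
        if (self.per_landmark < -1e-15).any():
            raise ValidationError("negative variance")


def procrustes_variance(aligned, partition=None, variant: str = "raw"
                        ) -> DisparityTable:
    """Per-landmark and per-module Procrustes variance of an aligned dataset.

    ``partition`` maps module name -> landmark indices; defaults to the
    dataset's scheme.  Module sums equal the sums of their landmarks'
    variances exactly, and the per-landmark variances sum to the total
    Procrustes variance of the dataset.
    """
    if isinstance(aligned, AlignedDataset):
        X = aligned.coords
        consensus = aligned.consensus
        scheme = aligned.scheme
    else:
        X = np.asarray(aligned, dtype=float)
        consensus = X.mean(axis=0)
        scheme = None
    n, k, _ = X.shape
    if n < 2:
        raise ValidationError("need at least 2 specimens")
    dev = X - X.mean(axis=0)
    per_lm = np.sum(dev ** 2, axis=(0, 2)) / (n - 1)
    ids = (list(scheme.landmark_ids) if scheme is not None
           else list(range(k)))
    per_landmark = pd.Series(per_lm, index=ids, name="variance")
    if partition is None and scheme is not None:
        partition = scheme.partition()
    rows = []
    if partition:
        for mod, idx in partition.items():
            idx = np.asarray(idx, dtype=int)
            s = float(per_lm[idx].sum())
            rows.append({"module": mod, "n_landmarks": int(idx.size),
                         "variance": s, "normalized": s / idx.size})
    per_module = (pd.DataFrame(rows).set_index("module") if rows
                  else pd.DataFrame())
    return DisparityTable(per_landmark=per_landmark, per_module=per_module,
                          total=float(per_lm.sum()), variant=variant)


def disparity_covariate_test(module_disparity, covariate
                             ) -> tuple[float, float, float]:
    """OLS of per-module disparity on a per-module covariate (e.g. growth
    rate, or within-module correlation); returns (slope, r, two-sided p)."""
    y = np.asarray(module_disparity, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValidationError("need matched covariate values for >= 3 modules")
    if np.var(x) <= 0:
        raise ValidationError("zero covariate variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue), float(fit.pvalue)
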