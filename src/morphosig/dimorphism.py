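"""Tests for sexual (bimodal) shape dimorphism.

In a pooled sample of unknown-sex individuals, sexual shape dimorphism is
expected to show up as bimodality of shape scores once the dominant
confound — allometric (size-related) variation — has been removed.  The
scan therefore applies Hartigan's dip test to the leading residual shape
components of allometry-corrected datasets, for the whole structure and per
module, with and without the smallest ('juvenile') specimens.

The dip null distribution is Monte Carlo from uniform samples (the
asymptotically least-favourable unimodal distribution); null dips are cached
per sample size, so scanning many components costs one null simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._dip import dip_statistic
from .data import ValidationError

__all__ = ["DipResult", "dip_statistic", "dip_test", "dimorphism_scan",
           "exclude_juveniles"]

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def null_dip_distribution(n: int, n_mc: int = 10000, seed: int = 0
                          ) -> np.ndarray:
    """Sorted dip statistics of ``n_mc`` uniform(0,1) samples of size ``n``."""
    key = (n, n_mc, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.0, 1.0, size=(n_mc, n))
        _NULL_CACHE[key] = np.sort([dip_statistic(row) for row in u])
    return _NULL_CACHE[key]


@dataclass
class DipResult:
    n: int
    statistic: float
    p_value: float
    component: int = 0
    variant: str = ""
    subset: str = "all"

    def __post_init__(self) -> None:
        lo, hi = 1.0 / (2.0 * self.n), 0.25
        if not (lo - 1e-12 <= self.statistic <= hi + 1e-12):
            raise ValidationError(
                f"dip {self.statistic} outside [{lo}, {hi}]")


def dip_test(values, n_mc: int = 10000, seed: int = 0) -> DipResult:
    """Hartigan's dip test with a Monte-Carlo uniform null.

    ``p = (1 + #{null dips >= observed}) / (1 + n_mc)`` — never exactly
    zero, monotone non-increasing in the observed statistic.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValidationError("dip test needs at least 4 values")
    d = dip_statistic(values)
    null = null_dip_distribution(values.size, n_mc, seed)
    exceed = null.size - np.searchsorted(null, d, side="left")
    p = (1.0 + exceed) / (1.0 + null.size)
    return DipResult(n=values.size, statistic=d, p_value=float(p))


def dimorphism_scan(score_sets: Mapping[str, np.ndarray],
                    n_components: int = 8, n_mc: int = 10000,
                    seed: int = 0, alpha: float = 0.05,
                    subset: str = "all") -> pd.DataFrame:
    """Dip-test the first ``n_components`` residual shape components of each
    dataset variant.

    ``score_sets`` maps a variant name (e.g. ``whole_skull``,
    ``frill_global``) to a specimens-by-components score matrix.  Returns one
    row per (variant, component) with the dip, its Monte-Carlo p-value and a
    ``flag`` at ``p < alpha``; the expected number of false flags
    (``n_tests * alpha``) is attached as ``DataFrame.attrs['expected_false_flags']``
    since no multiplicity correction is applied to the individual p-values.
    """
    rows = []
    for variant, scores in score_sets.items():
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2:
            raise ValidationError(f"variant {variant!r}: score matrix expected")
        m = min(n_components, scores.shape[1])
        for comp in range(m):
            res = dip_test(scores[:, comp], n_mc=n_mc, seed=seed)
            rows.append({
                "variant": variant, "subset": subset, "component": comp + 1,
                "n": res.n, "dip": res.statistic, "p": res.p_value,
                "flag": res.p_value < alpha,
            })
    out = pd.DataFrame(rows)
    out.attrs["expected_false_flags"] = len(out) * alpha
    out.attrs["alpha"] = alpha
    return out


def exclude_juveniles(log_sizes, gap_factor: float = 2.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic size-gap rule for flagging 'juvenile' specimens.

    Sorts log centroid sizes and finds the largest gap; when that gap
    exceeds ``gap_factor`` times the median of the remaining gaps, all
    specimens below it are flagged juvenile.  Returns
    ``(adult_indices, juvenile_mask)``.  With evenly spread sizes nothing is
    flagged.  This replaces a by-eye split of the allometry plot with a
    reproducible rule.
    """
    sizes = np.asarray(log_sizes, dtype=float).ravel()
    n = sizes.size
    if n < 4:
        raise ValidationError("too few specimens to identify juveniles")
    order = np.argsort(sizes, kind="stable")
    gaps = np.diff(sizes[order])
    i_max = int(np.argmax(gaps))
    others = np.delete(gaps, i_max)
    med = float(np.median(others)) if others.size else 0.0
    juvenile = np.zeros(n, dtype=bool)
    if med > 0 and gaps[i_max] > gap_factor * med and 0 < i_max + 1 < n:
        juvenile[order[: i_max + 1]] = True
    adults = np.flatnonzero(~juvenile)
    return adults, juvenile
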