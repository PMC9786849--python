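"""Mendelian segregation statistics and multiple-testing utilities.

A recessive monogenic trait segregates 3:1 (wild type : mutant) in an F2 or
selfed T1; the χ² goodness-of-fit test checks observed phenotype counts
against any such expected ratio.  No continuity correction is applied: the
uncorrected statistic is the one that reproduces the classic worked values
(55:15 against 3:1 gives χ²=0.48, P=0.49; 94:23 gives χ²=1.78, P=0.18).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["SegregationResult", "chi_square_gof", "bh_adjust"]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float

    def __str__(self) -> str:
        obs = ":".join(str(o) for o in self.observed)
        rat = ":".join(f"{r:g}" for r in self.ratio)
        return (
            f"observed {obs} vs ratio {rat}: "
            f"chi2={self.chi_square:.2f}, df={self.df}, P={self.p_value:.2f}"
        )


def chi_square_gof(
    observed: Sequence[int], ratio: Sequence[float]
) -> SegregationResult:
    """χ² goodness of fit of observed class counts to an expected ratio.

    Expected counts are total × ratio_i / Σratio; the statistic is
    Σ(obs−exp)²/exp with df = k−1, no continuity correction.  Full
    precision is kept internally; format to 2 dp for display.
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.shape != rat.shape:
        raise ValueError("observed and ratio must be 1-D and equal length")
    if np.any(obs < 0):
        raise ValueError("observed counts must be >= 0")
    if np.any(rat <= 0):
        raise ValueError("ratio entries must be > 0")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be > 0")
    expected = total * rat / rat.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        ratio=tuple(float(r) for r in rat),
        expected=tuple(float(e) for e in expected),
        chi_square=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
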