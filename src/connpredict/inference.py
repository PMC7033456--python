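"""Significance of cross-validated prediction correlations.

The averaged cross-validated correlation R between predicted and observed
scores is tested with the standard correlation t statistic,
t = R * sqrt(N - 2) / sqrt(1 - R^2) on N - 2 degrees of freedom, against
the positive tail only: a negative R means the model predicts worse than
chance, which is not interpretable as predictive power. Within each
hypothesis family the one-tailed p values receive a Benjamini-Hochberg
step-up false-discovery-rate adjustment, and findings are declared at
adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError
from .model import PredictionResult

__all__ = ["SignificanceResult", "r_to_p", "bh_fdr", "assemble_family"]


@dataclass(frozen=True)
class SignificanceResult:
    """One tested (network set, subscale) cell within a hypothesis family."""

    family: str
    network_set: str
    subscale: str
    R: float
    N: int
    t: float
    df: int
    p_uncorrected: float
    p_fdr: float
    significant: bool


def r_to_p(R: float, N: int, tails: str = "one") -> tuple[float, float]:
    """t statistic and p value for a correlation coefficient.

    Parameters
    ----------
    R : correlation, |R| < 1.
    N : number of paired observations (df = N - 2).
    tails : "one" for the positive upper tail (default), "two" for the
        conventional two-sided test.
    """
    if not np.isfinite(R) or abs(R) >= 1:
        raise ValueError(f"R must lie strictly inside (-1, 1), got {R}")
    if N < 3:
        raise DataError("need N >= 3 for a correlation test")
    df = N - 2
    t = R * np.sqrt(df) / np.sqrt(1.0 - R * R)
    if tails == "one":
        p = stats.t.sf(t, df)
    elif tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float(t), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assemble_family(
    results: list[PredictionResult],
    family: str,
    alpha: float = 0.05,
    tails: str = "one",
) -> list[SignificanceResult]:
    """Test every result in one hypothesis family with a shared BH correction.

    Significance requires adjusted p < `alpha` and R > 0; negative R is
    never flagged, whatever its p value.
    """
    if not results:
        raise DataError("empty result collection")
    Ns = {res.n_subjects for res in results}
    if len(Ns) != 1:
        raise DataError(f"mixed cohort sizes within one family: {sorted(Ns)}")
    N = Ns.pop()
    tps = [r_to_p(res.R, N, tails=tails) for res in results]
    p_adj = bh_fdr([p for _, p in tps])
    out = []
    for res, (t, p), q in zip(results, tps, p_adj):
        out.append(
            SignificanceResult(
                family=family,
                network_set=res.network_set,
                subscale=res.subscale,
                R=float(res.R),
                N=N,
                t=t,
                df=N - 2,
                p_uncorrected=p,
                p_fdr=float(q),
                significant=bool(q < alpha and res.R > 0),
            )
        )
    return out


def significance_table(results: list[SignificanceResult]) -> pd.DataFrame:
    """Flat results table (one row per tested cell)."""
    return pd.DataFrame(
        [
            {
                "family": s.family,
                "network_set": s.network_set,
                "subscale": s.subscale,
                "R": s.R,
                "t": s.t,
                "df": s.df,
                "p_uncorrected": s.p_uncorrected,
                "p_fdr": s.p_fdr,
                "significant": s.significant,
            }
            for s in results
        ]
    )
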