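"""IRI questionnaire scoring and descriptive statistics.

The trait-empathy instrument used here has 24 statements rated on an
integer 0-5 scale, six items per subscale: Fantasizing (FS), Empathic
Concern (EC), Perspective Taking (PT) and Personal Distress (PD). Each
subscale score is the plain sum of its six items, so scores live on
0..30. (The widely published long form of the instrument has 28 items
and reverse-scored statements; this implementation follows the 24-item,
positively-keyed variant and makes the item-to-subscale map explicit.)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataError, UndefinedReliabilityError

__all__ = [
    "SUBSCALES",
    "DEFAULT_ITEM_MAP",
    "item_columns",
    "score_iri",
    "cronbach_alpha",
    "sex_anova",
]

SUBSCALES = ("FS", "EC", "PT", "PD")

#: items 1-6 -> FS, 7-12 -> EC, 13-18 -> PT, 19-24 -> PD
DEFAULT_ITEM_MAP: dict[str, tuple[int, ...]] = {
    sub: tuple(range(6 * k + 1, 6 * k + 7)) for k, sub in enumerate(SUBSCALES)
}


def item_columns(items: tuple[int, ...] | list[int]) -> list[str]:
    return [f"item_{i:02d}" for i in items]


def _validate_item_map(item_map: dict[str, tuple[int, ...]]) -> None:
    if set(item_map) != set(SUBSCALES):
        raise ConfigError(f"item map must cover exactly {SUBSCALES}")
    all_items = [i for items in item_map.values() for i in items]
    if sorted(all_items) != list(range(1, 25)):
        raise ConfigError("item map must assign items 1..24 exactly once")
    if any(len(items) != 6 for items in item_map.values()):
        raise ConfigError("each subscale must be measured by exactly 6 items")


def score_iri(
    responses: pd.DataFrame,
    item_map: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Sum item ratings into the four subscale scores.

    Parameters
    ----------
    responses : DataFrame
        One row per subject with columns item_01..item_24 of integer
        ratings in 0..5 (a 'sex' column, if present, is carried through).
    item_map : dict, optional
        Subscale -> 6 item numbers; defaults to the contiguous block map.

    Returns
    -------
    DataFrame with columns FS, EC, PT, PD (and sex when present), indexed
    like `responses`.
    """
    item_map = DEFAULT_ITEM_MAP if item_map is None else item_map
    _validate_item_map(item_map)
    cols = item_columns(sorted(i for it in item_map.values() for i in it))
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise DataError(f"response table missing item columns: {missing[:3]}...")
    vals = responses[cols].to_numpy()
    if not np.isin(vals, np.arange(6)).all():
        raise DataError("item ratings must be integers in 0..5")
    out = pd.DataFrame(index=responses.index)
    for sub in SUBSCALES:
        out[sub] = responses[item_columns(item_map[sub])].sum(axis=1).astype(int)
    if "sex" in responses.columns:
        out["sex"] = responses["sex"]
    return out


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha internal-consistency reliability.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total
    score). Population (divide-by-n) variances are used throughout; the
    ratio, and hence alpha, is identical under any consistent variance
    convention.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DataError("need a 2-D matrix with at least 2 items")
    if X.shape[0] < 3:
        raise DataError("need at least 3 subjects")
    k = X.shape[1]
    total_var = X.sum(axis=1).var()
    if total_var == 0:
        raise UndefinedReliabilityError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0).sum() / total_var))


def sex_anova(scores, sex) -> tuple[float, float]:
    """One-way ANOVA comparing a score between the two sexes.

    Returns the classical F statistic with (1, N-2) degrees of freedom and
    its two-tailed p value.
    """
    scores = np.asarray(scores, dtype=float)
    sex = np.asarray(sex)
    groups = [scores[sex == g] for g in np.unique(sex)]
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        raise DataError("need exactly two groups with at least 2 members each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
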