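"""Exposure preparation: creatinine adjustment, decile coding, Spearman screen.

Concentrations are handled as a pandas DataFrame (subjects x metals) in
µg/g creatinine.  Each metal column is independently recoded to decile
ranks 0-9 using the empirical decile cut points of that column; the rank
matrix is the raw material of the weighted-index regression downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecileMatrix",
    "creatinine_adjust",
    "decile_transform",
    "decile_matrix",
    "spearman_matrix",
]


class DegenerateColumnError(ValueError):
    """Raised when a constant exposure column cannot be quantized."""


@dataclass(frozen=True)
class DecileMatrix:
    """Integer decile ranks (0-9) per subject x metal plus the cut points.

    ``ranks`` is a DataFrame of ints; ``thresholds`` maps each metal to
    its nine decile cut points (non-decreasing).
    """

    ranks: pd.DataFrame
    thresholds: pd.DataFrame  # 9 rows (q10..q90) x metals

    def __post_init__(self) -> None:
        vals = self.ranks.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 9):
            raise ValueError("decile ranks must lie in 0..9")

    @property
    def n_subjects(self) -> int:
        return len(self.ranks)

    def restrict(self, metals: list[str] | tuple[str, ...]) -> pd.DataFrame:
        return self.ranks.loc[:, list(metals)]


def creatinine_adjust(conc_ug_per_l, creatinine_g_per_l, subject_ids=None):
    """Convert µg/L concentrations to µg/g creatinine.

    Parameters are scalars or aligned arrays; creatinine must be strictly
    positive (urine with no creatinine has no defined dilution correction).
    """
    conc = np.asarray(conc_ug_per_l, dtype=float)
    crea = np.asarray(creatinine_g_per_l, dtype=float)
    bad = ~(crea > 0)
    if np.any(bad):
        if subject_ids is not None:
            ids = np.asarray(subject_ids)[np.atleast_1d(bad)]
            raise ValueError(f"non-positive creatinine for subjects {list(ids)}")
        raise ValueError("creatinine must be strictly positive")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    out = conc / crea
    return float(out) if out.ndim == 0 else out


def decile_transform(values) -> tuple[np.ndarray, np.ndarray]:
    """Decile-code one metal column.

    Returns ``(ranks, thresholds)``: nine cut points are the empirical
    deciles (linear interpolation of order statistics, the "type 7"
    convention) and each value receives the count of cut points strictly
    below it, so ties at a cut point fall in the lower bin and the top
    bin is closed.  The coding is invariant under strictly increasing
    transformations of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("decile_transform expects a 1-d column")
    if x.size < 10 or not np.all(np.isfinite(x)):
        raise ValueError("need at least 10 finite values to form deciles")
    if np.min(x) == np.max(x):
        raise DegenerateColumnError("constant column cannot be decile-coded")
    thresholds = np.quantile(x, np.arange(1, 10) / 10.0, method="linear")
    ranks = np.searchsorted(thresholds, x, side="left").astype(np.int64)
    counts = np.bincount(ranks, minlength=10)
    if counts.max() - counts.min() > 1 and len(np.unique(x)) == x.size:
        # unreachable for tie-free columns; kept as a sanity tripwire
        warnings.warn(f"unbalanced decile occupancy {counts.tolist()}")
    elif counts.max() - counts.min() > 1:
        warnings.warn(
            f"heavily tied column: decile occupancies {counts.tolist()}",
            stacklevel=2,
        )
    return ranks, thresholds


def decile_matrix(exposures: pd.DataFrame) -> DecileMatrix:
    """Decile-code every metal column of an exposure table.

    Deciles are computed once on the full analytic sample; training /
    validation subsets downstream reuse these codes rather than
    re-quantizing per split.
    """
    ranks = {}
    thr = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occupancy warnings handled per column
        for col in exposures.columns:
            r, t = decile_transform(exposures[col].to_numpy())
            ranks[col] = r
            thr[col] = t
    ranks_df = pd.DataFrame(ranks, index=exposures.index)
    thr_df = pd.DataFrame(thr, index=[f"q{10 * i}" for i in range(1, 10)])
    return DecileMatrix(ranks=ranks_df, thresholds=thr_df)


def spearman_matrix(exposures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between metal columns.

    Average ranks are used for ties.  A constant column has undefined
    rank correlation: its off-diagonal entries are reported as NaN (never
    silently zeroed); the diagonal is 1 by convention.
    """
    if len(exposures) < 3:
        raise ValueError("need at least 3 subjects for a correlation screen")
    X = exposures.to_numpy(dtype=float)
    cols = list(exposures.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:  # two-column tables collapse to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    constant = X.std(axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)
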