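"""Relative-change sign agreement, majority-vote fusion, and phase tests.

The predictive capacity of sensor and in-game features toward perceived
engagement is measured without assuming linearity: for every pair of
adjacent observation frames the *direction* of change of each feature is
recorded (+1 / −1, or excluded when no clear change is present), and the
agreement coefficient

    c^z_{i-j} = (1/N) Σ_k z_k,   z_k = +1 if the signs of features i and j
                                 match on pair k, −1 otherwise

is computed over the N retained pairs pooled across participants.  Under
the null of unrelated directions the number of matches is Binomial(N, ½),
which yields an exact two-sided p-value.  A multimodal feature V takes,
per pair, the majority sign over all primary features (ties excluded).
Wilcoxon signed-rank tests compare paired per-participant values between
game phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgumentError, UndefinedResultError

#: Sign alphabet: +1 increase, −1 decrease, 0 excluded (no clear change).
EXCLUDED = 0


def relative_change_sign(
    x1: float,
    x2: float,
    clarity: float = 0.05,
    floor: float = 1e-9,
) -> int:
    """Direction of change from x1 to x2, or 0 when the change is unclear.

    A change counts as clear when |x2 − x1| exceeds ``clarity`` times the
    scale max(|x1|, |x2|, ``floor``).  NaN inputs are excluded with a
    warning.
    """
    if np.isnan(x1) or np.isnan(x2):
        warnings.warn("NaN feature value: pair excluded", stacklevel=2)
        return EXCLUDED
    scale = max(abs(x1), abs(x2), floor)
    d = x2 - x1
    if d > clarity * scale:
        return 1
    if d < -clarity * scale:
        return -1
    return EXCLUDED


def sign_series(
    x1: np.ndarray, x2: np.ndarray, clarity: float = 0.05, floor: float = 1e-9
) -> np.ndarray:
    """Vector of relative-change signs for pooled frame pairs."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    out = np.zeros(len(x1), dtype=np.int8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(len(x1)):
            out[k] = relative_change_sign(x1[k], x2[k], clarity, floor)
    return out


@dataclass(frozen=True)
class AgreementResult:
    """The c^z statistic with its exact binomial significance."""

    coefficient: float  # c^z in [−1, 1]
    n_pairs: int  # N, retained pairs
    n_matches: int  # m
    p_value: float  # two-sided binomial


def agreement_coefficient(
    signs_i: np.ndarray, signs_j: np.ndarray
) -> AgreementResult:
    """c^z between two sign series; pairs excluded on either side are dropped.

    p is the exact two-sided binomial tail: 2·min(P[Bin(N,½) ≥ m],
    P[Bin(N,½) ≤ m]), capped at 1.
    """
    si = np.asarray(signs_i)
    sj = np.asarray(signs_j)
    if len(si) != len(sj):
        raise InvalidArgumentError("sign series must have equal length")
    keep = (si != EXCLUDED) & (sj != EXCLUDED)
    n = int(keep.sum())
    if n == 0:
        raise UndefinedResultError("no retained pairs (N = 0)")
    m = int((si[keep] == sj[keep]).sum())
    c = (2 * m - n) / n
    p = 2.0 * min(sps.binom.cdf(m, n, 0.5), sps.binom.sf(m - 1, n, 0.5))
    return AgreementResult(float(c), n, m, float(min(p, 1.0)))


def majority_vote(sign_matrix: np.ndarray) -> np.ndarray:
    """Per-pair majority sign over the feature columns (ties/empty → excluded)."""
    M = np.atleast_2d(np.asarray(sign_matrix))
    if M.shape[1] < 1:
        raise InvalidArgumentError("at least one feature column required")
    return np.sign(M.sum(axis=1)).astype(np.int8)


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention); the exact
    distribution is used for n ≤ 25 without ties, the tie-corrected normal
    approximation otherwise.  All-zero differences give p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidArgumentError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero: p = 1", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "approx" if (len(d) > 25 or has_ties) else "exact"
    res = sps.wilcoxon(d, alternative=alternative, method=method, correction=True)
    return float(res.pvalue)


HIGHLY_SIGNIFICANT = "highly-significant"
SIGNIFICANT = "significant"
NOT_SIGNIFICANT = "ns"


def significance_label(p: float) -> str:
    """Classify a p-value: <1% highly significant, <5% significant, else ns."""
    if not (0 <= p <= 1):
        raise InvalidArgumentError(f"invalid p-value {p}")
    if p < 0.01:
        return HIGHLY_SIGNIFICANT
    if p < 0.05:
        return SIGNIFICANT
    return NOT_SIGNIFICANT


def significance_labels(results: pd.DataFrame, p_col: str = "p_value") -> pd.DataFrame:
    """Append a ``significance`` column derived from ``p_col``."""
    out = results.copy()
    out["significance"] = [significance_label(p) for p in out[p_col]]
    return out


def agreement_table(
    signs: pd.DataFrame,
    annotation_features: list[str],
    primary_features: list[str],
    vote_column: str = "V",
) -> pd.DataFrame:
    """All c^z combinations of annotation × (primary + vote) sign columns.

    ``signs`` holds one row per pooled frame pair and one int8 sign column
    per feature.  Combinations with no retained pairs are reported with
    NaN coefficient and p = 1.
    """
    rows = []
    for i in annotation_features:
        for j in primary_features + [vote_column]:
            if j not in signs.columns:
                continue
            try:
                r = agreement_coefficient(signs[i].to_numpy(), signs[j].to_numpy())
                rows.append(
                    {
                        "annotation_feature": i,
                        "feature": j,
                        "c": r.coefficient,
                        "N": r.n_pairs,
                        "m": r.n_matches,
                        "p_value": r.p_value,
                    }
                )
            except UndefinedResultError:
                rows.append(
                    {
                        "annotation_feature": i,
                        "feature": j,
                        "c": np.nan,
                        "N": 0,
                        "m": 0,
                        "p_value": 1.0,
                    }
                )
    return significance_labels(pd.DataFrame(rows))
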