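"""Cognitive scores versus myelin: reference z-scoring, Spearman
correlations, and Benjamini-Yekutieli FDR control under dependence.

BTACT subscores are standardized against normative means/sds from a reference
cohort, then rank-correlated with regional or cortex-mean R measures.  Because
the subscores are intercorrelated, the multiplicity correction is the
Benjamini-Yekutieli step-up rule, which is valid under arbitrary dependence.
"""

from __future__ import annotations

from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscore_against_reference",
    "spearman_correlation",
    "by_fdr",
    "correlation_battery",
]


def zscore_against_reference(x, mu: float, sigma: float) -> np.ndarray:
    """z = (x - mu) / sigma against reference-cohort norms."""
    if sigma <= 0:
        raise ValueError("reference sigma must be positive")
    return (np.asarray(x, dtype=float) - mu) / sigma


def _exact_spearman_p(a_rank: np.ndarray, b_rank: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's r at small n."""
    n = len(a_rank)
    b_c = b_rank - b_rank.mean()
    a_c = a_rank - a_rank.mean()
    denom = np.sqrt((a_c**2).sum() * (b_c**2).sum())
    count = 0
    total = 0
    perm_iter = permutations(range(n))
    chunk = 200_000
    while True:
        block = np.array(list(islice(perm_iter, chunk)), dtype=np.intp)
        if block.size == 0:
            break
        r = a_c[block] @ b_c / denom
        count += int(np.count_nonzero(np.abs(r) >= abs(r_obs) - 1e-12))
        total += len(block)
    return count / total


def spearman_correlation(a, b) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    Average ranks for ties; p from the t approximation for n > 10 and from
    the exact permutation distribution for n <= 10 (where the approximation
    is unreliable).  Constant inputs are undefined and rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 4:
        raise ValueError("need paired samples of length >= 4")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant input; rank correlation undefined")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    r = float(np.corrcoef(ra, rb)[0, 1])
    n = len(a)
    if n <= 10:
        p = _exact_spearman_p(ra, rb, r)
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def by_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR control for dependent tests.

    Rejects the ordered p_(i) with p_(i) <= i * q / (m * c(m)), where
    c(m) = sum_{j<=m} 1/j is the harmonic penalty that buys validity under
    arbitrary dependence.  Returns ``(reject, p_adjusted)`` with monotone
    adjusted p values.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_by")
    return reject, np.minimum(p_adj, 1.0)


def correlation_battery(
    cognition: pd.DataFrame,
    myelin: pd.DataFrame,
    norms: pd.DataFrame | None = None,
    scores: tuple[str, ...] = ("EVMI", "EVMD", "WMS", "VF", "IR", "PS"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Correlate each cognitive score with each myelin measure, BY-corrected.

    Parameters
    ----------
    cognition
        One row per subject x visit with the score columns (raw units).
    myelin
        One row per subject with myelin measure columns (e.g. ``delta_r``,
        ``R_baseline``, ``R_followup``) indexed or keyed by ``subject_id``.
    norms
        Optional reference norms (columns score, mu, sigma) used to z-score
        the raw scores first; ranks (hence r) are unaffected, so this only
        matters for reporting standardized scores.
    q
        FDR level for the Benjamini-Yekutieli correction, applied over the
        whole battery (one family per call; build separate calls for
        separate analysis blocks).

    Returns a tidy table: score, visit, measure, n, r, p, p_adjusted,
    significant.
    """
    if norms is not None:
        lut = norms.set_index("score")
        cognition = cognition.copy()
        for s in scores:
            if s in lut.index:
                cognition[s] = zscore_against_reference(
                    cognition[s], float(lut.loc[s, "mu"]), float(lut.loc[s, "sigma"])
                )
    measures = [c for c in myelin.columns if c != "subject_id"]
    merged_rows = []
    for visit, block in cognition.groupby("visit"):
        joined = block.merge(myelin, on="subject_id", how="inner")
        for s in scores:
            for m in measures:
                sub = joined[[s, m]].dropna()
                if len(sub) < 4:
                    continue
                r, p = spearman_correlation(sub[s], sub[m])
                merged_rows.append(
                    {"score": s, "visit": visit, "measure": m, "n": len(sub), "r": r, "p": p}
                )
    out = pd.DataFrame(merged_rows)
    if out.empty:
        raise ValueError("no correlations could be computed")
    reject, p_adj = by_fdr(out["p"].to_numpy(), q=q)
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out
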