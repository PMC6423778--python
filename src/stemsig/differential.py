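"""Differential expression: t tests, FDR q-values, ratio calls, Venn
partitioning and ddCt relative quantification.

The default test is the classical two-sample pooled-variance t on log2
signals.  A moderated variant shrinks each gene's pooled variance toward
the across-gene mean variance with a fixed prior weight (an
empirical-Bayes stand-in for moderated linear-model statistics) and
refers the statistic to a t distribution with correspondingly augmented
degrees of freedom.

Significant genes (q at or below the threshold) are called up- or
downregulated from the ratio of linear-scale group means: a ratio
strictly above 1.33 is up, strictly below 0.75 is down, everything else
unchanged.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

RATIO_UP = 1.33
RATIO_DOWN = 0.75

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


def differential_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    moderated: bool = False,
    d0: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene two-sample t statistics and two-sided p-values.

    ``group_a``/``group_b`` are genes x samples arrays on the scale the
    test should run on (log2 for expression data).  With
    ``moderated=True`` the pooled variance is shrunk toward the mean
    variance across genes, s0^2, with prior weight ``d0``:
    ``s~^2 = (d0*s0^2 + df*s^2) / (d0 + df)``, and p-values use df + d0
    degrees of freedom.  Genes with zero pooled variance and zero mean
    difference report t = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if not moderated and (na < 2 or nb < 2):
        raise ValueError("unmoderated test needs >= 2 samples per group")
    diff = a.mean(axis=1) - b.mean(axis=1)
    df = na + nb - 2
    var_a = a.var(axis=1, ddof=1) if na > 1 else np.zeros(a.shape[0])
    var_b = b.var(axis=1, ddof=1) if nb > 1 else np.zeros(b.shape[0])
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / max(df, 1)
    if moderated:
        s0 = pooled.mean()
        pooled = (d0 * s0 + df * pooled) / (d0 + df)
        df_eff = df + d0
    else:
        df_eff = df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.empty_like(t)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_eff)
    # degenerate genes: zero variance
    zero_var = se == 0
    same = zero_var & (diff == 0)
    t[same] = 0.0
    p[same] = 1.0
    apart = zero_var & (diff != 0)
    t[apart] = np.sign(diff[apart]) * np.inf
    p[apart] = np.nextafter(0.0, 1.0)
    np.clip(p, np.nextafter(0.0, 1.0), 1.0, out=p)
    return t, p


def ttest_two_tailed(x, y) -> tuple[float, float]:
    """Two-tailed unpaired equal-variance Student's t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        warnings.warn("degenerate zero-variance identical samples; p = 1",
                      stacklevel=2)
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def fdr_qvalue(
    p_values,
    method: str = "qvalue",
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values (default) or Benjamini-Hochberg adjusted p-values.

    The null proportion pi0 is estimated from the tail counts
    ``#{p > lambda} / (m (1 - lambda))`` over a lambda grid
    {0.05, ..., 0.95}, smoothed with a cubic fit and evaluated at the
    largest lambda; pass ``pi0`` to override (``pi0=1`` reproduces BH).
    q-values are made monotone nondecreasing in p by the step-up pass and
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return stats.false_discovery_control(p, method="bh")
    if method != "qvalue":
        raise ValueError(f"unknown FDR method {method!r}")
    m = p.size
    if pi0 is None:
        lambdas = (
            np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
        )
        pi0_lambda = np.array(
            [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
        )
        # cubic smoother over the lambda grid, read off at the largest lambda
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ratio_call(
    mean_a,
    mean_b,
    q,
    q_threshold: float = 0.05,
    ratio_up: float = RATIO_UP,
    ratio_down: float = RATIO_DOWN,
):
    """Up/down/unchanged calls from linear-scale mean ratios.

    A gene is *up* iff ratio > ``ratio_up`` and q <= ``q_threshold``;
    *down* iff ratio < ``ratio_down`` and q <= ``q_threshold``.  The
    boundary ratios themselves are not calls (strict inequalities).
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    q = np.asarray(q, dtype=float)
    scalar = mean_a.ndim == 0
    mean_a, mean_b, q = np.atleast_1d(mean_a, mean_b, q)
    if np.any(mean_a <= 0) or np.any(mean_b <= 0):
        raise ValueError("group means must be positive")
    ratio = mean_a / mean_b
    calls = np.full(ratio.shape, UNCHANGED, dtype=object)
    sig = q <= q_threshold
    calls[sig & (ratio > ratio_up)] = UP
    calls[sig & (ratio < ratio_down)] = DOWN
    return calls[0] if scalar else calls


def diff_table(
    signals: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    moderated: bool = False,
    fdr_method: str = "qvalue",
    q_threshold: float = 0.05,
    ratio_up: float = RATIO_UP,
    ratio_down: float = RATIO_DOWN,
) -> pd.DataFrame:
    """Full per-gene differential table on a normalized linear matrix.

    The t test runs on log2(signal + 1); ratios are linear-scale group
    means.  Columns: t_stat, p_diff, q, ratio, call.
    """
    a = signals[samples_a].to_numpy()
    b = signals[samples_b].to_numpy()
    t, p = differential_test(np.log2(a + 1), np.log2(b + 1), moderated=moderated)
    q = fdr_qvalue(p, method=fdr_method)
    call = ratio_call(
        a.mean(axis=1), b.mean(axis=1), q,
        q_threshold=q_threshold, ratio_up=ratio_up, ratio_down=ratio_down,
    )
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_diff": p,
            "q": q,
            "ratio": a.mean(axis=1) / b.mean(axis=1),
            "call": call,
        },
        index=signals.index,
    )


def venn_partition(sets: dict[str, set]) -> dict[tuple[str, ...], set]:
    """Exclusive Venn regions of 2 or 3 labelled sets.

    Returns every nonempty combination of labels (as a sorted tuple) with
    the members belonging to exactly those sets; each element appears in
    exactly one region.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn_partition takes 2 or 3 sets")
    regions: dict[tuple[str, ...], set] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                set(), *(sets[c] for c in labels if c not in combo)
            )
            regions[tuple(sorted(combo))] = inside - outside
    return regions


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_housekeeping) in the sample minus the same
    difference in the calibrator; the fold change is 2 to the -ddCt.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dd = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-dd))
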