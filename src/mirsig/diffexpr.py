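"""Per-contrast differential expression with empirical-Bayes moderation.

Implements the moderated two-sample t-statistic: per-feature pooled
variances are shrunk toward a prior variance s0^2 with d0 prior degrees of
freedom, both estimated by moment-matching the distribution of log sample
variances (digamma/trigamma relations). Raw p-values come from a Student t
with d0 + d_resid degrees of freedom and are adjusted by the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix

__all__ = [
    "fit_contrast",
    "ebayes_moderate",
    "EBayesResult",
    "moderated_t",
    "adjust_bh",
    "signed_fold",
    "log2_from_signed_fold",
    "run_contrast",
    "run_all_contrasts",
    "contrasts_to_wide",
    "contrasts_to_long",
    "CONTRAST_COLUMNS",
]

CONTRAST_COLUMNS = ["feature", "log2_diff", "signed_fold", "t_mod", "p_raw", "p_adj"]


def signed_fold(log2_diff):
    """Convert a log2 difference to the signed multiplicative fold.

    Upregulation maps to ``2**log2_diff`` (>= 1); downregulation to
    ``-(2**-log2_diff)`` (<= -1). Zero maps to +1.
    """
    x = np.asarray(log2_diff, dtype=float)
    out = np.where(x >= 0, np.power(2.0, x), -np.power(2.0, -x))
    return out if out.ndim else float(out)


def log2_from_signed_fold(fold):
    """Inverse of :func:`signed_fold`, defined for |fold| >= 1."""
    f = np.asarray(fold, dtype=float)
    if np.any(np.abs(f) < 1):
        raise ValueError("signed folds must have absolute value >= 1")
    out = np.where(f >= 0, np.log2(np.abs(f)), -np.log2(np.abs(f)))
    return out if out.ndim else float(out)


def fit_contrast(matrix: ExpressionMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-feature mean difference and pooled within-group variance.

    ``log2_diff`` is mean(group_a) - mean(group_b); ``s2`` is the pooled
    variance on ``d_resid = n_a + n_b - 2`` degrees of freedom. Features
    with zero pooled variance are flagged (``zero_variance``).
    """
    a = matrix.values[matrix.samples_in(group_a)].to_numpy(dtype=float)
    b = matrix.values[matrix.samples_in(group_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >=2 samples (got {n_a} vs {n_b})")
    d_resid = n_a + n_b - 2
    log2_diff = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / d_resid
    return pd.DataFrame(
        {
            "feature": matrix.features,
            "log2_diff": log2_diff,
            "s2": s2,
            "d_resid": d_resid,
            "n_a": n_a,
            "n_b": n_b,
            "zero_variance": s2 == 0.0,
        }
    ).set_index("feature")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


@dataclass
class EBayesResult:
    d0: float  # prior degrees of freedom (may be inf)
    s0_2: float  # prior variance
    s2_post: np.ndarray  # posterior (shrunk) variance per feature


def ebayes_moderate(s2, d_resid: float) -> EBayesResult:
    """Estimate the variance prior (d0, s0^2) and shrink each s2 toward it.

    Moment-matching on z = log(s2): the mean of z - digamma(d/2) + log(d/2)
    identifies log s0^2 and its excess variance over trigamma(d/2)
    identifies d0. When the empirical variance of z does not exceed the
    trigamma term the variances are homogeneous and d0 = inf. Zero variances
    are excluded from estimation but still receive a posterior value.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all residual variances are zero")
    if positive.sum() < 10:
        raise ValueError("need >=10 features with positive variance to estimate the prior")
    z = np.log(s2[positive])
    d2 = d_resid / 2.0
    e = z - float(special.digamma(d2)) + math.log(d2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        # degenerate case: identical variances are known exactly, no
        # sampling-bias correction applies
        s0_2 = math.exp(float(z.mean())) if z.var() == 0 else math.exp(emean)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + d_resid * s2) / (d0 + d_resid)
    return EBayesResult(d0=d0, s0_2=s0_2, s2_post=s2_post)


def moderated_t(log2_diff, s2_post, n_a: int, n_b: int, d_resid: float, d0: float):
    """Moderated t-statistic and two-sided p-value.

    t = log2_diff / sqrt(s2_post * (1/n_a + 1/n_b)), referred to a Student t
    with d0 + d_resid degrees of freedom (normal tail when d0 is infinite).
    Features with s2_post = 0 get NaN statistics.
    """
    diff = np.asarray(log2_diff, dtype=float)
    s2p = np.asarray(s2_post, dtype=float)
    scale = np.sqrt(s2p * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, diff / scale, np.nan)
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + d_resid)
    p = np.where(np.isnan(t), np.nan, p)
    if np.ndim(log2_diff) == 0:
        return float(t), float(p)
    return t, p


def adjust_bh(p_values):
    """Benjamini-Hochberg step-up adjustment (order preserving, capped at 1).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    out = np.full(p.shape, np.nan)
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        res = np.empty(m)
        res[order] = adj
        out[valid] = res
    return out if np.ndim(p_values) else float(out)


def run_contrast(matrix: ExpressionMatrix, group: str, reference: str | None = None) -> pd.DataFrame:
    """Full single-contrast table: effect, moderated test, BH adjustment."""
    reference = reference or matrix.reference_group
    fit = fit_contrast(matrix, group, reference)
    eb = ebayes_moderate(fit["s2"].to_numpy(), float(fit["d_resid"].iloc[0]))
    t, p = moderated_t(
        fit["log2_diff"].to_numpy(),
        eb.s2_post,
        int(fit["n_a"].iloc[0]),
        int(fit["n_b"].iloc[0]),
        float(fit["d_resid"].iloc[0]),
        eb.d0,
    )
    out = fit.copy()
    out["signed_fold"] = signed_fold(out["log2_diff"].to_numpy())
    out["s2_post"] = eb.s2_post
    out["t_mod"] = t
    out["p_raw"] = p
    out["p_adj"] = adjust_bh(p)
    out.attrs["d0"] = eb.d0
    out.attrs["s0_2"] = eb.s0_2
    return out


def run_all_contrasts(matrix: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """One contrast per non-reference group, each against the reference."""
    return {
        g: run_contrast(matrix, g) for g in matrix.group_order if g != matrix.reference_group
    }


def contrasts_to_wide(contrasts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-line contrast tables into the wide fold/padj selection input."""
    pieces = {}
    for line, table in contrasts.items():
        pieces[f"fold_{line}"] = table["signed_fold"]
        pieces[f"padj_{line}"] = table["p_adj"]
    wide = pd.DataFrame(pieces)
    wide.index.name = "mirna"
    return wide


def contrasts_to_long(contrasts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-line contrast tables into (cell_line, feature, signed_fold, p_adj)."""
    frames = []
    for line, table in contrasts.items():
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": line,
                    "feature": table.index,
                    "signed_fold": table["signed_fold"].to_numpy(),
                    "p_adj": table["p_adj"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
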