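"""Paired differential-abundance testing with empirical-Bayes moderation.

Per intensity, each protein is tested on the per-subject paired
differences d_{g,s} = log2(post_{g,s}) - log2(pre_{g,s}). Per-protein
variances are shrunk toward a common prior estimated by the method of
moments on log sample variances: under a scaled inverse-chi-square prior
with d0 degrees of freedom and scale s0^2, the sample variance satisfies
s2_g / s0^2 ~ F(d_g, d0), whose log has closed-form mean and variance in
digamma/trigamma terms. The moderated statistic is

    t_g = mean(d_g) / (s_tilde_g / sqrt(n)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

referred to a t distribution with d0 + d_g degrees of freedom (capped at
the total residual degrees of freedom pooled over proteins). With d0 = 0
this is the ordinary paired t-test; with d0 = infinity every protein
uses the common variance s0^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from exprot.simulate import ProteomeStudy

__all__ = [
    "ModerationHyperparams",
    "paired_log_differences",
    "estimate_moderation",
    "moderated_paired_test",
    "bh_adjust",
    "paired_t_test",
    "run_differential",
]


@dataclass(frozen=True)
class ModerationHyperparams:
    """Empirical-Bayes prior: degrees of freedom d0 (may be ``inf``) and
    prior variance s0_sq on the log2 difference scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("prior variance s0_sq must be positive")


def paired_log_differences(study: ProteomeStudy, intensity: str) -> pd.DataFrame:
    """Per-subject log2(post/pre) differences at one intensity.

    Returns a proteins x subjects matrix; its row means are the log2 fold
    changes. Raises if a subject lacks a complete pre/post pair or if any
    abundance is nonpositive.
    """
    if intensity not in ("moderate", "high"):
        raise ValueError(f"unknown intensity {intensity!r}")
    sheet = study.samples[study.samples["intensity"] == intensity]
    pre = sheet[sheet["timepoint"] == "pre"].set_index("subject_id")["sample_id"]
    post = sheet[sheet["timepoint"] == "post"].set_index("subject_id")["sample_id"]
    subjects = sorted(set(pre.index) | set(post.index))
    for s in subjects:
        if s not in pre.index or s not in post.index:
            raise ValueError(
                f"subject {s} lacks a complete pre/post pair at "
                f"{intensity} intensity"
            )
    if (study.abundance.to_numpy() <= 0).any():
        raise ValueError("abundance must be strictly positive to take logs")
    pre_mat = study.abundance[pre.loc[subjects].to_numpy()].to_numpy()
    post_mat = study.abundance[post.loc[subjects].to_numpy()].to_numpy()
    diffs = np.log2(post_mat) - np.log2(pre_mat)
    return pd.DataFrame(diffs, index=study.abundance.index, columns=subjects)


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_moderation(
    sample_variances: np.ndarray, df: int | np.ndarray
) -> ModerationHyperparams:
    """Method-of-moments fit of the variance prior (d0, s0_sq).

    Matches the mean and variance of log s2_g to their expectations under
    s2_g / s0^2 ~ F(d_g, d0). Returns d0 = inf when the observed spread of
    log variances does not exceed the chi-square sampling contribution
    trigamma(d_g/2) (no excess dispersion). Proteins with nonpositive
    variance are excluded from the fit.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError(
            "need at least two proteins with positive variance to estimate "
            "the prior"
        )
    s2, df = s2[ok], df[ok]
    if (df < 1).any():
        raise ValueError("residual degrees of freedom must be >= 1")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (e.size - 1))
    evar -= float(_trigamma(df / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_paired_test(
    diffs: pd.DataFrame, hyper: ModerationHyperparams | None = None
) -> pd.DataFrame:
    """Moderated (or plain, if ``hyper.d0 == 0``) paired test per protein.

    ``diffs`` is the proteins x subjects paired log2-difference matrix.
    When ``hyper`` is None the prior is estimated from the matrix itself.
    Returns a DataFrame with log2_fc, t, df and two-sided p per protein.
    """
    X = diffs.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least two subjects")
    dg = n - 1
    mean = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    if hyper is None:
        hyper = estimate_moderation(s2, dg)
    d0, s0 = hyper.d0, hyper.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
    else:
        s2_post = (d0 * s0 + dg * s2) / (d0 + dg)
    if (s2_post <= 0).any():
        bad = diffs.index[s2_post <= 0].tolist()
        raise ValueError(
            f"zero posterior variance for proteins {bad[:5]}; the p-value is "
            "undefined (set d0 > 0 or remove constant proteins)"
        )
    t = mean / np.sqrt(s2_post / n)
    # information cannot exceed the residual df pooled over all proteins
    df_total = min(d0 + dg, dg * len(s2))
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"log2_fc": mean, "t": t, "df": df_total, "p_value": p},
        index=diffs.index,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def paired_t_test(pre_values, post_values) -> tuple[float, float]:
    """Classical two-sided paired t-test on post - pre (e.g. the cortisol
    intensity check)."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-d arrays of equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise ValueError(
            "differences have zero variance but nonzero mean; the t-statistic "
            "is degenerate"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), n - 1)
    return float(t), float(p)


def run_differential(
    study: ProteomeStudy,
    intensity: str,
    alpha: float = 0.05,
    moderation: str = "eb",
) -> pd.DataFrame:
    """Full per-intensity differential analysis.

    ``moderation`` is ``"eb"`` (empirical-Bayes shrinkage, default) or
    ``"none"`` (ordinary paired t). Returns one row per protein with
    fold_change (linear post/pre ratio), log2_fc, t, df, p_value, BH
    q_value, a significance flag at ``q < alpha`` and a direction.
    """
    if moderation not in ("eb", "none"):
        raise ValueError("moderation must be 'eb' or 'none'")
    diffs = paired_log_differences(study, intensity)
    hyper = ModerationHyperparams(d0=0.0, s0_sq=1.0) if moderation == "none" else None
    if moderation == "none":
        # d0=0 reduces the moderated statistic to the plain paired t
        res = moderated_paired_test(diffs, hyper)
    else:
        res = moderated_paired_test(diffs)
    res = res.copy()
    res.insert(0, "protein_id", res.index)
    res.insert(1, "intensity", intensity)
    res["fold_change"] = np.exp2(res["log2_fc"])
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["q_value"] < alpha
    res["direction"] = np.where(res["log2_fc"] >= 0, "up", "down")
    return res[
        [
            "protein_id",
            "intensity",
            "fold_change",
            "log2_fc",
            "t",
            "df",
            "p_value",
            "q_value",
            "significant",
            "direction",
        ]
    ]
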