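"""Differential abundance of hairpins: normalization, PCA outlier removal,
empirical-Bayes moderated t-statistics and Benjamini-Hochberg FDR.

The moderated t is the standard hierarchical-model statistic for small-n
genomics comparisons: per-hairpin residual variances s_g^2 (d_g degrees of
freedom) are assumed to follow a scaled F / scaled inverse-chi-square prior
with hyperparameters (d0, s0^2). The hyperparameters are estimated in closed
form by matching the first two moments of log s_g^2 to the scaled-F model
(digamma/trigamma inversion), the posterior variance is the precision-weighted
blend

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and t_mod = log_fc / (s~_g * sqrt(1/n_test + 1/n_ref)) is referred to a t
distribution with d0 + d_g degrees of freedom. With d0 = 0 this reduces to the
ordinary pooled-variance two-sample t; with d0 = inf every hairpin is tested
against the common variance s0^2.

These statistics are implemented here from the published formulas rather than
delegated, since they are the analytic core of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .deconvolve import CountMatrix

__all__ = [
    "ModeratedTestParams",
    "normalize_log_cpm",
    "pca_outliers",
    "fit_variance_prior",
    "moderated_t",
    "bh_adjust",
    "differential_table",
]


@dataclass(frozen=True)
class ModeratedTestParams:
    """Empirical-Bayes prior: d0 = prior degrees of freedom (may be inf),
    s0_sq = prior variance, both estimated from the observed s_g^2."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (possibly inf)")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValueError("s0_sq must be finite and positive")


def normalize_log_cpm(cm, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount:

        value = log2((count + pc) / (sample_total + 2 pc) * 1e6)

    Finite at zero counts. Depth-invariance per sample is exact at pc = 0 and
    holds to O(pc / count) otherwise — negligible at sequencing depths where
    counts are hundreds to thousands, which is where the transform is used.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else pd.DataFrame(cm)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return np.log2((counts + pseudocount) / (totals + 2 * pseudocount) * 1e6)


def pca_outliers(values: pd.DataFrame, group: list, mad_factor: float = 3.0):
    """Flag outlying samples within a replicate group by robust distance in
    PC1-2 space.

    Group samples (columns of ``values``) are projected onto the first two
    principal components of their centered profiles; a sample is flagged when
    its Euclidean distance from the componentwise median exceeds the median
    distance by more than ``mad_factor`` times the median absolute deviation
    of the distances. Deterministic and invariant under sample reordering.
    Returns ``(retained, flagged)`` sample-id lists in input order.
    """
    group = list(group)
    if len(group) < 3:
        raise ValueError("outlier detection needs >= 3 samples")
    missing = [s for s in group if s not in values.columns]
    if missing:
        raise ValueError(f"unknown samples {missing}")
    x = values[group].to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0)
    # SVD-based PCA; sign-fix each PC for permutation invariance
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    proj = x @ vt[:2].T if vt.shape[0] >= 2 else x @ vt[:1].T
    center = np.median(proj, axis=0)
    dist = np.linalg.norm(proj - center, axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    flagged_mask = dist - med > mad_factor * mad
    flagged = [s for s, f in zip(group, flagged_mask) if f]
    retained = [s for s, f in zip(group, flagged_mask) if not f]
    return retained, flagged


def _trigamma_inverse(y: float, tol: float = 1e-8, maxit: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(maxit):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < tol:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> ModeratedTestParams:
    """Closed-form moment estimate of (d0, s0^2) from observed residual
    variances with common degrees of freedom ``df``.

    Works on z = log(s_g^2), whose mean and variance under the scaled-F model
    are analytic in digamma/trigamma; the excess variance of z beyond
    trigamma(df/2) identifies d0. Non-positive excess means the variances are
    no more dispersed than sampling alone explains: d0 = inf, and s0^2 is the
    common value.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if pos.size == 0:
        raise ValueError("no variance information (all residual variances zero)")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if pos.size < 2:
        return ModeratedTestParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModeratedTestParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    values: pd.DataFrame,
    test: list,
    reference: list,
    prior: ModeratedTestParams | None = None,
) -> pd.DataFrame:
    """Two-group moderated t test per row of ``values`` (log2 abundances).

    Returns a DataFrame with log_fc (mean(test) - mean(reference)), ave_abund
    (mean over all samples in the comparison), s2 (residual variance), t_mod,
    p_value, plus the fitted prior in ``DataFrame.attrs['prior']``. Pass an
    explicit ``prior`` to override estimation (d0=0 gives the ordinary t).
    """
    test, reference = list(test), list(reference)
    if not reference:
        raise ValueError("reference group is empty")
    if not test:
        raise ValueError("test group is empty")
    if set(test) & set(reference):
        raise ValueError("test and reference groups overlap")
    n1, n2 = len(test), len(reference)
    if n1 + n2 < 3:
        raise ValueError("need >= 3 samples in the comparison")
    xt = values[test].to_numpy(dtype=float)
    xr = values[reference].to_numpy(dtype=float)
    log_fc = xt.mean(axis=1) - xr.mean(axis=1)
    ave = np.hstack([xt, xr]).mean(axis=1)
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xr - xr.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / df_resid
    if prior is None:
        prior = fit_variance_prior(s_sq, df_resid)
    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + df_resid * s_sq) / (d0 + df_resid)
        df_total = d0 + df_resid
    stderr = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(stderr > 0, log_fc / stderr, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(
        {
            "log_fc": log_fc,
            "ave_abund": ave,
            "s2": s_sq,
            "t_mod": t_mod,
            "p_value": p,
        },
        index=values.index,
    )
    out.attrs["prior"] = prior
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order:
    sort ascending, q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def differential_table(
    cm: CountMatrix,
    screen_id: str,
    tissue: str = "BM",
    gene_of: dict | None = None,
    pseudocount: float = 0.5,
    mad_factor: float = 3.0,
    prior: ModeratedTestParams | None = None,
):
    """Full per-screen differential-abundance pipeline for one tissue vs T0:

    normalize -> drop hairpins absent from every sample -> PCA outlier removal
    on the test group -> moderated t (test vs T0) -> BH adjustment within the
    comparison. Hairpins with zero counts everywhere are reported with status
    "absent" and no test; the rest get status "tested".

    Returns ``(table, flagged_samples)``.
    """
    sheet = cm.sheet
    reference = [sheet.reference_sample(screen_id)]
    test = sheet.samples(screen_id, tissue)
    if not test:
        raise ValueError(f"screen {screen_id!r} has no {tissue!r} samples")
    comparison = test + reference
    sub = cm.counts[comparison]
    present = sub.sum(axis=1) > 0
    log_cpm = normalize_log_cpm(
        CountMatrix(sub, cm.unassigned.reindex(comparison), sheet), pseudocount
    )
    flagged: list = []
    if len(test) >= 3:
        test, flagged = pca_outliers(log_cpm, test, mad_factor=mad_factor)
    if len(test) < 2:
        raise ValueError(
            f"screen {screen_id!r}: fewer than 2 {tissue} samples after outlier removal"
        )
    tested = moderated_t(log_cpm.loc[present], test, reference, prior=prior)
    tested["adj_p"] = bh_adjust(tested["p_value"].to_numpy())
    tested["status"] = "tested"
    absent = pd.DataFrame(
        {c: np.nan for c in tested.columns if c != "status"},
        index=log_cpm.index[~present],
    )
    absent["status"] = "absent"
    table = pd.concat([tested, absent]).reindex(cm.counts.index)
    table.index.name = "hairpin_id"
    if gene_of is not None:
        table.insert(0, "gene_symbol", [gene_of.get(h) for h in table.index])
    table.attrs["prior"] = tested.attrs["prior"]
    table.attrs["test_samples"] = list(test)
    table.attrs["reference_sample"] = reference[0]
    return table, flagged
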