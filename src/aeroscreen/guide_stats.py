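"""Per-spacer differential-abundance statistics.

Size factors are anchored on the non-targeting controls (assumed
fitness-neutral) by median-of-ratios; when too few controls are usable
the estimator falls back to all spacers. Overdispersion is estimated
from initial-timepoint replicates by method of moments, pooled into
mean-ordered bins and monotone-smoothed into a trend phi(mu). Each
spacer's log2 fold change (Tf vs Ti) then gets a delta-method standard
error under the NB variance mu + phi*mu^2, a Wald normal p-value, and a
Benjamini-Hochberg q-value within the condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix

PSEUDOCOUNT = 0.5
MIN_CONTROLS = 50


def normalize(
    counts: CountMatrix,
    control_ids=None,
    min_controls: int = MIN_CONTROLS,
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses only control spacers when at least ``min_controls`` of them have
    a nonzero median count across samples; otherwise all spacers. Heavily
    depleted essential-gene spacers would bias a total-count scaling,
    which is why the controls anchor the estimate.
    """
    mat = counts.counts
    if (mat.sum(axis=0) <= 0).any():
        bad = mat.columns[mat.sum(axis=0) <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")

    subset = mat
    if control_ids is not None:
        ctrl = mat.loc[mat.index.intersection(pd.Index(control_ids))]
        if (ctrl.median(axis=1) > 0).sum() >= min_controls:
            subset = ctrl

    arr = subset.to_numpy(dtype=float)
    ok = (arr > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no spacer has nonzero counts in every sample")
    logs = np.log(arr[ok])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=mat.columns, name="size_factor")


@dataclass
class DispersionTrend:
    """Monotone dispersion trend phi(mu), evaluable at any mean.

    Evaluation interpolates between bin means and clamps outside the
    fitted range.
    """

    bin_means: np.ndarray
    bin_phis: np.ndarray

    def __call__(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return np.interp(mu, self.bin_means, self.bin_phis)

    @classmethod
    def constant(cls, phi: float) -> "DispersionTrend":
        return cls(np.array([0.0, 1.0]), np.array([phi, phi]))


def fit_dispersion(
    counts: CountMatrix,
    size_factors: pd.Series,
    n_bins: int = 20,
) -> DispersionTrend:
    """Estimate the dispersion trend from Ti replicate variability.

    Method-of-moments estimation on the normalized scale within each
    condition's Ti replicate group, pooled into mean-ordered bins. The
    naive per-spacer estimator (var - mu) / mu^2 is biased downward by
    roughly (1/mu + phi)/r at r replicates because E[mu_hat^2] exceeds
    the squared true mean by Var(mu_hat); each bin therefore solves the
    bias-corrected moment equation

        phi_bin = sum(var - mu) / sum(mu^2 - var/r)

    with negative estimates floored at zero before smoothing by
    decreasing isotonic regression (screen dispersions shrink with
    abundance; the monotone fit also regularizes sparse bins).
    """
    groups = []
    for cond in counts.samples.condition.unique():
        sids = counts.sample_ids(condition=cond, timepoint="Ti")
        if len(sids) >= 2:
            groups.append(sids)
    if not groups:
        raise ValueError(
            "need >= 2 Ti replicates to fit dispersion; supply a constant "
            "trend via DispersionTrend.constant(phi) instead"
        )

    mus, nums, dens = [], [], []
    for sids in groups:
        r = len(sids)
        norm = counts.counts[sids].to_numpy(dtype=float) / size_factors[sids].to_numpy()
        mu = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        pos = mu > 0
        mus.append(mu[pos])
        nums.append(var[pos] - mu[pos])
        dens.append(mu[pos] ** 2 - var[pos] / r)
    mu = np.concatenate(mus)
    num = np.concatenate(nums)
    den = np.concatenate(dens)

    order = np.argsort(mu, kind="stable")
    mu, num, den = mu[order], num[order], den[order]
    n_bins = max(1, min(n_bins, len(mu)))
    edges = np.linspace(0, len(mu), n_bins + 1).astype(int)
    bm, bp = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            d = den[a:b].sum()
            bm.append(mu[a:b].mean())
            bp.append(max(num[a:b].sum() / d, 0.0) if d > 0 else 0.0)
    bm, bp = np.asarray(bm), np.asarray(bp)
    if len(bm) > 1:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        bp = iso.fit_transform(bm, bp)
    bp = np.maximum(bp, 0.0)
    if len(bm) == 1:
        bm = np.array([bm[0], bm[0] + 1.0])
        bp = np.array([bp[0], bp[0]])
    return DispersionTrend(bm, bp)


def _exact_nb_p(s_ti: int, s_tf: int, r_ti: int, r_tf: int, phi: float, q: float) -> float:
    """Two-sided exact NB test of Tf vs Ti, conditional on the total.

    Replicate sums within a group are NB with size r/phi under a common
    per-replicate mean q; the p-value doubles the smaller conditional
    tail of S_tf given S_ti + S_tf (the Poisson/binomial limit as
    phi -> 0). Used to refine extreme Wald tails, where the normal
    approximation to the log-ratio statistic is anti-conservative.
    """
    N = int(s_ti + s_tf)
    if N == 0 or q <= 0:
        return 1.0
    if N > 200_000:  # enumeration cost guard; Wald is accurate at such depth
        return np.nan
    s = int(s_tf)
    if phi < 1e-9:
        pr = r_tf / (r_ti + r_tf)
        lo = stats.binom.cdf(s, N, pr)
        hi = stats.binom.sf(s - 1, N, pr)
        return float(min(1.0, 2.0 * min(lo, hi)))
    size_ti, size_tf = r_ti / phi, r_tf / phi
    p_ti = size_ti / (size_ti + r_ti * q)
    p_tf = size_tf / (size_tf + r_tf * q)
    k = np.arange(N + 1)
    logw = stats.nbinom.logpmf(k, size_tf, p_tf) + stats.nbinom.logpmf(N - k, size_ti, p_ti)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    cdf = np.cumsum(w)
    lo = cdf[s]
    hi = 1.0 - (cdf[s - 1] if s > 0 else 0.0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def test_spacers(
    counts: CountMatrix,
    size_factors: pd.Series,
    trend: DispersionTrend,
    condition: str,
    library: pd.DataFrame | None = None,
    pseudocount: float = PSEUDOCOUNT,
    refine_tails: float = 1e-3,
) -> pd.DataFrame:
    """Per-spacer LFC, SE, Wald p and BH q for one condition.

    lfc = log2((mean normalized Tf + c) / (mean normalized Ti + c)) with
    c = 0.5. The SE propagates NB sampling variance (phi from the trend)
    through the log ratio; replicates are averaged on the normalized
    scale. Wald p-values below ``refine_tails`` are recomputed with the
    exact conditional NB test (set to 0 to disable), keeping the far
    tail calibrated where the normal approximation is not. Spacers with
    zero counts at both timepoints are reported with lfc = 0, p = 1 and
    flagged low-count.
    """
    ti = counts.sample_ids(condition=condition, timepoint="Ti")
    tf = counts.sample_ids(condition=condition, timepoint="Tf")
    if not ti or not tf:
        raise ValueError(f"condition {condition!r} lacks Ti or Tf samples")

    def group(sids):
        sf = size_factors[sids].to_numpy()
        norm = counts.counts[sids].to_numpy(dtype=float) / sf
        mean = norm.mean(axis=1)
        # Var(mean of normalized counts) under NB(mu*s_j, phi):
        #   (1/r^2) * sum_j (mu/s_j + phi*mu^2)
        phi = trend(mean)
        var = (mean[:, None] / sf[None, :] + phi[:, None] * mean[:, None] ** 2).sum(
            axis=1
        ) / len(sids) ** 2
        return mean, var

    m_ti, v_ti = group(ti)
    m_tf, v_tf = group(tf)

    lfc = np.log2((m_tf + pseudocount) / (m_ti + pseudocount))
    ln2sq = np.log(2.0) ** 2
    var_lfc = (v_tf / (m_tf + pseudocount) ** 2 + v_ti / (m_ti + pseudocount) ** 2) / ln2sq
    se = np.sqrt(var_lfc)

    zero_both = (m_ti == 0) & (m_tf == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    if refine_tails > 0:
        q_pool = (m_ti * len(ti) + m_tf * len(tf)) / (len(ti) + len(tf))
        norm_ti = counts.counts[ti].to_numpy(dtype=float) / size_factors[ti].to_numpy()
        norm_tf = counts.counts[tf].to_numpy(dtype=float) / size_factors[tf].to_numpy()
        phi_pool = trend(q_pool)
        for i in np.flatnonzero((p < refine_tails) & ~zero_both):
            pe = _exact_nb_p(
                round(norm_ti[i].sum()),
                round(norm_tf[i].sum()),
                len(ti),
                len(tf),
                float(phi_pool[i]),
                float(q_pool[i]),
            )
            if np.isfinite(pe):
                p[i] = pe

    lfc[zero_both] = 0.0
    p[zero_both] = 1.0
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        dict(
            spacer_id=counts.counts.index,
            condition=condition,
            lfc=lfc,
            se=se,
            p=p,
            q=q,
            low_count=zero_both,
        )
    )
    if library is not None:
        out = out.merge(
            library[["spacer_id", "gene_id"]], on="spacer_id", how="left"
        )
    return out
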