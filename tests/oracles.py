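"""Independent reference implementations used only to cross-check mrkit.

Everything here is written from the defining formulas with explicit
summation (or routed through statsmodels/scipy primitives that mrkit does
not use for the same quantity), so agreement with the package is a genuine
two-route check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats


def ivw_brute(bx, sx, by, sy):
    """IVW slope and analytic SE by explicit summation."""
    num = den = 0.0
    for bxj, syj, byj in zip(bx, sy, by):
        w = 1.0 / syj**2
        num += w * bxj * byj
        den += w * bxj**2
    theta = num / den
    return theta, den**-0.5


def cochran_brute(bx, by, sy, pooled):
    q = 0.0
    for bxj, byj, syj in zip(bx, by, sy):
        theta_j = byj / bxj
        se_j = syj / abs(bxj)
        q += (theta_j - pooled) ** 2 / se_j**2
    return q


def egger_brute_oriented(bx, by, sy):
    """Closed-form weighted simple linear regression (already oriented)."""
    w = [1.0 / s**2 for s in sy]
    sw = sum(w)
    swx = sum(wi * x for wi, x in zip(w, bx))
    swy = sum(wi * y for wi, y in zip(w, by))
    swxx = sum(wi * x * x for wi, x in zip(w, bx))
    swxy = sum(wi * x * y for wi, x, y in zip(w, bx, by))
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    j = len(bx)
    rss = sum(
        wi * (y - intercept - slope * x) ** 2 for wi, x, y in zip(w, bx, by)
    )
    phi = rss / (j - 2)
    scale = math.sqrt(max(1.0, phi))
    se_slope = scale * math.sqrt(sw / det)
    se_int = scale * math.sqrt(swxx / det)
    return intercept, slope, se_int, se_slope, phi


def weighted_median_brute(ratios, weights):
    """Weighted median by explicit cumulative-weight scan and interpolation."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    prev_s = None
    prev_t = None
    for t, w in pairs:
        s = (cum + w / 2.0) / total
        if s >= 0.5:
            if prev_s is None:
                return t
            frac = (0.5 - prev_s) / (s - prev_s)
            return prev_t + frac * (t - prev_t)
        cum += w
        prev_s, prev_t = s, t
    return pairs[-1][0]


def mvmr_wls_lstsq(BX, by, sy):
    """Multivariable weighted LS via lstsq on the sqrt(w)-transformed design."""
    w = 1.0 / np.asarray(sy) ** 2
    sqrtw = np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(np.asarray(BX) * sqrtw, np.asarray(by) * sqrtw.ravel(),
                               rcond=None)
    return coef


def chi2_sf_quad(x, df):
    """Upper-tail chi-square probability by numerical integration of the pdf."""
    def pdf(t):
        return t ** (df / 2 - 1) * math.exp(-t / 2) / (2 ** (df / 2) * math.gamma(df / 2))
    val, _ = integrate.quad(pdf, x, np.inf, limit=200)
    return val


def ncx2_sf_series(x, df, ncp, tol=1e-14):
    """Non-central chi-square upper tail as a Poisson mixture of central tails."""
    total = 0.0
    lam = ncp / 2.0
    log_pois = -lam
    i = 0
    while True:
        pois = math.exp(log_pois)
        total += pois * stats.chi2.sf(x, df + 2 * i)
        i += 1
        log_pois += math.log(lam) - math.log(i) if lam > 0 else -np.inf
        if pois < tol and i > lam:
            break
        if i > 10000:
            break
    return total


def empirical_wald_power_binary(n, r2_xz, k, or_alt, alpha, n_rep, seed):
    """Monte-Carlo rejection rate of the MR Wald test in a generative model.

    G ~ N(0,1) is the instrument score; the standardized exposure is
    X = sqrt(r2)·G + sqrt(1-r2)·e; the binary outcome follows
    P(Y=1|X) = k·OR^X / (1 - k + k·OR^X), i.e. odds multiplied by OR per
    exposure SD with marginal case fraction ~k.  The test regresses Y on
    the instrument-predicted exposure sqrt(r2)·G and Wald-tests the slope.
    """
    rng = np.random.default_rng(seed)
    crit = stats.chi2.isf(alpha, df=1)
    n = int(n)
    rejections = 0
    for _ in range(n_rep):
        g = rng.standard_normal(n)
        x = math.sqrt(r2_xz) * g + math.sqrt(1 - r2_xz) * rng.standard_normal(n)
        odds = k / (1 - k) * or_alt**x
        p = odds / (1 + odds)
        y = rng.random(n) < p
        xhat = math.sqrt(r2_xz) * g
        xc = xhat - xhat.mean()
        yc = y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        resid = yc - beta * xc
        var = (resid @ resid) / (n - 2) / (xc @ xc)
        if beta**2 / var > crit:
            rejections += 1
    return rejections / n_rep
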