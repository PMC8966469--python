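"""Per-SNP transmission-model likelihoods, MLEs, profile CIs and LRTs.

Three nested models describe the transmission of the alternative ("B")
allele from heterozygous parents to offspring:

* ``M0`` — Mendelian transmission: the B allele is transmitted with
  probability 1/2 to every child.
* ``M1`` — uniform transmission distortion: transmission probability is
  ``1/2 + eps`` regardless of offspring sex.
* ``M2`` — sex-specific transmission distortion: ``1/2 + eps_m`` for
  sons and ``1/2 + eps_f`` for daughters.

Every distortion parameter lives in ``[-1/2, +1/2]``.  The data at one
SNP reduce to four integers: ``k_m`` B-transmissions out of ``n_m``
informative meioses to sons, and ``k_f`` out of ``n_f`` to daughters.
The log-likelihood is a product of Bernoulli transmission events

    lnL = sum_sex [ k ln(1/2 + eps_sex) + (n - k) ln(1/2 - eps_sex) ]

with the convention ``0 * ln 0 = 0``.  Combinatorial constants are
omitted throughout: they cancel in MLEs, profile intervals and all
likelihood-ratio statistics.  All MLEs are closed-form binomial
proportions, so each model is maximized analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy as _xlogy  # 0*ln(0) = 0 convention

__all__ = [
    "loglik",
    "fit_site",
    "scan",
    "profile_ci",
    "SiteFit",
]

#: lnL drop defining a 95% profile interval: chi2(1df, 0.95)/2.
_CI_DROP = stats.chi2.ppf(0.95, df=1) / 2.0  # = 1.9207...

_MODELS = ("M0", "M1", "M2")


@dataclass
class SiteFit:
    """Maximum-likelihood summary of one SNP.

    Attributes
    ----------
    eps_hat : float
        MLE of the shared distortion parameter under M1.
    eps_m_hat, eps_f_hat : float
        Sex-specific MLEs under M2 (NaN when that sex has no meioses).
    lnl0, lnl1, lnl2 : float
        Maximized log-likelihoods of the three models.
    ci_1, ci_m, ci_f : tuple of float
        95% profile intervals, clipped to [-1/2, 1/2].
    d10, d20, d21 : float
        Deviance (LRT) statistics, 2*(lnL_big - lnL_small).
    p10, p20, p21 : float
        Chi-square p-values with 1, 2 and 1 degrees of freedom.
    collapsed_sex : str or None
        ``"male"``/``"female"`` when that sex contributed zero meioses,
        in which case M2 collapses onto M1 for the missing sex.
    """

    eps_hat: float
    eps_m_hat: float
    eps_f_hat: float
    lnl0: float
    lnl1: float
    lnl2: float
    ci_1: tuple
    ci_m: tuple
    ci_f: tuple
    d10: float
    d20: float
    d21: float
    p10: float
    p20: float
    p21: float
    collapsed_sex: str | None = None


def _binom_lnl(k, n, eps):
    """Bernoulli-product log-likelihood for one sex at parameter eps."""
    return _xlogy(k, 0.5 + eps) + _xlogy(n - k, 0.5 - eps)


def loglik(k_m, n_m, k_f, n_f, model="M2", eps=0.0, eps_m=0.0, eps_f=0.0):
    """Log-likelihood of transmission counts under one model.

    Parameters
    ----------
    k_m, n_m, k_f, n_f : int or array
        B-transmission counts / informative meioses per offspring sex.
    model : {"M0", "M1", "M2"}
    eps : float
        Shared distortion parameter (used by M1 only).
    eps_m, eps_f : float
        Sex-specific parameters (used by M2 only).

    Returns
    -------
    float or ndarray
        ``lnL`` up to an additive combinatorial constant.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == "M0":
        e_m = e_f = 0.0
    elif model == "M1":
        e_m = e_f = eps
    else:
        e_m, e_f = eps_m, eps_f
    for e in np.atleast_1d(e_m).ravel().tolist() + np.atleast_1d(e_f).ravel().tolist():
        if not (-0.5 <= e <= 0.5):
            raise ValueError(f"distortion parameter {e} outside [-1/2, 1/2]")
    return _binom_lnl(k_m, n_m, e_m) + _binom_lnl(k_f, n_f, e_f)


def profile_ci(k, n, drop=_CI_DROP, tol=1e-6):
    """95% profile-likelihood interval for a single binomial eps.

    The interval is ``{eps : lnL(eps) >= lnL(eps_hat) - drop}``, solved
    by bisection on each side of the MLE to ``|delta eps| < tol`` and
    clipped to ``[-1/2, 1/2]``.
    """
    lo, hi = _profile_ci_arrays(np.asarray([k], float), np.asarray([n], float),
                                drop=drop, tol=tol)
    return float(lo[0]), float(hi[0])


def _profile_ci_arrays(k, n, drop=_CI_DROP, tol=1e-6):
    """Vectorized profile intervals for binomial counts (see profile_ci)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        eps_hat = np.where(n > 0, k / np.maximum(n, 1) - 0.5, np.nan)
    lnl_hat = _binom_lnl(k, n, np.nan_to_num(eps_hat))
    target = lnl_hat - drop

    def _bisect(lo, hi, want_upper):
        # invariant: lnL(boundary side) < target <= lnL(eps_hat side)
        lo = lo.copy()
        hi = hi.copy()
        n_iter = int(np.ceil(np.log2(1.0 / tol))) + 2
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            with np.errstate(divide="ignore", invalid="ignore"):
                val = _binom_lnl(k, n, mid)
            ok = val >= target
            if want_upper:
                lo = np.where(ok, mid, lo)
                hi = np.where(ok, hi, mid)
            else:
                hi = np.where(ok, mid, hi)
                lo = np.where(ok, lo, mid)
        return 0.5 * (lo + hi)

    half = np.full_like(k, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        at_lo = _binom_lnl(k, n, -half) >= target
        at_hi = _binom_lnl(k, n, half) >= target
    lower = np.where(at_lo, -0.5, _bisect(-half, np.nan_to_num(eps_hat), False))
    upper = np.where(at_hi, 0.5, _bisect(np.nan_to_num(eps_hat), half, True))
    lower = np.where(n > 0, np.clip(lower, -0.5, 0.5), np.nan)
    upper = np.where(n > 0, np.clip(upper, -0.5, 0.5), np.nan)
    return lower, upper


def _fit_arrays(k_m, n_m, k_f, n_f, ci=True):
    """Vectorized model fitting over per-site count arrays.

    Returns a dict of equally shaped arrays (the columns of the scan
    output).  NaN marks an undefined sex-specific MLE (zero meioses in
    that sex); the overall fit is still valid because M2 collapses
    onto M1 for the missing sex.
    """
    k_m, n_m, k_f, n_f = (np.asarray(a, dtype=float) for a in (k_m, n_m, k_f, n_f))
    n_tot = n_m + n_f
    if np.any(n_tot < 1):
        raise ValueError("a site with zero informative meioses cannot be fitted")
    k_tot = k_m + k_f

    eps1 = k_tot / n_tot - 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        eps_m = np.where(n_m > 0, k_m / np.maximum(n_m, 1) - 0.5, np.nan)
        eps_f = np.where(n_f > 0, k_f / np.maximum(n_f, 1) - 0.5, np.nan)

    lnl0 = n_tot * np.log(0.5)
    lnl1 = _binom_lnl(k_tot, n_tot, eps1)
    # a sex with n = 0 contributes 0 to lnL2 either way
    lnl2 = (_binom_lnl(k_m, n_m, np.nan_to_num(eps_m))
            + _binom_lnl(k_f, n_f, np.nan_to_num(eps_f)))

    d10 = np.maximum(2.0 * (lnl1 - lnl0), 0.0)
    d20 = np.maximum(2.0 * (lnl2 - lnl0), 0.0)
    d21 = np.maximum(2.0 * (lnl2 - lnl1), 0.0)

    out = {
        "eps1": eps1, "eps_m": eps_m, "eps_f": eps_f,
        "lnl0": lnl0, "lnl1": lnl1, "lnl2": lnl2,
        "d10": d10, "d20": d20, "d21": d21,
        "p10": stats.chi2.sf(d10, df=1),
        "p20": stats.chi2.sf(d20, df=2),
        "p21": stats.chi2.sf(d21, df=1),
    }
    if ci:
        out["ci1_lo"], out["ci1_hi"] = _profile_ci_arrays(k_tot, n_tot)
        out["cim_lo"], out["cim_hi"] = _profile_ci_arrays(k_m, n_m)
        out["cif_lo"], out["cif_hi"] = _profile_ci_arrays(k_f, n_f)
    return out


def fit_site(k_m, n_m, k_f, n_f):
    """Fit M0/M1/M2 to one SNP's transmission counts.

    Closed-form MLEs: ``eps_hat = (k_m+k_f)/(n_m+n_f) - 1/2`` under M1
    and ``eps_s = k_s/n_s - 1/2`` per sex under M2.  Deviances are
    compared with chi-square distributions with 1 (M1 vs M0, M2 vs M1)
    and 2 (M2 vs M0) degrees of freedom.

    Raises
    ------
    ValueError
        If ``n_m + n_f`` is zero or any count is negative/inconsistent.
    """
    for k, n in ((k_m, n_m), (k_f, n_f)):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"inconsistent counts k={k}, n={n}")
    a = _fit_arrays([k_m], [n_m], [k_f], [n_f])
    collapsed = None
    if n_m == 0:
        collapsed = "male"
    elif n_f == 0:
        collapsed = "female"
    return SiteFit(
        eps_hat=float(a["eps1"][0]),
        eps_m_hat=float(a["eps_m"][0]),
        eps_f_hat=float(a["eps_f"][0]),
        lnl0=float(a["lnl0"][0]),
        lnl1=float(a["lnl1"][0]),
        lnl2=float(a["lnl2"][0]),
        ci_1=(float(a["ci1_lo"][0]), float(a["ci1_hi"][0])),
        ci_m=(float(a["cim_lo"][0]), float(a["cim_hi"][0])),
        ci_f=(float(a["cif_lo"][0]), float(a["cif_hi"][0])),
        d10=float(a["d10"][0]),
        d20=float(a["d20"][0]),
        d21=float(a["d21"][0]),
        p10=float(a["p10"][0]),
        p20=float(a["p20"][0]),
        p21=float(a["p21"][0]),
        collapsed_sex=collapsed,
    )


def scan(counts, ci=True):
    """Fit every site of a transmission-count table.

    Parameters
    ----------
    counts : pandas.DataFrame
        Must carry columns ``k_m, n_m, k_f, n_f`` (the output of
        :func:`triodistort.trio_io.count_transmissions`); any other
        columns (chrom, pos, ...) are passed through unchanged.
    ci : bool
        Compute profile intervals (skippable for large simulations).

    Returns
    -------
    pandas.DataFrame
        One row per input site, input order preserved.  Sites whose
        counts cannot be fitted (zero meioses) are flagged in the
        ``fit_error`` column rather than aborting the scan.
    """
    counts = pd.DataFrame(counts)
    if counts.empty:
        cols = ["eps1", "eps_m", "eps_f", "lnl0", "lnl1", "lnl2",
                "d10", "d20", "d21", "p10", "p20", "p21", "fit_error"]
        return counts.assign(**{c: pd.Series(dtype=float) for c in cols})
    k_m = counts["k_m"].to_numpy(float)
    n_m = counts["n_m"].to_numpy(float)
    k_f = counts["k_f"].to_numpy(float)
    n_f = counts["n_f"].to_numpy(float)
    bad = (n_m + n_f) < 1
    # fit the bad rows with a dummy meiosis, then blank them out
    n_m_safe = np.where(bad, 1.0, n_m)
    a = _fit_arrays(k_m, n_m_safe, k_f, n_f, ci=ci)
    out = counts.copy()
    for col, arr in a.items():
        out[col] = np.where(bad, np.nan, arr)
    out["fit_error"] = np.where(bad, "no_informative_meioses", "")
    return out
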