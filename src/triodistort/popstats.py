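"""Intersexual F_ST and region-level null comparisons.

The intersexual F_ST treats males and females of one cohort as two
"populations" and asks how much of the allele-frequency variance lies
between them.  Under random union of gametes this is ~0; sex-biased
transmission or sex-differential survival pushes it upward, most
strongly when the two sexes are distorted in opposite directions.

Per SNP we use the Weir & Cockerham (1984) variance-component
estimator for r = 2 populations: with per-sex sample sizes ``n_i``,
ALT frequencies ``p_i`` and observed heterozygote proportions ``h_i``,

    n_bar = mean(n_i)                     n_c = (2 n_bar - sum n_i^2 / (2 n_bar))
    p_bar = sum(n_i p_i) / (2 n_bar)      s2 = sum n_i (p_i - p_bar)^2 / n_bar
    h_bar = sum(n_i h_i) / (2 n_bar)

    a = n_bar/n_c * [ s2 - ( p_bar q_bar - s2/2 - h_bar/4 ) / (n_bar - 1) ]
    b = n_bar/(n_bar-1) * [ p_bar q_bar - s2/2 - (2 n_bar - 1)/(4 n_bar) h_bar ]
    c = h_bar / 2
    theta_hat = a / (a + b + c)

Negative estimates are reported as-is (the estimator is unbiased
around zero under the null); monomorphic sites have an undefined
theta and are flagged rather than fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FstRecord", "wc_fst_site", "wc_fst", "fst_from_dosages",
           "matched_null_sample", "quartile_enrichment"]


@dataclass
class FstRecord:
    chrom: str
    pos: int
    theta: float
    n_male: int
    n_female: int
    p_male: float
    p_female: float
    undefined: bool = False


def wc_fst(n_aa, n_ab, n_bb):
    """Vectorized two-population Weir-Cockerham theta.

    Parameters are ``(2, m)`` arrays of per-population genotype counts
    (rows = the two populations, columns = sites).  Returns
    ``(theta, p1, p2, defined)`` arrays; ``theta`` is NaN where the
    denominator vanishes (both populations monomorphic for the same
    allele).
    """
    n_aa, n_ab, n_bb = (np.atleast_2d(np.asarray(a, dtype=float))
                        for a in (n_aa, n_ab, n_bb))
    n_i = n_aa + n_ab + n_bb                      # (2, m) diploid counts
    if np.any(n_i < 2):
        raise ValueError("need >= 2 diploid individuals per population")
    r = 2.0
    p_i = (2 * n_bb + n_ab) / (2 * n_i)           # ALT frequency
    h_i = n_ab / n_i                              # observed het proportion
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
    pq = p_bar * (1 - p_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom == 0, 1, denom), np.nan)
    defined = denom != 0
    return theta, p_i[0], p_i[1], defined


def wc_fst_site(counts_male, counts_female, chrom="?", pos=0) -> FstRecord:
    """Weir-Cockerham theta between the sexes at one SNP.

    ``counts_male``/``counts_female`` are ``(n_AA, n_AB, n_BB)``
    genotype counts for each sex.
    """
    cm = np.asarray(counts_male, dtype=float)
    cf = np.asarray(counts_female, dtype=float)
    theta, p1, p2, defined = wc_fst(
        [[cm[0]], [cf[0]]], [[cm[1]], [cf[1]]], [[cm[2]], [cf[2]]])
    return FstRecord(chrom=chrom, pos=pos, theta=float(theta[0]),
                     n_male=int(cm.sum()), n_female=int(cf.sum()),
                     p_male=float(p1[0]), p_female=float(p2[0]),
                     undefined=not bool(defined[0]))


def fst_from_dosages(dosage, sexes, chroms=None, positions=None,
                     haploid_male=None) -> pd.DataFrame:
    """Per-site intersexual F_ST from an ALT-dosage matrix.

    Parameters
    ----------
    dosage : (n_sites, n_samples) int array, -1 = missing.
    sexes : per-sample sequence of "male"/"female".
    haploid_male : optional boolean mask over sites (e.g. X-linked
        sites) where male calls are hemizygous.  There the male allele
        counts enter the frequency estimate but heterozygosity terms
        come from females only; this is a nonstandard extension of the
        diploid estimator and results are flagged in the ``haploid``
        column.
    """
    d = np.asarray(dosage)
    sexes = np.asarray(sexes)
    male = sexes == "male"
    rows = []
    for s in range(d.shape[0]):
        hap = bool(haploid_male[s]) if haploid_male is not None else False
        row_m, row_f = d[s, male], d[s, ~male]
        cm = [(row_m == g).sum() for g in (0, 1, 2)]
        cf = [(row_f == g).sum() for g in (0, 1, 2)]
        chrom = chroms[s] if chroms is not None else "?"
        pos = positions[s] if positions is not None else s + 1
        if hap:
            rec = _fst_haploid_male(cm, cf, chrom, pos)
        else:
            rec = wc_fst_site(cm, cf, chrom, pos)
        rows.append({**vars(rec), "haploid": hap})
    return pd.DataFrame(rows)


def _fst_haploid_male(counts_male, counts_female, chrom, pos) -> FstRecord:
    """Hudson-style intersexual differentiation with hemizygous males.

    Males contribute one allele each; the estimator reduces to the
    two-population F_ST on allele frequencies with female-only
    heterozygosity correction: theta = (p_m - p_f)^2 adjusted for
    sampling, computed from the WC components with male "individuals"
    of ploidy 1 folded in as half-weight.
    """
    cm = np.asarray(counts_male, dtype=float)   # hemizygous: (n_A, n_B, 0)
    cf = np.asarray(counts_female, dtype=float)
    n_m = cm[:2].sum()
    n_f = cf.sum()
    if n_m < 2 or n_f < 2:
        raise ValueError("need >= 2 individuals per sex")
    p_m = cm[1] / n_m if n_m else np.nan
    p_f = (2 * cf[2] + cf[1]) / (2 * n_f)
    # weight males as haploid samples of size n_m alleles
    num = (p_m - p_f) ** 2 - p_m * (1 - p_m) / max(n_m - 1, 1) \
        - p_f * (1 - p_f) / max(2 * n_f - 1, 1)
    den = p_m * (1 - p_f) + p_f * (1 - p_m)
    theta = num / den if den != 0 else np.nan
    return FstRecord(chrom=chrom, pos=pos, theta=float(theta),
                     n_male=int(n_m), n_female=int(n_f),
                     p_male=float(p_m), p_female=float(p_f),
                     undefined=den == 0)


def matched_null_sample(targets: pd.DataFrame, pool: pd.DataFrame,
                        features=("length", "n_snps", "diversity"),
                        n_draws=10, rel_tol=0.2, seed=None, rng=None):
    """Sample null regions matched on genomic features.

    For each target region, draw ``n_draws`` pool rows whose features
    all fall within a multiplicative ``rel_tol`` band of the target's
    (|pool/target - 1| <= rel_tol; a zero target feature requires an
    exact zero).  Deterministic given ``seed``.

    Returns ``(draws, unmatched)``: a DataFrame of sampled pool rows
    with a ``target_index`` column, and the list of target indices
    with no admissible pool row.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    targets = pd.DataFrame(targets)
    pool = pd.DataFrame(pool)
    if len(pool) <= len(targets):
        raise ValueError("pool must be larger than the target set")
    out, unmatched = [], []
    pool_f = pool[list(features)].to_numpy(float)
    for idx, trow in targets.iterrows():
        tf = trow[list(features)].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(pool_f / tf - 1.0)
        ok = np.where(tf == 0, pool_f == 0, rel <= rel_tol).all(axis=1)
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            unmatched.append(idx)
            continue
        pick = rng.choice(cand, size=n_draws, replace=True)
        sel = pool.iloc[pick].copy()
        sel["target_index"] = idx
        out.append(sel)
    draws = pd.concat(out, ignore_index=True) if out else pool.iloc[:0].copy()
    return draws, unmatched


def quartile_enrichment(region_values, genome_values) -> pd.DataFrame:
    """Binomial tests of region counts per genome-rate quartile.

    Quartile breakpoints come from ``genome_values`` (e.g. window-mean
    recombination rates genome-wide); each region's value is binned
    and the count per quartile is tested against the null proportion
    0.25 with a two-sided exact binomial test.  The ``direction``
    column marks an excess (+) or deficit (-) relative to the null.
    """
    gv = np.asarray(genome_values, dtype=float)
    rv = np.asarray(region_values, dtype=float)
    if gv.size == 0:
        raise ValueError("genome_values must be nonempty")
    qs = np.quantile(gv, [0.25, 0.5, 0.75])
    bins = np.searchsorted(qs, rv, side="right")  # 0..3
    n = rv.size
    rows = []
    for q in range(4):
        k = int((bins == q).sum())
        test = stats.binomtest(k, n, 0.25, alternative="two-sided")
        rows.append({
            "quartile": q + 1,
            "lower": -np.inf if q == 0 else qs[q - 1],
            "upper": np.inf if q == 3 else qs[q],
            "n_regions": k,
            "expected": 0.25 * n,
            "direction": "+" if k > 0.25 * n else ("-" if k < 0.25 * n else "="),
            "p_value": test.pvalue,
        })
    return pd.DataFrame(rows)
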