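"""Candidate-region follow-up on phased haplotypes.

Once a region shows a sex-specific transmission-distortion signal, the
SNP-level picture is refined at the haplotype level: haplotypes are
embedded by allele-sharing distance, grouped by density clustering,
and the transmission of each haplotype class from heterozygous parents
to sons versus daughters is tested directly.

Phasing itself is out of scope — the functions here consume
already-phased haplotypes (a 0/1 matrix plus carrier metadata, or a
phased VCF read by :func:`read_phased_vcf`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from sklearn.cluster import DBSCAN

from .trio_io import MALE, TrioSet

__all__ = [
    "HaplotypeSet", "ClusterConfig", "asd_matrix", "classical_mds",
    "density_cluster", "transmission_records", "haplotype_transmission_tests",
    "mantel_sex_test", "read_phased_vcf",
]


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes over one region.

    ``haps`` is (n_sites, n_haplotypes) with -1 for missing alleles;
    ``carriers`` has one row per haplotype: sample, sex, role
    (father/mother/child) and hap index within the sample (0/1).
    """

    sites: np.ndarray
    haps: np.ndarray
    carriers: pd.DataFrame

    def __post_init__(self):
        self.haps = np.asarray(self.haps)
        if self.haps.shape[1] != len(self.carriers):
            raise ValueError("one carrier row per haplotype required")


@dataclass
class ClusterConfig:
    eps: float = 0.1      # neighborhood radius in MDS space
    min_pts: int = 5
    n_dims: int = 2

    def __post_init__(self):
        if self.eps <= 0 or self.min_pts < 2:
            raise ValueError("need eps > 0 and min_pts >= 2")


def asd_matrix(data, mode="haplotype") -> np.ndarray:
    """Pairwise allele-sharing distance in [0, 1].

    ``haplotype`` mode: proportion of mismatching sites between 0/1
    haplotype columns (normalized Hamming distance).  ``genotype``
    mode: mean |g1 - g2| / 2 over diploid dosage columns.  Missing
    values (negative entries) are excluded pairwise; a pair with no
    shared called site raises with the offending indices.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (sites x entities) matrix")
    if mode not in ("haplotype", "genotype"):
        raise ValueError(f"unknown mode {mode!r}")
    valid = (x >= 0).astype(float)
    shared = valid.T @ valid
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(f"entities {i} and {j} share no called site")
    # |a - b| for integer dosages = number of thresholds separating them,
    # so the pairwise L1 sum decomposes into 0/1 indicator products.
    thresholds = (0.5,) if mode == "haplotype" else (0.5, 1.5)
    num = np.zeros_like(shared)
    for t in thresholds:
        ind = ((x > t) & (valid > 0)).astype(float)
        above = ind.T @ valid      # [i, j] = sum over shared sites of 1(x_i > t)
        num += above + above.T - 2 * (ind.T @ ind)
    dist = num / shared
    if mode == "genotype":
        dist /= 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def classical_mds(dist, n_dims=2):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, eigendecomposes the
    Gram matrix and returns the top ``n_dims`` coordinates ordered by
    eigenvalue.  Dimensions with non-positive eigenvalues are dropped
    with a warning (``n_dims`` is reduced accordingly).
    """
    import warnings

    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * abs(evals[0])) if n > 0 else evals > 0
    n_pos = int(pos.sum())
    if n_dims > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing n_dims")
        n_dims = max(n_pos, 1)
    coords = evecs[:, :n_dims] * np.sqrt(np.maximum(evals[:n_dims], 0.0))
    return coords


def density_cluster(coords, config: ClusterConfig | None = None):
    """DBSCAN cluster labels in MDS space (-1 = noise).

    Core points have >= min_pts neighbours within eps (the point
    itself included, matching the classic formulation); clusters are
    the density-reachable components.  Deterministic given the input
    order.
    """
    config = config or ClusterConfig()
    coords = np.asarray(coords, dtype=float)
    if len(coords) < config.min_pts:
        raise ValueError("fewer points than min_pts")
    labels = DBSCAN(eps=config.eps, min_samples=config.min_pts).fit_predict(coords)
    return labels


def transmission_records(hapset: HaplotypeSet, labels, trio_set: TrioSet):
    """Resolve which parental haplotype class each child received.

    For every trio and each parent, the transmitted haplotype is the
    parental haplotype closest (allele-sharing distance) to one of the
    child's two haplotypes; with phased trio data the match is exact.
    Returns a DataFrame with one row per parental meiosis: parent
    role, parental class pair, transmitted class, child sex.
    """
    labels = np.asarray(labels)
    # map sample -> its two (or one) haplotype column indices
    by_sample = {}
    for i, row in hapset.carriers.reset_index(drop=True).iterrows():
        by_sample.setdefault(row["sample"], []).append(i)
    rows = []
    d = asd_matrix(hapset.haps, mode="haplotype")
    for t in trio_set:
        for role, parent in (("father", t.father_id), ("mother", t.mother_id)):
            pcols = by_sample.get(parent)
            ccols = by_sample.get(t.child_id)
            if not pcols or not ccols:
                continue
            # transmitted = parental hap minimizing distance to any child hap
            best = min(((d[p, c], p) for p in pcols for c in ccols))
            trans = best[1]
            pclasses = tuple(sorted(labels[p] for p in pcols))
            rows.append({
                "family": t.family_id, "parent_role": role,
                "parent_classes": pclasses,
                "transmitted": int(labels[trans]),
                "child_sex": t.child_sex,
            })
    return pd.DataFrame(rows)


def haplotype_transmission_tests(records: pd.DataFrame, p0=None,
                                 carrier_sexes=None, carrier_p0=0.5):
    """Sex-biased transmission tests per haplotype class.

    For each class ``h``, restrict to meioses from parents
    heterozygous h/other.  Let ``k`` be transmissions of h to sons out
    of ``m`` transmissions of h, and let the null son-fraction be the
    son share among *all* transmissions from such parents (or a fixed
    ``p0`` when supplied).  Reports a two-sided exact binomial test of
    k/m against that fraction, plus a 2x2 Fisher exact test of
    (transmitted h vs other) x (child sex).

    When ``carrier_sexes`` (a sequence of "male"/"female" per carrier
    of h) is given, a carrier sex-bias binomial test against
    ``carrier_p0`` is added.

    Classes with zero informative parents are skipped and listed in
    the ``skipped`` attribute of the returned frame.
    """
    records = pd.DataFrame(records)
    classes = sorted({c for pair in records["parent_classes"] for c in pair
                      if c >= 0})
    rows, skipped = [], []
    for h in classes:
        het = records[[(h in pc and len(set(pc)) > 1)
                       for pc in records["parent_classes"]]]
        if het.empty:
            skipped.append(h)
            continue
        is_h = het["transmitted"] == h
        to_son = het["child_sex"] == MALE
        m = int(is_h.sum())
        k = int((is_h & to_son).sum())
        null_frac = p0 if p0 is not None else float(to_son.mean())
        if m > 0 and 0 < null_frac < 1:
            binom_p = stats.binomtest(k, m, null_frac).pvalue
        else:
            binom_p = np.nan
        table = [[int((is_h & to_son).sum()), int((is_h & ~to_son).sum())],
                 [int((~is_h & to_son).sum()), int((~is_h & ~to_son).sum())]]
        fisher_p = stats.fisher_exact(table)[1]
        row = {
            "haplotype": h, "n_meioses": len(het),
            "n_transmitted": m, "n_transmitted_to_sons": k,
            "null_son_fraction": null_frac,
            "binom_p": binom_p, "fisher_p": fisher_p,
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    if carrier_sexes is not None:
        cs = pd.Series(carrier_sexes)
        k_male = int((cs == MALE).sum())
        out.attrs["carrier_bias_p"] = stats.binomtest(
            k_male, len(cs), carrier_p0).pvalue
    return out


def binomial_transmission_test(k, n, p0=0.5, alternative="two-sided"):
    """Exact binomial test of a transmission count (convenience wrapper)."""
    return stats.binomtest(int(k), int(n), p0, alternative=alternative).pvalue


def mantel_sex_test(dist, sexes, n_perm=9999, seed=None, rng=None):
    """Mantel-type permutation test for genetic structure by sex.

    Correlates the off-diagonal genetic distances with a 0/1
    same/different-sex indicator matrix; the permutation null shuffles
    individual labels.  Returns ``(r, p)`` with
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    d = np.asarray(dist, dtype=float)
    sexes = np.asarray(sexes)
    if len(set(sexes.tolist())) < 2:
        raise ValueError("need both sexes present")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d[iu]

    def indicator(s):
        return (s[iu[0]] != s[iu[1]]).astype(float)

    y = indicator(sexes)
    r_obs = np.corrcoef(x, y)[0, 1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_p = indicator(sexes[perm])
        r_p = np.corrcoef(x, y_p)[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-15:
            count += 1
    return float(r_obs), (1 + count) / (1 + n_perm)


def read_phased_vcf(path, region=None) -> HaplotypeSet:
    """Load phased GT calls into a :class:`HaplotypeSet`.

    Diploid samples contribute two haplotype columns; hemizygous calls
    contribute one.  Unphased heterozygous diploid calls raise.
    """
    sites, columns = [], None
    hap_rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        it = vcf.fetch(region=region) if region else vcf
        metas = None
        for rec in it:
            if len(rec.alts or ()) != 1:
                continue
            row = []
            metas_rec = []
            for s in samples:
                sm = rec.samples[s]
                gt = sm.get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                phased = bool(sm.phased) if gt else False
                if len(alleles) == 2 and alleles[0] != alleles[1] and not phased:
                    raise ValueError(f"unphased heterozygote for {s} at {rec.pos}")
                if gt is None or len(gt) == 0:
                    alleles = []
                for hi, a in enumerate(gt or ()):
                    row.append(-1 if a is None else int(a))
                    metas_rec.append((s, hi))
            if metas is None:
                metas = metas_rec
            elif metas_rec != metas:
                raise ValueError("inconsistent ploidy across records")
            sites.append(rec.pos)
            hap_rows.append(row)
    if not hap_rows:
        raise ValueError("no usable phased records found")
    carriers = pd.DataFrame(metas, columns=["sample", "hap"])
    return HaplotypeSet(np.asarray(sites), np.asarray(hap_rows), carriers)
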