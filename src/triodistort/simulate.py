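"""Trio simulation: power analyses, null calibration and VCF fixtures.

The generators here emulate the study conditions of a trio cohort of
the Genome-of-the-Netherlands scale: ~250 parent-offspring trios (98
sons / 152 daughters by default), biallelic autosomal and X-linked
SNPs with Hardy-Weinberg parents at intermediate frequencies, and
Mendelian or distorted transmission with optional sex-specific
distortion, Mendelian-error injection and missingness.

Two layers are provided:

* **count-level** simulation (:func:`simulate_site`,
  :func:`simulate_sites`, :func:`power_analysis`,
  :func:`simulate_counts_track`) — draws the sufficient statistics
  (k, n per offspring sex) directly; this is what the power and
  calibration analyses use.  The default power design is one
  informative meiosis per trio with balanced offspring sexes, and
  sex-antagonistic scenarios split symmetrically
  (eps_m = +delta/2, eps_f = -delta/2).
* **genotype-level** fixtures (:func:`make_fixture`) — writes a
  VCF + PED pair plus a ground-truth sidecar so that the whole
  input path (parsing, filtering, Mendelian masking, counting) can be
  exercised end to end.

Every operation takes a seed or an explicit :class:`numpy.random.Generator`
and is bit-reproducible given it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .likelihood import _fit_arrays
from .trio_io import SiteCounts

__all__ = [
    "SimConfig", "WindowSimConfig", "PlantedRegion",
    "simulate_site", "simulate_sites", "power_analysis",
    "simulate_window_lengths", "simulate_counts_track", "make_fixture",
]


@dataclass
class SimConfig:
    """Transmission-simulation parameters for one site.

    ``n_trios`` counts *informative* trios; each contributes one
    meiosis unless it is a het x het mating (``frac_double_het``),
    which contributes two.
    """

    n_trios: int = 150
    frac_double_het: float = 0.0
    p_male_child: float = 0.5
    model: str = "M0"            # M0 | M1 | M2
    eps: float = 0.0             # M1
    eps_m: float = 0.0           # M2
    eps_f: float = 0.0
    chrom_class: str = "autosome"
    seed: int | None = None

    def __post_init__(self):
        for e in (self.eps, self.eps_m, self.eps_f):
            if not -0.5 <= e <= 0.5:
                raise ValueError("distortion parameters must lie in [-1/2, 1/2]")
        for p in (self.frac_double_het, self.p_male_child):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        if self.model not in ("M0", "M1", "M2"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def eps_by_sex(self):
        if self.model == "M0":
            return 0.0, 0.0
        if self.model == "M1":
            return self.eps, self.eps
        return self.eps_m, self.eps_f


@dataclass
class WindowSimConfig:
    """Recombination-free-window simulation parameters.

    ``lam`` is the expected number of recombination events per unit of
    physical distance; with 1 cM/Mb and megabase units, lam = 0.01.
    """

    n_trios: int = 150
    lam: float = 0.01
    reps: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        if self.lam <= 0 or self.n_trios < 1:
            raise ValueError("need lam > 0 and n_trios >= 1")


@dataclass
class PlantedRegion:
    """A contiguous run of sites simulated under a non-null model."""

    start: int            # first site index (0-based, inclusive)
    end: int              # last site index (inclusive)
    model: str = "M2"
    eps: float = 0.0
    eps_m: float = 0.0
    eps_f: float = 0.0


def _sim_counts(reps, config: SimConfig, rng):
    """Vectorized sufficient-statistic draws for ``reps`` i.i.d. sites."""
    e_m, e_f = config.eps_by_sex
    n_sons = rng.binomial(config.n_trios, config.p_male_child, size=reps)
    n_daughters = config.n_trios - n_sons
    if config.frac_double_het > 0:
        n_m = n_sons + rng.binomial(n_sons, config.frac_double_het)
        n_f = n_daughters + rng.binomial(n_daughters, config.frac_double_het)
    else:
        n_m, n_f = n_sons, n_daughters
    k_m = rng.binomial(n_m, 0.5 + e_m)
    k_f = rng.binomial(n_f, 0.5 + e_f)
    return k_m, n_m, k_f, n_f


def simulate_site(config: SimConfig, rng=None) -> SiteCounts:
    """Draw the transmission counts of a single simulated SNP."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k_m, n_m, k_f, n_f = (int(a[0]) for a in _sim_counts(1, config, rng))
    return SiteCounts("sim", 1, "A", "B", config.chrom_class,
                      k_m, n_m, k_f, n_f, config.n_trios, 0)


def simulate_sites(reps, config: SimConfig, rng=None) -> pd.DataFrame:
    """Transmission counts for ``reps`` independent simulated SNPs."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k_m, n_m, k_f, n_f = _sim_counts(reps, config, rng)
    return pd.DataFrame({"k_m": k_m, "n_m": n_m, "k_f": k_f, "n_f": n_f})


def power_analysis(configs, test="M2vM0", alpha=0.05, reps=500,
                   seed=None, rng=None) -> pd.DataFrame:
    """Empirical power of one LRT over a grid of simulation scenarios.

    Parameters
    ----------
    configs : iterable of SimConfig (the grid cells).
    test : "M2vM0" (2 df) or "M1vM0" (1 df).
    alpha : significance level of the LRT.
    reps : simulated sites per cell.

    Returns a table with one row per cell: the scenario parameters,
    the rejection count and ``power = rejections / reps``.
    """
    if test not in ("M2vM0", "M1vM0"):
        raise ValueError(f"unknown test {test!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    pcol = "p20" if test == "M2vM0" else "p10"
    rows = []
    for cfg in configs:
        k_m, n_m, k_f, n_f = _sim_counts(reps, cfg, rng)
        fit = _fit_arrays(k_m, n_m, k_f, n_f, ci=False)
        rej = int((fit[pcol] < alpha).sum())
        e_m, e_f = cfg.eps_by_sex
        rows.append({
            "n_trios": cfg.n_trios, "model": cfg.model, "test": test,
            "eps": cfg.eps, "eps_m": e_m, "eps_f": e_f,
            "delta": abs(e_m - e_f), "alpha": alpha, "reps": reps,
            "rejections": rej, "power": rej / reps,
        })
    return pd.DataFrame(rows)


def simulate_window_lengths(config: WindowSimConfig, rng=None, chunk=5000):
    """Simulate recombination-free window lengths around a focal SNP.

    For each replicate, every one of ``n_trios`` trios receives an
    upstream and a downstream nearest-recombination-breakpoint
    distance, each Exponential(lam); the window in complete linkage
    across all trios is the minimum upstream distance plus the minimum
    downstream distance.  The sum of the two minima is
    Gamma(shape 2, rate n_trios * lam), which the returned
    method-of-moments estimates recover.

    Returns ``(lengths, summary)`` where summary holds the sample
    mean/variance and the MoM gamma ``shape`` (mean^2/var) and
    ``rate`` (mean/var).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = np.empty(config.reps)
    done = 0
    scale = 1.0 / config.lam
    while done < config.reps:
        b = min(chunk, config.reps - done)
        up = rng.exponential(scale, size=(b, config.n_trios)).min(axis=1)
        down = rng.exponential(scale, size=(b, config.n_trios)).min(axis=1)
        lengths[done:done + b] = up + down
        done += b
    mean = lengths.mean()
    var = lengths.var(ddof=1)
    summary = {
        "mean": float(mean), "var": float(var),
        "shape": float(mean ** 2 / var), "rate": float(mean / var),
        "theory_mean": 2.0 / (config.n_trios * config.lam),
    }
    return lengths, summary


def simulate_counts_track(n_sites=200, n_trios=250, planted=(),
                          chrom="1", spacing=5000, seed=None, rng=None,
                          p_male_child=0.5) -> pd.DataFrame:
    """A chromosome-length counts table with optional planted distortion.

    Sites outside every :class:`PlantedRegion` follow Mendelian
    transmission; sites inside follow the region's model.  Positions
    are regularly spaced.  This is the fast path for end-to-end
    region-recovery experiments (scan -> local score -> classify)
    without genotype-level I/O.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    frames = []
    member = np.full(n_sites, -1)
    for ri, reg in enumerate(planted):
        member[reg.start:reg.end + 1] = ri
    for s in range(n_sites):
        if member[s] >= 0:
            reg = planted[member[s]]
            cfg = SimConfig(n_trios=n_trios, model=reg.model, eps=reg.eps,
                            eps_m=reg.eps_m, eps_f=reg.eps_f,
                            p_male_child=p_male_child)
        else:
            cfg = SimConfig(n_trios=n_trios, model="M0",
                            p_male_child=p_male_child)
        k_m, n_m, k_f, n_f = (int(a[0]) for a in _sim_counts(1, cfg, rng))
        frames.append({"chrom": chrom, "pos": (s + 1) * spacing,
                       "k_m": k_m, "n_m": n_m, "k_f": k_f, "n_f": n_f,
                       "true_region": int(member[s])})
    return pd.DataFrame(frames)


# ---------------------------------------------------------------------------
# genotype-level fixture


def _hw_genotypes(rng, p, n):
    """Diploid ALT dosages under Hardy-Weinberg at ALT frequency p."""
    return rng.binomial(1, p, size=n) + rng.binomial(1, p, size=n)


def _transmit(rng, dosage, eps):
    """One allele from a diploid parent; het parents are distorted."""
    if dosage == 0:
        return 0
    if dosage == 2:
        return 1
    return int(rng.random() < 0.5 + eps)


def make_fixture(out_dir, n_trios=250, n_sons=98, n_sites=60, n_x_sites=30,
                 maf=(0.3, 0.5), planted=(), planted_x=(),
                 mendel_error_rate=0.0, missing_rate=0.0, seed=0,
                 autosome="1", spacing=5000, prefix="fixture"):
    """Write a synthetic trio VCF + PED + ground-truth table.

    Parents are drawn under Hardy-Weinberg at a per-site ALT frequency
    uniform over ``maf``; children follow each site's transmission
    model (Mendelian unless the site lies in a planted region).  The
    X block has hemizygous fathers and sons.  Mendelian errors replace
    the child's call with an incompatible dosage where one exists;
    missingness nulls genotypes at random.

    Returns ``(vcf_path, ped_path, truth_path)``.  All outputs are
    plain text; the truth table records the true per-site eps values.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sexes = np.array(["male"] * n_sons + ["female"] * (n_trios - n_sons))
    rng.shuffle(sexes)
    fams = [f"F{i+1}" for i in range(n_trios)]
    fathers = [f"{f}_fa" for f in fams]
    mothers = [f"{f}_mo" for f in fams]
    children = [f"{f}_ch" for f in fams]

    ped_path = out_dir / f"{prefix}.ped"
    with open(ped_path, "w") as fh:
        fh.write("family\tfather\tmother\tchild\tsex\n")
        for f, fa, mo, ch, sx in zip(fams, fathers, mothers, children, sexes):
            fh.write(f"{f}\t{fa}\t{mo}\t{ch}\t{'1' if sx == 'male' else '2'}\n")

    member_a = np.full(n_sites, -1)
    for ri, reg in enumerate(planted):
        member_a[reg.start:reg.end + 1] = ri
    member_x = np.full(n_x_sites, -1)
    for ri, reg in enumerate(planted_x):
        member_x[reg.start:reg.end + 1] = ri

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line(f'##contig=<ID={autosome},length={(n_sites + 2) * spacing}>')
    header.add_line(f'##contig=<ID=X,length={155_270_560}>')
    header.formats.add("GT", 1, "String", "Genotype")
    for s in [x for trio in zip(fathers, mothers, children) for x in trio]:
        header.add_sample(s)
    samples = list(header.samples)
    sample_idx = {s: i for i, s in enumerate(samples)}

    truth_rows = []
    vcf_path = out_dir / f"{prefix}.vcf"

    def _site_eps(member, planted_list, s):
        if member[s] < 0:
            return 0.0, 0.0, "M0"
        reg = planted_list[member[s]]
        if reg.model == "M1":
            return reg.eps, reg.eps, "M1"
        if reg.model == "M0":
            return 0.0, 0.0, "M0"
        return reg.eps_m, reg.eps_f, "M2"

    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        # autosomal block
        for s in range(n_sites):
            p = rng.uniform(*maf)
            e_m, e_f, model = _site_eps(member_a, planted, s)
            pos = (s + 1) * spacing
            rec = vcf.new_record(contig=autosome, start=pos - 1,
                                 alleles=("A", "C"))
            fa_d = _hw_genotypes(rng, p, n_trios)
            mo_d = _hw_genotypes(rng, p, n_trios)
            gts = {}
            for t in range(n_trios):
                eps = e_m if sexes[t] == "male" else e_f
                child = (_transmit(rng, fa_d[t], eps)
                         + _transmit(rng, mo_d[t], eps))
                gts[fathers[t]] = fa_d[t]
                gts[mothers[t]] = mo_d[t]
                gts[children[t]] = child
                if mendel_error_rate and rng.random() < mendel_error_rate:
                    bad = _incompatible_dosages(fa_d[t], mo_d[t])
                    if bad:
                        gts[children[t]] = int(rng.choice(bad))
            _write_gts(rec, gts, rng, missing_rate)
            truth_rows.append({"chrom": autosome, "pos": pos, "model": model,
                               "true_eps_m": e_m, "true_eps_f": e_f})
            vcf.write(rec)
        # X block (outside the pseudoautosomal intervals)
        x_base = 3_000_000
        for s in range(n_x_sites):
            p = rng.uniform(*maf)
            e_m, e_f, model = _site_eps(member_x, planted_x, s)
            pos = x_base + (s + 1) * spacing
            rec = vcf.new_record(contig="X", start=pos - 1, alleles=("A", "C"))
            fa_a = rng.binomial(1, p, size=n_trios)       # hemizygous fathers
            mo_d = _hw_genotypes(rng, p, n_trios)
            gts = {}
            for t in range(n_trios):
                gts[fathers[t]] = (int(fa_a[t]),)          # 1-ploid call
                gts[mothers[t]] = mo_d[t]
                if sexes[t] == "male":
                    gts[children[t]] = (_transmit(rng, mo_d[t], e_m),)
                else:
                    gts[children[t]] = int(fa_a[t]) + _transmit(rng, mo_d[t], e_f)
            _write_gts(rec, gts, rng, missing_rate)
            truth_rows.append({"chrom": "X", "pos": pos, "model": model,
                               "true_eps_m": e_m, "true_eps_f": e_f})
            vcf.write(rec)

    truth_path = out_dir / f"{prefix}.truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return vcf_path, ped_path, truth_path


def _incompatible_dosages(fa, mo):
    """Child dosages impossible for a diploid autosomal mating."""
    possible = {f + m for f in _alleles(fa) for m in _alleles(mo)}
    return sorted(set((0, 1, 2)) - possible)


def _alleles(dosage):
    return {0: (0,), 1: (0, 1), 2: (1,)}[int(dosage)]


def _write_gts(rec, gts, rng, missing_rate):
    for sample, g in gts.items():
        hemizygous = isinstance(g, tuple)
        if missing_rate and rng.random() < missing_rate:
            rec.samples[sample]["GT"] = (None,) if hemizygous else (None, None)
            continue
        if hemizygous:
            rec.samples[sample]["GT"] = g
        else:
            rec.samples[sample]["GT"] = ((0, 0), (0, 1), (1, 1))[int(g)]
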