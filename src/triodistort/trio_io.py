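"""Pedigree and VCF handling: sex checks, site filters, transmission counts.

This module turns a multi-sample VCF plus a trio pedigree into the
per-SNP sex-stratified transmission counts consumed by
:mod:`triodistort.likelihood`.  A trio is *informative* at an autosomal
SNP when at least one parent is heterozygous (and both parental
genotypes are called); on the X it is informative exactly when the
mother is heterozygous.  Transmission of the ALT allele ("B") is then
resolvable:

* hom x het autosomal mating: one meiosis — the child carries B from
  the heterozygous parent iff its B dosage exceeds the homozygous
  parent's contribution;
* het x het autosomal mating: two meioses, with B-transmission count
  equal to the child's B dosage;
* X-linked: a son's hemizygous allele is the maternal transmission; a
  daughter's maternal allele is her dosage minus the father's
  (hemizygous) allele.

Trios are assumed genetically unrelated; this is a documented modelling
assumption and is not checked.

Genotypes are represented internally as two small integer arrays per
site: ALT **dosage** (``-1`` = missing) and **ploidy** (1 for
hemizygous calls, 2 otherwise).  For biallelic SNPs this pair carries
all information the transmission and Mendelian-error logic needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Trio",
    "TrioSet",
    "FilterConfig",
    "SexCheckConfig",
    "SiteCounts",
    "load_pedigree",
    "verify_sex_labels",
    "detect_mendelian_error",
    "extract_transmissions",
    "site_filter",
    "count_transmissions",
]

MALE = "male"
FEMALE = "female"
MISSING = -1

_SEX_CODES = {
    "1": MALE, "2": FEMALE,
    "m": MALE, "f": FEMALE,
    "male": MALE, "female": FEMALE,
}

#: hg19 pseudoautosomal intervals on the X, 1-based inclusive.
DEFAULT_PAR = (("X", 60001, 2699520), ("X", 154931044, 155260560))


@dataclass(frozen=True)
class Trio:
    family_id: str
    father_id: str
    mother_id: str
    child_id: str
    child_sex: str  # "male" | "female"


@dataclass
class TrioSet:
    """A validated collection of parent-offspring trios."""

    trios: tuple

    def __post_init__(self):
        seen_children = set()
        for t in self.trios:
            if t.child_sex not in (MALE, FEMALE):
                raise ValueError(f"trio {t.family_id}: unknown child sex {t.child_sex!r}")
            ids = (t.father_id, t.mother_id, t.child_id)
            if any(not s for s in ids):
                raise ValueError(f"trio {t.family_id}: missing sample ID")
            if len(set(ids)) != 3:
                raise ValueError(f"trio {t.family_id}: sample IDs not unique within trio")
            if t.child_id in seen_children:
                raise ValueError(f"duplicate child ID {t.child_id!r}")
            seen_children.add(t.child_id)
        self.trios = tuple(self.trios)

    def __len__(self):
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    @property
    def n_sons(self):
        return sum(t.child_sex == MALE for t in self.trios)

    @property
    def n_daughters(self):
        return sum(t.child_sex == FEMALE for t in self.trios)

    @property
    def sample_ids(self):
        out = []
        for t in self.trios:
            out.extend((t.father_id, t.mother_id, t.child_id))
        return out

    def sample_sexes(self):
        """Pedigree sex per sample ID (parents by role, children by label)."""
        sexes = {}
        for t in self.trios:
            sexes[t.father_id] = MALE
            sexes[t.mother_id] = FEMALE
            sexes[t.child_id] = t.child_sex
        return sexes


@dataclass
class FilterConfig:
    """Site-level filter thresholds.

    ``max_mendel_errors`` is the number of per-trio Mendelian errors at
    which a site is discarded (default 2: sites with two or more errors
    are removed; a single error only masks that trio's genotypes).
    """

    min_informative_autosome: int = 150
    min_informative_x: int = 75
    max_mendel_errors: int = 2
    par_intervals: tuple = DEFAULT_PAR
    drop_male_het_x: bool = True
    pass_only: bool = False

    def __post_init__(self):
        if self.min_informative_autosome <= 0 or self.min_informative_x <= 0:
            raise ValueError("informative-trio thresholds must be positive")
        ivals = sorted(self.par_intervals, key=lambda iv: (iv[0], iv[1]))
        for a, b in zip(ivals, ivals[1:]):
            if a[0] == b[0] and b[1] <= a[2]:
                raise ValueError("PAR intervals overlap")


@dataclass
class SexCheckConfig:
    """X-heterozygosity thresholds used to verify pedigree sex labels."""

    male_max_het_frac: float = 0.02
    female_min_het_frac: float = 0.06

    def __post_init__(self):
        if not (0 <= self.male_max_het_frac < self.female_min_het_frac <= 1):
            raise ValueError("need 0 <= male_max < female_min <= 1")


@dataclass
class SiteCounts:
    """Sex-stratified transmission tallies for one SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    chrom_class: str  # "autosome" | "X"
    k_m: int
    n_m: int
    k_f: int
    n_f: int
    n_informative_trios: int
    mendel_errors: int

    def __post_init__(self):
        if not (0 <= self.k_m <= self.n_m and 0 <= self.k_f <= self.n_f):
            raise ValueError("transmission counts out of range")


def load_pedigree(source) -> TrioSet:
    """Read a PED-like table into a :class:`TrioSet`.

    Accepts a path or file-like object with whitespace/tab-separated
    columns ``family father mother child sex`` where sex is coded
    ``1``/``2``, ``M``/``F`` or ``male``/``female``.  A header line is
    optional (detected by non-sex content in column 5).
    """
    df = pd.read_csv(source, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise ValueError("pedigree needs >= 5 columns: family father mother child sex")
    if str(df.iloc[0, 4]).strip().lower() in ("sex", "gender", "child_sex"):
        df = df.iloc[1:]  # header row
    trios = []
    for _, row in df.iterrows():
        fam, father, mother, child, sex = (str(row[i]).strip() for i in range(5))
        code = _SEX_CODES.get(sex.lower())
        if code is None:
            raise ValueError(f"unknown sex code {sex!r} for child {child!r}")
        if father in ("0", "") or mother in ("0", ""):
            raise ValueError(f"trio {fam}: both parents must be named")
        trios.append(Trio(fam, father, mother, child, code))
    return TrioSet(tuple(trios))


def chrom_class(chrom: str) -> str:
    """"X" for the X chromosome under common naming schemes, else "autosome"."""
    c = chrom.lower().removeprefix("chr")
    return "X" if c == "x" else "autosome"


def in_par(chrom: str, pos: int, par_intervals=DEFAULT_PAR) -> bool:
    c = chrom.lower().removeprefix("chr")
    for pchrom, start, end in par_intervals:
        if c == pchrom.lower().removeprefix("chr") and start <= pos <= end:
            return True
    return False


# ---------------------------------------------------------------------------
# genotype codecs

def decode_gt(gt) -> tuple[int, int]:
    """pysam GT tuple -> (dosage, ploidy); dosage -1 when missing.

    Non-biallelic allele indices are rejected by the caller; anything
    malformed is treated as missing.
    """
    if gt is None:
        return MISSING, 2
    alleles = [a for a in gt if a is not None]
    if len(alleles) == 0:
        return MISSING, 2 if len(gt) != 1 else 1
    if any(a not in (0, 1) for a in alleles):
        return MISSING, len(alleles)
    if len(alleles) == 1:
        return alleles[0], 1
    return alleles[0] + alleles[1], 2


def _contrib(dosage: int, ploidy: int) -> tuple[int, ...]:
    """Possible single-allele contributions of a parent genotype."""
    if dosage == MISSING:
        return (0, 1)
    if ploidy == 1:
        return (dosage,)
    return {0: (0,), 1: (0, 1), 2: (1,)}[dosage]


def detect_mendelian_error(father, mother, child, chrom_class="autosome",
                           child_sex=FEMALE) -> bool:
    """True iff the child genotype is impossible given the parents.

    Each genotype is a ``(dosage, ploidy)`` pair as produced by
    :func:`decode_gt`.  Missing members never create an error.  On the
    X a son's single allele must be derivable from the mother, and a
    daughter must combine the father's allele with a maternal one.
    """
    fd, fp = father
    md, mp = mother
    cd, cp = child
    if cd == MISSING:
        return False
    if chrom_class == "X":
        if child_sex == MALE:
            # hemizygous son: allele (0 or 1) from the mother
            allele = cd if cp == 1 else {0: 0, 2: 1}.get(cd)
            if allele is None:  # heterozygous diploid male call: not testable here
                return False
            return allele not in _contrib(md, mp)
        pat = _contrib(fd, 1 if fp == 1 else fp) if fd != MISSING else (0, 1)
        if fd != MISSING and fp == 2:
            # diploid-coded father on X: use his hom allele, het is untestable
            pat = {0: (0,), 2: (1,)}.get(fd, (0, 1))
        return not any(p + m == cd for p in pat for m in _contrib(md, mp))
    return not any(f + m == cd for f in _contrib(fd, fp) for m in _contrib(md, mp))


def extract_transmissions(dosage, ploidy, trio_set: TrioSet, sample_index,
                          chrom_class="autosome", site_info=None) -> SiteCounts:
    """Reduce one site's genotypes to sex-stratified transmission counts.

    Parameters
    ----------
    dosage, ploidy : arrays over samples (see :func:`decode_gt`).
    trio_set : TrioSet
    sample_index : mapping sample ID -> array index.
    chrom_class : {"autosome", "X"}
    site_info : optional (chrom, pos, ref, alt) for the output record.

    Mendelian-error handling is the caller's job (see
    :func:`count_transmissions`, which masks offending trios first);
    here an unresolvable trio is silently skipped.
    """
    k_m = n_m = k_f = n_f = 0
    informative = 0
    for t in trio_set:
        fi, mi, ci = (sample_index[t.father_id], sample_index[t.mother_id],
                      sample_index[t.child_id])
        fd, fp = int(dosage[fi]), int(ploidy[fi])
        md, mp = int(dosage[mi]), int(ploidy[mi])
        cd, cp = int(dosage[ci]), int(ploidy[ci])
        if chrom_class == "X":
            if md == MISSING or mp != 2 or md != 1:
                continue  # informative iff the mother is a called het
            informative += 1
            if cd == MISSING:
                continue
            if t.child_sex == MALE:
                allele = cd if cp == 1 else {0: 0, 2: 1}.get(cd)
                if allele is None:
                    continue
                k_m += allele
                n_m += 1
            else:
                pat = fd if fp == 1 else {0: 0, 2: 1}.get(fd, None)
                if fd == MISSING or pat is None:
                    continue  # father's allele needed to subtract
                mat = cd - pat
                if mat in (0, 1):
                    k_f += mat
                    n_f += 1
            continue
        # autosome
        if fd == MISSING or md == MISSING:
            continue
        n_het = (fd == 1) + (md == 1)
        if n_het == 0:
            continue
        informative += 1
        if cd == MISSING:
            continue
        if n_het == 2:
            b_trans, meioses = cd, 2
        else:
            hom = fd if md == 1 else md
            b_trans, meioses = cd - hom // 2, 1
            if b_trans not in (0, 1):
                continue  # Mendelian inconsistency left unmasked: skip
        if t.child_sex == MALE:
            k_m += b_trans
            n_m += meioses
        else:
            k_f += b_trans
            n_f += meioses
    chrom, pos, ref, alt = site_info if site_info else ("?", 0, "N", "N")
    return SiteCounts(chrom, pos, ref, alt, chrom_class,
                      k_m, n_m, k_f, n_f, informative, 0)


def verify_sex_labels(x_dosage, sample_ids, config: SexCheckConfig | None = None,
                      pedigree_sexes=None):
    """Infer sample sex from X-chromosome heterozygosity.

    Parameters
    ----------
    x_dosage : (n_sites, n_samples) array
        ALT dosages at non-PAR X sites, ``-1`` for missing.
    sample_ids : sequence of str
    config : SexCheckConfig
    pedigree_sexes : optional mapping sample -> declared sex; when
        given, the returned frame includes a ``conflict`` column.

    Returns
    -------
    pandas.DataFrame indexed by sample with columns ``het_frac``,
    ``inferred`` (male / female / unassigned) and optionally
    ``conflict``.
    """
    config = config or SexCheckConfig()
    x = np.asarray(x_dosage)
    called = x >= 0
    n_called = called.sum(axis=0)
    if np.any(n_called == 0):
        warnings.warn("samples with zero usable X sites are 'unassigned'")
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0,
                       (x == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    inferred = np.full(len(sample_ids), "unassigned", dtype=object)
    inferred[het < config.male_max_het_frac] = MALE
    inferred[het > config.female_min_het_frac] = FEMALE
    out = pd.DataFrame({"het_frac": het, "inferred": inferred},
                       index=pd.Index(sample_ids, name="sample"))
    if pedigree_sexes is not None:
        declared = out.index.map(lambda s: pedigree_sexes.get(s))
        out["declared"] = declared
        out["conflict"] = [
            (d is not None and i != "unassigned" and i != d)
            for d, i in zip(out["declared"], out["inferred"])
        ]
    return out


# ---------------------------------------------------------------------------
# streaming VCF -> counts

def _site_arrays(rec, samples):
    dosage = np.empty(len(samples), dtype=np.int8)
    ploidy = np.empty(len(samples), dtype=np.int8)
    for i, s in enumerate(samples):
        try:
            gt = rec.samples[s].get("GT")
        except KeyError:
            gt = None
        d, p = decode_gt(gt)
        dosage[i] = d
        ploidy[i] = p
    return dosage, ploidy


def site_filter(rec, trio_set: TrioSet, config: FilterConfig,
                precomputed=None):
    """Keep/drop decision for one VCF record.

    Returns ``(keep, reason, counts_or_None)``.  The drop reasons, in
    the order tested, are ``not_biallelic``, ``filter_fail``, ``par``,
    ``male_het_x``, ``mendel_errors`` and ``informative``.  When the
    site is kept, the genotypes of trios with a Mendelian error are set
    missing (the child's call is masked) before counting, and the
    resulting :class:`SiteCounts` is returned.
    """
    if len(rec.alts or ()) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
        return False, "not_biallelic", None
    if config.pass_only and rec.filter.keys() not in ([], ["PASS"]):
        return False, "filter_fail", None
    cclass = chrom_class(rec.chrom)
    pos = rec.pos  # pysam .pos is 1-based
    if cclass == "X" and in_par(rec.chrom, pos, config.par_intervals):
        return False, "par", None

    samples = trio_set.sample_ids
    index = {s: i for i, s in enumerate(samples)}
    if precomputed is None:
        dosage, ploidy = _site_arrays(rec, samples)
    else:
        dosage, ploidy = precomputed

    if cclass == "X" and config.drop_male_het_x:
        sexes = trio_set.sample_sexes()
        for s, i in index.items():
            if sexes[s] == MALE and ploidy[i] == 2 and dosage[i] == 1:
                return False, "male_het_x", None

    n_errors = 0
    masked = dosage.copy()
    for t in trio_set:
        fi, mi, ci = index[t.father_id], index[t.mother_id], index[t.child_id]
        err = detect_mendelian_error((dosage[fi], ploidy[fi]),
                                     (dosage[mi], ploidy[mi]),
                                     (dosage[ci], ploidy[ci]),
                                     cclass, t.child_sex)
        if err:
            n_errors += 1
            masked[ci] = MISSING
    if n_errors >= config.max_mendel_errors:
        return False, "mendel_errors", None

    counts = extract_transmissions(
        masked, ploidy, trio_set, index, cclass,
        site_info=(rec.chrom, pos, rec.ref, rec.alts[0]))
    counts.mendel_errors = n_errors
    threshold = (config.min_informative_x if cclass == "X"
                 else config.min_informative_autosome)
    if counts.n_informative_trios < threshold:
        return False, "informative", None
    return True, "", counts


def count_transmissions(vcf_path, trio_set: TrioSet,
                        config: FilterConfig | None = None):
    """Stream a VCF into a transmission-count table plus a filter log.

    Returns ``(counts, log)`` DataFrames.  ``counts`` has one row per
    kept site with columns chrom, pos, ref, alt, chrom_class, k_m, n_m,
    k_f, n_f, informative, mendel_errors; ``log`` records every
    dropped site with its reason.
    """
    config = config or FilterConfig()
    rows, log = [], []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_samples = set(vcf.header.samples)
        missing = [s for s in trio_set.sample_ids if s not in header_samples]
        if missing:
            raise ValueError(f"samples absent from VCF header: {missing[:5]}")
        for rec in vcf:
            keep, reason, counts = site_filter(rec, trio_set, config)
            if keep:
                rows.append(counts)
            else:
                log.append((rec.chrom, rec.pos, reason))
    counts_df = pd.DataFrame([vars(c) for c in rows])
    if counts_df.empty:
        counts_df = pd.DataFrame(columns=[
            "chrom", "pos", "ref", "alt", "chrom_class",
            "k_m", "n_m", "k_f", "n_f", "n_informative_trios", "mendel_errors"])
    log_df = pd.DataFrame(log, columns=["chrom", "pos", "reason"])
    return counts_df, log_df


def x_dosage_matrix(vcf_path, sample_ids, par_intervals=DEFAULT_PAR,
                    max_sites=None):
    """Collect non-PAR X-chromosome ALT dosages for the sex check."""
    rows = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if chrom_class(rec.chrom) != "X":
                continue
            if in_par(rec.chrom, rec.pos, par_intervals):
                continue
            if len(rec.alts or ()) != 1:
                continue
            dosage, ploidy = _site_arrays(rec, sample_ids)
            # hemizygous ALT calls are homozygous-equivalent, not het
            dosage = np.where((ploidy == 1) & (dosage == 1), 2, dosage)
            rows.append(dosage)
            if max_sites and len(rows) >= max_sites:
                break
    if not rows:
        raise ValueError("no usable X-chromosome sites found")
    return np.vstack(rows)
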