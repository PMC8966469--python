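"""Pedigree parsing, sex verification, Mendelian logic, transmission counts."""

import io
import itertools

import numpy as np
import pytest

from triodistort.simulate import make_fixture
from triodistort.trio_io import (
    MISSING,
    FilterConfig,
    SexCheckConfig,
    Trio,
    TrioSet,
    count_transmissions,
    decode_gt,
    detect_mendelian_error,
    extract_transmissions,
    in_par,
    load_pedigree,
    verify_sex_labels,
)


def ped_text(rows):
    return io.StringIO("\n".join("\t".join(map(str, r)) for r in rows))


class TestPedigree:
    def test_single_trio_identity(self):
        ts = load_pedigree(ped_text([("F1", "dad1", "mom1", "kid1", "M")]))
        assert len(ts) == 1
        t = ts.trios[0]
        assert (t.father_id, t.mother_id, t.child_id, t.child_sex) == \
            ("dad1", "mom1", "kid1", "male")

    def test_unknown_sex_code(self):
        with pytest.raises(ValueError, match="sex"):
            load_pedigree(ped_text([("F1", "d", "m", "k", "U")]))

    def test_duplicate_child(self):
        rows = [("F1", "d1", "m1", "k", "1"), ("F2", "d2", "m2", "k", "2")]
        with pytest.raises(ValueError, match="duplicate"):
            load_pedigree(ped_text(rows))

    def test_ids_unique_within_trio(self):
        with pytest.raises(ValueError):
            TrioSet((Trio("F1", "x", "x", "k", "male"),))

    def test_fixture_round_trip(self, fixture_paths):
        ts = load_pedigree(fixture_paths[1])
        assert len(ts) == 250
        assert ts.n_sons == 98
        assert ts.n_daughters == 152


class TestSexVerification:
    def test_threshold_bands(self):
        # samples with 0%, 10% and 4% X heterozygosity
        x = np.zeros((50, 3), dtype=int)
        x[:5, 1] = 1   # 10% het
        x[:2, 2] = 1   # 4% het
        out = verify_sex_labels(x, ["a", "b", "c"], SexCheckConfig())
        assert list(out["inferred"]) == ["male", "female", "unassigned"]

    def test_zero_usable_sites_warns(self):
        x = np.full((5, 1), MISSING)
        with pytest.warns(UserWarning):
            out = verify_sex_labels(x, ["s"])
        assert out.loc["s", "inferred"] == "unassigned"

    def test_conflict_reporting(self):
        x = np.zeros((100, 2), dtype=int)
        x[:20, 1] = 1
        out = verify_sex_labels(x, ["p1", "p2"],
                                pedigree_sexes={"p1": "female", "p2": "female"})
        assert bool(out.loc["p1", "conflict"])     # all-hom declared female
        assert not bool(out.loc["p2", "conflict"])

    def test_fixture_sexes_recovered(self, fixture_paths, trio_set):
        from triodistort.trio_io import x_dosage_matrix

        ids = trio_set.sample_ids
        x = x_dosage_matrix(fixture_paths[0], ids)
        out = verify_sex_labels(x, ids, pedigree_sexes=trio_set.sample_sexes())
        # with few X sites some samples fall between thresholds, but no
        # confidently inferred sex may contradict the pedigree
        assert not out["conflict"].any()
        assert (out.loc[out["declared"] == "male", "inferred"] == "male").all()


def brute_force_autosome(fd, md, cd):
    """Oracle: child dosage composable from one allele per parent."""
    alleles = {0: [0], 1: [0, 1], 2: [1], MISSING: [0, 1]}
    return any(f + m == cd for f in alleles[fd] for m in alleles[md])


class TestMendelianErrors:
    def test_textbook_cases(self):
        aa, ab, bb = (0, 2), (1, 2), (2, 2)
        assert detect_mendelian_error(aa, aa, ab)          # AA x AA -> AB
        assert not detect_mendelian_error(ab, ab, bb)      # AB x AB -> BB
        # with one parent missing, a child call is an error only when it
        # is impossible under every completion of the missing genotype
        assert not detect_mendelian_error((MISSING, 2), aa, ab)
        assert detect_mendelian_error((MISSING, 2), aa, bb)
        assert not detect_mendelian_error(aa, aa, (MISSING, 2))

    def test_autosome_full_enumeration(self):
        # every (father, mother, child) dosage configuration vs the oracle
        for fd, md, cd in itertools.product([0, 1, 2, MISSING], repeat=3):
            expect = False if cd == MISSING else not brute_force_autosome(fd, md, cd)
            got = detect_mendelian_error((fd, 2), (md, 2), (cd, 2))
            assert got == expect, (fd, md, cd)

    def test_x_son_enumeration(self):
        # son allele must come from the mother; father irrelevant
        for md, allele in itertools.product([0, 1, 2, MISSING], [0, 1]):
            maternal = {0: [0], 1: [0, 1], 2: [1], MISSING: [0, 1]}[md]
            expect = allele not in maternal
            got = detect_mendelian_error((0, 1), (md, 2), (allele, 1),
                                         chrom_class="X", child_sex="male")
            assert got == expect, (md, allele)

    def test_x_daughter_enumeration(self):
        for fa, md, cd in itertools.product([0, 1], [0, 1, 2, MISSING], [0, 1, 2]):
            maternal = {0: [0], 1: [0, 1], 2: [1], MISSING: [0, 1]}[md]
            expect = not any(fa + m == cd for m in maternal)
            got = detect_mendelian_error((fa, 1), (md, 2), (cd, 2),
                                         chrom_class="X", child_sex="female")
            assert got == expect, (fa, md, cd)

    def test_error_free_fixture(self, fixture_paths, trio_set):
        counts, _ = count_transmissions(fixture_paths[0], trio_set)
        assert (counts["mendel_errors"] == 0).all()


def run_extract(dosages, sexes, chrom_class="autosome", ploidies=None):
    """Helper: one trio per (father, mother, child) dosage triple."""
    trios = tuple(
        Trio(f"F{i}", f"fa{i}", f"mo{i}", f"ch{i}", sexes[i])
        for i in range(len(dosages))
    )
    ts = TrioSet(trios)
    flat, pl = [], []
    default_pl = [(2, 2, 2)] * len(dosages) if ploidies is None else ploidies
    for d, p in zip(dosages, default_pl):
        flat.extend(d)
        pl.extend(p)
    index = {s: i for i, s in enumerate(ts.sample_ids)}
    return extract_transmissions(np.array(flat), np.array(pl), ts, index,
                                 chrom_class)


class TestExtractTransmissions:
    def test_forced_transmissions(self):
        # AA father x AB mother, son AB: B came from the mother
        c = run_extract([(0, 1, 1)], ["male"])
        assert (c.k_m, c.n_m) == (1, 1)
        # AB x AB, daughter BB: both meioses transmitted B
        c = run_extract([(1, 1, 2)], ["female"])
        assert (c.k_f, c.n_f) == (2, 2)

    def test_no_het_parent_uninformative(self):
        c = run_extract([(0, 2, 1)], ["male"])
        assert c.n_informative_trios == 0
        assert c.n_m + c.n_f == 0

    def test_missing_parent_uninformative(self):
        c = run_extract([(MISSING, 1, 1)], ["female"])
        assert c.n_informative_trios == 0

    def test_x_transmissions(self):
        # het mother: son's hemizygous allele is the maternal meiosis
        c = run_extract([(0, 1, 1)], ["male"], chrom_class="X",
                        ploidies=[(1, 2, 1)])
        assert (c.k_m, c.n_m) == (1, 1)
        # daughter: dosage minus the father's allele
        c = run_extract([(1, 1, 2)], ["female"], chrom_class="X",
                        ploidies=[(1, 2, 2)])
        assert (c.k_f, c.n_f) == (1, 1)
        # hom mother is uninformative on X even if the father is "het"
        c = run_extract([(1, 0, 1)], ["female"], chrom_class="X",
                        ploidies=[(1, 2, 2)])
        assert c.n_informative_trios == 0

    def test_round_trip_with_planted_meioses(self, rng):
        """Generate trios with known transmissions; recover counts exactly."""
        n = 120
        sexes = ["male" if s else "female" for s in rng.integers(0, 2, n)]
        dosages, k = [], {"male": 0, "female": 0}
        nmeio = {"male": 0, "female": 0}
        for i in range(n):
            fa, mo = rng.integers(0, 3, size=2)
            if fa != 1 and mo != 1:   # uninformative mating
                dosages.append((fa, mo, fa // 2 + mo // 2))
                continue
            child = 0
            for parent in (fa, mo):
                if parent == 1:
                    b = int(rng.random() < 0.5)
                    child += b
                    k[sexes[i]] += b
                    nmeio[sexes[i]] += 1
                else:
                    child += parent // 2
            dosages.append((fa, mo, child))
        c = run_extract(dosages, sexes)
        assert (c.k_m, c.n_m) == (k["male"], nmeio["male"])
        assert (c.k_f, c.n_f) == (k["female"], nmeio["female"])


class TestSiteFilter:
    def test_kept_sites_respect_informative_threshold(self, fixture_paths,
                                                      trio_set):
        cfg = FilterConfig(min_informative_autosome=150, min_informative_x=75)
        counts, log = count_transmissions(fixture_paths[0], trio_set, cfg)
        auto = counts[counts["chrom_class"] == "autosome"]
        xs = counts[counts["chrom_class"] == "X"]
        assert (auto["n_informative_trios"] >= 150).all()
        assert (xs["n_informative_trios"] >= 75).all()

    def test_informative_threshold_boundary(self, fixture_paths, trio_set):
        # an impossible threshold drops everything with reason "informative"
        cfg = FilterConfig(min_informative_autosome=10_000,
                           min_informative_x=10_000)
        counts, log = count_transmissions(fixture_paths[0], trio_set, cfg)
        assert counts.empty
        assert (log["reason"] == "informative").all()

    def test_mendel_error_masking_and_drop(self, tmp_path, trio_set):
        vcf, ped, _ = make_fixture(tmp_path, n_trios=250, n_sons=98,
                                   n_sites=30, n_x_sites=0,
                                   mendel_error_rate=0.004, seed=7)
        ts = load_pedigree(ped)
        counts, log = count_transmissions(vcf, ts)
        dropped = set(log.loc[log["reason"] == "mendel_errors", "pos"])
        assert dropped or (counts["mendel_errors"] > 0).any()
        # surviving sites carry at most one (masked) error
        assert (counts["mendel_errors"] < 2).all()

    def test_drop_reasons(self, tmp_path):
        import pysam

        header = pysam.VariantHeader()
        header.add_line("##contig=<ID=1,length=1000000>")
        header.add_line("##contig=<ID=X,length=156000000>")
        header.formats.add("GT", 1, "String", "Genotype")
        for s in ("fa", "mo", "ch"):
            header.add_sample(s)
        path = tmp_path / "tiny.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            r = vcf.new_record(contig="1", start=99, alleles=("A", "C", "G"))
            for s in ("fa", "mo", "ch"):
                r.samples[s]["GT"] = (0, 0)
            vcf.write(r)
            r = vcf.new_record(contig="X", start=3_000_000, alleles=("A", "C"))
            r.samples["fa"]["GT"] = (0, 1)       # heterozygous male on X
            r.samples["mo"]["GT"] = (0, 1)
            r.samples["ch"]["GT"] = (0,)
            vcf.write(r)
            r = vcf.new_record(contig="1", start=199, alleles=("A", "C"))
            r.samples["fa"]["GT"] = (0, 1)
            r.samples["mo"]["GT"] = (0, 0)
            r.samples["ch"]["GT"] = (0, 1)
            vcf.write(r)
        ts = TrioSet((Trio("F1", "fa", "mo", "ch", "male"),))
        cfg = FilterConfig(min_informative_autosome=1, min_informative_x=1)
        counts, log = count_transmissions(path, ts, cfg)
        assert list(log["reason"]) == ["not_biallelic", "male_het_x"]
        assert len(counts) == 1 and counts.loc[0, "k_m"] == 1

    def test_par_positions_excluded(self):
        assert in_par("chrX", 60001)
        assert in_par("X", 2699520)
        assert not in_par("chrX", 2699521)
        assert not in_par("chr2", 60001)

    def test_overlapping_par_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FilterConfig(par_intervals=(("X", 1, 100), ("X", 50, 150)))


class TestDecodeGt:
    @pytest.mark.parametrize("gt,expect", [
        ((0, 0), (0, 2)), ((0, 1), (1, 2)), ((1, 1), (2, 2)),
        ((None, None), (MISSING, 2)), ((1,), (1, 1)), (None, (MISSING, 2)),
        ((0, 2), (MISSING, 2)),  # non-biallelic index treated as missing
    ])
    def test_codec(self, gt, expect):
        assert decode_gt(gt) == expect
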