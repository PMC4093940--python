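import numpy as np
import pytest
from Bio.Seq import Seq

from mirsnp.core_io import Config, DataError, SequenceRecord, VariantRecord
from mirsnp.ldproxy import ProxyPair
from mirsnp.mirtarget import (
    CLASS_WEIGHT,
    STACK_ENERGY,
    AlleleDelta,
    align_score,
    allele_delta,
    call_consensus,
    duplex_energy,
    find_seed_sites,
    map_snps_to_sites,
    project_to_utr,
    seed_match_6,
    _m8_complement,
)

from conftest import STRONG_MIRNA, WEAK_MIRNA, make_utr


def mk_mirna(seq: str, name: str = "mir-x") -> SequenceRecord:
    return SequenceRecord(name=name, kind="mirna", sequence=seq)


# --------------------------------------------------------------------------
# independent oracle: classify every window by the literal class definitions
# --------------------------------------------------------------------------


def _rc(rna: str) -> str:
    return str(Seq(rna.replace("U", "T")).reverse_complement())


def oracle_sites(mirna_seq: str, utr_seq: str) -> set[tuple[str, int, int]]:
    rc28 = _rc(mirna_seq[1:8])  # site text for a 7mer-m8, 5'->3' on the mRNA
    rc27 = _rc(mirna_seq[1:7])
    L = len(utr_seq)
    out: set[tuple[str, int, int]] = set()
    if L < 8:
        return out
    for i in range(L):
        if utr_seq[i:i + 8] == rc28 + "A":
            out.add(("8mer", i + 1, i + 8))
        if utr_seq[i:i + 7] == rc28 and not (i + 7 < L and utr_seq[i + 7] == "A"):
            out.add(("7mer-m8", i + 1, i + 7))
        if utr_seq[i:i + 7] == rc27 + "A" and not (i > 0 and utr_seq[i - 1] == rc28[0]):
            out.add(("7mer-A1", i + 1, i + 7))
        if utr_seq[i:i + 6] == rc27:
            up_classed = (i > 0 and utr_seq[i - 1] == rc28[0]) or (
                i + 6 < L and utr_seq[i + 6] == "A"
            )
            if not up_classed:
                out.add(("6mer", i + 1, i + 6))
    return out


def random_mirna(rng) -> str:
    return "".join(rng.choice(list("ACGU"), size=int(rng.integers(18, 25))))


def random_utr_with_plants(rng, mirna_seq: str, max_len: int = 60) -> str:
    utr = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, max_len + 1))))
    if rng.random() < 0.7:  # boost hit rate by embedding seed-match text
        fragment = _rc(mirna_seq[1:8]) + ("A" if rng.random() < 0.5 else "G")
        cut = int(rng.integers(6, 9))
        pos = int(rng.integers(0, max(1, len(utr) - cut)))
        utr = utr[:pos] + fragment[:cut] + utr[pos + cut:]
    return utr


class TestFindSeedSites:
    def test_worked_8mer_example(self):
        mirna = mk_mirna("AUGGCUAAGCUAGCUAGCUA")
        utr = make_utr("GGGTTAGCCAAGGG")
        sites = find_seed_sites(mirna, utr)
        assert len(sites) == 1
        s = sites[0]
        assert (s.site_class, s.utr_start, s.utr_end) == ("8mer", 4, 11)
        assert utr.sequence[s.utr_start - 1:s.utr_end] == "TTAGCCAA"

    def test_non_a_t1_downgrades_to_7mer_m8(self):
        mirna = mk_mirna("AUGGCUAAGCUAGCUAGCUA")
        utr = make_utr("GGGTTAGCCAGGGG")
        sites = find_seed_sites(mirna, utr)
        assert [s.site_class for s in sites] == ["7mer-m8"]

    def test_no_complement_empty(self):
        mirna = mk_mirna("AUGGCUAAGCUAGCUAGCUA")
        assert find_seed_sites(mirna, make_utr("A" * 30)) == []

    def test_utr_shorter_than_8_empty(self):
        mirna = mk_mirna("AUGGCUAAGCUAGCUAGCUA")
        assert find_seed_sites(mirna, make_utr("TTAGCCA")) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_window_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            mi = random_mirna(rng)
            utr_seq = random_utr_with_plants(rng, mi)
            got = {
                (s.site_class, s.utr_start, s.utr_end)
                for s in find_seed_sites(mk_mirna(mi), make_utr(utr_seq))
            }
            assert got == oracle_sites(mi, utr_seq)

    def test_every_site_revalidates_its_class(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            mi = random_mirna(rng)
            utr_seq = random_utr_with_plants(rng, mi)
            for s in find_seed_sites(mk_mirna(mi), make_utr(utr_seq)):
                assert (s.site_class, s.utr_start, s.utr_end) in oracle_sites(mi, utr_seq)


class TestAlignScore:
    def test_fully_paired_first_eight_positions(self):
        # WC pairs at miRNA 1-8, nothing else: 5 + 7 * 10 = 75
        mirna = "AUGGCUAAGCUAGCUAGCUA"
        window = _rc(mirna[:8])
        assert align_score(mirna, window) == pytest.approx(75.0)

    def test_zero_complementarity_floors_at_zero(self):
        assert align_score("A" * 18, "AAAAAA") == 0.0

    def test_window_length_bounds(self):
        with pytest.raises(DataError):
            align_score("A" * 18, "ACGTA")
        with pytest.raises(DataError):
            align_score("A" * 18, "A" * 41)

    def test_matches_recursive_path_oracle(self):
        # oracle: top-down memoized recursion over alignment paths with
        # affine gap scoring, independent of the bottom-up matrix DP
        from functools import lru_cache

        WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
        WOBBLE = {("G", "T"), ("U", "G")}

        def pair(mi_b, w_b, mi_pos):
            w = 2.0 if 2 <= mi_pos <= 8 else 1.0
            if (mi_b, w_b) in WC:
                return 5.0 * w
            if (mi_b, w_b) in WOBBLE:
                return 2.0 * w
            return -3.0 * w

        def oracle(mi, window):
            win = window[::-1]
            n, m = len(mi), len(win)

            @lru_cache(maxsize=None)
            def f(i, j, last):
                # best path score starting at (i, j); stopping is allowed
                options = [0.0]
                if i < n and j < m:
                    options.append(pair(mi[i], win[j], i + 1) + f(i + 1, j + 1, "M"))
                if j < m:
                    options.append((-2.0 if last == "E" else -8.0) + f(i, j + 1, "E"))
                if i < n:
                    options.append((-2.0 if last == "F" else -8.0) + f(i + 1, j, "F"))
                return max(options)

            return max(f(i, j, "M") for i in range(n) for j in range(m))

        rng = np.random.default_rng(17)
        for _ in range(25):
            mi = "".join(rng.choice(list("ACGU"), size=int(rng.integers(4, 11))))
            window = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 10))))
            assert align_score(mi, window) == pytest.approx(oracle(mi, window))


class TestDuplexEnergy:
    def test_hand_summed_table_walk(self):
        # STRONG_MIRNA seed m2-m8 = GCUGGCC; consecutive WC stacks:
        # GC, CU, UG, GG, GC, CC read off the 16-entry table by hand,
        # plus the t1-A bonus of an 8mer
        mirna = mk_mirna(STRONG_MIRNA)
        site8 = _m8_complement(STRONG_MIRNA) + seed_match_6(STRONG_MIRNA) + "A"
        window = "TT" + site8 + "TT"
        expected = (-3.42) + (-2.08) + (-2.11) + (-3.26) + (-3.42) + (-3.26) - 0.3
        assert duplex_energy(mirna, window) == pytest.approx(expected)

    def test_no_site_in_window_errors(self):
        with pytest.raises(DataError):
            duplex_energy(mk_mirna(STRONG_MIRNA), "TTTTTTTTTT")

    def test_more_seed_pairs_never_destabilize(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            mi = random_mirna(rng)
            mirna = mk_mirna(mi)
            core = seed_match_6(mi)
            m8 = _m8_complement(mi)
            not_m8 = [b for b in "ACGT" if b != m8][0]
            e6 = duplex_energy(mirna, "TT" + not_m8 + core + "G" + "TT")
            e7m8 = duplex_energy(mirna, "TT" + m8 + core + "G" + "TT")
            e8 = duplex_energy(mirna, "TT" + m8 + core + "A" + "TT")
            assert e8 <= e7m8 <= e6

    def test_t1_bonus_applied_to_7mer_a1(self):
        rng = np.random.default_rng(29)
        mi = random_mirna(rng)
        mirna = mk_mirna(mi)
        core = seed_match_6(mi)
        m8 = _m8_complement(mi)
        not_m8 = [b for b in "ACGT" if b != m8][0]
        e6 = duplex_energy(mirna, "TT" + not_m8 + core + "G" + "TT")
        e7a1 = duplex_energy(mirna, "TT" + not_m8 + core + "A" + "TT")
        assert e7a1 == pytest.approx(e6 - 0.3)


class TestCallConsensus:
    def test_strong_8mer_supported_by_all_three(self):
        mirna = mk_mirna(STRONG_MIRNA)
        site8 = _m8_complement(STRONG_MIRNA) + seed_match_6(STRONG_MIRNA) + "A"
        utr = make_utr("TTTTT" + site8 + "TTTTT")
        calls = call_consensus(mirna, utr, k_min=3)
        assert len(calls) == 1
        assert calls[0].n_supporting == 3
        assert calls[0].site.site_class == "8mer"

    def test_weak_6mer_fails_energy_cutoff(self):
        # AU-rich seed: 6mer stacks sum to about -5.6, above the -8 cutoff
        mirna = mk_mirna(WEAK_MIRNA)
        core = seed_match_6(WEAK_MIRNA)
        m8 = _m8_complement(WEAK_MIRNA)
        not_m8 = [b for b in "CG" if b != m8][0]
        utr = make_utr("CGCGC" + not_m8 + core + "G" + "CGCGC")
        assert call_consensus(mirna, utr, k_min=3) == []
        calls = call_consensus(mirna, utr, k_min=2)
        assert len(calls) == 1 and calls[0].n_supporting == 2

    def test_k_min_zero_emits_every_seed_site(self):
        mirna = mk_mirna(WEAK_MIRNA)
        core = seed_match_6(WEAK_MIRNA)
        utr = make_utr("CCCCC" + core + "G" + "CCC" + core + "G" + "CCCCC")
        calls = call_consensus(mirna, utr, k_min=0)
        assert len(calls) == len(find_seed_sites(mirna, utr)) == 2

    def test_k_min_above_scorer_count_fatal(self):
        with pytest.raises(DataError):
            call_consensus(mk_mirna(STRONG_MIRNA), make_utr("ACGTACGTAC"), k_min=4)

    def test_consensus_monotone_in_k_min(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            mi = random_mirna(rng)
            utr = make_utr(random_utr_with_plants(rng, mi))
            previous = None
            for k in (0, 1, 2, 3):
                n = len(call_consensus(mk_mirna(mi), utr, k_min=k))
                if previous is not None:
                    assert n <= previous
                previous = n


class TestAlleleDelta:
    def _snp(self, ref, alt, pos=100):
        return VariantRecord("12", pos, "rs-test", ref, alt)

    def test_snp_outside_sites_delta_zero(self):
        mirna = mk_mirna(STRONG_MIRNA)
        utr = make_utr("T" * 20)
        d = allele_delta(mirna, utr, self._snp("T", "G"), 10)
        assert d.delta == 0.0
        assert d.predicted_expression_direction == "none"

    def test_breaking_8mer_predicts_upregulation(self):
        mirna = mk_mirna(STRONG_MIRNA)
        site8 = _m8_complement(STRONG_MIRNA) + seed_match_6(STRONG_MIRNA) + "A"
        utr = make_utr("TTTTT" + site8 + "TTTTT")
        off = 8  # inside the seed-pairing region
        ref = utr.sequence[off - 1]
        alt = [b for b in "ACGT" if b != ref][0]
        d = allele_delta(mirna, utr, self._snp(ref, alt), off)
        assert d.score_alt < d.score_ref
        assert d.delta < 0
        assert d.predicted_expression_direction == "up"

    def test_antisymmetry_under_allele_swap(self):
        rng = np.random.default_rng(41)
        mirna = mk_mirna(STRONG_MIRNA)
        site8 = _m8_complement(STRONG_MIRNA) + seed_match_6(STRONG_MIRNA) + "A"
        for off in range(6, 14):
            utr = make_utr("TTTTT" + site8 + "TTTTT")
            ref = utr.sequence[off - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fwd = allele_delta(mirna, utr, self._snp(ref, alt), off)
            swapped_utr = make_utr(
                utr.sequence[:off - 1] + alt + utr.sequence[off:]
            )
            rev = allele_delta(mirna, swapped_utr, self._snp(alt, ref), off)
            assert rev.delta == pytest.approx(-fwd.delta, abs=1e-12)

    def test_ref_mismatch_is_fatal(self):
        mirna = mk_mirna(STRONG_MIRNA)
        utr = make_utr("T" * 20)
        with pytest.raises(DataError, match="does not match"):
            allele_delta(mirna, utr, self._snp("A", "G"), 5)

    def test_offset_out_of_range_fatal(self):
        mirna = mk_mirna(STRONG_MIRNA)
        with pytest.raises(DataError):
            allele_delta(mirna, make_utr("T" * 20), self._snp("T", "G"), 21)


class TestProjection:
    def test_plus_strand(self):
        utr = make_utr("ACGTACGTAC", start=1000, strand="+")
        assert project_to_utr(utr, 1000) == 1
        assert project_to_utr(utr, 1009) == 10
        assert project_to_utr(utr, 1010) is None

    def test_minus_strand_runs_backwards(self):
        utr = make_utr("ACGTACGTAC", start=1000, strand="-")
        assert project_to_utr(utr, 1009) == 1
        assert project_to_utr(utr, 1000) == 10


class TestMapSnpsToSites:
    def _table1_like(self):
        mirna = mk_mirna(STRONG_MIRNA, name="mir-strong")
        site8 = _m8_complement(STRONG_MIRNA) + seed_match_6(STRONG_MIRNA) + "A"
        seq = "TTTTT" + site8 + "TTTTT"
        utr = make_utr(seq, name="TX77", start=2_061_975, gene="GENEX")
        snp_off = 8
        ref = seq[snp_off - 1]
        alt = [b for b in "ACGT" if b != ref][0]
        snp = VariantRecord("12", 2_061_975 + snp_off - 1, "rs-proxy", ref, alt)
        index = VariantRecord("12", 2_104_170, "rs-index", "G", "A")
        pair = ProxyPair(index=index, proxy=snp, r2=1.0,
                         distance_bp=abs(index.pos - snp.pos))
        return mirna, utr, pair

    def test_reconstructs_proxy_site_row(self):
        mirna, utr, pair = self._table1_like()
        table = map_snps_to_sites([pair], [utr], [mirna], k_min=1)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["r2"] == 1.0
        assert row["transcript"] == "TX77"
        assert row["gwas_snp"] == "rs-index"
        assert row["direction"] == "up"

    def test_snp_in_siteless_utr_no_row(self):
        mirna, utr, pair = self._table1_like()
        bare = make_utr("T" * 30, name="TX78", start=pair.proxy.pos - 5)
        table = map_snps_to_sites([pair], [bare], [mirna], k_min=1)
        assert table.empty

    def test_snp_outside_all_utrs_no_row(self):
        mirna, utr, pair = self._table1_like()
        far = make_utr("T" * 30, name="TX79", start=5_000_000)
        table = map_snps_to_sites([pair], [far], [mirna], k_min=1)
        assert table.empty
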