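import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hlatype.aligner import AlignerConfig, AlignmentHit, BulkMapper, \
    ReadCountDistribution
from hlatype.refdb import parse_allele_name
from hlatype.simdata import ReadSimConfig, simulate_fragments, simulate_reads
from hlatype.typer import (AMBIGUOUS, HETEROZYGOUS, HOMOZYGOUS, GroupCall,
                           calls_from_mapping, call_locus, outlier_pvalue,
                           remove_group_reads, top_group, type_sample,
                           zygosity)

# ---------------------------------------------------------------------------
# Independent statistical oracles


def normal_upper_tail_by_integration(a, mean, sd, n=2_000_001):
    """Upper-tail normal probability by direct numerical integration of the
    density (no CDF routine involved)."""
    hi = mean + 14 * sd
    if a >= hi:
        return 0.0
    t = np.linspace(a, hi, n)
    pdf = np.exp(-0.5 * ((t - mean) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    return float(np.trapezoid(pdf, t))


def binom_at_least_one_by_summation(x, p):
    """P(X >= 1 | Binomial(x, p)) by explicit term-wise summation."""
    return sum(math.comb(x, k) * p**k * (1 - p) ** (x - k)
               for k in range(1, x + 1))


def _dist(counts_by_allele, locus="A", iteration=1):
    counts = {}
    for allele, c in counts_by_allele.items():
        g = parse_allele_name(allele).group
        counts.setdefault(g, {})[allele] = c
    return ReadCountDistribution(locus=locus, iteration=iteration, counts=counts)


# ---------------------------------------------------------------------------
# top_group


def test_top_group_picks_group_of_max_allele():
    R = _dist({"A*01:01": 10, "A*02:01": 7, "A*01:02": 3})
    assert top_group(R) == ("A*01", 10)


def test_top_group_tie_breaks_lexicographically():
    R = _dist({"A*01:01": 10, "A*02:01": 10})
    assert top_group(R) == ("A*01", 10)


def test_top_group_all_zero_is_no_call():
    R = _dist({"A*01:01": 0, "A*02:01": 0})
    assert top_group(R) == ("A*01", 0)  # caller treats count 0 as no-call


# ---------------------------------------------------------------------------
# outlier_pvalue


def test_outlier_pvalue_against_integration_and_summation_oracles():
    """Tail probability matches numerical integration of the normal density
    to 1e-10, and the at-least-one correction matches exact binomial
    summation to 1e-12."""
    cases = [
        ([2, 4, 6, 8], 20),     # spec-style strong outlier
        ([10, 12, 9, 14, 11], 16),
        ([5, 50, 7, 9], 55),
        ([100, 140, 90, 130, 120, 95], 150),
    ]
    for counts, a in cases:
        tail, p = outlier_pvalue(counts, a, mode="include_top")
        mean = np.mean(counts)
        sd = np.std(counts, ddof=1)
        oracle_tail = normal_upper_tail_by_integration(a, mean, sd)
        assert tail == pytest.approx(oracle_tail, abs=1e-10)
        assert p == pytest.approx(
            binom_at_least_one_by_summation(len(counts), tail), abs=1e-12)


def test_outlier_pvalue_strong_outlier_example():
    """counts {2,4,6,8}, a=20: mean 5, sample sd ~2.582, z ~5.81."""
    tail, p = outlier_pvalue([2, 4, 6, 8], 20, mode="include_top")
    assert np.std([2, 4, 6, 8], ddof=1) == pytest.approx(2.5819888975)
    assert tail == pytest.approx(
        normal_upper_tail_by_integration(20, 5.0, 2.5819888975), rel=1e-6)
    assert p < 1e-6


def test_outlier_pvalue_exclude_top_removes_one_instance():
    # exclude_top on [3, 3, 20] with a=20 -> background [3, 3], sd 0, a > mean
    tail, p = outlier_pvalue([3, 3, 20], 20, mode="exclude_top")
    assert (tail, p) == (0.0, 0.0)


def test_outlier_pvalue_limit_cases():
    # tail forced to 0 (sd=0, a above the background) -> p = 0
    assert outlier_pvalue([5, 5, 5, 5], 50, mode="include_top")[1] == 0.0
    # tail forced to 1 (sd=0, a below) -> p = 1
    assert outlier_pvalue([5, 5, 5, 5], 1, mode="include_top")[1] == 1.0
    # empty background -> p = 1
    assert outlier_pvalue([7], 7, mode="exclude_top")[1] == 1.0


def test_outlier_pvalue_printed_form_is_lower_tail():
    from scipy.stats import binom

    counts, a = [4, 9, 2, 7], 12
    tail, p_compat = outlier_pvalue(counts, a, mode="include_top",
                                    printed_form=True)
    assert p_compat == pytest.approx(binom.cdf(0, len(counts), tail), abs=1e-14)
    _, p = outlier_pvalue(counts, a, mode="include_top")
    assert p == pytest.approx(1 - p_compat, abs=1e-12)


@given(st.lists(st.integers(0, 1000), min_size=2, max_size=30),
       st.floats(0, 1, allow_nan=False))
def test_at_least_one_correction_equals_binomial_summation(counts, tail):
    """1 - (1 - p)^x equals the exact binomial upper tail at quantile 0."""
    x = len(counts)
    p = 1 - (1 - tail) ** x
    assert p == pytest.approx(binom_at_least_one_by_summation(x, tail),
                              abs=1e-12)


@given(st.lists(st.integers(0, 500), min_size=3, max_size=20))
def test_include_top_is_stricter_than_exclude_top(counts):
    """Keeping the winner in the background never makes the call look more
    significant."""
    a = max(counts)
    _, p_ex = outlier_pvalue(counts, a, mode="exclude_top")
    _, p_in = outlier_pvalue(counts, a, mode="include_top")
    assert p_in >= p_ex - 1e-12


def test_pvalue_monotone_in_a():
    counts = [10, 14, 9, 12, 11, 13]
    ps = [outlier_pvalue(counts, a, mode="include_top")[1]
          for a in range(14, 60, 3)]
    assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))


def test_pvalue_grows_with_background_sd():
    a = 50
    p_tight = outlier_pvalue([10, 11, 9, 10], a, mode="include_top")[1]
    p_wide = outlier_pvalue([1, 25, 3, 11], a, mode="include_top")[1]
    assert p_wide > p_tight


# ---------------------------------------------------------------------------
# zygosity


def _zyg(median_counts, r2_counts, c2, hla_class, c2_p=0.001):
    R1 = _dist(median_counts, locus="A" if hla_class == "I" else "DQA1")
    R2 = _dist(r2_counts, locus=R1.locus, iteration=2)
    call2 = GroupCall(locus=R1.locus, iteration=2, group="A*02",
                      read_count=c2, tail_prob=0.0, p_value=c2_p)
    return zygosity(R1, R2, call2, hla_class)


def test_zygosity_above_median_is_heterozygous():
    z = _zyg({"A*01:01": 40, "A*01:02": 50, "A*02:01": 60}, {"A*02:01": 60},
             60, "I")
    assert z.threshold == 50 and z.status == HETEROZYGOUS


def test_zygosity_below_median_is_homozygous():
    z = _zyg({"A*01:01": 40, "A*01:02": 50, "A*02:01": 600}, {"A*02:01": 10},
             10, "I", c2_p=0.9)
    assert z.status == HOMOZYGOUS
    assert z.p_value is not None


def test_zygosity_class2_threshold_is_half_median():
    counts = {"DQA1*01:01": 40, "DQA1*01:02": 50, "DQA1*02:01": 60}
    z = _zyg(counts, {"DQA1*02:01": 30}, 30, "II")
    assert z.threshold == 25 and z.status == HETEROZYGOUS


def test_zygosity_even_count_median_averages_central_values():
    counts = {"A*01:01": 10, "A*01:02": 20, "A*02:01": 30, "A*02:02": 40}
    z = _zyg(counts, {"A*02:01": 40}, 40, "I")
    assert z.threshold == 25.0


def test_zygosity_borderline_significant_second_is_ambiguous():
    # second winner below but near the threshold, itself significant
    z = _zyg({"A*01:01": 100, "A*01:02": 100, "A*02:01": 2000},
             {"A*02:01": 80, "A*03:01": 3, "A*04:01": 2}, 80, "I", c2_p=0.01)
    assert z.status == AMBIGUOUS


def test_zygosity_stray_fragment_stays_homozygous():
    # a couple of stray fragments far below threshold: plain homozygous even
    # if normal theory flags them
    z = _zyg({"A*01:01": 100, "A*01:02": 100, "A*02:01": 2000},
             {"A*02:01": 2}, 2, "I", c2_p=0.05)
    assert z.status == HOMOZYGOUS


def test_calls_scale_invariant():
    """Multiplying all counts by k leaves winner and zygosity unchanged."""
    base = {"A*01:01": 40, "A*01:02": 38, "A*02:01": 120, "A*03:01": 9}
    for k in (2, 10, 100):
        scaled = {a: c * k for a, c in base.items()}
        assert top_group(_dist(base))[0] == top_group(_dist(scaled))[0]
        z1 = _zyg(base, {"A*03:01": 9}, 9, "I", c2_p=0.5)
        zk = _zyg(scaled, {"A*03:01": 9 * k}, 9 * k, "I", c2_p=0.5)
        assert z1.status == zk.status


# ---------------------------------------------------------------------------
# remove_group_reads


def test_remove_group_reads_scoped_to_winning_group(sim_db):
    a01 = sim_db.by_locus["A"][0]   # group A*01
    a02 = sim_db.by_locus["A"][5]   # group A*02
    b01 = sim_db.by_locus["B"][0]
    assert sim_db.records[a01].name.group == "A*01"
    assert sim_db.records[a02].name.group == "A*02"
    hits = {
        "only_winner": [AlignmentHit("only_winner", a01, 0, "+", 0)],
        "other_group": [AlignmentHit("other_group", a02, 0, "+", 0)],
        "both": [AlignmentHit("both", a01, 0, "+", 0),
                 AlignmentHit("both", a02, 1, "+", 1)],
        "other_locus": [AlignmentHit("other_locus", b01, 0, "+", 0)],
    }
    reduced = remove_group_reads(hits, "A*01", "A", sim_db)
    assert set(reduced) == {"other_group", "other_locus"}
    # reduced counts equal an independent recount of the surviving hits
    from hlatype.aligner import count_reads

    R = count_reads(reduced, sim_db, "A", iteration=2)
    recount = {}
    for rid, hs in reduced.items():
        for ai in {h.allele_index for h in hs}:
            name = sim_db.records[ai].name
            if name.locus == "A":
                recount[name.raw_name] = recount.get(name.raw_name, 0) + 1
    got = {a: c for _, a, c in R.allele_counts() if c > 0}
    assert got == recount


# ---------------------------------------------------------------------------
# End-to-end calling on simulated truth


@pytest.fixture(scope="module")
def small_sample(small_db):
    genotype = {
        "A": ("A*01:01", "A*03:02"),        # heterozygous
        "B": ("B*02:01", "B*02:01"),        # homozygous
        "DQA1": ("DQA1*01:01", "DQA1*04:02"),
        "DQB1": ("DQB1*02:02", "DQB1*02:02"),
    }
    cfg = ReadSimConfig(seed=99, genotype=genotype, fragments_per_locus=600)
    sim = simulate_fragments(small_db, cfg)
    mapping = BulkMapper(small_db, vmax=2).map_fragments(sim.reads1, sim.reads2)
    return sim, mapping


def test_call_locus_recovers_heterozygote(small_sample, small_db):
    sim, mapping = small_sample
    lc = call_locus(mapping, "A", AlignerConfig(v=1))
    assert {lc.call1.group, lc.call2.group} == {"A*01", "A*03"}
    assert lc.zygosity.status == HETEROZYGOUS
    assert lc.call1.p_value < 0.1 and lc.call2.p_value < 0.1


def test_call_locus_recovers_homozygote(small_sample, small_db):
    sim, mapping = small_sample
    for locus, group in [("B", "B*02"), ("DQB1", "DQB1*02")]:
        lc = call_locus(mapping, locus, AlignerConfig(v=1))
        assert lc.call1.group == group
        assert lc.zygosity.status == HOMOZYGOUS


def test_locus_without_reads_is_no_call(small_sample, small_db):
    _, mapping = small_sample
    lc = call_locus(mapping, "DRB1", AlignerConfig(v=1))  # not in genotype
    assert lc.is_no_call or lc.call1.p_value > 0.1  # background only


def test_type_sample_deterministic_and_matches_truth(tmp_path, small_db):
    genotype = {"A": ("A*02:02", "A*04:01"), "B": ("B*01:01", "B*01:01")}
    cfg = ReadSimConfig(seed=5, genotype=genotype, fragments_per_locus=500)
    paths, truth = simulate_reads(small_db, cfg, tmp_path, sample_id="s1")
    t1 = type_sample(paths[0], small_db, AlignerConfig(v=1), fastq2=paths[1])
    t2 = type_sample(paths[0], small_db, AlignerConfig(v=1), fastq2=paths[1])
    for locus in ("A", "B"):
        l1, l2 = t1.locus_calls[locus], t2.locus_calls[locus]
        assert (l1.call1.group, l1.call1.p_value) == (l2.call1.group,
                                                      l2.call1.p_value)
    assert {t1.locus_calls["A"].call1.group,
            t1.locus_calls["A"].call2.group} == set(truth.groups["A"])
    assert t1.locus_calls["B"].zygosity.status == HOMOZYGOUS


def test_type_sample_unequal_mates_raises(tmp_path, small_db):
    p1 = tmp_path / "r1.fastq"
    p2 = tmp_path / "r2.fastq"
    p1.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nIIII\n")
    p2.write_text("@r1\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="unequal"):
        type_sample(p1, small_db, AlignerConfig(v=1), fastq2=p2)


def test_empty_fastq_gives_no_calls(tmp_path, small_db):
    p1 = tmp_path / "e1.fastq"
    p2 = tmp_path / "e2.fastq"
    p1.write_text("")
    p2.write_text("")
    t = type_sample(p1, small_db, AlignerConfig(v=1), fastq2=p2)
    assert all(lc.is_no_call for lc in t.locus_calls.values())
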