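import numpy as np
import pytest

from invscan.breakpoint import (
    PrimerPair,
    breakpoint_pcr_panel,
    design_junction_pair,
    insilico_pcr,
    locate_breakpoints,
    primer_sites,
)
from invscan.records import SequenceRecord, revcomp

from conftest import random_seq

K = 15

FWD = "AAACTCACACCGCTCCGTTGTC"
REV = "CCTCTTCCGATCTTTGGGTACA"


def rec(seq, id="tpl"):
    return SequenceRecord(id=id, seq=seq)


# --- breakpoint localization ---------------------------------------------------


def test_split_query_yields_one_positional_jump_call():
    target = rec(random_seq(60_000, 31), id="ref")
    # left half from one locus, right half from a distal locus
    query = rec(target.seq[5_000:10_000] + target.seq[40_000:45_000], id="bac")
    calls = locate_breakpoints(query, target, k=K, max_gap=2_000, jump_threshold=5_000)
    assert len(calls) == 1
    c = calls[0]
    assert c.kind == "positional_jump"
    assert c.q_interval[0] <= 5_000 + K and c.q_interval[1] >= 5_000 - K
    assert c.left_ref_locus[1] == "+" and c.right_ref_locus[1] == "+"


def test_strand_switch_query_yields_one_call_with_prefix_length():
    target = rec(random_seq(40_000, 32), id="ref")
    query = rec(target.seq[5_000:10_000] + revcomp(target.seq[20_000:26_000]), id="bac")
    calls = locate_breakpoints(query, target, k=K, from_position=0)
    assert len(calls) == 1
    c = calls[0]
    assert c.kind == "strand_switch"
    assert abs(c.collinear_prefix_len - 5_000) <= K
    assert {c.left_ref_locus[1], c.right_ref_locus[1]} == {"+", "-"}


def test_collinear_query_yields_no_calls():
    target = rec(random_seq(30_000, 33), id="ref")
    query = rec(target.seq[4_000:20_000], id="bac")
    assert locate_breakpoints(query, target, k=K) == []


def test_revcomp_slice_is_not_a_breakpoint():
    target = rec(random_seq(30_000, 34), id="ref")
    query = rec(revcomp(target.seq[4_000:20_000]), id="bac")
    assert locate_breakpoints(query, target, k=K) == []


def test_anchorless_query_warns_and_returns_empty():
    target = rec(random_seq(5_000, 35), id="ref")
    query = rec(random_seq(3_000, 36), id="bac")
    with pytest.warns(UserWarning):
        assert locate_breakpoints(query, target, k=K) == []


# --- in-silico PCR --------------------------------------------------------------


def test_convergent_pair_yields_expected_product_length():
    spacer = random_seq(500, 41)
    tpl = rec(random_seq(300, 40) + FWD + spacer + revcomp(REV) + random_seq(300, 42))
    pair = PrimerPair("F", FWD, "R", REV)
    amps = insilico_pcr(tpl, pair)
    assert len(amps) == 1
    assert amps[0].status == "product"
    assert amps[0].product_len == len(FWD) + 500 + len(REV)


def test_same_orientation_primers_yield_no_product():
    tpl = rec(random_seq(300, 43) + FWD + random_seq(500, 44) + REV + random_seq(300, 45))
    assert insilico_pcr(tpl, PrimerPair("F", FWD, "R", REV)) == []


def test_divergent_primers_yield_no_product():
    tpl = rec(random_seq(300, 46) + revcomp(FWD) + random_seq(500, 47) + REV + random_seq(300, 48))
    assert insilico_pcr(tpl, PrimerPair("F", FWD, "R", REV)) == []


def test_long_convergent_pair_reported_over_max_len():
    spacer = random_seq(8_900 - len(FWD) - len(REV), 49)
    tpl = rec(random_seq(200, 50) + FWD + spacer + revcomp(REV) + random_seq(200, 51))
    amps = insilico_pcr(tpl, PrimerPair("F", FWD, "R", REV, max_product_len=5_000))
    assert [a.status for a in amps] == ["over_max_len"]
    assert amps[0].product_len == 8_900


def test_missing_forward_primer_yields_nothing():
    tpl = rec(random_seq(500, 52) + revcomp(REV) + random_seq(200, 53))
    assert insilico_pcr(tpl, PrimerPair("F", FWD, "R", REV)) == []


def test_pcr_is_strand_symmetric():
    spacer = random_seq(400, 54)
    tpl = rec(random_seq(250, 55) + FWD + spacer + revcomp(REV) + random_seq(250, 56))
    pair = PrimerPair("F", FWD, "R", REV)
    fwd_products = insilico_pcr(tpl, pair)
    rc_products = insilico_pcr(rec(revcomp(tpl.seq)), pair)
    assert [a.product_len for a in fwd_products] == [a.product_len for a in rc_products]
    L = len(tpl)
    for a, b in zip(fwd_products, rc_products):
        # each site reappears mirrored on the other strand
        assert b.fwd_site[0] == L - a.fwd_site[0] - len(FWD)
        assert b.rev_site[0] == L - a.rev_site[0] - len(REV)
        assert a.fwd_site[1] == "+" and b.fwd_site[1] == "-"


def test_mismatch_tolerance_requires_exact_3prime_tail():
    core = FWD
    mutated_mid = core[:5] + ("A" if core[5] != "A" else "C") + core[6:]
    mutated_tail = core[:-1] + ("A" if core[-1] != "A" else "C")
    tpl_mid = rec(random_seq(200, 57) + mutated_mid + random_seq(150, 58) + revcomp(REV) + random_seq(100, 59))
    tpl_tail = rec(random_seq(200, 60) + mutated_tail + random_seq(150, 61) + revcomp(REV) + random_seq(100, 62))
    pair0 = PrimerPair("F", FWD, "R", REV, max_mismatches=0)
    pair1 = PrimerPair("F", FWD, "R", REV, max_mismatches=1)
    assert insilico_pcr(tpl_mid, pair0) == []
    assert len(insilico_pcr(tpl_mid, pair1)) == 1  # internal mismatch tolerated
    assert insilico_pcr(tpl_tail, pair1) == []  # 3' mismatch never tolerated


def test_primer_pair_validation():
    with pytest.raises(ValueError):
        PrimerPair("F", "ACGT", "R", REV)  # too short
    with pytest.raises(ValueError):
        PrimerPair("F", FWD, "R", "ACGTACGTACGTACGTN")  # bad alphabet


def test_primer_sites_orientation_convention():
    tpl = rec(random_seq(100, 63) + FWD + random_seq(100, 64) + revcomp(FWD) + random_seq(100, 65))
    plus, minus = primer_sites(tpl, FWD)
    assert plus.tolist() == [100]
    assert minus.tolist() == [100 + len(FWD) + 100]


# --- diagnostic panel ------------------------------------------------------------


def test_empty_pair_list_gives_empty_matrix():
    tpl = rec(random_seq(1_000, 66))
    panel = breakpoint_pcr_panel({"a": tpl}, [])
    assert panel.shape == (1, 0)


def test_designed_junction_pair_separates_three_templates():
    # hand-built triple: reference, a diverged 'wild' allele of the right part,
    # and a recombinant carrying reference-left joined to wild-right
    rng = np.random.default_rng(67)
    left = random_seq(4_000, 68)
    right = random_seq(4_000, 69)
    wild_right = list(right)
    for i in rng.choice(4_000, size=80, replace=False):
        wild_right[i] = "ACGT"[("ACGT".index(wild_right[i]) + 1) % 4]
    wild_left = list(left)
    for i in rng.choice(4_000, size=80, replace=False):
        wild_left[i] = "ACGT"[("ACGT".index(wild_left[i]) + 1) % 4]
    reference = rec(left + right, id="reference")
    wild = rec("".join(wild_left) + "".join(wild_right), id="wild")
    recombinant = rec(left + "".join(wild_right), id="recombinant")

    junction = design_junction_pair(
        recombinant, 4_000, avoid_fwd=[wild], avoid_rev=[reference], name="jct"
    )
    ref_side = design_junction_pair(
        reference, 4_000, avoid_fwd=[], avoid_rev=[wild], name="ref"
    )
    panel = breakpoint_pcr_panel(
        {"reference": reference, "wild": wild, "recombinant": recombinant},
        [junction, ref_side],
    )
    assert panel.loc["recombinant", junction.name] == "product"
    assert panel.loc["reference", junction.name] == "none"
    assert panel.loc["wild", junction.name] == "none"
    assert panel.loc["reference", ref_side.name] == "product"
    assert panel.loc["recombinant", ref_side.name] == "none"
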