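import numpy as np
import pandas as pd
import pytest

import repshape as rs
from repshape.errors import ConfigurationError, EmptyProfileError
from repshape.io import Clonotype, Repertoire
from repshape.physchem import StrengthConfig


def func_clono(aa, v="TRBV4-1", count=1):
    """A functional clonotype with the requested CDR3aa (nt back-filled)."""
    codon = {"A": "GCA", "G": "GGA", "S": "TCA", "L": "CTG", "F": "TTC",
             "C": "TGT", "I": "ATC", "M": "ATG", "V": "GTG", "W": "TGG",
             "Y": "TAC", "T": "ACA", "P": "CCA", "N": "AAC", "E": "GAA",
             "K": "AAA", "Q": "CAA", "D": "GAC", "R": "AGA", "H": "CAC"}
    nt = "".join(codon[a] for a in aa)
    return Clonotype(cdr3_nt=nt, cdr3_aa=aa, v_gene=v, j_gene="TRBJ1-1",
                     umi_count=count, vd_insert_len=0, dj_insert_len=0)


def test_kidera_table_shape_and_centering():
    table = rs.load_kidera_table()
    assert table.shape == (20, 10)
    # published factors are near-orthonormal: each column is ~centred
    assert table.mean().abs().max() < 0.2


@pytest.mark.parametrize("aa,w,expected", [
    ("CASSLAPGATNEKLFF", 5, "APGAT"),
    ("CASSF", 5, "CASSF"),
    ("CAF", 5, None),
    ("CASSLG", 5, "CASSL"),  # even overhang splits floor-left
])
def test_central_window(aa, w, expected):
    assert rs.central_window(aa, w) == expected


def test_kidera_profile_of_constant_window_is_residue_row():
    rep = Repertoire("r", [func_clono("AAAAA")])
    table = rs.load_kidera_table()
    profile = rs.kidera_profile(rep, table)
    assert np.allclose(profile.to_numpy(), table.loc["A"].to_numpy())


def test_kidera_profile_linearity_between_clonotypes():
    rep = Repertoire("r", [func_clono("GGGGG"), func_clono("AAAAA", v="TRBV7-2")])
    table = rs.load_kidera_table()
    profile = rs.kidera_profile(rep, table, weighting="clonotype")
    midpoint = (table.loc["G"].to_numpy() + table.loc["A"].to_numpy()) / 2
    assert np.allclose(profile.to_numpy(), midpoint)


def test_kidera_profile_matches_hand_lookup():
    rep = Repertoire("r", [func_clono("GASSL")])
    table = rs.load_kidera_table()
    profile = rs.kidera_profile(rep, table)
    hand_kf1 = np.mean([table.loc[a, "kf1"] for a in "GASSL"])
    assert profile["kf1"] == pytest.approx(hand_kf1)


def test_kidera_profile_invariant_under_count_splitting():
    whole = Repertoire("r", [func_clono("CASSLAPGA", count=4),
                             func_clono("CASSYGQFF", count=4, v="TRBV7-2")])
    split = Repertoire("r", [func_clono("CASSLAPGA", count=2),
                             func_clono("CASSLAPGA", count=2),
                             func_clono("CASSYGQFF", count=4, v="TRBV7-2")])
    split = Repertoire.from_clonotypes("r", split.clonotypes)
    table = rs.load_kidera_table()
    a = rs.kidera_profile(whole, table, weighting="umi")
    b = rs.kidera_profile(split, table, weighting="umi")
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_kidera_profile_empty_error():
    rep = Repertoire("r", [func_clono("CAF")])  # shorter than the window
    with pytest.raises(EmptyProfileError):
        rs.kidera_profile(rep, rs.load_kidera_table())


@pytest.mark.parametrize("window,count,fraction", [
    ("LFIMV", 5, 1.0),
    ("GGGGG", 0, 0.0),
    ("CASSL", 2, 0.4),
])
def test_cdr3_strength_worked_examples(window, count, fraction):
    rep = Repertoire("r", [func_clono(window)])
    assert rs.strength_score(rep, StrengthConfig(score_kind="count"), "CDR3") == count
    assert rs.strength_score(rep, StrengthConfig(score_kind="fraction"), "CDR3") == \
        pytest.approx(fraction)


def test_strength_bounds():
    cfg = StrengthConfig(score_kind="fraction")
    rep = Repertoire("r", [func_clono("CASSLAPGATNEKLFF", count=3),
                           func_clono("CASSYGQFF", v="TRBV7-2")])
    assert 0.0 <= rs.strength_score(rep, cfg, "CDR3") <= 1.0
    cfg = StrengthConfig(score_kind="count")
    assert 0.0 <= rs.strength_score(rep, cfg, "CDR3") <= cfg.cdr3_window


def test_germline_cdr_strength_uses_library(default_library):
    # TRBV4-1 CDR2 "YFSYWV" scores 5; TRBV7-2 CDR2 "FNEGSQ" scores 1
    rep4 = Repertoire("r", [func_clono("CASSLAPGA", v="TRBV4-1")])
    rep7 = Repertoire("r", [func_clono("CASSLAPGA", v="TRBV7-2")])
    cfg = StrengthConfig()
    assert rs.strength_score(rep4, cfg, "CDR2", default_library) == 5
    assert rs.strength_score(rep7, cfg, "CDR2", default_library) == 1
    assert rs.strength_score(rep4, cfg, "CDR1", default_library) == 1  # MGHRA: M


def test_germline_scoring_requires_library():
    rep = Repertoire("r", [func_clono("CASSLAPGA")])
    with pytest.raises(ConfigurationError):
        rs.strength_score(rep, StrengthConfig(), "CDR2")


def test_residue_frequencies_constant_and_weighted():
    rep = Repertoire("r", [func_clono("SSSSS")])
    freq = rs.residue_frequencies(rep)
    assert freq["S"] == pytest.approx(1.0) and freq.drop("S").abs().sum() == 0
    rep = Repertoire("r", [func_clono("AAAAA", count=1),
                           func_clono("GGGGG", v="TRBV7-2", count=3)])
    freq = rs.residue_frequencies(rep, weighting="umi")
    assert freq["A"] == pytest.approx(0.25)
    assert freq["G"] == pytest.approx(0.75)


def test_residue_frequencies_sum_to_one(cohorts):
    pre, _ = cohorts
    freq = rs.residue_frequencies(pre[0])
    assert freq.sum() == pytest.approx(1.0, abs=1e-9)


def test_length_match_minimum_envelope():
    a = Repertoire("a", [func_clono("CASSLAPGATNEKL"[:14].ljust(14, "F"))] +
                   [func_clono(f"CASSLAPGATNEK{x}") for x in "AGSTVWYLC"])
    b = Repertoire("b", [func_clono(f"CASSLAPGATNE{x}Y") for x in "AGS"])
    out_a, out_b = rs.length_match_downsample([a, b], seed=0)
    assert len(out_a) == 3 and len(out_b) == 3
    assert all(len(c.cdr3_aa) == 14 for c in out_a.clonotypes)


def test_length_match_identity_on_identical_repertoires():
    clonos = [func_clono(f"CASSLAPGATNEK{x}") for x in "AGSTV"]
    a = Repertoire("a", list(clonos))
    b = Repertoire("b", list(clonos))
    out_a, out_b = rs.length_match_downsample([a, b], seed=1)
    assert {c.key for c in out_a.clonotypes} == {c.key for c in a.clonotypes}
    assert {c.key for c in out_b.clonotypes} == {c.key for c in b.clonotypes}


def test_length_match_equalizes_histograms(cohorts):
    pre, adu = cohorts
    outs = rs.length_match_downsample([pre[0], adu[0], adu[1]], seed=2)
    hists = []
    for rep in outs:
        h = pd.Series([len(c.cdr3_aa) for c in rep.clonotypes]).value_counts().sort_index()
        hists.append(h)
    assert hists[0].equals(hists[1]) and hists[1].equals(hists[2])


def test_biased_v_usage_raises_cdr2_strength(default_library):
    """Usage biased toward a strong-CDR2 V yields a higher CDR2 score than
    uniform usage (germline contribution to repertoire strength)."""
    strong_bias = {v.name: (0.6 if v.name == "TRBV4-1" else 0.4 / 12)
                   for v in default_library.v_segments}
    biased = rs.simulate_cohort(default_library, "adult_like", 3, 800, 2000, seed=5,
                                overrides={"v_weights": strong_bias})
    uniform = rs.simulate_cohort(default_library, "adult_like", 3, 800, 2000, seed=6)
    cfg = StrengthConfig()
    s_b = np.mean([rs.strength_score(r, cfg, "CDR2", default_library) for r in biased])
    s_u = np.mean([rs.strength_score(r, cfg, "CDR2", default_library) for r in uniform])
    assert s_b > s_u
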