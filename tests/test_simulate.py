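import numpy as np
import pytest
from scipy import stats as sps

import repshape as rs
from repshape.errors import ParameterError
from repshape.simulate import GenerativeModel

from helpers import enumerate_pgen, enumerate_zero_insert_sequences


def test_preset_insertion_activity_ordering(default_library):
    pre = rs.build_preset_model(default_library, "preterm_like")
    term = rs.build_preset_model(default_library, "term_like")
    adult = rs.build_preset_model(default_library, "adult_like")
    assert pre.insertion_zero_prob > term.insertion_zero_prob > adult.insertion_zero_prob


def test_override_out_of_range_raises(default_library):
    with pytest.raises(ParameterError):
        rs.build_preset_model(default_library, "preterm_like", {"pi0": 1.5})
    with pytest.raises(ParameterError):
        rs.build_preset_model(default_library, "preterm_like", {"no_such_knob": 1})


def test_degenerate_zero_insertion_model(default_library):
    model = rs.build_preset_model(default_library, "preterm_like", {"pi0": 1.0})
    rep = rs.simulate_repertoire(model, default_library, 300, 900, seed=5)
    assert all(c.vd_insert_len == 0 and c.dj_insert_len == 0 for c in rep.clonotypes)
    summ = rs.summary_features(rep, functional_only=False)
    assert summ.zero_insert_freq == pytest.approx(1.0, abs=1e-12)


def test_umi_conservation_and_determinism(default_library):
    model = rs.build_preset_model(default_library, "term_like")
    a = rs.simulate_repertoire(model, default_library, 250, 777, seed=9)
    b = rs.simulate_repertoire(model, default_library, 250, 777, seed=9)
    assert a.total_umis == 777
    assert [(c.key, c.umi_count) for c in a.clonotypes] == \
        [(c.key, c.umi_count) for c in b.clonotypes]


def test_model_yaml_round_trip(tmp_path, default_library):
    model = rs.build_preset_model(default_library, "term_like", {"q": 0.3})
    path = tmp_path / "model.yaml"
    model.save(path)
    assert GenerativeModel.load(path) == model


def test_pgen_forced_single_scenario(forced_library):
    model = rs.build_preset_model(forced_library, "adult_like",
                                  {"pi0": 1.0, "max_deletion": 0})
    assert rs.pgen_nt(model, forced_library, "TGTGCCGGGTTTTTC") == pytest.approx(1.0)
    assert rs.pgen_nt(model, forced_library, "TGTGCCAAATTTTTC") == 0.0


def test_pgen_rejects_non_dna(forced_library):
    model = rs.build_preset_model(forced_library, "adult_like")
    with pytest.raises(Exception):
        rs.pgen_nt(model, forced_library, "TGTGNX")


def test_pgen_matches_bruteforce_enumeration(small_library):
    """Scenario-sum pgen equals plain nested-loop enumeration exactly."""
    model = rs.build_preset_model(small_library, "term_like",
                                  {"pi0": 0.5, "max_deletion": 2})
    rearrs = rs.simulate_rearrangements(model, small_library, 50, seed=7)
    for r in rearrs:
        assert rs.pgen_nt(model, small_library, r.cdr3_nt) == \
            pytest.approx(enumerate_pgen(model, small_library, r.cdr3_nt), abs=1e-12)


def test_pgen_with_d_skip_matches_enumeration(small_library):
    model = rs.build_preset_model(small_library, "term_like",
                                  {"pi0": 0.6, "max_deletion": 2, "d_skip_prob": 0.3})
    rearrs = rs.simulate_rearrangements(model, small_library, 30, seed=17)
    assert any(r.d_name is None for r in rearrs)  # D-less scenarios occur
    for r in rearrs:
        assert rs.pgen_nt(model, small_library, r.cdr3_nt) == \
            pytest.approx(enumerate_pgen(model, small_library, r.cdr3_nt), abs=1e-12)


def test_pgen_total_probability_is_one_on_enumerable_model(small_library):
    """With no insertions the scenario space is finite: pgen sums to 1."""
    model = rs.build_preset_model(small_library, "term_like",
                                  {"pi0": 1.0, "max_deletion": 2})
    seqs = enumerate_zero_insert_sequences(model, small_library)
    total = sum(rs.pgen_nt(model, small_library, s) for s in seqs)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_scenario_prob_matches_pgen_on_unambiguous_sequence(forced_library):
    """For a single-scenario model the sampled scenario_prob equals pgen."""
    model = rs.build_preset_model(forced_library, "adult_like",
                                  {"pi0": 1.0, "max_deletion": 0})
    r = rs.simulate_rearrangements(model, forced_library, 1, seed=0)[0]
    assert r.scenario_prob == pytest.approx(
        rs.pgen_nt(model, forced_library, r.cdr3_nt), abs=1e-12)


def test_empirical_frequencies_consistent_with_pgen(small_library):
    """Sequence frequencies over many draws fall in 99% CIs around pgen."""
    model = rs.build_preset_model(small_library, "term_like",
                                  {"pi0": 0.7, "max_deletion": 1})
    seqs = enumerate_zero_insert_sequences(model, small_library)
    top = sorted(seqs, key=lambda s: -rs.pgen_nt(model, small_library, s))[:10]
    n = 20000
    rearrs = rs.simulate_rearrangements(model, small_library, n, seed=123)
    counts = {}
    for r in rearrs:
        counts[r.cdr3_nt] = counts.get(r.cdr3_nt, 0) + 1
    for s in top:
        k = counts.get(s, 0)
        lo = sps.beta.ppf(0.005, k, n - k + 1) if k > 0 else 0.0
        hi = sps.beta.ppf(0.995, k + 1, n - k)
        assert lo <= rs.pgen_nt(model, small_library, s) <= hi


def test_mean_cdr3_length_increases_with_insertion_activity(default_library):
    means = []
    for pi0 in (1.0, 0.5, 0.1):
        model = rs.build_preset_model(default_library, "term_like", {"pi0": pi0})
        rearrs = rs.simulate_rearrangements(model, default_library, 10000, seed=31)
        means.append(np.mean([len(r.cdr3_nt) for r in rearrs]))
    assert means[0] <= means[1] <= means[2]


@pytest.mark.parametrize("pi0", [0.1, 0.5, 0.9])
def test_zero_insert_rate_recovers_pi0_squared_without_deletions(default_library, pi0):
    """At max_deletion = 0 the zero-insert rate is exactly pi0**2."""
    model = rs.build_preset_model(default_library, "term_like",
                                  {"pi0": pi0, "max_deletion": 0})
    n = 10000
    rearrs = rs.simulate_rearrangements(model, default_library, n, seed=41)
    frac = np.mean([len(r.ins_vd) + len(r.ins_dj) == 0 for r in rearrs])
    expected = pi0**2
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 3 * se


def test_selection_filter_reaches_target_nonfunctional_share(default_library):
    model = rs.build_preset_model(default_library, "term_like")
    rep = rs.simulate_repertoire(model, default_library, 1500, 4000, seed=13)
    sel = rs.apply_selection(rep, nonfunctional_share=0.08, seed=14)
    _, by_umi = rs.nonfunctional_fractions(sel)
    assert by_umi == pytest.approx(0.08, abs=0.01)
    # functional clonotypes are untouched
    assert {c.key for c in sel.functional().clonotypes} == \
        {c.key for c in rep.functional().clonotypes}
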