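import numpy as np
import pytest
from scipy import stats as sps

from pcskit import classify, jtt, seqio, synthetic, triad


def test_scaffold_round_trip_by_construction():
    rec, truth = synthetic.generate_pcs_sequence(
        synthetic.ScaffoldSpec(subtype="N", include_thr7=True, seed=1))
    ann = triad.detect_triad(rec, mode="scan")
    assert (ann.cys_pos, ann.his_pos, ann.asp_pos) == (truth.cys_pos, truth.his_pos, truth.asp_pos)
    assert classify.classify_isoform(rec, ann).subtype == "N"


def test_his_asp_spacing_is_invariant():
    _, truth = synthetic.generate_pcs_sequence(synthetic.ScaffoldSpec(subtype="E", seed=2))
    assert truth.asp_pos - truth.his_pos - 1 == 17


def test_no_thr7_means_no_ck2_call():
    rec, truth = synthetic.generate_pcs_sequence(
        synthetic.ScaffoldSpec(subtype="D", include_thr7=False, seed=3))
    ann = triad.detect_triad(rec, mode="scan")
    assert not classify.check_ck2_context(rec, ann)


def test_truth_matches_planted_letters(random_scaffolds):
    for rec, truth in random_scaffolds:
        res = rec.residues
        assert res[truth.cys_pos - 1] == "C"
        assert res[truth.his_pos - 1] == "H"
        assert res[truth.asp_pos - 1] == "D"
        assert res[truth.cys_pos - 5] == truth.subtype
        assert truth.asp_pos - truth.his_pos - 1 == 17
        if truth.thr_pos:
            assert res[truth.thr_pos - 1] == "T"
        for p in truth.cc_positions:
            assert res[p - 1: p + 1] == "CC"
        for p in truth.cxxxc_positions:
            assert res[p - 1] == "C" and res[p + 3] == "C"


def test_dataset_counts_and_determinism(tmp_path):
    recs, truths = synthetic.generate_dataset(5, seed=42)
    assert len(recs) == len(truths) == 15
    assert len({r.seq_id for r in recs}) == 15
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    seqio.write_fasta(recs, p1)
    seqio.write_fasta(synthetic.generate_dataset(5, seed=42)[0], p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_invalid_specs_rejected():
    with pytest.raises(synthetic.ScaffoldError):
        synthetic.ScaffoldSpec(subtype="Q").validate()
    with pytest.raises(synthetic.ScaffoldError):
        synthetic.ScaffoldSpec(ch_spacing=5).validate()
    with pytest.raises(synthetic.ScaffoldError):
        synthetic.ScaffoldSpec(cterm_cys_frac=1.5).validate()
    with pytest.raises(synthetic.ScaffoldError):
        synthetic.ScaffoldSpec(background=tuple([0.1] * 20)).validate()


def test_plant_motif_full_occupancy(small_dataset):
    recs, _ = small_dataset
    planted, spans = synthetic.plant_motif(recs, "WWYYHHKKWWYY", occurrence_prob=1.0, seed=5)
    assert len(spans) == len(recs)
    for rec in planted:
        s, e = spans[rec.seq_id]
        assert rec.residues[s - 1:e] == "WWYYHHKKWWYY"


def test_plant_motif_occupancy_within_binomial_band():
    recs, _ = synthetic.generate_dataset(67, seed=8)  # 201 sequences
    recs = recs[:200]
    _, spans = synthetic.plant_motif(recs, "WWYYHHKKWWYY", occurrence_prob=0.5, seed=9)
    lo, hi = sps.binom.ppf([0.005, 0.995], 200, 0.5)
    assert lo <= len(spans) <= hi


def test_plant_motif_validates_width_and_length(small_dataset):
    recs, _ = small_dataset
    with pytest.raises(ValueError):
        synthetic.plant_motif(recs, "WWYY", seed=0)  # below minimum width
    with pytest.raises(ValueError):
        synthetic.plant_motif(recs, "W" * 500, seed=0)


def test_evolve_pair_identity_at_zero_divergence():
    a, b = synthetic.evolve_pair(500, 0.0, seed=4)
    assert a == b
    a2, b2 = synthetic.evolve_pair(500, 0.0, seed=4)
    assert (a, b) == (a2, b2)


def test_evolve_pair_difference_fraction_matches_model():
    # expected fraction of differing sites: 1 - sum_i pi_i P_ii(t)
    t, n = 0.1, 10000
    pi = jtt.equilibrium_frequencies()
    expected = 1.0 - float(pi @ np.diag(jtt.probability_matrix(t)))
    a, b = synthetic.evolve_pair(n, t, seed=6)
    observed = sum(x != y for x, y in zip(a, b)) / n
    se = (expected * (1 - expected) / n) ** 0.5
    assert abs(observed - expected) < 3 * se


def test_evolve_pair_divergence_monotone_on_average():
    fracs = []
    for t in (0.01, 0.1, 0.5, 1.0):
        a, b = synthetic.evolve_pair(10000, t, seed=10)
        fracs.append(sum(x != y for x, y in zip(a, b)) / 10000)
    assert fracs == sorted(fracs)


def test_two_group_dataset_labels_and_tail_motif():
    recs, groups, spans, info = synthetic.two_group_dataset(
        n_per_group=4, divergence=0.1, seed=3, tail_motif="WWYYHHKKWWYY")
    assert sorted(set(groups.values())) == ["1", "2"]
    assert set(spans) == {sid for sid, g in groups.items() if g == "2"}
    # the catalytic domain is an aligned block across both groups
    assert len({len(r.residues[:info["domain_end"]]) for r in recs}) == 1
    # the planted tail motif sits downstream of the catalytic Asp
    for sid, (start, _) in spans.items():
        assert start > info["domain_end"]
    # group 1 lacks the C-terminal extension, group 2 carries it
    len_by_group = {g: len(next(r for r in recs if groups[r.seq_id] == g))
                    for g in ("1", "2")}
    assert len_by_group["2"] > len_by_group["1"]
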