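"""Feature extraction, target-decoy FDR (cross-link composition counting),
and the iterative semi-supervised re-ranking."""
import numpy as np
import pytest

from xlopen.rescoring import (FEATURE_NAMES, compute_group_fdr, extract_features,
                              fdr_from_tally, filter_results, psm_composition,
                              rerank_group, rescore_psms, results_table,
                              select_training_samples, peptide_pair_rollup,
                              residue_pair_rollup, RescoredPSM)
from xlopen.search import CandidatePSM
from xlopen.sequence_db import ModifiedPeptide, Peptide, peptide_mass


def _mp(seq):
    return ModifiedPeptide(peptide=Peptide(seq, 0, ("P1",), 0),
                           modification_id=0, site_mods=(),
                           mono_mass=peptide_mass(seq))


def _psm(kind="cross", fine=1.0, runner=0.4, a="PEPKTIDE", b="SEQKENCE",
         a_decoy=False, b_decoy=False, group=None, spectrum="s1",
         alpha_int=400.0, beta_int=350.0, total=1000.0):
    return CandidatePSM(
        spectrum_id=spectrum, kind=kind,
        group=group or ("intra" if kind == "cross" else kind),
        alpha=_mp(a), alpha_site=3 if kind != "regular" else None,
        beta=_mp(b) if kind == "cross" else None,
        beta_site=3 if kind == "cross" else None,
        coarse_score=1.0, fine_score=fine, runner_up_score=runner,
        alpha_proteins=frozenset({"P1"}), beta_proteins=frozenset({"P1"}),
        alpha_is_decoy=a_decoy, beta_is_decoy=b_decoy,
        precursor_err_ppm=1.0, precursor_mass=2000.0, total_intensity=total,
        alpha_matched_intensity=alpha_int, beta_matched_intensity=beta_int,
        alpha_tag=4, beta_tag=4,
    )


def test_feature_vector_cross():
    f = extract_features(_psm(alpha_int=600.0, beta_int=400.0, total=1000.0))
    named = dict(zip(FEATURE_NAMES, f))
    assert named["AlphaIntRatio"] + named["BetaIntRatio"] == pytest.approx(1.0)
    assert named["ShortLen"] == 8
    assert named["ScoreDiff"] == pytest.approx(0.6)


def test_beta_features_zero_for_non_cross():
    f = dict(zip(FEATURE_NAMES, extract_features(_psm(kind="regular"))))
    assert f["BetaIntRatio"] == 0.0 and f["BetaTagRatio"] == 0.0


def test_score_diff_without_runner_up():
    f = dict(zip(FEATURE_NAMES, extract_features(_psm(fine=0.8, runner=0.0))))
    assert f["ScoreDiff"] == pytest.approx(0.8)


def test_composition_labels():
    assert psm_composition(_psm()) == "TT"
    assert psm_composition(_psm(b_decoy=True)) == "TD"
    assert psm_composition(_psm(a_decoy=True, b_decoy=True)) == "DD"
    assert psm_composition(_psm(kind="regular", a_decoy=True)) == "DD"


def test_fdr_point_formula():
    assert fdr_from_tally(95, 10, 5) == pytest.approx(5 / 95)
    assert fdr_from_tally(100, 7, 7) == 0.0
    assert fdr_from_tally(100, 3, 9) == 0.0       # clamped at zero
    assert fdr_from_tally(0, 1, 0) == 1.0


def test_group_fdr_matches_direct_counting():
    """Oracle: recount compositions at every cutoff over random score lists."""
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = int(rng.integers(5, 60))
        scores = rng.normal(size=n)
        comps = rng.choice(["TT", "TD", "DD"], size=n, p=[0.7, 0.2, 0.1])
        q = compute_group_fdr(scores, list(comps))
        order = np.argsort(-scores)
        # q non-increasing with score
        assert np.all(np.diff(q[order]) >= -1e-12)
        # each q equals the minimum point-FDR over cutoffs at or below this score
        for i in range(n):
            fdrs = []
            for cut in sorted(set(scores[scores <= scores[i]])):
                at = scores >= cut
                fdrs.append(fdr_from_tally(int(((comps == "TT") & at).sum()),
                                           int(((comps == "TD") & at).sum()),
                                           int(((comps == "DD") & at).sum())))
            assert q[i] == pytest.approx(min(fdrs), abs=1e-12)


def test_select_training_samples():
    rng = np.random.default_rng(0)
    # TT scores strictly dominate: all TT become positives
    scores = np.concatenate([rng.uniform(10, 20, 40), rng.uniform(0, 5, 40)])
    comps = np.array(["TT"] * 40 + ["TD"] * 20 + ["DD"] * 20)
    pos, neg = select_training_samples(scores, comps)
    assert pos.sum() == 40 and set(np.nonzero(pos)[0]) == set(range(40))
    assert neg.sum() == 40
    # a TD PSM never enters positives even with a top score
    comps2 = np.array(["TD"] * 40 + ["TT"] * 40)
    pos2, _ = select_training_samples(scores, comps2)
    assert not pos2[:40].any()
    # all-decoy input: positives empty
    pos3, _ = select_training_samples(scores, np.array(["DD"] * 80))
    assert pos3.sum() == 0


def _feature_fixture(rng, n_true=120, n_decoy=120, separation=3.0):
    f_true = rng.normal(separation, 1.0, size=(n_true, 9))
    f_rand = rng.normal(0.0, 1.0, size=(n_decoy, 9))
    feats = np.vstack([f_true, f_rand])
    raw = feats[:, 0].copy()
    comps = np.array(["TT"] * n_true + ["TD"] * (n_decoy // 2) + ["DD"] * (n_decoy - n_decoy // 2))
    err = rng.normal(0, 3, size=n_true + n_decoy)
    return feats, raw, comps, err


def test_rerank_separable_features_perfect_ranking():
    rng = np.random.default_rng(7)
    feats, raw, comps, err = _feature_fixture(rng, separation=4.0)
    scores, model = rerank_group(feats, raw, comps, err)
    assert model is not None and model.iterations <= 5
    # every TT outranks every decoy-containing PSM
    assert scores[comps == "TT"].min() > scores[comps != "TT"].max()
    # the probability-of-random-match convention: positives score <= 0.5
    probs = model.predict_random_prob(feats)
    assert np.all(probs[comps == "TT"] < 0.5)


def test_rerank_uninformative_features_rolls_back():
    """When targets and decoys share one feature distribution, re-ranking must
    not fabricate separation: the raw-score ranking is retained unless the
    model genuinely improves the 1%-FDR count."""
    rng = np.random.default_rng(11)
    n = 200
    feats = rng.normal(size=(n, 9))
    raw = rng.normal(size=n)
    # raw scores also uninformative: make TT slightly enriched at top so a
    # training set exists
    comps = np.array(["TT"] * 120 + ["TD"] * 40 + ["DD"] * 40)
    raw[:120] += 2.0
    scores, model = rerank_group(feats, raw, comps, rng.normal(size=n))
    pos_raw, _ = select_training_samples(raw, comps)
    pos_new, _ = select_training_samples(scores, comps)
    assert pos_new.sum() >= pos_raw.sum()


def test_small_group_keeps_raw_scores():
    rng = np.random.default_rng(2)
    feats, raw, comps, err = _feature_fixture(rng, n_true=10, n_decoy=10)
    scores, model = rerank_group(feats, raw, comps, err)
    assert model is None and np.array_equal(scores, raw)


def test_rescore_and_filter_end_to_end():
    rng = np.random.default_rng(4)
    psms = []
    for i in range(60):
        psms.append(_psm(fine=2.0 + rng.random(), spectrum=f"t{i}"))
    for i in range(30):
        psms.append(_psm(fine=rng.random(), b_decoy=True, spectrum=f"d{i}"))
    rescored = rescore_psms(psms, mode="separate")
    assert len(rescored) == 90
    kept = filter_results(rescored, fdr_threshold=0.05)
    assert all(r.composition == "TT" and r.q_value <= 0.05 for r in kept)
    assert len(kept) == 60
    with pytest.raises(ValueError):
        filter_results(rescored, fdr_threshold=1.5)


def test_filter_threshold_edges():
    rows = [RescoredPSM(_psm(spectrum=f"s{i}"), "TT", 1.0, q)
            for i, q in enumerate([0.01, 0.04, 0.06])]
    kept = filter_results(rows, fdr_threshold=0.05)
    assert [r.q_value for r in kept] == [0.01, 0.04]


def test_rollups_deduplicate():
    rows = [RescoredPSM(_psm(spectrum="s1", fine=1.0), "TT", 0.9, 0.0),
            RescoredPSM(_psm(spectrum="s2", fine=0.8), "TT", 0.8, 0.0)]
    table = results_table(rows)
    assert len(peptide_pair_rollup(table)) == 1
    assert len(residue_pair_rollup(table)) == 1
    # the best-scoring PSM represents the pair
    assert residue_pair_rollup(table).spectrum.iloc[0] == "s1"
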