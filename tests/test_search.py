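"""Query-key generation, alpha/beta retrieval, coarse/fine scoring, and
per-spectrum best-candidate selection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlopen.chemistry import PROTON, WATER, get_linker
from xlopen.io_app import SearchConfig
from xlopen.pipeline import build_indexes, make_searcher
from xlopen.search import (FineScorer, Spectrum, generate_query_keys,
                           peptide_ion_masses)
from xlopen.sequence_db import peptide_mass
from xlopen.simulator import DatasetProfile, simulate_dataset

BS3 = get_linker("BS3")


def _spectrum(mz, intensity=None, M=1000.0, title="s1"):
    mz = np.asarray(mz, float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return Spectrum(title=title, precursor_mass=M, precursor_charge=2,
                    mz=mz, intensity=np.asarray(intensity, float))


def ladder_spectrum(forms, title, kind, linker, sites=(), loop=None, M=None):
    """Noise-free, complete single-charge ladder for one hypothesis."""
    if kind == "cross":
        (alpha, sa), (beta, sb) = forms
        ab, _, ay, _ = peptide_ion_masses(alpha, linker.xl_mass + beta.mono_mass, (sa,))
        bb, _, by, _ = peptide_ion_masses(beta, linker.xl_mass + alpha.mono_mass, (sb,))
        ions = np.concatenate([ab, ay, bb, by])
        mass = alpha.mono_mass + beta.mono_mass + linker.xl_mass
    else:
        alpha = forms
        shift = {"mono": linker.mono_mass_delta, "loop": linker.xl_mass,
                 "regular": 0.0}[kind]
        b, _, y, _ = peptide_ion_masses(alpha, shift, sites, loop=loop)
        ions = np.concatenate([b, y])
        mass = alpha.mono_mass + shift
    return _spectrum(np.sort(ions) + PROTON, M=M or mass, title=title)


# --- query keys ----------------------------------------------------------------

def test_query_key_values():
    s = _spectrum([200.0], M=1000.0)
    k = generate_query_keys(s)
    assert k.m_b[0] == pytest.approx(200.0 - PROTON, abs=1e-6)
    assert k.m_y[0] == pytest.approx(200.0 - PROTON - WATER, abs=1e-6)
    assert k.m_bx[0] == pytest.approx(1000.0 - WATER - 200.0 + PROTON, abs=1e-6)
    assert k.m_yx[0] == pytest.approx(1000.0 - 200.0 + PROTON, abs=1e-6)
    assert k.m_b[0] + k.m_bx[0] == pytest.approx(1000.0 - WATER, abs=1e-9)


@settings(max_examples=200, deadline=None)
@given(st.floats(50.0, 4000.0), st.floats(500.0, 8000.0))
def test_query_key_complementarity(m, M):
    s = _spectrum([m], M=M)
    k = generate_query_keys(s)
    if len(k.m_b) and len(k.m_bx):
        assert abs(k.m_b[0] + k.m_bx[0] - (M - WATER)) < 1e-6
    if len(k.m_y) and len(k.m_yx):
        assert abs(k.m_y[0] + k.m_yx[0] - (M - WATER)) < 1e-6


def test_nonpositive_query_keys_dropped():
    s = _spectrum([5.0], M=1000.0)   # m - proton - water < 0
    k = generate_query_keys(s)
    assert len(k.m_y) == 0 and len(k.m_b) == 1


# --- searcher fixtures ---------------------------------------------------------

@pytest.fixture(scope="module")
def searcher(small_proteins):
    cfg = SearchConfig()
    db, fi, pi = build_indexes(small_proteins, cfg)
    return make_searcher(db, fi, pi, cfg)


def _form_for(searcher, seq):
    mods = searcher.db.mod_forms[seq][0]
    from xlopen.sequence_db import ModifiedPeptide, Peptide
    return ModifiedPeptide(
        peptide=Peptide(seq, 0, tuple(searcher.db.seq_proteins[seq]), 0),
        modification_id=0, site_mods=mods, mono_mass=peptide_mass(seq, dict(mods)))


# --- alpha retrieval and coarse scoring ----------------------------------------

def test_ideal_ladder_ranks_first(searcher):
    seq = "QISFVK"
    alpha = _form_for(searcher, seq)
    s = ladder_spectrum(alpha, "t", "regular", BS3)
    top = searcher.retrieve_alpha_candidates(s)
    assert top and top[0][0].sequence == seq
    assert len(top) <= 5
    # complete ladder, all intensity matched: coarse score = 2
    assert top[0][1] == pytest.approx(2.0, abs=1e-9)


def test_mic_one_candidates_removed(searcher):
    # single peak can give MIC = 1 at best; retrieval must return nothing
    alpha = _form_for(searcher, "QISFVK")
    b, _, y, _ = peptide_ion_masses(alpha, 0.0, ())
    s = _spectrum([b[0] + PROTON], M=alpha.mono_mass)
    assert searcher.retrieve_alpha_candidates(s) == []


def test_candidates_heavier_than_precursor_removed(searcher):
    alpha = _form_for(searcher, "QISFVK")
    s = ladder_spectrum(alpha, "t", "regular", BS3)
    light = Spectrum(title="t", precursor_mass=300.0, precursor_charge=2,
                     mz=s.mz, intensity=s.intensity)
    for mp, _, _ in searcher.retrieve_alpha_candidates(light):
        assert mp.mono_mass <= 300.0 * (1 + 20e-6)


def test_coarse_score_zero_and_monotone(searcher, rng):
    alpha = _form_for(searcher, "QISFVK")
    from xlopen.search import _sorted_query_arrays
    b, _, y, _ = peptide_ion_masses(alpha, 0.0, ())
    # zero matches
    far = _spectrum([3000.0, 3100.0], M=3500.0)
    k = generate_query_keys(far)
    qb, pb, qy, py = _sorted_query_arrays(k)
    assert searcher.coarse_score(alpha, qb, pb, qy, py, far) == 0.0
    # adding one more matched peak never lowers the score
    ladder = np.sort(np.concatenate([b, y])) + PROTON
    prev = -1.0
    for n in range(1, len(ladder) + 1):
        s = _spectrum(ladder[:n], M=alpha.mono_mass)
        k = generate_query_keys(s)
        qb, pb, qy, py = _sorted_query_arrays(k)
        score = searcher.coarse_score(alpha, qb, pb, qy, py, s)
        assert score >= prev - 1e-12
        prev = score


# --- beta retrieval ------------------------------------------------------------

def test_beta_retrieval_matches_linear_scan(searcher):
    alpha = _form_for(searcher, "QISFVK")
    targets = [mp for mp in _all_forms(searcher) if set(mp.sequence) & {"K"}]
    beta_true = targets[3]
    M = alpha.mono_mass + beta_true.mono_mass + BS3.xl_mass
    s = _spectrum([500.0], M=M)
    got = {(mp.sequence, mp.modification_id)
           for mp in searcher.retrieve_beta_candidates(alpha, s)}
    open_mass = M - alpha.mono_mass - BS3.xl_mass
    delta = 20e-6 * M
    want = {(mp.sequence, mp.modification_id) for mp in _all_forms(searcher)
            if abs(mp.mono_mass - open_mass) <= delta and set(mp.sequence) & {"K"}}
    assert got == want and (beta_true.sequence, 0) in got


def test_beta_retrieval_negative_open_mass(searcher):
    alpha = _form_for(searcher, "QISFVK")
    s = _spectrum([100.0], M=alpha.mono_mass + BS3.xl_mass - 50.0)
    assert searcher.retrieve_beta_candidates(alpha, s) == []


def _all_forms(searcher):
    from xlopen.sequence_db import ModifiedPeptide, Peptide
    out = []
    for seq, forms in searcher.db.mod_forms.items():
        for mid, mods in enumerate(forms):
            out.append(ModifiedPeptide(
                peptide=Peptide(seq, 0, tuple(searcher.db.seq_proteins[seq]), 0),
                modification_id=mid, site_mods=mods,
                mono_mass=peptide_mass(seq, dict(mods))))
    return out


# --- fine scoring --------------------------------------------------------------

def test_fine_score_zero_without_matches(searcher):
    alpha = _form_for(searcher, "QISFVK")
    beta = _form_for(searcher, "SHFSR")
    s = _spectrum([3000.0], M=alpha.mono_mass + beta.mono_mass + BS3.xl_mass)
    scorer = FineScorer(s, 20.0)
    score, _ = scorer.score_pair(alpha, beta, 5, 2, BS3.xl_mass)
    assert score == 0.0


def test_fine_score_symmetric_in_alpha_beta(searcher):
    alpha = _form_for(searcher, "QISFVK")
    beta = _form_for(searcher, "TLKGEITVEAVDAAEAEK")
    sa, sb = 5, 2
    s = ladder_spectrum(((alpha, sa), (beta, sb)), "t", "cross", BS3)
    scorer = FineScorer(s, 20.0)
    fwd, _ = scorer.score_pair(alpha, beta, sa, sb, BS3.xl_mass)
    rev, _ = scorer.score_pair(beta, alpha, sb, sa, BS3.xl_mass)
    assert fwd == pytest.approx(rev, abs=1e-12)
    assert fwd > 0.9


def test_true_pair_maximizes_fine_score(searcher):
    """Exhaustive pair-scoring oracle on the full small database."""
    alpha = _form_for(searcher, "QISFVK")
    beta = _form_for(searcher, "GSHMK")
    sa = alpha.sequence.index("K")
    sb = beta.sequence.index("K")
    s = ladder_spectrum(((alpha, sa), (beta, sb)), "t", "cross", BS3)
    scorer = FineScorer(s, 20.0)
    best = None
    forms = [f for f in _all_forms(searcher) if "K" in f.sequence]
    for i, a in enumerate(forms):
        for b in forms[i:]:
            for s1 in [k for k, aa in enumerate(a.sequence) if aa == "K"]:
                for s2 in [k for k, aa in enumerate(b.sequence) if aa == "K"]:
                    sc, _ = scorer.score_pair(a, b, s1, s2, BS3.xl_mass)
                    key = (a.sequence, s1, b.sequence, s2)
                    if best is None or sc > best[0]:
                        best = (sc, key)
    assert best[1] in (
        (alpha.sequence, sa, beta.sequence, sb),
        (beta.sequence, sb, alpha.sequence, sa),
    )


# --- full spectrum search ------------------------------------------------------

def test_search_spectrum_kinds(searcher, small_proteins):
    profile = DatasetProfile(counts={"cross": 8, "loop": 4, "mono": 4, "regular": 4},
                             dropout=0.0, noise_peaks=0, precursor_ppm_sd=0.0)
    spectra, truths = simulate_dataset(small_proteins, profile, linker="BS3", seed=5)
    for s, t in zip(spectra, truths):
        psm = searcher.search_spectrum(s)
        assert psm is not None, t
        assert psm.kind == t.kind
        seqs = {psm.alpha.sequence} | ({psm.beta.sequence} if psm.beta else set())
        true_seqs = {t.alpha_seq} | ({t.beta_seq} if t.beta_seq else set())
        assert seqs == true_seqs
        if psm.kind == "mono":
            assert psm.alpha.sequence[psm.alpha_site] in BS3.site_alpha
        if psm.kind == "cross":
            # precursor conservation
            theo = psm.alpha.mono_mass + psm.beta.mono_mass + BS3.xl_mass
            assert abs(theo - s.precursor_mass) <= s.precursor_mass * 20e-6
            # both peptides from one protein -> intra
            if psm.alpha_proteins & psm.beta_proteins:
                assert psm.group == "intra"


def test_search_is_deterministic(searcher, small_proteins):
    profile = DatasetProfile(counts={"cross": 5, "regular": 5, "loop": 0, "mono": 0})
    spectra, _ = simulate_dataset(small_proteins, profile, linker="BS3", seed=9)
    a = [searcher.search_spectrum(s) for s in spectra]
    b = [searcher.search_spectrum(s) for s in spectra]
    for x, y in zip(a, b):
        assert (x is None) == (y is None)
        if x is not None:
            assert (x.alpha.sequence, x.alpha_site, x.fine_score) == \
                   (y.alpha.sequence, y.alpha_site, y.fine_score)


def test_empty_spectrum_returns_nothing(searcher):
    s = Spectrum(title="e", precursor_mass=800.0, precursor_charge=2,
                 mz=np.empty(0), intensity=np.empty(0))
    assert searcher.search_spectrum(s) is None
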