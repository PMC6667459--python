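"""Semi-supervised re-ranking and cross-link-aware target-decoy FDR control.

PSMs are grouped into intra-protein, inter-protein, loop-linked, mono-linked,
and regular groups. Within each group an iterative, Percolator-style linear
SVM fuses nine features into one score; the group FDR at a score cutoff is

    FDR = max(0, (N_TD - N_DD) / N_TT)

where N_TT / N_TD / N_DD count PSMs by target/decoy composition at or above
the cutoff, and q-values are the running minimum of FDR from the lowest score
upward. Intra- and inter-protein FDRs are controlled separately by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .search import CandidatePSM

FEATURE_NAMES = (
    "KSDPScore", "AlphaIntRatio", "BetaIntRatio", "AlphaTagRatio",
    "BetaTagRatio", "ShortLen", "ScoreDiff", "ModRatio", "PrecursorErrFreq",
)

#: Bin edges (ppm, signed) for the dynamic precursor-error-frequency feature.
_PPM_BINS = np.linspace(-25.0, 25.0, 26)

MIN_GROUP_SIZE = 50
MAX_ITERATIONS = 5
TRAIN_FDR = 0.01


def extract_features(psm: CandidatePSM) -> np.ndarray:
    """The nine-feature vector of one PSM (beta features zero for non-cross).

    PrecursorErrFreq is a *dynamic* feature: it is initialized to zero here and
    filled in from the positive set's ppm-error histogram during re-ranking.
    """
    total = psm.total_intensity
    alpha_len = psm.alpha.length
    if psm.kind == "cross":
        beta_len = psm.beta.length
        short_len = min(alpha_len, beta_len)
        n_res = alpha_len + beta_len
        n_mod = len(psm.alpha.site_mods) + len(psm.beta.site_mods)
        beta_int = psm.beta_matched_intensity / total if total > 0 else 0.0
        beta_tag = psm.beta_tag / beta_len
    else:
        short_len = alpha_len
        n_res = alpha_len
        n_mod = len(psm.alpha.site_mods)
        beta_int = 0.0
        beta_tag = 0.0
    score_diff = psm.fine_score - psm.runner_up_score
    return np.array([
        psm.fine_score,
        psm.alpha_matched_intensity / total if total > 0 else 0.0,
        beta_int,
        psm.alpha_tag / alpha_len,
        beta_tag,
        float(short_len),
        score_diff,
        n_mod / n_res,
        0.0,
    ])


def psm_composition(psm: CandidatePSM) -> str:
    """TT / TD / DD composition; non-cross PSMs have a single peptide, so
    target -> TT and decoy -> DD. An alpha/beta pair hitting the target and
    decoy versions of the same protein is TD (and grouped intra upstream)."""
    if psm.kind != "cross":
        return "DD" if psm.alpha_is_decoy else "TT"
    n_decoy = int(psm.alpha_is_decoy) + int(psm.beta_is_decoy)
    return ("TT", "TD", "DD")[n_decoy]


def fdr_from_tally(n_tt: int, n_td: int, n_dd: int) -> float:
    """Point FDR estimate from composition counts, clamped at 0."""
    if n_tt == 0:
        return 1.0
    return max(0.0, (n_td - n_dd) / n_tt)


def compute_group_fdr(scores: np.ndarray, compositions: list[str]) -> np.ndarray:
    """q-value per PSM within one group.

    At each score cutoff (descending), FDR = max(0, (N_TD - N_DD)/N_TT) over
    PSMs at/above the cutoff; q-values monotonized by a running minimum from
    the lowest score upward.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        return np.empty(0)
    comp = np.asarray(compositions)
    order = np.argsort(-scores, kind="stable")
    tt = np.cumsum(comp[order] == "TT")
    td = np.cumsum(comp[order] == "TD")
    dd = np.cumsum(comp[order] == "DD")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(tt > 0, np.maximum(0.0, (td - dd) / np.maximum(tt, 1)), 1.0)
    # ties share the cutoff of the last tied PSM
    sorted_scores = scores[order]
    for i in range(n - 2, -1, -1):
        if sorted_scores[i] == sorted_scores[i + 1]:
            fdr[i] = fdr[i + 1]
    qvals = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty(n)
    out[order] = qvals
    return out


@dataclass
class RerankModel:
    """Standardized linear model with logistic probability calibration.

    ``predict_random_prob`` returns the probability of a PSM being a random
    match (liblinear ``-b`` convention: <= 0.5 means classified positive).
    """

    scaler: StandardScaler
    svm: LinearSVC
    calibrator: LogisticRegression
    iterations: int

    def decision(self, features: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.scaler.transform(features))

    def predict_random_prob(self, features: np.ndarray) -> np.ndarray:
        d = self.decision(features).reshape(-1, 1)
        # calibrator classes are (0 = true, 1 = random)
        return self.calibrator.predict_proba(d)[:, 1]


def _update_precursor_err_freq(features: np.ndarray, err_ppm: np.ndarray,
                               positive_mask: np.ndarray) -> None:
    """Dynamic feature: frequency of each PSM's precursor-error bin among the
    current positive set (uniform if no positives yet)."""
    ref = err_ppm[positive_mask] if positive_mask.any() else err_ppm
    hist, _ = np.histogram(ref, bins=_PPM_BINS)
    freq = hist / max(hist.sum(), 1)
    bins = np.clip(np.digitize(err_ppm, _PPM_BINS) - 1, 0, len(freq) - 1)
    features[:, 8] = freq[bins]


def select_training_samples(scores: np.ndarray, compositions: np.ndarray,
                            fdr_threshold: float = TRAIN_FDR
                            ) -> tuple[np.ndarray, np.ndarray]:
    """(positive mask, negative mask): positives are TT PSMs at q <= threshold;
    negatives carry at least one decoy peptide."""
    q = compute_group_fdr(scores, list(compositions))
    positives = (compositions == "TT") & (q <= fdr_threshold)
    negatives = compositions != "TT"
    return positives, negatives


def _fit_model(features: np.ndarray, positives: np.ndarray,
               negatives: np.ndarray, iteration: int) -> RerankModel | None:
    train_mask = positives | negatives
    X = features[train_mask]
    y = np.where(positives[train_mask], 0, 1)   # 0 = true match, 1 = random
    if len(np.unique(y)) < 2:
        return None
    scaler = StandardScaler().fit(X)
    svm = LinearSVC(C=1.0, loss="squared_hinge", penalty="l2", tol=1e-4,
                    class_weight="balanced", max_iter=10000)
    svm.fit(scaler.transform(X), y)
    d = svm.decision_function(scaler.transform(X)).reshape(-1, 1)
    calibrator = LogisticRegression(C=1e6, max_iter=1000).fit(d, y)
    return RerankModel(scaler=scaler, svm=svm, calibrator=calibrator,
                       iterations=iteration)


def rerank_group(features: np.ndarray, raw_scores: np.ndarray,
                 compositions: np.ndarray, err_ppm: np.ndarray,
                 max_iterations: int = MAX_ITERATIONS
                 ) -> tuple[np.ndarray, RerankModel | None]:
    """Iterative semi-supervised re-ranking of one PSM group.

    Returns (final scores oriented higher-is-better, fitted model or None).
    Falls back to the raw fine scores when the group is too small, training
    collapses, or re-ranking loses 1%-FDR positives relative to the raw score.
    """
    n = len(raw_scores)
    if n < MIN_GROUP_SIZE:
        return raw_scores.copy(), None
    features = features.copy()
    scores = raw_scores.copy()
    positives, negatives = select_training_samples(scores, compositions)
    raw_pos_count = int(positives.sum())
    if raw_pos_count == 0 or not negatives.any():
        return raw_scores.copy(), None

    model = None
    prev_pos: frozenset[int] | None = None
    for it in range(1, max_iterations + 1):
        _update_precursor_err_freq(features, err_ppm, positives)
        fitted = _fit_model(features, positives, negatives, it)
        if fitted is None:
            break
        model = fitted
        scores = 1.0 - model.predict_random_prob(features)
        positives, negatives = select_training_samples(scores, compositions)
        pos_set = frozenset(np.nonzero(positives)[0].tolist())
        if prev_pos is not None and pos_set == prev_pos:
            break
        prev_pos = pos_set

    if model is None:
        return raw_scores.copy(), None
    final_pos, _ = select_training_samples(scores, compositions)
    if int(final_pos.sum()) < raw_pos_count:
        # re-ranking degraded decoy discrimination: roll back to raw scores
        return raw_scores.copy(), None
    return scores, model


@dataclass
class RescoredPSM:
    psm: CandidatePSM
    composition: str
    svm_score: float
    q_value: float


def rescore_psms(psms: list[CandidatePSM], mode: str = "separate"
                 ) -> list[RescoredPSM]:
    """Group, re-rank, and attach q-values to a full PSM list.

    ``mode``: 'separate' controls intra- and inter-protein FDR independently;
    'global' pools all cross PSMs for one FDR estimate. Loop, mono, and
    regular groups are always handled within their own groups.
    """
    if mode not in ("separate", "global"):
        raise ValueError(f"mode must be 'separate' or 'global', got {mode!r}")
    out: list[RescoredPSM | None] = [None] * len(psms)
    comps = np.array([psm_composition(p) for p in psms])

    def group_key(p: CandidatePSM) -> str:
        if mode == "global" and p.group in ("intra", "inter"):
            return "cross"
        return p.group

    group_ids = np.array([group_key(p) for p in psms])
    for g in np.unique(group_ids):
        idx = np.nonzero(group_ids == g)[0]
        sub = [psms[i] for i in idx]
        features = np.array([extract_features(p) for p in sub])
        raw = np.array([p.fine_score for p in sub])
        err = np.array([p.precursor_err_ppm for p in sub])
        # re-ranking is always trained per separate FDR group
        scores, _model = rerank_group(features, raw, comps[idx], err)
        qvals = compute_group_fdr(scores, list(comps[idx]))
        for j, i in enumerate(idx):
            out[i] = RescoredPSM(psm=psms[i], composition=comps[i],
                                 svm_score=float(scores[j]), q_value=float(qvals[j]))
    return [r for r in out if r is not None]


def filter_results(rescored: list[RescoredPSM], fdr_threshold: float = 0.05,
                   keep_decoys: bool = False) -> list[RescoredPSM]:
    """PSMs passing the group q-value threshold; decoy-containing PSMs are
    dropped from the final report unless ``keep_decoys``."""
    if not 0 < fdr_threshold <= 1:
        raise ValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    kept = [r for r in rescored if r.q_value <= fdr_threshold]
    if not keep_decoys:
        kept = [r for r in kept if r.composition == "TT"]
    return kept


def results_table(rescored: list[RescoredPSM]) -> pd.DataFrame:
    """Flat report: one row per PSM. Link sites are 1-based peptide positions."""
    rows = []
    for r in rescored:
        p = r.psm
        rows.append({
            "spectrum": p.spectrum_id,
            "kind": p.kind,
            "group": p.group,
            "alpha_seq": p.alpha.sequence,
            "alpha_site": p.alpha_site + 1 if p.alpha_site is not None else "",
            "alpha_mods": _fmt_mods(p.alpha.site_mods),
            "beta_seq": p.beta.sequence if p.beta else "",
            "beta_site": p.beta_site + 1 if p.beta_site is not None else "",
            "beta_mods": _fmt_mods(p.beta.site_mods) if p.beta else "",
            "loop_site2": p.loop_site2 + 1 if p.loop_site2 is not None else "",
            "proteins": ";".join(sorted(p.alpha_proteins | p.beta_proteins)),
            "precursor_err_ppm": round(p.precursor_err_ppm, 4),
            "fine_score": round(p.fine_score, 6),
            "svm_score": round(r.svm_score, 6),
            "q_value": round(r.q_value, 6),
            "composition": r.composition,
        })
    return pd.DataFrame(rows, columns=[
        "spectrum", "kind", "group", "alpha_seq", "alpha_site", "alpha_mods",
        "beta_seq", "beta_site", "beta_mods", "loop_site2", "proteins",
        "precursor_err_ppm", "fine_score", "svm_score", "q_value", "composition",
    ])


def _fmt_mods(site_mods) -> str:
    return ",".join(f"{pos + 1}:{delta:+.6f}" for pos, delta in site_mods)


def peptide_pair_rollup(table: pd.DataFrame) -> pd.DataFrame:
    """Best PSM per (unordered) peptide pair."""
    t = table.copy()
    t["pair"] = [
        "--".join(sorted([f"{a}({sa})", f"{b}({sb})"])) if b else f"{a}({sa})"
        for a, sa, b, sb in zip(t.alpha_seq, t.alpha_site, t.beta_seq, t.beta_site)
    ]
    return (t.sort_values("svm_score", ascending=False)
             .drop_duplicates("pair").reset_index(drop=True))


def residue_pair_rollup(table: pd.DataFrame) -> pd.DataFrame:
    """Best PSM per cross-linked residue pair (protein + position agnostic to
    alpha/beta order); cross PSMs only."""
    t = table[table.kind == "cross"].copy()
    if t.empty:
        return t
    t["residue_pair"] = [
        "--".join(sorted([f"{pa}:{a}{sa}", f"{pb}:{b}{sb}"]))
        for pa, a, sa, pb, b, sb in zip(
            t.proteins, t.alpha_seq, t.alpha_site, t.proteins, t.beta_seq, t.beta_site)
    ]
    return (t.sort_values("svm_score", ascending=False)
             .drop_duplicates("residue_pair").reset_index(drop=True))
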