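"""Two-stage open search for cross-linked peptide pairs.

For each MS2 spectrum:

1. every peak is converted to four possible neutral fragment masses (regular
   b, regular y, xlink b, xlink y) that serve as query keys into the fragment
   index;
2. candidate alpha peptides are retrieved by matched fragment ion count (MIC),
   MIC = 1 candidates dropped, candidates heavier than the precursor dropped,
   and a dynamic top-5 list kept under coarse scoring;
3. for each alpha candidate, the open mass (precursor minus alpha minus
   linker) retrieves beta candidates from the intact-mass peptide index;
4. alpha/beta pairs -- and the competing loop-linked, mono-linked, and regular
   single-peptide hypotheses -- are fine-scored and the best candidate per
   spectrum is reported.

Mass conventions: the precursor mass ``M`` of a spectrum is its *neutral*
monoisotopic mass. With a singly charged peak of m/z ``m``, the four query
keys are

    m_b  = m - m_H+                       (regular b)
    m_y  = m - m_H+ - m_H2O               (regular y)
    m_b~ = M - m_H2O - m + m_H+           (xlink b; complement is a regular y)
    m_y~ = M - m + m_H+                   (xlink y; complement is a regular b)

so that m_b + m_b~ = m_y + m_y~ = M - m_H2O. The fragment index stores y
masses *with* water; y-type keys (m_y, m_b~) are therefore offset by +m_H2O at
lookup time, which makes the two conventions identical.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chemistry import PROTON, WATER, LinkerSpec
from .indexer import ION_B, MassIndex, decode_tetrad
from .sequence_db import ModifiedPeptide, Peptide, PeptideDatabase, residue_masses

GROUPS = ("intra", "inter", "loop", "mono", "regular")


@dataclass
class Spectrum:
    """A centroided MS2 spectrum with its neutral precursor mass."""

    title: str
    precursor_mass: float          # neutral monoisotopic, Da
    precursor_charge: int
    mz: np.ndarray                 # sorted ascending
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.precursor_mass <= 0:
            raise ValueError(f"spectrum {self.title!r}: non-positive precursor mass")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.title!r}: negative intensity")


@dataclass(frozen=True)
class QueryKeySet:
    """Per-peak query masses per the four ion-type interpretations."""

    m_b: np.ndarray
    m_y: np.ndarray
    m_bx: np.ndarray
    m_yx: np.ndarray
    peak_index_b: np.ndarray
    peak_index_y: np.ndarray
    peak_index_bx: np.ndarray
    peak_index_yx: np.ndarray


def generate_query_keys(spectrum: Spectrum) -> QueryKeySet:
    """Convert each peak to its four possible neutral fragment masses.

    Non-positive derived masses are dropped silently (with their peak index
    bookkeeping kept aligned).
    """
    m = spectrum.mz
    M = spectrum.precursor_mass
    idx = np.arange(len(m))
    out = {}
    for name, vals in (
        ("m_b", m - PROTON),
        ("m_y", m - PROTON - WATER),
        ("m_bx", M - WATER - m + PROTON),
        ("m_yx", M - m + PROTON),
    ):
        keep = vals > 0
        out[name] = vals[keep]
        out["peak_index_" + {"m_b": "b", "m_y": "y", "m_bx": "bx", "m_yx": "yx"}[name]] = idx[keep]
    return QueryKeySet(**out)


@dataclass(frozen=True)
class SiteLink:
    """A link-site assignment: 0-based residue positions within the peptide."""

    alpha_site: int
    beta_site: int | None = None


@dataclass
class CandidatePSM:
    """A spectrum matched to one identification hypothesis."""

    spectrum_id: str
    kind: str                           # cross | loop | mono | regular
    group: str                          # intra | inter | loop | mono | regular
    alpha: ModifiedPeptide
    alpha_site: int | None
    beta: ModifiedPeptide | None = None
    beta_site: int | None = None
    loop_site2: int | None = None       # second site for loop links
    coarse_score: float = 0.0
    fine_score: float = 0.0
    runner_up_score: float = 0.0
    alpha_proteins: frozenset[str] = frozenset()
    beta_proteins: frozenset[str] = frozenset()
    alpha_is_decoy: bool = False
    beta_is_decoy: bool = False
    precursor_err_ppm: float = 0.0
    precursor_mass: float = 0.0
    total_intensity: float = 0.0
    alpha_matched_intensity: float = 0.0
    beta_matched_intensity: float = 0.0
    alpha_tag: int = 0
    beta_tag: int = 0


def _sorted_query_arrays(keys: QueryKeySet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(b-series query masses, peak idx) and (y-series query masses, peak idx),
    each sorted by mass. y-type keys are shifted to the stored with-water
    convention here."""
    qb = np.concatenate([keys.m_b, keys.m_yx])
    pb = np.concatenate([keys.peak_index_b, keys.peak_index_yx])
    qy = np.concatenate([keys.m_y + WATER, keys.m_bx + WATER])
    py = np.concatenate([keys.peak_index_y, keys.peak_index_bx])
    ob, oy = np.argsort(qb), np.argsort(qy)
    return qb[ob], pb[ob], qy[oy], py[oy]


def _match_sorted(theoretical: np.ndarray, query: np.ndarray, peaks: np.ndarray,
                  tol_ppm: float) -> tuple[np.ndarray, np.ndarray]:
    """For each theoretical mass, whether any sorted query mass falls within
    tol_ppm; returns (matched mask over theoretical, set of matched peak indices)."""
    if len(query) == 0 or len(theoretical) == 0:
        return np.zeros(len(theoretical), bool), np.empty(0, np.intp)
    delta = np.abs(theoretical) * tol_ppm * 1e-6
    lo = np.searchsorted(query, theoretical - delta, side="left")
    hi = np.searchsorted(query, theoretical + delta, side="right")
    matched = hi > lo
    if not matched.any():
        return matched, np.empty(0, np.intp)
    hit_peaks = np.concatenate([peaks[a:b] for a, b in zip(lo[matched], hi[matched])])
    return matched, np.unique(hit_peaks)


class SpectrumSearcher:
    """Per-spectrum search against prebuilt fragment/peptide indexes."""

    def __init__(self, db: PeptideDatabase, frag_index: MassIndex,
                 pep_index: MassIndex, linker: LinkerSpec,
                 frag_tol_ppm: float = 20.0, prec_tol_ppm: float = 20.0,
                 top_k: int = 5):
        self.db = db
        self.frag_index = frag_index
        self.pep_index = pep_index
        self.linker = linker
        self.frag_tol_ppm = frag_tol_ppm
        self.prec_tol_ppm = prec_tol_ppm
        self.top_k = top_k

    # -- candidate materialization ------------------------------------------------

    def _materialize(self, code: int) -> ModifiedPeptide:
        """Decode a tetrad code back to a ModifiedPeptide via the database."""
        _, lfield, p, m = decode_tetrad(code)
        length = lfield + 1
        seq = self.db.sequence_at(p, length)
        site_mods = self.db.mod_forms[seq][m]
        from .sequence_db import peptide_mass
        pep = Peptide(sequence=seq, start_position=p,
                      protein_ids=tuple(sorted(self.db.seq_proteins[seq])),
                      missed_cleavages=0,
                      is_decoy=self._is_decoy(seq))
        return ModifiedPeptide(peptide=pep, modification_id=m, site_mods=site_mods,
                               mono_mass=peptide_mass(seq, dict(site_mods)))

    def _is_decoy(self, seq: str) -> bool:
        from .sequence_db import DECOY_PREFIX
        return all(pid.startswith(DECOY_PREFIX) for pid in self.db.seq_proteins[seq])

    def _base_proteins(self, seq: str) -> frozenset[str]:
        from .sequence_db import DECOY_PREFIX
        return frozenset(pid[len(DECOY_PREFIX):] if pid.startswith(DECOY_PREFIX) else pid
                         for pid in self.db.seq_proteins[seq])

    # -- stage 1: alpha retrieval -------------------------------------------------

    def retrieve_alpha_candidates(self, spectrum: Spectrum
                                  ) -> list[tuple[ModifiedPeptide, float, int]]:
        """Top-k alpha candidates as (peptide form, coarse score, MIC).

        MIC counts distinct peaks with at least one matching interpretation.
        Candidates with MIC = 1 and candidates heavier than the precursor are
        removed. Coarse scoring walks candidates in MIC-descending order and
        stops once the next MIC falls below the least MIC in the full top-k
        list. For each sequence only the top-scored modified form is kept.
        """
        if len(spectrum.mz) == 0:
            return []
        keys = generate_query_keys(spectrum)
        qb, pb, qy, py = _sorted_query_arrays(keys)

        # retrieve (code, peak) matches from both series, series-filtered on the
        # ion-type bit
        code_chunks, peak_chunks = [], []
        for qm, pk, want_b in ((qb, pb, True), (qy, py, False)):
            if len(qm) == 0:
                continue
            codes, qidx = self.frag_index.query_many(qm, self.frag_tol_ppm)
            if len(codes) == 0:
                continue
            is_b = (codes >> np.uint64(63)).astype(bool)
            keep = is_b if want_b else ~is_b
            code_chunks.append(codes[keep])
            peak_chunks.append(pk[qidx[keep]])
        if not code_chunks:
            return []
        codes = np.concatenate(code_chunks)
        peaks = np.concatenate(peak_chunks)

        # MIC per candidate: distinct peaks matched
        pair = np.unique(np.stack([codes, peaks.astype(np.uint64)], axis=1), axis=0)
        cand_codes, mic = np.unique(pair[:, 0], return_counts=True)
        keep = mic >= 2
        cand_codes, mic = cand_codes[keep], mic[keep]
        if len(cand_codes) == 0:
            return []

        # walk candidates MIC-descending; decode lazily, dedup by (sequence,
        # mod id), drop heavier-than-precursor, and keep a dynamic top-k under
        # coarse scoring with the MIC prune
        order = np.argsort(-mic, kind="stable")
        seen: set[tuple[str, int]] = set()
        limit = spectrum.precursor_mass * (1 + self.prec_tol_ppm * 1e-6)
        top: list[tuple[float, int, ModifiedPeptide]] = []   # (score, mic, form)
        for code, count in zip(cand_codes[order], mic[order]):
            count = int(count)
            if len(top) >= self.top_k and count < min(t[1] for t in top):
                break
            _, lfield, p, m = decode_tetrad(int(code))
            seq = self.db.sequence_at(int(p), lfield + 1)
            if (seq, m) in seen:
                continue
            seen.add((seq, m))
            mp = self._materialize(int(code))
            if mp.mono_mass > limit:
                continue
            score = self.coarse_score(mp, qb, pb, qy, py, spectrum)
            top.append((score, count, mp))
            top.sort(key=lambda t: (-t[0], -t[1], t[2].sequence, t[2].peptide.start_position))
            # keep only the best form per sequence
            dedup, kept = [], set()
            for item in top:
                if item[2].sequence not in kept:
                    dedup.append(item)
                    kept.add(item[2].sequence)
            top = dedup[: self.top_k]
        return [(mp, score, count) for score, count, mp in top]

    def coarse_score(self, mp: ModifiedPeptide, qb, pb, qy, py,
                     spectrum: Spectrum) -> float:
        """Fraction of the candidate's b/y fragments matched among the query
        keys, plus the fraction of total spectrum intensity carried by matched
        peaks. Range [0, 2]; monotone in the matched-peak set."""
        from .indexer import fragment_masses
        b, y = fragment_masses(mp)
        mb, peaks_b = _match_sorted(b, qb, pb, self.frag_tol_ppm)
        my, peaks_y = _match_sorted(y, qy, py, self.frag_tol_ppm)
        nfrag = len(b) + len(y)
        frac_frag = (mb.sum() + my.sum()) / nfrag if nfrag else 0.0
        total = spectrum.intensity.sum()
        hit = np.union1d(peaks_b, peaks_y)
        frac_int = spectrum.intensity[hit].sum() / total if total > 0 else 0.0
        return float(frac_frag + frac_int)

    # -- stage 2: beta retrieval --------------------------------------------------

    def retrieve_beta_candidates(self, alpha: ModifiedPeptide, spectrum: Spectrum
                                 ) -> list[ModifiedPeptide]:
        """Peptide-index lookup at the open mass, restricted to peptides
        bearing a linkable residue for the linker's beta end."""
        open_mass = spectrum.precursor_mass - alpha.mono_mass - self.linker.xl_mass
        if open_mass <= 0:
            return []
        # the open-mass uncertainty is the precursor tolerance in absolute Da
        # (open = M - m_alpha - xl inherits M's error), so widen the ppm window
        # by M / open_mass
        eff_ppm = self.prec_tol_ppm * spectrum.precursor_mass / open_mass
        codes = self.pep_index.query(open_mass, eff_ppm)
        out, seen = [], set()
        for code in codes:
            _, lfield, p, m = decode_tetrad(int(code))
            seq = self.db.sequence_at(int(p), lfield + 1)
            if (seq, m) in seen:
                continue
            seen.add((seq, m))
            if not set(seq) & self.linker.site_beta:
                continue
            out.append(self._materialize(int(code)))
        out.sort(key=lambda mp: (mp.sequence, mp.modification_id))
        return out

    # -- fine scoring -------------------------------------------------------------

    def link_sites(self, mp: ModifiedPeptide, residues: frozenset[str]) -> list[int]:
        sites = [i for i, aa in enumerate(mp.sequence) if aa in residues]
        if self.linker.protein_nterm and mp.peptide.start_position == 0 and 0 not in sites:
            sites.insert(0, 0)
        return sites

    def search_spectrum(self, spectrum: Spectrum) -> CandidatePSM | None:
        """Evaluate cross, loop, mono, and regular hypotheses; return the single
        best fine-scored candidate (None if the spectrum is unidentified)."""
        alphas = self.retrieve_alpha_candidates(spectrum)
        if not alphas:
            return None
        M = spectrum.precursor_mass
        tol = M * self.prec_tol_ppm * 1e-6
        scorer = FineScorer(spectrum, self.frag_tol_ppm)
        results: list[CandidatePSM] = []

        seen_pairs: set[tuple] = set()
        for alpha, coarse, _mic in alphas:
            # regular hypothesis
            if abs(alpha.mono_mass - M) <= tol:
                sc, detail = scorer.score_single(alpha, shift=0.0, sites=())
                results.append(self._make_psm(spectrum, "regular", alpha, None, None,
                                              None, None, coarse, sc, detail))
            # mono-linked hypothesis
            if self.linker.mono_mass_delta > 0 and \
                    abs(alpha.mono_mass + self.linker.mono_mass_delta - M) <= tol:
                best = None
                for s in self.link_sites(alpha, self.linker.site_alpha):
                    sc, detail = scorer.score_single(alpha, shift=self.linker.mono_mass_delta,
                                                     sites=(s,))
                    if best is None or sc > best[0]:
                        best = (sc, s, detail)
                if best:
                    results.append(self._make_psm(spectrum, "mono", alpha, best[1], None,
                                                  None, None, coarse, best[0], best[2]))
            # loop-linked hypothesis
            if abs(alpha.mono_mass + self.linker.xl_mass - M) <= tol:
                sites = self.link_sites(alpha, self.linker.site_alpha)
                bsites = self.link_sites(alpha, self.linker.site_beta)
                best = None
                for s1 in sites:
                    for s2 in bsites:
                        if s2 <= s1:
                            continue
                        sc, detail = scorer.score_loop(alpha, self.linker.xl_mass, s1, s2)
                        if best is None or sc > best[0]:
                            best = (sc, s1, s2, detail)
                if best:
                    results.append(self._make_psm(spectrum, "loop", alpha, best[1], None,
                                                  None, best[2], coarse, best[0], best[3]))
            # cross-linked hypothesis (two-stage)
            asites = self.link_sites(alpha, self.linker.site_alpha)
            if not asites:
                continue
            for beta in self.retrieve_beta_candidates(alpha, spectrum):
                key = tuple(sorted([(alpha.sequence, alpha.modification_id),
                                    (beta.sequence, beta.modification_id)]))
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                best = None
                for sa in asites:
                    for sb in self.link_sites(beta, self.linker.site_beta):
                        sc, detail = scorer.score_pair(alpha, beta, sa, sb, self.linker.xl_mass)
                        if best is None or sc > best[0]:
                            best = (sc, sa, sb, detail)
                if best:
                    results.append(self._make_psm(spectrum, "cross", alpha, best[1], beta,
                                                  best[2], None, coarse, best[0], best[3]))
        if not results:
            return None
        results.sort(key=_psm_order)
        best = results[0]
        if len(results) > 1:
            best.runner_up_score = results[1].fine_score
        return best

    def _make_psm(self, spectrum: Spectrum, kind: str, alpha: ModifiedPeptide,
                  alpha_site, beta, beta_site, loop_site2, coarse: float,
                  fine: float, detail: dict) -> CandidatePSM:
        alpha_prot = self._base_proteins(alpha.sequence)
        if kind == "cross":
            beta_prot = self._base_proteins(beta.sequence)
            group = "intra" if alpha_prot & beta_prot else "inter"
            theo = alpha.mono_mass + beta.mono_mass + self.linker.xl_mass
        else:
            beta_prot = frozenset()
            group = kind
            theo = alpha.mono_mass + {"loop": self.linker.xl_mass,
                                      "mono": self.linker.mono_mass_delta,
                                      "regular": 0.0}[kind]
        err_ppm = (spectrum.precursor_mass - theo) / theo * 1e6
        return CandidatePSM(
            spectrum_id=spectrum.title, kind=kind, group=group,
            alpha=alpha, alpha_site=alpha_site, beta=beta, beta_site=beta_site,
            loop_site2=loop_site2, coarse_score=coarse, fine_score=fine,
            alpha_proteins=alpha_prot, beta_proteins=beta_prot,
            alpha_is_decoy=alpha.peptide.is_decoy,
            beta_is_decoy=beta.peptide.is_decoy if beta is not None else False,
            precursor_err_ppm=float(err_ppm), precursor_mass=spectrum.precursor_mass,
            total_intensity=float(spectrum.intensity.sum()),
            alpha_matched_intensity=detail["alpha_intensity"],
            beta_matched_intensity=detail.get("beta_intensity", 0.0),
            alpha_tag=detail["alpha_tag"], beta_tag=detail.get("beta_tag", 0),
        )


def _psm_order(psm: CandidatePSM):
    """Deterministic best-first ordering: fine score desc, then lexicographic."""
    beta_seq = psm.beta.sequence if psm.beta is not None else ""
    return (-psm.fine_score, psm.kind, psm.alpha.sequence, beta_seq,
            psm.alpha.peptide.start_position,
            psm.alpha_site if psm.alpha_site is not None else -1,
            psm.beta_site if psm.beta_site is not None else -1)


def peptide_ion_masses(mp: ModifiedPeptide, shift: float, sites: tuple[int, ...],
                       loop: tuple[int, int] | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Theoretical b/y neutral masses of one peptide under a link hypothesis.

    ``shift`` is added to fragments containing all positions in ``sites``
    (cross/mono: one site; the shift is linker + partner mass for cross).
    For a loop link, fragments containing exactly one of the two sites are
    unobservable and excluded. Returns (b masses, b indices, y masses, y idx);
    indices are 1-based fragment numbers.
    """
    r = np.array(residue_masses(mp.sequence, mp.site_mod_dict()))
    L = len(r)
    prefix = np.cumsum(r)
    b = prefix[:-1].copy()
    y = (prefix[-1] - prefix[:-1] + WATER)[::-1].copy()
    bi = np.arange(1, L)
    yi = np.arange(1, L)
    if loop is not None:
        s1, s2 = loop
        # b_i covers residues [0, i); y_j covers [L-j, L)
        b_in1, b_in2 = bi > s1, bi > s2
        y_in1, y_in2 = yi >= L - s1, yi >= L - s2
        b_keep = ~(b_in1 ^ b_in2)
        y_keep = ~(y_in1 ^ y_in2)
        b[b_in1 & b_in2] += shift
        y[y_in1 & y_in2] += shift
        return b[b_keep], bi[b_keep], y[y_keep], yi[y_keep]
    for s in sites:
        b[bi > s] += shift
        y[yi >= L - s] += shift
    return b, bi, y, yi


class FineScorer:
    """Gaussian-ppm-weighted matched-intensity score against one spectrum.

    score = sum over matched peaks of (I_peak / total I) * exp(-(ppm err)^2 /
    (2 sigma^2)), sigma = tol_ppm / 2; each peak contributes once, at its best
    (smallest |ppm|) theoretical match. Symmetric in alpha/beta by
    construction.
    """

    def __init__(self, spectrum: Spectrum, tol_ppm: float):
        self.spectrum = spectrum
        self.tol_ppm = tol_ppm
        self.sigma = tol_ppm / 2.0
        self.total = float(spectrum.intensity.sum())

    def _match(self, theoretical_mz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(peak index, ppm error) of the best peak match for each theoretical
        m/z that matches anything."""
        mz = self.spectrum.mz
        t = theoretical_mz
        if len(mz) == 0 or len(t) == 0:
            return np.empty(0, np.intp), np.empty(0)
        delta = t * self.tol_ppm * 1e-6
        lo = np.searchsorted(mz, t - delta, side="left")
        hi = np.searchsorted(mz, t + delta, side="right")
        idx, errs = [], []
        for k in range(len(t)):
            if hi[k] <= lo[k]:
                continue
            window = mz[lo[k]:hi[k]]
            ppm = (window - t[k]) / t[k] * 1e6
            j = int(np.argmin(np.abs(ppm)))
            idx.append(lo[k] + j)
            errs.append(ppm[j])
        return np.array(idx, np.intp), np.array(errs)

    def _score_ions(self, ions: list[tuple[np.ndarray, np.ndarray]]
                    ) -> tuple[float, list[dict]]:
        """Score a set of per-peptide ion ladders; peaks deduplicated across
        all ladders (best |ppm| wins). Returns (score, per-peptide detail)."""
        per_peak: dict[int, float] = {}
        owner: dict[int, int] = {}
        matched_sets: list[set[int]] = []
        tags: list[int] = []
        for pi, (b_mz, y_mz) in enumerate(ions):
            mset: set[int] = set()
            runs = []
            for series in (b_mz, y_mz):
                pidx, errs = self._match(series + PROTON)
                hitmask = np.zeros(len(series), bool)
                # recover which theoretical ions matched for tag computation
                delta = (series + PROTON) * self.tol_ppm * 1e-6
                lo = np.searchsorted(self.spectrum.mz, series + PROTON - delta, "left")
                hi = np.searchsorted(self.spectrum.mz, series + PROTON + delta, "right")
                hitmask = hi > lo
                runs.append(_longest_run(hitmask))
                for p, e in zip(pidx, errs):
                    p = int(p)
                    mset.add(p)
                    if p not in per_peak or abs(e) < abs(per_peak[p]):
                        per_peak[p] = float(e)
                        owner[p] = pi
            matched_sets.append(mset)
            tags.append(max(runs) if runs else 0)
        if self.total <= 0:
            return 0.0, [{"intensity": 0.0, "tag": t} for t in tags]
        score = 0.0
        intensity = [0.0] * len(ions)
        for p, e in per_peak.items():
            w = self.spectrum.intensity[p] / self.total
            score += w * math.exp(-(e * e) / (2 * self.sigma ** 2))
        for pi, mset in enumerate(matched_sets):
            intensity[pi] = float(self.spectrum.intensity[sorted(mset)].sum())
        return score, [{"intensity": intensity[i], "tag": tags[i]} for i in range(len(ions))]

    def score_single(self, mp: ModifiedPeptide, shift: float, sites: tuple[int, ...]
                     ) -> tuple[float, dict]:
        b, _, y, _ = peptide_ion_masses(mp, shift, sites)
        score, det = self._score_ions([(b, y)])
        return score, {"alpha_intensity": det[0]["intensity"], "alpha_tag": det[0]["tag"]}

    def score_loop(self, mp: ModifiedPeptide, xl_mass: float, s1: int, s2: int
                   ) -> tuple[float, dict]:
        b, _, y, _ = peptide_ion_masses(mp, xl_mass, (), loop=(s1, s2))
        score, det = self._score_ions([(b, y)])
        return score, {"alpha_intensity": det[0]["intensity"], "alpha_tag": det[0]["tag"]}

    def score_pair(self, alpha: ModifiedPeptide, beta: ModifiedPeptide,
                   alpha_site: int, beta_site: int, xl_mass: float
                   ) -> tuple[float, dict]:
        shift_a = xl_mass + beta.mono_mass
        shift_b = xl_mass + alpha.mono_mass
        ab, _, ay, _ = peptide_ion_masses(alpha, shift_a, (alpha_site,))
        bb, _, by, _ = peptide_ion_masses(beta, shift_b, (beta_site,))
        score, det = self._score_ions([(ab, ay), (bb, by)])
        return score, {
            "alpha_intensity": det[0]["intensity"], "alpha_tag": det[0]["tag"],
            "beta_intensity": det[1]["intensity"], "beta_tag": det[1]["tag"],
        }


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for hit in mask:
        run = run + 1 if hit else 0
        best = max(best, run)
    return best


def search_all(spectra: list[Spectrum], searcher: SpectrumSearcher,
               progress: bool = False) -> list[CandidatePSM | None]:
    """Search every spectrum; unidentified spectra yield None records."""
    it = spectra
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(spectra, desc="searching")
        except ImportError:
            pass
    return [searcher.search_spectrum(s) for s in it]
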