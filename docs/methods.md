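# Methods

## Problem and approach

Cross-linking mass spectrometry (CXMS) identifies pairs of peptides joined by
a bifunctional reagent (e.g. BS3 on lysines) or a native disulfide bond. The
combinatorial difficulty is that a cross-linked MS2 spectrum is explained by a
*pair* of peptides plus a linker: an exhaustive search over a database of N
peptides scores O(N²) pairs per spectrum. `xlopen` implements a two-stage
open search that avoids the quadratic enumeration:

1. **Alpha-peptide retrieval.** Of the two linked peptides, one (the alpha
   peptide) usually fragments well. Each spectrum peak of m/z `m` is converted
   to four possible neutral fragment masses — regular b, regular y, xlink b,
   xlink y:

       m_b  = m − m_H+
       m_y  = m − m_H+ − m_H2O
       m_b̃ = M − m_H2O − m + m_H+
       m_ỹ = M − m + m_H+

   where `M` is the neutral precursor mass. The xlink interpretations exploit
   complementarity: if a peak is an xlink b ion of the alpha peptide (it
   carries the intact beta peptide through the linker), its complementary
   regular y ion mass is determined by `M` alone, without knowing the beta
   peptide — that is what makes the search "open". The identity
   `m_b + m_b̃ = m_y + m_ỹ = M − m_H2O` holds exactly and is enforced by a
   property test. These keys query a fragment-ion inverted index; candidates
   are ranked by matched fragment ion count (MIC), candidates with MIC = 1 or
   mass above the precursor are dropped, and a dynamic top-5 list is kept
   under coarse scoring. Coarse scoring of a candidate stops the scan once the
   next candidate's MIC falls below the least MIC in the full list.

2. **Beta-peptide retrieval.** For each retained alpha candidate the open
   mass `M − m_alpha − m_linker` queries an intact-mass peptide index; every
   returned peptide with a linkable residue is paired with the alpha
   candidate, all site pairs are fine-scored, and the best-scoring hypothesis
   per spectrum — cross-linked, loop-linked, mono-linked, or regular — is
   reported.

Identified PSMs are re-ranked per group (intra-protein, inter-protein, loop,
mono, regular) by an iterative semi-supervised linear SVM and filtered by
cross-link-aware target-decoy FDR.

## Index encoding

Each index entry packs (ion type t, peptide length l, start position p,
modification id m) into a 64-bit integer with 1/7/46/10 bits. The 7-bit
length field stores `length − 1`, so lengths 1–128 are encodable; the 46-bit
start position addresses 2^46 residues (64 TB of concatenated database); the
10-bit modification id caps enumeration at 1024 modified forms per peptide
sequence (forms with fewer variable modifications are enumerated, and hence
retained, first). Index keys are `round(mass × 1000)` (half away from zero);
queries scan the integer key range widened by 1 mDa per side and then
re-filter on the stored real-valued mass, so ppm windows are exact despite
integerization.

One convention needs care: the index stores y-fragment neutral masses *with*
water (the usual y-ion convention), whereas the query-key equations above
produce y-type keys *without* water. The two are reconciled at lookup time by
offsetting y-type keys (`m_y`, `m_b̃`) by +m_H2O before querying the y
series; the formulations are then algebraically identical, and both the
stated key values and the with-water index keys are preserved.

## Scoring

The coarse score of a single candidate is the fraction of its b/y fragments
matched among the query keys plus the fraction of total spectrum intensity
carried by matched peaks (range [0, 2], monotone in the matched-peak set).
The fine score of an assembled hypothesis builds the full theoretical
spectrum — regular b/y ions plus linker-shifted ions of both peptides given
the link sites (for a cross link, fragments of one peptide that span its link
site are shifted by the linker mass plus the intact partner mass) — and sums,
over matched peaks, relative intensity weighted by a Gaussian in the ppm
error (sigma = half the fragment tolerance), each peak counted once at its
best match. Both scores are deterministic surrogates for the original
pre-scoring/KSDP formulations, whose exact formulas are not public; they fill
the same ranking role but are not bit-compatible with any other engine.
For loop-linked peptides, fragments containing exactly one of the two linked
sites are unobservable and are excluded from the theoretical spectrum.

## Tolerances and mass windows

Precursor and fragment tolerances default to ±20 ppm. The beta-retrieval
window is the precursor tolerance in *absolute* daltons: the open mass
`M − m_alpha − m_linker` inherits the absolute error of `M`, so a ppm window
on the (often much smaller) open mass itself would lose true beta peptides;
the ppm window is therefore widened by `M / open_mass`. All match windows are
closed intervals.

## Re-ranking and FDR

Nine features are extracted per PSM: the fine score, alpha/beta matched
intensity ratios, alpha/beta tag ratios (longest consecutive matched fragment
run over peptide length), shorter-peptide length, score gap to the
spectrum's runner-up, modified-residue ratio, and a precursor-error frequency
feature. Beta features are zero for single-peptide PSMs. The precursor-error
feature is *dynamic*: it is recomputed each iteration as the frequency of the
PSM's signed ppm-error bin (2-ppm bins) among the current positive training
set; the other eight are static.

Training follows the Percolator scheme: positives are target-target PSMs at
≤1% group FDR (raw fine score in iteration 1, SVM score after), negatives are
all PSMs containing a decoy peptide. The classifier is an L2-regularized,
L2-loss linear SVM (C = 1, balanced class weights, termination tolerance
1e-4), with probabilities via logistic calibration of the decision values;
the calibrated output is the probability of a PSM being a random match
(≤ 0.5 ⇒ classified positive) and `1 − P` is reported so that higher is
better. At most 5 iterations are run, stopping early when the positive set
stops changing; groups with under 50 PSMs keep the raw ranking, and if
re-ranking yields fewer 1%-FDR positives than the raw score, it is rolled
back. Features are standardized to zero mean/unit variance before fitting;
the solver is deterministic, so no random seed is involved.

FDR at a score cutoff is `max(0, (N_TD − N_DD) / N_TT)` over the
target-target / target-decoy / decoy-decoy composition counts at or above
the cutoff (clamped at zero when decoy-decoy counts exceed target-decoy, and
1 when N_TT = 0); q-values are the running minimum from the lowest score
upward, with tied scores sharing one cutoff. Intra- and inter-protein cross
PSMs are controlled separately by default (`global` pools them); decoys are
mapped to their base protein for intra/inter grouping, so a target/decoy
pair of the same protein counts as an intra-group TD PSM. Loop, mono, and
regular PSMs always form their own groups.

## Decoys and digestion

Decoys are full protein reversals, one per target, identifier-prefixed
`REV_`. Digestion is fully specific (trypsin: after K/R, not before P), up to
2 missed cleavages, peptide length 4–100 by default; I and L are distinct
residues. Fixed modifications apply unconditionally; variable modifications
are enumerated over eligible-site subsets up to `max_var` (default 3).
Residue masses are the standard monoisotopic table; water 18.010565 Da,
proton 1.007276 Da. Shipped linkers: BS3 (cross +138.068074 Da on K or the
protein N-terminus; mono-link +156.078644 Da) and disulfide
(−2.015650 Da on C, no mono form). These are standard chemistry, overridable
in configuration.

## Synthetic data

The simulator emits idealized, fully annotated spectra: complete
singly-charged b/y ladders (regular plus linker-shifted ions) at exact
theoretical m/z, log-normal(0, 0.5) intensities, a dropout fraction of ladder
peaks removed (default 0.05), uniform random noise peaks added (default 5 per
spectrum), and Gaussian precursor jitter (default sd 5 ppm — typical of
calibrated high-resolution instruments). The default BS3 profile is 2,500
spectra each of cross-, loop-, mono-linked, and regular peptides (10,000
total); the disulfide profile has no mono-linked spectra (2,500/2,500/0/5,000),
since a hydrolyzed "dead-end" disulfide does not exist. Loop links spanning
an entire peptide (first to last residue) leave no observable fragment and
are never emitted. Protein sequences for self-contained runs are synthesized
i.i.d. from approximate proteome residue frequencies.

What the simulator does **not** emulate: learned fragmentation intensity
patterns, multiply charged fragments, isotope envelopes, co-isolated
chimeric precursors, or unidentifiable background spectra. Passing the
simulated benchmark therefore demonstrates correctness of the search,
pairing, re-ranking, and FDR machinery under ideal conditions, not
real-data sensitivity.

## Problem sizes and numerical choices

The packaged benchmark simulates 1,000 cross-linked plus 1,000 regular
spectra from 100 digested synthetic proteins and runs the full
index → search → rescore pipeline at 5% separate FDR; it completes in about
half a minute on one CPU. Ties in the top-5 coarse list break by higher MIC,
then lexicographic sequence, then lower start position; per-spectrum best
candidates break ties lexicographically, so identical inputs give identical
outputs. Unidentified spectra are reported as absent rows rather than
dropped, keeping identification rates computable.

## Known limitations

- Fully specific digestion only; no semi-tryptic or nonspecific search.
- Fragments are matched singly charged; no MS-cleavable linker logic.
- No protein-level FDR or protein inference.
- The coarse/fine scores are this package's own formulations; score values
  are not comparable across engines.
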