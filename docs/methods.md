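# Methods

## Scope and model

`etdscore` implements a likelihood-ratio score for peptide-spectrum
matching on ETD MS/MS data. The score treats the match events of
individual fragment ions as independent, so the log likelihood-ratio of
a peptide is the sum of per-ion contributions f_{i,j}(x_{i,j}), where
x_{i,j} is the *significance level* of the peak matched by the j-th ion
of type t_i and f_{i,j} is a trained, piecewise-linear approximation of
the log likelihood ratio between "this peak is a t_i match" and "this
peak is a random match". The independence assumption is knowingly
approximate — ions from the same cleavage site are correlated — but
dependence modelling (e.g. a Bayesian network) needs far more training
data than the ~10³ ions per type this design targets.

## Chemistry

Monoisotopic masses throughout (proton 1.007276, H 1.007825, H₂O
18.010565, NH₃ 17.026549, CO 27.994915 Da); residue masses ship as a
plain-text table. Carbamidomethyl-C (+57.02146) is a fixed modification
on by default (iodoacetamide-alkylated tryptic digests); variable
modifications are unsupported. Twelve ion types are constructible —
z', c, y, z, b, a, z'²⁺, y−H₂O, c−H₂O, z'−NH₃, a−NH₃, b−H₂O — and eight
are scored (z excluded as nearly redundant with z'). z' is interpreted
as the z ion plus one hydrogen atom (z+1, the ETD radical species):
offset +1.007825 Da from z. Fragmentation sites are indexed 1..n−1 from
the N-terminus for both termini; the c/z' complementarity constant
therefore holds at equal site index.

## Significance level

Four features per peak, each ≥ 1 so all log terms are ≥ 0:

- adjusted global rank: (count of peaks ≥ current) / (precursor neutral
  mass / 112 Da), floored at 1. The floor is a deliberate choice: the
  strongest-peak-scores-zero convention would otherwise break for every
  peptide larger than one residue. The peptide-size estimate uses the
  precursor *neutral* mass, not m/z.
- local rank: same count restricted to ±57 Da (inclusive), 57 being the
  glycine residue mass rounded to an integer; configurable.
- global intensity ratio: reference/h clamped to [1, 10⁶]; the
  reference is the mean of the 3rd..10th highest intensities
  (choice "c"), which is robust to the one-or-two-outlier-peak spectra
  produced by hard-to-fragment peptides. With < 10 peaks the window
  truncates at the last peak; with < 3 peaks the lowest intensity is
  used. Choices "a" (highest) and "b" (second highest) exist only for
  training comparisons.
- local intensity ratio: max(1, min(window max, reference)/h), same cap.

Zero-intensity peaks get capped ratios (10⁶) rather than infinities.
The level is the coefficient-weighted sum of the four natural logs;
default coefficients (0.22, 0.40, 0.05, 0.33). Re-training fixes
c_rl = 1, enumerates the other three over {step, 2·step, …, 1},
maximizes the signal/decoy ROC AUC (Mann-Whitney midrank), breaks ties
toward the lexicographically smallest triple, and normalizes the winner
to sum 1. The full 0.01 grid is 10⁶ combinations; the AUC evaluation is
vectorized (ranking a levels matrix column-block-wise), but coarser
steps (0.1–0.2) give near-identical optima on synthetic data and are
used in the test suite for speed.

## Matching and decoys

A theoretical ion matches the nearest peak within the fragment
tolerance (default 0.8 Da, the original search setting); exact distance
ties go to the higher-intensity peak. One ion takes at most one peak,
but peaks may be shared between ions — no bipartite assignment, in
keeping with the independence assumption. Decoy observations are
uniform random m/z draws over each spectrum's observed m/z range, 10
per signal ion by default, matched by the same rule. One decoy pool is
drawn per training run and shared across ion types (every type has
exactly n−1 ions per peptide, so per-type pools would be identically
distributed).

## Training f(x)

Per ion type and position class (N1: site 1, N2: site 2, C1: site n−1,
C2: site n−2, MID otherwise; for n ≤ 5 a contested site goes to the
earliest of N1, C1, N2, C2): the m matched signal levels are sorted and
split into four intervals of ⌈m/4⌉ (first m mod 4 intervals) or ⌊m/4⌋
records; interval boundaries are midpoints between adjacent interval
extremes. With n total ions and D decoy draws,

    f(c_j) = ln[ (count_j / n) / (decoy_count_j / D) ],

where c_j is the mean signal level in interval j. Both hypotheses'
interval masses are normalized by their full totals (n and D), so each
measure's interval masses plus its miss mass sum to 1. The fifth knot
c₅ is the centroid of the weakest 10% of matched levels; beyond it a
match is treated as no more informative than a miss:

    f(c₅) = miss value = ln[ ((n−m)/n) / (decoy miss fraction) ].

This miss formula is the natural likelihood-ratio completion (the
source material leaves it implicit). Zero counts on either side get a
0.5 pseudocount to keep the logs finite; if ties make c₅ ≤ c₄ it is
nudged up by 1e−9 to keep knots strictly increasing. Between knots f is
linear; outside them it clamps to f(c₁)/f(c₅); a miss contributes the
miss value. Position classes with fewer than 40 matched records fall
back to the type's pooled all-positions function.

## Scoring

Spectra are preprocessed by removing precursor-derived peaks: every
charge state 1..z of the precursor plus H₂O/NH₃ neutral-loss
satellites, ±2 Da (the original filter's window is unrecorded; 2 Da per
charge state is conservative and configurable, and covering all charge
states subsumes the charge-reduced species ubiquitous in ETD). Scores
are plain natural-log likelihood ratios, unnormalized by peptide length
and without p-value calibration. Candidate ranking checks a 10 ppm
parent-mass gate; violators are reported via warnings and still scored.
Because all features are ranks and ratios, the score is exactly
invariant under uniform intensity scaling.

## Synthetic data

The generator emulates: per-site fragment peaks appearing independently
with each type's empirical frequency (z' 0.819 … b−H₂O 0.245); peptide
lengths uniform on 10..19 (mean 14.5, matching the real test set's
average of 14.4) with tryptic K/R termini; log-normal signal
intensities (σ = 0.7) whose median is 1000× the type frequency, so more
frequent types are also systematically stronger; noise peaks 3× the
signal count, uniform in m/z over the theoretical fragment range with
log-normal intensities around a low median (50) — a density chosen to
reproduce the ~28% random-match rate observed on real data (the
generated world measures ~23%); Gaussian m/z jitter (σ = 0.05 Da, well
under a third of the matching tolerance); and residual precursor peaks
at every charge state with high intensity. The ground-truth ion→peak
map is built by the generator itself, never by the scoring code's
matcher, so it is an independent oracle.

What the generator does **not** emulate: sequence-dependent
fragmentation propensities (proline effect, basic-residue retention),
isotope envelopes, correlated same-site ion occurrences, lattice-bound
("peptide-like") chemical noise, and intensity correlation along a
fragment series. A green end-to-end test therefore establishes that the
pipeline is self-consistent and discriminative in a plausible ETD-like
world, not that it reproduces results on real instrument data.

One measurable consequence of the dense off-lattice noise: the raw
per-type match frequency m/n over-estimates the generating frequency by
roughly (1−φ)·0.16, because a missing ion still finds a noise peak
within ±0.8 Da about 16% of the time. The training report therefore
also prints a decoy-corrected estimate (f − p)/(1 − p) with p the decoy
match rate; it recovers the generating frequencies closely, though a
small residual bias remains because uniform decoys sample on- and
off-lattice m/z alike whereas fragment sites sit on the ~1 Da peptide
mass lattice.

## Evaluation

A predicted residue is correct when the true peptide contains a residue
of the same code (I/L merged — equal masses) whose N- and C-flanking
prefix masses both agree with the predicted residue's within 0.6 Da;
this is mass-position matching, not string alignment. Accuracy I is
total correct residues over total true length; Accuracy II over total
predicted length (the historical measure, inflated by short output).
The displayed formulas are reconstructed from the surrounding
description — the source text omits them — and chosen as the only pair
consistent with the remark that shorter output unfairly boosts the
second measure. L_max is the longest run of consecutively correct
predicted residues anchored to consecutive true residues; reports give
the fraction of predictions with L_max ≥ l for l = 3..10.

## Known limitations

- Coefficient grid search at the historical 0.01 step is expensive
  (10⁶ AUC evaluations); practical runs use 0.05–0.2.
- mzML input is not supported (MGF only); no profile data, centroiding,
  deisotoping or charge deconvolution.
- No FDR estimation or score calibration; scores are comparable between
  candidates for the same spectrum, not across spectra.
- The synthetic world's simplifications above; in particular, raw match
  frequencies are biased up under dense noise, as quantified.
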