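# Methods

This note documents the model behind `xicquant`, its tunable parameters, the
numerical conventions, what the synthetic data generator does and does not
emulate, and the design choices made where the method itself leaves room.

## Pipeline model and assumptions

The detector treats an LC-MS run as a 2-D point cloud: each MS1 scan is a
list of (m/z, intensity) points at one retention time. It assumes

- **profile-like spectra along m/z**: candidate picking takes per-scan local
  intensity maxima, i.e. it acts as the centroider. On already-centroided
  data where each ion is a single point, a weak ion whose nearest neighbour
  in the m/z list is a brighter ion is not a local maximum and will be
  missed; feed profile data or re-profile centroids if this matters.
- **intensity-ranked greediness is adequate**: the brightest signal defines
  its own XIC first and removes its points from consideration. There is no
  model fitting; overlapping analytes are separated only by the m/z window
  and the percentage-height test.
- **single-run scope**: no chromatographic alignment across runs. Replicate
  comparison matches features by (m/z, RT) proximity only, so RT drift must
  be small relative to the matching tolerance.

## Stage conventions and numerical choices

**Candidate picking.** Intensity must be strictly greater than the
threshold. A run of equal values (plateau) counts as one maximum at its
leftmost point; points at scan boundaries are compared against their single
neighbour. Ties in the global intensity ordering break toward lower m/z,
then lower RT, making the whole pipeline deterministic.

**XIC construction.** Neighbourhoods are closed windows: |Δm/z| ≤ `mz_tol`
(default 0.01 Th) and |ΔRT| ≤ `rt_tol` (default 1.0 min; the method states
no RT extent, so a symmetric window around the target was chosen wide enough
to hold any plausible elution profile at these column conditions). Inside
the fixed window each scan contributes its maximum raw intensity (per-scan
`sum` is available; `max` matches the one-point-per-scan reading of a base
peak chromatogram within the window). Scans with nothing in the window are
omitted, so traces contain only observed points. Tolerances are in Da (Th)
rather than ppm because the downstream matching tolerances are quoted in Da;
a ppm mode was considered and left out to keep one dialect.

**Peak detection.** The percentage-height line sits at
`height_fraction × apex` (default 0.5). "Crossing" on sampled data is
defined as the existence of a trace point *at or below* the line on each
side of the apex: at-or-below rather than strictly-below so that a valley
exactly at the line still separates two fused apexes — the boundary case
that the splitting behaviour is specified by. Boundaries are found by
walking outward from the apex to the *first* local minimum at or below the
line; minima above the line are walked through. Walking instead to the
globally lowest point would swallow neighbouring apexes and break the
shared-valley behaviour. If a side never reaches the line the apex is
rejected; if a boundary walk reaches the trace end, the end is the boundary.
Apexes are processed in descending intensity; points of an accepted peak are
claimed and cannot seed further apexes, but boundary points may be shared
between adjacent peaks. Area integrates all trace points between the
boundaries by the trapezoid rule (a `triangle` mode using only
start/apex/end exists for the minimal three-point reading, but discarding
measured points is not the default). FWHM interpolates linearly at half the
apex height on each side, clamping to the peak bounds when the trace never
drops that far. Undulation counts strict interior local minima — each is one
down-up reversal of the profile.

**Signal-to-noise.** The estimator sorts the trace intensities descending
(I₁ … Iₙ), uses the median as baseline, the RMS deviation about the median
with divisor n (population-style, exactly as defined — not n−1) as noise,
and scores (I₁ − baseline)/noise. Zero noise (all samples equal) reports +∞
with a flag. The samples are the peak's full parent trace by default
(`snr_scope = "trace"`), so the baseline reflects local background;
`"peak"` restricts to the peak's own points. One consequence of omitting
empty scans from traces: a clean, noise-free Gaussian trace is pure signal,
and its score is a *shape constant* — about 2.2 for a ±4σ sampled Gaussian,
independent of height. The default cut-off `min_snratio = 2.0` sits just
below that constant: it keeps ideal peaks while removing flat or degenerate
traces. On dense profile data whose XIC windows always contain background
points, scores run higher and a stricter cut-off is reasonable; the
threshold is a config field, not a constant.

**Filters.** Acceptance requires FWHM ≥ `min_fwhm` (0.05 min), undulation ≤
`max_undulation` (3), spectra count ≥ `min_spectra` (3) and S/N ≥
`min_snratio` (2.0), evaluated in that fixed order; a rejected peak is
annotated with the first failing criterion (all of them in verbose mode).

**Isotope clustering.** For each target (descending intensity) and each
candidate charge z ∈ 1–4, a window steps ±k·1.00335/z Th (k = 1, 2, …, up to
`max_isotopes` = 8) from the target m/z, collecting peaks within `iso_mz_tol`
(0.01 Th) of the window position whose apex RT is within `iso_rt_tol`
(0.1 min); the first empty step per direction closes the envelope. The
winning charge maximises (member count, envelope similarity, lower charge),
lexicographically: member count first because a wrong divisor of the true
charge collects a strict subset of the envelope yet can cosine-match a
lighter model envelope better than the full set matches its own.

The model envelope is an averagine-style Poisson approximation: the expected
number of +1 heavy-isotope substitutions grows as λ ≈ 5.36×10⁻⁴ per Da
(average amino-acid composition C₄.₉₄H₇.₇₆N₁.₃₆O₁.₄₈S₀.₀₄ per 111.1254 Da
with natural ¹³C/²H/¹⁵N/¹⁷O/³³S abundances), and relative abundances are the
Poisson pmf. Below ≈1.9 kDa the monoisotopic member dominates; above, the
+1/+2 members take over. Monoisotopic determination slides this model over
the members: hypothesis j aligns the model at member j with zeros below it
(the model has no isotopes lighter than the monoisotopic one, so members a
hypothesis abandons count against it), and the full member intensity vector
is scored by cosine similarity; a hypothesis must keep at least two members,
since a single surviving point matches any model perfectly. Degenerate
all-zero envelopes fall back to the lowest-m/z member with score 0.

After a cluster is emitted, only its monoisotopic member leaves the pool;
the other members can still be claimed by later, genuinely overlapping
clusters, but none of the members may seed a cluster of its own — otherwise
every suffix of an envelope would re-emit.

**Charge-state merging.** Neutral mass M = (m/z_mono − 1.007276)·z (proton
mass, positive mode). Clusters merge by single linkage when |ΔM| ≤
`merge_mass_tol` (0.02 Da) and |Δapex RT| ≤ `merge_rt_tol` (0.2 min); the
feature's area is the sum of all member peak areas (conserved exactly), its
coordinates come from its largest-area cluster. Charge-undetermined
singletons pass through unmerged.

**Evaluation.** TPR = x/t and FPR = (y − x)/z, where x is the number of
unique known entries matched by at least one detected feature, t the number
of known entries, y the detected count, z the average detected count per
group. FPR is deliberately not clamped: y − x > z yields FPR > 1, as the
definition implies. Feature matching is greedy one-to-one nearest-neighbour
in combined normalised (m/z, RT) distance within 0.01 Da / 0.2 min —
deterministic and cheap; optimal assignment would differ only in contrived
near-tie configurations. Bland–Altman uses d = 100·(a−b)/mean(a,b) per
matched pair, population-divisor SD by default (`ddof=1` available), and
counts pairs outside mean ± 2SD as outliers; pairs with a + b = 0 are
excluded with a warning.

## The synthetic data generator

`synth.generate_map` emulates an Orbitrap-class standard-mixture run:
a regular RT grid (0.02 min interval over 12 min by default), m/z 300–1500,
peptide-like features of 800–3000 Da at charges 1–4 with isotope abundances
from the same averagine model (spacing 1.00335/z), Gaussian elution (σ
0.05–0.12 min) with monoisotopic apex heights 10⁵–2×10⁶ counts, over a
uniform scatter of noise points (Poisson 40 per scan, intensities 500 +
exponential(2000)). Each ion is written as a five-point Gaussian hill along
m/z (σ 0.003 Th) — profile mode, matching the centroiding assumption above.
Feature points carry a 2% lognormal per-point jitter (ion-statistics
variability) drawn from the noise stream, so replicates with the same
feature seed and different noise seeds differ on the features themselves.
`true_area = apex_intensity·σ·√(2π)` is the analytic area of the
monoisotopic trace. Fixed seeds give byte-identical maps and mzML files.

What it does **not** emulate: m/z calibration drift and jitter, detector
saturation, chemical background ridges, chromatographic tailing and RT
drift between runs, co-eluting isobaric interference, and dynamic-range
compression. Passing tests on this generator demonstrate the pipeline's
correctness and internal consistency, not instrument-grade performance on
real samples.

`dilution_series` scales a designated feature subset by each factor of a
ladder (the tests use 1, 5, 25, 125, 625, 3125 — five-fold steps emulating a
serial dilution across ~3.5 orders of magnitude) while background features
stay constant, enabling linearity checks of recovered area versus
concentration.

## Problem sizes used by the test suite

The suite and acceptance script run on deliberately compact conditions
chosen to exercise every code path with stable statistics: 100-feature maps
(601 scans) for recall/FPR, 50 seeded 3-feature maps for the
consume-exactly-once audit, 400 envelopes for charge/mono accuracy,
16-feature maps across the six-point dilution ladder, and 50-feature
replicate pairs for Bland–Altman. The full suite completes in well under a
minute.

## Known limitations

- Real centroided input needs re-profiling (see assumptions above).
- The S/N score is support-dependent (see above); compare scores only
  between traces of similar sampling.
- Single-linkage charge merging can chain clusters across a mass ladder in
  pathological cases; tolerances are tight enough that this does not occur
  in practice, but the grouping is not a partition-optimal assignment.
- The averagine envelope is an approximation; molecules far from average
  peptide composition (glycans, metal adducts, halogenated metabolites)
  may get wrong monoisotopic assignments at high mass.
- mzML/mzXML support covers centroid/profile MS1 point lists with 32/64-bit
  float arrays and optional zlib compression — not the full breadth of the
  standards (no numpress, no vendor-specific extensions).
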