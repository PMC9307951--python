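# Methods

## Coordinate frame and isoforms

All residue positions are 1-based and refer to the canonical 441-residue human
2N4R tau sequence, the frame in which the field names sites (T231, S262,
K254, P301). The package ships three sequences: 2N4R, 1N4R (412 aa, lacking
the 29-residue N2 insert, canonical 74–102), and 1N4R-P301S (the transgene
product of the PS19 mouse line, P→S at canonical 301). Projection between an
isoform's local coordinates and the canonical frame uses a block-wise offset
map computed at load time by global pairwise alignment (Biopython
`PairwiseAligner`, match 2 / mismatch −1 / gap open −10 / extend −0.5 — gaps
are expensive so the single spliced-out insert aligns as one indel, and point
mutations stay inside aligned blocks). Canonical positions inside a
spliced-out insert are reported as *absent* (`None`), never silently shifted;
the map is validated to be a bijection over the mapped range.

## Tryptic digestion

Classical trypsin specificity: cleavage C-terminal to K or R, suppressed when
the following residue is P. `digest()` enumerates all peptides bounded by
cleavage sites or protein termini with 0..`max_missed` internal sites
(default 3, the usual search-engine setting for modified peptides) and length
within 6–50 (typical detectable tryptic range; both configurable). Only fully
tryptic peptides exist in this model; semi-tryptic input is rejected at
ingestion because the frequency denominator would otherwise double-count
overlapping evidence.

## PTM site-frequency model

For one modification type (phospho on S/T/Y; acetyl, ubiquitin on K — each
type a fully independent pass that never shares a denominator with another),
the occupancy at canonical residue r is

    f(r) = modified_abundance(r) / coverage(r)
    coverage(r)           = Σ abundance over peptides whose mapped span contains r
    modified_abundance(r) = Σ abundance over peptides modified at r

Decisions embodied here:

* **Denominator** — coverage counts *every* peptide containing r regardless
  of modification status elsewhere; a peptide phosphorylated at site a still
  attests that site b (also inside it) was observed. The alternative
  ("unmodified-anywhere" denominator) deflates coverage for multiply modified
  peptides and was rejected.
* **Zero vs missing** — coverage(r) = 0 yields NaN ("no coverage"), never 0;
  an additional *absent* state marks canonical positions the contributing
  isoform does not encode. Renderings show absent as a gap, no-coverage as
  grey, and only covered positions on the cyan→magenta scale.
* **Duplicates** — rows identical in (sequence, position, modification set,
  sample) — charge states, repeated PSMs — are summed before the ratio. This
  is a choice, not a constraint of the statistic; it leaves f(r) unchanged
  whenever duplicates carry the same modification set.
* **Ambiguity** — peptides whose sequence occurs at more than one position in
  their isoform (possible in tau's repeat region) are excluded and logged;
  there is no principled disambiguation without retention-time evidence.
* **FDR** — records are filtered at q ≤ 0.01 by default (config-exposed)
  before any frequency computation.
* Frequencies are within-sample abundance ratios and therefore invariant to
  any global rescaling of intensities; no cross-sample normalisation is
  applied or needed.

## FRET gating and integrated FRET density

The seeding readout per well is IFD = (100·p)·m with p the FRET-positive
fraction and m the median FRET intensity of the positive events (midpoint
interpolation for even counts; m := 0 when there are no positives, making
IFD exactly 0). The "percentage" convention (×100) is kept so magnitudes are
comparable across studies.

The positive gate is anchored on an unseeded control: the threshold is the
⌈q·n⌉-th order statistic (1-based, lower convention, no interpolation) of the
control's FRET channel at q = 0.995, so at most ⌈(1−q)·n⌉ control events sit
strictly above it. An optional CFP sub-gate (lower bound, same construction)
restricts to expressing cells. The true gating hierarchy used with physical
instruments (scatter gates, bivariate polygons) is deliberately not
reconstructed — the control-quantile gate is a reproducible substitute with a
designed false-positive allowance of 1−q, which is why an unseeded well never
reads 0 but ~0.5% positives; "no seeding" is defined as control-level IFD,
not zero.

Replicate aggregation reports mean, sample SD (ddof = 1; 0 for singletons)
and n per group. Group comparison is a Welch (unequal-variance) two-tailed t
test, implemented in closed form with the Welch–Satterthwaite df so the
degenerate zero-variance case can be handled explicitly: identical constant
groups give t = 0, p = 1; perfectly separated constant groups apply a
standard-error floor of 1e−12·max(1, |mean|) and pooled df, yielding p ≈ 0.
Non-degenerate inputs agree with `scipy.stats.ttest_ind(equal_var=False)` to
machine precision (cross-checked in tests).

## SEC calibration and n-mer assignment

Least-squares fit of log10(MW in kDa) on elution volume (mL); log10 rather
than ln so coefficients read directly in decades. Fewer than 3 standards is
an error; non-monotone standards warn but fit (the residuals expose them).
Apparent MW follows by inversion; the oligomer order is the nearest of
{1, 2, 3, 10, 20} to apparent_MW/monomer_MW by |log| distance, because SEC
resolution is log-linear — so bin boundaries sit at geometric midpoints
(e.g. √30 ≈ 5.5× monomer between trimer and 10-mer). Volumes outside the
standards' span are flagged `extrapolated`. Because tau is intrinsically
disordered and elutes anomalously against globular standards, the monomer
reference MW is configuration (default 45.9 kDa, the 2N4R formula weight),
and a declarative lookup of validated fraction identities
(B5/B7/B8/A7/A4 → 1/2/3/~10/~20) can bypass calibration entirely.

## Sequence-map rendering

Linear RGB interpolation between the anchors cyan (0, 255, 255) at f = 0 and
magenta (255, 0, 255) at f = 1; each channel is c0 + f·(c1−c0) rounded half
up, so the anchors are exact and every channel is monotone in f. The per-cell
CSV (row, position, residue, frequency, hex color, status) is the testable
contract; the SVG is generated from the same table and is deterministic in
content, though byte-identity across rendering-library versions is not
promised (the SVG here is hand-assembled, so in practice it is stable).

## Synthetic data: what it emulates and what it does not

* **Flow**: i.i.d. log-normal intensities; negatives with geometric median 50
  (log-sd 0.5) and positives with median 500 (log-sd 0.5) on the FRET
  channel, 20,000 events × 3 technical replicates by default. The positive
  median must clear the negatives' extreme quantile or a warning fires. Not
  emulated: spectral spillover/compensation (events are "post-compensation"),
  doublets, acquisition drift, well-to-well biological variance.
* **Peptides**: draws come from the isoform's actual tryptic digest
  (`digest()`, unique-location peptides only); each targeted site receives
  `draws_per_site` covering draws (acceptance-depth 500) and the whole
  sequence `background_depth` draws per peptide; any draw covering a true
  site is modified there with probability f\*(r), so coverage depth never
  biases occupancy. Abundances are log-normal with μ = 10, σ = 1 on the
  natural-log scale (heavy-tailed, MS-like). Decoys reuse real peptide
  sequences with q ~ U(0.05, 1); targets q ~ U(0, 0.01) — clean separation
  makes the FDR filter's effect exactly countable. Note the statistical
  consequence of weighting: the abundance-weighted occupancy estimator has
  standard error inflated over the plain binomial by the design effect
  √(E[w²])/E[w] = √e ≈ 1.65 at σ = 1; recovery tests therefore use either
  the mean absolute error across datasets or a weighted-SE band. Not
  emulated: spectra, misidentification of the peptide sequence itself,
  site-localisation error, correlated co-modification.
* **SEC**: standards placed exactly on the true line with Gaussian noise
  (σ = 0.02 in log10 MW) on the MW axis; fraction volumes constructed by
  inverting the true line at chosen monomer multiples. Not emulated: peak
  shapes, inter-fraction cross-contamination, column aging.

A green recovery test therefore establishes that the estimators are unbiased
and correctly scaled under idealised i.i.d. sampling — not that they are
robust to the instrumental artifacts listed above.

## Pipeline, configuration, determinism

One YAML document configures everything; CLI flags override. Validation
raises with the offending field's dotted path. Per-stage seeds derive
deterministically from the base seed (`seed·1000 + stage offset + index`,
reduced mod 2³¹−1), every generator is a pure function of (params, seed), and
every output file carries `# tauquant config_sha256=<12-hex> seed=<int>`,
so a run is reproducible byte-for-byte from its config. Exit codes: 0
success, 1 user error (invalid config, missing input), 2 internal error.

## Known limitations

* Flow-event ingestion is CSV only (a channel-role mapping accommodates
  instrument export column names); binary FCS 3.x files must be exported to
  CSV upstream.
* The occupancy statistic cannot distinguish positional isomers within a
  peptide beyond what the input's site assignments claim; site-localisation
  confidence is assumed resolved upstream.
* A single lone peptide species fully modified at a site reads 100%
  occupancy with no way to flag low evidence except its coverage value —
  consumers should inspect `coverage_abundance` before interpreting extreme
  frequencies.
* The fraction-letter lookup applies to the specific validated column
  protocol it came from; for any other column, fit a fresh calibration.
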