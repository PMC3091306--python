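# Methods

`lipidquery` implements the informatics core of MasterScan-style shotgun
lipidomics: resolution-dependent scan averaging, cross-acquisition spectra
alignment into a flat-file database, de-novo lipid identification through a
fragmentation query language, sum-composition enumeration under elemental
constraints, and isotopic correction of partially overlapping clusters.
This note records the models, the defaults and why they are what they are,
and the design choices made where the published descriptions leave the
design open.

## Scan averaging

Masses of one ion across repeated scans are modelled as Gaussian with
sigma = m/(2·R(m)), where R(m) is the FWHM resolution, assumed linear in m
(`ResolutionModel(R0, anchor, gradient)`); with that convention the bin
width m/R(m) equals 2·sigma, which is what makes the analytic one-pass
expected occupancy equal erf(1/√2) ≈ 0.68.

All scans' peaks are pooled, sorted, and swept left to right: a bin is the
half-open interval [m, m + m/R(m)) anchored at the lowest unconsumed mass;
its members are replaced by one peak at the intensity-weighted mean mass.
The weighted-mean formula is normalized by the most abundant member in the
original formulation; the normalization cancels, so the plain weighted mean
is computed.  The sweep is repeated (default three passes); after three
passes no two adjacent representative masses are closer than m/R(m), which
is asserted as an invariant.  Multi-pass merging is exact, not
approximate: each cluster carries its intensity-weighted mass sums, so the
final representative mass equals the weighted mean over all original
member peaks.

**Representative intensity** (left open by the original description): the
mean over *contributing* scans of the per-scan summed member intensity.
Scans lacking a member lower the peak's occupancy, not its intensity, so
intensities stay comparable across occupancies.

**Noise filter.** Peaks below `min_sn` (default 3.0, the usual
limit-of-detection factor) times the estimated noise are dropped before
binning.  The noise level of a scan is estimated as the median intensity of
its lower-intensity half — a dense population of weak noise peaks is
assumed.  Scans with fewer than 20 peaks have no estimable noise floor and
are passed through unfiltered; sparse spectra (including most synthetic
fixtures) would otherwise be annihilated by their own median.

## MasterScan alignment

Averaged spectra of all acquisitions are aligned with the same sweep, with
two deliberate differences: representative masses are **unweighted** means
of member masses (an intense acquisition must not drag the consensus mass),
and intensities are not merged — each entry carries one intensity slot per
acquisition (0 = absent).  Several peaks of one acquisition landing in one
bin have their intensities summed into that slot.  Occupancy of an entry is
the fraction of acquisitions with a non-zero slot, optionally evaluated
over a named acquisition group.

MS/MS spectra are grouped by recorded precursor m/z, averaged per
acquisition, and attached to *every* precursor entry within
± isolation_width/2 (default 1.0 Da) of the recorded precursor — with
windows wider than the peak spacing, several entries legitimately share one
fragment block.  Fragment blocks are themselves aligned with the MS2
resolution model.  MS/MS spectra matching no entry are kept in an orphan
list, logged, never fatal.

**Recalibration.** Given reference (lock) masses, each is matched to the
nearest entry within a match tolerance (default 20 ppm); the mass error
dm(m) = a·m + b is fitted by least squares (constant offset for a single
reference) and removed.  MS2 masses are only shifted when explicitly
requested, since fragment-level references are rarely available.

**Pre-filters.** Intensities below the per-level threshold are zeroed
first; occupancy is computed afterwards, and entries below the occupancy
threshold are dropped.  The benchmark-style defaults used throughout the
documentation are occupancy 0.5 (species present in at least half of the
replicates), S/N 3.0, three passes, 1.0 Da isolation, 5 ppm MS1 and 0.3 Da
MS2 match tolerance.

**Persistence** is a versioned JSON text file.  Scalar metadata is plain
JSON; the numeric vectors (entry masses, intensity matrices, fragment
blocks) are base64-encoded network-order 64-bit floats — the same
convention mzXML uses for peak data — so the file is exact (bit-for-bit
round trip), deterministic (two saves are byte-identical), and smaller
than the acquisitions it summarizes.

## Sum compositions, DBR, enumeration

Formulas are parsed in the `C5 H15 O4 N1 P1` dialect; constraints in the
bracket-range dialect `C[30..48]H[30..200]N[1]O[8]P[1]` with an ion charge
and a closed DBR interval.  Monoisotopic masses come from an embedded
IUPAC table (documented in `chem.ISOTOPES`); m/z subtracts one electron
mass per positive charge and adds one per negative, which matters below
1 ppm.

Double-bond equivalents use the generalized valence form
DBR = 1 + Σ nᵢ(vᵢ − 2)/2 with P assigned valence 3, i.e.
DBR = 1 + C − H/2 + (N + P)/2 over CHNOP.  DBR is evaluated on the ion
formula *as written* (charge-carrying hydrogens included): that convention
reproduces db = DBR − 1.5 = 1 for protonated PC 36:1, the arithmetic the
worked PC query relies on.  The protonated species therefore carries a
half-integer DBR; constraint ranges such as (1.5, 7.5) are expressed in the
same convention.

Enumeration of compositions under a constraint is an exhaustive
depth-first search over the element count ranges with residual-mass
pruning, checked in the test suite against a nested-loop oracle; results
are sorted by absolute mass error, ties broken by element counts, so
output order is deterministic.

Isotope patterns are computed by polynomial convolution of per-element
natural isotope distributions, aggregated by nominal mass offset, with the
offset-0 (monoisotopic) aggregate normalized to 1; each aggregate carries
its abundance-weighted exact m/z.

## Isotopic correction

Lipid class ladders differ by H2 (2.0157 Da); the M+2 isotopologue of the
species with one more double bond sits ~9 mDa below the monoisotopic peak
of its neighbour — inseparable at unit resolution, fully resolved at
R = 100,000.  The overlap criterion everywhere is |Δm| ≤ m/(2·R(m)), so
the same code reproduces both regimes.

**MS mode.** Identified precursors are swept light to heavy.  For each
species the expected M+1..M+depth intensities (default depth 2, which
covers glycerophospholipids) are computed from its bound composition and
subtracted from every identified peak inside the overlap window of that
isotopologue, per acquisition, clipped at zero; every subtraction is
recorded in an auditable ledger (exportable as a table).  Monoisotopic
peaks of the lightest species are never reduced.

**MS/MS mode.** Two contamination routes are corrected.  (1) Co-isolation:
when the M+k isotopologue of a lighter identified precursor falls inside a
block's isolation window, that species' fragments contaminate the block.
The model used in both the simulator and the corrector is the field's
standard first-order description of type-II overlap: the fragment of an
M+k precursor population appears at the fragment's own +k isotopologue
position (the heavy label is retained on the charged fragment).  The
corrector subtracts, at that position, the neighbour's fragment intensity
as observed in its own block scaled by the neighbour's precursor M+k/M0
ratio.  This first-order model ignores the partitioning of the label
between the charged fragment and the neutral loss; it is the convention
under which the classic "M+2 of the more unsaturated acyl anion overlaps
the next saturated one" correction is exact.  (2) Within-block envelope
overlap between different fragment species is removed with the same sweep
as MS mode, using the fragment compositions' own patterns.

On the simulated four-standard PA mixture (molar 1:9:1:1, where two
standards share an exact precursor mass) at unit resolution, the
uncorrected PA 18:0/18:1 channel is overestimated roughly two-fold in both
modes; corrected precursor intensities recover 10:1:1 and corrected
acyl-anion sums recover 1:9:1:1 within 5 % relative.

## MFQL

The query language (grammar in `docs/mfql.md`) is parsed by a hand-written
tokenizer and recursive-descent parser into a small AST; evaluation binds
constraint variables through the enumeration machinery and fragment
variables within each candidate precursor's own block, applies the boolean
structure of IDENTIFY, filters with SUCHTHAT, and formats REPORT rows.
Defaults: 5 ppm MS1, 0.3 Da MS2 (absolute tolerances suit low-resolution
ion traps; both accept `ppm`/`da`/`mda` suffixes).  Multiple compositions
matching one peak each produce their own row rather than being merged.
`%d` formatting truncates toward zero; `%f` prints one decimal by default
(`PC [36:1]`-style names).

## Synthetic data

The generators are first-class, seeded, pure functions of their parameters.

* **Template experiment** (alignment validation): a ladder with adjacent
  spacing exactly m/R_template (R = 500) over 500–945 Da gives 319 peaks
  spaced 1.4 Da on average; 256 replicate spectra draw each peak from
  N(m, m/(2·R_instrument)) with R_instrument = 100,000, unit intensity.
  Matching each template position to its nearest aligned entry reproduces
  the published occupancy ladder (≈0.65 after one pass — the main sweep
  bin captures Φ(1.13) − Φ(−0.87) ≈ 0.68 of the Gaussian, slightly eroded
  by anchor variability — and ≈0.97 after three) and mass errors (≈0.9 mDa
  after one pass, ≈0.4 ppm after three).
* **Lipid mixtures**: species defined by ionized sum composition, molar
  amount and fragment rules (head-group fragments, acyl anions); MS1 scans
  carry full isotope envelopes, MS2 scans carry the fragments of everything
  co-isolated within the isolation window under the retained-label model
  above.  Intensity noise is multiplicative log-normal (default CV 10 %,
  keeps intensities positive); optional uniform chemical-noise peaks stress
  the S/N filter.  Mass jitter is Gaussian with sigma = m/(2·R_jitter).
  By default R_jitter equals the binning resolution, as in the template
  experiment; for unit-resolution instruments the centroid precision is
  far better than the FWHM, so the unit-resolution simulations set
  R_jitter = 7,000 (≈50 mDa at m/z 700, typical ion-trap centroid
  stability) while binning at R = 800.

What the simulations do *not* emulate: profile peak shapes (centroids
only), retention time, spray-condition drift within an acquisition,
space-charge mass shifts, and the label-partition statistics of fragment
isotopologues beyond the first-order model.  Passing tests therefore
demonstrate algorithmic correctness under the stated models, not
instrument fidelity.

## Problem sizes and numerical choices

The package's own validation runs use 256 spectra × 319 peaks × 5 seeds
for the alignment experiment, 4 acquisitions × 12 scans for the PA and
PE/PE-O mixtures, and 3 acquisitions × 16 scans for the PC identification
fixture — sizes chosen to match the published experiment where one is
stated and to keep the full suite fast otherwise.  Ties in the binning
sweep need no randomness: equal masses merge in input order, and all
aggregations are carried as exact sums.  Degenerate inputs are defined:
an infinite-resolution template collapses to a single mass; an empty
fragment list is a valid (empty) block; zero-intensity bins fall back to
unweighted means.

## Known limitations

* One polarity per MasterScan; mixed-polarity files are split logically.
* MS3 and deeper levels are out of scope, as are spectral libraries and
  scoring models (deliberately: identification is rule-driven).
* The mzXML reader supports the common subset (32/64-bit network-order
  peaks, zlib or none); vendor dialect quirks are rejected with an error.
* Conversion of ion abundances to molar concentrations is deliberately not
  provided; reported intensities are instrument units.
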