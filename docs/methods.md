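# Methods

## Scope and model

`hilipid` implements class-resolved quantitative profiling of the four major
mitochondrial glycerophospholipid classes — PC, PE, PI and CL, with the
ether-linked subclasses PC O and PE O — from centroided HILIC-ESI-FTMS runs
that interleave MS1 full scans with all-ion-fragmentation (AIF) scans in one
polarity. Species are handled at sum-composition resolution (class + total
side-chain carbons C + total C=C bonds D); individual acyl/alk(en)yl chains,
sn-positions, oxidized and lyso species are out of scope. Plasmanyl and
plasmenyl ethers are not distinguished: one "O" stoichiometry per sum
composition is used and a vinyl-ether double bond counts inside D, which is
mass-identical and therefore neutral for annotation.

## Exact masses and formulas

All mass arithmetic uses one pinned constants table: monoisotopic masses
¹H 1.00782503, ²H 2.01410178, ¹²C 12 (exact), ¹⁴N 14.00307401,
¹⁶O 15.99491462, ³¹P 30.97376200 u; proton 1.00727646 u; aggregated
isotopologue spacing 1.00335484 u (¹³C−¹²C). Ion m/z uses proton bookkeeping
([M+H]⁺ = M + m_p, [M−2H]²⁻ = (M − 2 m_p)/2); diagnostic fragments are
specified as ion formulas and adjusted by one electron mass
(m_e = m(¹H) − m_p).

Elemental formulas follow fixed class stoichiometries (diacyl PC C:D →
C₍C+8₎H₍2C−2D+16₎NO₈P, ether PC −O+2H, PE with −3C on the head group, PI
C₍C+9₎H₍2C−2D+15₎O₁₃P). Cardiolipin uses the triglycerol-bis(phosphodiester)
backbone C₍C+9₎H₍2C−2D+14₎O₁₇P₂, verified in the tests by independent
assembly from 3 glycerols + 2 phosphoric acids + 4 acyl chains − 8 H₂O (for
CL 56:0 this gives C65H126O17P2, matching the tetramyristoyl standard).
Deuterated internal standards replace the stated number of hydrogens with
heavy labels, treated as monoisotopic sites.

## Isotope patterns

Aggregated isotopologue fractions f₀…f₅ (n_max = 5 by default) are computed
by per-element truncated polynomial powering of the pinned IUPAC
representative abundances (¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038,
¹⁸O 0.00205) and convolution across elements. The tests check the convolution
against an independent exhaustive composition-enumeration oracle (≤ 1e-9 for
small formulas, ≤ 1e-6 for PC 32:0). Truncation at n = 5 loses at most
5.9e-5 of pattern mass for PC/PE formulas, 1.1e-4 for the largest PI and
8.3e-4 for the largest CL (C81); neither correction is affected in its
leading terms, because type-I consumes only f₀ and type-II only f₂/f₀.

## Annotation and corrections

* **Matching** (tolerance 0.05 m/z, absolute): each target takes its nearest
  in-tolerance averaged peak; each peak serves at most one target; conflicts
  resolve by smaller |Δm/z| with ties toward the lower theoretical m/z.
* **Intensity filter**: endogenous species must exceed 1% of the endogenous
  base peak (raw M+0, before corrections — the workflow order); internal
  standards are always kept and never define the base peak.
* **Type-II** runs before **type-I**: the whole-pattern rescaling must
  consume an interference-free M+0. Within each (subclass, C) group the
  single descending-D pass is exact under the ΔD = 1 interference model, so
  no iteration is needed; members separated by ΔD ≠ 1 do not interfere.
  Over-subtraction clamps at zero with a warning. Interference is applied at
  full overlap by default (`overlap_fraction = 1.0`): at 140k resolving power
  the 0.0089 m/z split (singly charged; ~0.0045 for CL²⁻) is below the
  practical two-centroid resolution limit, and band averaging merges such
  near-isobars; the fraction is configurable.

Two residuals of this correction model are worth knowing. First, the M+4
isotopologue of the D+2 group member also lands on the merged centroid chain;
the M+0/M+2-only correction leaves it, a ≈1% surplus for species with an
abundant D+2 neighbour. Second, the 0.05 m/z tolerance admits systematic
near-isobar aliases — e.g. the M+2 isotopologue of diacyl PC C:0 falls
0.049 m/z from the PC O (C+2):6 target, and CL²⁻ targets at (C+1, D+7) lie
0.047 from (C, D) — so when the true species is absent, an isotopologue peak
can be annotated in its place and its type-II term then over-corrects a ΔD=1
neighbour. Both effects are bounded in the integration tests (subclass totals
recover within 3% at zero noise; irreproducible alias species are largely
removed by the RSD filter on real-noise cohorts) and are properties of the
published matching rule, not of this implementation.

## Quantification and aggregation

Concentrations use one internal standard per class (PC 33:1 d7, PE 33:1 d7,
PI 33:1 d7, exogenous CL 56:0), spiked at 3 μg/ml of final extract:
`conc = total(species)/total(class IS) × spike`. This assumes class-uniform
ionization yield, justified by head-group-driven ionization inside one HILIC
band; concentrations are per ml of extract (protein normalization is not
modeled). The five ratios use diacyl denominators (PE/PC, PI/PC, CL/PC and
PC O/PC against diacyl PC; PE O/PE against diacyl PE), switchable to combined
family denominators.

Relative abundances (fractions of type-I-corrected totals over the retained
endogenous species of a class family) are the chemometrics input. The 20% RSD
filter acts on these fractions across the extraction replicates of each
pellet, with sample standard deviation (n−1); a species exceeding the cutoff
in *any* pellet is excluded globally, so every retained variable is
reproducible in every group. The chemometrics matrix holds per-pellet
(biological replicate) means of the retained species — 9 rows in the full
design. Species missing from some replicates are zero-filled with a warning,
which makes flickering near-threshold species fail the RSD filter by
construction (intended: they are irreproducible).

## Chemometrics and statistics

Autoscaling z-scores each variable with sample standard deviation (n−1);
constant columns are dropped with a warning. PCA is an SVD of the centered
matrix; variance fractions are σ_k²/Σσ²; the sign of each component is fixed
by making its largest-magnitude loading positive. Per-line 95% confidence
ellipses use the group score covariance in the PC1/PC2 plane scaled by the
χ²(2 df) 0.95 quantile (5.991); disjointness is checked numerically on
boundary points. HCA is unweighted average linkage (UPGMA) on Euclidean
distances via `scipy.cluster.hierarchy`, with cophenetic matrices, Newick
export and heatmap ordering by dendrogram leaves. Tukey HSD uses
`scipy.stats.tukey_hsd` (cross-checked against statsmodels in the tests) with
stars at P < 0.01 / 0.005 / 0.001; tests run on biological-replicate means
(n = 3 per line), matching how the replicate hierarchy is averaged. If the
pooled within-group variance is exactly zero with unequal means, p is
reported as 1e-12.

## Synthetic-data model

The generator is the study-conditions oracle: a 3-line (WT, OPA1-null,
Mfn1/2-null) × 3 biological × 3 extraction design.

**Lipidome templates.** Each subclass has a Gaussian abundance surface over
(C, D) with class-typical centers (PC 34 C / 1.8 D, PC O 34/2.5, PE 38/4.0,
PE O 38/4.5, PI 37/3.0, CL 68/4.0; σ_C ≈ 2 in carbon units, σ_D 1.3–1.8).
Odd-carbon species (PI and CL only) carry a 0.05 weight factor. Species below
2% of the subclass maximum are pruned — a detectability floor that keeps
per-family species counts near those annotated in real mitochondrial extracts
(~60 PC, ~75 PE, ~40 PI, ~55 CL). Planted effects, all configuration choices
reproducing the study's qualitative directions rather than measured values:
ether incidence PE O/PE 0.90/0.60/0.35 and PC O/PC 0.50/0.40/0.25 for
WT/OPA1/Mfn; a +0.5 mean-double-bond shift in both knockouts (PI uses
line-specific +0.7/+0.35 so the two knockouts remain distinguishable there,
matching the observed PI unsaturation order WT < Mfn < OPA1); 72-carbon CLs
zeroed outside WT; class totals PC 30 μg/ml with PE/PC 0.8, PI/PC 0.15 and
CL/PC 0.30/0.27/0.23. Noise is per-species multiplicative log-normal:
biological CV 10% (shared across a pellet's extracts), extraction CV 5%, plus
a pellet-level scale factor (CV 10%) that cancels in all ratios and
fractions. Sub-seeding is per (line, pellet, extract), so subset designs
reproduce the corresponding samples of the full design bit-for-bit.

**Instrument model.** Class bands are Gaussians (σ = 0.1 min) at apexes
following the head-group elution order PI (7.0) < CL (8.5) < PE (10.0) <
PC (12.5) min, ether subclasses trailing their diacyl parent by 0.35 min;
full scans every 0.1 min with AIF scans interleaved at half-interval. Each
species contributes isotopologue peaks (fractions from the formula, spacing
1.00335/z) scaled by the band profile and a class response factor
(0.5–1.0 × 10⁶ counts per μg/ml). The ≤5 ppm mass-accuracy envelope is
decomposed into a per-run calibration offset (1.5 ppm SD, truncated at 2σ),
scan-to-scan drift (0.3 ppm) and per-centroid jitter (0.5 ppm) — mass error
in FTMS data is dominated by the systematic calibration term, and an
all-independent error model would split one species across averaging
clusters. Peaks closer than 1.5× the local FWHM (resolving power
140,000 × √(200/m/z)) merge into one intensity-weighted centroid; this is
what creates the ΔD = 1 M+0/M+2 interference across the whole precursor
range. AIF scans carry the four diagnostic fragments with intensity
proportional to the co-eluting class signal. Internal standards are rendered
at the same effective spike in every run. Per-peak intensity noise is
log-normal with CV 3%.

**What the generator does not emulate** — ionization suppression and
cross-class matrix effects, chromatographic tailing and retention drift,
chemical noise/background peaks, in-source fragmentation, and real acyl-chain
isomer diversity. Passing recovery tests therefore demonstrates correctness
of the processing chain under the stated instrument physics, not robustness
to every artifact of real data; the RSD filter and the ±0.05 matching rule
are, however, exercised under realistic mass error, coelution interference
and species dropout.

## Numerical choices

Retention times are minutes; RT windows are closed intervals. Band boundaries
take the contiguous region around the global XIC apex where the 3-point
moving-average-smoothed trace stays ≥ 5% of the apex (the boundary rule is a
stand-in for manual inspection; the threshold and smoothing make it robust to
centroid shot noise). Spectral averaging clusters peaks greedily in ascending
m/z at 5 ppm around the running intensity-weighted mean and divides cluster
sums by the number of in-window scans (zero-fill), emulating a vendor mean
spectrum. The pipeline chains stages through their on-disk files, so isolated
stage re-runs reproduce the chained results exactly; every CSV carries a
provenance header (config hash, seed) and identical configs and seeds give
byte-identical outputs.

mzML I/O is a minimal ElementTree-based reader/writer for centroided spectra
(64/32-bit, plain or zlib-compressed arrays, profile-mode rejection); the
tab-separated scan dialect is the primary interchange format for fixtures.

## Problem sizes in the test suite

The statistical acceptance checks run the full simulate→quantify chain in
memory on 27-sample cohorts (~2 s each): dendrogram purity and the CL
structure checks on 3 cohorts each, the PE O/PE Tukey power check on 50
cohorts, and ratio recovery on one 9-sample WT cohort — sizes chosen to give
stable pass/fail statistics at interactive runtimes. Determinism is checked
on a 1-line 2×2 design.
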