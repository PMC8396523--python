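# Methods

## Mass model

All species are bookkept as elemental compositions (signed multisets of
element counts).  Masses come from a fixed bundled snapshot
(`data/elements.tsv`): monoisotopic masses of the principal isotopes
(CODATA/AME2020 values) and IUPAC 2021 conventional standard atomic weights,
so results are bit-stable across environments.  Deconvoluted intact-mAb
spectra do not resolve isotopes at a resolution setting of 17,500, so the
*average* mass is the working domain for extraction, deconvolution, and
annotation; monoisotopic masses are carried alongside for completeness.

An intact antibody is assembled as 2x heavy chain + 2x light chain (free
peptides, i.e. residue sums plus one water each), minus 2 H per disulfide
bond (default 16 for an IgG1 — 4 interchain + 12 intrachain; configurable,
as exact counts vary by subclass), plus the glycan pair, plus k lysine
residues (k = 0, 1, 2), plus any extra deltas.  Key deltas (bundled registry,
`data/mods.yaml`):

| delta | composition | mono Da | avg Da |
|---|---|---|---|
| C-terminal Lys | C6H12N2O | +128.095 | +128.175 |
| hexose (galactose or glycation) | C6H10O5 | +162.053 | +162.141 |
| NeuAc | C11H17NO8 | +291.095 | +291.256 |
| deamidation (Asn→Asp) | −H −N +O | +0.984 | +0.984 |
| pyroGlu (N-term Gln) | −NH3 | −17.027 | −17.031 |
| LC N-terminal truncation (−QIVLS) | −C25H44N6O7 | −540.327 | −540.662 |

Two deliberate subtleties:

- *Glycation vs galactosylation*: both are one hexose; they share a
  composition but keep distinct registry names.  Because they are strictly
  isobaric at the intact level, neither is quantified by EICC — the
  pattern-shift detector flags the +162 Da shift instead.
- *The truncation magnitude*: summing the unmodified residues Q-I-V-L-S
  gives 540.33 Da (monoisotopic) / 540.66 Da (average).  The canonical
  quoted value for this variant, −540 Da, matches the unmodified-Gln
  pentapeptide; if the truncated species' exposed Gln cyclized to
  pyroglutamate the loss would instead be ~523.6 Da.  The package computes
  the unmodified-Gln value and leaves the pyroGlu question to the user's
  modification list.  Where a single number is reported for this shift the
  monoisotopic 540.33 is used; at the pattern-shift match tolerance (0.5 Da)
  the mono/avg distinction is immaterial to detection.

Chain sequences are an editable FASTA fixture (public rituximab record,
2x ~49 kDa HC + 2x ~23 kDa LC, assembly ~147 kDa with G0F/G0F).  The heavy
chain is lysine-clipped on load so library lysine counts are absolute.
Absolute masses inherit any fixture error; every mass-difference quantity
does not.

## Glycan nomenclature

Oxford-style labels map to monosaccharide counts: complex-type core
HexNAc2Hex3 + one HexNAc per antenna (A1/A2), one Hex per galactose (G) and
per sialic-acid cap (S, which sits on its own galactose), one NeuAc per S,
one core Fuc for a trailing F; M5–M9 are HexNAc2Hex5..9.  Arbitrary
label→composition registrations are supported for species outside the
grammar.  Glycan pairs are unordered, and pairs with identical summed
composition (A2G1F/A2G1F vs A2G0F/A2G2F) collapse into one library entry
with a combined label: no mass-based method can separate them, and under the
galactosylation formula below both readings contribute the same 2 galactoses.

## EICC quantitation

For proteoform mass M and charge z the theoretical ion is
m/z = (M + z·1.007276)/z.  Defaults: z = 22..32, which keeps a ~147 kDa
species inside the m/z 2500–8000 acquisition window (charges leaving the
window are dropped with a warning); extraction half-width
max(50 ppm · m/z, 0.6 Th) — at 17,500 resolution the unresolved isotope
envelope plus peak width of a ~148 kDa ion at z ≈ 25 spans ≳ 0.5 Th, so the
absolute floor dominates and the ppm term takes over for lighter/higher-z
ions.  Per scan, intensities within the window of *any* selected charge are
summed; the trace is integrated by the trapezoid rule over a half-open
retention-time window [start, end) in minutes (half-open so adjacent
windows never double-count a scan).  Areas normalize to fractions of the
quantified set; quantities are therefore relative ("semi-quantitation") and
scale-invariant by construction.

Retention windows are user-specified per variant group (lysine variants are
chromatographically separated and quantified separately); an auto mode fits
a Gaussian to the summed library EICC (moment initialisation, least-squares
refinement, moments as fallback) and takes apex ± 3σ.

**Galactosylation level.** Defined here as galactose-site occupancy over the
main core-fucosylated biantennary ladder G0F/G0F .. G2F/G2F:
100·Σ(a_i·g_i)/(4·Σa_i), with g_i ∈ {0..4} and abundances renormalized over
that main set.  This is the package's own definition — published values of
this attribute rarely print their formula — and the normalization set is
selectable (`over="main"` or `"all"`) rather than guessed.  Class fractions
are plain sums: sialylated = any NeuAc; oligomannose = both arms HexNAc2;
afucosylated = a complex-type arm (HexNAc > 2) without core fucose, which
excludes oligomannose arms so the two classes partition cleanly, matching
how the classes are reported in practice.

**Confidence intervals.** Replicate percentages get mean ± t·s/√n with
t = t(0.975, n−1); for triplicates t = 4.3027, so replicates (1, 2, 3)
give halfwidth 2.484.

## Zero-charge deconvolution and pattern shifts

The deconvolution is a transparent grid projection, intentionally *not* a
reimplementation of proprietary sliding-window algorithms: score(M) =
Σ_z max(intensity within tolerance of (M + zH)/z), local maxima above a
noise floor median + 5·MAD (plus a relative floor of 0.2% of the maximum
score, since sparse centroid data have zero median).  Flat-topped score
plateaus (tolerance wider than the grid step) are taken at their midpoint,
and each peak's mass is refined to the intensity-weighted mean of the masses
implied by its matched data points — this removes grid quantisation, giving
noise-free accuracy far below the 0.5 Da grid step (well under 10 ppm at
147 kDa).

Pattern-shift detection scans offsets (default −600..+600 Da, step 0.05 Da;
match tolerance 0.5 Da, average-mass domain): at each offset, reference
peaks greedily match the nearest unused query peak (descending reference
intensity), scoring Σ min of unit-normalized intensities (1.0 = identical
pattern).  Only offsets within the tolerance of some pairwise mass
difference can score, so only those are evaluated.  Ties across the
±tolerance plateau break by smaller weighted match distance, and the
returned offset is the match-weighted mean mass difference at the winning
grid point — exact for noiseless shifts, always within one grid step of the
grid argmax.

## Synthetic runs

The generator emulates the native SCX-HPLC-MS experiment: each component
elutes as a Gaussian (default σ = 0.15 min) and ionises into a Gaussian
charge envelope (default z₀ = 26, σ_z = 2, truncated at ±3σ_z and
renormalized); every scan holds one centroid per component x charge at the
theoretical m/z, with mean-one lognormal multiplicative intensity noise
(parameterized by CV), Gaussian m/z jitter in ppm, and Poisson-rate
uniform-m/z baseline centroids.  Scan interval 2 s (10 microscans at 200 ms
injection imply a slow duty cycle; the exact rate is a realism choice),
run length 16 min, resolution 17,500, m/z 2500–8000.  Deposited current is
normalized so a component's EICC area equals fraction × total ion current
(default 10⁶) exactly up to Gaussian truncation; everything is reproducible
from a single integer seed.

Class retention offsets relative to the main peak: monosialylated
−0.68 min, disialylated −1.35 min (acidic variants elute earlier on a pH
gradient), oligomannose +0.21 min, afucosylated and galactosylation
variants 0 (galactose count does not shift retention).  The three-ladder
preset places 0K/1K/2K groups at 9.5/11.0/12.5 min with the 0K group
carrying more oligomannose and slightly higher galactosylation, group
weights 0.5/0.3/0.2.

Preset abundance vectors are built from class levels: minor classes (M5/M5,
afucosylated, sialylated split 2:1 mono:di) take their target percentages
directly and the main ladder fills the remainder with a Binomial(4, p)
galactose-occupancy profile, p = galactosylation level — which reproduces
the requested level exactly under the site-occupancy formula.  Defaults are
an originator-like profile (32.67% galactosylation, 0.45% M5/M5, 0.44%
afucosylated, 2.24% sialylated) and a copy-product-like profile (23.86%,
2.30%, 4.28%, 0.79%); the per-lysine-variant preset uses 25.52/22.85/22.77%
galactosylation and 3.24/1.07/0.93% M5/M5 for 0K/1K/2K.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: isotopic fine structure and envelope shape
(one centroid per charge; profile-mode peak shape, adducts and salt
clusters are absent), chromatographic tailing/fronting and co-elution
interference beyond what the panel masses imply, detector saturation, and
the small-mass-shift congestion (deamidation, +1 Da) that makes those PTMs
unquantifiable by EICC on real instruments.  Recovery results on synthetic
runs bound algorithmic error, not instrumental error.

## Numerical choices and problem sizes

- Spectrum averaging bins are geometric with constant relative width
  1/(4R) (peak width over-sampled 4x), anchored at m/z 100; each output
  point is the intensity-weighted centroid of its bin, so an isolated
  centroid survives binning exactly.
- mzML I/O: PSI-mzML 1.1.0; writer emits uncompressed 64-bit little-endian
  arrays (lossless round trip); reader accepts 32/64-bit and zlib.
  Retention times are minutes internally; second-valued files are converted.
- Degenerate inputs raise: empty glycan-pair lists, all-zero areas, windows
  overlapping no scans, charge ranges emptied by the acquisition window,
  fewer than two replicates.
- Validation sizes: synthetic runs of 480 scans (16 min at 2 s), 9–27
  component panels, deconvolution grids of 0.25–0.5 Da step over 2.5–5 kDa
  mass windows; recovery checks run 5 seeds at 5% CV + 10 ppm jitter and
  triplicates in the acceptance script.  The full test suite and the
  acceptance script each complete in well under a minute.

## Known limitations

- Deamidated (+1 Da) and glycated (+162 Da, galactose-isobaric) species are
  deliberately not quantified by EICC; only the +162 pattern shift is
  detectable.
- Greedy pattern matching is not an optimal assignment; with heavily
  degenerate patterns an optimal matcher could score higher, at the cost of
  transparency.
- The deconvolution scorer assumes the charge-state spacing of a single
  species family; overlapping families with very different masses in one
  window are scored independently but share matched data points
  (no joint deconvolution or peak-area apportioning).
- No vendor raw-file support, no UV trace modelling, no MS2.
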