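# Methods

## Chemistry model

All masses are monoisotopic and derived at runtime from elemental masses
(pyteomics' NIST table); residue masses are recomputed from their elemental
compositions, so no peptide- or modification-level constant is hard-coded.
Protonation uses the proton mass (1.007276 u), not the hydrogen-atom mass;
the electron-mass difference (~0.5 mu at m/z 1000) matters at FTICR
accuracy, and the proton convention reproduces the published [M+H]⁺ values
to < 0.1 ppm. The alternative convention is obtained by adding
`element_masses["H"]` instead of `proton_mass`.

The photo-methionine state machine is a modification registry:

| state | target | Δm (u) | meaning |
|---|---|---|---|
| `pmet_intact` | M | +8.0341 | diazirine analog, unphotolysed |
| `pmet_terminated` | M | −19.9721 | photolysed, alkene termination product |
| `pmet_inserted` | M | −19.9721 | photolysed, carbene inserted into a partner (partner mass added separately) |
| `cam` | C | +57.0215 | carbamidomethyl (iodoacetamide), fixed on every Cys |
| `glycerol_adduct` | M | +92.0473 | whole glycerol captured by insertion; only on a photolysed site |
| `sodiated` | * | +21.9819 | one proton-bearing H exchanged for Na; stacks on the glycerol adduct |

`pmet_intact` exists in the registry but is excluded from default searches:
the MALDI laser photolyses the diazirine in-source, so intact-analog peaks
are not expected in the data this pipeline targets. `include_intact=True`
in the run configuration re-enables it.

## Digestion and numbering

Classic trypsin rule: cleave C-terminal to K/R, suppressed before Pro
(configurable to "cleave always"); none of the peptides relevant to the
14-3-3ζ analysis are affected by the Pro exception. Default `max_missed=2`
(the observed species carry at most one missed cleavage; the headroom is
cheap), default `min_length=4` for the candidate database. The protein
N-terminal peptide is always included. Residue numbering is a run of
consecutive integers from `first_index`, which may be negative — the study
protein numbers its His-tag remnant (−2)GSH(0) with Met1 at index 1 — and
index 0 is a legal position. All reported coordinates are parent numbering,
never array offsets.

The 159–167 peptide is EMQPTHPIR; a published transcription of it with a
G in place of Q is inconsistent with both the canonical P63104 sequence
and the printed [M+H]⁺ 1108.5568, and is treated as a typo. User input is
never silently corrected: sequences are taken as given.

## Candidate database

One species per (Met-bearing carrier peptide, partner peptide, Met site)
for interlinks; unordered peptide pairs are counted once, and a pair of two
Met-bearing peptides yields one entry per choice of reactive chain — same
mass, distinct identities (the m/z 1998 dual interpretation). A peptide
with n Met sites photolysed at k sites yields a *single* mass species
carrying all n-choose-k placements, because the placements are isobaric and
only MS/MS can tell them apart. The terminated dead end and the loop-link
of the same peptide are exact isobars and are cross-referenced
(`isobaric_with`) so that MS1 matching treats them as one interpretation.
Loop-links are only generated when the peptide offers at least two residues
besides the pMet site. In the homodimer, intra- vs inter-molecular cannot
be distinguished by mass; that is the job of the monomer-band control
subtraction, not of the database.

## MS1 matching and control subtraction

Default tolerances are the two instrument classes of the source data:
40 ppm (MALDI-TOF fingerprints) and 2 ppm (FTICR), overridable per run.
Peaks within 0.1 ppm are merged before matching. Control subtraction is
peak-level, not species-level: any dimer-band peak within tolerance of a
monomer-band peak is re-labelled `control_removed`, whatever its
interpretation — mirroring how monomer-band signals were discarded as
intramolecular. The operation is idempotent and keeps survivors' status.
The monomer control is compared at the tolerance of the dimer list's
instrument unless overridden.

## MS/MS model and localization

Only singly-charged b/y ions are modelled (TOF/TOF data), plus the
cross-link cleavage pair: the carrier chain released as its alkene
termination product and the partner chain restored to linear form; their
exact masses sum to the precursor [M+H]⁺ plus a proton. Fragments
containing the linked residue carry the full partner-chain mass minus the
termination shift. Nominal labels use floor(exact m/z), the convention of
the published integer labels (1214.69 → 1214); rounding would mislabel the
1086/1214-class ions. Default matching tolerance is 0.5 u; annotation is a
greedy nearest-match in which each observed peak explains at most one ion.

Localization enumerates every (partner residue × pMet site) hypothesis
across all mass-coincident readings of a precursor. Only *site-determining*
ions — those whose mass differs between at least two live hypotheses —
contribute. A hypothesis gains one support per observed site-determining
ion it predicts and one conflict per site-determining ion observed at a
mass it contradicts; the score is support minus conflicts. A unique
maximum with ≥ 2 supports and zero conflicts is `confirmed`; support with
conflicts, thin support, or a caller-supplied co-elution flag caps the tier
at `weak` (the treatment applied to the putative Met1–Gln77 contact, whose
spectrum is contaminated by a co-eluting glycerol-adduct species); ties are
`ambiguous`, never an arbitrary pick.

One domain rule is added beyond the published description: the C-terminal
K/R of a tryptic peptide is excluded as a candidate link site, because a
cross-linked side chain there would have blocked the cleavage that
produced the observed peptide boundary. Without this rule the published
five-fragment spectrum of the 1342.75 precursor cannot discriminate Gln8
from Lys9 (no observed ion separates them); with it the pipeline reproduces
the published Gln8 assignment. The rule is configurable
(`exclude_tryptic_cterm`).

Positional-isomer mixtures of monolinks are declared when at least two
placements each have ≥ 2 observed *exclusive* fragments (masses no
alternative placement predicts) — reproducing the pMet22 + pMet26 mixture
reading of the 1881.85 species. For adducted monolinks the adduct mass is
not placed on fragments (its site is unknown); only the termination-shift
pattern is used.

## Reconstructed reference spectra

The study's raw peak lists were never deposited. MS1 fixtures use the
printed experimental m/z values verbatim. MS/MS fixtures are rebuilt by
computing all theoretical fragments for the published interpretation and
keeping those whose floor *or* round equals a printed integer label (the
published figures mix both conventions); the fixture peaks carry the exact
theoretical masses the labels identify. This reconstructs which ions were
observed, not their sub-unit calibration errors.

## Synthetic experiments

The generator emulates the study design: the dimer band contains interlink
masses for every tryptic realization of each planted contact (missed
cleavages included) plus everything the monomer band contains; the monomer
band contains dead ends, loop-link isobars (emitted once) and glycerol/
glycerol-Na adducts, each included with probability `photolysis_yield`.
Noise is multiplicative Gaussian ppm error (`ppm_sigma`, default 0.5 ppm,
an FTICR-like scale) because the matching semantics are relative; MS/MS
spectra sample the true hypothesis' fragments at `fragment_coverage`
(default 0.9) with the same relative noise; decoys are tryptic peptides of
a seed-shuffled sequence, so they have realistic masses but cannot be true
positives. Default `photolysis_yield=0.5` reflects partial analog
incorporation; `max_missed=1` matches the observed species. All randomness
flows from one explicit seed.

What the simulation does *not* model: intensities and ionization
efficiency, isotope envelopes, chromatographic co-elution, charge states
above 1+, and calibration drift. Passing recovery tests therefore
demonstrates the identification logic under the stated noise model, not
instrument-level robustness.

Recovery is pair-exact: a planted contact counts as recovered when a
localization verdict equals it; false positives count confirmed-tier
verdicts that were not planted. With no noise and full coverage recovery
is exact by construction; the shipped recovery study uses one planted
contact over 20 seeds per condition, small enough to run in seconds and
large enough to expose a mis-set tolerance (recovery falls to ~0.25 when
the window is 0.1 ppm against 0.5 ppm noise).

## Numerical choices

Theoretical masses closer than 1e-6 u are treated as the same ion during
localization; species ids are stable strings derived from coordinates;
database range queries are closed intervals in relative (ppm) coordinates;
report m/z columns carry 6 decimals so ppm errors are recomputable from
the report itself to < 0.01 ppm. Restraint endpoints default to the
side-chain reactive heavy atom (Met SD, Gln CG, ...) with Cα fallback,
since the published model distances are quoted both ways; the upper bound
defaults to the 5 Å carbene radius.

## Known limitations

Heteromeric search spaces beyond two sequences, semi-tryptic peptides,
a/c/z ions, neutral losses, multiply-charged fragments, intensity-aware
scoring and spectrum-level FDR are out of scope. The monomer-control
subtraction assumes the monomer band was acquired at comparable accuracy
to the dimer band. Table-level sequence-coverage statistics of the source
study depend on unpublished peak lists and are not reproduced.
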