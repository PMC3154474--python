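# Methods

`ptgg` analyses conformational ensembles of B-DNA duplexes carrying a
platinum 1,2-intrastrand GG cross-link (cisplatin- or oxaliplatin-type).
It reimplements, as a reusable pipeline, the analyses typically applied to
such systems: local helical parameters, geometric classification of
Pt-amine hydrogen bonds, distribution comparisons between ensembles, and
superposition/RMSD machinery — together with a synthetic ensemble
generator that provides exact ground truth for all of it.

## Helical parameters

### Base reference frames

Each base gets an orthonormal frame by least-squares (Kabsch)
superposition of the standard reference base geometry (the Tsukuba
consensus coordinate set, embedded in `ptgg._refgeom`) onto the observed
ring atoms (9 atoms for purines, 6 for pyrimidines). The frame origin is
the image of the standard-frame origin; x points toward the major-groove
edge, y along the base long axis, z along the normal. The fit residual
(RMSD, Å) is reported on the frame; for idealized inputs it is numerically
zero, for real coordinates it measures non-planarity and ring distortion.

### Mid-frame decomposition

Intra-base-pair parameters (shear, stretch, stagger / buckle, propeller,
opening) and base-pair-step parameters (shift, slide, rise / tilt, roll,
twist) use the standard-reference-frame **mid-frame (CEHS-style)
convention**: the complementary base frame is flipped 180° about its x
axis; the relative rotation between the two frames is factored through the
symmetric mid-frame (roll/tilt combined via a hinge axis, twist about the
common normal), and translations are the origin displacement expressed in
mid-frame coordinates. Step parameters apply the same decomposition to the
mid-frames of two consecutive pairs.

This is deliberately **not** the curvilinear-axis algorithm of CURVES 5.3.
Values are comparable but not bit-identical for B-form DNA; the mid-frame
convention was chosen because it is fully published and exactly
invertible, which makes the builder/analyzer round-trip a machine-precision
contract (`compose_frames` ∘ `decompose_frames` = identity, verified to
≤1e-6 over the full working range |angles| ≤ 60°, |translations| ≤ 3 Å,
and to ~1e-13 in direct frame tests). Sign conventions are pinned by that
rebuild oracle, not by convention documents.

Angles are reported in degrees in (−180°, 180]; parameters are invariant
under global rigid motion to 1e-9.

### Derived quantities

- **GG plane dihedral** — the angle in [0°, 90°] between the least-squares
  (SVD) base-plane normals of the two cross-linked guanines. The
  literature speaks of a "dihedral angle" of the Pt-GG without defining
  it; this inter-plane-normal realization is our interpretation, chosen
  over signed variants for simplicity. The standard bases are planar only
  to ~1e-3 Å, so "coplanar" inputs give ~1e-4 degrees, not exactly zero.
- **Global bend** — the angle between entry and exit helix-axis estimates,
  each fitted to four terminal pair frames (principal direction of the
  pair normals plus normalized origin increments, oriented along the mean
  normal). A straight ideal duplex gives < 0.5°; a 40° roll planted at the
  central step is recovered within 5°.
- Default parameter designation is the **central four base pairs and the
  steps between them**; terminal pairs are computed only on request, since
  the analyses of interest concern the platinated core.

## Hydrogen-bond classification

A hydrogen bond is declared when the donor–acceptor distance is ≤ 3.5 Å
**and** the donor–H–acceptor angle is ≥ 135°. Both cutoffs are inclusive
(boundary tests codify this choice; the usual "cut-off" phrasing does not
specify strictness). Donors are base N–H/N–H₂ groups plus Pt carrier-ligand
amine N–H when a Pt moiety is present; acceptors are the base O/N lone-pair
sites (G-O6, G/A-N7, T-O4, T-O2, C-O2, …). Missing amine/imino hydrogens
(NMR or crystal-derived inputs) are placed at idealized sp2 geometry
(N–H 1.01 Å, in-plane), flagged in the output.

Frames are classified by which Pt-amine contacts they form — by default
G7-O6 (the O6 of the 3′ platinated guanine) and T8-O4 (the O4 of the
3′-flanking thymine) — giving the four-class taxonomy
{None, G7-O6, T8-O4, T8-O4+G7-O6}. The combination is its own class, so no
priority ordering is needed. Watson–Crick bonds are detected like any
others but cannot enter classification, because species definitions
restrict donors to the Pt residue. Frequency tables report percentages at
a configurable precision (integer by default); with k classes the printed
column may sum to 100 ± k/2 in the last digit — published tables of this
kind show exactly this behaviour — and the validation bound allows for it.
Per-bond occupancy is the sum over all classes containing that bond.

## Ensemble comparison statistics

- **Z-score** (small families, n ≈ 14): Welch form,
  Z = (m_a − m_b) / √(s²_a/n_a + s²_b/n_b). The source material for this
  statistic is not public; the Welch form was chosen because the families
  are small with no reason to assume equal variances, and it is isolated
  in one function so a pooled-SD variant is a one-line swap. Null
  calibration over seeded 14-vs-14 families keeps |Z| < 3 in ≥ 95% of
  heat-map cells.
- **KS statistic** (large MD-style ensembles): the exact two-sample
  sup-difference of ECDFs computed on the merged sorted samples
  (tie-exact; verified against an O(n²) scan and against
  `scipy.stats.ks_2samp`).
- **KS ratio**: D divided by the asymptotic two-sample critical value
  c(α)·√((n_a+n_b)/(n_a·n_b)), c(α) = √(−½ ln(α/2)), α = 0.05 by default,
  so a ratio above 1 marks significance at α. This normalization is an
  interpretation (the original formula is unavailable); it is flagged as
  such and kept behind one function.
- **Comparison matrices** hold one statistic per (parameter, comparison)
  cell over a shared designation; no multiple-testing correction is
  applied (matching how such heat maps are reported), but a Bonferroni
  threshold is available as metadata.
- **Class-conditional histograms** are normalized over the total frame
  count across *all* classes, so each class's area equals its frequency
  and curves show relative abundance. Bins are Freedman–Diaconis on the
  pooled sample, shared across classes for comparability. External
  single-structure reference values (e.g. from a protein–DNA co-crystal)
  are attached for rendering as vertical lines; they are user inputs, not
  package data.
- **Equilibration trimming** removes a burn-in fraction per run (default
  0.4, i.e. keep the final 60% — the convention of keeping the last 6 of
  10 ns); concatenated runs are recognized by a `run_id` column and
  trimmed independently.

## Superposition and RMSD

Kabsch superposition (proper rotations only; optional weights) underlies
everything. The **mean structure** is the iteratively superposed
coordinate average, initialized from model 1 and converged when the mean
moves < 1e-6 Å; the iteration is deterministic given model order, and the
published protocols for such numbers are rarely stated — the reported
spread absorbs protocol differences. **Family RMSD** reports each model's
RMSD to that mean. The **centroid** minimizes mean pairwise RMSD (ties to
the lowest index). **RMSD series** are mass-weighted by default (with unit
weights they equal unweighted exactly) and smoothed by a centered moving
average with truncated (not reflected) edge windows. "Heavy atoms" means
all non-hydrogen atoms including the Pt moiety.

## Synthetic ensemble generator

The generator is the stand-in for MD trajectories (tens of thousands of
frames) and NMR families (~14 conformers), with exact ground truth.

- **Sequence**: the default 12-mer is 5′-CCTCTGGTCTCC-3′ paired with
  5′-GGAGACCAGAGG-3′, numbered 1–12 / 13–24 with residue i paired with
  25−i; G6/G7 are the platinated guanines, T5/T8 the flanks. Positions
  2–4 are not constrained by any labelled analysis and were fixed once.
- **Parameter draws**: each pair/step parameter is Normal(mean, SD),
  independent across frames and parameters by default; an AR(1) knob
  exists for time-series-shaped tests (off by default). B-form means are
  twist 36°, rise 3.38 Å, all else 0. Free-DNA SDs default to 4° / 0.25 Å
  (typical room-temperature fluctuation scales for B-DNA).
- **Builder**: standard-geometry bases placed by chaining mid-frame
  transforms — the exact inverse of the analyzer. The sugar–phosphate
  backbone is an idealized rigid template per base frame: present so
  structures parse as nucleic acids, but with meaningless torsions. No
  analysis in this package reads backbone atoms beyond C1′.
- **Pt moiety**: Pt placed on the major-groove bisector of the two
  guanine N7 lone pairs at 2.0 Å from each N7 (requiring N7–N7 < 4 Å,
  i.e. a genuinely distorted step — attaching Pt to an undistorted B-form
  duplex fails loudly); two amine N atoms complete the square plane at
  2.05 Å; three sp3 hydrogens per amine at 109.47°.
- **The `pt_gg` distortion preset** (central step roll 26°, twist 25°,
  slide −0.9 Å, shift −0.3 Å, rise 3.2 Å; guanine-pair buckles +6°/−14°)
  encodes the hallmark cross-link distortion — elevated roll at an
  unwound, compressed step with roof-shaped buckling. These are config
  choices producing a chemically plausible geometry in which both amine
  contacts are realizable, **not** literature values. When Pt is on, the
  cross-linked pairs and their steps are clamped to 0.75° / 0.04 Å SD and
  the 3′ flank to 1.5° / 0.08 Å (the covalent cross-link rigidifies the
  core); these scales were fixed once, for ≥ ~5σ geometric feasibility
  margin of the planted contacts, before any recovery test was run.
- **Class planting** draws a class per frame from the requested fractions
  and realizes it deterministically through amine-hydrogen orientation
  alone: "formed" contacts aim an N–H straight at the acceptor (exact by
  construction, errors out if the acceptor is beyond the distance cutoff),
  "broken" contacts are found by a deterministic grid search over the sp3
  cone angles. Every generated ensemble is re-classified and any
  plant/classifier mismatch is a hard error, so ground-truth labels are
  exact at 100%, not approximately.

### What a green test does and does not establish

The generator emulates the *statistical shape* of duplex ensembles:
Gaussian helical-parameter fluctuations around a stated mean, a covalently
clamped platinated core, and planted hydrogen-bond class structure. It
does **not** emulate force-field energetics, solvent/counter-ions,
backbone conformational substates (BI/BII, sugar pucker), sequence-specific
bending beyond what is planted, or temporal correlation (unless AR(1) is
switched on). Recovery tests therefore establish the correctness of the
*analysis machinery* — decomposition, classification, statistics — on
ensembles whose truth is known; they do not validate any claim about real
Pt-DNA conformational dynamics.

## Numerical choices

- Both hydrogen-bond cutoffs inclusive; classification is a deterministic
  function of geometry (re-running is bit-identical).
- Angle wrapping to (−180°, 180]; mid-frame decomposition refuses
  anti-aligned normals (would indicate a strand-sense error).
- Kabsch excludes reflections by sign-correcting the smallest singular
  value; near-degenerate (collinear) point sets warn but return.
- Frequency-table rounding slack: k·½·10^(−p) for k classes at p decimals.
- All randomness flows from a single seed per generator spec
  (`numpy.random.default_rng`); derived sub-seeds use `SeedSequence`.
- Builder range guard: |translations| ≤ 6 Å, |angles| ≤ 85° (beyond which
  the mid-frame hinge construction approaches its ±90° singularity).

## Known limitations

- Helical parameters follow the mid-frame convention, not CURVES 5.3;
  whether the inter-convention differences affect any qualitative
  conclusion about a given dataset is untested here.
- The GG "dihedral angle" is the unsigned inter-plane angle; other
  definitions exist.
- The idealized backbone makes whole-model RMSD values on synthetic data
  systematically cleaner than on real structures.
- No mmCIF, RNA, triplex, or protein support; the reference values from
  protein–DNA co-crystals must be supplied by the user as numbers.
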