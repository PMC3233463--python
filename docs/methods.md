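# Methods

## Scope and model

`qsar3d` implements the ligand-based lattice-QSAR workflow for a
congeneric series: rigid substructure alignment, CoMFA/CoMSIA field
descriptors, PLS regression with leave-one-out (LOO) cross-validation,
external validation, robustness checks, and StDev\*Coeff contour
extraction. Receptor-based stages (docking-pose alignment, MD
refinement) are deliberately out of scope: they belong to external
engines, and the statistics here are agnostic to how the aligned
conformers were obtained.

The modelling assumptions are the classical ones of field-based QSAR:
one bioactive-like conformer per compound, a common binding mode
expressed through the shared anchor, and an activity that is (after
alignment) approximately linear in the sampled field values.

## Alignment

Least-squares rigid superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) of the atoms matched
by an anchor SMARTS; only mapped atoms enter the fit, matching the
semantics of database alignment in the standard tooling. The default
anchor — `[#15](~[#8])(~[#8])~[#8]`, a phosphorus bonded to at least
three oxygens — fits the phosphate/phosphonate group common to the
motivating inhibitor series and is configurable, since the exact atom
set of "the phosphate anchor" is a modelling choice. Symmetric
patterns produce several automorphic mappings; all are evaluated and
the minimal-RMSD one kept, with deterministic lexicographic ordering
of mappings so ties cannot depend on toolkit iteration order.
Superposition requires ≥3 non-collinear pairs (second singular value
of the centred point set > 1e-8), otherwise the fit is not unique and
an error is raised.

## Lattice and fields

- **Grid**: spacing 2.0 Å (the conventional CoMFA resolution), union
  bounding box of the aligned series extended by a 4.0 Å margin on
  every face and snapped outward to whole grid steps; degenerate axes
  widen to two points. Column order is documented (x fastest, then y,
  then z) so descriptor indices are stable across runs.
- **CoMFA steric**: 6-12 Lennard-Jones energy of an sp³-carbon probe
  (R = 1.70 Å, ε = 0.107 kcal/mol) against a Tripos-style element
  table (shipped in `params.py`); radii combine by sum, well depths by
  geometric mean. Energies are truncated to ±30.0 kcal/mol; the
  +30 clamp marks "probe inside molecule" points.
- **CoMFA electrostatic**: 332.0636·q_probe·q_i/(ε(r)·r) kcal/mol with
  distance-dependent dielectric ε(r) = r (the common SYBYL default;
  `dielectric="constant"` switches to ε = 1). At sterically clamped
  points the Coulomb value is physically meaningless, so it is
  replaced by the column mean over the unclamped molecules (0 when no
  molecule is unclamped); the replacement mask is kept in block
  metadata. The mean is taken over the molecules passed to the block
  builder — the pipeline passes the full aligned dataset.
- **CoMSIA**: A_k(q) = −Σᵢ ω_probe,k·ω_ik·e^(−α·r_iq²) with α = 0.3
  and a probe of radius 1.0 Å whose five properties are all +1. Atom
  properties follow the original convention: steric ω = r_vdW³,
  electrostatic ω = partial charge, hydrophobic ω = a per-atom
  contribution (Crippen logP contributions for file-derived
  molecules), donor/acceptor ω ∈ {0, 1} from rule-based flags (donor:
  N/O bearing an explicit hydrogen; acceptor: N/O without positive
  formal charge). No truncation — the Gaussian is smooth everywhere,
  which is the point of the similarity-index formulation.
- **Column filtering**: a minimum-sigma filter drops columns whose
  training-set standard deviation is below a threshold. The default is
  0.0 (keep everything): the threshold used by the original tooling is
  not knowable from published statistics, and a kcal/mol-scale default
  would be wrong for similarity-index units. It is exposed as config.

Charges: file-supplied partial charges always take precedence; missing
charges are filled by plain Gasteiger (PEOE) assignment. The
Gasteiger–Hückel hybrid used by commercial tooling is proprietary; the
downstream statistics are charge-scheme-agnostic, so this is a
substitution of convenience, not of substance.

## PLS and internal statistics

NIPALS PLS (scikit-learn's `PLSRegression` with scaling disabled)
behind a wrapper that owns centring, column scaling and coefficient
back-transformation to original descriptor units. Scaling options:
`none`, `autoscale`, and the default `block` — each field block
rescaled to equal total variance (CoMFA-standard scaling), which makes
predictions invariant to multiplying any one block by a constant and
prevents the kcal/mol-scale CoMFA columns from drowning the
dimensionless CoMSIA ones in mixed models.

- **q²** (Eq.-style definition): 1 − PRESS/Σ(y − ȳ)², where every LOO
  fold refits the entire pipeline (centring and scaling included) —
  stricter than per-model shortcuts — and ȳ is the training-set mean.
- **Component selection**: the q²-vs-components profile is scanned and
  the smallest count within 0.005 of the maximum is chosen; this
  mirrors the usual audit that "further improvement is not obtained"
  with additional components, and protects against overfitting the
  component count itself.
- **SEE** uses the n − PCs − 1 denominator and **F** is computed from
  r² with (PCs, n − PCs − 1) degrees of freedom — both conventions of
  the standard tooling's report, which prints the values without
  formulas.
- Degenerate constant predictions report r² = 0 with a warning rather
  than NaN, so batch sweeps never crash on a dead model.
- **Field contributions**: Σ|coefficient·sd| per block, normalised to
  sum to one.

A rank check (SVD of the preprocessed training matrix) rejects
component counts above the matrix rank with a suggestion to use fewer.

## External validation

r_pred² = 1 − PRESS/SD with SD the squared deviation of the test
activities about the **training** mean — this is what makes the
statistic sensitive to systematic offset, unlike r_test². The
through-origin quantities follow the Golbraikh–Tropsha convention:
k is the slope of observed-versus-predicted through the origin
(k′ the swapped orientation; both are always reported, which makes the
well-known orientation ambiguity in the literature harmless), and r_0²
is the through-origin r² in the observed-on-predicted orientation,
with the alternate r′_0² also emitted.

r_m² = r_test²·(1 − √(r_test² − r_0²)). The square-root form is
adopted deliberately: it is the form that reproduces the published
derived values (0.909/0.901 → 0.828 and 0.741/0.693 → 0.579 at three
decimals), and the form given in the statistic's defining reference;
printed versions of the formula elsewhere drop the radical. When
r_0² > r_test² the difference is clamped at zero with a warning
(r_m² = r_test²), the statistic's best case.

Acceptance: r_pred² > 0.5 (strict), r_test² > 0.6 (strict),
(r_test² − r_0²)/r_test² < 0.1, and k or k′ in [0.85, 1.15]. Bootstrap
(default 100 runs, resampling training rows with replacement at fixed
component count; degenerate resamples redrawn) and y-randomization
(default 50 activity permutations, LOO q² recomputed per scramble)
each use one seeded `numpy.random.Generator` stream.

## Contours

StDev\*Coeff = training-column standard deviation × PLS coefficient,
re-embedded on the grid with filtered columns rendered as 0 (keeps DX
grids rectangular). "Favoured level 80 %" is interpreted as the 80th
percentile of the nonzero StDev\*Coeff distribution on the positive
side (disfavoured analogously on the negative side) — a
contour-by-contribution analog chosen because the level semantics are
not defined anywhere publishable; the percentages are config. A level
falling on the wrong side (e.g. no negative values) is reported absent
with a warning. OpenDX export is hand-written (≈40 lines) so the
chosen iso-levels can be recorded as header comments; the format is
verified in tests against an independent DX parser.

## Synthetic pseudo-receptor

The generator emulates the *structure* of a real congeneric-series
study: a rigid shared anchor (phosphate + three-carbon core, explicit
charges approximating a deprotonated phosphate monoester), six
substituent sites at lattice positions around the core, pseudo-atom
substituents with randomized element, charge N(0, 0.35²),
hydrophobicity N(0, 0.6²) and donor/acceptor flags, site occupancy
0.65, and positional jitter σ = 0.3 Å — small relative to the 2.0 Å
grid so the planted signal remains resolvable. Molecules are emitted
at random rigid poses (molecule 0 stays in the canonical frame as the
alignment template) so the alignment stage is genuinely exercised.

Activities are planted as offset + Σ w_c·A_kind(c)(position_c) + ε,
ε ~ N(0, noise_sd²) with noise_sd = 0.1 pIC50 units by default (small
relative to the ~3-unit activity span, comparable to good assay
reproducibility), then affinely rescaled into the conventional
4.870–8.000 pIC50 window; the positive rescale preserves weight signs,
recorded in the returned ground truth. The default receptor mixes
steric, electrostatic and acceptor centers of both signs, so recovery
tests exercise multi-field models and sign recovery simultaneously.

What the generator does **not** emulate — and what passing recovery
tests therefore cannot show: real conformational flexibility,
charge-assignment error, activity cliffs from binding-mode switches,
correlated substituent chemistry, or assay heteroscedasticity. The
planted relation is exactly linear in field values at lattice
positions, so recovery results are an upper bound on what identical
settings would achieve on laboratory data.

## Problem sizes in the test suite

Recovery and null-control checks run at the emulated study size
(105 compounds, 77/28 stratified split, 10 seeds for recovery, 50
scrambles, 200 null datasets at n = 30); the 31-model field sweep and
pipeline determinism checks use reduced series (n = 24–40) with
correspondingly capped component counts, which the sweep's
enumeration count and report schema do not depend on.

## Known limitations

- The LJ element table covers the ten elements common in drug-like
  molecules; exotic elements raise rather than defaulting.
- MOL2 reading handles the TRIPOS MOLECULE/ATOM/BOND records as parsed
  by RDKit; SDF is restricted to V2000.
- `r_0²` on nearly constant prediction vectors is numerically
  fragile; the degenerate path reports r_test² = 0 with a warning
  instead of propagating NaNs.
- Bootstrap statistics are in-sample r²/SEE per resample (the
  convention of the emulated report), not out-of-bag estimates.
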