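# Methods

## Data model and conventions

All coordinates are in Å; readers of nm-based formats must convert at
the boundary (one canonical unit avoids silent factor-10 errors between
scattering-space and contact-map quantities). Residues are numbered
1-based everywhere; frames are 0-based internally. Elements are
inferred from PDB atom names; an unknown element is an error, never a
silent default mass. Hydrogens are optional in inputs; the
hydrogen-bond analysis requires them and fails loudly otherwise.
Multi-MODEL PDB I/O is delegated to biotite; round-trips are exact at
the format's 10⁻³ Å precision.

## Descriptors

- **R_g** = √(Σ wᵢ|rᵢ−r̄|²/Σ wᵢ), mass-weighted by default (the
  trajectory-tool convention); unweighted is available for comparison
  with polymer-model closed forms.
- **R_ee**: Euclidean distance between the first residue's backbone N
  and the last residue's backbone C by default. Whether termini heavy
  atoms or residue centers are meant varies between tools; the
  selectors are explicit parameters so users can pin either.
- **Polymer shape** P_S = R_ee²/R_g², dimensionless; exactly 12 for a
  continuum thin rod (a discrete n-point rod gives 12(n−1)/(n+1),
  which the tests assert exactly).
- **SASA** (Shrake–Rupley): per atom, the fraction of quasi-uniform
  golden-spiral points on the expanded sphere (r_vdw + probe) not
  inside any neighbor's expanded sphere, times the expanded-sphere
  area. Defaults: probe 1.4 Å (water), 960 points, Bondi vdW radii.
  A point exactly on a neighbor's surface counts as buried (tolerance
  10⁻⁸ Å) so coincident identical atoms have zero SASA. Validated
  against an independent Monte-Carlo surface integration (10⁴
  points/atom) to 2%.
- **Superposition**: Kabsch via SVD with a determinant correction
  (always a proper rotation); a (near-)collinear fitting subset is an
  error because the rotation is then ill-determined.
- **RMSF**: frames are first aligned to frame 0 (so results cannot
  depend on each frame's arbitrary global placement), then superposed
  onto the running mean structure for two iterations; per-atom
  fluctuations are averaged within residues. The fitting group is the
  backbone (N, CA, C) by default — the conventional choice when the
  original fitting group is unspecified.
- **Contact maps**: the minimum-distance map takes the minimum over
  all selected frames (an "ever came this close" statistic), while
  mean-minimum pair distances average the per-frame minima (a typical
  proximity statistic); the former is always a lower bound on the
  latter, which the tests assert. Hydrogen bonds use the geometric
  criterion donor–acceptor ≤ 3.5 Å and H–donor–acceptor ≤ 30° (the
  common trajectory-tool default); donors are N/O atoms with a
  covalent hydrogen (H within 1.25 Å), acceptors all N/O. Maps are
  donor-rows by default; symmetrization is a flag.

## Decomposition

X_conf,i = α·(R_g,i/⟨R_g⟩ + R_ee,i/⟨R_ee⟩ + SASA_i/⟨SASA⟩) with
arithmetic means pooled over all analyzed frames. α is a *multiplier*,
not an exponent: with α = 5 each ratio averaging to 1 puts the central
group at 15 with populated neighbors near 10 and 20, which is the
observed grouping; exponentiation (3⁵ = 243) is not compatible with
integer group labels of that magnitude. ⟨X_conf⟩ = 3α holds to machine
precision and is asserted.

Grouping is round-half-up to the nearest integer (the printed group
labels are integers but the tie rule is otherwise unstated; half-up is
deterministic and monotone). Empty groups are dropped from outputs.
Single-descriptor decomposition uses fixed-width bins with the same
nearest-multiple rule. Every decomposition asserts the partition
property (each frame in exactly one group).

Per-group summaries: DSSP class fractions (each group row sums to 1
over the 9-letter alphabet; the unassigned class can be hidden for
display but is never renormalized away), hydrogen-bond maps restricted
to group frames (group-size-weighted maps sum exactly to the
whole-ensemble map), and pair × group mean-minimum-distance tables.

The propensity–extension KDE uses scipy's Gaussian KDE with Scott's
rule; the evaluation grid extends 5 bandwidths past the data range so
the gridded density integrates to 1 within 1%. A zero-variance axis is
an error with guidance rather than a degenerate density.

## Landscapes

Backbone φ/ψ angles (IUPAC sign convention; verified against mdtraj in
the test suite) are encoded as sin/cos pairs to remove periodicity.
PCA uses an eigendecomposition of the covariance with a deterministic
sign convention (largest-magnitude loading positive). tICA solves
C(τ)v = λC(0)v on mean-free features with the symmetrized lagged
covariance and a ridge ε = 10⁻⁶ on C(0) for well-posedness; after
symmetrization the eigenvalues are real autocorrelations with |λ| ≤ 1
up to regularization error. The default lag is 50 frames; it is a raw
frame count with no physical-time claim, since the saving interval of
any given trajectory is not the package's to assume.

Free-energy landscapes: ΔF_i = −k_B T ln(n_i/n_max) on a 2D histogram
(default 64×64 over the projection's bounding box, T = 298 K, output
in k_BT or kJ/mol). The most populated bin is the zero of energy;
optionally the field is shifted so the least-populated *occupied* bin
sits at zero and all others are negative. Unoccupied bins are masked,
never ±∞, and serialize as a sentinel token.

## Clustering and representatives

k-means is scikit-learn's (k-means++ init, best of 10 restarts,
deterministic per seed). The elbow is the interior k maximizing the
second difference of the inertia curve; a flat or degenerate curve
falls back to the smallest candidate k. Representatives are *medoids*
— the member frame minimizing mean pairwise superposed RMSD — rather
than coordinate averages, because an averaged conformation of a
disordered ensemble is generally unphysical while a medoid is always a
real frame. Medoid search is exact up to 2000 members and seeded
subsampling beyond. The per-group pipeline (dihedral features → PCA to
2 components → elbow → k-means → medoids) is bit-reproducible from one
seed; 2 components matches the plotted projections and is a parameter.

## SAXS

Rebinning joins consecutive blocks of 10 points (means of q and I;
σ propagated as √(Σσ²)/n; a trailing partial block is averaged as-is).
χ² = Σ(E_i−S_i)²/S_i exactly as defined, with no division by N and no
σ weighting; a conventional σ-weighted reduced χ² is provided as a
clearly separate variant. The full comparison protocol normalizes both
curves by their own Guinier I(0), rebins the experimental curve, and
linearly interpolates the model onto the rebinned grid so the point
counts match.

The Guinier fit regresses ln I on q² starting from the 5 lowest-q
points and iteratively grows/shrinks the window to q·R_g ≤ 1.1 until
it stabilizes; R_g = √(−3·slope), I(0) = exp(intercept). On an exact
Guinier curve this recovers R_g to better than 0.1%. On a *flexible
chain* (Debye curve) the same protocol systematically underestimates
R_g by ≈4–5%: ln P_Debye(x) = −x/3 + x²/36 with x = (qR_g)², so the
linear fit's slope is biased by ≈(q_maxR_g)²/14 in R_g² — an intrinsic
property of the qR_g ≤ 1.1 window, not a defect of the optimizer. The
test suite pins this bias band (3–6% low) rather than pretending the
fit is unbiased; recoveries within ~1% require restricting to
qR_g ≲ 0.5.

The Debye calculator I(q) = ΣᵢΣⱼ sinc(q·rᵢⱼ) uses unit form factors —
a geometry-only model intensity for fixtures and desk-scale model
comparison, deliberately without atomic form factors or hydration
shells. I(q→0) → N², and a Guinier fit of a rigid cluster's Debye
curve recovers the cluster's unweighted R_g within 2%.

## Sequence parameters

Charges: K, R → +1; D, E → −1; histidine neutral by default (neutral-pH
convention, matching the simulation protocol these analyses accompany);
termini are not counted. κ follows Das–Pappu: blob asymmetry
σ = (f⁺−f⁻)²/(f⁺+f⁻) in sliding blobs of width 5 and 6,
δ = ⟨(σ_blob−σ_seq)²⟩, normalized by the δ_max of the maximally
segregated rearrangement of the same composition, averaging the two
blob sizes. δ_max is searched over segregated templates: all
three-block arrangements (neutrals split around a positive and a
negative block) *plus* arrangements splitting one charge type across
both ends — the latter family is needed because for some compositions
(e.g. a scarce minority charge) the true permutation maximum places the
minority at both termini. The constructive δ_max matches exhaustive
permutation on all short compositions tested, and a
fully-segregated sequence is its own δ_max arrangement (κ = 1 exactly).
κ is undefined (reported as not-applicable, never 0) without charges of
both signs or when the sequence is not longer than the largest blob.

Hydropathy is the mean Kyte–Doolittle value shifted by +4.5 onto
[0, 9]. The disorder-promoting set is {T, A, G, R, D, H, Q, K, S, E, P}.
Window profiles are unweighted means over odd windows, with
Kyte–Doolittle and Zhao–London trans-membrane tendency tables built in.
Phosphorylated residues are outside the 20-letter alphabet; analyses of
phosphopeptides run on the unmodified wild-type sequence.

## Synthetic generator

Backbones are built residue-by-residue from sampled (φ, ψ) with ideal
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, trans ω = 180°,
backbone N, H, CA, C, O only). Two dihedral basins are mixed per the
compactness parameter: helix-like (−57.8°, −47.0°) and extended/PPII
(−70°, +145°), each with Gaussian jitter σ = 15° (a planted helix span
uses σ = 2° so its i→i+4 hydrogen-bond geometry stays near-ideal, and
background helix labels are suppressed so the span carries the
occurrence-profile mass). The heterogeneous ensemble draws per-frame
compactness from Beta(1.2, 1.2) — broad with populated tails — which
makes R_g, R_ee and SASA broad and mutually correlated (pairwise
Pearson r > 0.5 at 38 residues) and populates several X_conf groups at
α = 5. Label series draw DSSP classes with a PPII probability linear in
the frame's R_ee percentile. The two-state series is a symmetric Markov
chain read through per-channel loadings plus Gaussian noise. All
generators are pure functions of their spec (seed-deterministic).

What the generator does *not* emulate: excluded volume (self-clashes
are not resolved), side chains, solvent, force-field energetics, or
realistic kinetics beyond a two-state switch. Passing tests therefore
demonstrate the correctness of the *analysis machinery* on ensembles
with the right broad-and-correlated descriptor structure — not the
physical realism of any particular peptide's ensemble.

## Problem sizes and numerical choices in the test suite

The suite runs on desk-scale inputs chosen to make each property
sharp: 38-residue chains, 400-frame heterogeneous ensembles (SASA at
96 sphere points there; 960 elsewhere), 10⁴ frames for partition
checks, 10⁵ points for histogram oracles, 20 seeds for tICA recovery
and 50 for medoid robustness. Dihedral recovery is exact to 10⁻⁶°
against stored ground truth and to ~0.1° against an external tool
through a PDB round trip (the format's 10⁻³ Å rounding dominates).

## Known limitations

- The Guinier-on-Debye bias above means fitted R_g values for
  disordered chains carry a systematic ≈4–5% underestimate at
  qR_g ≤ 1.1; compare like with like (same window) when comparing to
  other software.
- The hydrogen-bond donor inventory is inferred from frame-0 geometry
  (H within 1.25 Å of N/O), not from an explicit bond table.
- κ's δ_max template search is O(L²)–O(L³) in sequence length; fine
  for peptides, not intended for full-length proteins.
- The Debye calculator's unit form factors make absolute intensities
  arbitrary; only curve *shapes* are comparable to experiment.
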