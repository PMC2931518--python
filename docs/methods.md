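# Methods

## Scattering model

The intensity of M point scatterers, averaged over orientations, is the
Debye sum I(q) = Σᵢ Σⱼ Fᵢ(q)Fⱼ(q) sinc(q rᵢⱼ) with sinc(x) = sin(x)/x and
sinc(0) = 1. The double sum includes the i = j diagonal, so the forward
scattering I(0) = (Σᵢ Fᵢ(0))² holds exactly; this identity is used as a
closed-form test of the engine. Intensities are evaluated on a fixed grid
of Q = 51 bins of width Δq = 0.015 Å⁻¹ covering 0–0.75 Å⁻¹ at the left bin
edges (so q runs 0, 0.015, …, 0.750). The engine computes exact Euclidean
distances over the full M×M pair set — no distance-histogram binning — so
that equality with an independent brute-force evaluation is meaningful to
machine precision (the oracle-equivalence tests demand ≤ 1e-12 relative).
Off-grid q values are served by linear interpolation of the form factors;
grid-point evaluation is the canonical mode and interpolation never
extrapolates beyond [0, 0.75] Å⁻¹.

`np.sinc` handles the x = 0 singularity analytically, which matters
because q = 0 is a grid point and rᵢᵢ = 0 always occurs.

## Coarse-grained representations

Two bead alphabets are supported:

* **two-body** (21 labels): a generic backbone bead `BB` at the unweighted
  centroid of the N, CA, C, O, CB (and OXT) atoms present; a side-chain
  bead per residue type at the centroid of the remaining heavy atoms;
  glycine and alanine yield a single whole-residue bead (`GLY*`, `ALA*`).
  The Cβ atom is deliberately pooled into the backbone centroid.
* **one-body** (20 labels): one bead per residue at the centroid of all
  heavy atoms.

Centroids are unweighted means of heavy-atom coordinates (hydrogens are
excluded throughout). Heavy-atom masses are nearly equal, so an unweighted
centroid and a mass-weighted one differ negligibly; the unweighted form is
used because it is exactly reproducible from coordinates alone.

Parsing keeps altloc `' '`/`'A'` only (single-conformer convention), drops
HETATM records and waters, and works on one chain per run. A residue
missing all side-chain heavy atoms is emitted as a backbone-only bead with
a warning rather than an error, because real crystal structures contain
truncated side chains; a residue with no atoms at all, or an unknown
residue type without an entry in the optional residue map (e.g.
`{"MSE": "MET"}`), is an error.

## Error model

The assumed experimental error of a reference curve is the relative
profile

    σ_q = β (q + α) I_q,   α = 0.15, β = 0.3,

i.e. 4.5% of the intensity at q = 0 growing linearly to 27% at
q = 0.75 Å⁻¹. This tightens the classic flat 30% heuristic everywhere on
the grid, most strongly in the low-to-mid q range that matters for
structure prediction. σ is floored at 1e-12·max(I) to guard against zero
intensities. The same σ enters the training likelihood, the S statistic

    S = Σ_q [(I_q − I′_q)/σ_q]² / (Q − 1),

and the Gaussian log-likelihood (with normalization constants included;
they cancel in energy differences because all conformations of a decoy set
share the reference curve's σ).

## Form-factor estimation

For each q-bin independently, the posterior of the 20- or 21-dimensional
form-factor vector under a uniform box prior [0, f_max]^L (f_max = 40,
well beyond published dummy-atom amplitudes) is the product of per-structure
Gaussians N(I_q,i | I′_q,i, σ_q,i), with σ_q,i computed from each
structure's own reference intensity. The Debye sum is regrouped by bead
type once per structure, I′ = f̄ᵀ G f̄ with G_tu(q) = Σ pairs sinc(q r), so
each posterior evaluation costs O(L²) in the number of types, not O(M²) in
beads; the regrouped evaluation is tested against the direct kernel at
1e-10 relative.

Sampling is plain Metropolis–Hastings: a randomly chosen component f is
re-drawn uniformly from [max(0, f−m), min(f_max, f+m)] with m = 1.5, and
the acceptance ratio includes the forward/reverse window widths so
detailed balance holds at the box edges (verified empirically by
transition-count flow balance on a discretized target). Chains start from
a uniform draw in the box, run 2·10⁵ iterations by default with 5·10⁴
burn-in, and keep every 50th post-burn-in state; the thinning default
keeps the exact O(T²) medoid computation cheap while leaving ~3000 samples
per bin. Each bin derives its seed as (seed + bin index), so results are
reproducible under any execution order. The point estimate per bin is the
medoid — the sample minimizing the summed Euclidean distance to all other
samples, ties broken toward the earliest sample.

**Annealed burn-in.** When the likelihood σ is scaled far below the
nominal error model (see the recovery harness below) the posterior becomes
a thin curved valley, and a cold single-component chain freezes at the
first coordinate-wise local minimum it reaches. With `anneal=True` the
burn-in starts at the nominal σ and tightens it geometrically to the final
value, letting the chain settle into the global basin before sampling;
post-burn-in sampling is always plain MH at the final σ. Generalized-
ensemble samplers solve the same mixing problem in the large-scale
setting; annealing is the minimal equivalent for per-bin estimation and
leaves the equilibrium sampler untouched.  In the same regime
``estimate_table`` supports multi-start estimation (``restarts``): several
independently seeded chains per bin, keeping the one whose medoid attains
the highest posterior — a frozen chain loses this comparison by an
enormous margin, so the selection is unambiguous.

## Synthetic fixtures

The fixture generator emulates curated training/validation/decoy data:

* **structures** — self-avoiding Cα walks (3.8 Å steps, ≥ 4.0 Å
  non-neighbor clearance) with N, C, O, CB placed at fixed ideal offsets in
  a local frame and side-chain heavy atoms (real per-residue counts and
  element compositions, e.g. 4 side-chain heavy atoms for Leu, 10 for Trp)
  clustered 1.5–3.5 Å from CB. The default amino-acid composition follows
  natural frequencies, giving ≈ 7.8 heavy atoms per residue — hence
  two-body k ≈ 4.2 and one-body k ≈ 7.8.
* **reference curves** — the all-atom Debye oracle with q-independent
  electron-count factors (C 6, N 7, O 8, S 16), plus optional Gaussian
  noise of sd = noise_level·σ_q clipped at zero. The electron-count oracle
  is a simplified stand-in for a vacuum + excluded-volume atomic model, so
  fixture-trained tables are internally consistent but not comparable to
  tables trained on other reference generators.
* **decoys** — seeded rigid hinge rotations of chain suffixes with
  magnitude growing linearly across the set, yielding an RMSD ladder;
  scale 0 reproduces the native exactly.

What the fixtures do **not** model: Ramachandran-valid backbone geometry,
side-chain rotamers, hydration shells, or q-dependent atomic form factors.
Tests passing on fixtures therefore demonstrate the correctness and
internal consistency of the estimation and scoring machinery, not the
absolute accuracy of any particular form-factor table on experimental
data.

## Parameter-recovery harness

The recovery experiment regenerates a known "generating" table
(F_t(q) = A_t·exp(−q²R_t²/2), amplitudes 15–35, bead radii 1.2–2.2 Å —
electron-count-scale amplitudes with moiety-scale Gaussian decay), builds
20 training structures, computes their reference curves from that table,
and re-estimates it at reference-noise levels {1, 0.3, 0}·σ_q. Design
choices, made on identifiability grounds:

* **one-body granularity** — each structure contributes exactly one
  intensity observation per bin, so 20 structures match the 20 one-body
  parameters; the 21-parameter two-body posterior would retain an exactly
  flat direction at this training-set size (and at q = 0 the constraints
  are composition-only), making entrywise point recovery ill-posed there.
  The two-body path is exercised instead by the validation-S and decoy
  experiments, where the quantity of interest is the curve, not the
  individual parameter.
* **composition stratification** — training structure i is enriched (50%)
  in one amino-acid type, cycling through all 20. Large curated sets get
  their conditioning from sheer diversity; a 20-structure set needs
  designed contrast.
* **noise-matched likelihood** — the training σ is the actual noise sd of
  the generated reference curves (level·σ_q, floored when the level is
  zero). This is the correct specification of the synthetic experiment and
  is what makes the estimate converge on the generating table as the data
  improve; with the fixed nominal σ_q the posterior width would be
  noise-independent and the medoid would keep an irreducible skew offset
  of ~10–30% at mid/high q regardless of data quality.

A bead type counts as *dominant* at a bin when its share of the total
scattering amplitude (bead count × form factor) is at least 5%; recovery
accuracy is asserted for dominant entries only, since types that barely
contribute to the curves are genuinely undetermined (their posteriors
reproduce the flat prior — itself a tested property). With noiseless
reference data the recovered dominant entries agree with the generating
table to well under a percent on most bins (a few tenths of a percent
worst case at the highest bins), and the mean dominant error decreases
monotonically over the three noise levels. Smoothness of the recovered
columns in q is an emergent check: bins are estimated independently, so
continuity of the result testifies to sampler consistency.

## Decoy recognition

Each target is a fixture native with an oracle reference curve; 100
hinge-perturbed decoys per target are scored by the energy
E = −log likelihood of their table-computed curves, and the native's
Z-score is computed over **all** conformations of the set (native
included) with the sample standard deviation — the convention is fixed
because with ~10³ conformations the choice is numerically immaterial but
tests need a definite value. An externally supplied additive log-prior per
structure implements the posterior factorization likelihood × structural
prior without binding to any particular prior model; granting the native a
positive log-prior strictly improves its Z on the fixture benchmark.

## Problem sizes and runtime

Defaults used by the test suite and the acceptance script: training sets
of 20 structures × 30 residues; validation on 5 held-out 35-residue
structures; 10 decoy targets × 100 decoys × 40 residues; recovery chains
of 6·10⁵ iterations (3·10⁵ annealed burn-in) per bin. These sizes keep a
full pipeline run around a minute on one CPU while leaving every
statistical assertion comfortably powered; they are scaled-down analogues
of the original study design (hundreds of training proteins, 10³ decoys
per target), and Z-score magnitudes in particular depend on the decoy
generator, so only their sign and ordering are asserted.

## Known limitations

* No hydration-layer or excluded-volume solvent term; curves are
  comparable only to references generated under the same convention.
* The intensity scale is inherited from the reference curves used in
  training; no scale/offset fitting to experimental data is provided.
* Per-bin independence means no smoothness prior couples neighboring bins;
  smoothness is diagnostic, not enforced.
* Single chain per run; no assemblies, no mmCIF input.
* The fixture decoy generator produces geometrically plausible but
  physically unrefined conformations; absolute Z magnitudes are not
  meaningful benchmarks.
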