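# Methods

## Model

### Embeddings

Each atom starts from a feature vector of width `F` composed of:

- **x_z** — a learned per-element lookup table (elements H–Kr are supported;
  the table ships as plain text with one row of subshell occupancies per Z).
- **x_ez** — a learned linear map of the ground-state electron-configuration
  descriptor (occupancies of 1s…4p; entries sum to Z). This gives chemically
  related elements correlated starting points.
- **x_Q, x_S** — electronic embeddings derived from the *global* total
  charge Q (elementary charges) and spin state S (number of unpaired
  electrons; Fe(II): LS → 0, HS → 4). Spin parity against the electron count
  is checked when validation is requested.

The scaled electronic embedding follows, for s ∈ {Q, S} independently with
separate parameters:

1. equal sharing: raw_i = s/N;
2. importance weighting: a_i = softplus(MLP_a(x_N,i)) > 0,
   weighted_i = raw_i·a_i;
3. renormalization: scaled_i = weighted_i · s / Σ_j weighted_j, so that
   Σ_i scaled_i = s exactly; when s = 0 the renormalization target is 0 and
   every share is set to exactly 0 (this keeps the LS state well defined
   without a division by zero);
4. per-atom features: x_component,i = scaled_i · MLP_v(x_N,i).

MLP_a and MLP_v have one hidden layer of width F with softplus. The
attention variant computes queries from x_N, keys and values from two
independent linear maps of the scalar s, weights
softplus(q_i·k/√F) normalized over atoms, and output w_i·s·v; its output
therefore also vanishes identically at s = 0. The composed representation is
x⁰ = ResidualBlock(x_N + x_Q + x_S) (two linear layers, softplus, additive
skip); the residual block acts on the sum, not per component. All embedding
operations are pre-geometric and permutation equivariant.

### Short-range message passing

Distances within a cutoff (default 5.0 Å) are expanded in `n_rbf` (default
20) Gaussians with centers uniform on (0, cutoff] and width equal to the
center spacing, damped by the cosine switch ½(cos(πd/c)+1) which reaches 0
exactly at the cutoff. The filter network W(e) is two linear layers with a
softplus between, and the filter output is multiplied by the switch again so
messages vanish smoothly at the cutoff. One interaction is

    m_i = Σ_j W(e_ij) ⊙ (W_h h_j + b_h),   h_i ← h_i + U(m_i),

with U a one-hidden-layer MLP whose output layer is zero-initialized: a
fresh model is a pure readout of x⁰, which keeps early optimization stable.
T = 3 interactions by default. Messages depend on distances only, so the
short-range stack is exactly invariant under proper rigid motions.

### Long-range (Ewald-style) block

Features are projected onto a truncated frequency grid via structure factors
s(k) = Σ_j h_j e^{ik·r_j}, multiplied by learned per-frequency filter
vectors w(k) tied across ±k (tying makes the back-projected messages exactly
real), and returned per atom as

    m_i = (1/|K|) Σ_k Re[e^{−ik·r_i} s(k)] ⊙ w(k),

followed by a learned atomwise map and a residual update. The grid contains
every nonzero integer multiple of 2π/L with |k| ≤ k_max·2π/L; the threshold
is expressed in integer lattice units (default k_max = 3.6, |K| = 178) so
the *lattice shape* — and hence the filter parameterization — is identical
for every molecule, while the box edge L = (max interatomic distance) +
2·cutoff adapts to molecular size.

Two design choices here are the package's own, since the construction is
otherwise only loosely constrained for aperiodic systems:

- **Orientation canonicalization.** An axis-aligned frequency lattice is not
  rotation invariant. Coordinates are therefore rotated into a deterministic
  principal-axes frame (gyration-tensor eigenvectors, signs fixed by the
  third central moments, handedness enforced by a cross product) before any
  phase is evaluated. Structures related by a proper rigid motion map to
  identical canonical coordinates, making the block exactly E(3) invariant.
  Near-degenerate gyration eigenvalues only affect numerical conditioning,
  not correctness; in practice invariance holds to ~1e-13 eV.
- **Free filters.** w(k) are free learned vectors per ±k pair, with no
  radial parameterization — the simplest faithful reading of learned
  frequency filters.

### Couplings

- `base`: x⁰ → T short-range interactions → readout.
- `shared_plus`: one stream; each iteration applies the short-range then the
  Ewald update to the same state (interleaved by default; an append ordering
  — all short-range, then all Ewald — is switchable via `ewald_order`).
- `split_comma`: the nuclear embeddings x_N⁰ seed a stream updated only by
  short-range interactions, the electronic embeddings x_E⁰ = x_Q⁰ + x_S⁰
  seed a stream updated only by Ewald blocks; the shared residual block is
  applied to each stream's input separately, and the final states are summed
  before readout. This keeps the two interaction families additive and their
  parameter groups disjoint. `split_comma` with nuclear-only embeddings is
  rejected (the Ewald stream would be identically zero).

Readout is an atomwise two-layer MLP summed over atoms, plus per-element
reference energies fitted by least squares on the training set (subtracted
before training, re-added at prediction). The baseline also makes base-model
predictions size-extensive over non-interacting fragments; the Ewald
couplings are global and exempt from that property.

## Training

AdamW (weight decay 0.01) for every variant, MSE on baselined energies,
MAE reported. Batch size 16, initial learning rate 5e-4 at full scale. The
milestone-warmup schedule ramps linearly from a 0.2 factor over 50 000
warmup steps and multiplies by 0.1 at the milestones; the configured
milestone list is sorted at use (the printed reference list is
non-monotonic; normalization is recorded in the training log rather than
guessing intent). For short desk-scale runs the warmup and milestone steps
shrink proportionally to `max_steps` (reference length 400 000 steps), so
the schedule's shape is preserved. A plateau scheduler (decay 0.5, patience
10 validation evaluations) is available as an alternative. The best
validation checkpoint is returned. Two runs with the same seeds are
bit-identical (numpy `default_rng` throughout; no threading
nondeterminism).

The toy preset used by the packaged study is lr₀ = 1e-3 with the scaled
milestone-warmup schedule — a standard small-model choice; the 5e-4 default
belongs to the full-scale schedule it was published with.

## Evaluation protocol

For every configuration with conformers in both spin states the full cross
product of HS × LS conformers is enumerated (Σ_c n_HS(c)·n_LS(c) pairs, in
deterministic (config, HS index, LS index) order). ΔE_HS−LS = E_HS − E_LS;
positive ΔE means an LS ground state. Metrics: splitting MAE and the number
of sign-correct pairs, with a predicted ΔE of exactly 0 counted correct only
against a reference of exactly 0. The splitting MAE is invariant under any
global shift of total energies. Conversion to kcal/mol (1 eV = 23.0605
kcal/mol) exists only at I/O boundaries; everything internal is eV and Å.

## Curation

- `dedup_conformers`: greedy first-seen-kept pass removing conformers within
  0.1 Å optimal-alignment RMSD of a retained one. RMSD uses Kabsch
  superposition over proper rotations only (mirror images are distinct
  conformers) with index-wise atom correspondence — conformers of one
  configuration share atom order, so no graph matching is attempted. The
  greedy order dependence is deliberate; the tested contract is the retained
  *count*, which matches a connected-components clustering oracle on
  well-separated templates.
- `filter_qc`: drops non-converged and imaginary-frequency structures, and
  spin contamination |⟨S²⟩_actual − s(s+1)| > 1.0 (dimensionless; the
  tolerance is exposed as a flag).
- `split_dataset`: uniform random, by conformer, deterministic per seed;
  fractions floor with the remainder assigned to train.

## Synthetic data

`make_spin_dataset` draws, per configuration: a random 6-atom ligand
composition from {H, C, N, O, F, P, S, Cl}, a total charge Q uniform on
{0, 1, 2} (an Fe(II) center with anionic/neutral ligands), and a base
pseudo-octahedral geometry with bond lengths ~N(2.0 Å, 0.1) — multiplied by
1.10 in the HS state, mirroring the systematic HS bond elongation of real
Fe(II) complexes. Each spin state gets a conformer ensemble by Gaussian
jitter (σ = 0.05 Å). Energies come from the exact closed form

    E = Σ_{i<j} 4ε_ij[(σ_ij/d)¹² − (σ_ij/d)⁶] + Q·α Σ_{i<j} c_i c_j/d
      + S·(β0 + β1·r̄_M),

with ε and σ deterministic in Z (geometric/arithmetic combining of
0.05·(1+Z/20) eV and 1.5+0.02·Z Å, placing the Fe–C minimum near 2.0 Å),
c_Z = Z/10, α = 0.2 eV·Å, β0 = 0.05 eV, β1 = 0.02 eV/Å. The spin term
couples S to the mean metal–ligand distance so the splitting energy depends
on conformation. 20 % of HS conformers reuse the exact LS geometry,
creating geometry-degenerate (Q,S) pairs. All randomness flows from one
master seed through named substreams.

`irreducible_error_bound` formalizes the resulting floor: grouping records
by exact (elements, coordinates), the best any (Q,S)-blind predictor can do
on a group is its energy median, so the floor is the dataset-weighted mean
absolute deviation from per-group medians. In the packaged study this floor
is reported for the dataset as generated — inside a small random test split
the degenerate partners rarely co-occur, so the split-local floor would
understate the mechanism.

What the generator does *not* emulate: real ligand-field electronics,
anharmonic conformational landscapes, charge-dependent geometry relaxation,
or element distributions of crystallographic datasets. Passing tests
demonstrate the *mechanism* — that electronic embeddings remove a provable
blindness floor — not transferable accuracy on real Fe(II) chemistry.

## The packaged study and problem sizes

`spinmp.study.run_toy_study` generates 120 configurations × 10 conformers ×
2 spin states (2400 records, split 2000/200/200), then trains the scaled
and nuclear-only variants of the base coupling (F = 32, T = 2, 20 epochs,
batch 16, seed-shared initialization) and evaluates on the test split.
These sizes were chosen as the smallest at which the ablation contrast is
stable across seeds; the whole study runs in a few minutes on one CPU.
Typical outcome: the blind baseline lands at ~1.4 eV test MAE (dominated by
the unlearnable Q-term, far above its 0.038 eV degeneracy floor) while the
scaled model reaches ~0.2 eV, an improvement of ~85 %.

## Numerical choices and limitations

- Self-contained reverse-mode autodiff on numpy: the models here are small
  dense networks, and energies (not forces) are the only output, so
  geometric quantities enter the tape as constants. No GPU path.
- Neighbor lists via a KD-tree with exact distance recomputation; contract
  tested against an O(N²) scan.
- RMSD recomputes the deviation from aligned coordinates rather than using
  the decomposition's residual, which loses precision near zero — exact
  zeros matter for duplicate detection.
- Molecules are aperiodic; no cells, no PBC, no force prediction, no
  uncertainty estimates, and no equivariant vector features (the target
  property is invariant).
- extended XYZ is the single interchange format (ase-compatible dialect;
  per-frame keys `energy` (eV), `charge`, `spin`, `config_id`,
  `spin_label`, `split`); missing charge/spin default to 0 with a logged
  warning.
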