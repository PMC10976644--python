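# spinmp

Charge- and spin-aware message-passing potentials for open-shell transition
metal complexes, built around Fe(II) spin crossover.

## The problem

An Fe(II) complex (3d⁶) can sit in a low-spin (LS, t₂g⁶, S = 0 unpaired
electrons) or high-spin (HS, t₂g⁴e_g², S = 4) state, and the splitting
energy ΔE_HS−LS = E_HS − E_LS between them — typically within a few tenths of
an eV — decides the ground state. ΔE depends not only on ligand identity but
on ligand *conformation*, so screening spin-crossover candidates requires a
potential that resolves conformer-level energetics in both spin states.

Standard message-passing potentials see only element types and coordinates.
Two structures with identical geometry but different total charge Q or spin
state S are indistinguishable to them — a structural blindness that puts a
hard floor under their accuracy on spin-state datasets. `spinmp` implements
electronic embeddings that lift this degeneracy, plus everything needed to
train and evaluate them on synthetic spin-state data: no external dataset or
quantum chemistry is required.

## The model

Per-atom representations start from nuclear embeddings
x_N = x_z + x_ez (a learned per-element lookup plus a learned map of the
ground-state electron configuration). The **scaled electronic embedding**
turns a global scalar s ∈ {Q, S} into per-atom features: s is shared equally
over the N atoms (s/N each), the shares are re-weighted by learned positive
importances softplus(MLP(x_N)), renormalized so they sum exactly to s, and
each atom's scaled share multiplies a learned feature vector. An
attention-style variant (queries from x_N, keys/values from linear maps of
s) and a nuclear-only baseline are provided for ablation. The composed
x⁰ = ResidualBlock(x_N + x_Q + x_S) feeds T SchNet-style interactions

    m_i = Σ_{j∈N(i)} W(e_ij) ⊙ (W_h h_j + b_h),    h_i ← h_i + U(m_i)

with Gaussian radial-basis edge features e_ij and a cosine cutoff. An
optional Ewald-style long-range block exchanges messages through structure
factors s(k) = Σ_j h_j exp(i k·r_j) on a truncated frequency grid with
learned ±k-tied filters, coupled either to the same hidden stream (`+`) or
to an independent stream fed by the electronic embeddings (`,`). Energies
are sums of atomwise readouts plus fitted per-element reference energies.

The synthetic generator emits pseudo-octahedral complexes with conformer
ensembles in both spin states, longer HS bonds, and an exact closed-form
energy whose spin term couples to geometry; a configurable fraction of HS
conformers reuses the exact LS geometry, which makes the blind baseline's
error floor (`irreducible_error_bound`) strictly positive and measurable.

## Worked example

```python
import spinmp as sp

records, truth = sp.make_spin_dataset(n_configs=30, conformers_per_state=5, seed=7)
sp.split_dataset(records, sizes=(240, 30, 30), seed=7)

model = sp.build_model(sp.ModelConfig(embedding_variant="scaled", F=32, T=2, seed=7))
model, log = sp.train(model, records, sp.TrainConfig(lr0=1e-3, max_steps=1500, seed=7))

test = [r for r in records if r.split_tag == sp.SplitTag.TEST]
report = sp.evaluate_model(model, test)
print(f"energy MAE:    {report.energy_mae:.3f} eV")
print(f"splitting MAE: {report.splitting_mae:.3f} eV over {report.n_pairs} pairs")
print(f"correct ground spin states: {report.n_correct_spin}/{report.n_pairs}")
print(f"irreducible floor for a (Q,S)-blind model: {sp.irreducible_error_bound(records):.3f} eV")
```

prints (about half a minute on one CPU):

```
energy MAE:    0.407 eV
splitting MAE: 0.211 eV over 8 pairs
correct ground spin states: 6/8
irreducible floor for a (Q,S)-blind model: 0.037 eV
```

The energy MAE is the mean absolute error of predicted total energies on the
held-out conformers; the splitting MAE is the same for ΔE_HS−LS over every
configuration-matched HS × LS pair in the test split, and a pair counts as a
correct spin state when the predicted and reference ΔE agree in sign. The
floor is what *any* model blind to (Q, S) could at best achieve on this
dataset — the scaled model is not subject to it.

The same pipeline is scriptable from the shell:

```sh
spinmp generate --n-configs 30 --conformers 5 --seed 7 --out toy.extxyz
spinmp train --data toy.extxyz --out run/ --seed 7
spinmp evaluate --model run/checkpoint.json --data toy.extxyz --report report.json
```

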