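# Methods

This note records the model as implemented, the choices made where the design
was genuinely open, and what the desk-scale tests do and do not establish.

## Molecular representation

A molecule is (X, A, E): coordinates X ∈ ℝⁿˣ³ in Å, atom types A over the
six-element alphabet {C, N, O, F, S, Cl}, and an n×n×8 edge tensor E —
channels 0–3 bond-type one-hot (single/double/triple/aromatic), channel 4
pairwise Euclidean distance, channel 5 bond-angle cosine, channels 6–7
conjugation and ring flags. Hydrogens are implicit: validity is judged on
heavy-atom bond-order sums against v_max = {C:4, N:3, O:2, F:1, S:2 (6 by
config), Cl:1}, with aromatic bonds counting 1.5 and per-atom sums rounded
down. Coordinates are centered at zero mean on ingestion so the denoiser's
translation invariance is exact.

Two conventions were open and are fixed here:

- **Non-bonded pairs** keep a zero bond-type one-hot and zero flags but a
  *populated* distance channel — the bond-consistency loss needs d_ij for
  every pair.
- **Bond-angle cosine** is ambiguous for atoms with more than two neighbours;
  channel 5 stores the mean cosine over all angles the bond forms with
  adjacent bonds at either endpoint (0 when there are none), which is
  symmetric and well-defined for any degree.

## Diffusion

The ᾱ curve is squared-cosine (offset s = 0.008) with the implied β_t clipped
into [10⁻⁴, 0.02]; the clipping reconciles the cosine *shape* with the stated
β *range* (at T = 1000 the first and last β equal the range endpoints
exactly). A consequence worth knowing: ᾱ_T ≈ 3.2·10⁻³ rather than ~0, so the
terminal state retains correlation √ᾱ_T ≈ 0.057 with the clean molecule; the
tests assert this exact value rather than pretending it is zero.

Coordinates follow the standard Gaussian corruption. Categorical state (atom
types) is corrupted by **uniform resampling with probability 1−ᾱ_t** — the
simplest discrete process consistent with gradual structural corruption; the
source formulation specifies Gaussian corruption only for coordinates.

The composite loss is L_denoise + 0.1·L_bond + 0.5·L_valence. L_denoise is the
**mean** (not sum) squared error over noise elements — a documented constant.
L_bond sums binary cross-entropy over unordered pairs with probabilities
clamped at 10⁻⁷; the bond/no-bond label is d_ij < τ_bond = 1.8 Å. L_valence is
the squared hinge on the per-atom row sums of b̂ (the printed formula
duplicates symbols; the row-sum reading is the only coherent one and is used
throughout).

**Denoiser.** An EGNN: invariant node features are updated from messages
φ(h_i, h_j, d²_ij); coordinates move by Σ_j (x_i − x_j)·tanh(φ_x(m_ij))/(n−1),
so the predicted noise (x_out − x_in) is a weighted sum of relative-position
vectors — rotation-equivariant, translation-invariant and
permutation-equivariant *by construction*, which the test suite verifies at
10⁻⁵ (it holds to machine precision). The bond head scores symmetric pair
features (h_i + h_j, h_i⊙h_j, d²) with its final bias initialised at −2 so
untrained models propose sparse, mostly decodable graphs; atom and bond heads
read invariant features only. Timestep enters as a 64-dim sinusoidal
embedding of t/T. Full-scale defaults are 12 layers × 256 hidden units;
tests and smoke runs shrink to 3 × 16.

**DDIM.** Sub-schedule with uniform stride T//steps (default 1000 → 100
steps), η = 0: x̂₀ = (x_t − √(1−ᾱ_t)·ε̂)/√ᾱ_t, then x_{t_prev} = √ᾱ_{t_prev}·x̂₀
+ √(1−ᾱ_{t_prev})·ε̂. The α in the printed update is read as cumulative ᾱ
(standard DDIM); with ε̂ ≡ 0 the update telescopes, which the sub-schedule
consistency test exploits. Atom types are carried as softmax distributions
during the trajectory and argmax-decoded at the end; bonds decode at
b̂ ≥ 0.5.

## Conditioning

Continuous properties are **z-scored before sinusoidal encoding** (the
encoding is scale-sensitive; MW ~300 and QED ~0.7 would otherwise live on
incomparable frequency ranges). Default standardisation statistics match
drug-like corpora (MW 301 ± 28 Da, logP 2.45 ± 1.32, QED 0.73 ± 0.15,
SA 2.97 ± 0.71) and are stored with checkpoints. Discrete properties use
embedding tables over their vocabularies (ring 0–6, aromatic 0–4, HBD 0–5,
HBA 0–10); out-of-range values clamp with a logged warning.

Property tokens carry a **learned type embedding instead of positional
encoding**, making the encoder order-insensitive — the source never states how
multiple tokens are identified, and type embeddings are the choice that makes
the permutation test exact. A learned null token expresses unconditioned
generation through the same forward pass. Cross-attention at the conditioned
GNN layers is single-head with d_k = model width, followed by the gated
fusion h′ = σ(W_g h)⊙h + (1−σ)⊙c; zeroing the conditioning output projection
provably restores the unconditioned activations everywhere.

## Multi-objective RL

Objectives are f(m) = (QED, −SA, Novelty) in maximization orientation, with
per-molecule novelty 1 − max Tanimoto (Morgan, radius 2, 2048 bits) against
the training index. Ranks come from NSGA-II non-dominated sorting
(implemented as iterative peeling with a vectorised dominance test; verified
against a brute-force oracle on 1,000 random instances). The rank reward is
R_rank = 1 − (r−1)/(N−1) — an alternative printed form, 1 − rank/|B|, was
rejected because it cannot reach the natural endpoints {0, 1}. Crowding
distance follows NSGA-II except at front boundaries: instead of ∞ they get
**2× the maximum finite interior distance** (fronts of size ≤ 2: uniform 1) so
the normalized bonus α·CD/max(CD), α = 0.1, stays bounded and rewards stay in
[0, 1.1]. Phase 1 rewards raw QED; invalid molecules receive reward 0 in all
phases (validity-as-reward-zero is our resolution of an unstated
interaction).

**Policy parameterisation — the largest gap.** The deterministic DDIM update
has no defined π(a|s). We expose the denoiser as a **Gaussian policy over ε
with fixed σ = 1** at the rollout steps: actions a ~ N(ε̂_θ, I) drive the DDIM
update during RL rollouts (inference stays deterministic), making the PPO
ratio well-defined and the entropy a constant. One molecule rollout is one
episode; the Pareto reward is terminal, intermediate rewards zero.

PPO uses the printed configuration (clip 0.2, value coef 0.5, entropy coef
0.01, K = 4 epochs, minibatch 64, GAE γ = 0.99 / λ = 0.95, grad-norm clip
0.5, gradient accumulation 4). Advantages are normalized per minibatch.
Replay entries carry priority (1/rank)·novelty (capacity 10 000, sampling
∝ priority^0.6 without replacement, lowest-priority eviction with insertion-
order tie-break). Buffer samples feed **only** the value loss: the critic
reads detached trunk features and importance weights (ratios clipped to
[0.5, 2.0]) are computed outside the differentiated loss, so the policy
gradient of buffer samples is exactly zero — asserted by an autodiff probe.

Batch composition: the 70/20/10 split is realised as rounded shares for the
policy and buffer pools with the training share taking the residual — this
reproduces the stated counts (90, 26, 12) at batch 128 and (7, 2, 1) at 10,
which plain largest-remainder rounding does not; shortfalls backfill with
fresh samples. The curriculum is fixed at epochs 1–20 / 21–50 / 51+, with
both learning rates halved on phase entry. The 70% "new" samples are
on-policy rollouts from the current epoch (assumed; not stated).

## Synthetic data

`gen_toy_molecules` emulates a drug-like SMILES corpus at desk scale: ring or
chain cores over the six-element alphabet decorated with small substituents
(5–15 heavy atoms), 100% valid by construction, coordinates from RDKit's
seeded distance-geometry embedding with ≤ 0.05 Å jitter. We chose seeded
ETKDG over hand-idealised template geometry: it is equally deterministic,
chemically more realistic, and avoids bespoke geometry code. What it does
*not* emulate: the property marginals, scaffold diversity or size
distribution of real screening corpora — so a green metric test establishes
that the machinery computes the right quantity, not that a trained model
reaches any literature value. `gen_objective_cloud` places exactly
n_frontier points on a simplex (equal coordinate sums forbid mutual
dominance) and derives every other point by strict scaling, so the frontier
size is known by construction; `gen_closed_form_front` provides staircase
fronts with analytic hypervolume (k steps → (k+1)/2k).

## Metrics

Batch novelty (exact canonical-SMILES set membership, MOSES convention) is
deliberately distinct from the continuous per-molecule novelty objective;
both exist side by side. The Fréchet metric is generic over descriptor
vectors and labelled **FCD-style** — the trained ChemNet embedding of FCD
proper is an external artifact and out of scope. Hypervolume is exact for ≤ 3
objectives (z-slab sweep over a 2-D sweep) and Monte-Carlo above; the
reference point is (0, 0, 0) on normalized objectives (QED native, SA mapped
from [1, 10] inverted, novelty native). Desirability is the geometric mean of
normalized objectives (zero annihilates); the baseline-relative normalization
used in some reports requires an external reference system and is therefore
exposed only as the documented min–max mode. All-criteria thresholds are
QED ≥ 0.70, SA ≤ 3.5, novelty ≥ 0.90, inclusive.

## Numerical choices

- BCE probability clamp 10⁻⁷; softmax computed with max-subtraction.
- Crowding distance skips constant objectives; an all-coincident front gets
  uniform distance 1 (ties on continuous fronts are measure-zero, and the
  sorted-neighbour construction is order-dependent under ties — documented,
  not hidden).
- Eviction and sorting tie-breaks are stable by insertion index.
- One integer seed drives initialisation, noise draws and data order
  everywhere; `numpy.random.default_rng` throughout.
- Optimisation is Adam on the flattened parameter tree with global-norm
  clipping at 0.5; two optimiser instances realise the two printed learning
  rates (10⁻⁴ RL, 5·10⁻⁴ diffusion) over the shared parameters.

## Limitations

- Neural components run on numpy + autograd: correct gradients, small scale.
  The full-scale architecture (12 × 256, T = 1000, 100 DDIM steps) is the
  configured default but is not trained to convergence here; smoke runs
  demonstrate loss descent and curriculum mechanics, not benchmark-level
  sample quality.
- No stereochemistry assignment (SDF ingestion strips stereo flags to keep
  round-trips stable), no tautomer canonicalisation, no conformer generation
  beyond the fixture embedder.
- Surrogate property backend is a coarse stand-in (exact MW, additive logP,
  ring/branch SA proxy, bounded QED proxy); use the RDKit backend for any
  chemical conclusion.
- The fourth, "property-specific constraints" objective slot is exposed as an
  optional ``extra`` argument of ``objective_vector`` (user-supplied values
  appended in maximization orientation) and intentionally has no built-in
  content.
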