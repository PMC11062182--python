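# Methods

## Connectome representation

A connectome is a square non-negative matrix `w[s, t]` of projection
strength from source region `s` to target region `t`, with one
functional group per region (`sensation`, `motor`, `other`). Self
connections are dropped on load: the clustering neighborhood
n(i) = {j : w_ij > 0} is defined over other nodes, and none of the
downstream analyses uses them. Strengths are used as-is — no log
transform, normalization, or binarization — so clusters reflect the raw
anatomical weight scale.

Link clustering needs one strength per unordered region pair, so the
directed matrix is symmetrized first. The default combination is the
elementwise maximum of the two directed entries, which preserves the
stronger projection of a reciprocal pair; `sum` and `mean` are
available. The directed matrix itself is retained untouched for synapse
wiring and motif counting.

## Tanimoto link clustering

Each node `i` gets a weighted neighbor profile `a_i` with
`a_i[j] = w_ij` for neighbors `j` and a self term
`a_i[i] = (1/k_i) Σ_j w_ij`, the mean neighbor weight. For two links
sharing node `k`, similarity is the Tanimoto coefficient between the
profiles of the two *non-shared* endpoints,

    S = a_i · a_j / (|a_i|² + |a_j|² − a_i · a_j),

which is 1 for identical profiles and 0 for disjoint support.
Clustering is single-linkage agglomeration over links: every link
starts alone; adjacent link pairs are processed in descending S, equal
similarities broken lexicographically by link labels so runs are
deterministic across platforms. Cutting the dendrogram at height `h`
applies exactly the merges with S ≥ h — equivalently, the cut clusters
are the connected components of the "similarity ≥ h" graph over links,
which is what the test-suite oracle computes independently.

A cut is scored by partition density

    D = (2/M) Σ_c m_c (m_c + 1 − n_c) / ((n_c − 2)(n_c − 1)),

with `m_c` links and `n_c` incident nodes per cluster. Single-link
clusters (`n_c = 2`) contribute 0 — the normalization is undefined
there, and this convention keeps all-singleton partitions at D = 0
while a full clique cluster scores 1.

Community connectedness compares a cluster's external and internal
link counts:

    C_i = (n_i − 1) e_b(i) / (2 e_w(i) d̂),

where `e_w(i) = m_i`, `e_b(i)` counts links outside the cluster that
touch its node set, and `d̂ = 2M/N` is the whole-network mean degree.
The grouping of this expression was a genuinely open design point (the
constant factor and an `n_i` cancellation admit several readings); the
adopted form is increasing in external links and decreasing in internal
links, which is the verbal definition, and since all candidate readings
differ only by factors monotone in the same quantities, the band-based
selection below is insensitive to the choice. No config alternates are
offered for this reason.

## Subnetwork selection and construction

A link community becomes a policy-network candidate when (i) its
incident-node count falls in the size band, default 30–60 — large
enough to carry layered structure, small enough to simulate cheaply;
(ii) its connectedness C_i falls in a band, default 10–40 on real
connectome scales (very low values indicate isolated fragments or
artifacts, very high values clusters with no identity); and (iii) its
node set covers all three functional groups, so the network has input,
hidden, and output layers.

Construction keeps every positive directed entry among the selected
regions as a synapse. Roles map directly from groups. Signs are a
modeling choice: mesoscale tracing gives no neurotransmitter identity,
so exactly `round(exc_ratio · m)` synapses are labeled excitatory —
default ratio 0.7, the cortical excitatory fraction — chosen uniformly
at random under a seed. A strength-ranked rule (strongest synapses
excitatory) is available via `assignment="strength"` for sensitivity
checks. Networks are named `NET-<node count>`.

The random baseline `generate_net_rand` draws a uniform simple digraph
with exactly the reference's node count, synapse count, role histogram,
and excitatory count, with strengths resampled with replacement from
the reference's strengths (matching the scale without asserting a
parametric form). It is a G(n, m) null, not degree-preserving: the
claim under test is that the *specific* wiring matters, so only size is
matched. Network sparsity is 1 − m/(n(n−1)) over ordered pairs.

## Motif census and credible frequency

All weakly-connected unordered triples of the unsigned digraph are
classified into the 13 connected 3-node isomorphism classes. The
canonical adjacency matrices ship in `data/triad_motifs.json`, ordered
by the standard triad-census sequence; the implementation delegates
counting to networkx's triadic census and derives the code-to-class map
from the shipped dictionary at import, so the numbering cannot drift.
Significance per class uses a null of 1,000 uniform G(n, m) digraphs
(size-matched only, per the null's definition) and the one-sided
add-one estimator

    P = (1 + #{null frequency ≥ observed frequency}) / (size + 1),

which avoids P = 0 from a finite ensemble, counts ties against
significance, and makes the credible frequency
`frequency · (1 − P)` strictly smaller than the raw frequency. Tie
handling and sidedness are deliberate choices documented here rather
than alternatives hidden behind flags.

## Membrane dynamics and solvers

Neurons follow a conductance-based leaky-integration equation; each
synapse contributes `ω_C g(V_pre)(E_C − V_post)` with the logistic gate
`g = σ(σ_gate (V_pre − μ))`. Constants are on a millivolt-like
dimensionless scale: `E_L = −70` (rest), excitatory `E_C = 0`,
inhibitory `E_C = −90`, threshold `V_th = −45`. Defaults: `C_m = 1`,
`ω_L = 0.1` (leak time constant 10 time units), `dt = 0.3` (≈ 33 steps
per time constant), gate steepness 0.1 and half-activation −40 so the
gate spans the physiological voltage range. Initial conductances scale
the anatomical strengths by `omega_scale / max strength`.

Spiking (LIF) neurons freeze the membrane update through a `(1 − S)`
factor when the flag is raised at a threshold crossing; taken literally
that would latch the potential above threshold forever, so the step
*after* a spike resets V to `E_L` and clears the flag, emitting a
one-step spike. Hidden neurons default to non-spiking LI dynamics
(liquid-network style); `SNNConfig(lif_hidden=True)` switches them.

The explicit Euler solver exists mainly to expose first-order
convergence against the closed-form leak solution. The production
solver is a fused semi-implicit step: all conductance terms are
implicit in the post-synaptic potential while gates are evaluated at
the current pre-synaptic potentials, giving

    V ← [V C_m/dt + ω_L E_L + Σ ω_C g E_C + I_ext] /
        [C_m/dt + ω_L + Σ ω_C g].

This is a convex combination of V, E_L, and the reversal potentials:
with no external drive the trajectory can never leave the reversal
envelope at any dt, every fixed point of the continuous system is
preserved exactly, and each step costs O(|neurons| + |synapses|).
Degenerate inputs are handled explicitly: dt = 0 is the identity,
trained conductances are clamped at 0 (they are defined non-negative),
and gate steepness is stored as a magnitude with a 1e-6 floor.

## Policy I/O and training

Observations enter as external currents on input neurons through an
affine map; actions read output-neuron potentials relative to rest
through an affine map, clipped to the action bounds. The trainable
vector θ concatenates all synaptic `ω_C, σ, μ` and the I/O map
entries; the edge set, synapse signs (via E_C), and membrane constants
are fixed, so search can never rewire the topology.

Training is standard ARS, variant V2-t: `n_directions = 16` antithetic
Gaussian perturbation pairs per update, `top_b = 8` elites ranked by
`max(r+, r−)`, step size 0.02, noise scale 0.03, the update normalized
by the standard deviation of the kept rewards, and online Welford
whitening of observations (updated only during training rollouts,
frozen during evaluation). Fitness is the undiscounted episode return.
The step budget counts both rollouts of every direction pair;
evaluation — the mean return over noise-free episodes every
`eval_every` steps — is not charged against the budget. All randomness
flows from one seeded generator, so traces are bit-identical across
repeated runs.

## Synthetic connectomes and what they test

The generator plants a directed stochastic block model: modules with
within/between connection probabilities (defaults 0.5 / 0.02) and
log-normal strengths (heavy-tailed, like anatomical projection
strengths; `constant` exists for exact-count tests). Functional groups
are assigned per module with at least one sensation and one motor
region each, so generated modules satisfy the coverage rule. The
default whole-brain-scale spec (213 regions, five modules) stays below
the ~36% directed density of real mesoscale connectomes. Recovery is
scored as the adjusted Rand index between each node's dominant link
cluster (ties to the lowest cluster id) and the planted modules.

What the generator does *not* emulate: distance-dependent connection
probability, hub regions and rich-club structure, reciprocity bias,
hemispheric symmetry, or realistic strength-topology correlations.
Passing the planted-recovery and selection tests therefore shows the
machinery is correct on modular weighted digraphs, not that any
particular biological claim holds on real atlas data; runs on a real
connectome matrix use the same entry points but are an external check.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own reduced-scale protocol: clustering oracles
on graphs of ≤ 8 nodes (100 random instances), motif oracles on
digraphs of ≤ 7 nodes, null calibration at ensemble size 200, and the
topology-vs-random experiment on a 10-node planted network trained for
20,000 environment steps per seed (episodes capped at 500 steps,
8 directions, top-4 elites) across 10 seeds. The full-scale protocol —
300,000 steps, 1,000-step episodes, evaluation every 10,000 steps over
10 episodes — is the configured default of `ARSConfig` and is what the
CLI uses unless told otherwise. At the reduced budget the honest
summary statistic is per-seed improvement over the initial policy;
separating planted from random topologies by final score, as full-scale
physics benchmarks do, needs budgets far beyond a desk run, so no such
separation is claimed here.

## Known limitations

- Excitatory/inhibitory identity is synthetic (ratio-constrained random
  or strength-ranked), not anatomical.
- The G(n, m) null ignores degree sequences; motif significance partly
  reflects degree heterogeneity.
- The fused solver's gates are explicit in V_pre; it is robust, not
  symplectic or higher-order.
- ARS at small budgets mostly trims action cost; it demonstrates the
  training loop, not task mastery.
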