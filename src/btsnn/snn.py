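"""Leaky-integration (LI) and leaky integrate-and-fire (LIF) networks.

Each neuron follows a conductance-based membrane equation

    C_m dV/dt = omega_L (E_L - V) + sum_in I_ext + sum_syn omega_C g (E_C - V)
    g = 1 / (1 + exp(-sigma (V_pre - mu)))

where the sigmoidal gate g makes each chemical synapse a graded,
voltage-dependent conductance and the reversal potential E_C encodes
the synapse's sign: excitatory E_C sits above the resting range,
inhibitory below.  LIF neurons add a threshold V_th: the step after the
membrane crosses it, a one-step spike flag is raised, the potential is
frozen by the (1 - S) factor, then reset to E_L.

Two fixed-step solvers are provided.  ``step_euler`` is the explicit
Euler update, used for order-of-accuracy checks.  ``step_fused`` treats
every conductance term implicitly in the post-synaptic potential,

    V <- [V C_m/dt + omega_L E_L + sum omega_C g E_C + I_ext]
         / [C_m/dt + omega_L + sum omega_C g],

a convex-combination form that is unconditionally bounded by the
reversal potentials, preserves every fixed point of the continuous
system exactly, and costs O(|neurons| + |synapses|) per step.  The
fused solver is the default for policy rollouts.

Hidden neurons default to non-spiking LI dynamics (liquid-network
style); any subset can be switched to LIF via :class:`SNNConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .topology import BTNetwork

__all__ = [
    "SNNConfig",
    "NeuronParams",
    "SynapseParams",
    "SNNState",
    "PolicyIO",
    "WiredSNN",
    "SNNPolicy",
    "synapse_gate",
    "li_derivative",
    "step_euler",
    "step_fused",
    "encode_observation",
    "decode_action",
    "rollout",
]


@dataclass
class SNNConfig:
    """Fixed (non-trainable) constants of the membrane model.

    Potentials are on a millivolt-like dimensionless scale: resting
    E_L = -70, excitatory reversal 0, inhibitory reversal -90, firing
    threshold -45.  ``dt`` is the solver step in membrane time units
    (tau_leak = C_m / omega_L = 10 by default, so dt = 0.3 resolves the
    leak well).  ``omega_scale`` scales initial synaptic conductances
    derived from normalized anatomical strengths.
    """

    dt: float = 0.3
    solver: str = "fused"
    C_m: float = 1.0
    omega_L: float = 0.1
    E_L: float = -70.0
    E_exc: float = 0.0
    E_inh: float = -90.0
    V_th: float = -45.0
    sigma_init: float = 0.1
    mu_init: float = -40.0
    omega_scale: float = 0.5
    lif_hidden: bool = False


@dataclass
class NeuronParams:
    """Per-neuron membrane constants (arrays of length n_neurons)."""

    C_m: np.ndarray
    omega_L: np.ndarray
    E_L: np.ndarray
    V_th: np.ndarray
    spiking: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.C_m <= 0):
            raise ValueError("membrane capacitance must be positive")
        if np.any(self.omega_L < 0):
            raise ValueError("leak conductance must be non-negative")
        if np.any(self.spiking & (self.V_th <= self.E_L)):
            raise ValueError("firing threshold must exceed the leak reversal")


@dataclass
class SynapseParams:
    """Per-synapse parameters (arrays of length n_synapses).

    ``pre``/``post`` are neuron indices; ``omega_C`` the maximal
    conductance (clamped at 0 when trained values go negative);
    ``E_C`` the reversal potential fixing the sign; ``sigma``/``mu``
    the gate steepness and half-activation potential.
    """

    pre: np.ndarray
    post: np.ndarray
    omega_C: np.ndarray
    E_C: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("gate steepness must be positive")


@dataclass
class SNNState:
    """Membrane potentials and spike flags at one time point."""

    V: np.ndarray
    S: np.ndarray
    t: float = 0.0
    dt: float = 0.3

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.V)):
            raise ValueError("non-finite membrane potential")
        if self.dt < 0:
            raise ValueError("dt must be non-negative")


@dataclass
class PolicyIO:
    """Affine sensory encoding and motor decoding around the network.

    Observations map to external currents on the input neurons,
    I_ext = W_in @ obs + b_in; actions read the output-neuron
    potentials relative to the centering potential ``v_ref``,
    a = clip(W_out @ (V_out - v_ref) + b_out, act_bounds).
    """

    obs_dim: int
    act_dim: int
    input_idx: np.ndarray
    output_idx: np.ndarray
    W_in: np.ndarray
    b_in: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray
    act_bounds: tuple[float, float] = (-1.0, 1.0)
    v_ref: float = -70.0

    def __post_init__(self) -> None:
        if self.W_in.shape != (len(self.input_idx), self.obs_dim):
            raise ValueError("input map shape mismatch")
        if self.W_out.shape != (self.act_dim, len(self.output_idx)):
            raise ValueError("output map shape mismatch")


@dataclass
class WiredSNN:
    """A BTNetwork realized as neuron and synapse parameter arrays."""

    node_order: list[str]
    neurons: NeuronParams
    synapses: SynapseParams
    config: SNNConfig

    @property
    def n_neurons(self) -> int:
        return len(self.node_order)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses.pre)

    def step_cost(self) -> int:
        """Work per solver step in the O(|neurons| + |synapses|) model."""
        return self.n_neurons + self.n_synapses

    def initial_state(self) -> SNNState:
        return SNNState(
            V=self.neurons.E_L.copy(),
            S=np.zeros(self.n_neurons, dtype=bool),
            t=0.0,
            dt=self.config.dt,
        )


def wire(bt: BTNetwork, config: SNNConfig | None = None) -> WiredSNN:
    """Instantiate membrane and synapse parameters from a topology.

    Conductances start at ``omega_scale`` times the anatomical strength
    normalized by the strongest synapse; reversal potentials follow the
    synapse signs.
    """
    config = config or SNNConfig()
    n = bt.n_nodes
    idx = {node: i for i, node in enumerate(bt.nodes)}
    spiking = np.zeros(n, dtype=bool)
    if config.lif_hidden:
        spiking = np.array([bt.roles[u] == "hidden" for u in bt.nodes])
    neurons = NeuronParams(
        C_m=np.full(n, config.C_m),
        omega_L=np.full(n, config.omega_L),
        E_L=np.full(n, config.E_L),
        V_th=np.full(n, config.V_th),
        spiking=spiking,
    )
    w_max = max(w for *_, w, _ in bt.synapses)
    pre, post, omega, e_c = [], [], [], []
    for s, t, w, sign in bt.synapses:
        pre.append(idx[s])
        post.append(idx[t])
        omega.append(config.omega_scale * w / w_max)
        e_c.append(config.E_exc if sign == "excitatory" else config.E_inh)
    m = len(pre)
    synapses = SynapseParams(
        pre=np.array(pre, dtype=int),
        post=np.array(post, dtype=int),
        omega_C=np.array(omega),
        E_C=np.array(e_c),
        sigma=np.full(m, config.sigma_init),
        mu=np.full(m, config.mu_init),
    )
    return WiredSNN(
        node_order=list(bt.nodes), neurons=neurons, synapses=synapses,
        config=config,
    )


def synapse_gate(V_pre, s: SynapseParams):
    """Logistic conductance gate g = 1 / (1 + exp(-sigma (V_pre - mu)))."""
    return expit(s.sigma * (np.asarray(V_pre) - s.mu))


def _conductances(state: SNNState, net: WiredSNN):
    syn = net.synapses
    g = synapse_gate(state.V[syn.pre], syn)
    return np.maximum(syn.omega_C, 0.0) * g


def li_derivative(state: SNNState, net: WiredSNN, ext: np.ndarray) -> np.ndarray:
    """dV/dt per neuron under the conductance-based membrane equation."""
    nrn = net.neurons
    syn = net.synapses
    cond = _conductances(state, net)
    i_syn = np.zeros(net.n_neurons)
    np.add.at(i_syn, syn.post, cond * (syn.E_C - state.V[syn.post]))
    leak = nrn.omega_L * (nrn.E_L - state.V)
    return (leak + ext + i_syn) / nrn.C_m


def _apply_reset(state: SNNState, net: WiredSNN) -> SNNState:
    """One step after a spike, reset fired LIF neurons to rest."""
    nrn = net.neurons
    fired = nrn.spiking & state.S
    if fired.any():
        V = state.V.copy()
        V[fired] = nrn.E_L[fired]
        S = state.S.copy()
        S[fired] = False
        return replace(state, V=V, S=S)
    return state


def _detect_spikes(V: np.ndarray, net: WiredSNN) -> np.ndarray:
    nrn = net.neurons
    return nrn.spiking & (V > nrn.V_th)


def step_euler(
    state: SNNState, net: WiredSNN, ext: np.ndarray, dt: float | None = None
) -> SNNState:
    """Explicit Euler step V <- V + dt dV/dt, with LIF spike handling."""
    dt = state.dt if dt is None else dt
    state = _apply_reset(state, net)
    dv = li_derivative(state, net, ext)
    V = state.V + dt * dv * (~state.S)
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("explicit Euler step diverged")
    return SNNState(V=V, S=_detect_spikes(V, net), t=state.t + dt, dt=state.dt)


def step_fused(
    state: SNNState, net: WiredSNN, ext: np.ndarray, dt: float | None = None
) -> SNNState:
    """Semi-implicit fused step, unconditionally bounded.

    Conductance and leak terms are implicit in the post-synaptic
    potential while the gates are evaluated at the current
    pre-synaptic potentials; a dt of 0 is the identity.
    """
    dt = state.dt if dt is None else dt
    state = _apply_reset(state, net)
    if dt == 0:
        return state
    nrn = net.neurons
    syn = net.synapses
    cond = _conductances(state, net)
    num = state.V * nrn.C_m / dt + nrn.omega_L * nrn.E_L + ext
    den = nrn.C_m / dt + nrn.omega_L.astype(float).copy()
    np.add.at(num, syn.post, cond * syn.E_C)
    np.add.at(den, syn.post, cond)
    V = np.where(state.S, state.V, num / den)
    return SNNState(V=V, S=_detect_spikes(V, net), t=state.t + dt, dt=state.dt)


_SOLVERS = {"euler": step_euler, "fused": step_fused}


def encode_observation(obs: np.ndarray, io: PolicyIO) -> np.ndarray:
    """External currents on the input neurons: W_in @ obs + b_in."""
    obs = np.asarray(obs, dtype=float)
    if obs.shape != (io.obs_dim,):
        raise ValueError(f"observation shape {obs.shape} != ({io.obs_dim},)")
    return io.W_in @ obs + io.b_in


def decode_action(state: SNNState, io: PolicyIO) -> np.ndarray:
    """Action from output-neuron potentials, clipped to the bounds."""
    a = io.W_out @ (state.V[io.output_idx] - io.v_ref) + io.b_out
    return np.clip(a, io.act_bounds[0], io.act_bounds[1])


class SNNPolicy:
    """A wired network plus I/O maps, exposing a flat parameter vector.

    Trainable parameters are all synaptic (omega_C, sigma, mu) and all
    I/O map entries; the edge set, signs (via E_C) and membrane
    constants stay fixed, so search never alters the topology.
    """

    def __init__(self, net: WiredSNN, io: PolicyIO):
        self.net = net
        self.io = io
        self.state = net.initial_state()

    @classmethod
    def from_network(
        cls,
        bt: BTNetwork,
        obs_dim: int,
        act_dim: int,
        config: SNNConfig | None = None,
        act_bounds: tuple[float, float] = (-1.0, 1.0),
        init_scale: float = 0.05,
        seed: int = 0,
    ) -> "SNNPolicy":
        """Wire ``bt`` and attach small random affine I/O maps."""
        net = wire(bt, config)
        rng = np.random.default_rng(seed)
        input_idx = np.array(
            [i for i, u in enumerate(bt.nodes) if bt.roles[u] == "input"]
        )
        output_idx = np.array(
            [i for i, u in enumerate(bt.nodes) if bt.roles[u] == "output"]
        )
        if len(input_idx) == 0 or len(output_idx) == 0:
            raise ValueError("policy network needs input and output neurons")
        io = PolicyIO(
            obs_dim=obs_dim,
            act_dim=act_dim,
            input_idx=input_idx,
            output_idx=output_idx,
            W_in=init_scale * rng.standard_normal((len(input_idx), obs_dim)),
            b_in=np.zeros(len(input_idx)),
            W_out=init_scale * rng.standard_normal((act_dim, len(output_idx))),
            b_out=np.zeros(act_dim),
            act_bounds=act_bounds,
            v_ref=net.config.E_L,
        )
        return cls(net, io)

    # -- flat parameter vector ------------------------------------------
    def get_params(self) -> np.ndarray:
        syn = self.net.synapses
        return np.concatenate(
            [
                syn.omega_C,
                syn.sigma,
                syn.mu,
                self.io.W_in.ravel(),
                self.io.b_in,
                self.io.W_out.ravel(),
                self.io.b_out,
            ]
        )

    def set_params(self, theta: np.ndarray) -> None:
        syn = self.net.synapses
        m = self.net.n_synapses
        expected = 3 * m + self.io.W_in.size + self.io.b_in.size
        expected += self.io.W_out.size + self.io.b_out.size
        if theta.shape != (expected,):
            raise ValueError(f"parameter vector length {theta.size} != {expected}")
        i = 0
        syn.omega_C = theta[i : i + m].copy(); i += m
        # steepness must stay positive; trained values are magnitudes
        syn.sigma = np.maximum(np.abs(theta[i : i + m]), 1e-6); i += m
        syn.mu = theta[i : i + m].copy(); i += m
        k = self.io.W_in.size
        self.io.W_in = theta[i : i + k].reshape(self.io.W_in.shape); i += k
        k = self.io.b_in.size
        self.io.b_in = theta[i : i + k].copy(); i += k
        k = self.io.W_out.size
        self.io.W_out = theta[i : i + k].reshape(self.io.W_out.shape); i += k
        self.io.b_out = theta[i:].copy()

    @property
    def n_params(self) -> int:
        return self.get_params().size

    # -- acting ----------------------------------------------------------
    def reset(self) -> None:
        self.state = self.net.initial_state()

    def act(self, obs: np.ndarray) -> np.ndarray:
        ext_inputs = encode_observation(obs, self.io)
        ext = np.zeros(self.net.n_neurons)
        ext[self.io.input_idx] = ext_inputs
        stepper = _SOLVERS[self.net.config.solver]
        self.state = stepper(self.state, self.net, ext)
        return decode_action(self.state, self.io)


def rollout(
    policy: SNNPolicy,
    env,
    max_steps: int = 1000,
    env_seed: int | None = None,
    obs_transform=None,
) -> tuple[float, int]:
    """One episode: encode -> step -> decode -> env.step until done.

    Returns (undiscounted return, steps taken).  Deterministic given
    the policy parameters and ``env_seed``.
    """
    policy.reset()
    obs = env.reset(seed=env_seed)
    total = 0.0
    steps = 0
    for _ in range(max_steps):
        x = obs_transform(obs) if obs_transform is not None else obs
        action = policy.act(x)
        obs, reward, done = env.step(action)
        total += float(reward)
        steps += 1
        if done:
            break
    return total, steps
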