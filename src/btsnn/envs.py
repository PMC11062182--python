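"""Continuous-control environments satisfying the reset/step contract.

An environment exposes ``obs_dim``, ``act_dim``, ``reset(seed) -> obs``
and ``step(action) -> (obs, reward, done)``.  Two self-contained toy
tasks live here; an optional adapter wraps external gym-style
simulators behind the same contract.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ToyMountainCar", "PointMass", "GymAdapter", "toy_mountain_car"]


class ToyMountainCar:
    """Continuous mountain-car: drive an underpowered car up a hill.

    State (x, v) with x in [-1.2, 0.6], v in [-0.07, 0.07]; action
    a in [-1, 1].  Dynamics per step:

        v <- clip(v + 0.0015 a - 0.0025 cos(3x));  x <- clip(x + v)

    with velocity zeroed at the left wall.  Reward is -0.1 a^2 per
    step and +100 on reaching x >= 0.45 (episode ends).  Start is
    x = -0.5, v = 0, so a near-100 return marks success: gravity beats
    full throttle from the valley and the car must rock back and forth
    to build momentum.
    """

    obs_dim = 2
    act_dim = 1
    x_range = (-1.2, 0.6)
    v_range = (-0.07, 0.07)
    goal = 0.45

    def __init__(self) -> None:
        self._x = -0.5
        self._v = 0.0
        self._done = False

    def reset(self, seed: int | None = None) -> np.ndarray:
        self._x, self._v = -0.5, 0.0
        self._done = False
        return self._obs()

    def _obs(self) -> np.ndarray:
        return np.array([self._x, self._v])

    def step(self, action) -> tuple[np.ndarray, float, bool]:
        if self._done:
            raise RuntimeError("step() after episode end; call reset()")
        a = float(np.clip(np.asarray(action).ravel()[0], -1.0, 1.0))
        self._v = float(
            np.clip(
                self._v + 0.0015 * a - 0.0025 * np.cos(3.0 * self._x),
                *self.v_range,
            )
        )
        self._x += self._v
        if self._x <= self.x_range[0]:
            self._x, self._v = self.x_range[0], 0.0
        self._x = min(self._x, self.x_range[1])
        reward = -0.1 * a * a
        if self._x >= self.goal:
            reward += 100.0
            self._done = True
        return self._obs(), reward, self._done


class PointMass:
    """1-D point mass pushed toward the origin; dense quadratic reward.

    Cheap smoke-test task: reward -(x^2 + 0.01 a^2) per step, episode
    never terminates early.  Start position drawn from the seed.
    """

    obs_dim = 2
    act_dim = 1

    def __init__(self) -> None:
        self._x = 1.0
        self._v = 0.0

    def reset(self, seed: int | None = None) -> np.ndarray:
        rng = np.random.default_rng(0 if seed is None else seed)
        self._x = float(rng.uniform(0.5, 1.5))
        self._v = 0.0
        return np.array([self._x, self._v])

    def step(self, action) -> tuple[np.ndarray, float, bool]:
        a = float(np.clip(np.asarray(action).ravel()[0], -1.0, 1.0))
        self._v = 0.9 * self._v + 0.1 * a
        self._x += 0.1 * self._v
        reward = -(self._x ** 2) - 0.01 * a * a
        return np.array([self._x, self._v]), reward, False


def toy_mountain_car() -> ToyMountainCar:
    """Fresh :class:`ToyMountainCar` instance (obs_dim 2, act_dim 1)."""
    return ToyMountainCar()


class GymAdapter:
    """Wrap a gymnasium environment behind the reset/step contract.

    Thin optional shim for running external physics simulators; the
    import happens lazily so the package never requires gymnasium.
    """

    def __init__(self, env_id: str, **kwargs):
        import gymnasium

        self._env = gymnasium.make(env_id, **kwargs)
        self.obs_dim = int(np.prod(self._env.observation_space.shape))
        self.act_dim = int(np.prod(self._env.action_space.shape))

    def reset(self, seed: int | None = None):
        obs, _ = self._env.reset(seed=seed)
        return np.asarray(obs, dtype=float).ravel()

    def step(self, action):
        obs, reward, terminated, truncated, _ = self._env.step(
            np.asarray(action, dtype=np.float32)
        )
        return (
            np.asarray(obs, dtype=float).ravel(),
            float(reward),
            bool(terminated or truncated),
        )
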