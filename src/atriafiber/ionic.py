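"""Ionic-model contract for the monodomain reaction term.

The tissue model advances a normalized transmembrane potential u (0 at rest,
~1 at the action-potential peak); an affine map ``V = V_rest + V_amp * u``
converts to millivolts for activation-time detection.  A model supplies the
reaction current I_ion(y, u) entering the monodomain balance

    chi * C_m * du/dt + I_ion(y, u) + I_stim = div(sigma grad u),

with I_ion in uA/cm^3 on the normalized-potential scale (so a depolarizing
current is negative), and the gating dynamics dy/dt = g(y, u).

The shipped reaction model is a phenomenological two-current
(Mitchell-Schaeffer-type) model: one fast inward current gated by h and one
ungated outward leak.  It reproduces the tissue-scale features the harness
needs — a stable resting state, threshold excitation, a propagating upstroke
with conduction speed scaling as sqrt(sigma) — without the ionic detail of
biophysical atrial cell models, which plug in behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class IonicModel:
    """Contract: reaction term and state dynamics for the monodomain solver."""

    #: number of gating/state variables per node
    n_states: int = 0
    #: rest state of u (normalized) and y
    u_rest: float = 0.0
    #: millivolt map
    V_rest: float = -80.0
    V_amp: float = 100.0
    #: admissible normalized-potential range for stability monitoring
    u_range: tuple[float, float] = (-0.5, 1.6)

    def y_rest(self, n_nodes: int) -> np.ndarray:
        raise NotImplementedError

    def I_ion(self, y: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Reaction current (uA/cm^3); negative values depolarize."""
        raise NotImplementedError

    def g(self, y: np.ndarray, u: np.ndarray) -> np.ndarray:
        """State dynamics dy/dt (1/ms)."""
        raise NotImplementedError

    def step_states(self, y: np.ndarray, u: np.ndarray, dt: float) -> np.ndarray:
        """Advance y by dt; default explicit Euler on g."""
        return y + dt * self.g(y, u)

    def V_of(self, u: np.ndarray) -> np.ndarray:
        return self.V_rest + self.V_amp * np.asarray(u)


@dataclass
class TwoCurrentModel(IonicModel):
    """Two-current excitable membrane (fast inward, slow outward).

    du/dt = h u^2 (1-u)/tau_in - u/tau_out  (plus diffusion and stimulus)
    dh/dt = (1-h)/tau_open  for u < u_gate,  -h/tau_close otherwise

    The inward time constant sets the upstroke (~1 ms), the outward one the
    repolarization; the gate recovery constants set refractoriness.  The
    rest state (u, h) = (0, 1) is an exact equilibrium, so an unstimulated
    tissue does not drift.  ``chi`` (1/cm) and ``Cm`` (uF/cm^2) scale the
    reaction rate to a volumetric current density.
    """

    tau_in: float = 0.3      # ms
    tau_out: float = 6.0     # ms
    tau_open: float = 120.0  # ms
    tau_close: float = 80.0  # ms
    u_gate: float = 0.13
    chi: float = 1000.0      # 1/cm
    Cm: float = 1.0          # uF/cm^2

    n_states = 1
    u_rest = 0.0
    V_rest = -80.0
    V_amp = 100.0

    def y_rest(self, n_nodes: int) -> np.ndarray:
        return np.ones((1, n_nodes))

    def _rate(self, y, u):
        h = y[0]
        return h * u * u * (1.0 - u) / self.tau_in - u / self.tau_out

    def I_ion(self, y, u):
        return -self.chi * self.Cm * self._rate(y, u)

    def g(self, y, u):
        h = y[0]
        below = u < self.u_gate
        dh = np.where(below, (1.0 - h) / self.tau_open, -h / self.tau_close)
        return dh[None, :]

    def step_states(self, y, u, dt):
        # exact exponential relaxation of the gate toward its target
        h = y[0]
        below = u < self.u_gate
        h_inf = np.where(below, 1.0, 0.0)
        tau = np.where(below, self.tau_open, self.tau_close)
        h_new = h_inf + (h - h_inf) * np.exp(-dt / tau)
        return h_new[None, :]
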