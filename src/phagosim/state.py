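"""Shared field-state container for the two-phase cytoplasm model."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldState:
    """Nodal/element fields carried by the simulation.

    theta       : network (F-actin) volume fraction, one value per element
    v_network   : nodal cytoskeletal-network velocity, (N, 2) in µm/s, columns (r, z)
    v_solvent   : nodal cytosol velocity, (N, 2) in µm/s
    pressure    : element pressure in pN/µm² (numerically equal to Pa)
    messenger   : nodal concentration of the signaling messenger, a.u.
    """

    theta: np.ndarray
    v_network: np.ndarray
    v_solvent: np.ndarray
    pressure: np.ndarray
    messenger: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(
            theta=self.theta.copy(),
            v_network=self.v_network.copy(),
            v_solvent=self.v_solvent.copy(),
            pressure=self.pressure.copy(),
            messenger=self.messenger.copy(),
        )

    @classmethod
    def resting(cls, n_nodes: int, n_elements: int, theta_base: float) -> "FieldState":
        """A quiescent state: uniform resting network fraction, no flow, no messenger."""
        return cls(
            theta=np.full(n_elements, float(theta_base)),
            v_network=np.zeros((n_nodes, 2)),
            v_solvent=np.zeros((n_nodes, 2)),
            pressure=np.zeros(n_elements),
            messenger=np.zeros(n_nodes),
        )
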