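"""STN local field potential synthesis.

The LFP at each recording contact is the volume-conductor sum of all
STN synaptic currents,

    LFP_i(t) = (1 / 4πσ) Σ_j Σ_k I_syn,jk(t) / r_ij,

where all synapses of STN neuron j (excitatory and inhibitory alike)
sit at a single point: the neuron's (x, y) location offset 250 µm from
the electrode plane along z.  The recorded signal is the bipolar
difference between the two contacts, with the fixed sign convention
``contact at +x minus contact at -x``.

Units: synaptic currents in nA and distances in mm give the LFP
directly in µV for σ in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulation import SIGMA

__all__ = ["SynapseGeometry", "record_lfp"]

#: Offset of the STN synapse plane from the electrode plane (mm).
Z_OFFSET_MM = 0.25


@dataclass(frozen=True)
class SynapseGeometry:
    """Contact–synapse distances for the bipolar recording pair.

    ``positions_xy`` holds one (x, y) point per STN neuron; every
    synapse of that neuron contributes from that point, 250 µm off the
    electrode plane.  ``distances`` is the (2, n_neurons) matrix of
    contact-to-synapse distances in mm.
    """

    positions_xy: np.ndarray
    contacts_xyz: np.ndarray
    distances: np.ndarray
    sigma: float = SIGMA

    @classmethod
    def from_positions(
        cls,
        positions_xy: np.ndarray,
        contacts_xyz: np.ndarray,
        z_offset_mm: float = Z_OFFSET_MM,
        sigma: float = SIGMA,
    ) -> "SynapseGeometry":
        pos = np.asarray(positions_xy, dtype=float)
        contacts = np.asarray(contacts_xyz, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions_xy must have shape (n, 2)")
        if contacts.shape != (2, 3):
            raise ValueError("contacts_xyz must have shape (2, 3)")
        pts = np.column_stack([pos, np.full(len(pos), z_offset_mm)])
        d = np.linalg.norm(pts[None, :, :] - contacts[:, None, :], axis=2)
        if np.any(d <= 0):
            raise ValueError("synapse coincides with a recording contact")
        return cls(pos, contacts, d, sigma)


def record_lfp(
    syn_currents_na: np.ndarray,
    geometry: SynapseGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Monopolar contact potentials and the bipolar LFP trace (µV).

    ``syn_currents_na`` has shape (n_neurons, n_times): the summed
    synaptic current of each STN neuron (all of a neuron's synapses
    share one location, so their currents may be pre-summed).  Returns
    ``(monopolar, bipolar)`` with shapes (2, n_times) and (n_times,).
    """
    cur = np.atleast_2d(np.asarray(syn_currents_na, dtype=float))
    if cur.shape[0] != geometry.distances.shape[1]:
        raise ValueError(
            f"{cur.shape[0]} current rows for {geometry.distances.shape[1]} "
            "geometry entries"
        )
    scale = 1.0 / (4.0 * np.pi * geometry.sigma)
    monopolar = scale * (1.0 / geometry.distances) @ cur
    bipolar = monopolar[0] - monopolar[1]
    return monopolar, bipolar
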