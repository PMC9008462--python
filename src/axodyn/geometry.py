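"""Chamber geometry of the compartmentalized culture device.

The device is reduced to an along-axon coordinate system: a polyline axon
path runs from the axonal compartment (where ligand is added, arc 0)
through a microchannel into the cell-body compartment and terminates at a
soma.  Regions are half-open arc intervals ``[start, end)`` in um, so every
point gets exactly one label (boundary points belong to the downstream,
soma-ward region of the shared edge's two intervals by the half-open rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion import AxonPath

__all__ = ["ChamberGeometry", "REGION_LABELS"]

#: Region labels, ordered from ligand-addition point toward the soma.
REGION_LABELS = ("Ac", "microchannel", "CBc_axon", "soma")

OUTSIDE = "outside"


@dataclass(frozen=True)
class ChamberGeometry:
    """Arc-interval layout of the microfluidic device along one axon.

    Defaults: a 100-um axonal-compartment stretch, a 450 x 10 um
    microchannel, 1000 um of proximal axon in the cell-body compartment and
    a 50-um soma. ``source_arc_um`` is the ligand addition point from which
    transport distance is measured.
    """

    ac_length_um: float = 100.0
    microchannel_length_um: float = 450.0
    microchannel_width_um: float = 10.0
    cbc_length_um: float = 1000.0
    soma_length_um: float = 50.0
    source_arc_um: float = 0.0

    def __post_init__(self):
        for name in ("ac_length_um", "microchannel_length_um",
                     "cbc_length_um", "soma_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def boundaries(self):
        """Cumulative arc boundaries of the four regions."""
        b = np.cumsum([0.0, self.ac_length_um, self.microchannel_length_um,
                       self.cbc_length_um, self.soma_length_um])
        return b

    @property
    def total_length_um(self) -> float:
        return float(self.boundaries[-1])

    def default_path(self) -> AxonPath:
        """Straight axon path spanning the whole device."""
        return AxonPath.straight(self.total_length_um, origin=(0.0, 5.0))

    def region_of_arc(self, arc_um):
        """Region label(s) for arc coordinate(s); half-open intervals."""
        arc = np.atleast_1d(np.asarray(arc_um, float))
        b = self.boundaries
        idx = np.searchsorted(b, arc, side="right") - 1
        out = np.empty(arc.shape, dtype=object)
        for i, k in enumerate(idx):
            if 0 <= k < 4:
                out[i] = REGION_LABELS[k]
            elif k == 4 and arc[i] == b[-1]:
                out[i] = REGION_LABELS[3]
            else:
                out[i] = OUTSIDE
        return out if np.ndim(arc_um) else str(out[0])

    def region_interval(self, label: str):
        """Arc interval ``[start, end)`` of a region."""
        b = self.boundaries
        k = REGION_LABELS.index(label)
        return float(b[k]), float(b[k + 1])

    def distance_from_source(self, arc_um):
        """Along-path transport distance from the ligand addition point."""
        return np.maximum(np.asarray(arc_um, float) - self.source_arc_um, 0.0)
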