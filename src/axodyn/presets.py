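"""Simulation presets reproducing the study conditions.

The kinetic numbers are the region-stratified phase statistics measured for
BDNF-quantum-dot retrograde transport in compartmentalized DRG sensory
neuron cultures: distal axons (inside the 450-um microchannels), proximal
axons (in the cell-body compartment), and cargo inside cell bodies.  Active
and paused phase durations are mean +/- SD in seconds; active speed is the
per-phase net speed in um/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .camera import CameraModel
from .motion import BlinkModel, MotionParams

__all__ = ["KINETICS", "SimulationPreset", "PRESETS", "get_preset"]

#: Region-stratified run/pause kinetics (means and SDs).
KINETICS = {
    "distal": MotionParams(
        motion_class="AT",
        active_speed_mean=1.531, active_speed_sd=0.486,
        active_dur_mean=7.218, active_dur_sd=6.345,
        pause_dur_mean=5.285, pause_dur_sd=9.420),
    "proximal": MotionParams(
        motion_class="AT",
        active_speed_mean=1.544, active_speed_sd=0.446,
        active_dur_mean=6.721, active_dur_sd=6.634,
        pause_dur_mean=1.931, pause_dur_sd=1.842),
    "soma": MotionParams(
        motion_class="AT",
        active_speed_mean=1.10, active_speed_sd=0.55,
        active_dur_mean=1.955, active_dur_sd=1.945,
        pause_dur_mean=4.953, pause_dur_sd=3.777),
}


@dataclass(frozen=True)
class SimulationPreset:
    """A named simulation scenario: kinetics + where tracks live."""

    name: str
    motion: MotionParams
    region: str                 # region tracks start in (see geometry)
    n_tracks: int = 5
    total_time_s: float = 120.0
    blink: BlinkModel = field(default_factory=BlinkModel)
    description: str = ""


PRESETS = {
    "distal": SimulationPreset(
        "distal", KINETICS["distal"], region="microchannel",
        description="active transport along axons inside microchannels"),
    "proximal": SimulationPreset(
        "proximal", KINETICS["proximal"], region="CBc_axon",
        description="active transport along axons in the cell-body chamber"),
    "soma": SimulationPreset(
        "soma", KINETICS["soma"], region="soma",
        description="slow active transport inside cell bodies"),
    "bf": SimulationPreset(
        "bf", MotionParams(motion_class="B&F", confinement_length=5.0,
                           bf_diffusion=0.1),
        region="Ac",
        description="confined back-and-forth diffusion near axonal tips"),
    "pair": SimulationPreset(
        "pair", MotionParams(
            motion_class="AT_pair",
            active_speed_mean=1.544, active_speed_sd=0.446,
            active_dur_mean=6.721, active_dur_sd=6.634,
            pause_dur_mean=1.931, pause_dur_sd=1.842,
            pair_coupling_rest=0.5, pair_coupling_sd=0.15),
        region="CBc_axon", n_tracks=2,
        description="coordinated co-transported pair (< 2 um apart)"),
    # Dynein inhibition: active transport disabled, cargo stays diffusive /
    # stationary in the axonal compartment and never crosses the channels.
    "ehna": SimulationPreset(
        "ehna", MotionParams(motion_class="B&F", confinement_length=5.0,
                             bf_diffusion=0.1),
        region="Ac",
        description="dynein blocked: no active transport beyond the "
                    "axonal compartment"),
}


def get_preset(name: str) -> SimulationPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
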