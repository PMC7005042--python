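"""Transcranial Doppler indices for the MCA trunk.

Velocities come angle-corrected from transcranial colour-coded sonography:
peak systolic ``vps``, end-diastolic ``ved`` and mean ``vm``, all in cm/s.

* Pulsatility index ``PI = (vps − ved) / vm`` (dimensionless; Gosling's
  index, lower values indicate a less pulsatile, higher-throughput bed).
* Volume flow rate ``VFR = vm · p0`` with the trunk cross-section ``p0``
  supplied in mm² and the result in cm³/s — the mm²→cm² conversion
  (``p0 / 100``) happens here and nowhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DopplerRecord",
    "HemodynamicMetrics",
    "pulsatility_index",
    "volume_flow_rate",
]


@dataclass(frozen=True)
class DopplerRecord:
    """One MCA's velocities (cm/s); requires ``vps >= vm >= ved > 0``."""

    vps: float
    ved: float
    vm: float

    def __post_init__(self) -> None:
        if self.ved <= 0:
            raise ValueError("end-diastolic velocity must be positive")
        if not self.vps >= self.vm >= self.ved:
            raise ValueError("velocities must satisfy vps >= vm >= ved")


@dataclass(frozen=True)
class HemodynamicMetrics:
    pi: float
    vfr: float


def pulsatility_index(d: DopplerRecord) -> float:
    """Gosling pulsatility index ``(vps − ved)/vm``."""
    return (d.vps - d.ved) / d.vm


def volume_flow_rate(vm: float, p0: float) -> float:
    """Volume flow rate in cm³/s from ``vm`` (cm/s) and trunk area ``p0`` (mm²)."""
    if vm <= 0 or p0 <= 0:
        raise ValueError("vm and p0 must be positive")
    return vm * (p0 / 100.0)
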