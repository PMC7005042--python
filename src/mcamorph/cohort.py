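"""Seeded synthetic cohorts with the study's four-group structure.

The source study's patient-level data are unavailable; what is printed is the
per-group sample size and mean ± SD of each morphometric and hemodynamic
parameter.  This module turns those summary statistics into a reproducible
per-bifurcation table with the same group structure:

* ``An`` — aneurysmal MCA bifurcations (cases),
* ``nonAn`` — contralateral non-aneurysmal bifurcations of the same patients,
* ``R`` / ``L`` — right and left MCA bifurcations of control subjects.

Each parameter is modelled as a truncated normal with the printed location and
scale; truncation sits at physiologic bounds.  Only means and SDs are
recoverable from the published summaries, so the normal marginal is the
minimal distributional assumption — see ``docs/methods.md`` for what this
does and does not emulate.

Two generation modes:

* ``marginal`` (default) — every parameter drawn independently from its
  truncated normal; VFR and the angles used by the discrimination analyses
  come straight from their printed marginals.
* ``mechanistic`` — radii and ``vm`` are drawn and the dependent quantities
  derived (``p = π r²``, ``VFR = vm·p0/100``), with optional ``vm``–``r0``
  correlation; used to stress-test pipeline consistency, since it induces the
  cross-parameter correlations the marginal mode deliberately omits.

Derived indices (junction exponent, asymmetry/area ratios, PI from the
synthesised velocity triple) are never drawn — they are computed downstream
from the generated columns, exactly as for a measured cohort.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "GroupSpec",
    "CohortTable",
    "default_table1_specs",
    "generate_cohort",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
]

#: generated parameter columns (location/scale pairs per group)
PARAM_NAMES = (
    "r0", "r1", "r2", "p0", "p1", "p2", "tortuosity",
    "phi1", "phi2", "alpha", "vm", "vfr", "pi",
)

_INF = math.inf

#: physiologic truncation defaults: radii > 0.3 mm, angles in (5, 179) deg,
#: velocities > 5 cm/s; PI capped below 1.9 so the synthesised velocity
#: triple keeps vps >= vm >= ved > 0.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r0": (0.3, _INF),
    "r1": (0.3, _INF),
    "r2": (0.3, _INF),
    "p0": (0.1, _INF),
    "p1": (0.1, _INF),
    "p2": (0.1, _INF),
    "tortuosity": (0.0, _INF),
    "phi1": (5.0, 179.0),
    "phi2": (5.0, 179.0),
    "alpha": (5.0, 179.0),
    "vm": (5.0, _INF),
    "vfr": (0.1, _INF),
    "pi": (0.05, 1.9),
}

#: printed per-group summary statistics (mean, SD) per parameter
_TABLE1: dict[str, dict[str, tuple[float, float]]] = {
    "An": {
        "r0": (1.39, 0.18), "r1": (1.16, 0.17), "r2": (0.84, 0.20),
        "p0": (6.1, 1.6), "p1": (4.3, 1.2), "p2": (2.3, 1.0),
        "tortuosity": (0.06, 0.04),
        "phi1": (58.5, 24.8), "phi2": (82.4, 20.9), "alpha": (128.6, 24.2),
        "vm": (70.6, 14.1), "vfr": (4.42, 1.46), "pi": (0.81, 0.11),
    },
    "nonAn": {
        "r0": (1.42, 0.20), "r1": (1.17, 0.20), "r2": (0.89, 0.17),
        "p0": (6.3, 1.8), "p1": (4.3, 1.5), "p2": (2.51, 1.1),
        "tortuosity": (0.07, 0.05),
        "phi1": (48.3, 21.2), "phi2": (68.1, 20.6), "alpha": (105.8, 19.7),
        "vm": (67.1, 14.5), "vfr": (4.30, 1.54), "pi": (0.84, 0.11),
    },
    "R": {
        "r0": (1.35, 0.16), "r1": (1.14, 0.17), "r2": (0.85, 0.17),
        "p0": (5.7, 1.2), "p1": (4.2, 1.2), "p2": (2.3, 0.9),
        "tortuosity": (0.07, 0.06),
        "phi1": (47.4, 22.9), "phi2": (61.7, 17.1), "alpha": (98.6, 21.4),
        "vm": (67.0, 11.9), "vfr": (3.68, 0.92), "pi": (0.86, 0.15),
    },
    "L": {
        "r0": (1.31, 0.19), "r1": (1.11, 0.18), "r2": (0.84, 0.18),
        "p0": (5.4, 1.6), "p1": (3.9, 1.4), "p2": (2.3, 1.0),
        "tortuosity": (0.08, 0.07),
        "phi1": (42.8, 22.0), "phi2": (65.1, 18.3), "alpha": (93.1, 18.5),
        "vm": (66.8, 11.5), "vfr": (3.46, 1.21), "pi": (0.85, 0.14),
    },
}

_GROUP_N = {"An": 102, "nonAn": 82, "R": 88, "L": 87}


@dataclass(frozen=True)
class GroupSpec:
    """Distributional recipe for one group's parameters."""

    label: str
    n: int
    params: Mapping[str, tuple[float, float]]
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.label not in ("An", "nonAn", "R", "L"):
            raise ValueError(f"unknown group label {self.label!r}")
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name, (mean, sd) in self.params.items():
            if sd < 0:
                raise ValueError(f"{name}: SD must be >= 0")
            lo, hi = self.bounds.get(name, (-_INF, _INF))
            if not lo <= mean <= hi:
                raise ValueError(
                    f"{name}: truncation bounds ({lo}, {hi}) exclude the mean {mean}"
                )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "params": {k: list(v) for k, v in self.params.items()},
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSpec":
        return cls(
            label=d["label"],
            n=int(d["n"]),
            params={k: (float(a), float(b)) for k, (a, b) in d["params"].items()},
            bounds={k: (float(a), float(b)) for k, (a, b) in d["bounds"].items()},
        )


@dataclass(frozen=True)
class CohortTable:
    """Generated or loaded per-bifurcation table plus provenance."""

    data: pd.DataFrame
    provenance: dict


def default_table1_specs() -> list[GroupSpec]:
    """The four group specs calibrated to the printed group summaries."""
    return [
        GroupSpec(label=g, n=_GROUP_N[g], params=dict(_TABLE1[g]))
        for g in ("An", "nonAn", "R", "L")
    ]


def spec_hash(specs: Sequence[GroupSpec]) -> str:
    payload = json.dumps([s.to_dict() for s in specs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _draw_truncnorm(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _subject_ids(label: str, n: int) -> list[str]:
    # An and nonAn rows share patient ids (contralateral side of the same
    # patient); R and L rows share control-subject ids.
    prefix = "P" if label in ("An", "nonAn") else "C"
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _group_frame(
    spec: GroupSpec, rng: np.random.Generator, mode: str, rho_vm_r0: float
) -> pd.DataFrame:
    n = spec.n
    draws: dict[str, np.ndarray] = {}

    if mode == "marginal":
        for name in PARAM_NAMES:
            mean, sd = spec.params[name]
            lo, hi = spec.bounds.get(name, (-_INF, _INF))
            draws[name] = _draw_truncnorm(mean, sd, lo, hi, n, rng)
        r1, r2 = draws["r1"], draws["r2"]
        swap = r2 > r1
        draws["r1"], draws["r2"] = np.where(swap, r2, r1), np.where(swap, r1, r2)
    elif mode == "mechanistic":
        if abs(rho_vm_r0) >= 1:
            raise ValueError("rho_vm_r0 must lie in (-1, 1)")
        m0, s0 = spec.params["r0"]
        mv, sv = spec.params["vm"]
        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho_vm_r0], [rho_vm_r0, 1.0]], size=n
        )
        lo0, hi0 = spec.bounds["r0"]
        lov, hiv = spec.bounds["vm"]
        r0 = np.clip(m0 + s0 * z[:, 0], lo0, hi0)
        draws["r0"] = r0
        draws["vm"] = np.clip(mv + sv * z[:, 1], lov, hiv)
        for name in ("r1", "r2", "tortuosity", "phi1", "phi2", "alpha", "pi"):
            mean, sd = spec.params[name]
            lo, hi = spec.bounds.get(name, (-_INF, _INF))
            draws[name] = _draw_truncnorm(mean, sd, lo, hi, n, rng)
        r1, r2 = draws["r1"], draws["r2"]
        swap = r2 > r1
        draws["r1"], draws["r2"] = np.where(swap, r2, r1), np.where(swap, r1, r2)
        draws["p0"] = np.pi * draws["r0"] ** 2
        draws["p1"] = np.pi * draws["r1"] ** 2
        draws["p2"] = np.pi * draws["r2"] ** 2
        draws["vfr"] = draws["vm"] * draws["p0"] / 100.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # velocity triple consistent with the drawn mean velocity and PI:
    # spread the systolic-diastolic excursion symmetrically around vm
    vps = draws["vm"] * (1.0 + draws["pi"] / 2.0)
    ved = draws["vm"] * (1.0 - draws["pi"] / 2.0)

    side = {"R": "R", "L": "L"}.get(spec.label, "")
    return pd.DataFrame(
        {
            "subject_id": _subject_ids(spec.label, n),
            "group": spec.label,
            "side": side,
            "r0": draws["r0"],
            "r1": draws["r1"],
            "r2": draws["r2"],
            "p0": draws["p0"],
            "p1": draws["p1"],
            "p2": draws["p2"],
            "alpha_deg": draws["alpha"],
            "beta_deg": 180.0 - draws["phi1"],
            "gamma_deg": 180.0 - draws["phi2"],
            "vps": vps,
            "ved": ved,
            "vm": draws["vm"],
            "tortuosity": draws["tortuosity"],
            "vfr": draws["vfr"],
        }
    )


def generate_cohort(
    specs: Sequence[GroupSpec],
    seed: int,
    mode: str = "marginal",
    rho_vm_r0: float = 0.0,
) -> CohortTable:
    """Draw a cohort from ``specs``; deterministic for a fixed ``(specs, seed)``.

    In ``marginal`` mode the ``vfr`` column carries the marginally drawn
    volume flow rate (the quantity whose printed group summary is being
    emulated); in ``mechanistic`` mode it is derived from ``vm`` and ``p0``.
    """
    rng = np.random.default_rng(seed)
    frames = [_group_frame(s, rng, mode, rho_vm_r0) for s in specs]
    data = pd.concat(frames, ignore_index=True)
    prov = {
        "seed": int(seed),
        "mode": mode,
        "spec_hash": spec_hash(specs),
    }
    return CohortTable(data=data, provenance=prov)
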