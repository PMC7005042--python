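"""Optimal bifurcation angles under the principle of minimum work.

For a bifurcation with canonical radii ``r0 >= ... r1 >= r2`` the angles that
minimise the energetic cost of the junction have closed forms that depend on
which cost is minimised:

* minimum **surface** / minimum **endothelial drag** (cost ∝ Σ rᵢ·Lᵢ):
  the optimal angles are the angles of the triangle with side lengths
  ``r0, r1, r2``;
* minimum **volume** / minimum **pumping power** (cost ∝ Σ rᵢ²·Lᵢ):
  the same construction on the squared radii ``r0², r1², r2²``.

Both families follow from the weighted Fermat-point condition: the junction
position minimising ``Σ wᵢ·|J − Xᵢ|`` (with ``wᵢ = rᵢ`` or ``rᵢ²``) pulls the
three segments into directions whose pairwise cosines are
``(w₀² + wᵢ² − wⱼ²)/(2 w₀ wᵢ)``.  :func:`weighted_fermat_oracle` performs that
minimisation numerically and serves as an independent check of the closed
forms.

A rule is *infeasible* when its weights violate the triangle inequality (one
cosine argument leaves ``[-1, 1]``); no interior optimum exists and angles are
reported as missing rather than clamped to a fabricated 0°/180° solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "OptimalAngles",
    "AngleDeviations",
    "optimal_angles_surface",
    "optimal_angles_volume",
    "optimal_angles",
    "angle_deviations",
    "weighted_fermat_oracle",
]

# cosine arguments within this distance of +/-1 are accepted as boundary values
_BOUNDARY_EPS = 1e-12


class RuleAngles(NamedTuple):
    phi1_deg: float
    phi2_deg: float
    total_deg: float
    valid: bool


@dataclass(frozen=True)
class OptimalAngles:
    """Predicted optimal angles (degrees) under both rule families.

    ``_s`` fields: minimum surface / endothelial drag rules (ϕ1, ϕ2, ϕ1+ϕ2);
    ``_v`` fields: minimum volume / pumping power rules (ϕ′1, ϕ′2, ϕ′1+ϕ′2).
    Angles are NaN when the corresponding rule is infeasible.
    """

    phi1_s_deg: float
    phi2_s_deg: float
    total_s_deg: float
    valid_s: bool
    phi1_v_deg: float
    phi2_v_deg: float
    total_v_deg: float
    valid_v: bool


def _safe_arccos_deg(arg: float) -> Optional[float]:
    if abs(arg) > 1.0 + _BOUNDARY_EPS:
        return None
    return math.degrees(math.acos(min(1.0, max(-1.0, arg))))


def _triangle_angles(a: float, b: float, c: float) -> RuleAngles:
    """Angles (deg) opposite c, opposite b, and their sum, for sides a,b,c.

    ``a`` plays the role of the trunk weight; the returned angles are the
    optimal trunk-axis→branch angles and the total branch-to-branch angle.
    """
    phi1 = _safe_arccos_deg((a * a + b * b - c * c) / (2.0 * a * b))
    phi2 = _safe_arccos_deg((a * a + c * c - b * b) / (2.0 * a * c))
    total = _safe_arccos_deg((a * a - b * b - c * c) / (2.0 * b * c))
    if phi1 is None or phi2 is None or total is None:
        return RuleAngles(math.nan, math.nan, math.nan, False)
    return RuleAngles(phi1, phi2, total, True)


def _check_radii(r0: float, r1: float, r2: float) -> None:
    if r0 <= 0 or r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")


def optimal_angles_surface(r0: float, r1: float, r2: float) -> RuleAngles:
    """Optimal angles under the minimum surface / endothelial drag rules.

    cos ϕ1 = (r0²+r1²−r2²)/(2 r0 r1), cos ϕ2 = (r0²+r2²−r1²)/(2 r0 r2),
    cos(ϕ1+ϕ2) = (r0²−r1²−r2²)/(2 r1 r2).
    """
    _check_radii(r0, r1, r2)
    return _triangle_angles(r0, r1, r2)


def optimal_angles_volume(r0: float, r1: float, r2: float) -> RuleAngles:
    """Optimal angles under the minimum volume / pumping power rules.

    Same structure on squared radii: cos ϕ′1 = (r0⁴+r1⁴−r2⁴)/(2 r0² r1²), etc.
    """
    _check_radii(r0, r1, r2)
    return _triangle_angles(r0 * r0, r1 * r1, r2 * r2)


def optimal_angles(r0: float, r1: float, r2: float) -> OptimalAngles:
    """Both rule families for one radius triple."""
    s = optimal_angles_surface(r0, r1, r2)
    v = optimal_angles_volume(r0, r1, r2)
    return OptimalAngles(
        s.phi1_deg, s.phi2_deg, s.total_deg, s.valid,
        v.phi1_deg, v.phi2_deg, v.total_deg, v.valid,
    )


@dataclass(frozen=True)
class AngleDeviations:
    """Predicted − observed angle differences (degrees).

    ``d1_s = ϕ1 − Φ1`` etc.; ``dt`` rows compare the predicted total angle
    against the observed inter-branch angle α.  Infeasible rules propagate
    as NaN.
    """

    d1_s: float
    d2_s: float
    dt_s: float
    d1_v: float
    d2_v: float
    dt_v: float


def angle_deviations(
    opt: OptimalAngles,
    phi1_obs_deg: float,
    phi2_obs_deg: float,
    alpha_deg: float,
) -> AngleDeviations:
    """Six predicted−observed deviations; NaN where a rule is infeasible.

    The primed-family rows are differenced against the same observed angles
    Φ1, Φ2, α as the unprimed family (there is only one set of observations).
    """
    nan = math.nan
    return AngleDeviations(
        d1_s=opt.phi1_s_deg - phi1_obs_deg if opt.valid_s else nan,
        d2_s=opt.phi2_s_deg - phi2_obs_deg if opt.valid_s else nan,
        dt_s=opt.total_s_deg - alpha_deg if opt.valid_s else nan,
        d1_v=opt.phi1_v_deg - phi1_obs_deg if opt.valid_v else nan,
        d2_v=opt.phi2_v_deg - phi2_obs_deg if opt.valid_v else nan,
        dt_v=opt.total_v_deg - alpha_deg if opt.valid_v else nan,
    )


def weighted_fermat_oracle(
    r0: float,
    r1: float,
    r2: float,
    k: int,
    seed: Optional[int] = None,
    move_tol: float = 1e-10,
    max_iter: int = 200_000,
) -> tuple[float, float]:
    """Numerically recover the optimal branch angles from first principles.

    Places three endpoints in the plane (randomised by ``seed``, far from
    collinear), minimises the junction cost ``C(J) = Σ wᵢ·|J − Xᵢ|`` with
    weights ``wᵢ = rᵢᵏ`` (``k=1``: surface/drag rules, ``k=2``:
    volume/pumping-power rules) by Weiszfeld iteration started at the
    endpoint centroid, and measures the angles between the parent-flow
    direction (X0→J prolonged) and each branch segment at the optimum.

    Endpoint placement: a junction interior to the endpoint triangle exists
    only when each triangle angle is smaller than the corresponding
    force-balance angle of the weight triple (the classical generalisation of
    the 120° Fermat condition).  The endpoint triangle is therefore drawn
    with angles at random fractions (0.4–0.6, renormalised) of those
    feasibility margins; the *returned* angles are measured at the converged
    cost minimum and never come from the placement computation, so a defect
    in the closed forms shows up as a mismatch rather than being echoed.

    Raises ``ValueError`` when one weight is ≥ the sum of the others — the
    optimum then sits at an endpoint and no interior branching angle exists.
    """
    _check_radii(r0, r1, r2)
    if k not in (1, 2):
        raise ValueError("weight exponent k must be 1 or 2")
    w = np.array([r0, r1, r2], dtype=float) ** k
    if np.any(w >= w.sum() - w):
        raise ValueError("no interior optimum: one weight dominates the others")

    rng = np.random.default_rng(seed)
    # force-balance angles between the segment pairs at an interior optimum:
    # psi[i] = angle between the two segments not meeting endpoint i
    psi = math.pi - np.array([
        math.acos((w[1] ** 2 + w[2] ** 2 - w[0] ** 2) / (2 * w[1] * w[2])),
        math.acos((w[0] ** 2 + w[2] ** 2 - w[1] ** 2) / (2 * w[0] * w[2])),
        math.acos((w[0] ** 2 + w[1] ** 2 - w[2] ** 2) / (2 * w[0] * w[1])),
    ])
    theta = rng.uniform(0.4, 0.6, size=3) * psi
    theta *= math.pi / theta.sum()  # triangle angles; each stays < psi

    # build the triangle from its angles: X0 at origin, X1 on a random
    # heading, X2 by the law of sines; random scale and orientation
    heading = rng.uniform(0.0, 2.0 * math.pi)
    d01 = rng.uniform(3.0, 6.0)
    d02 = d01 * math.sin(theta[1]) / math.sin(theta[2])
    pts = np.array([
        [0.0, 0.0],
        [d01 * math.cos(heading), d01 * math.sin(heading)],
        [d02 * math.cos(heading + theta[0]), d02 * math.sin(heading + theta[0])],
    ])

    j = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - j, axis=1)
        if np.any(d < 1e-14):  # pragma: no cover - never hit for valid triples
            d = np.maximum(d, 1e-14)
        coef = w / d
        j_new = (coef[:, None] * pts).sum(axis=0) / coef.sum()
        if np.linalg.norm(j_new - j) < move_tol:
            j = j_new
            break
        j = j_new

    u_parent = (j - pts[0]) / np.linalg.norm(j - pts[0])  # parent flow direction
    out = []
    for i in (1, 2):
        v = (pts[i] - j) / np.linalg.norm(pts[i] - j)
        out.append(math.degrees(math.acos(float(np.clip(u_parent @ v, -1.0, 1.0)))))
    return out[0], out[1]
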