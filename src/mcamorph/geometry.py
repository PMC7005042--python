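"""Per-bifurcation morphometry.

A middle cerebral artery (MCA) bifurcation is described by the radii of the
parent trunk and its two branches (``r0 >= 0``, with the branches labelled so
that ``r1 >= r2``), their cross-sectional areas, and three measured angles:
``alpha`` between the post-bifurcation branches, ``beta`` between the trunk and
the larger branch, and ``gamma`` between the trunk and the smaller branch (all
in degrees).

Derived quantities:

* observed branch angles ``Phi1 = 180 - beta``, ``Phi2 = 180 - gamma``
  (branch direction relative to the trunk *axis*, i.e. the prolongation of the
  parent flow direction);
* asymmetry ratio ``r2^2 / r1^2`` and area ratio ``(r1^2 + r2^2) / r0^2``;
* the junction exponent ``n`` solving ``r0^n = r1^n + r2^n`` — equal to 3 for
  a bifurcation at the principle-of-minimum-work (Murray's law) optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from scipy.optimize import brentq

__all__ = [
    "BifurcationGeometry",
    "DerivedMetrics",
    "CanonicalBranches",
    "JunctionExponent",
    "canonicalize",
    "radius_from_diameter",
    "bifurcation_ratios",
    "observed_branch_angles",
    "junction_exponent",
    "derive_metrics",
    "DEFAULT_N_CAP",
    "DEFAULT_TOL",
]

DEFAULT_N_CAP = 20.0
DEFAULT_TOL = 1e-10
_BRACKET_LO = 1e-3


def _check_angle(name: str, value: float) -> None:
    if not 0.0 < value <= 180.0:
        raise ValueError(f"{name} must lie in (0, 180] degrees, got {value!r}")


@dataclass(frozen=True)
class BifurcationGeometry:
    """One bifurcation in canonical branch order (``r1 >= r2``).

    Radii in mm, cross-sectional areas in mm², angles in degrees.
    ``tortuosity`` is a dimensionless pass-through measured upstream; it is
    never computed here.
    """

    r0: float
    r1: float
    r2: float
    alpha_deg: float
    beta_deg: float
    gamma_deg: float
    p0: Optional[float] = None
    p1: Optional[float] = None
    p2: Optional[float] = None
    tortuosity: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r1 < self.r2:
            raise ValueError("canonical order requires r1 >= r2 (use canonicalize)")
        for name in ("p0", "p1", "p2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")
        for name in ("alpha_deg", "beta_deg", "gamma_deg"):
            _check_angle(name, getattr(self, name))


class CanonicalBranches(NamedTuple):
    """Branch data reordered so the larger-radius branch is branch 1."""

    r1: float
    r2: float
    beta_deg: float
    gamma_deg: float
    p1: Optional[float]
    p2: Optional[float]
    swapped: bool


def canonicalize(
    r_a: float,
    r_b: float,
    beta_raw: float,
    gamma_raw: float,
    p_a: Optional[float] = None,
    p_b: Optional[float] = None,
) -> CanonicalBranches:
    """Order two branches so that branch 1 has the larger radius.

    ``beta`` stays paired with the larger branch and ``gamma`` with the
    smaller one.  On an exact radius tie the input order is preserved.
    """
    if r_a <= 0 or r_b <= 0:
        raise ValueError("branch radii must be positive")
    if r_b > r_a:
        return CanonicalBranches(r_b, r_a, gamma_raw, beta_raw, p_b, p_a, True)
    return CanonicalBranches(r_a, r_b, beta_raw, gamma_raw, p_a, p_b, False)


def radius_from_diameter(d: float) -> float:
    """Radius from a best-fit diameter, ``r = d / 2``."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    return d / 2.0


def bifurcation_ratios(g: BifurcationGeometry) -> tuple[float, float]:
    """Asymmetry ratio ``r2²/r1²`` and area ratio ``(r1²+r2²)/r0²``.

    Both are dimensionless shape indices; the asymmetry ratio is 1 for a
    symmetric bifurcation and the area ratio exceeds 1 when the combined
    branch lumen is wider than the trunk.
    """
    asymmetry = (g.r2 / g.r1) ** 2
    area = (g.r1**2 + g.r2**2) / g.r0**2
    return asymmetry, area


def observed_branch_angles(beta_deg: float, gamma_deg: float) -> tuple[float, float]:
    """Observed trunk-axis→branch angles ``(Phi1, Phi2) = (180−β, 180−γ)``."""
    _check_angle("beta_deg", beta_deg)
    _check_angle("gamma_deg", gamma_deg)
    return 180.0 - beta_deg, 180.0 - gamma_deg


class JunctionExponent(NamedTuple):
    n: Optional[float]
    status: str  # "ok" | "no_solution" | "capped"


def junction_exponent(
    r0: float,
    r1: float,
    r2: float,
    tol: float = DEFAULT_TOL,
    n_cap: float = DEFAULT_N_CAP,
) -> JunctionExponent:
    """Solve ``r0^n = r1^n + r2^n`` for the junction exponent ``n > 0``.

    Works on the scale-invariant form ``f(n) = (r1/r0)^n + (r2/r0)^n − 1``,
    which is strictly decreasing in ``n`` when ``r0 > r1``, so the positive
    root is unique; it is bracketed on ``[1e-3, n_cap]`` and found with a
    safeguarded scalar root-finder to ``|f| < tol``.

    Status semantics:

    * ``ok`` — the root was found inside the bracket;
    * ``no_solution`` — ``r0 <= r1``: ``f(n) >= (r1/r0)^n >= 1`` plus a
      positive term, so ``f`` never crosses zero and no positive ``n`` exists;
    * ``capped`` — the root exceeds ``n_cap`` (``r0`` barely above ``r1``);
      ``n_cap`` is returned to avoid silently diverging exponents.
    """
    if r0 <= 0 or r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if r1 < r2:
        raise ValueError("canonical order requires r1 >= r2")
    if r0 <= r1:
        return JunctionExponent(None, "no_solution")

    q1, q2 = r1 / r0, r2 / r0

    def f(n: float) -> float:
        return q1**n + q2**n - 1.0

    if f(n_cap) > 0.0:
        return JunctionExponent(n_cap, "capped")
    root = brentq(f, _BRACKET_LO, n_cap, xtol=1e-13, rtol=8.9e-16)
    if abs(f(root)) >= tol:  # pragma: no cover - brentq at xtol=1e-13 is far tighter
        raise RuntimeError("junction exponent solver did not reach tolerance")
    return JunctionExponent(float(root), "ok")


@dataclass(frozen=True)
class DerivedMetrics:
    """Per-bifurcation derived indices (angles in degrees)."""

    phi1_obs_deg: float
    phi2_obs_deg: float
    asymmetry_ratio: float
    area_ratio: float
    junction_exponent: Optional[float]
    junction_exponent_status: str


def derive_metrics(
    g: BifurcationGeometry,
    tol: float = DEFAULT_TOL,
    n_cap: float = DEFAULT_N_CAP,
) -> DerivedMetrics:
    """All derived indices for one bifurcation."""
    phi1, phi2 = observed_branch_angles(g.beta_deg, g.gamma_deg)
    asymmetry, area = bifurcation_ratios(g)
    n, status = junction_exponent(g.r0, g.r1, g.r2, tol=tol, n_cap=n_cap)
    return DerivedMetrics(phi1, phi2, asymmetry, area, n, status)


def geometry_from_diameters(
    d0: float,
    d_a: float,
    d_b: float,
    alpha_deg: float,
    beta_raw: float,
    gamma_raw: float,
    p0: Optional[float] = None,
    p_a: Optional[float] = None,
    p_b: Optional[float] = None,
    tortuosity: Optional[float] = None,
) -> BifurcationGeometry:
    """Build a canonical geometry from best-fit diameters."""
    c = canonicalize(
        radius_from_diameter(d_a),
        radius_from_diameter(d_b),
        beta_raw,
        gamma_raw,
        p_a,
        p_b,
    )
    return BifurcationGeometry(
        r0=radius_from_diameter(d0),
        r1=c.r1,
        r2=c.r2,
        alpha_deg=alpha_deg,
        beta_deg=c.beta_deg,
        gamma_deg=c.gamma_deg,
        p0=p0,
        p1=c.p1,
        p2=c.p2,
        tortuosity=tortuosity,
    )
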