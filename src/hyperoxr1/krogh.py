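"""Step 2: Krogh-cylinder tissue oxygenation.

Each capillary supplies a coaxial tissue cylinder.  The cylinder radius R_t
follows from the voxel blood-volume fraction by arranging N_cap parallel,
unbranched, evenly spaced capillaries on a sqrt(N) x sqrt(N) cross-sectional
grid, which gives the voxel-size-independent identity

    bv = pi * R_c^2 / (4 * R_t^2)   <=>   R_t = (R_c/2) * sqrt(pi/bv).

The maximum consumption rate M0 is tied to the oxygen extraction fraction by
steady-state mass balance in the normoxic state: the oxygen delivered by one
capillary per unit time (v * pi * R_c^2 * Hct * c0 * SaO2 * OEF) equals the
consumption of its tissue annulus (M0 * pi * (R_t^2 - R_c^2) * L).

The radial tension profile is the Krogh-Erlang closed form for uniform
consumption; oxygen-dependent Michaelis-Menten consumption is incorporated by
a per-slice fixed point on the volume-weighted mean tension (the closed form
is exact only for uniform consumption, so one effective rate is used per
axial slice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PhysiologicalConstants
from .oxygen_transport import CapillaryProfile

__all__ = [
    "KroghGeometry",
    "ConsumptionModel",
    "TissueOxygenField",
    "SliceSolution",
    "TissueDelta",
    "DegenerateGeometryError",
    "TissueSolverError",
    "capillary_geometry",
    "max_consumption_from_oef",
    "krogh_radial_po2",
    "michaelis_menten_rate",
    "solve_tissue_slice",
    "tissue_field",
    "delta_tissue_po2",
]


class DegenerateGeometryError(ValueError):
    """Blood volume of 0 or 1 leaves no blood or no tissue cylinder."""


class TissueSolverError(RuntimeError):
    """The consumption fixed point failed to converge."""


@dataclass(frozen=True)
class KroghGeometry:
    """Capillary/tissue cylinder dimensions derived from blood volume."""

    r_c: float  # capillary radius, m
    r_t: float  # Krogh tissue radius, m
    cap_length: float  # m
    n_cap: float  # capillaries per voxel (continuous)
    voxel_width: float  # m
    bv: float  # blood volume fraction


@dataclass(frozen=True)
class ConsumptionModel:
    """Michaelis-Menten consumption: rate M0*PO2/(PO2+P_crit), diffusion K."""

    m0: float  # mlO2 ml-1 s-1
    p_crit: float  # mmHg
    k_diff: float  # Krogh diffusion constant K = D_T*a_T


def capillary_geometry(
    bv: float,
    constants: PhysiologicalConstants,
    voxel_volume: float = 1e-9,
) -> KroghGeometry:
    """Derive the Krogh geometry for a voxel with blood volume fraction bv."""
    if not 0.0 < bv < 1.0:
        raise DegenerateGeometryError(
            f"bv={bv} has no tissue (bv=1) or no blood (bv=0) cylinder; use the "
            "blood-only / tissue-only pipeline paths instead"
        )
    r_c = constants.cap_radius
    length = constants.cap_length
    v_cap = np.pi * r_c**2 * length
    n_cap = bv * voxel_volume / v_cap
    voxel_width = np.sqrt(voxel_volume / length)
    r_t = voxel_width / (2.0 * np.sqrt(n_cap))
    return KroghGeometry(r_c=r_c, r_t=float(r_t), cap_length=length,
                         n_cap=float(n_cap), voxel_width=float(voxel_width), bv=bv)


def max_consumption_from_oef(
    oef: float,
    hct: float,
    sao2_air: float,
    geometry: KroghGeometry,
    constants: PhysiologicalConstants,
) -> float:
    """Maximum consumption rate M0 from the normoxic oxygen extraction fraction.

    Mass balance over one Krogh cylinder at steady state:
    v*pi*R_c^2 * Hct*c0*SaO2*OEF = M0 * pi*(R_t^2 - R_c^2) * L.
    Linear in OEF; must be evaluated with normoxic (air-breathing) SaO2.
    """
    if not 0.0 <= oef < 1.0:
        raise ValueError("oef must lie in [0, 1)")
    if geometry.r_t <= geometry.r_c:
        raise DegenerateGeometryError("tissue radius must exceed capillary radius")
    num = oef * sao2_air * hct * constants.c0 * constants.cap_velocity * geometry.r_c**2
    den = (geometry.r_t**2 - geometry.r_c**2) * geometry.cap_length
    return num / den


def michaelis_menten_rate(po2, m0: float, p_crit: float):
    """Oxygen consumption rate M(PO2) = M0*PO2/(PO2+P_crit).

    For p_crit=0 the rate is m0 wherever PO2>0 and 0 at PO2=0.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    if p_crit == 0.0:
        out = np.where(po2 > 0, m0, 0.0)
    else:
        out = m0 * po2 / (po2 + p_crit)
    return float(out) if out.ndim == 0 else out


def krogh_radial_po2(
    r,
    p_cap: float,
    m_rate: float,
    geometry: KroghGeometry,
    k_diff: float,
    clamp: bool = True,
):
    """Krogh-Erlang steady-state radial tension profile for uniform consumption.

    PO2(r) = P_cap + (M/4K)(r^2 - R_c^2) - (M*R_t^2/2K)*ln(r/R_c); the radial
    gradient vanishes at r = R_t.  Negative values (oxygen cannot reach the
    outer annulus) are clamped at 0 when ``clamp`` is set.
    """
    r = np.asarray(r, dtype=float)
    eps = 1e-12 * geometry.r_t
    if np.any(r < geometry.r_c - eps) or np.any(r > geometry.r_t + eps):
        raise ValueError("r must lie within [R_c, R_t]")
    out = (
        p_cap
        + m_rate / (4.0 * k_diff) * (r**2 - geometry.r_c**2)
        - m_rate * geometry.r_t**2 / (2.0 * k_diff) * np.log(r / geometry.r_c)
    )
    if clamp:
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def _radial_mean(values: np.ndarray, r: np.ndarray) -> float:
    """Volume-weighted (weight r) mean over the annulus."""
    return float(np.trapezoid(values * r, r) / np.trapezoid(r, r))


@dataclass(frozen=True)
class SliceSolution:
    """Converged radial profile of one axial slice."""

    r_grid: np.ndarray
    po2: np.ndarray  # clamped at 0
    m_eff: float  # effective uniform consumption rate
    mean_po2: float
    iterations: int
    clamped_fraction: float  # volume fraction where the closed form went negative


def solve_tissue_slice(
    p_cap: float,
    consumption: ConsumptionModel,
    geometry: KroghGeometry,
    n_r: int = 101,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SliceSolution:
    """Fixed point coupling the Krogh-Erlang form to Michaelis-Menten rate.

    Starts from m = M0, evaluates the radial profile, recomputes
    m = M(mean slice PO2) and repeats until successive mean tensions differ by
    less than ``tol`` mmHg.  Oscillation triggers a damped (factor 0.5)
    update; non-convergence raises :class:`TissueSolverError`.  With p_crit=0
    and a positive mean the result is the closed form with m = M0.
    """
    if p_cap < 0:
        raise ValueError("p_cap must be non-negative")
    if n_r < 3:
        raise ValueError("n_r must be at least 3")
    r = np.linspace(geometry.r_c, geometry.r_t, n_r)
    weights_total = np.trapezoid(r, r)

    m = consumption.m0
    prev_mean = None
    prev_residual = np.inf
    for iteration in range(1, max_iter + 1):
        raw = krogh_radial_po2(r, p_cap, m, geometry, consumption.k_diff, clamp=False)
        po2 = np.maximum(raw, 0.0)
        mean = _radial_mean(po2, r)
        if prev_mean is not None:
            residual = abs(mean - prev_mean)
            if residual < tol:
                clamped = float(np.trapezoid((raw < 0).astype(float) * r, r) / weights_total)
                return SliceSolution(r_grid=r, po2=po2, m_eff=m, mean_po2=mean,
                                     iterations=iteration, clamped_fraction=clamped)
            damp = residual > prev_residual  # oscillation/divergence guard
            prev_residual = residual
        else:
            damp = False
        prev_mean = mean
        m_new = michaelis_menten_rate(mean, consumption.m0, consumption.p_crit)
        m = 0.5 * (m + m_new) if damp else m_new

    raise TissueSolverError(
        f"consumption fixed point did not converge in {max_iter} iterations "
        f"(last residual {prev_residual:g} mmHg, p_cap={p_cap:g})"
    )


@dataclass(frozen=True)
class TissueOxygenField:
    """PO2 over the tissue annulus (axial position x radius) with summaries."""

    r_grid: np.ndarray  # m, R_c..R_t
    z_grid: np.ndarray  # m, 0..L
    po2: np.ndarray  # shape (n_z, n_r), mmHg, clamped at 0
    mean_po2: float  # volume-weighted mean over the annulus
    min_po2: float
    clamped_fraction: float
    m_eff_of_z: np.ndarray
    max_iterations: int

    def to_frame(self, state: str = "") -> pd.DataFrame:
        rr, zz = np.meshgrid(self.r_grid, self.z_grid)
        return pd.DataFrame({
            "r_m": rr.ravel(),
            "z_m": zz.ravel(),
            "po2_mmHg": self.po2.ravel(),
            "state": state,
        })


def tissue_field(
    profile: CapillaryProfile,
    consumption: ConsumptionModel,
    geometry: KroghGeometry,
    n_r: int = 101,
) -> TissueOxygenField:
    """Solve every axial slice against its local capillary tension.

    The capillary tension profile provides the inner boundary condition
    PO2(R_c, z) = P_cap(z); the volume-weighted mean uses cylindrical weights
    r*dr*dz.
    """
    n_z = profile.z.size
    p_cap = np.asarray(profile.po2_of_z, dtype=float)
    if np.any(p_cap < 0):
        raise ValueError("capillary tensions must be non-negative")
    r = np.linspace(geometry.r_c, geometry.r_t, n_r)
    # vectorized per-slice fixed point (same scheme as solve_tissue_slice)
    quad = (r**2 - geometry.r_c**2) / (4.0 * consumption.k_diff)
    logt = geometry.r_t**2 * np.log(r / geometry.r_c) / (2.0 * consumption.k_diff)
    # radial volume weights: trapezoid rule on integrand po2*r over [r_c, r_t]
    w = np.empty(n_r)
    dr = r[1] - r[0]
    w[:] = r * dr
    w[0] *= 0.5
    w[-1] *= 0.5
    w /= w.sum()

    m = np.full(n_z, consumption.m0)
    prev_mean = None
    prev_res = np.full(n_z, np.inf)
    tol, max_iter = 1e-6, 100
    for iters in range(1, max_iter + 1):
        raw = p_cap[:, None] + m[:, None] * (quad[None, :] - logt[None, :])
        po2 = np.maximum(raw, 0.0)
        mean = po2 @ w
        if prev_mean is not None:
            res = np.abs(mean - prev_mean)
            if np.all(res < tol):
                break
            damp = res > prev_res
            prev_res = res
        else:
            damp = np.zeros(n_z, dtype=bool)
        prev_mean = mean
        m_new = michaelis_menten_rate(mean, consumption.m0, consumption.p_crit)
        m_new = np.atleast_1d(np.asarray(m_new, dtype=float))
        m = np.where(damp, 0.5 * (m + m_new), m_new)
    else:
        raise TissueSolverError(
            f"consumption fixed point did not converge in {max_iter} iterations "
            f"(worst slice residual {prev_res.max():g} mmHg)")
    m_eff = m
    slice_means = mean
    clamped = (raw < 0).astype(float) @ w
    mean = float(np.trapezoid(slice_means, profile.z) / (profile.z[-1] - profile.z[0]))
    clamped_total = float(np.trapezoid(clamped, profile.z) / (profile.z[-1] - profile.z[0]))
    return TissueOxygenField(
        r_grid=r, z_grid=profile.z.copy(), po2=po2, mean_po2=mean,
        min_po2=float(po2.min()), clamped_fraction=clamped_total,
        m_eff_of_z=m_eff, max_iterations=iters,
    )


@dataclass(frozen=True)
class TissueDelta:
    """Mean and pointwise tissue PO2 change between two gas states."""

    mean: float  # mmHg
    pointwise: np.ndarray  # shape (n_z, n_r)

    def __float__(self) -> float:
        return self.mean


def delta_tissue_po2(field_air: TissueOxygenField, field_ox: TissueOxygenField) -> TissueDelta:
    """Mean tissue PO2 change (oxygen minus air) plus the pointwise field."""
    if (field_air.po2.shape != field_ox.po2.shape
            or not np.array_equal(field_air.r_grid, field_ox.r_grid)
            or not np.array_equal(field_air.z_grid, field_ox.z_grid)):
        raise ValueError("tissue fields must share identical (r, z) grids")
    return TissueDelta(mean=field_ox.mean_po2 - field_air.mean_po2,
                       pointwise=field_ox.po2 - field_air.po2)
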