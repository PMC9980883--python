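"""Analytic volume-conductor forward model for concentric spherical shells.

A point current source on the scalp surface of a multishell sphere admits a
Legendre-series solution of the quasi-static equation ``-div(sigma grad V) = 0``.
In each shell the degree-``l`` harmonic of the potential is
``A_l r^l + B_l r^-(l+1)``; the coefficients follow from continuity of the
potential and of the radial current density at every interface, plus the
injected surface current density at the scalp.  The degree-0 (monopole) term
of a lone source does not conserve current and is dropped; it cancels exactly
in the source/reference pair the lead field is built from.

Conventions: shell radii in mm ordered outermost (scalp) first, conductivities
in S/m, currents in mA, fields in V/m.  Internally SI units are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereModel",
    "SeriesTruncationWarning",
    "homogeneous_surface_source_potential",
    "homogeneous_surface_source_radial_field",
]

#: Tissue conductivities in S/m: scalp, skull, CSF, gray matter (white matter
#: 0.126 S/m available as an optional fifth shell).
DEFAULT_CONDUCTIVITIES = (0.465, 0.010, 1.654, 0.276)
DEFAULT_RADII_MM = (92.0, 86.0, 80.0, 78.0)
WHITE_MATTER_CONDUCTIVITY = 0.126


class SeriesTruncationWarning(UserWarning):
    """Raised when the Legendre series has not converged at the cut-off order.

    Carries the estimated relative magnitude of the truncated tail.
    """


@dataclass(frozen=True)
class SphereModel:
    """Concentric-shell head model.

    Parameters
    ----------
    shell_radii:
        Outer radius of each shell in mm, strictly decreasing; the first entry
        is the scalp surface where electrodes sit.
    shell_conductivities:
        Conductivity of each shell in S/m, same length and order as the radii.
    series_order:
        Truncation degree L of the Legendre expansion.
    """

    shell_radii: tuple[float, ...] = DEFAULT_RADII_MM
    shell_conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES
    series_order: int = 120

    def __post_init__(self):
        radii = tuple(float(r) for r in self.shell_radii)
        conds = tuple(float(s) for s in self.shell_conductivities)
        if len(radii) != len(conds):
            raise ValueError("shell_radii and shell_conductivities must have "
                             "equal length")
        if len(radii) < 1:
            raise ValueError("at least one shell is required")
        if any(b >= a for a, b in zip(radii, radii[1:])):
            raise ValueError("shell radii must be strictly decreasing inward")
        if any(s <= 0 for s in conds):
            raise ValueError("conductivities must be positive")
        if self.series_order < 1:
            raise ValueError("series_order must be >= 1")
        object.__setattr__(self, "shell_radii", radii)
        object.__setattr__(self, "shell_conductivities", conds)

    @property
    def scalp_radius(self) -> float:
        return self.shell_radii[0]

    def inner_coefficients(self) -> np.ndarray:
        """Series coefficients ``a_l`` of the innermost shell (volts).

        The inner-ball potential of a +1 mA point source on the scalp surface
        is ``V = sum_l a_l (r/R)^l P_l(cos gamma)`` with ``R`` the scalp
        radius; the scaled powers stay O(1) at any series order.  Index 0
        holds degree l=1.
        """
        return _inner_coefficients(
            np.asarray(self.shell_radii, dtype=float) * 1e-3,
            np.asarray(self.shell_conductivities, dtype=float),
            self.series_order,
        )


def _inner_coefficients(radii_m: np.ndarray, sigmas: np.ndarray,
                        order: int) -> np.ndarray:
    """Solve the per-degree interface systems for a unit (1 mA) surface source.

    Shells are indexed outermost-first; shell k occupies
    ``radii_m[k+1] < r < radii_m[k]`` and the last shell is the inner ball.
    Unknowns per degree: (A_k, B_k) for every shell, with B dropped for the
    inner ball (regularity at the origin).
    """
    K = len(radii_m)
    R = radii_m[0]
    current_A = 1e-3  # 1 mA
    n_unk = 2 * K - 1
    out = np.zeros(order)
    # scale radii to the scalp radius to keep powers O(1)
    rho = radii_m / R
    for l in range(1, order + 1):
        M = np.zeros((n_unk, n_unk))
        rhs = np.zeros(n_unk)

        def col_A(k):
            return 2 * k

        def col_B(k):
            return 2 * k + 1  # undefined for k == K-1

        # outer boundary: sigma_0 dV/dr at r = R equals the source density
        # harmonic g_l = (2l+1) I / (4 pi R^2)
        row = 0
        M[row, col_A(0)] = sigmas[0] * l  # d/dr (r^l) = l r^(l-1); rho=1
        if K > 1:
            M[row, col_B(0)] = -sigmas[0] * (l + 1)
        elif K == 1:
            pass
        rhs[row] = (2 * l + 1) * current_A / (4.0 * np.pi * R ** 2) * R
        # (multiplied by R so entries use rho-powers; see scaling note below)
        row += 1
        # interface conditions at r = radii_m[k+1], between shell k and k+1
        for k in range(K - 1):
            r = rho[k + 1]
            inner_ball = (k + 1 == K - 1)
            # potential continuity
            M[row, col_A(k)] += r ** l
            M[row, col_B(k)] += r ** -(l + 1)
            M[row, col_A(k + 1)] -= r ** l
            if not inner_ball:
                M[row, col_B(k + 1)] -= r ** -(l + 1)
            row += 1
            # radial current density continuity
            M[row, col_A(k)] += sigmas[k] * l * r ** (l - 1)
            M[row, col_B(k)] += -sigmas[k] * (l + 1) * r ** -(l + 2)
            M[row, col_A(k + 1)] -= sigmas[k + 1] * l * r ** (l - 1)
            if not inner_ball:
                M[row, col_B(k + 1)] -= -sigmas[k + 1] * (l + 1) * r ** -(l + 2)
            row += 1
        sol = np.linalg.solve(M, rhs)
        out[l - 1] = sol[col_A(K - 1)]
    return out


def radial_field_matrix(model: SphereModel, node_coords_mm: np.ndarray,
                        electrode_units: np.ndarray,
                        tail_tol: float = 1e-6) -> np.ndarray:
    """Radial field (V/m per mA) at each node for a lone unit surface source.

    Returns an (N, M) matrix whose column ``m`` is the degree>=1 part of the
    radial field for a +1 mA source at ``electrode_units[m]``.  Lead-field
    columns are differences of these columns (source minus reference), which
    restores current conservation.
    """
    node_coords_mm = np.asarray(node_coords_mm, dtype=float)
    r_mm = np.linalg.norm(node_coords_mm, axis=1)
    if np.any(r_mm > model.scalp_radius + 1e-9):
        raise ValueError("cortex node lies outside the scalp radius")
    A = model.inner_coefficients()
    L = model.series_order
    rho = r_mm / model.scalp_radius
    R_m = model.scalp_radius * 1e-3
    with np.errstate(invalid="ignore", divide="ignore"):
        node_units = node_coords_mm / r_mm[:, None]
    node_units = np.where(np.isfinite(node_units), node_units, 0.0)
    cosg = np.clip(node_units @ np.asarray(electrode_units, float).T, -1.0, 1.0)

    # Legendre recurrence accumulated on the fly; E_r = -dV/dr.
    P_prev = np.ones_like(cosg)          # P_0
    P_curr = cosg.copy()                 # P_1
    E = np.zeros_like(cosg)
    last_term = np.zeros_like(cosg)
    for l in range(1, L + 1):
        coef = -A[l - 1] * l * rho ** (l - 1) / R_m   # per node
        last_term = coef[:, None] * P_curr
        E += last_term
        P_next = ((2 * l + 1) * cosg * P_curr - l * P_prev) / (l + 1)
        P_prev, P_curr = P_curr, P_next
    scale = np.max(np.abs(E))
    tail = np.max(np.abs(last_term)) / scale if scale > 0 else 0.0
    if tail > tail_tol:
        warnings.warn(
            f"Legendre series truncated at L={L} with estimated relative "
            f"tail magnitude {tail:.2e} (> {tail_tol:.0e}); increase "
            "series_order or move nodes away from the shell boundary",
            SeriesTruncationWarning,
        )
    return E


# ---------------------------------------------------------------------------
# Closed-form homogeneous-sphere solution (independent oracle)
# ---------------------------------------------------------------------------

def homogeneous_surface_source_potential(r_mm, cos_gamma, radius_mm,
                                         sigma, current_mA=1.0):
    """Potential (degree>=1 part) inside a homogeneous sphere, closed form.

    For a point source of ``current_mA`` on the surface of a homogeneous
    sphere the Legendre series sums in closed form via
    ``sum x^l P_l = (1 - 2 x c + x^2)^{-1/2} - 1`` (l>=1) and
    ``sum x^l P_l / l = log(2 / (1 - x c + sqrt(1 - 2 x c + x^2)))``.
    """
    R = radius_mm * 1e-3
    I = current_mA * 1e-3
    x = np.asarray(r_mm, float) / radius_mm
    c = np.asarray(cos_gamma, float)
    s = np.sqrt(1.0 - 2.0 * x * c + x * x)
    series2 = 1.0 / s - 1.0
    series1 = np.log(2.0 / (1.0 - x * c + s))
    return I / (4.0 * np.pi * sigma * R) * (2.0 * series2 + series1)


def homogeneous_surface_source_radial_field(r_mm, cos_gamma, radius_mm,
                                            sigma, current_mA=1.0):
    """Radial field ``-dV/dr`` (V/m) of the closed-form potential above."""
    R = radius_mm * 1e-3
    I = current_mA * 1e-3
    x = np.asarray(r_mm, float) / radius_mm
    c = np.asarray(cos_gamma, float)
    s = np.sqrt(1.0 - 2.0 * x * c + x * x)
    d_series2 = (c - x) / s ** 3
    u = 1.0 - x * c + s
    du = -c + (x - c) / s
    d_series1 = -du / u
    dV_dx = I / (4.0 * np.pi * sigma * R) * (2.0 * d_series2 + d_series1)
    return -dV_dx / R
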