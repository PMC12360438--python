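"""Radial grid and spherically symmetric discrete operators.

All spatial fields live on a normalized radial coordinate x = r / R(t)
in [0, 1] (node 0 at the tumor center, node n-1 at the tumor-host
interface), so the grid never has to be rebuilt as the tumor grows.
Operators below are written in finite-volume form on spherical shells,
which makes diffusive transport exactly conservative under the shell
volume measure returned by :func:`RadialGrid.cell_volumes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["RadialGrid"]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node set on the normalized radius x = r/R in [0, 1]."""

    n: int = 40

    x: np.ndarray = field(init=False, repr=False)
    dx: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("radial grid needs at least 3 nodes")
        object.__setattr__(self, "x", np.linspace(0.0, 1.0, self.n))
        object.__setattr__(self, "dx", 1.0 / (self.n - 1))

    # -- measures -----------------------------------------------------

    def faces(self) -> np.ndarray:
        """Cell-face positions x_{i±1/2}, including the 0 and 1 ends."""
        xf = np.empty(self.n + 1)
        xf[0] = 0.0
        xf[-1] = 1.0
        xf[1:-1] = 0.5 * (self.x[:-1] + self.x[1:])
        return xf

    def cell_volumes(self) -> np.ndarray:
        """Normalized shell volumes (x_{i+1/2}^3 - x_{i-1/2}^3)/3.

        Multiply by 4*pi*R^3 for physical volumes; ratios and averages
        only need the normalized measure.
        """
        xf = self.faces()
        return np.diff(xf**3) / 3.0

    def volume_average(self, c: np.ndarray) -> float:
        """Volume-weighted average of a field over the sphere."""
        v = self.cell_volumes()
        return float(np.dot(v, c) / v.sum())

    # -- differential operators ---------------------------------------

    def laplacian(self, c: np.ndarray, diffusivity: float, radius: float,
                  *, dirichlet_outer: float | None = None) -> np.ndarray:
        """Spherical D*lap(c) with zero flux at x=0 (symmetry).

        Outer boundary: zero diffusive flux by default, or a Dirichlet
        value held at the interface node when ``dirichlet_outer`` is
        given (in which case the returned derivative at the last node
        is 0 so the node stays pinned).
        """
        xf = self.faces()
        dr = self.dx * radius
        flux = np.zeros(self.n + 1)  # D * dc/dr at faces, times x_face^2
        grad = np.diff(c) / dr
        flux[1:-1] = diffusivity * grad * xf[1:-1] ** 2
        out = np.diff(flux) / (self.cell_volumes() * radius)
        if dirichlet_outer is not None:
            out[-1] = 0.0
        return out

    def advect_upwind(self, c: np.ndarray, u: np.ndarray,
                      radius: float) -> np.ndarray:
        """-u * dc/dr with first-order upwinding.

        ``u`` is the radial velocity of the carrier *relative to the
        grid* (same length as ``c``, units of length/time); a
        zero-gradient ghost value is used at the outer face for inflow.
        """
        dr = self.dx * radius
        dcdr_m = np.zeros_like(c)  # backward difference
        dcdr_p = np.zeros_like(c)  # forward difference
        dcdr_m[1:] = (c[1:] - c[:-1]) / dr
        dcdr_p[:-1] = (c[1:] - c[:-1]) / dr
        # ghost values: symmetry at the center, zero gradient outside
        return -(np.where(u > 0.0, u * dcdr_m, u * dcdr_p))

    def divergence(self, v: np.ndarray, radius: float) -> np.ndarray:
        """(1/r^2) d(r^2 v)/dr for a node-centred velocity field."""
        x = self.x
        dr = self.dx * radius
        r2v = x**2 * v
        div = np.empty_like(v)
        div[1:-1] = (r2v[2:] - r2v[:-2]) / (2.0 * dr * x[1:-1] ** 2)
        # r -> 0: div v -> 3 v'(0); v(0)=0 by symmetry
        div[0] = 3.0 * v[1] / (self.x[1] * radius)
        div[-1] = (3.0 * r2v[-1] - 4.0 * r2v[-2] + r2v[-3]) / (2.0 * dr)
        return div

    def cumulative_shell_integral(self, g: np.ndarray,
                                  radius: float) -> np.ndarray:
        """v(r) = (1/r^2) * integral_0^r g(r') r'^2 dr'.

        Used for the solid-phase velocity driven by a volumetric source
        g; returns 0 at the center by symmetry.
        """
        x = self.x
        integrand = g * x**2
        acc = np.concatenate(
            ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * self.dx))
        )
        v = np.zeros_like(g)
        v[1:] = radius * acc[1:] / x[1:] ** 2
        return v

    # -- quasi-static linear solves ------------------------------------

    def solve_reaction_diffusion(self, diffusivity: float, radius: float,
                                 uptake: np.ndarray, source: np.ndarray,
                                 outer_value: float,
                                 outer_conductance: float | None = None) -> np.ndarray:
        """Solve  D lap(c) - uptake*c + source = 0  on the sphere.

        Symmetry at x=0; at x=1 either a Dirichlet ``outer_value``
        (default) or, when ``outer_conductance`` g is given, the Robin
        exchange condition -D dc/dr = g (c - outer_value) describing a
        resistive exterior medium. ``uptake`` and ``source`` are
        per-node arrays (uptake must be >= 0). Assembled in
        finite-volume form and solved as a banded system.
        """
        n = self.n
        xf = self.faces()
        vol = self.cell_volumes()
        dr = self.dx * radius
        w = diffusivity * xf[1:-1] ** 2 / dr  # face conductances

        ab = np.zeros((3, n))
        rhs = -source * vol * radius
        diag = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        diag[0] = -w[0] - uptake[0] * vol[0] * radius
        upper[0] = w[0]
        for i in range(1, n - 1):
            diag[i] = -(w[i - 1] + w[i]) - uptake[i] * vol[i] * radius
            lower[i - 1] = w[i - 1]
            upper[i] = w[i]
        if outer_conductance is None:
            # Dirichlet row
            diag[-1] = 1.0
            lower[-1] = 0.0
            rhs[-1] = outer_value
        else:
            g = outer_conductance
            diag[-1] = -w[-1] - g - uptake[-1] * vol[-1] * radius
            lower[-1] = w[-1]
            rhs[-1] -= g * outer_value

        ab[0, 1:] = upper
        ab[1, :] = diag
        ab[2, :-1] = lower
        return solve_banded((1, 1), ab, rhs)
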