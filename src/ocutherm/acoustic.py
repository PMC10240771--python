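"""Pressure fields of planar-piston and spherically focused circular sources.

On-axis fields follow the classical Rayleigh–Sommerfeld reductions for a
uniformly vibrating circular aperture.  For a flat piston of radius ``a``,

    p(z) = rho c v0 (e^{ikz} - e^{ik sqrt(z^2 + a^2)}),

a superposition of a direct plane-wave phasor and an edge wave radiated from
the rim.  For a concave spherical cap of curvature radius ``R0`` (cap depth
``h = R0 - sqrt(R0^2 - a^2)``, geometric focus at z = R0),

    p(z) = rho c v0 / q0 * (e^{ikz} - e^{ik r_e}),
    q0 = 1 - z/R0,   r_e = sqrt((z - h)^2 + a^2),

with the removable singularity at the focus evaluated by its analytic limit
p(R0) = -i k h rho c v0 e^{ikR0} (so the focal gain is k*h).  Off-axis, the
field is obtained by direct numerical quadrature of the Rayleigh integral
over the spherical cap,

    p(r, z) = (i rho c k v0 / 2 pi) int_S e^{ikd}/d dS.

Sign convention under the edge-wave roots: the physically meaningful form
uses ``+ a^2`` (real for all z > 0) and is the default; ``as_printed=True``
evaluates the ``- a^2`` variant, defined only where the root is real, for
auditability against sources that print it that way.

Coordinates: z runs from the transducer face along the beam axis; in the
ocular setup the corneal anterior surface sits at z = standoff (28 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MediumAcoustic",
    "TransducerSpec",
    "AxialField",
    "Field2D",
    "onaxis_piston_pressure",
    "onaxis_focused_pressure",
    "field2d",
    "lateral_average",
]


@dataclass(frozen=True)
class MediumAcoustic:
    """Acoustic propagation medium: density rho (kg/m^3), sound speed c (m/s)."""

    rho: float = 1000.0
    c: float = 1500.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.c <= 0:
            raise ValueError("density and sound speed must be positive")


@dataclass(frozen=True)
class TransducerSpec:
    """Circular-aperture source geometry and drive.

    Parameters
    ----------
    a
        Aperture radius, m.
    f
        Drive frequency, Hz (single-frequency continuous wave).
    v0
        Uniform normal surface velocity amplitude, m/s.
    R0
        Spherical curvature radius, m; ``None`` means a flat piston.
    standoff
        Distance from the transducer face to the corneal surface, m.
    """

    a: float = 9.5e-3
    f: float = 4e6
    v0: float = 0.01
    R0: float | None = 38e-3
    standoff: float = 28e-3

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("aperture radius must be positive")
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        if self.R0 is not None and self.R0 <= self.a:
            raise ValueError("focused source requires R0 > a")

    @property
    def focused(self) -> bool:
        return self.R0 is not None

    @property
    def h(self) -> float:
        """Spherical-cap depth R0 - sqrt(R0^2 - a^2), m (focused only)."""
        if not self.focused:
            raise ValueError("cap depth undefined for a flat piston")
        return self.R0 - np.sqrt(self.R0**2 - self.a**2)

    def k_wave(self, medium: MediumAcoustic) -> float:
        """Wavenumber 2*pi*f/c in the given medium, rad/m."""
        return 2.0 * np.pi * self.f / medium.c

    def replace(self, **kw) -> "TransducerSpec":
        d = {
            "a": self.a,
            "f": self.f,
            "v0": self.v0,
            "R0": self.R0,
            "standoff": self.standoff,
        }
        d.update(kw)
        return TransducerSpec(**d)


@dataclass
class AxialField:
    """Complex pressure along the beam axis.

    ``z`` is measured from the transducer face and must be strictly
    increasing; ``p`` is the complex pressure phasor at each position.
    """

    z: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=complex)
        if self.z.shape != self.p.shape:
            raise ValueError("z and p must have the same length")
        if self.z.size and np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("pressure field contains non-finite values")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.p)


@dataclass
class Field2D:
    """Complex pressure on an axisymmetric (r, z) grid.

    The field depends on |r| only; ``p`` has shape ``(len(r), len(z))``.
    """

    r: np.ndarray
    z: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=complex)
        if self.p.shape != (self.r.size, self.z.size):
            raise ValueError("p must have shape (len(r), len(z))")

    def onaxis(self) -> AxialField:
        """The r = 0 column (nearest-to-axis row if 0 is absent)."""
        i = int(np.argmin(np.abs(self.r)))
        return AxialField(z=self.z, p=self.p[i])


# ---------------------------------------------------------------------------
# on-axis closed forms


def _check_z(z):
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("axial positions must be positive (field in front of the source)")
    return z


def onaxis_piston_pressure(
    z, spec: TransducerSpec, medium: MediumAcoustic, as_printed: bool = False
):
    """On-axis complex pressure of a flat circular piston, Pa.

    With ``as_printed=True`` the edge-wave path is taken as sqrt(z^2 - a^2),
    which is only defined for z >= a; the default sqrt(z^2 + a^2) is the
    standard (finite-everywhere) form.
    """
    z = _check_z(z)
    k = spec.k_wave(medium)
    if as_printed:
        if np.any(z < spec.a):
            raise ValueError(
                "as_printed edge-wave root sqrt(z^2 - a^2) is complex for z < a"
            )
        edge = np.sqrt(z**2 - spec.a**2)
    else:
        edge = np.sqrt(z**2 + spec.a**2)
    return medium.rho * medium.c * spec.v0 * (np.exp(1j * k * z) - np.exp(1j * k * edge))


def onaxis_focused_pressure(
    z, spec: TransducerSpec, medium: MediumAcoustic, as_printed: bool = False
):
    """On-axis complex pressure of a spherically focused source, Pa.

    The 1/q0 prefactor diverges at the geometric focus z = R0 while the
    phasor difference vanishes there (r_e(R0) = R0); the removable
    singularity is replaced by its analytic limit -i k h rho c v0 e^{ikR0}.
    """
    if not spec.focused:
        raise ValueError("spec has no curvature radius; use onaxis_piston_pressure")
    scalar = np.isscalar(z)
    z = np.atleast_1d(_check_z(z))
    k = spec.k_wave(medium)
    h = spec.h
    if as_printed:
        if np.any(np.abs(z - h) < spec.a):
            raise ValueError(
                "as_printed edge root sqrt((z-h)^2 - a^2) is complex for |z-h| < a"
            )
        r_e = np.sqrt((z - h) ** 2 - spec.a**2)
    else:
        r_e = np.sqrt((z - h) ** 2 + spec.a**2)
    q0 = 1.0 - z / spec.R0
    amp = medium.rho * medium.c * spec.v0
    p = np.empty(z.shape, dtype=complex)
    at_focus = np.abs(q0) < 1e-9
    safe = ~at_focus
    p[safe] = amp / q0[safe] * (np.exp(1j * k * z[safe]) - np.exp(1j * k * r_e[safe]))
    if np.any(at_focus):
        p[at_focus] = -1j * k * h * amp * np.exp(1j * k * z[at_focus])
    return p[0] if scalar else p


def edge_distance(z, spec: TransducerSpec):
    """Distance from the aperture rim to the on-axis point z, m."""
    z = np.asarray(z, dtype=float)
    return np.sqrt((z - spec.h) ** 2 + spec.a**2)


def focusing_factor(z, spec: TransducerSpec):
    """The q0 = 1 - z/R0 focusing denominator."""
    return 1.0 - np.asarray(z, dtype=float) / spec.R0


# ---------------------------------------------------------------------------
# off-axis quadrature


def _cap_quadrature(spec: TransducerSpec, n_quad: int):
    """Gauss–Legendre nodes/weights over the spherical cap surface.

    The cap is parametrised by the polar angle theta from the beam axis about
    the curvature centre (0, 0, R0): source points
    (rho_s, z_s) = (R0 sin t, R0 (1 - cos t)), t in [0, theta_max],
    dS = R0^2 sin t dt dphi.  Azimuth is handled separately (uniform grid,
    spectrally accurate for the periodic integrand).
    """
    theta_max = np.arcsin(spec.a / spec.R0)
    x, w = np.polynomial.legendre.leggauss(n_quad)
    t = 0.5 * theta_max * (x + 1.0)
    wt = 0.5 * theta_max * w * spec.R0**2 * np.sin(t)
    rho_s = spec.R0 * np.sin(t)
    z_s = spec.R0 * (1.0 - np.cos(t))
    return rho_s, z_s, wt


def field2d(
    r_grid,
    z_grid,
    spec: TransducerSpec,
    medium: MediumAcoustic,
    n_quad: int = 96,
    n_phi: int | None = None,
) -> Field2D:
    """Rayleigh-integral pressure field of a focused source on an (r, z) grid.

    The surface integral (i rho c k v0 / 2 pi) int_S e^{ikd}/d dS is
    evaluated with ``n_quad`` Gauss–Legendre nodes along the cap polar angle
    and ``n_phi`` (default ``4 * n_quad``) uniform azimuthal nodes.  Negative
    r values are filled by mirror symmetry.  Field points on or behind the
    source surface are rejected.
    """
    if not spec.focused:
        raise ValueError("field2d implements the spherical-cap source")
    r_grid = np.asarray(r_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if np.any(z_grid <= 0):
        raise ValueError("z grid must be strictly in front of the transducer face")
    if n_phi is None:
        n_phi = 4 * n_quad
    rho_s, z_s, wt = _cap_quadrature(spec, n_quad)
    # reject field points on the cap surface itself
    cap_z_at = lambda rr: spec.R0 - np.sqrt(spec.R0**2 - np.minimum(rr, spec.a) ** 2)
    for rr in np.abs(r_grid):
        if rr <= spec.a and np.any(np.abs(z_grid - cap_z_at(rr)) < 1e-12):
            raise ValueError("field point lies on the source surface")

    k = spec.k_wave(medium)
    # e^{+ikz} phase convention: the Rayleigh prefactor is -i rho c k v0 / 2pi
    # (the +i variant belongs to the conjugate convention and flips the sign)
    pref = -1j * medium.rho * medium.c * k * spec.v0 / (2.0 * np.pi)
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    cosphi = np.cos(phi)  # (n_phi,)
    dphi = 2.0 * np.pi / n_phi

    r_abs = np.abs(r_grid)
    uniq, inverse = np.unique(r_abs, return_inverse=True)
    p_uniq = np.empty((uniq.size, z_grid.size), dtype=complex)
    for iu, rr in enumerate(uniq):
        # d^2 = (z - z_s)^2 + rho_s^2 + r^2 - 2 rho_s r cos(phi)
        base = rho_s[:, None] ** 2 + rr**2 - 2.0 * rho_s[:, None] * rr * cosphi  # (nq, nphi)
        for iz, zz in enumerate(z_grid):
            d = np.sqrt((zz - z_s[:, None]) ** 2 + base)
            integrand = np.exp(1j * k * d) / d
            p_uniq[iu, iz] = pref * dphi * np.sum(wt[:, None] * integrand)
    p = p_uniq[inverse]
    return Field2D(r=r_grid, z=z_grid, p=p)


def lateral_average(field: Field2D, r_max: float) -> AxialField:
    """Area-weighted mean pressure amplitude over r in [0, r_max] at each z.

    Computes 2 int_0^{r_max} |p| r dr / r_max^2 by trapezoid on the stored
    radial grid, returning a real-amplitude axial profile (stored in the
    complex ``p`` slot with zero phase).  As r_max -> 0 this recovers the
    on-axis profile.
    """
    r = field.r
    mask = r >= 0
    r_pos = r[mask]
    order = np.argsort(r_pos)
    r_pos = r_pos[order]
    amp = np.abs(field.p[mask][order])
    if r_max < 0 or r_max > r_pos[-1]:
        raise ValueError(f"r_max={r_max:g} outside the stored radial grid")
    if r_max == 0 or r_pos.size == 1:
        return field.onaxis()
    sel = r_pos <= r_max + 1e-15
    rs, amps = r_pos[sel], amp[sel]
    if rs[-1] < r_max:  # interpolate the exact edge
        edge = np.array([np.interp(r_max, r_pos, a_col) for a_col in amp.T])
        rs = np.append(rs, r_max)
        amps = np.vstack([amps, edge])
    mean = 2.0 * np.trapezoid(amps * rs[:, None], rs, axis=0) / r_max**2
    return AxialField(z=field.z, p=mean.astype(complex))
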