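"""Two-state fast-exchange effective diffusion and ribosome-site census.

A probe that exchanges rapidly (relative to the measurement time) between a
free state with diffusion coefficient ``D_free`` and a bound state with
``D_bound`` shows a single apparent coefficient

    D_eff = f_free * D_free + (1 - f_free) * D_bound,

where ``f_free`` is the fraction of time spent free.  With binding sites in
large excess over the probe, the bound fraction follows a simple saturation
law, ``f_bound = [site] / (Kd + [site])``, which lets a dissociation
constant be read off a measured ``D_eff``.

The number of nonspecific sites per ribosome is estimated geometrically:
the RNA-covered fraction of a spherical ribosome surface divided by the
cross-sectional footprint of the probe.  Intermediate areas are rounded to
the precision conventionally reported (three significant figures for the
areas, two for the probe cross-section) so that the printed census is
reproduced exactly; full-precision inputs are retained on the result.

Concentrations in this module are in uM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TwoStateDiffusion",
    "BindingEquilibrium",
    "SiteGeometry",
    "effective_diffusion",
    "free_fraction",
    "bound_fraction",
    "kd_from_bound_fraction",
    "estimate_sites",
    "round_sig",
]


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def effective_diffusion(f_free: float, d_free: float, d_bound: float) -> float:
    """Population-weighted diffusion coefficient at fast exchange, um^2/s."""
    if not 0.0 <= f_free <= 1.0:
        raise ValueError("f_free must lie in [0, 1]")
    if d_bound < 0 or d_free < d_bound:
        raise ValueError("require d_free >= d_bound >= 0")
    return f_free * d_free + (1.0 - f_free) * d_bound


def free_fraction(
    d_eff: float,
    d_free: float,
    d_bound: float,
    return_clamped: bool = False,
):
    """Invert the two-state relation for the free fraction.

    Measurement noise can push ``d_eff`` slightly outside
    ``[d_bound, d_free]``; the result is then clamped to [0, 1] so that
    population histograms remain processable.  With ``return_clamped=True``
    a ``(f_free, clamped)`` pair is returned.
    """
    if d_free <= d_bound:
        raise ValueError("free_fraction undefined unless d_free > d_bound")
    raw = (d_eff - d_bound) / (d_free - d_bound)
    clamped = not 0.0 <= raw <= 1.0
    f = min(1.0, max(0.0, raw))
    if return_clamped:
        return f, clamped
    return f


def bound_fraction(kd: float, site_conc: float) -> float:
    """Saturation of the probe by excess binding sites (both in uM)."""
    if kd < 0 or site_conc < 0:
        raise ValueError("kd and site_conc must be non-negative")
    if kd == 0 and site_conc == 0:
        raise ValueError("kd and site_conc cannot both be zero")
    return site_conc / (kd + site_conc)


def kd_from_bound_fraction(f_bound: float, site_conc: float) -> float:
    """Dissociation constant (uM) from a bound fraction and site pool."""
    if not 0.0 < f_bound < 1.0:
        raise ValueError(
            "f_bound must lie strictly in (0, 1): a fully free or fully "
            "bound probe gives an infinite or zero Kd"
        )
    if site_conc <= 0:
        raise ValueError("site_conc must be positive")
    return site_conc * (1.0 - f_bound) / f_bound


@dataclass(frozen=True)
class TwoStateDiffusion:
    """(D_free, D_bound, f_free, D_eff) quartet of the two-state model."""

    d_free: float
    d_bound: float
    f_free: float
    d_eff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_free <= 1.0:
            raise ValueError("f_free must lie in [0, 1]")
        expected = effective_diffusion(self.f_free, self.d_free, self.d_bound)
        if not math.isclose(self.d_eff, expected, rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError("d_eff inconsistent with (f_free, d_free, d_bound)")

    @classmethod
    def from_free_fraction(
        cls, f_free: float, d_free: float, d_bound: float
    ) -> "TwoStateDiffusion":
        return cls(d_free, d_bound, f_free,
                   effective_diffusion(f_free, d_free, d_bound))

    @classmethod
    def from_effective(
        cls, d_eff: float, d_free: float, d_bound: float
    ) -> "TwoStateDiffusion":
        f = free_fraction(d_eff, d_free, d_bound)
        return cls(d_free, d_bound, f,
                   effective_diffusion(f, d_free, d_bound))

    @property
    def f_bound(self) -> float:
        return 1.0 - self.f_free

    def sigma_pair_squared(self, dt: float) -> tuple[float, float]:
        """Variances of the free- and bound-state Gaussian displacement
        kernels accumulated over a time window ``dt``: the convolution of
        the two kernels has total variance ``2 * d_eff * dt`` exactly."""
        return (2.0 * self.d_free * self.f_free * dt,
                2.0 * self.d_bound * (1.0 - self.f_free) * dt)


@dataclass(frozen=True)
class BindingEquilibrium:
    """Dissociation constant, site pool and resulting bound fraction (uM)."""

    kd: float
    site_conc: float
    f_bound: float

    def __post_init__(self) -> None:
        if self.kd < 0 or self.site_conc < 0:
            raise ValueError("kd and site_conc must be non-negative")
        expected = bound_fraction(self.kd, self.site_conc)
        if not math.isclose(self.f_bound, expected, rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError("f_bound inconsistent with kd and site_conc")

    @classmethod
    def from_kd(cls, kd: float, site_conc: float) -> "BindingEquilibrium":
        return cls(kd, site_conc, bound_fraction(kd, site_conc))


@dataclass(frozen=True)
class SiteGeometry:
    """Geometric census of nonspecific probe sites on the ribosome surface."""

    ribosome_diameter: float      # nm
    rna_surface_fraction: float
    probe_diameter: float         # nm
    ribosome_conc: float          # uM
    sphere_area: float            # nm^2, 3 s.f.
    rna_area: float               # nm^2, 3 s.f.
    probe_cross_section: float    # nm^2, 2 s.f.
    n_sites: int
    site_conc: float              # uM


def estimate_sites(
    ribosome_diameter: float = 20.0,
    rna_surface_fraction: float = 0.5,
    probe_diameter: float = 3.5,
    ribosome_conc: float = 10.0,
) -> SiteGeometry:
    """Count probe-sized patches on the RNA-covered ribosome surface.

    The ribosome is treated as a sphere; the RNA fraction of its surface is
    divided by the probe's circular cross-section and rounded to the
    nearest integer.  Multiplying by the cytoplasmic ribosome concentration
    gives the total site concentration (uM).
    """
    if ribosome_diameter <= 0 or probe_diameter <= 0:
        raise ValueError("diameters must be positive")
    if not 0.0 <= rna_surface_fraction <= 1.0:
        raise ValueError("rna_surface_fraction must lie in [0, 1]")
    if ribosome_conc < 0:
        raise ValueError("ribosome_conc must be non-negative")

    area = round_sig(math.pi * ribosome_diameter**2, 3)
    rna_area = round_sig(rna_surface_fraction * area, 3)
    cross = round_sig(math.pi * (probe_diameter / 2.0) ** 2, 2)
    n_sites = int(round(rna_area / cross)) if rna_area > 0 else 0
    return SiteGeometry(
        ribosome_diameter=ribosome_diameter,
        rna_surface_fraction=rna_surface_fraction,
        probe_diameter=probe_diameter,
        ribosome_conc=ribosome_conc,
        sphere_area=area,
        rna_area=rna_area,
        probe_cross_section=cross,
        n_sites=n_sites,
        site_conc=n_sites * ribosome_conc,
    )
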