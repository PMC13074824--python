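"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: the closed-form
focused-bowl axial solution, a breadth-first flood fill for connected
components, and Monte-Carlo uncertainty propagation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def oneil_on_axis(geom, z: float) -> float:
    """Closed-form on-axis pressure magnitude of a focused bowl radiator.

    For a concave spherical cap of radius of curvature F and half-angle
    theta_max vibrating with unit normal velocity, the Rayleigh integral
    evaluates in closed form on the axis:

        |p(z)| = rho*c * (F/|z|) * |exp(ikR_apex) - exp(ikR_edge)|,

    with R_apex = F + z and R_edge = sqrt(F^2 + z^2 + 2 F z cos(theta_max)),
    z measured from the focus toward the far field; the z -> 0 limit is
    rho*c*k*F*(1 - cos(theta_max)).
    """
    rho = 1000.0
    c = geom.medium_sound_speed
    k = 2 * math.pi * geom.frequency / c
    F = geom.focal_length
    theta = math.asin(geom.aperture_diameter / 2 / F)
    if z == 0:
        return rho * c * k * F * (1 - math.cos(theta))
    r_apex = F + z
    r_edge = math.sqrt(F**2 + z**2 + 2 * F * z * math.cos(theta))
    return (
        rho
        * c
        * (F / abs(z))
        * abs(np.exp(1j * k * r_apex) - np.exp(1j * k * r_edge))
    )


def flood_fill_largest(
    field: np.ndarray, threshold: float, strict: bool = True
) -> tuple[np.ndarray, int]:
    """Largest 6-connected supra-threshold component by explicit BFS."""
    above = field > threshold if strict else field >= threshold
    visited = np.zeros(field.shape, dtype=bool)
    best_mask = np.zeros(field.shape, dtype=bool)
    best_count = 0
    shape = field.shape
    for start in zip(*np.nonzero(above)):
        if visited[start]:
            continue
        queue = deque([start])
        visited[start] = True
        component = [start]
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in (
                (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
            ):
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and above[nz, ny, nx]
                    and not visited[nz, ny, nx]
                ):
                    visited[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
                    component.append((nz, ny, nx))
        if len(component) > best_count:
            best_count = len(component)
            best_mask = np.zeros(field.shape, dtype=bool)
            for idx in component:
                best_mask[idx] = True
    return best_mask, best_count


def mc_volume_sd(
    areas: np.ndarray,
    u_areas: np.ndarray,
    thicknesses: np.ndarray,
    u_thicknesses: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo standard deviation of V = sum_i A_i * t_i."""
    A = areas[None, :] + u_areas[None, :] * rng.standard_normal((n_draws, areas.size))
    t = thicknesses[None, :] + u_thicknesses[None, :] * rng.standard_normal(
        (n_draws, thicknesses.size)
    )
    return float((A * t).sum(axis=1).std())
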