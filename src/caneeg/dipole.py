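"""Equivalent current dipole modelling on a three-shell spherical head.

The forward model is the analytic series solution for a current dipole
inside concentric conducting shells (brain, skull, scalp; conductivities
0.3, 0.006, 0.3 S/m by default): expanding the potential in Legendre terms,
each order ``n`` obeys a small radial boundary-value system whose outer-
surface factor is solved once per model, and the electrode potential is

    V(e) = 1/(4 pi sigma_1 R^2) * sum_n F_n (b/R)^(n-1)
           [ n (q.r0_hat) P_n(cos g) + (q.(e_hat - cos g r0_hat)) P_n'(cos g) ]

with ``b`` the dipole eccentricity, ``R`` the scalp radius and ``g`` the
angle between dipole and electrode. Potentials are returned average-
referenced (the recording's physical reference is a linear transform of
this). Fitting scans a regular volumetric source grid (2-mm spacing by
default), solves the dipole moment linearly at every candidate location,
and refines the best candidates with a derivative-free local search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .erp import EvokedResponse

_MM = 1e-3  # mm -> m
_NAM = 1e-9  # nAm -> Am
_UV = 1e6  # V -> uV


@dataclass(frozen=True)
class SphereHeadModel:
    """Concentric brain/skull/scalp spheres.

    Radii in mm (strictly increasing), conductivities in S/m. The defaults
    approximate a beagle-sized head with a thick extracranial layer.
    """

    center_mm: tuple = (0.0, 0.0, 0.0)
    radii_mm: tuple = (35.0, 39.0, 45.0)
    conductivities: tuple = (0.3, 0.006, 0.3)

    def __post_init__(self) -> None:
        r = self.radii_mm
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must satisfy 0 < brain < skull < scalp")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if len(r) != len(self.conductivities):
            raise ValueError("one conductivity per shell is required")

    @property
    def brain_radius_mm(self) -> float:
        return self.radii_mm[0]

    @property
    def scalp_radius_mm(self) -> float:
        return self.radii_mm[-1]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Named scalp electrode positions (mm), on the outer shell surface."""

    positions_mm: dict
    reference: str = "average"

    def validate_on(self, model: SphereHeadModel, tol_mm: float = 1.0) -> None:
        c = np.asarray(model.center_mm)
        for name, pos in self.positions_mm.items():
            r = np.linalg.norm(np.asarray(pos) - c)
            if abs(r - model.scalp_radius_mm) > tol_mm:
                raise ValueError(
                    f"electrode {name} at radius {r:.1f} mm is not on the "
                    f"scalp shell ({model.scalp_radius_mm} mm)"
                )

    def as_array(self, channels) -> np.ndarray:
        missing = [ch for ch in channels if ch not in self.positions_mm]
        if missing:
            raise ValueError(f"layout lacks positions for channels {missing}")
        return np.asarray([self.positions_mm[ch] for ch in channels], dtype=float)


def default_canine_layout(model: SphereHeadModel | None = None) -> ElectrodeLayout:
    """Idealized 7-electrode layout on the upper scalp shell.

    Electrode positions were not published for the recording setup being
    emulated; this layout places F3/F4 antero-laterally, T3/T4 over the
    temples, P3/P4 postero-laterally and Cz at the vertex, in a
    head-centered frame (x right, y anterior, z dorsal). User-replaceable.
    """
    model = model or SphereHeadModel()
    R = model.scalp_radius_mm
    c = np.asarray(model.center_mm)

    def pos(theta_deg, phi_deg):
        th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
        u = np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])
        return tuple(c + R * u)

    return ElectrodeLayout(
        positions_mm={
            "F3": pos(45, -30), "F4": pos(45, 30),
            "T3": pos(70, -90), "T4": pos(70, 90),
            "Cz": pos(0, 0),
            "P3": pos(45, -150), "P4": pos(45, 150),
        }
    )


@dataclass
class Dipole:
    """A point current source: location (mm) and moment vector (nAm)."""

    location_mm: np.ndarray
    moment_nAm: np.ndarray

    def __post_init__(self) -> None:
        self.location_mm = np.asarray(self.location_mm, dtype=float).reshape(3)
        self.moment_nAm = np.asarray(self.moment_nAm, dtype=float).reshape(3)


@dataclass
class DipoleFit:
    """Fitted equivalent current dipole at one time point."""

    time_ms: float
    location_mm: np.ndarray
    moment_nAm: np.ndarray
    gof_percent: float

    @property
    def moment_magnitude_nAm(self) -> float:
        return float(np.linalg.norm(self.moment_nAm))


# --------------------------------------------------------------------------
# Forward solution
# --------------------------------------------------------------------------

def _surface_factors(model: SphereHeadModel, n_terms: int) -> np.ndarray:
    """Per-order outer-surface radial factors F_n (dimensionless).

    For each Legendre order the shell system (continuity of potential and
    of radial current at the interfaces, zero current at the outer surface)
    is solved with a unit source coefficient; only the right-hand side of
    the system depends on dipole eccentricity, so F_n factorizes out and is
    computed once per model. Radii are normalized to the scalp radius.
    """
    sig = np.asarray(model.conductivities, dtype=float)
    r = np.asarray(model.radii_mm, dtype=float) / model.scalp_radius_mm
    L = len(sig)
    n_arr = np.arange(1, n_terms + 1, dtype=float)
    # unknowns: A_1, A_2, B_2, ..., A_L, B_L  -> 2L-1 per order
    m = 2 * L - 1
    M = np.zeros((n_terms, m, m))
    rhs = np.zeros((n_terms, m))

    def a_cols(j):  # column of A_j
        return 0 if j == 1 else 2 * j - 3

    def b_cols(j):  # column of B_j (j >= 2)
        return 2 * j - 2

    row = 0
    for j in range(1, L):  # interfaces j | j+1 at radius r[j-1]
        rj = r[j - 1]
        # potential continuity
        M[:, row, a_cols(j)] = rj**n_arr
        if j >= 2:
            M[:, row, b_cols(j)] = rj ** -(n_arr + 1)
        M[:, row, a_cols(j + 1)] = -(rj**n_arr)
        M[:, row, b_cols(j + 1)] = -(rj ** -(n_arr + 1))
        if j == 1:
            rhs[:, row] = -(rj ** -(n_arr + 1))  # unit source term B_1 = 1
        row += 1
        # radial current continuity
        M[:, row, a_cols(j)] = sig[j - 1] * n_arr * rj ** (n_arr - 1)
        if j >= 2:
            M[:, row, b_cols(j)] = -sig[j - 1] * (n_arr + 1) * rj ** -(n_arr + 2)
        M[:, row, a_cols(j + 1)] = -sig[j] * n_arr * rj ** (n_arr - 1)
        M[:, row, b_cols(j + 1)] = sig[j] * (n_arr + 1) * rj ** -(n_arr + 2)
        if j == 1:
            rhs[:, row] = sig[0] * (n_arr + 1) * rj ** -(n_arr + 2)
        row += 1
    # outer boundary: zero radial current at r = 1
    M[:, row, a_cols(L)] = sig[-1] * n_arr
    M[:, row, b_cols(L)] = -sig[-1] * (n_arr + 1)

    sol = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]
    A_L, B_L = sol[:, a_cols(L)], sol[:, b_cols(L)]
    return A_L + B_L  # potential factor at the outer surface (rho_hat = 1)


class ForwardModel:
    """Cached lead-field evaluator for one head model and layout."""

    def __init__(
        self,
        model: SphereHeadModel | None = None,
        layout: ElectrodeLayout | None = None,
        channels=None,
        n_terms: int = 60,
    ):
        self.model = model or SphereHeadModel()
        self.layout = layout or default_canine_layout(self.model)
        self.layout.validate_on(self.model)
        self.channels = list(channels or self.layout.positions_mm)
        self.n_terms = int(n_terms)
        self._F = _surface_factors(self.model, self.n_terms)
        c = np.asarray(self.model.center_mm)
        elec = self.layout.as_array(self.channels) - c
        self._e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)

    def leadfield(self, locations_mm: np.ndarray) -> np.ndarray:
        """``(n_locations, n_electrodes, 3)`` average-referenced gain,
        microvolts per nAm of moment along each axis."""
        c = np.asarray(self.model.center_mm)
        loc = np.atleast_2d(np.asarray(locations_mm, dtype=float)) - c
        b = np.linalg.norm(loc, axis=1)  # mm
        R = self.model.scalp_radius_mm
        if np.any(b >= self.model.brain_radius_mm):
            raise ValueError("dipole location outside the brain shell")
        b_hat = b / R
        safe_b = np.where(b > 1e-9, b, 1.0)
        r0_hat = np.where(
            (b > 1e-9)[:, None], loc / safe_b[:, None], [[0.0, 0.0, 1.0]]
        )
        cgam = r0_hat @ self._e_hat.T  # (M, E)
        M, E = cgam.shape

        # Legendre recurrences accumulated into the two coefficient sums
        P_prev = np.ones_like(cgam)  # P_0
        P_cur = cgam.copy()  # P_1
        dP_prev = np.zeros_like(cgam)  # P_0'
        dP_cur = np.ones_like(cgam)  # P_1'
        S1 = np.zeros_like(cgam)
        S2 = np.zeros_like(cgam)
        ecc = np.ones_like(b_hat)  # (b/R)^(n-1)
        for n in range(1, self.n_terms + 1):
            Fn = self._F[n - 1]
            S1 += Fn * ecc[:, None] * n * P_cur
            S2 += Fn * ecc[:, None] * dP_cur
            ecc = ecc * b_hat
            P_next = ((2 * n + 1) * cgam * P_cur - n * P_prev) / (n + 1)
            dP_next = (2 * n + 1) * P_cur + dP_prev
            P_prev, P_cur = P_cur, P_next
            dP_prev, dP_cur = dP_cur, dP_next

        sigma1 = self.model.conductivities[0]
        pref = _NAM / (4.0 * np.pi * sigma1 * (R * _MM) ** 2) * _UV  # uV per nAm
        tang = self._e_hat[None, :, :] - cgam[:, :, None] * r0_hat[:, None, :]
        Lf = pref * (S1[:, :, None] * r0_hat[:, None, :] + S2[:, :, None] * tang)
        return Lf - Lf.mean(axis=1, keepdims=True)  # average reference


def forward_potential(
    model: SphereHeadModel,
    dipole: Dipole,
    layout: ElectrodeLayout,
    channels=None,
    n_terms: int = 60,
) -> np.ndarray:
    """Average-referenced electrode potentials (uV) of one dipole."""
    fwd = ForwardModel(model, layout, channels, n_terms)
    Lf = fwd.leadfield(dipole.location_mm[None, :])[0]
    return Lf @ dipole.moment_nAm


# --------------------------------------------------------------------------
# Dipole fitting
# --------------------------------------------------------------------------

def _source_grid(model: SphereHeadModel, spacing_mm: float,
                 max_radius_frac: float) -> np.ndarray:
    r_max = max_radius_frac * model.brain_radius_mm
    ax = np.arange(-r_max, r_max + spacing_mm / 2, spacing_mm)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= r_max]
    return pts + np.asarray(model.center_mm)


def _solve_moments(Lf: np.ndarray, topo: np.ndarray) -> tuple:
    """Batched linear moment solve; returns (moments, residual SS)."""
    G = np.einsum("mec,med->mcd", Lf, Lf)
    # tiny ridge keeps degenerate geometries (silent moment directions) solvable
    eps = 1e-12 * np.trace(G, axis1=1, axis2=2)[:, None, None] * np.eye(3)[None, :, :]
    b = np.einsum("mec,e->mc", Lf, topo)
    q = np.linalg.solve(G + eps, b[:, :, None])[:, :, 0]
    fitted = np.einsum("mec,mc->me", Lf, q)
    rss = np.sum((fitted - topo[None, :]) ** 2, axis=1)
    return q, rss


def fit_ecd(
    evoked: EvokedResponse,
    time_ms: float,
    model: SphereHeadModel | None = None,
    layout: ElectrodeLayout | None = None,
    grid_spacing_mm: float = 2.0,
    n_terms: int = 60,
    refine: bool = True,
    n_restarts: int = 5,
    max_radius_frac: float = 0.95,
) -> DipoleFit:
    """Fit an equivalent current dipole to the topography at one time point.

    The location is found by scanning a regular volumetric grid (2-mm
    spacing) inside the brain shell and refining from the best
    ``n_restarts`` grid points with a Nelder–Mead search; at every candidate
    the moment is the linear least-squares solution. Goodness of fit is
    ``100 * (1 - ||residual||^2 / ||measured||^2)`` on the average-
    referenced topography. A refinement step that leaves the brain shell is
    projected back with a warning.
    """
    model = model or SphereHeadModel()
    layout = layout or default_canine_layout(model)
    fwd = ForwardModel(model, layout, evoked.channels, n_terms)
    ti = int(np.argmin(np.abs(evoked.times - time_ms)))
    topo = evoked.data[:, ti]
    topo = topo - topo.mean()  # average reference
    tss = float(np.sum(topo**2))
    if tss == 0:
        raise ValueError(f"all-zero topography at {time_ms} ms; nothing to fit")

    grid = _source_grid(model, grid_spacing_mm, max_radius_frac)
    q_grid, rss_grid = _solve_moments(fwd.leadfield(grid), topo)
    order = np.argsort(rss_grid)

    center = np.asarray(model.center_mm)
    r_cap = max_radius_frac * model.brain_radius_mm

    def objective(x):
        p = x.copy()
        d = np.linalg.norm(p - center)
        if d > r_cap:  # evaluate at the projected point, penalize overshoot
            p = center + (p - center) * (r_cap / d)
        _, rss = _solve_moments(fwd.leadfield(p[None, :]), topo)
        return rss[0] + (max(d - r_cap, 0.0)) ** 2 * tss

    best_x, best_rss = grid[order[0]], rss_grid[order[0]]
    if refine:
        for k in order[:n_restarts]:
            res = minimize(objective, grid[k], method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-12 * max(tss, 1.0),
                                    "maxiter": 400})
            x = res.x
            d = np.linalg.norm(x - center)
            if d > r_cap:
                warnings.warn(
                    "dipole refinement left the brain shell; projecting back",
                    stacklevel=2,
                )
                x = center + (x - center) * (r_cap / d)
            _, rss = _solve_moments(fwd.leadfield(x[None, :]), topo)
            if rss[0] < best_rss:
                best_x, best_rss = x, float(rss[0])
    q, rss = _solve_moments(fwd.leadfield(best_x[None, :]), topo)
    gof = 100.0 * (1.0 - rss[0] / tss)
    return DipoleFit(
        time_ms=float(evoked.times[ti]),
        location_mm=np.asarray(best_x, dtype=float),
        moment_nAm=q[0],
        gof_percent=float(gof),
    )


def fit_ecd_window(
    evoked: EvokedResponse, window_ms: tuple = (90.0, 110.0), **kwargs
) -> list:
    """One :func:`fit_ecd` per time point inside ``window_ms`` (inclusive)."""
    t0, t1 = window_ms
    times = evoked.times[(evoked.times >= t0) & (evoked.times <= t1)]
    return [fit_ecd(evoked, t, **kwargs) for t in times]


def moment_timecourse(
    evoked: EvokedResponse,
    location_mm: np.ndarray,
    model: SphereHeadModel | None = None,
    layout: ElectrodeLayout | None = None,
    window_ms: tuple = (-50.0, 300.0),
    n_terms: int = 60,
):
    """Dipole moment over time at a fixed location.

    At every time point inside ``window_ms`` the moment is solved linearly
    at ``location_mm`` (typically the best fit's location); returns a
    DataFrame with the moment vector, magnitude (nAm) and per-time GOF.
    """
    import pandas as pd

    model = model or SphereHeadModel()
    layout = layout or default_canine_layout(model)
    fwd = ForwardModel(model, layout, evoked.channels, n_terms)
    Lf = fwd.leadfield(np.asarray(location_mm)[None, :])
    t0, t1 = window_ms
    mask = (evoked.times >= t0) & (evoked.times <= t1)
    rows = []
    for ti in np.flatnonzero(mask):
        topo = evoked.data[:, ti]
        topo = topo - topo.mean()
        tss = float(np.sum(topo**2))
        q, rss = _solve_moments(Lf, topo)
        gof = 100.0 * (1.0 - rss[0] / tss) if tss > 0 else np.nan
        rows.append(
            {
                "time_ms": float(evoked.times[ti]),
                "qx_nAm": q[0, 0], "qy_nAm": q[0, 1], "qz_nAm": q[0, 2],
                "moment_nAm": float(np.linalg.norm(q[0])),
                "gof_percent": gof,
            }
        )
    return pd.DataFrame(rows)
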