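"""Anisotropic monodomain reaction-diffusion solver on triangulated atrial surfaces.

Space is discretized with linear (P1) finite elements: the stiffness matrix
carries the per-element anisotropic conductivity tensor
sigma_l f f^T + sigma_t (I - f f^T) restricted to the triangle plane, with
natural no-flux boundaries; the mass matrix is barycentrically lumped.
Time stepping is operator-split: explicit forward-Euler reaction and
Crank-Nicolson diffusion (pre-factorized sparse solve).

The default ionic backend is a three-variable phenomenological model of the
Fenton-Karma family (fast inward, slow outward, slow inward currents with two
gates), with per-vertex current scalings derived from the named channel
multipliers of the tissue model. Its parameters were tuned once on the
desk-resolution synthetic atria (AF-remodeled action-potential duration
~150 ms, conduction velocity ~0.36 mm/ms, re-entrant rates near 5 Hz) and
then frozen; at this scale the induced re-entry is a transient episode of a
few rotations (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .synthetic_cohort import AtrialSurface, LA_BODY
from .tissue_model import TissueProperties, SIGMA_LONG_BASELINE

# voltage mapping for the normalized surrogate variable u in [0, 1]
V_REST_MV = -81.0
V_AMP_MV = 106.0
ACT_THRESHOLD_MV = -40.0
U_THRESHOLD = (ACT_THRESHOLD_MV - V_REST_MV) / V_AMP_MV
U_CAP = 1.2  # saturation guard on the normalized variable (~ +46 mV)

# diffusivity (mm^2/ms) per unit conductivity (S/m); 0.4 S/m -> 0.12 mm^2/ms.
# Chosen with the kinetics so AF-remodeled conduction velocity is ~0.35 mm/ms
# at the default mesh resolution.
DIFFUSIVITY_PER_SM = 0.30

#: three-variable surrogate kinetics (times in ms), tuned once and frozen
FK_PARAMS = dict(
    u_c=0.13, u_v=0.04, tau_d=0.25,
    tau_v1m=19.6, tau_v2m=1250.0, tau_vp=3.33,
    tau_wm=41.0, tau_wp=870.0,
    tau_0=12.5, tau_r=50.0, tau_si=38.0, u_csi=0.5, k_si=10.0,
)

# weights mapping named-channel multipliers onto the three surrogate currents
SO_WEIGHTS = {"gK1": 0.4, "gKr": 0.2, "gKs": 0.1, "gto": 0.15, "gKur": 0.15}


@dataclass
class IonicModelParams:
    """Per-vertex surrogate-current scalings plus voltage conventions."""

    model_kind: str                     # "phenomenological_3var"
    scale_fi: np.ndarray                # fast inward (excitability/upstroke)
    scale_si: np.ndarray                # slow inward (plateau/APD)
    scale_so: np.ndarray                # slow outward (repolarization)
    v_rest: float = V_REST_MV
    v_amp: float = V_AMP_MV
    params: dict = field(default_factory=lambda: dict(FK_PARAMS))
    nominal_so: float | None = None   # body-median outward scaling pre-heterogeneity

    @classmethod
    def from_tissue(cls, tissue: TissueProperties, seed: Optional[int] = None,
                    surface: Optional[AtrialSurface] = None,
                    repol_het_sd: float = 0.5,
                    repol_het_corr_mm: float = 13.0) -> "IonicModelParams":
        """Derive surrogate scalings from named channel multipliers.

        gNa scales the fast inward current; gCaL enters the slow inward
        current through a square root (the surrogate plateau responds more
        steeply than the full model's); potassium-channel multipliers combine
        into the slow outward current by a weighted geometric mean.

        When ``seed`` and ``surface`` are given, a smooth log-normal
        repolarization-heterogeneity field multiplies the outward current,
        emulating the cell-to-cell electrophysiological variability of real
        atria that the deterministic remodeling layers do not carry.
        """
        m = tissue.ionic_multipliers
        sfi = np.array(m["gNa"], dtype=float)
        ssi = np.sqrt(np.array(m["gCaL"], dtype=float))
        sso = np.ones_like(sfi)
        for ch, w in SO_WEIGHTS.items():
            sso = sso * np.array(m[ch], dtype=float) ** w
        nominal = float(np.median(sso))
        if seed is not None and surface is not None and repol_het_sd > 0:
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(len(surface.vertices))
            d2 = ((surface.vertices[:, None, :] - surface.vertices[None, :, :]) ** 2).sum(-1)
            w = np.exp(-0.5 * d2 / repol_het_corr_mm ** 2)
            h = w @ noise
            h = (h - h.mean()) / h.std()
            # clipping keeps the weakest repolarization above the level at
            # which the plateau current could hold tissue depolarized
            h = np.clip(h, -0.8, 2.0)
            sso = sso * np.exp(repol_het_sd * h)
        return cls(model_kind="phenomenological_3var",
                   scale_fi=sfi, scale_si=ssi, scale_so=sso,
                   nominal_so=nominal)

    @classmethod
    def uniform(cls, nv: int, af_remodeling: bool = True) -> "IonicModelParams":
        """Homogeneous LA-body parameters (used for calibration strips)."""
        from .tissue_model import apply_ionic_remodeling
        m = apply_ionic_remodeling(np.zeros(nv), np.full(nv, LA_BODY, dtype=int),
                                   af_remodeling)
        t = TissueProperties(sigma_long=None, sigma_trans=None, cv_band=None,
                             ionic_multipliers=m)
        return cls.from_tissue(t)


@dataclass
class SimulationResult:
    voltage: np.ndarray               # (n_frames, nv) mV, float32
    dt_output: float                  # ms
    duration: float                   # ms
    surface: AtrialSurface
    activation_times: np.ndarray      # (nv,) first threshold crossing, ms (-1 = never)
    final_state: tuple                # (u, v, w) arrays at end time
    clamped: np.ndarray               # bool mask of electrically removed vertices

    @property
    def n_frames(self) -> int:
        return self.voltage.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_output


def _step_reaction_numpy(u, v, w, dt, p, sfi, ssi, sso):
    uc = p["u_c"]
    above = u >= uc
    j_fi = np.where(above, -v / p["tau_d"] * (1.0 - u) * (u - uc), 0.0) * sfi
    j_so = np.where(above, 1.0 / p["tau_r"], u / p["tau_0"]) * sso
    j_si = -w / (2.0 * p["tau_si"]) * (1.0 + np.tanh(p["k_si"] * (u - p["u_csi"]))) * ssi
    tau_vm = np.where(u >= p["u_v"], p["tau_v2m"], p["tau_v1m"])
    v = v + dt * np.where(above, -v / p["tau_vp"], (1.0 - v) / tau_vm)
    w = w + dt * np.where(above, -w / p["tau_wp"], (1.0 - w) / p["tau_wm"])
    u = np.minimum(u + dt * (-(j_fi + j_so + j_si)), U_CAP)
    return u, v, w


try:  # optional numba acceleration of the pointwise kinetics
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _step_reaction_jit(u, v, w, dt, u_c, u_v, tau_d, tau_v1m, tau_v2m,
                           tau_vp, tau_wm, tau_wp, tau_0, tau_r, tau_si,
                           u_csi, k_si, sfi, ssi, sso):  # pragma: no cover
        for i in range(u.shape[0]):
            ui = u[i]
            if ui >= u_c:
                j_fi = -v[i] / tau_d * (1.0 - ui) * (ui - u_c) * sfi[i]
                j_so = sso[i] / tau_r
            else:
                j_fi = 0.0
                j_so = ui / tau_0 * sso[i]
            j_si = (-w[i] / (2.0 * tau_si)
                    * (1.0 + np.tanh(k_si * (ui - u_csi))) * ssi[i])
            if ui >= u_c:
                v[i] += dt * (-v[i] / tau_vp)
                w[i] += dt * (-w[i] / tau_wp)
            else:
                tvm = tau_v2m if ui >= u_v else tau_v1m
                v[i] += dt * (1.0 - v[i]) / tvm
                w[i] += dt * (1.0 - w[i]) / tau_wm
            un = ui + dt * (-(j_fi + j_so + j_si))
            u[i] = un if un < 1.2 else 1.2
        return u, v, w

    def _step_reaction(u, v, w, dt, p, sfi, ssi, sso):
        n = u.shape[0]
        if not (isinstance(sfi, np.ndarray) and sfi.flags.c_contiguous
                and sfi.shape == (n,)):
            sfi = np.ascontiguousarray(
                np.broadcast_to(np.asarray(sfi, dtype=float), (n,)))
            ssi = np.ascontiguousarray(
                np.broadcast_to(np.asarray(ssi, dtype=float), (n,)))
            sso = np.ascontiguousarray(
                np.broadcast_to(np.asarray(sso, dtype=float), (n,)))
        return _step_reaction_jit(
            np.ascontiguousarray(u, dtype=float), np.ascontiguousarray(v, dtype=float),
            np.ascontiguousarray(w, dtype=float), dt,
            p["u_c"], p["u_v"], p["tau_d"], p["tau_v1m"], p["tau_v2m"],
            p["tau_vp"], p["tau_wm"], p["tau_wp"], p["tau_0"], p["tau_r"],
            p["tau_si"], p["u_csi"], p["k_si"], sfi, ssi, sso)
except Exception:  # pragma: no cover - numba unavailable
    _step_reaction = _step_reaction_numpy


# ---------------------------------------------------------------------------
# spatial discretization
# ---------------------------------------------------------------------------

def build_diffusion_operator(surface: AtrialSurface, tissue: TissueProperties):
    """P1 anisotropic stiffness matrix (mm^2/ms units) and lumped mass vector.

    Returns ``(stiffness, lumped_mass)``. The stiffness matrix is symmetric
    with zero row sums; no-flux boundary conditions are natural.
    """
    p = surface.vertices
    t = surface.triangles
    nv = len(p)
    e0 = p[t[:, 2]] - p[t[:, 1]]
    e1 = p[t[:, 0]] - p[t[:, 2]]
    e2 = p[t[:, 1]] - p[t[:, 0]]
    n = np.cross(e2, -e1)
    dbl_area = np.linalg.norm(n, axis=1)
    if np.any(dbl_area < 1e-12):
        bad = np.where(dbl_area < 1e-12)[0]
        raise ValueError(f"degenerate triangles: {bad.tolist()}")
    area = 0.5 * dbl_area
    nh = n / dbl_area[:, None]
    grads = np.stack([np.cross(nh, e0), np.cross(nh, e1), np.cross(nh, e2)],
                     axis=1) / dbl_area[:, None, None]
    f = surface.fiber
    tangential = np.eye(3)[None] - nh[:, :, None] * nh[:, None, :]
    ff = f[:, :, None] * f[:, None, :]
    d_l = DIFFUSIVITY_PER_SM * np.asarray(tissue.sigma_long, dtype=float)
    d_t = DIFFUSIVITY_PER_SM * np.asarray(tissue.sigma_trans, dtype=float)
    tensor = d_l[:, None, None] * ff + d_t[:, None, None] * (tangential - ff)
    rows, cols, vals = [], [], []
    for i in range(3):
        dg = np.einsum("eab,eb->ea", tensor, grads[:, i])
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            vals.append(area * np.einsum("ea,ea->e", grads[:, j], dg))
    stiff = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nv, nv))
    mass = np.zeros(nv)
    for i in range(3):
        np.add.at(mass, t[:, i], area / 3.0)
    return stiff, mass


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

def run_simulation(surface: AtrialSurface, tissue: TissueProperties,
                   ionic: IonicModelParams, init, duration: float,
                   dt: float = 0.1, dt_output: float = 5.0) -> SimulationResult:
    """Integrate the monodomain system; deterministic for identical inputs.

    ``init`` is a dict with per-vertex state arrays ``u``, ``v``, ``w``
    (missing gates default to 1, missing u to 0). Stimulation is expressed
    through the initial condition. Vertices whose every incident element is
    ablated are clamped to rest.
    """
    if ionic.model_kind != "phenomenological_3var":
        raise NotImplementedError(
            "only the phenomenological three-variable backend is implemented")
    if dt > 0.25:
        raise ValueError(f"dt={dt} ms unstable for explicit reaction stepping")
    if dt_output < dt:
        raise ValueError("dt_output must be >= dt")
    nv = len(surface.vertices)
    stiff, mass = build_diffusion_operator(surface, tissue)

    clamped = np.zeros(nv, dtype=bool)
    if len(tissue.ablated_elements):
        incident = np.zeros(nv, dtype=int)
        ablated_inc = np.zeros(nv, dtype=int)
        abl = np.zeros(len(surface.triangles), dtype=bool)
        abl[tissue.ablated_elements] = True
        for i in range(3):
            np.add.at(incident, surface.triangles[:, i], 1)
            np.add.at(ablated_inc, surface.triangles[:, i], abl.astype(int))
        clamped = (incident > 0) & (ablated_inc == incident)

    lhs = sp.csc_matrix(sp.diags(mass / dt) + 0.5 * stiff)
    rhs = sp.csr_matrix(sp.diags(mass / dt) - 0.5 * stiff)
    lu = spla.splu(lhs)

    u = np.array(init.get("u", np.zeros(nv)), dtype=float).copy()
    v = np.array(init.get("v", np.ones(nv)), dtype=float).copy()
    w = np.array(init.get("w", np.ones(nv)), dtype=float).copy()
    u[clamped] = 0.0

    p = ionic.params
    sfi = np.ascontiguousarray(np.broadcast_to(
        np.asarray(ionic.scale_fi, dtype=float), (nv,)))
    ssi = np.ascontiguousarray(np.broadcast_to(
        np.asarray(ionic.scale_si, dtype=float), (nv,)))
    sso = np.ascontiguousarray(np.broadcast_to(
        np.asarray(ionic.scale_so, dtype=float), (nv,)))
    n_steps = int(round(duration / dt))
    every = int(round(dt_output / dt))
    n_frames = n_steps // every + 1
    voltage = np.empty((n_frames, nv), dtype=np.float32)
    voltage[0] = ionic.v_rest + ionic.v_amp * u
    tact = np.where(u > U_THRESHOLD, 0.0, -1.0)
    frame = 1
    for step in range(1, n_steps + 1):
        u, v, w = _step_reaction(u, v, w, dt, p, sfi, ssi, sso)
        u = lu.solve(rhs @ u)
        if clamped.any():
            u[clamped] = 0.0
        newly = (tact < 0) & (u > U_THRESHOLD)
        if newly.any():
            tact[newly] = step * dt
        if step % every == 0:
            voltage[frame] = ionic.v_rest + ionic.v_amp * u
            frame += 1
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"solution diverged at t={step * dt} ms")
    return SimulationResult(voltage=voltage, dt_output=dt_output,
                            duration=n_steps * dt, surface=surface,
                            activation_times=tact, final_state=(u, v, w),
                            clamped=clamped)


# ---------------------------------------------------------------------------
# calibration strip
# ---------------------------------------------------------------------------

def make_strip(length: float = 40.0, width: float = 10.0,
               edge_length: float = 0.5) -> AtrialSurface:
    """Rectangular strip surface with fibers along its length."""
    nx = int(round(length / edge_length)) + 1
    ny = int(round(width / edge_length)) + 1
    xs, ys = np.meshgrid(np.linspace(0, length, nx), np.linspace(0, width, ny),
                         indexing="ij")
    verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)], axis=1)
    idx = np.arange(nx * ny).reshape(nx, ny)
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            tris.append([a, b, c])
            tris.append([a, c, d])
    tris = np.array(tris, dtype=int)
    from .synthetic_cohort import _boundary_loops_of
    return AtrialSurface(
        vertices=verts, triangles=tris,
        region_label=np.zeros(nx * ny, dtype=int),
        boundary_loops=_boundary_loops_of(tris),
        surf_coord=np.stack([xs.ravel() / length, ys.ravel() / width], axis=1),
        fiber=np.tile([1.0, 0.0, 0.0], (len(tris), 1)),
        unit_dirs=verts.copy(),
        target_edge_length=edge_length,
    )


_STRIP_CACHE: dict = {}


def strip_tissue(surface: AtrialSurface, scale: float = 1.0,
                 longitudinal: bool = True) -> TissueProperties:
    ne = len(surface.triangles)
    from .tissue_model import apply_ionic_remodeling
    nv = len(surface.vertices)
    mult = apply_ionic_remodeling(np.zeros(nv), np.zeros(nv, dtype=int),
                                  af_remodeling=True)
    sl = SIGMA_LONG_BASELINE * scale
    st = sl / 4.0 if longitudinal else sl  # transverse handled by fiber direction
    return TissueProperties(sigma_long=np.full(ne, sl), sigma_trans=np.full(ne, st),
                            cv_band=np.full(nv, 100, dtype=int),
                            ionic_multipliers=mult)


def strip_cv(scale: float, edge_length: float = 0.5, dt: float = 0.1,
             transverse: bool = False) -> float:
    """Planar-wave CV (mm/ms) on the calibration strip at a conductivity scale."""
    key = (edge_length, transverse)
    if key not in _STRIP_CACHE:
        strip = make_strip(edge_length=edge_length)
        if transverse:
            strip.fiber = np.tile([0.0, 1.0, 0.0], (len(strip.triangles), 1))
        ionic = IonicModelParams.uniform(len(strip.vertices))
        _STRIP_CACHE[key] = (strip, ionic)
    strip, ionic = _STRIP_CACHE[key]
    tissue = strip_tissue(strip, scale)
    init = {"u": np.where(strip.vertices[:, 0] < 1.5, 1.0, 0.0)}
    # slowest waves (scale ~0.1) need ~300 ms to reach the far probe
    result = run_simulation(strip, tissue, ionic, init,
                            duration=420.0, dt=dt, dt_output=20.0)
    try:
        return measure_cv(result, _strip_probe(strip, 0.25),
                          _strip_probe(strip, 0.75))
    except RuntimeError:
        return 0.0  # conduction block at this conductivity


def _strip_probe(strip: AtrialSurface, frac: float) -> int:
    target = np.array([frac * strip.vertices[:, 0].max(),
                       0.5 * strip.vertices[:, 1].max(), 0.0])
    return int(np.argmin(np.linalg.norm(strip.vertices - target, axis=1)))


def measure_cv(result: SimulationResult, probe_a: int, probe_b: int) -> float:
    """Geodesic distance over activation-time difference between two probes."""
    ta, tb = result.activation_times[[probe_a, probe_b]]
    if ta < 0 or tb < 0:
        raise RuntimeError("probe not activated; cannot measure CV")
    if tb == ta:
        raise RuntimeError("probes activated simultaneously")
    d = result.surface.geodesic_distance([probe_a])[probe_b]
    return float(d / abs(tb - ta))


# ---------------------------------------------------------------------------
# spiral-wave initiation
# ---------------------------------------------------------------------------

SPIRAL_CENTERS = ((0.30, 0.25, +1), (0.70, 0.25, -1),
                  (0.30, 0.75, -1), (0.70, 0.75, +1))


def _chart_to_unit(c1: float, c2: float) -> np.ndarray:
    x = np.cos(np.pi * c1)
    s = np.sin(np.pi * c1)
    beta = 2.0 * np.pi * c2 - np.pi
    return np.array([x, s * np.sin(beta), s * np.cos(beta)])


def spiral_phase_field(surface: AtrialSurface, wavelength_mm: float = 45.0) -> np.ndarray:
    """Analytic four-vortex phase field in (-pi, pi].

    The phase is the argument of a rational function of the stereographic
    coordinate (projected from inside the mitral opening) with simple zeros
    and poles at the four spiral centers - two anterior, two posterior, with
    alternating chirality - plus a radial term that turns each vortex into an
    Archimedean spiral of the given wavelength. By construction the field
    contains exactly four phase singularities with charges +1, -1, -1, +1.
    """
    unit = surface.unit_dirs
    mv_dir = _unit_rows(unit[surface.mitral_loop()].mean(axis=0))
    rot = _rotation_to(mv_dir, np.array([0.0, 0.0, -1.0]))
    ur = unit @ rot.T
    zc = (ur[:, 0] + 1j * ur[:, 1]) / (1.0 + ur[:, 2] + 1e-12)
    radius = float(np.linalg.norm(surface.vertices, axis=1).mean())
    w = np.ones(len(unit), dtype=complex)
    dists = []
    for c1, c2, q in SPIRAL_CENTERS:
        cu = _chart_to_unit(c1, c2) @ rot.T
        a = (cu[0] + 1j * cu[1]) / (1.0 + cu[2])
        w = w * (zc - a) if q > 0 else w / (zc - a)
        dists.append(np.arccos(np.clip(unit @ _chart_to_unit(c1, c2), -1, 1)) * radius)
    phi = np.angle(w) + 2.0 * np.pi * np.min(dists, axis=0) / wavelength_mm
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def _unit_rows(v):
    return v / np.linalg.norm(v)


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    c = np.cross(a, b)
    d = float(a @ b)
    if np.linalg.norm(c) < 1e-12:
        return np.eye(3) if d > 0 else -np.eye(3)
    cx = np.array([[0, -c[2], c[1]], [c[2], 0, -c[0]], [-c[1], c[0], 0]])
    return np.eye(3) + cx + cx @ cx / (1.0 + d)


def reference_cycle(ionic: IonicModelParams, cycle_length: float,
                    dt: float = 0.1, edge_length: float = 2.0) -> np.ndarray:
    """Propagated action-potential cycle (u, v, w) recorded on a paced cable.

    One beat is paced at the end of a thin strip at the mesh resolution of
    the atrial runs; the state trajectory of a mid-cable vertex is recorded
    for one cycle length starting at its activation. The propagated beat
    carries the electrotonic load of tissue, unlike an isolated cell.
    Uses the median body scalings of the ionic parameter maps.
    """
    sfi = np.array([np.median(ionic.scale_fi)])
    ssi = np.array([np.median(ionic.scale_si)])
    sso = np.array([ionic.nominal_so if ionic.nominal_so is not None
                    else np.median(ionic.scale_so)])
    strip = make_strip(length=40.0, width=2.0 * edge_length,
                       edge_length=edge_length)
    nv = len(strip.vertices)
    tissue = strip_tissue(strip, 1.0)
    stiff, mass = build_diffusion_operator(strip, tissue)
    lhs = sp.csc_matrix(sp.diags(mass / dt) + 0.5 * stiff)
    rhs = sp.csr_matrix(sp.diags(mass / dt) - 0.5 * stiff)
    lu = spla.splu(lhs)
    u = np.where(strip.vertices[:, 0] < 1.5, 1.0, 0.0)
    v = np.ones(nv)
    w = np.ones(nv)
    probe = _strip_probe(strip, 0.6)
    p = ionic.params
    n_cycle = int(round(cycle_length / dt))
    rec = np.zeros((n_cycle, 3))
    t_act = None
    k = 0
    max_steps = n_cycle + int(round(200.0 / dt))
    for step in range(max_steps):
        u, v, w = _step_reaction(u, v, w, dt, p, sfi, ssi, sso)
        u = lu.solve(rhs @ u)
        if t_act is None and u[probe] > U_THRESHOLD:
            t_act = step * dt
        if t_act is not None and k < n_cycle:
            rec[k] = [u[probe], v[probe], w[probe]]
            k += 1
            if k == n_cycle:
                break
    if t_act is None:
        raise RuntimeError("reference beat failed to propagate on the cable")
    return rec


def init_spiral_field(surface: AtrialSurface, ionic: IonicModelParams,
                      cycle_length: float = 200.0, wavelength_mm: float = 45.0,
                      dt: float = 0.1) -> dict:
    """Initial state encoding four counter-rotating spiral re-entries.

    Each vertex receives the reference-cycle state at the phase implied by an
    activation-time field built from the four-vortex spiral phase map.
    """
    rec = reference_cycle(ionic, cycle_length, dt,
                          edge_length=min(surface.target_edge_length, 2.0))
    if rec[-1, 0] > 0.5:
        raise ValueError(
            f"cycle length {cycle_length} ms is shorter than the surrogate "
            "action potential; reference cell never repolarizes")
    phi = spiral_phase_field(surface, wavelength_mm)
    t_act = (np.mod(phi, 2.0 * np.pi) / (2.0 * np.pi)) * cycle_length
    idx = np.clip(((cycle_length - t_act) / dt).astype(int), 0, len(rec) - 1)
    return {"u": rec[idx, 0].copy(), "v": rec[idx, 1].copy(),
            "w": rec[idx, 2].copy(), "t_act": t_act, "phase": phi}


# ---------------------------------------------------------------------------
# termination detection
# ---------------------------------------------------------------------------

def detect_termination(result: SimulationResult,
                       quiescence_window: float = 300.0,
                       threshold_mv: float = ACT_THRESHOLD_MV):
    """Earliest time after which no vertex exceeds threshold for a full window.

    Returns the time in ms, 0.0 for an all-quiescent movie, or None when
    activity persists to the end of the recording.
    """
    active = (result.voltage > threshold_mv).any(axis=1)
    if not active.any():
        return 0.0
    last = int(np.nonzero(active)[0][-1])
    t_quiet = (last + 1) * result.dt_output
    if result.duration - t_quiet >= quiescence_window:
        return float(t_quiet)
    return None
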