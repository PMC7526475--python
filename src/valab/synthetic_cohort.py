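"""Seeded virtual-patient generator: left-atrial surface, labels, coordinates, fibers, LGE.

The generator produces an idealized left atrium: a bumpy ellipsoidal shell with
five openings (mitral valve and four pulmonary veins), per-vertex region labels
(body, appendage, four PV sleeves), a two-coordinate surface chart used for
lesion placement and roof-width measurement, a smooth random fiber field, and a
synthetic late-gadolinium-enhancement (LGE) intensity map with blood-pool
reference statistics and patchy high-intensity fibrotic regions.

Cohort presets are calibrated once so that mean left-atrial body area and mean
fibrotic area match the clinical cohort statistics this package emulates
(paroxysmal ~102 cm^2 body / ~23 cm^2 fibrosis; persistent ~120 / ~26).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import trimesh

REGION_NAMES = ("LA_body", "LAA", "LSPV", "LIPV", "RSPV", "RIPV")
LA_BODY, LAA, LSPV, LIPV, RSPV, RIPV = range(6)
PV_REGIONS = (LSPV, LIPV, RSPV, RIPV)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized LA shell.

    Hole centers are directions on the generating unit sphere; radii are
    angular (radians). The two superior PV ostia sit at the poles of the
    first surface coordinate so that the roof isocontour (coord2 = 0.5) runs
    from one superior vein to the other across the roof.
    """

    radii_mm: tuple = (34.0, 36.0, 30.0)
    radii_jitter: float = 0.06       # fractional SD of per-axis radius jitter
    bump_amp: float = 0.15           # fractional amplitude of smooth shape bumps
    bump_n: int = 6
    bump_width: tuple = (0.4, 0.7)   # angular sigma range (rad)
    jitter: float = 1.0              # global scale on all random shape variation
    subdivisions: int = 4            # icosphere subdivision level
    mv_center: tuple = (0.0, 0.0, -1.0)
    mv_radius: float = 0.50
    pv_centers: dict = field(default_factory=lambda: {
        "LSPV": (-1.0, 0.0, 0.0),
        "RSPV": (1.0, 0.0, 0.0),
        "LIPV": (-0.75, 0.62, -0.21),
        "RIPV": (0.75, 0.62, -0.21),
    })
    pv_radii: dict = field(default_factory=lambda: {
        "LSPV": 0.28, "RSPV": 0.28, "LIPV": 0.24, "RIPV": 0.24,
    })
    pv_label_extra: float = 0.25     # angular width of the labeled PV sleeve
    laa_center: tuple = (-0.35, -0.85, 0.35)
    laa_radius: float = 0.32
    min_hole_gap: float = 0.10       # required angular gap between hole rims

    def validate(self) -> None:
        holes = [(_unit(self.mv_center), self.mv_radius)]
        for name, c in self.pv_centers.items():
            holes.append((_unit(c), self.pv_radii[name]))
        for i in range(len(holes)):
            for j in range(i + 1, len(holes)):
                ci, ri = holes[i]
                cj, rj = holes[j]
                ang = float(np.arccos(np.clip(ci @ cj, -1.0, 1.0)))
                if ang < ri + rj + self.min_hole_gap:
                    raise ValueError(
                        f"hole {i} and hole {j} overlap: separation {ang:.3f} rad "
                        f"< {ri:.3f} + {rj:.3f} + gap {self.min_hole_gap:.3f}"
                    )


@dataclass(frozen=True)
class LGEParams:
    """Synthetic LGE intensity model: baseline + geodesic Gaussian blobs + noise.

    Intensities are in arbitrary units. Blood-pool statistics are synthetic
    metadata chosen so that blob cores exceed the fibrosis threshold
    (3 SD above the blood-pool mean).
    """

    bp_mean: float = 40.0
    bp_sd: float = 10.0
    baseline: float = 50.0
    n_blobs: int = 10
    blob_width: tuple = (0.12, 0.22)   # angular sigma range (rad)
    blob_amp: tuple = (35.0, 70.0)     # peak amplitude range
    noise_sd: float = 5.0

    def validate(self) -> None:
        if self.bp_sd <= 0:
            raise ValueError("blood-pool SD must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class AtrialSurface:
    """Triangulated left-atrial surface with labels, chart, and fibers.

    vertices are in mm. ``unit_dirs`` stores the generating unit-sphere
    direction of each vertex (the analytic parameterization from which the
    surface chart is computed). ``surf_coord`` column 0 runs septal-to-lateral
    between the two superior PV ostia; column 1 runs anterior-MV (0) over the
    roof (0.5) to posterior-MV (1).
    """

    vertices: np.ndarray          # (nv, 3) float, mm
    triangles: np.ndarray         # (nt, 3) int
    region_label: np.ndarray      # (nv,) int, index into REGION_NAMES
    boundary_loops: list          # 5 ordered vertex-index rings
    surf_coord: np.ndarray        # (nv, 2) in [0, 1]^2
    fiber: np.ndarray             # (nt, 3) unit tangent per triangle
    unit_dirs: np.ndarray         # (nv, 3) generating parameterization
    target_edge_length: float     # mean edge length, mm

    # -- derived geometry -------------------------------------------------
    def triangle_areas(self) -> np.ndarray:
        p = self.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]]), axis=1)

    def triangle_normals(self) -> np.ndarray:
        p = self.vertices
        t = self.triangles
        n = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
        return n / np.linalg.norm(n, axis=1)[:, None]

    def vertex_areas(self) -> np.ndarray:
        """One-third of incident triangle area per vertex (barycentric lumping)."""
        va = np.zeros(len(self.vertices))
        ta = self.triangle_areas()
        for i in range(3):
            np.add.at(va, self.triangles[:, i], ta / 3.0)
        return va

    def total_area_cm2(self) -> float:
        return float(self.triangle_areas().sum()) / 100.0

    def region_area_cm2(self, region: int) -> float:
        va = self.vertex_areas()
        return float(va[self.region_label == region].sum()) / 100.0

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_graph(self) -> sp.csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by Euclidean length."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = len(self.vertices)
        g = sp.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
        return (g + g.T).tocsr()

    def geodesic_distance(self, sources) -> np.ndarray:
        """Graph-geodesic distance (mm) from the source vertex set to all vertices."""
        sources = np.atleast_1d(np.asarray(sources, dtype=int))
        d = csgraph.dijkstra(self.vertex_graph(), directed=False, indices=sources,
                             min_only=True)
        return np.asarray(d)

    def element_adjacency(self) -> sp.csr_matrix:
        """Triangle-triangle adjacency across shared edges."""
        t = self.triangles
        nt = len(t)
        pairs = {}
        rows, cols = [], []
        for k in range(3):
            a, b = t[:, k], t[:, (k + 1) % 3]
            for ti in range(nt):
                key = (min(a[ti], b[ti]), max(a[ti], b[ti]))
                if key in pairs:
                    rows.append(pairs[key]); cols.append(ti)
                else:
                    pairs[key] = ti
        data = np.ones(len(rows))
        g = sp.coo_matrix((data, (rows, cols)), shape=(nt, nt))
        return (g + g.T).tocsr()

    def boundary_vertices(self) -> np.ndarray:
        return np.unique(np.concatenate([np.asarray(l) for l in self.boundary_loops]))

    def loop_region(self, loop) -> int:
        """Majority region label of a boundary loop's vertices."""
        lab = self.region_label[np.asarray(loop)]
        return int(np.bincount(lab, minlength=6).argmax())

    def mitral_loop(self) -> np.ndarray:
        for loop in self.boundary_loops:
            if self.loop_region(loop) in (LA_BODY, LAA):
                return np.asarray(loop)
        raise RuntimeError("no mitral boundary loop found")


@dataclass
class VirtualPatient:
    id: str
    af_class: str                 # "paroxysmal" | "persistent"
    surface: AtrialSurface
    lge: "LGEMap"
    rng_seed: int


# ---------------------------------------------------------------------------
# surface generation
# ---------------------------------------------------------------------------

def _boundary_loops_of(tris: np.ndarray) -> list:
    edge_count = {}
    for t in tris:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    bedges = [e for e, c in edge_count.items() if c == 1]
    adj = {}
    for a, b in bedges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen, loops = set(), []
    for a, _ in bedges:
        if a in seen:
            continue
        loop, cur = [a], a
        seen.add(a)
        while True:
            nxt = [x for x in adj[cur] if x not in seen]
            if not nxt:
                break
            cur = nxt[0]
            seen.add(cur)
            loop.append(cur)
        loops.append(np.array(loop, dtype=int))
    return loops


def generate_surface(seed: int, params: GeometryParams = GeometryParams()) -> AtrialSurface:
    """Build one seeded LA surface satisfying the mesh invariants.

    The shell is an icosphere scaled by jittered per-axis radii and deformed
    by smooth random radial bumps; five geodesic disks are removed for the
    mitral valve and the four pulmonary veins. With ``jitter=0`` the output
    is independent of the seed.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    ico = trimesh.creation.icosphere(subdivisions=params.subdivisions)
    unit = np.asarray(ico.vertices, dtype=float)

    keep = np.ones(len(unit), dtype=bool)
    holes = [(_unit(params.mv_center), params.mv_radius)]
    holes += [(_unit(params.pv_centers[nm]), params.pv_radii[nm])
              for nm in ("LSPV", "LIPV", "RSPV", "RIPV")]
    for c, r in holes:
        keep &= np.arccos(np.clip(unit @ c, -1.0, 1.0)) > r

    remap = -np.ones(len(unit), dtype=int)
    remap[keep] = np.arange(int(keep.sum()))
    fmask = keep[ico.faces].all(axis=1)
    tris = remap[ico.faces[fmask]]
    unit = unit[keep]

    radii = np.asarray(params.radii_mm, dtype=float)
    radii = radii * np.exp(params.jitter * params.radii_jitter *
                           rng.standard_normal(3))
    bump = np.zeros(len(unit))
    for _ in range(params.bump_n):
        c = _unit(rng.standard_normal(3))
        amp = rng.uniform(-1.0, 1.0)
        sig = rng.uniform(*params.bump_width)
        ang = np.arccos(np.clip(unit @ c, -1.0, 1.0))
        bump += amp * np.exp(-0.5 * (ang / sig) ** 2)
    peak = np.abs(bump).max()
    if peak > 0:
        bump = bump / peak
    verts = unit * radii * (1.0 + params.jitter * params.bump_amp * bump)[:, None]

    # region labels: PV sleeves to the nearest ostium, then the appendage
    label = np.full(len(unit), LA_BODY, dtype=int)
    pv_margin = np.full(len(unit), np.inf)
    for nm, reg in (("LSPV", LSPV), ("LIPV", LIPV), ("RSPV", RSPV), ("RIPV", RIPV)):
        c = _unit(params.pv_centers[nm])
        r = params.pv_radii[nm]
        ang = np.arccos(np.clip(unit @ c, -1.0, 1.0))
        margin = ang - r
        inside = margin <= params.pv_label_extra
        closer = inside & (margin < pv_margin)
        label[closer] = reg
        pv_margin[closer] = margin[closer]
    ang = np.arccos(np.clip(unit @ _unit(params.laa_center), -1.0, 1.0))
    label[(ang <= params.laa_radius) & (label == LA_BODY)] = LAA

    # analytic chart from the generating parameterization
    c1 = np.arccos(np.clip(unit[:, 0], -1.0, 1.0)) / np.pi
    c2 = (np.arctan2(unit[:, 1], unit[:, 2]) + np.pi) / (2.0 * np.pi)
    coords = np.stack([c1, c2], axis=1)

    loops = _boundary_loops_of(tris)
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges.sort(axis=1)
    edges = np.unique(edges, axis=0)
    elen = float(np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1).mean())

    surface = AtrialSurface(
        vertices=verts, triangles=tris, region_label=label,
        boundary_loops=loops, surf_coord=coords,
        fiber=np.zeros((len(tris), 3)), unit_dirs=unit,
        target_edge_length=elen,
    )
    surface.fiber = generate_fiber_field(surface, seed=seed + 1)
    _validate_surface(surface)
    return surface


def _validate_surface(s: AtrialSurface) -> None:
    if len(s.boundary_loops) != 5:
        raise RuntimeError(f"expected 5 boundary loops, got {len(s.boundary_loops)}")
    ncomp, _ = csgraph.connected_components(s.vertex_graph(), directed=False)
    if ncomp != 1:
        raise RuntimeError(f"mesh is not connected ({ncomp} components)")
    pv_loops = [s.loop_region(l) for l in s.boundary_loops]
    for reg in PV_REGIONS:
        if pv_loops.count(reg) != 1:
            raise RuntimeError(
                f"PV region {REGION_NAMES[reg]} incident to {pv_loops.count(reg)} loops")


def generate_fiber_field(surface: AtrialSurface, seed: int,
                         corr_len: float = 15.0) -> np.ndarray:
    """Smooth random unit tangent field per triangle.

    A white-noise 3-vector per vertex is smoothed with a Gaussian kernel of
    width ``corr_len`` (mm, Euclidean), averaged onto triangles, projected to
    the tangent plane, and normalized. As ``corr_len`` grows the field tends
    to a globally parallel direction (up to tangent projection).
    """
    if corr_len <= 0:
        raise ValueError("corr_len must be positive")
    rng = np.random.default_rng(seed)
    nv = len(surface.vertices)
    noise = rng.standard_normal((nv, 3))
    d2 = ((surface.vertices[:, None, :] - surface.vertices[None, :, :]) ** 2).sum(-1)
    w = np.exp(-0.5 * d2 / corr_len ** 2)
    sm = w @ noise
    fe = sm[surface.triangles].mean(axis=1)
    n = surface.triangle_normals()
    fe = fe - (fe * n).sum(axis=1)[:, None] * n
    norms = np.linalg.norm(fe, axis=1)
    # a tangentially-degenerate triangle is re-oriented along an arbitrary edge
    bad = norms < 1e-12
    if bad.any():
        t = surface.triangles[bad]
        ev = surface.vertices[t[:, 1]] - surface.vertices[t[:, 0]]
        fe[bad] = ev
        norms = np.linalg.norm(fe, axis=1)
    return fe / norms[:, None]


def generate_lge_map(surface: AtrialSurface, seed: int,
                     params: LGEParams = LGEParams()):
    """Synthetic per-vertex LGE intensity with blood-pool metadata."""
    from .tissue_model import LGEMap

    params.validate()
    rng = np.random.default_rng(seed)
    unit = surface.unit_dirs
    body = np.where(surface.region_label <= LAA)[0]
    intensity = np.full(len(unit), params.baseline, dtype=float)
    for _ in range(params.n_blobs):
        center = unit[rng.choice(body)]
        sig = rng.uniform(*params.blob_width)
        amp = rng.uniform(*params.blob_amp)
        ang = np.arccos(np.clip(unit @ center, -1.0, 1.0))
        intensity += amp * np.exp(-0.5 * (ang / sig) ** 2)
    if params.noise_sd > 0:
        intensity += rng.normal(0.0, params.noise_sd, len(unit))
    intensity = np.maximum(intensity, 0.0)
    return LGEMap(intensity=intensity, bp_mean=params.bp_mean, bp_sd=params.bp_sd)


# ---------------------------------------------------------------------------
# cohort presets (tuned once against the cohort-statistics table, then frozen)
# ---------------------------------------------------------------------------

PAROXYSMAL_GEOMETRY = GeometryParams(radii_mm=(34.0, 36.0, 30.0))
PERSISTENT_GEOMETRY = GeometryParams(radii_mm=(37.0, 39.0, 32.5))
PAROXYSMAL_LGE = LGEParams(n_blobs=9, blob_amp=(35.0, 68.0))
PERSISTENT_LGE = LGEParams(n_blobs=10, blob_amp=(38.0, 72.0))


def make_patient(seed: int, af_class: str, pid: Optional[str] = None,
                 geometry: Optional[GeometryParams] = None,
                 lge_params: Optional[LGEParams] = None,
                 subdivisions: Optional[int] = None) -> VirtualPatient:
    if af_class not in ("paroxysmal", "persistent"):
        raise ValueError(f"unknown AF class {af_class!r}")
    if geometry is None:
        geometry = PAROXYSMAL_GEOMETRY if af_class == "paroxysmal" else PERSISTENT_GEOMETRY
    if lge_params is None:
        lge_params = PAROXYSMAL_LGE if af_class == "paroxysmal" else PERSISTENT_LGE
    if subdivisions is not None:
        geometry = replace(geometry, subdivisions=subdivisions)
    ss = np.random.SeedSequence(seed)
    s_surf, s_lge = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2)]
    surface = generate_surface(s_surf, geometry)
    lge = generate_lge_map(surface, s_lge, lge_params)
    return VirtualPatient(id=pid or f"{af_class[:3]}-{seed}", af_class=af_class,
                          surface=surface, lge=lge, rng_seed=seed)


def generate_cohort(n_paroxysmal: int, n_persistent: int, seed: int,
                    subdivisions: Optional[int] = None) -> list:
    """Generate a mixed cohort; child seeds derive deterministically from ``seed``."""
    if n_paroxysmal < 0 or n_persistent < 0:
        raise ValueError("cohort counts must be non-negative")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_paroxysmal + n_persistent)
    cohort = []
    for i in range(n_paroxysmal):
        cs = int(children[i].generate_state(1)[0] % (2 ** 31))
        cohort.append(make_patient(cs, "paroxysmal", pid=f"par-{i:03d}",
                                   subdivisions=subdivisions))
    for j in range(n_persistent):
        cs = int(children[n_paroxysmal + j].generate_state(1)[0] % (2 ** 31))
        cohort.append(make_patient(cs, "persistent", pid=f"per-{j:03d}",
                                   subdivisions=subdivisions))
    return cohort
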