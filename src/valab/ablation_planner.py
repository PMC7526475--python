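"""Automated ablation lesion planning on atrial surfaces.

Six strategies are generated consistently on any synthetic atrium:

(i)   ``pvi``            - wide-area encirclement of the pulmonary veins at a
                           fixed geodesic distance from the PV/body junction;
(ii)  ``box``            - PVI plus roof and inferior lines (fixed surface-
                           coordinate isocontours) isolating the posterior wall;
(iii) ``single_fibrosis``- PVI plus ablation of the largest fibrotic region,
                           joined to the closest mesh boundary or lesion;
(iv)  ``all_fibrosis``   - PVI plus every fibrotic region, each joined;
(v)   ``single_hotspot`` - PVI plus the largest PS-density hotspot, joined;
(vi)  ``all_hotspots``   - PVI plus every hotspot, joined.

All strategies include the PVI lesion set; regions are filled (not encircled)
and every lesion component is connected to a mesh boundary or another lesion
so no free-floating island of ablated tissue can sustain re-entry around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .synthetic_cohort import AtrialSurface, LA_BODY, LAA, PV_REGIONS
from .tissue_model import TissueProperties, FibroticRegionSet

STRATEGIES = ("pvi", "box", "single_fibrosis", "all_fibrosis",
              "single_hotspot", "all_hotspots")

DEFAULT_PVI_DISTANCE_MM = 5.0
DEFAULT_LESION_WIDTH_MM = 3.0
ROOF_COORD2 = 0.5
INFERIOR_COORD2 = 0.85   # 0.15 above the mitral end of the posterior wall


@dataclass
class LesionSet:
    strategy: str
    elements: np.ndarray          # ablated element ids, sorted
    width_mm: float
    components: list              # element-id arrays per connected sublesion
    component_areas_cm2: np.ndarray

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def ablated_area_cm2(self, surface: AtrialSurface) -> float:
        return float(surface.triangle_areas()[self.elements].sum()) / 100.0


@dataclass
class PostAblationPartition:
    components: list              # element-id arrays, descending area
    areas_cm2: np.ndarray
    ablated_area_cm2: float
    vertex_component: np.ndarray  # (nv,) component index or -1

    @property
    def largest_region(self) -> np.ndarray:
        return self.components[0] if self.components else np.zeros(0, dtype=int)

    def largest_region_vertices(self) -> np.ndarray:
        return np.where(self.vertex_component == 0)[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _element_components(surface: AtrialSurface, mask: np.ndarray):
    """Connected components (shared-edge adjacency) of an element mask."""
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return []
    adj = surface.element_adjacency()[idx][:, idx]
    n, lab = csgraph.connected_components(adj, directed=False)
    comps = [idx[lab == k] for k in range(n)]
    ta = surface.triangle_areas()
    comps.sort(key=lambda c: -float(ta[c].sum()))
    return comps


def _finalize(surface: AtrialSurface, strategy: str, mask: np.ndarray,
              width: float) -> LesionSet:
    comps = _element_components(surface, mask)
    ta = surface.triangle_areas()
    areas = np.array([ta[c].sum() / 100.0 for c in comps])
    return LesionSet(strategy=strategy, elements=np.where(mask)[0],
                     width_mm=width, components=comps,
                     component_areas_cm2=areas)


def _element_vertex_distance(surface: AtrialSurface, sources) -> np.ndarray:
    """Per-element mean vertex geodesic distance to a source vertex set."""
    d = surface.geodesic_distance(sources)
    return d[surface.triangles].mean(axis=1)


def pv_junction_vertices(surface: AtrialSurface) -> np.ndarray:
    """Body-side vertices on the interface between the LA body and PV sleeves."""
    e = surface.edges()
    lab = surface.region_label
    body = np.isin(lab, (LA_BODY, LAA))
    pv = np.isin(lab, PV_REGIONS)
    cross = (body[e[:, 0]] & pv[e[:, 1]]) | (pv[e[:, 0]] & body[e[:, 1]])
    junction = np.unique(e[cross])
    return junction[body[junction]]


# ---------------------------------------------------------------------------
# strategy planners
# ---------------------------------------------------------------------------

def plan_pvi(surface: AtrialSurface,
             distance_threshold: float = DEFAULT_PVI_DISTANCE_MM,
             width: float = DEFAULT_LESION_WIDTH_MM) -> LesionSet:
    """Closed encircling bands at a fixed distance outside the PV/body junction.

    Elements whose distance to the junction contour differs from the
    threshold by at most half the lesion width are ablated, restricted to the
    body side. Ipsilateral bands merge naturally where their annuli overlap.
    """
    junction = pv_junction_vertices(surface)
    if len(junction) == 0:
        raise ValueError("surface has no PV/body junction to encircle")
    d = surface.geodesic_distance(junction)
    lab = surface.region_label
    body_side = np.sum(np.isin(lab, (LA_BODY, LAA))[surface.triangles], axis=1) >= 2
    dt = d[surface.triangles]
    straddle = (dt.min(axis=1) <= distance_threshold) & \
               (dt.max(axis=1) > distance_threshold)
    mask = body_side & straddle
    rings = max(0, int(round(width / 2.0 / 1.5)))
    adj = surface.element_adjacency()
    for _ in range(rings - 1 if rings else 0):
        mask = mask | ((adj @ mask > 0) & body_side)
    mv_loop = surface.mitral_loop()
    if d[mv_loop].min() <= distance_threshold + width / 2.0:
        raise ValueError(
            f"PVI distance threshold {distance_threshold} mm reaches the mitral "
            "valve; choose a smaller threshold")
    return _finalize(surface, "pvi", mask, width)


def _isocontour_band(surface: AtrialSurface, coord2_value: float,
                     width: float) -> np.ndarray:
    """Element mask of a band around a coord2 isocontour (one neighbor ring
    beyond the crossed elements per 1.5 mm of half-width)."""
    c2 = surface.surf_coord[:, 1][surface.triangles]
    straddle = (c2.min(axis=1) <= coord2_value) & (c2.max(axis=1) > coord2_value)
    mask = straddle.copy()
    rings = max(0, int(round(width / 2.0 / 1.5)) - 1)
    adj = surface.element_adjacency()
    for _ in range(rings):
        mask = mask | (adj @ mask > 0)
    return mask


def plan_box(surface: AtrialSurface, base: LesionSet | None = None,
             width: float = DEFAULT_LESION_WIDTH_MM) -> LesionSet:
    """PVI plus roof and inferior lines isolating the posterior wall.

    The lines are the coord2 isocontours at fixed values shared across the
    cohort; both run between (and into) the superior/inferior PV lesion bands.
    """
    if base is None:
        base = plan_pvi(surface, width=width)
    mask = np.zeros(len(surface.triangles), dtype=bool)
    mask[base.elements] = True
    lab = surface.region_label
    body_side = np.sum(np.isin(lab, (LA_BODY, LAA))[surface.triangles], axis=1) >= 2
    roof = _isocontour_band(surface, ROOF_COORD2, width) & body_side
    inferior = _isocontour_band(surface, INFERIOR_COORD2, width) & body_side
    for name, line in (("roof", roof), ("inferior", inferior)):
        joined = mask | line
        comps = _element_components(surface, joined)
        # every line element must land in a component that contains PVI elements
        pvi_set = set(base.elements.tolist())
        for c in comps:
            cs = set(c.tolist())
            if cs.intersection(np.where(line)[0].tolist()) and not cs.intersection(pvi_set):
                raise ValueError(f"{name} line fails to meet the PVI bands")
        mask = joined
    return _finalize(surface, "box", mask, width)


def plan_region_isolation(surface: AtrialSurface, regions, select: str,
                          base: LesionSet, strategy: str | None = None,
                          width: float = DEFAULT_LESION_WIDTH_MM) -> LesionSet:
    """Fill selected regions and join each to the closest boundary or lesion.

    ``regions`` is a FibroticRegionSet, HotspotMap, or plain list of vertex
    arrays sorted by descending area. ``select`` is "largest" or "all".
    Joining lesions follow the geodesic shortest path from the region to the
    closest of the mesh boundary loops or the lesion components of the
    growing set; exact ties prefer the boundary.
    """
    if select not in ("largest", "all"):
        raise ValueError(f"select must be 'largest' or 'all', got {select!r}")
    region_list = getattr(regions, "regions", regions)
    name = strategy or f"{select}_regions"
    mask = np.zeros(len(surface.triangles), dtype=bool)
    mask[base.elements] = True
    if len(region_list) == 0:
        warnings.warn("empty region set: returning the base lesion set")
        out = _finalize(surface, name, mask, width)
        return out
    chosen = region_list[:1] if select == "largest" else region_list
    graph = surface.vertex_graph()
    boundary = surface.boundary_vertices()
    tris = surface.triangles
    for region in chosen:
        region = np.asarray(region, dtype=int)
        in_region = np.zeros(len(surface.vertices), dtype=bool)
        in_region[region] = True
        mask |= np.any(in_region[tris], axis=1)
        lesion_verts = np.unique(tris[mask])
        d, pred, _ = csgraph.dijkstra(graph, directed=False, indices=region,
                                      return_predecessors=True, min_only=True)
        db = d[boundary]
        bi = int(boundary[np.argmin(db)])
        lv = lesion_verts[~in_region[lesion_verts]]
        target, dist = bi, float(db.min())
        if len(lv):
            dl = d[lv]
            li = int(lv[np.argmin(dl)])
            if float(dl.min()) < dist:
                target, dist = li, float(dl.min())
        # walk predecessors back into the region
        path = [target]
        cur = target
        while pred[cur] >= 0:
            cur = int(pred[cur])
            path.append(cur)
        on_path = np.zeros(len(surface.vertices), dtype=bool)
        on_path[path] = True
        mask |= np.any(on_path[tris], axis=1)
    return _finalize(surface, name, mask, width)


def plan_strategy(surface: AtrialSurface, strategy: str,
                  fibrotic_regions: FibroticRegionSet | None = None,
                  hotspots=None,
                  pvi_distance: float = DEFAULT_PVI_DISTANCE_MM,
                  width: float = DEFAULT_LESION_WIDTH_MM) -> LesionSet:
    """Dispatch one of the six named strategies."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    pvi = plan_pvi(surface, pvi_distance, width)
    if strategy == "pvi":
        return pvi
    if strategy == "box":
        return plan_box(surface, base=pvi, width=width)
    if strategy in ("single_fibrosis", "all_fibrosis"):
        if fibrotic_regions is None:
            raise ValueError(f"{strategy} requires fibrotic regions")
        sel = "largest" if strategy == "single_fibrosis" else "all"
        return plan_region_isolation(surface, fibrotic_regions, sel, pvi,
                                     strategy=strategy, width=width)
    if hotspots is None:
        raise ValueError(f"{strategy} requires a hotspot map")
    sel = "largest" if strategy == "single_hotspot" else "all"
    return plan_region_isolation(surface, hotspots, sel, pvi,
                                 strategy=strategy, width=width)


# ---------------------------------------------------------------------------
# electrical application and partitioning
# ---------------------------------------------------------------------------

def apply_lesions(tissue: TissueProperties, lesions: LesionSet) -> TissueProperties:
    """Zero conductivity on ablated elements; excitability of fully enclosed
    vertices is disabled by the solver."""
    sigma_l = np.array(tissue.sigma_long, dtype=float)
    sigma_t = np.array(tissue.sigma_trans, dtype=float)
    sigma_l[lesions.elements] = 0.0
    sigma_t[lesions.elements] = 0.0
    merged = np.union1d(tissue.ablated_elements, lesions.elements).astype(int)
    return dc_replace(tissue, sigma_long=sigma_l, sigma_trans=sigma_t,
                      ablated_elements=merged)


def partition_post_ablation(surface: AtrialSurface,
                            lesions: LesionSet | None) -> PostAblationPartition:
    """Connected non-ablated tissue regions with areas (cm^2)."""
    nt = len(surface.triangles)
    mask = np.ones(nt, dtype=bool)
    ablated_area = 0.0
    ta = surface.triangle_areas()
    if lesions is not None and len(lesions.elements):
        mask[lesions.elements] = False
        ablated_area = float(ta[lesions.elements].sum()) / 100.0
    comps = _element_components(surface, mask)
    areas = np.array([ta[c].sum() / 100.0 for c in comps])
    vc = np.full(len(surface.vertices), -1, dtype=int)
    for k in range(len(comps) - 1, -1, -1):
        vc[np.unique(surface.triangles[comps[k]])] = k
    return PostAblationPartition(components=comps, areas_cm2=areas,
                                 ablated_area_cm2=ablated_area,
                                 vertex_component=vc)
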