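"""Post-ablation outcome classification, lesion metrics, and strategy selection.

A simulation that goes quiescent is a *termination*. Sustained activity is
classified by mean dominant frequency (DF): organized macro-re-entrant
tachycardia (AT) below 4.7 Hz, continued fibrillation (AF) above. AT and
termination are acute responders. Five lesion metrics summarize the
post-ablation mesh: remaining LA / fibrosis / hotspot areas inside the
largest connected region, the conducting roof width at the roof isocontour,
and the smallest channel height between the mitral valve and significant
lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.signal

from .synthetic_cohort import AtrialSurface, LA_BODY, PV_REGIONS
from .monodomain_sim import SimulationResult, detect_termination, ACT_THRESHOLD_MV
from .ablation_planner import LesionSet, PostAblationPartition, ROOF_COORD2
from .phase_mapping import HotspotMap

DF_THRESHOLD_HZ = 4.7
DF_BAND_HZ = (0.5, 20.0)
DF_RESOLUTION_HZ = 0.05


@dataclass
class OutcomeLabel:
    category: str                  # "termination" | "AT" | "AF"
    mean_df: Optional[float]       # Hz; None when no DF is defined
    df_threshold: float = DF_THRESHOLD_HZ

    @property
    def responder(self) -> bool:
        return self.category != "AF"


@dataclass
class LesionMetrics:
    remaining_la_area: float        # cm^2, largest connected region
    remaining_fibrosis_area: float  # cm^2, normalized LGE > 0.56 in largest region
    remaining_hotspot_area: float   # cm^2, pre-ablation hotspots in largest region
    roof_width: float               # cm, conducting roof isocontour length
    min_channel_height: float       # cm, MV to nearest significant lesion
    channel_height_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "remaining_la_area": self.remaining_la_area,
            "remaining_fibrosis_area": self.remaining_fibrosis_area,
            "remaining_hotspot_area": self.remaining_hotspot_area,
            "roof_width": self.roof_width,
            "min_channel_height": self.min_channel_height,
        }


# ---------------------------------------------------------------------------
# dominant frequency
# ---------------------------------------------------------------------------

def vertex_dominant_frequency(result: SimulationResult,
                              min_amplitude_mv: float = 10.0):
    """Per-vertex DF (Hz) by Welch periodogram; NaN for invalid vertices.

    Valid vertices are non-clamped LA-body vertices (PV sleeves excluded)
    whose trace shows genuine activity. Windows of 2 s with 50% overlap are
    zero-padded to 0.05 Hz bin spacing.
    """
    from .phase_mapping import active_window
    n_act = active_window(result.voltage)
    v = result.voltage[:max(n_act, 1)]
    fs = 1000.0 / result.dt_output
    lab = result.surface.region_label
    valid = ~result.clamped & (lab == LA_BODY)
    valid &= (v.max(axis=0) - v.min(axis=0)) >= min_amplitude_mv
    # a defined rate needs at least two activation cycles at the vertex
    above = v > ACT_THRESHOLD_MV
    crossings = (~above[:-1] & above[1:]).sum(axis=0) + above[0].astype(int)
    valid &= crossings >= 2
    df = np.full(v.shape[1], np.nan)
    if not valid.any():
        return df, valid
    nper = min(v.shape[0], int(round(2000.0 / result.dt_output)))
    nfft = max(nper, int(round(fs / DF_RESOLUTION_HZ)))
    freqs, pxx = scipy.signal.welch(v[:, valid], fs=fs, axis=0, nperseg=nper,
                                    noverlap=nper // 2, nfft=nfft,
                                    detrend="constant")
    band = (freqs >= DF_BAND_HZ[0]) & (freqs <= DF_BAND_HZ[1])
    df[valid] = freqs[band][np.argmax(pxx[band], axis=0)]
    return df, valid


def dominant_frequency(result: SimulationResult) -> float:
    """Mean DF (Hz) over valid LA-body vertices."""
    df, valid = vertex_dominant_frequency(result)
    if not valid.any():
        raise RuntimeError("all vertices quiescent: dominant frequency undefined")
    return float(np.nanmean(df[valid]))


def classify_outcome(result: SimulationResult,
                     df_threshold: float = DF_THRESHOLD_HZ) -> OutcomeLabel:
    """Termination / AT / AF label. A DF exactly at threshold counts as AT."""
    terminated = detect_termination(result)
    if terminated is not None:
        mean_df = None
        try:
            mean_df = dominant_frequency(result)
        except RuntimeError:
            pass
        return OutcomeLabel("termination", mean_df, df_threshold)
    try:
        mean_df = dominant_frequency(result)
    except RuntimeError:
        # ongoing activity too short or disorganized for a rate estimate:
        # continued fibrillation without measurable organization
        return OutcomeLabel("AF", None, df_threshold)
    category = "AT" if mean_df <= df_threshold else "AF"
    return OutcomeLabel(category, mean_df, df_threshold)


# ---------------------------------------------------------------------------
# lesion metrics
# ---------------------------------------------------------------------------

def roof_isocontour_length_cm(surface: AtrialSurface, elements: np.ndarray,
                              coord2_value: float = ROOF_COORD2) -> float:
    """Length (cm) of the coord2 isocontour restricted to the given elements."""
    if len(elements) == 0:
        return 0.0
    t = surface.triangles[elements]
    c2 = surface.surf_coord[:, 1]
    p = surface.vertices
    total = 0.0
    for tri in t:
        vals = c2[tri] - coord2_value
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            va, vb = vals[a], vals[b]
            if (va <= 0 < vb) or (vb <= 0 < va):
                lam = va / (va - vb)
                pts.append(p[tri[a]] + lam * (p[tri[b]] - p[tri[a]]))
        if len(pts) == 2:
            total += float(np.linalg.norm(pts[1] - pts[0]))
    return total / 10.0


def compute_lesion_metrics(surface: AtrialSurface, lesions: LesionSet,
                           partition: PostAblationPartition,
                           lge_norm: np.ndarray,
                           hotspots: HotspotMap,
                           significance_fraction: float = 0.8) -> LesionMetrics:
    """Five lesion metrics on the post-ablation mesh.

    Areas are restricted to the largest connected region. Lesion components
    count as *significant* when their area exceeds ``significance_fraction``
    of the second-largest lesion component.
    """
    if len(partition.components) == 0:
        warnings.warn("empty post-ablation partition: all metrics zero")
        return LesionMetrics(0.0, 0.0, 0.0, 0.0, 0.0, channel_height_defined=False)
    vl = partition.largest_region_vertices()
    in_largest = np.zeros(len(surface.vertices), dtype=bool)
    in_largest[vl] = True
    va = surface.vertex_areas()

    fib_mask = in_largest & (np.asarray(lge_norm) > 0.56)
    hot_mask = np.zeros(len(surface.vertices), dtype=bool)
    for r in hotspots.regions:
        hot_mask[r] = True
    hot_mask &= in_largest

    roof = roof_isocontour_length_cm(surface, partition.largest_region)

    mv = surface.mitral_loop()
    if len(lesions.elements) == 0:
        d = np.linalg.norm(
            surface.vertices[mv][:, None, :] -
            surface.vertices[surface.boundary_vertices()][None, :, :], axis=-1)
        d = d[d > 0]
        channel = float(d.min()) / 10.0 if d.size else 0.0
        defined = False
    else:
        areas = lesions.component_areas_cm2
        cutoff = significance_fraction * (areas[1] if len(areas) > 1 else areas[0])
        sig = [c for c, a in zip(lesions.components, areas) if a > cutoff]
        if not sig:
            sig = [lesions.components[0]]
        lesion_verts = np.unique(surface.triangles[np.concatenate(sig)])
        d = np.linalg.norm(surface.vertices[mv][:, None, :] -
                           surface.vertices[lesion_verts][None, :, :], axis=-1)
        channel = float(d.min()) / 10.0
        defined = True

    return LesionMetrics(
        remaining_la_area=float(partition.areas_cm2[0]),
        remaining_fibrosis_area=float(va[fib_mask].sum()) / 100.0,
        remaining_hotspot_area=float(va[hot_mask].sum()) / 100.0,
        roof_width=roof,
        min_channel_height=channel,
        channel_height_defined=defined,
    )


def imaging_electrical_features(patient, preablation: SimulationResult,
                                hotspots: HotspotMap) -> dict:
    """Three imaging features (cm^2) and two electrical features (Hz, cm^2)."""
    from .tissue_model import lge_z_score, FIBROSIS_Z_THRESHOLD
    s = patient.surface
    va = s.vertex_areas()
    z = lge_z_score(patient.lge)
    try:
        mean_df = dominant_frequency(preablation)
    except RuntimeError:
        mean_df = 0.0  # episode too short for a rate estimate
    return {
        "la_body_area": float(va[s.region_label == LA_BODY].sum()) / 100.0,
        "pv_area": float(va[np.isin(s.region_label, PV_REGIONS)].sum()) / 100.0,
        "fibrosis_area": float(va[z > FIBROSIS_Z_THRESHOLD].sum()) / 100.0,
        "mean_df": mean_df,
        "hotspot_area": hotspots.total_area_cm2,
    }


# ---------------------------------------------------------------------------
# optimal-strategy selection
# ---------------------------------------------------------------------------

_CATEGORY_RANK = {"termination": 2, "AT": 1, "AF": 0}


def select_optimal_strategy(outcomes: dict, partitions: dict):
    """Best strategy: termination beats AT beats AF; ties broken by smallest
    ablation burden. Returns None when every strategy leaves AF."""
    from .ablation_planner import STRATEGIES
    missing = [s for s in STRATEGIES if s not in outcomes or s not in partitions]
    if missing:
        raise ValueError(f"missing strategies: {missing}")
    best_rank = max(_CATEGORY_RANK[outcomes[s].category] for s in STRATEGIES)
    if best_rank == 0:
        return None
    tied = [s for s in STRATEGIES
            if _CATEGORY_RANK[outcomes[s].category] == best_rank]
    return min(tied, key=lambda s: (partitions[s].ablated_area_cm2, s))
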