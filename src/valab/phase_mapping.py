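"""Instantaneous phase, phase-singularity detection, PS density, and hotspots.

Phase is the argument of the analytic signal (Hilbert transform) of each
vertex's mean-subtracted voltage trace. A phase singularity (PS) is localized
to a triangle whose wrapped phase circulation around its vertex loop is +-2pi;
the integer winding is its topological charge. PS events accumulated over the
analysis window, smoothed with a Gaussian kernel and normalized by area and
window length, form the PS density map; driver hotspots are the connected
components of vertices above mean + 1 SD of that density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .synthetic_cohort import AtrialSurface
from .tissue_model import connected_vertex_regions


@dataclass
class PSTrackSet:
    """PS events per frame: (frame index, element id, charge)."""

    events: np.ndarray            # (n_events, 3) int: frame, element, charge
    window_ms: float
    dt_output: float

    def __len__(self):
        return len(self.events)

    @property
    def charges(self) -> np.ndarray:
        return self.events[:, 2]


@dataclass
class HotspotMap:
    ps_density: np.ndarray        # (nv,) events per cm^2 per s
    threshold: float
    regions: list                 # vertex-index arrays, descending area
    areas_cm2: np.ndarray

    @property
    def total_area_cm2(self) -> float:
        return float(self.areas_cm2.sum())


def compute_phase(voltage: np.ndarray, min_amplitude: float = 1.0):
    """Analytic-signal phase of mean-subtracted voltage traces.

    Parameters
    ----------
    voltage : (n_frames, nv) array, mV.
    min_amplitude : traces whose peak-to-peak range falls below this (mV) are
        flagged invalid (phase undefined on flat signals).

    Returns ``(phase, valid)`` with phase in (-pi, pi].
    """
    voltage = np.asarray(voltage, dtype=float)
    ptp = voltage.max(axis=0) - voltage.min(axis=0)
    valid = ptp >= min_amplitude
    centered = voltage - voltage.mean(axis=0, keepdims=True)
    analytic = scipy.signal.hilbert(centered, axis=0)
    phase = np.angle(analytic)
    phase[:, ~valid] = 0.0
    return phase, valid


def detect_ps(phase_frame: np.ndarray, surface: AtrialSurface,
              valid: np.ndarray | None = None) -> list:
    """Phase singularities of one phase frame.

    The topological charge of each triangle is the wrapped phase circulation
    around its vertex loop divided by 2pi. Returns a list of
    ``(element_id, charge)`` with charge in {+1, -1}. Triangles touching an
    invalid vertex are skipped.
    """
    t = surface.triangles
    p = np.asarray(phase_frame)

    def wrap(d):
        return np.mod(d + np.pi, 2.0 * np.pi) - np.pi

    circ = (wrap(p[t[:, 1]] - p[t[:, 0]]) + wrap(p[t[:, 2]] - p[t[:, 1]])
            + wrap(p[t[:, 0]] - p[t[:, 2]]))
    charge = np.rint(circ / (2.0 * np.pi)).astype(int)
    hits = charge != 0
    if valid is not None:
        hits &= np.all(valid[t], axis=1)
    return [(int(e), int(charge[e])) for e in np.nonzero(hits)[0]]


def track_ps(voltage: np.ndarray, surface: AtrialSurface, dt_output: float,
             exclude_elements: np.ndarray | None = None) -> PSTrackSet:
    """Detect PS events on every frame of a voltage movie."""
    phase, valid = compute_phase(voltage)
    excl = np.zeros(len(surface.triangles), dtype=bool)
    if exclude_elements is not None and len(exclude_elements):
        excl[np.asarray(exclude_elements, dtype=int)] = True
    events = []
    for f in range(phase.shape[0]):
        for e, q in detect_ps(phase[f], surface, valid):
            if not excl[e]:
                events.append((f, e, q))
    events = np.array(events, dtype=int) if events else np.zeros((0, 3), dtype=int)
    return PSTrackSet(events=events, window_ms=(phase.shape[0] - 1) * dt_output,
                      dt_output=dt_output)


def ps_density(tracks: PSTrackSet, surface: AtrialSurface,
               smoothing_radius: float = 5.0) -> np.ndarray:
    """Smoothed PS event density (events per cm^2 per second).

    Each event at a triangle barycenter is spread over vertices with a
    Gaussian kernel of the given radius (mm) normalized against vertex areas,
    so the surface integral of density times window equals the event count.
    """
    if tracks.window_ms <= 0:
        raise ValueError("analysis window must be positive")
    nv = len(surface.vertices)
    va_mm2 = surface.vertex_areas()
    density = np.zeros(nv)
    if len(tracks) == 0:
        return density
    counts = np.bincount(tracks.events[:, 1], minlength=len(surface.triangles))
    active = np.nonzero(counts)[0]
    bary = surface.vertices[surface.triangles[active]].mean(axis=1)
    d2 = ((surface.vertices[None, :, :] - bary[:, None, :]) ** 2).sum(-1)
    kern = np.exp(-0.5 * d2 / smoothing_radius ** 2)
    # normalize each event kernel against vertex areas: integral = 1 event
    kern /= (kern * va_mm2[None, :]).sum(axis=1, keepdims=True)
    density = counts[active] @ kern
    window_s = tracks.window_ms / 1000.0
    return density * 100.0 / window_s  # 1/mm^2 -> 1/cm^2, per second


def find_hotspots(density: np.ndarray, surface: AtrialSurface,
                  k_sd: float = 1.0, valid: np.ndarray | None = None) -> HotspotMap:
    """Connected regions where density exceeds mean + k_sd * SD.

    Vertices flagged invalid are excluded from the mean/SD estimate and from
    the hotspot mask. A zero-variance density yields an empty hotspot set.
    """
    density = np.asarray(density, dtype=float)
    sel = np.ones(len(density), dtype=bool) if valid is None else np.asarray(valid)
    mu = float(density[sel].mean()) if sel.any() else 0.0
    sd = float(density[sel].std()) if sel.any() else 0.0
    threshold = mu + k_sd * sd
    if sd == 0.0:
        return HotspotMap(ps_density=density, threshold=threshold,
                          regions=[], areas_cm2=np.zeros(0))
    mask = (density > threshold) & sel
    regions = connected_vertex_regions(mask, surface)
    va = surface.vertex_areas()
    areas = np.array([va[r].sum() / 100.0 for r in regions])
    order = np.argsort(-areas) if len(areas) else np.array([], dtype=int)
    return HotspotMap(ps_density=density, threshold=threshold,
                      regions=[regions[i] for i in order], areas_cm2=areas[order])


def active_window(voltage: np.ndarray, threshold_mv: float = -40.0) -> int:
    """Number of leading frames up to and including the last active one.

    Hilbert phase is only meaningful while fibrillation lasts; the quiescent
    tail after self-termination is excluded from phase analysis.
    """
    active = (np.asarray(voltage) > threshold_mv).any(axis=1)
    if not active.any():
        return 0
    return int(np.nonzero(active)[0][-1]) + 1


def hotspot_map_from_result(result, smoothing_radius: float = 5.0,
                            k_sd: float = 1.0,
                            exclude_elements: np.ndarray | None = None) -> HotspotMap:
    """Full pipeline: voltage movie -> PS tracks -> density -> hotspots.

    Analysis is restricted to the active window of the recording.
    """
    n_act = active_window(result.voltage)
    if n_act < 3:
        nv = len(result.surface.vertices)
        return HotspotMap(ps_density=np.zeros(nv), threshold=0.0,
                          regions=[], areas_cm2=np.zeros(0))
    movie = result.voltage[:n_act]
    tracks = track_ps(movie, result.surface, result.dt_output,
                      exclude_elements)
    density = ps_density(tracks, result.surface, smoothing_radius)
    _, valid = compute_phase(movie)
    valid = valid & ~result.clamped
    return find_hotspots(density, result.surface, k_sd, valid)
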