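"""Spot detection, fiducial drift correction, and trace extraction.

Mirrors the standard CoSMoS image-analysis sequence: DNA locations are
mapped from blue-excitation reference frames, fluorescent impurities
from green+red reference frames, broadly fluorescent beads (visible in
both) serve as fiducials for thermal-drift correction, and intensity
traces are extracted by integrating 5x5-pixel windows centered on
(drift-corrected) DNA locations with a smoothed local-background
subtraction from the surrounding annulus.

Coordinates are 0-based ``(row, col)`` pixel indices; sub-pixel positions
refer to pixel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.feature import peak_local_max

from .render import ImageStack, Trace

__all__ = ["SpotLocation", "LocationSet", "DetectionParams", "DriftTrajectory",
           "detect_locations", "correct_drift", "extract_trace"]


@dataclass
class SpotLocation:
    id: int
    klass: str                      # dna | fiducial | impurity | non_dna_control
    row: float
    col: float
    excluded: bool = False
    reason: str = ""

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.row, self.col])


@dataclass
class LocationSet:
    locations: List[SpotLocation] = field(default_factory=list)
    shape: Tuple[int, int] = (0, 0)

    def of_class(self, klass: str, include_excluded: bool = False) -> List[SpotLocation]:
        return [s for s in self.locations
                if s.klass == klass and (include_excluded or not s.excluded)]

    def __len__(self) -> int:
        return len(self.locations)


@dataclass
class DetectionParams:
    threshold_sigma: float = 5.0    # robust (MAD-based) detection threshold
    min_distance: int = 3           # px between local maxima
    coloc_radius: float = 1.5       # px, impurity-exclusion radius
    fiducial_brightness_ratio: float = 2.0  # beads are this much brighter than DNA
    pair_reject_radius: float = 5.0  # px, too-close DNA pairs are excluded
    control_min_dist: float = 5.0   # px, controls kept this far from DNA
    n_controls: int = 1000
    margin: int = 6                 # px, ignore maxima near the border


@dataclass
class DriftTrajectory:
    """Per-frame (drow, dcol) stage offset relative to frame 0."""

    offsets: np.ndarray             # (T, 2)
    residual: float = 0.0           # px, scatter across fiducials

    def __len__(self) -> int:
        return len(self.offsets)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.offsets[i]

    @classmethod
    def identity(cls, n_frames: int) -> "DriftTrajectory":
        return cls(np.zeros((n_frames, 2)), residual=np.nan)


def _robust_threshold(img: np.ndarray, sigma: float) -> float:
    med = np.median(img)
    mad = np.median(np.abs(img - med)) * 1.4826
    return med + sigma * max(mad, 1e-12)


def _centroid_refine(img: np.ndarray, row: int, col: int, half: int = 2) -> np.ndarray:
    """Background-subtracted intensity-weighted centroid in a window.

    The local background is the median of the window border; without
    this subtraction the camera baseline pulls the centroid toward the
    window center and drift displacements are underestimated.
    """
    r0, r1 = max(0, row - half), min(img.shape[0], row + half + 1)
    c0, c1 = max(0, col - half), min(img.shape[1], col + half + 1)
    win = img[r0:r1, c0:c1].astype(float)
    border = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
    win = np.clip(win - np.median(border), 0, None)
    tot = win.sum()
    if tot <= 0:
        return np.array([float(row), float(col)])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return np.array([(win * rr).sum() / tot, (win * cc).sum() / tot])


def _detect_in_image(img: np.ndarray, params: DetectionParams) -> np.ndarray:
    thr = _robust_threshold(img, params.threshold_sigma)
    peaks = peak_local_max(img, min_distance=params.min_distance,
                           threshold_abs=thr, exclude_border=params.margin)
    return np.array([_centroid_refine(img, r, c) for r, c in peaks]).reshape(-1, 2)


def _match(a: np.ndarray, b: np.ndarray, radius: float) -> List[Tuple[int, int]]:
    """Greedy nearest-neighbor matches within ``radius`` between point sets."""
    pairs: List[Tuple[int, int]] = []
    if len(a) == 0 or len(b) == 0:
        return pairs
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    used_b: set = set()
    for i in np.argsort(d.min(axis=1)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= radius and j not in used_b:
            pairs.append((int(i), j))
            used_b.add(j)
    return pairs


def detect_locations(stack: ImageStack,
                     params: Optional[DetectionParams] = None) -> LocationSet:
    """Map DNA, fiducial, impurity, and non-DNA control locations.

    DNA spots are local maxima in the averaged blue reference frames,
    impurities in the averaged green+red reference frames; spots found in
    both are classified as fiducial beads.  DNA locations within the
    colocalization radius of an impurity, or closer than the pair-reject
    radius to another DNA, are kept but flagged excluded.  Control
    locations are sampled on a uniform grid at least ``control_min_dist``
    from every DNA.
    """
    params = params or DetectionParams()
    shape = stack.frames.shape[1:]
    blue = stack.select("blue")
    ref2 = stack.select("greenred")
    if len(blue) == 0:
        raise ValueError("stack contains no blue reference frames")
    blue_avg = blue.mean(axis=0)
    if np.ptp(blue_avg) <= 0:
        warnings.warn("blank reference frames; returning empty location set")
        return LocationSet([], shape)
    blue_pts = _detect_in_image(blue_avg, params)
    other_pts = (_detect_in_image(ref2.mean(axis=0), params)
                 if len(ref2) else np.zeros((0, 2)))

    # Fiducial beads are broadly fluorescent (appear in both reference
    # sets) AND bright; a dim blue/other coincidence is a DNA molecule
    # sitting on a fluorescent impurity, not a bead.
    med = float(np.median(blue_avg))
    bright = np.array([blue_avg[int(round(p[0])), int(round(p[1]))] - med
                       for p in blue_pts]) if len(blue_pts) else np.array([])
    typical = float(np.median(bright)) if len(bright) else 0.0
    fid_pairs = [(i, j) for i, j in _match(blue_pts, other_pts, 2.0)
                 if bright[i] >= params.fiducial_brightness_ratio * typical]
    fid_blue = {i for i, _ in fid_pairs}
    fid_other = {j for _, j in fid_pairs}
    fiducials = [blue_pts[i] for i in sorted(fid_blue)]
    dna = [p for i, p in enumerate(blue_pts) if i not in fid_blue]
    impurities = [p for j, p in enumerate(other_pts) if j not in fid_other]

    locs: List[SpotLocation] = []
    next_id = 0
    dna_arr = np.array(dna).reshape(-1, 2)
    for i, p in enumerate(dna):
        excluded, reason = False, ""
        if any(np.hypot(*(p - q)) <= params.coloc_radius for q in impurities):
            excluded, reason = True, "impurity colocalization"
        else:
            others = np.delete(dna_arr, i, axis=0)
            if len(others) and np.hypot(others[:, 0] - p[0],
                                        others[:, 1] - p[1]).min() < params.pair_reject_radius:
                excluded, reason = True, "unresolved DNA pair"
        locs.append(SpotLocation(next_id, "dna", p[0], p[1], excluded, reason))
        next_id += 1
    for p in fiducials:
        locs.append(SpotLocation(next_id, "fiducial", p[0], p[1]))
        next_id += 1
    for p in impurities:
        locs.append(SpotLocation(next_id, "impurity", p[0], p[1]))
        next_id += 1

    # Uniform-grid non-DNA controls, kept away from every DNA molecule.
    kept_dna = np.array([[s.row, s.col] for s in locs
                         if s.klass == "dna"]).reshape(-1, 2)
    step = max(2, int(np.ceil(np.sqrt(
        (shape[0] - 2 * params.margin) * (shape[1] - 2 * params.margin)
        / max(params.n_controls, 1)))))
    n_ctrl = 0
    for r in range(params.margin, shape[0] - params.margin, step):
        for c in range(params.margin, shape[1] - params.margin, step):
            if n_ctrl >= params.n_controls:
                break
            p = np.array([float(r), float(c)])
            if len(kept_dna) and np.hypot(kept_dna[:, 0] - r,
                                          kept_dna[:, 1] - c).min() < params.control_min_dist:
                continue
            locs.append(SpotLocation(next_id, "non_dna_control", p[0], p[1]))
            next_id += 1
            n_ctrl += 1
    return LocationSet(locs, shape)


def correct_drift(stack: ImageStack, fiducials: Sequence[SpotLocation] | LocationSet,
                  window_half: int = 4, smooth: int = 5) -> DriftTrajectory:
    """Estimate per-frame stage drift from fiducial bead displacements.

    Each bead is tracked by windowed centroid (window recentered on the
    running estimate so large cumulative drift is followed); the
    per-frame translation is the mean displacement across beads, smoothed
    with a running mean, and reported relative to frame 0.
    """
    if isinstance(fiducials, LocationSet):
        fiducials = fiducials.of_class("fiducial")
    n_frames = len(stack.frames)
    if len(fiducials) == 0:
        warnings.warn("no fiducials available; returning identity drift")
        return DriftTrajectory.identity(n_frames)
    disp = np.zeros((n_frames, len(fiducials), 2))
    for j, fid in enumerate(fiducials):
        est = fid.pos.copy()
        for f in range(n_frames):
            r, c = int(round(est[0])), int(round(est[1]))
            cen = _centroid_refine(stack.frames[f], r, c, half=window_half)
            disp[f, j] = cen - fid.pos
            est = cen
    traj = disp.mean(axis=1)
    residual = float(np.mean(disp.std(axis=1))) if len(fiducials) > 1 else 0.0
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        padded = np.pad(traj, ((pad, pad), (0, 0)), mode="edge")
        traj = np.column_stack([np.convolve(padded[:, k], kernel, mode="valid")
                                for k in range(2)])
    traj = traj - traj[0]
    return DriftTrajectory(traj, residual=residual)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < 2:
        return x.copy()
    half = window // 2
    pad = np.pad(x, half, mode="edge")
    return np.array([np.median(pad[i:i + window]) for i in range(len(x))])


def _box_integral(img: np.ndarray, center: Tuple[float, float],
                  half: float) -> float:
    """Integral of the underlying intensity over a box at a fractional center.

    Pixel values are integrals over [i-0.5, i+0.5]; their 2-D cumulative
    sum samples the smooth integral field at pixel corners, which is
    interpolated (bicubic) at the four box corners.  This keeps the
    integrated flux independent of where the box edges fall within a
    pixel, unlike per-pixel overlap weights.
    """
    # remove the flat offset first: the spline boundary handling distorts
    # the (large) bilinear baseline term of the cumulative sum otherwise
    med = float(np.median(img))
    resid = img - med
    cum = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    cum[1:, 1:] = np.cumsum(np.cumsum(resid, axis=0), axis=1)
    # corner (continuous) coordinate x maps to cum index x + 0.5
    r0, r1 = center[0] - half + 0.5, center[0] + half + 0.5
    c0, c1 = center[1] - half + 0.5, center[1] + half + 0.5
    pts = np.array([[r1, r1, r0, r0], [c1, c0, c1, c0]])
    v11, v10, v01, v00 = map_coordinates(cum, pts, order=5, mode="nearest")
    return float(v11 - v10 - v01 + v00) + med * (2 * half) ** 2


def extract_trace(stack: ImageStack, location: SpotLocation,
                  drift: Optional[DriftTrajectory] = None,
                  excitation: str = "red",
                  bg_smooth: int = 9) -> Trace:
    """Integrate a 5x5 window at a (drift-corrected) location per frame.

    The 5x5 window follows the fractional drift-corrected position
    (pixels weighted by their overlap with the window), so sub-pixel
    drift does not modulate the integrated flux.  The background is the
    per-frame median of the 9x9 annulus around the window (scaled to
    25 px), smoothed in time with a running median, then subtracted.  If
    the shifted window leaves the usable field the trace is truncated
    and flagged censored.
    """
    if drift is None:
        drift = DriftTrajectory.identity(len(stack.frames))
    frames_idx = [i for i, e in enumerate(stack.excitation) if e == excitation]
    shape = stack.frames.shape[1:]
    raw = []
    bg = []
    censored = False
    for f in frames_idx:
        pos = location.pos + drift[f]
        r, c = int(round(pos[0])), int(round(pos[1]))
        if r < 4 or c < 4 or r > shape[0] - 5 or c > shape[1] - 5:
            censored = True
            break
        patch = stack.frames[f, r - 4:r + 5, c - 4:c + 5]
        raw.append(_box_integral(patch, (pos[0] - r + 4, pos[1] - c + 4), 2.5))
        # annulus sampled at the fractional position (bilinear), so the
        # background estimate does not breathe as sub-pixel drift accrues
        off = np.arange(-4, 5, dtype=float)
        rr = pos[0] + off
        cc = pos[1] + off
        outer = map_coordinates(stack.frames[f],
                                np.meshgrid(rr, cc, indexing="ij"),
                                order=3, mode="nearest")
        mask = np.ones((9, 9), bool)
        mask[2:7, 2:7] = False
        bg.append(np.median(outer[mask]) * 25.0)
    raw_a = np.asarray(raw)
    bg_a = _running_median(np.asarray(bg), bg_smooth) if len(bg) else np.asarray(bg)
    values = raw_a - bg_a
    t = stack.times[frames_idx][:len(values)]
    dt = float(np.median(np.diff(stack.times[frames_idx]))) if len(frames_idx) > 1 else 1.0
    return Trace(location.id, excitation, values, dt,
                 excitation=excitation,
                 t0=float(t[0]) if len(t) else 0.0,
                 meta={"censored": censored, "class": location.klass})
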