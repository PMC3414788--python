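"""Focal-adhesion segmentation, tracking, filtering and property extraction.

Takes TIRF-like intensity stacks of cells expressing a fluorescent FA marker
(e.g. paxillin-EGFP) and produces per-adhesion records: centroid, area, mean
and integrated intensity, elongation, per frame; plus whole-track summaries
(time-averaged properties, sliding speed, lifetime) and per-frame FA counts
per cell.

Conventions
-----------
* Segmentation: the cell is the largest connected component above an Otsu
  threshold of a heavily smoothed frame (holes filled).  FAs are detected on
  a high-pass filtered frame (frame minus a wide Gaussian background)
  thresholded inside the cell mask, then each detected spot is re-delineated
  at half of its own background-subtracted peak so areas follow the
  half-maximum convention regardless of spot brightness.
* Filters: components under 3 px are discarded at segmentation time; tracks
  whose time-averaged area falls outside [0.05, 10] um^2 are excluded
  (boundary values retained).
* Lifetime: (last_frame - first_frame + 1) * frame_interval.  Tracks touching
  the first or last movie frame are censored: their lifetimes are excluded
  from lifetime statistics, other properties are retained.
* FA intensity: background-subtracted mean pixel intensity inside the FA
  region, multiplied by the movie's calibration ``intensity_scale``.
* Sliding speed: mean frame-to-frame centroid displacement rate, um/hr.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian
from skimage.morphology import h_maxima
from skimage.restoration import estimate_sigma
from skimage.segmentation import watershed
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "FAMovie",
    "FATrack",
    "segment_cell",
    "segment_fas",
    "track_fas",
    "filter_fas",
    "summarize_fa_properties",
    "fa_number_per_cell",
    "qc_intensity_drift",
    "analyze_fa_movie",
]

MIN_FA_PIXELS = 3  # components below this (after smoothing correction) are noise
MIN_FA_AREA_UM2 = 0.05
MAX_FA_AREA_UM2 = 10.0
DETECT_SIGMA_PX = 1.0  # detection pre-smoothing, px
SIZING_SIGMA_PX = 2.0  # sizing pre-smoothing, px (corrected in shape measures)
_HALFMAX_MEAN = (1.0 - 0.5) / math.log(2.0)  # Gaussian mean over half-max region / peak


@dataclass
class FAMovie:
    """An intensity image stack with calibration metadata.

    frames : (T, H, W) array; pixel_size in um/px; frame_interval in s;
    intensity_scale is a dimensionless calibration factor applied to all
    reported FA intensities (stand-in for a fixed laser-power/exposure
    reference condition).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    intensity_scale: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a (T>=2, H, W) stack")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FATrack:
    """One focal adhesion's per-frame record across its lifetime.

    Per-frame arrays are aligned with ``frames`` (movie frame indices,
    contiguous after gap closing; gap frames carry interpolated centroids and
    NaN measurements).  Centroids are in um, areas in um^2, elongation is the
    major/minor axis ratio of the equivalent ellipse (>= 1).
    """

    fa_id: object
    frames: np.ndarray
    centroids: np.ndarray  # (n, 2) um, (x, y)
    areas: np.ndarray  # um^2
    mean_intensities: np.ndarray
    integrated_intensities: np.ndarray
    elongations: np.ndarray
    censored_start: bool = False
    censored_end: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.mean_intensities = np.asarray(self.mean_intensities, dtype=float)
        self.integrated_intensities = np.asarray(self.integrated_intensities, dtype=float)
        self.elongations = np.asarray(self.elongations, dtype=float)

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def n_frames(self) -> int:
        return self.frames.size

    def lifetime_s(self, frame_interval: float) -> float:
        return (self.last_frame - self.first_frame + 1) * frame_interval

    def mean_area(self) -> float:
        return float(np.nanmean(self.areas))

    def mean_intensity(self) -> float:
        return float(np.nanmean(self.mean_intensities))

    def mean_elongation(self) -> float:
        return float(np.nanmean(self.elongations))

    def sliding_speed_um_hr(self, frame_interval: float) -> float:
        """Mean centroid displacement rate along the track, um/hr (NaN if 1 frame).

        Estimated as the length-weighted mean of linear-fit velocities over
        windows of up to 15 frames.  Naive frame-to-frame differencing is
        dominated by centroid localization jitter when the per-frame slide is
        deeply sub-pixel; the windowed fit recovers the same quantity for
        quasi-straight sliding while suppressing the jitter.
        """
        if self.n_frames < 2:
            return float("nan")
        c = self.centroids
        n = c.shape[0]
        if n == 2:
            step = np.linalg.norm(c[1] - c[0])
            return float(step / ((self.frames[1] - self.frames[0]) * frame_interval)
                         * 3600.0)
        t_s = self.frames * frame_interval
        # chunks of up to 15 frames; a short trailing chunk merges backwards
        edges = list(range(0, n, 15))
        if n - edges[-1] < 5 and len(edges) > 1:
            edges.pop()
        edges.append(n)
        speeds, weights = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            tt = t_s[lo:hi]
            m = hi - lo
            sxx = float(np.sum((tt - tt.mean()) ** 2))
            (vx, bx) = np.polyfit(tt, c[lo:hi, 0], 1)
            (vy, by) = np.polyfit(tt, c[lo:hi, 1], 1)
            speed2 = vx**2 + vy**2
            if m > 2 and sxx > 0:
                # debias: localization jitter adds Var(slope) per axis to the
                # squared speed; estimate it from the fit residuals
                rx = c[lo:hi, 0] - (vx * tt + bx)
                ry = c[lo:hi, 1] - (vy * tt + by)
                var_slope = (float(rx @ rx) + float(ry @ ry)) / (2 * (m - 2)) / sxx
                speed2 = max(speed2 - 2.0 * var_slope, 0.0)
            speeds.append(math.sqrt(speed2))
            weights.append(m)
        return float(np.average(speeds, weights=weights) * 3600.0)


def segment_cell(frame: np.ndarray, pixel_size: float, smooth_um: float = 1.2,
                 min_cell_area_um2: float = 20.0):
    """Whole-cell binary mask: threshold of a heavily smoothed frame.

    The background level is anchored on the image border (lower quartile of
    the smoothed border strip -- the imaged cell is assumed not to fill the
    field of view), the foreground level on the upper quartile of pixels
    clearly above background; the threshold is their midpoint, which places
    the boundary of a blur-smeared intensity step at its true position and
    is insensitive to bright adhesion halos inside the cell.  The largest
    connected component is kept, holes filled.  Frames with no foreground
    contrast above the noise, or whose largest component is smaller than a
    plausible cell (``min_cell_area_um2``), yield an empty mask with a
    warning.  All statistics are relative, so the mask is invariant to
    positive rescaling of the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if np.ptp(frame) == 0:
        warnings.warn("frame has no contrast; returning empty cell mask")
        return np.zeros(frame.shape, dtype=bool)
    sigma = smooth_um / pixel_size
    smoothed = gaussian(frame, sigma=sigma, preserve_range=True)
    strip = np.concatenate([
        smoothed[:3].ravel(), smoothed[-3:].ravel(),
        smoothed[3:-3, :3].ravel(), smoothed[3:-3, -3:].ravel(),
    ])
    bg = float(np.quantile(strip, 0.25))
    # white-noise sd surviving the smoothing (border-strip statistics are
    # boundary-inflated and spatially correlated, so derive it analytically)
    noise_sm = float(estimate_sigma(frame)) / math.sqrt(4.0 * math.pi * sigma**2)
    # pixels clearly above background: above the noise and above 10% of the
    # background-to-bright dynamic range (so smoothing tails near the
    # background level cannot dominate the foreground histogram)
    rel_floor = 0.1 * (float(np.quantile(smoothed, 0.99)) - bg)
    fg0 = smoothed > bg + max(4.0 * noise_sm, rel_floor, 1e-6 * np.ptp(smoothed))
    if not fg0.any():
        warnings.warn("no foreground above noise; returning empty cell mask")
        return np.zeros(frame.shape, dtype=bool)
    # foreground level = modal smoothed intensity above background: the
    # histogram peak tracks the cell's cytoplasmic plateau and ignores both
    # the boundary ramp and bright adhesion halos
    vals = smoothed[fg0]
    counts, edges = np.histogram(vals, bins=100)
    fg_level = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    t = 0.5 * (bg + fg_level)
    fg = smoothed > t
    if not fg.any() or fg.all():
        warnings.warn("degenerate threshold; returning empty cell mask")
        return np.zeros(frame.shape, dtype=bool)
    contrast = smoothed[fg].mean() - smoothed[~fg].mean()
    if noise_sm > 0 and contrast < 4.0 * noise_sm:
        warnings.warn("no foreground above noise; returning empty cell mask")
        return np.zeros(frame.shape, dtype=bool)
    lab = cc_label(fg)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(lab == largest)
    if mask.sum() * pixel_size**2 < min_cell_area_um2:
        warnings.warn("largest component below plausible cell size; "
                      "returning empty cell mask")
        return np.zeros(frame.shape, dtype=bool)
    return mask


def _halfmax_refine(size_hp: np.ndarray, labels: np.ndarray,
                    noise_sigma: float = 0.0):
    """Re-delineate each detected spot at half of its own peak value.

    A single global threshold sizes bright and dim spots inconsistently;
    re-thresholding each component at half its background-subtracted peak
    makes areas follow the half-maximum convention.  The refined region is
    grown within a padded neighborhood of the original component and kept
    connected to the peak; the refinement threshold never drops below
    3x the noise level, so near-noise detections cannot balloon.
    """
    out = np.zeros_like(labels)
    next_id = 0
    for region in regionprops(labels):
        rid = region.label
        pad = 8
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
        r1, c1 = min(r1 + pad, labels.shape[0]), min(c1 + pad, labels.shape[1])
        sub = size_hp[r0:r1, c0:c1]
        submask = labels[r0:r1, c0:c1] == rid
        peak = sub[submask].max()
        if peak <= 0:
            continue
        # the max of the (spatially correlated) sizing field over one spot
        # overshoots the true peak by about half a sd, which would shrink the
        # half-maximum region for dim spots
        peak_est = max(peak - 0.5 * noise_sigma, 0.5 * peak)
        cand = sub >= max(0.5 * peak_est, 3.0 * noise_sigma)
        # keep other components out of the neighborhood
        cand &= (labels[r0:r1, c0:c1] == 0) | submask
        # keep only the piece connected to this component's peak
        cand_lab = cc_label(cand, connectivity=2)
        seed = np.unravel_index(np.argmax(np.where(submask, sub, -np.inf)), sub.shape)
        keep = cand_lab[seed]
        if keep == 0:
            continue
        final = cand_lab == keep
        next_id += 1
        out[r0:r1, c0:c1][final & (out[r0:r1, c0:c1] == 0)] = next_id
    return out


def segment_fas(
    frame: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float,
    highpass_sigma_um: float = 2.0,
    min_pixels: int = MIN_FA_PIXELS,
    refine_halfmax: bool = True,
) -> np.ndarray:
    """Label mask of focal adhesions within the cell.

    High-pass filter (frame minus a wide Gaussian background) thresholded
    inside the cell mask at max(5x the estimated pixel noise, 2% of the
    in-cell high-pass maximum) -- a detection threshold that keeps dim
    assembling/disassembling adhesions while excluding isolated noise
    pixels.  Connected components with fewer than ``min_pixels`` pixels are
    removed (sub-resolution detections).  With ``refine_halfmax`` each spot
    is then re-delineated at half of its own peak, so areas follow the
    half-maximum convention independent of spot brightness.
    """
    frame = np.asarray(frame, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    labels = np.zeros(frame.shape, dtype=np.int32)
    if not cell_mask.any():
        return labels
    # shrink the working region: background estimation right at the cell
    # boundary mixes intra- and extracellular levels and leaves step
    # residuals that masquerade as adhesions
    cell_mask = ndimage.binary_erosion(cell_mask, iterations=5)
    if not cell_mask.any():
        return labels
    sigma = highpass_sigma_um / pixel_size
    noise_raw = float(estimate_sigma(frame))

    # pass 1: background from all in-cell pixels; pass 2: background from
    # non-adhesion pixels only, because a spot's own mass in the background
    # estimate would subtract a broad hump under the spot and shrink its
    # half-maximum region
    lab, highpass, noise, fg = _detect_spots(
        frame, cell_mask, cell_mask, sigma, noise_raw)
    if lab.max() > 0:
        fa_pixels = ndimage.binary_dilation(fg, iterations=3)
        support = cell_mask & ~fa_pixels
        if support.sum() > 0.05 * cell_mask.sum():
            lab, highpass, noise, fg = _detect_spots(
                frame, support, cell_mask, sigma, noise_raw)
    if lab.max() == 0:
        return labels
    if refine_halfmax:
        # delineate each spot at half of its own peak on a slightly more
        # smoothed image (stable region boundaries under noise); the extra
        # widening is removed analytically from area and elongation
        size_hp = gaussian(highpass, sigma=SIZING_SIGMA_PX, preserve_range=True)
        noise_size = noise_raw / math.sqrt(4.0 * math.pi * SIZING_SIGMA_PX**2)
        lab = _halfmax_refine(size_hp, lab, noise_sigma=noise_size)
        lab = _drop_small_corrected(lab, min_pixels, SIZING_SIGMA_PX)
    else:
        sizes = np.bincount(lab.ravel())
        small = np.nonzero(sizes < min_pixels)[0]
        lab = np.where(np.isin(lab, small), 0, lab)
        lab = cc_label(lab > 0, connectivity=2)
    return lab.astype(np.int32)


def _corrected_ellipse(region, sigma_px: float):
    """(area_px, elongation) of a region with the sizing smear removed.

    The half-maximum region of a Gaussian spot smoothed by ``sigma_px`` is an
    ellipse whose per-axis variances exceed the spot's by sigma_px^2; the
    correction subtracts 2 ln2 sigma_px^2 from each squared semi-axis.  The
    semi-axis product comes from the hole-filled pixel count (robust to
    noise-raggedness of the boundary, which inflates moment-based axes), the
    axis ratio from the region moments.  Returns None when the correction
    degenerates (region at the smoothing scale).
    """
    c = 2.0 * math.log(2.0) * sigma_px**2
    sa = region.axis_major_length / 2.0
    sb = region.axis_minor_length / 2.0
    if sb <= 0:
        return None
    ratio = sa / sb
    # raw (unfilled) pixel count: noise flips boundary pixels in and interior
    # pixels out at matching rates, so the count stays unbiased where the
    # moment-based axes inflate
    prod = float(region.area) / math.pi  # = sa * sb for an ellipse
    u, v = prod * ratio - c, prod / ratio - c
    if v <= 0.25:
        return None
    return math.pi * math.sqrt(u * v), max(math.sqrt(u / v), 1.0)


def _drop_small_corrected(labels, min_pixels: int, sigma_px: float):
    """Remove components whose smear-corrected area is below ``min_pixels``."""
    out = np.zeros_like(labels)
    next_id = 0
    for region in regionprops(labels):
        ce = _corrected_ellipse(region, sigma_px)
        # a degenerate correction means the object is at or below the
        # smoothing scale, i.e. an unresolved sub-pixel detection
        area = ce[0] if ce is not None else 0.0
        if area < min_pixels:
            continue
        next_id += 1
        out[labels == region.label] = next_id
    return out


def _detect_spots(frame, support_mask, cell_mask, sigma, noise_raw):
    """One background-subtract / detect / watershed pass.

    The background is a normalized convolution over ``support_mask`` (so the
    cell-boundary step and, on the second pass, the adhesions themselves do
    not bleed into it).  Detection happens on a lightly smoothed high-pass
    image -- a matched-filter-like step that lifts spot peaks above the
    per-pixel noise floor.  Touching spots are split by watershed from
    h-maxima markers: only maxima with prominence above the smoothed noise
    seed a region, so noise wiggles on one spot do not split it.

    Returns ``(labels, highpass, smoothed_noise_sd, detection_mask)``.
    """
    zeros = np.zeros(frame.shape, dtype=np.int32)
    mask_f = support_mask.astype(float)
    den = gaussian(mask_f, sigma=sigma, preserve_range=True)
    num = gaussian(frame * mask_f, sigma=sigma, preserve_range=True)
    background = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
    highpass = np.where(cell_mask, frame - background, 0.0)
    smooth_hp = gaussian(highpass, sigma=DETECT_SIGMA_PX, preserve_range=True)
    smooth_hp = np.where(cell_mask, smooth_hp, 0.0)
    vals = smooth_hp[cell_mask]
    noise = noise_raw / math.sqrt(4.0 * math.pi * DETECT_SIGMA_PX**2)
    if np.ptp(vals) == 0 or vals.max() <= 0:
        return zeros, highpass, noise, np.zeros(frame.shape, dtype=bool)
    # floors: relative to spot contrast, and to the frame scale (a blank
    # frame's float-precision ripple must not count as foreground).  6 sd
    # keeps the per-movie count of noise-blob detections near zero while
    # typical adhesion peaks sit far above it
    t = max(6.0 * noise, 1e-3 * float(np.ptp(vals)),
            1e-9 * max(float(np.abs(frame).max()), 1.0))
    fg = smooth_hp > t
    lab = cc_label(fg, connectivity=2)
    if lab.max() == 0:
        return zeros, highpass, noise, fg
    h = max(4.0 * noise, 1e-4 * float(vals.max()))
    maxima = h_maxima(np.where(fg, smooth_hp, 0.0), h) & fg
    markers = cc_label(maxima, connectivity=2)
    if markers.max():
        lab = watershed(-smooth_hp, markers=markers, mask=fg,
                        connectivity=2).astype(np.int32)
    return lab, highpass, noise, fg


@dataclass
class _ActiveTrack:
    fa_id: int
    frames: list
    centroids_px: list  # (row, col)
    areas: list
    means: list
    integrated: list
    elong: list
    last_label: int
    last_frame: int
    misses: int = 0


def _measure(labels: np.ndarray, intensity: np.ndarray | None,
             detect_sigma_px: float = 0.0):
    """regionprops keyed by label; elongation from equivalent-ellipse axes.

    Centroids are intensity-weighted when intensities are available: binary
    centroids of small rasterized regions jitter by a sizeable fraction of a
    pixel frame to frame, which would dominate sub-pixel sliding speeds.
    ``detect_sigma_px`` removes the widening introduced by the detection
    pre-smoothing from areas and elongations (each equivalent-ellipse
    variance shrinks by the smoothing variance).
    """
    if intensity is not None:
        intensity = np.clip(intensity, 0.0, None)
    props = {}
    for r in regionprops(labels, intensity_image=intensity):
        ce = _corrected_ellipse(r, detect_sigma_px) if detect_sigma_px > 0 else None
        if ce is not None:
            area, elong = ce
        else:
            sa = r.axis_major_length / 2.0
            sb = r.axis_minor_length / 2.0
            area = float(r.area)
            elong = max(sa / max(sb, 1e-9), 1.0)
        if intensity is not None:
            mean_i = float(r.intensity_mean)
            integ = mean_i * r.area
            if ce is not None and area > 0:
                # the measured region is the half-maximum region of the
                # *smoothed* spot, i.e. larger than the true half-maximum
                # region by the ratio r.area/area; the mean of a Gaussian
                # over a Mahalanobis region q <= q0 is peak (1-e^{-q0/2})
                # / (q0/2), so rescale to the q0 = 2 ln 2 convention
                q0 = 2.0 * math.log(2.0) * float(r.area) / area
                g = (1.0 - math.exp(-q0 / 2.0)) / (q0 / 2.0)
                mean_i *= _HALFMAX_MEAN / g
            centroid = tuple(r.centroid_weighted)
        else:
            mean_i = np.nan
            integ = np.nan
            centroid = r.centroid
        props[r.label] = dict(
            centroid=centroid, area=area, mean=mean_i, integrated=integ,
            elongation=elong,
        )
    return props


def track_fas(
    label_stack,
    frame_interval: float,
    pixel_size: float,
    intensity_frames=None,
    max_disp_um: float = 1.0,
    gap_frames: int = 1,
    intensity_scale: float = 1.0,
    detect_sigma_px: float = 0.0,
) -> list[FATrack]:
    """Link per-frame FA label masks into tracks.

    Frame-to-frame greedy assignment by maximal pixel overlap with the
    previous frame's components, falling back to nearest centroid within
    ``max_disp_um``; ties broken by smaller area change.  Components with no
    match start new tracks; tracks unmatched for more than ``gap_frames``
    frames are closed.  ``intensity_frames``, when given, must be
    background-subtracted; measured means are multiplied by
    ``intensity_scale``.
    """
    label_stack = [np.asarray(m) for m in label_stack]
    if len(label_stack) < 2:
        raise ValueError("need label masks for at least 2 frames")
    shape = label_stack[0].shape
    for i, m in enumerate(label_stack):
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch at frame {i}: {m.shape} vs {shape}")
    n_frames = len(label_stack)
    max_disp_px = max_disp_um / pixel_size

    def intensity_at(t):
        if intensity_frames is None:
            return None
        return np.asarray(intensity_frames[t], dtype=float)

    finished: list[_ActiveTrack] = []
    active: list[_ActiveTrack] = []
    next_id = 0

    props0 = _measure(label_stack[0], intensity_at(0), detect_sigma_px)
    for lbl, p in sorted(props0.items()):
        next_id += 1
        active.append(
            _ActiveTrack(next_id, [0], [p["centroid"]], [p["area"]], [p["mean"]],
                         [p["integrated"]], [p["elongation"]], lbl, 0)
        )

    for t in range(1, n_frames):
        labels = label_stack[t]
        props = _measure(labels, intensity_at(t), detect_sigma_px)
        cur_ids = sorted(props.keys())
        # overlap counts between previous assignment and current labels
        candidates = []  # (neg_overlap, area_change, track_idx, cur_label)
        prev_labels = label_stack[t - 1]
        for ti, tr in enumerate(active):
            if tr.last_frame == t - 1:
                prev_mask = prev_labels == tr.last_label
                cur_under = labels[prev_mask]
                counts = np.bincount(cur_under[cur_under > 0], minlength=0)
                for lbl in np.nonzero(counts)[0]:
                    candidates.append(
                        (-int(counts[lbl]), abs(props[lbl]["area"] - tr.areas[-1]),
                         ti, int(lbl))
                    )
        candidates.sort()
        assigned_tracks, assigned_labels = set(), set()
        matches = {}
        for negov, darea, ti, lbl in candidates:
            if ti in assigned_tracks or lbl in assigned_labels:
                continue
            assigned_tracks.add(ti)
            assigned_labels.add(lbl)
            matches[ti] = lbl
        # centroid fallback for tracks (incl. gapped) and labels still free
        free_labels = [l for l in cur_ids if l not in assigned_labels]
        dist_candidates = []
        for ti, tr in enumerate(active):
            if ti in assigned_tracks:
                continue
            gap = t - tr.last_frame  # 1 = consecutive
            if gap > gap_frames + 1:
                continue
            cy, cx = tr.centroids_px[-1]
            for lbl in free_labels:
                py, px = props[lbl]["centroid"]
                d = np.hypot(py - cy, px - cx)
                if d <= max_disp_px * gap:
                    dist_candidates.append(
                        (d, abs(props[lbl]["area"] - tr.areas[-1]), ti, lbl)
                    )
        dist_candidates.sort()
        for d, darea, ti, lbl in dist_candidates:
            if ti in assigned_tracks or lbl in assigned_labels:
                continue
            assigned_tracks.add(ti)
            assigned_labels.add(lbl)
            matches[ti] = lbl

        new_active = []
        for ti, tr in enumerate(active):
            if ti in matches:
                lbl = matches[ti]
                p = props[lbl]
                # fill gap frames with interpolated centroid, NaN measurements
                for gf in range(tr.last_frame + 1, t):
                    w = (gf - tr.last_frame) / (t - tr.last_frame)
                    cy = tr.centroids_px[-1][0] * (1 - w) + p["centroid"][0] * w
                    cx = tr.centroids_px[-1][1] * (1 - w) + p["centroid"][1] * w
                    tr.frames.append(gf)
                    tr.centroids_px.append((cy, cx))
                    tr.areas.append(np.nan)
                    tr.means.append(np.nan)
                    tr.integrated.append(np.nan)
                    tr.elong.append(np.nan)
                tr.frames.append(t)
                tr.centroids_px.append(p["centroid"])
                tr.areas.append(p["area"])
                tr.means.append(p["mean"])
                tr.integrated.append(p["integrated"])
                tr.elong.append(p["elongation"])
                tr.last_label = lbl
                tr.last_frame = t
                tr.misses = 0
                new_active.append(tr)
            else:
                tr.misses += 1
                if tr.misses > gap_frames:
                    finished.append(tr)
                else:
                    new_active.append(tr)
        for lbl in cur_ids:
            if lbl in assigned_labels:
                continue
            p = props[lbl]
            next_id += 1
            new_active.append(
                _ActiveTrack(next_id, [t], [p["centroid"]], [p["area"]], [p["mean"]],
                             [p["integrated"]], [p["elongation"]], lbl, t)
            )
        active = new_active
    finished.extend(active)
    finished.sort(key=lambda tr: tr.fa_id)

    px_area = pixel_size**2
    tracks = []
    for tr in finished:
        cents = np.array([(c[1] * pixel_size, c[0] * pixel_size) for c in tr.centroids_px])
        tracks.append(
            FATrack(
                fa_id=tr.fa_id,
                frames=np.array(tr.frames),
                centroids=cents,
                areas=np.array(tr.areas, dtype=float) * px_area,
                mean_intensities=np.array(tr.means, dtype=float) * intensity_scale,
                integrated_intensities=np.array(tr.integrated, dtype=float)
                * intensity_scale * px_area,
                elongations=np.array(tr.elong, dtype=float),
                censored_start=tr.frames[0] == 0,
                censored_end=tr.frames[-1] == n_frames - 1,
            )
        )
    return tracks


def filter_fas(
    tracks,
    min_area: float = MIN_FA_AREA_UM2,
    max_area: float = MAX_FA_AREA_UM2,
) -> list[FATrack]:
    """Exclude tracks whose time-averaged area lies outside [min_area, max_area].

    Boundary values are retained.  Sub-minimum regions are unresolved
    detections; super-maximum ones are likely clusters of several adhesions.
    """
    if min_area >= max_area:
        raise ValueError(f"min_area {min_area} must be < max_area {max_area}")
    return [t for t in tracks if min_area <= t.mean_area() <= max_area]


def summarize_fa_properties(tracks, frame_interval: float) -> pd.DataFrame:
    """Per-FA time-averaged property table.

    One row per track: mean intensity, area (um^2), elongation, sliding speed
    (um/hr, NaN for single-frame tracks), lifetime (s) and censoring flags.
    Censored lifetimes should be excluded from lifetime distributions; the
    other columns remain usable.
    """
    rows = []
    for t in tracks:
        rows.append(
            dict(
                fa_id=t.fa_id,
                mean_intensity=t.mean_intensity(),
                area_um2=t.mean_area(),
                elongation=t.mean_elongation(),
                slide_um_per_hr=t.sliding_speed_um_hr(frame_interval),
                lifetime_s=t.lifetime_s(frame_interval),
                censored_start=t.censored_start,
                censored_end=t.censored_end,
                censored=t.censored_start or t.censored_end,
                n_frames=t.n_frames,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fa_id", "mean_intensity", "area_um2", "elongation",
            "slide_um_per_hr", "lifetime_s", "censored_start", "censored_end",
            "censored", "n_frames",
        ],
    )


def fa_number_per_cell(tracks, n_frames: int) -> np.ndarray:
    """Per-frame count of (filtered) FAs live in each movie frame.

    The full per-frame sequence, not its mean, enters the number-per-cell
    distribution: each time point is one measurement.
    """
    counts = np.zeros(n_frames, dtype=int)
    for t in tracks:
        counts[t.frames] += 1
    return counts


def qc_intensity_drift(movie: FAMovie, cell_masks, tolerance: float = 0.10):
    """Photobleaching QC: slope of whole-cell mean intensity versus time.

    Returns ``(slope_per_s, fractional_loss, flagged)``.  Flagged when the
    fitted fractional intensity loss over the movie exceeds ``tolerance``
    (default 10%); beyond that, intensity-based comparisons need a bleaching
    correction.
    """
    if movie.n_frames < 10:
        raise ValueError("drift QC needs at least 10 frames")
    means = []
    for frame, mask in zip(movie.frames, cell_masks):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty cell mask in drift QC")
        means.append(float(frame[mask].mean()))
    times = np.arange(movie.n_frames) * movie.frame_interval
    slope, intercept = np.polyfit(times, means, 1)
    if intercept <= 0:
        raise ValueError("non-positive fitted baseline intensity")
    frac_loss = -slope * times[-1] / intercept
    return float(slope), float(frac_loss), bool(frac_loss > tolerance)


def analyze_fa_movie(
    movie: FAMovie,
    min_area: float = MIN_FA_AREA_UM2,
    max_area: float = MAX_FA_AREA_UM2,
    max_disp_um: float = 1.0,
    gap_frames: int = 1,
    cell_smooth_um: float = 1.2,
    highpass_sigma_um: float = 2.0,
):
    """Run the whole per-movie pipeline: segment, track, filter, summarize.

    Returns a dict with keys ``cell_masks``, ``label_masks``, ``tracks``
    (filtered), ``all_tracks``, ``summary`` (DataFrame), ``counts`` (per-frame
    FA number per cell) and ``qc`` (bleaching drift record or None).

    The intensity handed to the tracker is background-subtracted per frame:
    the median intensity of in-cell, non-FA pixels is the local background.
    """
    cell_masks, label_masks, intensity_frames = [], [], []
    for frame in movie.frames:
        cmask = segment_cell(frame, movie.pixel_size, smooth_um=cell_smooth_um)
        labels = segment_fas(frame, cmask, movie.pixel_size,
                             highpass_sigma_um=highpass_sigma_um)
        inside = cmask & (labels == 0)
        bg = float(np.median(frame[inside])) if inside.any() else float(np.median(frame))
        cell_masks.append(cmask)
        label_masks.append(labels)
        intensity_frames.append(np.asarray(frame, dtype=float) - bg)
    all_tracks = track_fas(
        label_masks, movie.frame_interval, movie.pixel_size,
        intensity_frames=intensity_frames, max_disp_um=max_disp_um,
        gap_frames=gap_frames, intensity_scale=movie.intensity_scale,
        detect_sigma_px=SIZING_SIGMA_PX,
    )
    tracks = filter_fas(all_tracks, min_area=min_area, max_area=max_area)
    summary = summarize_fa_properties(tracks, movie.frame_interval)
    counts = fa_number_per_cell(tracks, movie.n_frames)
    qc = None
    if movie.n_frames >= 10 and all(m.any() for m in cell_masks):
        slope, frac_loss, flagged = qc_intensity_drift(movie, cell_masks)
        qc = dict(slope_per_s=slope, fractional_loss=frac_loss, flagged=flagged)
    return dict(
        cell_masks=np.array(cell_masks),
        label_masks=np.array(label_masks),
        tracks=tracks,
        all_tracks=all_tracks,
        summary=summary,
        counts=counts,
        qc=qc,
    )
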