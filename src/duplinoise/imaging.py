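"""Nuclear-localization quantification from time-lapse fluorescence stacks.

The measure follows a matched-filter scheme: each cell's masked image is
filtered with a nucleus-shaped disk, the maximal filter response defines a
hypothetical nucleus centre, and the localization ratio is the mean
intensity inside that disk divided by the mean over the remaining cell
pixels. Because it is a ratio of means over the same frame, the measure is
invariant to global illumination scaling.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .datatypes import CellRecord, ImageStack, ParameterError, TraceSet


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_frames(
    stack: ImageStack, median_size: int = 3, background_size: int = 50
) -> ImageStack:
    """Median-filter, background-subtract, and patch missing frames.

    Each fluorescence frame gets a 3x3 median filter followed by subtraction
    of a 50x50 mean-filtered copy (a local background estimate; negative
    values are allowed). Missing frames are replaced by the mean of their two
    adjacent processed frames; a missing first/last frame, or two adjacent
    missing frames, cannot be interpolated and raise.
    """
    T = stack.n_frames
    if T < 3:
        raise ParameterError("need at least 3 frames")
    missing = stack.missing_frames
    for i in missing:
        if i == 0 or i == T - 1:
            raise ParameterError(f"missing frame {i} at the stack boundary")
        if i - 1 in missing or i + 1 in missing:
            raise ParameterError(f"missing frames adjacent to {i}; cannot interpolate")

    out = {}
    for ch, movie in stack.frames.items():
        proc = np.empty_like(movie, dtype=float)
        for t in range(T):
            if t in missing:
                continue
            f = ndimage.median_filter(movie[t], size=median_size)
            bg = ndimage.uniform_filter(f, size=background_size)
            proc[t] = f - bg
        for t in sorted(missing):
            proc[t] = 0.5 * (proc[t - 1] + proc[t + 1])
        out[ch] = proc
    return ImageStack(frames=out, frame_interval=stack.frame_interval, missing_frames=frozenset())


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk of the given pixel radius (the nucleus-shaped filter)."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


def gaussian_footprint_weights(radius: int) -> np.ndarray:
    """Gaussian alternative to the uniform disk (sigma = radius / 2)."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    w = np.exp(-(yy**2 + xx**2) / (2.0 * (r / 2.0) ** 2))
    return w / w.sum()


# ---------------------------------------------------------------------------
# Localization trace extraction
# ---------------------------------------------------------------------------

def nuclear_localization_trace(
    stack: ImageStack,
    cell: CellRecord,
    channel: str,
    nucleus_radius_px: int = 3,
    shape: str = "disk",
) -> np.ndarray:
    """Per-frame nucleus/cytoplasm mean-intensity ratio for one cell.

    Per frame: the within-mask image is filtered with a disk of radius
    ``nucleus_radius_px`` (mean over in-mask disk pixels); the maximal
    filtered coordinate inside the mask (ties broken toward the smallest
    row-major coordinate) defines the hypothetical nucleus centre; the ratio
    is the mean over disk pixels clipped to the mask divided by the mean
    over the mask pixels outside the disk.
    """
    mask = cell.mask
    if shape == "disk":
        foot = disk_footprint(nucleus_radius_px).astype(float)
    elif shape == "gaussian":
        foot = gaussian_footprint_weights(nucleus_radius_px)
    else:
        raise ParameterError(f"unknown filter shape {shape!r}")
    disk = disk_footprint(nucleus_radius_px)
    if mask.sum() <= disk.sum():
        raise ParameterError("cell mask smaller than the nucleus filter")

    movie = stack.frames[channel]
    T = movie.shape[0]
    maskf = mask.astype(float)
    denom = ndimage.correlate(maskf, foot, mode="constant")
    r = nucleus_radius_px
    H, W = mask.shape
    yy, xx = np.mgrid[0:H, 0:W]

    trace = np.empty(T)
    for t in range(T):
        img = movie[t]
        num = ndimage.correlate(img * maskf, foot, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            filt = np.where(denom > 0, num / denom, -np.inf)
        filt[~mask] = -np.inf
        centre = np.unravel_index(int(np.argmax(filt)), filt.shape)  # first max = row-major tiebreak
        nucleus = ((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= r**2) & mask
        cytoplasm = mask & ~nucleus
        if not cytoplasm.any():
            raise ParameterError("cytoplasm pixel set is empty")
        trace[t] = img[nucleus].mean() / img[cytoplasm].mean()
    return trace


def extract_traces(
    stacks: dict,
    cells: list[CellRecord],
    nucleus_radius_px: int = 3,
    shape: str = "disk",
) -> TraceSet:
    """Run :func:`nuclear_localization_trace` over cells x channels."""
    raw = {}
    for ch, stack in stacks.items():
        raw[ch] = np.vstack(
            [nuclear_localization_trace(stack, c, ch, nucleus_radius_px, shape) for c in cells]
        )
    return TraceSet(raw=raw, cell_ids=np.array([c.cell_id for c in cells]))


def normalize_traces(ts: TraceSet) -> TraceSet:
    """Min-normalize and z-score each cell's ratio series.

    normalized = raw / min(raw) (so each cell's minimum is exactly 1 and the
    series reads as signal-to-noise over the cell's own baseline);
    zscored = (normalized - mean) / SD; amplitude = max(normalized).
    Constant series get NaN z-scores and are excluded from correlations.
    """
    if ts.n_frames < 2:
        raise ParameterError("series length must be >= 2")
    normalized, zscored, amplitude = {}, {}, {}
    for ch, arr in ts.raw.items():
        mins = arr.min(axis=1, keepdims=True)
        if np.any(mins <= 0):
            raise ParameterError("ratio series must be strictly positive to min-normalize")
        norm = arr / mins
        mean = norm.mean(axis=1, keepdims=True)
        sd = norm.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (norm - mean) / sd, np.nan)
        normalized[ch] = norm
        zscored[ch] = z
        amplitude[ch] = norm.max(axis=1)
    return TraceSet(
        raw=ts.raw, cell_ids=ts.cell_ids, frame_interval=ts.frame_interval,
        normalized=normalized, zscored=zscored, amplitude=amplitude,
    )


# ---------------------------------------------------------------------------
# Cell filtering
# ---------------------------------------------------------------------------

def filter_cells(
    traces: TraceSet,
    cells: list[CellRecord],
    amp_low: float = 1.1,
    amp_high: float = 6.0,
    score_min: float = 8.0,
    frac: float = 0.10,
    mad_k: float = 3.0,
    require_from_start: bool = True,
) -> tuple[list, dict]:
    """Two-round quality filter; returns kept cell ids + rejection reasons.

    Round 1 (structural): a cell is removed when (a) its area leaves the
    band median +/- mad_k * mean-absolute-deviation (computed across cells,
    per frame) on at least ``frac`` of frames, (b) its segmentation score
    falls below ``score_min`` on at least ``frac`` of frames, or (c) it is
    absent at the first frame. Round 2 (dynamic): survivors with response
    amplitude (max of the min-normalized trace, max over channels) outside
    [amp_low, amp_high] are removed.
    """
    if len(cells) < 2:
        raise ParameterError("need >= 2 cells for the cross-cell area statistics")
    if traces.amplitude is None:
        traces = normalize_traces(traces)
    reasons: dict = {}

    areas = np.vstack([c.area for c in cells])  # (n_cells, T)
    med = np.nanmedian(areas, axis=0)
    mad = np.nanmean(np.abs(areas - med), axis=0)
    outside = np.abs(areas - med) > mad_k * mad
    area_bad = np.nanmean(outside, axis=1) >= frac

    for i, cell in enumerate(cells):
        why = []
        if area_bad[i]:
            why.append("area")
        if np.mean(cell.seg_score < score_min) >= frac:
            why.append("seg_score")
        if require_from_start and (cell.present_from > 0 or np.isnan(cell.area[0])):
            why.append("late_appearance")
        if why:
            reasons[cell.cell_id] = why

    id_index = {cid: j for j, cid in enumerate(traces.cell_ids)}
    for cell in cells:
        if cell.cell_id in reasons:
            continue
        j = id_index[cell.cell_id]
        amp = max(traces.amplitude[ch][j] for ch in traces.channels)
        if amp < amp_low:
            reasons[cell.cell_id] = ["amplitude_low"]
        elif amp > amp_high:
            reasons[cell.cell_id] = ["amplitude_high"]

    kept = [c.cell_id for c in cells if c.cell_id not in reasons]
    return kept, reasons


# ---------------------------------------------------------------------------
# Same-cell vs cross-cell correlation
# ---------------------------------------------------------------------------

def trace_correlations(
    zA: np.ndarray,
    zB: np.ndarray,
    window: tuple[int, int] | None = None,
    max_pairs: int = 10_000,
    seed: int = 0,
) -> dict:
    """Same-cell vs different-cell Pearson correlations of two channels.

    ``zA``/``zB`` are (n_cells, n_frames) z-scored trace matrices with
    matching cell order. The same-cell set correlates channel A and B of the
    same cell over the window; the cross-cell null correlates A of cell i
    with B of cell j (i != j) over a seeded subsample of at most
    ``max_pairs`` ordered pairs. Cells with undefined (NaN) z-scores in the
    window are dropped from both sets.
    """
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    if zA.shape != zB.shape:
        raise ParameterError("channel matrices must share shape")
    n_cells, n_frames = zA.shape
    if window is None:
        window = (0, n_frames)
    lo, hi = window
    if hi - lo < 3:
        raise ParameterError("correlation window must span at least 3 frames")
    A = zA[:, lo:hi]
    B = zB[:, lo:hi]
    ok = (
        np.isfinite(A).all(axis=1) & np.isfinite(B).all(axis=1)
        & (A.std(axis=1) > 0) & (B.std(axis=1) > 0)
    )
    idx = np.flatnonzero(ok)
    if idx.size < 2:
        raise ParameterError("need at least 2 usable cells")

    same = np.array([pearsonr(A[i], B[i])[0] for i in idx])

    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in idx for j in idx if i != j]
    if len(pairs) > max_pairs:
        pick = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[p] for p in pick]
    cross = np.array([pearsonr(A[i], B[j])[0] for i, j in pairs])

    def _summary(x: np.ndarray) -> dict:
        return {
            "median": float(np.median(x)),
            "q25": float(np.quantile(x, 0.25)),
            "q75": float(np.quantile(x, 0.75)),
            "n": int(x.size),
        }

    return {
        "same_cell": same,
        "cross_cell": cross,
        "same_summary": _summary(same),
        "cross_summary": _summary(cross),
    }


# ---------------------------------------------------------------------------
# Fallback segmentation for synthetic movies
# ---------------------------------------------------------------------------

def segment_threshold(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Label connected bright regions; synthetic-data fallback segmenter.

    Thresholds the frame (default: midpoint between background and
    foreground medians via Otsu-like two-means) and labels connected
    components. Intended only for rendered movies where cells are bright
    disks on a dark background.
    """
    img = np.asarray(frame, dtype=float)
    if threshold is None:
        lo, hi = img.min(), img.max()
        if hi <= lo:
            warnings.warn("flat frame; nothing to segment")
            return np.zeros(img.shape, dtype=np.int32)
        t = 0.5 * (lo + hi)
        for _ in range(50):  # two-means iteration
            fg = img[img > t]
            bg = img[img <= t]
            t_new = 0.5 * (fg.mean() + bg.mean())
            if abs(t_new - t) < 1e-9:
                break
            t = t_new
        threshold = t
    labels, _ = ndimage.label(img > threshold)
    return labels.astype(np.int32)
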