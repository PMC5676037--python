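"""Fluorescence profiles along the long cell axis and nucleoid condensation.

The condensation statistic is the fraction of cell length spanned by the
chromosome signal: after background subtraction the extent runs from the
first to the last position where the profile reaches a relative threshold
of its maximum.  Using the outermost crossings (not the largest contiguous
run) tolerates two-lobe nucleoids seen around chromosome segregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .spt import CellGeometry

logger = logging.getLogger(__name__)

#: fraction of positions adjacent to each pole used for background estimation
POLE_BACKGROUND_FRACTION = 0.05
#: default relative threshold on the background-subtracted maximum
DEFAULT_REL_THRESHOLD = 0.2
#: common positional grid used when averaging cohorts of unequal cells
GRID_POINTS = 100


@dataclass
class IntensityProfile:
    """1D fluorescence values at fractional positions along the long axis,
    measured from the distant (designated) cell pole."""

    cell_id: str
    channel: str
    positions: np.ndarray  # strictly increasing fractions in [0, 1]
    values: np.ndarray
    frame: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValidationError("positions and values must have equal length")
        if self.positions.size < 2:
            raise ValidationError("a profile needs at least 2 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any((self.positions < 0) | (self.positions > 1)):
            raise ValidationError("positions must lie in [0, 1]")


@dataclass
class CondensationResult:
    cell_id: str
    extent_fraction: float
    threshold_used: float


def profile_from_image(
    image: np.ndarray, geom: CellGeometry, n_samples: int = GRID_POINTS
) -> IntensityProfile:
    """Sample mean intensity in stripes perpendicular to the pole-to-pole axis.

    Pixels within the cell footprint (|w| <= 1 in normalized short-axis
    units) are binned by their fractional position along the long axis into
    ``n_samples`` equal stripes; empty stripes are filled by linear
    interpolation from their neighbours.
    """
    img = np.asarray(image, dtype=float)
    h, wpx = img.shape
    a = np.asarray(geom.pole_a, dtype=float)
    b = np.asarray(geom.pole_b, dtype=float)
    for p in (a, b):
        if not (0 <= p[0] <= wpx and 0 <= p[1] <= h):
            raise ValidationError("cell axis lies outside the image bounds")
    axis = (b - a) / geom.length
    normal = np.array([-axis[1], axis[0]])
    yy, xx = np.mgrid[0:h, 0:wpx]
    pts = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)
    rel = pts - a
    l = rel @ axis / geom.length
    w = rel @ normal / (geom.width / 2.0)
    inside = (l >= 0) & (l <= 1) & (np.abs(w) <= 1)
    edges = np.linspace(0.0, 1.0, n_samples + 1)
    idx = np.clip(np.digitize(l[inside], edges) - 1, 0, n_samples - 1)
    sums = np.bincount(idx, weights=img.ravel()[inside], minlength=n_samples)
    counts = np.bincount(idx, minlength=n_samples)
    centers = (edges[:-1] + edges[1:]) / 2.0
    vals = np.full(n_samples, np.nan)
    nz = counts > 0
    vals[nz] = sums[nz] / counts[nz]
    if not nz.any():
        raise ValidationError("no pixels fall inside the cell footprint")
    if (~nz).any():
        vals[~nz] = np.interp(centers[~nz], centers[nz], vals[nz])
    return IntensityProfile(geom.cell_id, "image", centers, vals)


def resample_profile(profile: IntensityProfile, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of the profile onto a common fractional grid."""
    return np.interp(grid, profile.positions, profile.values)


def average_profiles(
    profiles: list[IntensityProfile],
    n_grid: int = GRID_POINTS,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Pointwise mean profile with a t-distribution confidence interval.

    Profiles are resampled onto a common ``n_grid``-point fractional grid so
    cells of different absolute lengths can be pooled.  Columns: position,
    mean, ci_low, ci_high, n.  A single profile yields NaN CIs with a warning.
    """
    if not profiles:
        raise InsufficientDataError("no profiles to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    mat = np.array([resample_profile(p, grid) for p in profiles])
    mean = mat.mean(axis=0)
    n = len(profiles)
    if n == 1:
        logger.warning("single profile: confidence interval undefined")
        lo = hi = np.full(n_grid, np.nan)
    else:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    return pd.DataFrame(
        {"position": grid, "mean": mean, "ci_low": lo, "ci_high": hi, "n": n}
    )


def _background(profile: IntensityProfile) -> float:
    """Median intensity over the positions nearest each pole."""
    pos = profile.positions
    mask = (pos <= POLE_BACKGROUND_FRACTION) | (pos >= 1.0 - POLE_BACKGROUND_FRACTION)
    if not mask.any():
        return 0.0
    return float(np.median(profile.values[mask]))


def condensation_extent(
    profile: IntensityProfile, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> CondensationResult:
    """Nucleoid extent as a fraction of cell length.

    Background (pole-median) is subtracted, the threshold is
    ``rel_threshold`` times the remaining maximum, and the extent runs
    between the outermost positions at or above threshold.  The statistic is
    invariant to multiplying the profile by a positive constant.
    """
    if not 0 < rel_threshold < 1:
        raise ValidationError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    if profile.values.max() <= 0:
        logger.warning("cell %s: no signal; extent 0", profile.cell_id)
        return CondensationResult(profile.cell_id, 0.0, 0.0)
    v = profile.values - _background(profile)
    vmax = v.max()
    if vmax <= 0:
        # positive signal with no contrast over the pole background: the
        # stain fills the whole cell
        return CondensationResult(profile.cell_id, 1.0, float(_background(profile)))
    thr = rel_threshold * vmax
    above = np.nonzero(v >= thr)[0]
    pos = profile.positions
    # sub-grid precision: linearly interpolate the outermost threshold crossings
    i0, i1 = above[0], above[-1]
    left = pos[i0]
    if i0 > 0 and v[i0] > v[i0 - 1]:
        left = pos[i0 - 1] + (thr - v[i0 - 1]) / (v[i0] - v[i0 - 1]) * (pos[i0] - pos[i0 - 1])
    right = pos[i1]
    if i1 < len(pos) - 1 and v[i1] > v[i1 + 1]:
        right = pos[i1] + (v[i1] - thr) / (v[i1] - v[i1 + 1]) * (pos[i1 + 1] - pos[i1])
    extent = float(right - left)
    return CondensationResult(profile.cell_id, extent, float(thr))


def colocalization_overlap(p1: IntensityProfile, p2: IntensityProfile) -> float:
    """Pearson correlation of two background-subtracted channel profiles on a
    common grid; near 1 when the two stains overlap along the cell."""
    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    v1 = resample_profile(p1, grid) - _background(p1)
    v2 = resample_profile(p2, grid) - _background(p2)
    if np.std(v1) == 0 or np.std(v2) == 0:
        logger.warning("zero-variance channel; colocalization undefined")
        return float("nan")
    r, _ = stats.pearsonr(v1, v2)
    return float(r)


def timelapse_condensation(
    profiles: list[IntensityProfile],
    division_frames: list[int],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame condensation extent for one cell lineage, summarised per
    inter-division segment.

    The frame series is split at each division (sister chromosome
    separation) event; for each non-empty segment the mean extent and its
    t-distribution CI are reported.  Returns (per_frame, per_segment).
    """
    framed = [p for p in profiles if p.frame is not None]
    if not framed:
        raise InsufficientDataError("time-lapse requires profiles with frame indices")
    framed.sort(key=lambda p: p.frame)
    rows = [
        {"frame": p.frame, "extent": condensation_extent(p, rel_threshold).extent_fraction}
        for p in framed
    ]
    per_frame = pd.DataFrame(rows)

    bounds = sorted(division_frames)
    edges = [-np.inf] + bounds + [np.inf]
    seg_rows = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        seg = per_frame[(per_frame.frame >= lo) & (per_frame.frame < hi)]
        if seg.empty:
            logger.warning("segment %d (%s, %s) contains no frames; skipped", i, lo, hi)
            continue
        ext = seg.extent.to_numpy()
        mean = float(ext.mean())
        if len(ext) > 1 and ext.std(ddof=1) > 0:
            tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=len(ext) - 1)
            half = tcrit * ext.std(ddof=1) / np.sqrt(len(ext))
        else:
            half = 0.0
        seg_rows.append(
            {
                "segment": len(seg_rows),
                "frame_start": int(seg.frame.min()),
                "frame_end": int(seg.frame.max()),
                "n_frames": len(ext),
                "mean_extent": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    return per_frame, pd.DataFrame(seg_rows)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_profiles(path) -> list[IntensityProfile]:
    """CSV with columns cell_id, channel, position, value[, frame]."""
    df = pd.read_csv(path)
    has_frame = "frame" in df.columns
    keys = ["cell_id", "channel"] + (["frame"] if has_frame else [])
    out = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        grp = grp.sort_values("position")
        out.append(
            IntensityProfile(
                cell_id=str(key[0]),
                channel=str(key[1]),
                positions=grp.position.to_numpy(),
                values=grp.value.to_numpy(),
                frame=int(key[2]) if has_frame else None,
            )
        )
    return out


def write_profiles(profiles: list[IntensityProfile], path) -> None:
    rows = []
    for p in profiles:
        for pos, val in zip(p.positions, p.values):
            row = {"cell_id": p.cell_id, "channel": p.channel, "position": pos, "value": val}
            if p.frame is not None:
                row["frame"] = p.frame
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
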