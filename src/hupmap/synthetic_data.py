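"""Synthetic data generators emulating the study conditions of a
nucleoid-associated protein binding experiment.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes:

* ChIP-seq peak replicates whose density decreases from *oriC* toward
  *ter*, with replicate jitter and dropout, a heavy-tailed width
  distribution (a visible tail of peaks >= 1,000 bp), control-strain false
  peaks, and a per-dataset ground-truth table;
* PALM-style localizations of a two-population particle mixture (immobile
  emitters at the localization-error noise floor plus Brownian particles)
  inside rod-shaped cells, with geometric track-length attrition
  (photobleaching) and sparse photoactivation so at most one molecule is
  active per cell at a time;
* plateau-shaped two-channel nucleoid intensity profiles with logistic
  edges and additive noise;
* a densitometry calibration table plus samples for copy-number arithmetic.

Identical configurations (including the seed) give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import Feature, GenomeContext, Peak
from .nucleoid_profiles import IntensityProfile

LN4 = float(np.log(4.0))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


DEFAULT_GENOME = GenomeContext("chr_sim", 7_000_000, oric_pos=0)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSimConfig:
    """Generative model for replicate/control peak sets.

    The true binding-site midpoints follow an inhomogeneous point process on
    the circle with intensity decreasing with circular distance d from
    *oriC*: linear lambda(d) = lambda0 * (1 - beta * d / (L/2)) or
    exponential lambda(d) = lambda0 * exp(-beta * d / (L/2)).  Peak widths
    are log-normal (median 400 bp, sigma 0.8, floored at the ~150 bp fragment scale,
    putting ~13% of peaks at >= 1,000 bp).  Replicates observe each true site with midpoint jitter
    and independent dropout; fold enrichments share a per-site log-normal
    true value with replicate-level noise; control peaks are uniform and,
    by default, constructed disjoint from the truth.
    """

    n_peaks: int = 600
    gradient: str = "linear"  # or "exponential"
    gradient_strength: float = 0.6
    width_median_bp: float = 400.0
    width_sigma: float = 0.8
    jitter_bp: float = 50.0
    dropout: float = 0.02
    n_control: int = 30
    control_exclude_truth: bool = True
    fold_median: float = 5.5
    fold_sigma: float = 0.6
    fold_replicate_sigma: float = 0.1

    def validate(self) -> None:
        if self.n_peaks < 1:
            raise ValidationError("n_peaks must be >= 1")
        if self.gradient not in ("linear", "exponential"):
            raise ValidationError(f"unknown gradient shape {self.gradient!r}")
        if self.gradient == "linear" and not 0 <= self.gradient_strength <= 1:
            raise ValidationError(
                "linear gradient_strength must be in [0, 1] to keep intensity non-negative"
            )
        if self.gradient_strength < 0:
            raise ValidationError("gradient_strength must be >= 0")
        if not 0 <= self.dropout <= 1:
            raise ValidationError("dropout must be in [0, 1]")


@dataclass
class PeakSimResult:
    rep1: list[Peak]
    rep2: list[Peak]
    control: list[Peak]
    truth: pd.DataFrame  # site_id, midpoint, width_bp, start, end, fold_true, in_rep1, in_rep2


def _sample_distance_from_oric(
    cfg: PeakSimConfig, ctx: GenomeContext, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Rejection-sample circular distances d in [0, L/2] from the declining
    intensity profile."""
    half = ctx.length_bp / 2.0
    out = np.empty(0)
    while out.size < n:
        d = rng.uniform(0, half, size=2 * (n - out.size) + 16)
        u = rng.uniform(0, 1, size=d.size)
        if cfg.gradient == "linear":
            accept = u <= 1.0 - cfg.gradient_strength * d / half
        else:
            accept = u <= np.exp(-cfg.gradient_strength * d / half)
        out = np.concatenate([out, d[accept]])
    return out[:n]


def simulate_peaks(
    cfg: PeakSimConfig,
    ctx: GenomeContext = DEFAULT_GENOME,
    seed: int | np.random.Generator = 0,
) -> PeakSimResult:
    cfg.validate()
    rng = _rng(seed)
    L = ctx.length_bp

    d = _sample_distance_from_oric(cfg, ctx, rng, cfg.n_peaks)
    side = rng.choice([-1.0, 1.0], size=cfg.n_peaks)
    midpoints = (ctx.oric_pos + side * d) % L
    widths = cfg.width_median_bp * np.exp(rng.normal(0, cfg.width_sigma, cfg.n_peaks))
    widths = np.maximum(np.round(widths), 150).astype(int)
    fold_true = cfg.fold_median * np.exp(rng.normal(0, cfg.fold_sigma, cfg.n_peaks))

    truth_rows = []
    reps: dict[str, list[Peak]] = {"rep1": [], "rep2": []}
    present = {
        "rep1": rng.uniform(size=cfg.n_peaks) >= cfg.dropout,
        "rep2": rng.uniform(size=cfg.n_peaks) >= cfg.dropout,
    }
    for rep in ("rep1", "rep2"):
        jit = rng.normal(0, cfg.jitter_bp, cfg.n_peaks)
        folds = fold_true * np.exp(rng.normal(0, cfg.fold_replicate_sigma, cfg.n_peaks))
        for i in range(cfg.n_peaks):
            if not present[rep][i]:
                continue
            m = (midpoints[i] + jit[i]) % L
            half_w = widths[i] // 2
            start = int(m) - half_w
            end = start + widths[i]
            # clamp to the linear map so both replicates stay overlapping near the edges
            start = max(start, 0)
            if start + widths[i] > L:
                start = L - widths[i]
            reps[rep].append(
                Peak(ctx.chrom_name, start, start + widths[i],
                     float(folds[i]), rep, f"site_{i + 1:04d}")
            )
    for i in range(cfg.n_peaks):
        half_w = int(widths[i]) // 2
        s = int(midpoints[i]) - half_w
        s = min(max(s, 0), L - int(widths[i]))
        truth_rows.append(
            dict(
                site_id=f"site_{i + 1:04d}",
                midpoint=float(midpoints[i]),
                width_bp=int(widths[i]),
                start=s,
                end=s + int(widths[i]),
                fold_true=float(fold_true[i]),
                in_rep1=bool(present["rep1"][i]),
                in_rep2=bool(present["rep2"][i]),
            )
        )
    truth = pd.DataFrame(truth_rows)

    control: list[Peak] = []
    truth_iv = truth[["start", "end"]].to_numpy()
    attempts = 0
    while len(control) < cfg.n_control and attempts < 100 * max(cfg.n_control, 1):
        attempts += 1
        w = int(max(round(cfg.width_median_bp * np.exp(rng.normal(0, cfg.width_sigma))), 150))
        s = int(rng.integers(0, L - w))
        if cfg.control_exclude_truth and np.any(
            (truth_iv[:, 0] < s + w) & (s < truth_iv[:, 1])
        ):
            continue
        control.append(
            Peak(ctx.chrom_name, s, s + w, float(2.0 * np.exp(rng.normal(0, 0.4))),
                 "control", f"ctrl_{len(control) + 1:03d}")
        )

    return PeakSimResult(
        sorted(reps["rep1"], key=lambda p: p.start),
        sorted(reps["rep2"], key=lambda p: p.start),
        control,
        truth,
    )


def simulate_features(
    ctx: GenomeContext = DEFAULT_GENOME,
    seed: int | np.random.Generator = 0,
    median_length_bp: float = 2000.0,
    length_sigma: float = 0.4,
    gap_range_bp: tuple[int, int] = (50, 400),
) -> list[Feature]:
    """Tile the chromosome with non-overlapping operon-like features of
    log-normal length separated by short intergenic gaps, random strands."""
    rng = _rng(seed)
    feats: list[Feature] = []
    pos = int(rng.integers(*gap_range_bp))
    i = 0
    while True:
        length = int(max(round(median_length_bp * np.exp(rng.normal(0, length_sigma))), 150))
        if pos + length >= ctx.length_bp:
            break
        i += 1
        strand = "+" if rng.uniform() < 0.5 else "-"
        feats.append(Feature(f"opr_{i:05d}", pos, pos + length, strand))
        pos += length + int(rng.integers(*gap_range_bp))
    return feats


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSimConfig:
    """Two-population particle mobility model inside rod cells.

    The immobile fraction is an exact composition (``round(n * fraction)``
    tracks are immobile), so recovery tests measure classification error,
    not binomial label sampling.  Immobile particles sit at a fixed point
    blurred by per-frame Gaussian localization error; mobile particles take
    2D Brownian steps (variance 2 D dt per axis) reflected at the
    spherocylindrical cell boundary, plus the same localization error.
    Track lengths are min_locs + geometric (photobleaching).  Units:
    micrometres and seconds.
    """

    n_tracks: int = 384
    immobile_fraction: float = 1.0 / 3.0
    d_mobile: float = 0.5          # um^2/s
    sigma_loc: float = 0.02        # um, per-frame localization error
    dt: float = 0.02               # s
    min_locs: int = 5              # >= 4 steps for the MSD window
    mean_extra_locs: float = 4.0   # geometric tail beyond min_locs
    tracks_per_cell: int = 20
    cell_length_mean: float = 4.0  # um
    cell_length_sd: float = 0.5
    cell_width: float = 0.7        # um
    frame_gap_between_tracks: int = 3  # sparse photoactivation

    def validate(self) -> None:
        if self.n_tracks < 1:
            raise ValidationError("n_tracks must be >= 1")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValidationError("immobile_fraction must be in [0, 1]")
        if self.d_mobile <= 0 or self.sigma_loc <= 0:
            raise ValidationError("d_mobile and sigma_loc must be positive")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")


@dataclass
class TrackSimResult:
    localizations: pd.DataFrame  # cell_id, frame, x, y
    geometry: pd.DataFrame       # cell_id, ax, ay, bx, by, width
    truth: pd.DataFrame          # track_id, cell_id, label, d_true, start_frame, n_locs

    @property
    def noise_floor(self) -> float:
        """Expected D* of an immobile emitter: sigma_loc^2 / dt."""
        return float(self._noise_floor)

    _noise_floor: float = 0.0


def _inside_spherocylinder(p: np.ndarray, length: float, width: float) -> bool:
    r = width / 2.0
    x, y = p
    if abs(y) > r:
        return False
    if r <= x <= length - r:
        return True
    cx = r if x < r else length - r
    return (x - cx) ** 2 + y ** 2 <= r ** 2


def _reflect_spherocylinder(p: np.ndarray, length: float, width: float) -> np.ndarray:
    """Mirror a point back into the 2D rod footprint (flat sides folded,
    cap overshoots reflected radially); iterates for large excursions."""
    r = width / 2.0
    q = p.copy()
    for _ in range(8):
        if _inside_spherocylinder(q, length, width):
            return q
        # fold across the flat sides first
        if q[1] > r:
            q[1] = 2 * r - q[1]
            continue
        if q[1] < -r:
            q[1] = -2 * r - q[1]
            continue
        # radial reflection at whichever cap is overshot
        cx = r if q[0] < r else length - r
        v = q - np.array([cx, 0.0])
        d = np.hypot(*v)
        if d > 0:
            q = np.array([cx, 0.0]) + v * (2 * r - d) / d
        else:
            return np.array([cx, 0.0])
    return np.clip(q, [0.0, -r], [length, r])


def _uniform_point_in_rod(rng: np.random.Generator, length: float, width: float) -> np.ndarray:
    r = width / 2.0
    while True:
        p = np.array([rng.uniform(0, length), rng.uniform(-r, r)])
        if _inside_spherocylinder(p, length, width):
            return p


def simulate_tracks(
    cfg: TrackSimConfig, seed: int | np.random.Generator = 0
) -> TrackSimResult:
    cfg.validate()
    rng = _rng(seed)

    n_immobile = int(round(cfg.n_tracks * cfg.immobile_fraction))
    labels = np.array(["immobile"] * n_immobile + ["diffusing"] * (cfg.n_tracks - n_immobile))
    rng.shuffle(labels)

    n_cells = int(np.ceil(cfg.n_tracks / cfg.tracks_per_cell))
    cell_lengths = np.maximum(
        rng.normal(cfg.cell_length_mean, cfg.cell_length_sd, n_cells), 2.0
    )
    geom_rows = [
        dict(cell_id=f"cell_{c + 1:03d}", ax=0.0, ay=0.0,
             bx=float(cell_lengths[c]), by=0.0, width=cfg.cell_width)
        for c in range(n_cells)
    ]

    p_stop = 1.0 / (cfg.mean_extra_locs + 1.0)
    loc_rows, truth_rows = [], []
    next_frame = np.zeros(n_cells, dtype=int)
    for t in range(cfg.n_tracks):
        c = t % n_cells
        cell_id = geom_rows[c]["cell_id"]
        length = cell_lengths[c]
        n_locs = cfg.min_locs + int(rng.geometric(p_stop)) - 1
        start_frame = int(next_frame[c])
        next_frame[c] = start_frame + n_locs + cfg.frame_gap_between_tracks

        pos = _uniform_point_in_rod(rng, length, cfg.cell_width)
        pts = np.empty((n_locs, 2))
        if labels[t] == "immobile":
            pts[:] = pos
            d_true = 0.0
        else:
            step_sd = np.sqrt(2.0 * cfg.d_mobile * cfg.dt)
            pts[0] = pos
            for k in range(1, n_locs):
                prop = pts[k - 1] + rng.normal(0, step_sd, 2)
                pts[k] = _reflect_spherocylinder(prop, length, cfg.cell_width)
            d_true = cfg.d_mobile
        obs = pts + rng.normal(0, cfg.sigma_loc, pts.shape)
        for k in range(n_locs):
            loc_rows.append(
                dict(cell_id=cell_id, frame=start_frame + k,
                     x=float(obs[k, 0]), y=float(obs[k, 1]))
            )
        truth_rows.append(
            dict(track_id=f"true_{t + 1:05d}", cell_id=cell_id, label=labels[t],
                 d_true=d_true, start_frame=start_frame, n_locs=n_locs)
        )

    res = TrackSimResult(
        pd.DataFrame(loc_rows), pd.DataFrame(geom_rows), pd.DataFrame(truth_rows)
    )
    res._noise_floor = cfg.sigma_loc ** 2 / cfg.dt
    return res


def simulate_free_tracks(
    n_tracks: int,
    d_true: float,
    dt: float = 0.02,
    n_locs: int = 5,
    sigma_loc: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list:
    """Unconfined 2D Brownian tracks (optionally noise-free) for estimator
    calibration; returns :class:`~hupmap.spt.Trajectory` objects."""
    from .spt import Trajectory

    rng = _rng(seed)
    step_sd = np.sqrt(2.0 * d_true * dt)
    out = []
    for t in range(n_tracks):
        steps = rng.normal(0, step_sd, (n_locs - 1, 2))
        pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if sigma_loc > 0:
            pts = pts + rng.normal(0, sigma_loc, pts.shape)
        out.append(
            Trajectory(f"free_{t + 1:05d}", tuple(range(n_locs)), pts, dt)
        )
    return out


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSimConfig:
    """Plateau-shaped nucleoid profile model.

    The plateau has logistic edges of softness ``edge_softness`` (fraction
    of cell length) and is parameterised so that its width measured at 20%
    of plateau height equals ``occupancy`` — i.e. the generator's occupancy
    is defined on the same scale as the condensation-extent estimator's
    default threshold.  Channel 2 is the clean channel-1 structure scaled by
    ``coupling`` plus independent noise, for colocalization tests.
    """

    n_cells: int = 100
    occupancy: float = 0.75
    occupancy_sd: float = 0.0
    edge_softness: float = 0.01
    noise_sigma: float = 0.05
    coupling: float = 0.8
    center_jitter: float = 0.02
    n_grid: int = 100

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not 0 < self.occupancy <= 1:
            raise ValidationError("occupancy must be in (0, 1]")
        if self.occupancy / 2.0 <= self.edge_softness * LN4:
            raise ValidationError("occupancy too small for the chosen edge softness")
        if self.noise_sigma < 0 or self.edge_softness <= 0:
            raise ValidationError("noise_sigma must be >= 0 and edge_softness > 0")


@dataclass
class ProfileSimResult:
    profiles: list[IntensityProfile]       # channel "c1"
    profiles_ch2: list[IntensityProfile]   # channel "c2"
    truth: pd.DataFrame                    # cell_id, occupancy, center


def _plateau(x: np.ndarray, center: float, occupancy: float, softness: float) -> np.ndarray:
    # half-maximum points sit ln(4)*softness inside the 20%-level boundary
    h = occupancy / 2.0 - softness * LN4
    left = 1.0 / (1.0 + np.exp(-(x - (center - h)) / softness))
    right = 1.0 / (1.0 + np.exp((x - (center + h)) / softness))
    return left * right


def simulate_profiles(
    cfg: ProfileSimConfig, seed: int | np.random.Generator = 0
) -> ProfileSimResult:
    cfg.validate()
    rng = _rng(seed)
    grid = np.linspace(0.0, 1.0, cfg.n_grid)
    profiles, profiles2, rows = [], [], []
    for c in range(cfg.n_cells):
        occ = cfg.occupancy
        if cfg.occupancy_sd > 0:
            occ = float(np.clip(rng.normal(cfg.occupancy, cfg.occupancy_sd), 0.2, 1.0))
        margin = occ / 2.0 + 2 * cfg.edge_softness
        center = float(np.clip(rng.normal(0.5, cfg.center_jitter), margin, 1.0 - margin))
        clean = _plateau(grid, center, occ, cfg.edge_softness)
        v1 = clean + rng.normal(0, cfg.noise_sigma, grid.size)
        v2 = cfg.coupling * clean + rng.normal(0, cfg.noise_sigma, grid.size)
        cell_id = f"cell_{c + 1:03d}"
        profiles.append(IntensityProfile(cell_id, "c1", grid.copy(), v1))
        profiles2.append(IntensityProfile(cell_id, "c2", grid.copy(), v2))
        rows.append(dict(cell_id=cell_id, occupancy=occ, center=center))
    return ProfileSimResult(profiles, profiles2, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# abundance fixtures
# ---------------------------------------------------------------------------

@dataclass
class AbundanceSimConfig:
    """Densitometry calibration line with multiplicative-free Gaussian noise,
    plus samples drawn at known loaded amounts and CFU counts."""

    amounts_ng: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    slope: float = 1000.0
    intercept: float = 50.0
    noise_sigma: float = 30.0
    sample_ng: tuple[float, ...] = (10.0, 20.0)
    lane_cfu: float = 2.5e8


def simulate_abundance(
    cfg: AbundanceSimConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (calibration table, samples table with true ng)."""
    rng = _rng(seed)
    amounts = np.asarray(cfg.amounts_ng, dtype=float)
    intensities = cfg.intercept + cfg.slope * amounts + rng.normal(0, cfg.noise_sigma, amounts.size)
    calib = pd.DataFrame({"amount_ng": amounts, "intensity": intensities})
    s_ng = np.asarray(cfg.sample_ng, dtype=float)
    s_int = cfg.intercept + cfg.slope * s_ng + rng.normal(0, cfg.noise_sigma, s_ng.size)
    samples = pd.DataFrame(
        {"sample_id": [f"s{i + 1}" for i in range(s_ng.size)],
         "intensity": s_int, "cfu": cfg.lane_cfu, "true_ng": s_ng}
    )
    return calib, samples
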