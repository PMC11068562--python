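"""Synthetic 3D organoid / microtissue image generator with exact ground truth.

Emulates the statistical structure of mixed-population organoid imaging
experiments: two intermingled nuclear populations (wild-type liver cells
and intestinal cancer cells) arranged on an organoid shell or packed into
a solid mass, population-specific exponential growth, division arrest
into a FUCCI double-negative (G0-like) state, geometric compaction of the
wild-type population, per-channel marker intensity models and imaging
noise.  Every stage of the analysis pipeline can be validated against the
ground-truth table this module produces.

Coordinates are stored in physical micrometres throughout; anisotropic
voxel geometry only enters at rasterisation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ImageStack

__all__ = [
    "MarkerModel",
    "SyntheticParams",
    "default_marker_models",
    "generate_nucleus_field",
    "simulate_timelapse",
    "apply_compaction",
    "render_stack",
    "render_timelapse",
    "mixed_organoid_params",
    "pure_params",
    "write_fixture_suite",
    "TRUTH_COLUMNS",
]

WT = "WT"
CANCER = "cancer"

#: Phase-duration fractions of one cell cycle (G1, S, G2, M).
PHASE_FRACTIONS = {"G1": 0.50, "S": 0.30, "G2": 0.15, "M": 0.05}

#: Fraction of the cycle after S-phase entry during which both FUCCI
#: reporters are rendered (hCDT1 degradation lag): exercises the
#: double-positive branch of downstream classifiers.
FUCCI_OVERLAP_FRAC = 0.03

#: How each known channel is expressed.  ``style`` is the rendered
#: geometry, ``population`` restricts expression (None = both), and
#: ``phases`` restricts expression to cell-cycle phases (None = always).
CHANNEL_ROLES: dict[str, dict] = {
    "DAPI": {"style": "nuclear", "population": None, "phases": None},
    "H2B": {"style": "nuclear", "population": WT, "phases": None},
    "mTmG": {"style": "membrane", "population": WT, "phases": None},
    "Dendra2": {"style": "membrane", "population": CANCER, "phases": None},
    "mCherry": {"style": "nuclear", "population": WT, "phases": "fucci_g1"},
    "mVenus": {"style": "nuclear", "population": WT, "phases": "fucci_sgm"},
    "EdU": {"style": "nuclear", "population": None, "phases": ("S",)},
    "pH3": {"style": "nuclear", "population": None, "phases": ("M",)},
    "SOX9": {"style": "nuclear", "population": None, "phases": None},
    "Casp3": {"style": "nuclear", "population": None, "phases": "apoptotic"},
}

TRUTH_COLUMNS = [
    "nucleus_id", "frame", "time_h", "z_um", "y_um", "x_um",
    "semi_z_um", "semi_y_um", "semi_x_um", "population", "phase",
    "cycle_frac", "arrested", "sox9_level", "fate",
]


@dataclass(frozen=True)
class MarkerModel:
    """Intensity model for one channel.

    ``background`` and ``foreground`` are mean levels in camera counts;
    ``background_ramp`` adds a linear gradient along X (counts per µm) to
    emulate uneven illumination; ``noise_sd`` is additive Gaussian noise;
    ``poisson`` resamples each voxel from a Poisson law (shot noise).
    """

    background: float = 100.0
    foreground: float = 1000.0
    noise_sd: float = 0.0
    poisson: bool = False
    background_ramp: float = 0.0

    def __post_init__(self):
        if self.background < 0 or self.foreground < 0 or self.noise_sd < 0:
            raise ValueError("intensity levels and noise sd must be >= 0")


def default_marker_models(
    channels=("DAPI", "mTmG", "Dendra2"), noise_sd: float = 0.0,
) -> dict[str, MarkerModel]:
    unknown = set(channels) - set(CHANNEL_ROLES)
    if unknown:
        raise KeyError(f"unknown channels {sorted(unknown)}; "
                       f"known: {sorted(CHANNEL_ROLES)}")
    return {c: MarkerModel(noise_sd=noise_sd) for c in channels}


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for one synthetic organoid or microtissue.

    Defaults describe a pure wild-type cholangiocyte organoid imaged by
    confocal time-lapse: ~24 h doubling time, 2 h frame interval, 12-bit
    images with 2.5 µm optical sections.  Mixed-competition conditions
    are produced by :func:`mixed_organoid_params`.
    """

    image_shape: tuple[int, int, int] = (40, 256, 256)   # (Z, Y, X) voxels
    voxel_size: tuple[float, float, float] = (2.5, 0.83, 0.83)  # µm
    n_nuclei_initial: int = 200
    wt_fraction_initial: float = 1.0
    nucleus_radius_um: float = 4.0        # mean semi-axis
    nucleus_radius_sd_um: float = 0.5
    min_separation_um: float = 9.0
    geometry: str = "shell"               # shell | solid | microtissue_patches
    doubling_time_wt_h: float = 24.0
    doubling_time_cancer_h: float = 17.8
    arrest_prob_wt: float = 0.0           # per-division (and initial) probability
    competition_coupling: bool = False    # scale arrest by local cancer fraction
    apoptosis_rate_per_h: float = 0.0
    compaction_factor: float = 1.0        # < 1 shrinks WT inter-nuclear distances
    marker_models: dict[str, MarkerModel] = field(
        default_factory=default_marker_models)
    frame_interval_h: float = 2.0
    duration_h: float = 0.0
    deterministic_growth: bool = False    # divide exactly every doubling time
    n_patches: int = 3                    # cancer patches in microtissue mode
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self):
        for name in ("wt_fraction_initial", "arrest_prob_wt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nucleus_radius_um", "min_separation_um",
                     "doubling_time_wt_h", "doubling_time_cancer_h",
                     "frame_interval_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.apoptosis_rate_per_h < 0 or self.duration_h < 0:
            raise ValueError("rates and durations must be non-negative")
        if not 0 < self.compaction_factor <= 1:
            raise ValueError("compaction_factor must be in (0, 1]")
        if self.geometry not in ("shell", "solid", "microtissue_patches"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.duration_h:
            n = self.duration_h / self.frame_interval_h
            if abs(n - round(n)) > 1e-9:
                raise ValueError("frame_interval_h must divide duration_h")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.image_shape, self.voxel_size))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.frame_interval_h)) + 1

    def rng(self, *salt: int) -> np.random.Generator:
        """Deterministic sub-generator derived from the top-level seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *salt]))


def pure_params(population: str = WT, **overrides) -> SyntheticParams:
    """Pure-culture conditions (single population, default growth)."""
    frac = 1.0 if population == WT else 0.0
    return SyntheticParams(wt_fraction_initial=frac, **overrides)


def mixed_organoid_params(**overrides) -> SyntheticParams:
    """Mixed-competition conditions.

    Wild-type growth slows to a 33 h doubling time while cancer cells
    divide faster than either pure population; the wild-type population
    starts at ~55% of nuclei, compacts, and arrests into a G0-like state
    at a rate that scales with the local cancer fraction.
    """
    defaults = dict(
        wt_fraction_initial=0.55,
        doubling_time_wt_h=33.0,
        doubling_time_cancer_h=15.0,
        arrest_prob_wt=0.6,
        competition_coupling=True,
        compaction_factor=0.8,
    )
    defaults.update(overrides)
    return SyntheticParams(**defaults)


# ---------------------------------------------------------------------------
# phase bookkeeping


def _phase_from_frac(u: float) -> str:
    if u < 0.50:
        return "G1"
    if u < 0.80:
        return "S"
    if u < 0.95:
        return "G2"
    return "M"


def _doubling_time(params: SyntheticParams, population: str) -> float:
    return (params.doubling_time_wt_h if population == WT
            else params.doubling_time_cancer_h)


# ---------------------------------------------------------------------------
# frame-0 placement


def _sample_positions(params: SyntheticParams, rng: np.random.Generator
                      ) -> np.ndarray:
    """Place nuclei at >= min_separation, rejecting until packed.

    Raises a packing error naming the attempted density when the retry
    budget is exhausted.
    """
    n = params.n_nuclei_initial
    if n == 0:
        return np.empty((0, 3))
    ext = np.array(params.extent_um)
    margin = params.nucleus_radius_um + 3 * params.nucleus_radius_sd_um
    lo, hi = margin, ext - margin
    if np.any(hi <= lo):
        raise ValueError("image too small for requested nucleus radius")
    center = ext / 2
    # ellipsoidal shell: fills the (usually Z-flattened) field of view
    shell_semi = (hi - center) * 0.8

    accepted: list[np.ndarray] = []
    pts = np.empty((0, 3))
    max_tries = max(2000, 400 * n)
    tries = 0
    while len(accepted) < n:
        tries += 1
        if tries > max_tries:
            density = n / float(np.prod(ext))
            raise RuntimeError(
                f"could not place {n} nuclei at min separation "
                f"{params.min_separation_um} µm (density {density:.2e} "
                f"nuclei/µm³) after {max_tries} attempts"
            )
        if params.geometry == "shell":
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = center + v * shell_semi * (1 + rng.normal(0, 0.06))
            p = np.clip(p, lo, hi)
        else:  # solid and microtissue_patches share solid packing
            u = rng.uniform(-1, 1, size=3)
            if np.dot(u, u) > 1:
                continue
            p = center + u * (hi - center) * 0.95
        if pts.shape[0]:
            d2 = np.sum((pts - p) ** 2, axis=1)
            if d2.min() < params.min_separation_um ** 2:
                continue
        accepted.append(p)
        pts = np.asarray(accepted)
    return pts


def _assign_populations(params: SyntheticParams, pts: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    n = pts.shape[0]
    if n == 0:
        return np.empty(0, dtype=object)
    if params.geometry == "microtissue_patches":
        # Contiguous cancer patches surrounded by wild-type tissue.
        n_cancer = int(round((1 - params.wt_fraction_initial) * n))
        pop = np.full(n, WT, dtype=object)
        if n_cancer and params.n_patches:
            seeds = pts[rng.choice(n, size=min(params.n_patches, n),
                                   replace=False)]
            d = np.min(np.linalg.norm(pts[:, None, :] - seeds[None, :, :],
                                      axis=2), axis=1)
            pop[np.argsort(d)[:n_cancer]] = CANCER
        return pop
    # Intermingled populations: independent Bernoulli labels.
    return np.where(rng.random(n) < params.wt_fraction_initial, WT, CANCER
                    ).astype(object)


def _draw_sox9(population: str, arrested: bool,
               rng: np.random.Generator) -> float:
    """Relative SOX9 level: progenitors high, arrested/differentiated low."""
    if arrested:
        return float(rng.uniform(0.05, 0.30))
    return float(rng.uniform(0.60, 1.00))


def generate_nucleus_field(params: SyntheticParams) -> pd.DataFrame:
    """Generate the frame-0 ground-truth table.

    Nuclei are placed at pairwise distances >= ``min_separation_um``
    (shell, solid or patch geometry), populations are assigned per
    ``wt_fraction_initial``, cell-cycle positions are uniform, and
    wild-type nuclei start arrested with probability ``arrest_prob_wt``
    (scaled by the cancer fraction when competition coupling is on).
    """
    rng = params.rng(0)
    pts = _sample_positions(params, rng)
    n = pts.shape[0]
    pop = _assign_populations(params, pts, rng)

    semi = rng.normal(params.nucleus_radius_um, params.nucleus_radius_sd_um,
                      size=(n, 3))
    semi = np.clip(semi, 0.5 * params.nucleus_radius_um,
                   1.5 * params.nucleus_radius_um)

    cancer_frac = float(np.mean(pop == CANCER)) if n else 0.0
    p_arrest = params.arrest_prob_wt * (
        cancer_frac if params.competition_coupling else 1.0)
    arrested = (pop == WT) & (rng.random(n) < p_arrest)
    u0 = rng.random(n)
    rows = {
        "nucleus_id": np.arange(n),
        "frame": np.zeros(n, dtype=int),
        "time_h": np.zeros(n),
        "z_um": pts[:, 0] if n else np.empty(0),
        "y_um": pts[:, 1] if n else np.empty(0),
        "x_um": pts[:, 2] if n else np.empty(0),
        "semi_z_um": semi[:, 0] if n else np.empty(0),
        "semi_y_um": semi[:, 1] if n else np.empty(0),
        "semi_x_um": semi[:, 2] if n else np.empty(0),
        "population": pop,
        "phase": [("G0" if a else _phase_from_frac(u))
                  for a, u in zip(arrested, u0)],
        "cycle_frac": u0,
        "arrested": arrested,
        "sox9_level": [_draw_sox9(p, a, rng) for p, a in zip(pop, arrested)],
        "fate": np.full(n, "none", dtype=object),
    }
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if params.compaction_factor < 1.0:
        truth = apply_compaction(truth, params.compaction_factor)
    return truth


def apply_compaction(truth: pd.DataFrame, factor: float,
                     population: str = WT) -> pd.DataFrame:
    """Shrink one population's inter-nuclear distances by ``factor``.

    Coordinates of the selected population are scaled about that
    population's centroid within each frame, so every pairwise distance
    (and hence any k-nearest-neighbour statistic) scales by exactly
    ``factor``.  Compaction is imposed geometrically; no mechanics are
    simulated.
    """
    if not 0 < factor <= 1:
        raise ValueError("compaction factor must be in (0, 1]")
    out = truth.copy()
    cols = ["z_um", "y_um", "x_um"]
    for _, idx in out.groupby("frame").groups.items():
        sel = out.loc[idx, "population"] == population
        sub = idx[sel]
        if len(sub) < 2:
            continue
        center = out.loc[sub, cols].mean(axis=0)
        out.loc[sub, cols] = center + factor * (out.loc[sub, cols] - center)
    return out


# ---------------------------------------------------------------------------
# time-lapse simulation


def simulate_timelapse(truth0: pd.DataFrame,
                       params: SyntheticParams) -> pd.DataFrame:
    """Simulate stochastic branching growth over the full time-lapse.

    Each cycling nucleus divides between consecutive frames with
    probability ``2**(dt/Td) - 1`` so that the expected fold expansion at
    time t is exactly ``2**(t/Td)`` for non-arrested lineages.  Arrested
    (G0) nuclei never divide; apoptotic nuclei are removed.  With
    ``deterministic_growth`` divisions instead fire exactly every
    doubling time.  The fate column records the event each nucleus
    undergoes between a frame and the next.
    """
    dt = params.frame_interval_h
    n_frames = params.n_frames
    rng = params.rng(1)

    cols = ["nucleus_id", "z_um", "y_um", "x_um", "semi_z_um", "semi_y_um",
            "semi_x_um", "population", "cycle_frac", "arrested", "sox9_level"]
    state = truth0[cols].copy().reset_index(drop=True)
    state["birth_h"] = -state["cycle_frac"] * state["population"].map(
        lambda p: _doubling_time(params, p))
    next_id = int(state["nucleus_id"].max()) + 1 if len(state) else 0
    ext = np.array(params.extent_um)
    margin = params.nucleus_radius_um
    frames = [_snapshot_frame(state, 0, 0.0)]

    for k in range(1, n_frames):
        t_new = k * dt
        n = len(state)
        if n == 0:
            frames.append(_snapshot_frame(state, k, t_new))
            continue
        tds = state["population"].map(
            lambda p: _doubling_time(params, p)).to_numpy()
        cycling = ~state["arrested"].to_numpy()
        if params.deterministic_growth:
            divide = cycling & ((t_new - state["birth_h"].to_numpy()) >= tds)
        else:
            p_div = 2.0 ** (dt / tds) - 1.0
            divide = cycling & (rng.random(n) < p_div)
        p_die = 1.0 - math.exp(-params.apoptosis_rate_per_h * dt)
        die = (~divide) & (rng.random(n) < p_die)

        # record fates on the *previous* frame's rows
        fates = np.full(n, "none", dtype=object)
        fates[divide] = "divided"
        fates[die] = "died"
        frames[-1].loc[:, "fate"] = fates

        cancer_frac = float(np.mean(state["population"] == CANCER))
        p_arrest = params.arrest_prob_wt * (
            cancer_frac if params.competition_coupling else 1.0)

        survivors = state.loc[~divide & ~die].copy()
        survivors["cycle_frac"] = np.where(
            survivors["arrested"],
            survivors["cycle_frac"],
            ((t_new - survivors["birth_h"]) / tds[~divide & ~die]) % 1.0,
        )
        daughters = []
        for _, mother in state.loc[divide].iterrows():
            offset_scale = 0.7 * params.nucleus_radius_um
            for _ in range(2):
                d = rng.normal(size=3)
                d *= offset_scale / np.linalg.norm(d)
                pos = np.clip(
                    np.array([mother["z_um"], mother["y_um"],
                              mother["x_um"]]) + d, margin, ext - margin)
                arrested = (mother["population"] == WT
                            and rng.random() < p_arrest)
                daughters.append({
                    "nucleus_id": next_id,
                    "z_um": pos[0], "y_um": pos[1], "x_um": pos[2],
                    "semi_z_um": mother["semi_z_um"],
                    "semi_y_um": mother["semi_y_um"],
                    "semi_x_um": mother["semi_x_um"],
                    "population": mother["population"],
                    "cycle_frac": 0.0,
                    "arrested": arrested,
                    "sox9_level": _draw_sox9(mother["population"], arrested,
                                             rng),
                    "birth_h": t_new,
                })
                next_id += 1
        state = pd.concat(
            [survivors] + ([pd.DataFrame(daughters)] if daughters else []),
            ignore_index=True)
        frames.append(_snapshot_frame(state, k, t_new))

    out = pd.concat(frames, ignore_index=True)
    return out[TRUTH_COLUMNS]


def _snapshot_frame(state: pd.DataFrame, frame: int,
                    time_h: float) -> pd.DataFrame:
    """Snapshot the simulation state as ground-truth rows for one frame."""
    snap = state.copy().reset_index(drop=True)
    snap["frame"] = frame
    snap["time_h"] = time_h
    snap["phase"] = [
        "G0" if a else _phase_from_frac(u)
        for a, u in zip(snap["arrested"], snap["cycle_frac"])
    ] if len(snap) else []
    snap["fate"] = "none"
    return snap.reindex(columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# rendering


def _channel_level(channel: str, row: pd.Series, model: MarkerModel) -> float:
    """True mean foreground level contributed by one nucleus, or 0."""
    role = CHANNEL_ROLES[channel]
    if role["population"] is not None and row["population"] != role["population"]:
        return 0.0
    phases = role["phases"]
    if phases is None:
        level = model.foreground
        if channel == "SOX9":
            level *= row["sox9_level"]
        return level
    if phases == "apoptotic":
        return model.foreground if row["fate"] == "died" else 0.0
    if phases == "fucci_g1":
        # hCDT1-mCherry: on in G1 and briefly into S (degradation lag)
        on = row["phase"] == "G1" or (
            row["phase"] == "S"
            and row["cycle_frac"] < PHASE_FRACTIONS["G1"] + FUCCI_OVERLAP_FRAC)
        return model.foreground if on else 0.0
    if phases == "fucci_sgm":
        return model.foreground if row["phase"] in ("S", "G2", "M") else 0.0
    return model.foreground if row["phase"] in phases else 0.0


def _rasterize(canvas: np.ndarray, center_um, semi_um, level: float,
               voxel_size, style: str) -> None:
    """Add a filled ellipsoid (or membrane shell) to a (Z, Y, X) canvas."""
    vs = np.asarray(voxel_size, dtype=float)
    c = np.asarray(center_um, dtype=float) / vs
    outer_scale = 1.25 if style == "membrane" else 1.0
    s = np.maximum(np.asarray(semi_um, dtype=float) * outer_scale / vs, 1e-6)
    lo = np.maximum(np.floor(c - s).astype(int), 0)
    hi = np.minimum(np.ceil(c + s).astype(int) + 1, canvas.shape)
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    norm2 = (((zz - c[0]) / s[0]) ** 2 + ((yy - c[1]) / s[1]) ** 2
             + ((xx - c[2]) / s[2]) ** 2)
    if style == "membrane":
        # shell between 0.68 and 1.0 of the outer ellipsoid: straddles the
        # nuclear boundary so that membrane signal overlaps the outer part
        # of the nuclear volume, as blurred cortical signal does in images
        mask = (norm2 <= 1.0) & (norm2 >= 0.68 ** 2)
    else:
        mask = norm2 <= 1.0
    region = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[mask] = np.maximum(region[mask], level)


def render_stack(truth: pd.DataFrame, params: SyntheticParams,
                 frame: int = 0, channels=None) -> ImageStack:
    """Rasterise one frame of the ground truth into an image stack.

    Nuclear channels render filled ellipsoids at each nucleus's true mean
    level; membrane channels (mTmG / Dendra2) render shells around the
    owning population's nuclei.  An additive background (constant plus
    optional linear ramp) and Gaussian / Poisson noise are applied per
    the channel's :class:`MarkerModel`, and intensities are clipped to
    the declared bit depth.
    """
    if channels is None:
        channels = list(params.marker_models)
    unknown = [c for c in channels if c not in params.marker_models]
    if unknown:
        raise KeyError(f"channels {unknown} not in marker_models "
                       f"{sorted(params.marker_models)}")
    rows = truth[truth["frame"] == frame]
    shape = tuple(params.image_shape)
    vmax = 2 ** params.bit_depth - 1
    out = np.zeros((1, len(channels)) + shape, dtype=np.uint16)

    for ci, ch in enumerate(channels):
        model = params.marker_models[ch]
        canvas = np.zeros(shape, dtype=float)
        style = CHANNEL_ROLES[ch]["style"]
        for _, row in rows.iterrows():
            level = _channel_level(ch, row, model)
            if level <= 0:
                continue
            _rasterize(canvas,
                       (row["z_um"], row["y_um"], row["x_um"]),
                       (row["semi_z_um"], row["semi_y_um"], row["semi_x_um"]),
                       level, params.voxel_size, style)
        canvas += model.background
        if model.background_ramp:
            x_um = np.arange(shape[2]) * params.voxel_size[2]
            canvas += model.background_ramp * x_um[None, None, :]
        rng = params.rng(2, frame, ci)
        if model.poisson:
            canvas = rng.poisson(np.clip(canvas, 0, None)).astype(float)
        if model.noise_sd > 0:
            canvas += rng.normal(0.0, model.noise_sd, size=shape)
        out[0, ci] = np.clip(np.rint(canvas), 0, vmax).astype(np.uint16)

    return ImageStack(
        voxels=out,
        voxel_size=params.voxel_size,
        channel_names=list(channels),
        bit_depth=params.bit_depth,
        frame_interval_h=params.frame_interval_h if params.duration_h else None,
    )


def render_timelapse(truth: pd.DataFrame, params: SyntheticParams,
                     channels=None) -> ImageStack:
    """Rasterise every frame; returns a (T, C, Z, Y, X) stack."""
    frames = sorted(truth["frame"].unique())
    stacks = [render_stack(truth, params, frame=f, channels=channels)
              for f in frames]
    voxels = np.concatenate([s.voxels for s in stacks], axis=0)
    return replace(stacks[0], voxels=voxels)


def write_fixture_suite(outdir, seed: int = 0) -> dict:
    """Emit a small standard test suite: stacks (OME-TIFF) plus truth CSV.

    All stacks are at most 256x256x40 voxels.  Returns the written paths.
    """
    from .io import write_stack
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    specs = {
        "pure_wt": pure_params(
            n_nuclei_initial=120, seed=seed,
            marker_models=default_marker_models(
                ("DAPI", "mTmG", "Dendra2"), noise_sd=30.0)),
        "mixed": mixed_organoid_params(
            n_nuclei_initial=120, seed=seed + 1,
            marker_models=default_marker_models(
                ("DAPI", "mTmG", "Dendra2"), noise_sd=30.0)),
        "microtissue": SyntheticParams(
            geometry="microtissue_patches", n_nuclei_initial=150,
            wt_fraction_initial=2 / 3, seed=seed + 2,
            marker_models=default_marker_models(
                ("DAPI", "mTmG", "Dendra2", "Casp3"), noise_sd=30.0)),
    }
    for name, params in specs.items():
        truth = generate_nucleus_field(params)
        stack = render_stack(truth, params)
        tif = write_stack(stack, outdir / f"{name}.ome.tif")
        csv = outdir / f"{name}_truth.csv"
        truth.to_csv(csv, index=False)
        written[name] = {"stack": tif, "truth": csv}
    return written
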