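"""Synthetic input generators.

Everything the experiments consume is generated here: paired 2D cluster
sequences, slow Fourier-basis rate signals with shuffled controls,
time-varying Poisson spike rasters and procedurally generated
latent-factor glyph videos.  All generators are deterministic given their
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from lplnet.rate_lpl import PairedBatch

__all__ = [
    "ClusterSequenceConfig",
    "SlowSignalConfig",
    "LatentVideoConfig",
    "SpikeRaster",
    "gen_cluster_pairs",
    "gen_slow_signal",
    "make_shuffled_control",
    "gen_poisson_raster",
    "gen_latent_video",
    "LatentVideo",
]


# ---------------------------------------------------------------------------
# 2D cluster pair sequences
# ---------------------------------------------------------------------------


@dataclass
class ClusterSequenceConfig:
    """Two Gaussian clusters on the x axis emitting consecutive pairs.

    With probability ``1 - crossover_prob`` both members of a pair come
    from the same cluster; crossover pairs span the two clusters.  The
    crossover pairs are included as a fixed per-batch fraction
    ``round(P * n_pairs)``.
    """

    sigma_x: float = 0.1
    sigma_y: float = 0.5
    centers: Tuple[float, float] = (-1.0, 1.0)
    crossover_prob: float = 0.0
    n_pairs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be > 0")
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be >= 0")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")


def gen_cluster_pairs(
    config: ClusterSequenceConfig,
    n_pairs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PairedBatch:
    """Draw a batch of consecutive 2D input pairs.

    Both members of a pair are drawn independently from
    ``N(center, diag(sigma_x^2, sigma_y^2))``; the centers sit at
    ``(-1, 0)`` and ``(+1, 0)``.  Cluster labels of both members are
    attached to the returned batch.
    """
    n = config.n_pairs if n_pairs is None else int(n_pairs)
    if n <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    n_cross = int(round(config.crossover_prob * n))
    c_prev = rng.integers(0, 2, size=n)
    c_curr = c_prev.copy()
    if n_cross > 0:
        idx = rng.choice(n, size=n_cross, replace=False)
        c_curr[idx] = 1 - c_curr[idx]

    centers = np.asarray(config.centers, dtype=float)
    scale = np.array([config.sigma_x, config.sigma_y])

    def draw(labels: np.ndarray) -> np.ndarray:
        pts = rng.normal(0.0, 1.0, size=(n, 2)) * scale
        pts[:, 0] += centers[labels]
        return pts

    return PairedBatch(
        x_prev=draw(c_prev), x_curr=draw(c_curr), labels_prev=c_prev, labels_curr=c_curr
    )


# ---------------------------------------------------------------------------
# Slow Fourier-basis rate signals
# ---------------------------------------------------------------------------


@dataclass
class SlowSignalConfig:
    """Periodic rate signal built from a decaying Fourier basis.

    The raw signal is ``sum_k theta_k / alpha**k * sin(2 pi k t / T + phi_k)``
    with ``theta_k, phi_k ~ U[0, 1)`` and harmonic frequencies ``k / T``
    (the harmonic-index reading of the basis; see package notes).  The
    spectral decay ``alpha`` biases the signal toward slow frequencies.
    After sampling, the trace is variance-normalized, centered on
    ``base_rate`` and clipped below at ``clip_floor``.
    """

    period: float = 3.0
    spectral_decay: float = 1.1
    n_harmonics: int = 20
    sample_interval: float = 0.010
    base_rate: float = 5.0
    clip_floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectral_decay <= 1.0:
            raise ValueError("spectral_decay must be > 1")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.clip_floor < 0:
            raise ValueError("clip_floor must be >= 0")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


def gen_slow_signal(
    config: SlowSignalConfig,
    duration: Optional[float] = None,
    return_raw: bool = False,
) -> np.ndarray:
    """Sample the slow rate signal on the configured grid.

    ``duration`` defaults to 13 periods.  The normalization (zero mean,
    unit variance before re-centering on ``base_rate``) is computed over
    the returned sample window.  With ``return_raw=True`` the
    pre-clipping trace is returned alongside the clipped one.
    """
    cfg = config
    duration = 13.0 * cfg.period if duration is None else float(duration)
    rng = np.random.default_rng(cfg.seed)
    k = np.arange(1, cfg.n_harmonics + 1)
    theta = rng.uniform(0.0, 1.0, size=cfg.n_harmonics)
    phi = rng.uniform(0.0, 1.0, size=cfg.n_harmonics)
    t = np.arange(0.0, duration, cfg.sample_interval)
    # (n_t, K) -> sum over harmonics
    arg = 2.0 * np.pi * np.outer(t, k) / cfg.period + phi
    raw = np.sin(arg) @ (theta / cfg.spectral_decay**k)
    std = raw.std()
    if std == 0:
        raise ValueError("degenerate signal (zero variance); use a different seed")
    pre_clip = cfg.base_rate + (raw - raw.mean()) / std
    trace = np.maximum(pre_clip, cfg.clip_floor)
    if return_raw:
        return trace, pre_clip
    return trace


def make_shuffled_control(
    trace: np.ndarray,
    n_periods: int = 13,
    grid: float = 0.010,
    sample_interval: float = 0.010,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Destroy slow temporal structure while preserving the rate histogram.

    The trace is tiled ``n_periods`` times and then shuffled on a time
    grid of resolution ``grid`` (which must be a multiple of the trace's
    ``sample_interval``).  The returned trace is an exact permutation of
    the tiled trace's grid bins.
    """
    ratio = grid / sample_interval
    block = int(round(ratio))
    if abs(ratio - block) > 1e-9 or block < 1:
        raise ValueError("grid must be an integer multiple of sample_interval")
    rng = np.random.default_rng() if rng is None else rng
    tiled = np.tile(np.asarray(trace, dtype=float), n_periods)
    n_blocks = len(tiled) // block
    usable = tiled[: n_blocks * block].reshape(n_blocks, block)
    perm = rng.permutation(n_blocks)
    out = usable[perm].reshape(-1)
    tail = tiled[n_blocks * block :]
    return np.concatenate([out, tail]) if tail.size else out


# ---------------------------------------------------------------------------
# Poisson spike rasters
# ---------------------------------------------------------------------------


@dataclass
class SpikeRaster:
    """Timestamped spike events for named neuron populations."""

    times: np.ndarray  # seconds, sorted
    ids: np.ndarray  # neuron indices
    population_slices: Dict[str, slice]
    duration: float
    dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have the same length")
        if self.times.size:
            if self.times.min() < 0 or self.times.max() >= self.duration + self.dt / 2:
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("events must be time-sorted")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def n_neurons(self) -> int:
        return max((s.stop for s in self.population_slices.values()), default=0)

    def population(self, name: str) -> "SpikeRaster":
        """Sub-raster of one population (ids kept in global numbering)."""
        sl = self.population_slices[name]
        m = (self.ids >= sl.start) & (self.ids < sl.stop)
        return SpikeRaster(
            self.times[m], self.ids[m], {name: sl}, self.duration, self.dt
        )

    def mean_rate(self, name: Optional[str] = None) -> float:
        """Spikes per neuron per second, over the whole raster or one population."""
        if name is None:
            n = self.n_neurons()
            count = self.n_events
        else:
            sl = self.population_slices[name]
            n = sl.stop - sl.start
            count = int(np.sum((self.ids >= sl.start) & (self.ids < sl.stop)))
        return count / (n * self.duration) if n else 0.0

    def binned_counts(self, bin_width: float) -> np.ndarray:
        """(n_bins, n_neurons) spike-count matrix."""
        n_bins = int(round(self.duration / bin_width))
        n = self.n_neurons()
        counts = np.zeros((n_bins, n), dtype=float)
        if self.n_events:
            b = np.minimum((self.times / bin_width).astype(int), n_bins - 1)
            np.add.at(counts, (b, self.ids), 1.0)
        return counts


def gen_poisson_raster(
    group_rates: Dict[str, Tuple[np.ndarray, int]],
    duration: float,
    dt: float = 1e-4,
    rate_sample_interval: float = 0.010,
    seed: int = 0,
) -> SpikeRaster:
    """Inhomogeneous Poisson raster with per-population shared rates.

    ``group_rates`` maps population names to ``(rate_trace_hz, n_neurons)``;
    every neuron of a population follows the population's instantaneous
    rate but spikes independently.  Spikes are generated by per-time-step
    Bernoulli thinning with probability ``rate * dt`` (``dt`` defaults to
    0.1 ms so that ``rate * dt << 1``).  Rate traces shorter than the
    requested duration are tiled periodically.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > rate_sample_interval + 1e-12:
        raise ValueError("dt must not exceed the rate sample interval")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    steps_per_sample = int(round(rate_sample_interval / dt))

    slices: Dict[str, slice] = {}
    offset = 0
    all_times, all_ids = [], []
    chunk = max(1, int(2e5) // max(1, sum(n for _, n in group_rates.values())))
    chunk *= steps_per_sample  # align chunks with the rate grid

    for name, (trace, n_neurons) in group_rates.items():
        trace = np.atleast_1d(np.asarray(trace, dtype=float))
        if np.any(trace < 0):
            raise ValueError(f"negative rate in population {name!r}")
        slices[name] = slice(offset, offset + n_neurons)
        n_samples_needed = -(-n_steps // steps_per_sample)
        reps = -(-n_samples_needed // len(trace))
        full = np.tile(trace, reps)[:n_samples_needed]
        p_per_step = np.repeat(full * dt, steps_per_sample)[:n_steps]
        for start in range(0, n_steps, chunk):
            stop = min(start + chunk, n_steps)
            p = p_per_step[start:stop]
            if not np.any(p > 0):
                continue
            u = rng.random((stop - start, n_neurons))
            s_idx, n_idx = np.nonzero(u < p[:, None])
            if s_idx.size:
                all_times.append((start + s_idx) * dt)
                all_ids.append(n_idx + offset)
        offset += n_neurons

    if all_times:
        times = np.concatenate(all_times)
        ids = np.concatenate(all_ids)
        order = np.argsort(times, kind="stable")
        times, ids = times[order], ids[order]
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    return SpikeRaster(times, ids, slices, duration, dt)


# ---------------------------------------------------------------------------
# Latent-factor glyph videos
# ---------------------------------------------------------------------------

SHAPES = ("disk", "square", "triangle", "cross")


@dataclass
class LatentVideoConfig:
    """Procedural video of geometric glyphs with discrete latent factors.

    Each clip is ``clip_length`` frames; within a clip the shape is fixed
    and exactly one of the non-shape factors performs a random walk biased
    toward adjacent levels, while the others stay fixed.  The ordering of
    the hue levels is permuted once per run.
    """

    image_size: int = 32
    clip_length: int = 17
    n_frames: int = 1700
    n_scales: int = 6
    n_hues: int = 8
    n_orientations: int = 8
    adjacent_prob: float = 0.9
    hue_permutation_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_length < 2:
            raise ValueError("clip_length must be >= 2")
        if self.image_size < 12:
            raise ValueError("image too small to render the glyphs")


FACTOR_NAMES = ("shape", "scale", "hue", "orientation")


@dataclass
class LatentVideo:
    """Frames plus full per-frame factor annotation and the transition log."""

    frames: np.ndarray  # (n_frames, H, W) in [0, 1]
    labels: np.ndarray  # (n_frames, 4) integer factor levels (shape, scale, hue, orientation)
    varying_factor: np.ndarray  # (n_clips,) index into FACTOR_NAMES (never 0)
    clip_length: int
    hue_permutation: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_clips(self) -> int:
        return len(self.varying_factor)

    def paired_frames(self) -> tuple[np.ndarray, np.ndarray]:
        """Within-clip consecutive frame pairs, flattened to vectors."""
        n = self.frames.shape[0]
        idx = np.arange(n - 1)
        keep = (idx % self.clip_length) != self.clip_length - 1  # no cross-clip pairs
        prev = self.frames[idx[keep]].reshape(keep.sum(), -1)
        curr = self.frames[idx[keep] + 1].reshape(keep.sum(), -1)
        return prev, curr


def _render_glyph(shape: int, scale01: float, intensity: float, angle: float, size: int) -> np.ndarray:
    """Render one glyph on a black canvas via coordinate masks."""
    half = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx - half + 0.5) / half
    y = (yy - half + 0.5) / half
    ca, sa = math.cos(angle), math.sin(angle)
    xr = ca * x + sa * y
    yr = -sa * x + ca * y
    r = 0.25 + 0.65 * scale01  # glyph radius in [-1, 1] units
    name = SHAPES[shape]
    if name == "disk":
        mask = xr**2 + yr**2 <= r**2
    elif name == "square":
        mask = (np.abs(xr) <= r * 0.8) & (np.abs(yr) <= r * 0.8)
    elif name == "triangle":
        mask = (yr >= -r * 0.6) & (np.abs(xr) <= (r * 0.6 - yr) * 0.577)
        mask &= yr <= r * 0.6
    else:  # cross
        w = r * 0.3
        mask = ((np.abs(xr) <= w) & (np.abs(yr) <= r)) | (
            (np.abs(yr) <= w) & (np.abs(xr) <= r)
        )
    return mask.astype(float) * intensity


def _biased_walk(level: int, n_levels: int, adjacent_prob: float, rng: np.random.Generator) -> int:
    """One step of a random walk biased toward adjacent factor levels."""
    if n_levels == 1:
        return level
    if rng.random() < adjacent_prob:
        if level == 0:
            return 1
        if level == n_levels - 1:
            return n_levels - 2
        return level + (1 if rng.random() < 0.5 else -1)
    # occasional long-range jump to a different level
    step = rng.integers(1, n_levels)
    return int((level + step) % n_levels)


def gen_latent_video(config: LatentVideoConfig) -> LatentVideo:
    """Generate the glyph video with per-frame ground-truth factors."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    hue_perm = np.random.default_rng(cfg.hue_permutation_seed).permutation(cfg.n_hues)
    n_levels = {
        "shape": len(SHAPES),
        "scale": cfg.n_scales,
        "hue": cfg.n_hues,
        "orientation": cfg.n_orientations,
    }
    n_clips = -(-cfg.n_frames // cfg.clip_length)
    frames = np.zeros((cfg.n_frames, cfg.image_size, cfg.image_size))
    labels = np.zeros((cfg.n_frames, 4), dtype=np.int64)
    varying = np.zeros(n_clips, dtype=np.int64)

    frame = 0
    for clip in range(n_clips):
        state = {
            name: int(rng.integers(0, n_levels[name])) for name in FACTOR_NAMES
        }
        fvar = int(rng.integers(1, 4))  # never the shape within a clip
        varying[clip] = fvar
        for _ in range(cfg.clip_length):
            if frame >= cfg.n_frames:
                break
            labels[frame] = [state[n] for n in FACTOR_NAMES]
            intensity = 0.2 + 0.8 * hue_perm[state["hue"]] / max(1, cfg.n_hues - 1)
            frames[frame] = _render_glyph(
                state["shape"],
                state["scale"] / max(1, cfg.n_scales - 1),
                intensity,
                state["orientation"] * math.pi / cfg.n_orientations,
                cfg.image_size,
            )
            frame += 1
            name = FACTOR_NAMES[fvar]
            state[name] = _biased_walk(
                state[name], n_levels[name], cfg.adjacent_prob, rng
            )
    return LatentVideo(
        frames=frames,
        labels=labels,
        varying_factor=varying,
        clip_length=cfg.clip_length,
        hue_permutation=hue_perm,
    )
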