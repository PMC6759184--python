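"""In-silico dual-reporter (Bmal1 / Per1) time-lapse movie generation.

Builds synthetic bioluminescence movie stacks under two competing null
hypotheses about the origin of reporter dissociation in tissue recordings:

* ``H0_1`` — every cell carries both a Bmal1 and a Per1 signal with distinct
  periods (dissociation within single cells);
* ``H0_2`` — two disjoint half-populations, each carrying only one reporter.

Each cell emits a raised cosine ``I/2 * (1 + cos(2*pi*t/tau + phi))``; cells
are placed uniformly on the unit square, rendered as Gaussian blobs of
standard deviation ``sigma_g`` (a fraction of the field width), stacked over
``n_layers`` tissue layers whose intensity is attenuated by a constant factor
per layer, and finally corrupted by i.i.d. Gaussian observation noise per
pixel, frame and channel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateConfig",
    "CellField",
    "MovieStack",
    "place_cells",
    "cell_signal",
    "render_movie",
    "generate_surrogate",
]

_HYPOTHESES = ("H0_1", "H0_2")


@dataclass(frozen=True)
class SurrogateConfig:
    """Parameters of the surrogate movie generator.

    Defaults are the reference dual-reporter conditions: 150 cells per layer,
    Bmal1 period 23 h vs Per1 period 24 h, unit intensity, cell size
    ``sigma_g = 0.0132`` field widths, observation noise ``sigma_n = 1``,
    12 days sampled hourly, 3 tissue layers with 50% attenuation per layer,
    rendered on a 128 x 128 grid.

    ``kernel_gain`` is the camera gain: the rendered peak brightness of a
    unit-intensity cell, in the same arbitrary units as ``sigma_n``. The
    Gaussian rendering kernel fixes a cell's shape but not its absolute
    brightness relative to the observation noise; the default of 10 places
    cell-covered pixels in the clearly rhythmic regime (oscillations visible
    over the noise in single-pixel traces) while empty pixels stay
    noise-dominated, the regime depicted by published dual-reporter
    recordings and their in-silico counterparts.
    """

    n_cells: int = 150
    hypothesis: str = "H0_1"
    period_bmal: float = 23.0
    period_per: float = 24.0
    intensity: float = 1.0
    kernel_gain: float = 10.0
    sigma_g: float = 0.0132
    sigma_n: float = 1.0
    dt: float = 1.0
    duration_days: float = 12.0
    n_layers: int = 3
    layer_attenuation: float = 0.5
    grid_shape: tuple[int, int] = (128, 128)
    seed: int = 0
    phase_mode: str = "uniform"  # "uniform" or "common"
    cells_per_layer: bool = True  # False: n_cells split across layers

    def __post_init__(self) -> None:
        if self.hypothesis not in _HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {_HYPOTHESES}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt <= 0 or self.duration_days <= 0:
            raise ValueError("dt and duration must be positive")
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be positive")
        if not (0 < self.layer_attenuation <= 1):
            raise ValueError("layer_attenuation must lie in (0, 1]")
        if self.phase_mode not in ("uniform", "common"):
            raise ValueError("phase_mode must be 'uniform' or 'common'")

    def times(self) -> np.ndarray:
        n = int(round(self.duration_days * 24.0 / self.dt))
        return np.arange(n + 1) * self.dt

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


@dataclass(frozen=True)
class CellField:
    """Per-layer cell records generated from a :class:`SurrogateConfig`.

    Each layer is a DataFrame with columns ``x, y`` (unit-field coordinates),
    ``channel`` (``both``/``bmal``/``per``), per-channel periods
    ``period_bmal, period_per`` and phases ``phase_bmal, phase_per`` (NaN for
    a channel the cell does not carry), and ``intensity``.
    """

    layers: tuple[pd.DataFrame, ...]
    hypothesis: str


def cell_signal(intensity: float, period: float, phase: float, t) -> np.ndarray:
    """Raised-cosine single-cell signal ``I/2 * (1 + cos(2*pi*t/tau + phi))``.

    Bounded in ``[0, I]``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.asarray(t, dtype=float)
    return intensity / 2.0 * (1.0 + np.cos(2 * np.pi * t / period + phase))


def _layer_cells(config: SurrogateConfig, seed: int, layer: int, n: int) -> pd.DataFrame:
    ss = np.random.SeedSequence([int(seed), int(layer)])
    pos_rng, bmal_rng, per_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    xy = pos_rng.uniform(0.0, 1.0, size=(n, 2))

    def phases(rng, count):
        if config.phase_mode == "common":
            return np.zeros(count)
        return rng.uniform(0.0, 2 * np.pi, size=count)

    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    df["intensity"] = config.intensity
    if config.hypothesis == "H0_1":
        df["channel"] = "both"
        df["period_bmal"] = config.period_bmal
        df["period_per"] = config.period_per
        df["phase_bmal"] = phases(bmal_rng, n)
        df["phase_per"] = phases(per_rng, n)
    else:
        n_bmal = (n + 1) // 2  # odd counts: the extra cell is a Bmal1 cell
        channel = np.array(["bmal"] * n_bmal + ["per"] * (n - n_bmal))
        df["channel"] = channel
        df["period_bmal"] = np.where(channel == "bmal", config.period_bmal, np.nan)
        df["period_per"] = np.where(channel == "per", config.period_per, np.nan)
        pb = np.full(n, np.nan)
        pb[:n_bmal] = phases(bmal_rng, n_bmal)
        pp = np.full(n, np.nan)
        pp[n_bmal:] = phases(per_rng, n - n_bmal)
        df["phase_bmal"] = pb
        df["phase_per"] = pp
    return df


def place_cells(config: SurrogateConfig, rng_seed: int | None = None) -> CellField:
    """Draw cell positions, channel assignments, periods and initial phases.

    Positions are i.i.d. uniform on the unit square and depend only on the
    seed and layer index -- not on the hypothesis -- so the two hypotheses can
    be compared on identical cell layouts. Each layer receives an independent
    draw. Initial phases are i.i.d. uniform on [0, 2*pi) per cell and channel
    unless ``phase_mode == 'common'`` (all zero).
    """
    seed = config.seed if rng_seed is None else rng_seed
    counts = [config.n_cells] * config.n_layers
    if not config.cells_per_layer:
        base, extra = divmod(config.n_cells, config.n_layers)
        counts = [base + (1 if i < extra else 0) for i in range(config.n_layers)]
    layers = tuple(
        _layer_cells(config, seed, layer, counts[layer])
        for layer in range(config.n_layers)
    )
    return CellField(layers=layers, hypothesis=config.hypothesis)


@dataclass(frozen=True)
class MovieStack:
    """A rendered single-channel movie: frames (time x rows x cols), hours axis."""

    channel: str
    frames: np.ndarray
    dt: float
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.times.size:
            raise ValueError("frame count must match time axis")
        steps = np.diff(self.times)
        if steps.size and (np.any(steps <= 0) or np.any(np.abs(steps - self.dt) > 1e-9)):
            raise ValueError("times must increase with constant step dt")


def _cell_patches(field: CellField, config: SurrogateConfig):
    """Precompute the static Gaussian footprint of every cell.

    The kernel is truncated at +-4 sigma (mass loss < 1e-4) and deposited
    unnormalized: the blob's peak equals the cell's instantaneous signal, so
    ``sigma_g`` sets the cell's apparent size, not its total photon output.
    """
    nr, nc = config.grid_shape
    sigma_px = config.sigma_g * nc
    if sigma_px < 0.5:
        logger.warning(
            "Gaussian kernel std %.3f px is below 0.5 px; grid %s cannot resolve it",
            sigma_px,
            config.grid_shape,
        )
    radius = max(1, int(np.ceil(4.0 * sigma_px)))
    rows = np.arange(nr) + 0.5
    cols = np.arange(nc) + 0.5
    patches = []
    for layer_idx, df in enumerate(field.layers):
        weight = config.layer_attenuation**layer_idx
        for rec in df.itertuples(index=False):
            cr = rec.y * nr
            cc = rec.x * nc
            r0, r1 = max(0, int(cr - radius)), min(nr, int(cr + radius) + 2)
            c0, c1 = max(0, int(cc - radius)), min(nc, int(cc + radius) + 2)
            dr = rows[r0:r1] - cr
            dc = cols[c0:c1] - cc
            w = np.exp(-(dr[:, None] ** 2 + dc[None, :] ** 2) / (2 * sigma_px**2))
            patches.append((rec, weight, r0, r1, c0, c1, w))
    return patches


def render_movie(
    field: CellField, config: SurrogateConfig, rng_seed: int | None = None
) -> tuple[MovieStack, MovieStack]:
    """Rasterize a cell field into the (bmal, per) movie stacks.

    Layers are superimposed with weights ``1, a, a**2, ...`` where ``a`` is
    the per-layer attenuation; Gaussian observation noise of std ``sigma_n``
    is added independently per pixel, frame and channel after superposition.
    """
    seed = config.seed if rng_seed is None else rng_seed
    times = config.times()
    nt = times.size
    nr, nc = config.grid_shape
    patches = _cell_patches(field, config)

    stacks = {}
    noise_rng = {
        ch: np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + k]))
        for k, ch in enumerate(("bmal", "per"))
    }
    for ch in ("bmal", "per"):
        frames = np.zeros((nt, nr, nc))
        for rec, weight, r0, r1, c0, c1, w in patches:
            period = getattr(rec, f"period_{ch}")
            phase = getattr(rec, f"phase_{ch}")
            if np.isnan(period):
                continue
            s = (
                cell_signal(rec.intensity, period, phase, times)
                * weight
                * config.kernel_gain
            )
            frames[:, r0:r1, c0:c1] += s[:, None, None] * w[None, :, :]
        if config.sigma_n > 0:
            frames = frames + noise_rng[ch].normal(0.0, config.sigma_n, frames.shape)
        stacks[ch] = MovieStack(channel=ch, frames=frames, dt=config.dt, times=times)
    return stacks["bmal"], stacks["per"]


def generate_surrogate(
    config: SurrogateConfig,
    out_dir: str | Path | None = None,
    write_tiff: bool = False,
) -> tuple[MovieStack, MovieStack]:
    """Place cells and render both channels; optionally persist to disk.

    When ``out_dir`` is given, an NPZ archive (``frames_bmal``, ``frames_per``,
    ``times`` and a JSON metadata string) plus a sidecar YAML of the config are
    written; ``write_tiff`` additionally stores one multi-page TIFF per channel.
    """
    field = place_cells(config)
    bmal, per = render_movie(field, config)
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            meta = json.dumps({"config": config.to_dict()}, sort_keys=True)
            np.savez(
                out / "surrogate.npz",
                frames_bmal=bmal.frames,
                frames_per=per.frames,
                times=bmal.times,
                metadata=np.array(meta),
            )
            with open(out / "surrogate_config.yaml", "w") as fh:
                yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
            if write_tiff:
                import tifffile

                tifffile.imwrite(out / "bmal.tiff", bmal.frames.astype(np.float32))
                tifffile.imwrite(out / "per.tiff", per.frames.astype(np.float32))
        except OSError as exc:
            raise OSError(f"failed to write surrogate outputs under {out}: {exc}") from exc
    return bmal, per


def load_surrogate(path: str | Path) -> tuple[MovieStack, MovieStack, dict]:
    """Load an NPZ archive written by :func:`generate_surrogate`."""
    with np.load(path, allow_pickle=False) as npz:
        times = npz["times"]
        dt = float(times[1] - times[0])
        meta = json.loads(str(npz["metadata"]))
        bmal = MovieStack("bmal", npz["frames_bmal"], dt, times)
        per = MovieStack("per", npz["frames_per"], dt, times)
    return bmal, per, meta
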