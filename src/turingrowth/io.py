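"""File IO: snapshot export, manifests, spectra and config round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .engine import (
    GrowthSchedule,
    ReactionParams,
    SimulationConfig,
    SimulationHistory,
)

__all__ = [
    "save_history",
    "load_snapshot",
    "field_to_uint16",
    "save_color_png",
    "config_to_dict",
    "config_from_dict",
    "load_config",
]


def field_to_uint16(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linear map [lo, hi] -> [0, 65535] for 16-bit greyscale export."""
    scaled = (np.asarray(field, float) - lo) / (hi - lo)
    return np.clip(scaled * 65535.0, 0, 65535).round().astype(np.uint16)


def save_history(history: SimulationHistory, out_dir: str | Path) -> Path:
    """Write a-field snapshots as 16-bit greyscale PNGs plus a JSON manifest.

    The a-field is mapped linearly from its clamp range [minA, maxA]; the
    manifest records iteration, surface and file name per snapshot, the full
    configuration and the growth phase boundaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = history.config.reaction
    entries = []
    for t, s, a in zip(history.iterations, history.surface, history.a_snapshots):
        name = f"a_{t:07d}.png"
        iio.imwrite(out_dir / name, field_to_uint16(a, p.min_a, p.max_a))
        entries.append(dict(iteration=t, surface=s, file=name))
    manifest = dict(
        config=config_to_dict(history.config),
        growth_start_iteration=history.growth_start_iteration,
        growth_end_iteration=history.growth_end_iteration,
        value_range=[p.min_a, p.max_a],
        snapshots=entries,
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_snapshot(path: str | Path, value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Read a greyscale PNG back; optionally rescale to field units."""
    img = iio.imread(path).astype(float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if value_range is not None:
        lo, hi = value_range
        denom = 65535.0 if img.max() > 255 else 255.0
        img = lo + img / denom * (hi - lo)
    return img


def save_color_png(color: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) colour array in [0,1] as 8-bit RGB PNG."""
    iio.imwrite(Path(path), np.clip(color * 255.0, 0, 255).round().astype(np.uint8))


def config_to_dict(config: SimulationConfig) -> dict:
    p, g = config.reaction, config.growth
    return dict(
        reaction=dict(s=p.s, r=p.r, d=p.d, dt=p.dt, min_a=p.min_a, max_a=p.max_a,
                      min_b=p.min_b, max_b=p.max_b),
        growth=dict(g=g.g, t_start=g.t_start, max_surface=g.max_surface,
                    anisotropy=list(g.anisotropy) if g.anisotropy else None,
                    couple_diffusion=g.couple_diffusion),
        shape=list(config.shape),
        initial_condition=config.initial_condition,
        n_iter=config.n_iter,
        snapshot_interval=config.snapshot_interval,
        seed=config.seed,
        noise_amplitude=config.noise_amplitude,
        n_stripes=config.n_stripes,
        stripe_width=config.stripe_width,
    )


def config_from_dict(data: dict) -> SimulationConfig:
    growth = dict(data.get("growth", {}))
    if growth.get("anisotropy"):
        growth["anisotropy"] = tuple(growth["anisotropy"])
    return SimulationConfig(
        reaction=ReactionParams(**data["reaction"]),
        growth=GrowthSchedule(**growth),
        shape=tuple(data.get("shape", (200, 200))),
        initial_condition=data.get("initial_condition", "random_noise"),
        n_iter=data.get("n_iter", 75_000),
        snapshot_interval=data.get("snapshot_interval", 250),
        seed=data.get("seed", 0),
        noise_amplitude=data.get("noise_amplitude", 0.5),
        n_stripes=data.get("n_stripes", 5),
        stripe_width=data.get("stripe_width"),
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)
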