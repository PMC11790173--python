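"""Colour rendering of simulated patterns.

Two colouration mechanisms are supported.  The instantaneous readout paints
each pixel from the current activator state, either as a hard two-colour
threshold (pigment cells commit to one of two pigments) or as a continuous
interpolation (intermediate states give intermediate colours, the
non-equilibrium mechanism).  The memory mechanism averages the threshold
readout over the whole recorded history: a region that spent part of the
patterning period in each state ends up with an intermediate colour — this
is how rosette centres and intermediate bands acquire their third colour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .engine import MAX_A, MIN_A, SimulationHistory

__all__ = ["Palette", "PALETTES", "render_instant", "render_memory"]


#: Default binary-readout threshold on the substrate field a.  At pattern
#: equilibrium a is depleted inside pigment spots (~2.5) and elevated in the
#: background (~3.4); 3.0 splits the two states for all presets.  The
#: homogeneous fixed point (a = 4) is NOT a useful threshold: once a pattern
#: exists the whole field sits below it.
DEFAULT_THRESHOLD = 3.0


@dataclass(frozen=True)
class Palette:
    """Two pole colours (RGB in [0,1]) and the activator threshold for the
    binary readout."""

    dark: tuple[float, float, float] = (0.0, 0.0, 0.0)
    light: tuple[float, float, float] = (1.0, 1.0, 1.0)
    threshold: float = DEFAULT_THRESHOLD
    min_a: float = MIN_A
    max_a: float = MAX_A

    def __post_init__(self):
        for c in (*self.dark, *self.light):
            if not 0.0 <= c <= 1.0:
                raise ValueError("palette channels must lie in [0, 1]")
        if not self.min_a <= self.threshold <= self.max_a:
            raise ValueError("threshold must lie within the activator clamp range")


#: Named palettes: dark pigment vs light background.
PALETTES: dict[str, Palette] = {
    "leopard": Palette(dark=(0.15, 0.09, 0.05), light=(0.95, 0.82, 0.55)),
    "emu": Palette(dark=(0.12, 0.10, 0.08), light=(0.85, 0.78, 0.65)),
    "grey": Palette(),
}


def render_instant(
    a: np.ndarray,
    palette: Palette | None = None,
    mode: Literal["threshold", "continuous"] = "threshold",
) -> np.ndarray:
    """Colour one activator snapshot; returns an (H, W, 3) array in [0, 1].

    ``threshold``: dark where a <= threshold, light where a > threshold.
    ``continuous``: linear palette interpolation by (a - minA)/(maxA - minA).
    """
    if palette is None:
        palette = PALETTES["grey"]
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2D activator field")
    if not np.isfinite(a).all():
        raise FloatingPointError("non-finite activator field")
    dark = np.asarray(palette.dark)
    light = np.asarray(palette.light)
    if mode == "threshold":
        w = (a > palette.threshold).astype(float)
    elif mode == "continuous":
        w = np.clip((a - palette.min_a) / (palette.max_a - palette.min_a), 0.0, 1.0)
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    return w[..., None] * light + (1.0 - w[..., None]) * dark


def render_memory(
    history: SimulationHistory,
    palette: Palette | None = None,
    from_growth_start: bool = False,
) -> np.ndarray:
    """Memory-mechanism colouration: per-pixel mean of the threshold readout
    over all snapshots.

    Pixels dark throughout stay dark, light throughout stay light, and mixed
    histories give intermediate colours in proportion to the time spent in
    each state.  ``from_growth_start`` restricts the average to snapshots
    taken at or after the growth start.
    """
    if palette is None:
        palette = PALETTES["grey"]
    if len(history) == 0:
        raise ValueError("history is empty")
    snapshots = history.a_snapshots
    if from_growth_start and history.growth_start_iteration is not None:
        t0 = history.growth_start_iteration
        snapshots = [s for t, s in zip(history.iterations, snapshots) if t >= t0]
    acc = np.zeros((*snapshots[0].shape, 3))
    for snap in snapshots:
        acc += render_instant(snap, palette, mode="threshold")
    return acc / len(snapshots)
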