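"""Seeded synthetic-input generators.

Every generator is a pure function of its parameters and seed (regenerating
with the same arguments is bit-identical), so test inputs and demo data are
built at run time instead of being stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .timing import DistanceTrajectory, MotifCountSet

__all__ = [
    "generate_blob_image",
    "generate_trajectories",
    "generate_segment_table",
    "generate_record_set",
]


def generate_blob_image(
    n_blobs: int,
    shape: tuple[int, int] = (256, 256),
    min_separation: float = 30.0,
    seed: int = 0,
    sigma: float | None = None,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs at rejection-sampled positions.

    Returns the greyscale image (float, background 0, blob peaks ~1) and the
    (n, 2) array of true centres in (row, col) order.  Raises if the blobs
    cannot be packed at the requested separation within a bounded number of
    tries.
    """
    h, w = shape
    if n_blobs == 0:
        return np.zeros(shape), np.empty((0, 2))
    if min_separation > min(h, w):
        raise ValueError("blobs cannot fit at the requested separation")
    rng = np.random.default_rng(seed)
    margin = min_separation / 2
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_blobs:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_blobs} blobs at separation {min_separation} "
                f"in {shape} after {max_tries} tries")
        tries += 1
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - c)) >= min_separation for c in centers):
            centers.append(cand)
    centers_arr = np.array(centers)
    sigma = sigma if sigma is not None else min_separation / 6.0
    yy, xx = np.mgrid[:h, :w]
    image = np.zeros(shape)
    for cy, cx in centers_arr:
        image += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return image, centers_arr


def generate_trajectories(
    n_distances: int = 5,
    stages: tuple[float, ...] = tuple(range(1, 11)),
    formation_stage: float = 5.0,
    wavelength: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[DistanceTrajectory], MotifCountSet]:
    """Synthetic morphometric trajectories with a known formation stage.

    Each distance grows linearly through an exact integer number of
    wavelengths at ``formation_stage`` (so the noiseless recovery is exact);
    the reference distance ("head") grows slowest, making every relative
    trajectory strictly increasing and invertible.  ``noise`` applies
    multiplicative Gaussian noise to the motif counts only.
    """
    stages = tuple(float(s) for s in stages)
    if not stages[0] <= formation_stage <= stages[-1]:
        raise ValueError("formation_stage must lie within the stage range")
    rng = np.random.default_rng(seed)
    span = stages[-1] - stages[0]

    # integer motif counts at formation, head smallest
    k_head = 4
    ks = {"head": k_head}
    for i in range(n_distances):
        ks[f"dist{i + 1}"] = k_head + 2 * (i + 1)

    # growth rate per stage unit: head slowest, others faster and distinct,
    # capped so every length stays positive back to the first stage
    max_rate = 0.9 / max(formation_stage - stages[0], span / 4)
    rates = {"head": 0.05 * max_rate}
    for i in range(n_distances):
        rates[f"dist{i + 1}"] = max_rate * (0.4 + 0.6 * (i + 1) / (n_distances + 1))

    trajectories = []
    counts = {}
    for did, k in ks.items():
        length_at_formation = k * wavelength
        if length_at_formation <= 0:
            raise ValueError("wavelength too large for the shortest distance")
        rate = rates[did]
        lengths = tuple(
            length_at_formation * (1.0 + rate * (s - formation_stage)) for s in stages
        )
        if min(lengths) <= 0:
            raise ValueError("wavelength/rate combination yields non-positive lengths")
        trajectories.append(DistanceTrajectory(did, stages, lengths))
        c = float(k)
        if noise > 0:
            c = max(1.0, c * (1.0 + noise * rng.standard_normal()))
        counts[did] = c
    return trajectories, MotifCountSet(counts=counts, reference="head")


def generate_segment_table(
    n_segments: int = 22,
    shape: tuple[int, int] = (200, 200),
    factor_range: tuple[float, float] = (1.0, 4.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Random landmark segments with uniform growth factors.

    Columns: id, x1, y1, x2, y2, length_stage_a, length_stage_b (lengths are
    consistent with the drawn growth factor).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    rows = []
    for i in range(n_segments):
        while True:
            y1, y2 = rng.uniform(0, h - 1, 2)
            x1, x2 = rng.uniform(0, w - 1, 2)
            if (y1, x1) != (y2, x2):
                break
        factor = rng.uniform(*factor_range)
        length_a = rng.uniform(5.0, 50.0)
        rows.append(dict(id=f"seg{i + 1}", x1=x1, y1=y1, x2=x2, y2=y2,
                         length_stage_a=length_a, length_stage_b=length_a * factor))
    return pd.DataFrame(rows)


def generate_record_set(
    n_records: int = 620,
    n_growth_pattern: int = 62,
    n_classic_only: int = 268,
    rank: str = "order",
    seed: int = 0,
):
    """Survey records with prescribed label composition (for tally tests)."""
    from .survey import CATEGORIES, PatternRecord

    if n_growth_pattern + n_classic_only > n_records:
        raise ValueError("label counts exceed the record total")
    rng = np.random.default_rng(seed)
    cats = sorted(CATEGORIES)
    records = []
    for i in range(n_records):
        taxon = f"{rank}_{i + 1:05d}"
        if i < n_growth_pattern:
            records.append(PatternRecord(
                taxon=taxon, rank=rank, growth_label="Y", classic_label="Y",
                categories=frozenset({cats[int(rng.integers(len(cats)))]}),
                motif_count_at_least_3=True,
            ))
        elif i < n_growth_pattern + n_classic_only:
            records.append(PatternRecord(taxon=taxon, rank=rank,
                                         classic_label="Y", growth_label="N?"))
        else:
            records.append(PatternRecord(taxon=taxon, rank=rank,
                                         classic_label="N?", growth_label="N?"))
    return records
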