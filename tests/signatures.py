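"""Shared qualitative-signature checks for the published simulation
scenarios (used by both the scenario smoke tests and the acceptance suite)."""

from skimage.measure import label, regionprops

from turingrowth.metrics import binarize, count_motifs


def components(b_field) -> int:
    return int(label(binarize(b_field, 4.0).values, connectivity=2).max())


def check_spot_preset_subdivides(history, t_start):
    """Noise presets: a spot pattern exists before growth and the motif
    count rises clearly by the final equilibrium."""
    pre = count_motifs(history.b_snapshots[history.index_at(t_start)])
    final = count_motifs(history.b_snapshots[-1])
    assert pre >= 3
    assert final > 1.5 * pre
    return pre, final


def check_stripe_preset_interleaves(history, t_start):
    """Middle-stripe presets: the stripe count rises as new stripes are
    inserted between pre-existing ones."""
    pre = components(history.b_snapshots[history.index_at(t_start)])
    final = components(history.b_snapshots[-1])
    assert final > pre
    return pre, final


def check_stripes_break_into_dots(history, t_start):
    """Periodic stripes in the spot regime fragment into rows of dots."""
    lab_final = label(binarize(history.b_snapshots[-1], 4.0).values, connectivity=2)
    pre = components(history.b_snapshots[history.index_at(t_start)])
    assert lab_final.max() >= 3 * pre
    height = history.b_snapshots[-1].shape[0]
    tallest = max(r.bbox[2] - r.bbox[0] for r in regionprops(lab_final))
    assert tallest < height  # no surviving full-height stripe
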