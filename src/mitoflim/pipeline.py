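"""Convenience drivers composing fit -> segment -> measure -> track."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import fit_flim_image
from .scene import RenderedStack
from .segment import SegmentationParams, segment_frame
from .tcspc import IRFCurve, gaussian_irf
from .tracking import Track, track_lap, track_lifetime_traces


def measure_stack(
    rendered: RenderedStack,
    irf: IRFCurve | None = None,
    spatial_binning: int = 1,
    photon_floor: int = 100,
    seg_params: SegmentationParams = SegmentationParams(),
    with_tracks: bool = False,
    max_link_dist: float = 10.0,
    max_gap: int = 2,
):
    """Fit, segment and measure every frame of a rendered stack.

    Returns ``(objects, masks, maps_by_frame)`` — or with
    ``with_tracks=True`` ``(objects, tracks, traces)`` where traces are
    per-track lifetime time series.  Objects additionally carry
    ``true_object_id``: the majority ground-truth label under each
    segmented footprint (-1 where the footprint is mostly background),
    which lets tests score identity against the simulation truth.
    """
    irf = irf or gaussian_irf(rendered.cfg)
    nucleus = rendered.scene.nucleus_centroid
    frames = []
    masks = []
    maps_by_frame = []
    for f in range(rendered.counts.shape[0]):
        maps = fit_flim_image(
            rendered.counts[f], irf, spatial_binning=spatial_binning, photon_floor=photon_floor
        )
        mask, objects = segment_frame(
            maps["photons"], maps["tau"], nucleus, seg_params, frame=f
        )
        truth = rendered.label_mask[f]
        ids = []
        from skimage import measure as skmeasure

        labeled = skmeasure.label(mask, connectivity=2)
        for _, row in objects.iterrows():
            sel = labeled == row["label"]
            under = truth[sel]
            under = under[under > 0]
            ids.append(int(np.bincount(under).argmax()) - 1 if under.size else -1)
        objects = objects.assign(true_object_id=ids)
        frames.append(objects)
        masks.append(mask)
        maps_by_frame.append(maps)
    objects = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not with_tracks:
        return objects, masks, maps_by_frame
    tracks = track_lap(objects, max_link_dist=max_link_dist, max_gap=max_gap)
    traces = track_lifetime_traces(tracks, objects)
    return objects, tracks, traces
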