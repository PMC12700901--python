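"""Simple LAP tracking of segmented objects.

Frame-to-frame linking is posed as a linear assignment problem in the
Jaqaman formulation: the cost of linking object i (frame t) to object j
(frame t+1) is their squared centroid distance; links beyond
``max_link_dist`` are forbidden; every object may instead terminate (death)
or appear (birth) at an alternative cost of ``1.05 * max_link_dist**2``.
The augmented (n+m) x (n+m) matrix is solved exactly with the Hungarian
algorithm.  A second assignment round closes gaps: a track that disappears
for up to ``max_gap`` frames is reconnected to a later track start within
``gap_dist``.  The whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

ALT_COST_FACTOR = 1.05  # birth/death cost relative to max link cost
_FORBIDDEN = 1e18


@dataclass
class Track:
    """One object's identity over time."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)  # (last frame before, first after)

    def __len__(self) -> int:
        return len(self.frames)


def _link_pair(
    pos_a: np.ndarray, pos_b: np.ndarray, max_cost: float
) -> list[tuple[int, int]]:
    """Solve one frame-pair LAP with birth/death; returns (i, j) links."""
    n, m = len(pos_a), len(pos_b)
    if n == 0 or m == 0:
        return []
    d2 = ((pos_a[:, None, :] - pos_b[None, :, :]) ** 2).sum(axis=2)
    alt = ALT_COST_FACTOR * max_cost
    big = np.full((n + m, n + m), _FORBIDDEN)
    big[:n, :m] = np.where(d2 <= max_cost, d2, _FORBIDDEN)
    big[np.arange(n), m + np.arange(n)] = alt  # deaths
    big[n + np.arange(m), np.arange(m)] = alt  # births
    big[n:, m:] = big[:n, :m].T  # lower-right completion block
    rows, cols = linear_sum_assignment(big)
    return [(i, j) for i, j in zip(rows, cols) if i < n and j < m and big[i, j] < _FORBIDDEN]


def track_lap(
    objects: pd.DataFrame,
    max_link_dist: float = 10.0,
    max_gap: int = 2,
    gap_dist: float | None = None,
) -> list[Track]:
    """Link per-frame objects into tracks (Simple LAP with gap closing).

    ``objects`` needs columns frame, label, centroid_row, centroid_col
    (the layout produced by ``segment.label_and_measure``).  ``gap_dist``
    defaults to ``max_link_dist``.
    """
    required = {"frame", "label", "centroid_row", "centroid_col"}
    if not required.issubset(objects.columns):
        raise ValueError(f"objects table needs columns {sorted(required)}")
    if gap_dist is None:
        gap_dist = max_link_dist
    frames = sorted(objects["frame"].unique())
    if not frames:
        return []
    by_frame = {
        f: objects[objects["frame"] == f].reset_index(drop=True) for f in frames
    }

    # 1) frame-to-frame tracklets
    tracks: list[Track] = []
    active: dict[int, Track] = {}  # row index in current frame -> track
    f0 = frames[0]
    for idx, row in by_frame[f0].iterrows():
        t = Track(track_id=len(tracks), frames=[f0], labels=[int(row["label"])])
        tracks.append(t)
        active[idx] = t
    max_cost = max_link_dist**2
    for fa, fb in zip(frames[:-1], frames[1:]):
        a, b = by_frame[fa], by_frame[fb]
        pos_a = a[["centroid_row", "centroid_col"]].to_numpy()
        pos_b = b[["centroid_row", "centroid_col"]].to_numpy()
        links = _link_pair(pos_a, pos_b, max_cost) if fb == fa + 1 else []
        next_active: dict[int, Track] = {}
        linked_b = set()
        for i, j in links:
            t = active.get(i)
            if t is None:
                continue
            t.frames.append(fb)
            t.labels.append(int(b.loc[j, "label"]))
            next_active[j] = t
            linked_b.add(j)
        for j in range(len(b)):
            if j not in linked_b:
                t = Track(track_id=len(tracks), frames=[fb], labels=[int(b.loc[j, "label"])])
                tracks.append(t)
                next_active[j] = t
        active = next_active

    # 2) gap closing: connect track ends to later track starts
    def endpoints():
        ends, starts = [], []
        for t in tracks:
            ends.append((t.frames[-1], t))
            starts.append((t.frames[0], t))
        return ends, starts

    merged = True
    while merged:
        merged = False
        ends, starts = endpoints()
        candidates = []
        for fe, te in ends:
            pe = _centroid_of(by_frame[fe], te.labels[-1])
            for fs, ts in starts:
                if ts is te or not (1 < fs - fe <= max_gap + 1):
                    continue
                ps = _centroid_of(by_frame[fs], ts.labels[0])
                dist2 = ((pe - ps) ** 2).sum()
                if dist2 <= gap_dist**2:
                    candidates.append((dist2, te, ts))
        if not candidates:
            break
        # greedy-lowest-cost merge; re-scan after each (exact enough at the
        # small object counts this pipeline targets, and deterministic)
        candidates.sort(key=lambda c: c[0])
        _, te, ts = candidates[0]
        te.gaps.append((te.frames[-1], ts.frames[0]))
        te.frames.extend(ts.frames)
        te.labels.extend(ts.labels)
        te.gaps.extend(ts.gaps)
        tracks.remove(ts)
        merged = True

    for new_id, t in enumerate(tracks):
        t.track_id = new_id
    return tracks


def _centroid_of(frame_df: pd.DataFrame, label: int) -> np.ndarray:
    row = frame_df[frame_df["label"] == label].iloc[0]
    return row[["centroid_row", "centroid_col"]].to_numpy(dtype=float)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a (track_id, frame, label, gap_after) table."""
    rows = []
    for t in tracks:
        gap_starts = {g[0] for g in t.gaps}
        for f, lab in zip(t.frames, t.labels):
            rows.append(dict(track_id=t.track_id, frame=f, label=lab,
                             gap_after=f in gap_starts))
    return pd.DataFrame(rows, columns=["track_id", "frame", "label", "gap_after"])


def track_lifetime_traces(tracks: list[Track], objects: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Per-track (frame, mean_tau_ns) traces joined from the objects table."""
    out = {}
    keyed = objects.set_index(["frame", "label"])
    for t in tracks:
        recs = []
        for f, lab in zip(t.frames, t.labels):
            row = keyed.loc[(f, lab)]
            recs.append(dict(frame=f, mean_tau_ns=float(row["mean_tau_ns"])))
        out[t.track_id] = pd.DataFrame(recs)
    return out
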