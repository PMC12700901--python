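"""On-disk formats.

FLIM container
--------------
A rendered stack is a directory:

    counts.npy      uint32 array, shape (n_frames, H, W, n_bins)
    meta.json       {"bin_width_ps", "rep_rate_MHz", "n_bins", "n_frames",
                     "shape", "seed", "irf": "irf.csv", ...}
    irf.csv         two columns: bin_ns, counts
    truth_tau.tif   multi-page float32 TIFF, one page per frame (optional)
    truth_intensity.tif, truth_labels.tif        (optional)
    truth_objects.csv, truth_events.json         (optional)

Single decays travel as plain two-column CSV (bin_ns, counts); object and
track tables as CSV; maps as multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tcspc import DecayHistogram, IRFCurve


def write_decay_csv(path, hist: DecayHistogram) -> None:
    df = pd.DataFrame({"bin_ns": hist.bin_centers_ns, "counts": hist.counts})
    df.to_csv(path, index=False)


def read_decay_csv(path) -> DecayHistogram:
    df = pd.read_csv(path)
    if not {"bin_ns", "counts"}.issubset(df.columns):
        raise ValueError("decay CSV needs columns bin_ns, counts")
    t = df["bin_ns"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t)))
    return DecayHistogram(df["counts"].to_numpy(), bin_width_ps=dt * 1e3, t0_ns=float(t[0] - dt / 2))


def write_irf_csv(path, irf: IRFCurve) -> None:
    t = (np.arange(irf.counts.size) + 0.5) * irf.bin_width_ps * 1e-3
    pd.DataFrame({"bin_ns": t, "counts": irf.counts}).to_csv(path, index=False)


def read_irf_csv(path) -> IRFCurve:
    df = pd.read_csv(path)
    t = df["bin_ns"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t)))
    return IRFCurve(df["counts"].to_numpy(dtype=float), bin_width_ps=dt * 1e3)


def save_stack(outdir, rendered, irf: IRFCurve | None = None) -> Path:
    """Write a RenderedStack (counts + metadata + ground truth) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "counts.npy", rendered.counts)
    cfg = rendered.cfg
    meta = {
        "bin_width_ps": cfg.bin_width_ps,
        "rep_rate_MHz": cfg.rep_rate_MHz,
        "n_bins": cfg.n_bins,
        "n_frames": int(rendered.counts.shape[0]),
        "shape": list(rendered.counts.shape[1:3]),
        "seed": cfg.seed,
        "irf": "irf.csv",
        "irf_center_ns": cfg.irf_center_ns,
        "irf_fwhm_ns": cfg.irf_fwhm_ns,
        "nucleus_centroid": list(rendered.scene.nucleus_centroid)
        if rendered.scene.nucleus_centroid
        else None,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    if irf is None:
        from .tcspc import gaussian_irf

        irf = gaussian_irf(cfg)
    write_irf_csv(outdir / "irf.csv", irf)
    tifffile.imwrite(outdir / "truth_tau.tif", rendered.tau_map.astype(np.float32))
    tifffile.imwrite(outdir / "truth_intensity.tif", rendered.intensity_map.astype(np.float32))
    tifffile.imwrite(outdir / "truth_labels.tif", rendered.label_mask.astype(np.int32))
    rendered.objects.to_csv(outdir / "truth_objects.csv", index=False)
    events = [
        dict(object_id=e.object_id, onset_frame=e.onset_frame,
             duration_frames=e.duration_frames, delta_psi_shift=e.delta_psi_shift)
        for e in rendered.events
    ]
    (outdir / "truth_events.json").write_text(json.dumps(events, indent=1))
    return outdir


def load_stack(indir) -> tuple[np.ndarray, dict, IRFCurve]:
    """Load (counts, metadata, IRF) from a FLIM container directory."""
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    counts = np.load(indir / "counts.npy")
    irf = read_irf_csv(indir / meta.get("irf", "irf.csv"))
    return counts, meta, irf


def write_maps_tiff(path, maps: dict[str, np.ndarray], keys=("tau", "photons", "chi2_reduced")) -> None:
    """Stack selected maps into one multi-page float32 TIFF."""
    pages = np.stack([np.asarray(maps[k], dtype=np.float32) for k in keys])
    tifffile.imwrite(path, pages, metadata={"page_names": list(keys)})


def write_fit_table(path, fits, extra: dict | None = None) -> None:
    """FitResult sequence -> CSV (one row per decay)."""
    rows = []
    for i, f in enumerate(fits):
        row = dict(
            index=i,
            n=f.n,
            tau_av_int_ns=f.tau_av_int,
            chi2=f.chi2,
            chi2_reduced=f.chi2_reduced,
            converged=f.converged,
            accepted=f.accepted,
            total_photons=f.total_photons,
            tail_offset=f.tail_offset,
            irf_shift_bins=f.irf_shift,
            irf_background=f.irf_background,
        )
        for k in range(f.n):
            row[f"A{k + 1}"] = f.amplitudes[k]
            row[f"tau{k + 1}_ns"] = f.lifetimes[k]
        if extra:
            row.update(extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
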