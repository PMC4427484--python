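"""Writers: CSV traces, legacy-ASCII VTK structured grids, outlines, run logs, plots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .diagnostics import DiagnosticSeries
from .fluid import Grid

__all__ = [
    "write_traces_csv",
    "write_vtk_structured",
    "write_outline_csv",
    "write_outline_vtk",
    "write_run_log",
    "write_run_outputs",
    "plot_traces",
    "plot_snapshot",
]


def write_traces_csv(series: DiagnosticSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_dataframe().to_csv(path, index=False)
    return path


def write_vtk_structured(path, grid: Grid, fields: dict) -> Path:
    """Cell-centred fields as a legacy-ASCII VTK STRUCTURED_POINTS file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny = grid.nx, grid.ny
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nventriflow snapshot\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write(f"ORIGIN {grid.x0 + grid.h / 2} {grid.y0 + grid.h / 2} 0\n")
        f.write(f"SPACING {grid.h} {grid.h} 1\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # x-fastest ordering
            np.savetxt(f, arr.T.reshape(ny, nx), fmt="%.6e")
    return path


def write_outline_csv(outline_mm: np.ndarray, path) -> Path:
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"x_mm": outline_mm[:, 0], "y_mm": outline_mm[:, 1]}).to_csv(
        path, index=False
    )
    return path


def write_outline_vtk(outline_mm: np.ndarray, path) -> Path:
    """Closed outline as legacy-ASCII VTK POLYDATA polyline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(outline_mm)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nventriflow outline\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {n} float\n")
        for x, y in outline_mm:
            f.write(f"{x:.6f} {y:.6f} 0\n")
        f.write(f"LINES 1 {n + 1}\n")
        f.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")
    return path


def _grid_meta(grid: Grid) -> dict:
    return {"nx": grid.nx, "ny": grid.ny, "h_m": grid.h, "x0_m": grid.x0, "y0_m": grid.y0}


def write_run_log(series: DiagnosticSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(series.meta)
    meta["grid"] = _grid_meta(meta["grid"])
    meta["impacts"] = series.impacts
    meta["max_cfl"] = float(np.max(series.cfl_history)) if len(series.cfl_history) else None
    with open(path, "w") as f:
        json.dump(meta, f, indent=2, default=str)
    return path


def write_run_outputs(series: DiagnosticSeries, outdir, config_echo: dict | None = None):
    """Standard run directory: traces, config echo, log, snapshots (VTK + npz)."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_traces_csv(series, outdir / "traces.csv")
    write_run_log(series, outdir / "run_log.json")
    echo = config_echo if config_echo is not None else series.meta.get("config", {})
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=False))
    grid = series.meta["grid"]
    if series.snapshots:
        bundle = {}
        for ts, snap in series.snapshots.items():
            write_vtk_structured(outdir / f"snapshot_tstar_{ts:.3f}.vtk", grid, snap)
            for name, arr in snap.items():
                bundle[f"{ts:.3f}/{name}"] = arr
        np.savez_compressed(outdir / "snapshots.npz", **bundle)
    return outdir


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_traces(series: DiagnosticSeries, path) -> Path:
    """Four-panel trace figure: volume, inlet velocity, leaflet angles, rates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    ts = series.t_star
    axes[0, 0].plot(ts, series.volume_ml)
    axes[0, 0].set_ylabel("ventricular volume (ml)")
    axes[0, 1].plot(ts, series.v_inlet)
    axes[0, 1].set_ylabel("mitral inflow velocity (m/s)")
    styles = {"anterior": "-.", "posterior": "-"}
    for label in series.theta:
        axes[1, 0].plot(ts, series.theta[label], styles.get(label, "-"), label=label)
        axes[1, 1].plot(ts, series.omega[label], styles.get(label, "-"), label=label)
    axes[1, 0].set_ylabel("opening angle (deg)")
    axes[1, 1].set_ylabel("angular velocity (rad/s)")
    for ax in axes[1]:
        ax.set_xlabel("T* = t/T")
    axes[1, 0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path


def plot_snapshot(series_or_npz, t_star: float, path, clim: float | None = None) -> Path:
    """Vorticity contours + velocity quiver for the snapshot nearest to T*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(series_or_npz, DiagnosticSeries):
        have = sorted(series_or_npz.snapshots)
        nearest = min(have, key=lambda s: abs(s - t_star))
        snap = series_or_npz.snapshots[nearest]
        grid = series_or_npz.meta["grid"]
        meta = _grid_meta(grid)
    else:  # a snapshots.npz archive path
        data = np.load(series_or_npz)
        keys = sorted({k.split("/")[0] for k in data.files})
        nearest = min(keys, key=lambda s: abs(float(s) - t_star))
        snap = {n: data[f"{nearest}/{n}"] for n in ("u", "v", "p", "vorticity", "solid_mask")}
        nx, ny = snap["p"].shape
        meta = None
        nearest = float(nearest)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    om = np.ma.masked_where(snap["solid_mask"] > 0, snap["vorticity"])
    fig, ax = plt.subplots(figsize=(6, 8))
    lim = clim if clim is not None else float(np.nanpercentile(np.abs(om.filled(0.0)), 99))
    extent = None
    if meta:
        extent = [
            meta["x0_m"] * 1e3,
            (meta["x0_m"] + meta["nx"] * meta["h_m"]) * 1e3,
            meta["y0_m"] * 1e3,
            (meta["y0_m"] + meta["ny"] * meta["h_m"]) * 1e3,
        ]
    im = ax.imshow(
        om.T, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim, extent=extent
    )
    st = max(1, snap["u"].shape[0] // 32)
    ax.set_title(f"out-of-plane vorticity, T* = {nearest:.3f}")
    fig.colorbar(im, ax=ax, label="vorticity (1/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path
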