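"""Thin rendering layer: every plot's numbers are also written as CSV."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import BifurcationScan, PcaProjection, PhasePlane, RobustnessScan
from .limitcycle import Trajectory

__all__ = ["plot_timecourse", "plot_bifurcation", "plot_robustness",
           "plot_phase_plane", "plot_pca"]


def _save(fig, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_timecourse(traj: Trajectory, observables: dict[str, str],
                    out: str | Path) -> None:
    out = Path(out)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    frame = {"time_min": traj.t}
    for lab, var in observables.items():
        trace = traj.trace(var)
        ax.plot(traj.t, trace, label=lab)
        frame[lab] = trace
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (a.u.)")
    ax.legend(frameon=False)
    _save(fig, out)
    pd.DataFrame(frame).to_csv(out.with_suffix(".csv"), index=False)


def plot_bifurcation(scan: BifurcationScan, out: str | Path) -> None:
    out = Path(out)
    fig, ax = plt.subplots(figsize=(6, 4))
    osc = scan.env_max > scan.env_min
    ax.fill_between(scan.values, scan.env_min, scan.env_max, where=osc,
                    alpha=0.4, label="oscillation envelope")
    for k, (v, pts) in enumerate(zip(scan.values, scan.branches)):
        for bp in pts:
            style = {0: "-", 1: ":", 2: "--"}.get(bp.n_positive_eigenvalues, "--")
            ax.plot([v], [bp.value], marker=".", ls=style, color="gray",
                    markersize=3)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(scan.parameter)
    ax.set_ylabel(f"{scan.species} (a.u.)")
    _save(fig, out)
    rows = []
    for k in range(len(scan.values)):
        rows.append({"value": scan.values[k], "env_min": scan.env_min[k],
                     "env_max": scan.env_max[k], "verdict": scan.verdicts[k],
                     "branches": ";".join(
                         f"{bp.case_id}:{bp.value:.6g}:{bp.n_positive_eigenvalues}"
                         for bp in scan.branches[k])})
    pd.DataFrame(rows).to_csv(out.with_suffix(".csv"), index=False)


def plot_robustness(scan: RobustnessScan, out: str | Path) -> None:
    out = Path(out)
    fig, ax = plt.subplots(figsize=(5, 4))
    pc = ax.pcolormesh(scan.grid_x, scan.grid_y, scan.grid_amplitude,
                       shading="auto", cmap="Greens")
    fig.colorbar(pc, ax=ax, label=f"{scan.species} amplitude (a.u.)")
    ax.set_xlabel(f"log10 {scan.parameters[0]}")
    ax.set_ylabel(f"log10 {scan.parameters[1]}")
    _save(fig, out)
    pd.DataFrame({
        f"log10_{scan.parameters[0]}": scan.samples[:, 0],
        f"log10_{scan.parameters[1]}": scan.samples[:, 1],
        "amplitude": scan.amplitudes,
        "verdict": scan.verdicts,
    }).to_csv(out.with_suffix(".csv"), index=False)


def plot_phase_plane(plane: PhasePlane, out: str | Path,
                     color_by: str = "phenotype") -> None:
    out = Path(out)
    nx, ny = len(plane.grid_x), len(plane.grid_y)
    img = np.zeros((ny, nx))
    rows = []
    key_of: dict[tuple, int] = {}
    for j, yv in enumerate(plane.grid_y):
        for i, xv in enumerate(plane.grid_x):
            cell = plane.assignments[j][i]
            if color_by == "eigenvalues":
                img[j, i] = max((npos for _, npos in cell), default=-1)
            else:
                key = tuple(sorted(cid for cid, _ in cell))
                img[j, i] = key_of.setdefault(key, len(key_of))
            rows.append({
                f"log10_{plane.parameters[0]}": xv,
                f"log10_{plane.parameters[1]}": yv,
                "phenotypes": ";".join(str(cid) for cid, _ in cell),
                "positive_eigenvalues": ";".join(str(n) for _, n in cell),
            })
    fig, ax = plt.subplots(figsize=(5, 4))
    pc = ax.pcolormesh(plane.grid_x, plane.grid_y, img, shading="auto",
                       cmap="tab20" if color_by == "phenotype" else "viridis")
    fig.colorbar(pc, ax=ax)
    ax.set_xlabel(f"log10 {plane.parameters[0]}")
    ax.set_ylabel(f"log10 {plane.parameters[1]}")
    _save(fig, out)
    pd.DataFrame(rows).to_csv(out.with_suffix(".csv"), index=False)


def plot_pca(proj: PcaProjection, labels, out: str | Path) -> None:
    out = Path(out)
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(labels)
    uniq = sorted(set(labels))
    for u in uniq:
        idx = [i for i, lab in enumerate(labels) if lab == u]
        ax.scatter(proj.scores[idx, 0], proj.scores[idx, 1], s=14, label=str(u))
    evr = proj.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}% variance)")
    if len(uniq) <= 12:
        ax.legend(frameon=False, fontsize=7)
    _save(fig, out)
    pd.DataFrame({"PC1": proj.scores[:, 0], "PC2": proj.scores[:, 1],
                  "label": labels}).to_csv(out.with_suffix(".csv"), index=False)
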