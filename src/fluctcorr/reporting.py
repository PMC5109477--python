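"""Figure and HTML report generation from CLI artifacts.

Display conventions: stiffness difference maps are thresholded at
+/- 0.75 kcal/(mol A^2); correlation maps at +0.6 / -0.45 (red positive,
blue negative); decay-curve panels draw a 1/e guide line.  Thresholds live
here, not in the computation modules.
"""

from __future__ import annotations

import html
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .correlation import DEFAULT_NEG_MAX, DEFAULT_POS_MIN

__all__ = ["render_report", "DIFF_DISPLAY_THRESHOLD"]

#: |delta k| display threshold for difference heatmaps, kcal/(mol A^2)
DIFF_DISPLAY_THRESHOLD = 0.75


def _heatmap(matrix: np.ndarray, title: str, path: Path, cmap="viridis", vmin=None, vmax=None):
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(matrix, origin="lower", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_title(title)
    ax.set_xlabel("site index")
    ax.set_ylabel("site index")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _threshold_heatmap(matrix: np.ndarray, pos: float, neg: float, title: str, path: Path):
    mask = np.zeros_like(matrix)
    with np.errstate(invalid="ignore"):
        mask[matrix >= pos] = 1
        mask[matrix <= neg] = -1
    _heatmap(mask, title, path, cmap="bwr_r", vmin=-1, vmax=1)


def _curve_panel(df: pd.DataFrame, title: str, path: Path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df["lag_ps"], df["value"], lw=1.2)
    ax.axhline(1 / np.e, color="grey", ls="--", lw=0.8, label="1/e")
    ax.set_xlabel("lag (ps)")
    ax.set_ylabel("C(tau) / C(0)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _network_panel(edges: pd.DataFrame, path: Path):
    import networkx as nx

    fig, ax = plt.subplots(figsize=(5, 4.2))
    if edges.empty:
        ax.text(0.5, 0.5, "no edges", ha="center", va="center", fontsize=14)
        ax.set_axis_off()
    else:
        g = nx.DiGraph()
        for _, row in edges.iterrows():
            g.add_edge(row["driver"], row["follower"], weight=row["asymmetry"])
        pos = nx.circular_layout(g)
        nx.draw_networkx(g, pos=pos, ax=ax, node_color="#9ecae1", arrows=True, font_size=7)
        ax.set_axis_off()
    ax.set_title("causality network")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_report(outputs_dir) -> Path:
    """Render PNG panels + an HTML summary from whatever artifacts exist.

    Missing artifacts are listed as absent; the report always renders.
    Returns the path of the written HTML file.
    """
    outputs_dir = Path(outputs_dir)
    panels: list[tuple[str, Path]] = []
    absent: list[str] = []

    def matrix_csv(name: str):
        p = outputs_dir / name
        if not p.exists():
            absent.append(name)
            return None
        return pd.read_csv(p, index_col=0).to_numpy(dtype=float)

    k = matrix_csv("stiffness.csv")
    if k is not None:
        png = outputs_dir / "stiffness.png"
        _heatmap(k, "pairwise spring constants (kcal/mol/A^2)", png)
        panels.append(("Stiffness map", png))

    dk = matrix_csv("stiffness_diff.csv")
    if dk is not None:
        png = outputs_dir / "stiffness_diff.png"
        _threshold_heatmap(
            dk, DIFF_DISPLAY_THRESHOLD, -DIFF_DISPLAY_THRESHOLD,
            f"delta k thresholded at +/-{DIFF_DISPLAY_THRESHOLD}", png,
        )
        panels.append(("Stiffness difference", png))

    c = matrix_csv("xcorr.csv")
    if c is not None:
        png = outputs_dir / "xcorr.png"
        _threshold_heatmap(
            c, DEFAULT_POS_MIN, DEFAULT_NEG_MAX,
            f"correlations >= {DEFAULT_POS_MIN} (red) / <= {DEFAULT_NEG_MAX} (blue)", png,
        )
        panels.append(("Correlation map (thresholded)", png))

    curves = sorted(outputs_dir.glob("ctc_*.csv")) + sorted(outputs_dir.glob("autocorr*.csv"))
    if curves:
        for cf in curves:
            df = pd.read_csv(cf)
            if {"lag_ps", "value"} <= set(df.columns):
                png = cf.with_suffix(".png")
                _curve_panel(df, cf.stem, png)
                panels.append((f"Delayed correlation: {cf.stem}", png))
    else:
        absent.append("ctc_*.csv")

    edges_path = outputs_dir / "edges.csv"
    if edges_path.exists():
        edges = pd.read_csv(edges_path)
        png = outputs_dir / "network.png"
        _network_panel(edges, png)
        panels.append(("Causality network", png))
    else:
        absent.append("edges.csv")

    body = ["<html><head><title>fluctcorr report</title></head><body>"]
    body.append("<h1>fluctcorr analysis report</h1>")
    for title, png in panels:
        body.append(f"<h2>{html.escape(title)}</h2>")
        body.append(f'<img src="{png.name}" alt="{html.escape(title)}"/>')
    if absent:
        body.append("<h2>Absent artifacts</h2><ul>")
        body.extend(f"<li>{html.escape(a)}</li>" for a in absent)
        body.append("</ul>")
    summary = outputs_dir / "summary.json"
    if summary.exists():
        body.append("<h2>Summary</h2><pre>")
        body.append(html.escape(json.dumps(json.loads(summary.read_text()), indent=2)))
        body.append("</pre>")
    body.append("</body></html>")
    out = outputs_dir / "report.html"
    out.write_text("\n".join(body))
    return out
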