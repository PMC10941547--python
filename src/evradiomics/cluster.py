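"""Clustered heatmap of patients over the model inputs.

Patients (rows) are clustered over the 6 radiomic features + ΔEV PD-L1
(columns) after Z-score standardization of each variable, using Euclidean
distance and complete linkage.  The renderer draws the row dendrogram, the
reordered heatmap, and response/treatment annotation bars, and writes a
sidecar JSON with the leaf order and merge heights so the layout is
machine-checkable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

__all__ = ["StandardizedMatrix", "Dendrogram", "zscore_matrix", "hcluster", "render_heatmap"]


@dataclass
class StandardizedMatrix:
    """Patients x variables matrix of Z-scores plus optional annotations."""

    matrix: pd.DataFrame
    annotations: pd.DataFrame | None = None
    dropped_columns: tuple[str, ...] = ()


@dataclass
class Dendrogram:
    """Agglomeration result: SciPy linkage matrix and the leaf order."""

    linkage: np.ndarray
    leaf_order: np.ndarray
    method: str = "complete"
    metric: str = "euclidean"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def zscore_matrix(raw: pd.DataFrame, annotations: pd.DataFrame | None = None,
                  ddof: int = 1) -> StandardizedMatrix:
    """Z-score each variable (column): subtract its mean, divide by its SD.

    Sample SD (ddof=1) by default; constant columns carry no clustering
    information and are dropped with a warning.
    """
    raw = pd.DataFrame(raw)
    if len(raw) < 2:
        raise ValidationError("need at least 2 patients to standardize")
    if not np.all(np.isfinite(raw.to_numpy(dtype=np.float64))):
        raise ValidationError("matrix contains non-finite values")
    sd = raw.std(ddof=ddof)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {list(dropped)}", stacklevel=2)
        raw = raw.drop(columns=list(dropped))
        sd = sd.drop(labels=list(dropped))
    z = (raw - raw.mean()) / sd
    return StandardizedMatrix(matrix=z, annotations=annotations, dropped_columns=dropped)


def hcluster(matrix: pd.DataFrame | np.ndarray, metric: str = "euclidean",
             method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of rows; complete linkage merges at the
    maximum pairwise distance between clusters, so heights are monotone."""
    X = matrix.to_numpy(dtype=np.float64) if isinstance(matrix, pd.DataFrame) \
        else np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValidationError("matrix contains NaN/inf")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    return Dendrogram(linkage=Z, leaf_order=hierarchy.leaves_list(Z),
                      method=method, metric=metric)


_RESPONSE_COLORS = {"PR": "#1b9e77", "SD": "#7570b3", "PD": "#d95f02",
                    True: "#1b9e77", False: "#d95f02"}
_ARM_COLORS = {"ICI": "#386cb0", "chemo": "#fdb462"}


def render_heatmap(std: StandardizedMatrix, dendrogram: Dendrogram | None = None,
                   out_path: str | Path = "heatmap.png", cmap: str = "RdBu_r",
                   sidecar: bool = True) -> Path:
    """Render the clustered heatmap and write a JSON layout sidecar.

    Rows are reordered by the dendrogram's leaf order (computed on the fly
    when not given); annotation bars show response category and treatment
    when those columns exist in ``std.annotations``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    z = std.matrix
    if dendrogram is None:
        dendrogram = hcluster(z)
    order = dendrogram.leaf_order
    if len(order) != len(z):
        raise ValidationError("dendrogram size does not match matrix rows")
    zo = z.iloc[order]

    ann = std.annotations
    ann_cols = [c for c in ("response_category", "arm") if ann is not None and c in ann.columns]
    widths = [1.2] + [0.12] * len(ann_cols) + [4.0]
    fig, axes = plt.subplots(
        1, len(widths), figsize=(8 + 0.4 * len(ann_cols), max(4, 0.16 * len(z))),
        gridspec_kw={"width_ratios": widths, "wspace": 0.05})
    axes = np.atleast_1d(axes)

    ax_d = axes[0]
    with plt.rc_context({"lines.linewidth": 0.8}):
        hierarchy.dendrogram(dendrogram.linkage, orientation="left", ax=ax_d,
                             no_labels=True, color_threshold=0, above_threshold_color="k")
    ax_d.invert_yaxis()  # align leaf order with imshow's top-down rows
    ax_d.axis("off")

    for k, col in enumerate(ann_cols):
        ax = axes[1 + k]
        vals = ann[col].iloc[order]
        palette = _RESPONSE_COLORS if col == "response_category" else _ARM_COLORS
        colors = [palette.get(v, "#999999") for v in vals]
        # dendrogram plots leaves bottom-to-top in units of 10
        for i, c in enumerate(colors):
            ax.add_patch(plt.Rectangle((0, i), 1, 1, color=c))
        ax.set_xlim(0, 1)
        ax.set_ylim(0, len(colors))
        ax.invert_yaxis()
        ax.axis("off")
        ax.set_title(col.split("_")[0], fontsize=7, rotation=90, va="bottom")

    ax_h = axes[-1]
    vmax = float(np.nanmax(np.abs(zo.to_numpy()))) or 1.0
    im = ax_h.imshow(zo.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
                     interpolation="nearest")
    ax_h.set_yticks([])
    ax_h.set_xticks(range(zo.shape[1]))
    ax_h.set_xticklabels(zo.columns, rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax_h, shrink=0.5, label="Z-score")

    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    if sidecar:
        meta = {
            "leaf_order": [int(i) for i in order],
            "row_labels": [str(i) for i in z.index[order]],
            "merge_heights": [float(h) for h in dendrogram.merge_heights],
            "method": dendrogram.method,
            "metric": dendrogram.metric,
        }
        out_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return out_path
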