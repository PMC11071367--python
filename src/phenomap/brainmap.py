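"""Whole-brain ROI density mapping over aligned section images.

Each aligned section is polarity-normalized (stain high), divided by its
mean intensity, rescaled onto the 8-bit 0-255 scale by a fixed affine map,
and block-averaged over non-overlapping 5x5 tiles, giving one ROI grid per
animal (ROI edge = 5 px x 6.25 um ~ 31 um).  Per ROI, groups are compared by
one-way ANOVA with a Dunnett many-to-one post hoc against the control group;
maps of group means, F, or -log10 p are rendered as jet heatmaps on a fixed
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histoquant import SectionImage
from .stats import one_way_anova, posthoc

__all__ = [
    "RoiStatMap",
    "normalize_and_downsample",
    "roi_group_stats",
    "render_map",
]

#: fixed affine scale: an image at its own mean intensity maps to mid-gray
NORM_MIDPOINT = 127.5


@dataclass
class RoiStatMap:
    """Per-ROI group means, ANOVA F/p, and Dunnett-adjusted p-values."""

    table: pd.DataFrame  # one row per ROI
    grid_shape: tuple[int, int]
    groups: list[str]
    control: str
    alpha: float = 0.05
    fdr: bool = False
    extras: dict = field(default_factory=dict)

    def grid(self, column: str) -> np.ndarray:
        """Reshape one table column onto the ROI grid."""
        return self.table[column].to_numpy().reshape(self.grid_shape)

    @property
    def significant(self) -> np.ndarray:
        col = "q" if self.fdr else "p"
        return self.grid(col) < self.alpha


def normalize_and_downsample(img: SectionImage, block: int = 5) -> np.ndarray:
    """Normalize one section and block-average it onto the ROI grid.

    The stain-high image is divided by its mean and mapped through the fixed
    affine x -> 127.5*x (clipped to [0, 255]); 5x5 block means then define
    ~31 um ROIs at 6.25 um pixels.  Trailing partial tiles are dropped.
    """
    gray = img.stain_high()
    if gray.shape[0] < block or gray.shape[1] < block:
        raise ValueError("image smaller than one block")
    m = gray.mean()
    if m <= 0:
        raise ValueError("zero-mean image cannot be normalized")
    norm = np.clip(gray / m * NORM_MIDPOINT, 0.0, 255.0)
    r = (norm.shape[0] // block) * block
    c = (norm.shape[1] // block) * block
    tiles = norm[:r, :c].reshape(r // block, block, c // block, block)
    return tiles.mean(axis=(1, 3))


def roi_group_stats(
    grids: dict[str, list[np.ndarray]],
    control_label: str,
    alpha: float = 0.05,
    posthoc_method: str = "dunnett",
    fdr: bool = False,
) -> RoiStatMap:
    """Per-ROI one-way ANOVA across groups plus post hoc versus control.

    The post hoc is evaluated only for ROIs whose ANOVA p < alpha (post hoc
    analysis of significant ROIs); ``posthoc_method=None`` skips it.  Optional
    Benjamini-Hochberg correction across ROIs is off by default; enabling it
    is a deliberate departure from the per-ROI convention and is recorded in
    ``extras``.
    """
    if len(grids) < 2:
        raise ValueError("need at least 2 groups")
    if control_label not in grids:
        raise ValueError(f"control group {control_label!r} missing")
    shapes = {g.shape for lst in grids.values() for g in lst}
    if len(shapes) != 1:
        raise ValueError("all animals must share the ROI grid shape")
    shape = shapes.pop()
    for label, lst in grids.items():
        if len(lst) < 2:
            raise ValueError(f"group {label!r} has n < 2")

    stacked = {g: np.stack([a.ravel() for a in lst]) for g, lst in grids.items()}
    n_roi = int(np.prod(shape))
    groups = list(grids)
    others = [g for g in groups if g != control_label]

    rows = []
    ns = [len(lst) for lst in grids.values()]
    df_pair = (len(groups) - 1, int(sum(ns)) - len(groups))
    for i in range(n_roi):
        sample = {g: stacked[g][:, i] for g in groups}
        try:
            res = one_way_anova(sample)
            F, p = res.statistic, res.p
        except ValueError:
            # all animals identical at this ROI: no contrast, report F=0
            F, p = 0.0, 1.0
        row = {
            "roi_row": i // shape[1],
            "roi_col": i % shape[1],
            "F": F,
            "df1": df_pair[0],
            "df2": df_pair[1],
            "p": p,
        }
        for g in groups:
            row[f"mean_{g}"] = float(sample[g].mean())
        for g in others:
            row[f"p_{posthoc_method}_{g}"] = np.nan
        if posthoc_method and p < alpha:
            ph = posthoc(sample, method=posthoc_method,
                         control_label=control_label)
            for name, comp in ph.comparisons.items():
                g = name.split(" vs ")[0]
                row[f"p_{posthoc_method}_{g}"] = comp.p
        rows.append(row)
    table = pd.DataFrame(rows)

    extras = {}
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        extras["divergence"] = "BH-FDR across ROIs enabled (per-ROI p is the default)"
    return RoiStatMap(table, shape, groups, control_label, alpha, fdr, extras)


def render_map(
    values: np.ndarray,
    path: str,
    vmin: float,
    vmax: float,
    title: str = "",
    cmap: str = "jet",
) -> None:
    """Render one ROI-grid statistic as a heatmap PNG with a colorbar.

    ``vmin``/``vmax`` are caller-fixed so that all panels of one figure share
    the same scale.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not (np.isfinite(vmin) and np.isfinite(vmax)):
        raise ValueError("scale limits must be finite")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
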