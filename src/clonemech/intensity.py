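"""Junction fluorescence quantification.

Per-junction mean intensity is measured along the junction polyline
dilated to a configurable line width.  Raw intensities are normalized
per tissue by the mean intensity of that tissue's *external* junctions,
the internal control: normalized intensity Î = I / mean(I_external),
so the external class has mean 1 by construction and enrichment at
internal or peripheral junctions reads directly as a fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tissue import EXTERNAL, Tissue

DEFAULT_WIDTH_PX = 3  # measurement line width (the acquisition line width
# is not standardized; 3 px is a conventional thin-line choice)


def polyline_band(
    shape: tuple[int, int], polyline_px: np.ndarray, width_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) within ``width_px/2`` of a polyline, in px coords.

    ``polyline_px`` is (k, 2) in (x=col, y=row) pixel-center coordinates.
    Raises if the polyline leaves the image.
    """
    pts = np.asarray(polyline_px, dtype=float)
    h, w = shape
    if (
        pts[:, 0].min() < -0.5
        or pts[:, 1].min() < -0.5
        or pts[:, 0].max() > w - 0.5
        or pts[:, 1].max() > h - 0.5
    ):
        raise ValueError("polyline extends outside the image")
    half = width_px / 2.0
    pad = int(np.ceil(half)) + 1
    c0 = max(int(np.floor(pts[:, 0].min())) - pad, 0)
    c1 = min(int(np.ceil(pts[:, 0].max())) + pad + 1, w)
    r0 = max(int(np.floor(pts[:, 1].min())) - pad, 0)
    r1 = min(int(np.ceil(pts[:, 1].max())) + pad + 1, h)
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    d = _dist_to_polyline(cc.ravel(), rr.ravel(), pts)
    keep = d <= half
    return rr.ravel()[keep], cc.ravel()[keep]


def _dist_to_polyline(x: np.ndarray, y: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.column_stack([x, y]).astype(float)
    best = np.full(len(p), np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(p - a, axis=1)
        else:
            t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(p - proj, axis=1)
        best = np.minimum(best, d)
    if len(pts) == 1:
        best = np.linalg.norm(p - pts[0], axis=1)
    return best


def measure_junction(
    image: np.ndarray,
    polyline_um: np.ndarray,
    px: float,
    width_px: float = DEFAULT_WIDTH_PX,
) -> float:
    """Mean pixel intensity over the polyline dilated to ``width_px``.

    ``px`` is the image pixel size in µm.  Pixels near a shared vertex
    belong to the bands of all junctions meeting there (documented
    double counting).
    """
    if width_px < 1:
        raise ValueError("width must be ≥ 1 px")
    pts = np.asarray(polyline_um, dtype=float) / px
    rr, cc = polyline_band(image.shape, pts, width_px)
    if rr.size == 0:
        raise ValueError("empty measurement band")
    return float(image[rr, cc].mean())


def measure_tissue(
    image: np.ndarray,
    tissue: Tissue,
    classes: dict[int, str],
    px: float,
    width_px: float = DEFAULT_WIDTH_PX,
    tissue_id: str = "t0",
) -> pd.DataFrame:
    """Per-junction intensity records for all classified junctions."""
    rows = []
    for j in tissue.junctions:
        if j.id not in classes:
            continue
        rows.append(
            {
                "tissue": tissue_id,
                "junction_id": j.id,
                "cls": classes[j.id],
                "length_um": j.length,
                "intensity": measure_junction(image, j.polyline, px, width_px),
            }
        )
    return pd.DataFrame(rows)


def normalize_by_external(records: pd.DataFrame) -> pd.DataFrame:
    """Add Î = I / mean(I over external junctions of the same tissue).

    Denominators are strictly per tissue, never pooled.  Tissues without
    any external junction get NaN and ``norm_ok = False``.
    """
    df = records.copy()
    group = df.groupby("tissue") if "tissue" in df.columns else [(None, df)]
    denom = {}
    for name, sub in (group if isinstance(group, list) else group):
        ext = sub.loc[sub["cls"] == EXTERNAL, "intensity"]
        denom[name] = float(ext.mean()) if len(ext) else np.nan
    key = df["tissue"] if "tissue" in df.columns else pd.Series([None] * len(df))
    d = key.map(denom)
    df["norm_intensity"] = df["intensity"] / d
    df["norm_ok"] = d.notna() & (d != 0)
    return df


def class_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and median (the conventional headline statistic) of Î per class."""
    return (
        records.groupby("cls")["norm_intensity"]
        .agg(n="size", mean="mean", median="median", sd="std")
        .reset_index()
    )


@dataclass
class RegressionComparison:
    slope_a: float
    slope_b: float
    intercept_a: float
    intercept_b: float
    slope_diff: float
    slope_diff_p: float
    intercept_diff: float  # under a common slope
    intercept_diff_p: float


def intensity_length_regression(
    records: pd.DataFrame, class_a: str, class_b: str
) -> RegressionComparison:
    """OLS of raw intensity on junction length, compared between classes.

    The slope test is the interaction term of the two-class model; the
    intercept test is the class offset after imposing a common slope
    (standard ANCOVA sequence for comparing two regression lines).
    """
    sub = records[records["cls"].isin([class_a, class_b])]
    if sub.empty:
        raise ValueError("no records in the requested classes")
    y = sub["intensity"].to_numpy(dtype=float)
    length = sub["length_um"].to_numpy(dtype=float)
    is_b = (sub["cls"] == class_b).to_numpy(dtype=float)

    X_full = np.column_stack([np.ones_like(length), length, is_b, length * is_b])
    full = sm.OLS(y, X_full).fit()
    X_common = np.column_stack([np.ones_like(length), length, is_b])
    common = sm.OLS(y, X_common).fit()

    return RegressionComparison(
        slope_a=float(full.params[1]),
        slope_b=float(full.params[1] + full.params[3]),
        intercept_a=float(full.params[0]),
        intercept_b=float(full.params[0] + full.params[2]),
        slope_diff=float(full.params[3]),
        slope_diff_p=float(full.pvalues[3]),
        intercept_diff=float(common.params[2]),
        intercept_diff_p=float(common.pvalues[2]),
    )
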