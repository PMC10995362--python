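"""Choroidal thickness and vascularity from OCT B-scans.

The choroid on a structural OCT B-scan is the band between the retinal
pigment epithelium (RPE)-Bruch's membrane complex and the choroid-sclera
interface.  Given those two boundary polylines (one depth per image column,
supplied as annotations), the pipeline

1. *linearizes* the scan: every column is shifted vertically so the
   RPE-Bruch boundary lies on a common row, which removes retinal curvature
   before local thresholding;
2. binarizes the choroidal band with Niblack's local threshold
   ``T = local mean + k * local std`` — the dark (hyporeflective) class is
   the vessel *lumen*, the bright class the *stroma*;
3. integrates pixel counts into areas over eccentricity subfields on both
   sides of the fovea: luminal area LA, stromal area SA, total choroidal
   area TCA = LA + SA, and the choroidal vascularity index CVI = LA / TCA.

Retinal sublayer thicknesses (OPL, HFL+ONL, IS, OS, IZ+RPE) come from
intraretinal boundary polylines by per-column subtraction.  Repeatability of
repeated gradings is summarized by ICC(2,1) and the coefficient of
repeatability 1.96 x SD of paired differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_niblack

__all__ = [
    "BScan",
    "BoundarySet",
    "Subfield",
    "ChoroidQuant",
    "BinarizationParams",
    "SUBLAYER_BOUNDS",
    "INNER_SUBFIELD",
    "OUTER_SUBFIELD",
    "linearize",
    "niblack_binarize",
    "choroid_mask_from_boundaries",
    "choroid_metrics",
    "sublayer_thickness",
    "agreement_stats",
    "read_boundaries",
    "write_boundaries",
]

# layer name -> (upper boundary, lower boundary), shallow to deep
SUBLAYER_BOUNDS: dict[str, tuple[str, str]] = {
    "OPL": ("inl_opl", "opl_hfl"),
    "HFL+ONL": ("opl_hfl", "elm"),
    "IS": ("elm", "is_os"),
    "OS": ("is_os", "os_iz"),
    "IZ+RPE": ("os_iz", "rpe_bruch"),
}

# canonical depth order used to validate intraretinal annotations
_BOUNDARY_ORDER = ["inl_opl", "opl_hfl", "elm", "is_os", "os_iz", "rpe_bruch", "choroid_sclera"]


@dataclass(frozen=True)
class BScan:
    """One OCT B-scan with anisotropic physical scales (um/pixel)."""

    pixels: np.ndarray
    lateral_scale: float
    axial_scale: float
    fovea_column: int
    orientation: str = "horizontal"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("BScan.pixels must be 2-D")
        object.__setattr__(self, "pixels", px)
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("scales must be positive")
        if not (0 <= self.fovea_column < px.shape[1]):
            raise ValueError("fovea_column outside scan width")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be horizontal or vertical")


class BoundarySet:
    """Named boundary polylines: one depth (row, px) per column per boundary.

    Enforces choroid-sclera >= RPE-Bruch everywhere, and strict depth
    ordering of any intraretinal boundaries present.
    """

    def __init__(self, boundaries: dict[str, np.ndarray]):
        self._b = {k: np.asarray(v, dtype=float) for k, v in boundaries.items()}
        widths = {v.shape for v in self._b.values()}
        if len(widths) > 1:
            raise ValueError("all boundaries must span the same columns")
        for v in self._b.values():
            if v.ndim != 1:
                raise ValueError("each boundary must be a 1-D depth-per-column array")
        if "rpe_bruch" in self._b and "choroid_sclera" in self._b:
            if np.any(self._b["choroid_sclera"] < self._b["rpe_bruch"]):
                raise ValueError("choroid-sclera interface above RPE-Bruch complex")
        present = [n for n in _BOUNDARY_ORDER if n in self._b]
        for a, b in zip(present[:-1], present[1:]):
            if np.any(self._b[b] < self._b[a]):
                raise ValueError(f"boundary {b!r} crosses above {a!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self._b[name]

    def __contains__(self, name: str) -> bool:
        return name in self._b

    def names(self) -> list[str]:
        return list(self._b)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self._b.values())))

    def shifted(self, shifts: np.ndarray) -> "BoundarySet":
        return BoundarySet({k: v + shifts for k, v in self._b.items()})


@dataclass(frozen=True)
class Subfield:
    """Eccentricity strip applied on both sides of the fovea (mm)."""

    label: str
    lower_mm: float
    upper_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower_mm < self.upper_mm):
            raise ValueError("require 0 <= lower < upper eccentricity")


INNER_SUBFIELD = Subfield("inner", 0.5, 1.0)
OUTER_SUBFIELD = Subfield("outer", 1.0, 1.5)


@dataclass(frozen=True)
class ChoroidQuant:
    """CT (um) and LA/SA/TCA (mm^2) with CVI = LA/TCA."""

    CT: float
    LA: float
    SA: float
    TCA: float
    CVI: float
    subfield: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BinarizationParams:
    """Niblack local threshold T = mean + k*std over a square window (px)."""

    window: int = 51
    k: float = -0.2

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


def linearize(
    scan: BScan, boundaries: BoundarySet, fill_value: float = 0.0
) -> tuple[BScan, BoundarySet, np.ndarray]:
    """Flatten the scan so the RPE-Bruch boundary lies on a common row.

    Each column is shifted by an integer so RPE-Bruch lands on the median
    reference row; all boundaries are shifted consistently.  Returns the
    flattened scan, shifted boundaries, and a boolean mask of valid (in-frame)
    pixels; padded pixels carry ``fill_value`` and are False in the mask.
    """
    if "rpe_bruch" not in boundaries:
        raise ValueError("linearize requires the rpe_bruch boundary")
    rpe = boundaries["rpe_bruch"]
    h, w = scan.pixels.shape
    if len(rpe) != w:
        raise ValueError("boundary width does not match scan width")
    ref_row = int(round(np.median(rpe)))
    shifts = ref_row - np.round(rpe).astype(int)

    flat = np.full_like(scan.pixels, fill_value)
    valid = np.zeros(scan.pixels.shape, dtype=bool)
    for j in range(w):
        s = shifts[j]
        src0, src1 = max(0, -s), min(h, h - s)
        dst0, dst1 = max(0, s), min(h, h + s)
        flat[dst0:dst1, j] = scan.pixels[src0:src1, j]
        valid[dst0:dst1, j] = True
    flat_scan = BScan(
        pixels=flat,
        lateral_scale=scan.lateral_scale,
        axial_scale=scan.axial_scale,
        fovea_column=scan.fovea_column,
        orientation=scan.orientation,
    )
    return flat_scan, boundaries.shifted(shifts.astype(float)), valid


def niblack_binarize(
    scan: BScan,
    mask: np.ndarray,
    params: BinarizationParams = BinarizationParams(),
) -> np.ndarray:
    """Lumen mask: pixels strictly below the Niblack threshold, within ``mask``.

    Our sign convention is ``T = m + k*s`` with the classic dark-object weight
    ``k = -0.2``; skimage's ``threshold_niblack`` computes ``m - k*s``, hence
    the sign flip.
    """
    if params.window > min(scan.pixels.shape):
        raise ValueError("Niblack window larger than the image")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty choroid mask")
    thresh = threshold_niblack(scan.pixels, window_size=params.window, k=-params.k)
    return (scan.pixels < thresh) & mask


def _subfield_columns(scan: BScan, subfield: Subfield) -> np.ndarray:
    lo = subfield.lower_mm * 1000.0 / scan.lateral_scale
    hi = subfield.upper_mm * 1000.0 / scan.lateral_scale
    cols = np.arange(scan.pixels.shape[1])
    off = np.abs(cols - scan.fovea_column)
    sel = (off >= lo) & (off < hi)
    if not (sel & (cols < scan.fovea_column)).any() or not (
        sel & (cols > scan.fovea_column)
    ).any():
        raise ValueError(f"subfield {subfield.label!r} missing on one side of the fovea")
    return sel


def choroid_mask_from_boundaries(
    scan: BScan, boundaries: BoundarySet, columns: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of the choroidal band [RPE-Bruch, choroid-sclera) per column."""
    rpe = np.round(boundaries["rpe_bruch"]).astype(int)
    cs = np.round(boundaries["choroid_sclera"]).astype(int)
    h, w = scan.pixels.shape
    rows = np.arange(h)[:, None]
    mask = (rows >= rpe[None, :]) & (rows < cs[None, :])
    if columns is not None:
        mask &= np.asarray(columns, dtype=bool)[None, :]
    return mask


def choroid_metrics(
    scan: BScan,
    boundaries: BoundarySet,
    lumen_mask: np.ndarray,
    subfield: Subfield,
) -> ChoroidQuant:
    """Areas and CVI over a subfield (both sides of the fovea pooled).

    TCA/LA are pixel counts times the physical pixel area
    (lateral_scale x axial_scale, reported in mm^2); SA = TCA - LA exactly.
    CT is the mean per-column RPE-Bruch to choroid-sclera separation times
    the axial scale.
    """
    cols = _subfield_columns(scan, subfield)
    choroid = choroid_mask_from_boundaries(scan, boundaries, cols)
    lumen = np.asarray(lumen_mask, dtype=bool) & choroid
    px_area_mm2 = scan.lateral_scale * scan.axial_scale * 1e-6
    tca = int(choroid.sum()) * px_area_mm2
    la = int(lumen.sum()) * px_area_mm2
    sa = tca - la
    flags: tuple[str, ...] = ()
    if tca > 0:
        cvi = la / tca
    else:
        cvi = float("nan")
        flags = ("cvi_undefined_zero_tca",)
    sep = boundaries["choroid_sclera"][cols] - boundaries["rpe_bruch"][cols]
    ct = float(sep.mean()) * scan.axial_scale
    return ChoroidQuant(CT=ct, LA=la, SA=sa, TCA=tca, CVI=cvi, subfield=subfield.label, flags=flags)


def sublayer_thickness(
    boundaries: BoundarySet,
    subfield: Subfield,
    axial_scale: float,
    fovea_column: int,
    lateral_scale: float,
    layers: dict[str, tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Mean per-column thickness (um) of each requested retinal sublayer."""
    layers = SUBLAYER_BOUNDS if layers is None else layers
    n = boundaries.n_columns
    lo = subfield.lower_mm * 1000.0 / lateral_scale
    hi = subfield.upper_mm * 1000.0 / lateral_scale
    off = np.abs(np.arange(n) - fovea_column)
    sel = (off >= lo) & (off < hi)
    if not sel.any():
        raise ValueError("subfield has no columns at this lateral scale")
    out: dict[str, float] = {}
    for name, (top, bot) in layers.items():
        if top not in boundaries or bot not in boundaries:
            continue
        d = boundaries[bot][sel] - boundaries[top][sel]
        out[name] = float(d.mean()) * axial_scale
    return out


def agreement_stats(
    measurements_1: np.ndarray, measurements_2: np.ndarray
) -> dict[str, float]:
    """Test-retest agreement: ICC(2,1) and the coefficient of repeatability.

    ICC is the two-way random-effects, absolute-agreement, single-measurement
    coefficient; CoR = 1.96 x SD of the paired differences.
    """
    a = np.asarray(measurements_1, dtype=float)
    b = np.asarray(measurements_2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D series with n >= 3")
    diff = a - b
    cor = 1.96 * float(np.std(diff, ddof=1))
    if np.std(a) < 1e-15 and np.std(b) < 1e-15:
        return {"icc": float("nan"), "cor": cor, "flag": 1.0}
    import pingouin as pg

    n = len(a)
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["m1", "m2"], n),
            "score": np.concatenate([a, b]),
        }
    )
    icc_tab = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="score"
    )
    sel = icc_tab["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs by pingouin version
    icc2 = float(icc_tab.loc[sel, "ICC"].iloc[0])
    return {"icc": icc2, "cor": cor, "flag": 0.0}


def read_boundaries(path: str | Path) -> BoundarySet:
    """Read boundary annotations from JSON ({name: [depth per column]}) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as f:
            data = json.load(f)
        return BoundarySet({k: np.asarray(v, dtype=float) for k, v in data.items()})
    df = pd.read_csv(path)
    return BoundarySet({c: df[c].to_numpy(dtype=float) for c in df.columns})


def write_boundaries(boundaries: BoundarySet, path: str | Path) -> None:
    path = Path(path)
    data = {name: [round(float(v), 4) for v in boundaries[name]] for name in boundaries.names()}
    with open(path, "w") as f:
        json.dump(data, f, sort_keys=True)
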