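"""Empirical orthogonal function (EOF) analysis of annual anomaly fields.

The space-time anomaly field is weighted by sqrt(cos latitude) so that each
cell contributes in proportion to its area, and decomposed by singular value
decomposition of the (year x cell) matrix — numerically equivalent to an
eigendecomposition of the weighted spatial covariance matrix but better
conditioned. Eigenvector maps have unit Euclidean norm in the weighted
space; principal components (PCs) carry the mode's variance, so PC amplitude
is directly comparable to the anomaly amplitude. Explained variance of mode
i is its eigenvalue's share of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .containers import RegionBox
from .errors import NotAnomalizedError, RankError, RegionError, SizeError

__all__ = ["EOFResult", "eof_decompose", "regional_explained_variance"]


@dataclass
class EOFResult:
    """EOF decomposition of an annual anomaly field.

    Attributes
    ----------
    eigenvectors : DataArray (mode, lat, lon)
        Weighted-space spatial patterns, unit Euclidean norm over valid
        cells; masked (NaN) where the input had missing cells.
    pcs : DataFrame (year x mode)
        Principal components carrying the mode variance.
    explained_variance : ndarray
        Fraction of total weighted variance per mode; non-increasing, in
        [0, 1], summing to 1 over all modes.
    weights : DataArray (lat, lon)
        The sqrt(cos latitude) weights used, masked like the input.
    """

    eigenvectors: xr.DataArray
    pcs: pd.DataFrame
    explained_variance: np.ndarray
    weights: xr.DataArray
    n_modes: int
    singular_values: np.ndarray
    _v: np.ndarray = field(repr=False)            # (mode, valid cell)
    _u: np.ndarray = field(repr=False)            # (year, mode)
    _valid: np.ndarray = field(repr=False)        # flat boolean cell mask

    def pc(self, mode: int = 1) -> pd.Series:
        """1-based principal component series."""
        return self.pcs[f"PC{mode}"]

    def reconstruct(self, n_modes: Optional[int] = None) -> np.ndarray:
        """Weighted anomaly matrix (year x valid cell) rebuilt from the
        leading ``n_modes`` modes (default: all)."""
        k = self.singular_values.size if n_modes is None else n_modes
        return (self._u[:, :k] * self.singular_values[:k]) @ self._v[:k]

    def summary(self) -> str:
        lines = ["EOF decomposition",
                 f"  years: {self.pcs.index.min()}-{self.pcs.index.max()}"
                 f"  |  valid cells: {int(self._valid.sum())}  |  modes: {self.n_modes}"]
        for i in range(min(self.n_modes, 5)):
            lines.append(f"  mode {i + 1}: {100 * self.explained_variance[i]:5.1f}% of variance")
        return "\n".join(lines)

    def plot(self, mode: int = 1, axes=None):
        """Quick-look: eigenvector map and PC series for one mode."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3))
        self.eigenvectors.sel(mode=mode).plot(ax=axes[0])
        axes[1].plot(self.pcs.index, self.pc(mode))
        axes[1].axhline(0, color="k", lw=0.5)
        axes[1].set_title(f"PC{mode} ({100 * self.explained_variance[mode - 1]:.1f}%)")
        return axes


def _flatten_valid(field_arr: np.ndarray):
    """(year, lat, lon) -> (year, cell) keeping cells valid in every year."""
    nyr = field_arr.shape[0]
    flat = field_arr.reshape(nyr, -1)
    valid = ~np.isnan(flat).any(axis=0)
    return flat[:, valid], valid


def eof_decompose(
    anomaly_field: xr.DataArray,
    box: Optional[RegionBox] = None,
    n_modes: Optional[int] = None,
    sign_box: Optional[RegionBox] = None,
    center_tol: float = 1e-6,
) -> EOFResult:
    """EOF decomposition of an annual, per-cell anomalized field.

    Parameters
    ----------
    anomaly_field : DataArray (year, lat, lon)
        Must already be anomalized in time per cell (checked).
    box : RegionBox, optional
        Analysis domain; default is the full grid.
    n_modes : int, optional
        Number of modes to expose (all are retained internally so variance
        fractions always partition the total).
    sign_box : RegionBox, optional
        Each mode is flipped so the area-weighted mean of its eigenvector
        over this box is positive (default: the analysis domain), making the
        orientation of regional modes reproducible.
    """
    from .preprocess import _box_subset

    if "year" not in anomaly_field.dims:
        raise SizeError("eof_decompose expects an annual field with a 'year' dimension")
    sub = _box_subset(anomaly_field, box) if box is not None else anomaly_field
    sub = sub.transpose("year", "lat", "lon")
    years = sub["year"].values.astype(int)
    if years.size < 2:
        raise SizeError("EOF needs at least 2 years")

    data, valid = _flatten_valid(sub.values)
    ncell = int(valid.sum())
    if ncell < 2:
        raise RankError("EOF needs at least 2 non-missing cells")
    if n_modes is not None and n_modes > min(ncell, years.size):
        raise RankError(f"requested {n_modes} modes but rank is at most "
                        f"{min(ncell, years.size)}")

    scale = float(np.nanstd(sub.values))
    tol = center_tol * max(scale, 1e-12)
    cell_means = data.mean(axis=0)
    if np.abs(cell_means).max() > tol:
        raise NotAnomalizedError(
            "input is not anomalized in time: max |cell mean| = "
            f"{np.abs(cell_means).max():.3g} exceeds tolerance {tol:.3g}"
        )

    lat = sub["lat"].values
    lon = sub["lon"].values
    w2d = np.sqrt(np.cos(np.deg2rad(lat)))[:, None] * np.ones((1, lon.size))
    wflat = w2d.reshape(-1)[valid]
    xw = data * wflat  # (year, cell) weighted anomaly matrix

    u, s, vt = np.linalg.svd(xw, full_matrices=False)
    total = float(np.sum(s ** 2))
    explained = s ** 2 / total if total > 0 else np.zeros_like(s)

    # Sign convention: area-weighted eigenvector mean positive over sign_box.
    latlon_mask = np.ones((lat.size, lon.size), dtype=bool)
    sbox = sign_box if sign_box is not None else box
    if sbox is not None:
        latlon_mask = sbox.contains(lat[:, None], lon[None, :])
        if not latlon_mask.any():
            raise RegionError(f"sign box {sbox.name!r} contains no grid cells")
    sign_sel = latlon_mask.reshape(-1)[valid]
    aw = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, lon.size))
    sign_w = aw.reshape(-1)[valid] * sign_sel
    for k in range(s.size):
        m = float(np.dot(vt[k], sign_w))
        if m < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]

    nm = s.size if n_modes is None else n_modes
    maps = np.full((nm, lat.size, lon.size), np.nan)
    flat_maps = maps.reshape(nm, -1)
    flat_maps[:, valid] = vt[:nm]
    eigvec = xr.DataArray(
        maps, coords={"mode": np.arange(1, nm + 1), "lat": lat, "lon": lon},
        dims=("mode", "lat", "lon"), name="eigenvector",
        attrs={"norm": "unit Euclidean norm in sqrt(cos lat)-weighted space"},
    )
    wmask = w2d.copy().reshape(-1)
    wmask[~valid] = np.nan
    weights = xr.DataArray(wmask.reshape(lat.size, lon.size),
                           coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
    pcs = pd.DataFrame(u[:, :nm] * s[:nm], index=pd.Index(years, name="year"),
                       columns=[f"PC{k + 1}" for k in range(nm)])
    return EOFResult(eigenvectors=eigvec, pcs=pcs, explained_variance=explained[:nm],
                     weights=weights, n_modes=nm, singular_values=s,
                     _v=vt, _u=u, _valid=valid)


def regional_explained_variance(result: EOFResult, box: RegionBox) -> np.ndarray:
    """Fraction of a sub-box's total weighted variance captured by each mode.

    The mode-k reconstruction restricted to the sub-box has squared weighted
    norm s_k^2 * sum_{j in box} v_kj^2; dividing by the sub-box total gives
    fractions that sum to 1 over all modes. Returned for the exposed modes.
    """
    lat = result.eigenvectors["lat"].values
    lon = result.eigenvectors["lon"].values
    inbox = box.contains(lat[:, None], lon[None, :]).reshape(-1)[result._valid]
    if not inbox.any():
        raise RegionError(f"sub-box {box.name!r} contains no valid cells")
    s2 = result.singular_values ** 2
    per_mode = s2 * np.sum(result._v[:, inbox] ** 2, axis=1)
    total = float(per_mode.sum())
    if total == 0:
        return np.zeros(result.n_modes)
    return (per_mode / total)[: result.n_modes]
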