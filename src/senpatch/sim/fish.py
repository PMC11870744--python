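"""EASI-FISH sample simulator.

Somas are axis-aligned ellipsoids with analytic pre-expansion volumes; the
senescence-marker-high class (PY2) is stochastically larger and carries
higher transcript densities of its marker genes. Spots are drawn per cell
as Poisson counts with mean density x pre-expansion soma volume and placed
uniformly inside the (expanded) soma; coordinates are emitted on the
post-expansion micrometre scale of the microscope. ``volume`` mode
additionally renders a DAPI channel, a labelled soma mask, and one
Gaussian-spot channel per gene at the stated voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..specs import FishSimSpec

__all__ = ["FishSample", "gen_fish"]


@dataclass
class FishSample:
    """One simulated sample: soma table, spot table, optional rendered stacks."""

    #: per-cell table: class, center/semi-axes (post-expansion um), volumes
    cells: pd.DataFrame
    #: long spot table: gene, z/y/x (post-expansion um), quality
    spots: pd.DataFrame
    voxel_um: tuple
    expansion_factor: float
    #: imaged bounds (post-expansion um, (z, y, x))
    bounds_um: tuple
    #: labelled soma mask (volume mode only), 0 = background
    labels: np.ndarray | None = None
    #: DAPI intensity stack (volume mode only)
    dapi: np.ndarray | None = None
    #: per-gene spot-intensity stacks (volume mode only)
    channels: dict = field(default_factory=dict)


def _uniform_in_ellipsoid(rng, n, axes):
    """n points uniform in an axis-aligned ellipsoid with given semi-axes."""
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return pts * r[:, None] * np.asarray(axes)[None, :]


def gen_fish(spec: FishSimSpec, mode: str = "spot_table",
             exact_counts: bool = False) -> tuple[FishSample, dict]:
    """Simulate one EASI-FISH sample.

    Parameters
    ----------
    spec : FishSimSpec
    mode : {"spot_table", "volume"}
        ``spot_table`` emits analytic soma geometry plus spot coordinates;
        ``volume`` additionally rasterizes the DAPI/label/spot stacks (keep
        ``spec.n_cells`` small in this mode).
    exact_counts : bool
        Replace Poisson spot counts by the rounded expectation
        ``density x pre-expansion volume`` (noise-free ground truth).

    Returns the sample and a truth record (class labels, planted densities,
    expected per-cell counts, analytic volumes).
    """
    if mode not in ("spot_table", "volume"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    ef = spec.expansion_factor
    genes = spec.genes

    n_py2 = int(round(spec.fraction_py2 * n))
    classes = np.array(["PY2"] * n_py2 + ["PY1"] * (n - n_py2))
    rng.shuffle(classes)

    # per-cell ellipsoid semi-axes (pre-expansion): class mean x log-normal scale
    scale = rng.lognormal(0.0, spec.soma_sd_log, size=n)
    axes_pre = np.array([np.array(spec.soma_axes_um[c]) for c in classes])
    axes_pre = axes_pre * scale[:, None]
    vol_pre = 4.0 / 3.0 * np.pi * axes_pre.prod(axis=1)
    axes_post = axes_pre * ef
    vol_post = vol_pre * ef**3

    # jittered-grid centers (post-expansion um) with non-overlap spacing
    max_sa = float(axes_post.max())
    # jitter is +/-0.15 spacing per cell, so the minimal center distance is
    # 0.7 * spacing = 2.1 max semi-axes: ellipsoids cannot overlap
    spacing = 3.0 * max_sa
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.stack(np.meshgrid(*[np.arange(per_side)] * 3, indexing="ij"),
                    axis=-1).reshape(-1, 3)[:n]
    centers = (grid + 0.5) * spacing + rng.uniform(-0.15, 0.15, (n, 3)) * spacing
    bounds = tuple((grid.max(axis=0) + 1.0) * spacing)

    spot_frames = []
    expected = np.empty((n, len(genes)))
    counts = np.empty((n, len(genes)), dtype=np.int64)
    for gi, g in enumerate(genes):
        dens = np.array([spec.densities[c][g] for c in classes])
        expected[:, gi] = dens * vol_pre
        if exact_counts:
            k = np.round(expected[:, gi]).astype(np.int64)
        else:
            k = rng.poisson(expected[:, gi])
        counts[:, gi] = k
        for ci in np.flatnonzero(k):
            pts = centers[ci] + _uniform_in_ellipsoid(rng, k[ci], axes_post[ci])
            spot_frames.append(pd.DataFrame({
                "gene": g,
                "z": pts[:, 0], "y": pts[:, 1], "x": pts[:, 2],
                "quality": rng.uniform(0.5, 1.0, k[ci]),
            }))
    if spec.background_spots_per_um3 > 0:
        box_pre = np.prod(bounds) / ef**3
        n_bg = rng.poisson(spec.background_spots_per_um3 * box_pre)
        if n_bg:
            pts = rng.uniform(0, 1, (n_bg, 3)) * np.asarray(bounds)
            spot_frames.append(pd.DataFrame({
                "gene": rng.choice(list(genes), n_bg),
                "z": pts[:, 0], "y": pts[:, 1], "x": pts[:, 2],
                "quality": rng.uniform(0.5, 1.0, n_bg),
            }))
    spots = (pd.concat(spot_frames, ignore_index=True) if spot_frames
             else pd.DataFrame(columns=["gene", "z", "y", "x", "quality"]))

    cells = pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(n)],
        "true_class": classes,
        "center_z": centers[:, 0], "center_y": centers[:, 1], "center_x": centers[:, 2],
        "axis_z": axes_post[:, 0], "axis_y": axes_post[:, 1], "axis_x": axes_post[:, 2],
        "volume_pre_um3": vol_pre,
        "volume_post_um3": vol_post,
        "biocytin": rng.random(n) < 0.05,
    })
    sample = FishSample(cells=cells, spots=spots, voxel_um=tuple(spec.voxel_um),
                        expansion_factor=ef, bounds_um=bounds)

    if mode == "volume":
        vz, vy, vx = spec.voxel_um
        shape = (int(np.ceil(bounds[0] / vz)), int(np.ceil(bounds[1] / vy)),
                 int(np.ceil(bounds[2] / vx)))
        labels = np.zeros(shape, dtype=np.int32)
        zz = (np.arange(shape[0]) + 0.5) * vz
        yy = (np.arange(shape[1]) + 0.5) * vy
        xx = (np.arange(shape[2]) + 0.5) * vx
        for i in range(n):
            c, a = centers[i], axes_post[i]
            sl = tuple(slice(max(0, int((c[d] - a[d]) / v)),
                             min(shape[d], int((c[d] + a[d]) / v) + 2))
                       for d, v in enumerate((vz, vy, vx)))
            dz = (zz[sl[0]] - c[0]) / a[0]
            dy = (yy[sl[1]] - c[1]) / a[1]
            dx = (xx[sl[2]] - c[2]) / a[2]
            inside = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
                      + dx[None, None, :] ** 2) <= 1.0
            labels[sl][inside] = i + 1
        sample.labels = labels
        sample.dapi = (labels > 0).astype(np.float32)
        for g in genes:
            ch = np.zeros(shape, dtype=np.float32)
            sub = spots[spots["gene"] == g]
            if len(sub):
                iz = np.clip((sub["z"] / vz).astype(int), 0, shape[0] - 1)
                iy = np.clip((sub["y"] / vy).astype(int), 0, shape[1] - 1)
                ix = np.clip((sub["x"] / vx).astype(int), 0, shape[2] - 1)
                np.add.at(ch, (iz, iy, ix), 1.0)
                ch = gaussian_filter(ch, sigma=(1.0, 1.0, 1.0))
                peak = ch.max()
                if peak > 0:
                    ch /= peak
            sample.channels[g] = ch

    truth = {
        "classes": pd.Series(classes, index=cells["cell_id"], name="true_class"),
        "densities": {c: dict(d) for c, d in spec.densities.items()},
        "expected_counts": pd.DataFrame(expected, index=cells["cell_id"], columns=genes),
        "counts": pd.DataFrame(counts, index=cells["cell_id"], columns=genes),
        "volume_pre_um3": pd.Series(vol_pre, index=cells["cell_id"]),
        "n_py2": int(n_py2),
        "seed": spec.seed,
    }
    return sample, truth
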