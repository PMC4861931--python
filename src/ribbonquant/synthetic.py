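"""Synthetic inner-hair-cell (IHC) ribbon-synapse scenes with ground truth.

No public dataset accompanies the quantification problem this package
solves, so validation rests on simulation: we generate IHC scenes whose
statistical structure matches what the analysis assumes — per-cell ribbon
counts and orphan fractions from condition presets, multimodal
(small/medium/large) log-normal ribbon volume distributions, and two
positional clusters of synapses along the modiolar-pillar axis of the cell
— and render them into noisy two-channel confocal-like stacks.

The generative model, per cell:

* counts: paired ribbons, orphan ribbons and orphan receptor patches are
  independent Poisson draws with the preset means (total = paired + orphan
  exactly, by construction);
* positions: a synapse sits on the basolateral band of the ellipsoidal
  soma surface, displaced along the modiolar-pillar axis by plus or minus
  half the cluster separation according to its cluster label, plus
  isotropic Gaussian jitter.  Along that axis the coordinate is therefore
  an exact two-component Gaussian-location mixture;
* volumes: ribbon and receptor volumes are drawn from three-component
  log-normal mixtures (small / medium / large sub-populations);
* pairing: each paired ribbon carries a receptor patch a short random
  offset away (well inside the pairing distance).  Orphan components are
  kept at least the pairing distance away from every opposite-channel
  component, so the ground-truth labels are consistent with the proximity
  definition of a synaptic pair;
* image formation: each component is rendered as a solid sphere of its
  true volume (sub-voxel coverage by supersampling), blurred with a
  separable-Gaussian PSF, scaled to photons, and corrupted with Poisson
  shot noise plus additive Gaussian read noise before 16-bit quantization.

All randomness flows from a single ``numpy`` Generator seeded explicitly;
the seed is recorded in the truth sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .imaging import PSF, StackMeta

__all__ = [
    "ConditionPreset",
    "PRESETS",
    "SceneGeometry",
    "NoiseParams",
    "RibbonTruth",
    "ReceptorTruth",
    "IHCTruth",
    "GroundTruthScene",
    "sample_scene",
    "render_stack",
    "write_scene",
    "read_scene_dir",
]

MODIOLAR = "modiolar"
PILLAR = "pillar"


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionPreset:
    """Per-condition generative parameters.

    ``volume_mixture`` entries are ``(weight, log_mean, log_sd)`` of a
    log-normal component with volumes in cubic micrometres.  Count means are
    per inner hair cell.
    """

    name: str
    mean_total_ribbons: float
    mean_paired: float
    mean_orphan_ribbons: float
    orphan_receptor_rate: float
    volume_mixture: tuple[tuple[float, float, float], ...]
    receptor_volume_mixture: tuple[tuple[float, float, float], ...]
    cluster_separation: float = 3.0
    cluster_mix: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.mean_paired + self.mean_orphan_ribbons - self.mean_total_ribbons) > 1e-9:
            raise ValueError(
                f"{self.name}: mean_paired + mean_orphan_ribbons must equal "
                "mean_total_ribbons"
            )
        for mix in (self.volume_mixture, self.receptor_volume_mixture):
            w = sum(c[0] for c in mix)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: mixture weights must sum to 1")
            if any(c[2] <= 0 for c in mix):
                raise ValueError(f"{self.name}: mixture log-sd must be > 0")
        if not 0.0 <= self.cluster_mix <= 1.0:
            raise ValueError("cluster_mix must be in [0, 1]")

    def mixture_mean_variance(self, which: str = "ribbon") -> tuple[float, float]:
        """Analytic mean and variance of the volume mixture (closed form)."""
        mix = self.volume_mixture if which == "ribbon" else self.receptor_volume_mixture
        m1 = sum(w * math.exp(mu + sd * sd / 2) for w, mu, sd in mix)
        m2 = sum(w * math.exp(2 * mu + 2 * sd * sd) for w, mu, sd in mix)
        return m1, m2 - m1 * m1


def _preset(name, paired, orphan, orphan_rec, ribbon_mix, receptor_mix):
    return ConditionPreset(
        name=name,
        mean_total_ribbons=paired + orphan,
        mean_paired=paired,
        mean_orphan_ribbons=orphan,
        orphan_receptor_rate=orphan_rec,
        volume_mixture=ribbon_mix,
        receptor_volume_mixture=receptor_mix,
    )


# Three-component log-normal ribbon volume mixtures (µm³).  The control
# mixture has clearly separated small/medium/large modes; the post-noise
# 24 kHz mixtures deplete the small and large tails (mild after 30 min,
# collapse onto the medium mode after 60 min).  Exact parameters are package
# calibration choices, not literature values.
_RIBBON_CONTROL = ((0.40, math.log(0.05), 0.35),
                   (0.40, math.log(0.15), 0.30),
                   (0.20, math.log(0.45), 0.30))
_RIBBON_NOISE30 = ((0.15, math.log(0.05), 0.30),
                   (0.70, math.log(0.16), 0.28),
                   (0.15, math.log(0.42), 0.28))
_RIBBON_NOISE60 = ((0.05, math.log(0.05), 0.25),
                   (0.90, math.log(0.17), 0.20),
                   (0.05, math.log(0.40), 0.20))
_RECEPTOR_CONTROL = ((0.50, math.log(0.12), 0.35),
                     (0.35, math.log(0.30), 0.30),
                     (0.15, math.log(0.60), 0.30))
_RECEPTOR_NOISE30 = ((0.35, math.log(0.14), 0.32),
                     (0.45, math.log(0.32), 0.30),
                     (0.20, math.log(0.65), 0.30))
_RECEPTOR_NOISE60 = ((0.45, math.log(0.12), 0.32),
                     (0.45, math.log(0.28), 0.28),
                     (0.10, math.log(0.55), 0.28))

#: Packaged condition presets.  Count means (paired / orphan ribbons per
#: IHC) follow the reported per-condition synapse census; the 30-min 24 kHz
#: total is the consistent sum 12.3 + 2.9 = 15.2.
PRESETS: dict[str, ConditionPreset] = {
    p.name: p
    for p in [
        _preset("control_12k", 15.8, 1.5, 1.0, _RIBBON_CONTROL, _RECEPTOR_CONTROL),
        _preset("control_24k", 17.0, 1.4, 1.0, _RIBBON_CONTROL, _RECEPTOR_CONTROL),
        _preset("noise30_12k", 14.2, 1.9, 1.5, _RIBBON_NOISE30, _RECEPTOR_NOISE30),
        _preset("noise30_24k", 12.3, 2.9, 2.0, _RIBBON_NOISE30, _RECEPTOR_NOISE30),
        _preset("noise60_12k", 11.0, 3.4, 2.5, _RIBBON_NOISE60, _RECEPTOR_NOISE60),
        _preset("noise60_24k", 9.0, 4.5, 3.0, _RIBBON_NOISE60, _RECEPTOR_NOISE60),
    ]
}


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneGeometry:
    """Stack and soma geometry (micrometres; axes ordered z, y, x).

    Cells are laid out in a row along x with ``cell_pitch`` spacing, the
    cuticular-habenular axis along +z (habenular pole at high z) and the
    modiolar-pillar axis along y.  Synapses occupy the basolateral band of
    the soma surface, ``basolateral_band`` (fractions of the axial
    semi-axis) below the equator toward the habenular pole.

    ``min_clearance`` is the minimum surface-to-surface gap enforced between
    same-channel puncta at generation time: the scenes emulate data in which
    individual synaptic components are resolvable at confocal resolution,
    which is the regime the counting analysis assumes.
    """

    voxel_size: tuple[float, float, float] = (0.3, 0.08, 0.08)
    soma_axes: tuple[float, float, float] = (4.5, 3.0, 3.0)
    cell_pitch: float = 8.5
    margin: float = 1.4
    position_jitter: float = 0.5
    min_clearance: float = 0.7
    receptor_offset_range: tuple[float, float] = (0.15, 0.45)
    pairing_distance: float = 1.0
    basolateral_band: tuple[float, float] = (0.2, 0.92)

    def stack_extent(self, n_cells: int) -> tuple[float, float, float]:
        az, ay, ax = self.soma_axes
        ez = 2 * az + 2 * self.margin
        # y must hold the soma plus the cluster offsets and jitter tails
        ey = 2 * ay + 2 * self.margin + 3.0
        ex = (n_cells - 1) * self.cell_pitch + 2 * ax + 2 * self.margin
        return (ez, ey, ex)

    def stack_shape(self, n_cells: int) -> tuple[int, int, int]:
        return tuple(
            int(np.ceil(e / v))
            for e, v in zip(self.stack_extent(n_cells), self.voxel_size)
        )

    def soma_centers(self, n_cells: int) -> np.ndarray:
        ez, ey, _ = self.stack_extent(n_cells)
        x0 = self.margin + self.soma_axes[2]
        return np.array(
            [
                [ez / 2.0, ey / 2.0, x0 + i * self.cell_pitch]
                for i in range(n_cells)
            ]
        )


@dataclass(frozen=True)
class NoiseParams:
    """Image-formation noise: mean photons per fully covered voxel
    (photon_scale), flat background rate, and Gaussian read noise sd (both
    in photons)."""

    photon_scale: float = 200.0
    background: float = 5.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RibbonTruth:
    position: tuple[float, float, float]  # µm, (z, y, x)
    volume: float  # µm³
    cluster_label: str  # modiolar | pillar
    paired: bool


@dataclass(frozen=True)
class ReceptorTruth:
    position: tuple[float, float, float]
    volume: float
    paired_ribbon_index: int | None


@dataclass(frozen=True)
class IHCTruth:
    cell_id: int
    soma_center: tuple[float, float, float]
    soma_axes: tuple[float, float, float]
    cuticular_habenular_axis: tuple[float, float, float]
    modiolar_pillar_axis: tuple[float, float, float]
    ribbons: tuple[RibbonTruth, ...]
    receptors: tuple[ReceptorTruth, ...]

    def __post_init__(self) -> None:
        ch = np.asarray(self.cuticular_habenular_axis)
        mp = np.asarray(self.modiolar_pillar_axis)
        if abs(np.dot(ch, mp)) > 1e-9 or abs(ch @ ch - 1) > 1e-9 or abs(mp @ mp - 1) > 1e-9:
            raise ValueError("cell axes must be orthonormal unit vectors")

    @property
    def n_paired(self) -> int:
        return sum(r.paired for r in self.ribbons)

    @property
    def n_orphan_ribbons(self) -> int:
        return sum(not r.paired for r in self.ribbons)


@dataclass(frozen=True)
class GroundTruthScene:
    cells: tuple[IHCTruth, ...]
    voxel_size: tuple[float, float, float]
    stack_shape: tuple[int, int, int]
    seed: int
    preset_name: str = ""
    geometry: SceneGeometry = field(default_factory=SceneGeometry)

    def all_positions(self) -> np.ndarray:
        pts = [r.position for c in self.cells for r in c.ribbons]
        pts += [r.position for c in self.cells for r in c.receptors]
        return np.asarray(pts).reshape(-1, 3)

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "preset_name": self.preset_name,
            "voxel_size": list(self.voxel_size),
            "stack_shape": list(self.stack_shape),
            "geometry": asdict(self.geometry),
            "cells": [
                {
                    "cell_id": c.cell_id,
                    "soma_center": list(c.soma_center),
                    "soma_axes": list(c.soma_axes),
                    "cuticular_habenular_axis": list(c.cuticular_habenular_axis),
                    "modiolar_pillar_axis": list(c.modiolar_pillar_axis),
                    "ribbons": [
                        {
                            "position": list(r.position),
                            "volume": r.volume,
                            "cluster_label": r.cluster_label,
                            "paired": r.paired,
                        }
                        for r in c.ribbons
                    ],
                    "receptors": [
                        {
                            "position": list(r.position),
                            "volume": r.volume,
                            "paired_ribbon_index": r.paired_ribbon_index,
                        }
                        for r in c.receptors
                    ],
                }
                for c in self.cells
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruthScene":
        geo = SceneGeometry(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["geometry"].items()
        })
        cells = []
        for c in d["cells"]:
            cells.append(
                IHCTruth(
                    cell_id=c["cell_id"],
                    soma_center=tuple(c["soma_center"]),
                    soma_axes=tuple(c["soma_axes"]),
                    cuticular_habenular_axis=tuple(c["cuticular_habenular_axis"]),
                    modiolar_pillar_axis=tuple(c["modiolar_pillar_axis"]),
                    ribbons=tuple(
                        RibbonTruth(
                            tuple(r["position"]), r["volume"],
                            r["cluster_label"], r["paired"],
                        )
                        for r in c["ribbons"]
                    ),
                    receptors=tuple(
                        ReceptorTruth(
                            tuple(r["position"]), r["volume"],
                            r["paired_ribbon_index"],
                        )
                        for r in c["receptors"]
                    ),
                )
            )
        return cls(
            cells=tuple(cells),
            voxel_size=tuple(d["voxel_size"]),
            stack_shape=tuple(d["stack_shape"]),
            seed=d["seed"],
            preset_name=d.get("preset_name", ""),
            geometry=geo,
        )


# ---------------------------------------------------------------------------
# Scene sampling
# ---------------------------------------------------------------------------


def _sample_volumes(rng, mixture, n):
    if n == 0:
        return np.empty(0)
    w = np.array([c[0] for c in mixture])
    comp = rng.choice(len(mixture), size=n, p=w / w.sum())
    mu = np.array([c[1] for c in mixture])[comp]
    sd = np.array([c[2] for c in mixture])[comp]
    return np.exp(rng.normal(mu, sd))


def _inside_bounds(pos, extent, pad=0.2):
    return all(pad <= p <= e - pad for p, e in zip(pos, extent))


def _ribbon_position(rng, center, geo, preset, extent):
    """Sample one ribbon position; returns (position, cluster_label)."""
    az, ay, ax = geo.soma_axes
    modiolar = rng.random() < preset.cluster_mix
    sign = 1.0 if modiolar else -1.0
    for _ in range(200):
        u = sign * preset.cluster_separation / 2.0
        frac = rng.uniform(*geo.basolateral_band)
        v = frac * az
        rem = max(0.0, 1.0 - frac * frac)
        w = (1.0 if rng.random() < 0.5 else -1.0) * ax * math.sqrt(rem)
        jitter = rng.normal(0.0, geo.position_jitter, size=3)
        # cell frame: ch axis = +z, mp axis = +y, ring normal = x
        pos = (
            center[0] + v + jitter[0],
            center[1] + u + jitter[1],
            center[2] + w + jitter[2],
        )
        if _inside_bounds(pos, extent):
            return np.asarray(pos), MODIOLAR if modiolar else PILLAR
    raise RuntimeError("could not place ribbon inside stack bounds")


def _surface_position(rng, center, geo, extent):
    """Uniform-ish position on the basolateral soma surface (for orphan
    receptors)."""
    az, ay, ax = geo.soma_axes
    for _ in range(200):
        frac = rng.uniform(*geo.basolateral_band)
        v = frac * az
        phi = rng.uniform(0, 2 * math.pi)
        s = math.sqrt(max(0.0, 1.0 - frac * frac))
        u = ay * s * math.cos(phi)
        w = ax * s * math.sin(phi)
        jitter = rng.normal(0.0, geo.position_jitter, size=3)
        pos = (
            center[0] + v + jitter[0],
            center[1] + u + jitter[1],
            center[2] + w + jitter[2],
        )
        if _inside_bounds(pos, extent):
            return np.asarray(pos)
    raise RuntimeError("could not place component inside stack bounds")


def _radius(volume: float) -> float:
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def _min_gap(pos, r, placed):
    """Smallest surface-to-surface gap between a sphere (pos, r) and placed
    spheres [(pos, r), ...]; inf when nothing is placed."""
    gap = np.inf
    for q, rq in placed:
        d = float(np.linalg.norm(np.asarray(pos) - np.asarray(q)))
        gap = min(gap, d - r - rq)
    return gap


def _min_center_dist(pos, others):
    if not others:
        return np.inf
    arr = np.asarray([o[0] for o in others])
    return float(np.sqrt(((arr - np.asarray(pos)) ** 2).sum(axis=1)).min())


def sample_scene(
    preset: ConditionPreset,
    n_cells: int,
    geometry: SceneGeometry | None = None,
    seed: int = 0,
    stack_shape: tuple[int, int, int] | None = None,
) -> GroundTruthScene:
    """Draw a ground-truth scene of ``n_cells`` IHCs under ``preset``.

    Per-cell paired / orphan-ribbon / orphan-receptor counts are Poisson
    with the preset means; positions and volumes follow the generative model
    described in the module docstring.  Fully reproducible from ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    geo = geometry or SceneGeometry()
    extent = geo.stack_extent(n_cells)
    shape = stack_shape or geo.stack_shape(n_cells)
    phys = tuple(s * v for s, v in zip(shape, geo.voxel_size))
    if any(p + 1e-9 < e for p, e in zip(phys, extent)):
        raise ValueError(
            f"soma layout (physical extent {extent}) does not fit in the "
            f"stack bounds {phys}"
        )
    rng = np.random.default_rng(seed)
    centers = geo.soma_centers(n_cells)
    cells = []
    for cid in range(n_cells):
        center = centers[cid]
        n_paired = int(rng.poisson(preset.mean_paired))
        n_orphan_rib = int(rng.poisson(preset.mean_orphan_ribbons))
        n_orphan_rec = int(rng.poisson(preset.orphan_receptor_rate))

        # volumes first: placement keeps same-channel puncta resolvable,
        # i.e. surface-to-surface gaps of at least min_clearance
        rib_vol = _sample_volumes(rng, preset.volume_mixture, n_paired + n_orphan_rib)
        rec_vol = _sample_volumes(
            rng, preset.receptor_volume_mixture, n_paired + n_orphan_rec
        )
        # generation-time orphan guarantee: an orphan must not sit within the
        # pairing distance of any opposite-channel component, with a small
        # margin for centroid estimation error downstream
        orphan_excl = geo.pairing_distance + 0.2

        ribbons_placed: list[tuple[np.ndarray, float]] = []
        ribbon_lbl: list[str] = []
        receptors_placed: list[tuple[np.ndarray, float]] = []
        paired_index: list[int | None] = []

        # paired ribbons first, each with a receptor patch nearby
        for i in range(n_paired):
            r = _radius(rib_vol[i])
            best, best_gap = None, -np.inf
            for _ in range(300):
                pos, lbl = _ribbon_position(rng, center, geo, preset, extent)
                gap = _min_gap(pos, r, ribbons_placed)
                if gap >= geo.min_clearance:
                    best, best_gap = (pos, lbl), gap
                    break
                if gap > best_gap:
                    best, best_gap = (pos, lbl), gap
            ribbons_placed.append((best[0], r))
            ribbon_lbl.append(best[1])
        for i in range(n_paired):
            r = _radius(rec_vol[i])
            best, best_gap = None, -np.inf
            for _ in range(200):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = rng.uniform(*geo.receptor_offset_range)
                rpos = ribbons_placed[i][0] + direction * dist
                if not _inside_bounds(rpos, extent):
                    continue
                gap = _min_gap(rpos, r, receptors_placed)
                if gap >= geo.min_clearance:
                    best, best_gap = rpos, gap
                    break
                if gap > best_gap:
                    best, best_gap = rpos, gap
            receptors_placed.append((best, r))
            paired_index.append(i)

        # orphan ribbons: resolvable from other ribbons and beyond the
        # pairing distance from every receptor
        for i in range(n_paired, n_paired + n_orphan_rib):
            r = _radius(rib_vol[i])
            best, best_gap = None, -np.inf
            for _ in range(300):
                pos, lbl = _ribbon_position(rng, center, geo, preset, extent)
                if _min_center_dist(pos, receptors_placed) < orphan_excl:
                    continue
                gap = _min_gap(pos, r, ribbons_placed)
                if gap >= geo.min_clearance:
                    best, best_gap = (pos, lbl), gap
                    break
                if gap > best_gap:
                    best, best_gap = (pos, lbl), gap
            if best is None:  # pathological crowding: give up on exclusion
                pos, lbl = _ribbon_position(rng, center, geo, preset, extent)
                best = (pos, lbl)
            ribbons_placed.append((best[0], r))
            ribbon_lbl.append(best[1])

        # orphan receptors: uniform on the basolateral surface, beyond the
        # pairing distance from every ribbon
        rec_vol_used = list(rec_vol[:n_paired])
        for i in range(n_paired, n_paired + n_orphan_rec):
            r = _radius(rec_vol[i])
            placed = None
            for _ in range(300):
                rpos = _surface_position(rng, center, geo, extent)
                if (
                    _min_center_dist(rpos, ribbons_placed) >= orphan_excl
                    and _min_gap(rpos, r, receptors_placed) >= geo.min_clearance
                ):
                    placed = rpos
                    break
            if placed is not None:
                receptors_placed.append((placed, r))
                paired_index.append(None)
                rec_vol_used.append(rec_vol[i])

        ribbons = tuple(
            RibbonTruth(
                position=tuple(ribbons_placed[i][0]),
                volume=float(rib_vol[i]),
                cluster_label=ribbon_lbl[i],
                paired=i < n_paired,
            )
            for i in range(len(ribbons_placed))
        )
        receptors = tuple(
            ReceptorTruth(
                position=tuple(receptors_placed[i][0]),
                volume=float(rec_vol_used[i]),
                paired_ribbon_index=paired_index[i],
            )
            for i in range(len(receptors_placed))
        )
        cells.append(
            IHCTruth(
                cell_id=cid,
                soma_center=tuple(center),
                soma_axes=geo.soma_axes,
                cuticular_habenular_axis=(1.0, 0.0, 0.0),
                modiolar_pillar_axis=(0.0, 1.0, 0.0),
                ribbons=ribbons,
                receptors=receptors,
            )
        )
    return GroundTruthScene(
        cells=tuple(cells),
        voxel_size=geo.voxel_size,
        stack_shape=tuple(shape),
        seed=seed,
        preset_name=preset.name,
        geometry=geo,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 3


def _paint_sphere(channel: np.ndarray, voxel_size, position, volume) -> None:
    """Add the voxel coverage fractions of a solid sphere in place.

    Coverage is estimated with a 3x3x3 sub-voxel grid, so the painted mass
    sums to volume / voxel_volume even for spheres below voxel size.
    """
    vs = np.asarray(voxel_size)
    r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    lo = np.maximum(np.floor((position - r) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((position + r) / vs).astype(int) + 1, channel.shape)
    if np.any(lo >= hi):
        return
    s = _SUPERSAMPLE
    offs = (np.arange(s) + 0.5) / s
    grids = [
        (np.arange(lo[d], hi[d])[:, None] + offs[None, :]).ravel() * vs[d]
        - position[d]
        for d in range(3)
    ]
    dz2 = grids[0][:, None, None] ** 2
    dy2 = grids[1][None, :, None] ** 2
    dx2 = grids[2][None, None, :] ** 2
    inside = (dz2 + dy2 + dx2) <= r * r
    nz, ny, nx = hi - lo
    cov = inside.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5))
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += cov


def render_scene_ideal(
    scene: GroundTruthScene,
    channels: Sequence[str] = ("ribbon", "receptor"),
) -> np.ndarray:
    """Noise-free, unblurred coverage rendering, one channel per role."""
    out = np.zeros((len(channels), *scene.stack_shape), dtype=np.float32)
    idx = {role: i for i, role in enumerate(channels)}
    for cell in scene.cells:
        if "ribbon" in idx:
            for r in cell.ribbons:
                _paint_sphere(
                    out[idx["ribbon"]], scene.voxel_size,
                    np.asarray(r.position), r.volume,
                )
        if "receptor" in idx:
            for r in cell.receptors:
                _paint_sphere(
                    out[idx["receptor"]], scene.voxel_size,
                    np.asarray(r.position), r.volume,
                )
    return out


def render_photon_rate(
    scene: GroundTruthScene,
    psf: PSF | None = None,
    noise: NoiseParams | None = None,
    channels: Sequence[str] = ("ribbon", "receptor"),
) -> np.ndarray:
    """Deterministic expected-photon image: PSF-blurred coverage rendering
    scaled by photon_scale plus the flat background (no noise).  Linear in
    photon_scale by construction."""
    psf = psf or PSF()
    noise = noise or NoiseParams()
    ideal = render_scene_ideal(scene, channels)
    sig = psf.sigma_voxels(scene.voxel_size)
    rate = np.empty_like(ideal)
    for c in range(ideal.shape[0]):
        rate[c] = (
            noise.photon_scale * gaussian_filter(ideal[c], sig, mode="reflect")
            + noise.background
        )
    return rate


def render_stack(
    scene: GroundTruthScene,
    psf: PSF | None = None,
    noise: NoiseParams | None = None,
    seed: int | None = None,
    channels: Sequence[str] = ("ribbon", "receptor"),
) -> tuple[np.ndarray, StackMeta]:
    """Render a scene into a noisy 16-bit multi-channel stack.

    Overlapping components simply add intensity.  ``seed`` defaults to the
    scene seed; rendering the same scene with the same seed is
    bit-identical.  Returns the stack (channel, z, y, x) and its metadata.
    """
    psf = psf or PSF()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    rate = render_photon_rate(scene, psf, noise, channels)
    stack = np.empty_like(rate)
    for c in range(rate.shape[0]):
        img = rng.poisson(rate[c]).astype(np.float32)
        if noise.read_noise_sd > 0:
            img += rng.normal(0.0, noise.read_noise_sd, size=img.shape).astype(
                np.float32
            )
        stack[c] = img
    stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    meta = StackMeta(
        voxel_size=scene.voxel_size,
        shape=tuple(scene.stack_shape),
        channel_roles={i: role for i, role in enumerate(channels)},
        cells=tuple(
            {
                "cell_id": c.cell_id,
                "soma_center": list(c.soma_center),
                "cuticular_habenular_axis": list(c.cuticular_habenular_axis),
                "modiolar_pillar_axis": list(c.modiolar_pillar_axis),
            }
            for c in scene.cells
        ),
    )
    return stack, meta


# ---------------------------------------------------------------------------
# On-disk layout: stack.tif + meta.json + truth.json
# ---------------------------------------------------------------------------


def write_scene(
    out_dir: str | Path,
    scene: GroundTruthScene,
    stack: np.ndarray,
    meta: StackMeta,
) -> None:
    """Write a rendered scene: 16-bit TIFF (pages channel-major then z),
    metadata JSON, and the ground-truth sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "stack.tif", stack, photometric="minisblack")
    meta.to_json(out / "meta.json")
    (out / "truth.json").write_text(json.dumps(scene.to_json_dict(), indent=1))


def read_scene_dir(
    scene_dir: str | Path,
) -> tuple[np.ndarray, StackMeta, GroundTruthScene | None]:
    """Read back a scene directory; the truth sidecar is optional (external
    data has none)."""
    d = Path(scene_dir)
    meta = StackMeta.from_json(d / "meta.json")
    raw = tifffile.imread(d / "stack.tif")
    stack = np.asarray(raw).reshape(len(meta.channel_roles), *meta.shape)
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = GroundTruthScene.from_json_dict(json.loads(truth_path.read_text()))
    return stack, meta, truth
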