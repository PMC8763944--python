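"""Synthetic multiparametric head phantoms with voxel-exact ground truth.

The simulator stands in for a clinical cohort: it produces three
co-registered MR contrasts (TOF MRA, T1 post-contrast, T2) over a head
phantom whose every voxel carries a known tissue label — artery, vein,
brain parenchyma, CSF or embolized vessel (EV) inside an ellipsoidal
intracranial mask, and an excluded code outside it.

Geometry is deliberately schematic rather than anatomical: arterial and
venous trees are tortuous tubes obtained by dilating biased random-walk
centerlines, CSF forms a peripheral shell plus ventricle-like central
bodies, and an AVM nidus is a sphere in which artery, vein and EV
labels are mixed at configurable fractions. Class prevalences are
controlled directly: vessel growth stops when the requested voxel
budget per class is reached, so achieved fractions track the targets
closely.

Rendering maps each class to a per-contrast mean intensity (relative
units in [0, 1]), modulated by a smooth multiplicative bias field, plus
additive Gaussian noise. Optional confounders reproduce reported
failure modes of vessel mapping on real images: a draining vein that
does not enhance on T1+c, a thrombosed vein that is TOF-bright without
a T2 flow void, and a TOF acquisition slab that does not cover the
whole head.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import ARTERY, BRAIN, CSF, EV, EXCLUDED, TISSUE_CLASSES, VEIN, CLASS_NAMES
from . import volio

__all__ = [
    "PhantomConfig",
    "NidusConfig",
    "IntensityModel",
    "LabelVolume",
    "MultiparametricVolume",
    "default_intensity_model",
    "build_label_volume",
    "render_modalities",
    "inject_confounders",
    "make_cohort",
    "sample_contours",
    "PhantomGeometryError",
    "ConfounderError",
]

CONFOUNDER_NAMES = ("poorly_enhancing_vein", "thrombosed_vein", "tof_partial_slab")

#: fractions of intracranial voxels per class reported for a typical
#: clinical training cohort; used as the default simulation targets
DEFAULT_PREVALENCE = {ARTERY: 0.009, VEIN: 0.042, BRAIN: 0.843, CSF: 0.104, EV: 0.002}


class PhantomGeometryError(ValueError):
    """Requested phantom geometry cannot be realised."""


class ConfounderError(ValueError):
    """A requested confounder cannot be injected into this phantom."""


@dataclasses.dataclass
class NidusConfig:
    """AVM nidus: a sphere mixing artery/vein/EV labels.

    ``center`` is in fractional grid coordinates (0..1 per axis);
    ``radius`` in voxels. Mixing fractions are the per-voxel label
    probabilities inside the sphere (remainder stays brain).
    """

    center: tuple[float, float, float] = (0.5, 0.42, 0.58)
    radius: float = 8.0
    artery_fraction: float = 0.30
    vein_fraction: float = 0.40
    ev_fraction: float = 0.15

    def __post_init__(self) -> None:
        fr = (self.artery_fraction, self.vein_fraction, self.ev_fraction)
        if any(f < 0 for f in fr) or sum(fr) > 1.0 + 1e-9:
            raise ValueError("nidus mixing fractions must be >=0 and sum to <=1")


@dataclasses.dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 128, 128)
    voxel_size: tuple[float, float, float] = (1.2, 0.47, 0.47)
    n_vessel_trees: tuple[int, int] = (4, 6)  # (arterial, venous)
    vessel_radius_range: tuple[float, float] = (1.0, 2.4)
    nidus: NidusConfig = dataclasses.field(default_factory=NidusConfig)
    target_prevalence: dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    noise_sigma: float = 0.05
    bias_field_amplitude: float = 0.1
    confounders: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.vessel_radius_range[0] < 1.0:
            raise ValueError("vessel radii must be >= 1 voxel")
        prev = self.target_prevalence
        if any(p < 0 for p in prev.values()):
            raise ValueError("target_prevalence values must be >= 0")
        if sum(prev.values()) > 1.0 + 1e-9:
            raise ValueError("target_prevalence must sum to <= 1")
        unknown = set(self.confounders) - set(CONFOUNDER_NAMES)
        if unknown:
            raise ValueError(f"unknown confounders: {sorted(unknown)}")
        self.confounders = frozenset(self.confounders)

    @property
    def affine(self) -> np.ndarray:
        return volio.default_affine(self.voxel_size)


@dataclasses.dataclass
class IntensityModel:
    """Per-(class, contrast) mean relative intensity in [0, 1].

    The default mapping encodes the qualitative contrast behaviour of
    each tissue: arteries bright on TOF and enhancing on T1+c (with
    variable arterial T1+c intensity across subjects), veins enhancing
    on T1+c, CSF bright on T2, embolized vessels dark on all three.
    Numeric levels: low=0.10, low-moderate=0.25, moderate=0.50,
    high=0.90 — simulator conventions, fully configurable.
    """

    mean_intensity: dict[str, dict[int, float]]
    arterial_t1c_range: tuple[float, float] = (0.5, 0.9)
    background: float = 0.03

    def validate(self) -> None:
        m = self.mean_intensity
        for contrast in ("tof", "t1c", "t2"):
            if contrast not in m:
                raise ValueError(f"IntensityModel missing contrast {contrast!r}")
            for cls in TISSUE_CLASSES:
                if cls not in m[contrast]:
                    raise ValueError(
                        f"IntensityModel missing class {CLASS_NAMES[cls]!r} "
                        f"for contrast {contrast!r}"
                    )
        tof, t1c, t2 = m["tof"], m["t1c"], m["t2"]
        ok = (
            tof[ARTERY] > max(tof[VEIN], tof[BRAIN]) > tof[CSF] > tof[EV]
            and min(t1c[ARTERY], t1c[VEIN]) >= t1c[BRAIN] > t1c[CSF] > t1c[EV]
            and t2[CSF] > t2[BRAIN] > max(t2[ARTERY], t2[VEIN], t2[EV]) - 1e-12
        )
        if not ok:
            raise ValueError("class-mean ordering violates the contrast model")

    def lut(self, contrast: str) -> np.ndarray:
        """Length-6 lookup table over label codes (0 = background)."""
        table = np.full(6, self.background, dtype=np.float32)
        for cls in TISSUE_CLASSES:
            table[cls] = self.mean_intensity[contrast][cls]
        return table


LOW, LOWMOD, MOD, HIGH = 0.10, 0.25, 0.50, 0.90


def default_intensity_model(rng: np.random.Generator | None = None) -> IntensityModel:
    """Default contrast table; arterial T1+c drawn per subject if a
    generator is supplied (arterial enhancement is variable), else its
    midpoint."""
    t1c_artery = float(rng.uniform(0.5, 0.9)) if rng is not None else 0.7
    model = IntensityModel(
        mean_intensity={
            "tof": {ARTERY: HIGH, VEIN: MOD, CSF: LOWMOD, BRAIN: MOD, EV: LOW},
            "t1c": {ARTERY: t1c_artery, VEIN: HIGH, CSF: LOWMOD, BRAIN: MOD, EV: LOW},
            "t2": {ARTERY: LOW, VEIN: LOW, CSF: HIGH, BRAIN: MOD, EV: LOW},
        }
    )
    model.validate()
    return model


@dataclasses.dataclass
class LabelVolume:
    """Categorical tissue map plus component bookkeeping.

    ``components`` maps component names ("artery_trees", "vein_trees",
    "nidus", "ev_feeders") to voxel-index arrays of shape (M, 3), in
    the order the voxels were generated (tube voxels are approximately
    contiguous along the centerline).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    components: dict = dataclasses.field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        """Intracranial mask (True where not excluded)."""
        return self.data != EXCLUDED

    @property
    def affine(self) -> np.ndarray:
        return volio.default_affine(self.voxel_size)

    def to_image_volume(self) -> volio.ImageVolume:
        return volio.ImageVolume(self.data.astype(np.uint8), self.affine, "label")

    def prevalences(self) -> dict[int, float]:
        n = int(self.mask.sum())
        if n == 0:
            raise ValueError("label volume has no intracranial voxels")
        return {c: float((self.data == c).sum()) / n for c in TISSUE_CLASSES}


@dataclasses.dataclass
class MultiparametricVolume:
    """Three co-registered contrast channels on one voxel grid."""

    tof: np.ndarray
    t1c: np.ndarray
    t2: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.tof.shape == self.t1c.shape == self.t2.shape):
            raise ValueError("contrast channels must share one grid")

    @property
    def shape(self):
        return self.tof.shape

    @property
    def affine(self) -> np.ndarray:
        return volio.default_affine(self.voxel_size)

    def channel(self, contrast: str) -> np.ndarray:
        return {"tof": self.tof, "t1c": self.t1c, "t2": self.t2}[contrast]

    def features(self, indices: np.ndarray) -> np.ndarray:
        """Per-voxel (TOF, T1c, T2) triplets at (M, 3) voxel indices."""
        k, i, j = indices[:, 0], indices[:, 1], indices[:, 2]
        return np.stack([self.tof[k, i, j], self.t1c[k, i, j], self.t2[k, i, j]], axis=1)

    def copy(self) -> "MultiparametricVolume":
        return MultiparametricVolume(
            self.tof.copy(), self.t1c.copy(), self.t2.copy(), self.voxel_size
        )


# ---------------------------------------------------------------------------
# label-volume construction


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.42 * np.asarray(shape)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return q <= 1.0


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = zz**2 + yy**2 + xx**2 <= radius**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _take_smallest(flat_candidates: np.ndarray, key: np.ndarray, n: int) -> np.ndarray:
    """Flat indices of the n smallest key values among candidates."""
    if n >= flat_candidates.size:
        return flat_candidates
    order = np.argsort(key, kind="stable")
    return flat_candidates[order[:n]]


def _grow_trees(
    labels: np.ndarray,
    mask: np.ndarray,
    edt: np.ndarray,
    cls: int,
    n_trees: int,
    budget: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Grow tortuous tube trees of class ``cls`` until ``budget`` voxels
    are newly labeled; returns per-tree voxel-index arrays.

    Cerebral vessels traverse the whole head — every axial slice of a
    real brain contains arteries and veins — so each walk carries a
    persistent drift along the slice axis (alternating direction
    across trees, seeds spread over the slice range) and wanders
    in-plane under a curvature-limited random walk.
    """
    if n_trees <= 0 or budget <= 0:
        return []
    shape = np.asarray(labels.shape)
    center = (shape - 1) / 2.0
    trees: list[np.ndarray] = []
    remaining = budget
    seeds_flat = np.flatnonzero(mask & (edt >= 3.0))
    if seeds_flat.size == 0:
        raise PhantomGeometryError("intracranial mask too thin to seed vessel trees")
    seed_slices = np.array(np.unravel_index(seeds_flat, labels.shape))[0]
    slice_lo, slice_hi = int(seed_slices.min()), int(seed_slices.max())
    for t in range(n_trees):
        share = remaining if t == n_trees - 1 else max(1, budget // n_trees)
        share = min(share, remaining)
        if share <= 0:
            break
        radius = float(rng.uniform(*radius_range))
        offs = _ball_offsets(radius)
        # seed in a band of the slice range so trees jointly span it
        band = slice_lo + (slice_hi - slice_lo) * np.array(
            [t / n_trees, (t + 1) / n_trees]
        )
        in_band = (seed_slices >= band[0]) & (seed_slices <= band[1])
        pool = seeds_flat[in_band] if in_band.any() else seeds_flat
        pos = np.array(
            np.unravel_index(pool[rng.integers(pool.size)], labels.shape),
            dtype=float,
        )
        drift = 0.45 if t % 2 == 0 else -0.45  # persistent slice-axis course
        direction = rng.standard_normal(3)
        direction[0] = drift * 3
        direction /= np.linalg.norm(direction)
        voxels: list[np.ndarray] = []
        placed = 0
        for _ in range(20000):
            if placed >= share:
                break
            c = np.rint(pos).astype(int)
            inside = np.all(c >= 0) and np.all(c < shape)
            if not inside or not mask[tuple(c)] or edt[tuple(c)] < radius + 0.5:
                # steer back toward the interior; re-seed if badly lost
                to_center = center - pos
                nrm = np.linalg.norm(to_center)
                if nrm > 0:
                    direction = direction + 0.8 * to_center / nrm
                    direction /= np.linalg.norm(direction)
                pos = pos + direction
                drift = -drift  # bounce the axial course off the boundary
                c2 = np.rint(pos).astype(int)
                if not (np.all(c2 >= 0) and np.all(c2 < shape)) or not mask[tuple(c2)]:
                    pos = np.array(
                        np.unravel_index(pool[rng.integers(pool.size)], labels.shape),
                        dtype=float,
                    )
                continue
            cand = offs + c
            ok = np.all((cand >= 0) & (cand < shape), axis=1)
            cand = cand[ok]
            kk, ii, jj = cand[:, 0], cand[:, 1], cand[:, 2]
            new = labels[kk, ii, jj] == BRAIN
            if new.any():
                sel = cand[new]
                labels[sel[:, 0], sel[:, 1], sel[:, 2]] = cls
                voxels.append(sel)
                placed += sel.shape[0]
            # curvature-limited biased walk with axial drift
            direction = direction + 0.35 * rng.standard_normal(3)
            direction[0] += 0.25 * drift
            direction /= np.linalg.norm(direction)
            pos = pos + direction
        remaining -= placed
        if voxels:
            trees.append(np.concatenate(voxels, axis=0))
        if remaining <= 0:
            break
    return trees


def _grow_feeders(
    labels: np.ndarray,
    mask: np.ndarray,
    ball: np.ndarray | None,
    cls: int,
    budget: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Short tubes of class ``cls`` emanating outward from the nidus.

    Falls back to random interior seeds when no nidus exists.
    """
    if budget <= 0:
        return []
    shape = np.asarray(labels.shape)
    if ball is not None and ball.size:
        seed_pts = ball
        centroid = ball.mean(axis=0)
    else:
        interior = np.argwhere(mask)
        seed_pts = interior
        centroid = interior.mean(axis=0)
    tubes: list[np.ndarray] = []
    placed_total = 0
    for _ in range(40):  # feeder attempts
        if placed_total >= budget:
            break
        radius = float(rng.uniform(*radius_range))
        offs = _ball_offsets(radius)
        pos = seed_pts[rng.integers(seed_pts.shape[0])].astype(float)
        direction = pos - centroid  # radially outward
        nrm = np.linalg.norm(direction)
        direction = (
            direction / nrm if nrm > 0 else rng.standard_normal(3)
        )
        direction /= np.linalg.norm(direction)
        voxels: list[np.ndarray] = []
        for _step in range(60):
            if placed_total >= budget:
                break
            c = np.rint(pos).astype(int)
            if not (np.all(c >= 0) and np.all(c < shape)) or not mask[tuple(c)]:
                break
            cand = offs + c
            ok = np.all((cand >= 0) & (cand < shape), axis=1)
            cand = cand[ok]
            kk, ii, jj = cand[:, 0], cand[:, 1], cand[:, 2]
            new = labels[kk, ii, jj] == BRAIN
            if new.any():
                sel = cand[new]
                take = sel[: budget - placed_total]
                labels[take[:, 0], take[:, 1], take[:, 2]] = cls
                voxels.append(take)
                placed_total += take.shape[0]
            direction = direction + 0.3 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
        if voxels:
            tubes.append(np.concatenate(voxels, axis=0))
    return tubes


def _nidus_tangle(
    labels: np.ndarray,
    ball: np.ndarray,
    fractions: dict[int, float],
    rng: np.random.Generator,
) -> None:
    """Fill the nidus ball with a tangle of short vessel tubes.

    Each class receives a voxel quota (fraction of the ball's brain
    voxels); tubes of ~1-1.6 voxel radius are grown by short random
    walks reflected at the ball surface, stamping only brain voxels,
    so artery/vein/EV form interleaved serpentine segments rather than
    voxel noise. The remainder stays brain parenchyma (AVMs enmesh
    normal tissue).
    """
    shape = np.asarray(labels.shape)
    ball_mask = np.zeros(labels.shape, dtype=bool)
    ball_mask[ball[:, 0], ball[:, 1], ball[:, 2]] = True
    n_brain = int((labels[ball[:, 0], ball[:, 1], ball[:, 2]] == BRAIN).sum())
    quotas = {c: int(round(f * n_brain)) for c, f in fractions.items() if f > 0}
    if not quotas:
        return
    counts = {c: 0 for c in quotas}
    centroid = ball.mean(axis=0)
    for _ in range(400):  # rounds; each spawns one tube per unmet class
        unmet = [c for c in quotas if counts[c] < quotas[c]]
        if not unmet:
            break
        for cls in unmet:
            radius = float(rng.uniform(1.0, 1.6))
            offs = _ball_offsets(radius)
            brain_flat = np.flatnonzero(ball_mask.ravel() & (labels.ravel() == BRAIN))
            if brain_flat.size == 0:
                return
            pos = np.array(
                np.unravel_index(brain_flat[rng.integers(brain_flat.size)], labels.shape),
                dtype=float,
            )
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            for _step in range(30):
                if counts[cls] >= quotas[cls]:
                    break
                c = np.rint(pos).astype(int)
                if not (np.all(c >= 0) and np.all(c < shape)) or not ball_mask[tuple(c)]:
                    # reflect back toward the nidus centroid
                    to_c = centroid - pos
                    nrm = np.linalg.norm(to_c)
                    if nrm == 0:
                        break
                    direction = to_c / nrm
                    pos = pos + direction
                    continue
                cand = offs + c
                ok = np.all((cand >= 0) & (cand < shape), axis=1)
                cand = cand[ok]
                kk, ii, jj = cand[:, 0], cand[:, 1], cand[:, 2]
                new = ball_mask[kk, ii, jj] & (labels[kk, ii, jj] == BRAIN)
                if new.any():
                    sel = cand[new]
                    take = sel[: max(0, quotas[cls] - counts[cls])]
                    labels[take[:, 0], take[:, 1], take[:, 2]] = cls
                    counts[cls] += take.shape[0]
                direction = direction + 0.5 * rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                pos = pos + direction


def build_label_volume(config: PhantomConfig) -> LabelVolume:
    """Construct the ground-truth categorical volume for one phantom.

    Outside an ellipsoidal intracranial mask every voxel is excluded.
    Inside, CSF occupies a peripheral shell and ventricle-like central
    bodies, an AVM nidus sphere mixes artery/vein/EV at the configured
    fractions, and tortuous arterial/venous tubes are grown until each
    class reaches its target share of intracranial voxels.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0)))
    shape = tuple(config.grid_shape)
    mask = _ellipsoid_mask(shape)
    labels = np.where(mask, BRAIN, EXCLUDED).astype(np.uint8)
    n_ic = int(mask.sum())
    targets = {
        c: int(round(config.target_prevalence.get(c, 0.0) * n_ic))
        for c in TISSUE_CLASSES
    }
    edt = ndimage.distance_transform_edt(mask)  # voxel units
    components: dict[str, np.ndarray] = {}

    # --- nidus ball, resolved first so CSF carving cannot erode it
    ncfg = config.nidus
    nidus_center = np.array(
        [c * (s - 1) for c, s in zip(ncfg.center, shape)], dtype=float
    )
    ci = tuple(np.rint(nidus_center).astype(int))
    ev_target = targets[EV]
    fr_art, fr_vein = ncfg.artery_fraction, ncfg.vein_fraction
    fr_ev = ncfg.ev_fraction if ev_target > 0 else 0.0
    nidus_active = ncfg.radius > 0 and (fr_art + fr_vein + fr_ev) > 0
    ball = np.empty((0, 3), dtype=np.int64)
    if nidus_active:
        if not (all(0 <= ci[a] < shape[a] for a in range(3)) and mask[ci]):
            raise PhantomGeometryError(
                "nidus center lies outside the intracranial mask"
            )
        if edt[ci] <= ncfg.radius:
            raise PhantomGeometryError(
                "nidus radius exceeds the distance from its center to the "
                "intracranial boundary"
            )
        offs = _ball_offsets(ncfg.radius)
        ball = offs + np.asarray(ci)
        ok = np.all((ball >= 0) & (ball < np.asarray(shape)), axis=1)
        ball = ball[ok]
    in_nidus = np.zeros(shape, dtype=bool)
    if ball.size:
        in_nidus[ball[:, 0], ball[:, 1], ball[:, 2]] = True

    # --- CSF: peripheral shell (thinnest EDT values) + central ventricles
    csf_n = targets[CSF]
    if csf_n > 0:
        shell_n = csf_n // 2
        flat_ic = np.flatnonzero(mask & ~in_nidus)
        shell_idx = _take_smallest(flat_ic, edt.ravel()[flat_ic], shell_n)
        labels.ravel()[shell_idx] = CSF
        vent_n = csf_n - int(shell_idx.size)
        if vent_n > 0:
            grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
            ctr = (np.asarray(shape) - 1) / 2.0
            semi = np.asarray(shape) * np.array([0.16, 0.22, 0.07])
            off = shape[2] * 0.10
            q1 = sum(
                ((g - c - d) / s) ** 2
                for g, c, s, d in zip(grids, ctr, semi, (0.0, 0.0, off))
            )
            q2 = sum(
                ((g - c - d) / s) ** 2
                for g, c, s, d in zip(grids, ctr, semi, (0.0, 0.0, -off))
            )
            vent_metric = np.minimum(q1, q2).ravel()
            brain_flat = np.flatnonzero((labels == BRAIN) & ~in_nidus)
            vent_idx = _take_smallest(brain_flat, vent_metric[brain_flat], vent_n)
            labels.ravel()[vent_idx] = CSF

    # --- nidus: tangle of artery/vein/EV tubes at the configured shares
    if nidus_active:
        _nidus_tangle(
            labels, ball,
            {ARTERY: fr_art, VEIN: fr_vein, EV: fr_ev}, rng,
        )
        components["nidus"] = ball

    # --- vessel trees, grown until per-class budgets are met
    art_have = int((labels == ARTERY).sum())
    vein_have = int((labels == VEIN).sum())
    components["artery_trees"] = _grow_trees(
        labels, mask, edt, ARTERY, config.n_vessel_trees[0],
        targets[ARTERY] - art_have, config.vessel_radius_range, rng,
    )
    components["vein_trees"] = _grow_trees(
        labels, mask, edt, VEIN, config.n_vessel_trees[1],
        targets[VEIN] - vein_have, config.vessel_radius_range, rng,
    )

    # --- top up EV with embolized feeder tubes if the nidus fell short;
    # embolized vessels are feeding/nidal segments, so feeders emanate
    # from the nidus ball rather than arbitrary brain
    ev_have = int((labels == EV).sum())
    if ev_target > 0 and ev_have < ev_target:
        components["ev_feeders"] = _grow_feeders(
            labels, mask, ball if ball.size else None, EV,
            ev_target - ev_have,
            (1.0, max(1.0, config.vessel_radius_range[0] + 0.5)), rng,
        )
    elif ev_target == 0 and ev_have > 0:  # defensive; fr_ev forced 0 above
        labels[labels == EV] = BRAIN

    return LabelVolume(labels, tuple(config.voxel_size), components)


# ---------------------------------------------------------------------------
# rendering


def _bias_field(
    shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * B with max|B| = 1."""
    coarse = rng.standard_normal((3, 4, 4))
    field = ndimage.zoom(
        coarse,
        [s / c for s, c in zip(shape, coarse.shape)],
        order=3,
        mode="nearest",
        grid_mode=True,
    )
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak
    return (1.0 + amplitude * field).astype(np.float32)


def render_modalities(
    labels: LabelVolume, model: IntensityModel, config: PhantomConfig
) -> MultiparametricVolume:
    """Render the three contrast channels from a label volume.

    Each channel is the per-class mean intensity, multiplied by a
    smooth bias field (amplitude ``config.bias_field_amplitude``), plus
    i.i.d. Gaussian noise of s.d. ``config.noise_sigma``, clipped to
    [0, 1]. Excluded voxels render at the background level (near zero).
    """
    if labels.data.shape != tuple(config.grid_shape):
        raise ValueError(
            f"labels grid {labels.data.shape} does not match config grid "
            f"{tuple(config.grid_shape)}"
        )
    model.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 1)))
    channels = {}
    for contrast in ("tof", "t1c", "t2"):
        img = model.lut(contrast)[labels.data].astype(np.float32)
        if config.bias_field_amplitude > 0:
            img = img * _bias_field(labels.data.shape, config.bias_field_amplitude, rng)
        if config.noise_sigma > 0:
            img = img + config.noise_sigma * rng.standard_normal(
                labels.data.shape
            ).astype(np.float32)
        channels[contrast] = np.clip(img, 0.0, 1.0).astype(np.float32)
    return MultiparametricVolume(
        channels["tof"], channels["t1c"], channels["t2"], tuple(config.voxel_size)
    )


# ---------------------------------------------------------------------------
# confounders


def _vein_segment(labels: LabelVolume, rng: np.random.Generator, which: int) -> np.ndarray:
    trees = labels.components.get("vein_trees") or []
    trees = [t for t in trees if t.shape[0] >= 20]
    if not trees:
        raise ConfounderError("confounder requested but phantom has no vein tree")
    tree = trees[which % len(trees)]
    half = tree.shape[0] // 2
    return tree[half:] if which % 2 == 0 else tree[:half]


def inject_confounders(
    labels: LabelVolume,
    images: MultiparametricVolume,
    config: PhantomConfig,
    model: IntensityModel | None = None,
    slab: tuple[int, int] | None = None,
):
    """Inject the configured imaging confounders into rendered images.

    Returns ``(labels, images, affected)`` where ``affected`` maps each
    applied confounder to the (M, 3) voxel indices whose intensities
    were modified; labels are never changed. With an empty confounder
    set this is the identity.

    - ``poorly_enhancing_vein``: one vein segment rendered at the brain
      T1+c level (its flow void and label remain venous).
    - ``thrombosed_vein``: one vein segment rendered TOF-bright with a
      brain-level (moderate) T2 signal instead of a flow void.
    - ``tof_partial_slab``: the TOF channel is zeroed outside a
      contiguous slice slab covering the nidus (``slab`` overrides the
      derived slab as a half-open slice range).
    """
    if model is None:
        model = default_intensity_model()
    out = images.copy()
    affected: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 2)))
    for name in sorted(config.confounders):
        if name == "poorly_enhancing_vein":
            seg = _vein_segment(labels, rng, 0)
            out.t1c[seg[:, 0], seg[:, 1], seg[:, 2]] = model.mean_intensity["t1c"][BRAIN]
            affected[name] = seg
        elif name == "thrombosed_vein":
            seg = _vein_segment(labels, rng, 1)
            out.tof[seg[:, 0], seg[:, 1], seg[:, 2]] = model.mean_intensity["tof"][ARTERY]
            out.t2[seg[:, 0], seg[:, 1], seg[:, 2]] = model.mean_intensity["t2"][BRAIN]
            affected[name] = seg
        elif name == "tof_partial_slab":
            n_slices = labels.data.shape[0]
            if slab is None:
                nidus = labels.components.get("nidus")
                if nidus is not None and nidus.size:
                    lo = max(0, int(nidus[:, 0].min()) - 3)
                    hi = min(n_slices, int(nidus[:, 0].max()) + 4)
                else:
                    lo, hi = n_slices // 4, n_slices - n_slices // 4
            else:
                lo, hi = slab
            outside = np.ones(n_slices, dtype=bool)
            outside[lo:hi] = False
            if outside.any():
                idx = np.argwhere(
                    outside[:, None, None]
                    & np.ones(labels.data.shape[1:], dtype=bool)[None]
                )
                out.tof[outside] = 0.0
                affected[name] = idx
            else:
                affected[name] = np.empty((0, 3), dtype=np.int64)
    return labels, out, affected


# ---------------------------------------------------------------------------
# cohorts and sample contours


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    n_subjects: int,
    config: PhantomConfig,
    seed: int,
    out_dir,
) -> pd.DataFrame:
    """Simulate and write a cohort of phantom subjects.

    Writes per-subject NIfTI volumes (``tof/t1c/t2/labels.nii.gz``)
    under ``out_dir/sub-XX/`` plus ``manifest.csv``; returns the
    manifest (subject id, paths, seed, achieved intracranial
    prevalences, confounders).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_subjects):
        s = subject_seed(seed, i)
        cfg = dataclasses.replace(config, seed=s)
        labels, images, _ = simulate_subject(cfg)
        sub = f"sub-{i:02d}"
        sub_dir = out_dir / sub
        aff = cfg.affine
        volio.write_volume(
            volio.ImageVolume(images.tof, aff, "tof"), sub_dir / "tof.nii.gz"
        )
        volio.write_volume(
            volio.ImageVolume(images.t1c, aff, "t1c"), sub_dir / "t1c.nii.gz"
        )
        volio.write_volume(
            volio.ImageVolume(images.t2, aff, "t2"), sub_dir / "t2.nii.gz"
        )
        volio.write_volume(labels.to_image_volume(), sub_dir / "labels.nii.gz")
        prev = labels.prevalences()
        row = {
            "subject": sub,
            "path": str(sub_dir),
            "seed": s,
            "confounders": ";".join(sorted(cfg.confounders)),
        }
        row.update({f"prev_{CLASS_NAMES[c]}": prev[c] for c in TISSUE_CLASSES})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    meta = {"n_subjects": n_subjects, "master_seed": int(seed),
            "grid_shape": list(config.grid_shape)}
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2))
    return manifest


def simulate_subject(config: PhantomConfig):
    """Build labels, render contrasts and apply configured confounders
    for a single subject; returns (labels, images, affected)."""
    labels = build_label_volume(config)
    model = default_intensity_model(
        np.random.default_rng(np.random.SeedSequence((int(config.seed), 3)))
    )
    images = render_modalities(labels, model, config)
    affected: dict[str, np.ndarray] = {}
    if config.confounders:
        labels, images, affected = inject_confounders(labels, images, config, model)
    return labels, images, affected


_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def sample_contours(
    labels: LabelVolume, per_class_fraction: float, seed: int
) -> dict[int, np.ndarray]:
    """Draw small spatially contiguous per-class voxel samples.

    Emulates the manually contoured class samples used to train the
    per-subject bootstrap classifier: for every tissue class present,
    a region-grown random subset of approximately ``per_class_fraction``
    of that class's voxels (at least 10, or the whole class if
    smaller). Returns a map class code -> (M, 3) voxel indices; classes
    absent from the volume are absent from the result, and subsets are
    disjoint across classes by construction.
    """
    if not (0 < per_class_fraction <= 1):
        raise ValueError("per_class_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    shape = labels.data.shape
    out: dict[int, np.ndarray] = {}
    for cls in TISSUE_CLASSES:
        coords = np.argwhere(labels.data == cls)
        n = coords.shape[0]
        if n == 0:
            continue
        target = min(n, max(10, int(round(per_class_fraction * n))))
        cls_mask = labels.data == cls
        taken = np.zeros(shape, dtype=bool)
        order = rng.permutation(n)
        selected: list[tuple[int, int, int]] = []
        ptr = 0
        from collections import deque

        while len(selected) < target:
            while ptr < n and taken[tuple(coords[order[ptr]])]:
                ptr += 1
            if ptr >= n:
                break
            queue = deque([tuple(coords[order[ptr]])])
            taken[queue[0]] = True
            while queue and len(selected) < target:
                vox = queue.popleft()
                selected.append(vox)
                nb = _NEIGHBOR_OFFSETS + np.asarray(vox)
                ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
                for cand in nb[ok]:
                    t = tuple(cand)
                    if cls_mask[t] and not taken[t]:
                        taken[t] = True
                        queue.append(t)
        out[cls] = np.asarray(selected, dtype=np.int64)
    if not out:
        raise ValueError("label volume contains no tissue-class voxels to sample")
    return out
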