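"""Synthetic destruction-replenishment CEUS phantoms.

Generates ground-truthed contrast-enhanced ultrasound sequences for three
artificial tumour phenotypes.  Each phantom is a speckle-textured tumour
background with an embedded branching vessel network carrying microbubble
signal: a bolus ramp, a destructive pulse that zeroes the intravascular
signal, and mono-exponential replenishment ``A * (1 - exp(-beta * t))``
afterwards.  Breathing artifacts are simulated as whole-frame shifts at a
fixed period.  Studies mirror a small-animal test/retest design: per animal
two imaging positions, each acquired twice (dataset 1 and dataset 2 share
the identical phantom geometry but fresh noise), and three observer ROI
delineations per scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from skimage.morphology import disk, skeletonize

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "CEUSSequence",
    "ROIMask",
    "ScanRecord",
    "Study",
    "phenotype_config",
    "default_roi",
    "generate_vessel_tree",
    "render_sequence",
    "generate_study",
]

PHENOTYPES = ("P1", "P2", "P3")


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic tumour phantom.

    The three phenotype classes are encoded as parameter triplets that
    differ in vascular density, replenishment rate (i.e. perfusion speed)
    and speckle statistics; they stand in for three xenograft tumour
    lines with distinct vascular phenotypes.

    Parameters
    ----------
    image_size : (H, W) in pixels.
    n_frames : number of frames in the sequence.
    frame_rate : frames per second.
    destruction_frame : index of the microbubble destruction pulse.
    phenotype : class label, one of ``P1``, ``P2``, ``P3``.
    vessel_density : target vessel-pixel fraction of the ROI.
    n_seeds_vessels : number of vessel-tree root points.
    branch_probability : per-step branching probability of the growth walk.
    replenishment_rate_beta : replenishment rate constant, 1/s.
    plateau_amplitude_A : microbubble plateau intensity (intensity units).
    background_level : mean tissue background intensity (intensity units).
    speckle_scale : speckle fluctuation amplitude (intensity units).
    texture_granularity : speckle correlation length in pixels.
    bubble_flicker : log-sd of the per-frame multiplicative microbubble
        fluctuation (0 disables flicker; mean is exactly 1 regardless).
    temporal_noise : per-frame additive sensor noise sd, as a fraction of
        ``speckle_scale``.
    breathing_period : frames between simulated breathing shifts.
    breathing_shift : magnitude of the breathing displacement in pixels.
    rng_seed : seed controlling every random element of the phantom.
    """

    image_size: tuple[int, int] = (128, 128)
    n_frames: int = 60
    frame_rate: float = 10.0
    destruction_frame: int = 20
    phenotype: str = "P1"
    vessel_density: float = 0.08
    n_seeds_vessels: int = 4
    branch_probability: float = 0.08
    replenishment_rate_beta: float = 0.4
    plateau_amplitude_A: float = 60.0
    background_level: float = 20.0
    speckle_scale: float = 8.0
    texture_granularity: float = 2.0
    bubble_flicker: float = 0.6
    temporal_noise: float = 0.15
    breathing_period: int = 9
    breathing_shift: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.vessel_density < 1:
            raise ValueError("vessel_density must be in [0, 1)")
        if not 0 < self.destruction_frame < self.n_frames:
            raise ValueError("destruction_frame must lie inside the sequence")
        if self.replenishment_rate_beta <= 0:
            raise ValueError("replenishment_rate_beta must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def bolus_end(self) -> int:
        """Frame at which the bolus inflow ramp reaches its plateau."""
        return max(1, self.destruction_frame // 2)


# per-phenotype overrides; classes differ in vessel density, replenishment
# rate and speckle texture so that vascular, kinetic and textural features
# all carry class information
_PHENOTYPE_PARAMS: dict[str, dict] = {
    "P1": dict(vessel_density=0.08, replenishment_rate_beta=0.4,
               background_level=18.0, texture_granularity=1.6,
               n_seeds_vessels=3),
    "P2": dict(vessel_density=0.14, replenishment_rate_beta=0.8,
               background_level=22.0, texture_granularity=2.2,
               n_seeds_vessels=4),
    "P3": dict(vessel_density=0.22, replenishment_rate_beta=1.4,
               background_level=26.0, texture_granularity=2.8,
               n_seeds_vessels=6),
}


def phenotype_config(phenotype: str, **overrides) -> PhantomConfig:
    """Return the default :class:`PhantomConfig` for a phenotype class."""
    if phenotype not in _PHENOTYPE_PARAMS:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    params = dict(_PHENOTYPE_PARAMS[phenotype])
    params.update(overrides)
    return PhantomConfig(phenotype=phenotype, **params)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one phantom, for parameter-recovery tests."""

    true_vessel_mask: np.ndarray
    true_beta: float
    true_rbv: float
    true_network_length: int
    true_artifact_frames: frozenset[int]


@dataclass
class CEUSSequence:
    """Time-resolved 2-D B-mode intensity stack with acquisition metadata."""

    frames: np.ndarray  # (time, y, x), linear non-negative intensity
    frame_rate: float
    destruction_frame: int
    scan_id: str = ""
    mouse_id: str = ""
    model_label: str = ""
    position_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ROIMask:
    """Binary tumour delineation by one observer."""

    mask: np.ndarray
    user_id: str = "user1"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float],
                  radial_noise: np.ndarray | None = None) -> np.ndarray:
    """Filled ellipse, optionally with a smooth angular boundary perturbation.

    ``radial_noise`` is a periodic function of the polar angle sampled on a
    fixed 256-point grid; positive values push the boundary outwards (in
    units of the local radius, so the region stays star-shaped and hence
    connected for perturbations > -1).
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy = (yy - center[0]) / axes[0]
    dx = (xx - center[1]) / axes[1]
    r = np.hypot(dy, dx)
    if radial_noise is None:
        return r <= 1.0
    theta = np.arctan2(dy, dx)  # [-pi, pi]
    idx = ((theta + np.pi) / (2 * np.pi) * len(radial_noise)).astype(int) % len(radial_noise)
    return r <= 1.0 + radial_noise[idx]


def default_roi(config: PhantomConfig) -> np.ndarray:
    """The true tumour ROI: a centred ellipse covering ~half the frame."""
    h, w = config.image_size
    return _ellipse_mask((h, w), (h / 2, w / 2), (0.36 * h, 0.40 * w))


def generate_vessel_tree(config: PhantomConfig, roi: np.ndarray | None = None,
                         rng: Generator | None = None) -> np.ndarray:
    """Grow a branching curvilinear vessel network inside the ROI.

    Random walkers with direction persistence start from
    ``n_seeds_vessels`` root points, branch with ``branch_probability`` per
    step, and stamp 1-3 px wide segments until the vessel-pixel fraction of
    the ROI is within +/-10 % (relative) of ``vessel_density``.
    Deterministic given ``rng_seed``.

    Raises
    ------
    RuntimeError
        If the density target is unreachable within the step budget.
    """
    if roi is None:
        roi = default_roi(config)
    mask = np.zeros(config.image_size, dtype=bool)
    if config.vessel_density == 0:
        return mask
    if rng is None:
        rng = default_rng(config.rng_seed)

    roi_area = int(roi.sum())
    target_px = config.vessel_density * roi_area
    h, w = config.image_size
    roi_points = np.argwhere(roi)

    # stamp footprints for 1/2/3 px wide segments
    stamps = [np.array([[0, 0]]),
              np.argwhere(disk(1)) - 1,
              np.argwhere(disk(1)) - 1]  # width 2 approximated by 3px disk

    def spawn(from_vessel: bool) -> list:
        if from_vessel and mask.any():
            pts = np.argwhere(mask & roi)
            p = pts[rng.integers(len(pts))]
        else:
            p = roi_points[rng.integers(len(roi_points))]
        angle = rng.uniform(0, 2 * np.pi)
        width = int(rng.integers(0, 3))
        return [float(p[0]), float(p[1]), angle, width, 0]

    walkers = [spawn(False) for _ in range(max(1, config.n_seeds_vessels))]
    count = 0
    max_steps = 500_000
    max_lifetime = 80
    for _ in range(max_steps):
        if not walkers:
            walkers.append(spawn(True))
        wk = walkers[rng.integers(len(walkers))]
        wk[2] += rng.normal(0.0, 0.30)  # direction persistence with jitter
        wk[0] += math.sin(wk[2])
        wk[1] += math.cos(wk[2])
        wk[4] += 1
        y, x = int(round(wk[0])), int(round(wk[1]))
        if not (0 <= y < h and 0 <= x < w) or not roi[y, x] or wk[4] > max_lifetime:
            walkers.remove(wk)
            continue
        for oy, ox in stamps[wk[3]]:
            py, px = y + oy, x + ox
            if 0 <= py < h and 0 <= px < w and roi[py, px] and not mask[py, px]:
                mask[py, px] = True
                count += 1
        if count >= target_px:
            return mask
        if rng.random() < config.branch_probability and len(walkers) < 64:
            walkers.append([wk[0], wk[1], wk[2] + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2),
                            int(rng.integers(0, 3)), 0])
    raise RuntimeError(
        f"vessel density target {config.vessel_density} not reached after {max_steps} steps")


def _bubble_signal(config: PhantomConfig, frame_idx: int) -> float:
    """Mean intravascular intensity at a frame: bolus ramp, destruction, replenishment."""
    a = config.plateau_amplitude_A
    d = config.destruction_frame
    if frame_idx < d:
        return a * min(1.0, frame_idx / config.bolus_end)
    t = (frame_idx - d) / config.frame_rate
    return a * (1.0 - math.exp(-config.replenishment_rate_beta * t))


def scheduled_artifact_frames(config: PhantomConfig) -> frozenset[int]:
    """Breathing-shift schedule: every ``breathing_period``-th post-bolus frame."""
    if config.breathing_period <= 0:
        return frozenset()
    return frozenset(
        f for f in range(config.bolus_end, config.n_frames)
        if f % config.breathing_period == 0 and f != config.destruction_frame
    )


def render_sequence(tree: np.ndarray, config: PhantomConfig,
                    roi: np.ndarray | None = None,
                    rng: Generator | None = None) -> tuple[CEUSSequence, GroundTruth]:
    """Render a phantom vessel tree into a destruction-replenishment sequence.

    Background is smoothed multiplicative-style speckle (exponential noise
    low-pass filtered at ``texture_granularity``, standardized, scaled by
    ``speckle_scale`` and offset by ``background_level``).  Vessel pixels
    additionally carry the microbubble signal with per-frame lognormal
    flicker of mean exactly 1.  Every ``breathing_period`` post-bolus
    frames one frame is globally shifted by ``breathing_shift`` pixels and
    recorded in the ground truth.
    """
    if tree.shape != tuple(config.image_size):
        raise ValueError("tree shape does not match config.image_size")
    if roi is None:
        roi = default_roi(config)
    if rng is None:
        rng = default_rng(config.rng_seed + 1)

    h, w = config.image_size
    tree = tree & roi

    # static tissue speckle field (coherent interference pattern of
    # stationary scatterers; it does not redraw between frames)
    raw = rng.exponential(1.0, size=(h, w))
    sm = gaussian_filter(raw, config.texture_granularity)
    if config.speckle_scale > 0 and sm.std() > 0:
        z = (sm - sm.mean()) / sm.std()
        background = config.background_level + config.speckle_scale * z
    else:
        background = np.full((h, w), config.background_level)

    artifact_frames = scheduled_artifact_frames(config)
    frames = np.empty((config.n_frames, h, w), dtype=np.float32)
    n_vessel = int(tree.sum())
    for f in range(config.n_frames):
        img = background.copy()
        v = _bubble_signal(config, f)
        if n_vessel and v > 0:
            if config.bubble_flicker > 0:
                s = config.bubble_flicker
                flick = np.exp(rng.normal(-0.5 * s * s, s, size=n_vessel))
            else:
                flick = 1.0
            img[tree] += v * flick
        if config.temporal_noise > 0 and config.speckle_scale > 0:
            img = img + rng.normal(0.0, config.temporal_noise * config.speckle_scale, size=(h, w))
        if f in artifact_frames:
            img = np.roll(img, config.breathing_shift, axis=0)
        frames[f] = np.clip(img, 0.0, None)

    seq = CEUSSequence(frames=frames, frame_rate=config.frame_rate,
                       destruction_frame=config.destruction_frame)
    truth = GroundTruth(
        true_vessel_mask=tree,
        true_beta=config.replenishment_rate_beta,
        true_rbv=n_vessel / max(int(roi.sum()), 1),
        true_network_length=int(skeletonize(tree).sum()),
        true_artifact_frames=artifact_frames,
    )
    return seq, truth


def _perturbed_rois(config: PhantomConfig, rng: Generator) -> list[ROIMask]:
    """True ROI plus two observer perturbations (boundary jitter; +/-2 px)."""
    h, w = config.image_size
    center = (h / 2, w / 2)
    axes = (0.36 * h, 0.40 * w)
    true = _ellipse_mask((h, w), center, axes)

    # user 2: smooth radial boundary jitter (few low-order Fourier modes,
    # ~2 px amplitude at the boundary)
    n_theta = 256
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    noise = np.zeros(n_theta)
    for k in range(1, 5):
        noise += rng.normal(0, 1) * np.cos(k * theta) + rng.normal(0, 1) * np.sin(k * theta)
    amp = 2.0 / min(axes)  # ~2 px in units of local radius
    noise = noise / max(np.abs(noise).max(), 1e-12) * amp
    jittered = _ellipse_mask((h, w), center, axes, radial_noise=noise)

    # user 3: uniform dilation or erosion by 2 px
    if rng.random() < 0.5:
        resized = binary_dilation(true, disk(2))
    else:
        resized = binary_erosion(true, disk(2))

    return [ROIMask(true, "user1"), ROIMask(jittered, "user2"), ROIMask(resized, "user3")]


@dataclass
class ScanRecord:
    """One acquisition: sequence, ground truth and the three observer ROIs."""

    seq: CEUSSequence
    truth: GroundTruth
    rois: list[ROIMask]
    dataset: int  # 1 = test, 2 = retest


@dataclass
class Study:
    """A full synthetic test/retest study."""

    scans: list[ScanRecord] = field(default_factory=list)

    def dataset(self, n: int) -> list[ScanRecord]:
        return [s for s in self.scans if s.dataset == n]

    def manifest(self):
        import pandas as pd

        rows = [dict(scan_id=s.seq.scan_id, mouse_id=s.seq.mouse_id,
                     model_label=s.seq.model_label, position_id=s.seq.position_id,
                     dataset=s.dataset, n_users=len(s.rois)) for s in self.scans]
        return pd.DataFrame(rows)


def generate_study(n_per_class: tuple[int, int, int] = (5, 5, 4),
                   configs: dict[str, PhantomConfig] | None = None,
                   seed: int = 0) -> Study:
    """Generate the default test/retest study.

    For each animal: two imaging positions, each rendered twice (dataset 1
    and dataset 2) with identical phantom geometry but a fresh noise
    realization, and three observer ROI delineations per scan.  The default
    cohort is 14 animals (5 + 5 + 4 per class), i.e. 28 scans per dataset.
    The whole bundle is a pure function of ``(configs, seed)``.
    """
    if configs is None:
        configs = {p: phenotype_config(p) for p in PHENOTYPES}
    if any(n < 1 for n in n_per_class):
        raise ValueError("n_per_class entries must be >= 1")

    ss = SeedSequence(seed)
    study = Study()
    mouse_idx = 0
    for phen, n_animals in zip(PHENOTYPES, n_per_class):
        base = configs[phen]
        for _ in range(n_animals):
            mouse_idx += 1
            mouse_ss = ss.spawn(1)[0]
            for pos in (1, 2):
                geo_rng, noise1, noise2, roi_rng = (default_rng(s) for s in mouse_ss.spawn(4))
                cfg = replace(base, rng_seed=int(mouse_ss.entropy % (2**31)))
                roi = default_roi(cfg)
                tree = generate_vessel_tree(cfg, roi, rng=geo_rng)
                for ds, noise_rng in ((1, noise1), (2, noise2)):
                    seq, truth = render_sequence(tree, cfg, roi, rng=noise_rng)
                    seq.scan_id = f"m{mouse_idx:02d}_p{pos}_d{ds}"
                    seq.mouse_id = f"m{mouse_idx:02d}"
                    seq.model_label = phen
                    seq.position_id = f"p{pos}"
                    rois = _perturbed_rois(cfg, default_rng(roi_rng.integers(2**31)))
                    study.scans.append(ScanRecord(seq, truth, rois, ds))
    return study
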