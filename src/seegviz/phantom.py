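"""Synthetic sEEG study generator: CT phantom, tissue masks, ground truth,
and an annotated EDF recording.

The CT phantom emulates a brain-windowed post-implant head CT: an
ellipsoidal brain at soft-tissue intensity inside a hyperintense skull
shell, depth electrodes rendered as rows of blurred hyperintense contact
blobs (0.8 mm DIXI-style contacts, 3.5 mm centre-to-centre) along
straight or slightly bent trajectories, bright streak artifacts bridging
neighbouring contacts and radiating outward, and Gaussian noise.
Intensities are arbitrary CT-like units; the segmentation pipeline is
percentile-based, so only their ordering (metal >> skull >> tissue)
matters.

The recording emulates a 1 kHz clinical sEEG monitoring clip: pink-noise
background on every contact channel, a marked seizure-onset annotation,
and 80–250 Hz band sinusoidal bursts whose onset latency increases along
one electrode (the signal-propagation phenomenon the animation is meant
to show).

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf
from .volumes import VoxelGrid

_LABELS = "ABCDEFGH"


@dataclass
class Trajectory:
    """One implanted electrode: straight or slightly bent chain of contacts.

    ``direction`` points inward (entry -> deep end); contact 1 is the
    deepest contact, numbers ascend toward the entry point.
    """

    label: str
    entry_mm: np.ndarray  # outermost contact centre, world mm
    direction: np.ndarray  # unit vector, inward
    n_contacts: int = 6
    bend_deg: float = 0.0

    def contact_centers(self, spacing_mm: float) -> np.ndarray:
        """(n, 3) centres ordered by contact number (deepest first)."""
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        # walk from the entry inward, bending gradually about a fixed
        # perpendicular axis; bend_deg is the total deviation tip-to-tail
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        step_angle = np.deg2rad(self.bend_deg) / max(self.n_contacts - 1, 1)
        centers = [np.asarray(self.entry_mm, dtype=float)]
        cur = d.copy()
        for _ in range(self.n_contacts - 1):
            cur = _rotate(cur, perp, step_angle)
            centers.append(centers[-1] + cur * spacing_mm)
        return np.array(centers[::-1])  # deepest first


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 1.0
    brain_semiaxes_mm: tuple[float, float, float] = (48.0, 58.0, 42.0)
    electrodes: list[Trajectory] | None = None  # None -> two default electrodes
    contact_spacing_mm: float = 3.5
    contact_diameter_mm: float = 0.8
    contact_length_mm: float = 1.5
    metal_intensity: float = 3000.0
    tissue_intensity: float = 40.0
    skull_intensity: float = 1200.0
    streak_count: int = 3
    streak_intensity: float = 400.0
    artifact_rays: int = 250  # diffuse streaking throughout the volume
    noise_sd: float = 8.0
    psf_sigma_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_spacing_mm <= self.contact_diameter_mm:
            raise ValueError("contact spacing must exceed contact diameter")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def resolved_electrodes(self) -> list[Trajectory]:
        if self.electrodes is not None:
            return self.electrodes
        return default_trajectories(2, [6, 6], self.brain_semiaxes_mm,
                                    self.contact_spacing_mm)


@dataclass
class GroundTruth:
    """Oracle for every downstream stage."""

    contacts: pd.DataFrame  # electrode, number, name, x_mm, y_mm, z_mm
    tissue_masks: dict[str, VoxelGrid] = field(default_factory=dict)
    burst_onsets: pd.DataFrame | None = None  # channel, onset_s

    @property
    def channel_names(self) -> list[str]:
        return list(self.contacts["name"])

    def centers_mm(self) -> np.ndarray:
        return self.contacts[["x_mm", "y_mm", "z_mm"]].to_numpy()


_BASE_DIRECTIONS = np.array(
    [
        [-1.0, 0.15, 0.12],   # enters from +x side, heads -x
        [0.18, -1.0, 0.1],    # from +y side
        [1.0, 0.1, -0.15],    # from -x side
        [-0.12, 1.0, 0.18],   # from -y side
    ]
)


def _make_trajectory(
    k: int,
    n_contacts: int,
    semiaxes: np.ndarray,
    spacing_mm: float,
    rng: np.random.Generator | None = None,
    bend_deg: float = 0.0,
) -> Trajectory:
    """One well-separated trajectory aimed inward from side ``k``.

    The outermost contact keeps >= 5.5 mm clearance from the brain
    surface so the 3x mask erosion does not swallow it; the deepest
    contact must still sit >= 3 mm from the centre, else the electrode
    does not fit and a ValueError names it.
    """
    d = _BASE_DIRECTIONS[k].copy()
    if rng is not None:
        d = d + rng.normal(scale=0.05, size=3)
    d /= np.linalg.norm(d)
    r_dir = 1.0 / np.sqrt(((d / semiaxes) ** 2).sum())  # surface distance along d
    span = (n_contacts - 1) * spacing_mm
    entry_dist = r_dir - 5.5
    if entry_dist - span < 3.0:
        raise ValueError(
            f"electrode {_LABELS[k]}: {n_contacts} contacts do not fit "
            "inside the brain along this direction"
        )
    entry = -d * entry_dist  # entry on the side the direction points away from
    return Trajectory(
        label=_LABELS[k], entry_mm=entry, direction=d,
        n_contacts=n_contacts, bend_deg=bend_deg,
    )


def default_trajectories(
    n_electrodes: int,
    n_contacts: list[int],
    semiaxes: tuple[float, float, float],
    spacing_mm: float,
    rng: np.random.Generator | None = None,
    bend_deg: float = 0.0,
) -> list[Trajectory]:
    """Well-separated trajectories aimed inward from alternating sides."""
    if n_electrodes > len(_BASE_DIRECTIONS):
        raise ValueError(f"at most {len(_BASE_DIRECTIONS)} electrodes supported")
    semi = np.asarray(semiaxes, dtype=float)
    return [
        _make_trajectory(k, n_contacts[k], semi, spacing_mm, rng, bend_deg)
        for k in range(n_electrodes)
    ]


def random_study_spec(seed: int, streak_count: int = 3) -> PhantomSpec:
    """A randomized study condition: 2-4 electrodes of 6-12 contacts each,
    jittered directions, defaults otherwise; deterministic given seed.

    An electrode that does not fit along its jittered direction is
    shortened one contact at a time (never below 6).
    """
    rng = np.random.default_rng(seed)
    n_e = int(rng.integers(2, 5))
    semi = np.asarray(PhantomSpec.brain_semiaxes_mm, dtype=float)
    spacing = PhantomSpec.contact_spacing_mm
    trajectories = []
    for k in range(n_e):
        nc = int(rng.integers(6, 13))
        while True:
            try:
                trajectories.append(
                    _make_trajectory(k, nc, semi, spacing, rng)
                )
                break
            except ValueError:
                if nc <= 6:
                    raise
                nc -= 1
    return PhantomSpec(electrodes=trajectories, streak_count=streak_count, seed=seed)


def _world_axes(spec: PhantomSpec):
    shape = np.asarray(spec.grid_shape)
    affine = np.diag([spec.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * spec.spacing_mm  # brain centred at 0
    axes = [
        (np.arange(shape[i]) * spec.spacing_mm + affine[i, 3]) for i in range(3)
    ]
    return affine, axes


def make_ct_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, VoxelGrid, GroundTruth]:
    """Render the CT phantom.

    Returns
    -------
    ct : VoxelGrid
    brain_mask : VoxelGrid (binary)
    truth : GroundTruth with contact centres, names, and tissue masks
    """
    rng = np.random.default_rng(spec.seed)
    affine, (ax, ay, az) = _world_axes(spec)
    semi = np.asarray(spec.brain_semiaxes_mm)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij", sparse=True)

    def ellipsoid_r2(grow: float = 0.0):
        s = semi + grow
        return (X / s[0]) ** 2 + (Y / s[1]) ** 2 + (Z / s[2]) ** 2

    r2 = ellipsoid_r2()
    brain = r2 <= 1.0
    skull = (ellipsoid_r2(6.0) <= 1.0) & (ellipsoid_r2(2.0) > 1.0)

    ct = np.zeros(spec.grid_shape, dtype=float)
    ct[brain] = spec.tissue_intensity
    ct[skull] = spec.skull_intensity

    # tissue sub-masks: white core, gray shell, thin CSF rim
    white = r2 <= 0.75 ** 2
    gray = (r2 <= 0.95 ** 2) & ~white
    csf = brain & ~white & ~gray

    trajectories = spec.resolved_electrodes()
    rows = []
    all_centers = []
    for traj in trajectories:
        centers = traj.contact_centers(spec.contact_spacing_mm)
        rn = ((centers / semi) ** 2).sum(axis=1)
        if np.any(rn > 1.0):
            raise ValueError(f"electrode {traj.label} exits the brain ellipsoid")
        for num, c in enumerate(centers, start=1):
            rows.append(
                {
                    "electrode": traj.label,
                    "number": num,
                    "name": f"{traj.label}{num}",
                    "x_mm": c[0],
                    "y_mm": c[1],
                    "z_mm": c[2],
                }
            )
        all_centers.append(centers)

    # render contacts: blurred hyperintense blobs. The blob is a small
    # metal cylinder convolved with the scanner PSF, so its peak is the
    # metal intensity scaled by the partial-volume ratio (contact volume
    # over the Gaussian kernel normalization), capped at full metal.
    sigma = np.sqrt((spec.contact_diameter_mm / 2.355) ** 2 + spec.psf_sigma_mm ** 2)
    contact_vol = (
        np.pi * (spec.contact_diameter_mm / 2) ** 2 * spec.contact_length_mm
    )
    peak = min(
        spec.metal_intensity * contact_vol / ((2 * np.pi) ** 1.5 * sigma ** 3),
        spec.metal_intensity,
    )
    inv_aff = np.linalg.inv(affine)
    for centers in all_centers:
        for c in centers:
            _add_blob(ct, c, peak, sigma, inv_aff, spec.spacing_mm)

    # bright bridging streaks between random neighbouring contact pairs
    # (the failure mode the directional erosion is built to split)
    flat_centers = np.concatenate(all_centers) if all_centers else np.empty((0, 3))
    for _ in range(spec.streak_count):
        if len(flat_centers) == 0:
            break
        traj_idx = int(rng.integers(len(trajectories)))
        centers = trajectories[traj_idx].contact_centers(spec.contact_spacing_mm)
        if len(centers) < 2:
            continue
        i = int(rng.integers(len(centers) - 1))
        _add_segment(
            ct, centers[i], centers[i + 1], spec.streak_intensity, inv_aff,
            spec.spacing_mm,
        )
    # diffuse metal artifact: attenuating rays radiating from the
    # electrodes, as produced by CT reconstruction without metal artifact
    # reduction; these fill the upper intensity tail so the percentile
    # threshold sits well above soft tissue, the regime the high metal
    # threshold is meant for.  Rays start a few mm out from the contact
    # (the immediate neighbourhood is already covered by blur/bridges).
    for _ in range(spec.artifact_rays):
        if len(flat_centers) == 0:
            break
        origin = flat_centers[rng.integers(len(flat_centers))]
        ray_dir = rng.normal(size=3)
        ray_dir /= np.linalg.norm(ray_dir)
        amp = float(np.exp(rng.uniform(np.log(100.0), np.log(spec.streak_intensity))))
        start = float(rng.uniform(3.0, 8.0))
        length = float(rng.uniform(10.0, 35.0))
        _add_ray(
            ct, origin + ray_dir * start, ray_dir, amp, length, inv_aff,
            spec.spacing_mm, keepout_centers=flat_centers, keepout_mm=3.5,
        )

    ct += rng.normal(scale=spec.noise_sd, size=ct.shape)

    grid = VoxelGrid(ct, affine)
    brain_grid = VoxelGrid(brain.astype(np.uint8), affine.copy())
    truth = GroundTruth(
        contacts=pd.DataFrame(rows),
        tissue_masks={
            "gray": VoxelGrid(gray.astype(np.uint8), affine.copy()),
            "white": VoxelGrid(white.astype(np.uint8), affine.copy()),
            "csf": VoxelGrid(csf.astype(np.uint8), affine.copy()),
        },
    )
    return grid, brain_grid, truth


def _blob_window(arr, center, radius_mm, inv_aff, spacing):
    cidx = (inv_aff[:3, :3] @ center + inv_aff[:3, 3])
    half = int(np.ceil(radius_mm / spacing))
    lo = np.maximum(np.floor(cidx).astype(int) - half, 0)
    hi = np.minimum(np.floor(cidx).astype(int) + half + 1, arr.shape)
    if np.any(lo >= hi):
        return None
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    return sl, grids, cidx


def _add_blob(arr, center, amp, sigma_mm, inv_aff, spacing):
    win = _blob_window(arr, center, 4 * sigma_mm, inv_aff, spacing)
    if win is None:
        return
    sl, grids, cidx = win
    d2 = sum(((g - c) * spacing) ** 2 for g, c in zip(grids, cidx))
    arr[sl] += amp * np.exp(-d2 / (2 * sigma_mm ** 2))


def _add_segment(arr, p0, p1, amp, inv_aff, spacing):
    """Thin bright line segment between two points (bridging streak)."""
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / (0.4 * spacing))), 2)
    for t in np.linspace(0.0, 1.0, n):
        p = p0 + t * (p1 - p0)
        idx = np.round(inv_aff[:3, :3] @ p + inv_aff[:3, 3]).astype(int)
        if np.all(idx >= 0) and np.all(idx < arr.shape):
            arr[tuple(idx)] = max(arr[tuple(idx)], amp)


def _add_ray(
    arr, origin, direction, amp, length_mm, inv_aff, spacing,
    keepout_centers=None, keepout_mm=0.0,
):
    """Outward streak ray fading exponentially with distance.

    Voxels within ``keepout_mm`` of a contact centre are left untouched so
    diffuse artifact stays distinct from the contact blobs themselves (the
    near-contact artifact is modelled by the blur and bridge streaks).
    """
    n = max(int(np.ceil(length_mm / (0.4 * spacing))), 2)
    for s in np.linspace(0.0, length_mm, n):
        p = origin + direction * s
        if keepout_centers is not None and len(keepout_centers):
            if np.min(np.linalg.norm(keepout_centers - p, axis=1)) < keepout_mm:
                continue
        idx = np.round(inv_aff[:3, :3] @ p + inv_aff[:3, 3]).astype(int)
        if np.all(idx >= 0) and np.all(idx < arr.shape):
            val = amp * np.exp(-s / 8.0)
            arr[tuple(idx)] = max(arr[tuple(idx)], val)


def make_recording(
    truth: GroundTruth,
    path: str | Path,
    duration_s: float = 10.0,
    event_s: float = 5.0,
    event_label: str = "seizure onset",
    fs: float = 1000.0,
    burst_freq_hz: float = 120.0,
    burst_envelope_ms: float = 80.0,
    latency_step_ms: float = 100.0,
    burst_amp_uv: float = 60.0,
    noise_amp_uv: float = 15.0,
    propagate_electrode: str | None = None,
    seed: int = 0,
) -> tuple[Path, GroundTruth]:
    """Write an annotated EDF recording matching the phantom's contacts.

    One electrode (``propagate_electrode``, default the first) receives
    bursts whose onset latency after the event grows by
    ``latency_step_ms`` per contact number; other electrodes get a single
    weaker burst at a fixed latency.  Returns the path and the ground
    truth updated with per-channel burst onsets.
    """
    if not 0 < burst_freq_hz < fs / 2:
        raise ValueError("burst frequency must lie in (0, fs/2)")
    rng = np.random.default_rng(seed)
    names = truth.channel_names
    n_samp = int(round(duration_s * fs))
    t = np.arange(n_samp) / fs
    data = np.empty((len(names), n_samp))
    for i in range(len(names)):
        data[i] = _pink_noise(n_samp, rng) * noise_amp_uv

    electrodes = list(dict.fromkeys(truth.contacts["electrode"]))
    prop = propagate_electrode or electrodes[0]
    sigma = burst_envelope_ms / 1000.0
    onset_rows = []
    for i, (_, row) in enumerate(truth.contacts.iterrows()):
        if row["electrode"] == prop:
            onset = event_s + (row["number"] - 1) * latency_step_ms / 1000.0
            amp = burst_amp_uv
        else:
            k = electrodes.index(row["electrode"])
            onset = event_s + 0.25 + 0.2 * k
            amp = burst_amp_uv / 2
        center = onset + 2 * sigma  # envelope rises from ~zero at the onset
        if amp > 0:
            env = amp * np.exp(-((t - center) ** 2) / (2 * sigma ** 2))
            data[i] += env * np.sin(2 * np.pi * burst_freq_hz * (t - onset))
        onset_rows.append({"channel": row["name"], "onset_s": onset})

    out = write_edf(path, names, data, fs, [(event_s, event_label)])
    new_truth = replace(truth, burst_onsets=pd.DataFrame(onset_rows))
    return out, new_truth


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()
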