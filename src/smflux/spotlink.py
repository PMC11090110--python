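"""Spot detection and trajectory linking for single-particle tracking.

Diffraction-limited spots are detected per frame with a difference-of-Gaussians
(DoG) band-pass filter and localized to sub-pixel precision with an
intensity-weighted centroid. Frame-to-frame linking solves an optimal
bipartite assignment (linear assignment problem) with squared-displacement
costs, gated at a tracking radius, and closes short gaps caused by fluorophore
dark states. Splitting and merging of trajectories are deliberately not
handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Spot",
    "Trajectory",
    "detect_spots",
    "link_spots",
    "density_from_counts",
    "trajectories_to_frame",
    "frame_to_trajectories",
]

#: EMCCD pixel size of the TIRF setup, in um.
DEFAULT_PIXEL_UM = 0.167


@dataclass(frozen=True)
class Spot:
    """A localized fluorescent particle in one frame.

    Coordinates are continuous, in um, with the origin at the image corner.
    """

    frame: int
    x: float
    y: float
    I: float = 0.0

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class Trajectory:
    """A time-ordered sequence of spots belonging to one particle.

    ``gaps`` lists frames that were bridged by gap closing (the particle was
    dark there, so no spot exists for them).
    """

    id: int
    spots: list[Spot]
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("spot frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.I for s in self.spots], dtype=float)

    def displacements(self, max_frame_lag: int = 1) -> np.ndarray:
        """(dx, dy) between consecutive spots separated by <= max_frame_lag frames."""
        xy = self.xy
        frames = self.frames
        dxy = xy[1:] - xy[:-1]
        lag = np.diff(frames)
        return dxy[lag <= max_frame_lag]


def _dog_sigmas(est_diameter_um: float, pixel_um: float) -> tuple[float, float]:
    # sigma pair bracketing the spot size; standard 1.6 blur ratio
    d_px = est_diameter_um / pixel_um
    s1 = d_px / (2.0 * np.sqrt(2.0) * 1.6)
    return s1, 1.6 * s1


def detect_spots(
    frame_image: np.ndarray,
    est_diameter: float = 0.8,
    threshold: float | None = None,
    *,
    pixel_um: float = DEFAULT_PIXEL_UM,
    frame: int = 0,
    threshold_quantile: float = 0.999,
) -> list[Spot]:
    """Detect diffraction-limited spots in a single image with a DoG filter.

    The image is blurred with two Gaussians (sigma ratio 1.6) derived from the
    estimated particle diameter (um) and subtracted; local maxima of the
    band-passed image above ``threshold`` become detections. When ``threshold``
    is None it defaults to the ``threshold_quantile`` quantile of the filtered
    image. Sub-pixel positions come from an intensity-weighted centroid in a
    5x5 window; ``I`` is the background-subtracted integrated intensity there.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2D image")
    if est_diameter / pixel_um <= 2:
        raise ValueError("estimated diameter must exceed 2 pixels")
    s1, s2 = _dog_sigmas(est_diameter, pixel_um)
    dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
    if threshold is None:
        threshold = float(np.quantile(dog, threshold_quantile))
        if threshold <= 0:
            threshold = float(dog.max()) if dog.max() > 0 else np.inf
    # strict local maxima above threshold
    maxf = ndimage.maximum_filter(dog, size=3, mode="nearest")
    peaks = (dog >= maxf) & (dog > threshold)
    if not peaks.any():
        return []
    ny, nx = img.shape
    spots: list[Spot] = []
    bg = float(np.median(img))
    for r, c in zip(*np.nonzero(peaks)):
        r0, r1 = max(r - 2, 0), min(r + 3, ny)
        c0, c1 = max(c - 2, 0), min(c + 3, nx)
        patch = img[r0:r1, c0:c1] - bg
        patch = np.clip(patch, 0, None)
        total = patch.sum()
        if total <= 0:
            yc, xc = float(r), float(c)
        else:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            yc = float((rr * patch).sum() / total)
            xc = float((cc * patch).sum() / total)
        spots.append(Spot(frame=frame, x=xc * pixel_um, y=yc * pixel_um, I=max(total, 0.0)))
    return spots


def _gated_assignment(
    cost: np.ndarray, gate_cost: float
) -> list[tuple[int, int]]:
    """Optimal assignment with per-item birth/death alternatives at gate_cost.

    Rows/columns whose best option exceeds the gate are left unmatched. Uses
    the standard augmented square matrix: an (n+m) x (m+n) block layout with
    birth/death diagonal blocks.
    """
    n, m = cost.shape
    big = 1e12
    aug = np.full((n + m, m + n), big)
    aug[:n, :m] = np.where(cost <= gate_cost, cost, big)
    aug[:n, m:] = np.where(np.eye(n, dtype=bool), gate_cost, big)  # deaths
    aug[n:, :m] = np.where(np.eye(m, dtype=bool), gate_cost, big)  # births
    aug[n:, m:] = 0.0  # slack
    rows, cols = linear_sum_assignment(aug)
    return [(r, c) for r, c in zip(rows, cols) if r < n and c < m and aug[r, c] < big]


def link_spots(
    spots_by_frame: dict[int, list[Spot]] | list[list[Spot]],
    radius: float = 0.5,
    max_gap: float = 0.1,
    dt: float = 0.1,
) -> list[Trajectory]:
    """Link per-frame detections into gap-closed trajectories.

    Frame-to-frame correspondence minimizes the total squared displacement
    subject to a hard gate at ``radius`` (um); unmatched track ends stay
    eligible for re-linking for up to ``max_gap`` seconds (``max_gap/dt``
    frames), bridging fluorophore dark states. Each spot joins at most one
    trajectory; splitting/merging is not modelled.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    gap_frames = int(round(max_gap / dt))

    if isinstance(spots_by_frame, dict):
        frame_map = {int(k): list(v) for k, v in spots_by_frame.items()}
    else:
        frame_map = {i: list(v) for i, v in enumerate(spots_by_frame)}
    if not frame_map:
        return []

    # active tracks: list of dicts with spots, gaps, last position/frame
    active: list[dict] = []
    done: list[dict] = []
    gate = radius * radius

    for f in range(min(frame_map), max(frame_map) + 1):
        spots = sorted(
            frame_map.get(f, []), key=lambda s: (s.x, s.y, s.I)
        )  # canonical order: permutation-invariant linking
        # retire tracks that fell outside the gap window
        still = []
        for tr in active:
            if f - tr["last_frame"] > gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        if not spots:
            continue
        if not active:
            for s in spots:
                active.append({"spots": [s], "gaps": [], "last_frame": f})
            continue

        cost = np.full((len(active), len(spots)), np.inf)
        for i, tr in enumerate(active):
            last = tr["spots"][-1]
            for j, s in enumerate(spots):
                d2 = (s.x - last.x) ** 2 + (s.y - last.y) ** 2
                if d2 <= gate:
                    cost[i, j] = d2
        matches = _gated_assignment(cost, gate)
        matched_tracks = set()
        matched_spots = set()
        for i, j in matches:
            tr = active[i]
            s = spots[j]
            missed = range(tr["last_frame"] + 1, f)
            tr["gaps"].extend(missed)
            tr["spots"].append(s)
            tr["last_frame"] = f
            matched_tracks.add(i)
            matched_spots.add(j)
        for j, s in enumerate(spots):
            if j not in matched_spots:
                active.append({"spots": [s], "gaps": [], "last_frame": f})

    done.extend(active)
    done.sort(key=lambda tr: (tr["spots"][0].frame, tr["spots"][0].x, tr["spots"][0].y))
    return [
        Trajectory(id=i, spots=tr["spots"], gaps=tr["gaps"]) for i, tr in enumerate(done)
    ]


def density_from_counts(n_particles: int, area: float) -> float:
    """Surface density (molecules / um^2) from a particle count and membrane area."""
    if area <= 0:
        raise ValueError("area must be positive")
    if n_particles < 0:
        raise ValueError("particle count must be non-negative")
    return n_particles / area


def trajectories_to_frame(trajectories: list[Trajectory], dt: float) -> pd.DataFrame:
    """Tabulate trajectories with the stable CSV schema.

    Columns: traj_id, frame, t_s, x_um, y_um, I.
    """
    rows = [
        (tr.id, s.frame, s.frame * dt, s.x, s.y, s.I)
        for tr in trajectories
        for s in tr.spots
    ]
    return pd.DataFrame(rows, columns=["traj_id", "frame", "t_s", "x_um", "y_um", "I"])


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Rebuild Trajectory objects from the CSV schema written by this module."""
    out = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("frame")
        spots = [
            Spot(frame=int(r.frame), x=float(r.x_um), y=float(r.y_um), I=float(r.I))
            for r in grp.itertuples()
        ]
        frames = [s.frame for s in spots]
        gaps = [f for a, b in zip(frames, frames[1:]) for f in range(a + 1, b)]
        out.append(Trajectory(id=int(tid), spots=spots, gaps=gaps))
    return out
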