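"""Aggregate localized contacts into ordered, named electrodes.

Electrodes are built greedily from contact midpoints: the contact farthest
from the brain centre seeds a new electrode, its nearest neighbour joins
it, and the chain then grows by repeatedly adding the contact that lies
within the search distance of the most recently added contact and whose
turn angle relative to the previous inter-contact direction stays within
the deviation limit (which absorbs mild shaft bending without ever
jumping to a parallel electrode).  Contacts are numbered inner-to-outer:
contact 1 is the chain end nearest the brain centre, following the
deep-equals-one clinical convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import VoxelGrid, grid_as_bool

logger = logging.getLogger(__name__)


@dataclass
class BuildParams:
    search_distance_mm: float = 15.0
    max_deviation_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.search_distance_mm <= 0:
            raise ValueError("search distance must be positive")
        if not 0 < self.max_deviation_deg < 90:
            raise ValueError("max deviation must be in (0, 90) degrees")


@dataclass
class Electrode:
    """An ordered chain of contacts; ``numbers[i]`` is 1 for the deepest."""

    contact_ids: list[int]  # indices into the original contact list, chain order
    points_mm: np.ndarray  # (n, 3), chain order
    label: str | None = None
    numbers: list[int] = field(default_factory=list)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_ids)

    def contact_names(self) -> list[str]:
        if self.label is None or not self.numbers:
            raise ValueError("electrode is not yet labeled/numbered")
        return [f"{self.label}{n}" for n in self.numbers]

    def outer_point(self) -> np.ndarray:
        """World position of the highest-numbered (outermost) contact."""
        i = int(np.argmax(self.numbers)) if self.numbers else -1
        return self.points_mm[i]


def brain_center(mask: VoxelGrid) -> np.ndarray:
    """World-mm centroid of a binary brain mask."""
    data = grid_as_bool(mask)
    if not data.any():
        raise ValueError("brain mask is empty")
    idx = np.argwhere(data).mean(axis=0)
    return np.asarray(mask.index_to_world(idx), dtype=float)


def _turn_angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle between directions a->b and b->c."""
    u, v = b - a, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def build_electrodes(
    contacts_mm: np.ndarray,
    center: np.ndarray,
    params: BuildParams | None = None,
) -> list[Electrode]:
    """Partition contact midpoints into electrodes.

    The result does not depend on the input ordering: seeds and candidates
    are chosen by distance with lexicographic tie-breaks.
    """
    params = params or BuildParams()
    pts = np.atleast_2d(np.asarray(contacts_mm, dtype=float))
    if len(pts) == 0:
        return []
    center = np.asarray(center, dtype=float)
    # canonical processing order for permutation invariance
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    remaining = list(order)
    electrodes: list[Electrode] = []
    while remaining:
        rem_pts = pts[remaining]
        dist_c = np.linalg.norm(rem_pts - center, axis=1)
        seed_pos = int(np.argmax(np.round(dist_c, 9)))  # ties: lexicographic order
        chain = [remaining.pop(seed_pos)]
        if remaining:
            d = np.linalg.norm(pts[remaining] - pts[chain[0]], axis=1)
            nearest = int(np.argmin(np.round(d, 9)))
            if d[nearest] <= params.search_distance_mm:
                chain.append(remaining.pop(nearest))
                _grow_chain(chain, remaining, pts, params)
            else:
                logger.warning("orphan contact forms singleton electrode")
        electrodes.append(Electrode(chain, pts[chain]))
    return electrodes


def _grow_chain(chain, remaining, pts, params) -> None:
    while remaining:
        last = pts[chain[-1]]
        prev = pts[chain[-2]]
        cand_pts = pts[remaining]
        d = np.linalg.norm(cand_pts - last, axis=1)
        ang = np.array(
            [_turn_angle_deg(prev, last, p) for p in cand_pts]
        )
        ok = (d <= params.search_distance_mm) & (ang <= params.max_deviation_deg)
        if not ok.any():
            return
        idx = np.flatnonzero(ok)
        best = idx[np.lexsort((ang[idx], np.round(d[idx], 9)))][0]
        chain.append(remaining.pop(int(best)))


def number_contacts(electrode: Electrode, center: np.ndarray) -> Electrode:
    """Assign contact numbers 1..n, 1 at the chain end nearest the brain
    centre; a perfectly symmetric tie goes to the lexicographically lower
    endpoint."""
    if electrode.n_contacts == 0:
        raise ValueError("empty electrode")
    center = np.asarray(center, dtype=float)
    d_first = np.linalg.norm(electrode.points_mm[0] - center)
    d_last = np.linalg.norm(electrode.points_mm[-1] - center)
    if np.isclose(d_first, d_last):
        deep_first = tuple(electrode.points_mm[0]) <= tuple(electrode.points_mm[-1])
    else:
        deep_first = d_first < d_last
    n = electrode.n_contacts
    electrode.numbers = list(range(1, n + 1)) if deep_first else list(range(n, 0, -1))
    return electrode


def assign_labels(
    electrodes: list[Electrode],
    name_map: dict[str, object] | None,
    params: BuildParams | None = None,
) -> list[Electrode]:
    """Attach clinical names.

    ``name_map`` maps a name either to a 0-based electrode index or to a
    world-mm anchor point ``[x, y, z]`` near the electrode's outer (tail)
    contact; the nearest tail within the search distance wins.  Electrodes
    left unmapped are auto-named ``E<k>``.
    """
    params = params or BuildParams()
    name_map = name_map or {}
    if len(set(name_map)) != len(name_map):
        raise ValueError("electrode names must be unique")
    taken: dict[int, str] = {}
    for name, target in name_map.items():
        if isinstance(target, (int, np.integer)):
            idx = int(target)
            if not 0 <= idx < len(electrodes):
                raise ValueError(f"name {name!r}: electrode index {idx} out of range")
        else:
            anchor = np.asarray(target, dtype=float)
            if anchor.shape != (3,):
                raise ValueError(f"name {name!r}: anchor must be [x, y, z] in mm")
            tails = np.array([e.outer_point() for e in electrodes])
            d = np.linalg.norm(tails - anchor, axis=1)
            within = np.flatnonzero(d <= params.search_distance_mm)
            if within.size == 0:
                raise ValueError(
                    f"name {name!r}: no electrode tail within "
                    f"{params.search_distance_mm} mm of anchor {anchor.tolist()}"
                )
            dmin = d[within].min()
            nearest = within[np.isclose(d[within], dmin)]
            if nearest.size > 1:
                raise ValueError(
                    f"name {name!r}: ambiguous anchor, candidate electrodes "
                    f"{nearest.tolist()} are equally near"
                )
            idx = int(nearest[0])
        if idx in taken:
            raise ValueError(
                f"electrode {idx} claimed by both {taken[idx]!r} and {name!r}"
            )
        taken[idx] = name
        electrodes[idx].label = name
    auto = 1
    for e in electrodes:
        if e.label is None:
            e.label = f"E{auto}"
            logger.warning("unmapped electrode auto-named %s", e.label)
        auto += 1
    return electrodes


def electrodes_table(electrodes: list[Electrode]) -> pd.DataFrame:
    """Flat per-contact table: electrode, number, name, position."""
    rows = []
    for e in electrodes:
        for cid, num, name, p in zip(
            e.contact_ids, e.numbers, e.contact_names(), e.points_mm
        ):
            rows.append(
                {
                    "electrode": e.label,
                    "contact_number": num,
                    "contact_name": name,
                    "contact_id": cid,
                    "x_mm": p[0],
                    "y_mm": p[1],
                    "z_mm": p[2],
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["electrode", "contact_number"]).reset_index(drop=True)
    return df
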