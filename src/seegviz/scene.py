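"""4D scene assembly and glTF 2.0 export.

Tissue masks become marching-cubes triangle meshes in world millimetres;
each contact becomes a 3 mm cube node whose uniform scale is keyframed
from its normalized windowed power (power 0 renders the cube at its base
size, power 1 at a 60 mm extent, linear in between, so visually larger
contacts carry proportionally more power).  One data window maps to one
animation second: a 4 s clip cut into 24 ms windows plays as a 167 s
animation.  A timeline bar of second markers, with a red marker at the
annotated seizure onset, is laid out beneath the brain.

The exporter writes plain-JSON glTF 2.0 with an embedded base64 buffer;
scenes re-import bit-comparably (within float32) through
:func:`import_gltf` and load in any glTF viewer.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .signals import PowerTrace
from .volumes import VoxelGrid, grid_as_bool

BASE_CONTACT_MM = 3.0  # rendered extent of the representative contact cube
MAX_CONTACT_MM = 60.0  # rendered extent at normalized power 1

_MATERIALS = {
    "gray": {"baseColorFactor": [0.75, 0.65, 0.65, 0.35], "alphaMode": "BLEND"},
    "white": {"baseColorFactor": [0.9, 0.9, 0.85, 0.3], "alphaMode": "BLEND"},
    "csf": {"baseColorFactor": [0.5, 0.7, 0.9, 0.2], "alphaMode": "BLEND"},
    "contact": {"baseColorFactor": [1.0, 0.78, 0.1, 1.0], "metallicFactor": 0.8},
    "marker": {"baseColorFactor": [0.4, 0.4, 0.4, 1.0]},
    "marker_red": {"baseColorFactor": [0.9, 0.05, 0.05, 1.0]},
}


@dataclass
class TriangleMesh:
    vertices: np.ndarray  # (n, 3) world mm
    faces: np.ndarray  # (m, 3) vertex indices
    name: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a missing vertex")


@dataclass
class AnimationChannel:
    target: str  # contact node name
    times: np.ndarray  # seconds, strictly increasing from 0
    scales: np.ndarray  # uniform scale factor per keyframe

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if len(self.times) != len(self.scales):
            raise ValueError("one scale per keyframe required")
        if len(self.times) and (self.times[0] != 0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("keyframe times must strictly increase from 0")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")


@dataclass
class Timeline:
    second_markers: list[float]  # one per whole second of source data
    seizure_s: float
    clip_s: float


@dataclass
class SceneModel:
    tissue_meshes: list[TriangleMesh] = field(default_factory=list)
    contacts: list[tuple[str, np.ndarray]] = field(default_factory=list)
    channels: list[AnimationChannel] = field(default_factory=list)
    timeline: Timeline | None = None
    base_size_mm: float = BASE_CONTACT_MM

    def __post_init__(self) -> None:
        names = {n for n, _ in self.contacts}
        missing = [c.target for c in self.channels if c.target not in names]
        if missing:
            raise ValueError(f"animated targets without contact meshes: {missing}")


def mask_to_mesh(mask: VoxelGrid, name: str) -> TriangleMesh:
    """Closed iso-surface of a binary mask at level 0.5, in world mm.

    Uses the marching-cubes algorithm (Lewiner variant); the mask is
    zero-padded by one voxel so surfaces at the lattice boundary close.
    """
    data = grid_as_bool(mask)
    if not data.any():
        raise ValueError(f"mask {name!r} is empty; no surface to extract")
    padded = np.pad(data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, method="lewiner")
    verts -= 1.0  # undo padding offset -> voxel coordinates
    world = verts @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    flip = np.linalg.det(mask.affine[:3, :3]) < 0
    faces = faces[:, ::-1] if not flip else faces  # outward winding
    return TriangleMesh(world, faces, name)


def contact_scale_channels(
    trace: PowerTrace,
    contact_names: list[str],
    max_size_mm: float = MAX_CONTACT_MM,
    base_size_mm: float = BASE_CONTACT_MM,
) -> list[AnimationChannel]:
    """Per-contact scale keyframes, one per data window, 1 s apart.

    Normalized power maps linearly onto uniform scale so that power 0
    keeps the base (representative) size and power 1 renders the contact
    at ``max_size_mm`` extent; scale is strictly increasing in power.
    """
    if not trace.normalized:
        raise ValueError("trace must be min-max normalized first")
    known = {n for n in contact_names}
    unmatched = [ch for ch in trace.channels if ch not in known]
    if unmatched:
        raise ValueError(f"trace rows without a matching contact: {unmatched}")
    times = np.arange(trace.n_windows, dtype=float)
    gain = max_size_mm / base_size_mm - 1.0
    return [
        AnimationChannel(ch, times, 1.0 + gain * trace.values[i])
        for i, ch in enumerate(trace.channels)
    ]


def build_timeline(clip_s: float, event_s: float) -> Timeline:
    """Second markers 0..floor(clip) plus a red marker at the event."""
    if clip_s <= 0:
        raise ValueError("clip duration must be positive")
    if not 0 <= event_s <= clip_s:
        raise ValueError(f"event at {event_s} s outside the {clip_s} s clip")
    return Timeline([float(s) for s in range(int(np.floor(clip_s)) + 1)],
                    float(event_s), float(clip_s))


def build_scene(
    tissue_masks: dict[str, VoxelGrid],
    contact_names: list[str],
    contact_centers_mm: np.ndarray,
    trace: PowerTrace | None = None,
    timeline: Timeline | None = None,
) -> SceneModel:
    """Assemble the full scene from pipeline outputs."""
    meshes = [mask_to_mesh(m, name) for name, m in tissue_masks.items()]
    contacts = [
        (n, np.asarray(c, dtype=float))
        for n, c in zip(contact_names, np.atleast_2d(contact_centers_mm))
    ]
    channels = (
        contact_scale_channels(trace, contact_names) if trace is not None else []
    )
    return SceneModel(meshes, contacts, channels, timeline)


# ---------------------------------------------------------------------------
# glTF 2.0 encoding

class _Buffer:
    def __init__(self) -> None:
        self.blob = bytearray()
        self.views: list[dict] = []
        self.accessors: list[dict] = []

    def _add_view(self, raw: bytes) -> int:
        while len(self.blob) % 4:
            self.blob.append(0)
        self.views.append(
            {"buffer": 0, "byteOffset": len(self.blob), "byteLength": len(raw)}
        )
        self.blob.extend(raw)
        return len(self.views) - 1

    def add_f32(self, arr: np.ndarray, kind: str, with_bounds: bool = False) -> int:
        arr = np.asarray(arr, dtype=np.float32)
        view = self._add_view(arr.tobytes())
        acc = {
            "bufferView": view,
            "componentType": 5126,
            "count": int(arr.shape[0]),
            "type": kind,
        }
        if with_bounds:
            acc["min"] = arr.min(axis=0).tolist() if arr.ndim > 1 else [float(arr.min())]
            acc["max"] = arr.max(axis=0).tolist() if arr.ndim > 1 else [float(arr.max())]
        self.accessors.append(acc)
        return len(self.accessors) - 1

    def add_u32(self, arr: np.ndarray) -> int:
        arr = np.asarray(arr, dtype=np.uint32).ravel()
        view = self._add_view(arr.tobytes())
        self.accessors.append(
            {
                "bufferView": view,
                "componentType": 5125,
                "count": int(arr.size),
                "type": "SCALAR",
            }
        )
        return len(self.accessors) - 1


def _box_geometry(extent: float) -> tuple[np.ndarray, np.ndarray]:
    h = extent / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-h, h) for sy in (-h, h) for sz in (-h, h)]
    )
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],  # x faces
            [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],  # y faces
            [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],  # z faces
        ]
    )
    return corners, faces


def export_gltf(scene: SceneModel, path: str | Path) -> Path:
    """Serialize the scene to a glTF 2.0 file (.gltf JSON, embedded buffer).

    Contact power animation is encoded as per-node uniform-scale samplers
    with linear interpolation, one keyframe per data window, 1 s apart.
    """
    path = Path(path)
    buf = _Buffer()
    materials = []
    mat_index: dict[str, int] = {}

    def material(role: str) -> int:
        if role not in mat_index:
            props = dict(_MATERIALS.get(role, _MATERIALS["marker"]))
            alpha = props.pop("alphaMode", None)
            metallic = props.pop("metallicFactor", 0.1)
            mat = {
                "name": role,
                "pbrMetallicRoughness": {
                    "baseColorFactor": props["baseColorFactor"],
                    "metallicFactor": metallic,
                    "roughnessFactor": 0.6,
                },
            }
            if alpha:
                mat["alphaMode"] = alpha
            mat_index[role] = len(materials)
            materials.append(mat)
        return mat_index[role]

    meshes_json, nodes = [], []

    def add_mesh(verts, faces, name, role) -> int:
        pos = buf.add_f32(np.asarray(verts, dtype=np.float32), "VEC3", with_bounds=True)
        idx = buf.add_u32(faces)
        meshes_json.append(
            {
                "name": name,
                "primitives": [
                    {
                        "attributes": {"POSITION": pos},
                        "indices": idx,
                        "material": material(role),
                        "mode": 4,
                    }
                ],
            }
        )
        return len(meshes_json) - 1

    for mesh in scene.tissue_meshes:
        mi = add_mesh(mesh.vertices, mesh.faces, mesh.name, mesh.name)
        nodes.append({"name": mesh.name, "mesh": mi})

    node_of_contact: dict[str, int] = {}
    if scene.contacts:
        bverts, bfaces = _box_geometry(scene.base_size_mm)
        box_mesh = add_mesh(bverts, bfaces, "contact_template", "contact")
        for name, center in scene.contacts:
            nodes.append(
                {
                    "name": f"contact:{name}",
                    "mesh": box_mesh,
                    "translation": [float(v) for v in center],
                    "scale": [1.0, 1.0, 1.0],
                }
            )
            node_of_contact[name] = len(nodes) - 1

    if scene.timeline is not None:
        _add_timeline_nodes(scene, add_mesh, nodes)

    animations = []
    if scene.channels:
        samplers, channels_json = [], []
        for ch in scene.channels:
            t_acc = buf.add_f32(ch.times.reshape(-1), "SCALAR", with_bounds=True)
            s_acc = buf.add_f32(
                np.repeat(ch.scales.reshape(-1, 1), 3, axis=1), "VEC3"
            )
            samplers.append(
                {"input": t_acc, "output": s_acc, "interpolation": "LINEAR"}
            )
            channels_json.append(
                {
                    "sampler": len(samplers) - 1,
                    "target": {
                        "node": node_of_contact[ch.target],
                        "path": "scale",
                    },
                }
            )
        animations = [
            {"name": "windowed_power", "samplers": samplers, "channels": channels_json}
        ]

    uri = "data:application/octet-stream;base64," + base64.b64encode(
        bytes(buf.blob)
    ).decode("ascii")
    gltf = {
        "asset": {"version": "2.0", "generator": "seegviz"},
        "scene": 0,
        "scenes": [{"nodes": list(range(len(nodes)))}],
        "nodes": nodes,
        "meshes": meshes_json,
        "materials": materials,
        "accessors": buf.accessors,
        "bufferViews": buf.views,
        "buffers": [{"byteLength": len(buf.blob), "uri": uri}],
    }
    if animations:
        gltf["animations"] = animations
    path.write_text(json.dumps(gltf))
    return path


def _add_timeline_nodes(scene: SceneModel, add_mesh, nodes) -> None:
    tl = scene.timeline
    if scene.tissue_meshes:
        allv = np.concatenate([m.vertices for m in scene.tissue_meshes])
        lo, hi = allv.min(axis=0), allv.max(axis=0)
    elif scene.contacts:
        allv = np.array([c for _, c in scene.contacts])
        lo, hi = allv.min(axis=0) - 20, allv.max(axis=0) + 20
    else:
        lo, hi = np.zeros(3), np.ones(3) * 100
    z = float(lo[2] - 10.0)  # 10 mm below the brain bounding box
    y = float((lo[1] + hi[1]) / 2)
    span = max(float(hi[0] - lo[0]), 1.0)

    def xpos(t: float) -> float:
        return float(lo[0]) + span * (t / max(tl.clip_s, 1e-9))

    mverts, mfaces = _box_geometry(2.0)
    marker_mesh = add_mesh(mverts, mfaces, "timeline_marker", "marker")
    for s in tl.second_markers:
        nodes.append(
            {
                "name": f"second:{s:g}",
                "mesh": marker_mesh,
                "translation": [xpos(s), y, z],
            }
        )
    rverts, rfaces = _box_geometry(3.0)
    red_mesh = add_mesh(rverts, rfaces, "seizure_marker", "marker_red")
    nodes.append(
        {
            "name": "seizure_marker",
            "mesh": red_mesh,
            "translation": [xpos(tl.seizure_s), y, z],
        }
    )


# ---------------------------------------------------------------------------
# glTF 2.0 decoding (round-trip verification / inspection)

_COMPONENT = {5126: ("<f4", 4), 5125: ("<u4", 4), 5123: ("<u2", 2)}
_WIDTH = {"SCALAR": 1, "VEC3": 3, "VEC4": 4}


def import_gltf(path: str | Path) -> dict:
    """Light-weight reader for files written by :func:`export_gltf`.

    Returns a dict with ``meshes`` (name -> vertices/faces), ``nodes``
    (name -> translation/scale), and ``animations`` (target node name ->
    times/scales arrays).
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("asset", {}).get("version") != "2.0":
        raise ValueError("not a glTF 2.0 document")
    uri = doc["buffers"][0]["uri"]
    prefix = "data:application/octet-stream;base64,"
    if not uri.startswith(prefix):
        raise ValueError("expected an embedded base64 buffer")
    blob = base64.b64decode(uri[len(prefix):])

    def read_accessor(i: int) -> np.ndarray:
        acc = doc["accessors"][i]
        view = doc["bufferViews"][acc["bufferView"]]
        dtype, _ = _COMPONENT[acc["componentType"]]
        width = _WIDTH[acc["type"]]
        off = view.get("byteOffset", 0)
        raw = blob[off : off + view["byteLength"]]
        arr = np.frombuffer(raw, dtype=dtype)[: acc["count"] * width]
        return arr.reshape(acc["count"], width) if width > 1 else arr

    meshes = {}
    for mesh in doc.get("meshes", []):
        prim = mesh["primitives"][0]
        meshes[mesh["name"]] = {
            "vertices": read_accessor(prim["attributes"]["POSITION"]),
            "faces": read_accessor(prim["indices"]).reshape(-1, 3),
        }
    nodes = {}
    for node in doc.get("nodes", []):
        nodes[node["name"]] = {
            "mesh": doc["meshes"][node["mesh"]]["name"] if "mesh" in node else None,
            "translation": node.get("translation"),
            "scale": node.get("scale"),
        }
    animations = {}
    for anim in doc.get("animations", []):
        for ch in anim["channels"]:
            sampler = anim["samplers"][ch["sampler"]]
            target = doc["nodes"][ch["target"]["node"]]["name"]
            animations[target] = {
                "times": read_accessor(sampler["input"]).ravel(),
                "scales": read_accessor(sampler["output"]),
                "interpolation": sampler["interpolation"],
                "path": ch["target"]["path"],
            }
    return {"meshes": meshes, "nodes": nodes, "animations": animations}


def export_obj(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write a single mesh as Wavefront OBJ (1-based face indices)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"o {mesh.name}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    return path
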