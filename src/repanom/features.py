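"""Kinematic feature channels and the azimuthal equidistant (AZEQ) projection.

A repetitive upper-limb exercise is represented by nine feature channels:
two 3D-unit-vector channels (upper-arm and forearm pointing direction,
expressed in the upper-torso frame) and seven scalars (three torso angles,
forearm pronation, and the wrist position in a static *core* reference
frame).  Directional channels live on the unit sphere, which is awkward for
linear modeling: they are first rotated so the training-data mean direction
sits at the north pole and then flattened with the azimuthal equidistant
projection, which preserves angular distance from the pole and keeps the
wrap discontinuity at the (rarely visited) south pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Channel",
    "ChannelSchema",
    "DEFAULT_SCHEMA",
    "FeatureSequence",
    "SphereProjection",
    "fit_sphere_rotation",
    "azeq_project",
    "azeq_unproject",
    "core_frame",
    "RawPoseSequence",
    "extract_channels",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class Channel:
    name: str
    kind: str  # "sphere3" | "scalar"
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("sphere3", "scalar"):
            raise ValueError(f"unknown channel kind {self.kind!r}")

    @property
    def ndim(self) -> int:
        """Raw dimensions per sample (3 for sphere, 1 for scalar)."""
        return 3 if self.kind == "sphere3" else 1

    @property
    def flat_dim(self) -> int:
        """Dimensions per sample after AZEQ flattening (2 for sphere, 1 for scalar)."""
        return 2 if self.kind == "sphere3" else 1


@dataclass(frozen=True)
class ChannelSchema:
    channels: tuple[Channel, ...]

    def __post_init__(self):
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    def __iter__(self):
        return iter(self.channels)

    def __len__(self):
        return len(self.channels)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def sphere_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.kind == "sphere3"]

    @property
    def n_raw_dims(self) -> int:
        return sum(c.ndim for c in self.channels)

    @property
    def n_flat_dims(self) -> int:
        """Total per-sample dims after AZEQ (11 for the default schema)."""
        return sum(c.flat_dim for c in self.channels)

    def column_names(self) -> list[str]:
        cols = []
        for c in self.channels:
            if c.kind == "sphere3":
                cols += [f"{c.name}__{d}" for d in "xyz"]
            else:
                cols.append(c.name)
        return cols

    def raw_slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for c in self.channels:
            out[c.name] = slice(off, off + c.ndim)
            off += c.ndim
        return out

    def flat_slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for c in self.channels:
            out[c.name] = slice(off, off + c.flat_dim)
            off += c.flat_dim
        return out

    def to_dict(self) -> dict:
        return {
            "channels": [
                {"name": c.name, "kind": c.kind, "units": c.units}
                for c in self.channels
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSchema":
        return cls(tuple(Channel(**c) for c in d["channels"]))


#: The nine channels of the gross upper-limb exercise representation.
DEFAULT_SCHEMA = ChannelSchema(
    (
        Channel("ua_point", "sphere3", "unit"),
        Channel("fa_point", "sphere3", "unit"),
        Channel("ts_ffx", "scalar", "rad"),
        Channel("ts_turn", "scalar", "rad"),
        Channel("ts_lfx", "scalar", "rad"),
        Channel("fa_pron", "scalar", "rad"),
        Channel("wr_x", "scalar", "m"),
        Channel("wr_y", "scalar", "m"),
        Channel("wr_z", "scalar", "m"),
    )
)


@dataclass
class FeatureSequence:
    """Time-major multi-channel kinematic series (no missing samples)."""

    samples: np.ndarray  # (T, schema.n_raw_dims)
    schema: ChannelSchema = field(default=DEFAULT_SCHEMA)
    frame_rate: float = 30.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != self.schema.n_raw_dims:
            raise ValueError(
                f"samples must be (T, {self.schema.n_raw_dims}); got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN/inf; interpolate gaps first")
        for ch, sl in zip(self.schema, self.schema.raw_slices().values()):
            if ch.kind == "sphere3":
                norms = np.linalg.norm(self.samples[:, sl], axis=1)
                if np.any(np.abs(norms - 1.0) > 1e-3):
                    raise ValueError(f"sphere channel {ch.name!r} has non-unit samples")
                # renormalize away small numeric drift
                self.samples[:, sl] /= norms[:, None]

    def __len__(self):
        return self.samples.shape[0]

    def channel(self, name: str) -> np.ndarray:
        sl = self.schema.raw_slices()[name]
        arr = self.samples[:, sl]
        return arr[:, 0] if arr.shape[1] == 1 else arr


@dataclass(frozen=True)
class SphereProjection:
    """Rotation carrying the training-data mean direction to +Z, plus AZEQ."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)


def fit_sphere_rotation(training_dirs: np.ndarray) -> SphereProjection:
    """Minimal rotation mapping the mean of ``training_dirs`` to the north pole.

    The roll about Z is left at zero (unconstrained by the construction);
    data already centered at the pole yield the identity.
    """
    dirs = np.atleast_2d(np.asarray(training_dirs, dtype=float))
    if dirs.shape[0] < 1 or dirs.shape[1] != 3:
        raise ValueError("training_dirs must be (N, 3) with N >= 1")
    mean = dirs.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise ValueError("mean direction is zero (antipodally symmetric data)")
    u = mean / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(u @ z)
    if s < 1e-15:
        if c > 0:  # already at the pole
            return SphereProjection(np.eye(3))
        # antipodal: rotate by pi about X (any horizontal axis works; fixed for determinism)
        return SphereProjection(Rotation.from_rotvec([np.pi, 0.0, 0.0]).as_matrix())
    angle = np.arctan2(s, c)
    R = Rotation.from_rotvec(axis / s * angle).as_matrix()
    return SphereProjection(R)


def azeq_project(v: np.ndarray, proj: SphereProjection) -> np.ndarray:
    """Azimuthal equidistant projection of unit vector(s) ``v`` from the pole.

    With w = R v, theta = arccos(w_z) and alpha = atan2(w_y, w_x), the image is
    theta * (cos alpha, sin alpha); its norm is the great-circle angle from the
    north pole, in [0, pi].
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = np.atleast_2d(v)
    norms = np.linalg.norm(V, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("azeq_project expects unit vectors")
    W = (proj.rotation @ (V / norms[:, None]).T).T
    # arctan2(hypot, z) rather than arccos(z): keeps full precision near the poles
    theta = np.arctan2(np.hypot(W[:, 0], W[:, 1]), W[:, 2])
    alpha = np.arctan2(W[:, 1], W[:, 0])
    out = np.stack([theta * np.cos(alpha), theta * np.sin(alpha)], axis=1)
    return out[0] if single else out


def azeq_unproject(p: np.ndarray, proj: SphereProjection) -> np.ndarray:
    """Exact inverse of :func:`azeq_project` (points with ||p|| > pi are clamped)."""
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    P = np.atleast_2d(p)
    theta = np.linalg.norm(P, axis=1)
    # clamp outside the valid disk; keeps the inverse defined for wild reconstructions
    scale = np.where(theta > np.pi - 1e-9, (np.pi - 1e-9) / np.maximum(theta, 1e-300), 1.0)
    P = P * scale[:, None]
    theta = theta * scale
    alpha = np.arctan2(P[:, 1], P[:, 0])
    W = np.stack(
        [np.sin(theta) * np.cos(alpha), np.sin(theta) * np.sin(alpha), np.cos(theta)],
        axis=1,
    )
    V = (proj.rotation.T @ W.T).T
    return V[0] if single else V


def project_sequence(seq: FeatureSequence, projections: dict[str, SphereProjection]) -> np.ndarray:
    """Flatten a FeatureSequence to (T, n_flat_dims): AZEQ for spheres, pass-through scalars."""
    cols = []
    for ch in seq.schema:
        vals = seq.channel(ch.name)
        if ch.kind == "sphere3":
            cols.append(azeq_project(vals, projections[ch.name]))
        else:
            cols.append(vals[:, None])
    return np.concatenate(cols, axis=1)


def unproject_channel(flat: np.ndarray, ch: Channel, proj: SphereProjection | None) -> np.ndarray:
    """Inverse of the per-channel flattening used by :func:`project_sequence`."""
    if ch.kind == "sphere3":
        assert proj is not None
        return azeq_unproject(flat, proj)
    return flat.reshape(-1)


# ---------------------------------------------------------------------------
# Raw-pose path (optional): core frame and channel extraction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def core_frame(
    shoulder_l: np.ndarray,
    shoulder_r: np.ndarray,
    gravity: np.ndarray,
    table_height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Static *core* reference frame from the first recorded frame.

    Origin: shoulder midpoint shifted along gravity to table level.  Y opposes
    gravity, Z points horizontally toward the camera (taken as the horizontal
    component of origin->camera, here the -gravity-orthogonalized world +Z),
    X = Y x Z.  Returns (origin, R) with frame axes as columns of R.
    """
    sl, sr = np.asarray(shoulder_l, float), np.asarray(shoulder_r, float)
    g = np.asarray(gravity, float)
    if np.linalg.norm(g) < 1e-12:
        raise ValueError("gravity must be nonzero")
    if np.linalg.norm(sl - sr) < 1e-9:
        raise ValueError("degenerate pose: coincident shoulders")
    y = -g / np.linalg.norm(g)
    mid = 0.5 * (sl + sr)
    # drop the midpoint along gravity until its height equals the table level
    origin = mid + (table_height - mid @ y) * y
    camera_dir = np.array([0.0, 0.0, 1.0])
    z = camera_dir - (camera_dir @ y) * y
    if np.linalg.norm(z) < 1e-9:
        raise ValueError("camera direction parallel to gravity")
    z = z / np.linalg.norm(z)
    x = np.cross(y, z)
    R = np.stack([x, y, z], axis=1)
    return origin, R


@dataclass
class RawPoseSequence:
    """Per-frame joint positions (world coordinates, meters) for the right arm.

    ``thumb_dir`` is the thumb pointing direction (unit); ``gravity`` is the
    world gravity direction shared by all frames.
    """

    spine_base: np.ndarray
    neck: np.ndarray
    shoulder_l: np.ndarray
    shoulder_r: np.ndarray
    elbow_r: np.ndarray
    wrist_r: np.ndarray
    thumb_dir: np.ndarray
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    table_height: float = 0.7
    frame_rate: float = 30.0

    def __len__(self):
        return self.spine_base.shape[0]


def extract_channels(pose: RawPoseSequence) -> FeatureSequence:
    """Derive the nine feature channels from raw joint positions.

    Sign conventions: torso turn positive when turning left (positive rotation
    about the up axis), frontal flexion positive tilting forward (toward the
    camera), lateral flexion positive tilting to the subject's right,
    pronation positive past the zero reference (thumb in the plane
    perpendicular to the elbow folding axis).
    """
    T = len(pose)
    for name in ("spine_base", "neck", "shoulder_l", "shoulder_r", "elbow_r", "wrist_r", "thumb_dir"):
        arr = getattr(pose, name)
        if arr.shape != (T, 3) or not np.all(np.isfinite(arr)):
            bad = [] if arr.shape != (T, 3) else np.where(~np.isfinite(arr).all(axis=1))[0].tolist()
            raise ValueError(f"joint {name!r} missing/invalid (frames {bad})")

    up = -pose.gravity / np.linalg.norm(pose.gravity)
    origin, R_core = core_frame(
        pose.shoulder_l[0], pose.shoulder_r[0], pose.gravity, pose.table_height
    )
    x_c, y_c, z_c = R_core.T  # core axes as rows

    # per-frame torso frame: y along spine, z facing out of the chest
    ty = _unit(pose.neck - pose.spine_base)
    shoulder_line = _unit(pose.shoulder_l - pose.shoulder_r)  # points to subject's left
    tz = _unit(np.cross(shoulder_line, ty))
    tx = np.cross(ty, tz)

    # torso turn: heading of the chest normal in the horizontal plane, 0 facing camera
    tz_h = tz - (tz @ up)[:, None] * up[None, :]
    ts_turn = np.arctan2(tz_h @ x_c, tz_h @ z_c)

    # tilts: spine lean toward torso-forward (frontal) / torso-right (lateral)
    fwd = _unit(tz_h)
    right = _unit(-(tx - (tx @ up)[:, None] * up[None, :]))
    ts_ffx = np.arctan2(np.einsum("ij,ij->i", ty, fwd), ty @ up)
    ts_lfx = np.arctan2(np.einsum("ij,ij->i", ty, right), ty @ up)

    ua = _unit(pose.elbow_r - pose.shoulder_r)
    fa = _unit(pose.wrist_r - pose.elbow_r)
    # express pointing directions in the torso frame
    ua_t = np.stack([np.einsum("ij,ij->i", ua, a) for a in (tx, ty, tz)], axis=1)
    fa_t = np.stack([np.einsum("ij,ij->i", fa, a) for a in (tx, ty, tz)], axis=1)

    # pronation: thumb direction about the forearm axis, zero at the plane
    # perpendicular to the elbow folding axis
    fold = _unit(np.cross(ua, fa))  # elbow folding axis
    thumb = _unit(pose.thumb_dir)
    t_perp = _unit(thumb - np.einsum("ij,ij->i", thumb, fa)[:, None] * fa)
    ref = _unit(np.cross(fold, fa))
    sin_p = np.einsum("ij,ij->i", np.cross(ref, t_perp), fa)
    cos_p = np.einsum("ij,ij->i", ref, t_perp)
    fa_pron = np.arctan2(sin_p, cos_p)

    wr = (pose.wrist_r - origin) @ R_core  # components in core frame

    samples = np.concatenate(
        [
            ua_t,
            fa_t,
            ts_ffx[:, None],
            ts_turn[:, None],
            ts_lfx[:, None],
            fa_pron[:, None],
            wr,
        ],
        axis=1,
    )
    return FeatureSequence(samples, DEFAULT_SCHEMA, pose.frame_rate)
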