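"""Cochlear spiral model, electrode placement, and insertion morphometry.

The basilar membrane is modelled as a conical logarithmic spiral

    x = r0 * exp(-b * theta) * cos(theta)
    y = r0 * exp(-b * theta) * sin(theta)
    z = c * theta

with ``theta`` running from the basal origin (round-window end of the hook
region, ``s = 0``) to the apex over ``total_turns`` turns.  The taper rate
``b`` is solved numerically so that the arc length equals the requested
basilar-membrane length (default 18.5 mm, i.e. 2.59 mm ~ 14% of the
cochlear length).  Insertion metrics follow the rostro-caudal projection
construction: contacts are projected onto the plane perpendicular to the
mid-modiolar (z) axis, arc-length depth is measured to the nearest path
point of the apical contact (Ch1), and the insertion angle is the polar
angle of Ch1 measured from the reference direction through the summit
point (where the membrane reconstruction leaves the hook region),
accumulating beyond 360 degrees for deep insertions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, minimize_scalar

#: micro-CT voxel-scale tolerance for depth round trips (micrometre)
VOXEL_TOLERANCE_UM = 17.0

_DENSE_N = 32769


@dataclass
class CochlearSpiral:
    """Arc-length-parameterised cochlear spiral (micrometre units)."""

    r0: float
    b: float
    c: float
    total_turns: float
    bm_length: float
    hook_length: float
    _theta: np.ndarray = field(repr=False, default=None)
    _s: np.ndarray = field(repr=False, default=None)
    _pts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if min(self.r0, self.bm_length, self.total_turns) <= 0 or self.b <= 0:
            raise ValueError("non-physical spiral parameters")
        if not (0 <= self.hook_length < self.bm_length):
            raise ValueError("hook_length must lie within the membrane")
        theta_max = 2 * np.pi * self.total_turns
        theta = np.linspace(0.0, theta_max, _DENSE_N)
        r = self.r0 * np.exp(-self.b * theta)
        speed = np.sqrt(r * r * (1 + self.b * self.b) + self.c * self.c)
        s = cumulative_trapezoid(speed, theta, initial=0.0)
        # normalise so s(theta_max) == bm_length exactly (sub-0.1% rescale)
        s *= self.bm_length / s[-1]
        self._theta = theta
        self._s = s
        self._pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), self.c * theta])

    # -- parameterisation ---------------------------------------------------

    @property
    def theta_max(self) -> float:
        return 2 * np.pi * self.total_turns

    def s_of_theta(self, theta) -> np.ndarray | float:
        out = np.interp(theta, self._theta, self._s)
        return float(out) if np.ndim(theta) == 0 else out

    def theta_of_s(self, s) -> np.ndarray | float:
        out = np.interp(s, self._s, self._theta)
        return float(out) if np.ndim(s) == 0 else out

    def point_at_arc(self, s) -> np.ndarray:
        """3D coordinates of the path point at arc depth ``s``."""
        theta = np.atleast_1d(self.theta_of_s(s))
        r = self.r0 * np.exp(-self.b * theta)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), self.c * theta])
        return pts[0] if np.ndim(s) == 0 else pts

    def _point_at_theta(self, theta: float) -> np.ndarray:
        r = self.r0 * np.exp(-self.b * theta)
        return np.array([r * np.cos(theta), r * np.sin(theta), self.c * theta])

    def tangent_at_base(self) -> np.ndarray:
        """Unit tangent at s = 0 pointing into increasing arc length."""
        d = self._pts[1] - self._pts[0]
        return d / np.linalg.norm(d)

    @property
    def theta_ref(self) -> float:
        """Angular position of the summit-point reference (hook exit)."""
        return float(self.theta_of_s(self.hook_length))

    def nearest_on_path(self, point: np.ndarray) -> tuple[float, float]:
        """Arc depth and 3D distance of the path point nearest to ``point``."""
        point = np.asarray(point, dtype=float)
        d2 = np.sum((self._pts - point) ** 2, axis=1)
        i = int(np.argmin(d2))
        lo = self._theta[max(i - 2, 0)]
        hi = self._theta[min(i + 2, _DENSE_N - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda th: float(np.sum((self._point_at_theta(th) - point) ** 2)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            theta_star = float(res.x)
        else:
            theta_star = float(self._theta[i])
        dist = float(np.linalg.norm(self._point_at_theta(theta_star) - point))
        return float(self.s_of_theta(theta_star)), dist


def build_spiral(
    bm_length: float = 18500.0,
    turns: float = 4.25,
    r0: float = 1400.0,
    c: float | None = None,
    hook_length: float = 1000.0,
) -> CochlearSpiral:
    """Construct the default guinea-pig-like spiral.

    ``r0`` is the basal radius (~1.4 mm), ``c`` the elevation per radian
    (default gives a 2.5 mm apical rise over 4.25 turns), and the taper
    ``b`` is solved so the numerically integrated arc length equals
    ``bm_length`` (default 18.5 mm: 2.59 mm per octave over ~14% of the
    cochlear length).
    """
    if bm_length <= 0 or turns <= 0 or r0 <= 0:
        raise ValueError("non-physical spiral parameters")
    theta_max = 2 * np.pi * turns
    if c is None:
        c = (2500.0 * bm_length / 18500.0) / theta_max
    theta = np.linspace(0.0, theta_max, 8193)

    def arc_length(b: float) -> float:
        r = r0 * np.exp(-b * theta)
        speed = np.sqrt(r * r * (1 + b * b) + c * c)
        return float(np.trapezoid(speed, theta))

    f = lambda b: arc_length(b) - bm_length
    if f(1e-9) < 0:
        raise ValueError("bm_length too long for the requested radius/turns")
    b = brentq(f, 1e-9, 2.0, xtol=1e-12)
    return CochlearSpiral(
        r0=r0, b=float(b), c=float(c), total_turns=turns, bm_length=bm_length, hook_length=hook_length
    )


# ---------------------------------------------------------------------------
# electrode track
# ---------------------------------------------------------------------------

CONTACT_SPACING_UM = 700.0
TIP_TO_CH1_UM = 1000.0
N_CONTACTS = 6


@dataclass
class ElectrodeTrack:
    """Ordered contact coordinates, Ch1 (apical) first, Ch6 (basal) last."""

    contact_ids: np.ndarray
    coords_um: np.ndarray  # (n, 3)
    intracochlear: np.ndarray | None = None  # flags for placed tracks
    nominal_depths_um: np.ndarray | None = None
    tip_coord_um: np.ndarray | None = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.contact_ids = np.asarray(self.contact_ids, dtype=int)
        self.coords_um = np.asarray(self.coords_um, dtype=float)
        if self.coords_um.shape != (self.contact_ids.size, 3):
            raise ValueError("coords_um must be (n_contacts, 3)")

    @property
    def n_contacts(self) -> int:
        return int(self.contact_ids.size)

    @property
    def group_label(self) -> str:
        n_in = (
            int(np.sum(self.intracochlear))
            if self.intracochlear is not None
            else self.n_contacts
        )
        return f"{n_in}Ch"


def place_electrode(
    spiral: CochlearSpiral,
    tip_depth: float,
    n_contacts: int = N_CONTACTS,
    contact_spacing: float = CONTACT_SPACING_UM,
    tip_to_ch1: float = TIP_TO_CH1_UM,
) -> ElectrodeTrack:
    """Place the carrier tip at arc depth ``tip_depth`` along the spiral.

    Ch1 (apical) sits ``tip_to_ch1`` behind the tip and successive contacts
    ``contact_spacing`` apart toward the base.  Contacts whose nominal arc
    depth is negative lie outside the cochlea; they are flagged
    extracochlear and positioned on the basal tangent extension.
    """
    if tip_depth < 0:
        raise ValueError("tip_depth must be >= 0")
    if tip_depth > spiral.bm_length:
        raise ValueError("tip_depth exceeds the basilar-membrane length")
    depths = tip_depth - tip_to_ch1 - contact_spacing * np.arange(n_contacts)
    inside = depths >= -1e-9
    coords = np.empty((n_contacts, 3))
    base_pt = spiral.point_at_arc(0.0)
    tangent = spiral.tangent_at_base()
    for i, d in enumerate(depths):
        if inside[i]:
            coords[i] = spiral.point_at_arc(max(d, 0.0))
        else:
            coords[i] = base_pt + d * tangent  # d < 0: behind the basal origin
    return ElectrodeTrack(
        contact_ids=np.arange(1, n_contacts + 1),
        coords_um=coords,
        intracochlear=inside,
        nominal_depths_um=depths,
        tip_coord_um=spiral.point_at_arc(tip_depth),
        source="synthetic",
    )


# ---------------------------------------------------------------------------
# insertion metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InsertionMetrics:
    """Morphometry of one electrode track on one spiral."""

    depth_ch1_um: float
    depth_reference_um: float
    percent_bm: float
    insertion_angle_deg: float
    n_contacts_in: int
    endpoint_convention: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "depth_ch1_um": self.depth_ch1_um,
                "depth_reference_um": self.depth_reference_um,
                "percent_bm": self.percent_bm,
                "insertion_angle_deg": self.insertion_angle_deg,
                "n_contacts_in": self.n_contacts_in,
                "endpoint_convention": self.endpoint_convention,
            },
            indent=2,
            sort_keys=True,
        )


OFF_PATH_TOLERANCE_UM = 150.0


def measure_insertion(
    track: ElectrodeTrack,
    spiral: CochlearSpiral,
    endpoint: str = "apical_contact",
    off_path_tol: float = OFF_PATH_TOLERANCE_UM,
    tip_to_ch1: float = TIP_TO_CH1_UM,
) -> InsertionMetrics:
    """Project a track onto the spiral and compute insertion metrics.

    ``endpoint`` selects the depth used for percent coverage:
    ``apical_contact`` (Ch1, default), ``basal_contact`` (deepest-numbered
    intracochlear contact), or ``carrier_tip`` (Ch1 depth plus the
    tip-to-Ch1 offset).  The insertion angle is always referenced to Ch1.
    """
    if endpoint not in ("apical_contact", "basal_contact", "carrier_tip"):
        raise ValueError("unknown endpoint convention")
    order = np.argsort(track.contact_ids)
    ids = track.contact_ids[order]
    coords = track.coords_um[order]
    flags = track.intracochlear[order] if track.intracochlear is not None else None

    base_pt = spiral.point_at_arc(0.0)
    tangent = spiral.tangent_at_base()
    arc, dist, inside = [], [], []
    for i in range(len(ids)):
        s_i, d_i = spiral.nearest_on_path(coords[i])
        if flags is not None:
            is_in = bool(flags[i])
        else:
            # behind the basal origin: nearest point clamps to s=0 and the
            # contact lies on the negative side of the basal tangent
            behind = s_i < 1e-6 and float(np.dot(coords[i] - base_pt, tangent)) < 0
            is_in = not behind
        if is_in and d_i > off_path_tol:
            warnings.warn(
                f"contact {ids[i]} lies {d_i:.0f} um off the spiral path; "
                "using nearest-point projection",
                stacklevel=2,
            )
        arc.append(s_i)
        dist.append(d_i)
        inside.append(is_in)
    arc = np.array(arc)
    inside = np.array(inside)
    if not inside.any():
        raise ValueError("track has no intracochlear contact")

    s_ch1 = float(arc[0]) if inside[0] else float("nan")
    if not inside[0]:
        raise ValueError("apical contact (Ch1) must be intracochlear")
    if endpoint == "apical_contact":
        depth_ref = s_ch1
    elif endpoint == "carrier_tip":
        depth_ref = s_ch1 + tip_to_ch1
    else:  # basal_contact: most basal contact still inside the cochlea
        depth_ref = float(arc[np.flatnonzero(inside)[-1]])

    angle = np.degrees(spiral.theta_of_s(s_ch1) - spiral.theta_ref)
    if angle < 0:
        warnings.warn("Ch1 lies basal of the summit-point reference; clipping angle at 0")
        angle = 0.0
    return InsertionMetrics(
        depth_ch1_um=s_ch1,
        depth_reference_um=depth_ref,
        percent_bm=100.0 * depth_ref / spiral.bm_length,
        insertion_angle_deg=float(angle),
        n_contacts_in=int(inside.sum()),
        endpoint_convention=endpoint,
    )


# ---------------------------------------------------------------------------
# real-data entry point
# ---------------------------------------------------------------------------


def read_contacts(csv_path: str | Path) -> ElectrodeTrack:
    """Read per-contact 3D coordinates from a plain CSV.

    Expected columns: ``contact_id, x_um, y_um, z_um`` with 1-6 rows.
    Rows are sorted by contact id; a 5-row file is labelled a 5Ch track.
    Contact spacing is reported by :func:`contact_spacing_report`, not
    enforced.
    """
    df = pd.read_csv(csv_path)
    required = ["contact_id", "x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"contacts CSV missing columns: {missing}")
    if not (1 <= len(df) <= 6):
        raise ValueError("contacts CSV must contain between 1 and 6 rows")
    if df["contact_id"].duplicated().any():
        raise ValueError("duplicate contact_id in contacts CSV")
    if df[required].isna().any().any():
        raise ValueError("malformed rows in contacts CSV")
    df = df.sort_values("contact_id")
    return ElectrodeTrack(
        contact_ids=df["contact_id"].to_numpy(),
        coords_um=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        intracochlear=None,
        source="csv",
    )


def contact_spacing_report(track: ElectrodeTrack, spiral: CochlearSpiral) -> np.ndarray:
    """Successive contact arc distances (um) along the spiral (nominal 700)."""
    arcs = np.array([spiral.nearest_on_path(p)[0] for p in track.coords_um])
    return np.abs(np.diff(arcs))


def align_to_modiolar_axis(
    track: ElectrodeTrack, axis_point_a: np.ndarray, axis_point_b: np.ndarray
) -> ElectrodeTrack:
    """Rigidly transform a track so the given mid-modiolar axis maps onto +z.

    For read-in coordinate sets the mid-modiolar axis must be supplied as
    two points (template registration is out of scope); synthetic tracks
    are built in the spiral frame and need no alignment.
    """
    a = np.asarray(axis_point_a, float)
    b = np.asarray(axis_point_b, float)
    axis = b - a
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis points must be distinct")
    k = axis / norm
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(k, z)
    s = np.linalg.norm(v)
    cth = float(np.dot(k, z))
    if s < 1e-12:
        rot = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)
    coords = (track.coords_um - a) @ rot.T
    return ElectrodeTrack(
        contact_ids=track.contact_ids.copy(),
        coords_um=coords,
        intracochlear=None if track.intracochlear is None else track.intracochlear.copy(),
        source=track.source,
    )
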