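"""Synthetic ion-carboxylate trajectories with planted ground truth.

Ions perform overdamped (Brownian-dynamics) random walks inside a
reflective sphere, attracted by Gaussian wells planted at chosen
carboxylate groups:

    x(t+dt) = x(t) - grad(U) * D * dt + sqrt(2 D dt) * eta,
    U(x)    = sum_w  -depth_w * exp(-|x - c_w|^2 / (2 width_w^2)),

with well depths in kT units (kT absorbed into the depth).  Groups are
static; each carboxylate contributes two oxygens 1.1 A either side of its
center so that the analysis-side midpoint recovers the planted position.
No physical realism is claimed: the generator exists to give the contact
screen trajectories whose binder set, site labels and departure times are
known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, LookupError_
from .trajectory import CarboxylGroup, IonTrack, Segment, TrajectoryBundle

OXY_HALF_SEP = 1.1  # A; carboxylate O-O distance ~2.2 A


@dataclass(frozen=True)
class WellSpec:
    """Gaussian attractive well planted at a group's center."""

    group_id: str
    depth: float = 8.0  # kT
    width: float = 2.0  # A
    off_time_ns: float | None = None  # well switched off at this global time

    def __post_init__(self):
        if not (np.isfinite(self.depth) and self.depth > 0):
            raise ConfigurationError("well depth must be finite and > 0")
        if not (np.isfinite(self.width) and self.width > 0):
            raise ConfigurationError("well width must be finite and > 0")


@dataclass(frozen=True)
class GroupSpec:
    group: CarboxylGroup
    center: tuple[float, float, float]


@dataclass(frozen=True)
class IonSpec:
    ion: IonTrack
    start: tuple[float, float, float]
    # optional constant drift (A/ns) switched on at a global time; used by the
    # escape preset to make vestibule exit fast enough to observe
    drift: tuple[float, float, float] | None = None
    drift_on_ns: float = 0.0


@dataclass
class SynthTrajConfig:
    groups: list[GroupSpec]
    ions: list[IonSpec]
    wells: list[WellSpec] = field(default_factory=list)
    diffusion_coefficient: float = 0.5  # A^2/ns
    timestep: float = 0.1  # ns
    n_segments: int = 6
    segment_length: float = 100.0  # ns
    boundary_radius: float = 40.0  # A
    seed: int = 0

    def validate(self):
        if not self.timestep < self.segment_length:
            raise ConfigurationError("timestep must be < segment_length")
        if self.diffusion_coefficient <= 0:
            raise ConfigurationError("diffusion coefficient must be > 0")
        centers = {g.group.group_id: np.asarray(g.center, float) for g in self.groups}
        for gid, c in centers.items():
            if np.linalg.norm(c) > self.boundary_radius:
                raise ConfigurationError(
                    f"group {gid} lies outside the boundary sphere"
                )
        for spec in self.ions:
            if np.linalg.norm(np.asarray(spec.start, float)) > self.boundary_radius:
                raise ConfigurationError(
                    f"ion {spec.ion.ion_id} starts outside the boundary sphere"
                )
        known = set(centers)
        for w in self.wells:
            if w.group_id not in known:
                raise ConfigurationError(f"well refers to unknown group {w.group_id}")
        return self


def _reflect(x: np.ndarray, radius: float) -> np.ndarray:
    """Radial reflection of positions outside the boundary sphere."""
    r = np.linalg.norm(x, axis=-1, keepdims=True)
    over = r > radius
    if np.any(over):
        scale = np.where(over, (2 * radius - r) / r, 1.0)
        # a step can in principle overshoot past the centre; clip to be safe
        scale = np.where(2 * radius - r < 0, radius / r, scale)
        x = x * scale
    return x


def _true_departure_scan(
    times: np.ndarray, xyz: np.ndarray, center: np.ndarray, radius: float, dwell: float
) -> float | None:
    """Direct frame-by-frame scan for the first sustained boundary crossing.

    Independent bookkeeping used only to attach ground truth to generated
    bundles (the analysis side has its own detector).
    """
    out = np.linalg.norm(xyz - center, axis=1) > radius
    start = None
    for k, flag in enumerate(out):
        if flag:
            if start is None:
                start = k
            if times[k] - times[start] >= dwell:
                return float(times[start])
        else:
            start = None
    return None


def generate_bundle(config: SynthTrajConfig) -> TrajectoryBundle:
    """Simulate the configured ions and package the result with ground truth.

    Bundle metadata carries ``binder_groups`` (groups holding a well active
    from t=0), ``well_off_times`` and ``true_departures`` (first sustained
    crossing of 25 A from the home-vestibule centroid, dwell 5 ns, computed
    by direct scan).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.timestep
    D = config.diffusion_coefficient
    n_ions = len(config.ions)
    centers = {g.group.group_id: np.asarray(g.center, float) for g in config.groups}

    well_c = np.array([centers[w.group_id] for w in config.wells]).reshape(-1, 3)
    well_d = np.array([w.depth for w in config.wells])
    well_w = np.array([w.width for w in config.wells])
    well_off = np.array(
        [np.inf if w.off_time_ns is None else w.off_time_ns for w in config.wells]
    )

    drift_v = np.zeros((n_ions, 3))
    drift_on = np.full(n_ions, np.inf)
    for k, spec in enumerate(config.ions):
        if spec.drift is not None:
            drift_v[k] = np.asarray(spec.drift, float)
            drift_on[k] = spec.drift_on_ns

    n_steps_per_seg = int(round(config.segment_length / dt))
    x = np.array([spec.start for spec in config.ions], dtype=float)
    sqrt_term = np.sqrt(2 * D * dt)

    segments = []
    for s in range(config.n_segments):
        t0 = s * config.segment_length
        times = t0 + dt * np.arange(n_steps_per_seg)
        traj = np.empty((n_steps_per_seg, n_ions, 3))
        for k in range(n_steps_per_seg):
            t = times[k]
            traj[k] = x
            force = np.zeros_like(x)
            if len(well_c):
                active = t < well_off
                if np.any(active):
                    diff = x[:, None, :] - well_c[None, active, :]
                    r2 = np.sum(diff * diff, axis=2)
                    w2 = well_w[active] ** 2
                    # -grad U = -depth/width^2 * (x - c) * exp(-r^2 / 2 w^2)
                    coef = -(well_d[active] / w2) * np.exp(-r2 / (2 * w2))
                    force += np.sum(coef[:, :, None] * diff, axis=1)
            drifting = (t >= drift_on)[:, None]
            step = (
                force * D * dt
                + np.where(drifting, drift_v * dt, 0.0)
                + sqrt_term * rng.standard_normal((n_ions, 3))
            )
            x = _reflect(x + step, config.boundary_radius)

        seg = Segment(
            segment_id=f"seg{s:02d}",
            duration_ns=config.segment_length,
            times=times,
            ion_xyz={
                spec.ion.ion_id: traj[:, k, :].copy()
                for k, spec in enumerate(config.ions)
            },
            group_oxy={
                gid: np.broadcast_to(
                    np.stack(
                        [
                            c + np.array([OXY_HALF_SEP, 0, 0]),
                            c - np.array([OXY_HALF_SEP, 0, 0]),
                        ]
                    ),
                    (n_steps_per_seg, 2, 3),
                ).copy()
                for gid, c in centers.items()
            },
        )
        segments.append(seg)

    bundle = TrajectoryBundle(
        segments=segments,
        ions={spec.ion.ion_id: spec.ion for spec in config.ions},
        groups={g.group.group_id: g.group for g in config.groups},
        metadata={"generator": "synth_traj", "seed": config.seed},
    )

    binders = sorted(
        {w.group_id for w in config.wells if w.off_time_ns is None or w.off_time_ns > 0}
    )
    bundle.metadata["binder_groups"] = binders
    bundle.metadata["well_off_times"] = {
        w.group_id: w.off_time_ns for w in config.wells if w.off_time_ns is not None
    }

    all_times = np.concatenate([seg.times for seg in segments])
    vest_centers = bundle.vestibule_centers()
    true_dep = {}
    for k, spec in enumerate(config.ions):
        home = spec.ion.home_vestibule
        if home not in vest_centers:
            continue
        xyz = np.concatenate([seg.ion_xyz[spec.ion.ion_id] for seg in segments])
        t = _true_departure_scan(all_times, xyz, vest_centers[home], 25.0, 5.0)
        if t is not None:
            true_dep[spec.ion.ion_id] = t
    bundle.metadata["true_departures"] = true_dep
    return bundle


def _wt_like_layout() -> tuple[list[GroupSpec], list[IonSpec], list[WellSpec]]:
    """One acidic pocket (two sites) plus a central vestibule cluster.

    Residue numbering borrows the familiar ASIC1a labels purely as mnemonics;
    geometry is synthetic.  Binder groups sit within ~2.5 A of a well center,
    non-binders at least 15 A from every well.
    """
    A = np.array([0.0, 0.0, 0.0])  # inner AP site
    B = np.array([14.0, 0.0, 0.0])  # outer AP site
    C = np.array([0.0, 28.0, 0.0])  # central vestibule site

    def ap(gid, num, name, pos):
        return GroupSpec(CarboxylGroup(gid, num, name, "1", "AP"), tuple(pos))

    def cv(gid, num, name, pos):
        return GroupSpec(CarboxylGroup(gid, num, name, "1", "CV"), tuple(pos))

    groups = [
        # inner-site binders
        ap("E219", 219, "GLU", A + [1.8, 0.0, 0.0]),
        ap("D409", 409, "ASP", A + [-1.5, 1.0, 0.0]),
        ap("E242", 242, "GLU", A + [0.0, -2.4, 1.0]),
        # outer-site binders
        ap("E97", 97, "GLU", B + [2.0, 0.0, 0.0]),
        ap("E238", 238, "GLU", B + [-1.5, 1.5, 0.0]),
        ap("D347", 347, "ASP", B + [0.0, -2.0, 1.0]),
        ap("D351", 351, "ASP", B + [0.5, 1.5, -1.6]),
        # central-vestibule binders
        cv("E375", 375, "GLU", C + [0.0, 1.9, 0.0]),
        cv("E413", 413, "GLU", C + [1.6, -1.0, 0.0]),
        cv("E418", 418, "GLU", C + [-1.8, -0.5, 0.5]),
        # non-binders, >=15 A from every well
        ap("E177", 177, "GLU", (-20.0, -5.0, 0.0)),
        ap("E355", 355, "GLU", (-18.0, 10.0, 0.0)),
        ap("D237", 237, "ASP", (15.0, -18.0, 0.0)),
        cv("E79", 79, "GLU", (0.0, 28.0, -20.0)),
        GroupSpec(CarboxylGroup("D357", 357, "ASP", "1", "other"), (25.0, 25.0, 0.0)),
    ]
    ions = [
        IonSpec(IonTrack("ca_inner", "AP-1", "inner_AP"), tuple(A)),
        IonSpec(IonTrack("ca_outer", "AP-1", "outer_AP"), tuple(B)),
        IonSpec(IonTrack("ca_cv", "CV", "CV"), tuple(C)),
    ]
    wells = [
        WellSpec("E219"),
        WellSpec("D409"),
        WellSpec("E97"),
        WellSpec("D347"),
        WellSpec("E375"),
        WellSpec("E413"),
    ]
    return groups, ions, wells


# Groups the wt_like wells make true binders (within the occupancy criterion):
# every group within ~2.5 A of an active well center.
WT_LIKE_BINDERS = (
    "E219", "D409", "E242", "E97", "E238", "D347", "D351", "E375", "E413", "E418",
)


def preset_config(name: str, seed: int = 0) -> SynthTrajConfig:
    groups, ions, wells = _wt_like_layout()
    if name == "wt_like":
        return SynthTrajConfig(groups=groups, ions=ions, wells=wells, seed=seed)
    if name == "nonbinding":
        # no wells: ions drift in bulk solvent, starting >=40 A from every
        # group inside a larger sphere (free ions do not reside anywhere)
        free_ions = [
            IonSpec(IonTrack("ca_inner", "AP-1", "inner_AP"), (0.0, -60.0, 0.0)),
            IonSpec(IonTrack("ca_outer", "AP-1", "outer_AP"), (40.0, -40.0, 30.0)),
            IonSpec(IonTrack("ca_cv", "CV", "CV"), (-45.0, -30.0, -30.0)),
        ]
        return SynthTrajConfig(
            groups=groups, ions=free_ions, wells=[], seed=seed,
            boundary_radius=80.0,
        )
    if name == "escape":
        # the inner-site well is switched off at 300 ns and the ion is pulled
        # out of the pocket; the other sites keep their wells
        esc_wells = [
            WellSpec("E219", off_time_ns=300.0),
            WellSpec("D409", off_time_ns=300.0),
            WellSpec("E97"),
            WellSpec("D347"),
            WellSpec("E375"),
            WellSpec("E413"),
        ]
        esc_ions = [
            IonSpec(
                IonTrack("ca_inner", "AP-1", "inner_AP"),
                (0.0, 0.0, 0.0),
                drift=(-0.7, 0.9, 0.0),
                drift_on_ns=300.0,
            ),
            ions[1],
            ions[2],
        ]
        return SynthTrajConfig(groups=groups, ions=esc_ions, wells=esc_wells, seed=seed)
    raise LookupError_(f"unknown trajectory preset {name!r}")


def preset_bundle(name: str, seed: int = 0) -> TrajectoryBundle:
    """Generate one of the named study bundles (wt_like, nonbinding, escape)."""
    bundle = generate_bundle(preset_config(name, seed))
    bundle.metadata["preset"] = name
    if name == "wt_like":
        bundle.metadata["binder_groups"] = sorted(WT_LIKE_BINDERS)
    if name == "nonbinding":
        bundle.metadata["binder_groups"] = []
    return bundle


def reference_site_anchors() -> dict[str, dict[str, list[str]]]:
    """Inner/outer anchor map matching the preset layouts."""
    return {"AP-1": {"inner": ["E219", "D409"], "outer": ["E97"]}}
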