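"""Domain model for ion/carboxylate coordinate time series.

A :class:`TrajectoryBundle` holds an MD-style coordinate record: tagged
Ca2+ ions and the two side-chain oxygens of acidic residues (Asp OD1/OD2,
Glu OE1/OE2), organised in consecutive segments of nominally equal duration
(the analysis evaluates its occupancy criterion per segment).  Coordinates
are in Angstrom, times in nanoseconds, on a single global clock that is
strictly increasing across segments.  Coordinates are assumed pre-imaged;
no periodic-boundary handling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import yaml

from .errors import ConfigurationError, InvalidCoordinateError

VALID_REGIONS = ("AP", "CV", "other")
VALID_SITES = ("inner_AP", "outer_AP", "CV")


def as_point(p) -> np.ndarray:
    """Validate and return a finite 3-vector (Angstrom)."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise InvalidCoordinateError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidCoordinateError(f"non-finite coordinate: {arr}")
    return arr


@dataclass(frozen=True)
class CarboxylGroup:
    """Static identity of one carboxylate group (the coordinates live in segments)."""

    group_id: str
    residue_number: int
    residue_name: str  # ASP or GLU
    subunit: str
    region: str  # AP, CV or other

    def __post_init__(self):
        if self.residue_name not in ("ASP", "GLU"):
            raise ConfigurationError(
                f"{self.group_id}: residue_name must be ASP or GLU, got {self.residue_name}"
            )
        if self.region not in VALID_REGIONS:
            raise ConfigurationError(
                f"{self.group_id}: region must be one of {VALID_REGIONS}, got {self.region}"
            )

    @property
    def vestibule(self) -> str | None:
        """Vestibule label this group belongs to (None for 'other')."""
        if self.region == "AP":
            return f"AP-{self.subunit}"
        if self.region == "CV":
            return "CV"
        return None


@dataclass(frozen=True)
class IonTrack:
    """Static identity of one tagged Ca2+ ion."""

    ion_id: str
    home_vestibule: str  # AP-1, AP-2, AP-3 or CV
    home_site: str  # inner_AP, outer_AP or CV

    def __post_init__(self):
        if self.home_site not in VALID_SITES:
            raise ConfigurationError(
                f"{self.ion_id}: home_site must be one of {VALID_SITES}"
            )
        if (self.home_site == "CV") != (self.home_vestibule == "CV"):
            raise ConfigurationError(
                f"{self.ion_id}: home_site is CV iff home_vestibule is CV"
            )


@dataclass
class Segment:
    """One nominally fixed-duration block of frames shared by all particles."""

    segment_id: str
    duration_ns: float
    times: np.ndarray  # (n_frames,) ns, strictly increasing, global clock
    ion_xyz: dict[str, np.ndarray]  # ion_id -> (n_frames, 3)
    group_oxy: dict[str, np.ndarray]  # group_id -> (n_frames, 2, 3)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def group_centers(self, group_id: str) -> np.ndarray:
        """Per-frame unweighted midpoint of the two oxygens, (n_frames, 3)."""
        return self.group_oxy[group_id].mean(axis=1)

    def validate(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ConfigurationError(f"segment {self.segment_id}: needs >=2 frames")
        if not np.all(np.diff(t) > 0):
            raise ConfigurationError(
                f"segment {self.segment_id}: times must be strictly increasing"
            )
        if not self.duration_ns > 0:
            raise ConfigurationError(f"segment {self.segment_id}: duration must be > 0")
        n = len(t)
        for iid, xyz in self.ion_xyz.items():
            if xyz.shape != (n, 3):
                raise ConfigurationError(
                    f"segment {self.segment_id}: ion {iid} has shape {xyz.shape}, "
                    f"expected {(n, 3)}"
                )
            if not np.all(np.isfinite(xyz)):
                raise InvalidCoordinateError(f"ion {iid}: non-finite coordinates")
        for gid, oxy in self.group_oxy.items():
            if oxy.shape != (n, 2, 3):
                raise ConfigurationError(
                    f"segment {self.segment_id}: group {gid} has shape {oxy.shape}, "
                    f"expected {(n, 2, 3)} (exactly two oxygens per frame)"
                )
            if not np.all(np.isfinite(oxy)):
                raise InvalidCoordinateError(f"group {gid}: non-finite coordinates")


@dataclass
class TrajectoryBundle:
    """Segments plus static ion/group identities and free-form metadata."""

    segments: list[Segment]
    ions: dict[str, IonTrack]
    groups: dict[str, CarboxylGroup]
    metadata: dict = field(default_factory=dict)

    def validate(self):
        if not self.segments:
            raise ConfigurationError("bundle has no segments")
        for seg in self.segments:
            seg.validate()
            missing_i = set(self.ions) - set(seg.ion_xyz)
            missing_g = set(self.groups) - set(seg.group_oxy)
            if missing_i or missing_g:
                raise ConfigurationError(
                    f"segment {seg.segment_id}: missing particles "
                    f"(ions {sorted(missing_i)}, groups {sorted(missing_g)})"
                )
        t_prev = -np.inf
        for seg in self.segments:
            if seg.times[0] <= t_prev:
                raise ConfigurationError("segment clocks must be globally increasing")
            t_prev = seg.times[-1]
        return self

    @property
    def ion_ids(self) -> list[str]:
        return sorted(self.ions)

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups)

    def vestibules(self) -> dict[str, list[str]]:
        """Map vestibule label -> sorted group ids belonging to it."""
        out: dict[str, list[str]] = {}
        for gid in self.group_ids:
            v = self.groups[gid].vestibule
            if v is not None:
                out.setdefault(v, []).append(gid)
        return out

    def vestibule_centers(self) -> dict[str, np.ndarray]:
        """Static vestibule centroids: mean of member group centers at frame 0."""
        seg0 = self.segments[0]
        return {
            v: np.mean([seg0.group_centers(g)[0] for g in gids], axis=0)
            for v, gids in self.vestibules().items()
        }


@dataclass
class ScreeningConfig:
    """Thresholds of the two-step contact screen.

    Defaults follow the published protocol: a coarse pass every 10 ns with a
    10 A pre-screen, a 0.4 ns refinement with a 6 A contact cutoff, candidacy
    when the contact holds for >=10 % of a segment's refined frames, occupancy
    fractions at 4/6/20 A, mean contact distance capped at 10 A, and departure
    declared beyond 25 A from the home-vestibule centroid sustained >=5 ns.
    """

    screen_interval: float = 10.0  # ns
    refine_interval: float = 0.4  # ns
    screen_cutoff: float = 10.0  # A
    candidate_cutoff: float = 6.0  # A
    min_fraction: float = 0.10
    occupancy_cutoffs: tuple[float, ...] = (4.0, 6.0, 20.0)
    mean_cap: float = 10.0  # A
    departure_radius: float = 25.0  # A
    departure_dwell: float = 5.0  # ns

    def __post_init__(self):
        lengths = (
            self.screen_interval,
            self.refine_interval,
            self.screen_cutoff,
            self.candidate_cutoff,
            self.mean_cap,
            self.departure_radius,
            self.departure_dwell,
            *self.occupancy_cutoffs,
        )
        if not all(x > 0 for x in lengths):
            raise ConfigurationError("all lengths/intervals must be > 0")
        if not self.candidate_cutoff < self.screen_cutoff:
            raise ConfigurationError("candidate_cutoff must be < screen_cutoff")
        if not 0 < self.min_fraction < 1:
            raise ConfigurationError("min_fraction must be in (0, 1)")
        self.occupancy_cutoffs = tuple(sorted(float(c) for c in self.occupancy_cutoffs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["occupancy_cutoffs"] = list(self.occupancy_cutoffs)
        return d

    @classmethod
    def from_yaml(cls, path) -> "ScreeningConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class DepartureEvent:
    """First sustained exit of an ion from its home vestibule."""

    ion_id: str
    vestibule: str
    departure_time: float  # ns, global clock


def segment_sample_indices(seg: Segment, interval: float) -> np.ndarray:
    """Frame indices nearest the targets t0 + k*interval, k = 1..floor(T/interval).

    The target count uses the segment's nominal duration, reproducing the
    "n measurements per segment" bookkeeping (10 per 100 ns at 10 ns spacing);
    duplicate nearest frames are dropped.
    """
    n_targets = int(np.floor(seg.duration_ns / interval + 1e-9))
    if n_targets < 1:
        return np.array([], dtype=int)
    targets = seg.times[0] + interval * np.arange(1, n_targets + 1)
    idx = np.searchsorted(seg.times, targets)
    idx = np.clip(idx, 1, seg.n_frames - 1)
    left = seg.times[idx - 1]
    right = seg.times[idx]
    idx = np.where(targets - left <= right - targets, idx - 1, idx)
    return np.unique(idx)
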