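"""Multi-step screening of ion-carboxylate contacts.

Implements the two-step blind pair search used to rank acidic side chains
as candidate divalent-cation binders: a coarse distance extraction (every
10 ns by default) with a 10 A pre-screen, followed by a 0.4 ns refinement
restricted to retained pairs, a second-passage exclusion for ions that
left their vestibule, and per-residue occupancy/mean-distance metrics.

All distance thresholds are strict (<); the contact reference point of a
carboxylate group is the unweighted midpoint of its two side-chain oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    DomainError,
    EmptyInputError,
    LookupError_,
    UnknownPairError,
)
from .trajectory import (
    DepartureEvent,
    ScreeningConfig,
    Segment,
    TrajectoryBundle,
    as_point,
    segment_sample_indices,
)

TABLE_COLUMNS = ["segment_id", "time_ns", "ion_id", "group_id", "distance"]


@dataclass
class DistanceTable:
    """(segment, time, ion, group, distance) records at a fixed sampling interval."""

    frame: pd.DataFrame
    sampling_interval: float

    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self) -> set[tuple[str, str]]:
        if self.frame.empty:
            return set()
        uniq = self.frame[["ion_id", "group_id"]].drop_duplicates()
        return set(map(tuple, uniq.itertuples(index=False, name=None)))


def group_center(o1, o2) -> np.ndarray:
    """Unweighted midpoint of the two carboxylate oxygen positions."""
    return (as_point(o1) + as_point(o2)) / 2.0


def count_screening_distances(
    n_channels: int,
    n_ions_per_channel: int,
    n_acidic: int,
    n_segments: int,
    n_samples: int,
) -> int:
    """Bookkeeping twin of the coarse table's record count (a plain product)."""
    args = (n_channels, n_ions_per_channel, n_acidic, n_segments, n_samples)
    for a in args:
        if not (isinstance(a, (int, np.integer)) and a > 0):
            raise DomainError(f"all counts must be positive integers, got {args}")
    return int(np.prod([int(a) for a in args], dtype=object))


def build_distance_table(
    bundle: TrajectoryBundle,
    interval: float,
    pairs: set[tuple[str, str]] | None = None,
) -> DistanceTable:
    """Ion-to-group-center distances sampled every `interval` ns.

    For each segment, every (ion, group) pair (optionally restricted to
    `pairs`) contributes one record per sampled frame; sampled frames are
    those nearest t0 + k*interval (no interpolation).
    """
    if not bundle.segments:
        raise EmptyInputError("bundle has no segments")
    ion_ids = bundle.ion_ids
    group_ids = bundle.group_ids
    if not ion_ids or not group_ids:
        raise EmptyInputError("bundle has no ions or no groups")
    if pairs is not None:
        pair_list = sorted(pairs)
    else:
        pair_list = [(i, g) for i in ion_ids for g in group_ids]

    chunks = []
    for seg in bundle.segments:
        idx = segment_sample_indices(seg, interval)
        if len(idx) == 0:
            continue
        times = seg.times[idx]
        centers = {g: seg.group_centers(g)[idx] for g in group_ids}
        ions = {i: seg.ion_xyz[i][idx] for i in ion_ids}
        for iid, gid in pair_list:
            d = np.linalg.norm(ions[iid] - centers[gid], axis=1)
            chunks.append(
                pd.DataFrame(
                    {
                        "segment_id": seg.segment_id,
                        "time_ns": times,
                        "ion_id": iid,
                        "group_id": gid,
                        "distance": d,
                    }
                )
            )
    frame = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=TABLE_COLUMNS)
    )
    frame = frame.sort_values(
        ["segment_id", "ion_id", "group_id", "time_ns"], kind="stable"
    ).reset_index(drop=True)
    return DistanceTable(frame=frame, sampling_interval=float(interval))


def screen_pairs(table: DistanceTable, cutoff: float) -> set[tuple[str, str]]:
    """Pairs with at least one record strictly below `cutoff` (the pre-screen)."""
    if table.frame.empty:
        raise EmptyInputError("distance table is empty")
    hits = table.frame.loc[table.frame["distance"] < cutoff, ["ion_id", "group_id"]]
    return set(map(tuple, hits.drop_duplicates().itertuples(index=False, name=None)))


def fraction_within(distance_series, cutoff: float) -> float:
    """Fraction of sampled frames with distance strictly below `cutoff`."""
    d = np.asarray(distance_series, dtype=float)
    if d.size == 0:
        raise EmptyInputError("empty distance series")
    return float(np.count_nonzero(d < cutoff) / d.size)


def capped_mean_distance(distance_series, cap: float) -> tuple[float, int]:
    """Mean over records with distance <= cap; (nan, 0) when none qualify."""
    d = np.asarray(distance_series, dtype=float)
    if d.size == 0:
        raise EmptyInputError("empty distance series")
    kept = d[d <= cap]
    if kept.size == 0:
        return (float("nan"), 0)  # no-contact sentinel
    return (float(kept.mean()), int(kept.size))


def detect_departures(
    bundle: TrajectoryBundle,
    ion_id: str,
    config: ScreeningConfig,
    center: np.ndarray | None = None,
) -> DepartureEvent | None:
    """First sustained exit of `ion_id` from its home vestibule, if any.

    Departure is declared at the first time the ion's distance to the
    (static) home-vestibule centroid exceeds ``departure_radius``
    continuously for at least ``departure_dwell`` ns; an excursion still in
    progress at the end of the data counts only if it already spans the
    dwell.  Excursions may span segment boundaries (global clock).
    """
    if ion_id not in bundle.ions:
        raise LookupError_(f"unknown ion {ion_id!r}")
    home = bundle.ions[ion_id].home_vestibule
    if center is None:
        centers = bundle.vestibule_centers()
        if home not in centers:
            raise ConfigurationError(f"no groups define vestibule {home!r}")
        center = centers[home]
    center = as_point(center)

    times = np.concatenate([seg.times for seg in bundle.segments])
    xyz = np.concatenate([seg.ion_xyz[ion_id] for seg in bundle.segments])
    if len(times) != len(xyz):
        raise AlignmentError("ion series misaligned with frame times")
    outside = np.linalg.norm(xyz - center, axis=1) > config.departure_radius

    start = None
    for k in range(len(times)):
        if outside[k]:
            if start is None:
                start = k
            if times[k] - times[start] >= config.departure_dwell:
                return DepartureEvent(
                    ion_id=ion_id, vestibule=home, departure_time=float(times[start])
                )
        else:
            start = None
    return None


def detect_all_departures(
    bundle: TrajectoryBundle, config: ScreeningConfig
) -> list[DepartureEvent]:
    events = []
    centers = bundle.vestibule_centers()
    for iid in bundle.ion_ids:
        home = bundle.ions[iid].home_vestibule
        if home not in centers:
            continue
        ev = detect_departures(bundle, iid, config, center=centers[home])
        if ev is not None:
            events.append(ev)
    return events


def apply_passage_mask(
    table: DistanceTable,
    departures: list[DepartureEvent],
    bundle: TrajectoryBundle,
) -> DistanceTable:
    """Second-passage exclusion.

    After an ion has left its home vestibule, its records with groups
    outside that vestibule are removed; records up to and including the
    departure time, and all home-vestibule records, are untouched.
    """
    if not departures:
        return DistanceTable(table.frame.copy(), table.sampling_interval)
    frame = table.frame
    known = set(bundle.ions)
    drop = np.zeros(len(frame), dtype=bool)
    group_vest = frame["group_id"].map(
        lambda g: bundle.groups[g].vestibule if g in bundle.groups else None
    )
    for ev in departures:
        if ev.ion_id not in known:
            raise LookupError_(f"departure refers to unknown ion {ev.ion_id!r}")
        foreign = group_vest != ev.vestibule  # None compares unequal: masked too
        drop |= (
            (frame["ion_id"] == ev.ion_id)
            & (frame["time_ns"] > ev.departure_time)
            & foreign.to_numpy()
        )
    return DistanceTable(
        frame.loc[~drop].reset_index(drop=True), table.sampling_interval
    )


@dataclass
class CandidateReport:
    """Per-residue contact metrics and candidate flags.

    ``per_pairing`` carries one row per (group, vestibule-ion pairing) -- the
    individual "data points" of the occupancy/mean-distance display;
    ``summary`` aggregates over pairings per group (spread given as both s.d.
    and s.e.m.); ``segment_flags`` records the >=10 % criterion per segment
    (the overall flag is an OR over segments, a documented reading of the
    protocol's per-period wording).
    """

    per_pairing: pd.DataFrame
    summary: pd.DataFrame
    segment_flags: pd.DataFrame
    candidates: set[str]
    config: ScreeningConfig
    departures: list[DepartureEvent] = field(default_factory=list)

    def candidate_ids(self) -> list[str]:
        return sorted(self.candidates)


def refine_candidates(
    bundle: TrajectoryBundle,
    pairs: set[tuple[str, str]],
    config: ScreeningConfig,
    departures: list[DepartureEvent] | None = None,
) -> tuple[pd.DataFrame, set[str], DistanceTable]:
    """Refined-interval pass/fail of the occupancy criterion.

    Distances are recomputed at ``refine_interval`` for retained pairs only;
    a group passes a segment when, for some retained pair, the distance is
    below ``candidate_cutoff`` during at least ``min_fraction`` of that
    segment's refined frames (frames need not be contiguous).  Overall
    candidacy is a pass in at least one segment.  Returns (per-segment flag
    table, candidate group ids, the masked fine table).
    """
    all_pairs = {(i, g) for i in bundle.ions for g in bundle.groups}
    unknown = set(pairs) - all_pairs
    if unknown:
        raise UnknownPairError(f"pairs not in bundle: {sorted(unknown)}")
    if departures is None:
        departures = []
    seg_ids = [s.segment_id for s in bundle.segments]
    if not pairs:
        flags = pd.DataFrame(
            False, index=sorted(bundle.groups), columns=seg_ids, dtype=bool
        )
        flags.index.name = "group_id"
        empty = DistanceTable(
            pd.DataFrame(columns=TABLE_COLUMNS), config.refine_interval
        )
        return flags, set(), empty

    fine = build_distance_table(bundle, config.refine_interval, pairs=pairs)
    fine = apply_passage_mask(fine, departures, bundle)

    # denominator: refined frames per segment (independent of masking)
    n_frames = {
        s.segment_id: len(segment_sample_indices(s, config.refine_interval))
        for s in bundle.segments
    }
    flags = pd.DataFrame(False, index=sorted(bundle.groups), columns=seg_ids, dtype=bool)
    flags.index.name = "group_id"
    close = fine.frame[fine.frame["distance"] < config.candidate_cutoff]
    counts = close.groupby(["group_id", "ion_id", "segment_id"], sort=True).size()
    for (gid, _iid, sid), n_close in counts.items():
        if n_frames[sid] and n_close / n_frames[sid] >= config.min_fraction:
            flags.loc[gid, sid] = True
    candidates = set(flags.index[flags.any(axis=1)])
    return flags, candidates, fine


def _closest_ion_series(
    fine: pd.DataFrame, gid: str, vestibule: str, bundle: TrajectoryBundle
) -> np.ndarray:
    """Per-frame distance to the closest matching-vestibule ion (after masking)."""
    ion_ids = [
        i for i, ion in bundle.ions.items() if ion.home_vestibule == vestibule
    ]
    sub = fine[(fine["group_id"] == gid) & (fine["ion_id"].isin(ion_ids))]
    if sub.empty:
        return np.array([])
    return sub.groupby(["segment_id", "time_ns"], sort=True)["distance"].min().to_numpy()


def candidate_report(
    bundle: TrajectoryBundle, config: ScreeningConfig | None = None
) -> CandidateReport:
    """Full pipeline: build -> screen -> mask -> refine -> metrics.

    Candidate flags come from the two-step screen; the occupancy and
    capped-mean metrics are computed from a refined-interval table over all
    matching vestibule/ion pairings (one data point per pairing), with the
    closest-ion scope restricted to ions whose home vestibule matches the
    group's, after second-passage masking.
    """
    config = config or ScreeningConfig()
    bundle.validate()

    departures = detect_all_departures(bundle, config)
    coarse = build_distance_table(bundle, config.screen_interval)
    retained = screen_pairs(coarse, config.screen_cutoff)
    flags, candidates, _ = refine_candidates(bundle, retained, config, departures)

    # metrics need full fine-resolution coverage of matching pairings
    metric_pairs = {
        (iid, gid)
        for iid, ion in bundle.ions.items()
        for gid, grp in bundle.groups.items()
        if grp.vestibule is not None and ion.home_vestibule == grp.vestibule
    }
    if metric_pairs:
        fine_all = build_distance_table(
            bundle, config.refine_interval, pairs=metric_pairs
        )
        fine_all = apply_passage_mask(fine_all, departures, bundle)
    else:
        fine_all = DistanceTable(
            pd.DataFrame(columns=TABLE_COLUMNS), config.refine_interval
        )

    cutoffs = config.occupancy_cutoffs
    rows = []
    for gid in bundle.group_ids:
        vest = bundle.groups[gid].vestibule
        if vest is None:
            continue
        series = _closest_ion_series(fine_all.frame, gid, vest, bundle)
        if series.size == 0:
            continue
        mean, n_used = capped_mean_distance(series, config.mean_cap)
        row = {
            "group_id": gid,
            "pairing": vest,
            "capped_mean_distance": mean,
            "n_used": n_used,
            "n_frames": int(series.size),
        }
        for c in cutoffs:
            row[f"fraction_lt_{c:g}"] = fraction_within(series, c)
        rows.append(row)
    per_pairing = pd.DataFrame(rows)

    summary_rows = []
    for gid in bundle.group_ids:
        sub = per_pairing[per_pairing["group_id"] == gid] if len(per_pairing) else None
        row = {
            "group_id": gid,
            "region": bundle.groups[gid].region,
            "candidate": gid in candidates,
            "n_pairings": 0 if sub is None else int(len(sub)),
        }
        if sub is not None and len(sub):
            for c in cutoffs:
                col = f"fraction_lt_{c:g}"
                row[col] = float(sub[col].mean())
            means = sub["capped_mean_distance"].dropna()
            row["capped_mean_distance"] = float(means.mean()) if len(means) else np.nan
            row["capped_mean_sd"] = (
                float(means.std(ddof=1)) if len(means) > 1 else np.nan
            )
            row["capped_mean_sem"] = (
                float(means.std(ddof=1) / np.sqrt(len(means)))
                if len(means) > 1
                else np.nan
            )
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    return CandidateReport(
        per_pairing=per_pairing,
        summary=summary,
        segment_flags=flags,
        candidates=candidates,
        config=config,
        departures=departures,
    )


def classify_initial_sites(
    bundle: TrajectoryBundle, reference_groups: dict[str, dict[str, list[str]]]
) -> dict[str, str]:
    """Label each ion inner_AP/outer_AP/CV from its first-frame position.

    ``reference_groups`` maps an AP vestibule label to ``{"inner": [...],
    "outer": [...]}`` anchor group ids; an AP ion is labelled by the smaller
    first-frame distance to the respective anchor centroid, ties resolved to
    inner_AP.  CV ions are labelled CV.
    """
    seg0 = bundle.segments[0]
    labels: dict[str, str] = {}
    for iid in bundle.ion_ids:
        ion = bundle.ions[iid]
        if ion.home_vestibule == "CV":
            labels[iid] = "CV"
            continue
        anchors = reference_groups.get(ion.home_vestibule)
        if not anchors or not anchors.get("inner") or not anchors.get("outer"):
            raise ConfigurationError(
                f"no inner/outer anchors configured for {ion.home_vestibule!r}"
            )
        pos = seg0.ion_xyz[iid][0]
        cents = {}
        for side in ("inner", "outer"):
            missing = [g for g in anchors[side] if g not in bundle.groups]
            if missing:
                raise ConfigurationError(f"anchor groups not in bundle: {missing}")
            cents[side] = np.mean(
                [seg0.group_centers(g)[0] for g in anchors[side]], axis=0
            )
        d_in = np.linalg.norm(pos - cents["inner"])
        d_out = np.linalg.norm(pos - cents["outer"])
        labels[iid] = "inner_AP" if d_in <= d_out else "outer_AP"
    return labels


def distance_timecourse(
    bundle: TrajectoryBundle,
    ion_id: str,
    group_ids,
    interval: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Refined-resolution (time, distance) traces for one ion vs chosen groups."""
    if ion_id not in bundle.ions:
        raise LookupError_(f"unknown ion {ion_id!r}")
    group_ids = list(group_ids)
    for gid in group_ids:
        if gid not in bundle.groups:
            raise LookupError_(f"unknown group {gid!r}")
    interval = interval if interval is not None else ScreeningConfig().refine_interval
    table = build_distance_table(
        bundle, interval, pairs={(ion_id, g) for g in group_ids}
    )
    out = {}
    for gid in group_ids:
        sub = table.frame[table.frame["group_id"] == gid]
        out[gid] = sub[["time_ns", "distance"]].reset_index(drop=True)
    return out
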