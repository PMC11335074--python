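import numpy as np
import pytest

from casite.trajectory import CarboxylGroup, IonTrack, Segment, TrajectoryBundle


def make_bundle(segments_spec, ions_meta=None, groups_meta=None):
    """Hand-build a bundle from explicit arrays.

    ``segments_spec`` is a list of (segment_id, duration, times, ion_xyz,
    group_oxy) tuples; metadata defaults put every ion in AP-1/inner and
    every group in AP of subunit 1.
    """
    segments = []
    ion_ids, group_ids = set(), set()
    for sid, dur, times, ion_xyz, group_oxy in segments_spec:
        segments.append(
            Segment(
                segment_id=sid,
                duration_ns=dur,
                times=np.asarray(times, float),
                ion_xyz={k: np.asarray(v, float) for k, v in ion_xyz.items()},
                group_oxy={k: np.asarray(v, float) for k, v in group_oxy.items()},
            )
        )
        ion_ids |= set(ion_xyz)
        group_ids |= set(group_oxy)
    ions = ions_meta or {
        i: IonTrack(i, "AP-1", "inner_AP") for i in sorted(ion_ids)
    }
    groups = groups_meta or {
        g: CarboxylGroup(g, 100 + k, "ASP", "1", "AP")
        for k, g in enumerate(sorted(group_ids))
    }
    return TrajectoryBundle(segments=segments, ions=ions, groups=groups)


def random_bundle(rng, n_frames=5, n_ions=3, n_groups=5, n_segments=2, span=30.0):
    """Small random bundle for oracle-equivalence tests.

    Frames at 1 ns spacing starting at the segment origin; nominal segment
    duration equals the frame count.
    """
    spec = []
    for s in range(n_segments):
        t0 = s * (n_frames + 5.0)
        times = t0 + np.arange(n_frames, dtype=float)
        ion_xyz = {
            f"ion{i}": rng.uniform(-span, span, (n_frames, 3))
            for i in range(n_ions)
        }
        group_oxy = {
            f"g{g}": rng.uniform(-span, span, (n_frames, 2, 3))
            for g in range(n_groups)
        }
        spec.append((f"seg{s}", float(n_frames), times, ion_xyz, group_oxy))
    return make_bundle(spec)


def brute_force_distances(bundle, interval):
    """Independent frame-by-frame recomputation of the distance table.

    Pure-python loops; samples the frame nearest each t0 + k*interval target
    using the segment's nominal duration for the target count.
    """
    records = []
    for seg in bundle.segments:
        n_targets = int(np.floor(seg.duration_ns / interval + 1e-9))
        targets = [seg.times[0] + interval * (k + 1) for k in range(n_targets)]
        picked = sorted({
            min(range(len(seg.times)), key=lambda j: abs(seg.times[j] - t))
            for t in targets
        })
        for iid in sorted(bundle.ions):
            for gid in sorted(bundle.groups):
                for j in picked:
                    o1, o2 = seg.group_oxy[gid][j]
                    center = [(o1[a] + o2[a]) / 2.0 for a in range(3)]
                    ion = seg.ion_xyz[iid][j]
                    d = sum((ion[a] - center[a]) ** 2 for a in range(3)) ** 0.5
                    records.append((seg.segment_id, seg.times[j], iid, gid, d))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_bundle(rng):
    return random_bundle(rng)
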