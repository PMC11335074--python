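"""Readers and writers for coordinate bundles, reports and configs.

Two interchange formats carry a :class:`~casite.trajectory.TrajectoryBundle`:

* a flat CSV coordinate dialect with columns
  ``segment,time_ns,particle_id,kind{ion|oxygen},group_id,x,y,z`` (ions carry
  an empty ``group_id``; each group has two oxygen rows per frame), and
* a multi-model PDB (one MODEL per frame) in which tagged ions are residues
  named CAL (atom CA2) and carboxylate oxygens are OD1/OD2 (ASP) or OE1/OE2
  (GLU); segment boundaries and frame times ride in REMARK 250 header lines.

Neither format carries region/home-site metadata, so both writers emit and
both readers accept a JSON sidecar with the ion and group identities.
Without a sidecar, groups default to region ``other`` and ions must be
described before vestibule-aware stages run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import ConfigurationError
from .trajectory import CarboxylGroup, IonTrack, Segment, TrajectoryBundle

CSV_COLUMNS = ["segment", "time_ns", "particle_id", "kind", "group_id", "x", "y", "z"]

_OXY_NAMES = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
ION_RES_NAMES = ("CAL", "CA2+", "CA")


# ---------------------------------------------------------------------------
# metadata sidecar


def metadata_dict(bundle: TrajectoryBundle) -> dict:
    return {
        "ions": {
            iid: {"home_vestibule": ion.home_vestibule, "home_site": ion.home_site}
            for iid, ion in sorted(bundle.ions.items())
        },
        "groups": {
            gid: {
                "residue_number": g.residue_number,
                "residue_name": g.residue_name,
                "subunit": g.subunit,
                "region": g.region,
            }
            for gid, g in sorted(bundle.groups.items())
        },
        "metadata": {
            k: v for k, v in bundle.metadata.items() if _json_safe(v)
        },
    }


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_metadata(bundle: TrajectoryBundle, path):
    Path(path).write_text(json.dumps(metadata_dict(bundle), indent=1, sort_keys=True))


def _identities_from_sidecar(meta: dict | None, ion_ids, group_ids):
    ions, groups = {}, {}
    meta = meta or {}
    ion_meta = meta.get("ions", {})
    group_meta = meta.get("groups", {})
    for iid in ion_ids:
        m = ion_meta.get(iid)
        if m:
            ions[iid] = IonTrack(iid, m["home_vestibule"], m["home_site"])
        else:
            ions[iid] = IonTrack(iid, "CV", "CV")  # neutral default
    for gid in group_ids:
        m = group_meta.get(gid)
        if m:
            groups[gid] = CarboxylGroup(
                gid, int(m["residue_number"]), m["residue_name"],
                str(m["subunit"]), m["region"],
            )
        else:
            groups[gid] = CarboxylGroup(gid, 0, "ASP", "?", "other")
    return ions, groups


def _load_sidecar(meta) -> dict | None:
    if meta is None:
        return None
    if isinstance(meta, dict):
        return meta
    return json.loads(Path(meta).read_text())


# ---------------------------------------------------------------------------
# CSV coordinate dialect


def write_bundle_csv(bundle: TrajectoryBundle, path, metadata_path=None):
    rows = []
    for seg in bundle.segments:
        for iid in bundle.ion_ids:
            xyz = seg.ion_xyz[iid]
            for k, t in enumerate(seg.times):
                rows.append(
                    (seg.segment_id, t, iid, "ion", "", *xyz[k])
                )
        for gid in bundle.group_ids:
            oxy = seg.group_oxy[gid]
            for k, t in enumerate(seg.times):
                rows.append((seg.segment_id, t, f"{gid}:O1", "oxygen", gid, *oxy[k, 0]))
                rows.append((seg.segment_id, t, f"{gid}:O2", "oxygen", gid, *oxy[k, 1]))
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.6f")
    if metadata_path is not None:
        write_metadata(bundle, metadata_path)


def read_bundle_csv(path, metadata=None, segment_durations=None) -> TrajectoryBundle:
    """Read the flat CSV dialect back into a bundle.

    ``metadata`` is an optional sidecar (dict or JSON path); segment
    durations default to the observed time span plus one median frame step.
    """
    frame = pd.read_csv(path, dtype={"segment": str, "particle_id": str,
                                     "kind": str, "group_id": str},
                        keep_default_na=False)
    if frame.empty:
        raise ConfigurationError(f"{path}: empty coordinate table")
    bad_kind = set(frame["kind"].unique()) - {"ion", "oxygen"}
    if bad_kind:
        raise ConfigurationError(f"{path}: unknown kind values {sorted(bad_kind)}")

    meta = _load_sidecar(metadata)
    segments = []
    for sid, seg_frame in frame.groupby("segment", sort=True):
        times = np.sort(seg_frame["time_ns"].unique())
        t_index = {t: k for k, t in enumerate(times)}
        n = len(times)
        ion_xyz, group_oxy = {}, {}
        ions_f = seg_frame[seg_frame["kind"] == "ion"]
        for iid, sub in ions_f.groupby("particle_id"):
            arr = np.full((n, 3), np.nan)
            idx = sub["time_ns"].map(t_index).to_numpy()
            arr[idx] = sub[["x", "y", "z"]].to_numpy(float)
            ion_xyz[iid] = arr
        oxy_f = seg_frame[seg_frame["kind"] == "oxygen"]
        for gid, sub in oxy_f.groupby("group_id"):
            if not gid:
                raise ConfigurationError(f"{path}: oxygen row without group_id")
            arr = np.full((n, 2, 3), np.nan)
            o_names = sorted(sub["particle_id"].unique())
            if len(o_names) != 2:
                raise ConfigurationError(
                    f"{path}: group {gid} needs exactly two oxygen particles, "
                    f"found {o_names}"
                )
            for slot, pid in enumerate(o_names):
                s2 = sub[sub["particle_id"] == pid]
                idx = s2["time_ns"].map(t_index).to_numpy()
                arr[idx, slot] = s2[["x", "y", "z"]].to_numpy(float)
            group_oxy[gid] = arr
        if segment_durations and sid in segment_durations:
            duration = float(segment_durations[sid])
        else:
            step = float(np.median(np.diff(times))) if n > 1 else 1.0
            duration = float(times[-1] - times[0]) + step
        segments.append(
            Segment(segment_id=sid, duration_ns=duration, times=times,
                    ion_xyz=ion_xyz, group_oxy=group_oxy)
        )

    ion_ids = sorted({i for s in segments for i in s.ion_xyz})
    group_ids = sorted({g for s in segments for g in s.group_oxy})
    ions, groups = _identities_from_sidecar(meta, ion_ids, group_ids)
    bundle = TrajectoryBundle(
        segments=segments, ions=ions, groups=groups,
        metadata=(meta or {}).get("metadata", {}),
    )
    return bundle.validate()


# ---------------------------------------------------------------------------
# multi-model PDB


def write_bundle_pdb(bundle: TrajectoryBundle, path, metadata_path=None):
    """Write the bundle as a multi-model PDB (one model per frame).

    Ions become CAL residues (atom CA2); each group becomes one ASP/GLU
    residue carrying only its two side-chain oxygens.  Frame times and
    segment membership go into REMARK 250 header lines.
    """
    ion_ids = bundle.ion_ids
    group_ids = bundle.group_ids
    n_atoms = len(ion_ids) + 2 * len(group_ids)

    frames = []
    remarks = []
    model = 0
    for seg in bundle.segments:
        for k, t in enumerate(seg.times):
            coords = np.empty((n_atoms, 3))
            a = 0
            for iid in ion_ids:
                coords[a] = seg.ion_xyz[iid][k]
                a += 1
            for gid in group_ids:
                coords[a] = seg.group_oxy[gid][k, 0]
                coords[a + 1] = seg.group_oxy[gid][k, 1]
                a += 2
            frames.append(coords)
            model += 1
            remarks.append(
                f"REMARK 250 CASITE MODEL {model} SEGMENT {seg.segment_id} "
                f"TIME_NS {t:.6f} DURATION_NS {seg.duration_ns:.6f}"
            )

    template = struc.AtomArray(n_atoms)
    res_id = np.empty(n_atoms, dtype=int)
    res_name = np.empty(n_atoms, dtype="U5")
    atom_name = np.empty(n_atoms, dtype="U6")
    chain = np.empty(n_atoms, dtype="U4")
    hetero = np.zeros(n_atoms, dtype=bool)
    element = np.empty(n_atoms, dtype="U2")
    a = 0
    rid = 1
    for iid in ion_ids:
        res_id[a], res_name[a], atom_name[a] = rid, "CAL", "CA2"
        chain[a], hetero[a], element[a] = "I", True, "CA"
        a += 1
        rid += 1
    for gid in group_ids:
        g = bundle.groups[gid]
        names = _OXY_NAMES[g.residue_name]
        for slot in range(2):
            res_id[a] = g.residue_number if g.residue_number > 0 else rid
            res_name[a] = g.residue_name
            atom_name[a] = names[slot]
            chain[a] = (g.subunit or "A")[:4]
            element[a] = "O"
            a += 1
        rid += 1
    template.res_id = res_id
    template.res_name = res_name
    template.atom_name = atom_name
    template.chain_id = chain
    template.hetero = hetero
    template.element = element

    stack = struc.from_template(template, np.array(frames))
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.lines = remarks + f.lines
    f.write(str(path))
    if metadata_path is not None:
        write_metadata(bundle, metadata_path)


def read_bundle_pdb(path, metadata=None) -> TrajectoryBundle:
    """Read a multi-model PDB written by :func:`write_bundle_pdb`.

    Requires the REMARK 250 CASITE header (segment/time per model); ions are
    selected by residue name (CAL/CA2+/CA), carboxylate oxygens by OD1/OD2
    (ASP) and OE1/OE2 (GLU).
    """
    f = pdb.PDBFile.read(str(path))
    model_info = {}
    for line in f.lines:
        if line.startswith("REMARK 250 CASITE MODEL"):
            parts = line.split()
            model_info[int(parts[4])] = (
                parts[6], float(parts[8]), float(parts[10])
            )  # segment_id, time, duration
    if not model_info:
        raise ConfigurationError(f"{path}: missing CASITE REMARK header")
    stack = pdb.get_structure(f)  # AtomArrayStack over all models
    if stack.stack_depth() != len(model_info):
        raise ConfigurationError(
            f"{path}: {stack.stack_depth()} models but {len(model_info)} "
            "header entries"
        )

    arr0 = stack[0]
    is_ion = np.isin(arr0.res_name, ION_RES_NAMES)
    ion_atom_idx = np.flatnonzero(is_ion)
    meta = _load_sidecar(metadata)
    if meta and len(meta.get("ions", {})) == len(ion_atom_idx):
        # writer assigns ion residues in sorted ion-id order
        ion_ids = sorted(meta["ions"])
    else:
        ion_ids = [f"ion{arr0.res_id[a]:03d}" for a in ion_atom_idx]

    group_atoms = {}
    for a in np.flatnonzero(~is_ion):
        rn = arr0.res_name[a]
        if rn not in _OXY_NAMES or arr0.atom_name[a] not in _OXY_NAMES[rn]:
            continue
        key = (arr0.chain_id[a], int(arr0.res_id[a]), rn)
        group_atoms.setdefault(key, []).append(a)
    for key, atoms in group_atoms.items():
        if len(atoms) != 2:
            raise ConfigurationError(
                f"{path}: residue {key} has {len(atoms)} carboxylate oxygens"
            )

    # assemble per segment
    seg_models: dict[str, list[int]] = {}
    for m in sorted(model_info):
        seg_models.setdefault(model_info[m][0], []).append(m)

    group_label = {}
    for (ch, rid, rn) in sorted(group_atoms):
        short = "E" if rn == "GLU" else "D"
        group_label[(ch, rid, rn)] = f"{short}{rid}"

    segments = []
    for sid in sorted(seg_models):
        models = seg_models[sid]
        times = np.array([model_info[m][1] for m in models])
        order = np.argsort(times)
        models = [models[i] for i in order]
        times = times[order]
        coord = stack.coord[[m - 1 for m in models]]
        ion_xyz = {
            ion_ids[j]: coord[:, ion_atom_idx[j], :] for j in range(len(ion_ids))
        }
        group_oxy = {}
        for key, atoms in group_atoms.items():
            names = _OXY_NAMES[key[2]]
            ordered = sorted(atoms, key=lambda a: names.index(arr0.atom_name[a]))
            group_oxy[group_label[key]] = np.stack(
                [coord[:, ordered[0], :], coord[:, ordered[1], :]], axis=1
            )
        segments.append(
            Segment(segment_id=sid, duration_ns=model_info[models[0]][2],
                    times=times, ion_xyz=ion_xyz, group_oxy=group_oxy)
        )

    ions, groups = _identities_from_sidecar(meta, sorted(ion_ids),
                                            sorted(group_label.values()))
    # fill residue identity from the PDB itself when no sidecar entry exists
    if meta is None or not meta.get("groups"):
        groups = {}
        for key, label in group_label.items():
            groups[label] = CarboxylGroup(label, key[1], key[2], str(key[0]), "other")
    bundle = TrajectoryBundle(
        segments=segments, ions=ions, groups=groups,
        metadata=(meta or {}).get("metadata", {}),
    )
    return bundle.validate()


# ---------------------------------------------------------------------------
# report/table writers


def write_distance_table(table, path):
    table.frame.to_csv(path, index=False, float_format="%.6f")


def write_candidate_report(report, directory, stem="candidates"):
    """Write summary/per-pairing/segment-flag CSVs plus a JSON config echo."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": directory / f"{stem}_summary.csv",
        "per_pairing": directory / f"{stem}_per_pairing.csv",
        "segment_flags": directory / f"{stem}_segment_flags.csv",
        "json": directory / f"{stem}.json",
    }
    report.summary.to_csv(paths["summary"], index=False)
    report.per_pairing.to_csv(paths["per_pairing"], index=False)
    report.segment_flags.to_csv(paths["segment_flags"])
    payload = {
        "config": report.config.to_dict(),
        "candidates": report.candidate_ids(),
        "departures": [
            {"ion_id": e.ion_id, "vestibule": e.vestibule,
             "departure_time_ns": e.departure_time}
            for e in report.departures
        ],
        "note": "occupancy criterion evaluated per segment; overall flag is "
                "a pass in >= 1 segment",
    }
    paths["json"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def write_timecourses(courses: dict, path):
    frames = []
    for gid, df in sorted(courses.items()):
        d = df.copy()
        d.insert(0, "group_id", gid)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")
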