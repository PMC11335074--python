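"""Orchestration: end-to-end runs, manifests, and the reproduction harness."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contact import candidate_report
from .ephys import compare_groups, fit_peak_table, paired_shift, tau_ratio
from .errors import EmptyInputError
from .synth_traj import preset_bundle
from .trajectory import ScreeningConfig, TrajectoryBundle
from . import reproduce as _reproduce
from . import traj_io


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    command: str
    config: dict
    seeds: dict
    version: str = __version__
    row_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def validate_outputs(self):
        for name, p in self.outputs.items():
            path = Path(p)
            if not path.exists() or path.stat().st_size == 0:
                raise EmptyInputError(f"manifest output {name} missing/empty: {p}")
        return self

    def write(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True,
                                         default=str))


def run_traj_pipeline(
    source: TrajectoryBundle | str,
    config: ScreeningConfig | None = None,
    seed: int = 0,
    outdir=None,
):
    """Execute build -> screen -> mask -> refine -> metrics on a bundle or preset."""
    config = config or ScreeningConfig()
    if isinstance(source, str):
        bundle = preset_bundle(source, seed=seed)
        source_name = f"preset:{source}"
    else:
        bundle = source
        source_name = "bundle"
    report = candidate_report(bundle, config)
    manifest = RunManifest(
        command="run_traj_pipeline",
        config={"screening": config.to_dict(), "source": source_name},
        seeds={"traj": seed},
        row_counts={
            "groups": len(bundle.groups),
            "ions": len(bundle.ions),
            "per_pairing_rows": int(len(report.per_pairing)),
            "candidates": len(report.candidates),
        },
    )
    if outdir is not None:
        paths = traj_io.write_candidate_report(report, outdir)
        manifest.outputs = {k: str(v) for k, v in paths.items()}
        manifest.write(Path(outdir) / "manifest.json")
        manifest.validate_outputs()
    return report, manifest


def run_ephys_pipeline(
    peaks: pd.DataFrame,
    pair_on: str = "oocyte_id",
    outdir=None,
    seed: int | None = None,
):
    """Per-oocyte fits, paired shifts / tau ratios per protocol, and stats.

    The high-divalent arm of each protocol is the larger ``conc_mM``; shifts
    are low-arm minus high-arm midpoints, tau ratios follow the protocol
    orientation (recovery low/high, onset high/low).
    """
    fits = fit_peak_table(peaks)
    summaries = []
    for protocol, sub in fits.groupby("protocol", sort=True):
        concs = sorted(sub["conc_mM"].unique())
        if len(concs) != 2:
            continue
        lo_c, hi_c = concs[0], concs[-1]
        if protocol in ("activation", "ssd"):
            col = "midpoint"
        elif protocol in ("recovery", "onset"):
            col = "tau"
        else:
            continue
        lo = dict(zip(sub.loc[sub["conc_mM"] == lo_c, pair_on],
                      sub.loc[sub["conc_mM"] == lo_c, col]))
        hi = dict(zip(sub.loc[sub["conc_mM"] == hi_c, pair_on],
                      sub.loc[sub["conc_mM"] == hi_c, col]))
        entry = {"protocol": protocol, "conc_low_mM": lo_c, "conc_high_mM": hi_c}
        if protocol in ("activation", "ssd"):
            shift = paired_shift(lo, hi)
            t = compare_groups(
                {"low": [lo[k] for k in sorted(shift.deltas)],
                 "high": [hi[k] for k in sorted(shift.deltas)]},
                "paired-t",
            )[0]
            entry.update(shift_mean=shift.mean, shift_sd=shift.sd, n=shift.n,
                         paired_t=t.statistic, paired_p=t.p_value)
        else:
            ratio = tau_ratio(lo, hi, protocol)
            entry.update(ratio_mean=ratio.mean, ratio_sd=ratio.sd, n=ratio.n)
        summaries.append(entry)
    summary = pd.DataFrame(summaries)
    manifest = RunManifest(
        command="run_ephys_pipeline",
        config={"pair_on": pair_on},
        seeds={} if seed is None else {"ephys": seed},
        row_counts={"peaks": int(len(peaks)), "fits": int(len(fits)),
                    "summaries": int(len(summary))},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fits_path = outdir / "fits.csv"
        summary_path = outdir / "shifts.csv"
        fits.to_csv(fits_path, index=False)
        summary.to_csv(summary_path, index=False)
        manifest.outputs = {"fits": str(fits_path), "shifts": str(summary_path)}
        manifest.write(outdir / "manifest.json")
        manifest.validate_outputs()
    return {"fits": fits, "summary": summary, "manifest": manifest}


def reproduce(target_id: str, seed: int = 1, replicates: int = 1) -> dict:
    """Recompute one acceptance quantity from scratch; see casite.reproduce."""
    return _reproduce.run_target(target_id, seed=seed, replicates=replicates)


def reproduce_all(seed: int = 1, replicates: int = 1) -> pd.DataFrame:
    rows = [
        _reproduce.run_target(tid, seed=seed, replicates=replicates)
        for tid in _reproduce.TARGET_IDS
    ]
    return pd.DataFrame(rows)
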