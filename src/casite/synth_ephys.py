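"""Synthetic per-oocyte peak-current tables and a three-state gating simulator.

Presets encode, as generator ground truth, the WT/mutant/Mg2+/ASIC1b
population parameters of ASIC1a divalent-cation modulation: Hill midpoints
of activation and steady-state desensitization (SSD) in two divalent arms
with between-oocyte spread, the inhibition curve (pore block), the
pH50-vs-[Ca2+] relation, and recovery/onset kinetics.

The paired design mirrors the experiments: both divalent arms are drawn for
the same oocyte, with the per-oocyte arm difference drawn around the preset
shift.  Peak currents are inward (negative nA), carry multiplicative
measurement noise, and per-oocyte maximal amplitudes in the microampere
range.  Hill coefficients are generator assumptions (activation 1.5,
SSD 3.0); kinetic variability is lognormal with CV 0.4.

The optional gating simulator integrates a closed/open/desensitized (C/O/D)
scheme whose proton-binding midpoints are shifted acidic by Ca2+ through
a competition term pK_app = pK0 - log10(1 + [Ca]/K_Ca).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ephys import PEAK_COLUMNS, hill_curve, inhibition_curve
from .errors import DomainError, LookupError_, ScheduleError

# protocol stimulus grids (activation pH 7.4 -> 5.0; SSD conditioning
# 7.8 -> 6.6; inhibition in mM at pH 5.5; kinetics ladders in s)
ACTIVATION_PH = (7.4, 7.1, 6.9, 6.7, 6.5, 6.3, 6.0, 5.0)
SSD_PH = (7.8, 7.6, 7.45, 7.3, 7.15, 7.0, 6.8, 6.6)
INHIBITION_CONC = (0.1, 1.0, 3.0, 10.0, 30.0)
RECOVERY_INTERVALS = (0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 60.0, 180.0)
ONSET_DURATIONS = (1.0, 2.5, 5.0, 10.0, 20.0, 50.0, 100.0, 300.0)

CONC_100NM = 1e-4  # 100 nM free divalent, stored in mM


@dataclass(frozen=True)
class PhDependenceSpec:
    """Two-arm pH-dependence ground truth (activation or SSD)."""

    divalent: str
    conc_high: float  # mM
    conc_low: float  # mM
    mid_high: float  # midpoint in the high-divalent arm
    sd_high: float  # between-oocyte s.d. of the high-arm midpoint
    delta_mean: float  # per-oocyte shift, low arm minus high arm
    delta_sd: float
    n_hill: float


@dataclass(frozen=True)
class InhibitionSpec:
    ic50: float = 9.6  # mM; analytic block at 10 mM = 10/19.6 = 51 %
    n_hill: float = 1.0
    non_in: float = 0.0
    ph: float = 5.5


@dataclass(frozen=True)
class Ph50VsCaSpec:
    """pH50 as a function of [Ca2+]: inhibition-curve-shaped relation."""

    floor: float = 6.01
    ceiling: float = 6.78
    ic50: float = 3.5  # mM
    n_hill: float = 1.0

    def curve(self, conc_mM):
        return inhibition_curve(conc_mM, self.ceiling, self.floor, self.ic50,
                                self.n_hill)


@dataclass(frozen=True)
class KineticsSpec:
    divalent: str = "Ca"
    conc_high: float = 2.0
    conc_low: float = 0.1
    tau_recovery_high: float = 4.0  # s, 2 mM arm
    tau_recovery_low: float = 22.8  # s, 0.1 mM arm
    tau_onset_high: float = 63.6  # s, 2 mM arm
    tau_onset_low: float = 3.9  # s, 0.1 mM arm
    non_des: float = 0.05
    cv: float = 0.4  # lognormal CV of per-oocyte taus


@dataclass(frozen=True)
class EphysPreset:
    name: str
    construct: str
    activation: PhDependenceSpec | None = None
    ssd: PhDependenceSpec | None = None
    inhibition: InhibitionSpec | None = None
    ph50_vs_ca: Ph50VsCaSpec | None = None
    kinetics: KineticsSpec | None = None
    noise_sigma: float = 0.03  # multiplicative measurement noise
    amp_mean_nA: float = 5000.0  # per-oocyte maximal current magnitude
    amp_cv: float = 0.5


def wt_and_variant_presets() -> dict[str, EphysPreset]:
    """Registry of study presets keyed by name."""
    wt_act = PhDependenceSpec("Ca", 2.0, CONC_100NM, 6.50, 0.12, 0.25, 0.09, 1.5)
    wt_ssd = PhDependenceSpec("Ca", 2.0, 0.1, 7.14, 0.04, 0.28, 0.03, 3.0)
    kin = KineticsSpec()
    registry = {
        "wt_ca": EphysPreset(
            "wt_ca", "WT", activation=wt_act, ssd=wt_ssd,
            inhibition=InhibitionSpec(), ph50_vs_ca=Ph50VsCaSpec(), kinetics=kin,
        ),
        "wt_mg": EphysPreset(
            "wt_mg", "WT",
            activation=PhDependenceSpec("Mg", 2.0, CONC_100NM, 6.59, 0.11,
                                        0.13, 0.07, 1.5),
            ssd=PhDependenceSpec("Mg", 10.0, 0.1, 6.97, 0.07, 0.39, 0.03, 3.0),
        ),
        "wt_kinetics": EphysPreset("wt_kinetics", "WT", kinetics=kin),
        "asic1b": EphysPreset(
            "asic1b", "ASIC1b",
            activation=PhDependenceSpec("Ca", 2.0, CONC_100NM, 6.13, 0.06,
                                        0.20, 0.07, 1.5),
            ssd=PhDependenceSpec("Ca", 2.0, 0.1, 7.13, 0.07, 0.24, 0.06, 3.0),
        ),
        # mutant shift presets: printed per-oocyte shifts, high-arm midpoints
        # are plausible acidic-shifted placements (not printed)
        "ap_act": EphysPreset(
            "ap_act", "AP-Act",
            activation=PhDependenceSpec("Ca", 2.0, CONC_100NM, 6.30, 0.12,
                                        0.10, 0.09, 1.5),
        ),
        "d409a": EphysPreset(
            "d409a", "D409A",
            activation=PhDependenceSpec("Ca", 2.0, CONC_100NM, 6.50, 0.12,
                                        0.41, 0.09, 1.5),
        ),
        "ap_ssd": EphysPreset(
            "ap_ssd", "AP-SSD",
            ssd=PhDependenceSpec("Ca", 2.0, 0.1, 7.00, 0.05, 0.05, 0.11, 3.0),
        ),
        "cv_ssd": EphysPreset(
            "cv_ssd", "CV-SSD",
            ssd=PhDependenceSpec("Ca", 2.0, 0.1, 7.05, 0.05, 0.13, 0.03, 3.0),
        ),
        "asic1b_cv_ssd": EphysPreset(
            "asic1b_cv_ssd", "1b-CV-SSD",
            ssd=PhDependenceSpec("Ca", 2.0, 0.1, 7.10, 0.07, -0.14, 0.30, 3.0),
        ),
        # null preset: identical arms, zero shift
        "nonmodulated": EphysPreset(
            "nonmodulated", "null",
            activation=PhDependenceSpec("Ca", 2.0, CONC_100NM, 6.50, 0.12,
                                        0.0, 0.0, 1.5),
            ssd=PhDependenceSpec("Ca", 2.0, 0.1, 7.14, 0.04, 0.0, 0.0, 3.0),
        ),
    }
    return registry


def get_preset(name: str) -> EphysPreset:
    registry = wt_and_variant_presets()
    if name not in registry:
        raise LookupError_(
            f"unknown ephys preset {name!r}; known: {sorted(registry)}"
        )
    return registry[name]


def _lognormal_factor(rng, cv, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def _noise(rng, sigma, size):
    return 1.0 + rng.normal(0.0, sigma, size) if sigma > 0 else np.ones(size)


def simulate_peak_series(
    protocol: str,
    preset: EphysPreset | str,
    n_oocytes: int,
    seed: int,
) -> pd.DataFrame:
    """Per-oocyte peak-current table for one protocol, both divalent arms.

    Activation/SSD: the oocyte's high-arm midpoint is drawn around the preset
    mean, the low-arm midpoint adds an independent per-oocyte shift around
    the preset delta, and the Hill curve is evaluated on the protocol grid.
    Inhibition: the inhibition curve on the concentration grid at pH 5.5.
    Recovery/onset: per-oocyte lognormal taus, with a control row (empty
    stimulus) carrying the reference amplitude.  Every response is scaled by
    the oocyte amplitude and multiplied by (1 + N(0, sigma)) noise.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_oocytes < 1:
        raise DomainError("n_oocytes must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def emit(oo, divalent, conc, stimulus, peak):
        rows.append(
            {
                "oocyte_id": oo, "construct": preset.construct,
                "protocol": protocol, "divalent": divalent, "conc_mM": conc,
                "stimulus": stimulus, "peak_nA": peak,
            }
        )

    for i in range(n_oocytes):
        oo = f"oo{i:03d}"
        amp = preset.amp_mean_nA * _lognormal_factor(rng, preset.amp_cv)

        if protocol in ("activation", "ssd"):
            spec = preset.activation if protocol == "activation" else preset.ssd
            if spec is None:
                raise DomainError(
                    f"preset {preset.name!r} has no {protocol} parameters"
                )
            grid = np.array(ACTIVATION_PH if protocol == "activation" else SSD_PH)
            mid_high = rng.normal(spec.mid_high, spec.sd_high)
            mid_low = mid_high + rng.normal(spec.delta_mean, spec.delta_sd)
            for conc, mid in ((spec.conc_high, mid_high), (spec.conc_low, mid_low)):
                resp = hill_curve(grid, 1.0, mid, spec.n_hill, kind=protocol)
                resp = resp * _noise(rng, preset.noise_sigma, grid.size)
                for ph, r in zip(grid, resp):
                    emit(oo, spec.divalent, conc, float(ph), -float(r) * amp)

        elif protocol == "inhibition":
            spec = preset.inhibition
            if spec is None:
                raise DomainError(f"preset {preset.name!r} has no inhibition curve")
            grid = np.array(INHIBITION_CONC)
            resp = inhibition_curve(grid, 1.0, spec.non_in, spec.ic50, spec.n_hill)
            resp = resp * _noise(rng, preset.noise_sigma, grid.size)
            for c, r in zip(grid, resp):
                emit(oo, "Ca", float(c), float(c), -float(r) * amp)

        elif protocol in ("recovery", "onset"):
            kin = preset.kinetics
            if kin is None:
                raise DomainError(f"preset {preset.name!r} has no kinetics")
            grid = np.array(
                RECOVERY_INTERVALS if protocol == "recovery" else ONSET_DURATIONS
            )
            taus = {
                kin.conc_high: (
                    kin.tau_recovery_high if protocol == "recovery"
                    else kin.tau_onset_high
                ),
                kin.conc_low: (
                    kin.tau_recovery_low if protocol == "recovery"
                    else kin.tau_onset_low
                ),
            }
            for conc, tau_mean in taus.items():
                tau = tau_mean * _lognormal_factor(rng, kin.cv)
                if protocol == "recovery":
                    resp = 1.0 - np.exp(-grid / tau)
                else:
                    resp = kin.non_des + (1.0 - kin.non_des) * np.exp(-grid / tau)
                resp = resp * _noise(rng, preset.noise_sigma, grid.size)
                # control response (reference amplitude)
                ctrl = amp * float(_noise(rng, preset.noise_sigma, 1)[0])
                emit(oo, kin.divalent, float(conc), float("nan"), -ctrl)
                for t, r in zip(grid, resp):
                    emit(oo, kin.divalent, float(conc), float(t), -float(r) * amp)
        else:
            raise DomainError(f"unknown protocol {protocol!r}")

    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def simulate_ph50_vs_ca(
    preset: EphysPreset | str,
    n_oocytes: int = 20,
    seed: int = 3,
    concentrations=(CONC_100NM, 0.3, 1.0, 3.0, 10.0, 30.0),
    oocyte_sd: float = 0.12,
) -> pd.DataFrame:
    """Per-concentration mean pH50 values drawn on the preset pH50-vs-Ca curve.

    Emulates fitting activation midpoints at each stimulation [Ca2+]: each of
    `n_oocytes` oocytes contributes a midpoint with between-oocyte spread;
    the per-concentration mean is returned (columns: stimulus, response, n).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    spec = preset.ph50_vs_ca
    if spec is None:
        raise DomainError(f"preset {preset.name!r} has no pH50-vs-Ca curve")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        truth = float(spec.curve(c))
        vals = truth + rng.normal(0.0, oocyte_sd, n_oocytes)
        rows.append({"stimulus": float(c), "response": float(vals.mean()),
                     "n": n_oocytes})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# three-state (C/O/D) gating simulator


@dataclass(frozen=True)
class GatingModel:
    """Closed/open/desensitized scheme with proton-Ca2+ competition.

    Transition rates (s^-1): k_CO = k1*theta_a, k_OC = k2*(1-theta_a),
    k_OD = k3, k_CD = k4*theta_d, k_DC = k5*(1-theta_d), with proton
    occupancies theta_x = 1/(1 + 10^(n_x*(pH - pK_x,app))) and apparent
    midpoints pK_app = pK0 - log10(1 + [Ca]/K_Ca).  Defaults put the 2 mM Ca
    apparent activation/desensitization midpoints of the peak-response at the
    WT presets and keep the resting open probability below 1e-3 at pH 7.8.
    """

    k1: float = 20.0
    k2: float = 400.0
    k3: float = 0.5
    k4: float = 0.2
    k5: float = 0.1
    pk_act: float = 6.696  # intrinsic (zero-Ca) proton midpoint, activation
    pk_des: float = 7.336  # intrinsic midpoint, desensitization
    n_act: float = 1.5
    n_des: float = 3.0
    k_ca: float = 3.5  # mM, Ca2+ competition constant

    def theta(self, ph: float, ca_mM: float, which: str) -> float:
        pk0, n = (self.pk_act, self.n_act) if which == "act" else (
            self.pk_des, self.n_des)
        pk_app = pk0 - np.log10(1.0 + ca_mM / self.k_ca)
        return float(1.0 / (1.0 + 10.0 ** (n * (ph - pk_app))))

    def rates(self, ph: float, ca_mM: float) -> dict[str, float]:
        ta = self.theta(ph, ca_mM, "act")
        td = self.theta(ph, ca_mM, "des")
        return {
            "k_CO": self.k1 * ta, "k_OC": self.k2 * (1.0 - ta),
            "k_OD": self.k3, "k_CD": self.k4 * td, "k_DC": self.k5 * (1.0 - td),
        }


def simulate_three_state_trace(
    model: GatingModel,
    schedule,
    dt_out: float = 0.02,
    y0=(1.0, 0.0, 0.0),
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Integrate the C/O/D occupancies through a perfusion schedule.

    `schedule` is a sequence of (pH, ca_mM, duration_s) steps.  Returns a
    trace with columns time_s, pH, conc_mM, step, C, O, D, current_norm
    (current proportional to -O).  Conservation C+O+D = 1 is enforced by
    integrating C and O and recovering D.
    """
    y = np.asarray(y0, float)
    if y.shape != (3,) or abs(y.sum() - 1.0) > 1e-9 or np.any(y < 0):
        raise DomainError("y0 must be occupancies summing to 1")
    frames = []
    t_global = 0.0
    for step_idx, (ph, ca, duration) in enumerate(schedule):
        if duration < 0:
            raise ScheduleError(f"negative duration in step {step_idx}")
        if duration == 0:
            continue
        r = GatingModel.rates(model, float(ph), float(ca))

        def rhs(_t, co):
            c, o = co
            d = 1.0 - c - o
            dc = -(r["k_CO"] + r["k_CD"]) * c + r["k_OC"] * o + r["k_DC"] * d
            do = r["k_CO"] * c - (r["k_OC"] + r["k_OD"]) * o
            return [dc, do]

        t_eval = np.arange(0.0, duration + dt_out / 2, dt_out)
        sol = solve_ivp(
            rhs, (0.0, float(duration)), y[:2], t_eval=t_eval,
            method="LSODA", rtol=rtol, atol=1e-10,
        )
        c, o = sol.y
        d = 1.0 - c - o
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t_global + sol.t, "pH": float(ph),
                    "conc_mM": float(ca), "step": step_idx,
                    "C": c, "O": o, "D": d, "current_norm": -o,
                }
            )
        )
        y = np.array([c[-1], o[-1], d[-1]])
        t_global += float(duration)
    if not frames:
        raise ScheduleError("schedule has no positive-duration steps")
    return pd.concat(frames, ignore_index=True)


def peak_per_step(trace: pd.DataFrame) -> pd.DataFrame:
    """Maximal |O| within each schedule step (peak response extraction)."""
    peaks = trace.groupby("step").agg(
        pH=("pH", "first"), conc_mM=("conc_mM", "first"), peak_O=("O", "max")
    )
    return peaks.reset_index()


def gating_peak_response(
    model: GatingModel,
    ph_grid,
    ca_mM: float,
    stim_duration: float = 10.0,
) -> pd.DataFrame:
    """Peak open probability for stimulations from rest on a pH grid.

    Each stimulation starts from the fully closed state (fresh conditioning),
    matching the once-per-minute stimulation protocol with full recovery.
    """
    rows = []
    for ph in ph_grid:
        trace = simulate_three_state_trace(
            model, [(float(ph), ca_mM, stim_duration)]
        )
        rows.append({"stimulus": float(ph), "response": float(trace["O"].max())})
    return pd.DataFrame(rows)
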