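"""Synthetic peak-amplitude trace generator.

The generator commits to a minimal mechanistic reading of the drug access
pathway: bound drug is distributed between two kinetically distinct pools,

* a *hydrophilic trap* (putatively the aqueous inner vestibule) whose escape
  rate scales with the neutral fraction of the compound (deprotonation-limited
  egress), and
* a *lipophilic trap* (membrane phase / channel-membrane interface) whose
  escape rate scales with the charged fraction (protonation-limited egress).

During drug application, influx into both pools scales with

    conc * k_entry * fn * (1 - seq * fn),

where ``fn`` is the Henderson-Hasselbalch neutral fraction at the bath pH.
The optional sequestration coefficient ``seq`` (default 0) attenuates access
for very lipophilic, highly aromatic compounds at strongly alkalic pH, where
partitioning into the membrane phase competes with reaching the pore: this is
what lets a compound be *most* potent at neutral pH.  With ``seq = 0`` the
influx is strictly proportional to the neutral fraction.

Each pool follows db/dt = u*(1-b) - e*b with piecewise-constant coefficients
over the perfusion schedule, so the trajectory is integrated exactly as a
piecewise exponential.  The total blocked fraction combines the pools
independently, block = 1 - (1-b_hydro)*(1-b_lipo), so either trap alone can
saturate the block.  Extracellular acidification additionally scales every
amplitude by an instantaneous, memoryless proton-block factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .descriptors import fraction_neutral
from .errors import ConfigError
from .io import AmplitudeTrace
from .protocol import Protocol

REFERENCE_PH = 7.3


@dataclass(frozen=True)
class SimDrugConfig:
    """Kinetic parameters of one simulated compound."""

    drug_code: str
    conc: float  # µM
    pKa: float
    k_entry: float  # 1/(s*µM) scale of membrane-mediated access
    k_exit_lipo: float  # 1/s escape scale, lipophilic trap
    k_exit_hydro: float  # 1/s escape scale, hydrophilic trap
    lipo_weight: float  # fraction of influx routed to the lipophilic trap
    kd_site: float  # µM equilibrium constant at pH 7.3
    seq: float = 0.0  # membrane sequestration coefficient, [0, 1)
    charged_access: float = 0.0  # relative access of the charged form, [0, 1)
    class_label: str | None = None

    def __post_init__(self):
        if min(self.k_entry, self.k_exit_lipo, self.k_exit_hydro, self.kd_site) <= 0:
            raise ConfigError(f"{self.drug_code}: all rates must be > 0")
        if self.conc < 0:
            raise ConfigError(f"{self.drug_code}: concentration must be >= 0")
        if not 0.0 <= self.lipo_weight <= 1.0:
            raise ConfigError(f"{self.drug_code}: lipo_weight must lie in [0, 1]")
        if not 0.0 <= self.seq < 1.0:
            raise ConfigError(f"{self.drug_code}: seq must lie in [0, 1)")
        if not 0.0 <= self.charged_access < 1.0:
            raise ConfigError(f"{self.drug_code}: charged_access must lie in [0, 1)")
        if not 0.0 <= self.pKa <= 14.0:
            raise ConfigError(f"{self.drug_code}: pKa outside [0, 14]")


@dataclass(frozen=True)
class SimCohortConfig:
    """Replicate-cell ensemble: multiplicative per-train noise and proton block."""

    n_cells: int = 5
    noise_cv: float = 0.03
    proton_block_factor: float = 0.724
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ConfigError("n_cells must be >= 2")
        if not 0.0 < self.proton_block_factor <= 1.0:
            raise ConfigError("proton_block_factor must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")


def _access(drug: SimDrugConfig, fn: float) -> float:
    """pH-gated access factor: neutral-form entry (optionally attenuated by
    membrane sequestration) plus residual charged-form entry through the
    hydrophilic pathway."""
    return fn * (1.0 - drug.seq * fn) + drug.charged_access * (1.0 - fn)


def _pool_rates(drug: SimDrugConfig, pH: float, drug_on: bool):
    """(u, e) per pool at a given bath condition."""
    fn = fraction_neutral(pH, drug.pKa)
    influx = drug.conc * drug.k_entry * _access(drug, fn) if drug_on else 0.0
    u_h = (1.0 - drug.lipo_weight) * influx
    u_l = drug.lipo_weight * influx
    # hydrophilic-trap egress is deprotonation-limited, but the charged form
    # can also leave the vestibule back through the gate it entered by
    e_h = drug.k_exit_hydro * (fn + drug.charged_access * (1.0 - fn))
    e_l = drug.k_exit_lipo * (1.0 - fn)
    return (u_h, e_h), (u_l, e_l)


def equilibrium_block(drug: SimDrugConfig, pH: float) -> float:
    """Steady-state blocked fraction during prolonged drug application at ``pH``."""
    unblocked = 1.0
    for u, e in _pool_rates(drug, pH, drug_on=True):
        r = u + e
        b = u / r if r > 0 else 0.0
        unblocked *= 1.0 - b
    return 1.0 - unblocked


def apparent_kd(drug: SimDrugConfig, pH: float) -> float:
    """Equilibrium apparent affinity conc*(1-B)/B at ``pH`` (µM)."""
    b = equilibrium_block(drug, pH)
    return math.inf if b == 0 else drug.conc * (1.0 - b) / b


def onset_time_constant(drug: SimDrugConfig, pH: float) -> float:
    """Dominant (slowest) relaxation time of the occupied pools at ``pH``, s."""
    rates = [u + e for (u, e) in _pool_rates(drug, pH, drug_on=True)
             if u > 0]
    if not rates:
        return math.inf
    return 1.0 / min(rates)


def calibrate_k_entry(
    pKa: float,
    conc: float,
    kd_site: float,
    lipo_weight: float,
    k_exit_hydro: float,
    k_exit_lipo: float,
    seq: float = 0.0,
    charged_access: float = 0.0,
) -> float:
    """Entry-rate scale making equilibrium block at pH 7.3 equal conc/(conc+kd_site).

    Solves 1 - B = prod_p e_p/(u_p + e_p) for the common influx scale, which is
    linear (one pool) or quadratic (two pools) in the unknown.
    """
    fn = fraction_neutral(REFERENCE_PH, pKa)
    access = fn * (1.0 - seq * fn) + charged_access * (1.0 - fn)
    target = conc / (conc + kd_site)
    e_h = k_exit_hydro * (fn + charged_access * (1.0 - fn))
    e_l = k_exit_lipo * (1.0 - fn)
    w_h, w_l = 1.0 - lipo_weight, lipo_weight
    # x = conc * k_entry * access: total influx before pool routing
    if w_l == 0.0 or w_h == 0.0:
        w, e = (w_h, e_h) if w_l == 0.0 else (w_l, e_l)
        x = e * target / (1.0 - target) / w
    else:
        a = (1.0 - target) * w_h * w_l
        b = (1.0 - target) * (w_h * e_l + w_l * e_h)
        c = -target * e_h * e_l
        x = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    k_entry = x / (conc * access)
    if k_entry <= 0 or not math.isfinite(k_entry):
        raise ConfigError("calibration failed: non-positive or non-finite k_entry")
    return k_entry


def _segments(protocol: Protocol) -> list[tuple[float, float, float, bool]]:
    """Contiguous constant-condition stretches: (t_start, t_end, pH, drug_on).

    The bath condition feeding a train applies over the inter-train interval
    that precedes it, so a phase's condition starts one interval before its
    first train.
    """
    sched = protocol.schedule()
    iti = protocol.inter_train_interval
    segs = []
    start = -iti
    cur = None
    last_t = None
    for t, ph, on in zip(sched["time_s"], sched["pH"], sched["drug_on"]):
        cond = (float(ph), bool(on))
        if cur is None:
            cur = cond
        elif cond != cur:
            segs.append((start, last_t, cur[0], cur[1]))
            start, cur = last_t, cond
        last_t = float(t)
    segs.append((start, last_t, cur[0], cur[1]))
    return segs


def simulate_occupancy(drug: SimDrugConfig, protocol: Protocol) -> pd.DataFrame:
    """Exact trap-occupancy time course sampled at every train time.

    Returns a frame with columns time_s, b_hydro, b_lipo, block aligned with
    ``protocol.schedule()``.
    """
    sched = protocol.schedule()
    times = sched["time_s"].to_numpy(dtype=float)
    b = np.zeros(2)  # (hydro, lipo) at the running segment start
    out = np.empty((len(times), 2))
    idx = 0
    for t0, t1, pH, on in _segments(protocol):
        rates = _pool_rates(drug, pH, on)
        mask_end = idx + np.searchsorted(times[idx:], t1, side="right")
        seg_times = times[idx:mask_end]
        for p, (u, e) in enumerate(rates):
            r = u + e
            if r == 0.0:
                out[idx:mask_end, p] = b[p]
            else:
                b_ss = u / r
                out[idx:mask_end, p] = b_ss + (b[p] - b_ss) * np.exp(-r * (seg_times - t0))
                b[p] = b_ss + (b[p] - b_ss) * math.exp(-r * (t1 - t0))
        idx = mask_end
    block = 1.0 - (1.0 - out[:, 0]) * (1.0 - out[:, 1])
    return pd.DataFrame(
        {"time_s": times, "b_hydro": out[:, 0], "b_lipo": out[:, 1], "block": block}
    )


def render_trace(
    occupancy: pd.DataFrame,
    cohort: SimCohortConfig,
    protocol: Protocol,
) -> list[AmplitudeTrace]:
    """Turn a block time course into per-cell normalized amplitude traces.

    amplitude = (1 - block) * proton_block(pH) * lognormal noise, then
    normalized so the last control train of period 1 reads exactly 1.0.
    """
    sched = protocol.schedule()
    if len(occupancy) != len(sched) or not np.allclose(
        occupancy["time_s"].to_numpy(), sched["time_s"].to_numpy()
    ):
        raise ConfigError("occupancy is not sampled at the protocol's train times")
    acidic_ph = protocol.pH_levels.get("acidic")
    pf = np.where(sched["pH"].to_numpy() == acidic_ph, cohort.proton_block_factor, 1.0)
    base = (1.0 - occupancy["block"].to_numpy()) * pf
    ref_pos = _reference_position(sched)
    sigma = math.sqrt(math.log1p(cohort.noise_cv**2))
    traces = []
    for cell in range(cohort.n_cells):
        rng = np.random.default_rng([cohort.seed, cell])
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, len(base)))
        else:
            noise = np.ones(len(base))
        amp = base * noise
        amp = amp / amp[ref_pos]
        data = sched.copy()
        data["amplitude"] = amp
        traces.append(AmplitudeTrace(f"cell{cell:02d}", data))
    return traces


def _reference_position(sched: pd.DataFrame) -> int:
    mask = (sched["period_index"] == 1) & (sched["phase"] == "control")
    if not mask.any():
        raise ConfigError("protocol has no period-1 control phase to normalize against")
    return int(np.flatnonzero(mask)[-1])


def simulate_cohort(
    drug: SimDrugConfig, cohort: SimCohortConfig, protocol: Protocol | None = None
) -> list[AmplitudeTrace]:
    """Convenience: occupancy + rendering for one compound."""
    protocol = protocol or Protocol()
    occ = simulate_occupancy(drug, protocol)
    return render_trace(occ, cohort, protocol)


# ---------------------------------------------------------------------------
# Class presets: parameter sets reproducing the seven qualitative
# pH-dependence signatures (rates tuned to the signatures; no kinetic rate
# constants are available from experiments).
# ---------------------------------------------------------------------------

_PRESETS = {
    # label: (pKa, conc µM, kd_site µM, lipo_weight, k_exit_hydro, k_exit_lipo, seq)
    "A": (5.5, 300.0, 300.0, 0.0, 0.030, 0.05, 0.0),  # pH-independent, fast, reversible
    "B": (6.5, 100.0, 63.0, 0.40, 0.020, 3.0, 0.0),  # pH-dependent affinity & kinetics
    "C": (6.9, 10.0, 3.3, 1.0, 0.050, 0.025, 0.0),  # slow, alkalic trapping
    "D": (8.3, 30.0, 10.0, 0.0, 0.130, 0.05, 0.0),  # acidic trapping (hydrophilic pool)
    "E": (7.2, 3.0, 1.3, 1.0, 0.050, 0.004, 0.9),  # most potent at neutral pH
    "F": (8.2, 30.0, 32.0, 0.20, 0.050, 0.018, 0.0),  # intermediate, alkalization-helped
    "G": (6.3, 100.0, 43.0, 0.05, 0.040, 0.010, 0.0),  # weak pH-dependence
}


def class_preset(label: str) -> SimDrugConfig:
    """Preset compound for one of the seven pH-dependence classes A-G."""
    if label not in _PRESETS:
        raise KeyError(f"unknown class label {label!r}; expected one of A-G")
    pKa, conc, kd, lw, keh, kel, seq = _PRESETS[label]
    k_entry = calibrate_k_entry(pKa, conc, kd, lw, keh, kel, seq)
    return SimDrugConfig(
        drug_code=f"class{label}",
        conc=conc,
        pKa=pKa,
        k_entry=k_entry,
        k_exit_lipo=kel,
        k_exit_hydro=keh,
        lipo_weight=lw,
        kd_site=kd,
        seq=seq,
        class_label=label,
    )


def jittered_preset(label: str, rng: np.random.Generator, code: str) -> SimDrugConfig:
    """Preset with mild multiplicative parameter jitter; recalibrated entry rate."""
    pKa, conc, kd, lw, keh, kel, seq = _PRESETS[label]
    pKa = float(np.clip(pKa + rng.uniform(-0.04, 0.04), 0.5, 13.5))
    kd = kd * 10 ** rng.uniform(-0.08, 0.08)
    keh = keh * 10 ** rng.uniform(-0.05, 0.05)
    kel = kel * 10 ** rng.uniform(-0.05, 0.05)
    if 0.0 < lw < 1.0:
        lw = float(np.clip(lw + rng.uniform(-0.02, 0.02), 0.0, 1.0))
    k_entry = calibrate_k_entry(pKa, conc, kd, lw, keh, kel, seq)
    return SimDrugConfig(
        drug_code=code,
        conc=conc,
        pKa=pKa,
        k_entry=k_entry,
        k_exit_lipo=kel,
        k_exit_hydro=keh,
        lipo_weight=lw,
        kd_site=kd,
        seq=seq,
        class_label=label,
    )


DEFAULT_CLASS_COUNTS = {"A": 5, "B": 4, "C": 4, "D": 4, "E": 4, "F": 5, "G": 4}


def benchmark_cohort(
    seed: int, class_counts: dict[str, int] | None = None
) -> tuple[list[SimDrugConfig], list[str]]:
    """Planted-class cohort for clustering benchmarks: jittered presets.

    Returns (drug configs, planted class labels); 30 drugs by default.
    """
    counts = class_counts or DEFAULT_CLASS_COUNTS
    rng = np.random.default_rng([seed, 7])
    drugs, labels = [], []
    for label in sorted(counts):
        for i in range(counts[label]):
            drugs.append(jittered_preset(label, rng, f"{label}{i + 1}"))
            labels.append(label)
    return drugs, labels
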