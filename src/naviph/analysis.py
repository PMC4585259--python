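"""Per-cell and per-drug analysis of peak-amplitude traces.

From every drug-applied period of a trace the triple (c, i, w) is read off --
the last control, last drug-application and last washout train amplitudes --
together with mono-exponential onset/offset time constants.  Per drug the
module derives, at each pH:

* apparent affinity  K_app = conc * (1 - Inh) / Inh  from the reduced Hill
  equation Inh = conc / (conc + K_app)  (one-to-one binding, nH = 1),
* reversibility (w - i) / (c - i),
* onset/offset time constants from single-exponential fits,

then aggregates across replicate cells (geometric means for affinities and
time constants, arithmetic for reversibility; neutral pH as the per-cell
average of the first and the last neutral application) and runs paired
two-tailed t-tests between pH levels (log-transformed for affinity and time
constants) with a p < 0.01 significance rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DataError, FitError
from .io import AmplitudeTrace
from .protocol import Protocol

TAU_MIN = 0.1  # s
TAU_MAX = 1.0e4  # s
TAU_FAST_FLOOR = 10.0  # s; unresolvably fast kinetics pinned to half a train interval
SPAN_FLOOR = 0.01  # below this fitted span the kinetics are unresolved
RECOVERY_FLOOR = 0.1  # offset taus below this reversibility are unreliable
CENSOR_INHIBITION = 0.05  # detection floor used when imputing censored K_app

TRANSITIONS = (
    "neutral_to_acidic",
    "acidic_to_neutral",
    "neutral_to_alkalic",
    "alkalic_to_neutral",
)

CONTRASTS = (("acidic", "neutral"), ("neutral", "alkalic"), ("acidic", "alkalic"))


@dataclass
class ExpFit:
    tau: float
    plateau: float
    span: float
    residual_norm: float
    flags: set = field(default_factory=set)


@dataclass
class PeriodStats:
    """Amplitude triple and fitted kinetics of one drug application."""

    cell_id: str
    period_index: int
    pH: float
    c: float
    i: float
    w: float
    tau_onset: float
    tau_offset: float
    onset_flags: set
    offset_flags: set
    fit_quality: float


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def kapp_from_inhibition(conc: float, inhibition: float):
    """Apparent affinity from a single-concentration inhibition.

    Returns (K_app in µM, flags).  inhibition <= 0 (no block, or potentiation)
    is censored: the drug blocks less than the detection floor, so K_app is
    only known to exceed a bound and NaN is returned with a 'censored' flag.
    """
    if conc <= 0:
        raise DataError("concentration must be > 0")
    if inhibition >= 1:
        raise DataError("inhibition >= 1 is not a valid amplitude ratio")
    if inhibition <= 0:
        return math.nan, {"censored"}
    return conc * (1.0 - inhibition) / inhibition, set()


def kapp_censor_bound(conc: float) -> float:
    """Imputation value for censored K_app: the 5%-inhibition detection floor."""
    return conc * (1.0 - CENSOR_INHIBITION) / CENSOR_INHIBITION


def reversibility(c: float, i: float, w: float):
    """(w - i)/(c - i); NaN + flag when c <= i (no resolvable inhibition)."""
    if c <= i:
        return math.nan, {"undefined"}
    return (w - i) / (c - i), set()


def normalize_trace(trace: AmplitudeTrace) -> AmplitudeTrace:
    """Scale so the last control train of period 1 reads exactly 1.0."""
    sub = trace.data
    mask = (sub["period_index"] == 1) & (sub["phase"] == "control")
    if not mask.any():
        raise ConfigError(f"cell {trace.cell_id}: no period-1 control phase")
    ref = sub.loc[mask, "amplitude"].iloc[-1]
    if ref <= 0:
        raise DataError(f"cell {trace.cell_id}: non-positive reference amplitude")
    out = sub.copy()
    out["amplitude"] = out["amplitude"] / ref
    return AmplitudeTrace(trace.cell_id, out)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def _model(t, plateau, span, tau):
    return plateau + span * np.exp(-t / tau)


# fitted on log(tau): keeps tau positive and lets the fast unbounded
# Levenberg-Marquardt path handle the bound constraint; ltau is clamped to a
# generous window so runaway steps neither overflow nor produce gradient
_LTAU_LO, _LTAU_HI = math.log(TAU_MIN) - 5.0, math.log(TAU_MAX) + 5.0


def _model_ltau(t, plateau, span, ltau):
    return plateau + span * np.exp(-t * np.exp(-np.clip(ltau, _LTAU_LO, _LTAU_HI)))


def _model_ltau_jac(t, plateau, span, ltau):
    rate = np.exp(-np.clip(ltau, _LTAU_LO, _LTAU_HI))
    e = np.exp(-t * rate)
    return np.column_stack([np.ones_like(t), e, span * e * t * rate])


def fit_exponential(times, amplitudes) -> ExpFit:
    """Least-squares fit of A(t) = plateau + span * exp(-(t - t0)/tau).

    t0 is the first point's time; tau is constrained to (0.1 s, 1e4 s].
    Flat data and fits pinned to a tau bound or with negligible span are
    flagged 'kinetics unresolved'.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if len(t) < 3:
        raise ConfigError("exponential fit needs at least 3 points")
    t = t - t[0]
    if np.ptp(y) < 1e-12:
        return ExpFit(TAU_MAX, float(y.mean()), 0.0, 0.0, {"kinetics unresolved"})
    span0 = y[0] - y[-1]
    duration = max(t[-1], 1.0)
    starts = [duration / 5.0, duration / 2.0, duration * 2.0]
    # stop early once residuals reach the per-train noise floor
    good_enough = len(y) * (0.02 * max(abs(y).max(), 1.0)) ** 2
    best = None
    tried = []
    lmin, lmax = math.log(TAU_MIN), math.log(TAU_MAX)
    for tau0 in starts:
        p0 = (float(y[-1]), float(span0), float(np.clip(math.log(tau0), lmin, lmax)))
        tried.append(p0)
        # maxfev caps pathological flat-valley wandering; the best point
        # found is still returned and judged by its residuals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            popt, ier = optimize.leastsq(
                lambda p: _model_ltau(t, *p) - y,
                p0,
                Dfun=lambda p: _model_ltau_jac(t, *p),
                maxfev=300,
            )
        if ier not in (1, 2, 3, 4, 5):
            continue
        popt = np.atleast_1d(popt)
        popt[2] = np.clip(popt[2], lmin, lmax)
        ssr = float(np.sum((_model_ltau(t, *popt) - y) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
        if ssr <= good_enough:
            break
    if best is None:
        raise FitError("exponential fit did not converge", initial_guesses=tried)
    (plateau, span, ltau), ssr = best
    tau = math.exp(ltau)
    flags = set()
    if abs(span) < SPAN_FLOOR or tau >= TAU_MAX * 0.999 or tau <= TAU_MIN * 1.001:
        flags.add("kinetics unresolved")
    return ExpFit(float(tau), float(plateau), float(span), math.sqrt(ssr), flags)


# ---------------------------------------------------------------------------
# period-level extraction
# ---------------------------------------------------------------------------

def extract_period_stats(trace: AmplitudeTrace, period_index: int) -> PeriodStats:
    """(c, i, w) and onset/offset taus for one drug-applied period."""
    sub = trace.period(period_index)
    if sub.empty:
        raise ConfigError(f"period {period_index} absent from trace {trace.cell_id}")
    if not sub["drug_on"].any():
        raise ConfigError(f"period {period_index} is drug-free")
    phases = {ph: sub[sub["phase"] == ph] for ph in ("control", "drug", "washout")}
    for name, block in phases.items():
        if len(block) < 3:
            raise ConfigError(f"period {period_index}: phase {name} has fewer than 3 trains")
    c = float(phases["control"]["amplitude"].iloc[-1])
    i = float(phases["drug"]["amplitude"].iloc[-1])
    w = float(phases["washout"]["amplitude"].iloc[-1])
    onset = fit_exponential(phases["drug"]["time_s"], phases["drug"]["amplitude"])
    offset = fit_exponential(phases["washout"]["time_s"], phases["washout"]["amplitude"])
    rev, rev_flags = reversibility(c, i, w)
    offset_flags = set(offset.flags)
    if rev_flags or (not math.isnan(rev) and rev < RECOVERY_FLOOR):
        offset_flags.add("offset unreliable")
    return PeriodStats(
        cell_id=trace.cell_id,
        period_index=period_index,
        pH=float(sub["pH"].iloc[0]),
        c=c,
        i=i,
        w=w,
        tau_onset=onset.tau,
        tau_offset=offset.tau,
        onset_flags=set(onset.flags),
        offset_flags=offset_flags,
        fit_quality=onset.residual_norm,
    )


def transition_recovery_ratio(trace: AmplitudeTrace, transition: str,
                              protocol: Protocol | None = None) -> float:
    """Recovery evoked by a bath pH change alone.

    Ratio of the last over the first amplitude of the drug-free section that
    immediately follows the named pH transition.  Both trains share the bath
    pH, so the proton-block factor cancels; values > 1 signal
    pH-change-induced recovery.
    """
    if transition not in TRANSITIONS:
        raise ConfigError(f"unknown transition {transition!r}")
    protocol = protocol or Protocol()
    lab_from, lab_to = transition.split("_to_")
    ph_from = protocol.pH_levels[lab_from]
    ph_to = protocol.pH_levels[lab_to]
    data = trace.data
    periods = sorted(data["period_index"].unique())
    for prev, nxt in zip(periods, periods[1:]):
        if (
            float(data[data["period_index"] == prev]["pH"].iloc[0]) == ph_from
            and float(data[data["period_index"] == nxt]["pH"].iloc[0]) == ph_to
        ):
            after = data[data["period_index"] == nxt]
            on = after["drug_on"].to_numpy()
            n_free = int(on.argmax()) if on.any() else len(after)
            free = after.iloc[:n_free]
            if len(free) < 2:
                raise ConfigError(
                    f"post-transition drug-free section of {transition} has < 2 trains"
                )
            return float(free["amplitude"].iloc[-1] / free["amplitude"].iloc[0])
    raise ConfigError(f"transition {transition} not present in trace {trace.cell_id}")


# ---------------------------------------------------------------------------
# cohort-level summaries
# ---------------------------------------------------------------------------

def _gmean(values) -> float:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size == 0 or (arr <= 0).any():
        return math.nan
    return float(np.exp(np.mean(np.log(arr))))


def paired_pH_test(values_a, values_b, prop: str):
    """Paired two-tailed t-test across cells between two pH conditions.

    Affinity and time-constant values are log10-transformed first;
    reversibility is tested untransformed.  Returns (p, flags).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return math.nan, {"insufficient pairs"}
    if prop in ("affinity", "tau"):
        if (a <= 0).any() or (b <= 0).any():
            return math.nan, {"nonpositive values"}
        a, b = np.log10(a), np.log10(b)
    elif prop != "reversibility":
        raise ConfigError(f"unknown property {prop!r}")
    diffs = a - b
    if np.ptp(diffs) == 0.0:
        return 1.0, {"degenerate"}
    res = stats.ttest_rel(a, b)
    return float(res.pvalue), set()


@dataclass
class DrugSummary:
    """Per-drug pH profile: per-cell values, aggregates, significance tests."""

    drug_code: str
    conc: float
    per_cell: pd.DataFrame  # cell_id x ph_label rows with kapp/rev/taus
    summary: pd.DataFrame  # one row per ph_label
    pvalues: pd.DataFrame  # property x contrast
    transition_recovery: pd.DataFrame  # per transition: per-cell + geometric mean
    n_censored: int = 0


def _ph_label(protocol: Protocol, ph_value: float) -> str:
    for label, value in protocol.pH_levels.items():
        if value == ph_value:
            return label
    raise DataError(f"pH {ph_value} does not match a protocol level")


def analyze_cohort(
    traces: list[AmplitudeTrace],
    drug_code: str,
    conc: float,
    protocol: Protocol | None = None,
    alpha: float = 0.01,
) -> DrugSummary:
    """Full per-drug analysis of a replicate-cell trace bundle."""
    if len(traces) < 2:
        raise ConfigError("summaries need at least 2 cells")
    protocol = protocol or Protocol()
    drug_periods = [p for p in range(1, protocol.n_periods + 1) if protocol.drug_applied(p)]
    rows = []
    trans_rows = []
    n_censored = 0
    for trace in traces:
        trace = normalize_trace(trace)
        cell_values: dict[str, dict] = {}
        for p in drug_periods:
            ps = extract_period_stats(trace, p)
            inh = 1.0 - ps.i / ps.c
            kapp, kflags = kapp_from_inhibition(conc, inh) if inh < 1 else (math.nan, {"saturated"})
            if "censored" in kflags:
                n_censored += 1
            rev, _ = reversibility(ps.c, ps.i, ps.w)
            label = _ph_label(protocol, ps.pH)
            cell_values.setdefault(
                label,
                {"kapp": [], "kapp_imp": [], "inh": [], "rev": [], "rev_b": [], "tau_on": [],
                 "tau_on_rb": [], "tau_off": []},
            )
            cell_values[label]["kapp"].append(kapp)
            cell_values[label]["inh"].append(inh)
            # censoring-robust companion values used by the profiling stage:
            # censored affinities pinned to the detection bound, reversibility
            # bounded to its physically meaningful range
            cell_values[label]["kapp_imp"].append(
                kapp_censor_bound(conc) if math.isnan(kapp) else kapp
            )
            cell_values[label]["rev"].append(rev)
            cell_values[label]["rev_b"].append(
                1.0 if math.isnan(rev) else float(np.clip(rev, 0.0, 1.2))
            )
            # unresolved onsets carry no information beyond a bound: with no
            # measurable block the kinetics are slower than the observation
            # window; with clear block they are faster than the train spacing
            if "kinetics unresolved" in ps.onset_flags:
                tau_rb = TAU_MAX if inh < 0.1 else TAU_FAST_FLOOR
            else:
                tau_rb = ps.tau_onset
            cell_values[label]["tau_on_rb"].append(tau_rb)
            cell_values[label]["tau_on"].append(ps.tau_onset)
            cell_values[label]["tau_off"].append(
                ps.tau_offset if "offset unreliable" not in ps.offset_flags else math.nan
            )
        for label, vals in cell_values.items():
            rows.append(
                {
                    "cell_id": trace.cell_id,
                    "ph_label": label,
                    "pH": protocol.pH_levels[label],
                    # first-and-last averaging for the repeated neutral condition
                    "kapp": _gmean(vals["kapp"]),
                    "kapp_imputed": _gmean(vals["kapp_imp"]),
                    "inhibition": float(np.mean(vals["inh"])),
                    "reversibility": float(np.nanmean(vals["rev"]))
                    if not all(math.isnan(v) for v in vals["rev"]) else math.nan,
                    "reversibility_bounded": float(np.mean(vals["rev_b"])),
                    "tau_onset": _gmean(vals["tau_on"]),
                    "tau_onset_robust": _gmean(vals["tau_on_rb"]),
                    "tau_offset": _gmean(vals["tau_off"]),
                }
            )
        for transition in TRANSITIONS:
            try:
                ratio = transition_recovery_ratio(trace, transition, protocol)
            except ConfigError:
                ratio = math.nan
            trans_rows.append(
                {"cell_id": trace.cell_id, "transition": transition, "ratio": ratio}
            )
    per_cell = pd.DataFrame(rows)
    summary_rows = []
    for label, sub in per_cell.groupby("ph_label"):
        summary_rows.append(
            {
                "ph_label": label,
                "pH": float(sub["pH"].iloc[0]),
                "kapp": _gmean(sub["kapp"]),
                "kapp_imputed": _gmean(sub["kapp_imputed"]),
                # pooled estimator: cell-averaged inhibition inverted once --
                # far more stable than averaging per-cell K when block is weak
                "kapp_pooled": (
                    conc * (1.0 - sub["inhibition"].mean()) / sub["inhibition"].mean()
                    if 0.0 < sub["inhibition"].mean() < 1.0 else math.nan
                ),
                "kapp_n_censored": int(sub["kapp"].isna().sum()),
                "reversibility": float(sub["reversibility"].mean()),
                "reversibility_bounded": float(sub["reversibility_bounded"].mean()),
                "tau_onset": _gmean(sub["tau_onset"]),
                "tau_onset_robust": _gmean(sub["tau_onset_robust"]),
                "tau_offset": _gmean(sub["tau_offset"]),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("ph_label")

    pivot = {
        prop: per_cell.pivot(index="cell_id", columns="ph_label", values=col)
        for prop, col in (
            ("affinity", "kapp"),
            ("tau", "tau_onset"),
            ("reversibility", "reversibility"),
        )
    }
    pv_rows = []
    for prop, table in pivot.items():
        for lab_a, lab_b in CONTRASTS:
            if lab_a in table.columns and lab_b in table.columns:
                p, flags = paired_pH_test(table[lab_a], table[lab_b], prop)
            else:
                p, flags = math.nan, {"missing level"}
            pv_rows.append(
                {
                    "property": prop,
                    "contrast": f"{lab_a} vs {lab_b}",
                    "p": p,
                    "significant": bool(p < alpha) if not math.isnan(p) else False,
                    "flags": ";".join(sorted(flags)),
                }
            )
    pvalues = pd.DataFrame(pv_rows)

    trans = pd.DataFrame(trans_rows)
    trans_summary = (
        trans.groupby("transition")["ratio"].apply(_gmean).rename("geomean").reset_index()
    )
    transition_recovery = trans.merge(trans_summary, on="transition")

    return DrugSummary(
        drug_code=drug_code,
        conc=conc,
        per_cell=per_cell,
        summary=summary,
        pvalues=pvalues,
        transition_recovery=transition_recovery,
        n_censored=n_censored,
    )


def summarize_drug(*args, **kwargs) -> DrugSummary:
    """Alias for :func:`analyze_cohort` (the per-drug summary entry point)."""
    return analyze_cohort(*args, **kwargs)
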