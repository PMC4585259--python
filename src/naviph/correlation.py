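"""Descriptor-property correlations and derived pH-dependence metrics.

Seven per-drug metrics condense the pH profile: acidic/alkalic and
neutral/alkalic apparent-affinity ratios, the alkalic/neutral onset-time
ratio, acidic/neutral and neutral/alkalic reversibility ratios, the
acidification-induced recovery score (sum of the logs of the neutral-to-acidic
and alkalic-to-neutral transition-recovery steps) and the alkalization-induced
recovery (the neutral-to-alkalic transition-recovery ratio).

Correlations are ordinary least squares on optionally log10-transformed
variables; the reported p is the two-tailed slope t-test and flagged pairs are
excluded pairwise (no imputation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import DrugSummary
from .errors import DataError

METRIC_COLUMNS = (
    "affinity_ratio_acid_alk",
    "affinity_ratio_alk_neutral",
    "onset_ratio",
    "rev_ratio_acid_neutral",
    "rev_ratio_neutral_alk",
    "acidification_recovery",
    "alkalization_recovery",
)


@dataclass
class CorrelationResult:
    r2: float
    p: float
    slope: float
    n: int
    flags: frozenset = frozenset()


def _ratio(num: float, den: float) -> float:
    if any(math.isnan(v) or v <= 0 for v in (num, den)):
        return math.nan
    return num / den


def compute_metrics(summaries: list[DrugSummary]) -> pd.DataFrame:
    """Per-drug pH-dependence metrics; undefined ratios carried as NaN."""
    rows = {}
    for s in summaries:
        g = s.summary
        tr = s.transition_recovery.drop_duplicates("transition").set_index("transition")["geomean"]

        def lev(col, lab):
            if lab not in g.index:
                return math.nan
            # affinity ratios use the pooled-inhibition estimator: averaging
            # inhibition across cells before inverting the Hill relation is
            # far more stable than ratios of per-cell geometric means when the
            # block at one pH is close to the detection floor
            if col == "kapp" and "kapp_pooled" in g.columns:
                return float(g.loc[lab, "kapp_pooled"])
            return float(g.loc[lab, col])

        r_na = tr.get("neutral_to_acidic", math.nan)
        r_an = tr.get("alkalic_to_neutral", math.nan)
        acid_rec = (
            math.log10(r_na) + math.log10(r_an)
            if all(v > 0 and not math.isnan(v) for v in (r_na, r_an))
            else math.nan
        )
        rows[s.drug_code] = {
            "affinity_ratio_acid_alk": _ratio(lev("kapp", "acidic"), lev("kapp", "alkalic")),
            "affinity_ratio_alk_neutral": _ratio(lev("kapp", "neutral"), lev("kapp", "alkalic")),
            "onset_ratio": _ratio(lev("tau_onset", "alkalic"), lev("tau_onset", "neutral")),
            "rev_ratio_acid_neutral": _ratio(
                lev("reversibility", "acidic"), lev("reversibility", "neutral")
            ),
            "rev_ratio_neutral_alk": _ratio(
                lev("reversibility", "neutral"), lev("reversibility", "alkalic")
            ),
            "acidification_recovery": acid_rec,
            "alkalization_recovery": tr.get("neutral_to_alkalic", math.nan),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "drug"
    return out[list(METRIC_COLUMNS)]


def correlate(x, y, transform: str = "none") -> CorrelationResult:
    """OLS of y on x with optional log10 transforms; R^2 and slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if transform in ("log10-x", "log10-both"):
        x = np.where(x > 0, x, np.nan)
        x = np.log10(x)
    if transform in ("log10-y", "log10-both"):
        y = np.where(y > 0, y, np.nan)
        y = np.log10(y)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return CorrelationResult(math.nan, math.nan, math.nan, len(x), frozenset({"n < 3"}))
    if np.ptp(x) == 0.0:
        return CorrelationResult(
            math.nan, math.nan, math.nan, len(x), frozenset({"zero variance in x"})
        )
    if np.ptp(y) == 0.0:  # constant response: no relationship by definition
        return CorrelationResult(0.0, 1.0, 0.0, len(x))
    res = stats.linregress(x, y)
    return CorrelationResult(float(res.rvalue**2), float(res.pvalue), float(res.slope), len(x))


# the 24 inhibition properties entering the descriptor cross-matrix:
# 4 properties x 3 pH levels + 4 properties x 3 pH contrasts
def inhibition_property_table(summaries: list[DrugSummary]) -> pd.DataFrame:
    """Per-drug table of the 24 inhibition properties (log scale for K/tau)."""
    labs = ("acidic", "neutral", "alkalic")
    pairs = (("acidic", "neutral"), ("neutral", "alkalic"), ("acidic", "alkalic"))
    rows = {}
    for s in summaries:
        g = s.summary
        vals = {}
        for prop, col, logt in (
            ("K_app", "kapp", True),
            ("rev", "reversibility", False),
            ("tau_on", "tau_onset", True),
            ("tau_off", "tau_offset", True),
        ):
            level = {}
            for lab in labs:
                v = float(g.loc[lab, col]) if lab in g.index else math.nan
                if logt:
                    v = math.log10(v) if v > 0 else math.nan
                level[lab] = v
                vals[f"{prop}({lab})"] = v
            for a, b in pairs:
                vals[f"d_{prop}({a},{b})"] = level[a] - level[b]
        rows[s.drug_code] = vals
    out = pd.DataFrame(rows).T
    out.index.name = "drug"
    return out


def correlation_matrix(
    descriptors: pd.DataFrame, summaries: list[DrugSummary]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor x inhibition-property and descriptor x descriptor matrices.

    Returns two long frames of (x, y, r2, p, n, slope_sign) cells.  Drug codes
    must match between the two inputs.
    """
    props = inhibition_property_table(summaries)
    desc = descriptors.set_index("drug") if "drug" in descriptors.columns else descriptors
    unmatched = sorted(set(props.index).symmetric_difference(desc.index))
    if unmatched:
        raise DataError("drug codes do not match between tables: " + ", ".join(map(str, unmatched)))
    desc = desc.loc[props.index]
    num_desc = desc.select_dtypes(include=[np.number])

    def cells(xs: pd.DataFrame, ys: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for xc in xs.columns:
            for yc in ys.columns:
                if xc == yc:
                    continue
                res = correlate(xs[xc], ys[yc])
                rows.append(
                    {
                        "x": xc,
                        "y": yc,
                        "r2": res.r2,
                        "p": res.p,
                        "n": res.n,
                        "slope_sign": int(np.sign(res.slope)) if not math.isnan(res.slope) else 0,
                        "flags": ";".join(sorted(res.flags)),
                    }
                )
        return pd.DataFrame(rows)

    return cells(num_desc, props), cells(num_desc, num_desc)
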