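"""18-variable pH-dependence profile and Ward clustering.

Per drug the profile holds, for apparent affinity, reversibility and onset
time constant at pH 6.0 / 7.3 / 8.6:

* nine *level* variables, z-scored per column (log10-transformed first for
  affinity and time constants), and
* nine *difference* variables for the pH contrasts 6.0-7.3, 7.3-8.6 and
  6.0-8.6 (log-ratios for affinity and time constants), divided by the column
  standard deviation but NOT mean-centered, so the sign of a difference is
  preserved.

Sample standard deviations (n-1 denominator) throughout.  Offset time
constants are excluded from the base profile (unreliable at low recovery) and
only enter through the onset/offset-averaged sensitivity variant.  Censored
apparent affinities are imputed at the censoring bound (5%-inhibition
detection floor) before the log transform.

Clustering is agglomerative with Ward's minimum variance criterion on
(optionally column-weighted) Euclidean distances, cut at k = 7 clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .analysis import DrugSummary, kapp_censor_bound
from .errors import ConfigError, DataError

PH_LABELS = ("acidic", "neutral", "alkalic")
DIFF_PAIRS = (("acidic", "neutral"), ("neutral", "alkalic"), ("acidic", "alkalic"))


@dataclass
class FeatureMatrix:
    """Normalized drug x 18-variable profile plus column weights."""

    data: pd.DataFrame
    column_weights: pd.Series
    n_imputed: int = 0
    aux: pd.DataFrame | None = None  # onset/offset-averaged tau variant columns

    @property
    def drugs(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ClusterResult:
    assignments: pd.Series  # drug -> cluster id (1..k)
    linkage: np.ndarray
    k: int
    variant_tag: str = "base"


def _zscore(col: pd.Series, name: str) -> pd.Series:
    sd = col.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DataError(f"feature column {name!r} has zero standard deviation")
    return (col - col.mean()) / sd


def _sd_scale(col: pd.Series, name: str) -> pd.Series:
    sd = col.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DataError(f"feature column {name!r} has zero standard deviation")
    return col / sd


def _raw_levels(summaries: list[DrugSummary]) -> pd.DataFrame:
    rows = {}
    for s in summaries:
        row = {}
        for lab in PH_LABELS:
            if lab not in s.summary.index:
                raise DataError(f"{s.drug_code}: no {lab} summary")
            rec = s.summary.loc[lab]
            # censoring-robust companions: per-cell censored affinities were
            # imputed at the detection bound, reversibility bounded to [0, 1.2]
            kapp = rec.get("kapp_imputed", rec["kapp"])
            if np.isnan(kapp):
                kapp = kapp_censor_bound(s.conc)
                row[f"imputed_{lab}"] = 1
            elif rec["kapp_n_censored"] > 0:
                row[f"imputed_{lab}"] = 1
            row[f"logK_{lab}"] = np.log10(kapp)
            rev = rec.get("reversibility_bounded", rec["reversibility"])
            if np.isnan(rev):
                rev = 1.0  # no resolvable block: nothing left to recover from
                row[f"imputed_{lab}"] = row.get(f"imputed_{lab}", 0) + 1
            row[f"rev_{lab}"] = rev
            tau_on = rec.get("tau_onset_robust", rec["tau_onset"])
            row[f"logTauOn_{lab}"] = np.log10(tau_on)
            row[f"logTauOff_{lab}"] = np.log10(rec["tau_offset"]) if rec["tau_offset"] > 0 else np.nan
        rows[s.drug_code] = row
    return pd.DataFrame(rows).T


def build_features(summaries: list[DrugSummary]) -> FeatureMatrix:
    """Assemble the normalized 18-variable matrix from per-drug summaries."""
    raw = _raw_levels(summaries)
    n_imputed = int(raw.filter(like="imputed_").sum().sum())
    out = pd.DataFrame(index=raw.index)
    aux = pd.DataFrame(index=raw.index)
    specs = {"K_app": "logK", "rev": "rev", "tau_on": "logTauOn"}
    for prop, stem in specs.items():
        for lab in PH_LABELS:
            out[f"z{prop}({lab})"] = _zscore(raw[f"{stem}_{lab}"], f"z{prop}({lab})")
        for lab_a, lab_b in DIFF_PAIRS:
            diff = raw[f"{stem}_{lab_a}"] - raw[f"{stem}_{lab_b}"]
            out[f"d{prop}({lab_a},{lab_b})"] = _sd_scale(diff, f"d{prop}({lab_a},{lab_b})")
    # sensitivity variant: onset/offset-averaged time constant (geometric, i.e.
    # mean of the logs); offsets flagged unreliable fall back to the onset value
    log_avg = {}
    for lab in PH_LABELS:
        on, off = raw[f"logTauOn_{lab}"], raw[f"logTauOff_{lab}"]
        log_avg[lab] = np.where(off.notna(), (on + off.fillna(on)) / 2.0, on)
    for lab in PH_LABELS:
        aux[f"ztau_avg({lab})"] = _zscore(
            pd.Series(log_avg[lab], index=raw.index), f"ztau_avg({lab})"
        )
    for lab_a, lab_b in DIFF_PAIRS:
        diff = pd.Series(log_avg[lab_a] - log_avg[lab_b], index=raw.index)
        aux[f"dtau_avg({lab_a},{lab_b})"] = _sd_scale(diff, f"dtau_avg({lab_a},{lab_b})")
    weights = pd.Series(1.0, index=out.columns)
    return FeatureMatrix(out, weights, n_imputed, aux)


def ward_cluster(
    features: FeatureMatrix,
    k: int = 7,
    metric: str = "euclidean",
    variant_tag: str = "base",
    data: pd.DataFrame | None = None,
) -> ClusterResult:
    """Ward minimum-variance clustering of the profile, cut to k clusters."""
    X = features.data if data is None else data
    if k > len(X):
        raise ConfigError(f"k={k} exceeds the number of drugs ({len(X)})")
    w = features.column_weights.reindex(X.columns).fillna(1.0).to_numpy()
    if (w <= 0).any():
        raise ConfigError("column weights must be positive")
    # a weight scales a variable's contribution to squared distance
    scaled = X.to_numpy() * np.sqrt(w)
    if metric == "euclidean":
        Z = hierarchy.linkage(scaled, method="ward")
    else:
        Z = hierarchy.linkage(pdist(scaled, metric=metric), method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(pd.Series(labels, index=X.index, name="cluster"), Z, k, variant_tag)


def sensitivity_suite(
    features: FeatureMatrix,
    k: int = 7,
    variants: list[str] | None = None,
    weight_columns: list[str] | None = None,
    weight_grid: tuple = (1.0, 1.5, 2.0),
) -> list[ClusterResult]:
    """Base clustering plus the robustness variants.

    Variants: 'base' (Euclidean, unweighted), 'manhattan' (city-block
    distances), 'tau_avg' (onset time constants replaced by the
    onset/offset-averaged ones), and 'weight:<x>' for each grid value applied
    to the designated columns (default: the three reversibility levels).
    """
    all_variants = ["base", "manhattan", "tau_avg"] + [f"weight:{x:g}" for x in weight_grid]
    variants = all_variants if variants is None else list(variants)
    weight_columns = weight_columns or [f"zrev({lab})" for lab in PH_LABELS]
    results = []
    for tag in variants:
        if tag == "base":
            results.append(ward_cluster(features, k, variant_tag=tag))
        elif tag == "manhattan":
            results.append(ward_cluster(features, k, metric="cityblock", variant_tag=tag))
        elif tag == "tau_avg":
            if features.aux is None:
                raise ConfigError("feature matrix carries no tau_avg columns")
            swapped = features.data.copy()
            drop = [c for c in swapped.columns if "tau_on" in c]
            swapped = swapped.drop(columns=drop)
            swapped = pd.concat([swapped, features.aux], axis=1)
            results.append(ward_cluster(features, k, variant_tag=tag, data=swapped))
        elif tag.startswith("weight:"):
            x = float(tag.split(":", 1)[1])
            fm = FeatureMatrix(
                features.data, features.column_weights.copy(), features.n_imputed, features.aux
            )
            fm.column_weights.loc[[c for c in weight_columns if c in fm.column_weights.index]] = x
            results.append(ward_cluster(fm, k, variant_tag=tag))
        else:
            raise ConfigError(f"unknown sensitivity variant {tag!r}")
    return results


def pairwise_ari(results: list[ClusterResult]) -> pd.DataFrame:
    """Adjusted Rand index between every pair of variant assignments."""
    tags = [r.variant_tag for r in results]
    out = pd.DataFrame(np.eye(len(results)), index=tags, columns=tags)
    for a in range(len(results)):
        for b in range(a + 1, len(results)):
            common = results[a].assignments.index.intersection(results[b].assignments.index)
            ari = adjusted_rand_score(
                results[a].assignments.loc[common], results[b].assignments.loc[common]
            )
            out.iloc[a, b] = out.iloc[b, a] = ari
    return out


def wcss(data: pd.DataFrame | np.ndarray, labels) -> float:
    """Total within-cluster sum of squared Euclidean deviations from centroids."""
    X = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total
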