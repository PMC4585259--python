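"""Tabular I/O: amplitude traces, descriptor tables, summaries, manifests.

All artifacts are comma-separated UTF-8 text with one header row and '.' as
decimal separator.  Trace files are long-format, one row per train.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .errors import DataError, FormatError, RangeError
from .protocol import Protocol

TRACE_COLUMNS = [
    "cell_id",
    "time_s",
    "train_index",
    "period_index",
    "phase",
    "pH",
    "drug_on",
    "amplitude",
]

DESCRIPTOR_COLUMNS = [
    "drug",
    "conc_uM",
    "pKa",
    "logP",
    "logD_6.0",
    "logD_7.3",
    "logD_8.6",
    "PSA",
    "MW",
    "AAC",
    "ARC",
    "minProj",
    "HBD",
    "HBA",
]


@dataclass
class AmplitudeTrace:
    """Per-cell time series of normalized first-pulse peak amplitudes.

    ``data`` holds one row per train with columns time_s, train_index,
    period_index, phase, pH, drug_on, amplitude (sorted by time).
    """

    cell_id: str
    data: pd.DataFrame

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        t = self.data["time_s"].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise DataError(f"cell {self.cell_id}: times are not strictly increasing")
        if (self.data["amplitude"] < 0).any():
            raise DataError(f"cell {self.cell_id}: negative amplitude")

    def period(self, period_index: int) -> pd.DataFrame:
        return self.data[self.data["period_index"] == period_index]

    def copy(self) -> "AmplitudeTrace":
        return AmplitudeTrace(self.cell_id, self.data.copy())


@dataclass
class RunManifest:
    """Provenance record written as JSON alongside every output bundle."""

    seed: int
    config_digest: str
    software_version: str = __version__
    creation_time: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def digest_of(obj) -> str:
        return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing column(s): {', '.join(missing)}")


def read_trace(path, protocol: Protocol | None = None) -> list[AmplitudeTrace]:
    """Read a long-format trace CSV into one AmplitudeTrace per cell.

    Rows are grouped by cell_id and sorted by time.  If a protocol is given,
    period indices and phase labels are validated against it.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, f"trace file {path}")
    df["drug_on"] = df["drug_on"].astype(bool)
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        # rows must already be time-ordered within a cell; silently sorting
        # would mask corrupted files
        t = sub["time_s"].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise DataError(f"cell {cell_id}: non-monotone time")
        if protocol is not None:
            bad_phase = set(sub["phase"]) - {"control", "drug", "washout"}
            if bad_phase:
                raise DataError(f"cell {cell_id}: unknown phase label(s) {sorted(bad_phase)}")
            bad_period = set(sub["period_index"]) - set(range(1, protocol.n_periods + 1))
            if bad_period:
                raise DataError(f"cell {cell_id}: period index out of range: {sorted(bad_period)}")
        traces.append(AmplitudeTrace(str(cell_id), sub[TRACE_COLUMNS[1:]]))
    return traces


def write_trace(traces: list[AmplitudeTrace], path) -> None:
    """Write traces as one CSV, rows ordered by (cell, time)."""
    if not traces:
        raise DataError("write_trace: empty trace list")
    frames = []
    for tr in sorted(traces, key=lambda t: t.cell_id):
        sub = tr.data.sort_values("time_s").copy()
        sub.insert(0, "cell_id", tr.cell_id)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)[TRACE_COLUMNS]
    out.to_csv(path, index=False, lineterminator="\n")


def read_descriptors(path) -> pd.DataFrame:
    """Read a per-drug physicochemical descriptor table.

    One row per drug; pKa must lie in [0, 14] and concentrations must be
    positive.  Compounds flagged as acids/zwitterions (optional 'ion_class'
    column) are rejected: the neutral-fraction transform assumes monoprotic
    bases.
    """
    df = pd.read_csv(path)
    # derived columns round-trip under a d_ prefix
    df = df.rename(columns={f"d_{c}": c for c in ("N_pKa", "logN_pKa", "PSA_over_MW")})
    _require_columns(df, DESCRIPTOR_COLUMNS, f"descriptor file {path}")
    dup = df["drug"][df["drug"].duplicated()]
    if not dup.empty:
        raise DataError(f"duplicate drug code(s): {', '.join(map(str, dup.unique()))}")
    if ((df["pKa"] < 0) | (df["pKa"] > 14)).any():
        raise RangeError("pKa outside [0, 14]")
    if (df["conc_uM"] <= 0).any():
        raise DataError("non-positive concentration")
    if "ion_class" in df.columns:
        bad = df.loc[~df["ion_class"].isin(["base"]), "drug"]
        if not bad.empty:
            raise DataError(
                "only monoprotic bases are supported; flagged otherwise: "
                + ", ".join(map(str, bad))
            )
    return df.reset_index(drop=True)


def write_descriptors(table: pd.DataFrame, path) -> None:
    """Write a descriptor table; derived columns get a ``d_`` prefix."""
    out = table.copy()
    for col in ("N_pKa", "logN_pKa", "PSA_over_MW"):
        if col in out.columns:
            out = out.rename(columns={col: f"d_{col}"})
    out.to_csv(path, index=False, lineterminator="\n")
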