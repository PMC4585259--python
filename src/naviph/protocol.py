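"""Perfusion/stimulation protocol model.

The default experiment applies five consecutive perfusion periods
(neutral+drug, acidic+drug, neutral drug-free, alkalic+drug, neutral+drug).
Each period consists of a control, a drug-application and a washout phase of
10 stimulus trains each, with trains delivered every 20 s.  Only the peak
amplitude evoked by the first depolarization of each train is analyzed, so a
trace carries one row per train.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError

PHASES = ("control", "drug", "washout")

DEFAULT_PH_LEVELS = {"acidic": 6.0, "neutral": 7.3, "alkalic": 8.6}

#: (pH label, drug applied) for the five default periods.  The interposed
#: neutral period between the acidic and alkalic applications is drug-free.
DEFAULT_PERIOD_SEQUENCE = (
    ("neutral", True),
    ("acidic", True),
    ("neutral", False),
    ("alkalic", True),
    ("neutral", True),
)


@dataclass(frozen=True)
class Protocol:
    """Perfusion schedule: periods x (control/drug/washout) phases of trains."""

    period_sequence: tuple = DEFAULT_PERIOD_SEQUENCE
    trains_per_phase: tuple = (10, 10, 10)
    inter_train_interval: float = 20.0
    pulses_per_train: int = 5  # informational; only first-pulse peaks are kept
    pH_levels: dict = field(default_factory=lambda: dict(DEFAULT_PH_LEVELS))

    def __post_init__(self):
        if self.inter_train_interval <= 0:
            raise ConfigError("inter_train_interval must be > 0")
        if len(self.trains_per_phase) != len(PHASES):
            raise ConfigError("trains_per_phase must give counts for control/drug/washout")
        if any(n < 1 for n in self.trains_per_phase):
            raise ConfigError("every phase needs at least one train")
        if not self.period_sequence:
            raise ConfigError("period_sequence must not be empty")
        for label, _ in self.period_sequence:
            if label not in self.pH_levels:
                raise ConfigError(f"unknown pH label {label!r} in period_sequence")

    @property
    def n_periods(self) -> int:
        return len(self.period_sequence)

    @property
    def trains_per_period(self) -> int:
        return sum(self.trains_per_phase)

    @property
    def n_trains(self) -> int:
        return self.n_periods * self.trains_per_period

    def ph_of_period(self, period_index: int) -> float:
        """pH value of a 1-based period index."""
        label, _ = self.period_sequence[period_index - 1]
        return self.pH_levels[label]

    def drug_applied(self, period_index: int) -> bool:
        return self.period_sequence[period_index - 1][1]

    def schedule(self) -> pd.DataFrame:
        """Expand to one row per train slot.

        Columns: time_s, train_index (0-based within phase), period_index
        (1-based), phase, pH, drug_on.  drug_on is True only during the drug
        phase of periods where drug is applied.
        """
        rows = []
        g = 0
        for p, (label, applied) in enumerate(self.period_sequence, start=1):
            for phase, n in zip(PHASES, self.trains_per_phase):
                for j in range(n):
                    rows.append(
                        {
                            "time_s": g * self.inter_train_interval,
                            "train_index": j,
                            "period_index": p,
                            "phase": phase,
                            "pH": self.pH_levels[label],
                            "drug_on": bool(applied and phase == "drug"),
                        }
                    )
                    g += 1
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "period_sequence": [list(p) for p in self.period_sequence],
            "trains_per_phase": list(self.trains_per_phase),
            "inter_train_interval": self.inter_train_interval,
            "pulses_per_train": self.pulses_per_train,
            "pH_levels": dict(self.pH_levels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            period_sequence=tuple((str(a), bool(b)) for a, b in d.get(
                "period_sequence", DEFAULT_PERIOD_SEQUENCE)),
            trains_per_phase=tuple(d.get("trains_per_phase", (10, 10, 10))),
            inter_train_interval=float(d.get("inter_train_interval", 20.0)),
            pulses_per_train=int(d.get("pulses_per_train", 5)),
            pH_levels={k: float(v) for k, v in d.get(
                "pH_levels", DEFAULT_PH_LEVELS).items()},
        )

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
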