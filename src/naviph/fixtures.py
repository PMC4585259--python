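"""Synthetic 30-drug fixture cohort.

The descriptor table below is SYNTHETIC: values are plausible for the named
compounds and span the ranges discussed in the sodium-channel inhibitor
literature (pKa ~5-10.5, logP ~2-5.3, PSA up to ~90 A^2, aromatic atom counts
0-21), but they are not measurements and not the output of any descriptor
engine.  A handful of anchor values are fixed to widely cited figures
(lidocaine pKa 7.75, flecainide pKa 9.61, ritanserin logP 5.31).

``fixture_drug_configs`` maps descriptors onto simulator kinetics so that the
simulated cohort carries the descriptor-property structure the correlation
analyses probe: lipophilic compounds route their influx preferentially into
the lipophilic trap, aromaticity slows lipophilic-trap escape, polarity slows
hydrophilic-trap escape, and the two most lipophilic/aromatic compounds get a
membrane-sequestration term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .descriptors import fraction_neutral
from .simulate import SimDrugConfig, calibrate_k_entry

# drug, class, conc_uM, pKa, logP, PSA, MW, AAC, ARC, minProj, HBD, HBA
_FIXTURE_ROWS = [
    ("CBZ", "A", 300.0, 5.00, 2.4, 46.3, 236.3, 12, 2, 38.2, 2, 1),
    ("PHT", "A", 100.0, 5.30, 2.5, 58.2, 252.3, 12, 2, 39.5, 2, 2),
    ("LTG", "A", 100.0, 5.70, 2.5, 90.7, 256.1, 12, 2, 37.0, 2, 5),
    ("TRA", "A", 100.0, 6.70, 2.6, 42.4, 371.9, 15, 3, 49.8, 0, 6),
    ("RAN", "A", 100.0, 7.20, 2.8, 62.2, 427.5, 12, 2, 52.6, 2, 6),
    ("LID", "A", 300.0, 7.75, 2.2, 32.3, 234.3, 6, 1, 34.1, 1, 2),
    ("FLE", "B", 300.0, 9.61, 3.8, 59.6, 414.3, 6, 1, 64.8, 2, 6),
    ("BUP", "B", 100.0, 8.10, 3.6, 32.3, 288.4, 6, 1, 61.7, 1, 2),
    ("AMI", "C", 30.0, 9.40, 4.8, 3.2, 277.4, 12, 2, 48.0, 0, 1),
    ("IMI", "C", 30.0, 9.50, 4.4, 6.5, 280.4, 12, 2, 48.9, 0, 2),
    ("DMI", "C", 30.0, 10.20, 3.9, 15.3, 266.4, 12, 2, 47.3, 1, 2),
    ("FLX", "C", 30.0, 9.80, 4.2, 21.3, 309.3, 12, 2, 43.7, 1, 2),
    ("SER", "C", 10.0, 9.50, 5.1, 12.0, 306.2, 12, 2, 44.9, 1, 1),
    ("PRX", "C", 30.0, 9.90, 3.5, 39.7, 329.4, 12, 2, 45.6, 1, 4),
    ("VEN", "D", 100.0, 8.90, 2.7, 33.9, 277.4, 6, 1, 45.2, 1, 3),
    ("MIR", "D", 100.0, 7.80, 3.2, 20.6, 265.4, 12, 2, 42.8, 0, 3),
    ("RIT", "E", 10.0, 7.60, 5.31, 50.2, 477.6, 21, 4, 66.9, 1, 4),
    ("NFZ", "E", 30.0, 6.90, 4.7, 57.0, 470.0, 17, 3, 75.1, 0, 6),
    ("HAL", "F", 10.0, 8.30, 3.9, 40.5, 375.9, 12, 2, 51.2, 1, 3),
    ("NIS", "F", 30.0, 9.60, 3.14, 21.3, 271.4, 12, 2, 44.0, 1, 3),
    ("CLO", "F", 30.0, 7.90, 3.7, 30.9, 326.8, 15, 3, 50.3, 1, 4),
    ("MEX", "F", 100.0, 9.00, 2.2, 35.3, 179.3, 6, 1, 33.8, 1, 2),
    ("MEM", "F", 100.0, 10.27, 3.3, 26.0, 179.3, 0, 0, 36.5, 1, 1),
    ("SIL", "F", 100.0, 7.90, 2.5, 23.5, 273.8, 6, 1, 40.7, 0, 2),
    ("TOL", "F", 100.0, 7.50, 2.9, 23.5, 245.4, 6, 1, 41.9, 0, 2),
    ("AMB", "G", 100.0, 8.80, 2.7, 58.3, 378.1, 6, 1, 43.4, 3, 3),
    ("MAP", "G", 30.0, 10.50, 4.5, 12.0, 277.4, 12, 2, 46.1, 1, 1),
    ("MIA", "G", 30.0, 7.40, 3.6, 6.5, 264.4, 12, 2, 43.1, 0, 2),
    ("CPZ", "G", 30.0, 9.30, 5.2, 31.8, 318.9, 13, 2, 47.8, 0, 3),
    ("RIL", "G", 100.0, 5.90, 3.2, 48.2, 234.2, 9, 2, 36.9, 1, 4),
]


def fixture_descriptor_table() -> pd.DataFrame:
    """Synthetic descriptor table for the 30-compound fixture cohort."""
    df = pd.DataFrame(
        _FIXTURE_ROWS,
        columns=[
            "drug", "class", "conc_uM", "pKa", "logP", "PSA", "MW",
            "AAC", "ARC", "minProj", "HBD", "HBA",
        ],
    )
    # distribution coefficients of a monoprotic base from logP and pKa
    for ph in (6.0, 7.3, 8.6):
        df[f"logD_{ph}"] = df["logP"] + np.log10(
            [fraction_neutral(ph, pka) for pka in df["pKa"]]
        )
    cols = [
        "drug", "conc_uM", "pKa", "logP", "logD_6.0", "logD_7.3", "logD_8.6",
        "PSA", "MW", "AAC", "ARC", "minProj", "HBD", "HBA", "class",
    ]
    return df[cols]


#: residual access of the charged species through the hydrophilic pathway.
#: Zero for the fixture cohort: the apparent pH-dependence of hydrophilic-trap
#: compounds is kinetic (deprotonation-limited access), and a charged-form
#: shortcut would let their acidic block reach its pH-independent equilibrium
CHARGED_ACCESS = 0.0


def _inhibition_target(i: int) -> float:
    # deterministic spread of single-concentration inhibitions over 0.45-0.70
    return 0.45 + 0.25 * ((i * 7) % 13) / 12.0


def fixture_drug_configs(table: pd.DataFrame | None = None) -> list[SimDrugConfig]:
    """Simulator parameter sets for the fixture cohort, derived from descriptors."""
    table = fixture_descriptor_table() if table is None else table
    configs = []
    for i, row in table.reset_index(drop=True).iterrows():
        lipo_weight = float(np.clip(1.0 / (1.0 + 10 ** (0.8 * (3.0 - row["logP"]))), 0.02, 0.98))
        k_exit_lipo = 0.05 * 10 ** (-row["AAC"] / 18.0)
        k_exit_hydro = 0.15 * 10 ** (-row["PSA"] / 120.0)
        seq = 0.9 if (row["logP"] > 4.5 and row["AAC"] >= 15) else 0.0
        charged_access = CHARGED_ACCESS
        inh = _inhibition_target(i)
        kd = row["conc_uM"] * (1.0 - inh) / inh
        k_entry = calibrate_k_entry(
            row["pKa"], row["conc_uM"], kd, lipo_weight, k_exit_hydro, k_exit_lipo,
            seq, charged_access,
        )
        configs.append(
            SimDrugConfig(
                drug_code=str(row["drug"]),
                conc=float(row["conc_uM"]),
                pKa=float(row["pKa"]),
                k_entry=k_entry,
                k_exit_lipo=k_exit_lipo,
                k_exit_hydro=k_exit_hydro,
                lipo_weight=lipo_weight,
                kd_site=kd,
                seq=seq,
                charged_access=charged_access,
                class_label=str(row["class"]) if "class" in row.index else None,
            )
        )
    return configs
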