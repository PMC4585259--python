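"""Physicochemical descriptors and Henderson-Hasselbalch transforms.

Descriptors (pKa, logP, logD at the three working pH values, PSA, MW,
aromatic atom/ring counts, minimal projection area, H-bond donor/acceptor
counts) are *inputs* to the analysis, never computed from structures here.
The module adds the derived ionization transforms used throughout the
correlation analyses: the percentage of neutral (deprotonated) form of a
monoprotic base at a given pH,

    N(pKa) = 100 * 10^pH / (10^pH + 10^pKa),

its base-10 logarithm, and the polarity-per-size ratio PSA/MW.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import RangeError

DERIVED_COLUMNS = ("N_pKa", "logN_pKa", "PSA_over_MW")


def _check_ph_scale(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 14)):
        raise RangeError(f"{name} outside [0, 14]")
    return arr


def fraction_neutral(pH, pKa):
    """Fraction (0-1 scale) of a monoprotic base in its neutral form.

    Strictly increasing in pH and strictly decreasing in pKa; equals 0.5 at
    pH == pKa.
    """
    pH = _check_ph_scale(pH, "pH")
    pKa = _check_ph_scale(pKa, "pKa")
    # 10^pH/(10^pH+10^pKa) rewritten for numerical symmetry
    out = 1.0 / (1.0 + np.power(10.0, pKa - pH))
    return out if out.ndim else float(out)


def n_pka(pKa, pH=7.3):
    """Percentage of the neutral form at ``pH`` (default 7.3): 100 x fraction_neutral."""
    return 100.0 * fraction_neutral(pH, pKa)


def derive_transforms(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns N_pKa, logN_pKa and PSA_over_MW (idempotent)."""
    out = table.copy()
    out["N_pKa"] = n_pka(out["pKa"].to_numpy())
    out["logN_pKa"] = np.log10(out["N_pKa"])
    out["PSA_over_MW"] = out["PSA"] / out["MW"]
    return out


def sanity_check_logp(table: pd.DataFrame, tolerance: float = 1.5) -> list[str]:
    """Optionally compare supplied logP with a Crippen estimate; warn, never fail.

    Requires a 'smiles' column and rdkit; silently returns an empty list when
    either is unavailable.  Returns the list of drugs whose |delta logP|
    exceeds ``tolerance``.
    """
    if "smiles" not in table.columns:
        return []
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen
    except ImportError:  # pragma: no cover - rdkit optional
        return []
    flagged = []
    for _, row in table.iterrows():
        mol = Chem.MolFromSmiles(row["smiles"])
        if mol is None:
            continue
        delta = abs(Crippen.MolLogP(mol) - row["logP"])
        if delta > tolerance:
            flagged.append(str(row["drug"]))
            warnings.warn(
                f"{row['drug']}: supplied logP differs from Crippen estimate by {delta:.2f}",
                stacklevel=2,
            )
    return flagged
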