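"""Protein physicochemical profiling (ExPASy-style).

Molecular weight (average residue masses + one water), GRAVY (mean
Kyte-Doolittle hydropathy), the Guruprasad instability index, and the
theoretical isoelectric point.  The tables behind these statistics are the
published ExPASy/ProtParam tables as shipped with Biopython; the pI is found
by bisection on the Henderson-Hasselbalch net-charge curve (Bjellqvist pKa
set) and is refined until the residual net charge is below 1e-6, well inside
the 1e-4 contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import IsoelectricPoint

from .errors import ValidationError
from .records import check_protein

PI_CHARGE_TOL = 1e-6
INSTABILITY_THRESHOLD = 40.0


@dataclass
class PhyschemProfile:
    """ExPASy-style summary statistics for one protein."""

    length_aa: int
    mw_da: float
    pi: float
    gravy: float
    instability_index: float      # NaN for length-1 peptides (undefined)
    n_negative: int               # Asp + Glu
    n_positive: int               # Arg + Lys
    stability_class: str          # stable / unstable / undefined
    acid_base_class: str          # acidic / alkalescent


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (Bjellqvist pKa)."""
    seq = check_protein(seq)
    ip = IsoelectricPoint.IsoelectricPoint(seq)
    return ip.charge_at_pH(ph)


def isoelectric_point(seq: str, tol: float = PI_CHARGE_TOL) -> float:
    """pI by bisection on [0, 14]; the charge curve is strictly decreasing."""
    seq = check_protein(seq)
    ip = IsoelectricPoint.IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = ip.charge_at_pH(mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem_profile(seq: str) -> PhyschemProfile:
    """Full physicochemical profile of one protein sequence."""
    seq = check_protein(seq)
    if not seq:
        raise ValidationError("empty protein sequence")
    analysis = ProteinAnalysis(seq)
    mw = analysis.molecular_weight()
    gravy = analysis.gravy()
    if len(seq) >= 2:
        instability = analysis.instability_index()
        stability = ("unstable" if instability > INSTABILITY_THRESHOLD
                     else "stable")
    else:
        instability = math.nan
        stability = "undefined"
    pi = isoelectric_point(seq)
    return PhyschemProfile(
        length_aa=len(seq),
        mw_da=mw,
        pi=pi,
        gravy=gravy,
        instability_index=instability,
        n_negative=seq.count("D") + seq.count("E"),
        n_positive=seq.count("R") + seq.count("K"),
        stability_class=stability,
        acid_base_class="acidic" if pi < 7.0 else "alkalescent",
    )


def profile_table(records):
    """TSV-ready DataFrame of profiles for a list of ProteinRecord."""
    import pandas as pd

    rows = []
    for rec in records:
        p = physchem_profile(rec.seq)
        rows.append({
            "id": rec.id, "length_aa": p.length_aa,
            "mw_da": round(p.mw_da, 2), "pi": round(p.pi, 2),
            "n_negative": p.n_negative, "n_positive": p.n_positive,
            "gravy": round(p.gravy, 3),
            "instability_index": round(p.instability_index, 2)
            if math.isfinite(p.instability_index) else math.nan,
            "stability_class": p.stability_class,
            "acid_base_class": p.acid_base_class,
        })
    return pd.DataFrame(rows)
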