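"""Count normalisation, stage contrasts, correlations, and qPCR ratios.

Per-biotype normalisation follows the conventions used for the four RNA
classes: FPKM for mRNA and lncRNA, TPM for miRNA, and RPM (back-splice
junction reads per million) for circRNA.  Stage contrasts are expressed as
log2 fold changes of stage means and are binned into the categorical fold
classes Up/Down A-D: linear fold in (1, 2], (2, 5], (5, 10], and > 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

METHODS = ("FPKM", "TPM", "RPM")

#: default normalisation method per biotype
BIOTYPE_METHOD = {
    "mrna": "FPKM",
    "lncrna": "FPKM",
    "circrna": "RPM",
    "mirna": "TPM",
}

FOLD_BINS = (("A", 1.0, 2.0), ("B", 2.0, 5.0), ("C", 5.0, 10.0),
             ("D", 10.0, math.inf))


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with stage/replicate labels.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample named ``<stage>_<replicate>``.  ``features`` carries ``biotype``
    and ``length_bp`` per feature; ``library_size`` maps sample -> depth.
    For circRNAs the stored counts are back-splice junction read counts.
    """

    counts: pd.DataFrame
    features: pd.DataFrame  # index: feature id; columns: biotype, length_bp
    stages: List[str]
    library_size: Optional[pd.Series] = None

    def __post_init__(self):
        if not self.counts.index.equals(self.features.index):
            raise ValidationError("counts and features indices differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if (self.features["length_bp"] < 1).any():
            raise ValidationError("feature lengths must be >= 1")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        if (self.library_size <= 0).any():
            raise ValidationError("library sizes must be positive")
        if (self.library_size < self.counts.sum(axis=0) - 1e-9).any():
            raise ValidationError("library size below assigned counts")

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def sample_stage(self, sample: str) -> str:
        stage = sample.rsplit("_", 1)[0]
        if stage not in self.stages:
            raise ValidationError(f"sample {sample!r} has unknown stage")
        return stage

    def subset(self, biotype: str) -> "CountMatrix":
        mask = self.features["biotype"] == biotype
        return CountMatrix(self.counts.loc[mask], self.features.loc[mask],
                           self.stages, self.library_size)


@dataclass
class NormalizedMatrix:
    """Normalised expression values with the same layout as CountMatrix."""

    values: pd.DataFrame
    features: pd.DataFrame
    stages: List[str]
    method: str

    def stage_means(self) -> pd.DataFrame:
        """Features x stages matrix of replicate means (stage order kept)."""
        groups = {}
        for stage in self.stages:
            cols = [c for c in self.values.columns
                    if c.rsplit("_", 1)[0] == stage]
            if not cols:
                raise ValidationError(f"no samples for stage {stage!r}")
            groups[stage] = self.values[cols].mean(axis=1)
        return pd.DataFrame(groups, columns=self.stages)


def normalize(counts: CountMatrix, method: str) -> NormalizedMatrix:
    """Normalise a count matrix by FPKM, TPM, or RPM.

    FPKM = c * 1e9 / (N * L);  TPM = (c/L) / sum(c/L) * 1e6 (per sample);
    RPM = j * 1e6 / N with j the junction count.  N is the per-sample
    library size and L the feature length in bp.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown normalisation method {method!r}")
    c = counts.counts.to_numpy(dtype=float)
    L = counts.features["length_bp"].to_numpy(dtype=float)[:, None]
    N = counts.library_size.reindex(counts.counts.columns).to_numpy(float)
    if (N <= 0).any():
        raise ValidationError("zero library size")
    if method == "FPKM":
        vals = c * 1e9 / (N[None, :] * L)
    elif method == "TPM":
        rate = c / L
        total = rate.sum(axis=0)
        if (total <= 0).any():
            raise ValidationError("zero total rate in a TPM column")
        vals = rate / total[None, :] * 1e6
    else:  # RPM
        vals = c * 1e6 / N[None, :]
    values = pd.DataFrame(vals, index=counts.counts.index,
                          columns=counts.counts.columns)
    return NormalizedMatrix(values, counts.features, counts.stages, method)


def normalize_by_biotype(
    counts: CountMatrix,
    method_map: Dict[str, str] = BIOTYPE_METHOD,
) -> Dict[str, NormalizedMatrix]:
    """Normalise each biotype with its conventional method."""
    out = {}
    for biotype, method in method_map.items():
        sub = counts.subset(biotype)
        if len(sub.counts):
            out[biotype] = normalize(sub, method)
    return out


def fold_bin(log2fc: float) -> str:
    """Categorical fold class from a log2 fold change.

    Returns 'none' inside the flat band (linear fold exactly 1), otherwise
    A/B/C/D from the half-open linear-fold intervals (1,2], (2,5], (5,10],
    (10, inf).
    """
    if abs(log2fc) < 1e-12:
        return "none"
    fold = 2.0 ** abs(log2fc)
    for name, lo, hi in FOLD_BINS:
        if lo < fold <= hi:
            return name
    return "none"


def contrast(
    normalized: NormalizedMatrix,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Stage contrast ``stage_a / stage_b`` as log2 fold changes.

    Returns a DataFrame (feature, contrast, log2fc, direction, fold_bin);
    log2fc = log2((mean_a + eps) / (mean_b + eps)) over replicate means.
    """
    for stage in (stage_a, stage_b):
        if stage not in normalized.stages:
            raise ValidationError(f"unknown stage label {stage!r}")
    means = normalized.stage_means()
    a = means[stage_a].to_numpy() + pseudocount
    b = means[stage_b].to_numpy() + pseudocount
    if (a <= 0).any() or (b <= 0).any():
        raise ValidationError("non-positive mean + pseudocount in contrast")
    lfc = np.log2(a / b)
    rows = []
    label = f"{stage_a}/{stage_b}"
    for feat, value in zip(means.index, lfc):
        if abs(value) < 1e-12:
            direction = "flat"
        else:
            direction = "up" if value > 0 else "down"
        rows.append({
            "feature": feat, "contrast": label, "log2fc": float(value),
            "direction": direction, "fold_bin": fold_bin(float(value)),
        })
    return pd.DataFrame(rows)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (flagged undefined) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("correlation inputs differ in length")
    if x.size < 3:
        raise ValidationError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def ddct_ratio(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Comparative-Ct relative expression, 2**(-ddCt).

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator).
    """
    for value in (ct_target_sample, ct_ref_sample,
                  ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(value):
            raise ValidationError("Ct values must be finite")
    ddct = ((ct_target_sample - ct_ref_sample)
            - (ct_target_calibrator - ct_ref_calibrator))
    return 2.0 ** (-ddct)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    table = counts.features.copy()
    table.insert(0, "feature_id", table.index)
    out = pd.concat([table.reset_index(drop=True),
                     counts.counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, stages: Sequence[str]) -> CountMatrix:
    table = pd.read_csv(path, sep="\t")
    meta_cols = ["feature_id", "biotype", "length_bp"]
    for col in meta_cols:
        if col not in table.columns:
            raise ValidationError(f"counts table missing column {col!r}")
    table = table.set_index("feature_id")
    sample_cols = [c for c in table.columns if c not in ("biotype",
                                                         "length_bp")]
    counts = table[sample_cols].astype(int)
    features = table[["biotype", "length_bp"]]
    return CountMatrix(counts, features, list(stages))
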