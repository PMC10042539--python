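"""Small reporter quantifications: qPCR knockdown and ERK-KTR translocation.

``percent_knockdown`` implements the Livak relative-quantification method:
per condition, the cycle threshold of the target gene is referenced to a
housekeeping gene (dCT = CT_target - CT_reference, technical replicates
averaged first); ddCT = dCT_treated - dCT_control; percent knockdown is
(1 - 2**-ddCT) * 100.

``ktr_ratio_series`` converts nuclear/cytoplasmic mean fluorescence
intensities of a kinase translocation reporter into a cytoplasm:nucleus
ratio time series normalized to 1 at the first time point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["percent_knockdown", "knockdown_summary", "ktr_ratio_series"]

CT_COLUMNS = ("sample", "condition", "gene", "ct")


def _delta_ct(
    table: pd.DataFrame,
    condition: str,
    target_gene: str,
    reference_gene: str,
    convention: str,
) -> pd.Series:
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise InputError(f"condition {condition!r} absent from CT table")
    means = (
        sub.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    )
    for gene in (target_gene, reference_gene):
        if gene not in means.columns or means[gene].isna().any():
            raise InputError(f"gene {gene!r} missing for condition {condition!r}")
    d = means[target_gene] - means[reference_gene]
    return -d if convention == "reference_minus_target" else d


def _validate_ct(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"CT table missing columns {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise InputError("CT values must be finite and positive")


def percent_knockdown(
    table: pd.DataFrame,
    target_gene: str = "target",
    reference_gene: str = "reference",
    control: str = "control",
    treated: str = "treated",
    convention: str = "target_minus_reference",
) -> float:
    """Mean percent knockdown (1 - 2**-ddCT) * 100 across biological samples.

    Technical replicates (rows sharing sample/condition/gene) are averaged
    before dCT is formed.  When the same sample names appear in both
    conditions, ddCT is computed per sample and the per-sample knockdowns
    averaged; otherwise condition-mean dCTs are differenced.  The default
    convention is the standard Livak dCT = CT_target - CT_reference;
    ``convention="reference_minus_target"`` flips the sign.
    """
    _validate_ct(table)
    d_ctrl = _delta_ct(table, control, target_gene, reference_gene, convention)
    d_trt = _delta_ct(table, treated, target_gene, reference_gene, convention)
    common = d_ctrl.index.intersection(d_trt.index)
    if len(common) > 0:
        ddct = (d_trt.loc[common] - d_ctrl.loc[common]).to_numpy()
    else:
        ddct = np.array([d_trt.mean() - d_ctrl.mean()])
    kd = (1.0 - 2.0 ** (-ddct)) * 100.0
    return float(kd.mean())


def knockdown_summary(table: pd.DataFrame, **kwargs) -> dict[str, float]:
    """Per-sample knockdown mean and SEM (falls back to SEM 0 for one sample)."""
    _validate_ct(table)
    conv = kwargs.pop("convention", "target_minus_reference")
    d_ctrl = _delta_ct(table, kwargs.pop("control", "control"),
                       kwargs.get("target_gene", "target"),
                       kwargs.get("reference_gene", "reference"), conv)
    d_trt = _delta_ct(table, kwargs.pop("treated", "treated"),
                      kwargs.get("target_gene", "target"),
                      kwargs.get("reference_gene", "reference"), conv)
    common = d_ctrl.index.intersection(d_trt.index)
    if len(common) > 0:
        kd = (1.0 - 2.0 ** (-(d_trt.loc[common] - d_ctrl.loc[common]))) * 100.0
        kd = kd.to_numpy()
    else:
        kd = np.array([(1.0 - 2.0 ** (-(d_trt.mean() - d_ctrl.mean()))) * 100.0])
    sem = float(kd.std(ddof=1) / np.sqrt(kd.size)) if kd.size > 1 else 0.0
    return {"mean_percent_knockdown": float(kd.mean()), "sem": sem, "n": int(kd.size)}


def ktr_ratio_series(series: pd.DataFrame) -> pd.Series:
    """Cytoplasm:nucleus MFI ratio per time point, normalized to 1 at t0.

    ``series`` needs columns ``time_min``, ``nuc_mfi`` and ``cyto_mfi``;
    rows are sorted by time and the first row defines the normalization.
    """
    for col in ("time_min", "nuc_mfi", "cyto_mfi"):
        if col not in series.columns:
            raise InputError(f"KTR series missing column {col!r}")
    if series.empty:
        raise InputError("KTR series is empty")
    s = series.sort_values("time_min")
    nuc = s["nuc_mfi"].to_numpy(dtype=float)
    if np.any(nuc <= 0):
        raise InputError("nuclear MFI must be positive at every time point")
    ratio = s["cyto_mfi"].to_numpy(dtype=float) / nuc
    return pd.Series(ratio / ratio[0], index=s["time_min"].to_numpy(), name="cn_ratio")
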