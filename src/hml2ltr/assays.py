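"""Quantification of dual-luciferase, RT-qPCR and ChIP-qPCR readouts.

Implements the normalized fold change used for reporter assays — the mean
firefly/Renilla ratio of a construct under a stimulus divided by the mean
ratio of the empty vector in plain medium (the denominator is always the
medium condition) — the 2^−ΔΔCT relative-expression method normalized to a
reference gene, a ΔΔCT-style fold enrichment over a negative-control probe
for ChIP-qPCR, and the one-way ANOVA used for group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEDIUM = "medium"


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    required = {"construct", "stimulus", "replicate", "firefly", "renilla"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if (plate["renilla"] <= 0).any():
        raise ValueError("renilla readings must be positive")
    return plate


def normalized_fold_change(plate: pd.DataFrame, construct: str, stimulus: str,
                           empty_vector_id: str = "empty") -> float:
    """Mean F/R of (construct, stimulus) over mean F/R of the empty vector
    in plain medium.

    Replicates are aggregated as the arithmetic mean of per-well F/R
    ratios.  The denominator is always the empty vector in the medium
    condition, regardless of the stimulus in the numerator.
    """
    plate = _check_plate(plate)
    num = plate[(plate["construct"] == construct)
                & (plate["stimulus"] == stimulus)]
    den = plate[(plate["construct"] == empty_vector_id)
                & (plate["stimulus"] == MEDIUM)]
    if num.empty:
        raise ValueError(f"no wells for ({construct!r}, {stimulus!r})")
    if den.empty:
        raise ValueError(
            f"no empty-vector ({empty_vector_id!r}) wells in medium")
    den_mean = (den["firefly"] / den["renilla"]).mean()
    if den_mean <= 0:
        raise ValueError("empty-vector mean ratio is non-positive")
    return float((num["firefly"] / num["renilla"]).mean() / den_mean)


def _mean_ct(data: pd.DataFrame, sample: str, gene: str) -> float:
    sub = data[(data["sample"] == sample) & (data["gene"] == gene)]
    if sub.empty:
        raise ValueError(f"no CT values for sample {sample!r}, gene {gene!r}")
    return float(sub["ct"].mean())


def ddct_fold(data: pd.DataFrame, target_gene: str, ref_gene: str,
              treated: str, control: str) -> float:
    """Relative expression by the 2^−ΔΔCT method.

    ΔCT = mean CT(target) − mean CT(reference) per sample;
    ΔΔCT = ΔCT(treated) − ΔCT(control); returns 2^−ΔΔCT.
    """
    d_treated = _mean_ct(data, treated, target_gene) - _mean_ct(data, treated, ref_gene)
    d_control = _mean_ct(data, control, target_gene) - _mean_ct(data, control, ref_gene)
    return float(2.0 ** -(d_treated - d_control))


def chip_relative_enrichment(data: pd.DataFrame, target_probe: str,
                             nc_probe: str, ip_sample: str,
                             input_sample: str,
                             method: str = "ddct") -> float:
    """ChIP-qPCR enrichment of the target probe over the negative control.

    Default (``ddct``): 2^−[(CT_IP − CT_input)_target − (CT_IP − CT_input)_NC].
    ``percent_input`` returns the target probe's 2^−(CT_IP − CT_input) × 100
    without NC normalization.
    """
    dct_target = (_mean_ct(data, ip_sample, target_probe)
                  - _mean_ct(data, input_sample, target_probe))
    if method == "percent_input":
        return float(100.0 * 2.0 ** -dct_target)
    if method != "ddct":
        raise ValueError(f"unknown method {method!r}")
    dct_nc = (_mean_ct(data, ip_sample, nc_probe)
              - _mean_ct(data, input_sample, nc_probe))
    return float(2.0 ** -(dct_target - dct_nc))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    below_epsilon: bool = False


def one_way_anova(groups: list[np.ndarray | list[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA across replicate groups.

    The degenerate case of zero within-group variance with unequal means
    is reported as F = inf with ``below_epsilon`` set and p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    grand = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means_equal = np.allclose([a.mean() for a in arrays],
                              arrays[0].mean())
    if ssw == 0.0 and not means_equal:
        return AnovaResult(F=float("inf"), df_between=df1, df_within=df2,
                           p=0.0, below_epsilon=True)
    if np.allclose(grand, grand[0]):
        return AnovaResult(F=0.0, df_between=df1, df_within=df2, p=1.0)
    F, p = stats.f_oneway(*arrays)
    return AnovaResult(F=float(F), df_between=df1, df_within=df2, p=float(p))


def read_plate_tsv(path) -> pd.DataFrame:
    return _check_plate(pd.read_csv(path, sep="\t"))


def read_qpcr_tsv(path) -> pd.DataFrame:
    data = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if ((data["ct"] <= 0) | (data["ct"] >= 45)).any():
        raise ValueError("CT values must lie in (0, 45)")
    return data
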