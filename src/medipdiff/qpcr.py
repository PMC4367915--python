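"""Relative expression by the 2^-ddCt method.

dCt = mean Ct(target) - mean Ct(reference) per sample; ddCt is the sample's
dCt minus the calibrator's; relative expression is 2^(-ddCt). Replicate Ct
values are averaged before differencing and the standard error of the fold
is propagated from replicate variances by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


@dataclass
class DdctResult:
    fold: float
    ddct: float
    se_fold: float


def validate_ct_table(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Check the Ct table contract: columns, positive Ct, reference coverage."""
    missing = {"sample", "gene", "ct"} - set(table.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    for sample in table["sample"].unique():
        genes = set(table.loc[table["sample"] == sample, "gene"])
        if reference not in genes:
            raise ValidationError(
                f"reference gene {reference!r} missing in sample {sample!r}"
            )
    return table


def _cell_stats(table: pd.DataFrame, sample: str, gene: str) -> tuple[float, float]:
    """Mean Ct and variance of the mean for one (sample, gene) cell."""
    cts = table.loc[
        (table["sample"] == sample) & (table["gene"] == gene), "ct"
    ].to_numpy(dtype=float)
    if len(cts) == 0:
        raise ValidationError(f"no Ct for gene {gene!r} in sample {sample!r}")
    var_mean = cts.var(ddof=1) / len(cts) if len(cts) > 1 else 0.0
    return float(cts.mean()), float(var_mean)


def ddct(
    table: pd.DataFrame,
    target: str,
    sample: str,
    calibrator: str,
    reference: str = "actin1",
) -> DdctResult:
    """Relative expression fold of ``target`` in ``sample`` vs ``calibrator``.

    Returns 2^(-ddCt) with a delta-method standard error pooled over the
    four (sample, gene) replicate groups. The calibrator against itself
    gives fold = 1 exactly, and a global Ct shift leaves the fold unchanged.
    """
    validate_ct_table(table, reference)
    m_ts, v_ts = _cell_stats(table, sample, target)
    m_rs, v_rs = _cell_stats(table, sample, reference)
    m_tc, v_tc = _cell_stats(table, calibrator, target)
    m_rc, v_rc = _cell_stats(table, calibrator, reference)

    dct_sample = m_ts - m_rs
    dct_cal = m_tc - m_rc
    ddct_val = dct_sample - dct_cal
    fold = float(2.0 ** (-ddct_val))
    if sample == calibrator:
        var_ddct = 0.0
    else:
        var_ddct = v_ts + v_rs + v_tc + v_rc
    se_fold = fold * np.log(2.0) * np.sqrt(var_ddct)
    return DdctResult(fold=fold, ddct=float(ddct_val), se_fold=float(se_fold))
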