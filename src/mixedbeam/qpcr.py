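"""Relative qPCR quantification: Ct aggregation, ddCt and net 2^-dCt levels.

Technical-replicate Ct values are averaged per (sample, target); dCt is the
mean target Ct minus the mean reference (18S) Ct; the net transcript level
is 2^-dCt and the fold change versus the matched 0 Gy control of the same
(donor, season, week) block is 2^-ddCt.  No amplification-efficiency
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .study import REFERENCE_TARGET, CtRecord, ct_records_to_frame

#: Replicate-scatter QC threshold in cycles; a flag only, never an exclusion.
CT_QC_SD_THRESHOLD = 0.5


@dataclass(frozen=True)
class NetLevel:
    """Reference-normalised transcript level of one sample/target."""

    delta_ct: float
    net_level: float
    qc_flag: bool


@dataclass(frozen=True)
class FoldChange:
    """Expression relative to the matched 0 Gy control (2^-ddCt)."""

    ddct: float
    fold: float


def aggregate_ct(replicate_cts: Sequence[float]) -> tuple[float, bool]:
    """Mean Ct over technical replicates plus a scatter QC flag.

    The flag is raised when the replicate sample standard deviation exceeds
    0.5 cycles; the mean is returned regardless.
    """
    cts = [float(c) for c in replicate_cts]
    if not cts:
        raise ValueError("no Ct replicates to aggregate")
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct replicate")
    mean = float(np.mean(cts))
    sd = float(np.std(cts, ddof=1)) if len(cts) > 1 else 0.0
    return mean, sd > CT_QC_SD_THRESHOLD


def delta_ct(mean_ct_target: float, mean_ct_reference: float, qc_flag: bool = False) -> NetLevel:
    """dCt = target - reference; net level = 2^-dCt."""
    if not (math.isfinite(mean_ct_target) and math.isfinite(mean_ct_reference)):
        raise ValueError("Ct values must be finite")
    d = mean_ct_target - mean_ct_reference
    return NetLevel(delta_ct=d, net_level=2.0 ** (-d), qc_flag=qc_flag)


def fold_change(delta_ct_treated: float, delta_ct_control: float) -> FoldChange:
    """ddCt = dCt_treated - dCt_control; fold = 2^-ddCt."""
    if not (math.isfinite(delta_ct_treated) and math.isfinite(delta_ct_control)):
        raise ValueError("dCt values must be finite")
    dd = delta_ct_treated - delta_ct_control
    return FoldChange(ddct=dd, fold=2.0 ** (-dd))


SAMPLE_KEYS = ["donor", "season", "week", "radiation", "dose_gy"]
BLOCK_KEYS = ["donor", "season", "week"]


class MissingControlError(ValueError):
    """A (donor, season, week) block lacks its 0 Gy control for a target."""


def net_levels(ct: pd.DataFrame | Iterable[CtRecord]) -> pd.DataFrame:
    """Per-sample, per-target mean Ct, dCt and net 2^-dCt level.

    Accepts a long-format Ct frame (see study.CT_COLUMNS) or CtRecords.
    Returns one row per (donor, season, week, radiation, dose_gy, target)
    excluding the reference target, with columns mean_ct, ref_ct, delta_ct,
    net_level, qc_flag.
    """
    if not isinstance(ct, pd.DataFrame):
        ct = ct_records_to_frame(ct)
    if ct.empty:
        return pd.DataFrame(columns=SAMPLE_KEYS + ["target", "mean_ct", "ref_ct", "delta_ct", "net_level", "qc_flag"])

    agg = (
        ct.groupby(SAMPLE_KEYS + ["target"], sort=False)["ct"]
        .agg(mean_ct="mean", ct_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    agg["qc_flag"] = agg["ct_sd"].fillna(0.0) > CT_QC_SD_THRESHOLD

    ref = agg[agg["target"] == REFERENCE_TARGET][SAMPLE_KEYS + ["mean_ct", "qc_flag"]].rename(
        columns={"mean_ct": "ref_ct", "qc_flag": "ref_qc_flag"}
    )
    goi = agg[agg["target"] != REFERENCE_TARGET]
    merged = goi.merge(ref, on=SAMPLE_KEYS, how="left", validate="many_to_one")
    if merged["ref_ct"].isna().any():
        bad = merged.loc[merged["ref_ct"].isna(), SAMPLE_KEYS].drop_duplicates()
        raise MissingControlError(
            f"reference target {REFERENCE_TARGET} missing for samples:\n{bad.to_string(index=False)}"
        )
    merged["delta_ct"] = merged["mean_ct"] - merged["ref_ct"]
    merged["net_level"] = 2.0 ** (-merged["delta_ct"])
    merged["qc_flag"] = merged["qc_flag"] | merged["ref_qc_flag"]
    return merged[SAMPLE_KEYS + ["target", "mean_ct", "ref_ct", "delta_ct", "net_level", "qc_flag"]]


def fold_changes(ct: pd.DataFrame | Iterable[CtRecord]) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold change versus the block's 0 Gy control.

    The control dCt for each (donor, season, week, target) is the dCt of
    that block's control sample; every sample of the block (including the
    control itself, whose fold is exactly 1) is referenced to it.  Raises
    MissingControlError naming the block when no control is present.
    """
    nl = net_levels(ct)
    if nl.empty:
        return nl.assign(control_delta_ct=[], ddct=[], fold=[])
    ctrl = nl[(nl["radiation"] == "control") & (nl["dose_gy"] == 0)]
    ctrl = ctrl[BLOCK_KEYS + ["target", "delta_ct"]].rename(columns={"delta_ct": "control_delta_ct"})
    merged = nl.merge(ctrl, on=BLOCK_KEYS + ["target"], how="left", validate="many_to_one")
    if merged["control_delta_ct"].isna().any():
        bad = merged.loc[merged["control_delta_ct"].isna(), BLOCK_KEYS].drop_duplicates()
        raise MissingControlError(
            f"no 0 Gy control dCt for block(s):\n{bad.to_string(index=False)}"
        )
    merged["ddct"] = merged["delta_ct"] - merged["control_delta_ct"]
    merged["fold"] = 2.0 ** (-merged["ddct"])
    return merged
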