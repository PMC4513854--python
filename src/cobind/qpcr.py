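"""Quantification arithmetic for ChIP-qPCR and RT-qPCR validation.

Implements the percent-input method for ChIP enrichment, fold enrichment
over a gene-desert control amplicon, the Livak 2^(-ddCt) relative
expression method, and the classic pooled-variance unpaired t-test with
the conventional significance stars.

Sign convention for ddCt: dCt = Ct(target) - Ct(reference) per
condition, ddCt = dCt(treated) - dCt(control), fold = 2^(-ddCt) — so a
target whose Ct drops (more product) in the treated condition yields a
fold change above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate threshold-cycle values for one (sample, target) pair."""

    sample: str
    target: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_values) < 1:
            raise ValueError("need at least one replicate Ct")
        if any(not math.isfinite(c) or c <= 0 for c in self.ct_values):
            raise ValueError("Ct values must be finite and > 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.ct_values))

    @property
    def sd(self) -> float:
        if len(self.ct_values) < 2:
            return 0.0
        return float(np.std(self.ct_values, ddof=1))

    @property
    def n(self) -> int:
        return len(self.ct_values)


@dataclass(frozen=True)
class EnrichmentResult:
    percent_input: float
    sd: float
    fold_over_control: float | None = None

    def __post_init__(self) -> None:
        if self.percent_input < 0:
            raise ValueError("percent_input must be >= 0")


def percent_input(
    ct_ip: CtMeasurement,
    ct_input: CtMeasurement,
    input_fraction: float,
) -> EnrichmentResult:
    """ChIP enrichment as percent of input chromatin.

    The input Ct is first adjusted for the dilution (log2(1/fraction)
    cycles), then percent input = 100 * 2^(adjusted input Ct - IP Ct).
    The replicate SD is propagated through the exponent by the
    first-order delta method.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted_input = ct_input.mean - math.log2(1.0 / input_fraction)
    pct = 100.0 * 2.0 ** (adjusted_input - ct_ip.mean)
    var_exponent = ct_input.sd**2 / ct_input.n + ct_ip.sd**2 / ct_ip.n
    sd = pct * _LN2 * math.sqrt(var_exponent)
    return EnrichmentResult(pct, sd)


def fold_over_control(
    target: EnrichmentResult,
    desert_control: EnrichmentResult,
) -> float:
    """Target percent-input over the gene-desert control amplicon."""
    if desert_control.percent_input <= 0:
        raise ValueError("control percent_input must be > 0")
    return target.percent_input / desert_control.percent_input


def delta_delta_ct(
    ct_target_treated: CtMeasurement,
    ct_ref_treated: CtMeasurement,
    ct_target_control: CtMeasurement,
    ct_ref_control: CtMeasurement,
) -> float:
    """Relative expression fold change by the 2^(-ddCt) method."""
    d_treated = ct_target_treated.mean - ct_ref_treated.mean
    d_control = ct_target_control.mean - ct_ref_control.mean
    ddct = d_treated - d_control
    return 2.0 ** (-ddct)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ttest_unpaired(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, str]:
    """Two-sided unpaired Student's t-test with significance stars.

    Classic pooled-variance by default; Welch's correction by flag.
    Returns (t, p, stars).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(group_a, group_b, equal_var=not welch)
    t, p = float(t), float(p)
    if math.isnan(p):  # zero variance in both groups, identical means
        t, p = 0.0, 1.0
    return t, p, significance_stars(p)
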