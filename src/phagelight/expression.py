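"""Efficiency-corrected relative expression and splicing-ratio analysis.

Implements the Pfaffl ratio
``E_target^(dCT_target) / E_ref^(dCT_ref)`` with
``dCT = mean(control CTs) - mean(treated CTs)``, a REST-style fixed
reallocation randomisation test for its significance, the splicing-assay
ratio with either the host 16S reference (between conditions) or the
unspliced isoform as calibrator (within a sample group), and the
transcriptome mean-coverage fold-change comparison (Welch t-test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import QpcrPlate

__all__ = [
    "Assay",
    "RelativeExpression",
    "CoverageComparison",
    "pfaffl_ratio",
    "rest_randomisation_test",
    "splicing_ratio",
    "coverage_fold_change",
    "group_cts",
]


@dataclass(frozen=True)
class Assay:
    """A qPCR assay with its amplification efficiency (2 = perfect doubling)."""

    assay_id: str
    efficiency: float

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.1:
            raise ValueError(
                f"assay {self.assay_id!r}: efficiency {self.efficiency} outside (1, 2.1]"
            )


@dataclass(frozen=True)
class RelativeExpression:
    target_id: str
    ratio: float
    p_value: float
    n_iterations: int
    seed: int
    delta_ct_target: float
    delta_ct_reference: float


@dataclass(frozen=True)
class CoverageComparison:
    fold_change: float
    t_statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def _mean(cts) -> float:
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise ValueError("empty CT group")
    return float(arr.mean())


def pfaffl_ratio(
    target: Assay,
    ref: Assay,
    ct_target_control,
    ct_target_treated,
    ct_ref_control,
    ct_ref_treated,
) -> float:
    """Efficiency-corrected expression ratio of treated relative to control."""
    d_target = _mean(ct_target_control) - _mean(ct_target_treated)
    d_ref = _mean(ct_ref_control) - _mean(ct_ref_treated)
    return target.efficiency**d_target / ref.efficiency**d_ref


def rest_randomisation_test(
    target: Assay,
    ref: Assay,
    ct_target_control,
    ct_target_treated,
    ct_ref_control,
    ct_ref_treated,
    n_iterations: int = 2000,
    seed: int = 0,
) -> float:
    """Fixed reallocation randomisation p-value for the Pfaffl ratio.

    Samples are reallocated between control and treated groups jointly for
    target and reference CTs (a sample's CT pair moves together), preserving
    group sizes. The statistic is |log ratio|; the two-sided p-value carries
    the (b+1)/(n+1) correction. Seeded and reproducible.
    """
    tc = np.asarray(list(ct_target_control), dtype=float)
    tt = np.asarray(list(ct_target_treated), dtype=float)
    rc = np.asarray(list(ct_ref_control), dtype=float)
    rt = np.asarray(list(ct_ref_treated), dtype=float)
    if tc.size != rc.size or tt.size != rt.size:
        raise ValueError("target and reference CT lists must pair sample-wise")
    if min(tc.size, tt.size) < 2:
        raise ValueError("need >= 2 samples per group")

    def log_ratio(a_t, b_t, a_r, b_r) -> float:
        d_t = a_t.mean() - b_t.mean()
        d_r = a_r.mean() - b_r.mean()
        return d_t * math.log(target.efficiency) - d_r * math.log(ref.efficiency)

    observed = abs(log_ratio(tc, tt, rc, rt))
    pooled_t = np.concatenate([tc, tt])
    pooled_r = np.concatenate([rc, rt])
    n_control = tc.size
    n_total = pooled_t.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_iterations):
        perm = rng.permutation(n_total)
        c, t = perm[:n_control], perm[n_control:]
        stat = abs(log_ratio(pooled_t[c], pooled_t[t], pooled_r[c], pooled_r[t]))
        if stat >= observed - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_iterations + 1)


def group_cts(plate: QpcrPlate, assay_id: str, group: str) -> list[float]:
    """CT values of an assay for samples whose sample_id starts with ``group:``.

    Sample ids follow the "condition:timepoint:replicate" convention of the
    synthetic generator; ``group`` is e.g. "HL:late".
    """
    df = plate.df
    mask = (df["assay_id"] == assay_id) & df["sample_id"].str.startswith(group + ":")
    cts = df.loc[mask, "ct"].dropna().tolist()
    if not cts:
        raise ValueError(f"no CT values for assay {assay_id!r} in group {group!r}")
    return cts


def splicing_ratio(
    plate: QpcrPlate,
    assays: dict[str, Assay],
    mode: str,
    *,
    target: str = "spliced",
    control_group: str,
    treated_group: str | None = None,
    reference_assay: str = "ref16S",
    unspliced_assay: str = "unspliced",
    n_iterations: int = 0,
    seed: int = 0,
) -> RelativeExpression:
    """Splice-isoform expression ratio under the study's calibrator scheme.

    mode="vs_reference_16S": Pfaffl ratio of the ``target`` isoform in
    ``treated_group`` relative to ``control_group``, calibrated by the host
    16S assay; optionally with a REST randomisation p-value
    (``n_iterations`` > 0).

    mode="spliced_vs_unspliced": the within-group abundance ratio of spliced
    to unspliced isoforms in ``control_group``,
    ``E_s^(-mean CT_s) / E_u^(-mean CT_u)``; the 16S wells are unused.
    """
    if mode == "vs_reference_16S":
        if treated_group is None:
            raise ValueError("vs_reference_16S mode needs a treated_group")
        t_assay, r_assay = assays[target], assays[reference_assay]
        args = (
            group_cts(plate, target, control_group),
            group_cts(plate, target, treated_group),
            group_cts(plate, reference_assay, control_group),
            group_cts(plate, reference_assay, treated_group),
        )
        ratio = pfaffl_ratio(t_assay, r_assay, *args)
        p = (
            rest_randomisation_test(t_assay, r_assay, *args, n_iterations=n_iterations, seed=seed)
            if n_iterations > 0
            else float("nan")
        )
        return RelativeExpression(
            target_id=target,
            ratio=ratio,
            p_value=p,
            n_iterations=n_iterations,
            seed=seed,
            delta_ct_target=_mean(args[0]) - _mean(args[1]),
            delta_ct_reference=_mean(args[2]) - _mean(args[3]),
        )
    if mode == "spliced_vs_unspliced":
        s_assay, u_assay = assays[target], assays[unspliced_assay]
        ct_s = _mean(group_cts(plate, target, control_group))
        ct_u = _mean(group_cts(plate, unspliced_assay, control_group))
        ratio = s_assay.efficiency ** (-ct_s) / u_assay.efficiency ** (-ct_u)
        return RelativeExpression(
            target_id=f"{target}:{unspliced_assay}",
            ratio=ratio,
            p_value=float("nan"),
            n_iterations=0,
            seed=seed,
            delta_ct_target=ct_u - ct_s,
            delta_ct_reference=float("nan"),
        )
    raise ValueError(f"unknown mode {mode!r}")


def coverage_fold_change(coverage_a, coverage_b) -> CoverageComparison:
    """Fold change and Welch two-sample t-test of per-replicate mean coverages."""
    a = np.asarray(list(coverage_a), dtype=float)
    b = np.asarray(list(coverage_b), dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if b.mean() == 0:
        raise ValueError("zero mean coverage in denominator")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: no within-group variance; equal means give t = 0
        t_stat = 0.0 if a.mean() == b.mean() else math.inf * math.copysign(1, a.mean() - b.mean())
        return CoverageComparison(
            fold_change=float(a.mean() / b.mean()),
            t_statistic=t_stat,
            df=float(a.size + b.size - 2),
            p_value=1.0 if t_stat == 0.0 else 0.0,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    num = (va / a.size + vb / b.size) ** 2
    den = (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    welch_df = num / den if den > 0 else float(a.size + b.size - 2)
    return CoverageComparison(
        fold_change=float(a.mean() / b.mean()),
        t_statistic=float(res.statistic),
        df=float(welch_df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
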