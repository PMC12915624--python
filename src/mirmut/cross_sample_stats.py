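"""Cross-sample tests: one mutated sample versus a wild-type cohort (E3-E5).

All three experiments share one engine (:func:`cohort_compare`): the
wild-type values of the same cancer type are tested against the mutated
sample's value with a one-sample t test (two-sided, df = n_wt - 1), a
z-score against the cohort mean/sd, and a Tukey-style IQR outlier rule
(beyond 1.5 IQR outside the quartiles).  The endpoints are

* Experiment 3 -- gene-level miRNA expression on the log2(RPM + 1) scale,
* Experiment 4 -- L1 distance between a sample's 10-class isomiR profile
  and the average wild-type profile (range 0..2),
* Experiment 5 -- 5p/3p strand balance B = log2((c5p + 1)/(c3p + 1)).

The call rules combine Bonferroni-corrected t p-values, the z p-value, an
effect-size floor, and (for E3/E5) the outlier flag; the Bonferroni
denominator is the number of mutations tested in the same experiment in
the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from mirmut.isomir_model import ClassProfile


@dataclass(frozen=True)
class CohortComparison:
    """One value against a wild-type cohort: t, z, and IQR-outlier verdicts."""

    mut_value: float
    n_wt: int
    wt_mean: float
    wt_sd: float
    t_stat: float
    t_p: float
    z: float
    z_p: float
    outlier: bool
    degenerate: str | None = None  # 'cohort_too_small' | 'degenerate_cohort'


def cohort_compare(wt_values: Sequence[float], mut_value: float) -> CohortComparison:
    """Compare a single mutated-sample value against its wild-type cohort.

    The one-sample t tests the wild-type values against the hypothesized
    mean ``mut_value`` (the only orientation a single mutated observation
    permits); z = (mut - mean_wt)/sd_wt with a two-sided normal p.
    """
    wt = np.asarray(wt_values, dtype=float)
    if wt.size < 3:
        return CohortComparison(mut_value, wt.size, math.nan, math.nan, math.nan,
                                math.nan, math.nan, math.nan, False, "cohort_too_small")
    mean, sd = float(wt.mean()), float(wt.std(ddof=1))
    q1, q3 = np.percentile(wt, [25, 75])
    iqr = q3 - q1
    outlier = bool(mut_value < q1 - 1.5 * iqr or mut_value > q3 + 1.5 * iqr)
    if sd == 0:
        return CohortComparison(mut_value, wt.size, mean, 0.0, math.nan, math.nan,
                                math.nan, math.nan, outlier, "degenerate_cohort")
    t_stat, t_p = stats.ttest_1samp(wt, popmean=mut_value)
    z = (mut_value - mean) / sd
    z_p = float(2.0 * stats.norm.sf(abs(z)))
    return CohortComparison(mut_value, wt.size, mean, sd, float(t_stat), float(t_p), z, z_p, outlier)


def gene_level(records) -> float:
    """Gene-level miRNA expression: total RPM of both arms, all read types
    except ambiguous-mapping reads (exclusive + nontemplate + mutated)."""
    keep = records[records["source"] != "ambiguous"]
    return float(keep["rpm"].sum())


def profile_distance(p: ClassProfile, q: ClassProfile) -> float:
    """L1 distance between two class profiles: sum of |fraction differences|.

    Ranges from 0 (identical profiles) to 2 (completely disjoint isomiR
    sets).  Requires identical class label sets.
    """
    if p.class_labels != q.class_labels:
        raise ValueError("profiles have mismatched class label sets")
    return float(np.abs(np.asarray(p.fractions) - np.asarray(q.fractions)).sum())


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum())


def strand_balance(c5p: float, c3p: float) -> float:
    """5p/3p strand balance B = log2((c5p + 1)/(c3p + 1)); antisymmetric in the arms."""
    if c5p < 0 or c3p < 0:
        raise ValueError("counts must be nonnegative")
    return math.log2((c5p + 1.0) / (c3p + 1.0))


@dataclass(frozen=True)
class Exp3Result:
    mutation_id: str
    comparison: CohortComparison
    log2fc: float
    t_p_bonf: float = math.nan
    call: str = "ns"


def exp3(wt_rpm: Sequence[float], mut_rpm: float, mutation_id: str = "") -> Exp3Result:
    """Experiment 3 core (pre-Bonferroni): gene level on the log2(RPM+1) scale.

    log2FC is the mutated sample's log level minus the mean wild-type log
    level (consistent with testing on the transformed scale).
    """
    wt_log = np.log2(np.asarray(wt_rpm, dtype=float) + 1.0)
    mut_log = math.log2(mut_rpm + 1.0)
    cmp_ = cohort_compare(wt_log, mut_log)
    log2fc = mut_log - float(wt_log.mean()) if wt_log.size else math.nan
    return Exp3Result(mutation_id, cmp_, log2fc)


@dataclass(frozen=True)
class Exp4Result:
    mutation_id: str
    arm: str
    comparison: CohortComparison
    distance: float
    t_p_bonf: float = math.nan
    call: bool = False


def exp4(
    wt_profiles: Sequence[ClassProfile], mut_profile: ClassProfile,
    mutation_id: str = "", arm: str = "",
) -> Exp4Result:
    """Experiment 4 core (pre-Bonferroni) for one arm.

    The reference profile is the arithmetic per-class mean of the wild-type
    sample profiles; the mutated sample's distance to it is compared
    against each wild-type sample's distance to the same mean (no
    leave-one-out).
    """
    labels = mut_profile.class_labels
    if any(p.class_labels != labels for p in wt_profiles):
        raise ValueError("profiles have mismatched class label sets")
    mat = np.array([p.fractions for p in wt_profiles], dtype=float)
    ref = mat.mean(axis=0)
    wt_dists = [_l1(row, ref) for row in mat]
    mut_dist = _l1(np.asarray(mut_profile.fractions), ref)
    return Exp4Result(mutation_id, arm, cohort_compare(wt_dists, mut_dist), mut_dist)


@dataclass(frozen=True)
class Exp5Result:
    mutation_id: str
    comparison: CohortComparison
    delta_f5p: float  # percentage points
    t_p_bonf: float = math.nan
    call: bool = False


def exp5(
    wt_counts: Sequence[tuple[float, float]], mut_counts: tuple[float, float],
    mutation_id: str = "", min_reads: float = 50,
) -> Exp5Result:
    """Experiment 5 core (pre-Bonferroni): strand balance of one gene.

    ``wt_counts``/``mut_counts`` are (5p, 3p) read totals per sample
    (exclusive + nontemplate + mutated reads).  Wild-type samples with
    fewer than ``min_reads`` total reads are dropped from the cohort.
    delta_f5p is the change of the 5p fraction in percentage points
    against the wild-type mean fraction.
    """
    kept = [(a, b) for a, b in wt_counts if a + b >= min_reads]
    balances = [strand_balance(a, b) for a, b in kept]
    mut_b = strand_balance(*mut_counts)
    cmp_ = cohort_compare(balances, mut_b)
    f5p_wt = [a / (a + b) for a, b in kept]
    f5p_mut = mut_counts[0] / (mut_counts[0] + mut_counts[1])
    delta = 100.0 * (f5p_mut - float(np.mean(f5p_wt))) if f5p_wt else math.nan
    return Exp5Result(mutation_id, cmp_, delta)


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m) if not math.isnan(p) else math.nan


def call_exp3(
    results: Sequence[Exp3Result], alpha: float = 0.05, min_abs_log2fc: float = 1.0,
    m: int | None = None,
) -> list[Exp3Result]:
    """Call rule: Bonferroni t p < .05, z p < .05, |log2FC| > 1, and IQR outlier."""
    m = m or len(results)
    out = []
    for r in results:
        c = r.comparison
        pb = _bonferroni(c.t_p, m)
        sig = (
            c.degenerate is None and pb < alpha and c.z_p < alpha
            and abs(r.log2fc) > min_abs_log2fc and c.outlier
        )
        call = "ns" if not sig else ("increase" if r.log2fc > 0 else "decrease")
        out.append(replace(r, t_p_bonf=pb, call=call))
    return out


def call_exp4(
    results: Sequence[Exp4Result], alpha: float = 0.05, min_distance: float = 0.2,
    m: int | None = None,
) -> list[Exp4Result]:
    """Call rule: Bonferroni t p < .05, z p < .05, and distance > 0.2."""
    m = m or len(results)
    out = []
    for r in results:
        c = r.comparison
        pb = _bonferroni(c.t_p, m)
        call = bool(c.degenerate is None and pb < alpha and c.z_p < alpha and r.distance > min_distance)
        out.append(replace(r, t_p_bonf=pb, call=call))
    return out


def call_exp5(
    results: Sequence[Exp5Result], alpha: float = 0.05, min_delta_points: float = 10.0,
    m: int | None = None,
) -> list[Exp5Result]:
    """Call rule: Bonferroni t p < .05, z p < .05, |delta f5p| > 10 points, outlier."""
    m = m or len(results)
    out = []
    for r in results:
        c = r.comparison
        call = bool(
            c.degenerate is None and _bonferroni(c.t_p, m) < alpha and c.z_p < alpha
            and abs(r.delta_f5p) > min_delta_points and c.outlier
        )
        out.append(replace(r, t_p_bonf=_bonferroni(c.t_p, m), call=call))
    return out
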