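"""Within-sample, allele-resolved tests (Experiment 1 and Experiment 2).

Both experiments exploit mutations visible at the RNA level: reads from
the mutant and wild-type alleles of the same gene in the same sample.

* Experiment 1 compares the mutant-allele fraction at the RNA level with
  the mutant-allele fraction at the DNA level (Fisher's exact test on the
  2x2 read-count table; fold change on the ratio of fractions).
* Experiment 2 compares the 9-class isomiR profiles of the two alleles
  (Pearson chi-square on the pseudocounted 2x9 table, effect size by
  Cramer's V; V is computed on the same pseudocounted table as the
  chi-square so the two statistics stay internally consistent).

``fisher_exact_2x2`` sums hypergeometric probabilities no larger than the
observed table's, using exact integer arithmetic so ties are resolved
identically on every platform; the common convention for a two-sided exact
p, matching scipy's, but with deterministic tie handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirmut.isomir_model import CLASS_LABELS_NINE

#: Cramer's V interpretation bins: none (<0.1), small, medium, large (>0.4).
V_BINS = ((0.1, "none"), (0.2, "small"), (0.4, "medium"), (math.inf, "large"))

DEFAULT_PSEUDOCOUNT = 5


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums, over the hypergeometric distribution with the observed margins,
    the probabilities of all tables at most as probable as the observed
    one.  Probabilities are compared as exact integers (the denominator is
    shared), so the result is platform-independent.  Any zero margin makes
    the table degenerate: p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        raise ValueError("table total must be positive")
    if 0 in (r1, r2, c1, c2):
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    nums = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    p = Fraction(sum(v for v in nums if v <= obs), math.comb(n, c1))
    return float(min(p, Fraction(1)))


@dataclass(frozen=True)
class Exp1Result:
    """Allelic fraction test of one mutation: RNA vs DNA mutant fractions."""

    mutation_id: str
    frac_dna: float
    frac_rna: float
    log2fc: float
    p: float
    p_adj: float = math.nan
    call: str = "ns"
    undefined_fc: bool = False


def exp1_test(
    mut_rna: int, wt_rna: int, mut_dna: int, wt_dna: int, mutation_id: str = ""
) -> Exp1Result:
    """Experiment 1 core test (pre-adjustment).

    p is Fisher's exact test on the raw 2x2 read counts; the fold change is
    the ratio of mutant-allele fractions (RNA over DNA), with a Haldane-style
    0.5 correction applied to every cell for the FC estimate only whenever
    any cell is zero.
    """
    p = fisher_exact_2x2(mut_rna, wt_rna, mut_dna, wt_dna)
    frac_rna = mut_rna / (mut_rna + wt_rna) if mut_rna + wt_rna else math.nan
    frac_dna = mut_dna / (mut_dna + wt_dna) if mut_dna + wt_dna else math.nan
    cells = (mut_rna, wt_rna, mut_dna, wt_dna)
    if 0 in cells:
        mr, wr, md, wd = (x + 0.5 for x in cells)
    else:
        mr, wr, md, wd = cells
    fr = mr / (mr + wr)
    fd = md / (md + wd)
    undefined = fd == 0 or fr == 0
    log2fc = math.nan if undefined else math.log2(fr / fd)
    return Exp1Result(mutation_id, frac_dna, frac_rna, log2fc, p, undefined_fc=undefined)


def adjust_pvalues(ps: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or Bonferroni."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(ps, method=key)[1]


def call_exp1(
    results: Sequence[Exp1Result],
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    method: str = "BH",
) -> list[Exp1Result]:
    """Apply adjustment and the call rule: adjusted p < alpha and |log2FC| >= 1."""
    padj = adjust_pvalues([r.p for r in results], method)
    out = []
    for r, q in zip(results, padj):
        call = "ns"
        if q < alpha and not r.undefined_fc and abs(r.log2fc) >= min_abs_log2fc:
            call = "increase" if r.log2fc > 0 else "decrease"
        out.append(Exp1Result(r.mutation_id, r.frac_dna, r.frac_rna, r.log2fc, r.p, float(q), call, r.undefined_fc))
    return out


def chi2_stat(table: np.ndarray) -> float:
    """Pearson chi-square statistic of a contingency table (no continuity correction)."""
    chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2)


def cramers_v_from_counts(table: np.ndarray) -> float:
    """Cramer's V = sqrt(chi2 / (N * min(r-1, c-1))) of a contingency table."""
    table = np.asarray(table, dtype=float)
    k = min(table.shape[0] - 1, table.shape[1] - 1)
    n = table.sum()
    return float(math.sqrt(chi2_stat(table) / (n * k)))


def v_strength(v: float) -> str:
    for bound, label in V_BINS:
        if v < bound or bound is math.inf:
            return label
    return "large"


@dataclass(frozen=True)
class Exp2Result:
    """Allele-resolved isomiR-profile test of one mutation on one arm."""

    mutation_id: str
    arm: str
    chi2: float
    p: float
    cramers_v: float
    strength: str
    p_adj: float = math.nan
    call: bool = False


def exp2_test(
    wt_counts_by_class: Sequence[float],
    mut_counts_by_class: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mutation_id: str = "",
    arm: str = "",
) -> Exp2Result:
    """Experiment 2 core test (pre-adjustment) on nine-class count vectors.

    A pseudocount (+5 reads by default) is added to every class of both
    alleles before the chi-square; V uses the same pseudocounted table.
    """
    wt = np.asarray(wt_counts_by_class, dtype=float)
    mut = np.asarray(mut_counts_by_class, dtype=float)
    if wt.shape != mut.shape or wt.ndim != 1 or wt.size != len(CLASS_LABELS_NINE):
        raise ValueError("expected two nine-class count vectors")
    table = np.vstack([wt, mut]) + pseudocount
    chi2 = chi2_stat(table)
    p = float(stats.chi2.sf(chi2, df=table.shape[1] - 1))
    v = cramers_v_from_counts(table)
    return Exp2Result(mutation_id, arm, chi2, p, v, v_strength(v))


def call_exp2(
    results: Sequence[Exp2Result],
    alpha: float = 1e-11,
    min_v: float = 0.2,
    method: str = "BH",
) -> list[Exp2Result]:
    """Apply adjustment and the call rule: adjusted p < 1e-11 and V > 0.2."""
    padj = adjust_pvalues([r.p for r in results], method)
    return [
        Exp2Result(
            r.mutation_id, r.arm, r.chi2, r.p, r.cramers_v, r.strength,
            float(q), bool(q < alpha and r.cramers_v > min_v),
        )
        for r, q in zip(results, padj)
    ]


def pairwise_profile_v(
    count_vectors: Iterable[Sequence[float]], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """All pairwise Cramer's V values within a group of same-allele count vectors.

    Used to check that the V > 0.2 call threshold sits above ordinary
    inter-sample variability of the same allele.  A singleton group yields
    an empty array.
    """
    vecs = [np.asarray(v, dtype=float) for v in count_vectors]
    return np.array(
        [cramers_v_from_counts(np.vstack([a, b]) + pseudocount) for a, b in combinations(vecs, 2)]
    )


def sign_test_direction(n_up: int, n_down: int) -> float:
    """Two-sided exact binomial p for an excess of one call direction.

    Utility for summarizing call-direction asymmetry (e.g. decreases
    outnumbering increases); not tied to any single printed contingency
    construction.
    """
    return float(stats.binomtest(n_up, n_up + n_down, 0.5).pvalue)
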