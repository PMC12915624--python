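"""Precursor-stability change (ddG) with a pluggable folding backend.

The quantity of interest is ddG = dG(mutant) - dG(wild type), where dG is
the predicted minimum free energy of the extended precursor (hairpin plus
25-nt flanks).  Positive ddG destabilizes the hairpin.  Folding itself is
delegated to a backend contract: any callable object exposing
``fold(sequence) -> kcal/mol`` and a ``name``.  Two backends ship here:

* :class:`StubFoldBackend` -- a deterministic base-pairing proxy (pairs the
  sequence against its reverse as a naive hairpin and scores GC/AU/GU
  pairs).  It is not a thermodynamic model; it exists so the ddG
  arithmetic, bookkeeping and group statistics are testable anywhere and
  give identical numbers on every platform.
* :class:`RNAfoldBackend` -- shells out to the ViennaRNA ``RNAfold``
  program when it is installed; use this for real energy estimates.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import stats

from mirmut.reference_io import MirnaGeneAnnotation, ParsedVariant, VariantParseError, position_index


class FoldBackend(Protocol):
    name: str

    def fold(self, sequence: str) -> float: ...


class StubFoldBackend:
    """Deterministic dG proxy: score the naive hairpin pairing i <-> n-1-i.

    GC pairs count -3, AU -2, GU -1 (kcal/mol-like units). Purely a
    reproducible stand-in for tests and demos, not an energy model.
    """

    name = "stub-pairing-proxy"

    _SCORES = {
        frozenset("GC"): 3.0,
        frozenset("AT"): 2.0,
        frozenset("AU"): 2.0,
        frozenset("GT"): 1.0,
        frozenset("GU"): 1.0,
    }

    def fold(self, sequence: str) -> float:
        s = sequence.upper().replace("U", "T")
        score = 0.0
        for i in range(len(s) // 2):
            score += self._SCORES.get(frozenset({s[i], s[-1 - i]}), 0.0)
        return -score


class RNAfoldBackend:
    """Minimum-free-energy folding via the ViennaRNA ``RNAfold`` executable."""

    _MFE_RE = re.compile(r"\(\s*(-?\d+\.\d+)\)\s*$")

    def __init__(self, executable: str = "RNAfold"):
        path = shutil.which(executable)
        if path is None:
            raise RuntimeError(f"{executable} not found on PATH")
        self.executable = path
        self.name = f"RNAfold ({path})"

    def fold(self, sequence: str) -> float:
        out = subprocess.run(
            [self.executable, "--noPS"], input=sequence + "\n",
            capture_output=True, text=True, check=True,
        ).stdout
        for line in out.splitlines():
            m = self._MFE_RE.search(line.strip())
            if m:
                return float(m.group(1))
        raise RuntimeError(f"could not parse RNAfold output:\n{out}")


def extended_sequence(annotation: MirnaGeneAnnotation) -> str:
    """Flank5 + precursor + flank3: the L+50-nt sequence that gets folded."""
    return annotation.extended_seq


def mutate_sequence(extended_seq: str, variant: ParsedVariant) -> str:
    """Apply a parsed variant to the extended sequence.

    Substitutions replace in place, deletions remove the span, and
    duplications/insertions insert after the span, so the length changes by
    the indel size.  The reference allele must match the sequence.
    """
    seq = extended_seq.upper().replace("U", "T")
    i = position_index(variant.start)
    j = position_index(variant.end)
    ref = variant.ref.upper().replace("U", "T")
    if variant.kind in ("substitution", "deletion", "duplication"):
        if seq[i : j + 1] != ref:
            raise VariantParseError(
                "ref_mismatch", f"sequence has {seq[i:j+1]!r} at n.{variant.start}, variant says {ref!r}"
            )
    alt = variant.alt.upper().replace("U", "T")
    if variant.kind == "substitution":
        return seq[:i] + alt + seq[j + 1 :]
    if variant.kind == "deletion":
        return seq[:i] + seq[j + 1 :]
    if variant.kind == "duplication":
        return seq[: j + 1] + ref + seq[j + 1 :]
    if variant.kind == "insertion":
        return seq[: i + 1] + alt + seq[i + 1 :]
    raise ValueError(f"unknown variant kind {variant.kind!r}")


@dataclass(frozen=True)
class StabilityRecord:
    mutation_id: str
    dg_wt: float
    dg_mut: float
    backend: str

    @property
    def ddg(self) -> float:
        return self.dg_mut - self.dg_wt


def ddg(dg_wt: float, dg_mut: float, mutation_id: str = "", backend: str = "") -> StabilityRecord:
    """Stability change record; ddg = dg_mut - dg_wt, positive = destabilizing."""
    if not (math.isfinite(dg_wt) and math.isfinite(dg_mut)):
        raise ValueError("dG values must be finite")
    return StabilityRecord(mutation_id, dg_wt, dg_mut, backend)


def fold_mutation(
    annotation: MirnaGeneAnnotation, variant: ParsedVariant,
    backend: FoldBackend, mutation_id: str = "",
) -> StabilityRecord:
    """Fold wild-type and mutant extended sequences and record the ddG."""
    wt_seq = extended_sequence(annotation)
    mut_seq = mutate_sequence(wt_seq, variant)
    return ddg(backend.fold(wt_seq), backend.fold(mut_seq), mutation_id, backend.name)


def ddg_cohort_tests(
    records: Sequence[StabilityRecord],
    functional_flags: Sequence[bool],
    welch: bool = True,
) -> dict[str, float | str | None]:
    """Cohort-level stability statistics.

    A paired t test of mutant vs wild-type dG across all mutations (is the
    average mutant precursor less stable?), and a two-sample t test
    (Welch by default) of ddG in functional vs remaining mutations.
    When all flags agree the group test is skipped with a reason.
    """
    if len(records) < 2:
        raise ValueError("need at least two stability records")
    if len(functional_flags) != len(records):
        raise ValueError("flags and records must align")
    dg_wt = np.array([r.dg_wt for r in records])
    dg_mut = np.array([r.dg_mut for r in records])
    ddgs = dg_mut - dg_wt
    if np.allclose(ddgs.std(ddof=1) if len(ddgs) > 1 else 0.0, 0.0):
        paired_p = math.nan  # degenerate: all ddG identical
    else:
        paired_p = float(stats.ttest_rel(dg_mut, dg_wt).pvalue)
    flags = np.asarray(functional_flags, dtype=bool)
    out: dict[str, float | str | None] = {
        "mean_ddg": float(ddgs.mean()),
        "paired_t_p": paired_p,
        "group_t_p": math.nan,
        "mean_ddg_functional": math.nan,
        "mean_ddg_rest": math.nan,
        "group_skipped": None,
    }
    if flags.all() or not flags.any():
        out["group_skipped"] = "all_flags_identical"
        return out
    func, rest = ddgs[flags], ddgs[~flags]
    out["mean_ddg_functional"] = float(func.mean())
    out["mean_ddg_rest"] = float(rest.mean())
    out["group_t_p"] = float(stats.ttest_ind(func, rest, equal_var=not welch).pvalue)
    return out
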