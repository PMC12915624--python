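"""End-shift algebra and the 9/10-class isomiR taxonomy.

Each read of a mature miRNA is reduced to two signed end shifts relative to
the canonical miRBase ends: ``shift5`` for the 5' end and ``shift3`` for
the 3' end, written ``shift5|shift3``.  Positive means the end moved
downstream (3'-ward), negative upstream (5'-ward).  Collapsing each shift
to its sign yields the nine basic classes; a tenth class ``(nt)`` collects
reads with nontemplated 3'-end additions regardless of their shifts.

Note the sign semantics at the two ends differ in length terms: ``+1|0``
is one nucleotide *shorter* at the 5' end (the start moved into the
miRNA), while ``0|+1`` is one nucleotide longer at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mirmut.reference_io import MAX_SHIFT, position_index

#: The nine basic classes, canonical first; the image of the sign map {-,0,+}^2.
CLASS_LABELS_NINE = ("0|0", "0|-", "0|+", "+|0", "-|0", "+|-", "-|+", "+|+", "-|-")
#: Ten-class scheme: nontemplated 3' modifications form their own class.
CLASS_LABELS_TEN = CLASS_LABELS_NINE + ("(nt)",)

NT_CLASS = "(nt)"

_SIGN = {-1: "-", 0: "0", 1: "+"}


def end_shifts(read_start: int, read_end: int, arm_span: tuple[int, int]) -> tuple[int, int]:
    """Signed end shifts of a read against the canonical mature span.

    Coordinates are n.-frame gene positions (no zero); shifts count
    nucleotides, positive = downstream (3'-ward) movement of that end.
    """
    if position_index(read_end) < position_index(read_start):
        raise ValueError("read_end precedes read_start")
    shift5 = position_index(read_start) - position_index(arm_span[0])
    shift3 = position_index(read_end) - position_index(arm_span[1])
    return shift5, shift3


def basic_class(shift5: int, shift3: int, nontemplate: bool = False, scheme: str = "nine") -> str:
    """Class label from the signs of the two end shifts.

    ``scheme='nine'`` ignores the nontemplate flag; ``scheme='ten'`` routes
    any nontemplated read to ``(nt)`` regardless of its shifts.
    """
    if scheme not in ("nine", "ten"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "ten" and nontemplate:
        return NT_CLASS
    return f"{_SIGN[int(np.sign(shift5))]}|{_SIGN[int(np.sign(shift3))]}"


@dataclass(frozen=True)
class ClassProfile:
    """Normalized fraction vector over isomiR classes for one arm/allele/sample."""

    class_labels: tuple[str, ...]
    fractions: tuple[float, ...]
    n_reads: float

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.fractions):
            raise ValueError("labels and fractions differ in length")
        if self.n_reads <= 0:
            raise ValueError("empty_profile: profile needs positive total weight")
        total = float(np.sum(self.fractions))
        if abs(total - 1.0) > 1e-9 or min(self.fractions) < 0:
            raise ValueError("fractions must be nonnegative and sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(self.class_labels))

    def counts(self) -> np.ndarray:
        return np.asarray(self.fractions) * self.n_reads


def _profile_from_weights(weights: dict[str, float], labels: tuple[str, ...]) -> ClassProfile:
    values = np.array([weights.get(lbl, 0.0) for lbl in labels], dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("empty_profile: zero total weight")
    return ClassProfile(labels, tuple(values / total), float(total))


def build_profile(records: pd.DataFrame, scheme: str = "ten", weight: str = "count") -> ClassProfile:
    """Class profile of a set of isomiR records (one sample/gene/arm/allele).

    ``weight`` selects raw counts or normalized rpm.  The caller decides
    which records go in; allele-resolved profiles should exclude
    ``allele=AMBIG`` rows (reads that cannot be assigned to an allele).
    """
    if weight not in ("count", "rpm"):
        raise ValueError(f"unknown weight {weight!r}")
    labels = CLASS_LABELS_TEN if scheme == "ten" else CLASS_LABELS_NINE
    weights: dict[str, float] = {}
    for row in records.itertuples(index=False):
        lbl = basic_class(row.shift5, row.shift3, bool(row.nontemplate), scheme)
        weights[lbl] = weights.get(lbl, 0.0) + float(getattr(row, weight))
    return _profile_from_weights(weights, labels)


def fivep_label(shift5: int) -> str:
    """Label of a 5p-end group: '0|n', '+1|n', '-2|n', ..."""
    return ("0" if shift5 == 0 else f"{shift5:+d}") + "|n"


def fivep_profile(records: pd.DataFrame, weight: str = "count") -> ClassProfile:
    """Profile grouped on the 5p end only ('5p-isomiRs'), ignoring the 3p end.

    A coarsening of :func:`build_profile`: entries with the same ``shift5``
    collapse into one ``s|n`` group.  Labels span the full +/-10 shift
    range so profiles from different samples stay comparable.
    """
    labels = tuple(fivep_label(s) for s in range(-MAX_SHIFT, MAX_SHIFT + 1))
    weights: dict[str, float] = {}
    for row in records.itertuples(index=False):
        lbl = fivep_label(int(row.shift5))
        weights[lbl] = weights.get(lbl, 0.0) + float(getattr(row, weight))
    return _profile_from_weights(weights, labels)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Serialize profiles: (sample_id, gene_id, arm, allele, class, fraction, n_reads)."""
    cols = ["sample_id", "gene_id", "arm", "allele", "class", "fraction", "n_reads"]
    profiles[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
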