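"""Dataset-level exclusion criteria and per-experiment inclusion filters.

A mutation enters the analysis only if it survives nine dataset-level
exclusions (redundant gene copies, multiple mutations per gene/sample,
long indels, missing or duplicated sRNA-seq data, undefined arms, genes
without reads, samples dominated by ambiguously mapping reads, and absence
from the somatic-variant catalog when the mutation would need to be seen
at the RNA level).  Each experiment then applies its own read-depth /
expression floor.  Everything is reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mirmut.reference_io import MAX_INDEL, MirnaGeneAnnotation, Mutation, span_length

EXCLUSION_CODES = (
    "redundant_gene",
    "multi_mutation_same_gene_sample",
    "long_indel",
    "no_srna_data",
    "arm_undefined",
    "multiple_srna_datasets",
    "no_reads_in_gene",
    "many_ambiguous_reads",
    "not_in_catalog",
)

#: Reads within this many nt of a mature-arm end count as near a
#: DROSHA/DICER1 cleavage site for the catalog-membership criterion.
CLEAVAGE_PROXIMITY = 2

#: Default "many ambiguous reads" threshold: ambiguous share of the gene's
#: reads in the mutated sample above which the data are deemed unreliable.
#: No numeric value is standard; 0.5 is this package's configurable default.
DEFAULT_AMBIGUOUS_FRACTION = 0.5


@dataclass
class EligibilityReport:
    mutation_id: str
    reasons: list[str] = field(default_factory=list)
    per_experiment: dict[str, tuple[bool, str | None]] = field(default_factory=dict)

    @property
    def verdict(self) -> str:
        return "excluded" if self.reasons else "eligible"


def _near_cleavage(ann: MirnaGeneAnnotation, position: int) -> bool:
    """In a mature miRNA or within +/-2 nt of a mature-arm boundary."""
    if ann.in_mature(position):
        return True
    for lo, hi in (ann.mature5p_span, ann.mature3p_span):
        if lo - CLEAVAGE_PROXIMITY <= position <= lo or hi <= position <= hi + CLEAVAGE_PROXIMITY:
            return True
    return False


def dataset_exclusions(
    mutations: Sequence[Mutation],
    annotations: Mapping[str, MirnaGeneAnnotation],
    read_data: pd.DataFrame,
    catalog_flags: Mapping[str, bool] | None = None,
    multi_dataset_samples: Iterable[str] = (),
    max_ambiguous_fraction: float = DEFAULT_AMBIGUOUS_FRACTION,
) -> list[EligibilityReport]:
    """Apply the nine dataset-level exclusion criteria.

    ``catalog_flags`` maps mutation_id -> True if the variant is annotated
    in the external somatic-variant catalog (an input flag: the catalog is
    not bundled); missing ids default to True.  ``multi_dataset_samples``
    lists samples sequenced more than once.  A mutation may accumulate
    several reasons; an empty reason list means eligible.
    """
    catalog_flags = catalog_flags or {}
    multi_dataset = set(multi_dataset_samples)
    pair_counts: dict[tuple[str, str], int] = {}
    for mut in mutations:
        key = (mut.gene_id, mut.sample_id)
        pair_counts[key] = pair_counts.get(key, 0) + 1

    samples_with_reads = set(read_data["sample_id"].unique())
    by_sample_gene = read_data.groupby(["sample_id", "gene_id"], sort=False)
    gene_reads = by_sample_gene["count"].sum()
    ambig_reads = read_data[read_data["source"] == "ambiguous"].groupby(
        ["sample_id", "gene_id"], sort=False
    )["count"].sum()

    reports = []
    for mut in mutations:
        reasons: list[str] = []
        ann = annotations.get(mut.gene_id)
        if ann is None:
            reasons.append("arm_undefined")
        elif ann.redundant_group is not None:
            reasons.append("redundant_gene")
        if pair_counts[(mut.gene_id, mut.sample_id)] > 1:
            reasons.append("multi_mutation_same_gene_sample")
        v = mut.variant
        if v.kind != "substitution" and span_length(v.start, v.end) > MAX_INDEL:
            reasons.append("long_indel")
        if mut.sample_id not in samples_with_reads:
            reasons.append("no_srna_data")
        elif (mut.sample_id, mut.gene_id) not in gene_reads.index or gene_reads[(mut.sample_id, mut.gene_id)] == 0:
            reasons.append("no_reads_in_gene")
        else:
            total = gene_reads[(mut.sample_id, mut.gene_id)]
            ambig = ambig_reads.get((mut.sample_id, mut.gene_id), 0)
            if total > 0 and ambig / total > max_ambiguous_fraction:
                reasons.append("many_ambiguous_reads")
        if mut.sample_id in multi_dataset:
            reasons.append("multiple_srna_datasets")
        if ann is not None and not catalog_flags.get(mut.mutation_id, True):
            if _near_cleavage(ann, v.start):
                reasons.append("not_in_catalog")
        reports.append(EligibilityReport(mut.mutation_id, reasons))
    return reports


# Per-experiment read/expression floors (paper defaults).
E1_MIN_READS = 50
E2_MIN_READS_PER_ALLELE = 50
E3_MIN_RPM = 10.0
E4_MIN_RPM_PER_STRAND = 20.0
E5_MIN_READS = 50


def experiment_filter(
    experiment: str,
    mutation: Mutation,
    annotation: MirnaGeneAnnotation,
    *,
    total_reads: float | None = None,
    allele_reads: tuple[float, float] | None = None,
    mut_rpm: float | None = None,
    wt_mean_rpm: float | None = None,
    strand_rpm: tuple[float, float] | None = None,
    wt_mean_strand_rpm: tuple[float, float] | None = None,
) -> tuple[bool, str | None]:
    """Per-experiment inclusion decision for one eligible mutation.

    Returns (selected, reason).  The quantities each experiment needs:
    E1 -- total reads in the mutated sample for the mutated arm;
    E2 -- (wt, mut) allele read totals; E3 -- mutated-sample RPM and mean
    wild-type RPM; E4 -- per-strand (5p, 3p) RPM on both sides; E5 --
    total reads of the gene in the mutated sample.  E1/E2 additionally
    require the mutation to lie inside a mature-miRNA span, since only
    those are visible at the RNA level.
    """
    pos = mutation.variant.start
    if experiment in ("E1", "E2") and not annotation.in_mature(pos):
        return False, "not_in_mature"
    if experiment == "E1":
        if total_reads is None or total_reads < E1_MIN_READS:
            return False, "min_reads_50"
    elif experiment == "E2":
        if allele_reads is None or min(allele_reads) < E2_MIN_READS_PER_ALLELE:
            return False, "min_reads_per_allele_50"
    elif experiment == "E3":
        if mut_rpm is None or wt_mean_rpm is None or mut_rpm < E3_MIN_RPM or wt_mean_rpm < E3_MIN_RPM:
            return False, "min_rpm_10"
    elif experiment == "E4":
        if strand_rpm is None or wt_mean_strand_rpm is None:
            return False, "min_strand_rpm_20"
        ok5 = strand_rpm[0] >= E4_MIN_RPM_PER_STRAND and wt_mean_strand_rpm[0] >= E4_MIN_RPM_PER_STRAND
        ok3 = strand_rpm[1] >= E4_MIN_RPM_PER_STRAND and wt_mean_strand_rpm[1] >= E4_MIN_RPM_PER_STRAND
        if not (ok5 or ok3):
            return False, "min_strand_rpm_20"
    elif experiment == "E5":
        if total_reads is None or total_reads < E5_MIN_READS:
            return False, "min_reads_50"
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return True, None


def reports_to_frame(reports: Sequence[EligibilityReport]) -> pd.DataFrame:
    """One row per mutation with semicolon-joined reason codes."""
    return pd.DataFrame(
        {
            "mutation_id": [r.mutation_id for r in reports],
            "verdict": [r.verdict for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )
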