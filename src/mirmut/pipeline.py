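"""Run-level orchestration: eligibility -> E1..E5 -> roll-up and summaries.

The tables handed to :func:`analyze_cohort` are assumed to form one
cancer-type cohort (the unit at which all cross-sample comparisons are
defined); multi-cohort datasets are analyzed by running once per cohort.
``run_pipeline`` wraps the same computation with file IO, threshold
configuration and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mirmut._version import __version__ as _pkg_version
from mirmut import eligibility as elig
from mirmut.cross_sample_stats import (
    call_exp3, call_exp4, call_exp5, exp3, exp4, exp5,
)
from mirmut.isomir_model import CLASS_LABELS_NINE, CLASS_LABELS_TEN, basic_class, build_profile
from mirmut.reference_io import (
    MirnaGeneAnnotation, Mutation, parse_n_position,
    read_annotations, read_expression_matrix, read_isomir_tables, read_mutation_table,
)
from mirmut.within_sample_stats import (
    call_exp1, call_exp2, exp1_test, exp2_test, fisher_exact_2x2,
)


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of the pipeline; defaults are the published values."""

    alpha: float = 0.05                 # E1 adjusted-p and E3-E5 t/z threshold
    e2_alpha: float = 1e-11             # E2 adjusted chi-square p
    min_cramers_v: float = 0.2          # E2 effect-size floor
    min_distance: float = 0.2           # E4 profile-distance floor
    min_abs_log2fc: float = 1.0         # E1/E3 |log2FC| floor
    min_delta_f5p_points: float = 10.0  # E5 strand-fraction change (points)
    min_reads_e1: int = 50
    min_reads_per_allele_e2: int = 50
    min_rpm_e3: float = 10.0
    min_strand_rpm_e4: float = 20.0
    min_reads_e5: int = 50
    pseudocount: float = 5.0            # E2 chi-square pseudocount per class
    adjust_method: str = "BH"           # E1/E2 multiple-testing adjustment
    max_ambiguous_fraction: float = 0.5
    experiments: tuple[str, ...] = ("E1", "E2", "E3", "E4", "E5")
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def class_count_vector(records: pd.DataFrame, scheme: str = "nine", weight: str = "count") -> np.ndarray:
    """Count (or rpm) totals per isomiR class, in canonical label order."""
    labels = CLASS_LABELS_NINE if scheme == "nine" else CLASS_LABELS_TEN
    out = dict.fromkeys(labels, 0.0)
    for row in records.itertuples(index=False):
        lbl = basic_class(row.shift5, row.shift3, bool(row.nontemplate), scheme)
        out[lbl] += float(getattr(row, weight))
    return np.array([out[lbl] for lbl in labels])


def mutations_from_frame(
    df: pd.DataFrame, annotations: Mapping[str, MirnaGeneAnnotation]
) -> list[Mutation]:
    """Build Mutation objects from a mutation table in memory."""
    out = []
    for row in df.itertuples(index=False):
        ann = annotations[row.gene_id]
        variant = parse_n_position(row.hgvs_n, ann.length, ann.extended_seq)
        out.append(
            Mutation(
                mutation_id=row.mutation_id, gene_id=row.gene_id, sample_id=row.sample_id,
                cancer_type=row.cancer_type, variant=variant,
                dna_ref_reads=int(row.dna_ref_reads), dna_alt_reads=int(row.dna_alt_reads),
                homozygous=bool(int(row.homozygous)), subregion=ann.subregion(variant.start),
            )
        )
    return out


def analyze_cohort(
    isomirs: pd.DataFrame,
    expression: pd.DataFrame,
    mutations: Sequence[Mutation],
    annotations: Mapping[str, MirnaGeneAnnotation],
    config: RunConfig = RunConfig(),
    catalog_flags: Mapping[str, bool] | None = None,
    multi_dataset_samples: Sequence[str] = (),
) -> dict[str, pd.DataFrame]:
    """Run eligibility and the enabled experiments on one cohort.

    Returns a dict of result frames keyed ``eligibility, E1..E5, calls``.
    """
    reports = elig.dataset_exclusions(
        mutations, annotations, isomirs, catalog_flags,
        multi_dataset_samples, config.max_ambiguous_fraction,
    )
    eligible = {r.mutation_id for r in reports if r.verdict == "eligible"}
    nonambig = isomirs[isomirs["source"] != "ambiguous"]
    mutated_samples_of_gene: dict[str, set[str]] = {}
    for m in mutations:
        mutated_samples_of_gene.setdefault(m.gene_id, set()).add(m.sample_id)

    e1_in, e2_in, e3_in, e4_in, e5_in = [], [], [], [], []
    for mut in mutations:
        if mut.mutation_id not in eligible:
            continue
        ann = annotations[mut.gene_id]
        sample_recs = nonambig[
            (nonambig["sample_id"] == mut.sample_id) & (nonambig["gene_id"] == mut.gene_id)
        ]
        wt_samples = [
            s for s in expression.index
            if s not in mutated_samples_of_gene.get(mut.gene_id, set())
        ]
        arm = ann.arm_of(mut.position)

        if "E1" in config.experiments and arm is not None:
            arm_recs = sample_recs[sample_recs["arm"] == arm]
            total = arm_recs["count"].sum()
            ok, _ = elig.experiment_filter("E1", mut, ann, total_reads=total)
            if ok:
                mut_rna = int(arm_recs.loc[arm_recs["allele"] == "MUT", "count"].sum())
                wt_rna = int(arm_recs.loc[arm_recs["allele"] == "WT", "count"].sum())
                e1_in.append(exp1_test(mut_rna, wt_rna, mut.dna_alt_reads, mut.dna_ref_reads,
                                       mutation_id=mut.mutation_id))

        if "E2" in config.experiments and arm is not None:
            arm_recs = sample_recs[sample_recs["arm"] == arm]
            wt_vec = class_count_vector(arm_recs[arm_recs["allele"] == "WT"])
            mut_vec = class_count_vector(arm_recs[arm_recs["allele"] == "MUT"])
            ok, _ = elig.experiment_filter(
                "E2", mut, ann, allele_reads=(wt_vec.sum(), mut_vec.sum()))
            if ok:
                e2_in.append(exp2_test(wt_vec, mut_vec, config.pseudocount,
                                       mutation_id=mut.mutation_id, arm=arm))

        if mut.gene_id in expression.columns and mut.sample_id in expression.index:
            mut_rpm = float(expression.loc[mut.sample_id, mut.gene_id])
            wt_rpm = expression.loc[wt_samples, mut.gene_id].astype(float)

            if "E3" in config.experiments:
                ok, _ = elig.experiment_filter(
                    "E3", mut, ann, mut_rpm=mut_rpm, wt_mean_rpm=float(wt_rpm.mean()))
                if ok:
                    e3_in.append(exp3(wt_rpm.to_numpy(), mut_rpm, mutation_id=mut.mutation_id))

            gene_recs = nonambig[nonambig["gene_id"] == mut.gene_id]
            by_sample_arm = gene_recs.groupby(["sample_id", "arm"], sort=False)["rpm"].sum()

            def strand_rpm(sample: str) -> tuple[float, float]:
                return (
                    float(by_sample_arm.get((sample, "5p"), 0.0)),
                    float(by_sample_arm.get((sample, "3p"), 0.0)),
                )

            if "E4" in config.experiments:
                mut_strands = strand_rpm(mut.sample_id)
                wt_strands = np.array([strand_rpm(s) for s in wt_samples])
                wt_mean_strands = tuple(wt_strands.mean(axis=0)) if len(wt_strands) else (0.0, 0.0)
                ok, _ = elig.experiment_filter(
                    "E4", mut, ann, strand_rpm=mut_strands, wt_mean_strand_rpm=wt_mean_strands)
                if ok:
                    for arm_i, a in enumerate(("5p", "3p")):
                        if (mut_strands[arm_i] < config.min_strand_rpm_e4
                                or wt_mean_strands[arm_i] < config.min_strand_rpm_e4):
                            continue
                        wt_profiles = []
                        for s in wt_samples:
                            recs = gene_recs[(gene_recs["sample_id"] == s) & (gene_recs["arm"] == a)]
                            if recs["rpm"].sum() > 0:
                                wt_profiles.append(build_profile(recs, scheme="ten", weight="rpm"))
                        mut_recs = gene_recs[
                            (gene_recs["sample_id"] == mut.sample_id) & (gene_recs["arm"] == a)]
                        if len(wt_profiles) >= 3 and mut_recs["rpm"].sum() > 0:
                            e4_in.append(exp4(wt_profiles,
                                              build_profile(mut_recs, scheme="ten", weight="rpm"),
                                              mutation_id=mut.mutation_id, arm=a))

            if "E5" in config.experiments:
                by_sample_arm_counts = gene_recs.groupby(["sample_id", "arm"], sort=False)["count"].sum()

                def strand_counts(sample: str) -> tuple[float, float]:
                    return (
                        float(by_sample_arm_counts.get((sample, "5p"), 0.0)),
                        float(by_sample_arm_counts.get((sample, "3p"), 0.0)),
                    )

                mut_counts = strand_counts(mut.sample_id)
                ok, _ = elig.experiment_filter("E5", mut, ann, total_reads=sum(mut_counts))
                if ok:
                    wt_counts = [strand_counts(s) for s in wt_samples]
                    e5_in.append(exp5(wt_counts, mut_counts, mutation_id=mut.mutation_id,
                                      min_reads=config.min_reads_e5))

    results: dict[str, pd.DataFrame] = {"eligibility": elig.reports_to_frame(reports)}
    e1 = call_exp1(e1_in, config.alpha, config.min_abs_log2fc, config.adjust_method)
    e2 = call_exp2(e2_in, config.e2_alpha, config.min_cramers_v, config.adjust_method)
    e3 = call_exp3(e3_in, config.alpha, config.min_abs_log2fc)
    e4 = call_exp4(e4_in, config.alpha, config.min_distance)
    e5 = call_exp5(e5_in, config.alpha, config.min_delta_f5p_points)

    results["E1"] = pd.DataFrame(
        [{"mutation_id": r.mutation_id, "frac_dna": r.frac_dna, "frac_rna": r.frac_rna,
          "log2fc": r.log2fc, "p": r.p, "p_adj": r.p_adj, "call": r.call} for r in e1])
    results["E2"] = pd.DataFrame(
        [{"mutation_id": r.mutation_id, "arm": r.arm, "chi2": r.chi2, "p": r.p,
          "p_adj": r.p_adj, "cramers_v": r.cramers_v, "strength": r.strength,
          "call": r.call} for r in e2])
    results["E3"] = pd.DataFrame(
        [{"mutation_id": r.mutation_id, "mut_log_level": r.comparison.mut_value,
          "wt_mean_log_level": r.comparison.wt_mean, "log2fc": r.log2fc,
          "t_p": r.comparison.t_p, "t_p_bonf": r.t_p_bonf, "z": r.comparison.z,
          "z_p": r.comparison.z_p, "outlier": r.comparison.outlier, "call": r.call}
         for r in e3])
    results["E4"] = pd.DataFrame(
        [{"mutation_id": r.mutation_id, "arm": r.arm, "distance": r.distance,
          "t_p": r.comparison.t_p, "t_p_bonf": r.t_p_bonf, "z": r.comparison.z,
          "z_p": r.comparison.z_p, "call": r.call} for r in e4])
    results["E5"] = pd.DataFrame(
        [{"mutation_id": r.mutation_id, "balance": r.comparison.mut_value,
          "wt_mean_balance": r.comparison.wt_mean, "delta_f5p_points": r.delta_f5p,
          "t_p": r.comparison.t_p, "t_p_bonf": r.t_p_bonf, "z": r.comparison.z,
          "z_p": r.comparison.z_p, "outlier": r.comparison.outlier, "call": r.call}
         for r in e5])

    called: dict[str, set[str]] = {}
    for key, frame in results.items():
        if key in ("eligibility",) or frame.empty:
            continue
        for row in frame.itertuples(index=False):
            is_call = row.call if isinstance(row.call, (bool, np.bool_)) else row.call != "ns"
            if is_call:
                called.setdefault(row.mutation_id, set()).add(key)
    results["calls"] = pd.DataFrame(
        [{"mutation_id": m.mutation_id,
          "functional": int(m.mutation_id in called),
          "experiments": ";".join(sorted(called.get(m.mutation_id, ())))}
         for m in mutations if m.mutation_id in eligible])
    return results


def functional_enrichment(
    n_func_hom: int, n_hom: int, n_func_other: int, n_other: int
) -> dict[str, float]:
    """Enrichment of functional calls among homozygous mutations.

    Fold enrichment is the ratio of the two group proportions; p is the
    two-sided Fisher exact test on the implied 2x2 table
    [[func_hom, nonfunc_hom], [func_other, nonfunc_other]].
    """
    if not (0 <= n_func_hom <= n_hom and 0 <= n_func_other <= n_other):
        raise ValueError("functional counts must not exceed group totals")
    if n_hom == 0 or n_other == 0:
        return {"fold_enrichment": math.nan, "fisher_p": math.nan,
                "prop_hom": math.nan, "prop_other": math.nan}
    prop_hom = n_func_hom / n_hom
    prop_other = n_func_other / n_other
    fold = prop_hom / prop_other if prop_other > 0 else math.inf
    p = fisher_exact_2x2(n_func_hom, n_hom - n_func_hom, n_func_other, n_other - n_func_other)
    return {"fold_enrichment": fold, "fisher_p": p,
            "prop_hom": prop_hom, "prop_other": prop_other}


@dataclass
class RunPaths:
    annotations_fasta: str
    annotations_coords: str
    mutations: str
    isomirs: str
    expression: str | None = None
    out_dir: str = "mirmut_results"


def run_pipeline(paths: RunPaths, config: RunConfig = RunConfig()) -> dict[str, pd.DataFrame]:
    """File-level entry point: read inputs, analyze, write TSVs and a manifest.

    When no expression matrix is given, per-sample gene RPM totals are
    derived from the read table's rpm column.  Outputs are written with a
    fixed numeric format so identical runs are byte-identical.
    """
    annotations, ann_rejects = read_annotations(paths.annotations_fasta, paths.annotations_coords)
    mutations, mut_rejects = read_mutation_table(paths.mutations, annotations)
    isomirs, read_rejects = read_isomir_tables(paths.isomirs, dialect="native_tsv")
    if paths.expression:
        expression = read_expression_matrix(paths.expression)
    else:
        keep = isomirs[isomirs["source"] != "ambiguous"]
        expression = keep.pivot_table(index="sample_id", columns="gene_id", values="rpm",
                                      aggfunc="sum", fill_value=0.0)
        expression.columns.name = None

    results = analyze_cohort(isomirs, expression, mutations, annotations, config)

    out = Path(paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, frame in results.items():
        frame.to_csv(out / f"{key}.tsv", sep="\t", index=False, float_format="%.8g")
    manifest = {
        "package": "mirmut",
        "version": _pkg_version,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.hash(),
        "input_rejections": {
            "annotations": [(r.item_id, r.reason) for r in ann_rejects],
            "mutations": [(r.item_id, r.reason) for r in mut_rejects],
            "isomirs": [(r.item_id, r.reason) for r in read_rejects],
        },
        "n_mutations": len(mutations),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
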