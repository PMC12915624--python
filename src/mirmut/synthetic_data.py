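"""Synthetic allele-resolved isomiR cohorts with known injected effects.

The generator emulates the statistical structure the five experiments
assume: for each cancer-type cohort, wild-type samples drawn i.i.d. from a
per-gene generative model, plus one mutated sample per simulated mutation.
The model (this simulator's own, stated choice -- no distributional claim
is inherited from any dataset):

* gene expression: log-normal baseline RPM per gene, log-normal
  sample-to-sample noise;
* strand split: per-gene mean 5p fraction from a Beta prior, per-sample
  Beta noise around it (Beta-binomial arm counts);
* isomiR classes: per-gene Dirichlet template over the 10 classes per arm,
  per-sample Dirichlet-multinomial counts with a precision
  (overdispersion) knob;
* DNA support: Binomial(depth, VAF) alt reads;
* ambiguously mapping reads at a small configurable rate, to exercise the
  exclusion logic.

A mutated sample mixes a wild-type and a mutant allele.  The mutant
allele's expected output is the wild-type's times ``level_multiplier``
(lambda), so the RNA-level mutant read fraction is

    rho = vaf * lambda / (1 - vaf + vaf * lambda)

and the sample's total expected output scales by (1 - vaf + vaf*lambda).
Class shifts and strand shifts act on the mutant allele's template only;
the observed sample is the read-weighted mixture of the two alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from mirmut.isomir_model import CLASS_LABELS_TEN, NT_CLASS
from mirmut.reference_io import MirnaGeneAnnotation, ParsedVariant, format_n_position

#: Representative (shift5, shift3, nontemplate) per simulated class.
CLASS_SHIFTS = {
    "0|0": (0, 0, 0),
    "0|-": (0, -1, 0),
    "0|+": (0, 1, 0),
    "+|0": (1, 0, 0),
    "-|0": (-1, 0, 0),
    "+|-": (1, -1, 0),
    "-|+": (-1, 1, 0),
    "+|+": (1, 1, 0),
    "-|-": (-1, -1, 0),
    NT_CLASS: (0, 1, 1),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters (one simulated cancer type)."""

    n_wt_samples: int = 50
    n_genes: int = 1
    library_size: int = 1_000_000
    expr_log2_mean: float = 10.0    # baseline gene level ~ 2**10 = 1024 RPM
    expr_log2_sd: float = 1.0       # gene-to-gene spread (log2 units)
    sample_log2_sd: float = 0.4     # sample-to-sample level noise (log2 units)
    class_template: tuple[float, ...] = (30, 8, 6, 4, 3, 2, 2, 1, 1, 3)
    f5p_alpha: float = 8.0          # Beta prior of the per-gene mean 5p fraction
    f5p_beta: float = 2.0
    strand_precision: float = 300.0  # per-sample Beta precision around the gene f5p
    overdispersion: float = 150.0    # Dirichlet-multinomial precision per arm
    dna_depth: int = 100
    ambiguous_rate: float = 0.02
    cancer_type: str = "SIM"

    def __post_init__(self) -> None:
        if len(self.class_template) != len(CLASS_LABELS_TEN):
            raise ValueError("class_template must have 10 entries")
        if min(self.class_template) <= 0 or self.overdispersion <= 0 or self.strand_precision <= 0:
            raise ValueError("concentrations and precisions must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect of one simulated mutation on its gene.

    ``class_shift`` is a sequence of (from_label, to_label, mass) moves on
    the mutant allele's class-fraction template; ``strand_shift`` replaces
    the mutant allele's 5p fraction.  ``lambda = 1`` with no shifts is the
    null effect.  ``position`` (n. frame) defaults to a seed position of
    the 5p arm so the mutation is visible at the RNA level.
    """

    mutation_id: str
    gene_index: int = 0
    vaf_dna: float = 0.5
    level_multiplier: float = 1.0
    class_shift: tuple[tuple[str, str, float], ...] = ()
    strand_shift: float | None = None
    homozygous: bool = False
    position: int | None = None

    @property
    def is_null(self) -> bool:
        return self.level_multiplier == 1.0 and not self.class_shift and self.strand_shift is None


def mutant_rna_fraction(vaf_dna: float, level_multiplier: float) -> float:
    """Expected mutant-allele read fraction at the RNA level (mixing formula)."""
    v, lam = vaf_dna, level_multiplier
    denom = 1.0 - v + v * lam
    return v * lam / denom if denom > 0 else math.nan


def shift_template(template: Sequence[float], moves: Sequence[tuple[str, str, float]]) -> np.ndarray:
    """Move probability mass between classes; total mass is preserved.

    Raises on mass mismatch (moving more mass than the source class holds).
    """
    t = np.asarray(template, dtype=float).copy()
    idx = {lbl: i for i, lbl in enumerate(CLASS_LABELS_TEN)}
    for frm, to, mass in moves:
        if mass < 0:
            raise ValueError("class_shift mass must be nonnegative")
        if t[idx[frm]] < mass - 1e-12:
            raise ValueError(f"class_shift mass mismatch: {frm} holds {t[idx[frm]]:.4f} < {mass}")
        t[idx[frm]] -= mass
        t[idx[to]] += mass
    return t


@dataclass(frozen=True)
class AlleleModel:
    """Generative parameters of one allele of one gene."""

    rpm_scale: float              # multiplier on the gene's expected output
    f5p: float
    template5: np.ndarray         # 10-class fractions, 5p arm
    template3: np.ndarray


@dataclass(frozen=True)
class GeneModel:
    """Per-gene generative parameters shared by all samples of the cohort."""

    gene_id: str
    base_rpm: float
    wt: AlleleModel


def inject_effect(base: GeneModel, effect: EffectSpec) -> tuple[AlleleModel, float, float]:
    """Mutant-allele model plus RNA mutant fraction and total-output scale.

    Returns ``(mut_allele, rho, total_scale)`` where ``rho`` is the
    expected fraction of the gene's reads that come from the mutant allele
    and ``total_scale = 1 - vaf + vaf*lambda`` multiplies the gene's
    expected sample output.
    """
    wt = base.wt
    f5p = effect.strand_shift if effect.strand_shift is not None else wt.f5p
    if not 0.0 <= f5p <= 1.0:
        raise ValueError("strand_shift must be a fraction in [0, 1]")
    mut = AlleleModel(
        rpm_scale=effect.level_multiplier,
        f5p=f5p,
        template5=shift_template(wt.template5, effect.class_shift),
        template3=shift_template(wt.template3, effect.class_shift),
    )
    rho = mutant_rna_fraction(effect.vaf_dna, effect.level_multiplier)
    total_scale = 1.0 - effect.vaf_dna + effect.vaf_dna * effect.level_multiplier
    return mut, rho, total_scale


@dataclass
class SimulatedCohort:
    """Bundle of simulated tables in the native schemas."""

    isomirs: pd.DataFrame
    expression: pd.DataFrame
    mutations: pd.DataFrame
    truth: pd.DataFrame
    annotations: dict[str, MirnaGeneAnnotation]
    config: SimulationConfig
    gene_models: list["GeneModel"] = field(default_factory=list)


_BASES = np.array(list("ACGT"))


def _random_annotation(gene_id: str, rng: np.random.Generator) -> MirnaGeneAnnotation:
    """A plausible synthetic gene: 80-nt precursor, arms at 11-32 and 49-70."""
    precursor = "".join(rng.choice(_BASES, size=80))
    flank5 = "".join(rng.choice(_BASES, size=25))
    flank3 = "".join(rng.choice(_BASES, size=25))
    return MirnaGeneAnnotation(
        gene_id=gene_id, precursor_id=f"{gene_id}-pre", precursor_seq=precursor,
        flank5_seq=flank5, flank3_seq=flank3,
        mature5p_span=(11, 32), mature3p_span=(49, 70),
    )


def _sample_allele_counts(
    rng: np.random.Generator, n_reads: int, allele: AlleleModel,
    strand_precision: float, overdispersion: float,
) -> dict[str, np.ndarray]:
    """Draw (arm -> 10-class count vector) for one allele in one sample."""
    f = min(max(allele.f5p, 1e-6), 1 - 1e-6)
    f_s = rng.beta(f * strand_precision, (1 - f) * strand_precision)
    c5 = rng.binomial(n_reads, f_s)
    counts = {}
    for arm, n_arm, template in (("5p", c5, allele.template5), ("3p", n_reads - c5, allele.template3)):
        if n_arm == 0:
            counts[arm] = np.zeros(len(CLASS_LABELS_TEN), dtype=int)
            continue
        frac = rng.dirichlet(np.maximum(template, 1e-9) * overdispersion)
        counts[arm] = rng.multinomial(n_arm, frac)
    return counts


def simulate_cohort(
    config: SimulationConfig, effects: Sequence[EffectSpec] = (), seed: int = 0
) -> SimulatedCohort:
    """Simulate one cohort: wild-type samples plus one mutated sample per effect.

    Fully reproducible for a fixed seed: all draws come from one
    ``numpy.random.default_rng(seed)`` in a fixed order.
    """
    rng = np.random.default_rng(seed)
    for e in effects:
        if not 0 <= e.gene_index < config.n_genes:
            raise ValueError(f"effect {e.mutation_id} references unknown gene index {e.gene_index}")

    annotations = {}
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        gene_id = f"SIMG{g + 1}"
        annotations[gene_id] = _random_annotation(gene_id, rng)
        base_rpm = float(2.0 ** rng.normal(config.expr_log2_mean, config.expr_log2_sd))
        conc = np.asarray(config.class_template, dtype=float)
        wt = AlleleModel(
            rpm_scale=1.0,
            f5p=float(rng.beta(config.f5p_alpha, config.f5p_beta)),
            template5=rng.dirichlet(conc),
            template3=rng.dirichlet(conc),
        )
        genes.append(GeneModel(gene_id, base_rpm, wt))

    sample_ids = [f"WT{i + 1:03d}" for i in range(config.n_wt_samples)]
    mut_sample_of = {e.mutation_id: f"MUT_{e.mutation_id}" for e in effects}
    rows: dict[str, list] = {k: [] for k in
        ("sample_id", "gene_id", "arm", "shift5", "shift3", "nontemplate", "allele", "source", "count")}

    def emit(sample_id, gene_id, allele, source, counts_by_arm):
        for arm, vec in counts_by_arm.items():
            for lbl, n in zip(CLASS_LABELS_TEN, vec):
                if n == 0:
                    continue
                s5, s3, nt = CLASS_SHIFTS[lbl]
                rows["sample_id"].append(sample_id)
                rows["gene_id"].append(gene_id)
                rows["arm"].append(arm)
                rows["shift5"].append(s5)
                rows["shift3"].append(s3)
                rows["nontemplate"].append(nt)
                rows["allele"].append(allele)
                rows["source"].append(source)
                rows["count"].append(int(n))

    def draw_sample(sample_id: str, effect: EffectSpec | None) -> None:
        for g, gene in enumerate(genes):
            scale = 1.0
            mut_model, rho = None, 0.0
            if effect is not None and effect.gene_index == g:
                mut_model, rho, scale = inject_effect(gene, effect)
            expected_rpm = gene.base_rpm * scale * 2.0 ** rng.normal(0.0, config.sample_log2_sd)
            total = rng.poisson(expected_rpm * config.library_size / 1e6)
            n_mut = rng.binomial(total, rho) if mut_model is not None and rho > 0 else 0
            n_wt = total - n_mut
            if n_wt > 0:
                emit(sample_id, gene.gene_id, "WT", "exclusive",
                     _sample_allele_counts(rng, n_wt, gene.wt,
                                           config.strand_precision, config.overdispersion))
            if n_mut > 0:
                emit(sample_id, gene.gene_id, "MUT", "snps",
                     _sample_allele_counts(rng, n_mut, mut_model,
                                           config.strand_precision, config.overdispersion))
            n_ambig = rng.poisson(total * config.ambiguous_rate)
            if n_ambig > 0:
                emit(sample_id, gene.gene_id, "AMBIG", "ambiguous",
                     {"5p": np.array([n_ambig] + [0] * 9)})

    for sid in sample_ids:
        draw_sample(sid, None)
    for e in effects:
        draw_sample(mut_sample_of[e.mutation_id], e)

    isomirs = pd.DataFrame(rows)
    isomirs["rpm"] = isomirs["count"] / config.library_size * 1e6

    keep = isomirs[isomirs["source"] != "ambiguous"]
    expression = (
        keep.pivot_table(index="sample_id", columns="gene_id", values="rpm", aggfunc="sum", fill_value=0.0)
        .reindex(sample_ids + list(mut_sample_of.values()), fill_value=0.0)
    )
    expression.columns.name = None

    mut_rows, truth_rows = [], []
    for e in effects:
        gene = genes[e.gene_index]
        ann = annotations[gene.gene_id]
        pos = e.position if e.position is not None else ann.mature5p_span[0] + 3
        ref = ann.base_at(pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        variant = ParsedVariant("substitution", pos, pos, ref, alt)
        vaf = 1.0 if e.homozygous else e.vaf_dna
        alt_reads = int(rng.binomial(config.dna_depth, vaf))
        mut_rows.append({
            "mutation_id": e.mutation_id, "gene_id": gene.gene_id,
            "sample_id": mut_sample_of[e.mutation_id], "cancer_type": config.cancer_type,
            "hgvs_n": format_n_position(variant),
            "dna_ref_reads": config.dna_depth - alt_reads, "dna_alt_reads": alt_reads,
            "homozygous": int(e.homozygous),
        })
        shift_l1 = 2.0 * sum(m for _, _, m in e.class_shift)
        truth_rows.append({
            "mutation_id": e.mutation_id, "gene_id": gene.gene_id,
            "sample_id": mut_sample_of[e.mutation_id],
            "vaf_dna": e.vaf_dna, "level_multiplier": e.level_multiplier,
            "class_shift_l1": shift_l1,
            "strand_shift": math.nan if e.strand_shift is None else e.strand_shift,
            "wt_f5p": gene.wt.f5p,
            "affects_level": int(e.level_multiplier != 1.0),
            "affects_profile": int(bool(e.class_shift)),
            "affects_balance": int(e.strand_shift is not None),
            "seed": seed,
        })
    mut_cols = ["mutation_id", "gene_id", "sample_id", "cancer_type", "hgvs_n",
                "dna_ref_reads", "dna_alt_reads", "homozygous"]
    mutations = pd.DataFrame(mut_rows, columns=mut_cols)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(isomirs, expression, mutations, truth, annotations, config, genes)
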