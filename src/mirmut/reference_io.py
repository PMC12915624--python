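"""Reference annotations, mutation tables, and isomiR read tables.

Coordinate frame
----------------
All positions use the ``n.`` numbering of noncoding-RNA variants anchored on
the precursor hairpin: ``n.1`` is the first nucleotide of the pre-miRNA,
the 5' flank is numbered ``-25 .. -1`` (there is no position 0), and the
3' flank is ``L+1 .. L+25`` for a precursor of length ``L``.  Every gene is
represented by its *extended* sequence -- 25-nt 5' flank, precursor, 25-nt
3' flank -- so a coordinate maps to exactly one index of that string.

Subregion labels (``flank5``, ``duplex5p``, ``seed5p``, ``loop``,
``duplex3p``, ``seed3p``, ``flank3``) are derived from the annotated mature
arm spans, never from the raw number: everything 5' of the mature-5p start
counts as 5p flank and everything 3' of the mature-3p end as 3p flank,
which matches how positions in the basal stem are labelled in practice.
The seed is mature positions 2-8 of each arm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

FLANK_LEN = 25
MAX_INDEL = 4
MAX_SHIFT = 10

SUBREGIONS = ("flank5", "duplex5p", "seed5p", "loop", "duplex3p", "seed3p", "flank3")

ISOMIR_COLUMNS = [
    "sample_id",
    "gene_id",
    "arm",
    "shift5",
    "shift3",
    "nontemplate",
    "allele",
    "source",
    "count",
]

MUTATION_COLUMNS = [
    "mutation_id",
    "gene_id",
    "sample_id",
    "cancer_type",
    "hgvs_n",
    "dna_ref_reads",
    "dna_alt_reads",
    "homozygous",
]


class VariantParseError(ValueError):
    """Raised when an n.-style variant token cannot be interpreted.

    ``code`` is one of ``bad_token``, ``long_indel``, ``out_of_range``,
    ``ref_mismatch``.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def position_index(position: int) -> int:
    """0-based index of an n.-frame position in the extended sequence.

    ``n.-25`` maps to 0, ``n.-1`` to 24, ``n.1`` to 25 (the 26th letter),
    ``n.L`` to L+24.  Position 0 does not exist.
    """
    if position == 0:
        raise VariantParseError("out_of_range", "position 0 does not exist in the n. frame")
    return position + FLANK_LEN if position < 0 else position + FLANK_LEN - 1


def index_position(index: int) -> int:
    """Inverse of :func:`position_index`."""
    return index - FLANK_LEN if index < FLANK_LEN else index - FLANK_LEN + 1


def span_length(start: int, end: int) -> int:
    """Number of nucleotides in the closed span [start, end], skipping 0."""
    return position_index(end) - position_index(start) + 1


@dataclass(frozen=True)
class MirnaGeneAnnotation:
    """One miRNA gene: extended sequence plus canonical arm coordinates.

    ``mature5p_span`` / ``mature3p_span`` are closed intervals in the
    n. frame (1-based on the precursor sense strand).
    """

    gene_id: str
    precursor_id: str
    precursor_seq: str
    flank5_seq: str
    flank3_seq: str
    mature5p_span: tuple[int, int]
    mature3p_span: tuple[int, int]
    redundant_group: str | None = None

    def __post_init__(self) -> None:
        if len(self.flank5_seq) != FLANK_LEN or len(self.flank3_seq) != FLANK_LEN:
            raise ValueError("bad_flank: flanks must be exactly 25 nt")
        L = self.length
        for lo, hi in (self.mature5p_span, self.mature3p_span):
            if not (1 <= lo <= hi <= L):
                raise ValueError("span outside [1, L]")
        if self.mature5p_span[1] >= self.mature3p_span[0]:
            raise ValueError("mature5p span must strictly precede mature3p span")

    @property
    def length(self) -> int:
        return len(self.precursor_seq)

    @property
    def extended_seq(self) -> str:
        return self.flank5_seq + self.precursor_seq + self.flank3_seq

    def base_at(self, position: int) -> str:
        idx = position_index(position)
        ext = self.extended_seq
        if not 0 <= idx < len(ext):
            raise VariantParseError("out_of_range", f"position {position} outside the extended sequence")
        return ext[idx]

    def seed_span(self, arm: str) -> tuple[int, int]:
        """Seed = mature positions 2-8 of the given arm ('5p' or '3p')."""
        lo, _ = self.mature5p_span if arm == "5p" else self.mature3p_span
        return (lo + 1, lo + 7)

    def subregion(self, position: int) -> str:
        if position == 0 or not (-FLANK_LEN <= position <= self.length + FLANK_LEN):
            raise VariantParseError("out_of_range", f"position {position} outside [-25, L+25]")
        s5, e5 = self.mature5p_span
        s3, e3 = self.mature3p_span
        if position < s5:
            return "flank5"
        if position <= e5:
            lo, hi = self.seed_span("5p")
            return "seed5p" if lo <= position <= hi else "duplex5p"
        if position < s3:
            return "loop"
        if position <= e3:
            lo, hi = self.seed_span("3p")
            return "seed3p" if lo <= position <= hi else "duplex3p"
        return "flank3"

    def in_mature(self, position: int) -> bool:
        return self.subregion(position) in ("duplex5p", "seed5p", "duplex3p", "seed3p")

    def arm_of(self, position: int) -> str | None:
        sub = self.subregion(position)
        if sub in ("duplex5p", "seed5p"):
            return "5p"
        if sub in ("duplex3p", "seed3p"):
            return "3p"
        return None


@dataclass(frozen=True)
class ParsedVariant:
    """Outcome of parsing an n.-style token: coordinates, kind, alleles."""

    kind: str  # substitution | deletion | insertion | duplication
    start: int
    end: int
    ref: str
    alt: str


@dataclass(frozen=True)
class Mutation:
    """One somatic variant with its sample context and DNA read support."""

    mutation_id: str
    gene_id: str
    sample_id: str
    cancer_type: str
    variant: ParsedVariant
    dna_ref_reads: int
    dna_alt_reads: int
    homozygous: bool
    subregion: str | None = None

    @property
    def position(self) -> int:
        return self.variant.start


_SUB_RE = re.compile(r"^n\.(-?\d+)([ACGTUacgtu])>([ACGTUacgtu])$")
_INDEL_RE = re.compile(r"^n\.(-?\d+)(?:[-_](-?\d+))?(del|dup|ins)([ACGTUacgtu]+)$")


def parse_n_position(token: str, L: int, sequence: str | None = None) -> ParsedVariant:
    """Parse an n.-style variant token against a precursor of length ``L``.

    Accepted grammar: ``n.<pos><ref>><alt>`` substitutions,
    ``n.<a>-<b>del<seq>`` / ``n.<a>_<b>dup<seq>`` (either separator) for
    deletions and duplications, ``n.<a>_<b>ins<seq>`` insertions, and the
    single-position forms ``n.<a>del<seq>`` / ``n.<a>dup<seq>``.

    ``sequence``, when given, is the *extended* sequence (flank5 +
    precursor + flank3) used to check the reference allele.
    """
    token = token.strip()

    def check_range(pos: int) -> None:
        if pos == 0 or not (-FLANK_LEN <= pos <= L + FLANK_LEN):
            raise VariantParseError("out_of_range", f"{token}: position {pos} outside [-25, L+25]")

    def check_ref(start: int, ref: str) -> None:
        if sequence is None:
            return
        i = position_index(start)
        found = sequence[i : i + len(ref)].upper().replace("U", "T")
        want = ref.upper().replace("U", "T")
        if found != want:
            raise VariantParseError(
                "ref_mismatch", f"{token}: reference is {found!r} at n.{start}, token says {want!r}"
            )

    m = _SUB_RE.match(token)
    if m:
        pos = int(m.group(1))
        check_range(pos)
        ref, alt = m.group(2).upper(), m.group(3).upper()
        check_ref(pos, ref)
        return ParsedVariant("substitution", pos, pos, ref, alt)

    m = _INDEL_RE.match(token)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) is not None else start
        op = m.group(3)
        seq = m.group(4).upper()
        check_range(start)
        check_range(end)
        if position_index(end) < position_index(start):
            raise VariantParseError("bad_token", f"{token}: span end precedes start")
        if op == "ins":
            if m.group(2) is None or span_length(start, end) != 2:
                raise VariantParseError("bad_token", f"{token}: insertion needs two adjacent positions")
            if len(seq) > MAX_INDEL:
                raise VariantParseError("long_indel", f"{token}: insertion of {len(seq)} nt (> {MAX_INDEL})")
            return ParsedVariant("insertion", start, end, "", seq)
        n = span_length(start, end)
        if n != len(seq):
            raise VariantParseError("bad_token", f"{token}: span covers {n} nt but sequence has {len(seq)}")
        if n > MAX_INDEL:
            raise VariantParseError("long_indel", f"{token}: {op} of {n} nt (> {MAX_INDEL})")
        check_ref(start, seq)
        if op == "del":
            return ParsedVariant("deletion", start, end, seq, "")
        return ParsedVariant("duplication", start, end, seq, seq + seq)

    raise VariantParseError("bad_token", f"cannot parse variant token {token!r}")


def format_n_position(variant: ParsedVariant) -> str:
    """Serialize a parsed variant back to its n.-style token.

    Inverse of :func:`parse_n_position` on in-range tokens (range forms use
    the ``-`` separator for deletions and ``_`` for duplications and
    insertions, the spellings used for these kinds in mutation names).
    """
    if variant.kind == "substitution":
        return f"n.{variant.start}{variant.ref}>{variant.alt}"
    if variant.kind == "deletion":
        if variant.start == variant.end:
            return f"n.{variant.start}del{variant.ref}"
        return f"n.{variant.start}-{variant.end}del{variant.ref}"
    if variant.kind == "duplication":
        if variant.start == variant.end:
            return f"n.{variant.start}dup{variant.ref}"
        return f"n.{variant.start}_{variant.end}dup{variant.ref}"
    if variant.kind == "insertion":
        return f"n.{variant.start}_{variant.end}ins{variant.alt}"
    raise ValueError(f"unknown variant kind {variant.kind!r}")


@dataclass(frozen=True)
class Rejection:
    item_id: str
    reason: str


def read_annotations(
    path_fasta: str | Path, path_coords: str | Path
) -> tuple[dict[str, MirnaGeneAnnotation], list[Rejection]]:
    """Load gene annotations from an extended-sequence FASTA plus a coordinate TSV.

    The FASTA must contain, per gene, the extended sequence (25-nt 5' flank
    + precursor + 25-nt 3' flank) under the gene_id.  The TSV has columns
    ``gene_id, precursor_id, L, mature5p_span, mature3p_span,
    redundant_group`` with spans written ``start-end`` and missing values as
    ``.``.  Genes violating an invariant are reported with a reason code,
    not silently dropped.
    """
    seqs = {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path_fasta), "fasta")}
    coords = pd.read_csv(path_coords, sep="\t", dtype=str).fillna(".")

    def parse_span(text: str) -> tuple[int, int] | None:
        text = text.strip()
        if text in (".", "", "NA"):
            return None
        lo, hi = text.split("-")
        return (int(lo), int(hi))

    annotations: dict[str, MirnaGeneAnnotation] = {}
    rejections: list[Rejection] = []
    for row in coords.itertuples(index=False):
        gene_id = row.gene_id
        if gene_id not in seqs:
            rejections.append(Rejection(gene_id, "missing_sequence"))
            continue
        L = int(row.L)
        ext = seqs[gene_id]
        if len(ext) != L + 2 * FLANK_LEN:
            rejections.append(Rejection(gene_id, "bad_flank"))
            continue
        span5 = parse_span(row.mature5p_span)
        span3 = parse_span(row.mature3p_span)
        if span5 is None or span3 is None:
            rejections.append(Rejection(gene_id, "arm_undefined"))
            continue
        group = None if row.redundant_group in (".", "") else row.redundant_group
        try:
            annotations[gene_id] = MirnaGeneAnnotation(
                gene_id=gene_id,
                precursor_id=row.precursor_id,
                precursor_seq=ext[FLANK_LEN : FLANK_LEN + L],
                flank5_seq=ext[:FLANK_LEN],
                flank3_seq=ext[FLANK_LEN + L :],
                mature5p_span=span5,
                mature3p_span=span3,
                redundant_group=group,
            )
        except ValueError as err:
            rejections.append(Rejection(gene_id, str(err).split(":")[0]))
    return annotations, rejections


def write_annotations(
    annotations: Mapping[str, MirnaGeneAnnotation], path_fasta: str | Path, path_coords: str | Path
) -> None:
    with open(path_fasta, "w") as fh:
        for ann in annotations.values():
            fh.write(f">{ann.gene_id}\n{ann.extended_seq}\n")
    rows = [
        {
            "gene_id": ann.gene_id,
            "precursor_id": ann.precursor_id,
            "L": ann.length,
            "mature5p_span": f"{ann.mature5p_span[0]}-{ann.mature5p_span[1]}",
            "mature3p_span": f"{ann.mature3p_span[0]}-{ann.mature3p_span[1]}",
            "redundant_group": ann.redundant_group or ".",
        }
        for ann in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path_coords, sep="\t", index=False)


def read_mutation_table(
    path: str | Path, annotations: Mapping[str, MirnaGeneAnnotation] | None = None
) -> tuple[list[Mutation], list[Rejection]]:
    """Read a mutation TSV and parse the n.-style tokens.

    Rows whose token fails to parse (long indel, out-of-range position,
    reference mismatch against the annotation) come back as rejections
    carrying the parser's reason code.  Genes absent from ``annotations``
    are parsed without reference checking and get ``subregion=None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    mutations: list[Mutation] = []
    rejections: list[Rejection] = []
    for row in df.itertuples(index=False):
        ann = annotations.get(row.gene_id) if annotations else None
        L = ann.length if ann else 200  # permissive bound when the gene is unknown
        try:
            variant = parse_n_position(row.hgvs_n, L, ann.extended_seq if ann else None)
            sub = ann.subregion(variant.start) if ann else None
        except VariantParseError as err:
            rejections.append(Rejection(row.mutation_id, err.code))
            continue
        mutations.append(
            Mutation(
                mutation_id=row.mutation_id,
                gene_id=row.gene_id,
                sample_id=row.sample_id,
                cancer_type=row.cancer_type,
                variant=variant,
                dna_ref_reads=int(row.dna_ref_reads),
                dna_alt_reads=int(row.dna_alt_reads),
                homozygous=str(row.homozygous).strip().lower() in ("1", "true", "yes"),
                subregion=sub,
            )
        )
    return mutations, rejections


def write_mutation_table(mutations: Iterable[Mutation], path: str | Path) -> None:
    rows = [
        {
            "mutation_id": m.mutation_id,
            "gene_id": m.gene_id,
            "sample_id": m.sample_id,
            "cancer_type": m.cancer_type,
            "hgvs_n": format_n_position(m.variant),
            "dna_ref_reads": m.dna_ref_reads,
            "dna_alt_reads": m.dna_alt_reads,
            "homozygous": int(m.homozygous),
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


_ALLELES = {"WT", "MUT", "AMBIG", "NA"}
_SOURCES = {"exclusive", "ambiguous", "snps"}


def _validate_isomirs(df: pd.DataFrame) -> tuple[pd.DataFrame, list[Rejection]]:
    if (df["count"] < 0).any():
        raise ValueError("negative read counts in isomiR table")
    bad_allele = ~df["allele"].isin(_ALLELES)
    bad_source = ~df["source"].isin(_SOURCES)
    if bad_allele.any() or bad_source.any():
        raise ValueError("unknown allele/source labels in isomiR table")
    out_of_range = (df["shift5"].abs() > MAX_SHIFT) | (df["shift3"].abs() > MAX_SHIFT)
    rejections = [
        Rejection(f"{r.sample_id}:{r.gene_id}:{r.arm}:{r.shift5}|{r.shift3}", "shift_out_of_range")
        for r in df[out_of_range].itertuples(index=False)
    ]
    return df[~out_of_range].reset_index(drop=True), rejections


def read_isomir_tables(
    paths: str | Path | Sequence[str | Path] | Mapping[str, str | Path],
    dialect: str = "native_tsv",
) -> tuple[pd.DataFrame, list[Rejection]]:
    """Read isomiR-resolved read tables into the native schema.

    ``dialect='native_tsv'``: one or more TSVs with exactly the columns
    ``sample_id, gene_id, arm, shift5, shift3, nontemplate, allele, source,
    count[, rpm]``; unknown columns are a hard error, as are negative
    counts.  Records with |shift| > 10 are rejected with reason
    ``shift_out_of_range`` (ends are only trusted within 10 nt of the
    canonical ends).

    ``dialect='isomirmap'``: ``paths`` is a mapping from source
    (``exclusive`` / ``ambiguous`` / ``snps``) to a per-source file
    carrying the minimal column subset ``sample_id, gene_id, arm, shift5,
    shift3, nontemplate, count[, rpm]``.  Source and allele are assigned
    from the originating file (exclusive -> WT, ambiguous -> AMBIG,
    snps -> MUT); any extra columns in those files are ignored.
    """
    if dialect == "native_tsv":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        frames = []
        for p in paths:
            df = pd.read_csv(p, sep="\t")
            extra = [c for c in df.columns if c not in ISOMIR_COLUMNS + ["rpm"]]
            if extra:
                raise ValueError(f"unknown columns in native isomiR table: {extra}")
            missing = [c for c in ISOMIR_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"native isomiR table missing columns: {missing}")
            frames.append(df)
        merged = pd.concat(frames, ignore_index=True)
    elif dialect == "isomirmap":
        if not isinstance(paths, Mapping):
            raise ValueError("isomirmap dialect takes a mapping source -> path")
        allele_for = {"exclusive": "WT", "ambiguous": "AMBIG", "snps": "MUT"}
        frames = []
        for source, p in paths.items():
            if source not in _SOURCES:
                raise ValueError(f"unknown isoMiRmap source {source!r}")
            df = pd.read_csv(p, sep="\t")
            keep = [c for c in ISOMIR_COLUMNS + ["rpm"] if c in df.columns]
            df = df[keep].copy()
            df["source"] = source
            df["allele"] = allele_for[source]
            frames.append(df)
        merged = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown isomiR dialect {dialect!r}")

    merged = merged.astype(
        {"shift5": int, "shift3": int, "nontemplate": int, "count": int}
    )
    if "rpm" not in merged.columns:
        merged["rpm"] = merged["count"].astype(float)
    merged = merged[ISOMIR_COLUMNS + ["rpm"]]
    return _validate_isomirs(merged)


def write_isomir_tables(df: pd.DataFrame, path: str | Path) -> None:
    """Serialize the native isomiR schema; read -> write round-trips byte-identically."""
    out = df[ISOMIR_COLUMNS + ["rpm"]].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Sample x gene RPM matrix (TSV, first column sample_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")
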