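"""Parsing of somatic-mutation tables and construction of cohort matrices.

Input records are single-base substitutions (SNVs). Anything else --
insertions, deletions, multi-base or symbolic alleles -- is rejected at parse
time and accounted for in a rejection log, mirroring the usual pre-analysis
exclusion of non-SNV calls. Coordinates are 1-based inclusive (ICGC
convention); the trinucleotide context of a record at position ``pos`` is
``[pos-1, pos+1]`` on the reference.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-collapsed substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical ordering of the 96 trinucleotide substitution channels:
#: substitution class (slow), 5' base, 3' base (fast), e.g. "A[C>A]A".
MOTIF_CLASSES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

MOTIF_INDEX = {name: i for i, name in enumerate(MOTIF_CLASSES)}

#: Chromosome names treated as mitochondrial (excluded from signature catalogs).
MITOCHONDRIAL = frozenset({"MT", "M", "chrM", "chrMT"})


class DialectError(ValueError):
    """Unknown input dialect or header not matching the declared dialect."""


class ParseError(ValueError):
    """Malformed row encountered in strict parsing mode."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution.

    ``position`` is 1-based. ``ref_allele`` and ``alt_allele`` are single
    bases and differ; records violating this are rejected upstream and never
    stored.
    """

    sample_id: str
    donor_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene_id: str
    consequence: str
    cancer_type: str

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(f"alleles must be single bases, got "
                             f"{self.ref_allele!r}>{self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")


@dataclass
class GeneCatalog:
    """Mapping of gene_id -> (symbol, is_coding)."""

    entries: dict[str, tuple[str, bool]]

    def is_coding(self, gene_id: str) -> bool:
        entry = self.entries.get(gene_id)
        return entry is not None and entry[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def coding_genes(self) -> list[str]:
        return sorted(g for g, (_, c) in self.entries.items() if c)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        """Read a catalog TSV with columns gene_id, symbol, is_coding."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "symbol", "is_coding"}
        if not required.issubset(df.columns):
            raise DialectError(f"gene catalog needs columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_ids in catalog must be unique")
        entries = {
            row.gene_id: (row.symbol, str(row.is_coding).lower() in ("1", "true", "yes"))
            for row in df.itertuples()
        }
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, s, int(c)) for g, (s, c) in sorted(self.entries.items())]
        pd.DataFrame(rows, columns=["gene_id", "symbol", "is_coding"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class RejectionLog:
    """Machine-readable account of rows dropped during parsing/filtering."""

    rows: list[tuple[int, str, str]] = field(default_factory=list)

    def add(self, line_no: int, reason: str, detail: str = "") -> None:
        self.rows.append((line_no, reason, detail))

    def __len__(self) -> int:
        return len(self.rows)

    def counts(self) -> Counter:
        return Counter(reason for _, reason, _ in self.rows)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows, columns=["line", "reason", "detail"]).to_csv(
            path, sep="\t", index=False)


# Logical field -> column name, per dialect.
DIALECTS: dict[str, dict[str, str]] = {
    "icgc_tsv": {
        "sample_id": "icgc_sample_id",
        "donor_id": "icgc_donor_id",
        "chromosome": "chromosome",
        "position": "chromosome_start",
        "ref_allele": "reference_genome_allele",
        "alt_allele": "mutated_to_allele",
        "gene_id": "gene_affected",
        "consequence": "consequence_type",
        "cancer_type": "project_code",
    },
    "maf_like": {
        "sample_id": "Tumor_Sample_Barcode",
        "donor_id": "Patient_ID",
        "chromosome": "Chromosome",
        "position": "Start_Position",
        "ref_allele": "Reference_Allele",
        "alt_allele": "Tumor_Seq_Allele2",
        "gene_id": "Hugo_Symbol",
        "consequence": "Variant_Classification",
        "cancer_type": "Project_Code",
    },
}


def read_mutations(
    path: str | Path,
    dialect: str = "icgc_tsv",
    strict: bool = False,
    column_map: Mapping[str, str] | None = None,
    deduplicate: bool = True,
) -> tuple[list[MutationRecord], RejectionLog]:
    """Parse a mutation TSV into validated SNV records plus a rejection log.

    Non-SNV rows (multi-base or symbolic alleles, ref == alt) are rejected and
    counted, never returned. Duplicate calls (same sample, locus and alleles,
    as repeated by some exports across annotations) are collapsed with a
    logged count. In strict mode any malformed row raises :class:`ParseError`.
    """
    path = Path(path)
    if dialect not in DIALECTS and column_map is None:
        raise DialectError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    colmap = dict(DIALECTS.get(dialect, {}))
    if column_map:
        colmap.update(column_map)

    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read mutation file {path}: {exc}") from exc

    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise DialectError(
            f"header of {path} does not match dialect {dialect!r}: "
            f"missing columns {missing}")

    log = RejectionLog()
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    get = {logical: df[col].to_numpy() for logical, col in colmap.items()}
    for i in range(len(df)):
        line_no = i + 2  # 1-based, after header
        ref = get["ref_allele"][i].upper()
        alt = get["alt_allele"][i].upper()
        if len(ref) != 1 or len(alt) != 1 or ref == "-" or alt == "-":
            log.add(line_no, "non-SNV", f"{ref}>{alt}")
            if strict:
                raise ParseError(f"line {line_no}: non-SNV alleles {ref}>{alt}")
            continue
        if ref not in BASES or alt not in BASES:
            log.add(line_no, "invalid allele", f"{ref}>{alt}")
            if strict:
                raise ParseError(f"line {line_no}: invalid allele {ref}>{alt}")
            continue
        if ref == alt:
            log.add(line_no, "ref equals alt", ref)
            if strict:
                raise ParseError(f"line {line_no}: ref equals alt")
            continue
        try:
            pos = int(get["position"][i])
            if pos < 1:
                raise ValueError
        except ValueError:
            log.add(line_no, "bad position", str(get["position"][i]))
            if strict:
                raise ParseError(f"line {line_no}: bad position")
            continue
        rec = MutationRecord(
            sample_id=get["sample_id"][i],
            donor_id=get["donor_id"][i],
            chromosome=get["chromosome"][i],
            position=pos,
            ref_allele=ref,
            alt_allele=alt,
            gene_id=get["gene_id"][i],
            consequence=get["consequence"][i],
            cancer_type=get["cancer_type"][i],
        )
        if deduplicate:
            key = (rec.sample_id, rec.chromosome, rec.position, ref, alt, rec.gene_id)
            if key in seen:
                log.add(line_no, "duplicate", rec.sample_id)
                continue
            seen.add(key)
        records.append(rec)
    return records, log


def write_mutations(records: Iterable[MutationRecord], path: str | Path,
                    dialect: str = "icgc_tsv") -> None:
    """Serialize records back to a dialect TSV (round-trips with read_mutations)."""
    colmap = DIALECTS[dialect]
    rows = [
        {col: getattr(r, logical) for logical, col in colmap.items()}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(colmap.values())).to_csv(path, sep="\t", index=False)


def filter_coding(
    records: list[MutationRecord],
    catalog: GeneCatalog,
    strict: bool = False,
) -> tuple[list[MutationRecord], RejectionLog]:
    """Keep records in coding genes of the catalog, preserving order.

    Records whose gene is absent from the catalog are dropped and counted
    (fatal in strict mode); records in non-coding genes are dropped silently
    into the log as well.
    """
    if len(catalog) == 0:
        raise ValueError("gene catalog is empty")
    kept: list[MutationRecord] = []
    log = RejectionLog()
    for i, rec in enumerate(records):
        if rec.gene_id not in catalog:
            log.add(i, "gene not in catalog", rec.gene_id)
            if strict:
                raise ParseError(f"record {i}: gene {rec.gene_id!r} not in catalog")
            continue
        if not catalog.is_coding(rec.gene_id):
            log.add(i, "non-coding gene", rec.gene_id)
            continue
        kept.append(rec)
    return kept, log


@dataclass
class CohortMatrix:
    """Sample x gene nonnegative integer mutation-count matrix.

    ``counts`` is indexed by sample_id (rows) and gene_id (columns), both
    sorted lexicographically so orders are stable and deterministic. The
    binary view marks whether a sample carries >= 1 mutation in a gene.
    """

    counts: pd.DataFrame
    cancer_type_of_sample: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts > 0).astype(np.int64)

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.cancer_type_of_sample.unique())

    def samples_of_type(self, cancer_type: str) -> list[str]:
        mask = self.cancer_type_of_sample == cancer_type
        if not mask.any():
            raise KeyError(f"unknown cancer type {cancer_type!r}")
        return list(self.cancer_type_of_sample.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "cancer_type", self.cancer_type_of_sample.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        ctype = df.pop("cancer_type")
        df.index.name = None
        df.columns.name = None
        ctype.index.name = None
        ctype.name = None
        return cls(counts=df.astype(np.int64), cancer_type_of_sample=ctype)


def build_count_matrix(records: list[MutationRecord]) -> CohortMatrix:
    """Tally records into a CohortMatrix.

    counts[s, g] is the number of records for sample s in gene g, so the sum
    of the matrix equals the number of records; a sample mutated several
    times in one gene still contributes a single mutated sample to the
    binary view used for gene tallies.
    """
    if not records:
        return CohortMatrix(
            counts=pd.DataFrame(dtype=np.int64),
            cancer_type_of_sample=pd.Series(dtype=object),
        )
    samples = sorted({r.sample_id for r in records})
    genes = sorted({r.gene_id for r in records})
    s_idx = {s: i for i, s in enumerate(samples)}
    g_idx = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(samples), len(genes)), dtype=np.int64)
    ctype: dict[str, str] = {}
    for r in records:
        counts[s_idx[r.sample_id], g_idx[r.gene_id]] += 1
        ctype[r.sample_id] = r.cancer_type
    return CohortMatrix(
        counts=pd.DataFrame(counts, index=samples, columns=genes),
        cancer_type_of_sample=pd.Series(ctype).reindex(samples),
    )


class ReferenceMismatch(ValueError):
    """Reference genome base does not match the record's ref allele."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def motif_class(trinucleotide: str, alt: str) -> str:
    """Classify a substitution into one of the 96 pyrimidine-collapsed channels.

    ``trinucleotide`` is the reference context (5' base, mutated base, 3'
    base); purine-reference substitutions are reverse-complemented first.
    """
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3 or any(b not in BASES for b in tri) or alt not in BASES:
        raise ValueError(f"invalid context {trinucleotide!r} alt {alt!r}")
    if tri[1] == alt:
        raise ValueError("ref and alt must differ")
    if tri[1] in "AG":  # purine reference: collapse to the pyrimidine strand
        tri = revcomp(tri)
        alt = COMPLEMENT[alt]
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


def extract_motif(record: MutationRecord, reference) -> int:
    """Return the 96-channel index of a record's trinucleotide substitution.

    ``reference`` is a pyfaidx.Fasta-like accessor (``reference[chrom]``
    sliceable with 0-based coordinates). Raises :class:`ReferenceMismatch` if
    the reference base at the locus differs from the record's ref allele, and
    ValueError with an "ambiguous" tag if a flanking base is N or the locus
    touches a contig edge.
    """
    chrom = reference[record.chromosome]
    if record.position < 2 or record.position > len(chrom) - 1:
        raise ValueError(
            f"position {record.chromosome}:{record.position} at contig edge")
    tri = str(chrom[record.position - 2:record.position + 1]).upper()
    if tri[1] != record.ref_allele:
        raise ReferenceMismatch(
            f"{record.chromosome}:{record.position} reference is {tri[1]!r}, "
            f"record says {record.ref_allele!r}")
    if any(b not in BASES for b in tri):
        raise ValueError(
            f"ambiguous flanking base in context {tri!r} at "
            f"{record.chromosome}:{record.position}")
    return MOTIF_INDEX[motif_class(tri, record.alt_allele)]


def records_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    """Flat DataFrame view of records (one row per record)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
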