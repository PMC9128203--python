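"""On-disk formats and in-memory containers shared by the whole pipeline.

The central container is :class:`GenotypeMatrix`: a samples x variants dosage
matrix (values in [0, 2], ``NaN`` marks a missing dosage) whose columns carry
:class:`VariantRecord` metadata spanning three variant classes — ordinary
SNPs, classical (two-field) HLA alleles, and biallelic amino-acid indicator
variables derived from them.

Dosage input is accepted either as VCF with a per-sample ``DS`` FORMAT field,
or as a TSV dialect with variants as rows: the first six columns are
``id, kind, chrom, pos, ref, alt`` followed by one column per sample.  The
same TSV layout is reused for classical-allele dosage tables so that all
dosage tables in a study share one shape.

Coordinates are 1-based inclusive for variants and transcription start sites
(VCF convention) and 0-based half-open for BED intervals.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not follow its documented dialect."""


class ValidationError(ValueError):
    """Contents parse but violate a domain invariant (e.g. dosage > 2)."""


class IntegrityError(ValueError):
    """Conflicting or inconsistent records within one source."""


class VariantKind(str, enum.Enum):
    SNP = "SNP"
    HLA_ALLELE = "HLA_ALLELE"
    AA_POLY = "AA_POLY"


@dataclass(frozen=True)
class VariantRecord:
    """Metadata for one dosage column.

    ``residue_pos``/``residue`` are the protein position and amino acid for
    AA_POLY indicators; ``gene`` is set for HLA_ALLELE and AA_POLY variants.
    ``alt_frequency`` is the mean dosage / 2 over non-missing samples.
    """

    id: str
    kind: VariantKind
    chrom: str
    pos: int
    ref: str = "."
    alt: str = "."
    gene: str | None = None
    residue_pos: int | None = None
    residue: str | None = None
    alt_frequency: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind == VariantKind.AA_POLY:
            if self.gene is None or self.residue_pos is None or not self.residue:
                raise ValidationError(
                    f"AA_POLY variant {self.id!r} requires gene, residue_pos and residue"
                )
        if self.kind == VariantKind.HLA_ALLELE:
            if self.gene is None:
                raise ValidationError(f"HLA_ALLELE variant {self.id!r} requires gene")
            if "*" not in self.id or ":" not in self.id.split("*", 1)[1]:
                raise ValidationError(
                    f"HLA_ALLELE id {self.id!r} must encode a two-field allele name "
                    "(e.g. C*07:02)"
                )


class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Dosages are float64 in [0, 2]; missing entries are ``NaN``.  Column order
    matches ``variants``; sample and variant ids are unique.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        dosages: np.ndarray,
    ) -> None:
        sample_ids = list(sample_ids)
        variants = list(variants)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape != (len(sample_ids), len(variants)):
            raise ValidationError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(variants)} variants"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate variant ids: {dupes[:5]}")
        with np.errstate(invalid="ignore"):
            bad = (dosages < 0) | (dosages > 2)
        if bad.any():
            j = int(np.argwhere(bad.any(axis=0))[0][0])
            raise ValidationError(
                f"dosage outside [0, 2] for variant {variants[j].id!r}"
            )
        self.sample_ids = sample_ids
        self.variants = variants
        self.dosages = dosages

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None
        return self.dosages[:, j]

    def select(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v: j for j, v in enumerate(self.variant_ids)}
        cols = [index[v] for v in variant_ids]
        return GenotypeMatrix(
            self.sample_ids,
            [self.variants[j] for j in cols],
            self.dosages[:, cols],
        )

    def with_frequencies(self) -> "GenotypeMatrix":
        """Return a copy whose variant records carry computed alt frequencies."""
        freqs = alt_frequencies(self.dosages)
        variants = [
            dataclasses.replace(v, alt_frequency=float(f))
            for v, f in zip(self.variants, freqs)
        ]
        return GenotypeMatrix(self.sample_ids, variants, self.dosages)


def alt_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per column: mean dosage / 2 over non-missing entries."""
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(dosages), axis=0)
        sums = np.nansum(dosages, axis=0)
    freq = np.full(dosages.shape[1], np.nan)
    ok = counts > 0
    freq[ok] = sums[ok] / (2.0 * counts[ok])
    return freq


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes and covariates.

    ``binary`` columns contain only {0, 1, NaN}; ``quantitative`` and
    ``covariates`` are float columns of the same length as ``sample_ids``.
    """

    sample_ids: list[str]
    binary: dict[str, np.ndarray] = field(default_factory=dict)
    quantitative: dict[str, np.ndarray] = field(default_factory=dict)
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for group in (self.binary, self.quantitative, self.covariates):
            for name, col in group.items():
                arr = np.asarray(col, dtype=float)
                if arr.shape != (n,):
                    raise ValidationError(
                        f"column {name!r} has length {arr.shape}, expected {n}"
                    )
                group[name] = arr
        for name, col in self.binary.items():
            vals = col[~np.isnan(col)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValidationError(f"binary column {name!r} has values outside {{0,1}}")

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(self.covariates) if names is None else list(names)
        if not names:
            return np.empty((len(self.sample_ids), 0))
        return np.column_stack([self.covariates[n] for n in names])

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {}
        data.update(self.binary)
        data.update(self.quantitative)
        data.update(self.covariates)
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))


class AlleleAAMap:
    """gene -> allele -> {residue position -> residue} dictionary.

    Encodes which amino acid each classical allele carries at each numbered
    protein position; positions missing from an allele are sequence gaps.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Mapping[int, str]]]):
        self.entries: dict[str, dict[str, dict[int, str]]] = {
            g: {a: dict(pmap) for a, pmap in alleles.items()}
            for g, alleles in entries.items()
        }
        for gene, alleles in self.entries.items():
            for allele, pmap in alleles.items():
                for pos, res in pmap.items():
                    if not res:
                        raise ValidationError(
                            f"empty residue for {gene} {allele} position {pos}"
                        )

    def genes(self) -> list[str]:
        return list(self.entries)

    def alleles(self, gene: str) -> list[str]:
        return list(self.entries[gene])

    def residue(self, gene: str, allele: str, pos: int) -> str | None:
        return self.entries.get(gene, {}).get(allele, {}).get(pos)

    def positions(self, gene: str) -> list[int]:
        pos: set[int] = set()
        for pmap in self.entries.get(gene, {}).values():
            pos.update(pmap)
        return sorted(pos)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    label: str


@dataclass
class IntervalSet:
    intervals: list[Interval]

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv.start >= iv.end:
                raise ValidationError(f"empty interval {iv}")
            if not iv.label:
                raise ValidationError(f"interval without label: {iv}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValidationError(f"TSS must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_TSV_META_COLS = ["id", "kind", "chrom", "pos", "ref", "alt"]
MISSING_TOKENS = {".", "", "NA", "nan", "NaN"}


def load_genotypes(path: str | os.PathLike, format: str = "tsv") -> GenotypeMatrix:
    """Load a dosage matrix from VCF (FORMAT/DS) or the variants-as-rows TSV.

    ``alt_frequency`` is computed from the loaded dosages; missing entries
    (``.`` in TSV, missing DS in VCF) are preserved as NaN and excluded from
    the frequency.
    """
    if format == "vcf_ds":
        return _load_vcf_ds(os.fspath(path))
    if format == "tsv":
        return _load_tsv_dosages(os.fspath(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _load_vcf_ds(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise FormatError(
                f"variant {rec.ID or rec.POS} lacks a DS FORMAT field in {path}"
            )
        col = np.asarray(ds, dtype=float).reshape(len(sample_ids))
        col = np.where(col < -1, np.nan, col)  # htslib missing sentinel
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(
            VariantRecord(
                id=vid,
                kind=VariantKind.SNP,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
            )
        )
        rows.append(col)
    dosages = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, variants, dosages).with_frequencies()


def _load_tsv_dosages(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_META_COLS)] != _TSV_META_COLS:
            raise FormatError(
                f"{path}:1: header must start with {_TSV_META_COLS}, got {header[:6]}"
            )
        sample_ids = header[len(_TSV_META_COLS):]
        variants: list[VariantRecord] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            vid, kind, chrom, pos, ref, alt = fields[:6]
            try:
                kind_enum = VariantKind(kind)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unknown variant kind {kind!r}")
            gene = residue = None
            residue_pos = None
            if kind_enum == VariantKind.HLA_ALLELE:
                gene = vid.split("*", 1)[0]
            elif kind_enum == VariantKind.AA_POLY:
                # ids follow AA_<GENE>_<pos>_<RESIDUE>; the alt column keeps
                # the residue verbatim (ids are uppercased)
                try:
                    _, gene, rp, residue = vid.split("_", 3)
                    residue_pos = int(rp)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: AA_POLY id {vid!r} not AA_<GENE>_<pos>_<RES>"
                    )
                if alt not in (".", ""):
                    residue = alt
            vals = np.array(
                [np.nan if f in MISSING_TOKENS else float(f) for f in fields[6:]]
            )
            with np.errstate(invalid="ignore"):
                if np.any((vals < 0) | (vals > 2)):
                    raise ValidationError(
                        f"{path}:{lineno}: dosage outside [0, 2] for variant {vid!r}"
                    )
            variants.append(
                VariantRecord(
                    id=vid,
                    kind=kind_enum,
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    residue_pos=residue_pos,
                    residue=residue,
                )
            )
            rows.append(vals)
    dosages = (
        np.vstack(rows).T if rows else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids, variants, dosages).with_frequencies()


def write_genotypes(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the variants-as-rows dosage TSV (missing as ``.``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_META_COLS + list(G.sample_ids)) + "\n")
        for j, v in enumerate(G.variants):
            vals = [
                "." if math.isnan(d) else format(d, ".6g") for d in G.dosages[:, j]
            ]
            fh.write(
                "\t".join([v.id, v.kind.value, v.chrom, str(v.pos), v.ref, v.alt] + vals)
                + "\n"
            )


def load_allele_aa_map(path: str | os.PathLike) -> AlleleAAMap:
    """Load the flat 4-column allele -> amino-acid dictionary.

    TSV columns: gene, allele, residue_pos, residue.  Identical duplicate rows
    are tolerated; rows assigning two residues to one (gene, allele, position)
    are an integrity error.
    """
    entries: dict[str, dict[str, dict[int, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "allele", "residue_pos", "residue"]:
            raise FormatError(
                f"{path}:1: expected columns gene/allele/residue_pos/residue, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                gene, allele, rp, residue = line.rstrip("\n").split("\t")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                pos = int(rp)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: residue_pos {rp!r} is not an integer"
                )
            pmap = entries.setdefault(gene, {}).setdefault(allele, {})
            if pos in pmap and pmap[pos] != residue:
                raise IntegrityError(
                    f"{path}:{lineno}: conflicting residues {pmap[pos]!r} vs "
                    f"{residue!r} for {gene} {allele} position {pos}"
                )
            pmap[pos] = residue
    return AlleleAAMap(entries)


def write_allele_aa_map(aa_map: AlleleAAMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tallele\tresidue_pos\tresidue\n")
        for gene in sorted(aa_map.entries):
            for allele in sorted(aa_map.entries[gene]):
                for pos in sorted(aa_map.entries[gene][allele]):
                    fh.write(f"{gene}\t{allele}\t{pos}\t{aa_map.entries[gene][allele][pos]}\n")


def load_intervals(path: str | os.PathLike) -> IntervalSet:
    """Load BED3/BED4 intervals (0-based half-open); label defaults to filename stem."""
    stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end} (empty interval)"
                )
            label = fields[3] if len(fields) > 3 and fields[3] else stem
            intervals.append(Interval(chrom, start, end, label))
    return IntervalSet(intervals)


def load_phenotypes(path: str | os.PathLike,
                    binary: Sequence[str] = (),
                    quantitative: Sequence[str] = (),
                    covariates: Sequence[str] = ()) -> PhenotypeTable:
    """Load a sample_id-keyed phenotype/covariate TSV.

    Columns not named in any of the three groups are treated as covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing sample_id column")
    named = set(binary) | set(quantitative) | set(covariates)
    extra = [c for c in df.columns if c != "sample_id" and c not in named]
    return PhenotypeTable(
        sample_ids=df["sample_id"].tolist(),
        binary={c: df[c].to_numpy(float) for c in binary},
        quantitative={c: df[c].to_numpy(float) for c in quantitative},
        covariates={c: df[c].to_numpy(float) for c in list(covariates) + extra},
    )


def load_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene model TSV needs columns {sorted(required)}")
    strand = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        GeneModel(str(g), str(c), int(t), str(s))
        for g, c, t, s in zip(df["gene_id"], df["chrom"], df["tss"], strand)
    ]


# ---------------------------------------------------------------------------
# Generic result-table writer
# ---------------------------------------------------------------------------

_PVALUE_FIELDS = {"p", "p_two_sided", "p_one_sided", "p_het", "q", "hwe_p", "p_value"}


def _format_value(name: str, value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        if math.isnan(value):
            return "."
        if name in _PVALUE_FIELDS:
            return f"{value:.6e}"
        return format(value, ".6g")
    if isinstance(value, (list, tuple)):
        return ",".join(str(x) for x in value)
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def write_table(records: Iterable, path: str | os.PathLike) -> None:
    """Write homogeneous dataclass/dict records as a TSV.

    Column order is the dataclass field order (or first record's key order);
    floats are rendered at 6 significant digits, p-value columns in
    scientific notation, missing values as ``.``.  An empty record list
    produces a header-only file when the record type is known, otherwise an
    empty file.
    """
    records = list(records)
    with open(path, "w") as fh:
        if not records:
            return
        first = records[0]
        if dataclasses.is_dataclass(first):
            names = [f.name for f in dataclasses.fields(first)]
            rows = [
                [getattr(r, n) for n in names] for r in records
            ]
        elif isinstance(first, Mapping):
            names = list(first)
            rows = [[r.get(n) for n in names] for r in records]
        else:
            raise TypeError("records must be dataclasses or mappings")
        fh.write("\t".join(names) + "\n")
        for row in rows:
            fh.write("\t".join(_format_value(n, v) for n, v in zip(names, row)) + "\n")


def write_empty_table(fieldnames: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(fieldnames) + "\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a :func:`write_table` TSV with ``.`` as missing."""
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
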