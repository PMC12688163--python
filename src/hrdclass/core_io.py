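"""Typed readers/writers for the external formats and shared domain types.

All genomic coordinates are 1-based inclusive (SEG/ASCAT convention).
Converters from 0-based half-open intervals take an explicit ``zero_based``
flag.  Tri-state evidence flags serialise as {1, 0, NA}.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import schemas

log = logging.getLogger(__name__)

BLOCKS = ("CNA", "ASCN", "SNV")
VARIANT_CLASSES = ("SNV", "DNV", "insertion", "deletion", "other")
TRISTATE = ("yes", "no", "missing")

EVIDENCE_FLAGS = (
    "germline_brca1", "germline_brca2", "somatic_brca1", "somatic_brca2",
    "brca1_methylation", "loh_brca1", "loh_brca2",
)

SEGMENT_COLUMNS = ("sample_id", "chrom", "start_bp", "end_bp", "total_cn")
ASCN_COLUMNS = SEGMENT_COLUMNS + ("major_cn", "minor_cn")
MUTATION_COLUMNS = ("sample_id", "chrom", "pos", "ref_allele", "alt_allele",
                    "variant_class")


class FormatError(ValueError):
    """A file does not match its declared format."""


class ValidationError(ValueError):
    """A table violates a domain invariant."""


class BoundsError(ValidationError):
    """Coordinates fall outside the genome annotation."""


class SchemaError(ValueError):
    """Channel names do not match a canonical schema."""


class ConfigurationError(ValueError):
    """A requested name is absent from a catalogue/registry."""


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomeAnnotation:
    """Chromosome lengths plus centromere intervals (1-based, bp)."""

    chrom_names: tuple[str, ...]
    chrom_length: dict[str, int]
    centromere: dict[str, tuple[int, int]]

    def __post_init__(self):
        for c in self.chrom_names:
            s, e = self.centromere[c]
            if not (0 < s < e <= self.chrom_length[c]):
                raise ValidationError(
                    f"centromere interval ({s}, {e}) invalid for chromosome "
                    f"{c} of length {self.chrom_length[c]}")

    @property
    def uses_chr_prefix(self) -> bool:
        return any(c.startswith("chr") for c in self.chrom_names)

    def autosomes(self) -> tuple[str, ...]:
        sex = {"X", "Y", "chrX", "chrY"}
        return tuple(c for c in self.chrom_names if c not in sex)

    def harmonise_chrom(self, chrom: str) -> str:
        """Map a 'chr1'/'1'-dialect name onto this annotation's convention."""
        chrom = str(chrom)
        if chrom in self.chrom_length:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alt in self.chrom_length:
            return alt
        raise BoundsError(f"chromosome {chrom!r} not in genome annotation")

    def arm_of(self, chrom: str, pos: int) -> str:
        cen_start, cen_end = self.centromere[chrom]
        mid = (cen_start + cen_end) // 2
        return "p" if pos <= mid else "q"

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeAnnotation":
        required = {"chrom", "length", "cen_start", "cen_end"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"genome annotation missing columns {sorted(missing)}")
        names = tuple(str(c) for c in df["chrom"])
        return cls(
            chrom_names=names,
            chrom_length={str(r.chrom): int(r.length) for r in df.itertuples()},
            centromere={str(r.chrom): (int(r.cen_start), int(r.cen_end))
                        for r in df.itertuples()},
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_frame(df)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(c, self.chrom_length[c], *self.centromere[c])
                for c in self.chrom_names]
        pd.DataFrame(rows, columns=["chrom", "length", "cen_start", "cen_end"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def builtin(cls, build: str) -> "GenomeAnnotation":
        """Shipped annotation for 'GRCh37' or 'GRCh38'."""
        key = build.lower().replace("hg19", "grch37").replace("hg38", "grch38")
        if key not in ("grch37", "grch38"):
            raise ConfigurationError(f"unknown genome build {build!r}")
        with resources.as_file(
                resources.files("hrdclass.data").joinpath(f"{key}.tsv")) as p:
            return cls.from_tsv(p)


def toy_genome(n_chrom: int = 4,
               lengths_mb: tuple[int, ...] = (200, 150, 120, 100),
               cen_fraction: float = 0.40,
               cen_halfwidth_mb: float = 2.5) -> GenomeAnnotation:
    """Small genome used by the synthetic module and the test suite."""
    names = tuple(str(i + 1) for i in range(n_chrom))
    length = {c: lengths_mb[i] * 1_000_000 for i, c in enumerate(names)}
    cen = {}
    for c in names:
        mid = int(length[c] * cen_fraction)
        hw = int(cen_halfwidth_mb * 1_000_000)
        cen[c] = (mid - hw, mid + hw)
    return GenomeAnnotation(names, length, cen)


# ---------------------------------------------------------------------------
# segment tables
# ---------------------------------------------------------------------------

def validate_segments(df: pd.DataFrame, genome: GenomeAnnotation,
                      allele_specific: bool) -> pd.DataFrame:
    """Validate and harmonise a (AS)CN segment table in place; returns df."""
    cols = ASCN_COLUMNS if allele_specific else SEGMENT_COLUMNS
    missing = set(cols) - set(df.columns)
    if missing:
        raise FormatError(f"segment table missing column(s) {sorted(missing)}")
    df = df.copy()
    df["chrom"] = [genome.harmonise_chrom(c) for c in df["chrom"].astype(str)]
    df["start_bp"] = df["start_bp"].astype(np.int64)
    df["end_bp"] = df["end_bp"].astype(np.int64)
    if (df["start_bp"] > df["end_bp"]).any():
        raise ValidationError("segment with start_bp > end_bp")
    if (df["start_bp"] < 1).any():
        raise BoundsError("segment with start_bp < 1")
    if (df["total_cn"] < 0).any():
        raise ValidationError("negative total_cn")
    for chrom, sub in df.groupby("chrom"):
        if (sub["end_bp"] > genome.chrom_length[chrom]).any():
            raise BoundsError(f"segment beyond end of chromosome {chrom}")
    if allele_specific:
        major = df["major_cn"].astype(np.int64)
        minor = df["minor_cn"].astype(np.int64)
        if (minor < 0).any() or (major < minor).any():
            raise ValidationError("require major_cn >= minor_cn >= 0")
        if not np.allclose(df["total_cn"], major + minor):
            raise ValidationError("total_cn != major_cn + minor_cn")
        df["major_cn"], df["minor_cn"] = major, minor
    # non-overlap within each sample-chromosome
    for (sample, chrom), sub in df.groupby(["sample_id", "chrom"]):
        sub = sub.sort_values("start_bp")
        if (sub["start_bp"].values[1:] <= sub["end_bp"].values[:-1]).any():
            raise ValidationError(
                f"overlapping segments for sample {sample} chromosome {chrom}")
    return df.sort_values(["sample_id", "chrom", "start_bp"]).reset_index(drop=True)


def read_segments(path: str | Path, genome: GenomeAnnotation,
                  allele_specific: bool = False,
                  zero_based: bool = False) -> pd.DataFrame:
    """Read a SEG/ASCAT-like TSV into a validated segment table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {"sample": "sample_id", "chromosome": "chrom", "chr": "chrom",
              "start": "start_bp", "end": "end_bp",
              "nMajor": "major_cn", "nMinor": "minor_cn"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    if zero_based and "start_bp" in df.columns:
        df["start_bp"] = df["start_bp"] + 1  # 0-based half-open -> 1-based incl.
    if allele_specific and "total_cn" not in df.columns \
            and {"major_cn", "minor_cn"} <= set(df.columns):
        df["total_cn"] = df["major_cn"] + df["minor_cn"]
    return validate_segments(df, genome, allele_specific)


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

class ProvenanceError(ValueError):
    """Input contradicts the supplied reference sequence."""


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == 2 and len(alt) == 2:
        return "DNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "other"


def _extract_flanks(fasta, chrom: str, pos: int, ref: str,
                    width: int | None = None) -> tuple[str, str]:
    if width is None:
        width = max(30, 6 * len(ref))  # ID83 needs 6 repeat-unit-lengths
    seq = fasta[chrom]
    left = str(seq[max(0, pos - 1 - width):pos - 1]).upper()
    right = str(seq[pos - 1 + len(ref):pos - 1 + len(ref) + width]).upper()
    return left, right


def validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"mutation table missing column(s) {sorted(missing)}")
    if (df["ref_allele"] == df["alt_allele"]).any():
        raise ValidationError("row with ref_allele == alt_allele")
    bad = ~df["variant_class"].isin(VARIANT_CLASSES)
    if bad.any():
        raise ValidationError(
            f"unknown variant_class {df.loc[bad, 'variant_class'].iloc[0]!r}")
    snv = df["variant_class"] == "SNV"
    if (df.loc[snv, "ref_allele"].str.len() != 1).any() \
            or (df.loc[snv, "alt_allele"].str.len() != 1).any():
        raise ValidationError("SNV row with multi-base allele")
    return df.reset_index(drop=True)


def read_mutations(path: str | Path, fmt: str = "tsv",
                   reference_fasta: str | Path | None = None) -> pd.DataFrame:
    """Read somatic mutations from a VCF or MAF-like TSV.

    Multi-allelic VCF records are split into one row per alt allele.  When a
    reference FASTA is supplied, >=10 bp flanking sequences are extracted
    (and REF alleles are checked against the reference).
    """
    fasta = None
    if reference_fasta is not None:
        from pyfaidx import Fasta
        fasta = Fasta(str(reference_fasta), sequence_always_upper=True)

    if fmt == "vcf":
        from cyvcf2 import VCF
        vcf = VCF(str(path))
        sample = vcf.samples[0] if vcf.samples else Path(str(path)).stem
        rows = []
        for rec in vcf:
            for alt in rec.ALT:
                rows.append((sample, rec.CHROM, rec.POS, rec.REF, alt,
                             _variant_class(rec.REF, alt)))
        df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"chrom": str, "flank_5p": str, "flank_3p": str})
        rename = {"Tumor_Sample_Barcode": "sample_id", "Chromosome": "chrom",
                  "Start_Position": "pos", "Reference_Allele": "ref_allele",
                  "Tumor_Seq_Allele2": "alt_allele"}
        df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
        if "variant_class" not in df.columns:
            df["variant_class"] = [
                _variant_class(r, a)
                for r, a in zip(df["ref_allele"], df["alt_allele"])]
    else:
        raise FormatError(f"unknown mutation format {fmt!r}")

    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    if fasta is not None:
        flanks5, flanks3 = [], []
        for r in df.itertuples():
            ref_seq = str(fasta[r.chrom][r.pos - 1:r.pos - 1 + len(r.ref_allele)])
            if ref_seq.upper() != r.ref_allele.upper():
                raise ProvenanceError(
                    f"REF mismatch at {r.chrom}:{r.pos} "
                    f"(file {r.ref_allele}, reference {ref_seq})")
            f5, f3 = _extract_flanks(fasta, r.chrom, r.pos, r.ref_allele)
            flanks5.append(f5)
            flanks3.append(f3)
        df["flank_5p"] = flanks5
        df["flank_3p"] = flanks3
    return validate_mutations(df)


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature catalogues
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SignatureCatalogue:
    """Channels x signatures matrix of non-negative weights, columns sum to 1."""

    schema_id: str
    matrix: pd.DataFrame  # index = channel names, columns = signature names

    def __post_init__(self):
        if self.schema_id not in schemas.SCHEMA_IDS:
            raise SchemaError(f"unknown schema {self.schema_id!r}")
        if (self.matrix.values < 0).any():
            raise ValidationError("negative signature weight")
        if self.schema_id != "CX":
            canonical = schemas.channels(self.schema_id)
            if set(self.matrix.index) != set(canonical):
                extra = set(self.matrix.index) - set(canonical)
                missing = set(canonical) - set(self.matrix.index)
                raise SchemaError(
                    f"channel names do not match {self.schema_id}: "
                    f"unknown={sorted(extra)[:3]} missing={sorted(missing)[:3]}")
            self.matrix = self.matrix.loc[list(canonical)]
        sums = self.matrix.sum(axis=0)
        off = (sums - 1.0).abs()
        if (off > 1e-3).any():
            bad = sums.index[off.argmax()]
            raise ValidationError(
                f"signature column {bad!r} sums to {sums[bad]:.6f}, not 1")
        self.matrix = self.matrix / sums

    @property
    def signatures(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)

    def subset(self, wanted: list[str]) -> "SignatureCatalogue":
        missing = [w for w in wanted if w not in self.matrix.columns]
        if missing:
            raise ConfigurationError(
                f"signature(s) {missing} absent from catalogue")
        return SignatureCatalogue(self.schema_id, self.matrix[list(wanted)].copy())


def read_signature_catalogue(path: str | Path, schema_id: str) -> SignatureCatalogue:
    """Read a COSMIC-style tab-delimited channel x signature matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return SignatureCatalogue(schema_id, df)


def write_signature_catalogue(cat: SignatureCatalogue, path: str | Path) -> None:
    cat.matrix.rename_axis("channel").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FeatureMatrix:
    """Samples x features with per-feature block tags and raw/normalised state.

    ``values``: DataFrame indexed by sample id; ``blocks`` maps each feature
    name to one of CNA/ASCN/SNV.  Raw-state values must be non-negative (they
    feed the ln(x+1) transform).
    """

    values: pd.DataFrame
    blocks: dict[str, str]
    state: str = "raw"

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate feature name {dup!r}")
        unknown = set(self.values.columns) - set(self.blocks)
        if unknown:
            raise ValidationError(f"features without block tag: {sorted(unknown)}")
        bad = set(self.blocks.values()) - set(BLOCKS)
        if bad:
            raise ValidationError(f"unknown block tag(s) {sorted(bad)}")
        if self.state not in ("raw", "normalised"):
            raise ValidationError(f"unknown state {self.state!r}")
        if self.state == "raw" and (self.values.values < 0).any():
            raise ValidationError("raw feature matrix contains negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def features_in_block(self, block: str) -> list[str]:
        return [f for f in self.values.columns if self.blocks[f] == block]

    def join(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Column-bind two matrices on the shared sample index."""
        if self.state != other.state:
            raise ValidationError("cannot join matrices in different states")
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ValidationError(f"duplicate feature name {sorted(overlap)[0]!r}")
        values = self.values.join(other.values, how="inner")
        return FeatureMatrix(values, {**self.blocks, **other.blocks}, self.state)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        tags = " ".join(f"{f}={fm.blocks[f]}" for f in fm.feature_names)
        fh.write(f"#state={fm.state} blocks: {tags}\n")
        fm.values.rename_axis("sample_id").to_csv(
            fh, sep="\t", float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#state="):
            raise FormatError("feature matrix lacks its #state/blocks header")
        state, _, tag_str = header[1:].strip().partition(" blocks: ")
        state = state.split("=", 1)[1]
        blocks = dict(t.split("=") for t in tag_str.split())
        df = pd.read_csv(fh, sep="\t", index_col="sample_id")
    return FeatureMatrix(df, blocks, state)


# ---------------------------------------------------------------------------
# HRD label table
# ---------------------------------------------------------------------------

_FLAG_TO_SERIAL = {"yes": "1", "no": "0", "missing": "NA"}
_SERIAL_TO_FLAG = {"1": "yes", "0": "no", "NA": "missing",
                   "1.0": "yes", "0.0": "no", "": "missing"}


def validate_label_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = ({"sample_id"} | set(EVIDENCE_FLAGS)) - set(df.columns)
    if missing:
        raise FormatError(f"label table missing column(s) {sorted(missing)}")
    df = df.copy()
    for col in EVIDENCE_FLAGS:
        bad = ~df[col].isin(TRISTATE)
        if bad.any():
            raise ValidationError(
                f"flag {col} outside {{yes,no,missing}}: "
                f"{df.loc[bad, col].iloc[0]!r}")
    return df.reset_index(drop=True)


def read_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in EVIDENCE_FLAGS:
        if col in df.columns:
            df[col] = df[col].map(lambda v: _SERIAL_TO_FLAG.get(v, v))
    return validate_label_table(df)


def write_label_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in EVIDENCE_FLAGS:
        if col in out.columns:
            out[col] = out[col].map(_FLAG_TO_SERIAL)
    out.to_csv(path, sep="\t", index=False)
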