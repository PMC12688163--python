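"""SBS96 / ID83 mutation catalogues and signature exposure refitting (block SNV).

Substitutions are expressed on the pyrimidine strand: a G>T with flanks T..T
is recorded as A[C>A]A.  Indels follow the channel-definition file shipped in
``hrdclass/data/id83_channels.txt`` (1-bp indels by strand-collapsed base and
homopolymer context; longer indels by length and remaining repeat copies;
non-repeat deletions additionally by 3'/5' microhomology).  Double-nucleotide
variants are not covered by either schema and count as unclassifiable.

Exposures against a fixed signature catalogue are obtained by non-negative
least squares: minimise ||counts - S e||_2 subject to e >= 0 over the wanted
signature columns.  The refit is deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import schemas
from .core_io import ConfigurationError, FeatureMatrix, SchemaError, \
    SignatureCatalogue, ValidationError
from .schemas import revcomp

log = logging.getLogger(__name__)

SBS_WANTED = ("SBS1", "SBS2", "SBS3", "SBS5", "SBS6", "SBS8", "SBS13",
              "SBS17b", "SBS18", "SBS20", "SBS26", "SBS30")
ID_WANTED = tuple(f"ID{i}" for i in range(1, 19))

UNCLASSIFIABLE = "unclassifiable"

_PURINES = {"A", "G"}


def sbs96_channel(ref: str, alt: str, flank_5p: str, flank_3p: str) -> str:
    """Pyrimidine-strand trinucleotide channel, e.g. ``A[C>A]A``."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValidationError(f"not a single-base substitution: {ref}>{alt}")
    if not flank_5p or not flank_3p:
        return UNCLASSIFIABLE
    five, three = flank_5p[-1].upper(), flank_3p[0].upper()
    if ref in _PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    if "N" in (five, three, ref, alt):
        return UNCLASSIFIABLE
    return f"{five}[{ref}>{alt}]{three}"


def _indel_alleles(ref: str, alt: str) -> tuple[str, str, str, str]:
    """(kind, indel sequence, stripped prefix, stripped suffix).

    Strips the shared anchor bases of the VCF-style representation; the
    stripped prefix/suffix must be folded back into the flanking sequence
    before repeat/microhomology analysis.
    """
    ref, alt = ref.upper(), alt.upper()
    prefix = suffix = ""
    while ref and alt and ref[0] == alt[0]:
        prefix += ref[0]
        ref, alt = ref[1:], alt[1:]
    while ref and alt and ref[-1] == alt[-1]:
        suffix = ref[-1] + suffix
        ref, alt = ref[:-1], alt[:-1]
    if ref and not alt:
        return "Del", ref, prefix, suffix
    if alt and not ref:
        return "Ins", alt, prefix, suffix
    raise ValidationError("not a pure insertion or deletion")


def _repeat_copies(seq: str, unit: str) -> int:
    """Number of consecutive copies of ``unit`` at the start of ``seq``."""
    n = 0
    while seq.startswith(unit):
        n += 1
        seq = seq[len(unit):]
    return n


def _microhomology(deleted: str, flank_5p: str, flank_3p: str) -> int:
    """Longest shared prefix(deleted, 3' flank) or suffix(deleted, 5' flank)."""
    fwd = 0
    for a, b in zip(deleted, flank_3p):
        if a == b:
            fwd += 1
        else:
            break
    rev = 0
    for a, b in zip(reversed(deleted), reversed(flank_5p)):
        if a == b:
            rev += 1
        else:
            break
    return min(max(fwd, rev), len(deleted) - 1)


def id83_channel(ref: str, alt: str, flank_5p: str, flank_3p: str) -> str:
    """COSMIC-style ID83 channel per the shipped channel-definition file."""
    kind, seq, prefix, suffix = _indel_alleles(ref, alt)
    L = len(seq)
    # anchor bases sit between the recorded flanks and the indel proper
    flank_5p = flank_5p.upper() + prefix
    flank_3p = suffix + flank_3p.upper()
    if len(flank_3p) < 6 * L or len(flank_5p) < 6 * L:
        log.debug("insufficient flank for indel of length %d", L)
        return UNCLASSIFIABLE

    if L == 1:
        base = seq
        if base in _PURINES:
            base = revcomp(base)  # strand collapse: A/G context -> T/C
        run = _repeat_copies(flank_3p, seq) + _repeat_copies(flank_5p[::-1], seq)
        if kind == "Del":
            k = min(run, 5)      # identical bases remaining after deletion
        else:
            k = min(run, 5)      # existing homopolymer at the insertion site
        return f"1:{kind}:{base}:{k}"

    size = min(L, 5)
    copies = _repeat_copies(flank_3p, seq) + _repeat_copies(
        "".join(reversed(flank_5p)), "".join(reversed(seq)))
    if copies > 0 or kind == "Ins":
        k = min(copies, 5)
        return f"{size}:{kind}:R:{k}"

    mh = _microhomology(seq, flank_5p, flank_3p)
    if mh == 0:
        return f"{size}:Del:R:0"
    return f"{size}:Del:M:{min(mh, 5)}"


def build_catalogue(mutations: pd.DataFrame, schema_id: str) -> pd.DataFrame:
    """Per-sample channel counts for SBS96 or ID83.

    Returns rows = samples, columns = canonical channels plus an
    ``unclassifiable`` tally.  Rows lacking flanks raise a ValueError naming
    the first offending row.
    """
    if schema_id not in ("SBS96", "ID83"):
        raise SchemaError(f"no mutation catalogue for schema {schema_id!r}")
    wanted_classes = {"SBS96": ("SNV",), "ID83": ("insertion", "deletion")}[schema_id]
    channel_fn = sbs96_channel if schema_id == "SBS96" else id83_channel
    channels = schemas.channels(schema_id)

    counts: dict[str, dict[str, int]] = {}
    for sample in mutations["sample_id"].unique():
        counts[sample] = dict.fromkeys(channels, 0)
        counts[sample][UNCLASSIFIABLE] = 0
    relevant = mutations[mutations["variant_class"].isin(wanted_classes)]
    if len(relevant) and ("flank_5p" not in relevant.columns
                          or relevant["flank_5p"].isna().any()):
        bad = relevant.index[relevant["flank_5p"].isna()][0] \
            if "flank_5p" in relevant.columns else relevant.index[0]
        raise ValidationError(
            f"no flanking sequence for row {bad}; supply flanks or a "
            f"reference FASTA at read time")
    for rec in relevant.itertuples():
        ch = channel_fn(rec.ref_allele, rec.alt_allele,
                        rec.flank_5p, rec.flank_3p)
        counts[rec.sample_id][ch] += 1
    columns = list(channels) + [UNCLASSIFIABLE]
    if not counts:
        return pd.DataFrame(columns=columns, dtype=int)
    return pd.DataFrame.from_dict(counts, orient="index")[columns]


def nnls_refit(counts: pd.DataFrame, catalogue: SignatureCatalogue,
               wanted: tuple[str, ...], normalise: bool = False) -> pd.DataFrame:
    """Non-negative least-squares exposures of each sample's channel counts.

    ``normalise`` rescales each exposure vector to sum to the sample's
    classifiable mutation count.
    """
    missing = [w for w in wanted if w not in catalogue.signatures]
    if missing:
        raise ConfigurationError(f"signature(s) {missing} absent from catalogue")
    sub = catalogue.subset(list(wanted))
    chan = list(sub.channels)
    if not set(chan) <= set(counts.columns):
        raise SchemaError("count columns do not cover the catalogue channels")
    S = sub.matrix.values
    rows = {}
    for sample in counts.index:
        vec = counts.loc[sample, chan].to_numpy(dtype=float)
        exp, _ = nnls(S, vec)
        if normalise and exp.sum() > 0:
            exp = exp * (vec.sum() / exp.sum())
        rows[sample] = exp
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(wanted))


def snv_feature_matrix(mutations: pd.DataFrame,
                       sbs_catalogue: SignatureCatalogue,
                       id_catalogue: SignatureCatalogue,
                       sbs_wanted: tuple[str, ...] = SBS_WANTED,
                       id_wanted: tuple[str, ...] = ID_WANTED) -> FeatureMatrix:
    """Assemble block=SNV feature columns (SBS and ID exposures)."""
    sbs_counts = build_catalogue(mutations, "SBS96")
    id_counts = build_catalogue(mutations, "ID83")
    sbs = nnls_refit(sbs_counts, sbs_catalogue, sbs_wanted)
    ids = nnls_refit(id_counts, id_catalogue, id_wanted)
    values = sbs.join(ids, how="inner")
    blocks = {f: "SNV" for f in values.columns}
    return FeatureMatrix(values, blocks, state="raw")
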