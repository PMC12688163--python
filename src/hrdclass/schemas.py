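"""Canonical mutation / copy-number channel schemas.

Three channel vocabularies are used throughout:

* ``SBS96`` — single-base substitutions in trinucleotide context, expressed on
  the pyrimidine strand: ``5'[REF>ALT]3'`` with REF in {C, T}.  Generated
  programmatically (pure enumeration).
* ``ID83`` — small insertions/deletions classified by size, repeat context and
  microhomology.  The channel list (and hence the binning convention) ships as
  a data file, which is the single source of truth.
* ``CN48`` — allele-specific copy-number segments classified by heterozygosity
  state (homozygous deletion / LOH / heterozygous) x total-CN class x segment
  length.  Also shipped as a data file.

``CX`` is the exposure schema for total-copy-number signatures; it has no fixed
channel list here because exposures are normally supplied precomputed.
"""

from __future__ import annotations

import functools
from importlib import resources

SCHEMA_IDS = ("SBS96", "ID83", "CN48", "CX")

_PYRIMIDINES = ("C", "T")
_BASES = ("A", "C", "G", "T")
_SBS_ALTS = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _read_channel_file(name: str) -> tuple[str, ...]:
    text = resources.files("hrdclass.data").joinpath(name).read_text()
    return tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@functools.lru_cache(maxsize=None)
def channels(schema_id: str) -> tuple[str, ...]:
    """Canonical, ordered channel names for a schema."""
    if schema_id == "SBS96":
        out = []
        for ref in _PYRIMIDINES:
            for alt in _SBS_ALTS[ref]:
                for five in _BASES:
                    for three in _BASES:
                        out.append(f"{five}[{ref}>{alt}]{three}")
        return tuple(out)
    if schema_id == "ID83":
        chans = _read_channel_file("id83_channels.txt")
        if len(chans) != 83:
            raise RuntimeError("ID83 channel file is corrupt")
        return chans
    if schema_id == "CN48":
        chans = _read_channel_file("cn48_channels.txt")
        if len(chans) != 48:
            raise RuntimeError("CN48 channel file is corrupt")
        return chans
    raise KeyError(f"schema {schema_id!r} has no fixed channel list")
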