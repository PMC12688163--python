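"""HRD status labelling from BRCA1/2 evidence flags.

A tumour is called HRD-positive when a pathogenic BRCA1/2 hit (germline
mutation, somatic mutation, or BRCA1 promoter hypermethylation) coincides with
loss of the second allele (LOH) of the same gene.  It is called HRD-negative
when no BRCA1/2 mutation is detected at all, or when neither gene shows LOH.
Everything else — typically samples with missing assays — is left unknown.

Positive clauses take precedence over negative clauses; a sample where both a
methylation+LOH positive clause and the no-LOH negative clause could fire is
resolved as positive.  Missingness never manufactures a negative: the
"no detected mutations" clause requires all four mutation flags to be an
explicit "no" (methylation status, which the negative rule does not mention,
may be "no" or "missing").
"""

from __future__ import annotations

import logging

import pandas as pd

from .core_io import EVIDENCE_FLAGS, TRISTATE, ValidationError

log = logging.getLogger(__name__)

STATUSES = ("positive", "negative", "unknown")

_MUTATION_FLAGS = ("germline_brca1", "germline_brca2",
                   "somatic_brca1", "somatic_brca2")


def derive_hrd_status(evidence: dict[str, str]) -> str:
    """Derive HRD status for one sample from its tri-state evidence flags."""
    for flag in EVIDENCE_FLAGS:
        value = evidence.get(flag, "missing")
        if value not in TRISTATE:
            raise ValidationError(f"flag {flag}={value!r} outside {{yes,no,missing}}")
    ev = {f: evidence.get(f, "missing") for f in EVIDENCE_FLAGS}

    # positive: pathogenic hit + LOH of the same gene
    if ev["germline_brca1"] == "yes" and ev["loh_brca1"] == "yes":
        return "positive"
    if ev["germline_brca2"] == "yes" and ev["loh_brca2"] == "yes":
        return "positive"
    if ev["somatic_brca1"] == "yes" and ev["loh_brca1"] == "yes":
        return "positive"
    if ev["somatic_brca2"] == "yes" and ev["loh_brca2"] == "yes":
        return "positive"
    if ev["brca1_methylation"] == "yes" and ev["loh_brca1"] == "yes":
        return "positive"

    # negative: no detected mutations at all, or no LOH of either gene
    if all(ev[f] == "no" for f in _MUTATION_FLAGS):
        return "negative"
    if ev["loh_brca1"] == "no" and ev["loh_brca2"] == "no":
        if ev["brca1_methylation"] == "yes":
            # literal reading: methylation without LOH cannot rescue the call
            log.warning("brca1_methylation=yes with no LOH on either gene: "
                        "classified negative by the no-LOH clause")
        return "negative"

    return "unknown"


def label_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill ``hrd_status`` for every row; returns (table, per-status counts)."""
    out = table.copy()
    out["hrd_status"] = [
        derive_hrd_status({f: row[f] for f in EVIDENCE_FLAGS})
        for _, row in table.iterrows()
    ]
    counts = {s: int((out["hrd_status"] == s).sum()) for s in STATUSES}
    return out, counts
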