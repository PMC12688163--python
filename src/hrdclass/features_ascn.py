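"""Genomic scar scores and allele-specific CN channelization (block ASCN).

The three scar scores operate on allele-specific segment profiles in which
each segment carries integer major/minor copy numbers:

* LOH score  — maximal regions with minor_cn = 0 and total_cn >= 1, longer
  than ``min_len`` (default 15 Mb) but shorter than their chromosome's covered
  extent (whole-chromosome LOH does not count).
* TAI score  — allelic-imbalance regions (major != minor) that reach a covered
  chromosome end without crossing the centromere.
* LST score  — per chromosome arm, after removal of segments shorter than
  ``smooth_below`` (3 Mb) and re-merging, the number of breakpoints whose two
  flanking segments are each >= ``min_seg`` (10 Mb) with a gap <= ``max_gap``
  (3 Mb).

scarHRD = LOH + TAI + LST; scores >= 42 are conventionally called
HRD-positive.

A second group of functions bins each segment into the 48-channel
allele-specific CN schema (heterozygosity state x total-CN class x length) and
refits the per-sample channel counts against a CN48 signature catalogue by
non-negative least squares, keeping the breast-cancer-associated signatures
CN1, CN2, CN6, CN7, CN8, CN9, CN11 and CN17 as candidate features.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import schemas
from .core_io import ConfigurationError, FeatureMatrix, GenomeAnnotation, \
    SchemaError, SignatureCatalogue, ValidationError
from .features_cn import merge_adjacent

log = logging.getLogger(__name__)

CN_WANTED = ("CN1", "CN2", "CN6", "CN7", "CN8", "CN9", "CN11", "CN17")


@dataclasses.dataclass(frozen=True)
class ScarScores:
    loh: int
    tai: int
    lst: int

    @property
    def scarhrd(self) -> int:
        return self.loh + self.tai + self.lst


def _merged_ascn(sub: pd.DataFrame) -> pd.DataFrame:
    return merge_adjacent(sub, state_cols=("major_cn", "minor_cn"))


def _regions(sub_chrom: pd.DataFrame, mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive (sorted) segments where mask holds."""
    regions = []
    start = end = None
    for flag, rec in zip(mask, sub_chrom.itertuples()):
        if flag:
            if start is None:
                start = rec.start_bp
            end = rec.end_bp
        else:
            if start is not None:
                regions.append((start, end))
            start = None
    if start is not None:
        regions.append((start, end))
    return regions


def loh_score(segments: pd.DataFrame, genome: GenomeAnnotation,
              min_len: int = 15_000_000) -> int:
    """Count of sub-chromosomal LOH regions longer than ``min_len``."""
    count = 0
    for (_, chrom), sub in _merged_ascn(segments).groupby(
            ["sample_id", "chrom"], sort=False):
        if chrom not in genome.autosomes():
            continue
        sub = sub.sort_values("start_bp")
        covered_start = int(sub["start_bp"].min())
        covered_end = int(sub["end_bp"].max())
        mask = (sub["minor_cn"].to_numpy() == 0) & (sub["total_cn"].to_numpy() >= 1)
        for start, end in _regions(sub, mask):
            length = end - start + 1
            if length <= min_len:
                continue
            if start <= covered_start and end >= covered_end:
                continue  # whole-chromosome LOH excluded
            count += 1
    return count


def tai_score(segments: pd.DataFrame, genome: GenomeAnnotation,
              min_len: int = 0, telomere_slack: int = 0) -> int:
    """Count of telomeric allelic-imbalance regions not crossing the centromere."""
    count = 0
    for (_, chrom), sub in _merged_ascn(segments).groupby(
            ["sample_id", "chrom"], sort=False):
        if chrom not in genome.autosomes():
            continue
        sub = sub.sort_values("start_bp")
        covered_start = int(sub["start_bp"].min())
        covered_end = int(sub["end_bp"].max())
        cen_start, cen_end = genome.centromere[chrom]
        mask = sub["major_cn"].to_numpy() != sub["minor_cn"].to_numpy()
        for start, end in _regions(sub, mask):
            if end - start + 1 < min_len:
                continue
            telomeric = (start <= covered_start + telomere_slack
                         or end >= covered_end - telomere_slack)
            crosses_cen = start < cen_start and end > cen_end
            if telomeric and not crosses_cen:
                count += 1
    return count


def _split_at_centromere(sub: pd.DataFrame, genome: GenomeAnnotation,
                         chrom: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    cen_start, cen_end = genome.centromere[chrom]
    mid = (cen_start + cen_end) // 2
    recs_p, recs_q = [], []
    for rec in sub.sort_values("start_bp").to_dict("records"):
        if rec["end_bp"] <= mid:
            recs_p.append(rec)
        elif rec["start_bp"] > mid:
            recs_q.append(rec)
        else:  # straddles: split at the centromere midpoint
            left = dict(rec, end_bp=mid)
            right = dict(rec, start_bp=mid + 1)
            recs_p.append(left)
            recs_q.append(right)
    return pd.DataFrame(recs_p), pd.DataFrame(recs_q)


def _smooth_arm(recs: list[dict], smooth_below: int) -> list[dict]:
    """Remove segments < smooth_below by extending the larger neighbour, then
    merge identical-state neighbours.  Deterministic fixpoint."""
    recs = [dict(r) for r in recs]
    changed = True
    while changed:
        changed = False
        # drop the smallest sub-threshold segment first
        idx_len = [(r["end_bp"] - r["start_bp"] + 1, i) for i, r in enumerate(recs)]
        small = sorted((L, i) for L, i in idx_len if L < smooth_below)
        if small and len(recs) > 1:
            _, i = small[0]
            victim = recs.pop(i)
            left = recs[i - 1] if i > 0 else None
            right = recs[i] if i < len(recs) else None

            def _size(r):
                return r["end_bp"] - r["start_bp"] + 1
            if left is not None and (right is None or _size(left) >= _size(right)):
                left["end_bp"] = victim["end_bp"]
            elif right is not None:
                right["start_bp"] = victim["start_bp"]
            changed = True
        # merge identical-state adjacent neighbours
        merged = []
        for r in recs:
            if merged and merged[-1]["major_cn"] == r["major_cn"] \
                    and merged[-1]["minor_cn"] == r["minor_cn"] \
                    and r["start_bp"] - merged[-1]["end_bp"] <= 1:
                merged[-1]["end_bp"] = r["end_bp"]
                changed = changed or True
            else:
                merged.append(r)
        if len(merged) != len(recs):
            changed = True
        recs = merged
    return recs


def lst_score(segments: pd.DataFrame, genome: GenomeAnnotation,
              min_seg: int = 10_000_000, max_gap: int = 3_000_000,
              smooth_below: int = 3_000_000) -> int:
    """Count of large-scale state transitions, per chromosome arm."""
    count = 0
    for (_, chrom), sub in _merged_ascn(segments).groupby(
            ["sample_id", "chrom"], sort=False):
        if chrom not in genome.autosomes():
            continue
        for arm in _split_at_centromere(sub, genome, chrom):
            if arm.empty:
                continue
            recs = _smooth_arm(arm.sort_values("start_bp").to_dict("records"),
                               smooth_below)
            for left, right in zip(recs, recs[1:]):
                len_l = left["end_bp"] - left["start_bp"] + 1
                len_r = right["end_bp"] - right["start_bp"] + 1
                gap = right["start_bp"] - left["end_bp"] - 1
                if len_l >= min_seg and len_r >= min_seg and gap <= max_gap:
                    count += 1
    return count


def scar_scores(segments: pd.DataFrame, genome: GenomeAnnotation,
                **kwargs) -> ScarScores:
    """LOH/TAI/LST for one sample's segment table."""
    loh_kw = {k: kwargs[k] for k in ("min_len",) if k in kwargs}
    return ScarScores(
        loh=loh_score(segments, genome, **loh_kw),
        tai=tai_score(segments, genome),
        lst=lst_score(segments, genome),
    )


def scarhrd_call(scores: ScarScores, threshold: int = 42) -> tuple[int, bool]:
    """(scarHRD sum, HRD call at the conventional cut-off)."""
    return scores.scarhrd, scores.scarhrd >= threshold


# ---------------------------------------------------------------------------
# CN48 channelization + exposures
# ---------------------------------------------------------------------------

def _size_bin(length: int, homdel: bool) -> str:
    if homdel:
        if length <= 100_000:
            return "0-100kb"
        if length <= 1_000_000:
            return "100kb-1Mb"
        return ">1Mb"
    if length <= 100_000:
        return "0-100kb"
    if length <= 1_000_000:
        return "100kb-1Mb"
    if length <= 10_000_000:
        return "1Mb-10Mb"
    if length <= 40_000_000:
        return "10Mb-40Mb"
    return ">40Mb"


def _cn_class(total: int, loh: bool) -> str:
    if loh and total == 1:
        return "1"
    if total == 2:
        return "2"
    if 3 <= total <= 4:
        return "3-4"
    if 5 <= total <= 8:
        return "5-8"
    if total >= 9:
        return "9+"
    raise ValidationError(f"cannot bin total_cn={total}")


def cn48_channel(major_cn: int, minor_cn: int, length: int) -> str:
    total = major_cn + minor_cn
    if total == 0:
        if minor_cn > 0:
            raise ValidationError("total_cn=0 with minor_cn>0")
        return f"0:homdel:{_size_bin(length, homdel=True)}"
    state = "LOH" if minor_cn == 0 else "het"
    if state == "het" and total < 2:
        raise ValidationError("heterozygous segment with total_cn < 2")
    return f"{_cn_class(total, state == 'LOH')}:{state}:{_size_bin(length, False)}"


def cn48_catalogue(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample CN48 channel counts (rows = samples, columns = channels)."""
    channels = schemas.channels("CN48")
    counts = {}
    for sample, sub in segments.groupby("sample_id", sort=False):
        vec = dict.fromkeys(channels, 0)
        for rec in sub.itertuples():
            ch = cn48_channel(int(rec.major_cn), int(rec.minor_cn),
                              int(rec.end_bp - rec.start_bp + 1))
            vec[ch] += 1
        counts[sample] = vec
    return pd.DataFrame.from_dict(counts, orient="index")[list(channels)]


def cn_exposures(counts: pd.DataFrame, catalogue: SignatureCatalogue,
                 wanted: tuple[str, ...] = CN_WANTED,
                 refit_restricted: bool = False) -> pd.DataFrame:
    """NNLS refit of CN48 counts onto the catalogue, restricted to ``wanted``.

    By default the refit uses the full catalogue and then keeps the wanted
    columns; ``refit_restricted`` refits against the wanted subset only.
    """
    if catalogue.schema_id != "CN48":
        raise SchemaError("catalogue schema is not CN48")
    missing = [w for w in wanted if w not in catalogue.signatures]
    if missing:
        raise ConfigurationError(f"signature(s) {missing} absent from catalogue")
    cat = catalogue.subset(list(wanted)) if refit_restricted else catalogue
    S = cat.matrix.values
    rows = {}
    for sample in counts.index:
        vec = counts.loc[sample, list(cat.channels)].to_numpy(dtype=float)
        exp, _ = nnls(S, vec)
        rows[sample] = dict(zip(cat.signatures, exp))
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[list(wanted)]


def ascn_feature_matrix(segments: pd.DataFrame, genome: GenomeAnnotation,
                        catalogue: SignatureCatalogue | None = None) -> FeatureMatrix:
    """Assemble block=ASCN feature columns: LOH, TAI, LST, scarHRD, CN exposures."""
    rows = {}
    for sample, sub in segments.groupby("sample_id", sort=False):
        s = scar_scores(sub, genome)
        rows[sample] = {"LOH": s.loh, "TAI": s.tai, "LST": s.lst,
                        "scarHRD": s.scarhrd}
    values = pd.DataFrame.from_dict(rows, orient="index")
    if catalogue is not None:
        counts = cn48_catalogue(segments)
        values = values.join(cn_exposures(counts, catalogue), how="inner")
    blocks = {f: "ASCN" for f in values.columns}
    return FeatureMatrix(values, blocks, state="raw")
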