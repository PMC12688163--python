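"""Total-copy-number summary scores and CX signature exposures (block CNA).

Six per-sample scores summarise a total-CN segment profile:

* ``cna_burden``   — fraction of the covered autosomal genome with altered CN,
* ``cna_load``     — number of altered segments (after merging),
* ``macn``         — mean copy number over altered segments,
* ``td_score``     — count of tandem-duplication-like gains (local-maximum
  segments no longer than ``td_max_len``),
* ``td_region_size`` — mean length (Mb) of those gains,
* ``chromothripsis_score`` — number of chromosomes carrying a long run of
  segments oscillating between exactly two CN states.

A segment is "altered" when |total_cn - neutral_cn| > altered_margin on the
absolute CN scale.  All thresholds are keyword arguments; scores are computed
on ``merge_adjacent``-normalised profiles so they are robust to how a caller's
segmentation happened to fragment the genome.

The six CX exposures (CX1-5, CX9) are normally supplied precomputed by an
external quantification pipeline and validated/passed through here; an NNLS
refit of an encoding vector against a CX catalogue is available for synthetic
data and testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import ConfigurationError, FeatureMatrix, GenomeAnnotation, \
    SignatureCatalogue

log = logging.getLogger(__name__)

CX_WANTED = ("CX1", "CX2", "CX3", "CX4", "CX5", "CX9")

CNA_SCORE_NAMES = ("cna_burden", "cna_load", "macn", "td_score",
                   "td_region_size", "chromothripsis_score")


def _seg_len(df: pd.DataFrame) -> np.ndarray:
    return (df["end_bp"] - df["start_bp"] + 1).to_numpy()


def merge_adjacent(segments: pd.DataFrame, cn_tolerance: float = 0.1,
                   gap_max: int = 0, state_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    """Merge adjacent same-state segments per sample-chromosome.

    Two consecutive segments merge when their gap is <= ``gap_max`` bp and
    either |delta total_cn| <= cn_tolerance (total-CN tables) or all
    ``state_cols`` (e.g. major/minor) are identical.  Merged total_cn is the
    length-weighted mean.
    """
    rows = []
    for (sample, chrom), sub in segments.groupby(["sample_id", "chrom"], sort=False):
        sub = sub.sort_values("start_bp")
        cur = None
        for rec in sub.to_dict("records"):
            if cur is None:
                cur = dict(rec)
                continue
            gap = rec["start_bp"] - cur["end_bp"] - 1
            if state_cols:
                same = all(rec[c] == cur[c] for c in state_cols)
            else:
                same = abs(rec["total_cn"] - cur["total_cn"]) <= cn_tolerance
            if gap <= gap_max and same:
                l1 = cur["end_bp"] - cur["start_bp"] + 1
                l2 = rec["end_bp"] - rec["start_bp"] + 1
                cur["total_cn"] = (cur["total_cn"] * l1 + rec["total_cn"] * l2) / (l1 + l2)
                cur["end_bp"] = rec["end_bp"]
            else:
                rows.append(cur)
                cur = dict(rec)
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=segments.columns).reset_index(drop=True)


def _altered_mask(sub: pd.DataFrame, neutral_cn: float,
                  altered_margin: float) -> np.ndarray:
    return (sub["total_cn"] - neutral_cn).abs().to_numpy() > altered_margin


def _autosomal(sub: pd.DataFrame, genome: GenomeAnnotation) -> pd.DataFrame:
    return sub[sub["chrom"].isin(genome.autosomes())]


def cna_burden(sub: pd.DataFrame, genome: GenomeAnnotation,
               neutral_cn: float = 2.0, altered_margin: float = 0.1) -> float:
    """Fraction of the covered autosomal genome with altered copy number."""
    sub = _autosomal(sub, genome)
    covered = _seg_len(sub).sum()
    if covered == 0:
        log.warning("cna_burden on empty profile: returning 0")
        return 0.0
    altered = _seg_len(sub)[_altered_mask(sub, neutral_cn, altered_margin)].sum()
    return float(altered / covered)


def cna_load(sub: pd.DataFrame, genome: GenomeAnnotation,
             neutral_cn: float = 2.0, altered_margin: float = 0.1) -> int:
    """Number of altered segments."""
    sub = _autosomal(sub, genome)
    return int(_altered_mask(sub, neutral_cn, altered_margin).sum())


def macn(sub: pd.DataFrame, genome: GenomeAnnotation,
         neutral_cn: float = 2.0, altered_margin: float = 0.1) -> float:
    """Unweighted mean CN of altered segments; neutral_cn when none exist."""
    sub = _autosomal(sub, genome)
    mask = _altered_mask(sub, neutral_cn, altered_margin)
    if not mask.any():
        log.info("macn: no altered segments, returning neutral sentinel")
        return float(neutral_cn)
    return float(sub["total_cn"].to_numpy()[mask].mean())


def tandem_duplication_scores(sub: pd.DataFrame, genome: GenomeAnnotation,
                              td_max_len: int = 10_000_000,
                              cn_tolerance: float = 0.1) -> tuple[int, float]:
    """(td_score, td_region_size): count and mean length (Mb) of TD-like gains.

    A TD event is a segment whose CN exceeds both flanking segments' CN (or
    its single flank, for chromosome-terminal segments) by more than
    ``cn_tolerance``, with length <= ``td_max_len``.
    """
    sub = _autosomal(sub, genome)
    lengths = []
    for (_, _), chrom_sub in sub.groupby(["sample_id", "chrom"], sort=False):
        chrom_sub = chrom_sub.sort_values("start_bp")
        cn = chrom_sub["total_cn"].to_numpy()
        seg_len = _seg_len(chrom_sub)
        n = len(cn)
        for i in range(n):
            left_ok = i == 0 or cn[i] > cn[i - 1] + cn_tolerance
            right_ok = i == n - 1 or cn[i] > cn[i + 1] + cn_tolerance
            if n == 1:
                continue  # no flank to compare against
            if left_ok and right_ok and seg_len[i] <= td_max_len:
                lengths.append(seg_len[i])
    if not lengths:
        return 0, 0.0
    return len(lengths), float(np.mean(lengths) / 1e6)


def chromothripsis_score(sub: pd.DataFrame, genome: GenomeAnnotation,
                         min_oscillations: int = 10,
                         states_tolerance: float = 0.1) -> int:
    """Chromosomes whose longest two-state CN oscillation run >= min_oscillations.

    A run of consecutive segments oscillates when each segment alternates
    between two CN states A != B, each matched within ``states_tolerance``.
    """
    sub = _autosomal(sub, genome)
    score = 0
    for (_, _), chrom_sub in sub.groupby(["sample_id", "chrom"], sort=False):
        cn = chrom_sub.sort_values("start_bp")["total_cn"].to_numpy()
        if _longest_oscillation(cn, states_tolerance) >= min_oscillations:
            score += 1
    return score


def _longest_oscillation(cn: np.ndarray, tol: float) -> int:
    best = min(len(cn), 1)
    for start in range(len(cn) - 1):
        a, b = cn[start], cn[start + 1]
        if abs(a - b) <= tol:
            continue
        run = 2
        expect_a = True  # next segment should match state a again
        for j in range(start + 2, len(cn)):
            target = a if expect_a else b
            if abs(cn[j] - target) <= tol:
                run += 1
                expect_a = not expect_a
            else:
                break
        best = max(best, run)
    return best


def cna_scores(segments: pd.DataFrame, genome: GenomeAnnotation,
               neutral_cn: float = 2.0, altered_margin: float = 0.1,
               td_max_len: int = 10_000_000, min_oscillations: int = 10,
               cn_tolerance: float = 0.1) -> pd.DataFrame:
    """All six CNA scores per sample (rows = sample ids)."""
    merged = merge_adjacent(segments, cn_tolerance=cn_tolerance)
    rows = {}
    for sample, sub in merged.groupby("sample_id", sort=False):
        td, td_size = tandem_duplication_scores(sub, genome, td_max_len,
                                                cn_tolerance)
        rows[sample] = {
            "cna_burden": cna_burden(sub, genome, neutral_cn, altered_margin),
            "cna_load": cna_load(sub, genome, neutral_cn, altered_margin),
            "macn": macn(sub, genome, neutral_cn, altered_margin),
            "td_score": td,
            "td_region_size": td_size,
            "chromothripsis_score": chromothripsis_score(
                sub, genome, min_oscillations, cn_tolerance),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(CNA_SCORE_NAMES)]


def cx_exposures(precomputed: pd.DataFrame | None = None,
                 encoding: pd.DataFrame | None = None,
                 catalogue: SignatureCatalogue | None = None,
                 wanted: tuple[str, ...] = CX_WANTED) -> pd.DataFrame:
    """CX signature exposures, samples x wanted signatures.

    Production path: a precomputed per-sample exposure table is validated and
    passed through.  Testing path: a per-sample channel encoding is refit by
    NNLS against a CX catalogue.
    """
    if precomputed is not None:
        missing = [w for w in wanted if w not in precomputed.columns]
        if missing:
            raise ConfigurationError(f"CX exposure table lacks {missing}")
        out = precomputed[list(wanted)].astype(float)
        if (out.values < 0).any():
            raise ConfigurationError("negative CX exposure")
        return out
    if encoding is None or catalogue is None:
        raise ConfigurationError(
            "need either a precomputed CX table or encoding + catalogue")
    sub = catalogue.subset(list(wanted))
    S = sub.matrix.values
    enc = encoding[list(sub.channels)] if set(sub.channels) <= set(encoding.columns) \
        else encoding
    rows = {s: nnls(S, enc.loc[s].to_numpy(dtype=float))[0]
            for s in enc.index}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(wanted))


def cn_feature_matrix(scores: pd.DataFrame, cx: pd.DataFrame) -> FeatureMatrix:
    """Assemble block=CNA feature columns from scores + CX exposures."""
    values = scores.join(cx, how="inner")
    blocks = {f: "CNA" for f in values.columns}
    return FeatureMatrix(values, blocks, state="raw")
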