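"""Feature normalisation, univariate screening and correlation pruning.

Normalisation is the within-cohort z-score of the log-transformed feature:
z = (x - mean(x)) / sd(x) with x = ln(feature + 1), sd with n-1 denominator.
Stored per-cohort (mean, sd) parameters allow the same transform to be applied
to new samples when a fresh within-cohort fit is not sensible (n < 20).

Screening is a two-sided Wilcoxon rank-sum test of HRD-positive versus
HRD-negative samples per feature (exact for small untied samples, normal
approximation with continuity correction otherwise); features with p > alpha
(0.05) are excluded, deliberately without multiple-testing adjustment — the
screen is a permissive first pass.

Pruning operates within each block: pairs with |Pearson r| above the threshold
(0.8), processed by descending |r|, lose the member with the larger screening
p-value unless a manual override names the victim.  The shipped default
override list drops ``td_region_size`` and ``SBS2``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BLOCKS, ConfigurationError, FeatureMatrix, ValidationError

log = logging.getLogger(__name__)

DEFAULT_OVERRIDES = ("td_region_size", "SBS2")


@dataclasses.dataclass
class NormalisationParams:
    """Per (cohort, feature): mean and sd of ln(x+1), n-1 denominator."""
    mean: pd.DataFrame  # index = cohort, columns = features
    sd: pd.DataFrame

    def apply(self, values: pd.DataFrame, cohort: str) -> pd.DataFrame:
        mu = self.mean.loc[cohort, values.columns]
        sd = self.sd.loc[cohort, values.columns]
        z = (np.log1p(values) - mu) / sd.replace(0.0, np.inf)
        return z.fillna(0.0)


def lognorm(matrix: FeatureMatrix, group: pd.Series | None = None,
            ) -> tuple[FeatureMatrix, NormalisationParams]:
    """Within-cohort z-scores of ln(x+1); returns the stored parameters.

    ``group`` maps sample id -> cohort id; a single implicit cohort otherwise.
    Constant (sd = 0) features come out all-zero for that cohort, with a
    warning.
    """
    if matrix.state != "raw":
        raise ValidationError("lognorm expects a raw-state matrix")
    if (matrix.values.values < 0).any():
        raise ValidationError("negative raw feature value")
    values = matrix.values
    if group is None:
        group = pd.Series("all", index=values.index)
    group = group.reindex(values.index)

    logged = np.log1p(values)
    means, sds, pieces = {}, {}, []
    for cohort, sub in logged.groupby(group):
        if len(sub) < 2:
            raise ValidationError(f"cohort {cohort!r} has < 2 samples")
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            log.warning("constant feature(s) in cohort %s set to zero: %s",
                        cohort, list(sd.index[degenerate]))
        z = (sub - mu) / sd.replace(0.0, np.inf)
        pieces.append(z.fillna(0.0))
        means[cohort], sds[cohort] = mu, sd
    out = pd.concat(pieces).reindex(values.index)
    params = NormalisationParams(pd.DataFrame(means).T, pd.DataFrame(sds).T)
    return FeatureMatrix(out, dict(matrix.blocks), state="normalised"), params


def normalise_new_cohort(matrix: FeatureMatrix, params: NormalisationParams,
                         training_cohort: str, min_self_norm: int = 20
                         ) -> FeatureMatrix:
    """Normalise a prediction-time cohort.

    Cohorts with >= ``min_self_norm`` samples are normalised within
    themselves; smaller ones reuse stored training parameters (warned).
    """
    if len(matrix.values) >= min_self_norm:
        out, _ = lognorm(matrix)
        return out
    log.warning("cohort of %d samples (< %d): applying stored training "
                "normalisation parameters", len(matrix.values), min_self_norm)
    z = params.apply(matrix.values, training_cohort)
    return FeatureMatrix(z, dict(matrix.blocks), state="normalised")


def wilcoxon_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small untied samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (not ties and len(x) <= 25 and len(y) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def wilcoxon_screen(matrix: FeatureMatrix, labels: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Screen each feature by HRD+ vs HRD− rank-sum test.

    ``labels`` maps sample id to 'positive'/'negative'/'unknown'; unknowns are
    excluded from the test.  Returns the selection report with columns
    wilcoxon_p and retained_after_screen.
    """
    labels = labels.reindex(matrix.values.index)
    pos = matrix.values[labels == "positive"]
    neg = matrix.values[labels == "negative"]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need >= 2 samples per class for screening")
    report = pd.DataFrame(index=matrix.feature_names)
    report["block"] = [matrix.blocks[f] for f in report.index]
    report["wilcoxon_p"] = [
        wilcoxon_pvalue(pos[f].to_numpy(), neg[f].to_numpy())
        for f in report.index]
    report["retained_after_screen"] = report["wilcoxon_p"] <= alpha
    report["pruned_by"] = None
    report["final_retained"] = report["retained_after_screen"]
    return report


def correlation_prune(matrix: FeatureMatrix, report: pd.DataFrame,
                      r_threshold: float = 0.8,
                      manual_overrides: tuple[str, ...] = ()) -> pd.DataFrame:
    """Greedy within-block pruning of highly correlated feature pairs.

    Pairs with |Pearson r| > r_threshold are processed by descending |r|;
    the member with the larger screening p is dropped, unless a manual
    override names a victim in the pair.
    """
    unknown = set(manual_overrides) - set(report.index)
    if unknown:
        raise ConfigurationError(f"override names unknown feature(s) {sorted(unknown)}")
    report = report.copy()
    for block in BLOCKS:
        feats = [f for f in report.index
                 if report.at[f, "block"] == block
                 and report.at[f, "retained_after_screen"]]
        if len(feats) < 2:
            continue
        corr = matrix.values[feats].corr(method="pearson").abs()
        pairs = []
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                r = corr.at[a, b]
                if r > r_threshold:
                    pairs.append((r, a, b))
        # descending |r|; name order breaks exact ties deterministically
        for r, a, b in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
            if not (report.at[a, "final_retained"] and report.at[b, "final_retained"]):
                continue
            if a in manual_overrides and b not in manual_overrides:
                victim, keeper = a, b
            elif b in manual_overrides and a not in manual_overrides:
                victim, keeper = b, a
            elif report.at[a, "wilcoxon_p"] >= report.at[b, "wilcoxon_p"]:
                victim, keeper = a, b
            else:
                victim, keeper = b, a
            report.at[victim, "final_retained"] = False
            report.at[victim, "pruned_by"] = keeper
            log.info("pruned %s (|r|=%.3f with %s)", victim, r, keeper)
    return report


def select_features(matrix: FeatureMatrix, labels: pd.Series,
                    alpha: float = 0.05, r_threshold: float = 0.8,
                    manual_overrides: tuple[str, ...] = DEFAULT_OVERRIDES
                    ) -> pd.DataFrame:
    """Screen then prune; returns the full selection report."""
    overrides = tuple(o for o in manual_overrides if o in matrix.feature_names)
    report = wilcoxon_screen(matrix, labels, alpha)
    return correlation_prune(matrix, report, r_threshold, overrides)
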