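import itertools

import numpy as np
import pandas as pd
import pytest

from hrdclass.core_io import GenomeAnnotation, SchemaError, ValidationError
from hrdclass import schemas
from hrdclass.features_ascn import (ScarScores, cn48_catalogue, cn48_channel,
                                    cn_exposures, loh_score, lst_score,
                                    scar_scores, scarhrd_call, tai_score)
from hrdclass.features_cn import merge_adjacent
from hrdclass.synthetic import synthetic_catalogue

from conftest import make_ascn, random_ascn_profile

MB = 1_000_000


def one_chrom(length_mb=200, cen=(90, 100)):
    L = length_mb * MB
    return GenomeAnnotation(("1",), {"1": L}, {"1": (cen[0] * MB, cen[1] * MB)})


# ---------------------------------------------------------------------------
# independent brute-force oracles (literal restatements of the definitions)
# ---------------------------------------------------------------------------

def _merged_regions(sub):
    """Collapse identical-state neighbours; returns list of dicts."""
    regions = []
    for rec in sub.sort_values("start_bp").to_dict("records"):
        if regions and regions[-1]["major_cn"] == rec["major_cn"] \
                and regions[-1]["minor_cn"] == rec["minor_cn"] \
                and rec["start_bp"] - regions[-1]["end_bp"] <= 1:
            regions[-1]["end_bp"] = rec["end_bp"]
        else:
            regions.append(dict(rec))
    return regions


def oracle_loh(segments, genome, min_len=15 * MB):
    total = 0
    for (_, chrom), sub in segments.groupby(["sample_id", "chrom"]):
        if chrom not in genome.autosomes():
            continue
        regions = _merged_regions(sub)
        cov = (min(r["start_bp"] for r in regions),
               max(r["end_bp"] for r in regions))
        runs, cur = [], None
        for r in regions:
            if r["minor_cn"] == 0 and r["major_cn"] + r["minor_cn"] >= 1:
                if cur is None:
                    cur = [r["start_bp"], r["end_bp"]]
                else:
                    cur[1] = r["end_bp"]
            else:
                if cur:
                    runs.append(cur)
                cur = None
        if cur:
            runs.append(cur)
        for s, e in runs:
            if e - s + 1 > min_len and not (s <= cov[0] and e >= cov[1]):
                total += 1
    return total


def oracle_tai(segments, genome):
    total = 0
    for (_, chrom), sub in segments.groupby(["sample_id", "chrom"]):
        if chrom not in genome.autosomes():
            continue
        regions = _merged_regions(sub)
        cov = (min(r["start_bp"] for r in regions),
               max(r["end_bp"] for r in regions))
        cen = genome.centromere[chrom]
        runs, cur = [], None
        for r in regions:
            if r["major_cn"] != r["minor_cn"]:
                if cur is None:
                    cur = [r["start_bp"], r["end_bp"]]
                else:
                    cur[1] = r["end_bp"]
            else:
                if cur:
                    runs.append(cur)
                cur = None
        if cur:
            runs.append(cur)
        for s, e in runs:
            touches_end = s <= cov[0] or e >= cov[1]
            crosses = s < cen[0] and e > cen[1]
            if touches_end and not crosses:
                total += 1
    return total


def oracle_lst(segments, genome, min_seg=10 * MB, max_gap=3 * MB,
               smooth_below=3 * MB):
    total = 0
    for (_, chrom), sub in segments.groupby(["sample_id", "chrom"]):
        if chrom not in genome.autosomes():
            continue
        cen = genome.centromere[chrom]
        mid = (cen[0] + cen[1]) // 2
        arms = {"p": [], "q": []}
        for r in _merged_regions(sub):
            if r["end_bp"] <= mid:
                arms["p"].append(dict(r))
            elif r["start_bp"] > mid:
                arms["q"].append(dict(r))
            else:
                arms["p"].append(dict(r, end_bp=mid))
                arms["q"].append(dict(r, start_bp=mid + 1))
        for recs in arms.values():
            while True:
                small = [(r["end_bp"] - r["start_bp"] + 1, i)
                         for i, r in enumerate(recs)
                         if r["end_bp"] - r["start_bp"] + 1 < smooth_below]
                if small and len(recs) > 1:
                    _, i = min(small)
                    victim = recs.pop(i)
                    left = recs[i - 1] if i > 0 else None
                    right = recs[i] if i < len(recs) else None

                    def size(r):
                        return r["end_bp"] - r["start_bp"] + 1
                    if left is not None and (right is None
                                             or size(left) >= size(right)):
                        left["end_bp"] = victim["end_bp"]
                    else:
                        right["start_bp"] = victim["start_bp"]
                    recs = _merged_regions(pd.DataFrame(recs))
                    continue
                merged = _merged_regions(pd.DataFrame(recs)) if recs else []
                if len(merged) != len(recs):
                    recs = merged
                    continue
                break
            for a, b in zip(recs, recs[1:]):
                if (a["end_bp"] - a["start_bp"] + 1 >= min_seg
                        and b["end_bp"] - b["start_bp"] + 1 >= min_seg
                        and b["start_bp"] - a["end_bp"] - 1 <= max_gap):
                    total += 1
    return total


# ---------------------------------------------------------------------------
# LOH
# ---------------------------------------------------------------------------

class TestLohScore:
    def test_single_20mb_region_counts(self):
        g = one_chrom(200)
        df = make_ascn({"1": [(1, 100 * MB, 1, 1),
                              (100 * MB + 1, 120 * MB, 1, 0),
                              (120 * MB + 1, 200 * MB, 1, 1)]})
        assert loh_score(df, g) == 1 == oracle_loh(df, g)

    def test_10mb_region_below_threshold(self):
        g = one_chrom(200)
        df = make_ascn({"1": [(1, 100 * MB, 1, 1),
                              (100 * MB + 1, 110 * MB, 1, 0),
                              (110 * MB + 1, 200 * MB, 1, 1)]})
        assert loh_score(df, g) == 0

    def test_whole_chromosome_loh_excluded(self):
        g = one_chrom(200)
        df = make_ascn({"1": [(1, 200 * MB, 1, 0)]})
        assert loh_score(df, g) == 0 == oracle_loh(df, g)

    def test_fragmented_loh_region_counts_once(self):
        g = one_chrom(200)
        df = make_ascn({"1": [(1, 100 * MB, 1, 1),
                              (100 * MB + 1, 110 * MB, 1, 0),
                              (110 * MB + 1, 125 * MB, 1, 0),
                              (125 * MB + 1, 200 * MB, 2, 1)]})
        assert loh_score(df, g) == 1

    def test_homozygous_deletion_not_loh(self):
        g = one_chrom(200)
        df = make_ascn({"1": [(1, 100 * MB, 1, 1),
                              (100 * MB + 1, 130 * MB, 0, 0),
                              (130 * MB + 1, 200 * MB, 1, 1)]})
        assert loh_score(df, g) == 0


class TestTaiScore:
    def test_telomeric_ai_counts(self):
        g = one_chrom(100, cen=(45, 50))
        df = make_ascn({"1": [(1, 80 * MB, 1, 1), (80 * MB + 1, 100 * MB, 2, 1)]})
        assert tai_score(df, g) == 1 == oracle_tai(df, g)

    def test_centromere_crossing_ai_excluded(self):
        g = one_chrom(100, cen=(45, 50))
        df = make_ascn({"1": [(1, 40 * MB, 1, 1), (40 * MB + 1, 60 * MB, 2, 1),
                              (60 * MB + 1, 100 * MB, 1, 1)]})
        assert tai_score(df, g) == 0 == oracle_tai(df, g)

    def test_interstitial_ai_excluded(self):
        g = one_chrom(100, cen=(45, 50))
        df = make_ascn({"1": [(1, 60 * MB, 1, 1), (60 * MB + 1, 80 * MB, 2, 1),
                              (80 * MB + 1, 100 * MB, 1, 1)]})
        assert tai_score(df, g) == 0


class TestLstScore:
    def test_two_large_segments_one_transition(self):
        g = one_chrom(200, cen=(150, 160))  # both segments on the p arm
        df = make_ascn({"1": [(1, 40 * MB, 2, 1), (40 * MB + 1, 90 * MB, 3, 1),
                              (90 * MB + 1, 200 * MB, 3, 1)]})
        assert lst_score(df, g) == 1 == oracle_lst(df, g)

    def test_small_interposed_segment_smoothed_away(self):
        g = one_chrom(200, cen=(150, 160))
        df = make_ascn({"1": [(1, 40 * MB, 2, 1),
                              (40 * MB + 1, 42 * MB, 4, 2),
                              (42 * MB + 1, 90 * MB, 3, 1),
                              (90 * MB + 1, 200 * MB, 3, 1)]})
        assert lst_score(df, g) == 1 == oracle_lst(df, g)

    def test_single_whole_arm_segment_no_transition(self):
        g = one_chrom(200, cen=(90, 100))
        df = make_ascn({"1": [(1, 200 * MB, 2, 1)]})
        assert lst_score(df, g) == 0

    def test_transition_across_centromere_not_counted(self):
        # arms are scored separately: a state change at the centromere is
        # split between arms and never a within-arm transition
        g = one_chrom(200, cen=(90, 100))
        df = make_ascn({"1": [(1, 95 * MB, 2, 1), (95 * MB + 1, 200 * MB, 3, 1)]})
        assert lst_score(df, g) == 0 == oracle_lst(df, g)


class TestScarAggregate:
    def test_scarhrd_sum_and_threshold(self):
        assert scarhrd_call(ScarScores(10, 15, 17)) == (42, True)
        assert scarhrd_call(ScarScores(0, 0, 0)) == (0, False)
        assert scarhrd_call(ScarScores(20, 20, 1)) == (41, False)

    @pytest.mark.parametrize("seed", range(40))
    def test_scores_equal_bruteforce_oracle_on_random_profiles(self, seed,
                                                               genome):
        rng = np.random.default_rng(1000 + seed)
        df = random_ascn_profile(rng, genome)
        s = scar_scores(df, genome)
        assert s.loh == oracle_loh(df, genome)
        assert s.tai == oracle_tai(df, genome)
        assert s.lst == oracle_lst(df, genome)

    def test_scores_invariant_under_state_preserving_refragmentation(self, genome):
        rng = np.random.default_rng(7)
        base = random_ascn_profile(rng, genome)
        rows = []
        for rec in base.to_dict("records"):
            if rec["end_bp"] - rec["start_bp"] > 10 and rng.random() < 0.7:
                cut = int(rng.integers(rec["start_bp"] + 1, rec["end_bp"]))
                rows.append(dict(rec, end_bp=cut))
                rows.append(dict(rec, start_bp=cut + 1))
            else:
                rows.append(rec)
        frag = pd.DataFrame(rows)
        assert scar_scores(base, genome) == scar_scores(frag, genome)


# ---------------------------------------------------------------------------
# CN48
# ---------------------------------------------------------------------------

class TestCn48:
    def test_loh_total2_25mb_channel(self):
        assert cn48_channel(2, 0, 25 * MB) == "2:LOH:10Mb-40Mb"

    def test_homozygous_deletion_small_channel(self):
        assert cn48_channel(0, 0, 50_000) == "0:homdel:0-100kb"

    def test_channel_sum_equals_segment_count(self, genome):
        rng = np.random.default_rng(3)
        df = random_ascn_profile(rng, genome)
        counts = cn48_catalogue(df)
        assert counts.to_numpy().sum() == len(df)

    def test_every_channel_is_canonical(self, genome):
        rng = np.random.default_rng(4)
        df = random_ascn_profile(rng, genome)
        assert set(cn48_catalogue(df).columns) == set(schemas.channels("CN48"))


class TestCnExposures:
    def _setup(self, seed=0):
        sigs = ("CN1", "CN2", "CN6", "CN7", "CN8", "CN9", "CN11", "CN17")
        return synthetic_catalogue("CN48", sigs, seed=seed)

    def test_exact_recovery(self):
        cat = self._setup()
        rng = np.random.default_rng(0)
        truth = rng.random((3, 8)) * 30
        counts = pd.DataFrame(truth @ cat.matrix.values.T,
                              index=list("ABC"), columns=list(cat.channels))
        out = cn_exposures(counts, cat)
        assert np.allclose(out.values, truth, atol=1e-6)

    def test_zero_counts_zero_exposures(self):
        cat = self._setup()
        counts = pd.DataFrame(0.0, index=["A"], columns=list(cat.channels))
        assert np.allclose(cn_exposures(counts, cat).values, 0.0)

    def test_noisy_counts_beat_grid_oracle(self):
        sigs = ("CN1", "CN2", "CN6")
        cat = synthetic_catalogue("CN48", sigs, seed=2)
        rng = np.random.default_rng(5)
        counts_vec = rng.poisson(20, size=48).astype(float)
        counts = pd.DataFrame([counts_vec], index=["A"],
                              columns=list(cat.channels))
        exp = cn_exposures(counts, cat, wanted=sigs).iloc[0].to_numpy()
        S = cat.matrix.values
        resid = np.linalg.norm(counts_vec - S @ exp)
        levels = np.linspace(0, counts_vec.sum(), 11)
        best = min(np.linalg.norm(counts_vec - S @ np.array(c))
                   for c in itertools.product(levels, repeat=3))
        assert resid <= best + 1e-9

    def test_schema_mismatch_rejected(self):
        cat = synthetic_catalogue("SBS96", ("CN1", "CN2", "CN6", "CN7",
                                            "CN8", "CN9", "CN11", "CN17"))
        counts = pd.DataFrame(0.0, index=["A"], columns=list(cat.channels))
        with pytest.raises(SchemaError):
            cn_exposures(counts, cat)


def test_planting_extra_loh_regions_increments_score(genome):
    base = make_ascn({"1": [(1, genome.chrom_length["1"], 1, 1)],
                      "2": [(1, genome.chrom_length["2"], 1, 1)]})
    assert loh_score(base, genome) == 0
    spans = [(10 * MB, 30 * MB, "1"), (60 * MB, 80 * MB, "1"),
             (100 * MB, 120 * MB, "2")]
    for k in range(1, 4):
        rows = []
        for chrom in ("1", "2"):
            L = genome.chrom_length[chrom]
            events = sorted((s, e) for s, e, c in spans[:k] if c == chrom)
            cursor = 1
            for s, e in events:
                rows.append({"sample_id": "S", "chrom": chrom, "start_bp": cursor,
                             "end_bp": s - 1, "total_cn": 2, "major_cn": 1,
                             "minor_cn": 1})
                rows.append({"sample_id": "S", "chrom": chrom, "start_bp": s,
                             "end_bp": e, "total_cn": 1, "major_cn": 1,
                             "minor_cn": 0})
                cursor = e + 1
            rows.append({"sample_id": "S", "chrom": chrom, "start_bp": cursor,
                         "end_bp": L, "total_cn": 2, "major_cn": 1,
                         "minor_cn": 1})
        assert loh_score(pd.DataFrame(rows), genome) == k
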