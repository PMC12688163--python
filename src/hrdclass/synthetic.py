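"""Synthetic cohort generation with planted HRD structure.

Two levels of simulation support the pipeline without any external data:

* ``simulate_genome_level`` emits allele-specific segment tables, mutation
  tables and BRCA1/2 evidence flags.  Scar events (interstitial LOH regions,
  telomeric allelic imbalance, large-scale transitions) are planted at
  class-conditional Poisson rates on top of a diploid baseline, and mutation
  channel counts are drawn from class-conditional signature mixtures; the
  truth record stores the counts actually planted per sample, so the scar
  modules' scores can be checked against them directly.  Planted event types
  interact (an interstitial LOH region necessarily adds two large-segment
  state transitions), so single-score round-trip checks should plant only the
  score's own events.

* ``simulate_feature_level`` emits a feature matrix directly: per feature,
  ln(value) is Gaussian with a class shift (in sd units) determined by the
  feature's block.  This isolates selection/training/evaluation from the
  feature-extraction stages.

Default conditions (chosen once as field-realistic): 35% true-HRD
prevalence, 30% of labels masked, HRD+ scar-event means 17/18/20
(LOH/TAI/LST; scarHRD-scale sum well above the conventional 42 cut-off)
versus 5/6/7 for HRD−, SBS3/ID6-dominated mutation mixtures in HRD+ tumours,
and WES-scale mutation burdens.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import schemas
from .core_io import ConfigurationError, EVIDENCE_FLAGS, FeatureMatrix, \
    GenomeAnnotation, SignatureCatalogue
from .labelling import label_cohort
from .ssc_train import load_registry

DEFAULT_SBS_MIX = {
    "positive": {"SBS3": 0.45, "SBS1": 0.10, "SBS5": 0.15, "SBS8": 0.10,
                 "SBS13": 0.10, "SBS18": 0.10},
    "negative": {"SBS1": 0.35, "SBS5": 0.40, "SBS13": 0.10, "SBS18": 0.15},
}
DEFAULT_ID_MIX = {
    "positive": {"ID6": 0.50, "ID8": 0.20, "ID1": 0.15, "ID2": 0.15},
    "negative": {"ID1": 0.45, "ID2": 0.35, "ID4": 0.10, "ID5": 0.10},
}

DEFAULT_BLOCK_SHIFTS = {"CNA": 0.5, "ASCN": 0.9, "SNV": 0.6}


@dataclasses.dataclass
class SimulationConfig:
    n_samples: int = 200
    prevalence: float = 0.35
    unknown_fraction: float = 0.30
    genome: GenomeAnnotation | None = None  # default: GRCh37 autosomes
    # genome-level scar intensities (Poisson means per class)
    loh_mean: dict = dataclasses.field(
        default_factory=lambda: {"positive": 17.0, "negative": 5.0})
    tai_mean: dict = dataclasses.field(
        default_factory=lambda: {"positive": 18.0, "negative": 6.0})
    lst_mean: dict = dataclasses.field(
        default_factory=lambda: {"positive": 20.0, "negative": 7.0})
    # mutation burdens (lognormal median counts) and signature mixtures
    snv_burden_median: float = 100.0
    indel_burden_median: float = 15.0
    burden_sigma: float = 0.4
    sbs_mix: dict = dataclasses.field(default_factory=lambda: DEFAULT_SBS_MIX)
    id_mix: dict = dataclasses.field(default_factory=lambda: DEFAULT_ID_MIX)
    # feature-level controls
    block_shifts: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BLOCK_SHIFTS))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.prevalence <= 1 or not 0 <= self.unknown_fraction <= 1:
            raise ConfigurationError("prevalence/unknown_fraction outside [0,1]")
        for d in (self.loh_mean, self.tai_mean, self.lst_mean):
            if min(d.values()) < 0:
                raise ConfigurationError("Poisson means must be >= 0")
        for mix in (*self.sbs_mix.values(), *self.id_mix.values()):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError("signature mixture weights must sum to 1")


# ---------------------------------------------------------------------------
# synthetic signature catalogues
# ---------------------------------------------------------------------------

def synthetic_catalogue(schema_id: str, signatures: tuple[str, ...],
                        seed: int = 0) -> SignatureCatalogue:
    """A deterministic random catalogue with the canonical channel list.

    Columns are sparse-ish Dirichlet draws; a stand-in for reference
    catalogues in tests and simulations (synthetic, not COSMIC-derived).
    """
    channels = schemas.channels(schema_id)
    rng = np.random.default_rng(seed)
    cols = {}
    for i, sig in enumerate(signatures):
        w = rng.gamma(0.3, size=len(channels))
        cols[sig] = w / w.sum()
    return SignatureCatalogue(
        schema_id, pd.DataFrame(cols, index=list(channels)))


# ---------------------------------------------------------------------------
# channel -> exemplar variant construction (inverse of channelization)
# ---------------------------------------------------------------------------

_FILLER = "GTGCATGCAGTACTGGATCCAGTACTGCAATGGCATCAGT"


def _pad(avoid: str, n: int = 30) -> str:
    """Filler sequence whose boundary base differs from ``avoid``."""
    seq = _FILLER * (n // len(_FILLER) + 1)
    seq = seq[:n]
    if seq[0] == avoid:
        seq = ("A" if avoid != "A" else "C") + seq[1:]
    return seq


def sbs_exemplar(channel: str) -> dict:
    """A concrete SNV row classifying into the given SBS96 channel."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return {"ref_allele": ref, "alt_allele": alt,
            "flank_5p": _pad("N")[:29] + five, "flank_3p": three + _pad("N")[:29],
            "variant_class": "SNV"}


_UNITS = {2: "AC", 3: "ACG", 4: "ACGT", 5: "ACGTC"}


def _anchor_for(first: str, last: str) -> str:
    """A base differing from both the unit's first and last base.

    The anchor sits immediately 5' of the indel; it must neither extend the
    repeat run nor create spurious reverse microhomology.
    """
    for b in "TGCA":
        if b not in (first, last):
            return b
    raise AssertionError("unreachable")


def id_exemplar(channel: str) -> dict:
    """A concrete anchored indel row classifying into the given ID83 channel."""
    size_s, kind, ctx, bin_s = channel.split(":")
    size, k = int(size_s), int(bin_s)
    if size == 1:
        unit = ctx  # C or T on the collapsed strand; emit as-is
        f3 = unit * k + _pad(unit)
    elif ctx == "R":
        unit = _UNITS[size]
        f3 = unit * k + _pad(unit[0])
    else:  # microhomology channel: mh length k needs a deletion longer than k
        unit = _UNITS[size] if k < size else "ACGTCG"
        stop = _anchor_for(unit[k], unit[k])
        f3 = unit[:k] + stop + _pad("N", 40)
    anchor = _anchor_for(unit[0], unit[-1])
    f5 = _pad("N", 40)  # anchor insulates the 5' side; any filler works
    if len(f3) < 6 * len(unit):
        f3 = f3 + _pad("N", 6 * len(unit) - len(f3))
    if kind == "Del":
        ref, alt, vclass = anchor + unit, anchor, "deletion"
    else:
        ref, alt, vclass = anchor, anchor + unit, "insertion"
    return {"ref_allele": ref, "alt_allele": alt, "flank_5p": f5,
            "flank_3p": f3, "variant_class": vclass}


def exemplar(schema_id: str, channel: str) -> dict:
    return sbs_exemplar(channel) if schema_id == "SBS96" else id_exemplar(channel)


# ---------------------------------------------------------------------------
# genome-level simulation
# ---------------------------------------------------------------------------

_BASELINE = (1, 1)  # diploid heterozygous major/minor


def _place_interval(rng, genome, chrom_occupancy, chrom_list, length_range,
                    margin: int = 11_000_000, max_tries: int = 60):
    """Find a free interior interval; returns (chrom, start, end) or None."""
    for _ in range(max_tries):
        chrom = chrom_list[rng.integers(len(chrom_list))]
        L = genome.chrom_length[chrom]
        length = int(rng.uniform(*length_range))
        if length + 2 * margin >= L:
            continue
        start = int(rng.uniform(margin, L - length - margin))
        end = start + length - 1
        if _is_free(chrom_occupancy[chrom], start - margin, end + margin):
            chrom_occupancy[chrom].append((start, end))
            return chrom, start, end
    return None


def _is_free(intervals, start, end) -> bool:
    return all(end < s or start > e for s, e in intervals)


def _sample_segments(rng, genome: GenomeAnnotation, n_loh: int, n_tai: int,
                     n_lst: int) -> tuple[list[dict], dict]:
    """Plant events on a diploid baseline; returns (segment rows, planted counts)."""
    autosomes = list(genome.autosomes())
    occupancy = {c: [] for c in autosomes}
    events = []  # (chrom, start, end, major, minor)
    planted = {"loh": 0, "tai": 0, "lst": 0}
    margin = 11_000_000

    # telomeric AI first (they need chromosome ends)
    tel_slots = [(c, arm) for c in autosomes for arm in ("p", "q")]
    rng.shuffle(tel_slots)
    for chrom, arm in tel_slots[:n_tai]:
        L = genome.chrom_length[chrom]
        cen_start, cen_end = genome.centromere[chrom]
        if arm == "p":
            max_len = cen_start - margin
            if max_len < 6_000_000:
                continue
            length = int(rng.uniform(5_000_000, min(max_len, 30_000_000)))
            start, end = 1, length
        else:
            max_len = L - cen_end - margin
            if max_len < 6_000_000:
                continue
            length = int(rng.uniform(5_000_000, min(max_len, 30_000_000)))
            start, end = L - length + 1, L
        if not _is_free(occupancy[chrom], start - margin, end + margin):
            continue
        occupancy[chrom].append((start, end))
        events.append((chrom, start, end, 2, 1))  # AI, not LOH
        planted["tai"] += 1

    for _ in range(n_loh):
        hit = _place_interval(rng, genome, occupancy, autosomes,
                              (16_000_000, 40_000_000), margin)
        if hit is None:
            continue
        chrom, start, end = hit
        events.append((chrom, start, end, 1, 0))  # interstitial LOH
        planted["loh"] += 1

    for _ in range(n_lst):
        # terminal balanced-gain block: exactly one large-segment transition
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        L = genome.chrom_length[chrom]
        cen_start, cen_end = genome.centromere[chrom]
        arm = "p" if rng.random() < 0.5 else "q"
        if arm == "p":
            max_len = cen_start - margin
            if max_len < 12_000_000:
                continue
            length = int(rng.uniform(10_500_000, min(max_len, 25_000_000)))
            start, end = 1, length
        else:
            max_len = L - cen_end - margin
            if max_len < 12_000_000:
                continue
            length = int(rng.uniform(10_500_000, min(max_len, 25_000_000)))
            start, end = L - length + 1, L
        if not _is_free(occupancy[chrom], start - margin, end + margin):
            continue
        occupancy[chrom].append((start, end))
        events.append((chrom, start, end, 2, 2))  # balanced gain: no AI/LOH
        planted["lst"] += 1

    # assemble per-chromosome segment lists: baseline filled around events
    rows = []
    for chrom in autosomes:
        L = genome.chrom_length[chrom]
        evs = sorted([e for e in events if e[0] == chrom], key=lambda e: e[1])
        cursor = 1
        for _, start, end, major, minor in evs:
            if start > cursor:
                rows.append({"chrom": chrom, "start_bp": cursor,
                             "end_bp": start - 1, "major_cn": _BASELINE[0],
                             "minor_cn": _BASELINE[1]})
            rows.append({"chrom": chrom, "start_bp": start, "end_bp": end,
                         "major_cn": major, "minor_cn": minor})
            cursor = end + 1
        if cursor <= L:
            rows.append({"chrom": chrom, "start_bp": cursor, "end_bp": L,
                         "major_cn": _BASELINE[0], "minor_cn": _BASELINE[1]})
    for r in rows:
        r["total_cn"] = r["major_cn"] + r["minor_cn"]
    return rows, planted


def _sample_mutations(rng, sample_id: str, status: str, config: SimulationConfig,
                      sbs_cat: SignatureCatalogue, id_cat: SignatureCatalogue
                      ) -> list[dict]:
    rows = []
    for cat, mix, median in (
            (sbs_cat, config.sbs_mix[status], config.snv_burden_median),
            (id_cat, config.id_mix[status], config.indel_burden_median)):
        weights = np.zeros(len(cat.signatures))
        for sig, w in mix.items():
            if sig not in cat.signatures:
                raise ConfigurationError(f"mixture signature {sig} not in catalogue")
            weights[list(cat.signatures).index(sig)] = w
        channel_p = cat.matrix.values @ weights
        channel_p = channel_p / channel_p.sum()
        n = int(rng.lognormal(np.log(median), config.burden_sigma))
        counts = rng.multinomial(n, channel_p)
        pos = 1000
        for channel, count in zip(cat.channels, counts):
            for _ in range(count):
                row = exemplar(cat.schema_id, channel)
                row.update({"sample_id": sample_id, "chrom": "1", "pos": pos})
                rows.append(row)
                pos += 100
    return rows


def _evidence_flags(rng, status: str, masked: bool) -> dict:
    flags = {f: "no" for f in EVIDENCE_FLAGS}
    if masked:
        return {f: "missing" for f in EVIDENCE_FLAGS}
    if status == "positive":
        if rng.random() < 2 / 3:
            gene = "brca1" if rng.random() < 0.5 else "brca2"
            flags[f"germline_{gene}"] = "yes"
            flags[f"loh_{gene}"] = "yes"
        else:
            flags["brca1_methylation"] = "yes"
            flags["loh_brca1"] = "yes"
    else:
        # negative via the no-mutation clause; LOH flags free to vary
        flags["loh_brca1"] = "yes" if rng.random() < 0.2 else "no"
        flags["loh_brca2"] = "yes" if rng.random() < 0.2 else "no"
    return flags


def simulate_genome_level(config: SimulationConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                     pd.DataFrame]:
    """(ASCN segment table, mutation table, label table, truth record)."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome or GenomeAnnotation.builtin("GRCh37")
    sbs_cat = synthetic_catalogue("SBS96", tuple(DEFAULT_SBS_MIX["positive"])
                                  + tuple(k for k in DEFAULT_SBS_MIX["negative"]
                                          if k not in DEFAULT_SBS_MIX["positive"]),
                                  seed=101)
    id_cat = synthetic_catalogue("ID83", tuple(DEFAULT_ID_MIX["positive"])
                                 + tuple(k for k in DEFAULT_ID_MIX["negative"]
                                         if k not in DEFAULT_ID_MIX["positive"]),
                                 seed=202)

    seg_rows, mut_rows, label_rows, truth_rows = [], [], [], []
    for i in range(config.n_samples):
        sample = f"S{i:04d}"
        status = "positive" if rng.random() < config.prevalence else "negative"
        n_loh = rng.poisson(config.loh_mean[status])
        n_tai = rng.poisson(config.tai_mean[status])
        n_lst = rng.poisson(config.lst_mean[status])
        rows, planted = _sample_segments(rng, genome, n_loh, n_tai, n_lst)
        for r in rows:
            r["sample_id"] = sample
        seg_rows.extend(rows)
        mut_rows.extend(_sample_mutations(rng, sample, status, config,
                                          sbs_cat, id_cat))
        masked = rng.random() < config.unknown_fraction
        label_rows.append({"sample_id": sample,
                           **_evidence_flags(rng, status, masked)})
        truth_rows.append({"sample_id": sample, "true_status": status,
                           "masked": masked, **{f"planted_{k}": v
                                                for k, v in planted.items()}})

    segments = pd.DataFrame(seg_rows)[
        ["sample_id", "chrom", "start_bp", "end_bp", "total_cn",
         "major_cn", "minor_cn"]]
    mutations = pd.DataFrame(mut_rows)[
        ["sample_id", "chrom", "pos", "ref_allele", "alt_allele",
         "variant_class", "flank_5p", "flank_3p"]]
    labels, _ = label_cohort(pd.DataFrame(label_rows))
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return segments, mutations, labels, truth


# ---------------------------------------------------------------------------
# feature-level simulation
# ---------------------------------------------------------------------------

def simulate_feature_level(config: SimulationConfig,
                           feature_shifts: dict[str, float] | None = None
                           ) -> tuple[FeatureMatrix, pd.DataFrame, pd.DataFrame]:
    """(FeatureMatrix[raw], label table, truth record).

    Per feature f: ln(value) ~ N(mu0 + shift_f * 1[HRD+], noise_sd) with
    shift_f from ``feature_shifts`` or the feature's block default.  Values
    are strictly positive, so the matrix is valid raw-state input to the
    normalisation stage.
    """
    rng = np.random.default_rng(config.seed)
    registry = load_registry()
    features = list(registry["SNV+ASCN"].features)
    blocks = {}
    for f in features:
        if f in registry["SNV"].features:
            blocks[f] = "SNV"
        elif f in registry["CNA"].features:
            blocks[f] = "CNA"
        else:
            blocks[f] = "ASCN"
    shifts = {f: (feature_shifts or {}).get(
        f, config.block_shifts[blocks[f]]) for f in features}

    status = np.where(rng.random(config.n_samples) < config.prevalence,
                      "positive", "negative")
    mu0 = 1.0
    g = np.empty((config.n_samples, len(features)))
    for j, f in enumerate(features):
        g[:, j] = rng.normal(mu0 + shifts[f] * (status == "positive"),
                             config.noise_sd)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    values = pd.DataFrame(np.exp(g), index=sample_ids, columns=features)
    fm = FeatureMatrix(values, blocks, state="raw")

    masked = rng.random(config.n_samples) < config.unknown_fraction
    label_rows = [{"sample_id": s, **_evidence_flags(rng, st, mk)}
                  for s, st, mk in zip(sample_ids, status, masked)]
    labels, _ = label_cohort(pd.DataFrame(label_rows))
    truth = pd.DataFrame({"true_status": status, "masked": masked},
                         index=sample_ids)
    truth.index.name = "sample_id"
    for f in features:
        truth[f"shift_{f}"] = shifts[f]
    return fm, labels, truth
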