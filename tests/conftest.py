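import numpy as np
import pandas as pd
import pytest

from hrdclass import SimulationConfig, simulate_feature_level, toy_genome
from hrdclass.core_io import GenomeAnnotation


@pytest.fixture(scope="session")
def genome() -> GenomeAnnotation:
    return toy_genome()


@pytest.fixture(scope="session")
def feature_cohort():
    """Default feature-level cohort (120 samples) shared across tests."""
    cfg = SimulationConfig(n_samples=120, seed=11)
    fm, labels_tab, truth = simulate_feature_level(cfg)
    labels = labels_tab.set_index("sample_id")["hrd_status"]
    return fm, labels, truth


def random_ascn_profile(rng: np.random.Generator, genome: GenomeAnnotation,
                        sample_id: str = "S") -> pd.DataFrame:
    """Random valid allele-specific profile on the toy genome."""
    rows = []
    states = [(1, 1), (1, 1), (1, 1), (1, 0), (2, 1), (2, 0), (2, 2),
              (3, 1), (0, 0), (4, 2)]
    for chrom in genome.chrom_names:
        L = genome.chrom_length[chrom]
        n_seg = int(rng.integers(1, 13))
        cuts = np.unique(rng.integers(2, L, size=n_seg - 1)) \
            if n_seg > 1 else np.array([], int)
        bounds = [1, *cuts.tolist(), L + 1]
        for s, e in zip(bounds[:-1], bounds[1:]):
            major, minor = states[int(rng.integers(len(states)))]
            rows.append({"sample_id": sample_id, "chrom": chrom,
                         "start_bp": int(s), "end_bp": int(e - 1),
                         "total_cn": major + minor,
                         "major_cn": major, "minor_cn": minor})
    return pd.DataFrame(rows)


def make_segments(chrom_profiles: dict[str, list[tuple[int, int, float]]],
                  sample_id: str = "S") -> pd.DataFrame:
    """Total-CN table from {chrom: [(start, end, cn), ...]}."""
    rows = [{"sample_id": sample_id, "chrom": c, "start_bp": s, "end_bp": e,
             "total_cn": cn}
            for c, segs in chrom_profiles.items() for s, e, cn in segs]
    return pd.DataFrame(rows)


def make_ascn(chrom_profiles: dict[str, list[tuple[int, int, int, int]]],
              sample_id: str = "S") -> pd.DataFrame:
    """ASCN table from {chrom: [(start, end, major, minor), ...]}."""
    rows = [{"sample_id": sample_id, "chrom": c, "start_bp": s, "end_bp": e,
             "total_cn": ma + mi, "major_cn": ma, "minor_cn": mi}
            for c, segs in chrom_profiles.items() for s, e, ma, mi in segs]
    return pd.DataFrame(rows)
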