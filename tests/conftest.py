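import numpy as np
import pytest

from tmbpair.regions import GenomicInterval, RegionSet
from tmbpair.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-patient default-conditions cohort, generated once per session."""
    return generate_cohort(CohortConfig(n_patients=5, seed=11))


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    small_cohort.write(d, overwrite=True)
    from tmbpair.cli import _write_run_configs

    _write_run_configs(d, small_cohort.config)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(20230313)


# ---- oracles shared across test modules ------------------------------------

TOY_CHROMS = {"cA": 10_000, "cB": 5_000}


def random_region_set(rng, n=20, chroms=TOY_CHROMS, max_len=400, label="rand"):
    ivs = []
    names = list(chroms)
    for _ in range(n):
        c = names[rng.integers(len(names))]
        start = int(rng.integers(0, chroms[c] - 1))
        end = int(min(start + 1 + rng.integers(max_len), chroms[c]))
        ivs.append(GenomicInterval(c, start, end))
    return RegionSet(ivs, label=label)


def mask_of(region_set, chroms=TOY_CHROMS):
    """Per-base boolean-mask oracle for interval algebra on toy genomes."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in chroms.items()}
    for iv in region_set:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
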