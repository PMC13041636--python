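import numpy as np
import pytest

from vinekit import (
    GenotypeMatrix,
    default_config,
    deduplicate_samples,
    find_duplicates,
    run_iterative_curation,
    simulate_candidate_vcf,
    simulate_panel,
)

SEED = 1


@pytest.fixture(scope="session")
def sim():
    """Default study-conditions panel: 120 samples, ~5,000 markers."""
    return simulate_panel(default_config(seed=SEED))


@pytest.fixture(scope="session")
def curation_run(sim):
    """Duplicate removal followed by iterative Mendelian curation.

    Kinship statistics run on nuclear markers only: maternally inherited
    plastid loci violate biparental transmission by construction.
    """
    gm = sim.nuclear_gm
    dups = find_duplicates(gm, max_diff=10)
    gm_u = deduplicate_samples(gm, dups)
    run = run_iterative_curation(gm_u, sim.pedigree)
    return {"duplicates": dups, "gm_unique": gm_u, "run": run}


@pytest.fixture(scope="session")
def candidate_pool(tmp_path_factory):
    """Synthetic candidate VCF with planted filter-failure truth."""
    from vinekit import read_candidate_vcf

    path = tmp_path_factory.mktemp("vcf") / "candidates.vcf"
    truth = simulate_candidate_vcf(default_config(seed=SEED), path)
    variants = read_candidate_vcf(path)
    return {"path": path, "truth": truth, "variants": variants}


def gm_from_calls(rows: dict[str, list[str]], marker_ids=None) -> GenotypeMatrix:
    """Small-matrix helper: {sample: [letter calls]} -> GenotypeMatrix."""
    code = {"AA": 0, "AB": 1, "BB": 2, "NC": -1}
    samples = list(rows)
    n_markers = len(next(iter(rows.values())))
    markers = marker_ids or [f"M{j + 1}" for j in range(n_markers)]
    codes = np.array([[code[c] for c in rows[s]] for s in samples], dtype=np.int8)
    return GenotypeMatrix(samples, markers, codes)


def random_gm(rng: np.random.Generator, n_samples: int, n_markers: int,
              nc_rate: float = 0.05) -> GenotypeMatrix:
    codes = rng.integers(0, 3, (n_samples, n_markers)).astype(np.int8)
    codes[rng.random(codes.shape) < nc_rate] = -1
    return GenotypeMatrix(
        [f"S{i:03d}" for i in range(n_samples)],
        [f"M{j:04d}" for j in range(n_markers)],
        codes,
    )
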