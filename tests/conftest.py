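import numpy as np
import pytest

import promoterfoot as pf


@pytest.fixture(scope="session")
def small_universe():
    """60-gene, 2-chromosome universe used by cheap unit tests."""
    return pf.simulate_gene_universe(60, 2, seed=7)


@pytest.fixture(scope="session")
def signal_study():
    """Planted-signal training cohort at the study scale.

    40 cases vs 40 controls over 2000 promoters, 50 promoters planted at a
    target log2 fold change of 1.5, ~10% placental fraction, depletion 0.6.
    """
    universe = pf.simulate_gene_universe(2000, 2, seed=20)
    occupancy = pf.OccupancyModel(depletion_depth=0.6)
    planted = tuple(universe.transcripts["transcript_id"].iloc[10::40][:50])
    spec = pf.CohortSpec(
        n_cases=40,
        n_controls=40,
        planted_promoters=planted,
        effect_lfc=1.5,
        fragments_per_sample=150_000,
        seed=20,
    )
    samples, meta, truth = pf.simulate_cohort(
        universe, occupancy, spec, cohort_name="training"
    )
    windows = pf.build_ptss_windows(universe.to_transcript_models())
    matrix = pf.build_coverage_matrix(samples, windows, meta)
    return {
        "universe": universe,
        "occupancy": occupancy,
        "spec": spec,
        "windows": windows,
        "matrix": matrix,
        "truth": truth,
        "planted": list(planted),
    }


@pytest.fixture(scope="session")
def validation_matrix(signal_study):
    """Independent cohort from the same generative parameters, new seed."""
    universe = signal_study["universe"]
    occupancy = signal_study["occupancy"]
    spec = signal_study["spec"]
    val_spec = pf.CohortSpec(
        n_cases=spec.n_cases,
        n_controls=spec.n_controls,
        planted_promoters=spec.planted_promoters,
        effect_lfc=spec.effect_lfc,
        fragments_per_sample=spec.fragments_per_sample,
        seed=spec.seed + 1,
    )
    samples, meta, _truth = pf.simulate_cohort(
        universe, occupancy, val_spec, cohort_name="validation"
    )
    return pf.build_coverage_matrix(samples, signal_study["windows"], meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
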