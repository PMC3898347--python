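import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130)


@pytest.fixture(scope="session")
def small_panel():
    """A tiny deterministic 3-SNP panel."""
    from gxemyo import SNPPanel

    return SNPPanel(
        pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2", "rs3"],
                "effect_allele": ["A", "C", "G"],
                "other_allele": ["G", "T", "A"],
                "beta": [0.10, 0.20, 0.05],
            }
        )
    )


@pytest.fixture(scope="session")
def status_cohort():
    """Factory: cohort table with sentinel SE encoding case (−4 D) /
    control (+4 D) status."""

    def build(case, **extra):
        case = np.asarray(case, bool)
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(case))],
                "se_mean": np.where(case, -4.0, 4.0),
                "excluded": False,
            }
        )
        for key, value in extra.items():
            df[key] = np.asarray(value)
        return df

    return build


@pytest.fixture(scope="session")
def generated_cohort():
    """Interaction-structured continuous cohort at the default study size."""
    from gxemyo import CohortSpec, generate_cohort, generate_snp_panel, rotterdam_panel_spec

    panel = generate_snp_panel(rotterdam_panel_spec(7))
    cohort = generate_cohort(panel, CohortSpec(n_subjects=9194, seed=7))
    return cohort
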