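import numpy as np
import pytest

from gliorisk import DATASET2_PANEL, Cohort, SimConfig, simulate_cohort
from gliorisk.panels import SnpSpec


@pytest.fixture(scope="session")
def dataset2_cohort() -> Cohort:
    """One cohort at the published dataset2 sample sizes (743/900)."""
    return simulate_cohort(
        DATASET2_PANEL, SimConfig(n_case=743, n_ctrl=900, seed=20160728)
    )


@pytest.fixture(scope="session")
def large_cohort() -> Cohort:
    """A large cohort for law-of-large-numbers checks."""
    return simulate_cohort(
        DATASET2_PANEL, SimConfig(n_case=50000, n_ctrl=50000, seed=7)
    )


def make_snp(snp_id="rs1", p_case=0.5, p_ctrl=0.5, allelic_or=1.0):
    return SnpSpec(snp_id, "1", "A", "G", p_case, p_ctrl, allelic_or)


@pytest.fixture
def make_cohort():
    """Factory building a Cohort directly from a dosage matrix."""

    def _make(dosages, is_case, fmc=None, ors=None):
        dosages = np.asarray(dosages, float)
        k = dosages.shape[1]
        panel = [
            make_snp(f"rs{i + 1}", allelic_or=(ors[i] if ors else 1.0))
            for i in range(k)
        ]
        return Cohort(
            dosages=dosages,
            is_case=np.asarray(is_case),
            panel=panel,
            fmc=None if fmc is None else np.asarray(fmc),
        )

    return _make
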