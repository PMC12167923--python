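import numpy as np
import pytest

from pvdose.population import PopulationSpec, generate_stratified_population
from pvdose.twin import HctPD, LineagePD, PatientParameters


@pytest.fixture(scope="session")
def typical_patient() -> PatientParameters:
    """A hand-fixed PV patient with elevated PLT and WBC (no HCT issue)."""
    return PatientParameters(
        ka=2.0,
        cl=150.0,
        v=50.0,
        ke0=0.1,
        plt=LineagePD(baseline=650.0, mtt=10.0, gamma=0.3, slope=0.34),
        wbc=LineagePD(baseline=13.0, mtt=5.0, gamma=0.25, slope=0.20),
        hct=HctPD(baseline=42.0, kout=0.05, slope=0.25),
    )


@pytest.fixture(scope="session")
def high_hct_patient() -> PatientParameters:
    """A patient needing the baseline phlebotomy (HCT >= 45)."""
    return PatientParameters(
        ka=2.0,
        cl=150.0,
        v=50.0,
        ke0=0.1,
        plt=LineagePD(baseline=650.0, mtt=10.0, gamma=0.3, slope=0.34),
        wbc=LineagePD(baseline=13.0, mtt=5.0, gamma=0.25, slope=0.20),
        hct=HctPD(baseline=48.0, kout=0.05, slope=0.25),
    )


@pytest.fixture(scope="session")
def small_population():
    """Seeded 7-patient stratified population (one per baseline pattern)."""
    return generate_stratified_population(PopulationSpec(n_patients=7, seed=1234))
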