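import numpy as np
import pytest

from epiphany.cohort_io import PatientEpisode, cohort_from_episodes
from epiphany.synthetic_cohort import CohortConfig, generate_cohort

#: benign defaults: an episode meeting no adapted Hestia criterion, with an
#: incidental asymptomatic presentation and controlled disease -> low risk
_DEFAULTS = dict(
    episode_id="e1",
    age=66,
    sex="male",
    ecog_ps=1,
    tumor_type="lung",
    stage_iv=True,
    recist="sd",
    primary_resected=False,
    sbp=130.0,
    hr=82.0,
    rr=16.0,
    spo2=96.0,
    pe_symptoms=frozenset(),
    presentation="unsuspected_asymptomatic",
    clinically_relevant_bleeding=False,
    high_bleeding_risk=False,
    platelets=250_000.0,
    other_admission_criterion=False,
    prior_anticoagulation=False,
    outpatient=True,
    complication_15d=False,
    complication_day=None,
    death_30d=False,
    os_time=12.0,
    os_event=False,
)


def make_episode(**overrides) -> PatientEpisode:
    kw = dict(_DEFAULTS)
    kw.update(overrides)
    return PatientEpisode(**kw)


@pytest.fixture
def episode_factory():
    return make_episode


@pytest.fixture(scope="session")
def default_cohort():
    """The 900-episode synthetic cohort under study defaults, fixed seed."""
    return generate_cohort(CohortConfig(), seed=20171014)


@pytest.fixture(scope="session")
def table3_cohort():
    """A cohort reproducing the published per-stratum counts exactly:
    232 low-risk with 5 complications, 229 intermediate with 12,
    439 high-risk with 90 (and 1/7/57 thirty-day deaths)."""
    episodes = []
    spec = [
        # (n, events, deaths, overrides pinning the stratum)
        (232, 5, 1, dict()),  # defaults are low risk
        (229, 12, 7, dict(recist="pd", primary_resected=False)),  # intermediate
        (439, 90, 57, dict(presentation="suspected",
                           pe_symptoms=frozenset({"sudden_or_progressive_dyspnea"}),
                           hr=120.0)),  # Hestia-positive symptomatic -> high
    ]
    i = 0
    for n, events, deaths, overrides in spec:
        for j in range(n):
            i += 1
            death = j < deaths
            episodes.append(
                make_episode(
                    episode_id=f"t{i:04d}",
                    complication_15d=j < events,
                    complication_day=2 if j < events else None,
                    death_30d=death,
                    os_time=0.5 if death else 12.0,
                    os_event=death,
                    **overrides,
                )
            )
    return cohort_from_episodes(episodes)
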