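import numpy as np
import pytest

from aptt_cwa.cohort import CohortSpec, LabDistribution
from aptt_cwa.curves import GeneratorPreset
from aptt_cwa.report import run_all


@pytest.fixture
def logistic_preset() -> GeneratorPreset:
    """Symmetric logistic: A=400, m=40 s, s=4 s; closed forms are
    elementary."""
    return GeneratorPreset(amplitude=400.0, center=40.0, slope=4.0, asymmetry=1.0)


@pytest.fixture
def small_spec() -> CohortSpec:
    """Scaled-down cohort spec (22 patients + 3 HVs) for fast pipeline
    tests."""
    return CohortSpec(
        group_sizes={"non_dic": 12, "pre_dic": 3, "dic_no_hf": 4, "dic_hf": 3, "hv": 3},
        disease_counts={
            "sepsis": 6, "pneumonia": 4, "other_infection": 1,
            "trauma": 5, "aneurysm": 2, "hematopoietic_malignancy": 2,
            "cardiopulmonary_arrest": 2,
        },
        infectious_quota={"dic_no_hf": 3, "dic_hf": 1},
        n_non_survivors=6,
        n_hb_low=6,
        seed=7,
    )


def random_preset(rng: np.random.Generator) -> GeneratorPreset:
    """Valid pure-sigmoid preset with the peaks well inside the
    acquisition window."""
    while True:
        nu = rng.uniform(-0.45, 2.0)
        s = rng.uniform(2.5, 9.0)
        m = rng.uniform(30.0, 90.0)
        A = rng.uniform(150.0, 900.0)
        p = GeneratorPreset(
            amplitude=A, center=m, slope=s, asymmetry=nu,
            scale_1st=rng.uniform(0.5, 8.0), scale_2nd=rng.uniform(0.5, 40.0),
        )
        # keep the acceleration peak clear of the front edge, the
        # deceleration lobe's half crossing inside the window, and the
        # curve settled at baseline when acquisition starts
        from aptt_cwa.curves import analytic_parameters, model_absorbance

        ap = analytic_parameters(p)
        settled = model_absorbance(p, p.t_start) < 1e-3 * A
        if settled and ap.t_2nd1 > 8.0 and not ap.censored_widths and ap.t_halfff < 150.0:
            return p


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One seeded end-to-end pipeline run on the full default cohort,
    shared across report-level tests."""
    out = tmp_path_factory.mktemp("default_run")
    return run_all(seed=0, out_dir=out)
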