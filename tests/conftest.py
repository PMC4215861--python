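"""Shared fixtures: small, fast synthetic cohorts and pipeline runs."""

from __future__ import annotations

from dataclasses import replace

import pytest

import lvatlas as lv
from lvatlas.pipeline import RunConfig, run_pipeline


def small_population(n_control=120, n_patient=60, seed=0, noise=0.5,
                     grid=None, effect_scale=1.0, **overrides):
    """Default conditions at reduced size/grid.  ``effect_scale`` < 1 shrinks
    the patient-vs-control mean differences toward zero: at the default
    effect sizes small cohorts are perfectly separable, which is the wrong
    regime for testing fitting machinery."""
    cfg = lv.default_population_config(
        n_control=n_control, n_patient=n_patient, seed=seed,
        point_noise_sd=noise, grid=grid or lv.SurfaceGrid(16, 16))
    if effect_scale != 1.0:
        ctl, pat = cfg.control, cfg.patient

        def mix(c, p):
            return {k: c[k] + effect_scale * (p[k] - c[k]) for k in c}

        cfg = replace(cfg, patient=replace(
            pat,
            latent_means=mix(ctl.latent_means, pat.latent_means),
            covariate_means=mix(ctl.covariate_means, pat.covariate_means),
            male_fraction=ctl.male_fraction + effect_scale
            * (pat.male_fraction - ctl.male_fraction)))
    return replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_cohort():
    """Default-distribution cohort at reduced size and grid."""
    return lv.generate_cohort(small_population())


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline on a reduced cohort, protocol bias + correction on."""
    cfg = RunConfig(population=small_population(n_control=150, n_patient=60,
                                                seed=5, effect_scale=0.4),
                    seed=5)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def unbiased_run():
    """Pipeline without protocol bias, tight alignment tolerance; used for
    exact scoring-consistency checks."""
    cfg = RunConfig(population=small_population(n_control=80, n_patient=40,
                                                seed=9, effect_scale=0.3),
                    seed=9, apply_protocol_bias=False, gpa_tol=1e-10)
    return run_pipeline(cfg)
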