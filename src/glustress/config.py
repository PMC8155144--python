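"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator emulates a four-arm acute-stress MRS study: two stressed
healthy-control samples (one of which serves as the calibration sample for
the expected glutamate-change line), a no-stress control (NSC) arm, and an
MDD arm with markedly higher perceived stress.  Defaults encode the cohort
structure of that study design: group sizes, per-group Perceived Stress
Scale (PSS) moments, and the linear law linking PSS to percent change in
creatine-normalized glutamate in stressed healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

GROUP_HC_CALIBRATION = "hc_stress_calibration"
GROUP_HC_REPLICATION = "hc_stress_replication"
GROUP_NSC = "nsc"
GROUP_MDD = "mdd"

GROUPS = (GROUP_HC_CALIBRATION, GROUP_HC_REPLICATION, GROUP_NSC, GROUP_MDD)
#: groups that receive the acute stressor (everyone but the no-stress arm)
STRESS_GROUPS = (GROUP_HC_CALIBRATION, GROUP_HC_REPLICATION, GROUP_MDD)
#: groups followed with ecological momentary assessment (the two arms
#: scored for the maladaptive glutamate response)
EMA_GROUPS = (GROUP_HC_REPLICATION, GROUP_MDD)


@dataclass
class GroupParams:
    """Per-arm cohort parameters.

    PSS moments and demographics follow the study's demographic table;
    ``slope_multiplier`` scales the PSS -> %dGlu law (1 for stressed healthy
    controls, 0 for the no-stress arm and for MDD, whose adaptive response
    is absent).
    """

    n: int
    pss_mean: float
    pss_sd: float
    age_mean: float
    age_sd: float
    female_frac: float
    slope_multiplier: float
    site: str

    def validate(self, name: str) -> None:
        if self.n <= 0:
            raise ValueError(f"groups[{name}].n must be > 0")
        if self.pss_sd < 0 or self.age_sd < 0:
            raise ValueError(f"groups[{name}]: standard deviations must be >= 0")
        if not 0.0 <= self.female_frac <= 1.0:
            raise ValueError(f"groups[{name}].female_frac must be in [0, 1]")


def _default_groups() -> dict:
    return {
        GROUP_HC_CALIBRATION: GroupParams(
            n=25, pss_mean=10.12, pss_sd=3.70, age_mean=26.04, age_sd=6.20,
            female_frac=0.600, slope_multiplier=1.0, site="mclean"),
        GROUP_HC_REPLICATION: GroupParams(
            n=22, pss_mean=9.00, pss_sd=5.04, age_mean=28.36, age_sd=8.21,
            female_frac=0.688, slope_multiplier=1.0, site="emory"),
        GROUP_NSC: GroupParams(
            n=18, pss_mean=12.11, pss_sd=5.45, age_mean=23.44, age_sd=4.40,
            female_frac=0.778, slope_multiplier=0.0, site="emory"),
        GROUP_MDD: GroupParams(
            n=23, pss_mean=27.43, pss_sd=5.89, age_mean=29.87, age_sd=10.61,
            female_frac=0.696, slope_multiplier=0.0, site="emory"),
    }


@dataclass
class EmaParams:
    """Parameters of the ecological-momentary-assessment stream generator.

    Surveys go out on alternate days for four weeks (14 active days), six
    per active day spaced two hours apart.  ``coupling`` is the target
    group-adjusted correlation between a participant's maladaptive
    glutamate response and their scored mean pessimistic-expectation
    magnitude; it is realized through a Gaussian copula on the latent
    per-subject pessimism level.
    """

    n_days: int = 14
    surveys_per_day: int = 6
    completion_prob: float = 0.844
    invalid_fraction: float = 0.05
    coupling: float = 0.5
    #: latent mean/sd of the per-subject pessimistic-delta magnitude
    pess_magnitude_mean: float = 2.0
    pess_magnitude_sd: float = 0.8
    opt_magnitude_mean: float = -2.0
    delta_noise_sd: float = 1.0
    expectation_sd: float = 1.2
    happened_prob: float = 0.85
    # per diagnostic arm: expectation mean, positive/negative affect means,
    # and (accurate, pessimistic, optimistic) class probabilities
    expectation_mean: dict = field(default_factory=lambda: {"hc": 0.8, "mdd": 0.0})
    pos_affect_mean: dict = field(default_factory=lambda: {"hc": 3.5, "mdd": 2.5})
    neg_affect_mean: dict = field(default_factory=lambda: {"hc": 1.8, "mdd": 2.8})
    affect_sd: float = 0.8
    class_probs: dict = field(default_factory=lambda: {
        "hc": (0.53, 0.28, 0.19), "mdd": (0.38, 0.38, 0.24)})

    def validate(self) -> None:
        if self.n_days <= 0:
            raise ValueError("ema.n_days must be > 0")
        if not 1 <= self.surveys_per_day <= 6:
            raise ValueError("ema.surveys_per_day must be in 1..6")
        if not 0.0 <= self.completion_prob <= 1.0:
            raise ValueError("ema.completion_prob must be in [0, 1]")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("ema.invalid_fraction must be in [0, 1]")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("ema.coupling must be in [-1, 1]")
        for key, probs in self.class_probs.items():
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"ema.class_probs[{key}] must sum to 1")


@dataclass
class GeneratorConfig:
    """Full stated world of the synthetic study.

    The calibration law defaults to the published healthy-control line
    (%dGlu expected = 35.647 - 3.093 * PSS).  ``residual_sd`` (percent) is
    chosen so the population PSS-%dGlu correlation in stressed healthy
    controls is about -0.5, matching the reported effect sizes.  Baseline
    metabolite levels are plausible placeholders (no reference values are
    available); the post-stress ratio is derived from the baseline and the
    target percent change, so the percent-change equation is exactly
    invertible.
    """

    seed: int = 0
    groups: dict = field(default_factory=_default_groups)
    intercept: float = 35.647          # percent, at PSS = 0
    slope: float = -3.093              # percent per PSS unit
    residual_sd: float = 20.0          # percent
    pss_clip: bool = False             # clip PSS to the 0-40 instrument range
    age_range: tuple = (18.0, 60.0)
    baseline_glu_mean: float = 1.0     # Glu/Cr, dimensionless
    baseline_glu_sd: float = 0.1
    baseline_glx_mean: float = 1.6
    baseline_glx_sd: float = 0.15
    baseline_cho_mean: float = 0.25
    baseline_cho_sd: float = 0.03
    age_glu_corr: float = -0.237       # age / baseline Glu/Cr copula target
    glx_glu_coupling: float = 0.8      # %dGlx tracks %dGlu with extra noise
    glx_extra_sd: float = 8.0
    cho_change_sd: float = 8.0         # %dCho carries no PSS signal
    # scan-quality metric distributions (kept comfortably inside QC bounds)
    snr_mean: float = 15.0
    snr_sd: float = 2.5
    fwhm_mean: float = 0.08
    fwhm_sd: float = 0.02
    crlb_mean: float = 8.0
    crlb_sd: float = 2.5
    qc_fail_fraction: float = 0.0      # fraction of scans corrupted to fail QC
    # cortisol response: percent rise at ~20 and ~40 min post-stressor
    cortisol_baseline_mean: float = 5.0    # nmol/L, log-normal location
    cortisol_baseline_sigma: float = 0.4
    cortisol_peak_rise: float = 25.0       # percent, stress arms
    cortisol_late_rise: float = 10.0
    cortisol_nsc_drift: tuple = (-5.0, -8.0)
    cortisol_noise_sd: float = 65.0        # percent-change noise
    # VAMS negativity trajectory over the four administrations (0-100)
    vams_stress_traj: tuple = (35.0, 38.0, 55.0, 45.0)
    vams_nsc_traj: tuple = (35.0, 34.0, 33.0, 30.0)
    vams_mdd_offset: float = 12.0
    vams_subject_sd: float = 8.0
    vams_item_sd: float = 10.0
    ema: EmaParams = field(default_factory=EmaParams)

    def validate(self) -> None:
        for name, gp in self.groups.items():
            gp.validate(name)
            if self.pss_clip and not (0.0 <= gp.pss_mean <= 40.0):
                raise ValueError(
                    f"groups[{name}].pss_mean outside the 0-40 instrument range")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for fld in ("baseline_glu_sd", "baseline_glx_sd", "baseline_cho_sd",
                    "snr_sd", "fwhm_sd", "crlb_sd", "cortisol_noise_sd",
                    "vams_subject_sd", "vams_item_sd"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be >= 0")
        if not -1.0 <= self.age_glu_corr <= 1.0:
            raise ValueError("age_glu_corr must be in [-1, 1]")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must be in [0, 1]")
        self.ema.validate()


@dataclass
class PipelineConfig:
    """Orchestration options for the end-to-end analysis."""

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    calibration_group: str = GROUP_HC_CALIBRATION
    min_snr: float = 9.0
    max_fwhm: float = 0.15
    max_crlb_glu: float = 20.0
    outlier_z: float = 3.0
    min_usable_surveys: int = 20
    bootstrap_B: int = 0               # 0 disables bootstrap CIs in the report
    seed: int = 0

    def validate(self) -> None:
        if self.generator is None and self.input_dir is None:
            raise ValueError("either generator or input_dir must be set")
        if self.generator is not None:
            self.generator.validate()
            if self.calibration_group not in self.generator.groups:
                raise ValueError(
                    f"calibration_group {self.calibration_group!r} not in groups")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
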