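"""Synthetic solid-tumour cohorts with a latent cachexia state.

The generator emulates the statistical structure the screening analysis
assumes, so every pipeline stage is testable without patient data:

1. a tumour type is drawn from a configurable case mix;
2. a latent cachexia state is drawn from the type-specific prevalence
   (the per-type prevalences are rescaled so the mixture hits the overall
   prevalence target, default 17%);
3. a single continuous *severity* factor ``s = shift * cachexia + z`` with
   ``z ~ N(0, 1)`` drives every observed measure: weight-loss percentage,
   BMI, muscle anthropometry (MAMC, CC, grip strength), biomarkers and the
   two instrument scores are class-conditional normals with loadings on
   ``z`` plus independent measurement noise (all noise standard deviations
   scale with ``noise_scale``; at 0 the cohort is a deterministic function
   of the latent draws);
4. prior weight is generated jointly with current weight,
   ``prior = current / (1 - WL/100)``, so the derived six-month weight-loss
   percentage reproduces the drawn value exactly;
5. configured per-field missingness is applied last.

Class-conditional means/SDs default to the published baseline table of the
reference cohort (e.g. BMI 23.57 +/- 3.06 without vs 19.53 +/- 3.39 with
cachexia).  Instrument-score mappings were solved analytically so that, at
the default latent shift of 2.4, the NRS-2002 at-risk rates and the PG-SGA
triage-bin rates match the reference cohort's published joint rates
(at-risk 13.3% of non-cachectic vs 88.8% of cachectic subjects; PG-SGA bins
50.8 / 30.6 / 18.6% overall).

The latent state is returned (and written by the CLI) as a *separate* truth
table; it never appears in the cohort CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluate import CrossTab
from .records import PatientRecord, derive_record

#: Default tumour case mix (fractions; sum to 1).  The five types with
#: published per-type prevalence carry those values; the rest are plausible
#: free parameters for a mixed Chinese solid-tumour inpatient cohort.
DEFAULT_CANCER_MIX: dict[str, float] = {
    "lung": 0.19,
    "gastric": 0.15,
    "colorectal": 0.15,
    "esophageal": 0.08,
    "liver": 0.06,
    "pancreatic": 0.04,
    "nasopharyngeal": 0.05,
    "breast": 0.12,
    "cervical": 0.06,
    "ovarian": 0.04,
    "other": 0.06,
}

DEFAULT_TYPE_PREVALENCE: dict[str, float] = {
    "pancreatic": 0.450,
    "gastric": 0.325,
    "esophageal": 0.285,
    "ovarian": 0.238,
    "colorectal": 0.217,
    "lung": 0.120,
    "liver": 0.140,
    "nasopharyngeal": 0.070,
    "breast": 0.060,
    "cervical": 0.080,
    "other": 0.110,
}

FEMALE_ONLY = {"breast", "cervical", "ovarian", "endometrial"}
MALE_ONLY = {"prostate"}

#: TNM stage distribution conditional on latent class (stages I-IV).
TNM_PROBS = {
    False: (0.162, 0.253, 0.339, 0.246),
    True: (0.086, 0.189, 0.382, 0.343),
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "mac": 0.02, "tsf": 0.02, "mamc": 0.02, "cc": 0.02, "hgs": 0.02,
    "albumin": 0.03, "nlr": 0.03,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator (defaults = the study conditions)."""

    n: int = 1000
    seed: int = 0
    prevalence_target: float = 0.17
    cancer_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CANCER_MIX))
    type_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PREVALENCE))
    #: latent severity shift between cachectic and non-cachectic classes
    severity_shift: float = 2.4
    # class-conditional means (non-cachexia, cachexia)
    bmi_mean: tuple[float, float] = (23.57, 19.53)
    bmi_sd: tuple[float, float] = (3.06, 3.39)
    wl_mean: tuple[float, float] = (0.5, 9.0)
    mamc_mean: tuple[float, float] = (21.03, 19.88)
    cc_mean: tuple[float, float] = (33.72, 30.80)
    mac_mean: tuple[float, float] = (27.08, 24.16)
    tsf_mean: tuple[float, float] = (17.79, 12.59)
    albumin_mean: tuple[float, float] = (39.89, 37.78)
    anorexia_rate: tuple[float, float] = (0.104, 0.248)
    #: loading of the within-class severity residual z on weight loss / BMI
    wl_severity_load: float = 1.2
    bmi_severity_load: float = 0.8
    #: pure measurement-noise SDs (multiplied by noise_scale)
    wl_noise_sd: float = 2.0
    nrs_noise_sd: float = 0.2505
    pgsga_noise_sd: float = 1.574
    noise_scale: float = 1.0
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    asmi_enabled: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError(f"cohort size must be positive, got {self.n}")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ConfigurationError("prevalence target must lie in (0, 1)")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        mix_sum = sum(self.cancer_mix.values())
        if abs(mix_sum - 1.0) > 1e-6:
            raise ConfigurationError(f"cancer mix must sum to 1, sums to {mix_sum}")
        for t, p in self.type_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence for {t} outside [0, 1]: {p}")
        for t in self.cancer_mix:
            if t not in self.type_prevalence:
                raise ConfigurationError(f"no prevalence configured for type {t!r}")
        for rate in self.missingness.values():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("missingness rates must lie in [0, 1]")

    def scaled_prevalence(self) -> dict[str, float]:
        """Per-type prevalences rescaled so the mixture equals the target."""
        types = list(self.cancer_mix)
        mix = np.array([self.cancer_mix[t] for t in types])
        prev = np.array([self.type_prevalence[t] for t in types])
        mean = float(mix @ prev)
        scale = self.prevalence_target / mean
        return {t: float(np.clip(p * scale, 0.0, 1.0))
                for t, p in zip(types, prev)}


# instrument mapping constants solved from the reference cohort's joint rates
_NRS_CUT = 1.1464      # severity value at which NRS-2002 reaches the >= 3 bin
_NRS_SLOPE = 1.7
_PGSGA_CUT1 = 0.39     # severity value entering the 4-8 bin
_PGSGA_CUT2 = 2.20     # severity value entering the >= 9 bin
_PGSGA_SLOPE = 5.0 / (_PGSGA_CUT2 - _PGSGA_CUT1)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a synthetic cohort plus its latent-truth table.

    Deterministic given ``config.seed``.  Returns derived
    :class:`PatientRecord` objects and a DataFrame with columns
    ``id, cancer_type, cachexia, severity`` (the latent state; keep it out
    of the cohort CSV).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    ns = config.noise_scale

    types_list = list(config.cancer_mix)
    mix = np.array([config.cancer_mix[t] for t in types_list])
    prev = config.scaled_prevalence()

    type_idx = rng.choice(len(types_list), size=n, p=mix / mix.sum())
    ctype = np.array(types_list)[type_idx]
    p_cach = np.array([prev[t] for t in ctype])
    latent = rng.random(n) < p_cach

    # sex consistent with tumour site
    male = rng.random(n) < 0.55
    male[np.isin(ctype, list(FEMALE_ONLY))] = False
    male[np.isin(ctype, list(MALE_ONLY))] = True

    z = rng.normal(0.0, 1.0, n)                      # within-class severity
    severity = config.severity_shift * latent + z

    age = np.clip(np.rint(rng.normal(56.75, 12.05, n)), 18, 95).astype(int)
    height = np.where(male,
                      rng.normal(1.70, 0.065, n),
                      rng.normal(1.58, 0.060, n))
    height = np.clip(height, 1.40, 2.00)

    def pick(pair):
        return np.where(latent, pair[1], pair[0])

    bmi_resid = np.sqrt(np.maximum(
        np.asarray(config.bmi_sd) ** 2 - config.bmi_severity_load ** 2, 0.01))
    bmi = (pick(config.bmi_mean)
           - config.bmi_severity_load * z
           + rng.normal(0.0, 1.0, n) * pick(bmi_resid) * ns)
    bmi = np.clip(bmi, 10.0, 50.0)

    wl = (pick(config.wl_mean)
          + config.wl_severity_load * z
          + rng.normal(0.0, config.wl_noise_sd, n) * ns)
    wl = np.clip(wl, -15.0, 60.0)

    weight = bmi * height**2
    weight_prior = weight / (1.0 - wl / 100.0)

    sexshift = np.where(male, 1.0, -1.0)
    dbmi = bmi - pick(config.bmi_mean)
    mamc = pick(config.mamc_mean) + 1.4 * sexshift + 0.45 * dbmi - 0.3 * z \
        + rng.normal(0.0, 2.4, n) * ns
    mamc = np.clip(mamc, 8.0, 35.0)
    cc = pick(config.cc_mean) + 1.6 * sexshift + 0.50 * dbmi - 0.3 * z \
        + rng.normal(0.0, 2.2, n) * ns
    cc = np.clip(cc, 18.0, 50.0)
    mac = pick(config.mac_mean) + 1.2 * sexshift + 0.55 * dbmi \
        + rng.normal(0.0, 2.2, n) * ns
    mac = np.clip(mac, 15.0, 40.0)
    tsf = pick(config.tsf_mean) - 2.0 * sexshift + 0.9 * dbmi \
        + rng.normal(0.0, 5.0, n) * ns
    tsf = np.clip(tsf, 1.0, 45.0)
    hgs = np.where(male, 30.0, 20.0) - 2.0 * z - 1.5 * latent \
        + 0.3 * (bmi - 23.0) + rng.normal(0.0, 4.0, n) * ns
    hgs = np.clip(hgs, 2.0, 70.0)

    asmi = None
    if config.asmi_enabled:
        asmi = np.where(male, 7.9, 6.2) - 0.40 * severity \
            + 0.25 * (bmi - 23.0) + rng.normal(0.0, 0.6, n) * ns
        asmi = np.clip(asmi, 3.0, 12.0)

    nrs_latent = severity + rng.normal(0.0, config.nrs_noise_sd, n) * ns
    nrs_total = np.clip(
        np.floor(3.0 + _NRS_SLOPE * (nrs_latent - _NRS_CUT)), 0, 7).astype(int)

    pg_latent = severity + rng.normal(0.0, config.pgsga_noise_sd, n) * ns
    pgsga_total = np.clip(
        np.floor(4.0 + _PGSGA_SLOPE * (pg_latent - _PGSGA_CUT1)), 0, 25).astype(int)

    anorexia = rng.random(n) < pick(config.anorexia_rate)

    tnm = np.empty(n, dtype=object)
    stages = np.array(["I", "II", "III", "IV"])
    for state in (False, True):
        mask = latent == state
        tnm[mask] = rng.choice(stages, size=int(mask.sum()), p=TNM_PROBS[state])

    albumin = pick(config.albumin_mean) - 1.0 * z + rng.normal(0.0, 8.0, n) * ns
    albumin = np.clip(albumin, 15.0, 55.0)
    nlr = np.exp(rng.normal(0.95 + 0.25 * latent + 0.08 * z, 0.65, n))
    nlr = np.clip(nlr, 0.1, 80.0)
    kps = np.clip(np.rint((90.0 - 4.0 * severity
                           + rng.normal(0.0, 7.0, n) * ns) / 10.0) * 10,
                  10, 100).astype(int)

    # per-field missingness masks (drawn even at rate 0 for stream stability)
    miss = {f: rng.random(n) < rate for f, rate in config.missingness.items()}

    def opt(field_name: str, arr, i: int):
        if field_name in miss and miss[field_name][i]:
            return None
        return float(arr[i])

    records: list[PatientRecord] = []
    for i in range(n):
        rec = PatientRecord(
            id=f"S{i:06d}",
            sex="male" if male[i] else "female",
            age=int(age[i]),
            height=float(height[i]),
            weight_current=float(weight[i]),
            weight_6mo_prior=opt("weight_6mo_prior", weight_prior, i),
            mac=opt("mac", mac, i),
            tsf=opt("tsf", tsf, i),
            mamc=opt("mamc", mamc, i),
            cc=opt("cc", cc, i),
            hgs=opt("hgs", hgs, i),
            asmi=opt("asmi", asmi, i) if asmi is not None else None,
            anorexia=bool(anorexia[i]),
            cancer_type=str(ctype[i]),
            tnm_stage=str(tnm[i]),
            nrs2002_total=int(nrs_total[i]),
            pgsga_total=int(pgsga_total[i]),
            albumin=opt("albumin", albumin, i),
            nlr=opt("nlr", nlr, i),
            kps=int(kps[i]),
        )
        records.append(derive_record(rec))

    truth = pd.DataFrame({
        "id": [r.id for r in records],
        "cancer_type": ctype,
        "cachexia": latent,
        "severity": severity,
    })
    return records, truth


def crosstab_to_cohort(crosstab: CrossTab) -> list[tuple[str, bool]]:
    """Expand a printed summary table into per-subject (level, reference) pairs.

    The output length equals the table total and the multiset of pairs
    matches the counts exactly, so published aggregate tables can be pushed
    through the per-subject evaluation engine.
    """
    return crosstab.to_pairs()
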