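"""Synthetic cohort and LC-MS run generation with known ground truth.

The generator emulates a family-structured middle-aged cohort with metabolic
covariates, per-sample subclass glycosylation traits driven by a linear model
with exchangeable within-family correlation, and centroided MS1 runs that
contain the panel's isotope envelopes at 2+/3+ with baseline noise, m/z
miscalibration, retention-time shifts and plate-level batch effects.

Everything downstream (extraction, curation, association) can be checked
against the ground truth stored alongside the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mzml_io import RunSpectra, Scan
from .panel import Panel, build_panel
from .association import friedewald_ldlc

# ---------------------------------------------------------------------------
# default cohort distributions (middle-aged family cohort)

AGE_MEAN, AGE_SD, AGE_RANGE = 59.1, 6.7, (30.2, 79.2)
MALE_FRACTION = 0.471

#: metabolic parameters: name -> (mean, SD, distribution)
COVARIATE_DISTRIBUTIONS = {
    "crp": (2.86, 9.5, "lognormal"),
    "il6": (0.67, 1.2, "lognormal"),
    "glucose": (5.94, 1.5, "lognormal"),
    "insulin": (23.23, 22.1, "lognormal"),
    "tc": (5.55, 1.2, "normal"),
    "hdlc": (1.42, 0.4, "normal"),
    "tg": (1.82, 1.2, "lognormal"),
    "free_t3": (4.12, 0.8, "lognormal"),
}
BINARY_COVARIATES = {"smoking": 0.136, "cmv": 0.459}
OFFSPRING_FRACTION = 0.641  # family-level long-lived membership

#: variables analysed on the natural-log scale
LOG_VARS = ["crp", "il6", "glucose", "insulin", "tg", "free_t3"]

#: per-subclass trait baselines: trait -> (mean %, SD %); IgG4 fucosylation
#: is not quantifiable and therefore absent
TRAIT_BASELINES = {
    "IgG1": {"fucosylation": (91.2, 4.1), "bisection": (19.1, 3.3),
             "galactosylation": (50.1, 6.4), "sialylation": (6.8, 1.4)},
    "IgG2": {"fucosylation": (97.4, 0.9), "bisection": (13.9, 2.7),
             "galactosylation": (39.5, 6.2), "sialylation": (6.2, 1.4)},
    "IgG4": {"bisection": (19.6, 4.4), "galactosylation": (43.7, 6.9),
             "sialylation": (9.1, 2.0)},
}

#: default age/sex trends (% per year; % male-female difference): ageing
#: lowers galactosylation/sialylation and raises bisection
DEFAULT_AGE_EFFECTS = {"galactosylation": -0.35, "sialylation": -0.05,
                       "bisection": 0.06, "fucosylation": 0.01}
DEFAULT_SEX_EFFECTS = {"galactosylation": -1.5, "sialylation": -0.3,
                       "bisection": 0.3, "fucosylation": 0.2}


@dataclass
class CohortConfig:
    n_individuals: int = 1826
    n_families: int = 600
    plate_size: int = 96
    rho_fam: float = 0.2          # exchangeable within-family trait correlation
    trait_residual_frac: float = 0.85  # residual SD as fraction of marginal SD
    effect_map: dict = field(default_factory=dict)  # (trait, covariate) -> beta1
    age_effects: dict = field(default_factory=lambda: dict(DEFAULT_AGE_EFFECTS))
    sex_effects: dict = field(default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))
    age_sex_effects: dict = field(default_factory=dict)
    batch_sd: float = 0.08        # per-plate log-scale multiplicative analyte shift
    calib_offset_sd: float = 0.01  # per-run m/z miscalibration (Th)
    rt_shift_sd: float = 3.0      # per-run retention-time shift (s)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho_fam < 1:
            raise ValueError("rho_fam must lie in [0, 1)")
        if self.n_families > self.n_individuals and self.n_individuals > 0:
            raise ValueError("more families than individuals")


@dataclass
class RunConfig:
    scan_rate_hz: float = 0.5
    mz_range: tuple = (600.0, 2000.0)
    rt_start: float = 200.0
    rt_end: float = 460.0
    peak_sigma_s: float = 4.0      # chromatographic peak width
    charge_split: dict = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    subclass_scale: dict = field(default_factory=lambda: {
        "IgG1": 1e6, "IgG2": 4e5, "IgG4": 1e5})
    baseline_peaks_per_scan: float = 4000.0  # Poisson rate of uniform m/z peaks
    baseline_intensity_scale: float = 30.0  # exponential intensity scale
    measurement_rsd: float = 0.003  # per-analyte per-run multiplicative noise

    def noiseless(self) -> "RunConfig":
        return replace(self, baseline_peaks_per_scan=0.0, measurement_rsd=0.0)


@dataclass
class GroundTruth:
    """Per-sample generative state: profiles, traits, plate and distortions."""

    sample_ids: list
    plate: pd.Series                 # sample -> plate id
    traits: pd.DataFrame             # sample x (subclass, trait) true values
    profiles: dict                   # sample -> subclass -> {glycoform: fraction}
    batch_factors: dict              # plate -> {(subclass, glycoform): factor}
    calib_offset: pd.Series          # sample -> Th
    rt_shift: pd.Series              # sample -> s
    seed: int = 0


# ---------------------------------------------------------------------------
# trait -> glycoform profile inversion


def traits_to_profile(targets: dict, subclass: str) -> dict:
    """Closed-form glycoform fractions realizing target trait values.

    ``targets`` maps trait name to percent (fucosylation omitted or None for
    IgG4).  Mass is distributed over the spanning set {G0, G0F, G0FN, G2F,
    G1FS1, G2FS1}; sialylated mass goes on G2FS1 (and G1FS1 once SA-per-gal
    exceeds 50%).  The derived traits of the returned profile equal the
    targets exactly.

    Raises
    ------
    ValueError
        For infeasible targets: sialylation > galactosylation, sialylation
        without galactose, or bisection + max(gal, 2*sial) > fucosylation.
    """
    f_pct = targets.get("fucosylation")
    if subclass == "IgG4" or f_pct is None:
        f = 1.0
    else:
        f = f_pct / 100.0
    b = targets.get("bisection", 0.0) / 100.0
    gal = targets.get("galactosylation", 0.0) / 100.0
    sia = targets.get("sialylation", 0.0) / 100.0
    if not (0 <= f <= 1 and 0 <= b <= 1 and 0 <= gal <= 1 and 0 <= sia <= 1):
        raise ValueError("trait targets must lie in [0, 100]%")
    if sia > gal:
        raise ValueError("sialylation exceeding galactosylation is infeasible "
                         "(each sialic acid requires a galactose)")
    if 2 * sia <= gal:
        x1, x2, y2 = 0.0, 2 * sia, gal - 2 * sia
    else:
        x1, x2, y2 = 2 * (2 * sia - gal), 2 * (gal - sia), 0.0
    filler = f - b - (x1 + x2 + y2)
    if filler < -1e-12:
        raise ValueError(
            "infeasible targets: bisection + galactose/sialic carriers exceed "
            "the fucosylated fraction")
    profile = {
        "G0": 1.0 - f,
        "G0FN": b,
        "G1FS1": x1,
        "G2FS1": x2,
        "G2F": y2,
        "G0F": max(filler, 0.0),
    }
    return {k: v for k, v in profile.items() if v > 0}


def _clip_feasible(subclass: str, vals: dict) -> dict:
    """Clip sampled trait values into the feasible region of traits_to_profile."""
    out = dict(vals)
    if subclass == "IgG4":
        f = 100.0
    else:
        f = out["fucosylation"] = float(np.clip(out["fucosylation"], 60.0, 99.5))
    b = out["bisection"] = float(np.clip(out["bisection"], 1.0, 35.0))
    gal_cap = max(f - b - 0.5, 1.0)
    g = out["galactosylation"] = float(np.clip(out["galactosylation"], 1.0, gal_cap))
    sia_cap = max(min(0.45 * g, gal_cap / 2.0 - 0.25), 0.05)
    out["sialylation"] = float(np.clip(out["sialylation"], 0.05, sia_cap))
    return out


# ---------------------------------------------------------------------------
# cohort simulation


def _lognormal_params(mean: float, sd: float) -> tuple:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_cohort(config: CohortConfig, panel: Panel | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a family-structured cohort with traits and ground truth.

    Returns the cohort table (one row per individual: family, plate, age,
    sex, metabolic parameters) and a :class:`GroundTruth` with true trait
    values and glycoform fractions per subclass.
    """
    n = config.n_individuals
    panel = panel or build_panel()
    sample_ids = [f"S{i:05d}" for i in range(n)]
    if n == 0:
        empty = pd.DataFrame()
        truth = GroundTruth(sample_ids=[], plate=pd.Series(dtype=int),
                            traits=pd.DataFrame(), profiles={},
                            batch_factors={}, calib_offset=pd.Series(dtype=float),
                            rt_shift=pd.Series(dtype=float), seed=config.seed)
        return empty, truth

    rng = np.random.default_rng([config.seed, 7])

    # families: individuals dealt round-robin so sizes differ by at most one
    family = np.sort(np.arange(n) % config.n_families)
    plate = np.arange(n) // config.plate_size

    age = rng.normal(AGE_MEAN, AGE_SD, size=n)
    lo, hi = AGE_RANGE
    while True:  # truncate by redrawing
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(AGE_MEAN, AGE_SD, size=bad.sum())
    sex = (rng.random(n) < MALE_FRACTION).astype(int)  # 1 = male

    cohort = pd.DataFrame({"sample_id": sample_ids, "family_id": family,
                           "plate": plate, "age": age, "sex": sex})
    for name, (mean, sd, dist) in COVARIATE_DISTRIBUTIONS.items():
        if dist == "lognormal":
            mu, sigma = _lognormal_params(mean, sd)
            cohort[name] = rng.lognormal(mu, sigma, size=n)
        else:
            vals = rng.normal(mean, sd, size=n)
            cohort[name] = np.clip(vals, 0.05, None)
    for name, p in BINARY_COVARIATES.items():
        cohort[name] = (rng.random(n) < p).astype(int)
    fam_longevity = (rng.random(config.n_families) < OFFSPRING_FRACTION).astype(int)
    cohort["longevity"] = fam_longevity[family]
    cohort["ldlc"] = [friedewald_ldlc(tc, hdl, tg)
                      for tc, hdl, tg in zip(cohort.tc, cohort.hdlc, cohort.tg)]
    cohort = cohort.set_index("sample_id", drop=False)

    # traits: linear model + exchangeable family effect + noise
    trait_cols = {}
    for subclass, baselines in TRAIT_BASELINES.items():
        for trait, (mean, sd) in baselines.items():
            sigma = sd * config.trait_residual_frac
            fam_eff = rng.normal(0.0, math.sqrt(config.rho_fam) * sigma,
                                 size=config.n_families)[family]
            noise = rng.normal(0.0, math.sqrt(1 - config.rho_fam) * sigma, size=n)
            val = (mean
                   + config.age_effects.get(trait, 0.0) * (age - AGE_MEAN)
                   + config.sex_effects.get(trait, 0.0) * (sex - MALE_FRACTION)
                   + config.age_sex_effects.get(trait, 0.0)
                   * (age - AGE_MEAN) * (sex - MALE_FRACTION)
                   + fam_eff + noise)
            for (t_name, covariate), beta in config.effect_map.items():
                if t_name != trait:
                    continue
                x = cohort[covariate].to_numpy(dtype=float)
                if covariate in LOG_VARS:
                    x = np.log(x)
                val = val + beta * (x - x.mean())
            trait_cols[(subclass, trait)] = val
    traits = pd.DataFrame(trait_cols, index=cohort.index)
    traits.columns = pd.MultiIndex.from_tuples(traits.columns,
                                               names=["subclass", "trait"])

    # clip into the feasible region and build per-sample glycoform fractions
    profiles = {}
    for i, sid in enumerate(sample_ids):
        profiles[sid] = {}
        for subclass in TRAIT_BASELINES:
            vals = {t: traits.loc[sid, (subclass, t)]
                    for t in TRAIT_BASELINES[subclass]}
            vals = _clip_feasible(subclass, vals)
            for t, v in vals.items():
                traits.loc[sid, (subclass, t)] = v
            profiles[sid][subclass] = traits_to_profile(vals, subclass)

    # plate-level multiplicative batch factors per analyte
    plates = sorted(set(plate.tolist()))
    batch_factors = {}
    for p in plates:
        prng = np.random.default_rng([config.seed, 11, int(p)])
        batch_factors[p] = {
            (a.subclass, a.shorthand): float(np.exp(prng.normal(0, config.batch_sd)))
            for a in panel.analytes}

    calib = pd.Series(rng.normal(0, config.calib_offset_sd, size=n),
                      index=cohort.index)
    rt_shift = pd.Series(rng.normal(0, config.rt_shift_sd, size=n),
                         index=cohort.index)
    truth = GroundTruth(sample_ids=sample_ids,
                        plate=pd.Series(plate, index=cohort.index),
                        traits=traits, profiles=profiles,
                        batch_factors=batch_factors, calib_offset=calib,
                        rt_shift=rt_shift, seed=config.seed)
    return cohort, truth


# ---------------------------------------------------------------------------
# LC-MS run simulation


def simulate_run(truth: GroundTruth, sample_id: str, panel: Panel,
                 run_config: RunConfig | None = None,
                 replicate: int = 0) -> RunSpectra:
    """Simulate one centroided MS1 run for a sample.

    Each panel analyte contributes a Gaussian chromatographic peak at its
    subclass apex (+ the sample's RT shift); every scan holds centroids at
    the first three isotopologue m/z values in 2+ and 3+ (+ the sample's
    calibration offset), scaled by glycoform fraction, isotope envelope,
    charge split, plate batch factor and per-run measurement noise, plus
    uniform baseline peaks with exponential intensities.  Deterministic for
    a given ground truth and sample.
    """
    cfg = run_config or RunConfig()
    idx = truth.sample_ids.index(sample_id)
    rng = np.random.default_rng([truth.seed, 1009, idx, replicate])
    offset = float(truth.calib_offset.get(sample_id, 0.0))
    shift = float(truth.rt_shift.get(sample_id, 0.0))
    plate = int(truth.plate.get(sample_id, 0))
    factors = truth.batch_factors.get(plate, {})

    period = 1.0 / cfg.scan_rate_hz
    rts = np.arange(cfg.rt_start, cfg.rt_end + 1e-9, period)
    mz_lo, mz_hi = cfg.mz_range

    # per-analyte flat target list: (mz, base intensity, apex rt)
    targets_mz, targets_amp, targets_rt = [], [], []
    for analyte in panel.analytes:
        frac = truth.profiles[sample_id][analyte.subclass].get(analyte.shorthand, 0.0)
        if frac <= 0:
            continue
        meas = float(np.exp(rng.normal(0, cfg.measurement_rsd))) \
            if cfg.measurement_rsd > 0 else 1.0
        base = (cfg.subclass_scale[analyte.subclass] * frac
                * factors.get((analyte.subclass, analyte.shorthand), 1.0) * meas)
        apex = analyte.expected_rt + shift
        # deposit the analyte's total current into the monitored
        # isotopologues: envelope renormalized over the first k peaks, so
        # extraction recovers intensities proportional to the fractions
        env = np.asarray(analyte.envelope)
        env = env / env.sum()
        for z, split in cfg.charge_split.items():
            for i, mz in enumerate(analyte.target_mz(z)):
                if not (mz_lo <= mz <= mz_hi):
                    continue
                targets_mz.append(mz + offset)
                targets_amp.append(base * split * env[i])
                targets_rt.append(apex)
    targets_mz = np.array(targets_mz)
    targets_amp = np.array(targets_amp)
    targets_rt = np.array(targets_rt)

    scans = []
    for rt in rts:
        w = np.exp(-0.5 * ((rt - targets_rt) / cfg.peak_sigma_s) ** 2) \
            if targets_rt.size else np.empty(0)
        keep = w > 1e-6
        mz = targets_mz[keep]
        inten = targets_amp[keep] * w[keep]
        if cfg.baseline_peaks_per_scan > 0:
            n_b = rng.poisson(cfg.baseline_peaks_per_scan)
            if n_b:
                mz = np.concatenate([mz, rng.uniform(mz_lo, mz_hi, n_b)])
                inten = np.concatenate(
                    [inten, rng.exponential(cfg.baseline_intensity_scale, n_b)])
        order = np.argsort(mz)
        scans.append(Scan(float(rt), mz[order], inten[order]))
    return RunSpectra(scans, sample_id=sample_id)


def simulate_runs(truth: GroundTruth, panel: Panel,
                  run_config: RunConfig | None = None):
    """Yield (sample_id, RunSpectra) for every sample in the ground truth."""
    for sid in truth.sample_ids:
        yield sid, simulate_run(truth, sid, panel, run_config)
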