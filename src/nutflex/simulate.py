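"""Synthetic phenology, feeding-follow and urine tables with known truth.

The generator emulates a multi-year field study of wild orangutan feeding
ecology: monthly phenology plots give a fruit availability index (FAI, the
percentage of monitored trees in fruit), full-day follows give daily
macronutrient intakes in kcal, and next-morning urine samples carry
biomarkers of metabolic state (C-peptide, urea, delta-15N, ketone bodies)
diluted by hydration and measured with assay noise.

The generating model is chosen so every downstream estimator is
well-specified against it:

* total energy:   log E = log(P_ref + NPe_link(FAI)) + u_j + e,
  with NPe_link a saturating logistic in FAI;
* protein share:  log %P = log %P_ref + L (log E - log E_ref) + a_j + eps,
  so the protein-prioritization exponent L is exact by construction
  (L = -1: constant absolute protein; L = 0: constant proportion);
* biomarkers:     location parameters are known smooth functions of the
  prior day's intake, with per-individual random intercepts, and families
  log-normal (C-peptide), gamma (urea), Gaussian (delta-15N) and
  Bernoulli (ketone presence);
* urine concentrations are multiplied by (SG - 1)/(SG_ref - 1), so the
  standard specific-gravity correction inverts the dilution exactly.

All numeric defaults encode the study conditions (FAI range 0.5-14% with
low/high-period means near 2.44%/6.68%, ~10.1% of energy from protein,
NPe:P near 9.7, ketone positivity calibrated to 9.2%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .biomarkers import SG_REFERENCE

__all__ = [
    "SCENARIOS",
    "SimConfig",
    "SimTruth",
    "make_truth",
    "simulate_phenology",
    "simulate_follows",
    "simulate_urine",
    "simulate_constant_protein_trial",
    "truth_to_dict",
]

SCENARIOS = (
    "complete_prioritization",
    "partial_prioritization",
    "no_prioritization",
    "flat_null",
)

_SCENARIO_L = {
    "complete_prioritization": -1.0,
    "partial_prioritization": -0.73,
    "no_prioritization": 0.0,
    "flat_null": 0.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study dimensions for one simulated data set.

    Defaults give ~1600 follow-days over 40 individuals and 84 months —
    the scale at which the recovery properties are checked.
    """

    n_individuals: int = 40
    n_months: int = 84
    trees_per_plot: int = 1600
    follows_per_individual: int = 40
    urine_match_fraction: float = 0.75
    scenario: str = "partial_prioritization"
    start_month: str = "2010-01"
    full_day_fraction: float = 0.95
    unmatched_urine_fraction: float = 0.05
    ar1_day: float = 0.0  # optional within-individual day-to-day intake correlation
    #: per-analyte missingness mirroring the relative assay sample sizes
    miss_cpeptide: float = 0.55
    miss_urea: float = 0.35
    miss_d15n: float = 0.85
    miss_ketone: float = 0.20

    def __post_init__(self):
        for name in ("n_individuals", "n_months", "trees_per_plot", "follows_per_individual"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.urine_match_fraction <= 1.0:
            raise ValueError("urine_match_fraction must be in [0, 1]")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid scenarios: {SCENARIOS}"
            )


@dataclass
class SimTruth:
    """Generating parameters (the ground truth recovery tests target)."""

    scenario: str
    seed: int
    # protein prioritization
    L_true: float = -0.73
    a_protein: float = 255.0       # protein kcal at the reference energy
    pct_protein_ref: float = 9.45  # median %energy from protein at E_ref
    e_ref: float = 2525.0
    # saturating NPe(FAI) link
    npe_lo: float = 1770.0
    npe_hi: float = 2450.0
    fai_mid: float = 4.2
    fai_scale: float = 1.3
    flat_fai_link: bool = False
    # intake noise (log scale)
    sigma_log_e: float = 0.30
    sd_individual_e: float = 0.13
    sigma_log_pct: float = 0.19
    sd_individual: float = 0.09    # random intercept SD on log %P
    # NPe composition shares (TNC, NDF, lipid) and their log-jitter SD
    npe_shares: tuple[float, float, float] = (0.70, 0.18, 0.12)
    share_jitter_sd: float = 0.18
    # FAI monthly process
    fai_base: float = 4.45
    fai_amp: float = 2.9
    fai_ar1_rho: float = 0.6
    fai_ar1_sd: float = 0.7
    fai_spike_prob: float = 0.05
    fai_spike_range: tuple[float, float] = (4.0, 9.0)
    fai_clip: tuple[float, float] = (0.6, 13.8)
    # biomarker links: location = b0 + b1 * g(intake); flat scenario sets b1 = 0
    cp_b0: float = np.log(1800.0)
    cp_b1: float = 0.45
    cp_mid_e: float = 2500.0
    cp_scale_e: float = 900.0
    urea_b0: float = np.log(3.0)
    urea_b1: float = 0.5
    urea_mid_tnc: float = 1600.0
    urea_scale_tnc: float = 400.0
    d15n_b0: float = 9.0
    d15n_b1: float = 1.2
    d15n_mid_tnc: float = 900.0
    d15n_scale_tnc: float = 300.0
    ketone_k1: float = 1.1
    ketone_k2: float = 0.5   # habitat-level (FAI) component of ketosis risk
    ketone_target_rate: float = 0.092
    sd_individual_bio: float = 0.15
    sd_individual_ketone: float = 0.30
    # biomarker family dispersion/shape
    family_params: dict = field(
        default_factory=lambda: {
            "sigma_log_cpeptide": 0.45,
            "shape_urea": 4.0,
            "sigma_d15n": 0.5,
        }
    )
    # urine sampling
    sg_mean: float = SG_REFERENCE
    sg_sd: float = 0.009
    cv_shape: float = 4.0
    cv_scale: float = 1.75
    # filled in by make_truth (calibrated against an internal reference sample)
    ketone_k0: float = np.nan
    tnc_ref: float = np.nan
    tnc_sd: float = np.nan
    fai_ref: float = np.nan
    fai_sd: float = np.nan
    rho_matrix: np.ndarray | None = None

    # -- link functions -------------------------------------------------
    def fai_link(self, fai):
        """Expected NPe kcal as a saturating (non-decreasing) function of FAI."""
        fai = np.asarray(fai, float)
        if self.flat_fai_link:
            out = np.full_like(fai, 0.5 * (self.npe_lo + self.npe_hi))
            return float(out) if out.ndim == 0 else out
        out = self.npe_lo + (self.npe_hi - self.npe_lo) * expit(
            (fai - self.fai_mid) / self.fai_scale
        )
        return float(out) if out.ndim == 0 else out

    def expected_energy(self, fai):
        """Noise-free expected total kcal at a given FAI."""
        return self.a_protein + self.fai_link(fai)

    def pct_protein_mean_log(self, log_e):
        """E[log %P | log E] — the exact power-law location."""
        return np.log(self.pct_protein_ref) + self.L_true * (log_e - np.log(self.e_ref))

    def implied_exponent(self, n_grid: int = 50) -> float:
        """Slope of log %P vs log E on a noiseless energy grid.

        By construction equals ``L_true``; exposed so tests can verify the
        claim instead of trusting it.
        """
        log_e = np.linspace(np.log(800.0), np.log(6000.0), n_grid)
        y = self.pct_protein_mean_log(log_e)
        return float(np.polyfit(log_e, y, 1)[0])

    def _z_tnc(self, tnc):
        return (np.asarray(tnc, float) - self.tnc_ref) / self.tnc_sd

    def cpeptide_link(self, kcal_total):
        """Log-scale location of C-peptide (pg/ml) given prior-day energy."""
        e = np.asarray(kcal_total, float)
        return self.cp_b0 + self.cp_b1 * expit((e - self.cp_mid_e) / self.cp_scale_e)

    def urea_link(self, kcal_tnc):
        """Log mean urea (mg/ml): elevated when carbohydrate intake is low."""
        t = np.asarray(kcal_tnc, float)
        return self.urea_b0 + self.urea_b1 * (
            1.0 - expit((t - self.urea_mid_tnc) / self.urea_scale_tnc)
        )

    def d15n_link(self, kcal_tnc):
        """Mean urinary delta-15N (permil): enriched under carbohydrate shortfall."""
        t = np.asarray(kcal_tnc, float)
        return self.d15n_b0 + self.d15n_b1 * (
            1.0 - expit((t - self.d15n_mid_tnc) / self.d15n_scale_tnc)
        )

    def ketone_logit(self, kcal_tnc, fai=None):
        """Logit P(ketone positive) from prior-day carbohydrate intake.

        Detectable ketosis tracks sustained scarcity as well as the single
        day's intake, so the month's fruit availability enters alongside
        TNC when supplied.
        """
        out = self.ketone_k0 - self.ketone_k1 * self._z_tnc(kcal_tnc)
        if fai is not None:
            out = out - self.ketone_k2 * (np.asarray(fai, float) - self.fai_ref) / self.fai_sd
        return out

    @property
    def biomarker_links(self) -> dict:
        return {
            "cpeptide_pg_ml": self.cpeptide_link,
            "urea_mg_ml": self.urea_link,
            "d15n_permil": self.d15n_link,
            "ketone": self.ketone_logit,
        }


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def make_truth(scenario: str, seed: int) -> SimTruth:
    """Build a fully-populated :class:`SimTruth` for a named scenario.

    Scenarios: ``complete_prioritization`` (constant absolute protein,
    L = -1), ``partial_prioritization`` (L = -0.73, the study-like
    default), ``no_prioritization`` (constant %protein, L = 0) and
    ``flat_null`` (no prioritization, flat FAI link, flat biomarker
    links).  The ketone intercept and the implied correlation matrix among
    log macronutrient intakes are calibrated against an internal
    noise-bearing reference sample drawn deterministically from ``seed``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid scenarios: {SCENARIOS}")
    truth = SimTruth(scenario=scenario, seed=int(seed), L_true=_SCENARIO_L[scenario])
    if scenario == "flat_null":
        truth.flat_fai_link = True
        truth.cp_b1 = 0.0
        truth.urea_b1 = 0.0
        truth.d15n_b1 = 0.0
        truth.ketone_k1 = 0.0
        truth.ketone_k2 = 0.0
    _calibrate_truth(truth)
    return truth


def _reference_intakes(truth: SimTruth, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Large internal draw of daily intakes used only for calibration."""
    months_fai = _fai_process(truth, 120, rng)
    fai = rng.choice(months_fai, size=n)
    fai_col = fai
    log_e = (
        np.log(truth.expected_energy(fai))
        + rng.normal(0.0, truth.sd_individual_e, n)
        + rng.normal(0.0, truth.sigma_log_e, n)
    )
    e = np.exp(log_e)
    log_pct = (
        truth.pct_protein_mean_log(log_e)
        + rng.normal(0.0, truth.sd_individual, n)
        + rng.normal(0.0, truth.sigma_log_pct, n)
    )
    pct = np.clip(np.exp(log_pct), 0.3, 80.0)
    protein = pct / 100.0 * e
    npe = e - protein
    shares = _npe_shares(truth, n, rng)
    return pd.DataFrame(
        {
            "kcal_protein": protein,
            "kcal_tnc": npe * shares[:, 0],
            "kcal_ndf": npe * shares[:, 1],
            "kcal_lipid": npe * shares[:, 2],
            "kcal_total": e,
            "fai": fai_col,
        }
    )


def _calibrate_truth(truth: SimTruth, n: int = 20000) -> None:
    rng = _rng(truth.seed, 0)
    ref = _reference_intakes(truth, n, rng)
    tnc = ref["kcal_tnc"].to_numpy()
    truth.tnc_ref = float(tnc.mean())
    truth.tnc_sd = float(tnc.std())
    fai_ref = ref["fai"].to_numpy()
    truth.fai_ref = float(fai_ref.mean())
    truth.fai_sd = float(fai_ref.std())
    z = (tnc - truth.tnc_ref) / truth.tnc_sd
    zf = (fai_ref - truth.fai_ref) / truth.fai_sd
    target = truth.ketone_target_rate
    if truth.ketone_k1 == 0.0 and truth.ketone_k2 == 0.0:
        truth.ketone_k0 = float(logit(target))
    else:
        truth.ketone_k0 = float(
            brentq(
                lambda k0: expit(k0 - truth.ketone_k1 * z - truth.ketone_k2 * zf).mean()
                - target,
                -12.0,
                6.0,
            )
        )
    logs = np.log(ref[["kcal_protein", "kcal_tnc", "kcal_lipid", "kcal_ndf"]].to_numpy())
    truth.rho_matrix = np.corrcoef(logs, rowvar=False)


def _npe_shares(truth: SimTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    g = np.log(np.asarray(truth.npe_shares)) + rng.normal(
        0.0, truth.share_jitter_sd, size=(n, 3)
    )
    w = np.exp(g)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# phenology


def _fai_process(truth: SimTruth, n_months: int, rng: np.random.Generator) -> np.ndarray:
    """Monthly FAI target: annual sinusoid + AR(1) noise + fruiting spikes."""
    t = np.arange(n_months)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    base = truth.fai_base + truth.fai_amp * np.sin(2.0 * np.pi * t / 12.0 + phase)
    ar = np.zeros(n_months)
    innov = rng.normal(0.0, truth.fai_ar1_sd, n_months)
    for i in range(1, n_months):
        ar[i] = truth.fai_ar1_rho * ar[i - 1] + innov[i]
    spikes = np.where(
        rng.random(n_months) < truth.fai_spike_prob,
        rng.uniform(*truth.fai_spike_range, n_months),
        0.0,
    )
    return np.clip(base + ar + spikes, *truth.fai_clip)


def _month_index(config: SimConfig) -> pd.PeriodIndex:
    return pd.period_range(config.start_month, periods=config.n_months, freq="M")


def simulate_phenology(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """One row per tagged tree per month with a fruiting flag.

    The number of fruiting trees each month is the rounded target FAI, so
    the realised monthly FAI reproduces the target process exactly (to
    half a tree) and stays inside the observed 0.5-14% range; which trees
    fruit is random.
    """
    rng = _rng(truth.seed, 1)
    months = _month_index(config)
    target = _fai_process(truth, config.n_months, rng)
    n_trees = config.trees_per_plot
    rows = []
    tree_ids = np.array([f"T{i:05d}" for i in range(n_trees)])
    for m, pct in zip(months, target):
        k = int(round(pct / 100.0 * n_trees))
        fruiting = np.zeros(n_trees, bool)
        fruiting[rng.choice(n_trees, size=k, replace=False)] = True
        rows.append(
            pd.DataFrame({"tree_id": tree_ids, "month": str(m), "fruiting": fruiting})
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# follows


def _individuals(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"ID{i:03d}" for i in range(config.n_individuals)]
    sex = rng.choice(["F", "M"], size=config.n_individuals, p=[0.6, 0.4])
    cls = np.where(
        sex == "F",
        "adult_female",
        rng.choice(["flanged_male", "unflanged_male"], size=config.n_individuals),
    )
    return pd.DataFrame({"individual_id": ids, "sex": sex, "age_sex_class": cls})


def simulate_follows(
    config: SimConfig, truth: SimTruth, phenology: pd.DataFrame
) -> pd.DataFrame:
    """Full-day follow table: per individual-day macronutrient kcal.

    Expected NPe follows ``truth.fai_link`` at the month's realised FAI;
    %protein follows the scenario's power law in total energy with
    per-individual random intercepts.  Raises if the phenology table does
    not cover the configured month span.
    """
    from .intake import compute_fai  # local import to avoid a cycle at import time

    rng = _rng(truth.seed, 2)
    fai_series = compute_fai(phenology)
    fai_by_month = dict(zip(fai_series["month"], fai_series["fai"]))
    months = _month_index(config)
    missing = [str(m) for m in months if str(m) not in fai_by_month]
    if missing:
        raise ValueError(f"phenology does not cover months: {missing[:5]}")

    inds = _individuals(config, rng)
    all_days = pd.date_range(
        months[0].to_timestamp(), months[-1].to_timestamp(how="end"), freq="D"
    )
    frames = []
    for _, ind in inds.iterrows():
        days = np.sort(
            rng.choice(len(all_days), size=config.follows_per_individual, replace=False)
        )
        dates = all_days[days]
        fai = np.array([fai_by_month[d.strftime("%Y-%m")] for d in dates])
        n = len(dates)
        u_j = rng.normal(0.0, truth.sd_individual_e)
        a_j = rng.normal(0.0, truth.sd_individual)
        e_noise = rng.normal(0.0, truth.sigma_log_e, n)
        if config.ar1_day > 0.0:
            rho = config.ar1_day
            for i in range(1, n):
                e_noise[i] = rho * e_noise[i - 1] + np.sqrt(1 - rho**2) * e_noise[i]
        log_e = np.log(truth.expected_energy(fai)) + u_j + e_noise
        e = np.exp(log_e)
        log_pct = (
            truth.pct_protein_mean_log(log_e)
            + a_j
            + rng.normal(0.0, truth.sigma_log_pct, n)
        )
        pct = np.clip(np.exp(log_pct), 0.3, 80.0)
        protein = pct / 100.0 * e
        npe = e - protein
        shares = _npe_shares(truth, n, rng)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind["individual_id"],
                    "date": dates.strftime("%Y-%m-%d"),
                    "sex": ind["sex"],
                    "age_sex_class": ind["age_sex_class"],
                    "kcal_protein": protein,
                    "kcal_tnc": npe * shares[:, 0],
                    "kcal_ndf": npe * shares[:, 1],
                    "kcal_lipid": npe * shares[:, 2],
                    "full_day": rng.random(n) < config.full_day_fraction,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.drop_duplicates(["individual_id", "date"], keep="first")
    from .intake import add_derived_intakes

    return add_derived_intakes(out)


# ---------------------------------------------------------------------------
# urine


def simulate_urine(
    follows: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    fai: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Urine samples dated the day after a follow, with known-truth biomarkers.

    Concentration analytes are stored both as generator truth
    (``*_true``) and as observed values diluted by (SG-1)/(SG_ref-1); the
    standard specific-gravity correction inverts the dilution exactly.
    A small fraction of extra samples is dated two days after a follow so
    the prior-day match logic has genuine misses to drop.  Passing the
    monthly ``fai`` series activates the habitat-level component of the
    ketone link; without it ketosis depends on the prior day's TNC only.
    """
    if follows.empty:
        raise ValueError("follows table is empty")
    rng = _rng(truth.seed, 3)
    inds = follows["individual_id"].unique()
    bio_re = {
        name: dict(zip(inds, rng.normal(0.0, sd, len(inds))))
        for name, sd in (
            ("cp", truth.sd_individual_bio),
            ("urea", truth.sd_individual_bio),
            ("d15n", truth.sd_individual_bio),
            ("ket", truth.sd_individual_ketone),
        )
    }

    full = follows.loc[follows["full_day"]].reset_index(drop=True)
    take = rng.random(len(full)) < config.urine_match_fraction
    sel = full.loc[take].reset_index(drop=True)
    offsets = np.ones(len(sel), int)
    n_extra = int(round(config.unmatched_urine_fraction * len(sel)))
    if n_extra:
        extra_idx = rng.choice(len(sel), size=n_extra, replace=False)
        offsets[extra_idx] = 2  # prior day (almost surely) not followed

    n = len(sel)
    e = sel["kcal_total"].to_numpy()
    tnc = sel["kcal_tnc"].to_numpy()
    ids = sel["individual_id"].to_numpy()
    re_cp = np.array([bio_re["cp"][i] for i in ids])
    re_ur = np.array([bio_re["urea"][i] for i in ids])
    re_dn = np.array([bio_re["d15n"][i] for i in ids])
    re_kt = np.array([bio_re["ket"][i] for i in ids])

    fp = truth.family_params
    cp_true = np.exp(
        truth.cpeptide_link(e) + re_cp + rng.normal(0.0, fp["sigma_log_cpeptide"], n)
    )
    urea_mean = np.exp(truth.urea_link(tnc) + re_ur)
    shape = fp["shape_urea"]
    urea_true = rng.gamma(shape, urea_mean / shape)
    d15n = rng.normal(truth.d15n_link(tnc) + re_dn, fp["sigma_d15n"])
    if fai is not None:
        fai_by_month = dict(zip(fai["month"], fai["fai"]))
        months = pd.to_datetime(sel["date"]).dt.strftime("%Y-%m")
        fai_vals = np.array([fai_by_month[mo] for mo in months])
        p_ket = expit(truth.ketone_logit(tnc, fai_vals) + re_kt)
    else:
        p_ket = expit(truth.ketone_logit(tnc) + re_kt)
    positive = rng.random(n) < p_ket

    a, b = (1.0 - truth.sg_mean) / truth.sg_sd, np.inf
    sg = truncnorm.rvs(a, b, loc=truth.sg_mean, scale=truth.sg_sd, size=n, random_state=rng)
    dilution = (sg - 1.0) / (SG_REFERENCE - 1.0)

    severity = rng.choice(["trace", "+", "++", "+++"], size=n, p=[0.5, 0.3, 0.15, 0.05])
    ketone_cat = np.where(positive, severity, "negative")

    out = pd.DataFrame(
        {
            "individual_id": ids,
            "collection_date": (
                pd.to_datetime(sel["date"]) + pd.to_timedelta(offsets, unit="D")
            ).dt.strftime("%Y-%m-%d"),
            "sg": sg,
            "cpeptide_true": cp_true,
            "urea_true": urea_true,
            "cpeptide_pg_ml": cp_true * dilution,
            "urea_mg_ml": urea_true * dilution,
            "d15n_permil": d15n,
            "ketone_category": ketone_cat,
            "cv_cpeptide": rng.gamma(truth.cv_shape, truth.cv_scale, n),
            "cv_urea": rng.gamma(truth.cv_shape, truth.cv_scale, n),
        }
    )
    for col, frac in (
        ("cpeptide_pg_ml", config.miss_cpeptide),
        ("urea_mg_ml", config.miss_urea),
        ("d15n_permil", config.miss_d15n),
    ):
        out.loc[rng.random(n) < frac, col] = np.nan
    out.loc[rng.random(n) < config.miss_ketone, "ketone_category"] = "missing"
    return out


# ---------------------------------------------------------------------------
# analytic-benchmark simulation


def simulate_constant_protein_trial(
    n_individuals: int = 40,
    days_per_individual: int = 40,
    protein_kcal: float = 255.0,
    energy_fold: float = 4.0,
    noise_sd: float = 0.05,
    sd_individual: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Constant-absolute-protein diet across a log-uniform energy range.

    The analytic benchmark for complete protein prioritization: with
    absolute protein fixed, %protein-energy is proportional to 1/E, so the
    fitted power-law exponent must be -1.  ``noise_sd`` is small
    multiplicative noise on %protein.
    """
    rng = np.random.default_rng(seed)
    n = n_individuals * days_per_individual
    ids = np.repeat([f"ID{i:03d}" for i in range(n_individuals)], days_per_individual)
    alpha = np.repeat(rng.normal(0.0, sd_individual, n_individuals), days_per_individual)
    e_lo = 4.0 * protein_kcal  # keep %P below ~25% at the energy floor
    log_e = rng.uniform(np.log(e_lo), np.log(e_lo * energy_fold), n)
    e = np.exp(log_e)
    pct = 100.0 * protein_kcal / e * np.exp(alpha + rng.normal(0.0, noise_sd, n))
    protein = pct / 100.0 * e
    npe = e - protein
    dates = pd.date_range("2015-01-01", periods=days_per_individual, freq="D")
    return pd.DataFrame(
        {
            "individual_id": ids,
            "date": np.tile(dates.strftime("%Y-%m-%d"), n_individuals),
            "sex": "F",
            "age_sex_class": "adult_female",
            "kcal_protein": protein,
            "kcal_tnc": npe * 0.70,
            "kcal_ndf": npe * 0.18,
            "kcal_lipid": npe * 0.12,
            "kcal_npe": npe,
            "kcal_total": e,
            "pct_protein_energy": pct,
            "full_day": True,
        }
    )


def truth_to_dict(truth: SimTruth) -> dict:
    """JSON/YAML-serialisable view of the generating parameters."""
    d = dataclasses.asdict(truth)
    d["rho_matrix"] = None if truth.rho_matrix is None else truth.rho_matrix.tolist()
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
        elif isinstance(v, (np.floating, np.integer)):
            d[k] = float(v)
    return d
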