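"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure each stage assumes so
the whole pipeline is testable without any array download:

* an Infinium-style tumor/PBL β cohort with planted high-separation
  markers, leukocyte-methylated probes, failed measurements and SNP /
  repeat annotation flags;
* methylation-specific PCR (MethyLight) Ct panels with engineered
  screen fates (design failure, M.SssI-control failure, PBL background,
  plasma background) for the verification counter-screens;
* digital-PCR plates from a known molecule concentration (Poisson
  molecule counts scattered uniformly over wells);
* post-resection patient trajectories in which a shared latent tumor
  burden drives both CA-125 and the methylated-molecule concentration.

Beta distributions are parameterized by (mean, precision) with
a = mean·precision, b = (1−mean)·precision, which makes planted effect
sizes direct to state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PBL, TUMOR, BetaCohort, ProbeAnnotation
from .digital import DigitalPlateSet
from .longitudinal import PatientSeries

__all__ = [
    "SimConfig",
    "TrajectoryConfig",
    "PlantedTruth",
    "MethylightPanelConfig",
    "MethylightPanel",
    "generate_infinium_cohort",
    "generate_patient_series",
    "generate_digital_plates",
    "generate_methylight_panel",
    "correlated_marker_series",
    "synthetic_concordance_cohort",
    "true_burden",
    "beta_params",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


def beta_params(mean: float, precision: float) -> tuple[float, float]:
    """Convert (mean, precision) to the (a, b) shape of a Beta distribution."""
    if not 0 < mean < 1 or precision <= 0:
        raise ConfigError(f"invalid beta params mean={mean}, precision={precision}")
    return mean * precision, (1.0 - mean) * precision


@dataclass
class SimConfig:
    """Configuration of the synthetic Infinium cohort.

    Distributions are (mean, precision) pairs. Defaults emulate the
    screened discovery cohort: 41 tumors, 2 PBL subjects assayed in
    technical duplicate, and a panel of planted markers methylated in
    every tumor but essentially unmethylated in leukocytes.
    """

    n_probes: int = 2000
    n_tumors: int = 41
    n_pbl: int = 2                      # PBL subjects; each run in duplicate
    n_planted_markers: int = 40
    planted_tumor_beta_dist: tuple[float, float] = (0.6, 30.0)
    planted_pbl_beta_dist: tuple[float, float] = (0.02, 50.0)
    background_beta_dist: tuple[float, float] = (0.10, 8.0)
    pbl_high_beta_dist: tuple[float, float] = (0.70, 20.0)
    pbl_high_fraction: float = 0.20
    fail_fraction: float = 0.005        # probe×sample cells with detection p > 0.05
    snp_fraction: float = 0.10
    repeat_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("pbl_high_fraction", "fail_fraction", "snp_fraction",
                     "repeat_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if self.n_planted_markers > self.n_probes:
            raise ConfigError("n_planted_markers exceeds n_probes")
        if min(self.n_probes, self.n_tumors, self.n_pbl) < 1:
            raise ConfigError("counts must be positive")
        for dist in (self.planted_tumor_beta_dist, self.planted_pbl_beta_dist,
                     self.background_beta_dist, self.pbl_high_beta_dist):
            beta_params(*dist)


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic cohort, for recovery checks."""

    planted_probe_ids: list[str]
    pbl_high_probe_ids: list[str]
    failed_cells: list[tuple[str, str]]
    burden_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_probe_ids) & set(self.pbl_high_probe_ids):
            raise ConfigError("planted and pbl-high probe sets must be disjoint")


def generate_infinium_cohort(
    config: SimConfig,
) -> tuple[BetaCohort, ProbeAnnotation, PlantedTruth]:
    """Simulate a tumor/PBL β cohort with planted markers.

    Planted markers draw tumor β from ``planted_tumor_beta_dist`` and
    PBL β from ``planted_pbl_beta_dist``; a ``pbl_high_fraction`` of the
    remaining probes is methylated in leukocytes (and tumors alike);
    everything else shares ``background_beta_dist`` across groups.
    Detection failures and SNP/repeat flags are planted on non-marker
    probes only, emulating markers with robust assay chemistry, so that
    cascade recall of the planted set is a meaningful target.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    probe_ids = [f"cg{i:06d}" for i in range(config.n_probes)]
    tumor_ids = [f"T{i + 1:02d}" for i in range(config.n_tumors)]
    pbl_subjects = [f"PBL{i + 1}" for i in range(config.n_pbl)]
    pbl_ids = [f"{s}_r{r}" for s in pbl_subjects for r in (1, 2)]
    sample_ids = tumor_ids + pbl_ids

    # probe roles
    perm = rng.permutation(config.n_probes)
    planted_idx = np.sort(perm[: config.n_planted_markers])
    n_pbl_high = int(round(config.pbl_high_fraction
                           * (config.n_probes - config.n_planted_markers)))
    pbl_high_idx = np.sort(perm[config.n_planted_markers:
                                config.n_planted_markers + n_pbl_high])

    n_probes, n_samples = config.n_probes, len(sample_ids)
    a_bg, b_bg = beta_params(*config.background_beta_dist)
    beta = rng.beta(a_bg, b_bg, size=(n_probes, n_samples))

    a, b = beta_params(*config.pbl_high_beta_dist)
    beta[pbl_high_idx, :] = rng.beta(a, b, size=(len(pbl_high_idx), n_samples))

    a, b = beta_params(*config.planted_tumor_beta_dist)
    beta[np.ix_(planted_idx, np.arange(config.n_tumors))] = rng.beta(
        a, b, size=(len(planted_idx), config.n_tumors)
    )
    a, b = beta_params(*config.planted_pbl_beta_dist)
    beta[np.ix_(planted_idx, np.arange(config.n_tumors, n_samples))] = rng.beta(
        a, b, size=(len(planted_idx), len(pbl_ids))
    )

    # detection p: failed cells uniform on (0.05, 1], the rest on [0, 0.05];
    # failures land only on non-planted probes
    detp = rng.uniform(0.0, 0.05, size=(n_probes, n_samples))
    planted_set = set(planted_idx.tolist())
    eligible_rows = np.array([i for i in range(n_probes) if i not in planted_set])
    n_fail = int(round(config.fail_fraction * n_probes * n_samples))
    failed_cells: list[tuple[str, str]] = []
    if n_fail > 0 and eligible_rows.size > 0:
        flat = rng.choice(eligible_rows.size * n_samples, size=n_fail, replace=False)
        rows = eligible_rows[flat // n_samples]
        cols = flat % n_samples
        detp[rows, cols] = rng.uniform(0.05, 1.0, size=n_fail) + 1e-12
        np.clip(detp, 0.0, 1.0, out=detp)
        failed_cells = [(probe_ids[r], sample_ids[c]) for r, c in zip(rows, cols)]

    # annotation flags, also restricted to non-planted probes
    n_snp = int(round(config.snp_fraction * n_probes))
    n_rep = int(round(config.repeat_fraction * n_probes))
    snp_flag = np.zeros(n_probes, dtype=bool)
    rep_flag = np.zeros(n_probes, dtype=bool)
    if eligible_rows.size:
        snp_rows = rng.choice(eligible_rows, size=min(n_snp, eligible_rows.size),
                              replace=False)
        rep_rows = rng.choice(eligible_rows, size=min(n_rep, eligible_rows.size),
                              replace=False)
        snp_flag[snp_rows] = True
        rep_flag[rep_rows] = True

    # two probes may share a gene; ~1.9 probes per gene on the real array
    n_genes = max(1, int(round(n_probes / 1.9)))
    gene_of = [f"GENE{rng.integers(0, n_genes):05d}" for _ in range(n_probes)]

    probe_index = pd.Index(probe_ids, name="probe_id")
    beta_df = pd.DataFrame(beta, index=probe_index, columns=sample_ids)
    detp_df = pd.DataFrame(detp, index=probe_index, columns=sample_ids)
    groups = pd.Series(
        {**{t: TUMOR for t in tumor_ids}, **{p: PBL for p in pbl_ids}}, name="group"
    )
    replicate_of = pd.Series(
        {**{t: t for t in tumor_ids},
         **{p: p.split("_r")[0] for p in pbl_ids}},
        name="subject_id",
    )
    cohort = BetaCohort(beta_df, detp_df, groups, replicate_of)
    ann = ProbeAnnotation(
        pd.DataFrame(
            {"gene_symbol": gene_of, "snp_flag": snp_flag, "repeat_flag": rep_flag},
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )
    truth = PlantedTruth(
        planted_probe_ids=[probe_ids[i] for i in planted_idx],
        pbl_high_probe_ids=[probe_ids[i] for i in pbl_high_idx],
        failed_cells=failed_cells,
    )
    return cohort, ann, truth


# ---------------------------------------------------------------------------
# patient trajectories


@dataclass
class TrajectoryConfig:
    """One patient's post-resection kinetics.

    A latent tumor burden (arbitrary units) is constant until surgery,
    decays exponentially afterwards, and regrows exponentially from the
    relapse week on. CA-125 is burden scaled to U/ml with multiplicative
    lognormal noise plus a non-tumor production floor; the methylated
    molecule count in the assayed serum volume is Poisson with mean
    proportional to burden.
    """

    patient_id: str = "P1"
    baseline_burden: float = 10.0
    surgery_week: float = 0.0
    clearance_rate: float = 0.4         # per week; ~1.7-week post-resection half-life
    residual_burden: float = 0.05       # minimal residual disease floor
    relapse_week: float | None = 40.0
    regrowth_rate: float = 0.12         # per week, post-relapse growth
    ca125_scale: float = 30.0           # U/ml per burden unit
    ca125_noise_cv: float = 0.2
    ca125_floor: float = 10.0           # U/ml, non-tumor production
    molecule_scale: float = 20.0        # molecules/ml serum per burden unit
    background_molecules_per_assay: float = 0.0
    draw_weeks: tuple[float, ...] = (0, 6, 12, 18, 24, 30, 36, 42, 48, 54,
                                     60, 66, 72, 78, 84, 90)  # ~6-week visits
    serum_volume_ul: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_burden < 0:
            raise ConfigError("baseline_burden must be >= 0")
        for name in ("clearance_rate", "residual_burden", "regrowth_rate", "ca125_scale",
                     "ca125_noise_cv", "ca125_floor", "molecule_scale",
                     "background_molecules_per_assay"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.draw_weeks:
            raise ConfigError("draw_weeks must be non-empty")
        if list(self.draw_weeks) != sorted(self.draw_weeks):
            raise ConfigError("draw_weeks must be sorted")
        if self.serum_volume_ul <= 0:
            raise ConfigError("serum_volume_ul must be positive")


def true_burden(config: TrajectoryConfig, week: float) -> float:
    """Piecewise-exponential latent burden at ``week``."""
    if week < config.surgery_week or config.baseline_burden == 0:
        return config.baseline_burden
    floor = min(config.residual_burden, config.baseline_burden)

    def decayed(t: float) -> float:
        return max(
            config.baseline_burden
            * math.exp(-config.clearance_rate * (t - config.surgery_week)),
            floor,
        )

    if config.relapse_week is not None and week >= config.relapse_week:
        return decayed(config.relapse_week) * math.exp(
            config.regrowth_rate * (week - config.relapse_week)
        )
    return decayed(week)


def generate_patient_series(config: TrajectoryConfig) -> PatientSeries:
    """Simulate serial (week, CA-125, molecules/ml) draws for one patient."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vol_ml = config.serum_volume_ul / 1000.0
    cv = config.ca125_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    mu = -0.5 * sigma * sigma  # unit-mean lognormal

    rows = []
    for week in config.draw_weeks:
        b = true_burden(config, week)
        ca_mean = config.ca125_scale * b + config.ca125_floor
        noise = rng.lognormal(mu, sigma) if sigma > 0 else 1.0
        ca125 = ca_mean * noise
        lam = config.molecule_scale * b * vol_ml + config.background_molecules_per_assay
        count = int(rng.poisson(lam))
        rows.append(
            dict(week=float(week), ca125=float(ca125),
                 marker_conc=count / vol_ml, molecule_count=count,
                 true_burden=b)
        )
    draws = pd.DataFrame(rows)
    return PatientSeries(
        patient_id=config.patient_id,
        draws=draws,
        surgery_week=config.surgery_week,
        relapse_week=config.relapse_week,
        baseline_is_presurgery=config.draw_weeks[0] <= config.surgery_week,
    )


def correlated_marker_series(ca125: np.ndarray, r: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Construct a non-negative series with EXACT sample Pearson r to ``ca125``.

    Gram–Schmidt: draw noise, orthogonalize it against the centered
    CA-125 vector, mix standardized components as r·x̂ + √(1−r²)·ẑ, then
    map affinely (positive slope) onto a non-negative molecules/ml
    scale. Affine maps preserve the sample correlation, so the returned
    series has correlation exactly ``r`` up to float rounding.
    """
    if not -1.0 <= r <= 1.0:
        raise ConfigError(f"target correlation must lie in [-1,1], got {r}")
    x = np.asarray(ca125, dtype=float)
    n = x.size
    if n < 3:
        raise ConfigError("need at least 3 draws")
    xc = x - x.mean()
    if np.allclose(xc, 0):
        raise ConfigError("ca125 series has zero variance")
    xs = xc / np.linalg.norm(xc)
    z = rng.standard_normal(n)
    zc = z - z.mean()
    zc = zc - (zc @ xs) * xs          # orthogonal to x and to the constant
    if np.linalg.norm(zc) == 0:       # astronomically unlikely; redraw
        return correlated_marker_series(ca125, r, rng)
    zs = zc / np.linalg.norm(zc)
    y0 = r * xs + math.sqrt(max(0.0, 1.0 - r * r)) * zs
    y = (y0 - y0.min()) * 400.0       # non-negative molecules/ml scale
    return y


def synthetic_concordance_cohort(
    r_targets: dict[str, float],
    n_draws: int = 15,
    seed: int = 0,
) -> list[PatientSeries]:
    """SYNTHETIC stand-in cohort of serial draws with planted correlations.

    For each patient id in ``r_targets``, builds a post-resection-shaped
    CA-125 trajectory and a marker series whose sample Pearson
    correlation with it equals the requested value exactly by
    construction. This is a synthetic fixture for exercising the
    concordance statistics — it carries no measured patient data.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for pid, r in r_targets.items():
        weeks = np.arange(n_draws, dtype=float) * 6.0
        # baseline peak, post-resection decay, late regrowth + noise
        base = 300.0 * np.exp(-0.12 * weeks) + 120.0 * np.exp(
            0.05 * (weeks - weeks[-1])
        )
        ca125 = base * rng.lognormal(0.0, 0.25, size=n_draws) + 8.0
        marker = correlated_marker_series(ca125, r, rng)
        draws = pd.DataFrame(
            {"week": weeks, "ca125": ca125, "marker_conc": marker}
        )
        cohort.append(
            PatientSeries(
                patient_id=pid,
                draws=draws,
                surgery_week=0.0,
                relapse_week=None,
                baseline_is_presurgery=True,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# digital plates


def generate_digital_plates(
    concentration: float,
    volume_ul: float = 100.0,
    wells: int = 96,
    detection_efficiency: float = 1.0,
    seed: int = 0,
    n_plates: int = 1,
    sample_id: str = "S1",
) -> DigitalPlateSet:
    """Simulate digital-PCR plates from a known molecule concentration.

    Each plate assays ``volume_ul`` of serum equivalent. The number of
    template molecules reaching a plate is Poisson with mean
    concentration × volume(ml) × efficiency; molecules land in wells
    uniformly at random and a well is positive iff it received at least
    one molecule.
    """
    if concentration < 0:
        raise ConfigError("concentration must be >= 0")
    if wells < 1 or n_plates < 1:
        raise ConfigError("wells and n_plates must be >= 1")
    if not 0 <= detection_efficiency <= 1:
        raise ConfigError("detection_efficiency must lie in [0,1]")
    rng = np.random.default_rng(seed)
    vol_ml = volume_ul / 1000.0
    plates = []
    for _ in range(n_plates):
        n_mol = rng.poisson(concentration * vol_ml * detection_efficiency)
        if n_mol == 0:
            positive = 0
        else:
            hit_wells = rng.integers(0, wells, size=n_mol)
            positive = int(np.unique(hit_wells).size)
        plates.append((wells, positive))
    return DigitalPlateSet(
        sample_id=sample_id,
        plates=plates,
        volume_assayed_ul=volume_ul * n_plates,
    )


# ---------------------------------------------------------------------------
# MethyLight screen panel


@dataclass
class MethylightPanelConfig:
    """Engineered fates for a marker panel entering the PCR screens.

    Defaults mirror the verification-stage funnel: 15 candidates, 3
    failing assay design, 1 failing the fully-methylated (M.SssI)
    control, 3 methylated in leukocytes, and all but one of the rest
    showing background methylation in control plasma.
    """

    n_design_fail: int = 3
    n_mssi_fail: int = 1
    n_pbl_methylated: int = 3
    n_plasma_positive: int = 7
    n_pbl_samples: int = 2
    n_plasma_controls: int = 10
    n_tumors: int = 15
    ct_target_ref: float = 25.0
    ct_alu_ref: float = 17.0
    seed: int = 0


@dataclass
class MethylightPanel:
    """Generated Ct tables for the verification screens.

    ``ct`` is a tidy table (marker_id, sample_id, reaction, ct) with
    ``None`` for undetected reactions; reference Cts are carried so PMR
    can be computed downstream. ``fates`` records the engineered truth.
    """

    marker_ids: list[str]
    ct: pd.DataFrame
    ct_target_ref: float
    ct_alu_ref: float
    fates: pd.DataFrame  # marker_id → fate ∈ {design_fail, mssi_fail, pbl, plasma, pass}


def _pmr_to_target_ct(pmr: float, ct_alu_sample: float,
                      ct_target_ref: float, ct_alu_ref: float) -> float | None:
    """Invert the PMR formula to the target Ct producing that PMR."""
    if pmr <= 0:
        return None
    return ct_alu_sample + (ct_target_ref - ct_alu_ref) - math.log2(pmr / 100.0)


def generate_methylight_panel(
    truth: PlantedTruth | None,
    config: MethylightPanelConfig,
    marker_ids: list[str] | None = None,
) -> MethylightPanel:
    """Build a Ct panel whose markers carry engineered screen fates.

    ``marker_ids`` default to the cohort's planted markers (or synthetic
    ids); fates are assigned in order design-fail, M.SssI-fail,
    PBL-methylated, plasma-positive, survivor, shuffled by seed.
    """
    rng = np.random.default_rng(config.seed)
    if marker_ids is None:
        if truth is not None and truth.planted_probe_ids:
            marker_ids = list(truth.planted_probe_ids)
        else:
            marker_ids = [f"MK{i + 1:02d}" for i in range(15)]
    n = len(marker_ids)
    n_assigned = (config.n_design_fail + config.n_mssi_fail
                  + config.n_pbl_methylated + config.n_plasma_positive)
    if n_assigned > n:
        raise ConfigError(
            f"panel of {n} markers cannot absorb {n_assigned} engineered failures"
        )
    fates = (["design_fail"] * config.n_design_fail
             + ["mssi_fail"] * config.n_mssi_fail
             + ["pbl"] * config.n_pbl_methylated
             + ["plasma"] * config.n_plasma_positive
             + ["pass"] * (n - n_assigned))
    order = rng.permutation(n)
    fate_of = {marker_ids[i]: fates[j] for j, i in enumerate(order)}

    pbl_samples = [f"PBL_ctrl{i + 1}" for i in range(config.n_pbl_samples)]
    plasma_samples = [f"PLASMA{i + 1}" for i in range(config.n_plasma_controls)]
    tumor_samples = [f"TUM{i + 1:02d}" for i in range(config.n_tumors)]

    rows: list[dict] = []

    def add(marker, sample, reaction, ct):
        rows.append(dict(marker_id=marker, sample_id=sample,
                         reaction=reaction, ct=ct))

    for m in marker_ids:
        fate = fate_of[m]
        if fate == "design_fail":
            continue  # no reactions exist for this marker
        # M.SssI fully-methylated control
        mssi_ct = None if fate == "mssi_fail" else float(rng.uniform(26.0, 31.0))
        add(m, "MSSSI", "target", mssi_ct)
        add(m, "MSSSI", "alu", float(rng.uniform(16.0, 18.0)))
        if fate == "mssi_fail":
            continue
        # PBL counter-screen against excess leukocyte DNA
        for s in pbl_samples:
            if fate == "pbl":
                ct = float(rng.uniform(28.0, 34.0))
            else:
                ct = None if rng.random() < 0.5 else float(rng.uniform(36.0, 45.0))
            add(m, s, "target", ct)
            add(m, s, "alu", float(rng.uniform(16.0, 19.0)))
        if fate == "pbl":
            continue
        # control plasma PMR screen
        for j, s in enumerate(plasma_samples):
            alu_ct = float(rng.uniform(16.0, 19.0))
            if fate == "plasma" and j == 0:
                pmr = float(rng.uniform(6.0, 40.0))   # at least one plasma ≥ cutoff
            elif fate == "plasma":
                pmr = float(rng.uniform(0.0, 8.0))
            else:
                pmr = float(rng.uniform(0.0, 2.0))    # survivor: PMR < 5 everywhere
            add(m, s, "target",
                _pmr_to_target_ct(pmr, alu_ct, config.ct_target_ref, config.ct_alu_ref))
            add(m, s, "alu", alu_ct)
        if fate == "plasma":
            continue
        # tumor PMR panel for the survivor(s)
        for s in tumor_samples:
            alu_ct = float(rng.uniform(16.0, 19.0))
            pmr = float(rng.uniform(25.0, 95.0))
            add(m, s, "target",
                _pmr_to_target_ct(pmr, alu_ct, config.ct_target_ref, config.ct_alu_ref))
            add(m, s, "alu", alu_ct)

    ct = pd.DataFrame(rows, columns=["marker_id", "sample_id", "reaction", "ct"])
    fates_df = pd.DataFrame(
        {"marker_id": marker_ids, "fate": [fate_of[m] for m in marker_ids]}
    )
    return MethylightPanel(
        marker_ids=list(marker_ids),
        ct=ct,
        ct_target_ref=config.ct_target_ref,
        ct_alu_ref=config.ct_alu_ref,
        fates=fates_df,
    )
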