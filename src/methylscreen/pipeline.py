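"""End-to-end orchestration: simulate → select → verify → digital → monitor.

One config object carries every stage threshold, with the protocol's
values as defaults so no threshold is a buried constant. The pipeline
is fully deterministic under its seed: all stage seeds are derived from
the config seed with ``numpy`` SeedSequence spawning.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as msio
from .digital import quantify_sample
from .longitudinal import bootstrap_auc_ci, cohort_concordance, post_resection_drop
from .methylight import run_marker_screen
from .select import run_selection
from .simulate import (
    MethylightPanelConfig,
    SimConfig,
    TrajectoryConfig,
    generate_digital_plates,
    generate_infinium_cohort,
    generate_methylight_panel,
    generate_patient_series,
)

logger = logging.getLogger("methylscreen")


@dataclass
class PipelineConfig:
    """Thresholds and sizes for every stage, protocol defaults throughout."""

    alpha: float = 0.05             # detection p-value QC
    pbl_beta: float = 0.2           # PBL methylation exclusion (≥)
    top_k: int = 15                 # markers carried to the PCR stage
    unique_genes: bool = False
    pbl_min_ct: float = 35.0        # PBL counter-screen (> to pass)
    alu_max_ct: float = 21.0        # ALU DNA-quality gate (strict <)
    plasma_pmr_max: float = 5.0     # control plasma pass rule (<)
    tumor_pmr_min: float = 20.0     # tumor positivity rule (>)
    saturation_hits: int = 15       # per 96 wells
    boot: int = 2000                # bootstrap resamples for the AUC CI
    sig_alpha: float = 0.05         # Pearson significance cutoff
    n_case_sera: int = 16
    n_control_sera: int = 8
    n_patients: int = 9
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    funnel: dict[str, int]
    selected_marker_ids: list[str]
    screen_survivors: list[str]
    auc: float
    auc_ci: tuple[float, float]
    n_significant: int
    n_patients_tested: int
    drops: dict[str, dict[str, bool]]
    truth_planted: list[str] = field(default_factory=list)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _panel_config_for(n_markers: int, seed: int) -> MethylightPanelConfig:
    """Default screen fates, shrunk proportionally for short marker lists."""
    cfg = MethylightPanelConfig(seed=seed)
    fates = {"n_design_fail": cfg.n_design_fail, "n_mssi_fail": cfg.n_mssi_fail,
             "n_pbl_methylated": cfg.n_pbl_methylated,
             "n_plasma_positive": cfg.n_plasma_positive}
    while sum(fates.values()) >= n_markers:  # keep >=1 passing slot
        biggest = max(fates, key=fates.get)
        if fates[biggest] == 0:
            break
        fates[biggest] -= 1
    for k, v in fates.items():
        setattr(cfg, k, v)
    return cfg


def run_pipeline(config: PipelineConfig,
                 sim: SimConfig | None = None) -> PipelineResult:
    """Run the whole discovery-and-verification funnel on synthetic data.

    Stages, in order: simulate an Infinium cohort with planted markers;
    run the selection cascade; push the top-k markers through the
    MethyLight screens; quantify case/control baseline sera by digital
    PCR and compute ROC/AUC with bootstrap CI; simulate serial patient
    trajectories and test marker-vs-CA-125 concordance. Writes every
    table to ``config.out_dir`` when set.
    """
    seeds = _spawn_seeds(config.seed, 6)
    sim = sim if sim is not None else SimConfig(seed=seeds[0])

    cohort, ann, truth = generate_infinium_cohort(sim)
    logger.info("simulated cohort: %d probes, %d samples",
                len(cohort.probe_ids), len(cohort.sample_ids))

    ranked, top, reports = run_selection(
        cohort, ann, alpha=config.alpha, pbl_threshold=config.pbl_beta,
        top_k=config.top_k, unique_genes=config.unique_genes,
    )
    if len(ranked) < config.top_k:
        logger.warning("only %d ranked survivors for top_k=%d; carrying all",
                       len(ranked), config.top_k)
    funnel = {"probes_in": reports[0].probes_in}
    for r in reports:
        funnel[r.stage] = r.probes_out
        logger.info("stage %-16s %6d -> %6d probes (alpha=%.3g, pbl>=%.3g)",
                    r.stage, r.probes_in, r.probes_out,
                    config.alpha, config.pbl_beta)
    funnel["top_k"] = len(top)

    panel = generate_methylight_panel(
        truth, _panel_config_for(len(top), seeds[1]),
        marker_ids=[m.probe_id for m in top],
    )
    screen, survivors = run_marker_screen(
        panel, pbl_min_ct=config.pbl_min_ct,
        plasma_pmr_max=config.plasma_pmr_max,
        tumor_pmr_min=config.tumor_pmr_min,
    )
    funnel["screen_survivors"] = len(survivors)
    logger.info("PCR screens: %d/%d markers survive", len(survivors), len(top))

    # baseline case/control digital quantification
    rng = np.random.default_rng(seeds[2])
    case_conc, control_conc = [], []
    for i in range(config.n_case_sera):
        true_c = float(rng.lognormal(np.log(200.0), 1.5))
        plates = generate_digital_plates(
            true_c, volume_ul=100.0, seed=int(rng.integers(2**31)),
            sample_id=f"CASE{i + 1}",
        )
        case_conc.append(quantify_sample(plates, method="naive").concentration)
    for i in range(config.n_control_sera):
        plates = generate_digital_plates(
            0.0, volume_ul=100.0, seed=int(rng.integers(2**31)),
            sample_id=f"CTRL{i + 1}",
        )
        # rare background molecules in healthy serum
        background = int(rng.poisson(0.25))
        n, k = plates.plates[0]
        plates.plates[0] = (n, min(n, k + background))
        control_conc.append(quantify_sample(plates, method="naive").concentration)
    roc = bootstrap_auc_ci(case_conc, control_conc, n_boot=config.boot,
                           seed=seeds[3])
    logger.info("baseline ROC: AUC=%.3f [%.3f, %.3f]",
                roc.auc, roc.ci_low, roc.ci_high)

    # longitudinal monitoring
    patient_seeds = _spawn_seeds(seeds[4], config.n_patients)
    series = [
        generate_patient_series(
            TrajectoryConfig(patient_id=f"P{i + 1}", seed=patient_seeds[i])
        )
        for i in range(config.n_patients)
    ]
    results, n_sig, untestable = cohort_concordance(series, alpha=config.sig_alpha)
    drops = {}
    for s in series:
        try:
            drops[s.patient_id] = post_resection_drop(s)
        except ValueError:
            continue
    logger.info("concordance: %d/%d patients significant at p<%g",
                n_sig, len(series) - len(untestable), config.sig_alpha)

    if config.out_dir:
        out = msio.ensure_dir(config.out_dir)
        msio.write_beta_cohort(cohort, out / "beta.tsv", out / "detection_p.tsv",
                               out / "samples.csv")
        msio.write_annotation(ann, out / "annotation.tsv")
        msio.write_ranked_markers(out / "ranked_markers.tsv", ranked)
        msio.write_filter_reports(out / "filter_reports.tsv", reports)
        msio.write_ct_table(out / "methylight_ct.csv", panel.ct)
        screen.to_csv(out / "screen_outcomes.tsv", sep="\t", index=False)
        msio.write_series(out / "patient_series.csv", series)
        msio.write_concordance(out / "concordance.tsv", results, untestable)

    return PipelineResult(
        funnel=funnel,
        selected_marker_ids=[m.probe_id for m in top],
        screen_survivors=survivors,
        auc=roc.auc,
        auc_ci=(roc.ci_low, roc.ci_high),
        n_significant=n_sig,
        n_patients_tested=len(series) - len(untestable),
        drops=drops,
        truth_planted=list(truth.planted_probe_ids),
    )
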