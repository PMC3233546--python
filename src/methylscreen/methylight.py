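"""Methylation-specific PCR (MethyLight) verification screens.

Candidate markers leaving the array stage are pushed through an ordered
cascade of counter-screens before any patient testing:

    design → M.SssI control → PBL Ct counter-screen → control-plasma PMR
    → tumor PMR

A marker failing a stage is eliminated and never evaluated at later
stages. Quantification is by PMR (Percent of Methylated Reference): the
methylation-specific signal normalized to an ALU repeat control and
scaled to a fully methylated (M.SssI-treated) reference,

    PMR = 100 · 2^(−[(Ct_target,sample − Ct_ALU,sample)
                     − (Ct_target,ref − Ct_ALU,ref)]).

An undetected reaction is a distinct state (``ct=None``), never a large
Ct number, so it cannot silently enter arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CtValue",
    "PmrResult",
    "ScreenOutcome",
    "alu_qc",
    "mssi_gate",
    "pbl_counter_screen",
    "compute_pmr",
    "categorize_pmr",
    "plasma_screen",
    "tumor_positivity",
    "run_marker_screen",
    "MAX_CYCLES",
]

MAX_CYCLES = 50.0  # PCR cycle ceiling; a Ct can only exist below it

STAGES = ("design", "mssi", "pbl_ct", "plasma_pmr", "tumor_pmr")


@dataclass(frozen=True)
class CtValue:
    """A PCR cycle threshold for one (marker, sample) reaction.

    ``ct=None`` encodes an undetected reaction (no amplification within
    the cycle budget).
    """

    marker_id: str
    sample_id: str
    ct: float | None

    def __post_init__(self) -> None:
        if self.ct is not None and not 0 < self.ct <= MAX_CYCLES:
            raise ValueError(
                f"Ct must lie in (0, {MAX_CYCLES}] or be undetected, got {self.ct}"
            )

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass
class PmrResult:
    marker_id: str
    sample_id: str
    pmr: float
    category: str  # low / mid / high

    def __post_init__(self) -> None:
        if self.pmr < 0:
            raise ValueError(f"PMR must be >= 0, got {self.pmr}")


@dataclass
class ScreenOutcome:
    marker_id: str
    stage: str
    passed: bool
    evidence: dict


def alu_qc(ct_alu: CtValue, max_ct: float = 21.0) -> bool:
    """Sample-quality gate: ALU control must amplify strictly below ``max_ct``.

    An undetected ALU reaction means the DNA is unusable (False, not an
    error).
    """
    if max_ct <= 0:
        raise ValueError("max_ct must be positive")
    return ct_alu.detected and ct_alu.ct < max_ct


def mssi_gate(ct_mssi_control: CtValue) -> bool:
    """Assay-validity gate: the fully methylated control must amplify."""
    return ct_mssi_control.detected


def pbl_counter_screen(
    cts: list[CtValue], min_ct: float = 35.0
) -> ScreenOutcome:
    """Pass iff every leukocyte control sample has Ct > ``min_ct`` or none.

    A detectable methylation signal (Ct ≤ min_ct) in even one PBL sample
    means leukocyte background would swamp blood-based detection.
    """
    if not cts:
        raise ValueError("pbl_counter_screen requires at least one Ct")
    passed = all((not c.detected) or c.ct > min_ct for c in cts)
    return ScreenOutcome(
        marker_id=cts[0].marker_id,
        stage="pbl_ct",
        passed=passed,
        evidence={c.sample_id: c.ct for c in cts},
    )


def compute_pmr(
    ct_target_sample: CtValue,
    ct_alu_sample: CtValue,
    ct_target_ref: float,
    ct_alu_ref: float,
) -> PmrResult:
    """Percent of Methylated Reference by the ΔΔCt closed form.

    An undetected target with a valid ALU yields PMR 0 (no methylation
    detected); an undetected ALU makes normalization impossible and is
    an error.
    """
    if not ct_alu_sample.detected:
        raise ValueError(
            f"ALU control undetected for sample {ct_alu_sample.sample_id!r}; "
            "cannot normalize"
        )
    if ct_target_ref is None or ct_alu_ref is None:
        raise ValueError("reference Cts must be present")
    if not ct_target_sample.detected:
        pmr = 0.0
    else:
        ddct = (ct_target_sample.ct - ct_alu_sample.ct) - (ct_target_ref - ct_alu_ref)
        pmr = 100.0 * 2.0 ** (-ddct)
    return PmrResult(
        marker_id=ct_target_sample.marker_id,
        sample_id=ct_target_sample.sample_id,
        pmr=pmr,
        category=categorize_pmr(pmr),
    )


def categorize_pmr(pmr: float, low_cut: float = 10.0, high_cut: float = 50.0) -> str:
    """Bin a PMR: low < 10 ≤ mid ≤ 50 < high (closed middle interval)."""
    if pmr < 0:
        raise ValueError(f"PMR must be >= 0, got {pmr}")
    if pmr < low_cut:
        return "low"
    if pmr <= high_cut:
        return "mid"
    return "high"


def plasma_screen(pmrs: list[PmrResult], cutoff: float = 5.0) -> ScreenOutcome:
    """Pass iff every control plasma sample has PMR < ``cutoff``."""
    if not pmrs:
        raise ValueError("plasma_screen requires at least one PMR")
    passed = all(p.pmr < cutoff for p in pmrs)
    return ScreenOutcome(
        marker_id=pmrs[0].marker_id,
        stage="plasma_pmr",
        passed=passed,
        evidence={p.sample_id: p.pmr for p in pmrs},
    )


def tumor_positivity(pmrs: list[PmrResult], cutoff: float = 20.0) -> float:
    """Fraction of tumors with PMR strictly above ``cutoff``."""
    if not pmrs:
        raise ValueError("tumor_positivity requires at least one PMR")
    return sum(p.pmr > cutoff for p in pmrs) / len(pmrs)


def _panel_cts(panel, marker: str, samples_like: str, reaction: str) -> list[CtValue]:
    t = panel.ct
    sel = t[(t.marker_id == marker) & (t.reaction == reaction)
            & t.sample_id.str.startswith(samples_like)]
    return [CtValue(marker, r.sample_id, None if pd.isna(r.ct) else float(r.ct))
            for r in sel.itertuples()]


def run_marker_screen(
    panel,
    pbl_min_ct: float = 35.0,
    plasma_pmr_max: float = 5.0,
    tumor_pmr_min: float = 20.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the ordered, short-circuiting screen cascade over a Ct panel.

    ``panel`` is a :class:`~methylscreen.simulate.MethylightPanel`-shaped
    object (tidy Ct table plus reference Cts). Returns the per-marker
    per-stage outcome table and the surviving marker ids. A marker has
    no rows for stages after its first failure.
    """
    rows = []
    survivors = []
    t = panel.ct
    for m in panel.marker_ids:
        mine = t[t.marker_id == m]
        # design: does any reaction exist for this marker at all
        designed = len(mine) > 0
        rows.append(dict(marker_id=m, stage="design", passed=designed))
        if not designed:
            continue
        mssi = mine[(mine.sample_id == "MSSSI") & (mine.reaction == "target")]
        mssi_ct = CtValue(
            m, "MSSSI",
            None if (len(mssi) == 0 or pd.isna(mssi.ct.iloc[0]))
            else float(mssi.ct.iloc[0]),
        )
        ok = mssi_gate(mssi_ct)
        rows.append(dict(marker_id=m, stage="mssi", passed=ok))
        if not ok:
            continue
        pbl_cts = _panel_cts(panel, m, "PBL", "target")
        out = pbl_counter_screen(pbl_cts, min_ct=pbl_min_ct)
        rows.append(dict(marker_id=m, stage="pbl_ct", passed=out.passed))
        if not out.passed:
            continue
        plasma_targets = _panel_cts(panel, m, "PLASMA", "target")
        plasma_alus = {c.sample_id: c for c in _panel_cts(panel, m, "PLASMA", "alu")}
        pmrs = [
            compute_pmr(c, plasma_alus[c.sample_id],
                        panel.ct_target_ref, panel.ct_alu_ref)
            for c in plasma_targets
        ]
        out = plasma_screen(pmrs, cutoff=plasma_pmr_max)
        rows.append(dict(marker_id=m, stage="plasma_pmr", passed=out.passed))
        if not out.passed:
            continue
        tumor_targets = _panel_cts(panel, m, "TUM", "target")
        tumor_alus = {c.sample_id: c for c in _panel_cts(panel, m, "TUM", "alu")}
        tumor_pmrs = [
            compute_pmr(c, tumor_alus[c.sample_id],
                        panel.ct_target_ref, panel.ct_alu_ref)
            for c in tumor_targets
        ]
        frac = tumor_positivity(tumor_pmrs, cutoff=tumor_pmr_min) if tumor_pmrs else 0.0
        passed = bool(tumor_pmrs) and frac == 1.0
        rows.append(dict(marker_id=m, stage="tumor_pmr", passed=passed))
        if passed:
            survivors.append(m)
    return pd.DataFrame(rows, columns=["marker_id", "stage", "passed"]), survivors
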