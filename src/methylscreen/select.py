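"""Marker-selection cascade for tumor-vs-leukocyte methylation separation.

The cascade turns a probe × sample β matrix into a ranked shortlist of
candidate blood-based markers:

1. drop probes that failed detection QC (p > α) in any sample;
2. drop probes flagged as SNP-containing or repeat-derived;
3. average PBL technical replicates to one column per subject;
4. drop probes methylated in leukocytes (averaged PBL β ≥ threshold in
   any subject) — these would swamp a blood assay with background;
5. rank survivors by the separation statistic d = T_L − PBL_H, the β of
   the least-methylated tumor minus the β of the most-methylated PBL
   subject, keeping only d > 0 (every tumor above every PBL);
6. take the top k (optionally one probe per gene).

Probes passing step 5 are methylated in *all* tumors and in *no*
leukocyte sample, the property that favours sensitive and specific
detection in patient blood. The cascade is also packaged as a
scikit-learn compatible feature selector, :class:`MarkerSelector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import PBL, TUMOR, BetaCohort, CohortValidationError, ProbeAnnotation

__all__ = [
    "FilterReport",
    "RankedMarker",
    "drop_failed_probes",
    "drop_annotated_probes",
    "average_replicates",
    "drop_pbl_methylated",
    "rank_by_separation",
    "select_top_markers",
    "summarize_group_distributions",
    "run_selection",
    "MarkerSelector",
]


@dataclass
class FilterReport:
    """Accounting for one cascade stage: what went in, what was removed."""

    stage: str
    probes_in: int
    probes_out: int
    removed_probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.probes_out != self.probes_in - len(self.removed_probe_ids):
            raise ValueError(
                f"stage {self.stage}: probes_out {self.probes_out} != "
                f"probes_in {self.probes_in} - removed {len(self.removed_probe_ids)}"
            )


@dataclass
class RankedMarker:
    """Per-probe separation record.

    ``t_low`` is the β of the least-methylated tumor (T_L), ``pbl_high``
    the β of the most-methylated averaged PBL subject (PBL_H), and
    ``delta`` their difference; retained markers have delta > 0.
    """

    probe_id: str
    gene_symbol: str
    t_low: float
    pbl_high: float
    delta: float
    rank: int


def drop_failed_probes(
    cohort: BetaCohort, alpha: float = 0.05
) -> tuple[BetaCohort, FilterReport]:
    """Remove every probe whose detection p exceeds ``alpha`` in ANY sample."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if cohort.detection_p is None:
        raise CohortValidationError("detection p-value matrix required")
    failed = (cohort.detection_p > alpha).any(axis=1)
    removed = list(cohort.probe_ids[failed])
    kept = cohort.probe_ids[~failed]
    report = FilterReport(
        stage="detection_qc",
        probes_in=len(cohort.probe_ids),
        probes_out=len(kept),
        removed_probe_ids=removed,
    )
    return cohort.subset_probes(kept), report


def drop_annotated_probes(
    cohort: BetaCohort, ann: ProbeAnnotation
) -> tuple[BetaCohort, FilterReport]:
    """Remove probes flagged as SNP-associated or repeat-derived.

    Every probe must carry an annotation record; a missing record is an
    error rather than a silent keep.
    """
    unannotated = cohort.probe_ids.difference(ann.table.index)
    if len(unannotated) > 0:
        raise CohortValidationError(
            f"{len(unannotated)} probes lack annotation records, "
            f"e.g. {list(unannotated[:5])}"
        )
    flags = ann.table.loc[cohort.probe_ids]
    bad = flags["snp_flag"] | flags["repeat_flag"]
    removed = list(cohort.probe_ids[bad.to_numpy()])
    kept = cohort.probe_ids[~bad.to_numpy()]
    report = FilterReport(
        stage="snp_repeat",
        probes_in=len(cohort.probe_ids),
        probes_out=len(kept),
        removed_probe_ids=removed,
    )
    return cohort.subset_probes(kept), report


def average_replicates(cohort: BetaCohort) -> BetaCohort:
    """Collapse PBL technical replicates to one averaged column per subject.

    β is the arithmetic mean over replicates; detection p is the max over
    replicates (a probe is only trusted if it passed QC in every
    replicate). Tumor columns pass through untouched.
    """
    pbl_cols = cohort.pbl_samples
    tumor_cols = cohort.tumor_samples
    subjects = cohort.replicate_of.loc[pbl_cols]
    # a subject id must not span tumor and PBL columns
    tumor_subjects = set(cohort.replicate_of.loc[tumor_cols])
    overlap = tumor_subjects & set(subjects)
    if overlap:
        raise CohortValidationError(
            f"subject ids span tumor and PBL groups: {sorted(overlap)}"
        )

    beta_cols: dict[str, pd.Series] = {}
    detp_cols: dict[str, pd.Series] = {}
    new_groups: dict[str, str] = {}
    new_subjects: dict[str, str] = {}
    for c in tumor_cols:
        beta_cols[c] = cohort.beta[c]
        detp_cols[c] = cohort.detection_p[c]
        new_groups[c] = TUMOR
        new_subjects[c] = cohort.replicate_of.loc[c]
    for subj in dict.fromkeys(subjects):  # preserve order of first appearance
        reps = [c for c in pbl_cols if cohort.replicate_of.loc[c] == subj]
        beta_cols[subj] = cohort.beta[reps].mean(axis=1)
        detp_cols[subj] = cohort.detection_p[reps].max(axis=1)
        new_groups[subj] = PBL
        new_subjects[subj] = subj

    beta = pd.DataFrame(beta_cols)
    detp = pd.DataFrame(detp_cols)
    return BetaCohort(
        beta=beta,
        detection_p=detp,
        groups=pd.Series(new_groups, name="group"),
        replicate_of=pd.Series(new_subjects, name="subject_id"),
    )


def drop_pbl_methylated(
    cohort: BetaCohort, threshold: float = 0.2
) -> tuple[BetaCohort, FilterReport]:
    """Remove probes with averaged PBL β ≥ ``threshold`` in any PBL subject.

    The boundary is inclusive: a probe sitting exactly at the threshold
    is already considered methylated in leukocytes and excluded.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    pbl_cols = cohort.pbl_samples
    if not pbl_cols:
        raise CohortValidationError("no PBL samples in cohort")
    hot = (cohort.beta[pbl_cols] >= threshold).any(axis=1)
    removed = list(cohort.probe_ids[hot])
    kept = cohort.probe_ids[~hot]
    report = FilterReport(
        stage="pbl_methylated",
        probes_in=len(cohort.probe_ids),
        probes_out=len(kept),
        removed_probe_ids=removed,
    )
    return cohort.subset_probes(kept), report


def rank_by_separation(
    cohort: BetaCohort, ann: ProbeAnnotation | None = None
) -> list[RankedMarker]:
    """Rank probes by d = T_L − PBL_H, dropping d ≤ 0.

    T_L is the minimum β over tumors, PBL_H the maximum β over PBL
    subjects. Probes where even the least-methylated tumor exceeds the
    most-methylated leukocyte sample (d > 0) are kept, sorted by d
    descending with ties broken by probe id ascending.
    """
    tumor_cols = cohort.tumor_samples
    pbl_cols = cohort.pbl_samples
    if not tumor_cols or not pbl_cols:
        raise CohortValidationError("need at least one tumor and one PBL sample")
    tumor_beta = cohort.beta[tumor_cols]
    if tumor_beta.isna().all(axis=1).any():
        bad = cohort.probe_ids[tumor_beta.isna().all(axis=1)][0]
        raise CohortValidationError(f"probe {bad!r} has no tumor β values")
    if cohort.beta[tumor_cols + pbl_cols].isna().any().any():
        raise CohortValidationError(
            "missing β among surviving probes; failed probes must be removed first"
        )
    t_low = tumor_beta.min(axis=1)
    pbl_high = cohort.beta[pbl_cols].max(axis=1)
    delta = t_low - pbl_high
    keep = delta > 0
    frame = pd.DataFrame(
        {
            "pid": cohort.probe_ids[keep.to_numpy()].astype(str),
            "t_low": t_low[keep].to_numpy(),
            "pbl_high": pbl_high[keep].to_numpy(),
            "delta": delta[keep].to_numpy(),
        }
    ).sort_values(by=["delta", "pid"], ascending=[False, True], kind="mergesort")
    out = []
    for rank, (_, row) in enumerate(frame.iterrows(), start=1):
        pid = row["pid"]
        gene = ann.gene_of(pid) if ann is not None else ""
        out.append(
            RankedMarker(
                probe_id=str(pid),
                gene_symbol=gene,
                t_low=float(row["t_low"]),
                pbl_high=float(row["pbl_high"]),
                delta=float(row["delta"]),
                rank=rank,
            )
        )
    return out


def select_top_markers(
    ranked: list[RankedMarker], k: int = 15, unique_genes: bool = False
) -> list[RankedMarker]:
    """First ``k`` records by rank; optionally one (best) probe per gene.

    ``k`` beyond the list length returns the whole list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    records = sorted(ranked, key=lambda m: m.rank)
    if unique_genes:
        seen: set[str] = set()
        kept = []
        for m in records:
            key = m.gene_symbol or m.probe_id
            if key in seen:
                continue
            seen.add(key)
            kept.append(m)
        records = kept
    return records[:k]


def summarize_group_distributions(
    cohorts: dict[str, BetaCohort], marker_ids: list[str]
) -> pd.DataFrame:
    """Per (marker, cohort, group) β summaries for cross-cohort checks.

    Returns a tidy frame with median, quartiles and n; a marker missing
    from a cohort is recorded with n=0 and NaN summaries rather than
    raising.
    """
    rows = []
    for cohort_name, cohort in cohorts.items():
        for group in (TUMOR, PBL):
            cols = cohort.samples_in_group(group)
            for pid in marker_ids:
                if pid not in cohort.probe_ids or not cols:
                    rows.append(
                        dict(
                            marker_id=pid,
                            cohort=cohort_name,
                            group=group,
                            n=0,
                            median=np.nan,
                            q1=np.nan,
                            q3=np.nan,
                        )
                    )
                    continue
                vals = cohort.beta.loc[pid, cols].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                rows.append(
                    dict(
                        marker_id=pid,
                        cohort=cohort_name,
                        group=group,
                        n=int(vals.size),
                        median=float(np.median(vals)) if vals.size else np.nan,
                        q1=float(np.percentile(vals, 25)) if vals.size else np.nan,
                        q3=float(np.percentile(vals, 75)) if vals.size else np.nan,
                    )
                )
    return pd.DataFrame(rows)


def run_selection(
    cohort: BetaCohort,
    ann: ProbeAnnotation,
    alpha: float = 0.05,
    pbl_threshold: float = 0.2,
    top_k: int = 15,
    unique_genes: bool = False,
) -> tuple[list[RankedMarker], list[RankedMarker], list[FilterReport]]:
    """Run the full cascade; returns (all ranked, top-k, stage reports)."""
    c1, r1 = drop_failed_probes(cohort, alpha=alpha)
    c2, r2 = drop_annotated_probes(c1, ann)
    c3 = average_replicates(c2)
    c4, r4 = drop_pbl_methylated(c3, threshold=pbl_threshold)
    ranked = rank_by_separation(c4, ann)
    r5 = FilterReport(
        stage="separation_rank",
        probes_in=len(c4.probe_ids),
        probes_out=len(ranked),
        removed_probe_ids=sorted(
            set(map(str, c4.probe_ids)) - {m.probe_id for m in ranked}
        ),
    )
    top = select_top_markers(ranked, k=top_k, unique_genes=unique_genes)
    return ranked, top, [r1, r2, r4, r5]


class MarkerSelector(BaseEstimator, TransformerMixin):
    """Supervised feature selector implementing the marker cascade.

    Views the cohort the scikit-learn way: ``X`` is a samples × probes
    DataFrame of β values, ``y`` the per-sample group labels ("tumor" /
    "pbl"). Auxiliary matrices (detection p, annotation, replicate map)
    are passed to :meth:`fit`.

    Parameters
    ----------
    alpha : float, default 0.05
        Detection p-value above which a measurement counts as failed.
    pbl_threshold : float, default 0.2
        Averaged PBL β at or above which a probe is excluded.
    top_k : int, default 15
        Number of top-ranked markers to retain.
    unique_genes : bool, default False
        Keep only the best-ranked probe per gene before truncation.

    Attributes
    ----------
    ranked_markers_ : list of RankedMarker
        Full positive-separation ranking.
    selected_markers_ : list of RankedMarker
        The top-k shortlist.
    filter_reports_ : list of FilterReport
        Per-stage funnel accounting.
    support_ : ndarray of bool, shape (n_probes_in,)
        Mask over input probe columns marking the selected markers.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        pbl_threshold: float = 0.2,
        top_k: int = 15,
        unique_genes: bool = False,
    ):
        self.alpha = alpha
        self.pbl_threshold = pbl_threshold
        self.top_k = top_k
        self.unique_genes = unique_genes

    def fit(self, X: pd.DataFrame, y, *, detection_p: pd.DataFrame,
            annotation: ProbeAnnotation, replicate_of: pd.Series | None = None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples × probes DataFrame of β values")
        groups = pd.Series(np.asarray(y), index=X.index, name="group")
        cohort = BetaCohort(
            beta=X.T,
            detection_p=detection_p.T if detection_p.index.equals(X.index)
            else detection_p,
            groups=groups,
            replicate_of=replicate_of,
        )
        ranked, top, reports = run_selection(
            cohort,
            annotation,
            alpha=self.alpha,
            pbl_threshold=self.pbl_threshold,
            top_k=self.top_k,
            unique_genes=self.unique_genes,
        )
        self.ranked_markers_ = ranked
        self.selected_markers_ = top
        self.filter_reports_ = reports
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        selected = {m.probe_id for m in top}
        self.support_ = np.array([c in selected for c in X.columns])
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        cols = [m.probe_id for m in self.selected_markers_ if m.probe_id in X.columns]
        return X[cols]
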