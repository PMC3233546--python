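"""Core containers for Infinium-style methylation cohorts.

A cohort couples a probe × sample matrix of β values (fractional DNA
methylation, in [0, 1]) with the matching matrix of per-measurement
detection p-values, a group label per sample (tumor or peripheral-blood
leukocyte, PBL), and a subject id mapping technical replicates to the
subject they measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
PBL = "pbl"
VALID_GROUPS = frozenset({TUMOR, PBL})


class CohortValidationError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class BetaCohort:
    """Probe × sample β matrix with detection p-values and sample metadata.

    Parameters
    ----------
    beta : DataFrame, shape (n_probes, n_samples)
        Fractional methylation values in [0, 1]. Index = probe ids,
        columns = sample ids.
    detection_p : DataFrame, same shape/labels as ``beta``
        Per-measurement detection p-values in [0, 1]. A value above the
        QC threshold (conventionally 0.05) marks a failed measurement.
    groups : Series, indexed by sample id
        Group label per sample, ``"tumor"`` or ``"pbl"``.
    replicate_of : Series, indexed by sample id
        Subject id per sample; technical replicates of one subject share
        a value. Defaults to each sample being its own subject.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    groups: pd.Series
    replicate_of: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.replicate_of is None:
            self.replicate_of = pd.Series(
                self.beta.columns, index=self.beta.columns, name="subject_id"
            )
        self.validate()

    def validate(self) -> None:
        b, p = self.beta, self.detection_p
        if b.shape != p.shape:
            raise CohortValidationError(
                f"beta {b.shape} and detection_p {p.shape} shapes differ"
            )
        if not (b.index.equals(p.index) and b.columns.equals(p.columns)):
            raise CohortValidationError(
                "beta and detection_p must share probe index and sample columns"
            )
        if b.index.has_duplicates:
            raise CohortValidationError("duplicate probe ids")
        if b.columns.has_duplicates:
            raise CohortValidationError("duplicate sample ids")
        vals = b.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if ((vals < 0) & finite).any() or ((vals > 1) & finite).any():
            bad = np.argwhere(((vals < 0) | (vals > 1)) & finite)[0]
            raise CohortValidationError(
                f"beta value out of [0,1] at probe {b.index[bad[0]]!r}, "
                f"sample {b.columns[bad[1]]!r}"
            )
        pv = p.to_numpy(dtype=float)
        if ((pv < 0) | (pv > 1)).any():
            raise CohortValidationError("detection p-values must lie in [0,1]")
        missing = set(b.columns) - set(self.groups.index)
        if missing:
            raise CohortValidationError(f"samples without group label: {sorted(missing)}")
        bad_groups = set(self.groups.loc[list(b.columns)]) - VALID_GROUPS
        if bad_groups:
            raise CohortValidationError(
                f"unknown group labels {sorted(bad_groups)}; expected {sorted(VALID_GROUPS)}"
            )
        missing_rep = set(b.columns) - set(self.replicate_of.index)
        if missing_rep:
            raise CohortValidationError(
                f"samples without subject mapping: {sorted(missing_rep)}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def samples_in_group(self, group: str) -> list[str]:
        cols = [s for s in self.beta.columns if self.groups.loc[s] == group]
        return cols

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in_group(TUMOR)

    @property
    def pbl_samples(self) -> list[str]:
        return self.samples_in_group(PBL)

    def subset_probes(self, probe_ids) -> "BetaCohort":
        """Return a cohort restricted to ``probe_ids`` (order preserved)."""
        return BetaCohort(
            beta=self.beta.loc[probe_ids],
            detection_p=self.detection_p.loc[probe_ids],
            groups=self.groups,
            replicate_of=self.replicate_of,
        )

    def equals(self, other: "BetaCohort") -> bool:
        return (
            self.beta.equals(other.beta)
            and self.detection_p.equals(other.detection_p)
            and self.groups.loc[list(self.sample_ids)].equals(
                other.groups.loc[list(other.sample_ids)]
            )
            and self.replicate_of.loc[list(self.sample_ids)].equals(
                other.replicate_of.loc[list(other.sample_ids)]
            )
        )


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: gene symbol plus SNP / repeat exclusion flags.

    Flags are explicit booleans for every probe; an absent record is an
    error downstream, never an implicit False.
    """

    table: pd.DataFrame  # index: probe_id; columns: gene_symbol, snp_flag, repeat_flag

    def __post_init__(self) -> None:
        required = {"gene_symbol", "snp_flag", "repeat_flag"}
        missing = required - set(self.table.columns)
        if missing:
            raise CohortValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise CohortValidationError("duplicate probe ids in annotation")
        for col in ("snp_flag", "repeat_flag"):
            if self.table[col].isna().any():
                raise CohortValidationError(f"annotation column {col} has missing values")
            self.table[col] = self.table[col].astype(bool)

    def gene_of(self, probe_id: str) -> str:
        return str(self.table.loc[probe_id, "gene_symbol"])
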