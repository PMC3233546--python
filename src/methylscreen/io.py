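"""Plain-text I/O for every pipeline table.

All formats are headered TSV/CSV. β and detection-p matrices are TSV
with probes as rows and samples as columns; the sample sheet, Ct table,
plate table and serial-series table are tidy CSVs. Undetected Ct values
are written as the literal ``ND``. Readers validate ranges and report
offending probes/samples/line numbers; writers and readers round-trip
losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import VALID_GROUPS, BetaCohort, CohortValidationError, ProbeAnnotation
from .digital import DigitalPlateSet, DigitalQuant
from .longitudinal import PatientSeries
from .select import FilterReport, RankedMarker

ND = "ND"  # undetected-Ct sentinel in Ct CSV files


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


# -- β cohort ----------------------------------------------------------------


def write_beta_cohort(
    cohort: BetaCohort, beta_path, detp_path, samples_path
) -> None:
    cohort.beta.rename_axis("probe_id").to_csv(beta_path, sep="\t")
    cohort.detection_p.rename_axis("probe_id").to_csv(detp_path, sep="\t")
    sheet = pd.DataFrame(
        {
            "sample_id": list(cohort.sample_ids),
            "group": [cohort.groups.loc[s] for s in cohort.sample_ids],
            "subject_id": [cohort.replicate_of.loc[s] for s in cohort.sample_ids],
        }
    )
    sheet.to_csv(samples_path, index=False)


def read_beta_cohort(beta_path, detp_path, samples_path) -> BetaCohort:
    beta = pd.read_csv(beta_path, sep="\t", index_col="probe_id")
    detp = pd.read_csv(detp_path, sep="\t", index_col="probe_id")
    sheet = pd.read_csv(samples_path)
    _require_columns(sheet, {"sample_id", "group", "subject_id"}, samples_path)
    if sheet.empty:
        raise SchemaError(f"{samples_path}: empty sample sheet")
    bad = set(sheet["group"]) - VALID_GROUPS
    if bad:
        raise SchemaError(
            f"{samples_path}: unknown group labels {sorted(bad)}"
        )
    if beta.shape != detp.shape:
        raise SchemaError(
            f"β matrix {beta.shape} and detection-p matrix {detp.shape} differ in shape"
        )
    vals = beta.to_numpy(dtype=float)
    out = np.argwhere((vals < 0) | (vals > 1))
    if out.size:
        r, c = out[0]
        raise SchemaError(
            f"{beta_path}: β value {vals[r, c]} out of [0,1] at probe "
            f"{beta.index[r]!r}, sample {beta.columns[c]!r}"
        )
    groups = pd.Series(sheet["group"].values, index=sheet["sample_id"], name="group")
    subjects = pd.Series(
        sheet["subject_id"].values, index=sheet["sample_id"], name="subject_id"
    )
    try:
        return BetaCohort(beta, detp, groups, subjects)
    except CohortValidationError as e:
        raise SchemaError(str(e)) from e


def write_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.rename_axis("probe_id").to_csv(path, sep="\t")


def read_annotation(path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="probe_id")
    _require_columns(table, {"gene_symbol", "snp_flag", "repeat_flag"}, path)
    return ProbeAnnotation(table)


# -- selection outputs -------------------------------------------------------


def write_ranked_markers(path, records: list[RankedMarker]) -> None:
    pd.DataFrame(
        [
            dict(probe_id=m.probe_id, gene_symbol=m.gene_symbol, t_low=m.t_low,
                 pbl_high=m.pbl_high, delta=m.delta, rank=m.rank)
            for m in records
        ],
        columns=["probe_id", "gene_symbol", "t_low", "pbl_high", "delta", "rank"],
    ).to_csv(path, sep="\t", index=False)


def read_ranked_markers(path) -> list[RankedMarker]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, {"probe_id", "gene_symbol", "t_low", "pbl_high", "delta", "rank"}, path
    )
    return [
        RankedMarker(
            probe_id=str(r.probe_id),
            gene_symbol="" if pd.isna(r.gene_symbol) else str(r.gene_symbol),
            t_low=float(r.t_low),
            pbl_high=float(r.pbl_high),
            delta=float(r.delta),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]


def write_filter_reports(path, reports: list[FilterReport]) -> None:
    pd.DataFrame(
        [
            dict(stage=r.stage, probes_in=r.probes_in, probes_out=r.probes_out,
                 n_removed=len(r.removed_probe_ids))
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


# -- Ct tables ---------------------------------------------------------------


def write_ct_table(path, ct: pd.DataFrame) -> None:
    out = ct.copy()
    out["ct"] = out["ct"].map(lambda v: ND if pd.isna(v) else f"{float(v):.4f}")
    out.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ct": str})
    _require_columns(df, {"marker_id", "sample_id", "reaction", "ct"}, path)
    bad_reactions = set(df["reaction"]) - {"target", "alu"}
    if bad_reactions:
        raise SchemaError(f"{path}: unknown reactions {sorted(bad_reactions)}")

    def parse(v, line):
        if isinstance(v, str) and v.strip().upper() == ND:
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            raise SchemaError(f"{path}: line {line}: unparseable Ct {v!r}") from None

    df["ct"] = [parse(v, i + 2) for i, v in enumerate(df["ct"])]
    return df


# -- digital plates ----------------------------------------------------------


def write_plates(path, plate_sets: list[DigitalPlateSet]) -> None:
    rows = []
    for ps in plate_sets:
        per_plate_vol = ps.volume_assayed_ul / len(ps.plates)
        for i, (n, k) in enumerate(ps.plates):
            rows.append(
                dict(sample_id=ps.sample_id, plate_id=f"{ps.sample_id}_p{i + 1}",
                     wells_total=n, wells_positive=k,
                     volume_assayed_ul=per_plate_vol)
            )
    pd.DataFrame(
        rows, columns=["sample_id", "plate_id", "wells_total", "wells_positive",
                       "volume_assayed_ul"]
    ).to_csv(path, index=False)


def read_plates(path) -> list[DigitalPlateSet]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        {"sample_id", "plate_id", "wells_total", "wells_positive",
         "volume_assayed_ul"},
        path,
    )
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        out.append(
            DigitalPlateSet(
                sample_id=str(sid),
                plates=[(int(r.wells_total), int(r.wells_positive))
                        for r in grp.itertuples()],
                volume_assayed_ul=float(grp["volume_assayed_ul"].sum()),
            )
        )
    return out


def write_quants(path, quants: list[DigitalQuant]) -> None:
    pd.DataFrame(
        [
            dict(sample_id=q.sample_id, molecules_detected=q.molecules_detected,
                 molecules_estimated=q.molecules_estimated,
                 concentration_per_ml=q.concentration, saturated=q.saturated)
            for q in quants
        ]
    ).to_csv(path, sep="\t", index=False)


# -- patient series ----------------------------------------------------------


def write_series(path, cohort: list[PatientSeries]) -> None:
    rows = []
    for s in cohort:
        for r in s.draws.itertuples():
            rows.append(
                dict(patient_id=s.patient_id, week=r.week,
                     ca125_u_per_ml=r.ca125,
                     marker_molecules_per_ml=r.marker_conc,
                     surgery_week="" if s.surgery_week is None else s.surgery_week,
                     relapse_week="" if s.relapse_week is None else s.relapse_week)
            )
    pd.DataFrame(
        rows, columns=["patient_id", "week", "ca125_u_per_ml",
                       "marker_molecules_per_ml", "surgery_week", "relapse_week"]
    ).to_csv(path, index=False)


def read_series(path) -> list[PatientSeries]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        {"patient_id", "week", "ca125_u_per_ml", "marker_molecules_per_ml",
         "surgery_week", "relapse_week"},
        path,
    )
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        surgery = grp["surgery_week"].iloc[0]
        relapse = grp["relapse_week"].iloc[0]
        draws = pd.DataFrame(
            {
                "week": grp["week"].to_numpy(dtype=float),
                "ca125": grp["ca125_u_per_ml"].to_numpy(dtype=float),
                "marker_conc": grp["marker_molecules_per_ml"].to_numpy(dtype=float),
            }
        )
        out.append(
            PatientSeries(
                patient_id=str(pid),
                draws=draws,
                surgery_week=None if pd.isna(surgery) else float(surgery),
                relapse_week=None if pd.isna(relapse) else float(relapse),
            )
        )
    return out


def write_concordance(path, results: list, untestable: list[str]) -> None:
    rows = []
    for res in results:
        if res is None:
            continue
        rows.append(
            dict(patient_id=res.patient_id, n=res.n_pairs, r=res.r,
                 t=res.t_stat, p=res.p, significant=res.significant)
        )
    for pid in untestable:
        rows.append(dict(patient_id=pid, n=0, r=np.nan, t=np.nan, p=np.nan,
                         significant=False))
    pd.DataFrame(
        rows, columns=["patient_id", "n", "r", "t", "p", "significant"]
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
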