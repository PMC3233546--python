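import numpy as np
import pandas as pd
import pytest

from methylscreen.cohort import BetaCohort, ProbeAnnotation


def make_cohort(beta_rows, detection_p=None, tumor_cols=None, pbl_cols=None,
                replicate_map=None):
    """Build a small cohort from a {probe: [values]} dict.

    Columns default to T1..Tn tumors followed by B1..Bm PBLs according
    to ``tumor_cols``/``pbl_cols`` name lists.
    """
    probes = list(beta_rows)
    n_cols = len(next(iter(beta_rows.values())))
    if tumor_cols is None and pbl_cols is None:
        tumor_cols = [f"T{i + 1}" for i in range(n_cols - 2)]
        pbl_cols = ["B1", "B2"]
    cols = list(tumor_cols) + list(pbl_cols)
    beta = pd.DataFrame.from_dict(beta_rows, orient="index", columns=cols)
    if detection_p is None:
        detp = pd.DataFrame(0.0, index=beta.index, columns=cols)
    else:
        detp = pd.DataFrame.from_dict(detection_p, orient="index", columns=cols)
    groups = pd.Series(
        {**{c: "tumor" for c in tumor_cols}, **{c: "pbl" for c in pbl_cols}},
        name="group",
    )
    rep = pd.Series({c: c for c in cols}, name="subject_id")
    if replicate_map:
        for k, v in replicate_map.items():
            rep[k] = v
    return BetaCohort(beta, detp, groups, rep)


def make_annotation(probes, snp=(), repeat=(), genes=None):
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "gene_symbol": [genes[p] if genes else f"G_{p}" for p in probes],
                "snp_flag": [p in snp for p in probes],
                "repeat_flag": [p in repeat for p in probes],
            },
            index=pd.Index(list(probes), name="probe_id"),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
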