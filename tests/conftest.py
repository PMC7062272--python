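import numpy as np
import pandas as pd
import pytest

from sgtools import CriteriaConfig, WideDataset, default_demo


@pytest.fixture(scope="session")
def demo():
    """The bundled synthetic demo dataset with its planted ground truth."""
    return default_demo(with_truth=True)


@pytest.fixture(scope="session")
def default_config():
    return CriteriaConfig(crit1_cutoff=7)


def make_wide(rows, n_sessions=None, prefix="bdi_s", id_column="id",
              secondary=None):
    """Build a WideDataset from {id: [scores...]} with None for missing."""
    n_sessions = n_sessions or max(len(v) for v in rows.values())
    cols = [f"{prefix}{k}" for k in range(1, n_sessions + 1)]
    records = []
    for sid, values in rows.items():
        rec = {id_column: sid}
        for c, v in zip(cols, values):
            rec[c] = np.nan if v is None else float(v)
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    sec_cols = None
    if secondary is not None:
        sec_cols = [f"rq_s{k}" for k in range(1, n_sessions + 1)]
        for sid_idx, (sid, values) in enumerate(secondary.items()):
            for c, v in zip(sec_cols, values):
                frame.loc[frame[id_column] == sid, c] = (
                    np.nan if v is None else float(v)
                )
    return WideDataset(data=frame, id_column=id_column, session_columns=cols,
                       secondary_columns=sec_cols, measure_name="bdi")


@pytest.fixture
def planted_gain_dataset():
    """One clean planted gain: 30,29,28 -> 18,17,16 inside an 8-session run.

    The 28->18 drop at pregain session 4 meets all three criteria (drop 10,
    36% of 28, window means 29 vs 17 with pooled SD 1); no other interval
    comes close. Treatment runs 32 -> 12.
    """
    return make_wide({
        1: [32, 30, 29, 28, 18, 17, 16, 12],
        2: [31, 30, 30, 29, 29, 28, 28, 27],
    })
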