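import numpy as np
import pandas as pd
import pytest

from omicshape.model import Condition, IntensityMatrix, SampleKey, Scale


def make_matrix(values, conditions, timepoints, replicates, scale=Scale.RAW, ids=None):
    """Build an IntensityMatrix from a dense grid and parallel sample specs."""
    values = np.asarray(values, dtype=float)
    samples = [
        SampleKey(Condition(c), float(t), int(r))
        for c, t, r in zip(conditions, timepoints, replicates)
    ]
    ids = ids or [f"P{i + 1}" for i in range(values.shape[0])]
    data = pd.DataFrame(
        values, index=pd.Index(ids, name="entity_id"), columns=[s.label for s in samples]
    )
    return IntensityMatrix(data, samples, scale)


@pytest.fixture
def paired_design():
    """2 conditions x 3 timepoints x 2 replicates sample layout."""
    conds, tps, reps = [], [], []
    for c in ("N-", "N+"):
        for t in (3, 6, 12):
            for r in (1, 2):
                conds.append(c)
                tps.append(t)
                reps.append(r)
    return conds, tps, reps


@pytest.fixture
def protein_groups_file(tmp_path):
    """Minimal MaxQuant-style proteinGroups table: 3 rows, 1 contaminant."""
    path = tmp_path / "proteinGroups.txt"
    header = [
        "Protein IDs",
        "LFQ intensity N-_3h_r1",
        "LFQ intensity N-_3h_r2",
        "LFQ intensity N+_3h_r1",
        "LFQ intensity N+_3h_r2",
        "Reverse",
        "Potential contaminant",
    ]
    rows = [
        ["IMET_0001", "1000", "1100", "900", "0", "", ""],
        ["IMET_0002", "2000", "2100", "1900", "1800", "", "+"],
        ["IMET_0003", "400", "0", "450", "500", "", ""],
    ]
    path.write_text("\n".join("\t".join(r) for r in [header] + rows) + "\n")
    sample_map = {
        "N-_3h_r1": SampleKey(Condition.N_MINUS, 3, 1),
        "N-_3h_r2": SampleKey(Condition.N_MINUS, 3, 2),
        "N+_3h_r1": SampleKey(Condition.N_PLUS, 3, 1),
        "N+_3h_r2": SampleKey(Condition.N_PLUS, 3, 2),
    }
    return path, sample_map
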