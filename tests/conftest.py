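from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from structconn.io import Cohort, ConnectivityMatrix, ParcellationTable, SubjectRecord


def make_parcellation(n: int, mtl: list[int] | None = None, dmn: list[int] | None = None) -> ParcellationTable:
    """Generic n-node parcellation; first half left, second half right."""
    rows = []
    for i in range(n):
        hemi = "left" if i < n // 2 else "right"
        sub = "MTL" if mtl and i in mtl else ("DMN" if dmn and i in dmn else "none")
        rows.append((i, f"region{i:02d}", hemi, sub))
    return ParcellationTable(
        pd.DataFrame(rows, columns=["node_index", "label", "hemisphere", "subsystem"])
    )


def matrix_from(weights, parcellation: ParcellationTable | None = None) -> ConnectivityMatrix:
    w = np.asarray(weights, dtype=float)
    return ConnectivityMatrix(w, parcellation or make_parcellation(w.shape[0]))


@pytest.fixture(scope="session")
def parc84():
    from structconn.io import default_parcellation

    return default_parcellation()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic 2+2 cohort on a 6-node parcellation."""
    parc = make_parcellation(6, mtl=[0, 3], dmn=[1, 4])
    rng = np.random.default_rng(7)
    subjects = []
    for k in range(4):
        w = np.zeros((6, 6))
        iu, ju = np.triu_indices(6, 1)
        vals = rng.integers(1, 50, size=len(iu)).astype(float)
        w[iu, ju] = vals
        w[ju, iu] = vals
        subjects.append(
            SubjectRecord(
                subject_id=f"s{k}",
                group="patient" if k < 2 else "control",
                matrix=ConnectivityMatrix(w, parc),
                age=30.0 + k,
                education=12.0,
                icv=1.5e6 + 1e4 * k,
                regional_volumes={"left_hippocampus": 4000.0 + 10 * k},
                scores={"ravlt_delayed": 8.0 + k},
            )
        )
    return Cohort(subjects)


@pytest.fixture(scope="session")
def synth_cohort_small():
    """A reduced synthetic cohort (12 + 12 subjects) on the full 84-node scheme."""
    from structconn.simulate import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_patients=12, n_controls=12, n_pilot=30, seed=42)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth
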