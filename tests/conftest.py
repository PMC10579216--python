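import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import urimex as ux

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(values, samples=None, compounds=None, state=ux.NormalizationState.RAW):
    """Build a PeakTable from a nested list / array with generated ids."""
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"S{i + 1}" for i in range(arr.shape[0])]
    compounds = compounds or [f"C{j + 1}" for j in range(arr.shape[1])]
    return ux.PeakTable(pd.DataFrame(arr, index=samples, columns=compounds), state)


@pytest.fixture
def small_study():
    """Two-method pre/post study with an IS and creatinine on the sheet."""
    rng = np.random.default_rng(7)
    samples, rows, meta = [], [], []
    for method in ("Method A", "Method B"):
        for group in ("pre", "post"):
            for rep in (1, 2, 3):
                sid = f"{method}_{group}_{rep}"
                samples.append(sid)
                rows.append(rng.uniform(0.5, 2.0, size=6))
                meta.append(
                    ux.SampleMeta(
                        sample_id=sid,
                        method_label=method,
                        spike_group=ux.SpikeGroup(group),
                        replicate=rep,
                        creatinine_value=float(rng.uniform(0.8, 1.2)),
                    )
                )
    compounds = ["Citric acid", "Glucose", "Urea", "Alanine", "Xylose",
                 ux.peaktable_io.DEFAULT_INTERNAL_STANDARD]
    table = ux.PeakTable(pd.DataFrame(rows, index=samples, columns=compounds))
    return table, meta
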