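import numpy as np
import pandas as pd
import pytest

from methwas.simulate import CohortConfig, generate_cohort
from methwas.types import Amplicon, BetaMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at reduced probe count, shared across tests."""
    cfg = CohortConfig(n_probes=3000, n_true_mvps=10, effect_size=0.12, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_amplicon():
    ref = "ATTCGATACGTTACCTAGGCATTACGTTAGGACATTGGCA"
    offs = tuple(i for i in range(len(ref) - 1) if ref[i : i + 2] == "CG")
    return Amplicon("toy", ref, offs)


def make_beta(values, sample_ids=None, probe_ids=None, detection=None):
    """Small BetaMatrix from a 2-D array."""
    v = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(v.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(v.shape[1])]
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, dtype=float), index=probe_ids, columns=sample_ids)
    return BetaMatrix(pd.DataFrame(v, index=probe_ids, columns=sample_ids), det)


def make_sheet(sample_ids, groups=None, batches=None, rebatch_of=None, sexes=None, ages=None):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups if groups is not None else ["case"] * (n // 2) + ["control"] * (n - n // 2),
            "sex": sexes if sexes is not None else ["F"] * n,
            "age": ages if ages is not None else [5.0] * n,
            "batch": batches if batches is not None else ["B0"] * n,
            "rebatch_of": rebatch_of if rebatch_of is not None else [""] * n,
            "tissue": "blood",
        }
    )
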